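"""Sure-independence-screening feature ranking over all dummy predictors.

For L SNPs the candidate pool is

* CDC: the 9 cell indicators of every pair (9 L(L-1)/2) plus 3 genotype
  indicators per SNP, i.e. 9 L(L-1)/2 + 3 L predictors;
* ADC: one best-balanced-accuracy partition indicator per pair plus the
  3 L main-effect indicators, i.e. L(L-1)/2 + 3 L predictors.

Each candidate is reduced to its 2x2 exposed/unexposed table, continuity
corrected if any cell is zero, and scored by either the 2x2 likelihood-ratio
(G^2) statistic or the Wald p-value of the log odds ratio.  The top ``d``
survive to the penalized-regression step.

The scan is blocked: pair-cell counts for a block of "row" SNPs against all
partner SNPs are obtained from four indicator-matrix products per phenotype
group (the remaining five cells follow from the genotype margins), and a
running top-``d`` pool is merged block by block, so the full candidate set
is never materialized.  Counts are exact in float32 (they are integers well
below 2^24); scores are computed in float64 through the same kernels used
by the scalar API, so blocked and naive rankings agree bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .coding import Table2x2, partition_table, pair_counts, adc_best_partition
from .genotypes import GenotypeMatrix, PhenotypeVector

__all__ = [
    "ScreeningConfig",
    "RankedPredictor",
    "STRATEGIES",
    "continuity_correct",
    "odds_ratio_stats",
    "lr_statistic",
    "recommended_d",
    "rank_features",
    "ranking_to_frame",
]

#: published strategy names -> (coding, criterion)
STRATEGIES = {
    "lcdc": ("cdc", "likelihood"),
    "pcdc": ("cdc", "p_value"),
    "padc": ("adc", "p_value"),
}


@dataclass(frozen=True)
class ScreeningConfig:
    """Coding/criterion strategy and screening size for the ranking step.

    ``d`` defaults to 256 (the fixed choice used throughout; see
    :func:`recommended_d` for the sample-size based alternative) and
    ``block_size`` controls how many row-SNPs are cross-tabulated per block.
    """

    coding: str = "cdc"
    criterion: str = "p_value"
    d: int = 256
    block_size: int = 128

    def __post_init__(self):
        if self.coding not in ("cdc", "adc"):
            raise ValueError(f"coding must be 'cdc' or 'adc', got {self.coding!r}")
        if self.criterion not in ("likelihood", "p_value"):
            raise ValueError(
                f"criterion must be 'likelihood' or 'p_value', got {self.criterion!r}"
            )
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    @classmethod
    def from_method(cls, method: str, d: int = 256, block_size: int = 128):
        coding, criterion = STRATEGIES[method.lower()]
        return cls(coding=coding, criterion=criterion, d=d, block_size=block_size)


@dataclass(frozen=True)
class RankedPredictor:
    """One screened dummy predictor with its score and effect summary.

    ``kind`` is ``pair_cell`` (CDC), ``pair_partition`` (ADC) or
    ``main_effect``; ``cell`` holds the 3x3 cell index for pair cells and
    the genotype value for main effects; ``mask`` the partition mask.
    Effect summaries (OR, CI, p) come from the continuity-corrected table.
    """

    kind: str
    snp1: str
    snp2: Optional[str]
    i: int
    j: Optional[int]
    cell: Optional[int]
    mask: Optional[int]
    score: float
    odds_ratio: float
    ci95: tuple
    p_value: float

    @property
    def cell_or_mask(self):
        return self.mask if self.kind == "pair_partition" else self.cell

    def indicator(self, g) -> np.ndarray:
        """Length-n 0/1 indicator vector of this predictor on genotypes ``g``."""
        G = g.genotypes if isinstance(g, GenotypeMatrix) else np.asarray(g)
        if self.kind == "main_effect":
            return (G[:, self.i] == self.cell).astype(np.float64)
        if self.kind == "pair_cell":
            g1, g2 = divmod(self.cell, 3)
            return ((G[:, self.i] == g1) & (G[:, self.j] == g2)).astype(np.float64)
        cells = 3 * G[:, self.i].astype(np.int64) + G[:, self.j]
        return ((self.mask >> cells) & 1).astype(np.float64)


# ---------------------------------------------------------------------------
# 2x2 association statistics (shared scalar/vector kernels)
# ---------------------------------------------------------------------------

def _wald_z(a, b, c, d):
    """Signed Wald statistic log(OR)/SE of a zero-free 2x2 table."""
    return np.log((a * d) / (b * c)) / np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def _xlogx(x):
    """x*log(x) with the 0*log(0) = 0 limit (elementwise)."""
    x = np.asarray(x, dtype=np.float64)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out


def _g2(a, b, c, d):
    """G^2 statistic of a 2x2 table in entropy (margin-sum) form.

    ``2 [sum f(cell) - sum f(margin) + f(n)]`` with f(x) = x log x; the
    fixed summation order is shared with the table-lookup fast path so both
    produce bit-identical values.
    """
    fa, fb, fc, fd = _xlogx(a), _xlogx(b), _xlogx(c), _xlogx(d)
    fab, fcd = _xlogx(a + b), _xlogx(c + d)
    fac, fbd = _xlogx(a + c), _xlogx(b + d)
    fn = _xlogx(a + b + c + d)
    return 2.0 * (fa + fb + fc + fd - fab - fcd - fac - fbd + fn)


def _xlogx_half_table(nmax: int) -> np.ndarray:
    """Lookup table t[i] = f(i/2) for half-integer counts up to nmax."""
    x = np.arange(2 * nmax + 3, dtype=np.float64) / 2.0
    t = np.zeros_like(x)
    t[1:] = x[1:] * np.log(x[1:])
    return t


def _g2_tabulated(a, b, c, d, table):
    """G^2 via half-integer x*log(x) lookups; counts must be half-integers.

    Mirrors :func:`_g2` term-for-term (each table entry equals the direct
    f(x) evaluation at the same float), so results are bit-identical.
    """
    ia = (2.0 * a).astype(np.int64)
    ib = (2.0 * b).astype(np.int64)
    ic = (2.0 * c).astype(np.int64)
    id_ = (2.0 * d).astype(np.int64)
    fa, fb, fc, fd = table[ia], table[ib], table[ic], table[id_]
    fab, fcd = table[ia + ib], table[ic + id_]
    fac, fbd = table[ia + ic], table[ib + id_]
    fn = table[ia + ib + ic + id_]
    return 2.0 * (fa + fb + fc + fd - fab - fcd - fac - fbd + fn)


def continuity_correct(t: Table2x2) -> Table2x2:
    """Add 0.5 to all four cells if any cell is zero; idempotent."""
    if min(t.cells) == 0:
        return Table2x2(*(c + 0.5 for c in t.cells))
    return t


def odds_ratio_stats(t: Table2x2):
    """OR, log-OR SE, two-sided Wald p, and 95% CI of a corrected table.

    The table must already be continuity corrected: a zero cell here is a
    contract violation, not a value to patch.
    """
    a, b, c, d = t.cells
    if min(a, b, c, d) <= 0:
        raise ValueError("odds_ratio_stats requires a continuity-corrected table "
                         "with all cells > 0")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = math.log(or_) / se
    p = 2.0 * float(norm.sf(abs(z)))
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    return or_, se, p, (lo, hi)


def lr_statistic(t: Table2x2) -> float:
    """G^2 of a 2x2 table; zero-count cells contribute their 0*log(0)=0 limit."""
    a, b, c, d = t.cells
    return float(_g2(a, b, c, d))


def recommended_d(n: int) -> int:
    """Screening size floor(0.25 n / ln n) recommended for sample size n."""
    if n < 3:
        raise ValueError("sample size must be >= 3")
    return int(math.floor(0.25 * n / math.log(n)))


# ---------------------------------------------------------------------------
# blocked exhaustive ranking
# ---------------------------------------------------------------------------

def _sort_key(a, b, c, d, criterion):
    """Ranking key (smaller = stronger) from corrected table cell arrays.

    For the likelihood criterion the key is -G^2.  For the p-value
    criterion ordering by ascending p equals ordering by descending |z|
    (p is strictly decreasing in |z| until it underflows, where |z| is the
    prescribed fallback), so the key is -|z|.
    """
    if criterion == "likelihood":
        return -_g2(a, b, c, d)
    return -np.abs(_wald_z(a, b, c, d))


def _sort_key_tab(a, b, c, d, criterion, table):
    """`_sort_key` with the half-integer G^2 lookup fast path (bit-identical)."""
    if criterion == "likelihood":
        return -_g2_tabulated(a, b, c, d, table)
    return -np.abs(_wald_z(a, b, c, d))


def _best_masks_closed(wc, wn, n_case, n_ctrl):
    """Balanced-accuracy-optimal partition mask per pair, closed form.

    ``wc``/``wn`` are (9, ...) case/control cell counts.  Maximizing BA over
    masks maximizes ``sum_{k in mask} w_k`` with
    ``w_k = case_k * n_ctrl - ctrl_k * n_case``, so the optimum keeps the
    cells with w_k > 0.  Ties resolve to the smallest mask integer, exactly
    as the 510-way enumeration does: zero-weight cells are excluded; if no
    cell has w_k > 0 the best single cell (smallest index among maxima) is
    used; if every cell has w_k > 0 (full mask is illegal) the
    largest-indexed cell among the minima is dropped.
    """
    w = wc.astype(np.int64) * n_ctrl - wn.astype(np.int64) * n_case
    pos = w > 0
    powers = (np.int64(1) << np.arange(9, dtype=np.int64)).reshape(
        (9,) + (1,) * (w.ndim - 1)
    )
    mask = (pos * powers).sum(axis=0)
    npos = pos.sum(axis=0)
    none_pos = npos == 0
    if np.any(none_pos):
        wmax = w.max(axis=0)
        k0 = (w == wmax).argmax(axis=0)  # smallest index among maxima
        mask = np.where(none_pos, np.int64(1) << k0, mask)
    all_pos = npos == 9
    if np.any(all_pos):
        wmin = w.min(axis=0)
        k1 = 8 - (w[::-1] == wmin).argmax(axis=0)  # largest index among minima
        mask = np.where(all_pos, 511 - (np.int64(1) << k1), mask)
    bits = ((mask[None, ...] >> np.arange(9).reshape(powers.shape)) & 1)
    a = (bits * wc.astype(np.int64)).sum(axis=0)
    c = (bits * wn.astype(np.int64)).sum(axis=0)
    return mask, a, c


def _corrected(a, b, c, d):
    corr = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    h = np.where(corr, 0.5, 0.0)
    return a + h, b + h, c + h, d + h


def _merge_top(pool_keys, pool_idx, keys, idx, d):
    """Merge candidates into the running top-d pool (key asc, index asc)."""
    if keys.size > d:
        kth = np.partition(keys, d - 1)[d - 1]
        keep = keys <= kth
        keys, idx = keys[keep], idx[keep]
    keys = np.concatenate([pool_keys, keys])
    idx = np.concatenate([pool_idx, idx])
    order = np.lexsort((idx, keys))[:d]
    return keys[order], idx[order]


def _cell_counts_block(A, cols, blk):
    """(9, b, L) pair-cell counts for row-SNPs ``blk`` against all SNPs.

    ``A`` = per-genotype indicator matrices (n_g x L, float32) of one
    phenotype group; four products give cells (0,0),(0,1),(1,0),(1,1) and
    the rest follow from row/column genotype margins.
    """
    A0, A1, A2 = A
    B0, B1 = A0[:, blk], A1[:, blk]
    c00 = B0.T @ A0
    c01 = B0.T @ A1
    c10 = B1.T @ A0
    c11 = B1.T @ A1
    r0 = cols[0][blk][:, None]
    r1 = cols[1][blk][:, None]
    r2 = cols[2][blk][:, None]
    c02 = r0 - c00 - c01
    c12 = r1 - c10 - c11
    c20 = cols[0][None, :] - c00 - c10
    c21 = cols[1][None, :] - c01 - c11
    c22 = r2 - c20 - c21
    return np.stack([c00, c01, c02, c10, c11, c12, c20, c21, c22])


def rank_features(g: GenotypeMatrix, y: PhenotypeVector, cfg: ScreeningConfig):
    """Score every candidate dummy predictor and return the top ``d``.

    Returns an ordered (strongest first) list of :class:`RankedPredictor`.
    Ties break deterministically: pair candidates in row-major (i, j) order
    with ascending cell/mask, then main effects by SNP and genotype.
    If fewer than ``d`` candidates exist, all are returned with a warning.
    """
    L = g.n_snps
    if L < 2:
        raise ValueError("screening requires at least two SNPs")
    G = g.genotypes
    case = y.status == 1
    n_case = int(case.sum())
    n_ctrl = int((~case).sum())
    n_pairs = L * (L - 1) // 2
    per_pair = 9 if cfg.coding == "cdc" else 1
    offset = per_pair * n_pairs  # main-effect candidate indices start here
    total = offset + 3 * L
    d = cfg.d
    if d > total:
        warnings.warn(
            f"only {total} candidates available for d={d}; returning all",
            stacklevel=2,
        )
        d = total

    Ac = [np.asarray(G[case] == v, dtype=np.float32) for v in (0, 1, 2)]
    An = [np.asarray(G[~case] == v, dtype=np.float32) for v in (0, 1, 2)]
    cols_c = [a.sum(axis=0) for a in Ac]
    cols_n = [a.sum(axis=0) for a in An]
    xlx = _xlogx_half_table(n_case + n_ctrl + 2)

    # pair ranks: pr(i, j) = starts[i] + (j - i - 1) for i < j, row-major
    starts = np.zeros(L, dtype=np.int64)
    starts[1:] = np.cumsum(np.arange(L - 1, 0, -1))
    jgrid = np.arange(L, dtype=np.int64)

    pool_keys = np.empty(0, dtype=np.float64)
    pool_idx = np.empty(0, dtype=np.int64)

    for s in range(0, L - 1, cfg.block_size):
        e = min(s + cfg.block_size, L - 1)
        blk = slice(s, e)
        b = e - s
        cc = _cell_counts_block(Ac, cols_c, blk).astype(np.float64)
        cn = _cell_counts_block(An, cols_n, blk).astype(np.float64)
        ivals = np.arange(s, e, dtype=np.int64)
        valid = jgrid[None, :] > ivals[:, None]  # (b, L)
        pr = starts[ivals][:, None] + (jgrid[None, :] - ivals[:, None] - 1)

        if cfg.coding == "cdc":
            # score only the valid (j > i) entries, flattened
            a = cc[:, valid]
            c = cn[:, valid]
            a, bb, c, dd = _corrected(a, n_case - a, c, n_ctrl - c)
            keys = _sort_key_tab(a, bb, c, dd, cfg.criterion, xlx)  # (9, m)
            idx = pr[valid][None, :] * 9 + np.arange(9, dtype=np.int64)[:, None]
            pool_keys, pool_idx = _merge_top(
                pool_keys, pool_idx, keys.ravel(), idx.ravel(), d
            )
        else:
            _, a, c = _best_masks_closed(cc, cn, n_case, n_ctrl)
            a = a.astype(np.float64)
            c = c.astype(np.float64)
            aa, bb, cc_, dd = _corrected(a, n_case - a, c, n_ctrl - c)
            keys = _sort_key_tab(aa, bb, cc_, dd, cfg.criterion, xlx)
            pool_keys, pool_idx = _merge_top(
                pool_keys, pool_idx, keys[valid], pr[valid], d
            )

    # main effects: exposed = one genotype value of one SNP
    me_keys = []
    me_idx = []
    for v in (0, 1, 2):
        a = cols_c[v].astype(np.float64)
        c = cols_n[v].astype(np.float64)
        aa, bb, cc_, dd = _corrected(a, n_case - a, c, n_ctrl - c)
        me_keys.append(_sort_key_tab(aa, bb, cc_, dd, cfg.criterion, xlx))
        me_idx.append(offset + 3 * jgrid + v)
    pool_keys, pool_idx = _merge_top(
        pool_keys, pool_idx, np.concatenate(me_keys), np.concatenate(me_idx), d
    )

    return [_materialize(g, y, cfg, int(ix), starts) for ix in pool_idx]


def _materialize(g, y, cfg, idx, starts):
    """Rebuild the RankedPredictor for one winning candidate index."""
    L = g.n_snps
    n_pairs = L * (L - 1) // 2
    per_pair = 9 if cfg.coding == "cdc" else 1
    offset = per_pair * n_pairs
    if idx >= offset:
        snp, v = divmod(idx - offset, 3)
        from .coding import main_effect_tables

        t = main_effect_tables(g, y, snp)[v][1]
        kind, i, j, cell, mask = "main_effect", snp, None, v, None
        snp1, snp2 = g.snp_ids[snp], None
    elif cfg.coding == "cdc":
        pr, cell = divmod(idx, 9)
        i = int(np.searchsorted(starts, pr, side="right") - 1)
        j = int(pr - starts[i] + i + 1)
        pc = pair_counts(g, y, i, j)
        from .coding import cdc_tables

        t = cdc_tables(pc)[cell][1]
        kind, mask = "pair_cell", None
        snp1, snp2 = g.snp_ids[i], g.snp_ids[j]
    else:
        pr = idx
        i = int(np.searchsorted(starts, pr, side="right") - 1)
        j = int(pr - starts[i] + i + 1)
        pc = pair_counts(g, y, i, j)
        ps = adc_best_partition(pc)
        t = partition_table(pc, ps.mask)
        kind, cell, mask = "pair_partition", None, ps.mask
        snp1, snp2 = g.snp_ids[i], g.snp_ids[j]
    tc = continuity_correct(t)
    or_, _, p, ci = odds_ratio_stats(tc)
    score = lr_statistic(tc) if cfg.criterion == "likelihood" else p
    return RankedPredictor(
        kind=kind, snp1=snp1, snp2=snp2, i=i, j=j, cell=cell, mask=mask,
        score=score, odds_ratio=or_, ci95=ci, p_value=p,
    )


def ranking_to_frame(ranking):
    """Tabulate a ranking as a DataFrame (the optional TSV dump payload)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "snp1": [r.snp1 for r in ranking],
            "snp2": [r.snp2 if r.snp2 is not None else "" for r in ranking],
            "kind": [r.kind for r in ranking],
            "cell_or_mask": [r.cell_or_mask for r in ranking],
            "score": [r.score for r in ranking],
            "OR": [r.odds_ratio for r in ranking],
            "CI_low": [r.ci95[0] for r in ranking],
            "CI_high": [r.ci95[1] for r in ranking],
            "p": [r.p_value for r in ranking],
        }
    )
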