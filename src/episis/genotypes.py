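"""Genotype containers and quality-control operations.

The data model is deliberately minimal: a dense matrix of minor-allele
counts (0/1/2, no missing values) with SNP metadata, and a binary
case/control phenotype.  Missing genotypes are a hard error at
construction time -- the downstream screening statistics assume complete
3x3 genotype-pair tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "QcThresholds",
    "minor_allele_freq",
    "hwe_exact_test",
    "qc_filter",
]


@dataclass
class GenotypeMatrix:
    """n individuals x L SNPs, entries counting copies of the minor allele.

    Parameters
    ----------
    genotypes : (n, L) integer array with entries in {0, 1, 2}
    snp_ids : L unique SNP identifiers (default ``SNP1..SNPL``)
    alleles : per-SNP ``(minor, major)`` allele labels
    sample_ids : n sample identifiers (default ``S1..Sn``)
    """

    genotypes: np.ndarray
    snp_ids: list = None
    alleles: list = None
    sample_ids: list = None

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n, L = g.shape
        if n < 2 or L < 1:
            raise ValueError(f"need n >= 2 individuals and L >= 1 SNPs, got {n}x{L}")
        if not np.issubdtype(g.dtype, np.integer):
            gi = g.astype(np.int64)
            if not np.array_equal(gi, g):
                raise ValueError("genotype entries must be integers in {0, 1, 2}")
            g = gi
        bad = (g < 0) | (g > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {g[i, j]} at sample {i}, SNP {j}; "
                "only 0/1/2 minor-allele counts are accepted (no missing values)"
            )
        self.genotypes = np.ascontiguousarray(g, dtype=np.int8)
        if self.snp_ids is None:
            self.snp_ids = [f"SNP{k + 1}" for k in range(L)]
        else:
            self.snp_ids = [str(s) for s in self.snp_ids]
        if len(self.snp_ids) != L:
            raise ValueError("snp_ids length does not match number of SNPs")
        if len(set(self.snp_ids)) != L:
            raise ValueError("snp_ids must be unique")
        if self.alleles is None:
            self.alleles = [("a", "A")] * L
        if len(self.alleles) != L:
            raise ValueError("alleles length does not match number of SNPs")
        if self.sample_ids is None:
            self.sample_ids = [f"S{k + 1}" for k in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of samples")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def subset_snps(self, keep) -> "GenotypeMatrix":
        """Return a new matrix restricted to the SNP indices/mask `keep`."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.genotypes[:, keep],
            snp_ids=[self.snp_ids[k] for k in keep],
            alleles=[self.alleles[k] for k in keep],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class PhenotypeVector:
    """Binary disease status per individual: 0 = control, 1 = case."""

    status: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.status)
        if s.ndim != 1:
            raise ValueError("status must be 1-D")
        vals = np.unique(s)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("phenotype entries must be 0 (control) or 1 (case)")
        if not (np.any(s == 0) and np.any(s == 1)):
            raise ValueError("need at least one case and one control")
        self.status = np.ascontiguousarray(s, dtype=np.int8)

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.status == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.status == 0))

    def __len__(self):
        return len(self.status)


@dataclass(frozen=True)
class QcThresholds:
    """Standard per-SNP QC filter thresholds (applied in controls).

    SNPs are kept when control MAF > ``maf_min`` and control HWE exact
    p-value >= ``hwe_alpha``; ``missing_max`` is reserved for readers that
    supply a missingness channel (the dense data model itself admits none).
    """

    maf_min: float = 0.05
    hwe_alpha: float = 5.7e-7
    missing_max: float = 0.05

    def __post_init__(self):
        for name in ("maf_min", "hwe_alpha", "missing_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def minor_allele_freq(g: GenotypeMatrix, snp_index: int, subset=None) -> float:
    """Folded allele frequency min(f, 1-f) of one SNP, optionally in a sample subset."""
    col = g.genotypes[:, snp_index]
    if subset is not None:
        col = col[np.asarray(subset)]
        if col.size == 0:
            raise ValueError("empty sample subset")
    f = float(col.sum()) / (2.0 * col.size)
    return min(f, 1.0 - f)


def hwe_exact_test(n_aa: int, n_aA: int, n_AA: int) -> float:
    """Exact conditional Hardy-Weinberg test on the heterozygote count.

    Given genotype counts, conditions on the allele counts and returns the
    probability of observing a heterozygote count no more probable than the
    one observed (the standard two-sided exact HWE test).
    """
    counts = (n_aa, n_aA, n_AA)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    na = 2 * n_aa + n_aA  # copies of the 'a' allele
    na = min(na, 2 * n - na)
    if na == 0:
        return 1.0  # monomorphic: single attainable configuration
    obs_het = n_aA
    hets = np.arange(na % 2, na + 1, 2)
    homs_a = (na - hets) // 2
    homs_b = n - homs_a - hets
    valid = homs_b >= 0
    hets, homs_a, homs_b = hets[valid], homs_a[valid], homs_b[valid]
    # log multinomial orderings, conditional on allele counts
    logw = (
        hets * np.log(2.0)
        - gammaln(homs_a + 1)
        - gammaln(hets + 1)
        - gammaln(homs_b + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    p_obs = probs[hets == obs_het][0]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def qc_filter(g: GenotypeMatrix, y: PhenotypeVector, t: QcThresholds = QcThresholds()):
    """Remove SNPs failing control-based MAF / HWE thresholds.

    Returns ``(filtered, report)`` where ``report`` is a per-SNP DataFrame
    with the computed control MAF, control HWE p-value, and pass flags.
    An empty result is allowed: when no SNP passes, the filtered matrix is
    ``None`` and the report carries the per-SNP failure reasons.
    """
    import pandas as pd

    if len(y) != g.n_samples:
        raise ValueError("phenotype length does not match genotype matrix")
    controls = y.status == 0
    Gc = g.genotypes[controls]
    nc = Gc.shape[0]
    f = Gc.sum(axis=0) / (2.0 * nc)
    maf = np.minimum(f, 1.0 - f)
    n1 = (Gc == 1).sum(axis=0)
    n2 = (Gc == 2).sum(axis=0)
    n0 = nc - n1 - n2
    hwe_p = np.array(
        [hwe_exact_test(int(a), int(b), int(c)) for a, b, c in zip(n2, n1, n0)]
    )
    pass_maf = maf > t.maf_min
    pass_hwe = hwe_p >= t.hwe_alpha
    passed = pass_maf & pass_hwe
    report = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "maf_control": maf,
            "hwe_p_control": hwe_p,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "passed": passed,
        }
    )
    if passed.all():
        return g, report
    if not passed.any():
        return None, report
    return g.subset_snps(passed), report
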