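"""Dummy coding of SNP pairs: CDC cells, main effects, ADC partitions.

A pair of biallelic SNPs forms a 3x3 genotype contingency table.  Cell-wise
dummy coding (CDC) turns each of the nine cells into an indicator predictor;
adaptive dummy coding (ADC) merges the cells into a high-risk/low-risk
bipartition chosen, per pair, to maximize balanced accuracy over all
2^9 - 2 nontrivial assignments.  Either way the predictor collapses to a
2x2 case/control x exposed/unexposed table, avoiding the sparse-cell issue
of testing the full 3x3 table.

Cell index convention: ``cell = 3*g1 + g2`` where g is the minor-allele
count (0, 1 or 2), so cells run row-major from (0,0) to (2,2).  The allele
orientation of the underlying 3x3 table is arbitrary; fixing the index to
the minor-allele counts makes output labels reproducible.  Partition masks
are 9-bit integers with bit k set iff cell k is assigned to the high-risk
group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .genotypes import GenotypeMatrix, PhenotypeVector

__all__ = [
    "PairCounts",
    "Table2x2",
    "PartitionScore",
    "N_PARTITIONS",
    "genotype_cell_index",
    "pair_counts",
    "cdc_tables",
    "main_effect_tables",
    "partition_table",
    "balanced_accuracy",
    "adc_best_partition",
    "partition_masks",
]

N_PARTITIONS = 2**9 - 2  # 510 nontrivial high/low-risk assignments

_MASKS = np.arange(1, 511, dtype=np.int64)
# (510, 9) matrix: row m, column k = bit k of mask m+1
_MASK_BITS = ((_MASKS[:, None] >> np.arange(9)[None, :]) & 1).astype(np.float32)


def partition_masks() -> np.ndarray:
    """All 510 legal partition masks, ascending."""
    return _MASKS.copy()


@dataclass(frozen=True)
class Table2x2:
    """2x2 case/control x exposed/unexposed count table.

    Entries are reals because the 0.5 continuity correction may apply.
    """

    case_exposed: float
    case_unexposed: float
    control_exposed: float
    control_unexposed: float

    def __post_init__(self):
        cells = self.cells
        if any(c < 0 for c in cells):
            raise ValueError("table cells must be nonnegative")
        if sum(cells) <= 0:
            raise ValueError("table total must be positive")

    @property
    def cells(self):
        return (
            self.case_exposed,
            self.case_unexposed,
            self.control_exposed,
            self.control_unexposed,
        )

    @property
    def n_cases(self) -> float:
        return self.case_exposed + self.case_unexposed

    @property
    def n_controls(self) -> float:
        return self.control_exposed + self.control_unexposed


@dataclass(frozen=True)
class PairCounts:
    """3x3 genotype-pair counts for cases and controls, cell-indexed 0..8."""

    case_counts: tuple
    control_counts: tuple
    pair: tuple = (0, 1)

    def __post_init__(self):
        for name in ("case_counts", "control_counts"):
            c = tuple(int(v) for v in getattr(self, name))
            if len(c) != 9 or any(v < 0 for v in c):
                raise ValueError(f"{name} must be 9 nonnegative integers")
            object.__setattr__(self, name, c)
        i, j = self.pair
        if not i < j:
            raise ValueError("pair must satisfy i < j")

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)


class BalancedAccuracy(NamedTuple):
    ba: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class PartitionScore:
    """Best high-risk/low-risk assignment of the nine cells for one pair."""

    mask: int
    ba: float
    sensitivity: float
    specificity: float

    def __post_init__(self):
        if not (1 <= self.mask <= 510):
            raise ValueError("mask must be a 9-bit integer excluding 0 and 511")


def genotype_cell_index(g1: int, g2: int) -> int:
    """Cell index 3*g1 + g2 of a genotype pair (minor-allele counts)."""
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise ValueError(f"genotype codes must be in {{0,1,2}}, got ({g1}, {g2})")
    return 3 * g1 + g2


def pair_counts(g: GenotypeMatrix, y: PhenotypeVector, i: int, j: int) -> PairCounts:
    """Tally the 3x3 genotype-pair table for SNPs i < j, split by status."""
    if i == j:
        raise ValueError("a pair requires two distinct SNPs")
    if not i < j:
        raise ValueError("pair indices must satisfy i < j")
    cells = 3 * g.genotypes[:, i].astype(np.int64) + g.genotypes[:, j]
    case = y.status == 1
    cc = np.bincount(cells[case], minlength=9)
    cn = np.bincount(cells[~case], minlength=9)
    return PairCounts(tuple(cc), tuple(cn), pair=(i, j))


def cdc_tables(pc: PairCounts):
    """The nine cell-wise 2x2 tables (exposed = in cell, unexposed = rest)."""
    nca, nco = pc.n_cases, pc.n_controls
    return [
        (
            k,
            Table2x2(
                pc.case_counts[k],
                nca - pc.case_counts[k],
                pc.control_counts[k],
                nco - pc.control_counts[k],
            ),
        )
        for k in range(9)
    ]


def main_effect_tables(g: GenotypeMatrix, y: PhenotypeVector, i: int):
    """Three single-SNP 2x2 tables, one per genotype value (exposed = that genotype)."""
    col = g.genotypes[:, i]
    case = y.status == 1
    nca, nco = int(case.sum()), int((~case).sum())
    out = []
    for v in (0, 1, 2):
        a = int(np.sum(col[case] == v))
        c = int(np.sum(col[~case] == v))
        out.append((v, Table2x2(a, nca - a, c, nco - c)))
    return out


def partition_table(pc: PairCounts, mask: int) -> Table2x2:
    """Collapse the nine cells into the high-risk (bit set) / low-risk groups."""
    if not (1 <= int(mask) <= 510):
        raise ValueError("mask must be a 9-bit integer excluding 0 and 511")
    mask = int(mask)
    ce = sum(pc.case_counts[k] for k in range(9) if (mask >> k) & 1)
    co = sum(pc.control_counts[k] for k in range(9) if (mask >> k) & 1)
    return Table2x2(ce, pc.n_cases - ce, co, pc.n_controls - co)


def balanced_accuracy(t: Table2x2) -> BalancedAccuracy:
    """BA = (sensitivity + specificity)/2 of 'high-risk predicts case'."""
    if t.n_cases <= 0 or t.n_controls <= 0:
        raise ValueError("balanced accuracy needs both cases and controls")
    sens = t.case_exposed / t.n_cases
    spec = t.control_unexposed / t.n_controls
    return BalancedAccuracy((sens + spec) / 2.0, sens, spec)


def adc_best_partition(pc: PairCounts) -> PartitionScore:
    """Exhaustively score all 510 partitions on the original counts.

    Returns the balanced-accuracy maximizer; ties break to the smallest
    mask integer.  Comparisons use the integer statistic
    ``case_high * n_controls - control_high * n_cases`` (an affine function
    of BA), so tie-breaking is exact.
    """
    nca, nco = pc.n_cases, pc.n_controls
    if nca <= 0 or nco <= 0:
        raise ValueError("both phenotype groups must be non-empty")
    cc = np.asarray(pc.case_counts, dtype=np.int64)
    cn = np.asarray(pc.control_counts, dtype=np.int64)
    bits = _MASK_BITS.astype(np.int64)
    case_high = bits @ cc
    ctrl_high = bits @ cn
    score = case_high * nco - ctrl_high * nca
    best = int(np.argmax(score))  # first max = smallest mask
    mask = int(_MASKS[best])
    sens = case_high[best] / nca
    spec = (nco - ctrl_high[best]) / nco
    return PartitionScore(mask, (sens + spec) / 2.0, sens, spec)
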