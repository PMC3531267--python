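"""Shared naive-oracle helpers for screening tests."""

import numpy as np

from episis import (
    adc_best_partition,
    cdc_tables,
    continuity_correct,
    lr_statistic,
    main_effect_tables,
    pair_counts,
    partition_table,
)
from episis.screening import _wald_z


def naive_rank_indices(g, y, cfg):
    """Independent all-candidates-in-memory sort: returns candidate indices."""
    L = g.n_snps
    n_pairs = L * (L - 1) // 2
    per = 9 if cfg.coding == "cdc" else 1
    cands = []
    for i in range(L):
        for j in range(i + 1, L):
            pr = i * L - i * (i + 1) // 2 + (j - i - 1)
            pc = pair_counts(g, y, i, j)
            if cfg.coding == "cdc":
                for k, t in cdc_tables(pc):
                    cands.append((pr * 9 + k, t))
            else:
                ps = adc_best_partition(pc)
                cands.append((pr, partition_table(pc, ps.mask)))
    for i in range(L):
        for v, t in main_effect_tables(g, y, i):
            cands.append((per * n_pairs + 3 * i + v, t))
    keyed = []
    for idx, t in cands:
        tc = continuity_correct(t)
        if cfg.criterion == "likelihood":
            key = -lr_statistic(tc)
        else:
            key = -abs(float(_wald_z(*(np.float64(x) for x in tc.cells))))
        keyed.append((key, idx))
    keyed.sort()
    return [idx for _, idx in keyed[: cfg.d]]


def engine_indices(ranking, L, coding):
    """Map RankedPredictor objects back to global candidate indices."""
    base = (9 if coding == "cdc" else 1) * L * (L - 1) // 2
    out = []
    for r in ranking:
        if r.kind == "main_effect":
            out.append(base + 3 * r.i + r.cell)
        else:
            pr = r.i * L - r.i * (r.i + 1) // 2 + (r.j - r.i - 1)
            out.append(pr * 9 + r.cell if r.kind == "pair_cell" else pr)
    return out
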