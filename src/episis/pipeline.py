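"""End-to-end driver: input -> QC -> screening -> selection -> report files."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotypes import QcThresholds, qc_filter
from .model import EpisisModel, EpisisResults
from .simulate import NullSimConfig, simulate_null

log = logging.getLogger("episis")

__all__ = ["RunConfig", "run_episis", "write_results", "read_simulate_config"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one input source must be set: ``bfile`` (PLINK prefix),
    ``table`` (plain genotype table) or ``simulate`` (a NullSimConfig or a
    flat key=value config path for the null simulator).
    """

    bfile: Optional[str] = None
    table: Optional[str] = None
    simulate: Optional[object] = None
    method: str = "padc"
    d: int = 256
    gammas: Sequence[float] = (0.6,)
    qc: Optional[QcThresholds] = field(default_factory=QcThresholds)
    seed: int = 0
    block_size: int = 128
    out: Optional[str] = None
    rank_dump: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        sources = sum(x is not None for x in (self.bfile, self.table, self.simulate))
        if sources != 1:
            raise ValueError("exactly one of bfile/table/simulate must be given")
        for gval in self.gammas:
            if not (0.0 <= gval <= 1.0):
                raise ValueError(f"gamma must lie in [0, 1], got {gval}")


def read_simulate_config(path: str) -> NullSimConfig:
    """Parse a flat key=value file into a NullSimConfig."""
    kwargs = {}
    casts = {
        "n_snps": int, "n_case": int, "n_control": int,
        "maf_low": float, "maf_high": float, "seed": int,
    }
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: malformed line {line!r} (expected key=value)")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in casts:
                raise ValueError(f"{path}: unknown simulator key {key!r}")
            kwargs[key] = casts[key](val)
    return NullSimConfig(**kwargs)


def _load(cfg: RunConfig):
    if cfg.bfile is not None:
        from .io import read_plink_bed

        log.info("reading PLINK fileset %s", cfg.bfile)
        return read_plink_bed(cfg.bfile)
    if cfg.table is not None:
        from .io import read_genotype_table

        log.info("reading genotype table %s", cfg.table)
        return read_genotype_table(cfg.table)
    sim = cfg.simulate
    if isinstance(sim, str):
        sim = read_simulate_config(sim)
    if not isinstance(sim, NullSimConfig):
        raise ValueError("simulate must be a NullSimConfig or a config path")
    log.info("simulating null dataset (%d SNPs, %d/%d)", sim.n_snps, sim.n_case,
             sim.n_control)
    return simulate_null(sim, seed=cfg.seed)


def run_episis(cfg: RunConfig) -> EpisisResults:
    """Execute QC -> screening -> penalized selection; returns EpisisResults.

    Deterministic given the config and input.  Output files are written when
    ``cfg.out`` is set (see :func:`write_results`).
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    g, y = _load(cfg)
    qc_report = None
    if cfg.qc is not None:
        g, qc_report = qc_filter(g, y, cfg.qc)
        if g is None or g.n_snps < 2:
            raise ValueError(
                "fewer than 2 SNPs passed QC; nothing to search "
                f"({0 if g is None else g.n_snps} remain)"
            )
        log.info("QC: %d of %d SNPs retained", g.n_snps, len(qc_report))
    model = EpisisModel(g, y)
    log.info("screening %d SNPs (%s, d=%d)", g.n_snps, cfg.method, cfg.d)
    res = model.fit(cfg.method, d=cfg.d, gamma=tuple(cfg.gammas),
                    block_size=cfg.block_size)
    res.qc_report = qc_report
    res.run_config = cfg
    if cfg.out is not None:
        write_results(res, cfg.out, rank_dump=cfg.rank_dump, seed=cfg.seed)
    return res


def write_results(res: EpisisResults, prefix: str, *, rank_dump: bool = False,
                  seed: Optional[int] = None):
    """Write the selected-predictor TSV plus a JSON metadata sidecar.

    Files are byte-identical across reruns with the same config/input:
    ``{prefix}.interactions.tsv`` (header-only when nothing is selected),
    ``{prefix}.meta.json``, and optionally ``{prefix}.ranking.tsv``.
    """
    sel = res.selection()
    tsv = prefix + ".interactions.tsv"
    cols = ["snp1", "snp2", "kind", "cell_or_mask", "coefficient", "OR",
            "CI_low", "CI_high", "p", "gamma"]
    with open(tsv, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in sel.iterrows():
            fh.write(
                "\t".join(
                    f"{row[c]:.10g}" if isinstance(row[c], float) else str(row[c])
                    for c in cols
                )
                + "\n"
            )
    meta = res.run_metadata()
    if seed is not None:
        meta["seed"] = seed
    with open(prefix + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written = [tsv, prefix + ".meta.json"]
    if rank_dump:
        rpath = prefix + ".ranking.tsv"
        res.ranking_frame().to_csv(rpath, sep="\t", index=False, float_format="%.10g")
        written.append(rpath)
    return written
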