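"""Synthetic case-control GWAS generators and experiment harnesses.

Two generators: a global null (independent HWE genotypes with per-SNP MAF
drawn uniformly, phenotype assigned by group membership) and a two-locus
penetrance-model disease simulator (causal pair placed at the first and
last SNP, disease sampled from a 3x3 penetrance matrix, rejection sampling
until both groups fill).  The harnesses reproduce the study-wise type-1
error (any predictor selected under the null) and power (the causal *pair*
detected) experiments over an EBIC gamma grid; one screening and one
lambda path is computed per replicate and re-scored per gamma.

Default null conditions are the scenario used in the type-1-error study:
1000 SNPs, MAF ~ Uniform(0.05, 0.5), 500 cases / 500 controls, no LD.

The shipped penetrance examples (:func:`example_penetrance_models`) are
synthetic reconstructions of four classic two-locus epistasis families
(multiplicative, threshold, XOR-like, heterogeneity), not copies of any
published table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotypes import GenotypeMatrix, PhenotypeVector
from .model import EpisisModel

__all__ = [
    "NullSimConfig",
    "PenetranceModel",
    "ExperimentResult",
    "simulate_null",
    "simulate_null_ld",
    "simulate_epistasis",
    "detection_outcome",
    "type1_error_experiment",
    "power_experiment",
    "example_penetrance_models",
]


@dataclass(frozen=True)
class NullSimConfig:
    """Global-null generator settings (defaults: the no-LD null scenario)."""

    n_snps: int = 1000
    n_case: int = 500
    n_control: int = 500
    maf_low: float = 0.05
    maf_high: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_snps < 1 or self.n_case < 1 or self.n_control < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class PenetranceModel:
    """Two-locus disease model: P(disease | g1, g2) over the 3x3 genotype grid.

    ``penetrance[g1, g2]`` with g = minor-allele count; causal loci sit at
    the first and last simulated SNP.
    """

    penetrance: np.ndarray
    maf1: float = 0.2
    maf2: float = 0.2

    def __post_init__(self):
        f = np.asarray(self.penetrance, dtype=np.float64)
        if f.shape != (3, 3):
            raise ValueError("penetrance must be a 3x3 matrix")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("penetrances must lie in [0, 1]")
        object.__setattr__(self, "penetrance", f)
        for m in (self.maf1, self.maf2):
            if not (0.0 < m <= 0.5):
                raise ValueError("causal MAFs must lie in (0, 0.5]")


@dataclass
class ExperimentResult:
    """Per-gamma detection tallies of a simulation experiment."""

    gammas: tuple
    replicates: int
    detections: np.ndarray  # per-gamma counts
    details: list = field(default_factory=list)  # per replicate: gamma -> labels
    n_failed: int = 0

    @property
    def rates(self) -> np.ndarray:
        """Per-gamma detection proportion (the type-1 error or power estimate)."""
        return self.detections / max(self.replicates, 1)

    def rate(self, gamma: float) -> float:
        k = self.gammas.index(gamma)
        return float(self.rates[k])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gamma": list(self.gammas),
                "replicates": self.replicates,
                "detections": self.detections,
                "rate": self.rates,
            }
        )

    def write_tsv(self, prefix: str):
        """Write ``{prefix}.rates.tsv`` plus a per-replicate detail log."""
        import json

        rates_path = prefix + ".rates.tsv"
        self.to_frame().to_csv(rates_path, sep="\t", index=False)
        log_path = prefix + ".details.log"
        with open(log_path, "w") as fh:
            for r, detail in enumerate(self.details):
                fh.write(f"{r}\t{json.dumps(detail, default=str)}\n")
        return [rates_path, log_path]


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_null(cfg: NullSimConfig, seed=None):
    """Independent HWE genotypes, phenotype independent of genotype.

    Per SNP a MAF is drawn uniformly from [maf_low, maf_high]; genotypes are
    Binomial(2, MAF) per individual (HWE, no LD).  The phenotype labels the
    first ``n_case`` rows cases.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    n = cfg.n_case + cfg.n_control
    mafs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_snps)
    geno = rng.binomial(2, mafs, size=(n, cfg.n_snps)).astype(np.int8)
    status = np.concatenate(
        [np.ones(cfg.n_case, dtype=np.int8), np.zeros(cfg.n_control, dtype=np.int8)]
    )
    return GenotypeMatrix(geno), PhenotypeVector(status)


def simulate_null_ld(cfg: NullSimConfig, rho: float = 0.8, seed=None):
    """Null data with Markov-decaying LD via an AR(1) haplotype copula.

    Each haplotype arises from a latent standard-normal AR(1) series with
    lag-one correlation ``rho``, thresholded per SNP at the normal quantile
    of its drawn allele frequency; two independent haplotypes per
    individual sum to the genotype.  Marginals match :func:`simulate_null`
    (per-SNP MAF ~ U(maf_low, maf_high), HWE) while adjacent SNPs show
    correlation decaying with distance.  A smoke-test generator only; it
    reproduces no particular LD map.
    """
    from scipy.stats import norm as _norm

    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    rng = _rng(cfg.seed if seed is None else seed)
    n = cfg.n_case + cfg.n_control
    L = cfg.n_snps
    mafs = rng.uniform(cfg.maf_low, cfg.maf_high, size=L)
    thr = _norm.ppf(mafs)
    geno = np.zeros((n, L), dtype=np.int8)
    scale = np.sqrt(1.0 - rho**2)
    for _hap in range(2):
        z = np.empty((n, L))
        z[:, 0] = rng.standard_normal(n)
        for k in range(1, L):
            z[:, k] = rho * z[:, k - 1] + scale * rng.standard_normal(n)
        geno += (z < thr).astype(np.int8)
    status = np.concatenate(
        [np.ones(cfg.n_case, dtype=np.int8), np.zeros(cfg.n_control, dtype=np.int8)]
    )
    return GenotypeMatrix(geno), PhenotypeVector(status)


def simulate_epistasis(
    model: PenetranceModel,
    n_snps: int = 1000,
    n_case: int = 400,
    n_control: int = 400,
    seed=None,
    *,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    max_draws: int = 10_000_000,
):
    """Two-locus penetrance-model case-control data.

    The causal pair occupies the first and last SNP columns; the remaining
    ``n_snps - 2`` SNPs are null.  Causal genotypes are drawn under HWE at
    the model MAFs, disease status is Bernoulli(penetrance), and rejection
    sampling runs until both groups are filled (bounded by ``max_draws``).
    """
    if n_snps < 2:
        raise ValueError("need at least the two causal SNPs")
    rng = _rng(seed)
    f = model.penetrance
    cases, controls = [], []
    drawn = 0
    batch = max(4 * (n_case + n_control), 1000)
    while (len(cases) < n_case or len(controls) < n_control) and drawn < max_draws:
        g1 = rng.binomial(2, model.maf1, size=batch)
        g2 = rng.binomial(2, model.maf2, size=batch)
        dis = rng.random(batch) < f[g1, g2]
        drawn += batch
        for a, b, s in zip(g1, g2, dis):
            if s and len(cases) < n_case:
                cases.append((a, b))
            elif not s and len(controls) < n_control:
                controls.append((a, b))
    if len(cases) < n_case or len(controls) < n_control:
        raise RuntimeError(
            "rejection sampling could not fill both phenotype groups "
            f"within {max_draws} draws; check the penetrance matrix"
        )
    pairs = np.array(cases + controls, dtype=np.int8)
    n = n_case + n_control
    geno = np.empty((n, n_snps), dtype=np.int8)
    geno[:, 0] = pairs[:, 0]
    geno[:, -1] = pairs[:, 1]
    if n_snps > 2:
        mafs = rng.uniform(maf_low, maf_high, size=n_snps - 2)
        geno[:, 1:-1] = rng.binomial(2, mafs, size=(n, n_snps - 2))
    status = np.concatenate(
        [np.ones(n_case, dtype=np.int8), np.zeros(n_control, dtype=np.int8)]
    )
    return GenotypeMatrix(geno), PhenotypeVector(status)


def detection_outcome(selection, causal_pair: Optional[tuple] = None) -> str:
    """Classify one run's selection table.

    Returns ``null_clean`` (nothing selected), ``causal_detected`` (a *pair*
    predictor -- cell or partition -- over the causal pair selected), or
    ``any_detection``.  Main-effect dummies of a causal SNP do not count as
    detecting the interaction.
    """
    if len(selection) == 0:
        return "null_clean"
    if causal_pair is not None:
        target = frozenset(causal_pair)
        for _, row in selection.iterrows():
            if row["kind"] in ("pair_cell", "pair_partition"):
                if frozenset((row["snp1"], row["snp2"])) == target:
                    return "causal_detected"
    return "any_detection"


def _replicate_seed(seed: int, r: int) -> np.random.Generator:
    """One reproducible stream per (experiment seed, replicate index)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))


def _run_experiment(make_data, causal, strategy, gammas, replicates, seed,
                    d, block_size):
    gammas = tuple(float(g) for g in gammas)
    detections = np.zeros(len(gammas), dtype=np.int64)
    details = []
    n_failed = 0
    for r in range(replicates):
        rng = _replicate_seed(seed, r)
        try:
            g, y = make_data(rng)
            res = EpisisModel(g, y).fit(
                coding=strategy[0], criterion=strategy[1], d=d, gamma=gammas,
                block_size=block_size,
            )
            detail = {}
            cp = causal(g) if causal is not None else None
            for k, gval in enumerate(gammas):
                sel = res.selection(gval)
                outcome = detection_outcome(sel, cp)
                hit = (outcome == "causal_detected") if cp is not None else (
                    outcome != "null_clean"
                )
                detections[k] += hit
                detail[gval] = {
                    "outcome": outcome,
                    "selected": [
                        f"{a}|{b}|{k_}" for a, b, k_ in
                        zip(sel["snp1"], sel["snp2"], sel["kind"])
                    ],
                }
            details.append(detail)
        except Exception as err:  # replicate skipped, denominator adjusted
            warnings.warn(f"replicate {r} failed and was skipped: {err}", stacklevel=2)
            n_failed += 1
            details.append({"error": str(err)})
    return ExperimentResult(
        gammas=gammas, replicates=replicates - n_failed, detections=detections,
        details=details, n_failed=n_failed,
    )


def _resolve_strategy(strategy):
    from .screening import STRATEGIES, ScreeningConfig

    if isinstance(strategy, ScreeningConfig):
        return (strategy.coding, strategy.criterion), strategy.d, strategy.block_size
    if isinstance(strategy, str):
        return STRATEGIES[strategy.lower()], 256, 128
    return tuple(strategy), 256, 128


def type1_error_experiment(cfg: NullSimConfig, strategy, gammas, replicates: int,
                           seed: int = 0) -> ExperimentResult:
    """Study-wise type-1 error: fraction of null replicates with any selection.

    ``strategy`` is a ScreeningConfig, a method name (``lcdc``/``pcdc``/
    ``padc``) or a ``(coding, criterion)`` tuple.  The reported rate per
    gamma is 1 - (proportion of replicates with zero selected predictors);
    every non-intercept selection, main effects included, counts as a false
    positive under the global null.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    strat, d, block_size = _resolve_strategy(strategy)
    return _run_experiment(
        lambda rng: simulate_null(cfg, seed=rng),
        None, strat, gammas, replicates, seed, d, block_size,
    )


def power_experiment(model: PenetranceModel, strategy, gammas, replicates: int,
                     seed: int = 0, *, n_snps: int = 1000, n_case: int = 400,
                     n_control: int = 400) -> ExperimentResult:
    """Power: fraction of replicates in which the causal pair is selected."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    strat, d, block_size = _resolve_strategy(strategy)
    return _run_experiment(
        lambda rng: simulate_epistasis(
            model, n_snps=n_snps, n_case=n_case, n_control=n_control, seed=rng
        ),
        lambda g: (g.snp_ids[0], g.snp_ids[-1]),
        strat, gammas, replicates, seed, d, block_size,
    )


def example_penetrance_models(baseline: float = 0.05, effect: float = 2.0,
                              maf: float = 0.2) -> dict:
    """Synthetic reconstructions of four classic epistasis pattern families.

    multiplicative : risk multiplies with each risk-allele pairing,
        f = baseline * effect^(g1*g2)
    threshold : elevated risk once both loci carry a minor allele
    xor : elevated risk when exactly one locus carries a minor allele
    heterogeneity : independent risk routes through either locus

    These are illustrative shapes, not published tables; penetrances are
    clipped to [0, 1].
    """
    g = np.arange(3)
    g1, g2 = np.meshgrid(g, g, indexing="ij")
    mult = baseline * effect ** (g1 * g2)
    thresh = np.where((g1 >= 1) & (g2 >= 1), baseline * effect, baseline)
    xor = np.where(((g1 >= 1) ^ (g2 >= 1)), baseline * effect, baseline)
    a1 = baseline * np.where(g1 >= 1, effect, 1.0)
    a2 = baseline * np.where(g2 >= 1, effect, 1.0)
    het = 1.0 - (1.0 - a1) * (1.0 - a2)
    out = {}
    for name, f in (("multiplicative", mult), ("threshold", thresh),
                    ("xor", xor), ("heterogeneity", het)):
        out[name] = PenetranceModel(np.clip(f, 0.0, 1.0), maf1=maf, maf2=maf)
    return out
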