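"""Model/Results interface for the two-step interaction search.

:class:`EpisisModel` holds a case-control genotype dataset; ``fit`` runs the
screening step (CDC/ADC dummy coding ranked by likelihood or odds-ratio
p-value), builds the design matrix from the d survivors, computes the ridge
smooth-thresholding path once, and scores it with the EBIC at one or more
gamma values.  The returned :class:`EpisisResults` exposes the selected
predictors per gamma with their coefficients and marginal odds ratios, a
``summary()`` table, and a simple selection-path plot.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PhenotypeVector, QcThresholds, qc_filter
from .screening import (
    RankedPredictor,
    ScreeningConfig,
    STRATEGIES,
    rank_features,
    ranking_to_frame,
)
from .stlogit import (
    EbicConfig,
    RidgeInit,
    StFit,
    adaptive_ridge_init,
    ebic,
    fit_path,
    select_from_path,
)

__all__ = ["EpisisModel", "EpisisResults"]


def _p_full(coding: str, L: int) -> int:
    """Saturated predictor count before screening (the EBIC dimension p)."""
    if coding == "cdc":
        return 9 * L * (L - 1) // 2 + 3 * L
    return L * (L - 1) // 2


class EpisisModel:
    """Case-control SNP dataset ready for exhaustive interaction search.

    Parameters
    ----------
    genotypes : GenotypeMatrix or (n, L) array of 0/1/2 minor-allele counts
    phenotype : PhenotypeVector or length-n 0/1 array
    snp_ids, sample_ids : optional identifiers when arrays are passed
    """

    def __init__(self, genotypes, phenotype, *, snp_ids=None, sample_ids=None):
        if not isinstance(genotypes, GenotypeMatrix):
            genotypes = GenotypeMatrix(
                np.asarray(genotypes), snp_ids=snp_ids, sample_ids=sample_ids
            )
        if not isinstance(phenotype, PhenotypeVector):
            phenotype = PhenotypeVector(np.asarray(phenotype))
        if len(phenotype) != genotypes.n_samples:
            raise ValueError("phenotype length does not match genotype matrix")
        self.data = genotypes
        self.phenotype = phenotype

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_plink(cls, path_prefix: str, qc: Optional[QcThresholds] = None):
        """Build from a PLINK .bed/.bim/.fam fileset, optionally QC-filtered."""
        from .io import read_plink_bed

        g, y = read_plink_bed(path_prefix)
        return cls._maybe_qc(g, y, qc)

    @classmethod
    def from_table(cls, path: str, qc: Optional[QcThresholds] = None):
        """Build from a plain whitespace-delimited genotype table."""
        from .io import read_genotype_table

        g, y = read_genotype_table(path)
        return cls._maybe_qc(g, y, qc)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phenotype: str = "phenotype"):
        """Build from a DataFrame with a phenotype column and 0/1/2 SNP columns."""
        y = df[phenotype].to_numpy()
        gcols = [c for c in df.columns if c != phenotype]
        return cls(df[gcols].to_numpy(), y, snp_ids=gcols,
                   sample_ids=[str(i) for i in df.index])

    @classmethod
    def _maybe_qc(cls, g, y, qc):
        if qc is not None:
            g, report = qc_filter(g, y, qc)
            if g is None:
                raise ValueError("no SNP passed the QC filter")
            model = cls(g, y)
            model.qc_report = report
            return model
        return cls(g, y)

    # -- statsmodels-flavoured aliases --------------------------------------

    @property
    def endog(self) -> np.ndarray:
        return self.phenotype.status

    @property
    def exog(self) -> np.ndarray:
        return self.data.genotypes

    @property
    def n_samples(self) -> int:
        return self.data.n_samples

    @property
    def n_snps(self) -> int:
        return self.data.n_snps

    def apply_qc(self, thresholds: QcThresholds = QcThresholds()):
        """Return ``(filtered EpisisModel or None, per-SNP report)``."""
        g, report = qc_filter(self.data, self.phenotype, thresholds)
        if g is None:
            return None, report
        return EpisisModel(g, self.phenotype), report

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        method: Optional[str] = None,
        *,
        coding: Optional[str] = None,
        criterion: Optional[str] = None,
        d: int = 256,
        gamma: Union[float, Sequence[float]] = 0.6,
        block_size: int = 128,
    ) -> "EpisisResults":
        """Run screening and the penalized-regression path.

        ``method`` is one of the published strategies ``lcdc``/``pcdc``/
        ``padc`` (likelihood- or p-value-ranked CDC, p-value-ranked ADC);
        alternatively give ``coding`` and ``criterion`` explicitly.
        ``gamma`` may be a single EBIC value or a grid -- the screening and
        the lambda path are computed once and re-scored per gamma.
        """
        if method is not None:
            if coding is not None or criterion is not None:
                raise ValueError("give either method or coding/criterion, not both")
            if method.lower() not in STRATEGIES:
                raise ValueError(f"unknown method {method!r}; choose from "
                                 f"{sorted(STRATEGIES)}")
            coding, criterion = STRATEGIES[method.lower()]
        else:
            coding = coding or "adc"
            criterion = criterion or "p_value"
        gammas = (float(gamma),) if np.isscalar(gamma) else tuple(float(x) for x in gamma)
        for gval in gammas:
            if not (0.0 <= gval <= 1.0):
                raise ValueError(f"gamma must lie in [0, 1], got {gval}")
        cfg = ScreeningConfig(coding=coding, criterion=criterion, d=d,
                              block_size=block_size)
        ranking = rank_features(self.data, self.phenotype, cfg)
        X = np.column_stack([r.indicator(self.data) for r in ranking])
        y = self.phenotype.status.astype(np.float64)
        init = adaptive_ridge_init(X, y)
        path = fit_path(X, y, init)
        return EpisisResults(
            model=self, config=cfg, method=(method.lower() if method else None),
            gammas=gammas, ranking=ranking, ridge_init=init, path=path,
        )


class EpisisResults:
    """Fitted search results over a gamma grid.

    The lambda path and screening are shared across gammas; per-gamma model
    choice is a cheap EBIC re-scoring of the same fitted path.
    """

    def __init__(self, model, config, method, gammas, ranking, ridge_init, path):
        self.model = model
        self.config = config
        self.method = method
        self.gammas = gammas
        self.ranking: list[RankedPredictor] = ranking
        self.ridge_init: RidgeInit = ridge_init
        self.path: list[StFit] = path
        self.n = model.n_samples
        self.L = model.n_snps
        self.p_full = _p_full(config.coding, self.L)
        self.d_used = len(ranking)

    # -- per-gamma selection ------------------------------------------------

    def _ebic_cfg(self, gamma: float) -> EbicConfig:
        return EbicConfig(gamma=gamma, p_full=self.p_full, n=self.n)

    def fit_for(self, gamma: float) -> StFit:
        """The EBIC-selected path fit at one gamma."""
        return select_from_path(self.path, self._ebic_cfg(gamma))

    def dimension(self, gamma: float) -> int:
        return self.fit_for(gamma).dim

    def selected_predictors(self, gamma: float):
        """List of ``(RankedPredictor, coefficient)`` selected at ``gamma``."""
        fit = self.fit_for(gamma)
        return [(self.ranking[k], float(fit.beta[k])) for k in fit.active_set]

    def selection(self, gamma: Optional[float] = None) -> pd.DataFrame:
        """Selected-predictor table (one row per predictor, per gamma).

        With ``gamma=None`` all fitted gammas are stacked.  OR and CI are the
        marginal 2x2-table values from screening; ``coefficient`` is the
        multivariable logistic coefficient.
        """
        gammas = self.gammas if gamma is None else (float(gamma),)
        rows = []
        for gval in gammas:
            for pred, coef in self.selected_predictors(gval):
                rows.append(
                    {
                        "snp1": pred.snp1,
                        "snp2": pred.snp2 if pred.snp2 is not None else "",
                        "kind": pred.kind,
                        "cell_or_mask": pred.cell_or_mask,
                        "coefficient": coef,
                        "OR": pred.odds_ratio,
                        "CI_low": pred.ci95[0],
                        "CI_high": pred.ci95[1],
                        "p": pred.p_value,
                        "gamma": gval,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["snp1", "snp2", "kind", "cell_or_mask", "coefficient",
                     "OR", "CI_low", "CI_high", "p", "gamma"],
        )

    def ranking_frame(self) -> pd.DataFrame:
        """The full top-d ranking as a DataFrame."""
        return ranking_to_frame(self.ranking)

    # -- reporting ----------------------------------------------------------

    def run_metadata(self) -> dict:
        meta = {
            "n": self.n,
            "L": self.L,
            "n_cases": self.model.phenotype.n_cases,
            "n_controls": self.model.phenotype.n_controls,
            "coding": self.config.coding,
            "criterion": self.config.criterion,
            "method": self.method,
            "d": self.config.d,
            "d_used": self.d_used,
            "p_full": self.p_full,
            "lambda2": self.ridge_init.lambda2,
            "gammas": list(self.gammas),
            "selected": {},
        }
        for gval in self.gammas:
            fit = self.fit_for(gval)
            meta["selected"][f"{gval:g}"] = {
                "lambda": fit.lam,
                "dim": fit.dim,
                "ebic": ebic(fit, self._ebic_cfg(gval)),
            }
        return meta

    def summary(self) -> str:
        """Human-readable run summary in the spirit of statsmodels results."""
        lines = [
            "EPISIS interaction search results",
            "=" * 64,
            f"samples: {self.n} ({self.model.phenotype.n_cases} cases / "
            f"{self.model.phenotype.n_controls} controls)   SNPs: {self.L}",
            f"coding: {self.config.coding.upper()}   criterion: "
            f"{self.config.criterion}   d: {self.d_used} of {self.p_full} candidates",
            f"ridge lambda2: {self.ridge_init.lambda2:g}   "
            f"path points: {len(self.path)}",
            "-" * 64,
        ]
        for gval in self.gammas:
            fit = self.fit_for(gval)
            lines.append(
                f"gamma={gval:g}: dim={fit.dim}  lambda={fit.lam:.6g}  "
                f"EBIC={ebic(fit, self._ebic_cfg(gval)):.4f}"
            )
            for pred, coef in self.selected_predictors(gval):
                tag = pred.snp1 if pred.snp2 is None else f"{pred.snp1} x {pred.snp2}"
                lines.append(
                    f"    {tag:<28s} {pred.kind:<14s} "
                    f"{'cm='}{pred.cell_or_mask!s:<4s} beta={coef:+.4f}  "
                    f"OR={pred.odds_ratio:.3f} "
                    f"({pred.ci95[0]:.3f}-{pred.ci95[1]:.3f})  p={pred.p_value:.3g}"
                )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_dimension_path(self, gammas=None, ax=None):
        """Plot selected model dimension against the EBIC gamma grid."""
        import matplotlib.pyplot as plt

        if gammas is None:
            gammas = np.round(np.arange(0.0, 1.01, 0.1), 10)
        dims = [self.dimension(gval) for gval in gammas]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(gammas, dims, marker="o")
        ax.set_xlabel("EBIC gamma")
        ax.set_ylabel("selected predictors")
        ax.set_title(f"{(self.method or self.config.coding).upper()} selection path")
        return ax
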