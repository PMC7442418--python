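"""Model/Results interface for two-sample MR, in the statsmodels idiom.

:class:`MRModel` holds a harmonized instrument set (exposure effects in SD
units, outcome effects in log-odds, with SEs); :meth:`MRModel.fit` dispatches
to an estimator and returns an :class:`MRResults` (or :class:`EggerResults`)
carrying the estimate, its uncertainty, the OR_SD transform and a printable
summary table.

Example
-------
>>> from mrscreen import MRModel, simulate
>>> exp, out, truth = simulate.simulate_pair(simulate.scenario_presets("all_valid"))
>>> from mrscreen.gwas_io import harmonize
>>> model = MRModel.from_instruments(harmonize(exp, out).instruments)
>>> res = model.fit("ivw_fe")
>>> round(res.odds_ratio, 2)  # doctest: +SKIP
1.22
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import estimators as est
from .gwas_io import HarmonizedInstrument
from .instruments import InstrumentStrength, set_f_statistics

__all__ = ["MRModel", "MRResults", "EggerResults"]

#: methods requiring >= 3 instruments
MULTI_SNP_METHODS = ("ivw_fe", "mle", "weighted_median", "weighted_mode")


class MRModel:
    """Two-sample MR model over a harmonized instrument set.

    Parameters
    ----------
    beta_exposure, se_exposure
        Per-allele SNP-exposure effects (SD units of the trait) and SEs.
    beta_outcome, se_outcome
        Per-allele SNP-outcome effects (log-odds) and SEs, already oriented
        to the same effect allele as the exposure.
    snp_ids
        Optional identifiers, used in leave-one-out reports.
    """

    def __init__(
        self,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        snp_ids: Sequence[str] | None = None,
        exposure: str = "exposure",
        outcome: str = "outcome",
    ):
        self.beta_exposure = np.asarray(beta_exposure, dtype=float)
        self.se_exposure = np.asarray(se_exposure, dtype=float)
        self.beta_outcome = np.asarray(beta_outcome, dtype=float)
        self.se_outcome = np.asarray(se_outcome, dtype=float)
        k = len(self.beta_exposure)
        for name in ("se_exposure", "beta_outcome", "se_outcome"):
            if len(getattr(self, name)) != k:
                raise ValueError("all input arrays must have equal length")
        if k == 0:
            raise est.EstimationError("empty instrument set")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")
        self.snp_ids = (
            [str(s) for s in snp_ids]
            if snp_ids is not None
            else [f"snp_{j}" for j in range(k)]
        )
        if len(self.snp_ids) != k:
            raise ValueError("snp_ids length mismatch")
        self.exposure = exposure
        self.outcome = outcome

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_instruments(
        cls,
        insts: Sequence[HarmonizedInstrument],
        exposure: str = "exposure",
        outcome: str = "outcome",
    ) -> "MRModel":
        kept = [i for i in insts if getattr(i, "kept", True)]
        return cls(
            beta_exposure=[i.beta_exposure for i in kept],
            se_exposure=[i.se_exposure for i in kept],
            beta_outcome=[i.beta_outcome for i in kept],
            se_outcome=[i.se_outcome for i in kept],
            snp_ids=[i.snp_id for i in kept],
            exposure=exposure,
            outcome=outcome,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        beta_exposure: str = "beta_exposure",
        se_exposure: str = "se_exposure",
        beta_outcome: str = "beta_outcome",
        se_outcome: str = "se_outcome",
        snp_id: str | None = "snp_id",
        exposure: str = "exposure",
        outcome: str = "outcome",
    ) -> "MRModel":
        ids = df[snp_id].tolist() if snp_id and snp_id in df.columns else None
        return cls(
            df[beta_exposure], df[se_exposure], df[beta_outcome], df[se_outcome],
            snp_ids=ids, exposure=exposure, outcome=outcome,
        )

    # -- properties ---------------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.beta_exposure)

    def f_statistics(self) -> InstrumentStrength:
        return set_f_statistics(self.to_instruments())

    def to_instruments(self) -> list[HarmonizedInstrument]:
        return [
            HarmonizedInstrument(
                snp_id=self.snp_ids[j],
                beta_exposure=float(self.beta_exposure[j]),
                se_exposure=float(self.se_exposure[j]),
                beta_outcome=float(self.beta_outcome[j]),
                se_outcome=float(self.se_outcome[j]),
            )
            for j in range(self.n_snps)
        ]

    def _subset(self, mask: np.ndarray) -> "MRModel":
        idx = np.flatnonzero(mask)
        return MRModel(
            self.beta_exposure[idx], self.se_exposure[idx],
            self.beta_outcome[idx], self.se_outcome[idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            exposure=self.exposure, outcome=self.outcome,
        )

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        method: str = "ivw_fe",
        *,
        se_order: str = "first",
        tol: float = 1e-8,
        maxiter: int = 200,
        n_boot: int = 1000,
        phi: float = 1.0,
        seed: int = 0,
        level: float = 0.95,
    ) -> "MRResults":
        """Fit one estimator and return its results object.

        ``method`` is one of ``wald`` (single SNP only), ``ivw_fe``, ``mle``,
        ``weighted_median``, ``weighted_mode`` or ``egger``.
        """
        bx, sx = self.beta_exposure, self.se_exposure
        by, sy = self.beta_outcome, self.se_outcome
        if method == "wald":
            if self.n_snps != 1:
                raise est.EstimationError(
                    f"wald applies to a single instrument, got {self.n_snps}"
                )
            e = est._wald_arrays(bx[0], sx[0], by[0], sy[0], se_order, level)
        elif method == "ivw_fe":
            e = est._ivw_arrays(bx, sx, by, sy, se_order, level)
        elif method == "mle":
            e = est._mle_arrays(bx, sx, by, sy, tol=tol, maxiter=maxiter, level=level)
        elif method == "weighted_median":
            e = est._weighted_median_arrays(
                bx, sx, by, sy, n_boot=n_boot, seed=seed, level=level
            )
        elif method == "weighted_mode":
            e = est._weighted_mode_arrays(
                bx, sx, by, sy, phi=phi, n_boot=n_boot, seed=seed, level=level
            )
        elif method == "egger":
            r = est._egger_arrays(bx, sx, by, sy, level=level)
            return EggerResults(self, r)
        else:
            raise ValueError(f"unknown method {method!r}")
        return MRResults(self, e)

    def fit_all(
        self,
        methods: Sequence[str] = MULTI_SNP_METHODS,
        seeds: Mapping[str, int] | None = None,
        **fit_kwargs,
    ) -> dict[str, "MRResults"]:
        """Fit several estimators; per-method seeds may be supplied."""
        out: dict[str, MRResults] = {}
        for m in methods:
            kw = dict(fit_kwargs)
            if seeds and m in seeds:
                kw["seed"] = seeds[m]
            out[m] = self.fit(m, **kw)
        return out

    def leave_one_out(self, method: str = "ivw_fe", alpha: float = 0.05, **kw):
        from .sensitivity import leave_one_out

        return leave_one_out(self.to_instruments(), method=method, alpha=alpha, **kw)


class MRResults:
    """Results of one MR fit: effect, uncertainty, OR_SD and summary table."""

    def __init__(self, model: MRModel, estimate: est.MREstimate):
        self.model = model
        self.estimate = estimate

    # statsmodels-flavoured accessors
    @property
    def method(self) -> str:
        return self.estimate.method

    @property
    def theta(self) -> float:
        return self.estimate.theta

    params = theta

    @property
    def bse(self) -> float:
        return self.estimate.se

    se = bse

    @property
    def pvalue(self) -> float:
        return self.estimate.pvalue

    @property
    def odds_ratio(self) -> float:
        return self.estimate.or_sd

    @property
    def n_snps(self) -> int:
        return self.estimate.n_snps

    nobs = n_snps

    def conf_int(self, level: float = 0.95, scale: str = "or") -> tuple[float, float]:
        """Confidence interval on the OR_SD (default) or log-odds scale."""
        _, lo, hi, _ = est.to_or_scale(self.theta, self.bse, level)
        if scale == "or":
            return lo, hi
        if scale == "log":
            return float(np.log(lo)), float(np.log(hi))
        raise ValueError(f"scale must be 'or' or 'log', got {scale!r}")

    def _summary_rows(self) -> list[list[str]]:
        lo, hi = self.conf_int()
        return [
            ["method", self.method],
            ["n_snps", f"{self.n_snps}"],
            ["theta (log OR_SD)", f"{self.theta:.4f}"],
            ["se", f"{self.bse:.4f}"],
            ["OR_SD", f"{self.odds_ratio:.3f}"],
            ["95% CI", f"({lo:.3f}, {hi:.3f})"],
            ["p-value", f"{self.pvalue:.3g}"],
        ]

    def summary(self) -> SimpleTable:
        title = f"Two-sample MR: {self.model.exposure} -> {self.model.outcome}"
        return SimpleTable(self._summary_rows(), title=title)

    def __repr__(self) -> str:
        lo, hi = self.conf_int()
        return (
            f"<MRResults {self.method}: OR_SD={self.odds_ratio:.3f} "
            f"({lo:.3f}-{hi:.3f}), p={self.pvalue:.3g}, n_snps={self.n_snps}>"
        )


class EggerResults(MRResults):
    """MR-Egger results: pleiotropy-adjusted slope plus intercept test."""

    def __init__(self, model: MRModel, result: est.EggerResult):
        super().__init__(model, result.slope)
        self.egger = result

    @property
    def intercept(self) -> float:
        return self.egger.intercept

    @property
    def intercept_se(self) -> float:
        return self.egger.intercept_se

    @property
    def intercept_pvalue(self) -> float:
        return self.egger.intercept_pvalue

    def _summary_rows(self) -> list[list[str]]:
        return super()._summary_rows() + [
            ["egger intercept", f"{self.intercept:.5f}"],
            ["intercept se", f"{self.intercept_se:.5f}"],
            ["intercept p", f"{self.intercept_pvalue:.3g}"],
        ]
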