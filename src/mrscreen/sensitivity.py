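"""Leave-one-out analysis and cross-method concordance.

A multi-SNP MR association can be an artifact of one influential variant
(often one sitting in a known disease locus or a pleiotropic gene such as
GCKR). Leave-one-out re-estimates the causal effect with each instrument
removed in turn; an association is *driven* by a SNP when the full estimate
is significant at ``alpha`` but the estimate without that SNP is not. Drivers
whose excluded-SNP p-value sits just above alpha (within ``near_window``) are
additionally flagged as near-drivers — the borderline pattern seen when an
association weakens without fully collapsing.

Concordance asks whether the four multi-SNP estimators (IVW-FE, MLE,
weighted median, weighted mode) agree in direction and are all significant —
the stability screen applied before taking any single-method association
seriously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import EggerResult, MREstimate
from .gwas_io import HarmonizedInstrument

__all__ = ["LeaveOneOutReport", "ConcordanceReport", "leave_one_out", "concordance"]

CONCORDANCE_METHODS = ("ivw_fe", "mle", "weighted_median", "weighted_mode")

_ESTIMATOR_FNS = {
    "ivw_fe": est.ivw_fe,
    "mle": est.max_likelihood,
    "weighted_median": est.weighted_median,
    "weighted_mode": est.weighted_mode,
}


@dataclass
class LeaveOneOutReport:
    """Full-set estimate, per-exclusion re-estimates and driver flags."""

    full_estimate: MREstimate
    per_exclusion: list[tuple[str, MREstimate]]
    driver_snps: list[str]
    near_driver_snps: list[str]
    driver_rule_alpha: float
    method: str = "ivw_fe"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "excluded_snp": snp,
                "theta": e.theta,
                "se": e.se,
                "or_sd": e.or_sd,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pvalue": e.pvalue,
                "n_snps": e.n_snps,
                "driver": snp in self.driver_snps,
                "near_driver": snp in self.near_driver_snps,
            }
            for snp, e in self.per_exclusion
        ]
        return pd.DataFrame(rows)


def leave_one_out(
    insts: Sequence[HarmonizedInstrument],
    method: str = "ivw_fe",
    alpha: float = 0.05,
    near_window: float = 0.01,
    seed: int = 0,
    **fit_kwargs,
) -> LeaveOneOutReport:
    """Re-estimate with each SNP excluded in turn; flag single-SNP drivers.

    A SNP is a driver iff the full estimate has p < ``alpha`` while the
    estimate excluding it has p >= ``alpha``; drivers with excluded-p within
    ``[alpha, alpha + near_window]`` are also listed as near-drivers.
    Bootstrap-based estimators receive deterministic per-exclusion seeds
    derived from ``seed``.
    """
    kept = [i for i in insts if getattr(i, "kept", True)]
    if len(kept) < 2:
        raise est.EstimationError("leave-one-out requires >= 2 instruments")
    if method not in _ESTIMATOR_FNS:
        raise ValueError(f"unknown method {method!r}; one of {sorted(_ESTIMATOR_FNS)}")
    fn = _ESTIMATOR_FNS[method]
    needs_seed = method in ("weighted_median", "weighted_mode")
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(kept) + 1)

    def _fit(subset, child):
        kw = dict(fit_kwargs)
        if needs_seed:
            kw.setdefault("n_boot", 1000)
            kw["seed"] = int(child)
        return fn(subset, **kw)

    full = _fit(kept, child_seeds[0])
    per_exclusion: list[tuple[str, MREstimate]] = []
    drivers: list[str] = []
    near: list[str] = []
    for j, excluded in enumerate(kept):
        subset = kept[:j] + kept[j + 1:]
        e = _fit(subset, child_seeds[j + 1])
        per_exclusion.append((excluded.snp_id, e))
        if full.pvalue < alpha and e.pvalue >= alpha:
            drivers.append(excluded.snp_id)
            if e.pvalue <= alpha + near_window:
                near.append(excluded.snp_id)
    return LeaveOneOutReport(
        full_estimate=full,
        per_exclusion=per_exclusion,
        driver_snps=drivers,
        near_driver_snps=near,
        driver_rule_alpha=alpha,
        method=method,
    )


@dataclass
class ConcordanceReport:
    """Direction + significance agreement across the four multi-SNP methods."""

    estimates: dict[str, MREstimate]
    consistent: bool
    alpha: float


def _as_estimate(obj) -> MREstimate:
    if isinstance(obj, MREstimate):
        return obj
    if isinstance(obj, EggerResult):
        return obj.slope
    if hasattr(obj, "estimate"):  # MRResults
        return obj.estimate
    raise TypeError(f"cannot interpret {type(obj).__name__} as an MR estimate")


def concordance(
    estimates: Mapping[str, object], alpha: float = 0.05
) -> ConcordanceReport:
    """Consistent iff all four methods share sign(theta) and all p < alpha."""
    missing = [m for m in CONCORDANCE_METHODS if m not in estimates]
    if missing:
        raise ValueError(f"missing method(s) for concordance: {', '.join(missing)}")
    ests = {m: _as_estimate(estimates[m]) for m in CONCORDANCE_METHODS}
    signs = {np.sign(e.theta) for e in ests.values()}
    consistent = (
        len(signs) == 1
        and 0.0 not in signs
        and all(e.pvalue < alpha for e in ests.values())
    )
    return ConcordanceReport(estimates=ests, consistent=bool(consistent), alpha=alpha)
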