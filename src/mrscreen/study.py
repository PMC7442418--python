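"""Full-screen orchestration: many exposures x outcomes, multiplicity, power.

The screening design tests each candidate exposure against each outcome
stratum (e.g. all glioma, GBM, non-GBM), applies a Bonferroni correction
sized to the number of exposures examined (alpha / n_tests), and labels an
IVW association *significant* below the corrected threshold, *suggestive*
between the corrected threshold and alpha, otherwise *null*. A priori power
for a binary outcome uses the standard normal approximation: the test
statistic has approximate mean |theta| * sqrt(n * R^2 * cf * (1 - cf)) where
R^2 is the variance of the exposure explained by the instruments and cf the
case fraction; power sums both rejection tails so the null limit is exactly
alpha.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import __version__
from . import estimators as est
from .gwas_io import harmonize, read_summary_stats
from .instruments import (
    DEFAULT_R2,
    GENOME_WIDE_P,
    LDMatrix,
    select_instruments,
    set_f_statistics,
)
from .model import MRModel
from .sensitivity import concordance, leave_one_out
from .simulate import SimulationConfig, scenario_presets, simulate_screen

__all__ = [
    "bonferroni_threshold",
    "classify",
    "PowerInput",
    "power_binary_outcome",
    "detectable_or",
    "StudyConfig",
    "StudyReport",
    "run_study",
    "null_screen",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise corrected significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def classify(pvalue: float, threshold_sig: float, threshold_sug: float) -> str:
    """'significant' (p < sig), 'suggestive' (sig <= p < sug) or 'null'.

    Both comparisons are strict at the lower edge, so a p-value exactly at
    the corrected threshold is only suggestive and one exactly at
    ``threshold_sug`` is null.
    """
    if not 0 < threshold_sig < threshold_sug < 1:
        raise ValueError("require 0 < threshold_sig < threshold_sug < 1")
    if pvalue < threshold_sig:
        return "significant"
    if pvalue < threshold_sug:
        return "suggestive"
    return "null"


@dataclass(frozen=True)
class PowerInput:
    """Inputs for a priori power with a binary outcome."""

    r2_exposure: float
    n_total: int
    case_fraction: float
    theta: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.r2_exposure < 1:
            raise ValueError("r2_exposure must be in [0, 1)")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def power_binary_outcome(pi: PowerInput) -> float:
    """Approximate power of the two-sided level-alpha test of theta = 0."""
    if pi.r2_exposure == 0:
        warnings.warn(
            "r2_exposure = 0: instruments explain no exposure variance; "
            "power degenerates to alpha",
            stacklevel=2,
        )
        return pi.alpha
    z = stats.norm.ppf(1 - pi.alpha / 2)
    ncp = abs(pi.theta) * np.sqrt(
        pi.n_total * pi.r2_exposure * pi.case_fraction * (1 - pi.case_fraction)
    )
    # both rejection tails: reduces to alpha exactly at theta = 0
    return float(stats.norm.cdf(-z + ncp) + stats.norm.cdf(-z - ncp))


def detectable_or(
    r2_exposure: float,
    n_total: int,
    case_fraction: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> float:
    """Smallest OR_SD (> 1) detectable at ``target_power``, by root-finding."""
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    if r2_exposure <= 0:
        raise ValueError("r2_exposure must be positive to invert power")

    def gap(theta: float) -> float:
        pi = PowerInput(r2_exposure, n_total, case_fraction, theta, alpha)
        return power_binary_outcome(pi) - target_power

    theta_star = optimize.brentq(gap, 1e-12, 50.0, xtol=1e-12)
    return float(np.exp(theta_star))


# ---------------------------------------------------------------------------
# study configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class TraitFile:
    label: str
    path: str
    ld_path: str | None = None
    column_map: dict | None = None


@dataclass
class StudyConfig:
    """Configuration for a multi-exposure screen; mirrors the YAML document."""

    exposures: list[TraitFile]
    outcomes: list[TraitFile]
    n_tests: int = 37
    alpha: float = 0.05
    p_instrument: float = GENOME_WIDE_P
    r2_threshold: float = DEFAULT_R2
    palindrome_policy: str = "drop"
    eaf_window: float = 0.08
    seeds: dict[str, int] = field(
        default_factory=lambda: {"weighted_median": 1, "weighted_mode": 2}
    )
    n_boot: int = 1000
    phi: float = 1.0
    se_order: str = "first"

    def __post_init__(self) -> None:
        self.exposures = [
            TraitFile(**e) if isinstance(e, dict) else e for e in self.exposures
        ]
        self.outcomes = [
            TraitFile(**o) if isinstance(o, dict) else o for o in self.outcomes
        ]
        if self.n_tests < len(self.exposures):
            raise ValueError(
                f"n_tests ({self.n_tests}) must be >= number of exposures "
                f"({len(self.exposures)})"
            )
        for tf in self.exposures + self.outcomes:
            if not Path(tf.path).exists():
                raise FileNotFoundError(f"summary-statistic file not found: {tf.path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def canonical_json(self) -> str:
        def enc(obj):
            if isinstance(obj, TraitFile):
                return vars(obj)
            raise TypeError(type(obj))

        return json.dumps(vars(self), default=enc, sort_keys=True)


@dataclass
class StudyReport:
    """Tidy result tables plus the reproducibility manifest."""

    estimates: pd.DataFrame
    loo: pd.DataFrame
    skipped: list[dict]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
        self.loo.to_csv(out_dir / "leave_one_out.tsv", sep="\t", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


_EST_COLS = [
    "exposure", "outcome", "method", "n_snps", "theta", "se",
    "or_sd", "ci_low", "ci_high", "pvalue", "classification",
    "mean_F", "weak_instruments", "concordant",
    "egger_intercept", "egger_intercept_se", "egger_intercept_pvalue",
]


def _estimate_row(exposure, outcome, e, **extra):
    row = dict.fromkeys(_EST_COLS)
    row.update(
        exposure=exposure, outcome=outcome, method=e.method, n_snps=e.n_snps,
        theta=e.theta, se=e.se, or_sd=e.or_sd, ci_low=e.ci_low,
        ci_high=e.ci_high, pvalue=e.pvalue,
    )
    row.update(extra)
    return row


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Run the full screen: selection, harmonization, estimation, LOO, labels.

    Per exposure x outcome, all applicable estimators are fitted (Wald only
    for a single instrument; the four multi-SNP methods plus Egger from three
    instruments), leave-one-out runs under IVW-FE, and the IVW (or Wald)
    p-value is classified against both the Bonferroni-corrected and the
    nominal threshold. Deterministic given the configured seeds; a manifest
    records the config hash, seeds and library versions.
    """
    sig_threshold = bonferroni_threshold(config.alpha, config.n_tests)
    est_rows: list[dict] = []
    loo_rows: list[dict] = []
    skipped: list[dict] = []

    outcome_cache = {
        o.label: list(read_summary_stats(o.path, o.column_map, o.label))
        for o in config.outcomes
    }

    for exp_file in config.exposures:
        assocs = list(read_summary_stats(exp_file.path, exp_file.column_map, exp_file.label))
        ld = LDMatrix.from_tsv(exp_file.ld_path) if exp_file.ld_path else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected = select_instruments(
                assocs, config.p_instrument, ld, config.r2_threshold
            )
        if not selected:
            skipped.append(
                {"exposure": exp_file.label, "reason": "no instruments pass selection"}
            )
            continue
        for out_file in config.outcomes:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                harmonized = harmonize(
                    selected, outcome_cache[out_file.label],
                    config.palindrome_policy, config.eaf_window,
                )
            insts = harmonized.instruments
            if not insts:
                skipped.append(
                    {
                        "exposure": exp_file.label,
                        "outcome": out_file.label,
                        "reason": "no instruments survive harmonization",
                    }
                )
                continue
            model = MRModel.from_instruments(
                insts, exposure=exp_file.label, outcome=out_file.label
            )
            strength = set_f_statistics(insts)
            base = dict(mean_F=strength.mean, weak_instruments=strength.weak)

            if model.n_snps == 1:
                res = model.fit("wald", se_order=config.se_order)
                cls = classify(res.pvalue, sig_threshold, config.alpha)
                est_rows.append(
                    _estimate_row(
                        exp_file.label, out_file.label, res.estimate,
                        classification=cls, **base,
                    )
                )
                continue

            fits = {"ivw_fe": model.fit("ivw_fe", se_order=config.se_order)}
            fits["mle"] = model.fit("mle")
            conc = None
            if model.n_snps >= 3:
                fits["weighted_median"] = model.fit(
                    "weighted_median", n_boot=config.n_boot,
                    seed=config.seeds.get("weighted_median", 1),
                )
                fits["weighted_mode"] = model.fit(
                    "weighted_mode", n_boot=config.n_boot, phi=config.phi,
                    seed=config.seeds.get("weighted_mode", 2),
                )
                conc = concordance(fits, alpha=config.alpha)

            ivw_p = fits["ivw_fe"].pvalue
            cls = classify(ivw_p, sig_threshold, config.alpha)
            for name, res in fits.items():
                est_rows.append(
                    _estimate_row(
                        exp_file.label, out_file.label, res.estimate,
                        classification=cls if name == "ivw_fe" else None,
                        concordant=None if conc is None else conc.consistent,
                        **base,
                    )
                )
            if model.n_snps >= 3:
                eg = model.fit("egger")
                est_rows.append(
                    _estimate_row(
                        exp_file.label, out_file.label, eg.estimate,
                        egger_intercept=eg.intercept,
                        egger_intercept_se=eg.intercept_se,
                        egger_intercept_pvalue=eg.intercept_pvalue,
                        **base,
                    )
                )

            report = leave_one_out(
                insts, method="ivw_fe", alpha=config.alpha,
                se_order=config.se_order,
            )
            frame = report.to_frame()
            frame.insert(0, "exposure", exp_file.label)
            frame.insert(1, "outcome", out_file.label)
            loo_rows.append(frame)

    estimates = pd.DataFrame(est_rows, columns=_EST_COLS)
    loo = (
        pd.concat(loo_rows, ignore_index=True)
        if loo_rows
        else pd.DataFrame()
    )
    import scipy
    import statsmodels

    manifest = {
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()
        ).hexdigest(),
        "seeds": config.seeds,
        "n_tests": config.n_tests,
        "significance_threshold": sig_threshold,
        "suggestive_threshold": config.alpha,
        "power_formula": "two-sided normal approximation, "
        "ncp = |theta|*sqrt(n*R2*cf*(1-cf)) (approximate)",
        "n_estimate_rows": len(estimates),
        "n_loo_rows": len(loo),
        "skipped": skipped,
        "versions": {
            "mrscreen": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    report = StudyReport(estimates=estimates, loo=loo, skipped=skipped, manifest=manifest)
    if out_dir is not None:
        report.write(out_dir)
    return report


def null_screen(
    n_runs: int = 100,
    seed: int = 0,
    config: SimulationConfig | None = None,
    alpha: float = 0.05,
    n_tests: int = 37,
) -> pd.DataFrame:
    """Repeated synthetic null screens: IVW classification of null exposures.

    Each run simulates ``config.n_traits`` independent null exposures against
    one outcome, estimates each with IVW-FE on the genome-wide-significant
    instruments, and counts suggestive-or-better and significant calls at the
    Bonferroni-corrected threshold alpha / n_tests.
    """
    cfg = config if config is not None else scenario_presets("null_screen_37")
    sig = bonferroni_threshold(alpha, n_tests)
    run_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)
    rows = []
    for r in range(n_runs):
        from dataclasses import replace

        run_cfg = replace(cfg, seed=int(run_seeds[r]))
        n_suggestive = n_significant = 0
        for _, exposure, outcome, _truth in simulate_screen(run_cfg):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                from .instruments import filter_significant

                selected = filter_significant(exposure, GENOME_WIDE_P)
                if not selected:
                    continue
                insts = harmonize(selected, outcome).instruments
            if not insts:
                continue
            e = est.ivw_fe(insts)
            label = classify(e.pvalue, sig, alpha)
            if label != "null":
                n_suggestive += 1
            if label == "significant":
                n_significant += 1
        rows.append(
            {"run": r, "suggestive_or_better": n_suggestive, "significant": n_significant}
        )
    return pd.DataFrame(rows)
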