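"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator draws summary statistics directly — the quantities a two-sample
MR analysis actually consumes — rather than simulating individual-level
genotypes. Per SNP j:

* minor-allele frequency  maf_j ~ Uniform(maf_low, maf_high);
* true SNP-exposure effect  gamma_j ~ Normal(gamma_mean, gamma_sd)  (SD units
  per allele);
* a direct (horizontally pleiotropic) outcome effect  alpha_j, zero for valid
  instruments; for the configured invalid fraction, drawn symmetric about
  zero ("balanced") or with non-zero mean ("directional");
* true outcome effect  theta_true * gamma_j + alpha_j  (log-odds per allele);
* observed effects are normal draws around the truths with the standard
  large-sample SEs  se_x = 1/sqrt(2 maf (1-maf) n_exposure)  and
  se_y = 1/sqrt(2 maf (1-maf) n_outcome cf (1-cf))  for a case fraction cf;
* two-sided normal p-values.

Exposure and outcome noise are independent (non-overlapping samples), and
alpha_j is drawn independently of gamma_j, so the InSIDE condition holds by
construction. Default sample sizes mirror a large continuous-trait GWAS
(n = 100 000) screened against a glioma-scale case-control study
(12 488 cases / 18 169 controls). Everything is reproducible from the seed,
and the returned truth record stores every latent quantity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .gwas_io import VariantAssociation, write_summary_stats

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_pair",
    "simulate_screen",
    "scenario_presets",
    "simulate_to_files",
    "PRESET_NAMES",
]

#: glioma-scale outcome study: 12 488 cases + 18 169 controls
DEFAULT_N_OUTCOME = 30_657
DEFAULT_CASE_FRACTION = 12_488 / 30_657

PLEIOTROPY_MODES = ("none", "balanced", "directional")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic exposure/outcome pair."""

    n_snps: int = 30
    theta_true: float = 0.0
    gamma_mean: float = 0.04
    gamma_sd: float = 0.01
    n_exposure: int = 100_000
    n_outcome: int = DEFAULT_N_OUTCOME
    case_fraction: float = DEFAULT_CASE_FRACTION
    invalid_fraction: float = 0.0
    pleiotropy: str = "none"
    pleiotropy_magnitude: float = 0.08
    outlier: tuple[int, float] | None = None
    maf_low: float = 0.1
    maf_high: float = 0.5
    seed: int = 0
    n_traits: int = 1

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.pleiotropy not in PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy must be one of {PLEIOTROPY_MODES}, got {self.pleiotropy!r}"
            )
        if not 0 <= self.invalid_fraction < 1:
            raise ValueError("invalid_fraction must be in [0, 1)")
        if self.invalid_fraction > 0 and self.pleiotropy == "none":
            raise ValueError("invalid_fraction > 0 requires a pleiotropy mode")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        if self.gamma_sd < 0:
            raise ValueError("gamma_sd must be >= 0")
        if self.outlier is not None:
            idx, _ = self.outlier
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"outlier index {idx} out of range")
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")

    @property
    def n_invalid(self) -> int:
        return round(self.invalid_fraction * self.n_snps)


@dataclass
class TruthRecord:
    """Every latent quantity behind one simulated pair; JSON round-trips."""

    theta_true: float
    maf: list[float]
    gamma: list[float]
    pleiotropy_effect: list[float]
    true_outcome_effect: list[float]
    invalid_indices: list[int]
    outlier: tuple[int, float] | None
    seed: int

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if d["outlier"] is not None:
            d["outlier"] = list(d["outlier"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        if d.get("outlier") is not None:
            d["outlier"] = (int(d["outlier"][0]), float(d["outlier"][1]))
        return cls(**d)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def simulate_pair(
    cfg: SimulationConfig,
) -> tuple[list[VariantAssociation], list[VariantAssociation], TruthRecord]:
    """Draw one exposure/outcome summary-statistic pair plus its truth record."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, n)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, n)

    alpha = np.zeros(n)
    invalid = np.array([], dtype=int)
    if cfg.n_invalid > 0:
        invalid = np.sort(rng.choice(n, size=cfg.n_invalid, replace=False))
        if cfg.pleiotropy == "balanced":
            alpha[invalid] = rng.normal(0.0, cfg.pleiotropy_magnitude, cfg.n_invalid)
        elif cfg.pleiotropy == "directional":
            alpha[invalid] = rng.normal(
                cfg.pleiotropy_magnitude, cfg.pleiotropy_magnitude / 2, cfg.n_invalid
            )

    true_out = cfg.theta_true * gamma + alpha
    if cfg.outlier is not None:  # injected last, on top of any pleiotropy
        idx, eff = cfg.outlier
        true_out[idx] += eff

    het = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(het * cfg.n_exposure)
    cf = cfg.case_fraction
    se_y = 1.0 / np.sqrt(het * cfg.n_outcome * cf * (1.0 - cf))

    bx = gamma + se_x * rng.standard_normal(n)
    by = true_out + se_y * rng.standard_normal(n)
    px = _two_sided_p(bx, se_x)
    py = _two_sided_p(by, se_y)

    exposure, outcome = [], []
    for j in range(n):
        common = dict(
            snp_id=f"snp_{j:03d}", chrom="1", pos=10_000 + 1000 * j,
            effect_allele="A", other_allele="G", eaf=float(maf[j]),
        )
        exposure.append(
            VariantAssociation(
                beta=float(bx[j]), se=float(se_x[j]),
                pvalue=float(max(px[j], 5e-324)), n=cfg.n_exposure,
                trait="exposure", **common,
            )
        )
        outcome.append(
            VariantAssociation(
                beta=float(by[j]), se=float(se_y[j]),
                pvalue=float(max(py[j], 5e-324)), n=cfg.n_outcome,
                trait="outcome", **common,
            )
        )
    truth = TruthRecord(
        theta_true=cfg.theta_true,
        maf=maf.tolist(),
        gamma=gamma.tolist(),
        pleiotropy_effect=alpha.tolist(),
        true_outcome_effect=true_out.tolist(),
        invalid_indices=invalid.tolist(),
        outlier=cfg.outlier,
        seed=cfg.seed,
    )
    return exposure, outcome, truth


def simulate_screen(cfg: SimulationConfig):
    """Simulate ``cfg.n_traits`` independent exposures, each with its outcome.

    Per-trait seeds are derived deterministically from ``cfg.seed``; yields
    (trait_label, exposure, outcome, truth) tuples.
    """
    child = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=cfg.n_traits)
    for t in range(cfg.n_traits):
        sub = replace(cfg, seed=int(child[t]), n_traits=1)
        exposure, outcome, truth = simulate_pair(sub)
        yield f"trait_{t:02d}", exposure, outcome, truth


_PRESETS = {
    # clean instrument set at the paper-scale causal effect used in recovery checks
    "all_valid": dict(n_snps=30, theta_true=0.2),
    # 40% invalid instruments, pleiotropy symmetric about zero
    "balanced_40": dict(
        n_snps=30, theta_true=0.2, invalid_fraction=0.4, pleiotropy="balanced"
    ),
    # 40% invalid instruments, all pushed the same way (violates IVW, not WME)
    "directional_40": dict(
        n_snps=30, theta_true=0.2, invalid_fraction=0.4, pleiotropy="directional"
    ),
    # null effect with one large direct-effect SNP: the single-driver pattern
    "driver_snp": dict(n_snps=11, theta_true=0.0, outlier=(0, 0.4)),
    # 37 independent null exposures against one outcome: multiplicity screen
    "null_screen_37": dict(n_snps=30, theta_true=0.0, n_traits=37),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def scenario_presets(name: str, seed: int = 0) -> SimulationConfig:
    """Documented parameter set for a named scenario."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    return SimulationConfig(seed=seed, **_PRESETS[name])


def simulate_to_files(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write exposure.tsv / outcome.tsv / truth.json for one simulated pair."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, truth = simulate_pair(cfg)
    paths = {
        "exposure": out_dir / "exposure.tsv",
        "outcome": out_dir / "outcome.tsv",
        "truth": out_dir / "truth.json",
    }
    write_summary_stats(exposure, paths["exposure"])
    write_summary_stats(outcome, paths["outcome"])
    paths["truth"].write_text(truth.to_json())
    return paths
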