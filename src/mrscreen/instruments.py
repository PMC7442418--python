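"""Instrument selection: significance filtering, LD clumping, F-statistics.

Valid genetic instruments for MR must be robustly associated with the
exposure (genome-wide significance, P <= 5e-8), approximately independent of
one another (pairwise r^2 below a clumping threshold, strongest effect
retained), and strong (F-statistic conventionally > 10).

Clumping here operates on a caller-supplied :class:`LDMatrix` rather than a
reference-panel query, keeping the step deterministic and fully offline; a
SNP absent from the matrix is an error, never silently assumed independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas_io import HarmonizedInstrument, VariantAssociation

__all__ = [
    "LDMatrix",
    "InstrumentSet",
    "InstrumentStrength",
    "filter_significant",
    "ld_clump",
    "f_statistic",
    "set_f_statistics",
    "select_instruments",
    "GENOME_WIDE_P",
    "DEFAULT_R2",
]

GENOME_WIDE_P = 5e-8
DEFAULT_R2 = 0.01
WEAK_F_THRESHOLD = 10.0


@dataclass
class LDMatrix:
    """Squared-correlation (r^2) matrix over an ordered set of SNPs."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 shape {self.r2.shape} does not match {k} snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        if not np.all(np.diag(self.r2) == 1.0):
            raise ValueError("r2 diagonal must be exactly 1")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != k:
            raise ValueError("duplicate snp_ids in LDMatrix")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=[str(s) for s in df.index], r2=df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t"
        )


def filter_significant(
    assocs: Sequence[VariantAssociation], p_threshold: float = GENOME_WIDE_P
) -> list[VariantAssociation]:
    """Keep associations with p <= ``p_threshold`` (inclusive), input order."""
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must be in (0,1), got {p_threshold}")
    kept = [a for a in assocs if a.pvalue <= p_threshold]
    if not kept:
        warnings.warn(
            f"no associations reach p <= {p_threshold:g}; instrument set is empty",
            stacklevel=2,
        )
    return kept


def _clump_rank_key(a: VariantAssociation):
    # strongest |beta| first; ties by smaller p, then snp_id, so the ranking
    # is total and clumping is invariant to input order
    return (-abs(a.beta), a.pvalue, a.snp_id)


def ld_clump(
    assocs: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float = DEFAULT_R2,
) -> list[VariantAssociation]:
    """Greedy clumping retaining the strongest effect in each correlated set.

    Repeatedly accepts the remaining SNP with the largest |beta| and discards
    every remaining SNP with r^2 >= ``r2_threshold`` against it; the returned
    list (in acceptance order) is therefore pairwise r^2 < threshold.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError(f"r2_threshold must be in (0,1], got {r2_threshold}")
    for a in assocs:
        if a.snp_id not in ld:
            raise ValueError(f"SNP {a.snp_id!r} missing from the LD matrix")
    remaining = sorted(assocs, key=_clump_rank_key)
    accepted: list[VariantAssociation] = []
    while remaining:
        top = remaining.pop(0)
        accepted.append(top)
        remaining = [
            a for a in remaining if ld.r2_between(top.snp_id, a.snp_id) < r2_threshold
        ]
    return accepted


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument-strength F = (beta/se)^2."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return (beta / se) ** 2


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-SNP and mean F with the conventional weak-instrument flag."""

    per_snp: np.ndarray
    mean: float
    weak: bool

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        flag = " (weak)" if self.weak else ""
        return f"InstrumentStrength(mean F = {self.mean:.1f}, n = {len(self.per_snp)}{flag})"


def set_f_statistics(
    instruments: Sequence[HarmonizedInstrument] | Sequence[VariantAssociation],
) -> InstrumentStrength:
    """F-statistics for an instrument set (exposure effects).

    Accepts harmonized instruments (``beta_exposure``/``se_exposure``) or raw
    exposure associations (``beta``/``se``). The set-level summary is the mean
    per-SNP F; ``weak`` is raised when the mean is <= 10.
    """
    if len(instruments) == 0:
        raise ValueError("empty instrument set")
    first = instruments[0]
    if hasattr(first, "beta_exposure"):
        per = np.array(
            [f_statistic(i.beta_exposure, i.se_exposure) for i in instruments]
        )
    else:
        per = np.array([f_statistic(i.beta, i.se) for i in instruments])
    mean = float(per.mean())
    return InstrumentStrength(per_snp=per, mean=mean, weak=mean <= WEAK_F_THRESHOLD)


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with the selection thresholds."""

    exposure_label: str
    instruments: list[HarmonizedInstrument]
    p_threshold: float
    r2_threshold: float | None
    per_snp_F: np.ndarray = field(default_factory=lambda: np.empty(0))


def select_instruments(
    assocs: Sequence[VariantAssociation],
    p_threshold: float = GENOME_WIDE_P,
    ld: LDMatrix | None = None,
    r2_threshold: float = DEFAULT_R2,
) -> list[VariantAssociation]:
    """Significance filter followed by LD clumping when a matrix is supplied."""
    kept = filter_significant(assocs, p_threshold)
    if ld is not None and kept:
        kept = ld_clump(kept, ld, r2_threshold)
    return kept
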