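"""Reading, writing and allele harmonization of GWAS summary statistics.

Two-sample Mendelian randomization consumes per-variant association summaries
from two independent studies: per-allele effects on a continuous exposure (in
SD units of the trait) and on a binary outcome (log-odds). This module parses
delimited summary-statistic tables into validated :class:`VariantAssociation`
records and aligns exposure and outcome effects onto a shared effect-allele
orientation (:func:`harmonize`), the step that in database-backed MR pipelines
is performed server-side.

Harmonization rules
-------------------
For each SNP present in both studies the outcome allele pair is compared with
the exposure pair, trying in order: identity, allele swap (outcome effect
negated), strand complement, and complemented swap. Pairs that cannot be
reconciled are recorded as ``dropped_incompatible``. Palindromic SNPs (A/T or
C/G) carry no strand information in their allele labels; by default they are
dropped, or — under the permissive policy — kept only when both effect-allele
frequencies are informative (outside ``0.5 ± eaf_window``) and agree on the
side of 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "VariantAssociation",
    "HarmonizedInstrument",
    "HarmonizationResult",
    "ParsedSummaryStats",
    "SummaryStatsError",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "write_harmonized",
    "read_harmonized",
]

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names; ``column_map`` maps these onto file headers
REQUIRED_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")
OPTIONAL_COLUMNS = ("chrom", "pos", "eaf", "n")

ORIENTATION_ACTIONS = (
    "unchanged",
    "flipped",
    "dropped_palindromic",
    "dropped_incompatible",
)


class SummaryStatsError(ValueError):
    """Malformed summary-statistic input (configuration-level failure)."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association summary with one trait.

    ``beta`` is the per-allele effect: SD units of the trait for a continuous
    exposure, log-odds for a case-control outcome. ``eaf`` is the frequency of
    ``effect_allele``.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None
    trait: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (math.isfinite(self.beta)):
            raise ValueError(f"{self.snp_id}: beta must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.snp_id}: pvalue must be in (0,1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf must be in [0,1], got {self.eaf}")
        if self.pos is not None and self.pos < 0:
            raise ValueError(f"{self.snp_id}: pos must be non-negative")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.snp_id}: n must be positive")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G pairs, whose strand cannot be read off alleles."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def pvalue_consistent(self, factor: float = 2.0) -> bool:
        """Check the stored p against 2*Phi(-|beta/se|) within ``factor``."""
        z = abs(self.beta) / self.se
        log_implied = math.log(2.0) + stats.norm.logsf(z)
        return abs(math.log(self.pvalue) - log_implied) <= math.log(factor)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects for one SNP on a common effect allele.

    ``eaf`` is the exposure-study effect-allele frequency; ``eaf_outcome`` is
    the outcome-study frequency re-expressed for the same allele (so flipped
    records carry ``1 - eaf`` relative to the source file).
    """

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float | None = None
    eaf_outcome: float | None = None
    orientation_action: str = "unchanged"

    def __post_init__(self) -> None:
        if self.orientation_action not in ORIENTATION_ACTIONS:
            raise ValueError(f"unknown orientation_action {self.orientation_action!r}")
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.snp_id}: standard errors must be positive")

    @property
    def kept(self) -> bool:
        return self.orientation_action in ("unchanged", "flipped")


@dataclass
class ParsedSummaryStats(Sequence):
    """Parsed records plus the rows rejected during validation."""

    records: list[VariantAssociation]
    rejected: list[tuple[int, str]] = field(default_factory=list)
    trait: str | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)


def _detect_sep(path: Path) -> str:
    header = path.open("r").readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise SummaryStatsError(
        f"{path}: cannot detect delimiter (no tab or comma in header line)"
    )


def _opt(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "nan", "NaN"):
        return None
    return cast(value)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str | None = None,
) -> ParsedSummaryStats:
    """Read a delimited summary-statistic table into validated records.

    Parameters
    ----------
    path
        TSV or CSV file with a header line; the delimiter is auto-detected.
    column_map
        Mapping from canonical field names (``snp_id``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, ``pvalue`` and the optional
        ``chrom``, ``pos``, ``eaf``, ``n``) to the file's column headers.
        Omitted canonical names are looked up verbatim.
    trait_label
        Stored on every record's ``trait`` field.

    Rows failing type or invariant checks are rejected individually and
    reported (with 1-based data-row numbers) on the returned object; a summary
    warning is emitted. A missing *required* column is a configuration error.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False)

    colmap = {name: name for name in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    if column_map:
        colmap.update(column_map)

    missing = [c for c in REQUIRED_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise SummaryStatsError(
            f"{path}: required column(s) not found: "
            + ", ".join(f"{c!r} (mapped to {colmap[c]!r})" for c in missing)
        )
    have_optional = [c for c in OPTIONAL_COLUMNS if colmap[c] in df.columns]

    records: list[VariantAssociation] = []
    rejected: list[tuple[int, str]] = []
    inconsistent = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            kwargs = dict(
                snp_id=str(rowd[colmap["snp_id"]]),
                effect_allele=str(rowd[colmap["effect_allele"]]),
                other_allele=str(rowd[colmap["other_allele"]]),
                beta=float(rowd[colmap["beta"]]),
                se=float(rowd[colmap["se"]]),
                pvalue=float(rowd[colmap["pvalue"]]),
                trait=trait_label,
            )
            for opt in have_optional:
                raw = rowd[colmap[opt]]
                if opt == "chrom":
                    kwargs[opt] = _opt(raw, str)
                elif opt in ("pos", "n"):
                    kwargs[opt] = _opt(raw, lambda v: int(float(v)))
                else:
                    kwargs[opt] = _opt(raw, float)
            rec = VariantAssociation(**kwargs)
        except (ValueError, TypeError) as exc:
            rejected.append((i, str(exc)))
            continue
        if not rec.pvalue_consistent():
            inconsistent += 1
        records.append(rec)

    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} of {len(df)} rows "
            f"(first: row {rejected[0][0]}: {rejected[0][1]})",
            stacklevel=2,
        )
    if inconsistent:
        warnings.warn(
            f"{path}: {inconsistent} row(s) have p-values inconsistent with "
            "|beta/se| under the normal approximation (factor > 2); kept as-is",
            stacklevel=2,
        )
    return ParsedSummaryStats(records=records, rejected=rejected, trait=trait_label)


def write_summary_stats(
    records: Sequence[VariantAssociation], path: str | Path, sep: str = "\t"
) -> None:
    """Write records as delimited text; round-trips bit-exact via ``repr``."""
    cols = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in cols})
    df = pd.DataFrame(rows, columns=list(cols), dtype=object)
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def _pair(rec: VariantAssociation) -> tuple[str, str]:
    return rec.effect_allele, rec.other_allele


def _complement_pair(pair: tuple[str, str]) -> tuple[str, str]:
    return _COMPLEMENT[pair[0]], _COMPLEMENT[pair[1]]


@dataclass
class HarmonizationResult(Sequence):
    """All intersection SNPs (exposure order), each with an orientation action.

    ``instruments`` is the estimation-ready subset; every dropped record keeps
    its reason in ``orientation_action`` so no SNP disappears silently.
    """

    records: list[HarmonizedInstrument]
    missing_from_outcome: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.records)

    @property
    def instruments(self) -> list[HarmonizedInstrument]:
        return [r for r in self.records if r.kept]

    @property
    def dropped(self) -> list[tuple[str, str]]:
        return [(r.snp_id, r.orientation_action) for r in self.records if not r.kept]


def _index_unique(records: Sequence[VariantAssociation], side: str):
    index: dict[str, VariantAssociation] = {}
    for r in records:
        if r.snp_id in index:
            raise SummaryStatsError(f"duplicate snp_id {r.snp_id!r} in {side} records")
        index[r.snp_id] = r
    return index


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_policy: str = "drop",
    eaf_window: float = 0.08,
) -> HarmonizationResult:
    """Align outcome effects onto the exposure's effect-allele orientation.

    Parameters
    ----------
    palindrome_policy
        ``"drop"`` (default) discards every palindromic SNP;
        ``"keep_if_eaf_informative"`` keeps a palindromic SNP only when both
        studies report an allele frequency outside ``0.5 ± eaf_window`` and
        on the same side of 0.5.
    """
    if palindrome_policy not in ("drop", "keep_if_eaf_informative"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    out_index = _index_unique(outcome, "outcome")
    _index_unique(exposure, "exposure")

    records: list[HarmonizedInstrument] = []
    missing: list[str] = []
    for exp in exposure:
        out = out_index.get(exp.snp_id)
        if out is None:
            missing.append(exp.snp_id)
            continue
        records.append(_harmonize_one(exp, out, palindrome_policy, eaf_window))
    if not records:
        raise SummaryStatsError("no SNPs shared between exposure and outcome")
    if missing:
        warnings.warn(
            f"{len(missing)} exposure SNP(s) absent from the outcome and dropped "
            f"(first: {missing[0]})",
            stacklevel=2,
        )
    return HarmonizationResult(records=records, missing_from_outcome=missing)


def _harmonize_one(
    exp: VariantAssociation,
    out: VariantAssociation,
    palindrome_policy: str,
    eaf_window: float,
) -> HarmonizedInstrument:
    base = dict(
        snp_id=exp.snp_id,
        beta_exposure=exp.beta,
        se_exposure=exp.se,
        se_outcome=out.se,
        eaf=exp.eaf,
    )
    ep, op = _pair(exp), _pair(out)

    if exp.is_palindromic:
        # allele labels cannot resolve strand; adjudicate by frequency or drop
        if op not in (ep, ep[::-1]):
            return HarmonizedInstrument(
                beta_outcome=out.beta, eaf_outcome=out.eaf,
                orientation_action="dropped_incompatible", **base,
            )
        keep = False
        if palindrome_policy == "keep_if_eaf_informative":
            if exp.eaf is not None and out.eaf is not None:
                informative = (
                    abs(exp.eaf - 0.5) > eaf_window and abs(out.eaf - 0.5) > eaf_window
                )
                same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
                keep = informative and same_side
        action = "unchanged" if keep else "dropped_palindromic"
        return HarmonizedInstrument(
            beta_outcome=out.beta, eaf_outcome=out.eaf,
            orientation_action=action, **base,
        )

    if op == ep or _complement_pair(op) == ep:
        return HarmonizedInstrument(
            beta_outcome=out.beta, eaf_outcome=out.eaf,
            orientation_action="unchanged", **base,
        )
    if op == ep[::-1] or _complement_pair(op) == ep[::-1]:
        flipped_eaf = None if out.eaf is None else 1.0 - out.eaf
        return HarmonizedInstrument(
            beta_outcome=-out.beta, eaf_outcome=flipped_eaf,
            orientation_action="flipped", **base,
        )
    return HarmonizedInstrument(
        beta_outcome=out.beta, eaf_outcome=out.eaf,
        orientation_action="dropped_incompatible", **base,
    )


_HARMONIZED_COLS = (
    "snp_id",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
    "eaf",
    "eaf_outcome",
    "orientation_action",
)


def write_harmonized(
    result: HarmonizationResult | Sequence[HarmonizedInstrument],
    path: str | Path,
    sep: str = "\t",
) -> None:
    records = list(result)
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in _HARMONIZED_COLS} for r in records],
        columns=list(_HARMONIZED_COLS),
        dtype=object,
    )
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_harmonized(path: str | Path) -> HarmonizationResult:
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False)
    records = []
    for rowd in df.to_dict("records"):
        records.append(
            HarmonizedInstrument(
                snp_id=str(rowd["snp_id"]),
                beta_exposure=float(rowd["beta_exposure"]),
                se_exposure=float(rowd["se_exposure"]),
                beta_outcome=float(rowd["beta_outcome"]),
                se_outcome=float(rowd["se_outcome"]),
                eaf=_opt(rowd.get("eaf"), float),
                eaf_outcome=_opt(rowd.get("eaf_outcome"), float),
                orientation_action=str(rowd["orientation_action"]),
            )
        )
    return HarmonizationResult(records=records)
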