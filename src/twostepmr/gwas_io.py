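"""Reading, validation, and harmonization of GWAS summary statistics.

Summary-statistic tables hold per-variant association records for one trait
measured in one sample. Harmonization aligns the effect alleles of an
exposure table and an outcome table so that each shared variant's effects
refer to the same allele, resolving swapped alleles by sign flips and
palindromic (A/T, G/C) variants by allele-frequency inference or exclusion.

All effect sizes for binary traits are carried as log-odds; conversion to
odds ratios happens only at reporting time (see :func:`twostepmr.mr_core.to_odds_ratio`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VALID_ALLELES",
    "SummaryRecord",
    "SummaryTable",
    "HarmonizedSet",
    "ConfigurationError",
    "EmptyInputError",
    "EmptyOverlapError",
    "read_summary_table",
    "write_summary_table",
    "harmonize",
    "write_harmonization_report",
]

VALID_ALLELES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the TSV dialect written by this package
CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "eaf",
    "n",
)


class ConfigurationError(ValueError):
    """A required column or parameter is missing or out of range."""


class EmptyInputError(ValueError):
    """No valid rows survived validation."""


class EmptyOverlapError(ValueError):
    """Exposure and outcome tables share no variants."""


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for
    binary traits, SD units for quantitative traits), ``se`` its standard
    error, ``eaf`` the effect-allele frequency when known.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be A/C/G/T, got {ea}/{oa}")
        if ea == oa:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.variant_id}: se must be a positive finite number")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta must be finite")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.variant_id}: pvalue must lie in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.variant_id}: eaf must lie in (0, 1)")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.variant_id}: n must be positive")

    @property
    def is_palindromic(self) -> bool:
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass
class SummaryTable:
    """An ordered collection of :class:`SummaryRecord`, unique by variant id."""

    trait_label: str
    records: dict[str, SummaryRecord] = field(default_factory=dict)
    sample_label: str = ""

    def __post_init__(self) -> None:
        # accept any iterable of records for convenience
        if not isinstance(self.records, dict):
            recs = list(self.records)
            self.records = {}
            for r in recs:
                self.add(r)

    def add(self, record: SummaryRecord) -> None:
        if record.variant_id in self.records:
            raise ValueError(f"duplicate variant_id {record.variant_id!r}")
        self.records[record.variant_id] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __getitem__(self, variant_id: str) -> SummaryRecord:
        return self.records[variant_id]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def variant_ids(self) -> list[str]:
        return list(self.records)

    def subset(self, variant_ids: Iterable[str]) -> "SummaryTable":
        keep = [self.records[v] for v in variant_ids if v in self.records]
        return SummaryTable(self.trait_label, keep, self.sample_label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "eaf": r.eaf,
                "n": r.n,
            }
            for r in self
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass
class HarmonizedSet:
    """Exposure-outcome effect pairs aligned to a common effect allele.

    Arrays are parallel over the retained variants: ``gamma``/``se_gamma``
    are the instrument-exposure effects and ``Gamma``/``se_Gamma`` the
    instrument-outcome effects. After orientation every ``gamma`` is
    non-negative (joint sign flips preserve each Wald ratio ``Gamma/gamma``).
    """

    exposure_label: str
    outcome_label: str
    variant_ids: list[str]
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    orientation_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.se_gamma = np.asarray(self.se_gamma, dtype=float)
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.se_Gamma = np.asarray(self.se_Gamma, dtype=float)
        n = len(self.variant_ids)
        if not (len(self.gamma) == len(self.se_gamma) == len(self.Gamma) == len(self.se_Gamma) == n):
            raise ValueError("harmonized arrays must have equal length")
        if n < 1:
            raise ValueError("harmonized set must contain at least one variant")
        if np.any(self.se_gamma <= 0) or np.any(self.se_Gamma <= 0):
            raise ValueError("standard errors must be strictly positive")
        if not self.orientation_flags:
            self.orientation_flags = ["kept"] * n

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)

    def subset(self, index: Sequence[int]) -> "HarmonizedSet":
        idx = list(index)
        return HarmonizedSet(
            self.exposure_label,
            self.outcome_label,
            [self.variant_ids[i] for i in idx],
            self.gamma[idx],
            self.se_gamma[idx],
            self.Gamma[idx],
            self.se_Gamma[idx],
            [self.orientation_flags[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "gamma": self.gamma,
                "se_gamma": self.se_gamma,
                "Gamma": self.Gamma,
                "se_Gamma": self.se_Gamma,
                "orientation": self.orientation_flags,
            }
        )


# ---------------------------------------------------------------------------
# reading / writing


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
    sample_label: str = "",
) -> tuple[SummaryTable, list[dict]]:
    """Read a tab-separated summary-statistic file into a :class:`SummaryTable`.

    ``column_map`` maps canonical field names (``variant_id``,
    ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``pvalue`` and
    optionally ``eaf``, ``n``) to the header names actually present, so
    IEU-style and GWAS-catalog-style files need no bespoke readers. Rows
    violating record invariants are rejected, not fatal; the second return
    value reports each rejection as ``{"row", "variant_id", "reason"}``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = dict(column_map or {})
    mandatory = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]
    resolved: dict[str, str] = {}
    for canon in mandatory + ["eaf", "n"]:
        source = colmap.get(canon, canon)
        if source in df.columns:
            resolved[canon] = source
        elif canon in mandatory:
            raise ConfigurationError(
                f"{path.name}: mandatory column {canon!r} (mapped to {source!r}) absent from header"
            )

    table = SummaryTable(trait_label or path.stem, {}, sample_label)
    rejects: list[dict] = []
    for i, row in df.iterrows():
        try:
            rec = SummaryRecord(
                variant_id=str(row[resolved["variant_id"]]),
                effect_allele=str(row[resolved["effect_allele"]]),
                other_allele=str(row[resolved["other_allele"]]),
                beta=float(row[resolved["beta"]]),
                se=float(row[resolved["se"]]),
                pvalue=float(row[resolved["pvalue"]]),
                eaf=_opt_float(row, resolved.get("eaf")),
                n=_opt_int(row, resolved.get("n")),
            )
            table.add(rec)
        except (ValueError, TypeError) as exc:
            rejects.append(
                {
                    "row": int(i),
                    "variant_id": str(row.get(resolved["variant_id"], "?")),
                    "reason": str(exc),
                }
            )
    if len(table) == 0:
        raise EmptyInputError(f"{path.name}: no valid rows after validation")
    return table, rejects


def _opt_float(row, col):
    if col is None:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or (isinstance(v, str) and not v.strip()):
        return None
    return float(v)


def _opt_int(row, col):
    v = _opt_float(row, col)
    return None if v is None else int(v)


def write_summary_table(table: SummaryTable, path: str | Path) -> None:
    """Write ``table`` in the canonical TSV dialect (round-trips with the reader)."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# harmonization


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindromic_policy: str = "infer_by_eaf",
    eaf_tolerance: float = 0.08,
) -> tuple[HarmonizedSet, list[dict]]:
    """Align outcome effects onto the exposure's effect alleles.

    For each shared variant: matching allele pairs are kept as-is; swapped
    pairs flip the sign of the outcome beta (and mirror its frequency);
    strand-complement matches are aligned the same way after complementing.
    Palindromic variants (A/T or G/C) cannot be resolved by allele labels:
    under ``infer_by_eaf`` they are retained only when both frequencies sit
    on the same side of 0.5 and outside ``0.5 ± eaf_tolerance``; under
    ``drop`` (or when a frequency is missing) they are excluded.

    Finally every variant is re-oriented so the exposure effect is
    non-negative, flipping exposure and outcome signs together — the joint
    flip leaves each Wald ratio unchanged and fixes the sign convention the
    pleiotropy-intercept regression requires.

    Returns the harmonized set and a per-variant action report.
    """
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise ConfigurationError(f"unknown palindromic_policy {palindromic_policy!r}")
    shared = [v for v in exposure.variant_ids() if v in outcome]
    if not shared:
        raise EmptyOverlapError(
            f"no shared variants between {exposure.trait_label!r} and {outcome.trait_label!r}"
        )

    ids: list[str] = []
    gamma, se_gamma, Gamma, se_Gamma = [], [], [], []
    flags: list[str] = []
    report: list[dict] = []

    for vid in shared:
        e = exposure[vid]
        o = outcome[vid]
        resolution = _resolve_alleles(e, o, palindromic_policy, eaf_tolerance)
        action, out_beta, flag = resolution
        if action == "drop":
            report.append({"variant": vid, "action": "dropped", "reason": flag})
            continue
        g, G = e.beta, out_beta
        if g < 0:  # orientation convention: positive exposure effect
            g, G = -g, -G
            flag = "sign-flipped"
        ids.append(vid)
        gamma.append(g)
        se_gamma.append(e.se)
        Gamma.append(G)
        se_Gamma.append(o.se)
        flags.append(flag)
        report.append({"variant": vid, "action": "kept", "reason": flag})

    if not ids:
        raise EmptyOverlapError("all shared variants dropped during harmonization")
    hs = HarmonizedSet(
        exposure.trait_label,
        outcome.trait_label,
        ids,
        np.array(gamma),
        np.array(se_gamma),
        np.array(Gamma),
        np.array(se_Gamma),
        flags,
    )
    return hs, report


def _resolve_alleles(
    e: SummaryRecord, o: SummaryRecord, policy: str, tol: float
) -> tuple[str, float, str]:
    """Return (action, aligned outcome beta, flag/reason) for one variant."""
    ea, oa = e.effect_allele, e.other_allele
    if e.is_palindromic:
        # allele labels cannot distinguish strands; same pair on both sides
        if {o.effect_allele, o.other_allele} != {ea, oa}:
            return "drop", 0.0, "irreconcilable-alleles"
        if policy == "drop":
            return "drop", 0.0, "dropped-palindromic"
        if e.eaf is None or o.eaf is None:
            return "drop", 0.0, "dropped-palindromic-no-eaf"
        lo, hi = 0.5 - tol, 0.5 + tol
        if lo <= e.eaf <= hi or lo <= o.eaf <= hi:
            return "drop", 0.0, "dropped-palindromic-ambiguous-eaf"
        # frequencies identify orientation only when unambiguous and concordant
        same_side = (e.eaf < 0.5) == (
            (o.eaf < 0.5) if o.effect_allele == ea else (o.eaf > 0.5)
        )
        if not same_side:
            return "drop", 0.0, "dropped-palindromic-discordant-eaf"
        beta = o.beta if o.effect_allele == ea else -o.beta
        return "keep", beta, "inferred-from-frequency"

    if (o.effect_allele, o.other_allele) == (ea, oa):
        return "keep", o.beta, "kept"
    if (o.effect_allele, o.other_allele) == (oa, ea):
        return "keep", -o.beta, "kept"
    cea, coa = _COMPLEMENT[o.effect_allele], _COMPLEMENT[o.other_allele]
    if (cea, coa) == (ea, oa):
        return "keep", o.beta, "kept"
    if (cea, coa) == (oa, ea):
        return "keep", -o.beta, "kept"
    return "drop", 0.0, "irreconcilable-alleles"


def write_harmonization_report(report: list[dict], path: str | Path) -> None:
    pd.DataFrame(report, columns=["variant", "action", "reason"]).to_csv(
        path, sep="\t", index=False
    )
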