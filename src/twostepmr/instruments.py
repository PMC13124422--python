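"""Instrument selection and quality control.

Genetic instruments for a drug-target exposure are chosen by a p-value
screen, pruned for linkage disequilibrium (LD) by greedy clumping, and
filtered for strength by the F-statistic (squared instrument z-score;
variants with F < 10 are conventionally considered weak and removed).
Bayesian colocalization assesses whether two traits share a single causal
variant in a region via per-variant approximate Bayes factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .gwas_io import ConfigurationError, SummaryTable

__all__ = [
    "LDMatrix",
    "InstrumentSet",
    "ColocResult",
    "EmptyInstrumentError",
    "InsufficientRegionError",
    "f_statistic",
    "clump",
    "select_instruments",
    "coloc_abf",
]


class EmptyInstrumentError(ValueError):
    """A selection stage removed every candidate instrument."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no instruments survive the {stage} stage")


class InsufficientRegionError(ValueError):
    """Too few shared variants for regional colocalization."""


@dataclass
class LDMatrix:
    """Pairwise LD correlations (signed r, unit diagonal) over named variants."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix dimensions must match variant_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2(self, a: str, b: str) -> float | None:
        """Squared correlation between two variants, None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib] ** 2)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", float_format="%.6g"
        )


@dataclass
class InstrumentSet:
    """Selected instruments with a per-variant audit trail.

    ``members`` rows are (variant_id, gamma, se_gamma, pvalue, f_statistic);
    ``selection_log`` rows are (variant_id, stage, verdict).
    """

    exposure_label: str
    members: list[tuple[str, float, float, float, float]] = field(default_factory=list)
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return [m[0] for m in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.members,
            columns=["variant_id", "gamma", "se_gamma", "pvalue", "f_statistic"],
        )

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.selection_log, columns=["variant_id", "stage", "verdict"])


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    H0: no association with either trait; H1/H2: association with one trait
    only; H3: both traits, distinct causal variants; H4: both traits, one
    shared causal variant.
    """

    pp: dict[str, float]
    n_variants: int
    priors: tuple[float, float, float]

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors must sum to 1, got {total}")
        if any(not (0 <= v <= 1) for v in self.pp.values()):
            raise ValueError("posteriors must lie in [0, 1]")


def f_statistic(beta: float, se: float) -> float:
    """Instrument strength F = (beta/se)^2, the squared Wald z-score."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def clump(
    candidates: SummaryTable,
    ld: LDMatrix | None,
    r2_threshold: float = 0.8,
    window_kb: float = 250.0,
    positions: Mapping[str, float] | None = None,
) -> InstrumentSet:
    """Greedy LD clumping: keep the most significant variant of each correlated set.

    Candidates are visited in ascending p-value order (ties broken by
    variant id); each is accepted unless its squared correlation with an
    already-accepted variant reaches ``r2_threshold``. When per-variant
    positions are supplied, only pairs within ``window_kb`` kilobases can
    exclude each other. Pairs missing from the LD matrix are treated as
    uncorrelated, with a warning. Deterministic given its inputs.
    """
    if not (0 < r2_threshold <= 1):
        raise ConfigurationError("r2_threshold must lie in (0, 1]")
    if len(candidates) == 0:
        raise ValueError("candidates table is empty")
    if ld is None:
        warnings.warn("no LD matrix supplied; clumping passes all candidates through")
        out = InstrumentSet(candidates.trait_label)
        for r in candidates:
            out.members.append((r.variant_id, r.beta, r.se, r.pvalue, f_statistic(r.beta, r.se)))
            out.selection_log.append((r.variant_id, "clump", "kept-no-ld"))
        return out

    order = sorted(candidates, key=lambda r: (r.pvalue, r.variant_id))
    accepted: list = []
    out = InstrumentSet(candidates.trait_label)
    missing_warned = False
    for rec in order:
        excluded_by = None
        for kept in accepted:
            if positions is not None:
                pa, pb = positions.get(rec.variant_id), positions.get(kept.variant_id)
                if pa is not None and pb is not None and abs(pa - pb) > window_kb * 1000:
                    continue
            r2 = ld.r2(rec.variant_id, kept.variant_id)
            if r2 is None:
                if not missing_warned:
                    warnings.warn("LD matrix missing some candidate pairs; treating r=0")
                    missing_warned = True
                continue
            if r2 >= r2_threshold:
                excluded_by = kept.variant_id
                break
        if excluded_by is None:
            accepted.append(rec)
            out.members.append(
                (rec.variant_id, rec.beta, rec.se, rec.pvalue, f_statistic(rec.beta, rec.se))
            )
            out.selection_log.append((rec.variant_id, "clump", "kept"))
        else:
            out.selection_log.append((rec.variant_id, "clump", f"pruned-r2-with-{excluded_by}"))
    return out


def select_instruments(
    exposure: SummaryTable,
    p_threshold: float = 1e-4,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.8,
    f_min: float = 10.0,
    window_kb: float = 250.0,
    positions: Mapping[str, float] | None = None,
) -> InstrumentSet:
    """Full instrument pipeline: p-value screen, LD clump, F-statistic filter.

    Every exclusion is recorded with its stage in the selection log; an
    :class:`EmptyInstrumentError` names the stage that emptied the set.
    """
    if not (0 < p_threshold <= 1):
        raise ConfigurationError("p_threshold must lie in (0, 1]")
    if f_min < 0:
        raise ConfigurationError("f_min must be non-negative")

    log: list[tuple[str, str, str]] = []
    passed = []
    for rec in exposure:
        if rec.pvalue < p_threshold:
            passed.append(rec)
            log.append((rec.variant_id, "p_screen", "kept"))
        else:
            log.append((rec.variant_id, "p_screen", f"excluded-p={rec.pvalue:.3g}"))
    if not passed:
        raise EmptyInstrumentError("p_screen")

    screened = SummaryTable(exposure.trait_label, passed, exposure.sample_label)
    clumped = clump(screened, ld, r2_threshold, window_kb, positions)
    log.extend(clumped.selection_log)
    if len(clumped) == 0:
        raise EmptyInstrumentError("clump")

    out = InstrumentSet(exposure.trait_label, selection_log=log)
    for vid, beta, se, p, f in clumped.members:
        if f >= f_min:
            out.members.append((vid, beta, se, p, f))
            out.selection_log.append((vid, "f_filter", "kept"))
        else:
            out.selection_log.append((vid, "f_filter", f"excluded-F={f:.2f}"))
    if len(out) == 0:
        raise EmptyInstrumentError("f_filter")
    return out


def _labf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Per-variant log approximate Bayes factor (Wakefield approximation)."""
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(v / (v + w)) + z2 * w / (v + w))


def coloc_abf(
    trait1: SummaryTable,
    trait2: SummaryTable,
    priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5),
    prior_sd: tuple[float, float] = (0.15, 0.15),
) -> ColocResult:
    """Bayesian colocalization over the variants shared by two traits.

    Assumes at most one causal variant per trait in the region. Per-variant
    log approximate Bayes factors for each trait are combined over the
    possible causal configurations of the five hypotheses H0-H4, weighted by
    the per-variant priors ``p1``, ``p2`` (trait-specific causality) and
    ``p12`` (shared causality), and normalized to posterior probabilities.
    """
    p1, p2, p12 = priors
    shared = [v for v in trait1.variant_ids() if v in trait2]
    if len(shared) < 2:
        raise InsufficientRegionError("colocalization needs at least 2 shared variants")

    b1 = np.array([trait1[v].beta for v in shared])
    s1 = np.array([trait1[v].se for v in shared])
    b2 = np.array([trait2[v].beta for v in shared])
    s2 = np.array([trait2[v].se for v in shared])
    l1 = _labf(b1, s1, prior_sd[0])
    l2 = _labf(b2, s2, prior_sd[1])

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    # H3 sums over distinct causal pairs: (sum_i ABF1_i)(sum_j ABF2_j) - sum_i ABF1_i*ABF2_i
    lh3_all = lsum1 + lsum2
    with np.errstate(divide="ignore"):
        lh3 = lh3_all + np.log1p(-np.exp(np.clip(lsum12 - lh3_all, None, 0.0)))

    lterms = np.array(
        [
            0.0,
            np.log(p1) + lsum1,
            np.log(p2) + lsum2,
            np.log(p1) + np.log(p2) + lh3,
            np.log(p12) + lsum12,
        ]
    )
    post = np.exp(lterms - logsumexp(lterms))
    post = post / post.sum()
    pp = {f"H{i}": float(post[i]) for i in range(5)}
    return ColocResult(pp=pp, n_variants=len(shared), priors=(p1, p2, p12))
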