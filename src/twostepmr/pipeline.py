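"""Study orchestration: total-effect MR, mediator screens, and mediation.

The pipeline reproduces a drug-target study layout: one genetically proxied
exposure, a panel of candidate metabolite mediators, and a set of binary
disease outcomes. ``run_total_effects`` estimates the exposure's effect on
every outcome with the full sensitivity battery; ``run_two_step`` runs the
mediator screen, the mediator->outcome estimates, and the product-of-
coefficients mediation decomposition for every surviving pathway.

Every run writes a manifest (thresholds, seed, per-stage instrument counts)
so a bundle can be replayed exactly from its config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnostics import cochran_q, leave_one_out, mr_presso
from .gwas_io import SummaryTable, harmonize, read_summary_table
from .instruments import EmptyInstrumentError, InstrumentSet, LDMatrix, select_instruments
from .mediation import mediate_pathway, screen_mediators
from .mr_core import MREstimate, egger, ivw, to_odds_ratio, weighted_median

logger = logging.getLogger("twostepmr")

__all__ = ["StudyConfig", "StudyBundle", "run_total_effects", "run_two_step", "load_study_tables"]


@dataclass
class StudyConfig:
    """Thresholds and paths for one study run.

    Defaults are the analysis rules of the drug-target design: exposure
    instruments at P < 1e-4, mediator instruments at genome-wide
    significance P < 5e-8, mediator/outcome screens at P < .01, LD pruning
    at r^2 < 0.8 within 250 kb, weak instruments removed below F = 10, and
    random-effects IVW gated on Cochran-Q p < .05.
    """

    exposure_path: str | None = None
    mediator_paths: dict[str, str] = field(default_factory=dict)
    outcome_paths: dict[str, str] = field(default_factory=dict)
    ld_path: str | None = None
    exposure_p: float = 1e-4
    mediator_p: float = 5e-8
    screen_p: float = 0.01
    outcome_sig_p: float = 0.05
    r2: float = 0.8
    window_kb: float = 250.0
    f_min: float = 10.0
    het_alpha: float = 0.05
    egger_alpha: float = 0.05
    presso_sims: int = 1000
    presso_gate: str = "gated"  # "gated" (on the Egger-intercept p) or "always"
    n_boot: int = 2000
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("exposure_p", "mediator_p", "screen_p", "outcome_sig_p", "het_alpha", "egger_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 < self.r2 <= 1):
            raise ValueError("r2 must lie in (0, 1]")
        if self.f_min < 0 or self.window_kb <= 0 or self.presso_sims < 1:
            raise ValueError("invalid threshold configuration")
        if self.presso_gate not in ("gated", "always"):
            raise ValueError("presso_gate must be 'gated' or 'always'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StudyBundle:
    """In-memory results of a pipeline run."""

    results: pd.DataFrame
    diagnostics: pd.DataFrame
    loo: pd.DataFrame
    mediation: pd.DataFrame | None
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(self.results, out / "mr_results.tsv")
        _write_tsv(self.diagnostics, out / "diagnostics.tsv")
        _write_tsv(self.loo, out / "leave_one_out.tsv")
        if self.mediation is not None:
            _write_tsv(self.mediation, out / "mediation.tsv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    # fixed formatting (3 dp effects, scientific p) keeps outputs byte-stable
    formatted = df.copy()
    for col in formatted.columns:
        if formatted[col].dtype.kind == "f":
            if col.endswith(("pvalue", "_p")) or col in ("p", "q_p"):
                formatted[col] = formatted[col].map(lambda x: f"{x:.3E}" if pd.notna(x) else "")
            else:
                formatted[col] = formatted[col].map(lambda x: f"{x:.3f}" if pd.notna(x) else "")
    formatted.to_csv(path, sep="\t", index=False)


def load_study_tables(cfg: StudyConfig):
    """Load the exposure, mediator, and outcome tables named in the config."""
    if cfg.exposure_path is None:
        raise ValueError("config names no exposure table")
    exposure, _ = read_summary_table(cfg.exposure_path, trait_label="exposure")
    mediators = {
        label: read_summary_table(p, trait_label=label)[0]
        for label, p in cfg.mediator_paths.items()
    }
    outcomes = {
        label: read_summary_table(p, trait_label=label)[0]
        for label, p in cfg.outcome_paths.items()
    }
    ld = LDMatrix.read_tsv(cfg.ld_path) if cfg.ld_path else None
    return exposure, mediators, outcomes, ld


def _mr_battery(
    instruments: InstrumentSet,
    exposure: SummaryTable,
    outcome: SummaryTable,
    cfg: StudyConfig,
    seed: int,
):
    """Harmonize and run the estimator + sensitivity battery for one outcome."""
    exp_sub = exposure.subset(instruments.variant_ids)
    h, report = harmonize(exp_sub, outcome)
    primary = ivw(h, model="auto")
    out: dict = {"harmonized": h, "report": report, "ivw": primary}
    out["wm"] = (
        weighted_median(h, n_boot=cfg.n_boot, seed=seed) if h.n_snps >= 3 else None
    )
    out["egger"] = egger(h) if h.n_snps >= 3 else None
    out["q"] = cochran_q(h, primary) if h.n_snps >= 2 else None
    presso = None
    if h.n_snps >= 4:
        gate_open = cfg.presso_gate == "always" or (
            out["egger"] is not None
            and out["egger"].extras["egger_intercept_p"] < cfg.egger_alpha
        )
        if gate_open:
            presso = mr_presso(h, n_sim=cfg.presso_sims, seed=seed + 1)
    out["presso"] = presso
    out["loo"] = leave_one_out(h) if h.n_snps >= 3 else None
    return out


def _result_rows(exposure_label: str, outcome_label: str, battery) -> list[dict]:
    rows = []
    for est in (battery["ivw"], battery["egger"], battery["wm"]):
        if est is None:
            continue
        o, lo, hi = to_odds_ratio(est)
        rows.append(
            {
                "exposure": exposure_label,
                "outcome": outcome_label,
                "method": est.method,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "or": o,
                "or_ci_low": lo,
                "or_ci_high": hi,
            }
        )
    return rows


def run_total_effects(
    exposure: SummaryTable,
    outcomes: dict[str, SummaryTable],
    cfg: StudyConfig,
    ld: LDMatrix | None = None,
) -> StudyBundle:
    """Estimate the exposure's total effect on every outcome.

    Per outcome: harmonize, IVW (random-effects when Cochran-Q p < .05),
    MR-Egger, weighted median, heterogeneity and pleiotropy diagnostics,
    gated outlier testing, and leave-one-out. Failures are isolated per
    outcome and logged; the pipeline continues.
    """
    instruments = select_instruments(
        exposure,
        p_threshold=cfg.exposure_p,
        ld=ld,
        r2_threshold=cfg.r2,
        f_min=cfg.f_min,
        window_kb=cfg.window_kb,
    )
    stage_counts = _stage_counts(instruments, len(exposure))
    results, diag_rows, loo_rows = [], [], []
    failures: dict[str, str] = {}
    for i, (label, table) in enumerate(sorted(outcomes.items())):
        try:
            battery = _mr_battery(instruments, exposure, table, cfg, seed=cfg.seed + 101 * (i + 1))
        except Exception as exc:  # per-outcome isolation
            logger.warning("outcome %s failed: %s", label, exc)
            failures[label] = str(exc)
            continue
        results.extend(_result_rows(exposure.trait_label, label, battery))
        diag_rows.append(_diag_row(label, battery))
        if battery["loo"] is not None:
            for row in battery["loo"].rows:
                loo_rows.append({"outcome": label, **row})

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "instrument_counts": stage_counts,
        "instruments": instruments.variant_ids,
        "n_outcomes": len(outcomes),
        "failed_outcomes": failures,
    }
    return StudyBundle(
        results=pd.DataFrame(results),
        diagnostics=pd.DataFrame(diag_rows),
        loo=pd.DataFrame(loo_rows),
        mediation=None,
        manifest=manifest,
    )


def _stage_counts(instruments: InstrumentSet, n_input: int) -> dict:
    log = instruments.log_frame()
    counts = {"input": n_input}
    for stage in ("p_screen", "clump", "f_filter"):
        sub = log[log.stage == stage]
        counts[stage] = int((sub.verdict.str.startswith("kept")).sum())
    counts["final"] = len(instruments)
    return counts


def _diag_row(label: str, battery) -> dict:
    q = battery["q"]
    eg = battery["egger"]
    presso = battery["presso"]
    return {
        "outcome": label,
        "n_snps": battery["ivw"].n_snps,
        "q": q.q if q else np.nan,
        "q_df": q.df if q else np.nan,
        "q_p": q.pvalue if q else np.nan,
        "egger_intercept": eg.extras["egger_intercept"] if eg else np.nan,
        "egger_intercept_se": eg.extras["egger_intercept_se"] if eg else np.nan,
        "egger_intercept_p": eg.extras["egger_intercept_p"] if eg else np.nan,
        "presso_global_p": presso.global_p if presso else np.nan,
        "presso_outliers": ";".join(presso.outliers) if presso else "",
    }


def run_two_step(
    exposure: SummaryTable,
    mediators: dict[str, SummaryTable],
    outcomes: dict[str, SummaryTable],
    cfg: StudyConfig,
    ld: LDMatrix | None = None,
    total_bundle: StudyBundle | None = None,
) -> StudyBundle:
    """Two-step mediation over every (mediator, significant outcome) pair.

    Step 1 estimates the exposure's effect on each mediator with the
    exposure's instruments and screens at ``cfg.screen_p``. Outcomes whose
    primary IVW p-value passes ``cfg.outcome_sig_p`` are carried forward.
    Step 2 instruments each surviving mediator from its own summary
    statistics (``cfg.mediator_p`` screen) and estimates its effect on each
    carried outcome; ``mediate_pathway`` then decomposes each pathway.
    """
    if total_bundle is None:
        total_bundle = run_total_effects(exposure, outcomes, cfg, ld)
    ivw_rows = total_bundle.results
    ivw_rows = ivw_rows[ivw_rows.method.str.startswith("ivw")] if len(ivw_rows) else ivw_rows

    instruments = select_instruments(
        exposure, p_threshold=cfg.exposure_p, ld=ld, r2_threshold=cfg.r2,
        f_min=cfg.f_min, window_kb=cfg.window_kb,
    )

    # step 1: exposure -> mediator
    step1: dict[str, MREstimate] = {}
    for i, (label, table) in enumerate(sorted(mediators.items())):
        try:
            exp_sub = exposure.subset(instruments.variant_ids)
            h, _ = harmonize(exp_sub, table)
            step1[label] = ivw(h, model="auto")
        except Exception as exc:
            logger.warning("step-1 failed for mediator %s: %s", label, exc)
    screen = screen_mediators(step1, p_threshold=cfg.screen_p)

    sig_outcomes = (
        sorted(set(ivw_rows[ivw_rows.pvalue < cfg.outcome_sig_p].outcome))
        if len(ivw_rows)
        else []
    )

    med_rows = []
    totals = {
        row.outcome: row for row in ivw_rows.itertuples() if row.outcome in sig_outcomes
    }
    exposure_snps = set(instruments.variant_ids)
    for label in screen["selected"]:
        med_table = mediators[label]
        try:
            # the exposure's own instruments act on the mediator through the
            # exposure, so they violate the exclusion restriction of the
            # mediator->outcome step and are removed from its candidate pool
            candidates = med_table.subset(
                [v for v in med_table.variant_ids() if v not in exposure_snps]
            )
            med_inst = select_instruments(
                candidates, p_threshold=cfg.mediator_p, ld=ld,
                r2_threshold=cfg.r2, f_min=cfg.f_min, window_kb=cfg.window_kb,
            )
        except EmptyInstrumentError as exc:
            logger.warning("no instruments for mediator %s: %s", label, exc)
            continue
        for out_label in sig_outcomes:
            try:
                med_sub = med_table.subset(med_inst.variant_ids)
                h2, _ = harmonize(med_sub, outcomes[out_label])
                est2 = ivw(h2, model="auto")
                t = totals[out_label]
                total_est = MREstimate(
                    method="ivw_total", beta=t.beta, se=t.se, ci_low=t.ci_low,
                    ci_high=t.ci_high, pvalue=t.pvalue, n_snps=t.n_snps,
                )
                res = mediate_pathway(
                    total_est, step1[label], est2,
                    exposure=exposure.trait_label, mediator=label, outcome=out_label,
                    screen_p=cfg.screen_p,
                )
                med_rows.append(
                    {
                        "exposure": res.exposure,
                        "mediator": res.mediator,
                        "outcome": res.outcome,
                        "total": res.total,
                        "total_p": res.total_p,
                        "step1": res.step1,
                        "step1_p": res.step1_p,
                        "step2": res.step2,
                        "step2_p": res.step2_p,
                        "mediation": res.indirect,
                        "proportion_pct": res.proportion,
                        "proportion_ci_low": res.proportion_ci[0],
                        "proportion_ci_high": res.proportion_ci[1],
                        "valid": res.valid,
                        "invalid_reason": res.invalid_reason or "",
                    }
                )
            except Exception as exc:
                logger.warning("mediation failed for %s -> %s: %s", label, out_label, exc)

    med_df = pd.DataFrame(med_rows)
    if len(med_df):
        med_df = med_df.sort_values(
            ["outcome", "proportion_pct"],
            key=lambda s: s if s.name == "outcome" else -s.abs(),
        ).reset_index(drop=True)

    manifest = dict(total_bundle.manifest)
    manifest["mediator_screen"] = {
        "tested": len(step1),
        "selected": len(screen["selected"]),
        "positive": len(screen["positive"]),
        "negative": len(screen["negative"]),
    }
    manifest["significant_outcomes"] = sig_outcomes
    if not screen["selected"]:
        manifest["mediation_note"] = "no mediators passed the step-1 screen"
    return StudyBundle(
        results=total_bundle.results,
        diagnostics=total_bundle.diagnostics,
        loo=total_bundle.loo,
        mediation=med_df,
        manifest=manifest,
    )
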