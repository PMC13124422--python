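"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are simulated directly at the summary level under a
linear structural model: true per-SNP instrument effects gamma_j are drawn
from Normal(0, gamma_sd^2); each sample observes a noisy estimate whose
standard error follows the usual single-variant approximation
se ~ 1/sqrt(2*maf*(1-maf)*n); outcome effects follow
Gamma_j = beta_total*gamma_j + alpha_j, where alpha_j encodes the chosen
horizontal-pleiotropy regime. For mediation scenarios a third, independent
sample observes the mediator path, and the outcome carries the combined
direct-plus-indirect effect. Optional LD blocks induce correlated sampling
noise across instruments and are exported as the true LD matrix.

Defaults mirror the drug-target study the package is designed around:
10 instruments, instrument effects of about 0.015 SD per allele, and
UK-Biobank-scale sample sizes, which give instrument F-statistics in the
printed 13-72 range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_io import SummaryRecord, SummaryTable
from .instruments import LDMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_two_sample",
    "simulate_mediation_triplet",
    "simulate_coloc_region",
]

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)


@dataclass
class SimConfig:
    """Parameters of one synthetic two-sample (or three-sample) scenario."""

    n_snps: int = 10
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_sd: float = 0.015
    n_exposure: int = 344_182
    n_outcome: int = 490_089
    n_mediator: int = 121_000
    true_beta: float = 0.0          # direct exposure->outcome effect
    true_beta1: float = 0.0         # exposure->mediator
    true_beta2: float = 0.0         # mediator->outcome
    pleiotropy: str = "none"        # none | balanced | directional | inside_violating
    pleiotropy_magnitude: float = 0.0
    ld_blocks: list[tuple[int, float]] | None = None
    palindromic_fraction: float = 0.2
    outcome_case_fraction: float | None = None
    n_mediator_snps: int = 10      # instruments specific to the mediator
    delta_sd: float = 0.05         # scale of the mediator-instrument effects
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if min(self.n_exposure, self.n_outcome, self.n_mediator) < 100:
            raise ValueError("sample sizes must be at least 100")
        if self.n_snps < 1:
            raise ValueError("need at least one SNP")
        if self.pleiotropy not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if self.pleiotropy != "none" and self.pleiotropy_magnitude <= 0:
            raise ValueError("pleiotropy modes other than 'none' need a positive magnitude")
        if not (0 <= self.palindromic_fraction <= 1):
            raise ValueError("palindromic_fraction must lie in [0, 1]")
        if self.ld_blocks is not None and sum(b for b, _ in self.ld_blocks) > self.n_snps:
            raise ValueError("ld_blocks cover more SNPs than n_snps")


@dataclass
class SimTruth:
    """Generating parameters retained for parameter-recovery tests."""

    gamma: np.ndarray
    alpha: np.ndarray
    true_beta: float
    true_beta1: float = 0.0
    true_beta2: float = 0.0
    total_effect: float = 0.0
    mediated_proportion: float = field(default=float("nan"))

    @property
    def indirect_effect(self) -> float:
        return self.true_beta1 * self.true_beta2


def _per_snp_se(maf: np.ndarray, n: int, case_fraction: float | None = None) -> np.ndarray:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    if case_fraction is not None:
        # binary traits lose information with case-control imbalance
        se = se / np.sqrt(case_fraction * (1.0 - case_fraction))
    return se


def _alpha(cfg: SimConfig, gamma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP pleiotropic outcome effect, on the exposure-increasing allele.

    A "directional" shift is only meaningful in a fixed allele orientation;
    defining it relative to the allele that raises the exposure means the
    shift survives harmonization (which orients every SNP that way) instead
    of averaging out. The returned effect is therefore multiplied by
    sign(gamma) before being applied in the raw allele frame.
    """
    m = cfg.pleiotropy_magnitude
    if cfg.pleiotropy == "none":
        return np.zeros(cfg.n_snps)
    if cfg.pleiotropy == "balanced":
        return rng.normal(0.0, m, cfg.n_snps)
    if cfg.pleiotropy == "directional":
        return rng.normal(m, 0.5 * m, cfg.n_snps)
    # inside_violating: pleiotropy proportional to instrument strength
    return m * np.abs(gamma) / cfg.gamma_sd


def _ld_matrix(cfg: SimConfig, variant_ids: list[str]) -> LDMatrix:
    r = np.eye(cfg.n_snps)
    if cfg.ld_blocks:
        start = 0
        for size, rho in cfg.ld_blocks:
            block = np.full((size, size), rho)
            np.fill_diagonal(block, 1.0)
            r[start : start + size, start : start + size] = block
            start += size
    return LDMatrix(variant_ids, r)


def _correlated_noise(rng: np.random.Generator, se: np.ndarray, ld: LDMatrix) -> np.ndarray:
    z = rng.standard_normal(len(se))
    chol = np.linalg.cholesky(ld.r + 1e-12 * np.eye(len(se)))
    return se * (chol @ z)


def _alleles(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    return _alleles_n(cfg, rng, cfg.n_snps)


def _alleles_n(cfg: SimConfig, rng: np.random.Generator, n: int) -> list[tuple[str, str]]:
    pairs = []
    for _ in range(n):
        if rng.random() < cfg.palindromic_fraction:
            pairs.append(_PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))])
        else:
            pairs.append(_NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))])
    return pairs


def _table(
    label: str,
    sample_label: str,
    variant_ids: list[str],
    alleles: list[tuple[str, str]],
    beta_hat: np.ndarray,
    se: np.ndarray,
    maf: np.ndarray,
    n: int,
) -> SummaryTable:
    records = []
    for i, vid in enumerate(variant_ids):
        z = beta_hat[i] / se[i]
        records.append(
            SummaryRecord(
                variant_id=vid,
                effect_allele=alleles[i][0],
                other_allele=alleles[i][1],
                beta=float(beta_hat[i]),
                se=float(se[i]),
                pvalue=float(max(2 * stats.norm.sf(abs(z)), 1e-300)),
                eaf=float(maf[i]),
                n=n,
            )
        )
    return SummaryTable(label, records, sample_label)


def simulate_two_sample(
    cfg: SimConfig,
) -> tuple[SummaryTable, SummaryTable, SimTruth, LDMatrix]:
    """Simulate exposure and outcome summary statistics from independent samples.

    The outcome carries the total effect ``cfg.true_beta`` of the exposure
    plus any per-SNP pleiotropic effect. Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = [f"snp{i + 1:04d}" for i in range(cfg.n_snps)]
    maf = rng.uniform(*cfg.maf_range, cfg.n_snps)
    gamma = rng.normal(0.0, cfg.gamma_sd, cfg.n_snps)
    alpha = _alpha(cfg, gamma, rng)
    alleles = _alleles(cfg, rng)
    ld = _ld_matrix(cfg, ids)

    se_exp = _per_snp_se(maf, cfg.n_exposure)
    se_out = _per_snp_se(maf, cfg.n_outcome, cfg.outcome_case_fraction)
    gamma_hat = gamma + _correlated_noise(rng, se_exp, ld)
    alpha_raw = np.where(gamma < 0, -alpha, alpha)  # back to the raw allele frame
    Gamma_hat = cfg.true_beta * gamma + alpha_raw + _correlated_noise(rng, se_out, ld)

    exposure = _table("exposure", "sample1", ids, alleles, gamma_hat, se_exp, maf, cfg.n_exposure)
    outcome = _table("outcome", "sample2", ids, alleles, Gamma_hat, se_out, maf, cfg.n_outcome)
    truth = SimTruth(
        gamma=gamma,
        alpha=alpha,
        true_beta=cfg.true_beta,
        total_effect=cfg.true_beta,
        mediated_proportion=float("nan"),
    )
    return exposure, outcome, truth, ld


def simulate_mediation_triplet(
    cfg: SimConfig,
) -> tuple[SummaryTable, SummaryTable, SummaryTable, SimTruth, LDMatrix]:
    """Simulate exposure, mediator, and outcome tables from three independent samples.

    Two instrument groups are generated. Exposure instruments (``snpE*``)
    carry gamma_j on the exposure, ``true_beta1 * gamma_j`` on the mediator,
    and the total effect ``true_beta + true_beta1*true_beta2`` (plus
    pleiotropy) on the outcome, so the generator's decomposition identity
    total = direct + indirect holds exactly. Mediator instruments
    (``snpM*``) carry delta_j ~ Normal(0, delta_sd^2) on the mediator,
    ``true_beta2 * delta_j`` on the outcome, and nothing on the exposure —
    they are what a genome-wide screen of the mediator trait would find,
    and what the second MR step needs.
    """
    rng = np.random.default_rng(cfg.seed)
    ne, nm = cfg.n_snps, cfg.n_mediator_snps
    ids = [f"snpE{i + 1:04d}" for i in range(ne)] + [f"snpM{i + 1:04d}" for i in range(nm)]
    maf = rng.uniform(*cfg.maf_range, ne + nm)
    gamma = rng.normal(0.0, cfg.gamma_sd, ne)
    delta = rng.normal(0.0, cfg.delta_sd, nm)
    alpha = _alpha(cfg, gamma, rng)
    alleles = _alleles_n(cfg, rng, ne + nm)
    # LD blocks apply to the exposure instruments; mediator instruments are
    # drawn from unlinked regions
    r = np.eye(ne + nm)
    r[:ne, :ne] = _ld_matrix(cfg, ids[:ne]).r
    ld = LDMatrix(ids, r)

    total = cfg.true_beta + cfg.true_beta1 * cfg.true_beta2
    alpha_raw = np.where(gamma < 0, -alpha, alpha)  # oriented -> raw allele frame
    true_exp = np.concatenate([gamma, np.zeros(nm)])
    true_med = np.concatenate([cfg.true_beta1 * gamma, delta])
    true_out = np.concatenate([total * gamma + alpha_raw, cfg.true_beta2 * delta])

    se_exp = _per_snp_se(maf, cfg.n_exposure)
    se_med = _per_snp_se(maf, cfg.n_mediator)
    se_out = _per_snp_se(maf, cfg.n_outcome, cfg.outcome_case_fraction)

    exp_hat = true_exp + _correlated_noise(rng, se_exp, ld)
    med_hat = true_med + _correlated_noise(rng, se_med, ld)
    out_hat = true_out + _correlated_noise(rng, se_out, ld)

    exposure = _table("exposure", "sample1", ids, alleles, exp_hat, se_exp, maf, cfg.n_exposure)
    mediator = _table("mediator", "sample2", ids, alleles, med_hat, se_med, maf, cfg.n_mediator)
    outcome = _table("outcome", "sample3", ids, alleles, out_hat, se_out, maf, cfg.n_outcome)
    truth = SimTruth(
        gamma=gamma,
        alpha=alpha,
        true_beta=cfg.true_beta,
        true_beta1=cfg.true_beta1,
        true_beta2=cfg.true_beta2,
        total_effect=total,
        mediated_proportion=(
            100.0 * cfg.true_beta1 * cfg.true_beta2 / total if total != 0 else float("nan")
        ),
    )
    return exposure, mediator, outcome, truth, ld


def simulate_coloc_region(
    n_variants: int = 50,
    n1: int = 5000,
    n2: int = 5000,
    z_causal: float = 8.0,
    shared: bool = True,
    null: bool = False,
    maf: float = 0.3,
    seed: int = 0,
) -> tuple[SummaryTable, SummaryTable]:
    """Simulate a genomic region for colocalization tests.

    Each trait has one causal variant with expected z-score ``z_causal``
    (the same variant when ``shared``, distinct variants otherwise, no
    causal variant at all under ``null``); the remaining variants are pure
    noise in linkage equilibrium.
    """
    rng = np.random.default_rng(seed)
    ids = [f"snp{i + 1:04d}" for i in range(n_variants)]
    mafs = np.full(n_variants, maf)
    se1 = _per_snp_se(mafs, n1)
    se2 = _per_snp_se(mafs, n2)
    b1_true = np.zeros(n_variants)
    b2_true = np.zeros(n_variants)
    if not null:
        causal1 = 0
        causal2 = 0 if shared else n_variants // 2
        b1_true[causal1] = z_causal * se1[causal1]
        b2_true[causal2] = z_causal * se2[causal2]
    b1 = b1_true + rng.normal(0, se1)
    b2 = b2_true + rng.normal(0, se2)
    alleles = [("A", "G")] * n_variants
    t1 = _table("trait1", "sample1", ids, alleles, b1, se1, mafs, n1)
    t2 = _table("trait2", "sample2", ids, alleles, b2, se2, mafs, n2)
    return t1, t2
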