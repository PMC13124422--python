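import numpy as np
import pytest
from scipy import stats

from twostepmr import HarmonizedSet, MREstimate, SummaryRecord, SummaryTable, worked_example


def estimate_from_beta_p(beta: float, p: float, n_snps: int = 9) -> MREstimate:
    """Back out an estimate whose z-score reproduces a printed (beta, p) pair."""
    z = stats.norm.isf(p / 2)
    se = abs(beta) / z if (z > 0 and beta != 0) else 1.0
    return MREstimate(
        method="ivw_fixed",
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        pvalue=p,
        n_snps=n_snps,
    )


@pytest.fixture(scope="session")
def instruments_df():
    return worked_example.load_instruments()


@pytest.fixture(scope="session")
def screen_df():
    return worked_example.load_metabolite_screen()


@pytest.fixture(scope="session")
def mediation_df():
    return worked_example.load_mediation_pathways()


@pytest.fixture
def proportional_h():
    """Exact-proportionality toy: Gamma = 0.5 * gamma for every SNP."""
    return HarmonizedSet(
        "exposure",
        "outcome",
        ["rs1", "rs2", "rs3"],
        gamma=np.array([0.1, 0.2, 0.3]),
        se_gamma=np.array([0.01, 0.01, 0.01]),
        Gamma=np.array([0.05, 0.10, 0.15]),
        se_Gamma=np.array([0.01, 0.01, 0.01]),
    )


@pytest.fixture(scope="session")
def instruments_table(instruments_df):
    """The ten published instruments as a SummaryTable."""
    records = [
        SummaryRecord(
            variant_id=r.variant_id,
            effect_allele=r.effect_allele,
            other_allele=r.other_allele,
            beta=r.beta,
            se=r.se,
            pvalue=r.pvalue,
        )
        for r in instruments_df.itertuples()
    ]
    return SummaryTable("SGLT2 inhibition", records)


def random_harmonized(rng: np.random.Generator, n_snps: int = 8, beta: float = 0.3) -> HarmonizedSet:
    """A quick random harmonized set with heterogeneous noise for identity tests."""
    gamma = np.abs(rng.normal(0.1, 0.03, n_snps)) + 0.01
    se_g = rng.uniform(0.005, 0.02, n_snps)
    se_G = rng.uniform(0.005, 0.03, n_snps)
    Gamma = beta * gamma + rng.normal(0, se_G)
    return HarmonizedSet(
        "x", "y", [f"rs{i}" for i in range(n_snps)], gamma, se_g, Gamma, se_G
    )
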