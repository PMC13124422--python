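import itertools

import numpy as np
import pytest

from twostepmr import LDMatrix, SummaryTable, clump, coloc_abf, f_statistic, select_instruments
from twostepmr.gwas_io import SummaryRecord
from twostepmr.instruments import EmptyInstrumentError, InsufficientRegionError
from twostepmr.synthetic import simulate_coloc_region


class TestFStatistic:
    def test_matches_all_published_values_to_2dp(self, instruments_df):
        for r in instruments_df.itertuples():
            assert round(f_statistic(r.beta, r.se), 2) == pytest.approx(r.f_statistic)

    def test_null_effect_gives_zero(self):
        assert f_statistic(0.0, 1.0) == 0.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


def _candidates(pvals, label="exposure"):
    recs = [
        SummaryRecord(f"rs{i + 1}", "A", "G", 0.02, 0.004, p) for i, p in enumerate(pvals)
    ]
    return SummaryTable(label, recs)


def _ld(ids, r2_pairs, default=0.0):
    k = len(ids)
    r = np.full((k, k), np.sqrt(default))
    np.fill_diagonal(r, 1.0)
    for (a, b), r2 in r2_pairs.items():
        r[a, b] = r[b, a] = np.sqrt(r2)
    return LDMatrix(list(ids), r)


def _brute_force_clump(pvals, ids, r2, threshold):
    """Oracle: among all pairwise-admissible subsets, the one whose sorted
    p-rank tuple is lexicographically smallest (ties by id) and maximal."""
    order = sorted(range(len(ids)), key=lambda i: (pvals[i], ids[i]))
    rank = {i: k for k, i in enumerate(order)}
    admissible = []
    for size in range(len(ids), 0, -1):
        for subset in itertools.combinations(range(len(ids)), size):
            ok = all(r2[a][b] < threshold for a, b in itertools.combinations(subset, 2))
            if not ok:
                continue
            # maximality: nothing outside can be added
            if any(
                all(r2[a][b] < threshold for b in subset)
                for a in set(range(len(ids))) - set(subset)
            ):
                continue
            admissible.append(tuple(sorted(rank[i] for i in subset)))
    best = min(admissible)
    inv = {v: k for k, v in rank.items()}
    return sorted(ids[inv[r]] for r in best)


class TestClump:
    def test_mutually_correlated_block_keeps_only_best(self):
        t = _candidates([1e-8, 1e-6, 1e-5])
        ld = _ld(t.variant_ids(), {}, default=0.9)
        kept = clump(t, ld, r2_threshold=0.8)
        assert kept.variant_ids == ["rs1"]

    def test_uncorrelated_candidates_all_retained(self):
        t = _candidates([1e-8, 1e-6, 1e-5])
        kept = clump(t, _ld(t.variant_ids(), {}), r2_threshold=0.8)
        assert sorted(kept.variant_ids) == ["rs1", "rs2", "rs3"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        pvals = rng.uniform(1e-10, 1e-3, k)
        r2 = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                r2[a, b] = r2[b, a] = rng.choice([0.0, 0.3, 0.85, 0.95])
        t = _candidates(pvals)
        ids = t.variant_ids()
        ld = LDMatrix(ids, np.sqrt(r2) + np.eye(k) * 1.0)
        kept = clump(t, ld, r2_threshold=0.8)
        assert sorted(kept.variant_ids) == _brute_force_clump(pvals, ids, r2, 0.8)

    def test_invariant_to_input_row_order(self):
        rng = np.random.default_rng(5)
        pvals = list(rng.uniform(1e-9, 1e-4, 6))
        t = _candidates(pvals)
        ld = _ld(t.variant_ids(), {(0, 1): 0.9, (2, 3): 0.85, (4, 5): 0.95})
        kept1 = clump(t, ld, 0.8).variant_ids
        shuffled = SummaryTable("exposure", list(reversed(list(t))))
        kept2 = clump(shuffled, ld, 0.8).variant_ids
        assert sorted(kept1) == sorted(kept2)

    def test_window_limits_exclusion_range(self):
        t = _candidates([1e-8, 1e-6])
        ld = _ld(t.variant_ids(), {(0, 1): 0.95})
        far = {"rs1": 0, "rs2": 500_000}  # 500 kb apart: outside the window
        kept = clump(t, ld, 0.8, window_kb=250, positions=far)
        assert sorted(kept.variant_ids) == ["rs1", "rs2"]

    def test_bad_threshold_rejected(self):
        t = _candidates([1e-8])
        with pytest.raises(Exception):
            clump(t, _ld(t.variant_ids(), {}), r2_threshold=1.5)


class TestSelectInstruments:
    def test_published_rows_all_survive_default_thresholds(self, instruments_table):
        ld = LDMatrix(instruments_table.variant_ids(), np.eye(10))
        inst = select_instruments(instruments_table, p_threshold=1e-4, ld=ld, f_min=10)
        assert len(inst) == 10
        assert min(m[4] for m in inst.members) == pytest.approx(13.44, abs=0.005)

    def test_stricter_f_filter_removes_weak_instruments(self, instruments_table, instruments_df):
        ld = LDMatrix(instruments_table.variant_ids(), np.eye(10))
        inst = select_instruments(instruments_table, p_threshold=1e-4, ld=ld, f_min=15)
        expected = (instruments_df.beta / instruments_df.se) ** 2 >= 15
        assert len(inst) == int(expected.sum())
        logged = [v for v, stage, verdict in inst.selection_log if stage == "f_filter" and "excluded" in verdict]
        assert len(logged) == 10 - len(inst)

    def test_overstrict_screen_raises_at_screen_stage(self, instruments_table):
        with pytest.raises(EmptyInstrumentError) as err:
            select_instruments(instruments_table, p_threshold=1e-20)
        assert err.value.stage == "p_screen"


class TestColocAbf:
    def test_shared_causal_variant_gives_high_h4(self):
        t1, t2 = simulate_coloc_region(shared=True, n1=5000, n2=5000, z_causal=8, seed=1)
        res = coloc_abf(t1, t2)
        assert res.pp["H4"] > 0.70

    def test_distinct_causal_variants_favour_h3(self):
        t1, t2 = simulate_coloc_region(shared=False, z_causal=8, seed=2)
        res = coloc_abf(t1, t2)
        assert res.pp["H3"] == max(res.pp.values())

    def test_pure_noise_favours_h0(self):
        t1, t2 = simulate_coloc_region(null=True, seed=3)
        res = coloc_abf(t1, t2)
        assert res.pp["H0"] == max(res.pp.values())

    def test_posteriors_sum_to_one(self):
        t1, t2 = simulate_coloc_region(shared=True, seed=4)
        res = coloc_abf(t1, t2)
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_inflating_all_ses_moves_mass_toward_h0(self):
        t1, t2 = simulate_coloc_region(shared=True, z_causal=6, seed=5)

        def scaled(t, k):
            recs = [
                SummaryRecord(r.variant_id, r.effect_allele, r.other_allele,
                              r.beta, r.se * k, r.pvalue)
                for r in t
            ]
            return SummaryTable(t.trait_label, recs)

        h0 = [coloc_abf(scaled(t1, k), scaled(t2, k)).pp["H0"] for k in (1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(h0, h0[1:]))

    def test_single_shared_variant_rejected(self):
        t1, t2 = simulate_coloc_region(n_variants=1, seed=6)
        with pytest.raises(InsufficientRegionError):
            coloc_abf(t1, t2)
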