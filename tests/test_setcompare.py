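"""Comparison battery: filtering rules, Mann-Whitney against brute-force
enumeration, trimming, LD confound removal, tail enrichment and the
orchestrated pipeline's bookkeeping."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from polyfst.fst import SNPPanel
from polyfst.setcompare import (
    PipelineConfig,
    filter_panel,
    ld_confound_filter,
    mann_whitney_one_tailed,
    run_comparison,
    tail_enrichment,
    trim_outliers,
)
from polyfst.synthetic import SynthSpec, balding_nichols_panel, synth_ld_table, synth_scores


def brute_mw(cand, back):
    """Direct pairwise U and full-enumeration one-tailed p (oracle)."""
    cand, back = list(cand), list(back)
    u = sum(1.0 if c > b else 0.5 if c == b else 0.0 for c in cand for b in back)
    pooled = cand + back
    m = len(cand)
    count = total = 0
    for idx in combinations(range(len(pooled)), m):
        sub = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u_perm = sum(1.0 if c > b else 0.5 if c == b else 0.0 for c in sub for b in rest)
        total += 1
        if u_perm >= u - 1e-9:
            count += 1
    return u, count / total


def panel_from_freqs(p, n=50):
    """HWE genotype-count panel from an (n_snps, n_pops) frequency array."""
    p = np.asarray(p, dtype=float)
    ids = np.array([f"s{i}" for i in range(p.shape[0])], dtype=object)
    pops = [f"pop{j+1}" for j in range(p.shape[1])]
    return SNPPanel.from_frequencies(ids, pops, np.full_like(p, n), p)


class TestFilterPanel:
    def test_maf_rule_all_samples(self):
        """Dropped only when MAF is below threshold in every sample."""
        panel = panel_from_freqs([[0.02, 0.03, 0.04], [0.02, 0.10, 0.02], [0.5, 0.5, 0.5]])
        out, log = filter_panel(panel, PipelineConfig())
        assert list(out.snp_ids) == ["s1", "s2"]
        assert log.loc[log.snp_id == "s0", "rule"].item() == "low_maf"

    def test_maf_any_sample_switch(self):
        panel = panel_from_freqs([[0.02, 0.10, 0.02], [0.5, 0.5, 0.5]])
        out, _ = filter_panel(panel, PipelineConfig(maf_any_sample=True))
        assert list(out.snp_ids) == ["s1"]

    def test_monomorphic_only_if_everywhere(self):
        panel = panel_from_freqs([[0.0, 0.0, 0.3], [1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
        out, log = filter_panel(panel, PipelineConfig())
        assert list(out.snp_ids) == ["s0"]
        assert set(log.rule) == {"monomorphic"}

    def test_unsampled_everywhere_dropped(self, small_panel):
        counts = small_panel.counts.copy()
        counts[0] = 0.0
        panel = SNPPanel(small_panel.snp_ids, small_panel.populations, counts)
        out, log = filter_panel(panel, PipelineConfig())
        assert "rs1" not in out.snp_ids
        assert log.loc[log.snp_id == "rs1", "rule"].item() == "unsampled"


class TestMannWhitney:
    def test_shifted_pair_example(self):
        r = mann_whitney_one_tailed([2, 3], [0, 1])
        assert r.U == 4 and r.method == "exact"
        assert r.p == pytest.approx(1 / 6, abs=1e-12)

    def test_wrong_direction_shift(self):
        r = mann_whitney_one_tailed([1, 2], [3, 4])
        assert r.U == 0
        assert r.p == pytest.approx(1.0, abs=1e-12)

    def test_identical_multisets_p_at_least_half(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        r = mann_whitney_one_tailed(vals, vals)
        assert r.p >= 0.5 - 1e-9

    def test_exhaustive_agreement_small_sizes(self, rng):
        """Implementation equals brute-force enumeration for all m+n <= 12,
        including tied values (values drawn from a small integer support)."""
        for m in range(1, 12):
            for n in range(1, 13 - m):
                cand = rng.integers(0, 6, size=m).astype(float)
                back = rng.integers(0, 6, size=n).astype(float)
                u_ref, p_ref = brute_mw(cand, back)
                r = mann_whitney_one_tailed(cand, back)
                assert r.method == "exact"
                assert r.U == pytest.approx(u_ref, abs=1e-9)
                assert r.p == pytest.approx(p_ref, abs=1e-12)

    @given(st.floats(-5, 5, allow_nan=False), st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rank_invariance_under_shift(self, shift, seed):
        rng = np.random.default_rng(seed)
        cand = rng.normal(size=30)
        back = rng.normal(size=200)
        r0 = mann_whitney_one_tailed(cand, back)
        r1 = mann_whitney_one_tailed(cand + shift, back + shift)
        assert r1.U == pytest.approx(r0.U, abs=1e-9)
        assert r1.p == pytest.approx(r0.p, rel=1e-9)

    def test_large_sample_uses_tie_corrected_normal(self, rng):
        cand = rng.normal(0.3, 1, size=100)
        back = rng.normal(0, 1, size=1000)
        r = mann_whitney_one_tailed(cand, back)
        ref = stats.mannwhitneyu(cand, back, alternative="greater", method="asymptotic")
        assert r.method == "asymptotic"
        assert r.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([], [1.0])


class TestTrimOutliers:
    def test_tail_values_removed(self):
        back = np.arange(0.01, 1.001, 0.01)
        cand = pd.DataFrame({"snp_id": ["a", "b", "c"], "theta": [0.001, 0.5, 2.0]})
        core, n_top, n_bottom = trim_outliers(cand, back, PipelineConfig())
        assert core == ["b"] and n_top == 1 and n_bottom == 1

    def test_all_kept_when_interior(self):
        back = np.linspace(0, 1, 200)
        cand = pd.DataFrame({"snp_id": ["a", "b"], "theta": [0.4, 0.6]})
        core, n_top, n_bottom = trim_outliers(cand, back, PipelineConfig())
        assert core == ["a", "b"] and n_top == 0 and n_bottom == 0

    def test_small_background_rejected(self):
        cand = pd.DataFrame({"snp_id": ["a"], "theta": [0.5]})
        with pytest.raises(ValueError):
            trim_outliers(cand, np.arange(10), PipelineConfig())

    def test_exchangeable_removal_fraction(self, rng):
        """Candidates drawn from the background itself lose ~2*tail_fraction."""
        removed = trials = 0
        for _ in range(60):
            back = rng.normal(size=1000)
            cand_vals = rng.choice(back, size=100, replace=False)
            cand = pd.DataFrame({"snp_id": [f"c{i}" for i in range(100)], "theta": cand_vals})
            core, n_top, n_bottom = trim_outliers(cand, back, PipelineConfig())
            removed += n_top + n_bottom
            trials += 100
        frac = removed / trials
        se = np.sqrt(0.1 * 0.9 / trials)
        assert abs(frac - 0.10) < 3 * se


class TestLDConfound:
    @staticmethod
    def row(cand, r2, trait="type 2 diabetes", pop="pop1"):
        return {"candidate_snp": cand, "other_snp": "x", "population": pop, "r2": r2, "trait": trait}

    def test_strictly_above_threshold_removed(self):
        ld = pd.DataFrame([self.row("a", 0.85), self.row("b", 0.80)])
        kept, removed = ld_confound_filter(["a", "b", "c"], ld, PipelineConfig())
        assert removed == ["a"] and kept == ["b", "c"]

    def test_empty_table_keeps_all(self):
        kept, removed = ld_confound_filter(["a", "b"], pd.DataFrame(), PipelineConfig())
        assert kept == ["a", "b"] and removed == []

    def test_height_trait_rows_do_not_confound(self):
        ld = pd.DataFrame([self.row("a", 0.95, trait="height")])
        kept, removed = ld_confound_filter(["a"], ld, PipelineConfig())
        assert kept == ["a"]

    def test_malformed_r2_rejected(self):
        ld = pd.DataFrame([self.row("a", 1.2)])
        with pytest.raises(ValueError):
            ld_confound_filter(["a"], ld, PipelineConfig())


class TestTailEnrichment:
    @staticmethod
    def make_scores(rng, n_back=2000, n_cand=100, cand_shift=0.0):
        ids = [f"b{i}" for i in range(n_back)] + [f"c{i}" for i in range(n_cand)]
        vals = np.concatenate([rng.normal(size=n_back), rng.normal(cand_shift, 1, size=n_cand)])
        df = pd.DataFrame({"snp_id": ids, "population": "pop1", "score": vals})
        return df, [f"c{i}" for i in range(n_cand)]

    def test_null_proportion_p_one(self, rng):
        """Exactly 5 of 100 above the threshold gives binomial p = 1."""
        df, cand = self.make_scores(rng)
        cfg = PipelineConfig()
        res = tail_enrichment(df, cand, cfg)[0]
        # recompute with a forced count of 5 to pin the binomial
        assert stats.binomtest(5, 100, 0.05).pvalue == pytest.approx(1.0)
        assert 0 <= res.n_in_tail <= 100 and res.n_scored == 100

    def test_zero_hits_pvalue(self):
        p0 = stats.binomtest(0, 100, 0.05).pvalue
        df = pd.DataFrame(
            {
                "snp_id": [f"b{i}" for i in range(1000)] + [f"c{i}" for i in range(100)],
                "population": "pop1",
                "score": np.concatenate([np.random.default_rng(0).normal(size=1000), np.full(100, -10.0)]),
            }
        )
        res = tail_enrichment(df, [f"c{i}" for i in range(100)], PipelineConfig())[0]
        assert res.n_in_tail == 0 and res.proportion == 0.0
        assert res.p == pytest.approx(p0, rel=1e-12)

    def test_unscored_population_omitted(self, rng):
        df, cand = self.make_scores(rng)
        other = pd.DataFrame({"snp_id": ["b0"], "population": "pop2", "score": [0.0]})
        res = tail_enrichment(pd.concat([df, other]), cand, PipelineConfig())
        assert [e.population for e in res] == ["pop1"]

    def test_exchangeable_mean_proportion(self, rng):
        props = []
        for _ in range(50):
            df, cand = self.make_scores(rng, n_back=1000, n_cand=100)
            props.append(tail_enrichment(df, cand, PipelineConfig())[0].proportion)
        se = np.sqrt(0.05 * 0.95 / (50 * 100))
        assert abs(np.mean(props) - 0.05) < 4 * se


class TestRunComparison:
    @pytest.fixture
    def synth_inputs(self):
        spec = SynthSpec(n_background_snps=2000, n_candidate_snps=80,
                         F_background=0.08, F_candidate=0.2, seed=7)
        panel, cand = balding_nichols_panel(spec)
        ld = synth_ld_table(cand, 0.1, (0.81, 0.99), spec)
        scores = synth_scores(panel, cand, 1.0, spec)
        return panel, cand, ld, scores

    def test_bookkeeping_identity(self, synth_inputs):
        panel, cand, ld, scores = synth_inputs
        rep = run_comparison(panel, cand, ld, scores)
        assert rep.n_candidates_used == len(rep.core_set) + rep.n_removed_top + rep.n_removed_bottom
        assert set(rep.core_set) <= set(cand)
        assert set(rep.ld_removed) <= set(rep.core_set)
        assert -1 <= rep.median_background <= 1 and -1 <= rep.median_candidates <= 1

    def test_missing_candidates_logged_not_fatal(self, synth_inputs):
        panel, cand, ld, scores = synth_inputs
        rep = run_comparison(panel, cand + ["rs_not_there"], ld, scores)
        assert "rs_not_there" in rep.candidates_missing
        assert rep.n_candidates_input == len(cand) + 1

    def test_spiked_candidates_detected(self, synth_inputs):
        panel, cand, ld, scores = synth_inputs
        rep = run_comparison(panel, cand, ld, scores)
        assert rep.median_candidates > rep.median_background
        assert rep.full_test.p < 0.05

    def test_no_surviving_candidate_is_error(self, synth_inputs):
        panel, _, _, _ = synth_inputs
        with pytest.raises(ValueError, match="no candidate"):
            run_comparison(panel, ["nope1", "nope2"])

    def test_report_serializes(self, synth_inputs):
        import json
        panel, cand, ld, scores = synth_inputs
        rep = run_comparison(panel, cand, ld, scores)
        doc = json.dumps(rep.to_dict())
        assert "full_test" in doc and rep.summary()
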