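import dataclasses

import numpy as np
import pandas as pd
import pytest

from chromsig import (
    SimulationConfig,
    assign_peaks_to_genes,
    build_signatures,
    compute_scores,
    delta_expression,
    differential_contribution,
    gene_activity_matrix,
    gene_contributions,
    log_normalize_reference,
    score_timecourse,
    simulate_atac_experiment,
    simulate_reference,
    state_mean_profiles,
)
from chromsig.io import ValidationError
from chromsig.signatures import SignatureVectors, StateProfiles


def _samples(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "donor", "condition", "day", "replicate"]
    )


def _activity(arr, genes, sample_ids):
    return pd.DataFrame(
        np.asarray(arr, dtype=float),
        index=pd.Index(genes, name="gene_id"), columns=sample_ids,
    )


def _sig(genes, w_eff, w_mem):
    return SignatureVectors(
        pd.DataFrame({"w_eff": w_eff, "w_mem": w_mem},
                     index=pd.Index(genes, name="gene_id"))
    )


@pytest.fixture(scope="module")
def small_chain(small_cfg):
    """Full chain on the small planted design (raw-count activity source)."""
    peaks, genes, counts, samples, truth = simulate_atac_experiment(small_cfg)
    ref, _ = simulate_reference(small_cfg)
    pg_map = assign_peaks_to_genes(peaks, genes)
    activity = gene_activity_matrix(counts.astype(float), pg_map)
    prof = state_mean_profiles(log_normalize_reference(ref))
    universe = [g for g in prof.means.index if g in set(activity.index)]
    sig = build_signatures(prof, universe=universe)
    delta = delta_expression(activity, samples)
    return activity, samples, truth, sig, delta


class TestDeltaExpression:
    def test_single_day0_sample_has_zero_delta(self):
        samples = _samples([("s0", "d1", "A", 0, 1), ("s1", "d1", "A", 7, 1)])
        act = _activity([[5.0, 9.0]], ["g1"], ["s0", "s1"])
        delta = delta_expression(act, samples)
        assert delta.values.loc["g1", "s0"] == 0.0
        assert delta.values.loc["g1", "s1"] == 4.0

    def test_two_replicate_baseline(self):
        samples = _samples([("s0", "d1", "A", 0, 1), ("s1", "d2", "A", 0, 2)])
        act = _activity([[2.0, 4.0]], ["g1"], ["s0", "s1"])
        delta = delta_expression(act, samples)
        np.testing.assert_allclose(
            delta.values.loc["g1"].to_numpy(), [-1.0, 1.0]
        )

    def test_per_condition_baselines_are_independent(self):
        samples = _samples([
            ("a0", "d1", "A", 0, 1), ("a7", "d1", "A", 7, 1),
            ("b0", "d1", "B", 0, 1), ("b7", "d1", "B", 7, 1),
        ])
        act = _activity([[1.0, 2.0, 10.0, 12.0]], ["g1"],
                        ["a0", "a7", "b0", "b7"])
        delta = delta_expression(act, samples)
        np.testing.assert_allclose(
            delta.values.loc["g1"].to_numpy(), [0.0, 1.0, 0.0, 2.0]
        )

    def test_global_policy_uses_all_day0(self):
        samples = _samples([
            ("a0", "d1", "A", 0, 1), ("b0", "d1", "B", 0, 1),
            ("a7", "d1", "A", 7, 1),
        ])
        act = _activity([[2.0, 4.0, 9.0]], ["g1"], ["a0", "b0", "a7"])
        delta = delta_expression(act, samples, policy="global_day0")
        assert delta.values.loc["g1", "a7"] == 6.0

    def test_missing_day0_names_group(self):
        samples = _samples([("a7", "d1", "A", 7, 1), ("b0", "d1", "B", 0, 1)])
        act = _activity([[1.0, 2.0]], ["g1"], ["a7", "b0"])
        with pytest.raises(ValidationError, match="'A'"):
            delta_expression(act, samples)

    def test_matches_elementwise_oracle(self, small_chain):
        activity, samples, *_ , delta = small_chain
        day0 = samples[samples["day"] == 0]
        for cond, grp in samples.groupby("condition"):
            base = activity[day0.loc[day0["condition"] == cond, "sample_id"]
                            .tolist()].mean(axis=1)
            for s in grp["sample_id"]:
                np.testing.assert_allclose(
                    delta.values[s].to_numpy(),
                    (activity[s] - base).to_numpy(), atol=1e-9,
                )

    def test_day0_group_mean_delta_is_zero(self, small_chain):
        _, samples, *_, delta = small_chain
        day0 = samples[samples["day"] == 0]
        for cond, grp in day0.groupby("condition"):
            mean0 = delta.values[grp["sample_id"].tolist()].mean(axis=1)
            np.testing.assert_allclose(mean0.to_numpy(), 0.0, atol=1e-9)


class TestComputeScores:
    def test_inner_product_example(self):
        samples = _samples([("s0", "d1", "A", 0, 1), ("s1", "d1", "A", 7, 1)])
        act = _activity([[0.0, 1.0], [0.0, 2.0]], ["g1", "g2"], ["s0", "s1"])
        delta = delta_expression(act, samples)
        scores = compute_scores(delta, _sig(["g1", "g2"], [3.0, -1.0], [1.0, 1.0]))
        s1 = scores.set_index("sample_id")
        assert s1.loc["s1", "effector_score"] == 1.0
        assert s1.loc["s1", "memory_score"] == 3.0
        assert s1.loc["s0", "effector_score"] == 0.0

    def test_empty_gene_intersection_rejected(self):
        samples = _samples([("s0", "d1", "A", 0, 1)])
        act = _activity([[0.0]], ["g1"], ["s0"])
        delta = delta_expression(act, samples)
        with pytest.raises(ValidationError, match="no genes shared"):
            compute_scores(delta, _sig(["other"], [1.0], [1.0]))

    def test_matches_brute_force_double_loop(self, small_chain):
        *_, sig, delta = small_chain
        scores = compute_scores(delta, sig).set_index("sample_id")
        shared = delta.values.index.intersection(sig.gene_ids)
        for s in list(delta.values.columns)[::7]:
            eff = sum(
                delta.values.loc[g, s] * sig.w_eff[g] for g in shared
            )
            mem = sum(
                delta.values.loc[g, s] * sig.w_mem[g] for g in shared
            )
            assert scores.loc[s, "effector_score"] == pytest.approx(eff, rel=1e-9)
            assert scores.loc[s, "memory_score"] == pytest.approx(mem, rel=1e-9)

    def test_linearity_in_delta(self, small_chain):
        *_, sig, delta = small_chain
        base = compute_scores(delta, sig)
        scaled = dataclasses.replace(delta, values=delta.values * 2.5)
        double = compute_scores(scaled, sig)
        np.testing.assert_allclose(
            double["memory_score"].to_numpy(),
            2.5 * base["memory_score"].to_numpy(), rtol=1e-9,
        )

    def test_zero_w_mem_gives_zero_memory_scores(self, small_chain):
        """Identical effector and memory reference states null the memory score."""
        activity, samples, *_ = small_chain
        genes = list(activity.index)
        rng = np.random.default_rng(0)
        means = pd.DataFrame(
            {"naive": rng.normal(size=len(genes)),
             "effector": rng.normal(size=len(genes))}, index=genes,
        )
        means["memory"] = means["effector"]
        sig = build_signatures(StateProfiles(means, {}))
        delta = delta_expression(activity, samples)
        scores = compute_scores(delta, sig)
        np.testing.assert_allclose(scores["memory_score"].to_numpy(), 0.0, atol=1e-9)


class TestGeneContributions:
    def test_single_term(self):
        samples = _samples([("s0", "d1", "A", 0, 1), ("s1", "d1", "A", 7, 1)])
        act = _activity([[0.0, 2.0]], ["g1"], ["s0", "s1"])
        delta = delta_expression(act, samples)
        contrib = gene_contributions(delta, _sig(["g1"], [1.0], [-0.5]))
        assert contrib.c_mem.loc["g1", "s1"] == -1.0

    def test_columns_sum_to_scores(self, small_chain):
        *_, sig, delta = small_chain
        scores = compute_scores(delta, sig).set_index("sample_id")
        contrib = gene_contributions(delta, sig)
        np.testing.assert_allclose(
            contrib.c_mem.sum(axis=0).to_numpy(),
            scores["memory_score"].loc[contrib.c_mem.columns].to_numpy(),
            rtol=1e-9, atol=1e-9,
        )
        np.testing.assert_allclose(
            contrib.c_eff.sum(axis=0).to_numpy(),
            scores["effector_score"].loc[contrib.c_eff.columns].to_numpy(),
            rtol=1e-9, atol=1e-9,
        )

    def test_matches_elementwise_oracle(self, small_chain):
        *_, sig, delta = small_chain
        contrib = gene_contributions(delta, sig)
        shared = delta.values.index.intersection(sig.gene_ids)
        expected = delta.values.loc[shared].mul(sig.w_mem.loc[shared], axis=0)
        pd.testing.assert_frame_equal(contrib.c_mem, expected)


class TestDifferentialContribution:
    def test_zero_delta_difference_exact(self, small_chain):
        activity, samples, truth, sig, delta = small_chain
        contrib = gene_contributions(delta, sig)
        diff = differential_contribution(
            contrib, delta, samples, "BATF3", "BATF", 14
        )
        day14 = samples[samples["day"] == 14]
        a = day14.loc[day14["condition"] == "BATF3", "sample_id"].tolist()
        b = day14.loc[day14["condition"] == "BATF", "sample_id"].tolist()
        manual = delta.values[a].mean(axis=1) - delta.values[b].mean(axis=1)
        np.testing.assert_allclose(
            diff["delta_between_conditions"].to_numpy(),
            manual.loc[diff.index].to_numpy(), atol=1e-9,
        )

    def test_planted_memory_genes_called_high(self, small_chain):
        activity, samples, truth, sig, delta = small_chain
        contrib = gene_contributions(delta, sig)
        diff = differential_contribution(
            contrib, delta, samples, "BATF3", "BATF", 14
        )
        mem = [g for g in truth.memory_genes if g in diff.index]
        recall = (diff.loc[mem, "call"] == "high_memory").mean()
        assert recall >= 0.8

    def test_calls_partition_genes(self, small_chain):
        activity, samples, _, sig, delta = small_chain
        contrib = gene_contributions(delta, sig)
        diff = differential_contribution(
            contrib, delta, samples, "BATF3", "untransduced", 14
        )
        assert set(diff["call"]).issubset({"high_memory", "low_memory", "ns"})
        assert (diff["adjusted_p"] >= diff["p_value"] - 1e-12).all()

    def test_missing_condition_rejected(self, small_chain):
        activity, samples, _, sig, delta = small_chain
        contrib = gene_contributions(delta, sig)
        with pytest.raises(ValidationError, match="day 3"):
            differential_contribution(contrib, delta, samples, "BATF3", "BATF", 3)


class TestScoreTimecourse:
    def _scores(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "condition", "day",
                           "effector_score", "memory_score"],
        )

    def test_pair_mean_and_sem(self):
        tc = score_timecourse(self._scores([
            ("s0", "A", 7, 1.0, 1.0), ("s1", "A", 7, 3.0, 3.0),
        ]))
        row = tc.iloc[0]
        assert row["effector_mean"] == 2.0
        assert row["effector_sem"] == pytest.approx(1.0)

    def test_singleton_group_sem_missing(self):
        tc = score_timecourse(self._scores([("s0", "A", 0, 1.0, 2.0)]))
        assert np.isnan(tc.iloc[0]["memory_sem"])
        assert tc.iloc[0]["n"] == 1

    def test_matches_groupby_oracle(self, small_chain):
        *_, sig, delta = small_chain
        scores = compute_scores(delta, sig)
        tc = score_timecourse(scores).set_index(["condition", "day"])
        for (cond, day), grp in scores.groupby(["condition", "day"]):
            vals = grp["memory_score"].to_numpy()
            assert tc.loc[(cond, day), "memory_mean"] == pytest.approx(vals.mean())
            assert tc.loc[(cond, day), "memory_sem"] == pytest.approx(
                vals.std(ddof=1) / np.sqrt(len(vals))
            )

    def test_planted_trajectories_recovered(self, small_chain):
        """Memory rises monotonically only in the planted condition; effector
        peaks at day 7 in every condition."""
        *_, sig, delta = small_chain
        scores = compute_scores(delta, sig)
        tc = score_timecourse(scores).set_index(["condition", "day"])
        for cond in ("untransduced", "BATF", "BATF3"):
            m0, m7, m14 = (tc.loc[(cond, d), "memory_mean"] for d in (0, 7, 14))
            e0, e7, e14 = (tc.loc[(cond, d), "effector_mean"] for d in (0, 7, 14))
            assert e7 > e0 and e7 > e14
            if cond == "BATF3":
                assert m0 < m7 < m14
            else:
                assert not (m0 < m7 < m14)
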