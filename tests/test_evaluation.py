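"""Ground-truth labeling, confusion/accuracy, alpha diversity, recovery."""

import numpy as np
import pandas as pd
import pytest

from contambench.community_data import AsvTable, ExpectedReference, ValidationError
from contambench.evaluation import (
    alpha_diversity,
    composition_recovery,
    confusion_and_accuracy,
    dataset_confusion,
    expected_alpha,
    label_ground_truth,
    percent_contaminants,
    sample_summary,
)
from contambench.removal_methods import RemovalResult


def binary_result(kept_frame):
    return RemovalResult(
        method_name="test",
        params={},
        retained_fraction=kept_frame.astype(float),
        kept=kept_frame.astype(bool),
    )


class TestLabeling:
    def test_reference_membership(self):
        table = AsvTable.from_arrays(["a", "b", "c"], ["s"], [[1], [2], [3]])
        labels = label_ground_truth(table, ExpectedReference(("a", "b")))
        assert labels.to_dict() == {"a": "mock", "b": "mock", "c": "contaminant"}

    def test_reference_superset_all_mock(self):
        table = AsvTable.from_arrays(["a"], ["s"], [[1]])
        labels = label_ground_truth(table, ExpectedReference(("a", "b", "c")))
        assert (labels == "mock").all()


class TestPercentContaminants:
    def test_permille(self):
        table = AsvTable.from_arrays(["m", "c"], ["s"], [[999], [1]])
        labels = pd.Series({"m": "mock", "c": "contaminant"})
        assert percent_contaminants(table, labels)["s"] == pytest.approx(0.1)

    def test_all_contaminant_and_ratio(self):
        table = AsvTable.from_arrays(["c", "m"], ["s1", "s2"], [[50, 80], [0, 20]])
        labels = pd.Series({"c": "contaminant", "m": "mock"})
        pct = percent_contaminants(table, labels)
        assert pct["s1"] == 100.0
        assert pct["s2"] == pytest.approx(80.0)

    def test_zero_read_sample_missing(self):
        table = AsvTable.from_arrays(["a"], ["s", "empty"], [[5, 0]])
        labels = pd.Series({"a": "mock"})
        pct = percent_contaminants(table, labels)
        assert np.isnan(pct["empty"])

    def test_clean_simulation_is_zero_everywhere(self):
        from contambench.synthetic_data import SimulationConfig, simulate_dilution_series

        cfg = SimulationConfig(contaminant_template=0.0, crosstalk_rate=0.0,
                               negative_control_mock_leak=0.5, seed=2)
        exp = simulate_dilution_series(cfg)
        labels = label_ground_truth(exp.table, exp.reference)
        pct = percent_contaminants(
            exp.table.subset_samples(exp.dilution_sample_ids), labels
        )
        assert (pct == 0).all()

    def test_empty_reference_means_all_contaminant(self, tiny_table):
        labels = pd.Series("contaminant", index=tiny_table.asv_ids)
        pct = percent_contaminants(tiny_table, labels)
        assert (pct == 100.0).all()


class TestConfusion:
    def test_hand_counted_example(self):
        # 8 contaminants (6 removed) + 2 mock (2 kept) -> accuracy 0.8
        asvs = [f"c{i}" for i in range(8)] + ["m1", "m2"]
        counts = np.ones((10, 1), dtype=int)
        table = AsvTable.from_arrays(asvs, ["s"], counts)
        labels = pd.Series(
            ["contaminant"] * 8 + ["mock"] * 2, index=asvs
        )
        kept = pd.DataFrame(
            {"s": [False] * 6 + [True] * 2 + [True, True]}, index=asvs
        )
        summary = confusion_and_accuracy(binary_result(kept), labels, table)
        row = summary.loc["s"]
        assert (row["tp"], row["fn"], row["tn"], row["fp"]) == (6, 2, 2, 0)
        assert row["accuracy"] == pytest.approx(0.8)
        assert row["pct_contaminant_correct"] == pytest.approx(75.0)
        assert row["pct_mock_misclassified"] == 0.0

    def test_perfect_method(self):
        table = AsvTable.from_arrays(["c", "m"], ["s"], [[3], [4]])
        labels = pd.Series({"c": "contaminant", "m": "mock"})
        kept = pd.DataFrame({"s": [False, True]}, index=["c", "m"])
        summary = confusion_and_accuracy(binary_result(kept), labels, table)
        assert summary.loc["s", "accuracy"] == 1.0

    def test_no_contaminants_present_scores_one(self):
        table = AsvTable.from_arrays(["m1", "m2", "c"], ["s"], [[3], [4], [0]])
        labels = pd.Series({"m1": "mock", "m2": "mock", "c": "contaminant"})
        kept = pd.DataFrame({"s": [True, True, True]}, index=["m1", "m2", "c"])
        summary = confusion_and_accuracy(binary_result(kept), labels, table)
        assert summary.loc["s", "accuracy"] == 1.0  # absent ASVs not counted
        assert np.isnan(summary.loc["s", "pct_contaminant_correct"])

    def test_missing_call_for_present_asv_rejected(self):
        table = AsvTable.from_arrays(["a", "b"], ["s"], [[1], [1]])
        labels = pd.Series({"a": "mock", "b": "contaminant"})
        kept = pd.DataFrame({"s": [True]}, index=["a"])
        with pytest.raises(ValidationError, match="no call"):
            confusion_and_accuracy(binary_result(kept), labels, table)

    def test_matches_bruteforce_recount_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_asv, n_samp = rng.integers(2, 12), rng.integers(1, 5)
            asvs = [f"a{i}" for i in range(n_asv)]
            samples = [f"s{j}" for j in range(n_samp)]
            counts = rng.integers(0, 5, (n_asv, n_samp))
            counts[0] += 1
            table = AsvTable.from_arrays(asvs, samples, counts)
            labels = pd.Series(
                rng.choice(["mock", "contaminant"], n_asv), index=asvs
            )
            kept = pd.DataFrame(
                rng.random((n_asv, n_samp)) < 0.5, index=asvs, columns=samples
            )
            summary = confusion_and_accuracy(binary_result(kept), labels, table)
            for s in samples:
                tp = fn = tn = fp = 0
                for a in asvs:
                    if counts[asvs.index(a), samples.index(s)] == 0:
                        continue
                    contam = labels[a] == "contaminant"
                    k = bool(kept.at[a, s])
                    tp += contam and not k
                    fn += contam and k
                    tn += (not contam) and k
                    fp += (not contam) and not k
                row = summary.loc[s]
                assert (row["tp"], row["fn"], row["tn"], row["fp"]) == (tp, fn, tn, fp)
                if tp + fn + tn + fp:
                    assert row["accuracy"] == pytest.approx(
                        (tp + tn) / (tp + fn + tn + fp)
                    )

    def test_dataset_wide_variant_counts_each_asv_once(self):
        table = AsvTable.from_arrays(
            ["c1", "m1"], ["s1", "s2"], [[4, 5], [6, 7]]
        )
        labels = pd.Series({"c1": "contaminant", "m1": "mock"})
        kept = pd.DataFrame(
            {"s1": [False, True], "s2": [False, True]}, index=["c1", "m1"]
        )
        ds = dataset_confusion(binary_result(kept), labels, table)
        assert (ds["tp"], ds["fn"], ds["tn"], ds["fp"]) == (1, 0, 1, 0)
        assert ds["accuracy"] == 1.0


class TestAlphaDiversity:
    def test_uniform_closed_forms(self):
        counts = [10, 10, 10, 10]
        assert alpha_diversity(counts, "observed") == 4
        assert alpha_diversity(counts, "shannon") == pytest.approx(np.log(4), abs=1e-12)
        assert alpha_diversity(counts, "shannon", shannon_base=2) == pytest.approx(
            2.0, abs=1e-12
        )
        assert alpha_diversity(counts, "inv_simpson") == pytest.approx(4.0, abs=1e-12)

    def test_hand_computed_three_taxa(self):
        # p = (0.5, 0.25, 0.25): H = 1.5 ln 2 ~ 1.039721, 1/sum p^2 = 8/3
        counts = [2, 1, 1]
        assert alpha_diversity(counts, "shannon") == pytest.approx(1.039721, abs=1e-6)
        assert alpha_diversity(counts, "inv_simpson") == pytest.approx(8 / 3, abs=1e-12)

    def test_single_taxon(self):
        assert alpha_diversity([7], "observed") == 1
        assert alpha_diversity([7], "shannon") == 0.0
        assert alpha_diversity([7], "inv_simpson") == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            alpha_diversity([0, 0], "shannon")

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValidationError, match="unknown metric"):
            alpha_diversity([1], "chao1")

    def test_matches_skbio_and_bounds_on_random_vectors(self):
        import skbio.diversity.alpha as ska

        rng = np.random.default_rng(1)
        for _ in range(200):
            counts = rng.integers(0, 50, size=rng.integers(2, 30))
            counts[rng.integers(len(counts))] += 1
            observed = alpha_diversity(counts, "observed")
            shannon = alpha_diversity(counts, "shannon")
            inv_simpson = alpha_diversity(counts, "inv_simpson")
            assert observed == ska.sobs(counts)
            assert shannon == pytest.approx(ska.shannon(counts, base=np.e), abs=1e-10)
            assert inv_simpson == pytest.approx(ska.enspie(counts), abs=1e-8)
            assert inv_simpson <= observed + 1e-12
            assert shannon <= np.log(observed) + 1e-12


class TestExpectedAlpha:
    def test_identity_when_sample_is_all_expected(self):
        table = AsvTable.from_arrays(["a", "b"], ["s"], [[5], [5]])
        ref = ExpectedReference(("a", "b"))
        assert expected_alpha(table, ref, "observed")["s"] == 2
        assert expected_alpha(table, ref, "shannon")["s"] == pytest.approx(np.log(2))

    def test_invariant_to_added_contaminants(self):
        ref = ExpectedReference(("a", "b"))
        clean = AsvTable.from_arrays(["a", "b"], ["s"], [[6], [3]])
        dirty = AsvTable.from_arrays(["a", "b", "x"], ["s"], [[6], [3], [100]])
        for metric in ("observed", "shannon", "inv_simpson"):
            assert expected_alpha(dirty, ref, metric)["s"] == pytest.approx(
                expected_alpha(clean, ref, metric)["s"]
            )

    def test_no_expected_reads_is_missing(self):
        table = AsvTable.from_arrays(["x"], ["s"], [[10]])
        ref = ExpectedReference(("a",))
        assert np.isnan(expected_alpha(table, ref, "observed")["s"])


class TestCompositionRecovery:
    def test_perfect_correction_zero_error(self):
        truth = pd.Series({"a": 0.5, "b": 0.5})
        corrected = AsvTable.from_arrays(["a", "b"], ["s"], [[50], [50]])
        labels = pd.Series({"a": "mock", "b": "mock"})
        report = composition_recovery(corrected, truth, labels)
        assert report.loc["s", "l1_error"] == pytest.approx(0.0, abs=1e-12)

    def test_removed_expected_asv_hand_arithmetic(self):
        # even 5-taxon truth; method removed taxon e (share 0.2):
        # |0 - 0.2| + 4 * |0.25 - 0.2| = 0.4
        ids = ["a", "b", "c", "d", "e"]
        truth = pd.Series(0.2, index=ids)
        corrected = AsvTable.from_arrays(ids, ["s"], [[10], [10], [10], [10], [0]])
        labels = pd.Series("mock", index=ids)
        report = composition_recovery(corrected, truth, labels)
        assert report.loc["s", "l1_error"] == pytest.approx(0.4, abs=1e-12)

    def test_uncorrected_half_contaminated_sample(self):
        # 50% contaminant reads, even 2-taxon truth: each expected share
        # halves (sums to 0.5) + contaminant mass 0.5 -> L1 = 1.0
        truth = pd.Series({"a": 0.5, "b": 0.5})
        corrected = AsvTable.from_arrays(
            ["a", "b", "x"], ["s"], [[25], [25], [50]]
        )
        labels = pd.Series({"a": "mock", "b": "mock", "x": "contaminant"})
        report = composition_recovery(corrected, truth, labels)
        assert report.loc["s", "l1_error"] == pytest.approx(1.0, abs=1e-12)
        assert report.loc["s", "contaminant_share"] == pytest.approx(0.5)

    def test_zero_sum_sample_rejected(self):
        truth = pd.Series({"a": 1.0})
        corrected = AsvTable.from_arrays(["a"], ["s"], [[0]])
        with pytest.raises(ValidationError, match="zero reads"):
            composition_recovery(corrected, truth, pd.Series({"a": "mock"}))


def test_sample_summary_matches_components(default_experiment):
    exp = default_experiment
    labels = label_ground_truth(exp.table, exp.reference)
    summary = sample_summary(exp.table, labels)
    assert (summary["n_reads"] == exp.table.sample_sums()).all()
    assert (summary["n_unique_asvs"] == (exp.table.frame > 0).sum(axis=0)).all()
    pct = percent_contaminants(exp.table, labels)
    assert np.allclose(summary["pct_contaminants"], pct)
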