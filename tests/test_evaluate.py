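import numpy as np
import pytest

import enhseq as e
from enhseq.evaluate import equalize


def auc_oracle(scores, labels):
    """Exhaustive positive x negative pair counting; ties score one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAccuracy:
    def test_perfect_and_inverted(self):
        assert e.accuracy([0.9, 0.1], [1, 0]) == 1.0
        assert e.accuracy([0.9, 0.1], [0, 1]) == 0.0

    def test_threshold_tie_counts_positive(self):
        assert e.accuracy([0.5], [1]) == 1.0
        assert e.accuracy([0.5], [0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            e.accuracy([0.5, 0.5], [1])


class TestAuc:
    def test_perfect_separation(self):
        assert e.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_half_concordant_pairs(self):
        # pairs (0.9,0.4) (0.9,0.6) concordant; (0.3,0.4) (0.3,0.6) not
        assert e.auc([0.9, 0.4, 0.6, 0.3], [1, 0, 0, 1]) == 0.5

    def test_all_ties_give_half(self):
        assert e.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            e.auc([0.1, 0.9], [1, 1])

    def test_matches_pair_counting_oracle_exhaustively(self, rng):
        for trial in range(200):
            n = int(rng.integers(2, 21))
            labels = np.zeros(n, dtype=int)
            labels[:int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if len(np.unique(labels)) < 2:
                continue
            # discretized scores so ties actually occur
            scores = rng.integers(0, 5, size=n) / 4.0
            assert e.auc(scores, labels) == pytest.approx(
                auc_oracle(scores, labels))


class TestRoc:
    def test_monotone_and_anchored(self, rng):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        fpr, tpr = e.roc_points(scores, labels)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert fpr[0] == 0 and tpr[0] == 0
        assert fpr[-1] == 1 and tpr[-1] == 1


class TestEqualize:
    def test_downsamples_larger_side(self, rng):
        a, b = equalize(list(range(10)), list(range(4)), rng)
        assert len(a) == len(b) == 4
        assert set(a) <= set(range(10))


def _tiny_eval_inputs(sim, data_a):
    """Small positive/negative segment sets for fast CV runs."""
    return data_a.positives, data_a.negative.segments


class TestRunSingleType:
    def test_planted_signal_recovered_and_report_consistent(self, small_sim,
                                                            small_data):
        pos, neg = _tiny_eval_inputs(small_sim, small_data)
        report = e.run_single_type(
            pos, neg, small_data.dicts,
            e.ModelConfig(arch="mlp", seed=0), n_folds=5, seed=0,
            cell_type="typeA")
        assert report.mean_accuracy >= 0.9
        assert len(report.per_fold) == 5
        for a, u in report.per_fold:
            assert 0 <= a <= 1 and 0 <= u <= 1
        assert report.mean_accuracy == pytest.approx(
            np.mean([a for a, _ in report.per_fold]))
        assert report.mean_auc == pytest.approx(
            np.mean([u for _, u in report.per_fold]))

    def test_background_vs_background_strict_mode_is_chance(self, small_sim,
                                                            small_data):
        # "positives" drawn from background: no signal; with per-fold
        # (training-only) dictionaries accuracy sits at chance
        ctrl = small_data.control.segments
        neg = small_data.negative.segments
        report = e.run_single_type(
            ctrl[:30], neg[:30], None,
            e.ModelConfig(arch="mlp", seed=1), n_folds=5, seed=1,
            ks=e.KSet((5, 7)), dictionary_scope="train", controls=ctrl[30:])
        assert abs(report.mean_accuracy - 0.5) <= 0.25  # tiny n, wide band

    def test_all_positive_dictionaries_leak_membership(self, small_sim,
                                                       small_data):
        # with dictionaries built from ALL positives, held-out positives are
        # recognizable by their own memorized long k-mers even without motifs
        ctrl = small_data.control.segments
        neg = small_data.negative.segments
        dicts = e.build_dictionaries([s.core for s in ctrl[:30]],
                                     [s.core for s in ctrl[30:]], ks=(5, 7, 9))
        report = e.run_single_type(
            ctrl[:30], neg[:30], dicts,
            e.ModelConfig(arch="mlp", seed=1), n_folds=5, seed=1,
            ks=e.KSet((5, 7, 9)))
        assert report.mean_accuracy > 0.7

    def test_input_order_invariance(self, small_sim, small_data):
        pos, neg = _tiny_eval_inputs(small_sim, small_data)
        config = e.ModelConfig(arch="mlp", seed=3, max_epochs=5)
        r1 = e.run_single_type(pos, neg, small_data.dicts, config,
                               n_folds=5, seed=3)
        r2 = e.run_single_type(pos[::-1], neg[::-1], small_data.dicts, config,
                               n_folds=5, seed=3)
        assert r1.mean_accuracy == pytest.approx(r2.mean_accuracy)
        assert r1.mean_auc == pytest.approx(r2.mean_auc)


class TestRunPairwise:
    def test_disjoint_vocabularies_discriminated(self, small_sim, small_data):
        data_b = e.prepare_from_sim(small_sim, "typeB", seed=5)
        result = e.run_pairwise(
            small_data.positives, data_b.positives,
            small_data.dicts, data_b.dicts,
            e.ModelConfig(arch="mlp", seed=0), n_folds=5, seed=0,
            cell_a="typeA", cell_b="typeB")
        assert result.averaged_accuracy >= 0.9
        assert result.averaged_accuracy == pytest.approx(np.mean(
            [r.mean_accuracy for r in result.per_direction]))
        assert len(result.per_direction) == 2

    def test_both_dictionaries_feature_mode(self, small_sim, small_data):
        data_b = e.prepare_from_sim(small_sim, "typeB", seed=5)
        result = e.run_pairwise(
            small_data.positives, data_b.positives,
            small_data.dicts, data_b.dicts,
            e.ModelConfig(arch="mlp", seed=4, max_epochs=8), n_folds=5,
            seed=4, cell_a="typeA", cell_b="typeB", feature_channels="both")
        assert result.averaged_accuracy >= 0.9  # 8-channel features also work
        with pytest.raises(ValueError):
            e.run_pairwise(
                small_data.positives, data_b.positives, None, None,
                e.ModelConfig(arch="mlp"), dictionary_scope="train",
                controls_a=small_data.control.segments,
                controls_b=data_b.control.segments, feature_channels="both")

    def test_swap_symmetry(self, small_sim, small_data):
        data_b = e.prepare_from_sim(small_sim, "typeB", seed=5)
        config = e.ModelConfig(arch="mlp", seed=2, max_epochs=5)
        ab = e.run_pairwise(small_data.positives, data_b.positives,
                            small_data.dicts, data_b.dicts, config,
                            n_folds=5, seed=2, cell_a="A", cell_b="B")
        ba = e.run_pairwise(data_b.positives, small_data.positives,
                            data_b.dicts, small_data.dicts, config,
                            n_folds=5, seed=2, cell_a="B", cell_b="A")
        assert ab.averaged_accuracy == pytest.approx(ba.averaged_accuracy)
        assert ab.averaged_auc == pytest.approx(ba.averaged_auc)


class TestSubsampleRepeat:
    def test_single_repeat_reduces_to_single_type_run(self, small_sim,
                                                      small_data):
        pos, neg = _tiny_eval_inputs(small_sim, small_data)
        config = e.ModelConfig(arch="mlp", seed=0, max_epochs=5)
        reports, summary = e.subsample_repeat(
            pos, neg, small_data.dicts, config, n_per_class=30, repeats=1,
            n_folds=5, seed=0)
        assert len(reports) == 1
        assert summary["mean_accuracy"] == pytest.approx(reports[0].mean_accuracy)

    def test_distinct_repeats_and_summary_mean(self, small_sim, small_data):
        pos, neg = _tiny_eval_inputs(small_sim, small_data)
        config = e.ModelConfig(arch="mlp", seed=0, max_epochs=3)
        reports, summary = e.subsample_repeat(
            pos, neg, small_data.dicts, config, n_per_class=20, repeats=3,
            n_folds=4, seed=7)
        assert len(reports) == 3
        assert summary["mean_accuracy"] == pytest.approx(
            np.mean([r.mean_accuracy for r in reports]))
        # distinct repeat seeds draw distinct subsample index sets
        from enhseq.evaluate import _downsample
        subsets = {
            tuple(_downsample(list(range(60)), 20,
                              np.random.default_rng(seed)))
            for seed in range(3)
        }
        assert len(subsets) == 3

    def test_report_serialization(self, tmp_path, small_sim, small_data):
        pos, neg = _tiny_eval_inputs(small_sim, small_data)
        report = e.run_single_type(
            pos[:20], neg[:20], small_data.dicts,
            e.ModelConfig(arch="mlp", seed=0, max_epochs=3), n_folds=4, seed=0)
        report.save(tmp_path / "r.json", tmp_path / "roc.tsv")
        import json
        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["mean_accuracy"] == pytest.approx(report.mean_accuracy)
        roc_lines = (tmp_path / "roc.tsv").read_text().splitlines()
        assert roc_lines[0] == "fpr\ttpr"
        assert len(roc_lines) > 2
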