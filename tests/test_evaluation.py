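import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicenas.cell_network import NetworkConfig
from splicenas.evaluation import (
    TrainConfig,
    compute_metrics,
    evaluate_model,
    load_model,
    predict_scores,
    save_model,
    train_fixed,
    trim_for_transfer,
    write_curve_tsv,
    write_metrics_tsv,
)
from splicenas.seqdata import DNASequence, encode_dataset, split_dataset
from splicenas.synthetic import SyntheticConfig, default_motif, generate_splice_dataset


def _pairwise_auc(labels, scores):
    """Brute-force AUC oracle: P(pos outranks neg), ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_confusion_arithmetic(self):
        # (TP=90, FN=10, TN=80, FP=20) by construction
        labels = [1] * 90 + [1] * 10 + [0] * 80 + [0] * 20
        scores = [0.9] * 90 + [0.1] * 10 + [0.2] * 80 + [0.8] * 20
        m = compute_metrics(labels, scores)
        assert m.confusion == (90, 20, 80, 10)
        assert m.accuracy == pytest.approx(0.85)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.80)
        # oracle: 2 * precision * recall / (precision + recall)
        precision = 90 / 110
        assert m.f_score == pytest.approx(2 * precision * 0.9 / (precision + 0.9))

    def test_perfect_classifier(self):
        m = compute_metrics([1, 1, 0, 0], [1.0, 1.0, 0.0, 0.0])
        for name, v in m.as_dict().items():
            assert v == pytest.approx(1.0), name

    def test_ordered_pair_auc(self):
        assert compute_metrics([1, 0], [0.9, 0.1]).auc == pytest.approx(1.0)

    def test_tie_convention(self):
        assert compute_metrics([1, 0], [0.5, 0.5]).auc == pytest.approx(0.5)

    def test_all_identical_scores(self):
        m = compute_metrics([1, 0, 1, 0], [0.3] * 4)
        assert m.auc == pytest.approx(0.5)

    def test_auc_against_pairwise_oracle_seeded(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]  # both classes present
        scores = np.round(rng.random(50), 2)  # rounding induces ties
        m = compute_metrics(labels, scores)
        assert m.auc == pytest.approx(_pairwise_auc(labels, scores), abs=1e-12)

    @given(st.integers(2, 200), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_auc_pairwise_property(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(n), 1)
        m = compute_metrics(labels, scores)
        assert m.auc == pytest.approx(_pairwise_auc(labels, scores), abs=1e-9)

    def test_roc_passes_through_corners(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        m = compute_metrics(labels, rng.random(30))
        assert m.roc_points[0] == (0.0, 0.0)
        assert m.roc_points[-1] == (1.0, 1.0)

    def test_metrics_in_unit_interval(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        m = compute_metrics(labels, rng.random(40))
        for v in m.as_dict().values():
            assert 0.0 <= v <= 1.0

    def test_single_class_auc_undefined(self):
        with pytest.warns(UserWarning, match="single-class"):
            m = compute_metrics([1, 1, 1], [0.9, 0.8, 0.2])
        assert math.isnan(m.auc)
        assert "auc" in m.undefined
        assert m.accuracy == pytest.approx(2 / 3)  # other metrics still returned

    def test_degenerate_denominator_not_silent(self):
        with pytest.warns(UserWarning):
            m = compute_metrics([0, 0], [0.1, 0.2])
        assert math.isnan(m.sensitivity)
        assert "sensitivity" in m.undefined

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            compute_metrics([1, 0], [0.5])

    def test_threshold_configurable(self):
        m = compute_metrics([1, 0], [0.45, 0.35], threshold=0.4)
        assert m.confusion == (1, 0, 1, 0)


class TestTrimForTransfer:
    def test_602_to_141(self):
        rng = np.random.default_rng(0)
        bases = "".join("ACGT"[i] for i in rng.integers(0, 4, 602))
        bases = bases[:300] + "GT" + bases[302:]
        seq = DNASequence("s", bases, 1)
        out = trim_for_transfer(seq, source_site_offset=300, target_length=141,
                                target_site_offset=70)
        assert len(out.bases) == 141
        # oracle: window starts at 300 - 70 = 230
        assert out.bases == bases[230:371]
        assert out.bases[70:72] == "GT"

    def test_identity_trim(self):
        seq = DNASequence("s", "ACGTACGT", 0)
        out = trim_for_transfer(seq, 4, 8, 4)
        assert out.bases == seq.bases

    def test_out_of_bounds_no_padding(self):
        seq = DNASequence("s", "A" * 100, 1)
        with pytest.raises(ValueError, match="padding"):
            trim_for_transfer(seq, source_site_offset=10, target_length=50,
                              target_site_offset=40)

    @given(st.integers(50, 200), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_window_is_substring_of_input(self, n, seed):
        rng = np.random.default_rng(seed)
        bases = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        seq = DNASequence("s", bases, 1)
        src = int(rng.integers(0, n))
        tlen = int(rng.integers(1, n + 1))
        toff = int(rng.integers(0, tlen))
        start = src - toff
        if start < 0 or start + tlen > n:
            with pytest.raises(ValueError):
                trim_for_transfer(seq, src, tlen, toff)
        else:
            out = trim_for_transfer(seq, src, tlen, toff)
            assert len(out.bases) == tlen
            assert out.bases in bases
            assert out.bases[toff] == bases[src]


def _tiny_data(n=60, length=12, seed=0):
    motif = default_motif(length, flank=2)
    seqs = generate_splice_dataset(
        SyntheticConfig(n=n, length=length, motif=motif, decoy_rate=0.0, seed=seed)
    )
    return split_dataset(encode_dataset(seqs), seed=seed)


class TestTrainFixed:
    net_cfg = NetworkConfig(layers=1, init_channels=4, input_length=12)

    def test_zero_epochs_keeps_init(self, sep3_genotype):
        data = _tiny_data()
        model = train_fixed(sep3_genotype, data, self.net_cfg,
                            TrainConfig(epochs=0, batch_size=20, seed=5))
        fresh = train_fixed(sep3_genotype, data, self.net_cfg,
                            TrainConfig(epochs=0, batch_size=20, seed=5))
        from autograd.misc import flatten

        assert np.array_equal(flatten(model.params)[0], flatten(fresh.params)[0])
        assert model.history == []

    def test_deterministic(self, sep3_genotype):
        data = _tiny_data()
        cfg = TrainConfig(epochs=1, batch_size=20, seed=5)
        m1 = train_fixed(sep3_genotype, data, self.net_cfg, cfg)
        m2 = train_fixed(sep3_genotype, data, self.net_cfg, cfg)
        assert m1.history == m2.history

    def test_training_changes_params_and_logs(self, sep3_genotype):
        data = _tiny_data()
        model = train_fixed(sep3_genotype, data, self.net_cfg,
                            TrainConfig(epochs=2, batch_size=20, seed=5))
        assert len(model.history) == 2
        assert all(np.isfinite(l) for _, l, _ in model.history)

    def test_save_load_roundtrip(self, sep3_genotype, tmp_path):
        data = _tiny_data()
        model = train_fixed(sep3_genotype, data, self.net_cfg,
                            TrainConfig(epochs=1, batch_size=20, seed=5))
        save_model(model, tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        x, _ = data.arrays("test")
        assert np.allclose(predict_scores(model, x), predict_scores(loaded, x))


class TestEvaluateModel:
    def test_metrics_from_tiny_model(self, sep3_genotype):
        data = _tiny_data()
        model = train_fixed(sep3_genotype, data, TestTrainFixed.net_cfg,
                            TrainConfig(epochs=1, batch_size=20, seed=5))
        m = evaluate_model(model, data.test)
        assert 0.0 <= m.accuracy <= 1.0
        assert 0.0 <= m.auc <= 1.0

    def test_empty_test_set_rejected(self, sep3_genotype):
        data = _tiny_data()
        model = train_fixed(sep3_genotype, data, TestTrainFixed.net_cfg,
                            TrainConfig(epochs=0, batch_size=20, seed=5))
        with pytest.raises(ValueError, match="empty"):
            evaluate_model(model, [])


class TestReports:
    def test_metrics_tsv(self, tmp_path):
        m = compute_metrics([1, 0], [0.9, 0.1])
        write_metrics_tsv([m, m], tmp_path / "m.tsv")
        lines = (tmp_path / "m.tsv").read_text().strip().split("\n")
        assert lines[0] == "metric\tmean\tsd"
        assert len(lines) == 6

    def test_curve_tsv(self, tmp_path):
        write_curve_tsv([(0.0, 0.0), (1.0, 1.0)], tmp_path / "c.tsv", "fpr", "tpr")
        assert (tmp_path / "c.tsv").read_text().startswith("fpr\ttpr\n")
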