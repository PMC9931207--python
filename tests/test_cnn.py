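"""Architecture arithmetic, scoring invariances and threshold calibration."""

import numpy as np
import pytest

from enhancergain.cnn import (
    ConvNet,
    ModelConfig,
    REFERENCE_DENSE_UNITS,
    REFERENCE_KERNELS,
    TrainedScorer,
    allele_effect_accuracy,
    calibrate_threshold,
    count_parameters,
    delta_score,
    load_scorer,
    one_hot,
    save_scorer,
    solve_reference_architecture,
    train,
)
from enhancergain.intervals import reverse_complement
from enhancergain.simulate import random_sequence


class TestCountParameters:
    def test_single_conv_layer_closed_form(self):
        cfg = ModelConfig(
            input_len=50, conv_kernels=(8,), kernel_widths=(5,), pool_sizes=(50,),
            dense_units=1, output_units=1,
        )
        # conv: 4*5*8+8 = 168; dense: 8*1+1; output: 1*1+1
        assert count_parameters(cfg) == 168 + 9 + 2

    def test_doubling_kernels_doubles_conv_weights_and_biases(self):
        def conv_part(k):
            cfg = ModelConfig(
                input_len=50, conv_kernels=(k,), kernel_widths=(5,),
                pool_sizes=(50,), dense_units=1, output_units=1,
            )
            # subtract the dense+output tail, which also scales with k
            return 4 * 5 * k + k

        assert conv_part(16) == 2 * conv_part(8)

    def test_matches_instantiated_network_for_random_configs(self):
        """Closed form equals the network's own parameter-array total."""
        rng = np.random.default_rng(77)
        for _ in range(20):
            n_layers = int(rng.integers(1, 4))
            cfg = ModelConfig(
                input_len=int(rng.integers(60, 400)),
                conv_kernels=tuple(int(x) for x in rng.integers(2, 48, n_layers)),
                kernel_widths=tuple(int(x) for x in rng.integers(2, 20, n_layers)),
                pool_sizes=tuple(int(x) for x in rng.integers(1, 6, n_layers)),
                dense_units=int(rng.integers(2, 128)),
                output_units=int(rng.integers(1, 3)),
            )
            assert count_parameters(cfg) == ConvNet(cfg, seed=0).n_parameters

    def test_overpooling_is_config_error(self):
        cfg = ModelConfig(
            input_len=10, conv_kernels=(4, 4), kernel_widths=(3, 3),
            pool_sizes=(8, 8), dense_units=4,
        )
        with pytest.raises(ValueError, match="below 1"):
            count_parameters(cfg)


class TestSolveReferenceArchitecture:
    def test_recovers_known_single_layer_width(self):
        cfg = solve_reference_architecture(
            168 + 9 + 2,
            conv_kernels=(8,),
            dense_units=1,
            input_len=50,
            pool_bounds=(50, 50),
        )
        assert cfg is not None and cfg.kernel_widths == (5,)

    def test_unreachable_target_reports_no_solution(self):
        assert (
            solve_reference_architecture(
                168 + 9 + 2 + 1,
                conv_kernels=(8,),
                dense_units=1,
                input_len=50,
                pool_bounds=(50, 50),
            )
            is None
        )

    def test_search_is_deterministic(self):
        a = solve_reference_architecture(3_631_401)
        b = solve_reference_architecture(3_631_401)
        assert a == b

    def test_full_scale_reference_reaches_printed_total(self):
        cfg = solve_reference_architecture(3_631_401)
        assert cfg is not None
        assert cfg.conv_kernels == REFERENCE_KERNELS
        assert cfg.dense_units == REFERENCE_DENSE_UNITS
        assert count_parameters(cfg) == 3_631_401


class TestScoring:
    def test_one_hot_shapes_and_n(self):
        x = one_hot("ACGTN")
        assert x.shape == (5, 4)
        assert np.allclose(x[:4], np.eye(4))
        assert np.allclose(x[4], 0.25)
        with pytest.raises(ValueError):
            one_hot("ACGX")

    def test_score_is_exactly_reverse_complement_invariant(
        self, trained_tiny_scorer
    ):
        scorer, _ = trained_tiny_scorer
        rng = np.random.default_rng(3)
        for _ in range(5):
            s = random_sequence(rng, scorer.config.input_len)
            assert scorer.score(s) == scorer.score(reverse_complement(s))

    def test_all_n_sequence_scores_in_unit_interval(self, trained_tiny_scorer):
        scorer, _ = trained_tiny_scorer
        v = scorer.score("N" * scorer.config.input_len)
        assert 0.0 <= v <= 1.0

    def test_wrong_length_is_an_error(self, trained_tiny_scorer):
        scorer, _ = trained_tiny_scorer
        with pytest.raises(ValueError, match="length"):
            scorer.score("ACGT")

    def test_planted_motif_outscored_its_scramble(
        self, trained_tiny_scorer, activator_pwm
    ):
        scorer, _ = trained_tiny_scorer
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(10):
            flank = random_sequence(rng, scorer.config.input_len)
            cons = activator_pwm.consensus
            off = 90
            planted = flank[:off] + cons + flank[off + len(cons):]
            scrambled_motif = "".join(
                np.array(list(cons))[rng.permutation(len(cons))]
            )
            control = flank[:off] + scrambled_motif + flank[off + len(cons):]
            wins += scorer.score(planted) > scorer.score(control)
        assert wins >= 9

    def test_checkpoint_round_trip_preserves_scores(
        self, trained_tiny_scorer, tmp_path
    ):
        scorer, _ = trained_tiny_scorer
        path = tmp_path / "model.npz"
        save_scorer(path, scorer)
        loaded = load_scorer(path)
        s = random_sequence(np.random.default_rng(0), scorer.config.input_len)
        assert loaded.score(s) == scorer.score(s)


class TestTraining:
    def test_separable_construction_reaches_high_auroc(self, trained_tiny_scorer):
        _, metrics = trained_tiny_scorer
        assert metrics["auroc"] > 0.95
        assert metrics["auprc"] > 0.95

    def test_shuffled_labels_score_at_chance(self, shuffled_label_metrics):
        assert abs(shuffled_label_metrics["auroc"] - 0.5) <= 0.05

    def test_beats_null_by_wide_margin(
        self, trained_tiny_scorer, shuffled_label_metrics
    ):
        _, metrics = trained_tiny_scorer
        assert metrics["auroc"] - shuffled_label_metrics["auroc"] >= 0.4

    def test_training_is_seed_reproducible(self):
        rng = np.random.default_rng(2)
        chroms = ["chr1", "chr6", "chr8", "chr2"]
        pos = [(random_sequence(rng, 80), chroms[i % 4]) for i in range(80)]
        neg = [(random_sequence(rng, 80), chroms[i % 4]) for i in range(80)]
        cfg = ModelConfig(input_len=80, conv_kernels=(8,), kernel_widths=(6,),
                          pool_sizes=(4,), dense_units=8)
        _, m1 = train(cfg, pos, neg, seed=9, epochs=3)
        _, m2 = train(cfg, pos, neg, seed=9, epochs=3)
        assert m1["auroc"] == m2["auroc"]
        assert m1["history"] == m2["history"]

    def test_missing_class_in_split_is_descriptive_error(self):
        rng = np.random.default_rng(2)
        cfg = ModelConfig(input_len=80, conv_kernels=(8,), kernel_widths=(6,),
                          pool_sizes=(4,), dense_units=8)
        pos = [(random_sequence(rng, 80), "chr1")] * 10  # never on chr8/9
        neg = [(random_sequence(rng, 80), c) for c in ("chr1", "chr6", "chr8")] * 5
        with pytest.raises(ValueError, match="split is missing a class"):
            train(cfg, pos, neg, seed=0, epochs=1)
        with pytest.raises(ValueError, match="non-empty"):
            train(cfg, [], neg, seed=0, epochs=1)


class TestCalibrateThreshold:
    def test_order_statistic_example(self):
        scores = [round(0.01 * i, 2) for i in range(1, 11)]
        thr = calibrate_threshold(scores, fpr=0.1)
        assert thr.value == pytest.approx(0.10)

    def test_fpr_one_returns_min_score(self):
        scores = [0.3, 0.2, 0.9, 0.5] + [0.4] * 6
        assert calibrate_threshold(scores, fpr=1.0).value == pytest.approx(0.2)

    def test_tied_scores_move_cutoff_above_ties(self):
        thr = calibrate_threshold([0.5] * 10, fpr=0.1)
        assert thr.value > 0.5
        assert sum(s >= thr.value for s in [0.5] * 10) == 0

    def test_empirical_fpr_never_exceeds_target_on_own_input(self):
        rng = np.random.default_rng(4)
        scores = rng.random(500)
        for fpr in (0.01, 0.05, 0.1, 0.3):
            thr = calibrate_threshold(scores, fpr=fpr)
            assert (scores >= thr.value).mean() <= fpr

    def test_threshold_monotone_in_fpr(self):
        rng = np.random.default_rng(4)
        scores = rng.random(200)
        thrs = [calibrate_threshold(scores, fpr=f).value for f in (0.02, 0.1, 0.5)]
        assert thrs[0] >= thrs[1] >= thrs[2]

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([0.1] * 9)


class TestDeltaScore:
    def test_empty_edit_list_is_exactly_zero(self, trained_tiny_scorer):
        scorer, _ = trained_tiny_scorer
        s = random_sequence(np.random.default_rng(1), scorer.config.input_len)
        assert delta_score(scorer, s, []) == 0.0

    def test_edit_and_revert_deltas_cancel(self, trained_tiny_scorer):
        scorer, _ = trained_tiny_scorer
        s = random_sequence(np.random.default_rng(1), scorer.config.input_len)
        new = "A" if s[50] != "A" else "C"
        edited = s[:50] + new + s[51:]
        d1 = delta_score(scorer, s, [(50, new)])
        d2 = delta_score(scorer, edited, [(50, s[50])])
        assert d1 + d2 == pytest.approx(0.0, abs=1e-12)

    def test_motif_completing_edit_is_positive(
        self, trained_tiny_scorer, activator_pwm
    ):
        scorer, _ = trained_tiny_scorer
        rng = np.random.default_rng(8)
        cons = activator_pwm.consensus
        key = activator_pwm.max_info_position()
        flank = random_sequence(rng, scorer.config.input_len)
        off = 100
        broken = cons[:key] + ("A" if cons[key] != "A" else "G") + cons[key + 1:]
        base = flank[:off] + broken + flank[off + len(cons):]
        assert delta_score(scorer, base, [(off + key, cons[key])]) > 0

    def test_out_of_range_and_identity_edits_rejected(self, trained_tiny_scorer):
        scorer, _ = trained_tiny_scorer
        s = "A" * scorer.config.input_len
        with pytest.raises(IndexError):
            delta_score(scorer, s, [(len(s), "C")])
        with pytest.raises(ValueError):
            delta_score(scorer, s, [(0, "A")])


class TestAlleleEffectAccuracy:
    def test_perfect_agreement_is_one_at_every_margin(self):
        deltas = [0.4, -0.2, 0.1, -0.5]
        labels = [1, -1, 1, -1]
        curve = allele_effect_accuracy(deltas, labels, margins=[0.0, 0.1, 0.3])
        assert (curve["accuracy"] == 1.0).all()

    def test_random_labels_sit_at_chance_at_margin_zero(self):
        rng = np.random.default_rng(0)
        deltas = rng.normal(size=10_000)
        labels = rng.choice([-1, 1], size=10_000)
        curve = allele_effect_accuracy(deltas, labels, margins=[0.0])
        assert abs(curve.loc[0, "accuracy"] - 0.5) < 0.02
        assert curve.loc[0, "coverage"] == 1.0

    def test_margin_above_max_delta_is_missing_point(self):
        curve = allele_effect_accuracy([0.1, -0.1], [1, -1], margins=[0.5])
        assert np.isnan(curve.loc[0, "accuracy"])
        assert curve.loc[0, "coverage"] == 0.0
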