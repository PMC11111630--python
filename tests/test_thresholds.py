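"""Threshold math: EMA updates, MaxNorm combination, selection rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stfl.synthetic import ConfidenceStreamSpec, generate_confidence_stream
from stfl.thresholds import (
    combined_thresholds,
    init_state,
    select_samples,
    update_global,
    update_per_class,
)


class TestInit:
    def test_initial_thresholds_are_chance_level(self):
        st7 = init_state(7, momentum=0.9)
        assert st7.T_g == pytest.approx(1 / 7)
        assert np.allclose(st7.T_c, 1 / 7)
        assert st7.t == 0
        st2 = init_state(2, momentum=0.9)
        assert np.allclose(st2.T_c, [0.5, 0.5])

    @pytest.mark.parametrize("momentum", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_momentum_rejected(self, momentum):
        with pytest.raises(ValueError):
            init_state(3, momentum=momentum)


class TestGlobalUpdate:
    def test_hand_computed_ema_step(self):
        # lambda=0.9, previous 0.5, batch max-confidences {0.7, 0.9}
        state = init_state(2, momentum=0.9)
        state = state.__class__(t=0, T_g=0.5, T_c=state.T_c, momentum=0.9, n_classes=2)
        probs = np.array([[0.7, 0.3], [0.9, 0.1]])
        new = update_global(state, probs)
        assert new.T_g == pytest.approx(0.9 * 0.5 + 0.1 * 0.8, abs=1e-12)
        assert new.t == 1
        assert state.T_g == 0.5  # pure update

    def test_uniform_predictions_are_fixed_point(self):
        state = init_state(4, momentum=0.7)
        probs = np.full((16, 4), 0.25)
        for _ in range(5):
            state = update_global(state, probs)
            state = update_per_class(state, probs)
        assert state.T_g == pytest.approx(0.25, abs=1e-12)
        assert np.allclose(state.T_c, 0.25, atol=1e-12)

    @pytest.mark.parametrize("lam", [0.5, 0.9, 0.99])
    def test_geometric_convergence_to_constant_batch_mean(self, lam):
        # closed form: |T_g(k) - m| = lam^k |T_g(0) - m|
        m = 0.85
        probs = np.array([[m, 1 - m]] * 8)
        state = init_state(2, momentum=lam)
        t0_gap = abs(state.T_g - m)
        for _ in range(200):
            state = update_global(state, probs)
        assert abs(state.T_g - m) < lam**200 * t0_gap + 1e-12

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            update_global(init_state(3, 0.9), np.empty((0, 3)))

    def test_bounds_preserved_with_valid_confidences(self):
        # confidences in [1/Nc, 1] keep T_g in [1/Nc, 1] by EMA convexity
        rng = np.random.default_rng(0)
        state = init_state(5, momentum=0.8)
        for _ in range(100):
            x = rng.random((32, 5)) + 1e-6
            probs = x / x.sum(axis=1, keepdims=True)
            state = update_global(state, probs)
            assert 1 / 5 - 1e-12 <= state.T_g <= 1.0 + 1e-12


class TestPerClassUpdate:
    def test_hand_computed_expected_reading(self):
        state = init_state(2, momentum=0.5)
        probs = np.array([[0.9, 0.1], [0.7, 0.3]])
        new = update_per_class(state, probs)
        assert np.allclose(new.T_c, [0.65, 0.35], atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.random((20, 4))
        probs = x / x.sum(axis=1, keepdims=True)
        state = init_state(4, momentum=0.9)
        a = update_per_class(state, probs)
        b = update_per_class(state, probs[rng.permutation(20)])
        assert np.allclose(a.T_c, b.T_c, atol=1e-12)

    def test_argmax_mean_reading_keeps_absent_classes(self):
        state = init_state(3, momentum=0.5)
        probs = np.array([[0.8, 0.1, 0.1], [0.6, 0.3, 0.1]])  # argmax always 0
        new = update_per_class(state, probs, mode="argmax_mean")
        assert new.T_c[0] == pytest.approx(0.5 * (1 / 3) + 0.5 * 0.7)
        assert new.T_c[1] == pytest.approx(1 / 3)
        assert new.T_c[2] == pytest.approx(1 / 3)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            update_per_class(init_state(3, 0.9), np.full((2, 3), 1 / 3), mode="bogus")


class TestCombined:
    def test_hand_computed_maxnorm(self):
        state = init_state(2, momentum=0.9)
        state = state.__class__(
            t=5, T_g=0.6, T_c=np.array([0.2, 0.4]), momentum=0.9, n_classes=2
        )
        assert np.allclose(combined_thresholds(state), [0.3, 0.6], atol=1e-12)

    def test_equal_locals_collapse_to_global(self):
        state = init_state(6, momentum=0.9)
        assert np.allclose(combined_thresholds(state), state.T_g, atol=1e-15)

    def test_max_of_combined_equals_global(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            tc = rng.uniform(0.05, 1.0, size=5)
            state = init_state(5, momentum=0.9).__class__(
                t=1, T_g=rng.uniform(0.2, 1.0), T_c=tc, momentum=0.9, n_classes=5
            )
            v = combined_thresholds(state)
            assert abs(v.max() - state.T_g) < 1e-12
            assert (v <= state.T_g + 1e-12).all()


class TestSelection:
    def test_confident_sample_kept_with_its_argmax_label(self):
        sel = select_samples(np.array([[0.9, 0.05, 0.05]]), np.full(3, 0.8))
        assert sel.keep_mask.tolist() == [True]
        assert sel.pseudo_labels[0] == 0
        assert sel.per_class_counts.tolist() == [1, 0, 0]

    def test_tie_with_threshold_is_excluded(self):
        sel = select_samples(np.array([[0.8, 0.1, 0.1]]), np.full(3, 0.8))
        assert sel.n_selected == 0

    def test_boundary_thresholds(self):
        rng = np.random.default_rng(1)
        x = rng.random((40, 4))
        probs = x / x.sum(axis=1, keepdims=True)
        assert select_samples(probs, np.zeros(4)).n_selected == 40
        assert select_samples(probs, np.ones(4)).n_selected == 0

    def test_counts_sum_to_kept_and_kept_exceed_threshold(self):
        rng = np.random.default_rng(2)
        x = rng.random((100, 5))
        probs = x / x.sum(axis=1, keepdims=True)
        thr = rng.uniform(0, 0.6, size=5)
        sel = select_samples(probs, thr)
        assert sel.per_class_counts.sum() == sel.n_selected
        kept = np.flatnonzero(sel.keep_mask)
        assert (
            probs[kept].max(axis=1) > thr[probs[kept].argmax(axis=1)]
        ).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            select_samples(np.full((2, 3), 1 / 3), np.array([0.5, 0.5]))


class TestStreamProperties:
    def test_vectorized_updates_match_scalar_brute_force(self):
        """Oracle equivalence on a seeded 100-batch stream at 1e-10."""
        spec = ConfidenceStreamSpec(
            n_classes=4,
            batch_size=64,
            n_batches=100,
            per_class_confidence_params=((9, 3), (5, 5), (2, 6), (12, 2)),
            class_priors=np.array([0.4, 0.3, 0.2, 0.1]),
            corruption_rate=0.2,
            seed=5,
        )
        lam = 0.95
        state = init_state(4, momentum=lam)
        tg, tc = 1 / 4, [1 / 4] * 4
        for probs, _ in generate_confidence_stream(spec):
            state = update_global(state, probs)
            state = update_per_class(state, probs)
            # scalar brute force, plain Python floats
            confs = [max(row) for row in probs.tolist()]
            tg = lam * tg + (1 - lam) * (sum(confs) / len(confs))
            for c in range(4):
                col = [row[c] for row in probs.tolist()]
                tc[c] = lam * tc[c] + (1 - lam) * (sum(col) / len(col))
            assert abs(state.T_g - tg) < 1e-10
            assert np.abs(state.T_c - np.array(tc)).max() < 1e-10

    def test_thresholds_rise_with_stream_confidence(self):
        """Low early thresholds admit more samples; confident streams push
        the global threshold higher than weak ones (warm-up behavior)."""
        def terminal_tg(mean_conf, seed=3):
            alpha = mean_conf * 40
            beta = (1 - mean_conf) * 40
            spec = ConfidenceStreamSpec(
                n_classes=2,
                batch_size=64,
                n_batches=50,
                per_class_confidence_params=((alpha, beta), (alpha, beta)),
                class_priors=np.array([0.5, 0.5]),
                seed=seed,
            )
            state = init_state(2, momentum=0.9)
            for probs, _ in generate_confidence_stream(spec):
                state = update_global(state, probs)
            return state.T_g

        assert terminal_tg(0.9) > terminal_tg(0.5) > 0.5  # starts at 1/2, rises

    def test_adaptive_selection_more_class_balanced_than_fixed(
        self, two_class_stream_spec
    ):
        """Central qualitative claim: combined adaptive thresholds select
        rare low-confidence classes at a rate closer to the majority's."""
        batches = generate_confidence_stream(two_class_stream_spec)
        state = init_state(2, momentum=0.99)
        for probs, _ in batches:
            state = update_global(state, probs)
            state = update_per_class(state, probs)

        def min_max_ratio(thresholds):
            kept = np.zeros(2)
            total = np.zeros(2)
            for probs, true in batches:
                sel = select_samples(probs, thresholds)
                for c in (0, 1):
                    total[c] += (true == c).sum()
                    kept[c] += (sel.keep_mask & (true == c)).sum()
            rates = kept / total
            return rates.min() / rates.max()

        adaptive = min_max_ratio(combined_thresholds(state))
        fixed = min_max_ratio(np.full(2, state.T_g))
        assert adaptive > fixed


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    lam=st.floats(0.05, 0.95),
    data=st.lists(
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3), min_size=1, max_size=8
    ),
)
def test_update_pipeline_stays_in_unit_interval(lam, data):
    probs = np.array(data)
    probs = probs / probs.sum(axis=1, keepdims=True)
    state = init_state(3, momentum=lam)
    state = update_global(state, probs)
    state = update_per_class(state, probs)
    assert 0.0 <= state.T_g <= 1.0
    assert ((state.T_c >= 0.0) & (state.T_c <= 1.0)).all()
    v = combined_thresholds(state)
    assert abs(v.max() - state.T_g) < 1e-12
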