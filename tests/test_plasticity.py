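"""Plasticity rules against hand-derived values and per-synapse loop oracles."""

import numpy as np
import pytest

from stlrnet.plasticity import (
    classify_regions,
    heblr_update,
    normalize_vectors,
    normalized_coincidence,
    normalized_state,
    stlr_coincidence,
    stlr_update,
)


def loop_heblr(w, x, dw, eta):
    """Per-synapse reference implementation of the Hebbian step."""
    w = np.array(w, dtype=float)
    out = w.copy()
    for i in range(w.shape[0]):
        s = sum(w[i, j] * x[j] for j in range(w.shape[1]))
        if s >= eta:
            for j in range(w.shape[1]):
                if x[j] == 1:
                    out[i, j] = w[i, j] + dw
    return out


def loop_stlr(w, x, dw, theta1, theta2, form="approximate", normalized=False):
    """Per-synapse reference implementation of the spatiotemporal step."""
    w = np.array(w, dtype=float)
    out = w.copy()
    nx = np.sqrt(sum(v * v for v in x))
    for i in range(w.shape[0]):
        s = sum(w[i, j] * x[j] for j in range(w.shape[1]))
        nw = np.sqrt(sum(v * v for v in w[i]))
        for j in range(w.shape[1]):
            if x[j] != 1:
                continue
            if normalized:
                coeff = (w[i, j] / nw) * sum(
                    (w[i, m] / nw) * (x[m] / nx) for m in range(w.shape[1])
                )
            elif form == "exact":
                coeff = w[i, j] * x[j] * sum(
                    w[i, m] * x[m] for m in range(w.shape[1]) if m != j
                )
            else:
                coeff = w[i, j] * x[j] / s
            if coeff >= theta1:
                out[i, j] = w[i, j] + dw
            elif coeff <= theta2:
                out[i, j] = w[i, j] - dw
    return out


class TestHebbianUpdate:
    def test_hand_derived_single_row(self):
        """s = 0.2+0.3 = 0.5 >= 0.4, so both active synapses gain 0.1."""
        w = np.array([[0.2, 0.5, 0.3]])
        out = heblr_update(w, np.array([1, 0, 1]), dw=0.1, eta=0.4)
        np.testing.assert_allclose(out, [[0.3, 0.5, 0.4]])

    def test_no_firing_no_change(self, small_instance):
        w, x = small_instance
        out = heblr_update(w, x, dw=0.1, eta=1e9)
        assert (out == w).all()

    def test_all_zero_input_no_change(self, small_instance):
        w, _ = small_instance
        out = heblr_update(w, np.zeros(8, dtype=np.uint8), dw=0.1, eta=-1.0)
        assert (out == w).all()

    def test_monotone_nondecreasing_over_run(self, rng):
        w = rng.uniform(size=(12, 12))
        for _ in range(6):
            x = (rng.uniform(size=12) > 0.5).astype(np.uint8)
            w_next = heblr_update(w, x, dw=0.07, eta=float(np.median(w @ x)))
            assert (w_next >= w).all()
            w = w_next

    def test_input_not_mutated(self, small_instance):
        w, x = small_instance
        w_before = w.copy()
        heblr_update(w, x, dw=0.1, eta=0.0)
        assert (w == w_before).all()


class TestCoincidence:
    def test_hand_derived_approximate(self):
        """s = 0.2+0.5 = 0.7; I = (0.2/0.7, 0.5/0.7, 0)."""
        w = np.array([[0.2, 0.5, 0.3]])
        out = stlr_coincidence(w, np.array([1, 1, 0]), form="approximate")
        np.testing.assert_allclose(out, [[2 / 7, 5 / 7, 0.0]])

    def test_single_active_input_gives_one(self):
        w = np.array([[0.4, 0.6]])
        out = stlr_coincidence(w, np.array([1, 0]), form="approximate")
        np.testing.assert_allclose(out, [[1.0, 0.0]])

    def test_row_sums_to_one_when_driven(self, rng):
        w = rng.uniform(0.1, 1.0, size=(20, 20))
        x = (rng.uniform(size=20) > 0.4).astype(np.uint8)
        out = stlr_coincidence(w, x, form="approximate")
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_exact_form_matches_loop(self, rng):
        w = rng.uniform(size=(6, 6))
        x = (rng.uniform(size=6) > 0.5).astype(np.uint8)
        out = stlr_coincidence(w, x, form="exact")
        for i in range(6):
            s = (w[i] * x).sum()
            for j in range(6):
                expected = w[i, j] * x[j] * (s - w[i, j] * x[j])
                assert out[i, j] == pytest.approx(expected, abs=1e-12)

    def test_inactive_columns_zero(self, small_instance):
        w, x = small_instance
        for form in ("approximate", "exact"):
            out = stlr_coincidence(w, x, form=form)
            assert (out[:, x == 0] == 0).all()

    def test_zero_drive_warns_and_zeroes(self):
        w = np.zeros((2, 3))
        with pytest.warns(RuntimeWarning):
            out = stlr_coincidence(w, np.array([1, 1, 0]), form="approximate")
        assert (out == 0).all()


class TestSTLRUpdate:
    def test_hand_derived_single_row(self):
        """I = (0.286, 0.714, 0): first synapse <= theta2 (-dw), second >=
        theta1 (+dw), third inactive (unchanged)."""
        w = np.array([[0.2, 0.5, 0.3]])
        out = stlr_update(
            w, np.array([1, 1, 0]), dw=0.1, theta1=0.5, theta2=0.3, normalized=False
        )
        np.testing.assert_allclose(out, [[0.1, 0.6, 0.3]])

    def test_pure_invariance_band(self):
        w = np.array([[0.5, 0.5]])
        # both coefficients are 0.5: strictly inside (theta2, theta1)
        out = stlr_update(w, np.array([1, 1]), dw=0.1, theta1=0.9, theta2=0.1, normalized=False)
        assert (out == w).all()

    def test_all_zero_input_no_change(self, small_instance):
        w, _ = small_instance
        out = stlr_update(w, np.zeros(8), dw=0.1, theta1=0.6, theta2=0.4)
        assert (out == w).all()

    def test_inactive_synapses_bit_identical(self, small_instance):
        w, x = small_instance
        out = stlr_update(w, x, dw=0.1, theta1=0.6, theta2=0.4, normalized=True)
        assert (out[:, x == 0] == w[:, x == 0]).all()

    def test_weights_can_go_negative(self):
        w = np.full((1, 4), 0.05)
        x = np.ones(4, dtype=np.uint8)
        out = stlr_update(w, x, dw=0.2, theta1=0.9, theta2=0.5, normalized=False)
        assert (out < 0).all()

    def test_threshold_ordering_enforced(self, small_instance):
        w, x = small_instance
        with pytest.raises(ValueError):
            stlr_update(w, x, dw=0.1, theta1=0.3, theta2=0.3)

    @pytest.mark.parametrize("form", ["approximate", "exact"])
    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_loop_oracle(self, rng, form, normalized):
        for _ in range(10):
            w = rng.uniform(0.05, 1.0, size=(8, 8))
            x = np.zeros(8, dtype=np.uint8)
            x[rng.permutation(8)[: rng.integers(1, 8)]] = 1
            theta2, theta1 = np.sort(rng.uniform(0.0, 0.5, size=2))
            theta1 += 1e-6
            got = stlr_update(
                w, x, dw=0.1, theta1=theta1, theta2=theta2, form=form, normalized=normalized
            )
            want = loop_stlr(w, x, 0.1, theta1, theta2, form=form, normalized=normalized)
            np.testing.assert_allclose(got, want, atol=1e-12)


class TestNormalization:
    def test_unit_norms_and_bounded_state(self, rng):
        x = (rng.uniform(size=30) > 0.5).astype(float)
        w_row = rng.uniform(size=30)
        x_t, w_t, s_t = normalize_vectors(x, w_row)
        assert np.linalg.norm(x_t) == pytest.approx(1.0)
        assert np.linalg.norm(w_t) == pytest.approx(1.0)
        assert 0.0 <= s_t <= 1.0

    def test_parallel_vectors_state_one(self):
        v = np.array([1.0, 2.0, 2.0])
        _, _, s_t = normalize_vectors(v, 3.5 * v)
        assert s_t == pytest.approx(1.0)

    def test_matches_dot_product_oracle(self):
        x = np.zeros(120)
        x[:60] = 1
        w_row = np.full(120, 0.7)
        _, _, s_t = normalize_vectors(x, w_row)
        oracle = (w_row / np.linalg.norm(w_row)) @ (x / np.linalg.norm(x))
        assert s_t == pytest.approx(oracle)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            normalize_vectors(np.zeros(4), np.ones(4))
        with pytest.raises(ValueError):
            normalize_vectors(np.ones(4), np.zeros(4))

    def test_matrix_form_agrees_with_row_form(self, rng):
        w = rng.uniform(size=(5, 9))
        x = (rng.uniform(size=9) > 0.3).astype(float)
        x_t, w_t, s_t = normalized_state(w, x)
        for i in range(5):
            xi, wi, si = normalize_vectors(x, w[i])
            np.testing.assert_allclose(w_t[i], wi)
            assert s_t[i] == pytest.approx(si)


class TestNormalizedCoincidence:
    def test_zero_slope_gives_zero(self):
        out = normalized_coincidence(np.array([0.3, 0.4]), 0.0)
        assert (out == 0).all()

    def test_unit_slope_identity(self):
        out = normalized_coincidence(np.array([0.1, 0.2]), 1.0)
        np.testing.assert_allclose(out, [0.1, 0.2])

    def test_linear_in_weight_with_slope_s(self, rng):
        w_t = rng.uniform(size=12)
        s_t = 0.73
        out = normalized_coincidence(w_t, s_t)
        np.testing.assert_allclose(out / w_t, s_t)

    def test_active_input_restriction(self):
        out = normalized_coincidence(np.array([0.1, 0.2]), 0.5, x=np.array([1, 0]))
        np.testing.assert_allclose(out, [0.05, 0.0])


class TestClassifyRegions:
    def test_region_assignment_and_boundaries(self):
        s = np.array([0.7, 0.5, 0.3, 0.6, 0.4])
        labels = classify_regions(s, theta1=0.6, theta2=0.4)
        # boundaries inclusive on the R1 (>= theta1) and R3 (<= theta2) sides
        assert labels.tolist() == ["R1", "R2", "R3", "R1", "R3"]

    def test_labels_partition(self, rng):
        s = rng.normal(size=200)
        labels = classify_regions(s, theta1=0.5, theta2=-0.5)
        assert set(labels) <= {"R1", "R2", "R3"}
        assert len(labels) == 200

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            classify_regions(np.array([0.5]), theta1=0.1, theta2=0.2)
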