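import numpy as np
import pytest
from scipy.special import expit

from sstseg.config import LossWeights
from sstseg.losses import (EPS, compute_all, loss_cell_calling, loss_neg_marker,
                           loss_nuclei_encapsulation, loss_overlap,
                           loss_oversegmentation, loss_pos_marker, total_loss)

SIG_P = float(expit(0.5))   # ~0.6225
SIG_M = float(expit(-0.5))  # ~0.3775


def _rand_instance(seed, M=2, h=8, w=8):
    rng = np.random.default_rng(seed)
    q = rng.uniform(0.05, 0.95, (M, h, w))
    x = (rng.random((M, h, w)) < 0.2).astype(float)
    e = np.maximum(x, (rng.random((M, h, w)) < 0.4)).astype(float)
    mp = (rng.random((M, h, w)) < 0.1).astype(float)
    mn = (rng.random((M, h, w)) < 0.1).astype(float)
    return q, x, e, mp, mn, x.max(axis=0)


class TestClosedForms:
    def test_bce_perfect_prediction_near_zero(self):
        # single-cell patch: aggregated prediction equals the cell's own
        x = (np.random.default_rng(0).random((1, 8, 8)) < 0.3).astype(float)
        y = np.clip(x, EPS, 1 - EPS)
        v, _ = loss_nuclei_encapsulation(x, y, reduction="mean")
        assert v <= 2 * EPS * abs(np.log(EPS))

    def test_nuclei_encapsulation_aggregates_over_cells(self):
        # two cells each predicting their own nucleus: the mean prediction is
        # 1/2 on nucleus pixels, so the union-mask BCE is strictly positive
        x = np.zeros((2, 8, 8))
        x[0, :2, :2] = 1
        x[1, 5:7, 5:7] = 1
        v, _ = loss_nuclei_encapsulation(x, x.copy(), reduction="mean")
        frac = 8 / 64
        assert v == pytest.approx(frac * -np.log(0.5), abs=1e-6)

    def test_bce_at_half_is_ln2(self):
        x = (np.random.default_rng(1).random((3, 8, 8)) < 0.3).astype(float)
        y = np.full_like(x, 0.5)
        for fn in (loss_nuclei_encapsulation, loss_cell_calling, loss_pos_marker):
            v, _ = fn(x, y, reduction="mean")
            assert v == pytest.approx(np.log(2))

    def test_bce_inverted_prediction_maximal(self):
        x = (np.random.default_rng(2).random((1, 8, 8)) < 0.5).astype(float)
        v, _ = loss_nuclei_encapsulation(x, 1.0 - x, reduction="mean")
        assert v == pytest.approx(abs(np.log(EPS)), rel=1e-3)

    def test_cell_calling_average_of_perfect_and_half(self):
        e = np.zeros((2, 8, 8))
        e[0] = 1.0
        y = np.empty_like(e)
        y[0] = 1 - EPS   # perfect for cell 0
        y[1] = 0.5       # ln 2 for cell 1
        e[1] = (np.random.default_rng(3).random((8, 8)) < 0.4).astype(float)
        v, _ = loss_cell_calling(e, y, reduction="mean")
        assert v == pytest.approx(np.log(2) / 2, rel=1e-4)

    def test_oversegmentation_zero_prediction_hinges_to_zero(self):
        q = np.zeros((1, 8, 8))
        x = np.zeros((1, 8, 8))
        x[0, :2, :2] = 1
        v, g = loss_oversegmentation(q, x)
        assert v == 0.0 and not g.any()

    def test_oversegmentation_prediction_inside_nuclei_is_zero(self):
        x = np.zeros((1, 8, 8))
        x[0, :2, :2] = 1
        v, _ = loss_oversegmentation(x.copy(), x)  # q = x_nuc
        assert v == 0.0

    def test_oversegmentation_everything_foreground(self):
        # 8x8 patch, 4-pixel nucleus, q = 1: 56*(sig(.5)-sig(-.5)) ~ 13.72
        x = np.zeros((1, 8, 8))
        x[0, :2, :2] = 1
        q = np.ones((1, 8, 8))
        v, _ = loss_oversegmentation(q, x)
        assert v == pytest.approx(56 * (SIG_P - SIG_M), rel=1e-6)

    def test_overlap_single_quiet_cell_hinges_to_zero(self):
        x = np.zeros((8, 8))
        x[:2, :2] = 1
        q = np.zeros((1, 8, 8))
        v, g = loss_overlap(q, x)
        assert v == 0.0 and not g.any()

    def test_overlap_two_greedy_cells(self):
        x = np.zeros((8, 8))
        x[:2, :2] = 1
        q = np.ones((2, 8, 8))
        expected = (60 * (2 * SIG_P - 1) + 4 * 2 * SIG_M) / (2 * 64)
        v, _ = loss_overlap(q, x)
        assert v == pytest.approx(expected, rel=1e-6)

    def test_neg_marker_constant_floor(self):
        q = np.random.default_rng(4).uniform(0, 1, (1, 8, 8))
        v, g = loss_neg_marker(np.zeros((1, 8, 8)), q)
        assert v == pytest.approx(64 * SIG_M, rel=1e-6)
        assert not g.any()

    def test_neg_marker_single_active_pixel(self):
        q = np.zeros((1, 8, 8))
        m = np.zeros((1, 8, 8))
        m[0, 3, 3] = 1
        q[0, 3, 3] = 1
        v, _ = loss_neg_marker(m, q)
        assert v == pytest.approx(63 * SIG_M + SIG_P, rel=1e-6)

    def test_pos_marker_bce_at_half_independent_of_target(self):
        m = np.zeros((1, 8, 8))
        m[0, 2:5, 2:5] = 1
        v, _ = loss_pos_marker(m, np.full((1, 8, 8), 0.5), reduction="mean")
        assert v == pytest.approx(np.log(2))


class TestTotalLoss:
    def test_zero_weights(self):
        parts = dict(ne=1, cc=2, os=3, ov=4, pos=5, neg=6)
        w = LossWeights(ne=0, cc=0, os=0, ov=0, pos=0, neg=0)
        assert total_loss(parts, w) == 0.0

    def test_unit_weights_sum(self):
        parts = dict(ne=1, cc=2, os=3, ov=4, pos=5, neg=6)
        assert total_loss(parts) == 21.0

    def test_additivity_against_parts(self):
        q, x, e, mp, mn, xu = _rand_instance(9)
        parts, total, _ = compute_all(q, x, e, mp, mn, xu)
        assert total == pytest.approx(sum(parts.values()))

    def test_non_finite_part_aborts_with_name(self):
        parts = dict(ne=1, cc=np.nan, os=3, ov=4, pos=5, neg=6)
        with pytest.raises(FloatingPointError, match="cc"):
            total_loss(parts)


@pytest.mark.parametrize("seed", range(12))
def test_gradients_match_finite_differences(seed):
    """Analytic gradient of the weighted total vs central differences."""
    q, x, e, mp, mn, xu = _rand_instance(seed)
    _, _, g = compute_all(q, x, e, mp, mn, xu)
    rng = np.random.default_rng(seed + 100)
    eps = 1e-6
    for _ in range(6):
        idx = tuple(rng.integers(s) for s in q.shape)
        qp, qm = q.copy(), q.copy()
        qp[idx] += eps
        qm[idx] -= eps
        _, tp, _ = compute_all(qp, x, e, mp, mn, xu)
        _, tm, _ = compute_all(qm, x, e, mp, mn, xu)
        fd = (tp - tm) / (2 * eps)
        assert g[idx] == pytest.approx(fd, abs=1e-4)


@pytest.mark.parametrize("seed", range(100))
def test_vectorised_losses_match_bruteforce_pixel_sums(seed):
    """Pure-python per-pixel oracle for the sigmoid-sum losses."""
    q, x, e, mp, mn, xu = _rand_instance(seed, M=2, h=8, w=8)
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    M, h, w = q.shape
    # over-segmentation oracle
    diff = 0.0
    for c in range(M):
        for i in range(h):
            for j in range(w):
                diff += sig(q[c, i, j] * x[c, i, j] * 1.0 - 0.5) * -1.0
                diff += sig(q[c, i, j] * (1 - x[c, i, j]) - 0.5)
    expected_os = diff / M if diff > 0 else 0.0
    v_os, _ = loss_oversegmentation(q, x)
    assert v_os == pytest.approx(expected_os, abs=1e-6)
    # overlap oracle
    s = 0.0
    for i in range(h):
        for j in range(w):
            s += -(1 - xu[i, j])
            for c in range(M):
                s += sig(q[c, i, j] * (1 - xu[i, j]) - 0.5)
    expected_ov = s / (M * h * w) if s > 0 else 0.0
    v_ov, _ = loss_overlap(q, xu)
    assert v_ov == pytest.approx(expected_ov, abs=1e-6)
    # negative-marker oracle
    t = sum(sig(q[c, i, j] * mn[c, i, j] - 0.5)
            for c in range(M) for i in range(h) for j in range(w))
    v_neg, _ = loss_neg_marker(mn, q)
    assert v_neg == pytest.approx(t / M, abs=1e-6)


def test_all_losses_nonnegative_random():
    for seed in range(20):
        q, x, e, mp, mn, xu = _rand_instance(seed + 500)
        parts, total, _ = compute_all(q, x, e, mp, mn, xu)
        assert all(v >= 0 for v in parts.values())
        assert total >= 0
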