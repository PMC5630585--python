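import numpy as np
import pytest

from uscut.image_io import PointPx, UltrasoundImage
from uscut.radial_graph import (
    GraphParams,
    _edge_arrays,
    average_seed_gray,
    build_graph,
    oracle_min_cut,
    sample_rays,
    solve_min_cut,
    terminal_weights,
)

from conftest import disc_image, random_graph


def test_ray_geometry_clockwise_from_up():
    img = UltrasoundImage(np.zeros((101, 101), dtype=np.uint8))
    g = sample_rays(img, PointPx(50, 50), GraphParams(4, 2, 10.0, 2, 1))
    expect = np.array(
        [
            [[50, 45], [50, 40]],  # up
            [[55, 50], [60, 50]],  # right
            [[50, 55], [50, 60]],  # down
            [[45, 50], [40, 50]],  # left
        ],
        dtype=float,
    )
    assert np.allclose(g.positions, expect, atol=1e-9)


def test_uniform_image_samples_constant():
    img = UltrasoundImage(np.full((64, 64), 42, dtype=np.uint8))
    g = sample_rays(img, PointPx(32, 32), GraphParams(8, 10, 20.0, 2, 1))
    assert np.allclose(g.grays, 42.0)


def test_bilinear_midpoint():
    px = np.zeros((16, 16), dtype=np.uint8)
    px[:, :8] = 10
    px[:, 8:] = 20
    img = UltrasoundImage(px)
    # ray 1 points right from (6.5, 8): nodes at x = 7.5 (blend of 10 and
    # 20) and x = 8.5 (pure 20)
    g = sample_rays(img, PointPx(6.5, 8.0), GraphParams(4, 2, 2.0, 0, 1))
    assert g.grays[1, 0] == pytest.approx(15.0)
    assert g.grays[1, 1] == pytest.approx(20.0)


def test_seed_outside_rejected():
    img = UltrasoundImage(np.zeros((32, 32), dtype=np.uint8))
    with pytest.raises(ValueError, match="seed"):
        sample_rays(img, PointPx(40, 10), GraphParams())


class TestAverageSeedGray:
    def test_uniform(self):
        img = UltrasoundImage(np.full((32, 32), 30, dtype=np.uint8))
        assert average_seed_gray(img, PointPx(16, 16), 7) == 30.0

    def test_arithmetic_sequence(self):
        px = np.zeros((16, 16), dtype=np.uint8)
        px[7:10, 7:10] = np.arange(9).reshape(3, 3)
        img = UltrasoundImage(px)
        assert average_seed_gray(img, PointPx(8, 8), 3) == pytest.approx(4.0)

    def test_corner_clipping(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        img = UltrasoundImage(px)
        # 5x5 window at (0,0) clips to the 3x3 top-left block
        assert average_seed_gray(img, PointPx(0, 0), 5) == pytest.approx(px[:3, :3].mean())


class TestTerminalWeights:
    def test_constant_ray(self):
        sink, cap = terminal_weights(np.full(5, 20.0), 20.0)
        assert np.allclose(cap, 0.0)
        assert not sink[0] and sink[-1]
        assert sink[1:-1].all()  # tie rule: zero differences go to the sink

    def test_step_profile(self):
        sink, cap = terminal_weights(np.array([20.0, 20.0, 120.0, 120.0]), 20.0)
        assert list(cap) == [0.0, 0.0, 100.0, 100.0]
        assert list(sink) == [False, True, True, True]

    def test_decreasing_deviation(self):
        sink, cap = terminal_weights(np.array([10.0, 5.0, 0.0]), 0.0)
        assert list(cap) == [10.0, 5.0, 0.0]
        assert list(sink) == [False, False, True]


def test_edge_counts():
    img = disc_image()
    K, N = 6, 9
    g = build_graph(img, PointPx(64, 64), GraphParams(K, N, 40.0, 2, 9))
    rows, cols, data, src, snk = _edge_arrays(g)
    inf = data.max()
    n_inf = int((data == inf).sum())
    n_term = int((data < inf).sum())
    # all terminal caps here are < inf (sum+1), so the split is exact
    assert n_inf == K * (N - 1) + 2 * K * N
    assert n_term == K * N


def test_solver_matches_dp_oracle_exactly(rng):
    for _ in range(200):
        g = random_graph(rng)
        s = solve_min_cut(g)
        o = oracle_min_cut(g)
        assert s.flow_value == pytest.approx(o.flow_value, abs=1e-9)


def test_float_capacities_agree_with_oracle(rng):
    for _ in range(50):
        g = random_graph(rng, int_caps=False)
        s = solve_min_cut(g)
        o = oracle_min_cut(g)
        # float caps go through fixed-point quantization in the solver
        assert s.flow_value == pytest.approx(o.flow_value, rel=1e-5, abs=1e-4)


def test_cut_satisfies_smoothness_on_random_images(rng):
    for _ in range(100):
        size = int(rng.integers(32, 64))
        px = rng.integers(0, 256, (size, size)).astype(np.uint8)
        img = UltrasoundImage(px)
        dr = int(rng.integers(0, 4))
        params = GraphParams(8, 10, size // 3, dr, 3)
        cut = solve_min_cut(build_graph(img, PointPx(size // 2, size // 2), params))
        diffs = np.abs(np.diff(np.append(cut.cut_index, cut.cut_index[0])))
        assert diffs.max() <= dr


def test_delta_zero_forces_constant_cut(rng):
    px = rng.integers(0, 256, (48, 48)).astype(np.uint8)
    img = UltrasoundImage(px)
    cut = solve_min_cut(build_graph(img, PointPx(24, 24), GraphParams(8, 10, 16.0, 0, 3)))
    assert len(set(cut.cut_index.tolist())) == 1


def test_flow_monotone_in_delta_r(rng):
    px = rng.integers(0, 256, (48, 48)).astype(np.uint8)
    img = UltrasoundImage(px)
    flows = []
    for dr in range(4):
        cut = solve_min_cut(build_graph(img, PointPx(24, 24), GraphParams(10, 12, 18.0, dr, 3)))
        flows.append(cut.flow_value)
    assert all(a >= b - 1e-9 for a, b in zip(flows, flows[1:]))


def test_determinism(rng):
    px = rng.integers(0, 256, (48, 48)).astype(np.uint8)
    img = UltrasoundImage(px)
    params = GraphParams(12, 10, 18.0, 2, 5)
    c1 = solve_min_cut(build_graph(img, PointPx(24, 24), params))
    c2 = solve_min_cut(build_graph(img, PointPx(24, 24), params))
    assert np.array_equal(c1.cut_index, c2.cut_index)
    assert c1.flow_value == c2.flow_value


def test_disc_cut_tracks_boundary(disc):
    params = GraphParams(24, 30, 45.0, 2, 9)
    g = build_graph(disc, PointPx(64, 64), params)
    cut = solve_min_cut(g)
    node_radius = (cut.cut_index + 1) * g.node_spacing
    assert np.all(np.abs(node_radius - 30.0) <= g.node_spacing + 1e-9)


def test_oracle_unconstrained_is_per_ray_argmin(rng):
    g = random_graph(rng, n_rays=5, n_nodes=8, delta_r=8)
    o = oracle_min_cut(g)
    # delta_r >= N makes the smoothness constraint vacuous
    sink_cum = np.cumsum(np.where(g.term_sink, g.term_cap, 0.0), axis=1)
    src_tail = np.where(~g.term_sink, g.term_cap, 0.0)[:, ::-1].cumsum(axis=1)[:, ::-1]
    cost = sink_cum + np.concatenate([src_tail[:, 1:], np.zeros((5, 1))], axis=1)
    assert o.flow_value == pytest.approx(cost.min(axis=1).sum())


def test_oracle_size_guard(rng):
    g = random_graph(rng, n_rays=8, n_nodes=12)
    with pytest.raises(ValueError, match="too large"):
        oracle_min_cut(g, max_nodes=10)
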