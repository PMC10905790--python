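"""Rice crown-root tip localization: peak finding, fitting, paths, counts."""

import numpy as np
import pytest

from rootfos import (
    ElasticParams,
    ParameterError,
    RootTip,
    count_roots_by_depth,
    find_tip_candidates,
    fit_tips,
    hyperbolic_path,
    strains_for_tips,
    threshold_negative,
)
from rootfos.rice_reconstruction import RootSystem


class TestFindTipCandidates:
    def test_flat_snapshot_empty(self, layout):
        assert find_tip_candidates(np.zeros(len(layout)), layout, 1.0) == []

    def test_single_tip_single_candidate(self, layout, elastic):
        tip = RootTip(position=[5.0, 2.0, 70.0])
        snap = strains_for_tips([tip], layout, elastic)
        cands = find_tip_candidates(np.maximum(snap, 0.0), layout, 5.0)
        assert len(cands) == 1
        peak_gauge = int(np.argmax(snap))
        assert abs(
            layout.arc_positions[peak_gauge]
            - layout.arc_positions[
                int(np.argmin(np.linalg.norm(layout.xyz - cands[0].position, axis=1)))
            ]
        ) <= 30.0

    def test_two_separated_tips_two_candidates(self, layout, elastic):
        t1 = RootTip(position=[6.0, 0.0, 40.0])
        t2 = RootTip(position=[-6.0, 0.0, 100.0])
        snap = np.maximum(strains_for_tips([t1, t2], layout, elastic), 0.0)
        cands = find_tip_candidates(snap, layout, 5.0)
        assert len(cands) == 2

    def test_candidates_nudged_inward(self, layout, elastic):
        tip = RootTip(position=[8.0, 0.0, 70.0])
        snap = np.maximum(strains_for_tips([tip], layout, elastic), 0.0)
        cand = find_tip_candidates(snap, layout, 5.0)[0]
        peak = int(np.argmax(snap))
        r_gauge = layout.spiral_radius[peak]
        r_cand = np.hypot(cand.position[0], cand.position[1])
        assert r_cand == pytest.approx(r_gauge - 5.0, abs=1e-9)

    def test_mismatched_snapshot_rejected(self, layout):
        with pytest.raises(ParameterError):
            find_tip_candidates(np.zeros(3), layout, 1.0)


class TestThresholdNegative:
    def test_examples(self):
        np.testing.assert_allclose(
            threshold_negative(np.array([-5.0, 3.0, -1.0])), [0.0, 3.0, 0.0]
        )
        pos = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(threshold_negative(pos), pos)

    def test_floor_respected(self, rng):
        snap = rng.normal(0, 10, 100)
        assert threshold_negative(snap, floor=-2.5).min() >= -2.5


class TestFitTips:
    def test_noiseless_single_tip_recovery(self, layout, elastic):
        """Candidate 10 mm off a planted tip converges to it within 1 mm."""
        truth = RootTip(position=[4.0, -3.0, 65.0])
        snap = strains_for_tips([truth], layout, elastic)
        start = RootTip(position=truth.position + np.array([6.0, 6.0, 5.3]))
        system = fit_tips([start], snap, layout, elastic)
        assert system.n_roots == 1
        err = np.linalg.norm(system.tips[0].position - truth.position)
        assert err <= 1.0
        assert system.final_residual < 1e-6
        assert system.final_residual <= system.initial_residual

    def test_residual_never_increases(self, layout, elastic, rng):
        for _ in range(10):
            n = rng.integers(1, 4)
            tips = [
                RootTip(position=rng.uniform([-8, -8, 30], [8, 8, 110]))
                for _ in range(n)
            ]
            snap = strains_for_tips(tips, layout, elastic)
            snap = snap + rng.normal(0, 2.0, snap.shape)
            cands = find_tip_candidates(np.maximum(snap, 0), layout, 5.0)
            if not cands:
                continue
            system = fit_tips(
                cands, snap, layout, elastic, maxiter_per_tip=60, n_rounds=1
            )
            assert system.final_residual <= system.initial_residual + 1e-12

    def test_empty_candidates_flagged(self, layout, elastic):
        system = fit_tips([], np.zeros(len(layout)), layout, elastic)
        assert system.n_roots == 0
        assert "no-candidates" in system.flags
        assert np.isnan(system.final_residual)

    def test_duplicate_candidates_merged(self, layout, elastic):
        truth = RootTip(position=[4.0, -3.0, 65.0])
        snap = strains_for_tips([truth], layout, elastic)
        c1 = RootTip(position=truth.position + np.array([4.0, 0.0, 2.0]))
        c2 = RootTip(position=truth.position + np.array([-4.0, 1.0, -2.0]))
        system = fit_tips([c1, c2], snap, layout, elastic)
        assert system.n_roots == 1
        assert "merged-duplicates" in system.flags


class TestHyperbolicPath:
    def test_endpoints_exact(self):
        tip = RootTip(position=[20.0, 10.0, 90.0])
        path = hyperbolic_path([0.0, 0.0, 0.0], tip, n_points=80)
        np.testing.assert_allclose(path.polyline[0], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(path.polyline[-1], tip.position)

    def test_depth_monotone(self):
        tip = RootTip(position=[15.0, -8.0, 70.0])
        path = hyperbolic_path([0.0, 0.0, 0.0], tip)
        assert np.all(np.diff(path.polyline[:, 2]) >= 0)

    def test_vertical_degenerate(self):
        tip = RootTip(position=[0.0, 0.0, 50.0])
        path = hyperbolic_path([0.0, 0.0, 0.0], tip, n_points=30)
        np.testing.assert_allclose(path.polyline[:, :2], 0.0, atol=1e-12)

    @pytest.mark.parametrize("d,z", [(10.0, 60.0), (25.0, 90.0), (30.0, 120.0)])
    def test_gravitropic_asymptote(self, d, z):
        """The final segment approaches vertical (within 5 degrees)."""
        tip = RootTip(position=[d, 0.0, z])
        path = hyperbolic_path([0.0, 0.0, 0.0], tip, n_points=60)
        seg = path.polyline[-1] - path.polyline[-2]
        angle = np.degrees(np.arctan2(np.hypot(seg[0], seg[1]), seg[2]))
        assert angle <= 5.0

    def test_tip_above_base_rejected(self):
        with pytest.raises(ParameterError):
            hyperbolic_path([0.0, 0.0, 50.0], RootTip(position=[5.0, 0.0, 30.0]))


class TestCountRootsByDepth:
    def _system(self, depths):
        paths = tuple(
            hyperbolic_path([0.0, 0.0, 0.0], RootTip(position=[5.0, 0.0, d]))
            for d in depths
        )
        return RootSystem(paths=paths, initial_residual=1.0, final_residual=0.5)

    def test_single_root_to_80mm(self):
        edges, counts = count_roots_by_depth(self._system([80.0]), bin_width=10.0)
        np.testing.assert_array_equal(counts, [1] * 8)

    def test_empty_system(self):
        system = RootSystem(paths=(), initial_residual=np.nan, final_residual=np.nan)
        edges, counts = count_roots_by_depth(system, bin_width=10.0, max_depth=100.0)
        assert counts.sum() == 0

    def test_matches_plane_crossing_oracle(self, rng):
        depths = rng.uniform(10.0, 140.0, 6)
        system = self._system(depths)
        edges, counts = count_roots_by_depth(system, bin_width=12.5)
        for lo, got in zip(edges[:-1], counts):
            # brute force: count polylines crossing the horizontal plane z = lo
            crossing = sum(
                1
                for p in system.paths
                if p.polyline[:, 2].min() <= lo < p.polyline[:, 2].max()
            )
            assert got == crossing
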