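"""Track statistics against brute-force and constructed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import blastosim as bs
from blastosim.errors import FitError
from blastosim.metrics import PhaseWindows, correlation_distance_r2, voronoi_centroids
from blastosim.tracks import TRACK_COLUMNS


class TestLocalDensity:
    def test_two_nuclei_inside_and_outside_radius(self):
        assert np.array_equal(
            bs.local_density([[0, 0, 0], [100, 0, 0]]), [1, 1]
        )
        assert np.array_equal(
            bs.local_density([[0, 0, 0], [200, 0, 0]]), [0, 0]
        )

    def test_matches_all_pairs_brute_force(self, rng):
        pts = rng.uniform(0, 400, size=(100, 3))
        got = bs.local_density(pts, radius_um=150)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        want = ((d <= 150).sum(axis=1)) - 1
        assert np.array_equal(got, want)

    def test_invariant_under_rigid_motion(self, rng):
        pts = rng.uniform(0, 300, size=(50, 3))
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = pts @ R.T + np.array([50.0, -20.0, 5.0])
        assert np.array_equal(bs.local_density(pts), bs.local_density(moved))

    def test_2d_projection_mode_uses_discs(self):
        # separated only in z: neighbors in the projection, not in 3D
        pts = [[0, 0, 0], [0, 0, 400]]
        assert np.array_equal(bs.local_density(pts, radius_um=150), [0, 0])
        assert np.array_equal(bs.local_density(pts, radius_um=150, projection="xy"), [1, 1])


class TestSpeed:
    def test_stationary_and_constant_velocity(self):
        t = bs.make_scripted_lineage([30], seed=0)  # stationary between divisions
        sp = bs.nucleus_speed(t).merge(t.df, on=["nucleus_id", "frame"])
        births = t.df.groupby("nucleus_id")["frame"].min()
        interior = sp[sp.frame > sp.nucleus_id.map(births)]
        assert np.allclose(interior["speed_um_min"].dropna(), 0.0)
        # 3 um over 1.5 min -> 2 um/min
        t2 = bs.make_ballistic_tracks(n=3, speed_um_min=2.0, frames=4, seed=1)
        assert np.allclose(bs.nucleus_speed(t2)["speed_um_min"].dropna(), 2.0)

    def test_random_walk_matches_displacement_oracle(self, rng):
        rows = []
        pos = {0: np.zeros(3), 1: np.array([500.0, 0, 0])}
        history = {0: [], 1: []}
        for f in range(10):
            for nid in (0, 1):
                history[nid].append(pos[nid].copy())
                rows.append((nid, None, f, 1.5 * f, *pos[nid]))
                pos[nid] = pos[nid] + rng.normal(0, 2, 3)
        t = bs.TrackTable(pd.DataFrame(rows, columns=TRACK_COLUMNS))
        sp = bs.nucleus_speed(t)
        for nid in (0, 1):
            want = [
                np.linalg.norm(history[nid][k] - history[nid][k - 1]) / 1.5
                for k in range(1, 10)
            ]
            got = sp[(sp.nucleus_id == nid) & (sp.frame > 0)]["speed_um_min"].to_numpy()
            assert np.allclose(got, want)


class TestCountChangeAndPeaks:
    def test_doubling_is_plus_hundred_percent(self):
        t = bs.make_scripted_lineage([6.0], seed=0, tail_frames=4)
        raw = bs.count_change_series(t, smooth_window_frames=1)
        assert raw.max() == pytest.approx(100.0)

    def test_constant_counts_give_zero_series_and_no_peaks(self):
        t = bs.make_ballistic_tracks(n=5, speed_um_min=1.0, frames=10, seed=0)
        s = bs.count_change_series(t)
        assert np.allclose(s.to_numpy(), 0.0)
        pk = bs.detect_division_peaks(s, t.frame_interval_min)
        assert len(pk["peak_times_min"]) == 0
        assert len(pk["intervals_min"]) == 0

    def test_synchronous_divisions_recover_programmed_interval(self):
        """Perfectly synchronous 49-min cycles -> mean peak interval 49 +/- one frame."""
        t = bs.make_scripted_lineage([49, 49, 49, 49], seed=0)
        s = bs.count_change_series(t, smooth_window_frames=5)
        pk = bs.detect_division_peaks(s, t.frame_interval_min, min_separation_min=30.0)
        assert len(pk["peak_times_min"]) >= 3
        assert np.abs(pk["intervals_min"] - 49.0).max() <= t.frame_interval_min


class TestCycleLengths:
    def test_birth_to_division_interval(self):
        t = bs.make_scripted_lineage([49.5, 49.5], seed=0)
        cyc = bs.cycle_lengths(t)
        assert np.allclose(cyc["cycle_length_min"], 49.5)

    def test_leaves_and_roots_excluded(self):
        t = bs.make_scripted_lineage([30, 30], seed=0)
        cyc = bs.cycle_lengths(t)
        parents = t.df.groupby("nucleus_id")["parent_id"].first()
        internal = set(parents.dropna().astype(int))
        roots = set(t.roots().tolist())
        assert set(cyc["nucleus_id"]) == (internal - roots)


class TestLocalProliferationTime:
    def test_scripted_neighborhood_growth(self):
        """4 neighbors at t0, a 5th arriving 30 min later -> 30 (ceil(5.0) = 5)."""
        rows = []
        base = [[0, 0, 0], [50, 0, 0], [0, 50, 0], [0, 0, 50], [50, 50, 0]]
        for f in range(25):
            for nid, p in enumerate(base):
                rows.append((nid, None, f, 1.5 * f, *p))
        # nucleus 5 starts far away and arrives within 150 um of the origin at t=30
        for f in range(25):
            x = 400.0 if f < 20 else 100.0
            rows.append((5, None, f, 1.5 * f, x, 0.0, 0.0))
        t = bs.TrackTable(pd.DataFrame(rows, columns=TRACK_COLUMNS))
        res = bs.local_proliferation_time(t, t0_min=0.0).set_index("nucleus_id")
        assert res.loc[0, "prolif_time_min"] == pytest.approx(30.0)

    def test_never_growing_neighborhood_unreached(self):
        t = bs.make_ballistic_tracks(n=6, speed_um_min=0.0, frames=10, seed=3, box_um=100)
        res = bs.local_proliferation_time(t, t0_min=0.0)
        assert res["prolif_time_min"].isna().all()

    def test_matches_frame_by_frame_recount(self):
        """Brute-force oracle on a dividing fixture."""
        t = bs.make_scripted_lineage([20, 25, 30], seed=6, noise_sd_min=3.0, daughter_offset_um=40)
        res = bs.local_proliferation_time(t, t0_min=0.0).set_index("nucleus_id")
        df = t.df
        frames = sorted(df["frame"].unique())
        for nid in df[df.frame == 0]["nucleus_id"]:
            sub = df[df.nucleus_id == nid].set_index("frame")
            p0 = sub.loc[0, ["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
            all0 = df[df.frame == 0][["x_um", "y_um", "z_um"]].to_numpy()
            c0 = (np.linalg.norm(all0 - p0, axis=1) <= 150).sum() - 1
            target = int(np.ceil(1.25 * c0))
            expect = np.nan
            if c0 >= target:
                expect = 0.0
            else:
                for f in frames[1:]:
                    if f not in sub.index:
                        break
                    p = sub.loc[f, ["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
                    allf = df[df.frame == f][["x_um", "y_um", "z_um"]].to_numpy()
                    c = (np.linalg.norm(allf - p, axis=1) <= 150).sum() - 1
                    if c >= target:
                        expect = f * 1.5
                        break
            got = res.loc[nid, "prolif_time_min"]
            assert (np.isnan(got) and np.isnan(expect)) or got == pytest.approx(expect)


class TestConcordance:
    def test_two_nucleus_extremes(self):
        assert bs.density_cycle_concordance([1, 5], [10.0, 20.0]) == 100.0
        assert bs.density_cycle_concordance([1, 5], [20.0, 10.0]) == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_pairwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 10, 50).astype(float)
        t = rng.normal(30, 10, 50)
        got = bs.density_cycle_concordance(d, t)
        conc = disc = 0
        for i in range(50):
            for j in range(i + 1, 50):
                if d[i] == d[j] or t[i] == t[j]:
                    continue
                if (d[i] - d[j]) * (t[i] - t[j]) > 0:
                    conc += 1
                else:
                    disc += 1
        if conc + disc == 0:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(100.0 * conc / (conc + disc))

    def test_no_valid_pairs_is_nan(self):
        assert np.isnan(bs.density_cycle_concordance([3, 3], [5.0, 9.0]))


class TestSpaceSeeking:
    def test_cosine_extremes(self, sphere_domain):
        pos = np.array([[200.0, 0.0, 0.0], [420.0, 0.0, 0.0]])
        cent = voronoi_centroids(pos, sphere_domain)
        target = cent[0] - pos[0]
        rows = []
        for nid, p in enumerate(pos):
            rows.append((nid, None, 0, 0.0, *p))
        step = 2.0 * target / np.linalg.norm(target)
        orth = np.array([0.0, 0.0, 2.0])
        for nid, p, d in ((0, pos[0], step), (1, pos[1], orth)):
            rows.append((nid, None, 1, 1.5, *(p + d)))
        t = bs.TrackTable(pd.DataFrame(rows, columns=TRACK_COLUMNS))
        scores = bs.space_seeking_score(t, sphere_domain, 0).set_index("nucleus_id")["score"]
        assert scores[0] == pytest.approx(1.0, abs=1e-6)
        # moving exactly away
        rows[-2] = (0, None, 1, 1.5, *(pos[0] - step))
        t2 = bs.TrackTable(pd.DataFrame(rows, columns=TRACK_COLUMNS))
        s2 = bs.space_seeking_score(t2, sphere_domain, 0).set_index("nucleus_id")["score"]
        assert s2[0] == pytest.approx(-1.0, abs=1e-6)
        # nucleus 1 moved orthogonally to its (x-axis-aligned) target
        assert abs(s2[1]) < 0.15

    def test_voxel_centroid_matches_monte_carlo(self, sphere_domain, rng):
        """Voronoi-cell centroid from voxel assignment vs rejection-sampled
        Monte-Carlo centroid of the same cell: angular error < 2 degrees."""
        pos = np.array(
            [[220.0, 40.0, 0.0], [380.0, -60.0, 30.0], [300.0, 120.0, -80.0]]
        )
        cent = voronoi_centroids(pos, sphere_domain)
        samples = rng.uniform(-300, 300, size=(2_000_000, 3)) + np.array([300.0, 0.0, 0.0])
        inside = np.linalg.norm(samples - np.array([300.0, 0.0, 0.0]), axis=1) <= 300
        samples = samples[inside]
        d = np.linalg.norm(samples[:, None, :] - pos[None], axis=2)
        owner = d.argmin(axis=1)
        for k in range(len(pos)):
            mc = samples[owner == k].mean(axis=0)
            v1 = cent[k] - pos[k]
            v2 = mc - pos[k]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 2.0

    def test_single_centered_nucleus_hits_sentinel(self, sphere_domain):
        """A lone nucleus at the center of a symmetric domain has a ~zero
        target vector -> undefined score."""
        rows = [
            (0, None, 0, 0.0, 300.0, 0.0, 0.0),
            (0, None, 1, 1.5, 302.0, 0.0, 0.0),
        ]
        t = bs.TrackTable(pd.DataFrame(rows, columns=TRACK_COLUMNS))
        s = bs.space_seeking_score(t, sphere_domain, 0)
        assert np.isnan(s["score"]).all()

    def test_rotation_invariance(self, rng):
        """Score is invariant under a global rotation of positions + domain.

        The spherical domain is rotation-symmetric, so rotating the nuclei
        about its center must leave every score unchanged (up to voxel
        re-discretization)."""
        dom = bs.build_domain(bs.ShapeSpec(kind="ellipsoid", length_um=600, width_um=600), 15)
        center = np.array([300.0, 0.0, 0.0])
        pos = center + rng.uniform(-150, 150, size=(6, 3))
        disp = rng.normal(0, 3, size=(6, 3))
        theta = np.pi / 2  # exact grid symmetry: 90-degree rotation about x
        R = np.array(
            [[1, 0, 0], [0, np.cos(theta), -np.sin(theta)], [0, np.sin(theta), np.cos(theta)]]
        )

        def scores(p0, d0):
            rows = []
            for nid in range(6):
                rows.append((nid, None, 0, 0.0, *p0[nid]))
                rows.append((nid, None, 1, 1.5, *(p0[nid] + d0[nid])))
            t = bs.TrackTable(pd.DataFrame(rows, columns=TRACK_COLUMNS))
            return bs.space_seeking_score(t, dom, 0)["score"].to_numpy()

        s1 = scores(pos, disp)
        s2 = scores((pos - center) @ R.T + center, disp @ R.T)
        assert np.allclose(s1, s2, atol=1e-9)


class TestPairwiseCorrelation:
    def test_rigid_translation_field(self):
        dirs = np.tile(np.array([[1.0, 0.0, 0.0]]), (12, 1))
        t = bs.make_ballistic_tracks(n=12, speed_um_min=1.0, frames=3, seed=2, directions=dirs)
        pairs = bs.pairwise_movement_correlation(t, frame=0)
        assert np.allclose(pairs["correlation"], 1.0)
        assert correlation_distance_r2(pairs) == pytest.approx(0.0, abs=1e-12)

    def test_vortex_flow_decorrelates_with_distance(self):
        """Smooth vortex: nearby nuclei move alike, distant ones don't."""
        rng = np.random.default_rng(8)
        pos = rng.uniform(-200, 200, size=(60, 3))
        rows = []
        for nid, p in enumerate(pos):
            v = np.array([-p[1], p[0], 0.0])
            v = 2.0 * v / max(np.linalg.norm(v), 1e-9)
            rows.append((nid, None, 0, 0.0, *p))
            rows.append((nid, None, 1, 1.5, *(p + v)))
        t = bs.TrackTable(pd.DataFrame(rows, columns=TRACK_COLUMNS))
        pairs = bs.pairwise_movement_correlation(t, frame=0)
        near = pairs[pairs.separation_um < 150]["correlation"].mean()
        far = pairs[pairs.separation_um > 300]["correlation"].mean()
        assert near > far

    def test_sister_pairs_excluded(self):
        rows = [(0, None, 0, 0.0, 0.0, 0.0, 0.0), (0, None, 1, 1.5, 0.0, 0.0, 0.0)]
        for f in (2, 3, 4):
            t = f * 1.5
            rows.append((1, 0, f, t, 10.0 + 2 * f, 0.0, 0.0))  # daughters moving apart
            rows.append((2, 0, f, t, -10.0 - 2 * f, 0.0, 0.0))
            rows.append((3, None, f - 2, t - 3.0, 300.0 + f, 0.0, 0.0))  # unrelated mover
        rows.append((3, None, 3, 4.5, 306.0, 0.0, 0.0))
        rows.append((3, None, 4, 6.0, 308.0, 0.0, 0.0))
        df = pd.DataFrame(rows, columns=TRACK_COLUMNS).drop_duplicates(["nucleus_id", "frame"])
        t = bs.TrackTable(df)
        with_sisters = bs.pairwise_movement_correlation(t, 2, exclude_sisters=False)
        without = bs.pairwise_movement_correlation(t, 2, exclude_sisters=True)
        assert len(with_sisters) == 3
        assert len(without) == 2
        assert not {(1, 2)} & set(zip(without["id_a"], without["id_b"]))


class TestPhasesAndFit:
    def test_phase_window_assignment(self):
        w = PhaseWindows()
        assert list(bs.assign_phase([5.0, 36.0, 20.0], w)) == ["A", "B", "outside"]
        with pytest.raises(ValueError):
            bs.assign_phase([-1.0], w)

    def test_density_bins_match_published_edges(self):
        assert list(bs.density_bin([0, 10, 11, 28, 29, 50])) == [
            "low", "low", "medium", "medium", "high", "high",
        ]

    def test_noiseless_fit_recovers_exactly(self):
        x = np.arange(0.0, 61.0)
        y = 2.3 * np.exp(-x / 30.0)
        fit = bs.fit_density_scale(y, x, n_boot=50, seed=0)
        assert fit.y0 == pytest.approx(2.3, abs=1e-6)
        assert fit.x0 == pytest.approx(30.0, abs=1e-6)
        assert fit.ci90[0] <= fit.x0 <= fit.ci90[1]

    def test_noisy_fit_within_ten_percent(self):
        speeds, dens = bs.make_expdecay_dataset(2.3, 30.0, 0.1, 500, seed=42)
        fit = bs.fit_density_scale(speeds, dens, n_boot=200, seed=1)
        assert abs(fit.x0 - 30.0) / 30.0 < 0.10

    def test_all_equal_densities_rejected(self):
        with pytest.raises(FitError, match="unidentifiable"):
            bs.fit_density_scale(np.ones(20), np.full(20, 5.0), seed=0)

    def test_bootstrap_is_seeded(self):
        speeds, dens = bs.make_expdecay_dataset(2.0, 25.0, 0.1, 200, seed=9)
        f1 = bs.fit_density_scale(speeds, dens, n_boot=100, seed=3)
        f2 = bs.fit_density_scale(speeds, dens, n_boot=100, seed=3)
        assert f1.ci90 == f2.ci90
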