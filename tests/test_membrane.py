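import numpy as np
import pandas as pd
import pytest

from helixcov.membrane import (
    BilayerTrajectory, hydrogen_bonds, hydropathy_height_profile,
    local_energy_average, positional_variance, thickness_map,
)
from helixcov.synth import gen_bilayer_trajectory


class TestThicknessMap:
    def test_flat_slabs_exact_separation(self):
        traj = gen_bilayer_trajectory(n_frames=2, slab_sep=38.0)
        tm = thickness_map(traj)
        vals = tm.thickness[~np.isnan(tm.thickness)]
        assert vals.size > 0
        np.testing.assert_allclose(vals, 38.0, atol=1e-6)

    def test_two_frame_average(self):
        t30 = gen_bilayer_trajectory(n_frames=1, slab_sep=30.0)
        t40 = gen_bilayer_trajectory(n_frames=1, slab_sep=40.0)
        traj = BilayerTrajectory(
            frames=np.concatenate([t30.frames, t40.frames]),
            metadata=t30.metadata,
        )
        tm = thickness_map(traj)
        vals = tm.thickness[~np.isnan(tm.thickness)]
        np.testing.assert_allclose(vals, 35.0, atol=1e-6)

    def test_planted_depression_recovered(self):
        traj = gen_bilayer_trajectory(
            n_frames=5, slab_sep=38.0, depression=(8.0, 10.0, (0.0, 0.0)),
            jitter=0.3, seed=9,
        )
        tm = thickness_map(traj)
        depth, x, y = tm.minimum()
        assert depth == pytest.approx(30.0, abs=1.0)
        assert abs(x) < 6 and abs(y) < 6

    def test_depression_in_both_leaflet_maps(self):
        traj = gen_bilayer_trajectory(
            n_frames=3, slab_sep=38.0, depression=(8.0, 10.0, (0.0, 0.0)),
            seed=4,
        )
        for leaflet in ("upper", "lower"):
            tm = thickness_map(traj, leaflet=leaflet)
            assert tm.minimum()[0] == pytest.approx(30.0, abs=1.0)

    def test_in_plane_translation_shifts_map_values_unchanged(self):
        traj = gen_bilayer_trajectory(n_frames=1, slab_sep=38.0,
                                      depression=(6.0, 8.0, (0.0, 0.0)))
        shifted = BilayerTrajectory(
            frames=traj.frames + np.array([15.0, -7.0, 0.0]),
            metadata=traj.metadata,
        )
        a, b = thickness_map(traj), thickness_map(shifted)
        da, (xa, ya) = a.minimum()[0], a.minimum()[1:]
        db, (xb, yb) = b.minimum()[0], b.minimum()[1:]
        assert da == pytest.approx(db, abs=1e-6)
        assert xb - xa == pytest.approx(15.0, abs=2.0)
        assert yb - ya == pytest.approx(-7.0, abs=2.0)

    def test_empty_leaflet_rejected(self):
        traj = gen_bilayer_trajectory(n_frames=1)
        meta = traj.metadata.copy()
        upper = meta.leaflet == "upper"
        meta.loc[upper, "role"] = "other"
        meta.loc[upper, "leaflet"] = "n/a"
        broken = BilayerTrajectory(frames=traj.frames, metadata=meta)
        with pytest.raises(ValueError):
            thickness_map(broken)

    def test_positive_where_occupied(self):
        traj = gen_bilayer_trajectory(n_frames=2, slab_sep=38.0, jitter=0.5,
                                      seed=2)
        tm = thickness_map(traj)
        assert np.all(tm.thickness[tm.occupancy > 0] > 0)


def protein_traj(frames):
    n_atoms = frames.shape[1]
    n_res = n_atoms // 4
    meta = pd.DataFrame({
        "resid": np.repeat(np.arange(1, n_res + 1), 4),
        "atom_name": ["N", "CA", "C", "O"] * n_res,
        "role": ["protein_backbone"] * n_atoms,
        "leaflet": ["n/a"] * n_atoms,
    })
    return BilayerTrajectory(frames=frames, metadata=meta)


class TestPositionalVariance:
    def test_static_trajectory_all_zero(self):
        base = np.random.default_rng(0).uniform(-5, 5, size=(8, 3))
        traj = protein_traj(np.repeat(base[None], 4, axis=0))
        pv = positional_variance(traj)
        np.testing.assert_allclose(pv.values, 0.0)

    def test_isotropic_jitter_closed_form(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(-5, 5, size=(8, 3))
        sigma = 0.7
        frames = base[None] + rng.normal(scale=sigma, size=(10_000, 8, 3))
        pv = positional_variance(protein_traj(frames))
        np.testing.assert_allclose(pv.values, 3 * sigma**2, rtol=0.05)

    def test_rigid_drift_increases_every_residue(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(-5, 5, size=(8, 3))
        frames = base[None] + rng.normal(scale=0.3, size=(200, 8, 3))
        pv0 = positional_variance(protein_traj(frames))
        drift = np.linspace(0, 5, 200)[:, None, None] * np.array([1.0, 0, 0])
        pv1 = positional_variance(protein_traj(frames + drift))
        assert np.all(pv1.values > pv0.values)

    def test_single_frame_rejected(self):
        base = np.zeros((1, 8, 3))
        with pytest.raises(ValueError):
            positional_variance(protein_traj(base))

    def test_selection_restricts_residues(self):
        rng = np.random.default_rng(6)
        frames = rng.normal(size=(10, 8, 3))
        pv = positional_variance(protein_traj(frames), selection=[1])
        assert list(pv.index) == [1]


class TestHydrogenBonds:
    def test_ideal_geometry_counted(self):
        # D at origin, H towards A, A at 2.9 A, 5 degrees off linearity
        ang = np.deg2rad(5.0)
        frame = np.array([
            [0.0, 0.0, 0.0],             # donor heavy
            [np.cos(ang), np.sin(ang), 0.0],  # hydrogen (D->H at 5 deg)
            [2.9, 0.0, 0.0],             # acceptor
        ])
        out = hydrogen_bonds(frame, donors=[(0, 1)], acceptors=[2])
        assert out == [(0, 2)]

    def test_distance_beyond_cutoff_not_counted(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [4.0, 0, 0]])
        assert hydrogen_bonds(frame, [(0, 1)], [2]) == []

    def test_boundaries_inclusive(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.8, 0, 0]])
        assert hydrogen_bonds(frame, [(0, 1)], [2]) == [(0, 2)]
        ang = np.deg2rad(20.0)
        frame20 = np.array([
            [0.0, 0, 0], [np.cos(ang), np.sin(ang), 0.0], [3.0, 0, 0],
        ])
        assert hydrogen_bonds(frame20, [(0, 1)], [2]) == [(0, 2)]

    def test_angle_beyond_cutoff_not_counted(self):
        ang = np.deg2rad(25.0)
        frame = np.array([
            [0.0, 0, 0], [np.cos(ang), np.sin(ang), 0.0], [3.0, 0, 0],
        ])
        assert hydrogen_bonds(frame, [(0, 1)], [2]) == []

    def test_random_frame_matches_brute_force(self):
        rng = np.random.default_rng(17)
        frame = rng.uniform(0, 12, size=(50, 3))
        donors = [(i, i + 1) for i in range(0, 20, 2)]
        acceptors = list(range(20, 50))
        got = hydrogen_bonds(frame, donors, acceptors)
        # independent double loop
        expected = []
        for d, h in donors:
            for a in acceptors:
                da = frame[a] - frame[d]
                dh = frame[h] - frame[d]
                dist = np.linalg.norm(da)
                if dist == 0 or dist > 3.8:
                    continue
                cosang = dh @ da / (np.linalg.norm(dh) * dist)
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 20.0:
                    expected.append((d, a))
        assert got == expected
        assert len(got) > 0  # the fixture actually exercises the cutoffs

    def test_count_monotone_in_cutoffs(self):
        rng = np.random.default_rng(23)
        frame = rng.uniform(0, 10, size=(40, 3))
        donors = [(i, i + 1) for i in range(0, 16, 2)]
        acceptors = list(range(16, 40))
        prev = -1
        for dist, angle in ((3.0, 10.0), (3.8, 20.0), (5.0, 40.0)):
            n = len(hydrogen_bonds(frame, donors, acceptors, dist, angle))
            assert n >= prev
            prev = n

    def test_missing_hydrogen_rejected(self):
        frame = np.zeros((3, 3))
        with pytest.raises(ValueError):
            hydrogen_bonds(frame, donors=[(0, 99)], acceptors=[2])


class TestHydropathyProfile:
    def test_all_leucine_has_no_hydrophilic(self):
        names = ["LEU"] * 20
        z = np.linspace(-14, 14, 20)
        df = hydropathy_height_profile(names, z, (-15.0, 15.0), 6)
        assert df.hydrophilic.sum() == 0
        assert df.hydrophobic.sum() == 20

    def test_counts_conserved_with_overflow(self):
        rng = np.random.default_rng(2)
        names = list(rng.choice(["LEU", "SER", "LYS", "PHE"], size=30))
        z = rng.uniform(-25, 25, size=30)  # some outside the slab
        df = hydropathy_height_profile(names, z, (-15.0, 15.0), 5)
        assert (df.hydrophobic.sum() + df.hydrophilic.sum()) == 30
        assert df.iloc[0]["bin"] == "below" and df.iloc[-1]["bin"] == "above"

    def test_mixed_sequence_manual_binning(self):
        names = ["LEU", "SER", "ILE", "LYS"]
        z = [-10.0, -10.0, 10.0, 10.0]
        df = hydropathy_height_profile(names, z, (-15.0, 15.0), 2)
        # bin 1: [-15, 0): LEU (phobic) + SER (philic)
        assert df.iloc[1].hydrophobic == 1 and df.iloc[1].hydrophilic == 1
        # bin 2: [0, 15): ILE + LYS
        assert df.iloc[2].hydrophobic == 1 and df.iloc[2].hydrophilic == 1

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_height_profile(["LEU"], [0.0], (5.0, -5.0), 3)


class TestLocalEnergyAverage:
    def test_isolated_residue_keeps_own_average(self):
        series = pd.DataFrame({1: [1.0, 3.0], 2: [10.0, 10.0]})
        coords = {1: np.zeros(3), 2: np.array([100.0, 0, 0])}
        out = local_energy_average(series, coords, cutoff=10.0)
        assert out[1] == pytest.approx(2.0)
        assert out[2] == pytest.approx(10.0)

    def test_uniform_energies_unchanged(self):
        series = pd.DataFrame({r: [5.0, 5.0] for r in range(1, 6)})
        rng = np.random.default_rng(1)
        coords = {r: rng.uniform(-5, 5, 3) for r in range(1, 6)}
        out = local_energy_average(series, coords, cutoff=10.0)
        np.testing.assert_allclose(out.values, 5.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(20)
        resids = list(range(1, 21))
        series = pd.DataFrame({r: rng.normal(size=30) for r in resids})
        coords = {r: rng.uniform(0, 15, 3) for r in resids}
        out = local_energy_average(series, coords, cutoff=10.0)
        tavg = {r: series[r].mean() for r in resids}
        for r in resids:
            neigh = [s for s in resids
                     if np.linalg.norm(coords[s] - coords[r]) <= 10.0]
            assert out[r] == pytest.approx(np.mean([tavg[s] for s in neigh]))

    def test_global_mean_preserved_at_infinite_cutoff(self):
        rng = np.random.default_rng(21)
        resids = list(range(1, 11))
        series = pd.DataFrame({r: rng.normal(size=5) for r in resids})
        coords = {r: rng.uniform(0, 5, 3) for r in resids}
        out = local_energy_average(series, coords, cutoff=1e9)
        np.testing.assert_allclose(out.values, series.values.mean())

    def test_missing_residue_rejected(self):
        series = pd.DataFrame({1: [0.0]})
        with pytest.raises(KeyError):
            local_energy_average(series, {1: np.zeros(3), 2: np.ones(3)})
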