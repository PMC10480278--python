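import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from phspec.ensemble import (
    CA,
    ConformationalEnsemble,
    PkaSeries,
    Selection,
    contact_metrics,
    gromos_cluster,
    hbond_count,
    kabsch_superpose,
    pairwise_rmsd,
    pka_populations,
    rmsd_series,
    rmsf_windows,
)
from phspec.synth import gen_pka_series, gen_two_state_ensemble


def make_ensemble(coords, elements=None, atom_names=None):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    atoms = pd.DataFrame(
        {
            "residue_index": np.arange(1, n + 1),
            "residue_name": ["ALA"] * n,
            "atom_name": atom_names if atom_names is not None else ["CA"] * n,
            "element": elements if elements is not None else ["C"] * n,
        }
    )
    return ConformationalEnsemble(coords, atoms, frame_spacing_ps=100.0)


def rigid_transform(coords, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.uniform(-20, 20, 3)
    return coords @ rot.T + shift


class TestKabsch:
    def test_identical_coordinates_zero_rmsd(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered(self):
        x = np.random.default_rng(1).normal(size=(12, 3))
        rot37 = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        moved = x @ rot37.T + np.array([5.0, -2.0, 1.0])
        r, t, rmsd = kabsch_superpose(moved, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(moved @ r.T + t, x, atol=1e-10)
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_matches_brute_force_rotation_grid(self):
        # 3-atom toy pair: optimum from a dense rotation grid
        mob = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0]])
        ref = np.array([[0.2, 0.1, 0], [3.5, 0.4, 0.3], [4.0, 3.6, -0.2]])
        _, _, rmsd = kabsch_superpose(mob, ref)
        xc = mob - mob.mean(axis=0)
        yc = ref - ref.mean(axis=0)
        def angle_rmsd(angles):
            m = Rotation.from_euler("zyz", angles).as_matrix()
            return np.sqrt(np.mean(np.sum((xc @ m.T - yc) ** 2, axis=1)))

        best, best_angles = np.inf, None
        grid = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        for a in grid:
            for b in np.linspace(0, np.pi, 15):
                for c in grid:
                    val = angle_rmsd([a, b, c])
                    if val < best:
                        best, best_angles = val, [a, b, c]
        refined = minimize(angle_rmsd, best_angles, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14})
        assert rmsd <= refined.fun + 1e-9
        assert rmsd == pytest.approx(refined.fun, abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_reference_frame_zero(self):
        ens = gen_two_state_ensemble(n_frames=20, seed=0)
        series = rmsd_series(ens)
        assert series[0] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_global_rigid_motion(self):
        ens = gen_two_state_ensemble(n_frames=20, seed=0)
        moved = make_ensemble(
            np.stack([rigid_transform(f, seed=i) for i, f in enumerate(ens.coords)])
        )
        np.testing.assert_allclose(rmsd_series(ens), rmsd_series(moved), atol=1e-9)

    def test_two_state_separation_visible(self):
        ens = gen_two_state_ensemble(n_frames=200, jitter_sd=0.1, seed=2)
        series = rmsd_series(ens, reference_frame=int(np.argmax(ens.states == 0)))
        hi = series[ens.states == 1]
        lo = series[ens.states == 0]
        assert hi.min() > lo.max()


class TestRmsfWindows:
    def test_static_ensemble_zero_rmsf(self):
        base = np.random.default_rng(3).normal(size=(30, 3)) * 5
        ens = make_ensemble(np.repeat(base[None], 10, axis=0))
        df = rmsf_windows(ens, window_ps=300.0)
        np.testing.assert_allclose(df["rmsf"], 0.0, atol=1e-9)

    def test_isotropic_jitter_calibration(self):
        # per-coordinate sd sigma -> per-atom RMSF sigma*sqrt(3);
        # superposition to the window mean removes 6 of 3N dof
        sigma, n_atoms = 0.3, 30
        ens = gen_two_state_ensemble(
            n_atoms=n_atoms, n_frames=1000, state_weights=(1, 0),
            jitter_sd=sigma, frame_spacing_ps=1.0, seed=3,
        )
        df = rmsf_windows(ens, window_ps=1000.0)
        expected = sigma * np.sqrt(3.0)
        assert df["rmsf"].mean() == pytest.approx(expected, rel=0.05)

    def test_loop_fluctuates_more_than_scaffold(self):
        # a small displaced loop: its fluctuation must dominate in every
        # window that samples both conformations
        ens = gen_two_state_ensemble(n_frames=400, seed=4, stickiness=0.0,
                                     loop_atoms=np.arange(45, 55))
        df = rmsf_windows(ens, window_ps=2000.0)
        loop = set(ens.atoms["residue_index"].to_numpy()[ens.loop_atoms])
        frames_per = int(2000.0 // ens.frame_spacing_ps)
        for w, g in df.groupby("window"):
            states = ens.states[w * frames_per:(w + 1) * frames_per]
            if states.min() == states.max():
                continue
            loop_mean = g[g["residue_index"].isin(loop)]["rmsf"].mean()
            scaff_mean = g[~g["residue_index"].isin(loop)]["rmsf"].mean()
            assert loop_mean > scaff_mean

    def test_short_window_rejected(self):
        ens = gen_two_state_ensemble(n_frames=10, seed=0)
        with pytest.raises(ValueError, match="2 frames"):
            rmsf_windows(ens, window_ps=100.0)  # spacing is 100 ps


class TestGromosCluster:
    def test_single_cluster_when_cutoff_exceeds_spread(self):
        ens = gen_two_state_ensemble(n_frames=30, seed=5)
        res = gromos_cluster(ens, cutoff=1e3)
        assert len(res.populations) == 1
        assert res.populations[0] == 1.0

    def test_two_state_population_recovery(self):
        ens = gen_two_state_ensemble(
            displacement=5.0, jitter_sd=0.3, state_weights=(0.8, 0.2),
            n_frames=500, seed=1,
        )
        res = gromos_cluster(ens, cutoff=2.0)
        top2 = np.sort(res.populations)[::-1][:2]
        assert top2[0] == pytest.approx(0.80, abs=0.03)
        assert top2[1] == pytest.approx(0.20, abs=0.03)
        # recovered clusters coincide with the generator's state labels
        true = np.bincount(ens.states, minlength=2) / ens.n_frames
        np.testing.assert_allclose(np.sort(top2), np.sort(true), atol=1e-12)

    def test_matches_brute_force_on_random_frames(self):
        ens = gen_two_state_ensemble(n_frames=20, seed=6)
        res = gromos_cluster(ens, cutoff=2.0)
        # independent oracle: per-pair Kabsch + explicit greedy loop
        coords = ens.coords[:, CA.mask(ens.atoms), :]
        n = len(coords)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = kabsch_superpose(coords[i], coords[j])[2]
        unassigned = set(range(n))
        expected = np.full(n, -1)
        cid = 0
        while unassigned:
            best_center, best_members = None, None
            for c in sorted(unassigned):
                members = [j for j in sorted(unassigned) if d[c, j] <= 2.0]
                if best_members is None or len(members) > len(best_members):
                    best_center, best_members = c, members
            for m in best_members:
                expected[m] = cid
                unassigned.discard(m)
            cid += 1
        np.testing.assert_array_equal(res.assignment, expected)

    def test_populations_sum_and_center_membership(self):
        ens = gen_two_state_ensemble(n_frames=50, seed=7)
        res = gromos_cluster(ens, cutoff=2.0)
        assert res.populations.sum() == pytest.approx(1.0)
        for cid, center in enumerate(res.centers):
            assert res.assignment[center] == cid

    def test_cluster_count_non_increasing_in_cutoff(self):
        ens = gen_two_state_ensemble(n_frames=60, seed=8)
        counts = [
            len(gromos_cluster(ens, cutoff=c).populations)
            for c in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_invariant_to_global_rigid_motion(self):
        ens = gen_two_state_ensemble(n_frames=40, seed=9)
        moved = make_ensemble(
            np.stack([rigid_transform(f, seed=i) for i, f in enumerate(ens.coords)])
        )
        a = gromos_cluster(ens, cutoff=2.0)
        b = gromos_cluster(moved, cutoff=2.0)
        np.testing.assert_array_equal(a.assignment, b.assignment)


class TestDistanceCounters:
    def test_hbond_cutoff_boundary(self):
        for dist, expect in [(3.3, 1), (3.5, 0)]:
            ens = make_ensemble(
                [[0, 0, 0], [dist, 0, 0]], elements=["N", "O"]
            )
            a = Selection.make(residues=(1, 1))
            b = Selection.make(residues=(2, 2))
            assert hbond_count(ens, 0, a, b) == expect

    def test_carbon_atoms_never_hbond(self):
        ens = make_ensemble([[0, 0, 0], [2.0, 0, 0]], elements=["C", "C"])
        a = Selection.make(residues=(1, 1))
        b = Selection.make(residues=(2, 2))
        assert hbond_count(ens, 0, a, b) == 0

    def test_overlapping_selections_rejected(self):
        ens = make_ensemble([[0, 0, 0], [3.0, 0, 0]], elements=["N", "O"])
        with pytest.raises(ValueError, match="disjoint"):
            hbond_count(ens, 0, Selection.make(), Selection.make(residues=(2, 2)))

    def test_hbond_matches_brute_force(self):
        rng = np.random.default_rng(10)
        n = 50
        coords = rng.uniform(0, 15, (n, 3))
        elements = rng.choice(["C", "N", "O", "S"], n)
        ens = make_ensemble(coords, elements=list(elements))
        a = Selection.make(residues=(1, 25))
        b = Selection.make(residues=(26, 50))
        expected = 0
        for i in range(25):
            for j in range(25, 50):
                if elements[i] in "NO" and elements[j] in "NO":
                    if np.linalg.norm(coords[i] - coords[j]) <= 3.4:
                        expected += 1
        assert hbond_count(ens, 0, a, b) == expected

    def test_contact_cutoff_and_minimum(self):
        for dist, count in [(5.9, 1), (6.1, 0)]:
            ens = make_ensemble([[0, 0, 0], [dist, 0, 0]], elements=["C", "C"])
            a = Selection.make(residues=(1, 1))
            b = Selection.make(residues=(2, 2))
            got = contact_metrics(ens, 0, a, b)
            assert got == (count, pytest.approx(dist))

    def test_contacts_match_brute_force(self):
        rng = np.random.default_rng(11)
        n = 60
        coords = rng.uniform(0, 20, (n, 3))
        elements = rng.choice(["C", "N", "O"], n)
        ens = make_ensemble(coords, elements=list(elements))
        a = Selection.make(residues=(1, 30))
        b = Selection.make(residues=(31, 60))
        count, dmin = 0, np.inf
        for i in range(30):
            for j in range(30, 60):
                if elements[i] == "C" and elements[j] == "C":
                    d = np.linalg.norm(coords[i] - coords[j])
                    dmin = min(dmin, d)
                    if d <= 6.0:
                        count += 1
        assert contact_metrics(ens, 0, a, b) == (count, pytest.approx(dmin))

    def test_no_carbon_selection_rejected(self):
        ens = make_ensemble([[0, 0, 0], [3.0, 0, 0]], elements=["N", "O"])
        with pytest.raises(ValueError, match="carbon"):
            contact_metrics(ens, 0, Selection.make(residues=(1, 1)),
                            Selection.make(residues=(2, 2)))


class TestPkaPopulations:
    TRANS = np.array([[0.9, 0.1], [0.3 / 7 * 0.9, 1 - 0.3 / 7 * 0.9]])

    def test_two_population_recovery(self):
        series = gen_pka_series([3.0, 10.0], [0.5, 0.5], self.TRANS,
                                n_frames=4000, seed=0)
        dec = pka_populations(series, seed=0)
        assert dec.n_components == 2
        np.testing.assert_allclose(dec.means, [3.0, 10.0], atol=0.2)
        np.testing.assert_allclose(dec.weights, [0.3, 0.7], atol=0.05)
        np.testing.assert_allclose(dec.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert dec.low_pka_fraction == pytest.approx(0.3, abs=0.05)

    def test_constant_series_degenerate(self):
        series = PkaSeries("E216", np.arange(1, 101.0), np.full(100, 4.2))
        dec = pka_populations(series)
        assert dec.degenerate and dec.n_components == 1
        assert dec.weights[0] == 1.0

    def test_three_population_recovery(self):
        trans = np.full((3, 3), 0.05)
        np.fill_diagonal(trans, 0.90)
        series = gen_pka_series([3.0, 8.0, 10.0], [0.4, 0.4, 0.4], trans,
                                n_frames=6000, seed=1)
        dec = pka_populations(series, max_components=3, seed=0)
        assert dec.n_components == 3
        assert dec.means[1] == pytest.approx(8.0, abs=0.3)

    def test_short_series_rejected(self):
        series = PkaSeries("D186", np.arange(1, 11.0),
                           np.random.default_rng(0).normal(5, 1, 10))
        with pytest.raises(ValueError, match="50"):
            pka_populations(series)


class TestPdbRoundTrip:
    def test_coordinates_survive_at_pdb_precision(self, tmp_path):
        ens = gen_two_state_ensemble(n_frames=5, seed=12)
        path = tmp_path / "ens.pdb"
        ens.to_pdb(path)
        back = ConformationalEnsemble.from_pdb(path)
        assert back.n_frames == ens.n_frames
        assert np.abs(back.coords - ens.coords).max() <= 1e-3 + 1e-9
        pd.testing.assert_series_equal(
            back.atoms["residue_index"].astype(int),
            ens.atoms["residue_index"].astype(int),
            check_names=False,
        )
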