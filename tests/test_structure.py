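"""Fibril structural metrics vs independent brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.linalg import eigvalsh
from scipy.spatial.transform import Rotation
from scipy.stats import special_ortho_group

from hdlamyloid import structure as fs
from hdlamyloid import synth
from hdlamyloid.datatypes import FibrilCoordinates, TrajectorySeries
from hdlamyloid.errors import StructureError


# --------------------------------------------------------------------------- #
# Oracles (independent, brute-force)
# --------------------------------------------------------------------------- #

def ordp_oracle(f, i, j, z):
    """Per-residue python-loop average of normalized dot products."""
    total = 0.0
    for r in range(f.n_residues):
        v = f.coords[j, r] - f.coords[i, r]
        total += sum(v[k] * z[k] for k in range(3)) / (
            math.sqrt(sum(x * x for x in v)) * math.sqrt(sum(x * x for x in z)))
    return total / f.n_residues


def rmsd_oracle(P, Q):
    """Minimum RMSD via scipy's align_vectors (independent Kabsch route)."""
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Qc, Pc)
    diff = rot.apply(Pc) - Qc
    return math.sqrt(float(np.mean(np.sum(diff ** 2, axis=1))))


def pca_eigvals_oracle(frames_flat):
    """Population covariance by an explicit outer-product sum + scipy eigh."""
    F, D = frames_flat.shape
    mu = frames_flat.mean(axis=0)
    cov = np.zeros((D, D))
    for x in frames_flat:
        d = x - mu
        cov += np.outer(d, d)
    cov /= F
    return np.sort(eigvalsh(cov))[::-1]


# --------------------------------------------------------------------------- #
# Order parameter
# --------------------------------------------------------------------------- #

class TestOrderParameter:
    def test_ideal_stack_is_one(self, ideal_fibril):
        assert fs.order_parameter(ideal_fibril) == 1.0

    def test_perpendicular_offset_is_zero(self, ideal_fibril):
        coords = ideal_fibril.coords.copy()
        coords[:, :, 2] = 0.0                    # collapse the rise
        coords[-1, :, 1] += 2.0                  # offset last chain along y
        f = FibrilCoordinates(ideal_fibril.chains, coords,
                              ideal_fibril.residue_numbers,
                              axis=np.array([0.0, 0.0, 1.0]))
        assert fs.order_parameter(f) == pytest.approx(0.0, abs=1e-12)

    def test_sixty_degree_displacement_is_half(self, ideal_fibril):
        coords = ideal_fibril.coords.copy()
        # displace the stack direction to 60° from z: cos 60° = 0.5
        rise = np.diff(coords[:, 0, 2])[0]
        for k in range(coords.shape[0]):
            coords[k, :, 1] += k * rise * np.tan(np.radians(60.0))
        f = FibrilCoordinates(ideal_fibril.chains, coords,
                              ideal_fibril.residue_numbers,
                              axis=np.array([0.0, 0.0, 1.0]))
        assert fs.order_parameter(f) == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, random_fibril_factory):
        f = random_fibril_factory(seed)
        z = np.array([0.3, -0.2, 0.93])
        got = fs.order_parameter(f, axis=z)
        want = ordp_oracle(f, 0, f.n_chains - 1, z / np.linalg.norm(z))
        assert got == pytest.approx(want, rel=1e-10)

    def test_bounded_and_rotation_translation_invariant(self, random_fibril_factory):
        f = random_fibril_factory(99)
        z = np.array([0.0, 0.0, 1.0])
        base = fs.order_parameter(f, axis=z)
        assert -1.0 <= base <= 1.0
        R = special_ortho_group.rvs(3, random_state=12345)
        shifted = FibrilCoordinates(f.chains, f.coords @ R.T + np.array([3, -1, 7.0]),
                                    f.residue_numbers)
        assert fs.order_parameter(shifted, axis=R @ z) == pytest.approx(base, rel=1e-9)

    def test_coincident_atoms_raise(self, ideal_fibril):
        coords = ideal_fibril.coords.copy()
        coords[-1] = coords[0]
        f = FibrilCoordinates(ideal_fibril.chains, coords,
                              ideal_fibril.residue_numbers,
                              axis=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(StructureError):
            fs.order_parameter(f)

    def test_signed_cosine_can_be_negative(self, ideal_fibril):
        assert fs.order_parameter(ideal_fibril,
                                  axis=np.array([0.0, 0.0, -1.0])) == -1.0


class TestOrdpEquilibrium:
    def test_identical_frames_zero_sem(self, ideal_fibril):
        traj = TrajectorySeries([ideal_fibril] * 6, np.arange(6.0))
        res = fs.ordp_equilibrium(traj)
        assert res.equilibrium_sem == 0.0
        assert res.equilibrium_mean == 1.0

    def test_full_window_uses_all_frames(self):
        traj = synth.gen_fibril_trajectory(
            synth.IdealFibrilSpec(seed=2), 8,
            distortion_schedule=[0.1] * 8)
        traj.equilibrium_window = 1.0
        res = fs.ordp_equilibrium(traj)
        assert res.equilibrium_mean == pytest.approx(
            float(np.mean(res.ordP_per_frame)))

    def test_distorted_mean_matches_monte_carlo(self):
        # oracle: fresh Monte-Carlo draws at the same distortion level
        sd = 0.15
        traj = synth.gen_fibril_trajectory(
            synth.IdealFibrilSpec(seed=10), 40, distortion_schedule=[sd] * 40)
        traj.equilibrium_window = 1.0
        res = fs.ordp_equilibrium(traj)
        mc = [fs.order_parameter(synth.gen_ideal_fibril(
            synth.IdealFibrilSpec(distortion_sd=sd, seed=1000 + s)))
            for s in range(60)]
        sem_tot = math.hypot(res.equilibrium_sem,
                             np.std(mc, ddof=1) / math.sqrt(len(mc)))
        assert abs(res.equilibrium_mean - np.mean(mc)) < 3 * sem_tot


# --------------------------------------------------------------------------- #
# Superposition / RMSD
# --------------------------------------------------------------------------- #

class TestKabschRmsd:
    def test_rigid_copy_aligns_to_zero(self, random_fibril_factory):
        f = random_fibril_factory(1)
        R = special_ortho_group.rvs(3, random_state=7)
        moved = f.coords.reshape(-1, 3) @ R.T + np.array([1.0, -2.0, 0.5])
        assert fs.rmsd(moved, f) < 1e-9

    def test_alignment_idempotent(self, random_fibril_factory):
        t = TrajectorySeries([random_fibril_factory(s) for s in range(3)],
                             np.arange(3.0))
        once = fs.kabsch_align(t)
        twice = fs.kabsch_align(once)
        for a, b in zip(once.frames, twice.frames):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_alignment_never_increases_rmsd(self, seed, random_fibril_factory):
        a, b = random_fibril_factory(seed), random_fibril_factory(seed + 100)
        assert fs.rmsd(a, b, align=True) <= fs.rmsd(a, b, align=False) + 1e-12

    def test_identical_frames_zero(self, ideal_fibril):
        assert fs.rmsd(ideal_fibril, ideal_fibril) == pytest.approx(0.0, abs=1e-12)

    def test_single_displaced_atom_hand_formula(self, ideal_fibril):
        moved = ideal_fibril.coords.copy()
        d = 0.7
        moved[0, 0, 0] += d
        N = moved.shape[0] * moved.shape[1]
        assert fs.rmsd(moved, ideal_fibril, align=False) == pytest.approx(
            math.sqrt(d ** 2 / N), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_kabsch_oracle(self, seed, random_fibril_factory):
        a = random_fibril_factory(seed).coords.reshape(-1, 3)
        b = random_fibril_factory(seed + 50).coords.reshape(-1, 3)
        assert fs.rmsd(a, b) == pytest.approx(rmsd_oracle(a, b), rel=1e-10)

    def test_collinear_configuration_raises(self):
        line = np.zeros((10, 3))
        line[:, 0] = np.arange(10.0)
        with pytest.raises(StructureError):
            fs.kabsch(line, line + 1.0)


# --------------------------------------------------------------------------- #
# PCA
# --------------------------------------------------------------------------- #

class TestPCA:
    def test_constant_trajectory_all_zero(self, ideal_fibril):
        traj = TrajectorySeries([ideal_fibril] * 4, np.arange(4.0))
        res = fs.pca_trajectory(traj)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_two_frame_single_atom_displacement(self, ideal_fibril):
        moved = FibrilCoordinates(ideal_fibril.chains,
                                  ideal_fibril.coords.copy(),
                                  ideal_fibril.residue_numbers)
        d = 0.8
        moved.coords[2, 5, 0] += d
        traj = TrajectorySeries([ideal_fibril, moved], np.array([0.0, 1.0]))
        res = fs.pca_trajectory(traj, align=False)
        # population covariance of two points separated by d: d²/4
        assert res.first_eigenvalue == pytest.approx(d ** 2 / 4, rel=1e-12)
        assert np.all(res.eigenvalues[1:] < 1e-12)

    @pytest.mark.parametrize("align", [False, True])
    def test_eigenvalue_sum_equals_trace(self, align, random_fibril_factory):
        frames = [random_fibril_factory(s) for s in range(6)]
        traj = TrajectorySeries(frames, np.arange(6.0))
        res = fs.pca_trajectory(traj, align=align)
        X = np.array([f.coords.reshape(-1) if not align else None
                      for f in frames]) if not align else None
        if not align:
            dev = X - X.mean(axis=0)
            trace = np.sum(dev ** 2) / len(frames)
            assert res.eigenvalues.sum() == pytest.approx(trace, rel=1e-9)
        else:
            # trace equals the total per-frame variance of the aligned coords
            assert res.eigenvalues.sum() == pytest.approx(
                np.sum(res.projections ** 2) / len(frames), rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed, random_fibril_factory):
        frames = [random_fibril_factory(seed * 10 + s) for s in range(5)]
        traj = TrajectorySeries(frames, np.arange(5.0))
        res = fs.pca_trajectory(traj, align=False)
        flat = np.array([f.coords.reshape(-1) for f in frames])
        want = pca_eigvals_oracle(flat)
        scale = max(want.max(), 1.0)
        np.testing.assert_allclose(res.eigenvalues, np.clip(want, 0, None),
                                   atol=1e-10 * scale)

    def test_single_frame_raises(self, ideal_fibril):
        traj = TrajectorySeries([ideal_fibril, ideal_fibril],
                                np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            fs.pca_trajectory(traj, window=1e-9)


# --------------------------------------------------------------------------- #
# Secondary structure
# --------------------------------------------------------------------------- #

def helical_stack(n_chains=2, n_res=20, separation=1.5):
    """Ideal α-helical Cα traces: radius 0.23 nm, rise 0.15 nm, 100°/residue."""
    t = np.radians(100.0) * np.arange(n_res)
    chain = np.column_stack([0.23 * np.cos(t), 0.23 * np.sin(t),
                             0.15 * np.arange(n_res)])
    coords = np.array([chain + np.array([k * separation, 0, 0])
                       for k in range(n_chains)])
    return FibrilCoordinates([chr(65 + k) for k in range(n_chains)], coords,
                             np.arange(1, n_res + 1))


class TestBetaSheet:
    def test_ideal_stack_fully_beta(self, ideal_fibril):
        prof = fs.beta_sheet_content(ideal_fibril)
        assert prof.beta_fraction == 1.0
        interior = prof.states[:, 1:-1]
        assert np.all(interior == "beta")

    def test_helical_trace_has_no_beta(self):
        prof = fs.beta_sheet_content(helical_stack())
        assert prof.beta_fraction == 0.0
        assert np.any(prof.states == "helix")

    def test_short_chain_raises(self):
        coords = np.random.default_rng(0).normal(size=(2, 4, 3))
        f = FibrilCoordinates(["A", "B"], coords, np.arange(4))
        with pytest.raises(StructureError):
            fs.beta_sheet_content(f)

    def test_distortion_lowers_beta_fraction(self):
        distorted = synth.gen_ideal_fibril(
            synth.IdealFibrilSpec(distortion_sd=0.25, seed=5))
        prof = fs.beta_sheet_content(distorted)
        assert prof.beta_fraction < 1.0

    def test_trajectory_reports_per_residue_probability(self):
        traj = synth.gen_fibril_trajectory(
            synth.IdealFibrilSpec(seed=1), 5, distortion_schedule=[0.1] * 5)
        prof = fs.beta_sheet_content(traj)
        assert prof.per_residue_beta is not None
        vals = prof.per_residue_beta[~np.isnan(prof.per_residue_beta)]
        assert np.all((0 <= vals) & (vals <= 1))


# --------------------------------------------------------------------------- #
# SASA / interface
# --------------------------------------------------------------------------- #

class TestInterface:
    def test_single_atom_closed_form(self):
        r = 0.17
        area = fs.sasa(np.zeros((1, 3)), np.array([r]), n_points=960)
        assert area == pytest.approx(4 * math.pi * (r + 0.14) ** 2, rel=0.01)

    def test_separated_groups_zero_interface(self):
        coords = np.vstack([np.zeros((4, 3)), np.full((4, 3), 10.0)])
        coords[:4, 0] += np.arange(4) * 0.3
        coords[4:, 0] += np.arange(4) * 0.3
        res = fs.interface_area(coords, np.arange(4))
        assert abs(res.interface_area) < 1e-3

    def test_superimposed_copy_buries_half_of_each_surface(self):
        # a duplicate partner makes the complex surface equal one copy's
        # surface, so interface = (2·SASA_A − SASA_A)/2 = SASA_A/2; the tiny
        # offset breaks the exact sphere-on-sphere sampling degeneracy
        rng = np.random.default_rng(3)
        A = rng.normal(0, 0.3, size=(6, 3))
        B = A + 1e-4
        res = fs.interface_area(np.vstack([A, B]), np.arange(6))
        assert res.interface_area == pytest.approx(res.sasa_A / 2, rel=0.05)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            fs.interface_area(np.zeros((3, 3)), np.array([], dtype=int))

    def test_fibril_complex_interface_positive(self, ideal_fibril):
        coords = ideal_fibril.coords.reshape(-1, 3)
        n = ideal_fibril.n_residues
        res = fs.interface_area(coords, np.arange(n))   # chain A vs rest
        assert res.interface_area > 0


# --------------------------------------------------------------------------- #
# PDB round trip
# --------------------------------------------------------------------------- #

class TestPdbIO:
    def test_roundtrip_to_format_precision(self, ideal_fibril, tmp_path):
        path = str(tmp_path / "fibril.pdb")
        fs.write_fibril(ideal_fibril, path)
        back = fs.read_fibril(path)
        assert back.n_chains == 5 and back.n_residues == 26
        np.testing.assert_allclose(back.coords, ideal_fibril.coords, atol=1e-4)
        assert fs.order_parameter(back, axis=np.array([0, 0, 1.0])) == \
            pytest.approx(1.0, abs=1e-6)

    def test_residue_selection(self, ideal_fibril, tmp_path):
        path = str(tmp_path / "fibril.pdb")
        fs.write_fibril(ideal_fibril, path)
        sub = fs.read_fibril(path, residue_range=(20, 30))
        assert sub.n_residues == 11

    def test_missing_chain_raises(self, ideal_fibril, tmp_path):
        path = str(tmp_path / "fibril.pdb")
        fs.write_fibril(ideal_fibril, path)
        with pytest.raises(StructureError):
            fs.read_fibril(path, chains=["F"])

    def test_missing_residues_raise(self, ideal_fibril, tmp_path):
        path = str(tmp_path / "fibril.pdb")
        fs.write_fibril(ideal_fibril, path)
        with pytest.raises(StructureError):
            fs.read_fibril(path, residue_range=(17, 60))

    def test_trajectory_roundtrip(self, tmp_path):
        traj = synth.gen_fibril_trajectory(
            synth.IdealFibrilSpec(seed=3), 4, distortion_schedule=[0.05] * 4)
        path = str(tmp_path / "traj.pdb")
        fs.write_fibril(traj, path)
        back = fs.read_trajectory(path)
        assert len(back.frames) == 4
        for a, b in zip(back.frames, traj.frames):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-4)

    def test_derived_axis_matches_construction(self, ideal_fibril, tmp_path):
        path = str(tmp_path / "fibril.pdb")
        fs.write_fibril(ideal_fibril, path)
        back = fs.read_fibril(path)       # axis not recorded in PDB
        np.testing.assert_allclose(fs.fibril_axis(back), [0, 0, 1.0], atol=1e-6)
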