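"""Structural-order metrics for cross-β fibril coordinate models.

The central statistic is the fibril order parameter

    ordP = (1/Nr) Σ_r cos α_r,   cos α_r = <v_r, z> / (|v_r| |z|)

where v_r joins the Cα of residue r in the first chain to the same residue's
Cα in the last chain and z is the fibril axis. ordP = 1 for a perfectly
aligned amyloid stack; values below 1 indicate a distorted structure. The
cosine is signed, so anti-aligned geometries map to negative values.

The module also provides Kabsch superposition and RMSD, essential-dynamics
PCA of the Cα coordinate covariance over a trajectory, a Cα-geometry
secondary-structure assignment (β-sheet content), and the buried
solvent-accessible surface between two groups of a complex.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .datatypes import (FibrilCoordinates, InterfaceResult, OrderParameterResult,
                        PCAResult, SecondaryStructureProfile, TrajectorySeries)
from .errors import StructureError

#: Uniform pseudo-atom radius for Cα-only models, nm.
CA_PSEUDO_RADIUS = 0.17
#: Water probe radius for SASA, nm.
PROBE_RADIUS = 0.14


# --------------------------------------------------------------------------- #
# PDB I/O (coordinates stored in nm, PDB files in Å)
# --------------------------------------------------------------------------- #

def _fibril_to_atom_array(f: FibrilCoordinates) -> bst.AtomArray:
    n = f.n_chains * f.n_residues
    arr = bst.AtomArray(n)
    arr.coord = (f.coords.reshape(n, 3) * 10.0).astype(np.float32)  # nm -> Å
    arr.chain_id = np.repeat([str(c) for c in f.chains], f.n_residues)
    arr.res_id = np.tile(f.residue_numbers, f.n_chains)
    arr.res_name = np.full(n, "ALA")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_fibril(f: Union[FibrilCoordinates, TrajectorySeries], path: str) -> None:
    """Write a fibril model (or trajectory, one MODEL per frame) as PDB."""
    pdb = PDBFile()
    if isinstance(f, TrajectorySeries):
        arrays = [_fibril_to_atom_array(fr) for fr in f.frames]
        stack = bst.stack(arrays)
        pdb.set_structure(stack)
    else:
        pdb.set_structure(_fibril_to_atom_array(f))
    pdb.write(path)


def _extract_frame(arr: bst.AtomArray, chains: Optional[Sequence[str]],
                   residue_range: Optional[tuple[int, int]]) -> FibrilCoordinates:
    ca = arr[(arr.atom_name == "CA") & ~arr.hetero]
    file_chains = list(dict.fromkeys(ca.chain_id))  # order as in file
    sel_chains = [str(c) for c in chains] if chains is not None else file_chains
    coords = []
    residues = None
    for ch in sel_chains:
        sub = ca[ca.chain_id == ch]
        if sub.array_length() == 0:
            raise StructureError(f"chain {ch!r} absent or has no CA atoms "
                                 f"(file has chains {file_chains})")
        res = sub.res_id
        if residue_range is not None:
            lo, hi = residue_range
            want = np.arange(lo, hi + 1)
            missing = np.setdiff1d(want, res)
            if missing.size:
                raise StructureError(
                    f"chain {ch!r} is missing CA atoms for residues "
                    f"{missing.tolist()}")
            mask = (res >= lo) & (res <= hi)
            sub = sub[mask]
            res = sub.res_id
        order = np.argsort(res, kind="stable")
        res = res[order]
        if residues is None:
            residues = res
        elif not np.array_equal(residues, res):
            raise StructureError("chains have differing residue index sets")
        coords.append(sub.coord[order] / 10.0)  # Å -> nm
    return FibrilCoordinates(sel_chains, np.array(coords), residues)


def read_fibril(path: str, chains: Optional[Sequence[str]] = None,
                residue_range: Optional[tuple[int, int]] = (17, 42),
                model: int = 1) -> FibrilCoordinates:
    """Read Cα coordinates for the selected chains/residues from a PDB file.

    Missing chains, residues or Cα atoms raise StructureError naming the gap.
    The fibril axis is left unset (derived from chain stacking on demand).
    """
    pdb = PDBFile.read(path)
    arr = pdb.get_structure(model=model)
    return _extract_frame(arr, chains, residue_range)


def read_trajectory(path: str, chains: Optional[Sequence[str]] = None,
                    residue_range: Optional[tuple[int, int]] = (17, 42),
                    times: Optional[np.ndarray] = None,
                    equilibrium_window: float = 0.2) -> TrajectorySeries:
    """Read a multi-MODEL PDB as a trajectory (one frame per MODEL)."""
    pdb = PDBFile.read(path)
    stack = pdb.get_structure()
    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    frames = []
    for i in range(stack.stack_depth()):
        frames.append(_extract_frame(stack[i], chains, residue_range))
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return TrajectorySeries(frames, times, equilibrium_window=equilibrium_window)


# --------------------------------------------------------------------------- #
# Order parameter
# --------------------------------------------------------------------------- #

def fibril_axis(f: FibrilCoordinates) -> np.ndarray:
    """Fibril axis: the recorded axis, or the normalized mean displacement
    between consecutive-chain centroids when none is recorded."""
    if f.axis is not None:
        return f.axis
    centroids = f.coords.mean(axis=1)
    disp = np.diff(centroids, axis=0).mean(axis=0)
    n = np.linalg.norm(disp)
    if n == 0:
        raise StructureError("cannot derive a fibril axis: "
                             "consecutive chain centroids coincide")
    return disp / n


def order_parameter(f: FibrilCoordinates,
                    first_chain: Optional[str] = None,
                    last_chain: Optional[str] = None,
                    axis: Optional[np.ndarray] = None) -> float:
    """Fibril order parameter: mean signed cosine between the per-residue
    first→last chain vectors and the fibril axis.

    Defaults compare the first and last chains in stacking order (A and E
    for a pentamer).
    """
    i = f.chain_index(first_chain) if first_chain is not None else 0
    j = f.chain_index(last_chain) if last_chain is not None else f.n_chains - 1
    z = np.asarray(axis, dtype=float) if axis is not None else fibril_axis(f)
    zn = np.linalg.norm(z)
    if zn == 0:
        raise ValueError("axis must be non-zero")
    v = f.coords[j] - f.coords[i]            # (Nr, 3)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        bad = f.residue_numbers[norms == 0]
        raise StructureError(f"coincident CA atoms for residues {bad.tolist()}")
    cos = (v @ z) / (norms * zn)
    return float(cos.mean())


def ordp_equilibrium(traj: TrajectorySeries,
                     first_chain: Optional[str] = None,
                     last_chain: Optional[str] = None,
                     axis: Optional[np.ndarray] = None) -> OrderParameterResult:
    """Per-frame ordP plus mean ± SEM over the trailing equilibrium window.

    The SEM treats equilibrium-window frames as independent samples; frame
    autocorrelation is not corrected for.
    """
    per_frame = np.array([order_parameter(fr, first_chain, last_chain, axis)
                          for fr in traj.frames])
    mask = traj.equilibrium_mask()
    sel = per_frame[mask]
    sem = float(sel.std(ddof=1) / np.sqrt(sel.size)) if sel.size > 1 else 0.0
    return OrderParameterResult(ordP_per_frame=per_frame,
                                equilibrium_mean=float(sel.mean()),
                                equilibrium_sem=sem)


# --------------------------------------------------------------------------- #
# Superposition, RMSD, PCA
# --------------------------------------------------------------------------- #

def _as_points(x) -> np.ndarray:
    if isinstance(x, FibrilCoordinates):
        return x.coords.reshape(-1, 3)
    arr = np.asarray(x, dtype=float)
    return arr.reshape(-1, 3)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t superposing mobile onto reference.

    Returns (R, t) such that ``mobile @ R.T + t`` minimizes the RMSD to the
    reference (proper rotation only; reflections are excluded). Degenerate
    (collinear) point sets raise StructureError.
    """
    P, Q = _as_points(mobile), _as_points(reference)
    if P.shape != Q.shape:
        raise ValueError("point sets must have the same shape")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-12 * max(S[0], 1e-300):
        raise StructureError("degenerate (collinear) configuration: "
                             "superposition rotation is not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return R, t


def _apply_kabsch(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    R, t = kabsch(coords, reference)
    return coords.reshape(-1, 3) @ R.T + t


def kabsch_align(traj: TrajectorySeries,
                 reference: Union[int, FibrilCoordinates, np.ndarray] = 0
                 ) -> TrajectorySeries:
    """Superpose every frame of a trajectory onto a reference frame."""
    ref = traj.frames[reference] if isinstance(reference, int) else reference
    ref_pts = _as_points(ref)
    frames = []
    for fr in traj.frames:
        pts = _apply_kabsch(_as_points(fr), ref_pts)
        frames.append(FibrilCoordinates(fr.chains,
                                        pts.reshape(fr.coords.shape),
                                        fr.residue_numbers, axis=fr.axis))
    return TrajectorySeries(frames, traj.times,
                            equilibrium_window=traj.equilibrium_window)


def rmsd(frame, reference, align: bool = True) -> float:
    """Root-mean-square Cα deviation, after Kabsch superposition by default."""
    P, Q = _as_points(frame), _as_points(reference)
    if align:
        P = _apply_kabsch(P, Q)
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def pca_trajectory(traj: TrajectorySeries, window: Optional[float] = None,
                   align: bool = True) -> PCAResult:
    """Essential-dynamics PCA of the Cα coordinate covariance.

    The covariance of the 3N Cartesian Cα coordinates is computed over the
    selected frames (population normalization, equal frame weights, no mass
    weighting) and diagonalized. ``window`` restricts the analysis to the
    trailing fraction of the time span (``None`` uses all frames). When
    ``align`` is true, frames are superposed onto their mean structure
    (two fixed-point passes) before the covariance is formed.
    """
    if window is None:
        mask = np.ones(len(traj.frames), dtype=bool)
    else:
        sub = TrajectorySeries(traj.frames, traj.times, equilibrium_window=window)
        mask = sub.equilibrium_mask()
    frames = [traj.frames[i] for i in np.flatnonzero(mask)]
    if len(frames) < 2:
        raise ValueError("PCA needs at least 2 frames in the window")
    X = np.array([_as_points(fr) for fr in frames])         # (F, N, 3)
    if align:
        mean = X[0]
        for _ in range(2):
            X = np.array([_apply_kabsch(x, mean) for x in X])
            mean = X.mean(axis=0)
    F, N, _ = X.shape
    flat = X.reshape(F, 3 * N)
    mu = flat.mean(axis=0)
    dev = flat - mu
    cov = dev.T @ dev / F
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PCAResult(eigenvalues=evals, components=evecs,
                     mean_structure=mu.reshape(N, 3),
                     projections=dev @ evecs)


# --------------------------------------------------------------------------- #
# Secondary structure (Cα geometry)
# --------------------------------------------------------------------------- #

#: d(i, i+3) window for helical geometry, nm (α-helix ≈ 0.50-0.55).
HELIX_D13 = (0.42, 0.60)
#: Minimum bend angle at residue i for extended (strand-like) geometry, deg.
EXTENDED_MIN_ANGLE = 120.0
#: Maximum same-residue inter-chain Cα distance for cross-β pairing, nm
#: (ideal cross-β spacing ≈ 0.48).
BETA_PAIR_CUTOFF = 0.6
#: Minimum chain length for the assignment stencil.
MIN_CHAIN_LENGTH = 5


def _assign_states(f: FibrilCoordinates) -> np.ndarray:
    """Per-chain, per-residue states.

    A residue is *helix* when a Cα(i)-Cα(i±3) distance falls in the helical
    window; *beta* when its local backbone is extended (bend angle at i at
    least EXTENDED_MIN_ANGLE) and the same residue of another chain lies
    within the cross-β pairing cutoff; otherwise *coil*. Terminal residues
    without a full bend stencil are left unassigned ("").
    """
    nc, nr = f.n_chains, f.n_residues
    if nr < MIN_CHAIN_LENGTH:
        raise StructureError(
            f"chains of {nr} residues are shorter than the "
            f"{MIN_CHAIN_LENGTH}-residue assignment stencil")
    states = np.full((nc, nr), "", dtype=object)
    for c in range(nc):
        xyz = f.coords[c]
        for i in range(nr):
            helix = False
            for j in (i + 3, i - 3):
                if 0 <= j < nr:
                    d = np.linalg.norm(xyz[i] - xyz[j])
                    if HELIX_D13[0] <= d <= HELIX_D13[1]:
                        helix = True
            if helix:
                states[c, i] = "helix"
                continue
            if not (0 < i < nr - 1):
                continue  # no bend stencil at the termini
            b1 = xyz[i] - xyz[i - 1]
            b2 = xyz[i + 1] - xyz[i]
            n1, n2 = np.linalg.norm(b1), np.linalg.norm(b2)
            if n1 == 0 or n2 == 0:
                states[c, i] = "coil"
                continue
            # bend angle at i: 180° = perfectly straight
            cosv = np.clip(b1 @ b2 / (n1 * n2), -1.0, 1.0)
            bend = 180.0 - np.degrees(np.arccos(cosv))
            extended = bend >= EXTENDED_MIN_ANGLE
            paired = False
            if extended and nc > 1:
                others = np.delete(f.coords[:, i, :], c, axis=0)
                paired = bool(np.min(np.linalg.norm(others - xyz[i], axis=1))
                              <= BETA_PAIR_CUTOFF)
            states[c, i] = "beta" if (extended and paired) else "coil"
    return states


def beta_sheet_content(f: Union[FibrilCoordinates, TrajectorySeries]
                       ) -> SecondaryStructureProfile:
    """β-sheet content from Cα geometry.

    For a single model, returns per-residue states and the fraction of
    assignable residues in the β state. For a trajectory, states are
    assigned per frame over the equilibrium window and the per-residue β
    probability plus its mean is reported.
    """
    if isinstance(f, TrajectorySeries):
        mask = f.equilibrium_mask()
        frames = [f.frames[i] for i in np.flatnonzero(mask)]
        all_states = [_assign_states(fr) for fr in frames]
        assignable = all_states[0] != ""
        beta_prob = np.mean([(s == "beta") for s in all_states], axis=0)
        frac = float(np.mean([
            (s == "beta").sum() / max((s != "").sum(), 1) for s in all_states]))
        return SecondaryStructureProfile(states=all_states[-1],
                                         beta_fraction=frac,
                                         per_residue_beta=np.where(assignable,
                                                                   beta_prob, np.nan))
    states = _assign_states(f)
    assignable = states != ""
    n_assignable = int(assignable.sum())
    frac = float((states == "beta").sum() / n_assignable) if n_assignable else 0.0
    return SecondaryStructureProfile(states=states, beta_fraction=frac)


# --------------------------------------------------------------------------- #
# Solvent-accessible surface / interface area
# --------------------------------------------------------------------------- #

def sasa(coords_nm: np.ndarray, radii_nm: Optional[np.ndarray] = None,
         probe_nm: float = PROBE_RADIUS, n_points: int = 960) -> float:
    """Shrake-Rupley solvent-accessible surface area, nm².

    Sphere-point sampling with ``n_points`` per atom; uniform Cα pseudo-atom
    radius (0.17 nm) unless per-atom radii are given.
    """
    coords_nm = np.asarray(coords_nm, dtype=float).reshape(-1, 3)
    n = coords_nm.shape[0]
    if n == 0:
        raise ValueError("empty coordinate set")
    if radii_nm is None:
        radii_nm = np.full(n, CA_PSEUDO_RADIUS)
    radii_nm = np.asarray(radii_nm, dtype=float)
    arr = bst.AtomArray(n)
    arr.coord = (coords_nm * 10.0).astype(np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.full(n, "ALA")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    per_atom = bst.sasa(arr, probe_radius=probe_nm * 10.0,
                        vdw_radii=(radii_nm * 10.0).astype(np.float32),
                        point_number=n_points)
    return float(np.nansum(per_atom)) / 100.0  # Å² -> nm²


def interface_area(coords_nm: np.ndarray, group_a: np.ndarray,
                   radii_nm: Optional[np.ndarray] = None,
                   probe_nm: float = PROBE_RADIUS,
                   n_points: int = 960) -> InterfaceResult:
    """Buried solvent-accessible surface between two groups of a complex.

    ``group_a`` is a boolean mask (or index array) over the atoms; the
    complement forms group B. interface = (SASA_A + SASA_B − SASA_AB) / 2.
    """
    coords_nm = np.asarray(coords_nm, dtype=float).reshape(-1, 3)
    n = coords_nm.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[np.asarray(group_a)] = True
    if mask.all() or not mask.any():
        raise ValueError("both groups must be non-empty")
    if radii_nm is None:
        radii_nm = np.full(n, CA_PSEUDO_RADIUS)
    radii_nm = np.asarray(radii_nm, dtype=float)
    a = sasa(coords_nm[mask], radii_nm[mask], probe_nm, n_points)
    b = sasa(coords_nm[~mask], radii_nm[~mask], probe_nm, n_points)
    ab = sasa(coords_nm, radii_nm, probe_nm, n_points)
    return InterfaceResult(sasa_A=a, sasa_B=b, sasa_complex=ab)
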