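"""Core data containers.

Units follow AFM / structural-biology conventions throughout: lengths and
heights in nanometres, areas in nm² (SASA) or cm² (membranes), transwell
times in minutes, ThT times in hours, trajectory times in nanoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


# --------------------------------------------------------------------------- #
# AFM imaging
# --------------------------------------------------------------------------- #

@dataclass
class HeightMap:
    """A 2D AFM height field.

    Parameters
    ----------
    heights : ndarray, shape (ny, nx)
        Surface heights in nm. Must be finite.
    pixel_size : float
        Lateral pixel size in nm (> 0).
    label : str
        Free-text sample label.
    time : float, optional
        Incubation time in hours, when the map belongs to a timecourse.
    """

    heights: np.ndarray
    pixel_size: float
    label: str = ""
    time: Optional[float] = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ValueError("heights must be a non-empty 2D grid")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def field_size(self) -> tuple[float, float]:
        """Physical extent (y, x) in nm."""
        return (self.heights.shape[0] * self.pixel_size,
                self.heights.shape[1] * self.pixel_size)


@dataclass
class ThresholdSummary:
    """Pixel count above a fixed height threshold."""

    threshold: float
    n_above: int
    n_total: int

    @property
    def percent_above(self) -> float:
        return 100.0 * self.n_above / self.n_total


@dataclass
class FibrillationTimecourse:
    """Mean threshold pixel percentage vs incubation time.

    ``normalized`` is populated by :func:`hdlamyloid.afm.normalize_timecourse`
    (each value divided by the t=0 value) and is ``None`` until then.
    """

    times: np.ndarray            # hours, strictly increasing
    percent_above: np.ndarray    # mean over replicates, per time
    dispersion: np.ndarray       # SD over replicates, per time
    threshold: float
    normalized: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.percent_above = np.asarray(self.percent_above, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


# --------------------------------------------------------------------------- #
# Particle morphometry
# --------------------------------------------------------------------------- #

@dataclass
class HeightDistribution:
    """Normalized per-pixel height histogram over an analysis range."""

    bin_edges: np.ndarray        # nm, length n_bins + 1
    density: np.ndarray          # per-nm density; integrates to 1
    range: tuple[float, float]
    n_pixels_counted: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class SphereFit:
    """Tangent-sphere height-model fit result."""

    diameter_2Rs: float          # nm
    broadening_sd: float         # nm
    goodness: float              # residual sum of squares


@dataclass
class DiscFit:
    """Broadened δ-peak disc-model fit plus upper-tail regression."""

    height_hD: float             # nm
    broadening_sd: float         # nm
    goodness: float
    tail_slope: float            # density per nm; NaN when undefined
    tail_intercept: float
    tail_defined: bool = True


@dataclass
class ShapeClassification:
    """Outcome of the sphere-vs-disc model comparison."""

    model: str                   # "sphere" | "disc"
    sphere_fit: SphereFit
    disc_fit: DiscFit
    margin: float                # losing RSS / winning RSS (≥ 1)
    uncertain: bool


@dataclass
class LipidationRatio:
    """Lipid:protein stoichiometry of an HDL preparation."""

    weight_ratio: float
    mw_lipid: float              # g/mol
    mw_protein: float            # g/mol

    @property
    def molar_ratio(self) -> float:
        return self.weight_ratio * self.mw_protein / self.mw_lipid


# --------------------------------------------------------------------------- #
# Fibril coordinate models
# --------------------------------------------------------------------------- #

@dataclass
class FibrilCoordinates:
    """Cα coordinates of a stacked cross-β fibril model.

    Parameters
    ----------
    chains : sequence of str
        Chain identifiers in stacking order (e.g. ``["A", ..., "E"]``).
    coords : ndarray, shape (n_chains, n_residues, 3)
        Cα positions in nm.
    residue_numbers : ndarray of int
        Residue numbers shared by every chain (default range 17-42).
    axis : ndarray shape (3,), optional
        Fibril axis z as a unit vector. ``None`` means "derive from the
        chain stacking" (mean consecutive-centroid displacement).
    """

    chains: Sequence[str]
    coords: np.ndarray
    residue_numbers: np.ndarray
    axis: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_chains, n_residues, 3)")
        if self.coords.shape[0] != len(self.chains):
            raise ValueError("coords first dimension must match chains")
        if self.coords.shape[1] != len(self.residue_numbers):
            raise ValueError("coords second dimension must match residue_numbers")
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=float)
            n = np.linalg.norm(self.axis)
            if n == 0:
                raise ValueError("axis must be non-zero")
            self.axis = self.axis / n

    @property
    def n_chains(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def chain_index(self, chain: str) -> int:
        try:
            return list(self.chains).index(chain)
        except ValueError:
            raise KeyError(f"chain {chain!r} not present (have {list(self.chains)})")


@dataclass
class TrajectorySeries:
    """Time-ordered fibril snapshots with an equilibrium window.

    The equilibrium window is the trailing fraction of the simulated time
    span over which structural observables are averaged (default 0.2,
    i.e. the final fifth of the trajectory).
    """

    frames: Sequence[FibrilCoordinates]
    times: np.ndarray            # ns, strictly increasing
    equilibrium_window: float = 0.2

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0 < self.equilibrium_window <= 1):
            raise ValueError("equilibrium_window must be in (0, 1]")
        shapes = {f.coords.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames must be structurally congruent")

    def equilibrium_mask(self) -> np.ndarray:
        """Boolean mask of frames inside the trailing equilibrium window."""
        t0, t1 = self.times[0], self.times[-1]
        cutoff = t1 - self.equilibrium_window * (t1 - t0)
        mask = self.times >= cutoff
        if not mask.any():  # single-frame trajectories
            mask[-1] = True
        return mask


@dataclass
class OrderParameterResult:
    ordP_per_frame: np.ndarray
    equilibrium_mean: float
    equilibrium_sem: float


@dataclass
class PCAResult:
    """Essential-dynamics decomposition of Cα fluctuations."""

    eigenvalues: np.ndarray          # nm², descending
    components: np.ndarray           # (3N, 3N) eigenvectors as columns
    mean_structure: np.ndarray       # (n_atoms, 3) nm
    projections: np.ndarray          # (n_frames, 3N) nm

    @property
    def first_eigenvalue(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def variance_fraction_pc1(self) -> float:
        tot = float(self.eigenvalues.sum())
        return float(self.eigenvalues[0]) / tot if tot > 0 else 0.0


@dataclass
class SecondaryStructureProfile:
    """Per-residue, per-chain secondary-structure states.

    ``states`` holds one of ``"beta"``, ``"helix"``, ``"coil"`` per
    assignable residue and ``""`` for terminal residues outside the
    assignment stencil.
    """

    states: np.ndarray               # (n_chains, n_residues) of str
    beta_fraction: float
    per_residue_beta: Optional[np.ndarray] = None   # trajectory probability


@dataclass
class InterfaceResult:
    """Buried solvent-accessible surface between two groups."""

    sasa_A: float                # nm²
    sasa_B: float                # nm²
    sasa_complex: float          # nm²

    @property
    def interface_area(self) -> float:
        return 0.5 * (self.sasa_A + self.sasa_B - self.sasa_complex)


# --------------------------------------------------------------------------- #
# Transwell / ThT
# --------------------------------------------------------------------------- #

@dataclass
class TranswellExperiment:
    """Two-compartment transwell concentration series.

    ``direction`` records which compartment is donor: ``"b2a"`` for
    basolateral→apical (efflux) or ``"a2b"`` for apical→basolateral.
    TEER (Ω·cm²) is carried as metadata only and never enters any
    computation.
    """

    donor_volume: float          # mL
    receiver_volume: float       # mL
    area: float                  # cm²
    times: np.ndarray            # minutes
    receiver_conc: np.ndarray    # amount / mL, per time
    donor_conc0: float           # amount / mL at t=0
    direction: str = "b2a"
    teer: Optional[float] = None
    true_permeability: Optional[float] = None   # ground truth when simulated

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.receiver_conc = np.asarray(self.receiver_conc, dtype=float)
        if self.area <= 0 or self.donor_volume <= 0 or self.receiver_volume <= 0:
            raise ValueError("volumes and area must be > 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.receiver_conc < 0):
            raise ValueError("receiver concentrations must be >= 0")
        if self.direction not in ("b2a", "a2b"):
            raise ValueError("direction must be 'b2a' or 'a2b'")


@dataclass
class PermeabilityResult:
    """Apparent endothelial permeability from the sink-condition regression."""

    EP: float                    # cm/min (reported ≥ 0)
    fit_intercept: float         # amount
    r_squared: float
    n_points_used: int
    negative_slope: bool = False


@dataclass
class ThTTrace:
    """Thioflavin-T fluorescence vs time."""

    times: np.ndarray            # hours
    intensity: np.ndarray        # a.u., ≥ 0
    normalized: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


# --------------------------------------------------------------------------- #
# Statistics
# --------------------------------------------------------------------------- #

@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict = field(default_factory=dict)


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float
    q: float
    p_adj: float
    significant: bool


@dataclass
class TukeyResult:
    pairs: list
    alpha: float

    def pair(self, a: str, b: str) -> TukeyPair:
        for p in self.pairs:
            if {p.group_a, p.group_b} == {a, b}:
                return p
        raise KeyError(f"pair ({a}, {b}) not found")
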