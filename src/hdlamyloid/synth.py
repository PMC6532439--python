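"""Synthetic-data generators with known ground truth.

Every downstream analysis in this package can be exercised without external
data: AFM fields of spherical or discoidal HDL particles and of worm-like
fibrils, ideal cross-β Cα stacks with controllable distortion, two-compartment
transwell permeation series with a known permeability, and monotone ThT
decays. All generators are bit-reproducible under a fixed seed and carry
their ground-truth parameters in the returned objects (or in the spec object
the caller keeps), so estimator recovery error is always quantifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .datatypes import FibrilCoordinates, HeightMap, ThTTrace, TranswellExperiment, TrajectorySeries
from .errors import PlacementError

_MAX_PLACEMENT_TRIES = 10_000


# --------------------------------------------------------------------------- #
# Field specs
# --------------------------------------------------------------------------- #

@dataclass
class SphereFieldSpec:
    """Spherical-particle AFM field (models mature spherical HDL).

    Particles are rendered as the upper surface of a sphere of the stated
    diameter tangent to the substrate plane, so the apex height equals the
    diameter. Centers are placed at least one diameter apart.
    """

    n_particles: int
    diameter: float              # nm
    field_size: float            # nm (square field)
    pixel_size: float            # nm
    noise_sd: float = 0.0        # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.pixel_size <= 0:
            raise ValueError("diameter and pixel_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.diameter >= self.field_size:
            raise ValueError("diameter must be smaller than field_size")


@dataclass
class DiscFieldSpec:
    """Discoidal-particle AFM field (models nascent discoidal HDL).

    Discs are flat plateaus of ``disc_height`` over circular footprints.
    """

    n_particles: int
    disc_height: float           # nm
    disc_diameter: float         # nm
    field_size: float            # nm
    pixel_size: float            # nm
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disc_height <= 0 or self.disc_diameter <= 0 or self.pixel_size <= 0:
            raise ValueError("disc_height, disc_diameter and pixel_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.disc_diameter >= self.field_size:
            raise ValueError("disc_diameter must be smaller than field_size")


@dataclass
class FibrilFieldSpec:
    """Worm-like-chain fibril AFM field.

    Each fibril is a discretized worm-like chain: tangent angle diffuses with
    per-step variance ``step / persistence_length`` (step = one pixel), and
    the path is rasterized at constant ``fibril_height``. Paths reflect at
    field boundaries so the rasterized fibril stays inside the field.
    """

    n_fibrils: int
    contour_length: float        # nm
    persistence_length: float    # nm
    fibril_height: float         # nm
    field_size: float            # nm
    pixel_size: float            # nm
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibrils > 0 and self.contour_length <= 0:
            raise ValueError("contour_length must be > 0")
        if self.persistence_length <= 0 or self.fibril_height <= 0:
            raise ValueError("persistence_length and fibril_height must be > 0")
        if self.pixel_size <= 0 or self.noise_sd < 0:
            raise ValueError("pixel_size must be > 0 and noise_sd >= 0")


@dataclass
class IdealFibrilSpec:
    """Ideal cross-β Cα stack: n_chains copies of an extended template.

    Chain k is the template translated by ``(k-1) * rise_per_chain`` along z
    and rotated by ``(k-1) * twist_deg_per_chain`` about z, then perturbed by
    isotropic Gaussian noise of sd ``distortion_sd`` per atom. The default
    rise of 0.48 nm is the canonical cross-β inter-strand spacing; the
    default residue range 17-42 covers the amyloid core of Aβ1-42.
    """

    n_chains: int = 5
    residue_start: int = 17
    residue_stop: int = 42       # inclusive
    rise_per_chain: float = 0.48     # nm
    twist_deg_per_chain: float = 0.0
    distortion_sd: float = 0.0       # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.residue_stop < self.residue_start:
            raise ValueError("residue range must be non-empty")
        if self.distortion_sd < 0:
            raise ValueError("distortion_sd must be >= 0")

    @property
    def n_residues(self) -> int:
        return self.residue_stop - self.residue_start + 1


@dataclass
class TranswellSimSpec:
    """Two-compartment transwell permeation with known permeability.

    Defaults mirror a standard 12-well insert BBB setup: 1.12 cm² membrane,
    0.5 mL apical and 1.0 mL basolateral medium.
    """

    true_permeability: float     # cm/min
    donor_conc0: float           # amount/mL
    sample_times: np.ndarray     # minutes, strictly increasing from 0
    donor_volume: float = 0.5    # mL
    receiver_volume: float = 1.0  # mL
    area: float = 1.12           # cm²
    noise_cv: float = 0.0
    direction: str = "a2b"
    seed: int = 0

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if min(self.donor_volume, self.receiver_volume, self.area) <= 0:
            raise ValueError("volumes and area must be > 0")
        if self.donor_conc0 <= 0:
            raise ValueError("donor_conc0 must be > 0")
        if self.true_permeability < 0:
            raise ValueError("true_permeability must be >= 0")
        if self.sample_times[0] < 0 or np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing from 0")


@dataclass
class ThTSimSpec:
    """Monotone ThT fluorescence trace with optional decay.

    ``decay_model`` is one of ``"none"``, ``"exponential"`` or
    ``"sigmoidal"``. The exponential model relaxes from the baseline to
    ``plateau_fraction * baseline`` at rate ``decay_rate`` (1/h); the
    sigmoidal model is a logistic decay with midpoint ``1 / decay_rate``.
    """

    baseline_intensity: float    # a.u.
    sample_times: np.ndarray     # hours
    decay_model: str = "none"
    decay_rate: float = 0.0      # 1/h
    plateau_fraction: float = 0.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")
        if not 0 <= self.plateau_fraction <= 1:
            raise ValueError("plateau_fraction must be in [0, 1]")
        if self.decay_model not in ("none", "exponential", "sigmoidal"):
            raise ValueError("decay_model must be none|exponential|sigmoidal")


# --------------------------------------------------------------------------- #
# Particle placement
# --------------------------------------------------------------------------- #

def _place_centers(rng: np.random.Generator, n: int, field_size: float,
                   margin: float, min_dist: float) -> np.ndarray:
    """Dart-throwing placement of n centers with a minimum pairwise distance.

    Centers keep ``margin`` from the field edge so footprints stay inside.
    """
    centers: list[np.ndarray] = []
    lo, hi = margin, field_size - margin
    if hi <= lo and n > 0:
        raise PlacementError("field too small for requested particle size")
    tries = 0
    while len(centers) < n:
        if tries >= _MAX_PLACEMENT_TRIES:
            raise PlacementError(
                f"could not place {n} particles with min distance {min_dist} nm "
                f"in a {field_size} nm field after {tries} tries")
        c = rng.uniform(lo, hi, size=2)
        tries += 1
        if all(np.hypot(*(c - p)) >= min_dist for p in centers):
            centers.append(c)
    return np.array(centers).reshape(n, 2)


def _pixel_grid(field_size: float, pixel_size: float) -> tuple[np.ndarray, np.ndarray, int]:
    n_px = int(round(field_size / pixel_size))
    coords = (np.arange(n_px) + 0.5) * pixel_size
    return coords, coords, n_px


# --------------------------------------------------------------------------- #
# AFM field generators
# --------------------------------------------------------------------------- #

def gen_sphere_field(spec: SphereFieldSpec) -> HeightMap:
    """Render a field of tangent spheres plus i.i.d. Gaussian pixel noise.

    The height at lateral offset r from a particle center is
    ``R + sqrt(R² - r²)`` for r ≤ R (R = diameter/2): the upper hemisphere of
    a sphere resting on the substrate, so the apex reads the full diameter.
    """
    rng = np.random.default_rng(spec.seed)
    xs, ys, n_px = _pixel_grid(spec.field_size, spec.pixel_size)
    heights = np.zeros((n_px, n_px))
    R = spec.diameter / 2.0
    centers = _place_centers(rng, spec.n_particles, spec.field_size,
                             margin=R, min_dist=spec.diameter)
    for cx, cy in centers:
        _render_sphere(heights, xs, ys, cx, cy, R, spec.pixel_size)
    if spec.noise_sd > 0:
        heights += rng.normal(0.0, spec.noise_sd, size=heights.shape)
    return HeightMap(heights, spec.pixel_size, label="sphere_field")


def _render_sphere(heights: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                   cx: float, cy: float, R: float, px: float) -> None:
    i0 = max(0, int((cy - R) / px) - 1)
    i1 = min(len(ys), int((cy + R) / px) + 2)
    j0 = max(0, int((cx - R) / px) - 1)
    j1 = min(len(xs), int((cx + R) / px) + 2)
    yy = ys[i0:i1, None]
    xx = xs[None, j0:j1]
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    inside = r2 <= R ** 2
    patch = np.where(inside, R + np.sqrt(np.maximum(R ** 2 - r2, 0.0)), 0.0)
    np.maximum(heights[i0:i1, j0:j1], patch, out=heights[i0:i1, j0:j1])


def gen_disc_field(spec: DiscFieldSpec) -> HeightMap:
    """Render a field of flat discs (plateau height over circular footprint)."""
    rng = np.random.default_rng(spec.seed)
    xs, ys, n_px = _pixel_grid(spec.field_size, spec.pixel_size)
    heights = np.zeros((n_px, n_px))
    R = spec.disc_diameter / 2.0
    centers = _place_centers(rng, spec.n_particles, spec.field_size,
                             margin=R, min_dist=spec.disc_diameter)
    for cx, cy in centers:
        i0 = max(0, int((cy - R) / spec.pixel_size) - 1)
        i1 = min(n_px, int((cy + R) / spec.pixel_size) + 2)
        j0 = max(0, int((cx - R) / spec.pixel_size) - 1)
        j1 = min(n_px, int((cx + R) / spec.pixel_size) + 2)
        yy = ys[i0:i1, None]
        xx = xs[None, j0:j1]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= R ** 2
        patch = np.where(inside, spec.disc_height, 0.0)
        np.maximum(heights[i0:i1, j0:j1], patch, out=heights[i0:i1, j0:j1])
    if spec.noise_sd > 0:
        heights += rng.normal(0.0, spec.noise_sd, size=heights.shape)
    return HeightMap(heights, spec.pixel_size, label="disc_field")


def gen_fibril_field(spec: FibrilFieldSpec) -> HeightMap:
    """Render worm-like-chain fibrils rasterized at constant height.

    Tangent angles perform a Gaussian random walk with per-step variance
    step/persistence_length (step = one pixel); paths reflect off the field
    boundary so the whole contour stays inside the field.
    """
    rng = np.random.default_rng(spec.seed)
    _, _, n_px = _pixel_grid(spec.field_size, spec.pixel_size)
    heights = np.zeros((n_px, n_px))
    step = spec.pixel_size
    if spec.n_fibrils > 0:
        n_steps = max(1, int(round(spec.contour_length / step)))
        angle_sd = np.sqrt(step / spec.persistence_length)
        for _ in range(spec.n_fibrils):
            pos = rng.uniform(0.0, spec.field_size, size=2)
            theta = rng.uniform(0.0, 2 * np.pi)
            for _ in range(n_steps):
                i = min(n_px - 1, max(0, int(pos[1] / step)))
                j = min(n_px - 1, max(0, int(pos[0] / step)))
                heights[i, j] = spec.fibril_height
                theta += rng.normal(0.0, angle_sd)
                nxt = pos + step * np.array([np.cos(theta), np.sin(theta)])
                # reflect at the walls, component-wise
                for d in (0, 1):
                    if nxt[d] < 0:
                        nxt[d] = -nxt[d]
                        theta = np.pi - theta if d == 0 else -theta
                    elif nxt[d] >= spec.field_size:
                        nxt[d] = 2 * spec.field_size - nxt[d] - 1e-9
                        theta = np.pi - theta if d == 0 else -theta
                pos = nxt
    if spec.noise_sd > 0:
        heights += rng.normal(0.0, spec.noise_sd, size=heights.shape)
    return HeightMap(heights, spec.pixel_size, label="fibril_field")


# --------------------------------------------------------------------------- #
# Coordinate-model generators
# --------------------------------------------------------------------------- #

#: Cα-Cα spacing of the extended template chain, nm. Only the inter-chain
#: geometry matters for the order parameter, so a straight extended chain
#: is a sufficient template.
TEMPLATE_CA_SPACING = 0.35

_CHAIN_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _template_chain(n_residues: int) -> np.ndarray:
    """Straight extended Cα template along x, centred on the z axis."""
    x = TEMPLATE_CA_SPACING * (np.arange(n_residues) - (n_residues - 1) / 2.0)
    out = np.zeros((n_residues, 3))
    out[:, 0] = x
    return out


def gen_ideal_fibril(spec: IdealFibrilSpec,
                     rng: Optional[np.random.Generator] = None) -> FibrilCoordinates:
    """Build an ideal cross-β stack, optionally distorted.

    With zero twist and zero distortion the inter-chain vectors are exact
    multiples of z, so the fibril order parameter of the output is exactly 1.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    template = _template_chain(spec.n_residues)
    coords = np.empty((spec.n_chains, spec.n_residues, 3))
    for k in range(spec.n_chains):
        ang = np.deg2rad(k * spec.twist_deg_per_chain)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                        [np.sin(ang), np.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        coords[k] = template @ rot.T
        coords[k, :, 2] += k * spec.rise_per_chain
    if spec.distortion_sd > 0:
        coords += rng.normal(0.0, spec.distortion_sd, size=coords.shape)
    chains = [_CHAIN_LABELS[k % 26] for k in range(spec.n_chains)]
    residues = np.arange(spec.residue_start, spec.residue_stop + 1)
    return FibrilCoordinates(chains, coords, residues, axis=np.array([0.0, 0.0, 1.0]))


def gen_fibril_trajectory(spec: IdealFibrilSpec, n_frames: int,
                          distortion_schedule: Optional[Sequence[float]] = None,
                          times: Optional[np.ndarray] = None) -> TrajectorySeries:
    """Draw a pseudo-trajectory of distorted stacks.

    ``distortion_schedule`` gives the per-frame distortion sd (nm); when
    omitted, ``spec.distortion_sd`` is used for every frame. A constant
    zero schedule yields identical frames.
    """
    if distortion_schedule is None:
        schedule = np.full(n_frames, spec.distortion_sd)
    else:
        schedule = np.asarray(distortion_schedule, dtype=float)
        if len(schedule) != n_frames:
            raise ValueError("distortion_schedule length must equal n_frames")
    if times is None:
        times = np.arange(n_frames, dtype=float)
    rng = np.random.default_rng(spec.seed)
    frames = []
    for sd in schedule:
        frame_spec = IdealFibrilSpec(
            n_chains=spec.n_chains, residue_start=spec.residue_start,
            residue_stop=spec.residue_stop, rise_per_chain=spec.rise_per_chain,
            twist_deg_per_chain=spec.twist_deg_per_chain,
            distortion_sd=float(sd), seed=spec.seed)
        frames.append(gen_ideal_fibril(frame_spec, rng=rng))
    return TrajectorySeries(frames, np.asarray(times, dtype=float))


# --------------------------------------------------------------------------- #
# Kinetics generators
# --------------------------------------------------------------------------- #

def transwell_receiver_conc(spec: TranswellSimSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free receiver concentration of the two-compartment exchange.

    dQ_r/dt = P·A·(C_d − C_r) with mass conservation gives the closed form
    C_r(t) = C_eq·(1 − exp(−k t)), C_eq = Q0/(V_d+V_r),
    k = P·A·(1/V_d + 1/V_r).
    """
    t = np.asarray(t, dtype=float)
    q0 = spec.donor_conc0 * spec.donor_volume
    c_eq = q0 / (spec.donor_volume + spec.receiver_volume)
    k = spec.true_permeability * spec.area * (1.0 / spec.donor_volume +
                                              1.0 / spec.receiver_volume)
    return c_eq * (1.0 - np.exp(-k * t))


def gen_transwell_series(spec: TranswellSimSpec) -> TranswellExperiment:
    """Sample the exact two-compartment relaxation, with optional CV noise.

    Noise is multiplicative: each sampled receiver concentration is scaled by
    a Gaussian factor of mean 1 and sd ``noise_cv``, truncated at zero.
    """
    rng = np.random.default_rng(spec.seed)
    conc = transwell_receiver_conc(spec, spec.sample_times)
    if spec.noise_cv > 0:
        factors = np.maximum(rng.normal(1.0, spec.noise_cv, size=conc.shape), 0.0)
        conc = conc * factors
    return TranswellExperiment(
        donor_volume=spec.donor_volume, receiver_volume=spec.receiver_volume,
        area=spec.area, times=spec.sample_times, receiver_conc=conc,
        donor_conc0=spec.donor_conc0, direction=spec.direction,
        true_permeability=spec.true_permeability)


def tht_model_intensity(spec: ThTSimSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free model intensity at times t (hours)."""
    t = np.asarray(t, dtype=float)
    b, p, k = spec.baseline_intensity, spec.plateau_fraction, spec.decay_rate
    if spec.decay_model == "none":
        return np.full_like(t, b)
    if spec.decay_model == "exponential":
        return b * (p + (1.0 - p) * np.exp(-k * t))
    # sigmoidal: logistic decay, midpoint at 1/k hours
    t_half = 1.0 / k if k > 0 else np.inf
    frac = 1.0 / (1.0 + np.exp(k * (t - t_half))) if np.isfinite(t_half) else np.ones_like(t)
    frac0 = 1.0 / (1.0 + np.exp(-k * t_half)) if np.isfinite(t_half) else 1.0
    return b * (p + (1.0 - p) * frac / frac0)


def gen_tht_trace(spec: ThTSimSpec) -> ThTTrace:
    """Sample a ThT trace with multiplicative CV noise (truncated at zero)."""
    rng = np.random.default_rng(spec.seed)
    intensity = tht_model_intensity(spec, spec.sample_times)
    if spec.noise_cv > 0:
        factors = np.maximum(rng.normal(1.0, spec.noise_cv, size=intensity.shape), 0.0)
        intensity = intensity * factors
    return ThTTrace(spec.sample_times, intensity)
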