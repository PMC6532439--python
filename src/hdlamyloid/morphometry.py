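"""Sphere-vs-disc HDL morphometry from AFM height statistics.

Spherical and discoidal HDL of near-identical lateral size are separated by
the *shape* of their per-pixel height distribution:

* a sphere of diameter D resting on the substrate produces heights
  h = R + sqrt(R² − r²) over a uniformly sampled footprint, giving the
  triangular density P(h) ∝ (h − R) on [R, 2R] (R = D/2) — derived from the
  area element of the tangent sphere's upper surface, assuming a
  zero-width tip;
* a disc of height h_D produces a δ-peak at h_D, broadened by pixel noise
  into a Gaussian, with an instrument/population tail on the high side that
  is summarized by a linear regression over the upper tail.

Both models are fitted by least squares to the normalized height histogram
and the lower residual decides the population shape. Lipidation
stoichiometry (mol lipid per mol protein) is computed from the preparation's
lipid:protein weight ratio and the molecular masses.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datatypes import (DiscFit, HeightDistribution, HeightMap,
                        LipidationRatio, ShapeClassification, SphereFit)
from .errors import EmptyDistributionError, FitError

#: Default analysis range for HDL particle heights, nm.
DEFAULT_RANGE = (4.0, 25.0)
#: Default number of histogram bins over the analysis range (0.25 nm bins).
DEFAULT_BINS = 84
#: Residual-ratio margin below which a classification is flagged uncertain.
UNCERTAIN_MARGIN = 2.0


# --------------------------------------------------------------------------- #
# Height distribution
# --------------------------------------------------------------------------- #

def height_distribution(hmap: HeightMap,
                        range: tuple[float, float] = DEFAULT_RANGE,
                        n_bins: int = DEFAULT_BINS) -> HeightDistribution:
    """Normalized per-pixel height histogram over an analysis range.

    Only pixels whose height falls inside ``range`` are counted (the lower
    bound excludes the substrate background); the density is normalized so
    that sum(density * bin_width) = 1 over the counted pixels.
    """
    lo, hi = range
    if hi <= lo:
        raise ValueError("range must be an increasing interval")
    h = hmap.heights.ravel()
    in_range = h[(h >= lo) & (h <= hi)]
    if in_range.size == 0:
        raise EmptyDistributionError(
            f"no pixels with height in [{lo}, {hi}] nm")
    density, edges = np.histogram(in_range, bins=n_bins, range=(lo, hi),
                                  density=True)
    return HeightDistribution(bin_edges=edges, density=density,
                              range=(lo, hi), n_pixels_counted=int(in_range.size))


# --------------------------------------------------------------------------- #
# Theoretical sphere height density
# --------------------------------------------------------------------------- #

def sphere_model_density(h: np.ndarray, diameter: float,
                         broadening_sd: float = 0.0) -> np.ndarray:
    """Theoretical per-pixel height density for a tangent sphere.

    Base model P(h) = 2(h − R)/R² on [R, 2R] with R = diameter/2 (the
    triangular law from uniformly sampling the footprint of the upper
    hemisphere), convolved analytically with a Gaussian of sd
    ``broadening_sd`` and renormalized (the convolution preserves unit mass).
    """
    h = np.asarray(h, dtype=float)
    R = diameter / 2.0
    if R <= 0:
        raise ValueError("diameter must be > 0")
    if broadening_sd < 0:
        raise ValueError("broadening_sd must be >= 0")
    if broadening_sd == 0:
        out = np.where((h >= R) & (h <= 2 * R), 2.0 * (h - R) / R ** 2, 0.0)
        return out
    s = broadening_sd
    # closed-form Gaussian convolution of the triangular ramp on [R, 2R]:
    # ∫_R^{2R} (u-R) φ_s(h-u) du
    #   = (h-R)[Φ((2R-h)/s) − Φ((R-h)/s)] + s²[φ_s(h-R) − φ_s(h-2R)]
    phi = stats.norm(scale=s).pdf
    Phi = stats.norm.cdf
    integral = ((h - R) * (Phi((2 * R - h) / s) - Phi((R - h) / s))
                + s ** 2 * (phi(h - R) - phi(h - 2 * R)))
    return 2.0 / R ** 2 * integral


# --------------------------------------------------------------------------- #
# Estimators
# --------------------------------------------------------------------------- #

class SphereHeightModel(BaseEstimator):
    """Least-squares fit of the broadened tangent-sphere height density.

    Follows the scikit-learn estimator protocol: ``fit(X, y)`` takes bin
    centers (nm) and histogram density values. Fitted attributes:

    - ``diameter_`` : fitted sphere diameter 2R_S, nm
    - ``broadening_sd_`` : fitted Gaussian broadening, nm
    - ``amplitude_`` : fitted scale factor (absorbs range truncation)
    - ``rss_`` : residual sum of squares of the fit
    """

    def __init__(self, diameter_init: Optional[float] = None,
                 broadening_init: Optional[float] = None):
        self.diameter_init = diameter_init
        self.broadening_init = broadening_init

    def fit(self, X, y):
        h = np.asarray(X, dtype=float).ravel()
        dens = np.asarray(y, dtype=float).ravel()
        if h.size != dens.size or h.size < 3:
            raise ValueError("need matching bin centers and densities (>= 3 bins)")
        bw = np.median(np.diff(np.sort(h)))
        d0 = self.diameter_init
        if d0 is None:
            # the noiseless mode sits at h = D; use the density-weighted
            # upper region as the starting diameter
            d0 = float(h[np.argmax(dens)])
        s0 = self.broadening_init if self.broadening_init is not None else bw

        def resid(p):
            d, s, a = p
            return a * sphere_model_density(h, d, s) - dens

        lo = [max(h.min(), 1e-3), 1e-4, 1e-6]
        hi = [2 * h.max(), (h.max() - h.min()), 1e6]
        p0 = [np.clip(d0, lo[0], hi[0]), max(s0, 1e-3), 1.0]
        sol = optimize.least_squares(resid, p0, bounds=(lo, hi))
        if not sol.success:
            raise FitError(f"sphere model fit did not converge: {sol.message}")
        self.diameter_, self.broadening_sd_, self.amplitude_ = map(float, sol.x)
        self.rss_ = float(np.sum(sol.fun ** 2))
        return self

    def predict(self, X):
        h = np.asarray(X, dtype=float)
        return self.amplitude_ * sphere_model_density(h, self.diameter_,
                                                      self.broadening_sd_)


class DiscHeightModel(BaseEstimator):
    """Gaussian-broadened δ-peak fit for discoidal particle heights.

    The δ-peak location is found as the distribution mode (ties broken
    toward the lowest bin) and refined by a Gaussian least-squares fit; a
    straight line is regressed over the upper ``tail_fraction`` of occupied
    bins above the mode. Fitted attributes:

    - ``height_`` : fitted disc height h_D, nm
    - ``broadening_sd_`` : Gaussian broadening, nm (0 for a pure δ input)
    - ``rss_`` : residual sum of squares
    - ``tail_slope_``, ``tail_intercept_`` : upper-tail regression (NaN when
      the tail support is degenerate)
    - ``tail_defined_`` : whether the tail regression had >= 2 bins
    """

    def __init__(self, tail_fraction: float = 0.25):
        self.tail_fraction = tail_fraction

    def fit(self, X, y):
        h = np.asarray(X, dtype=float).ravel()
        dens = np.asarray(y, dtype=float).ravel()
        occupied = np.flatnonzero(dens > 0)
        if occupied.size == 0:
            raise FitError("empty distribution")
        mode_idx = int(occupied[np.argmax(dens[occupied])])
        # np.argmax already returns the first (lowest-h) maximal bin
        mode_h = float(h[mode_idx])
        bw = np.median(np.diff(np.sort(h))) if h.size > 1 else 1.0

        if occupied.size < 3:
            # pure (or nearly pure) δ input: the mode bin is the answer
            self.height_ = mode_h
            self.broadening_sd_ = 0.0
            model = np.zeros_like(dens)
            model[occupied] = dens[occupied]
            self.rss_ = 0.0
        else:
            def gauss(x, mu, s, a):
                return a * stats.norm(loc=mu, scale=s).pdf(x)
            try:
                popt, _ = optimize.curve_fit(
                    gauss, h, dens, p0=[mode_h, max(bw, 1e-3), 1.0],
                    bounds=([h.min(), 1e-4, 1e-6], [h.max(), h.max() - h.min(), 1e6]),
                    maxfev=10_000)
            except RuntimeError as exc:
                raise FitError(f"disc model fit did not converge: {exc}") from exc
            self.height_, self.broadening_sd_, self._amplitude = map(float, popt)
            self.rss_ = float(np.sum((gauss(h, *popt) - dens) ** 2))

        # upper-tail regression over occupied bins strictly above the mode
        above = occupied[h[occupied] > self.height_]
        n_tail = int(np.ceil(self.tail_fraction * above.size))
        tail = above[-n_tail:] if n_tail > 0 else above
        if tail.size >= 2:
            reg = stats.linregress(h[tail], dens[tail])
            self.tail_slope_ = float(reg.slope)
            self.tail_intercept_ = float(reg.intercept)
            self.tail_defined_ = True
        else:
            self.tail_slope_ = float("nan")
            self.tail_intercept_ = float("nan")
            self.tail_defined_ = False
        return self


class ParticleShapeClassifier(BaseEstimator):
    """Sphere-vs-disc discrimination by competing height-model residuals.

    Both height models are fitted to the same distribution; the model with
    the lower residual sum of squares wins. The margin (losing RSS / winning
    RSS) is reported, and classifications with margin below
    ``uncertain_margin`` are flagged uncertain.

    Fitted attributes: ``shape_`` ("sphere"|"disc"), ``margin_``,
    ``uncertain_``, ``sphere_fit_``, ``disc_fit_``.
    """

    def __init__(self, uncertain_margin: float = UNCERTAIN_MARGIN,
                 tail_fraction: float = 0.25):
        self.uncertain_margin = uncertain_margin
        self.tail_fraction = tail_fraction

    def fit(self, X, y):
        sphere = SphereHeightModel().fit(X, y)
        disc = DiscHeightModel(tail_fraction=self.tail_fraction).fit(X, y)
        self.sphere_fit_ = sphere
        self.disc_fit_ = disc
        if sphere.rss_ <= disc.rss_:
            self.shape_ = "sphere"
            self.margin_ = disc.rss_ / sphere.rss_ if sphere.rss_ > 0 else float("inf")
        else:
            self.shape_ = "disc"
            self.margin_ = sphere.rss_ / disc.rss_ if disc.rss_ > 0 else float("inf")
        self.uncertain_ = bool(self.margin_ < self.uncertain_margin)
        return self


# --------------------------------------------------------------------------- #
# Functional wrappers
# --------------------------------------------------------------------------- #

def fit_sphere(dist: HeightDistribution) -> SphereFit:
    """Fit the tangent-sphere height model to a height distribution."""
    est = SphereHeightModel().fit(dist.bin_centers, dist.density)
    return SphereFit(diameter_2Rs=est.diameter_, broadening_sd=est.broadening_sd_,
                     goodness=est.rss_)


def fit_disc(dist: HeightDistribution, tail_fraction: float = 0.25) -> DiscFit:
    """Fit the broadened δ-peak disc model plus upper-tail regression."""
    est = DiscHeightModel(tail_fraction=tail_fraction).fit(dist.bin_centers,
                                                           dist.density)
    return DiscFit(height_hD=est.height_, broadening_sd=est.broadening_sd_,
                   goodness=est.rss_, tail_slope=est.tail_slope_,
                   tail_intercept=est.tail_intercept_,
                   tail_defined=est.tail_defined_)


def classify_population(dist: HeightDistribution,
                        uncertain_margin: float = UNCERTAIN_MARGIN) -> ShapeClassification:
    """Classify a particle population as spherical or discoidal."""
    est = ParticleShapeClassifier(uncertain_margin=uncertain_margin).fit(
        dist.bin_centers, dist.density)
    s, d = est.sphere_fit_, est.disc_fit_
    return ShapeClassification(
        model=est.shape_,
        sphere_fit=SphereFit(s.diameter_, s.broadening_sd_, s.rss_),
        disc_fit=DiscFit(d.height_, d.broadening_sd_, d.rss_,
                         d.tail_slope_, d.tail_intercept_, d.tail_defined_),
        margin=est.margin_, uncertain=est.uncertain_)


def lipidation_molar_ratio(weight_ratio: float, mw_lipid: float,
                           mw_protein: float) -> float:
    """Mol lipid per mol protein from a lipid:protein weight ratio.

    molar_ratio = weight_ratio * mw_protein / mw_lipid. For a discoidal
    preparation at a 2.5:1 POPC:apoA-I weight ratio (POPC 760.1 g/mol,
    apoA-I 28 kDa) this gives 92 lipids per apoA-I after rounding.
    """
    if min(weight_ratio, mw_lipid, mw_protein) <= 0:
        raise ValueError("weight ratio and molecular masses must be > 0")
    return LipidationRatio(weight_ratio, mw_lipid, mw_protein).molar_ratio
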