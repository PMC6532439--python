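"""Fixed-threshold AFM quantification of fibril growth and disassembly.

The aggregation index is deliberately simple: the percentage of image pixels
whose height exceeds a fixed threshold (default 1.5 nm). Because fibrils are
unbranched filaments of roughly constant diameter, the above-threshold pixel
count is proportional to the total deposited fibril length, which makes the
pixel fraction a quantitative index of fibrillation and, normalized to its
starting point, of disaggregation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .datatypes import FibrillationTimecourse, HeightMap, ThresholdSummary
from .errors import NormalizationError

#: Default height threshold for fibril pixels, nm.
DEFAULT_THRESHOLD = 1.5


def level_map(hmap: HeightMap, order: int = 1) -> HeightMap:
    """Subtract a best-fit background from a height map.

    order 0 removes the mean height; order 1 removes the least-squares plane
    (the usual first-order AFM background). No clipping is applied to the
    residual heights.
    """
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    z = hmap.heights
    if order == 0:
        leveled = z - z.mean()
    else:
        ny, nx = z.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        A = np.column_stack([xx.ravel(), yy.ravel(), np.ones(z.size)])
        coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
        leveled = z - (A @ coef).reshape(z.shape)
    return HeightMap(leveled, hmap.pixel_size, label=hmap.label, time=hmap.time)


def pixel_fraction_above(hmap: HeightMap, threshold: float = DEFAULT_THRESHOLD) -> ThresholdSummary:
    """Count pixels strictly above a height threshold.

    "Above" is strict (>), so a map equal to the threshold everywhere counts
    zero pixels.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n_above = int(np.count_nonzero(hmap.heights > threshold))
    return ThresholdSummary(threshold=threshold, n_above=n_above,
                            n_total=int(hmap.heights.size))


def fibrillation_timecourse(maps: Iterable[HeightMap],
                            threshold: float = DEFAULT_THRESHOLD) -> FibrillationTimecourse:
    """Aggregate threshold pixel percentages into a timecourse.

    Maps are grouped by their ``time`` attribute (hours); per time point the
    arithmetic mean percentage over replicate images is reported together
    with the sample SD (0 for a single replicate). Output is sorted by time
    regardless of input order.
    """
    by_time: dict[float, list[float]] = {}
    for m in maps:
        if m.time is None:
            raise ValueError(f"map {m.label!r} has no time attached")
        by_time.setdefault(float(m.time), []).append(
            pixel_fraction_above(m, threshold).percent_above)
    if not by_time:
        raise ValueError("no maps supplied")
    times = np.array(sorted(by_time))
    means = np.array([np.mean(by_time[t]) for t in times])
    sds = np.array([np.std(by_time[t], ddof=1) if len(by_time[t]) > 1 else 0.0
                    for t in times])
    return FibrillationTimecourse(times=times, percent_above=means,
                                  dispersion=sds, threshold=threshold)


def normalize_timecourse(tc: FibrillationTimecourse) -> FibrillationTimecourse:
    """Normalize each sample to its starting point (value at t = 0).

    Raises NormalizationError when the first percentage is zero.
    """
    p0 = tc.percent_above[0]
    if p0 == 0:
        raise NormalizationError("percent_above at the first time point is zero; "
                                 "normalization undefined")
    return FibrillationTimecourse(
        times=tc.times, percent_above=tc.percent_above,
        dispersion=tc.dispersion, threshold=tc.threshold,
        normalized=tc.percent_above / p0)
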