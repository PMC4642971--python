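"""Peak counting and shape features of pSTAT6 time courses.

The topology screen classifies simulated total-pSTAT6 traces by the
number of *distinct* interior local maxima: two neighboring maxima count
as distinct only if the minimum between them lies below both by at least
a relative prominence delta (default 2% of the trace range), which
suppresses solver ripple.  Boundary extrema are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = ["PeakFeatureSet", "find_distinct_maxima", "count_local_maxima",
           "extract_features", "fit_smoothing_spline", "DEFAULT_PROMINENCE_FRAC"]

DEFAULT_PROMINENCE_FRAC = 0.02


@dataclass(frozen=True)
class PeakFeatureSet:
    """Shape features of one trace; two-peak fields are None when n_peaks < 2."""

    n_peaks: int
    final_value: float
    h1: float | None = None
    h2: float | None = None
    t1: float | None = None
    t2: float | None = None

    @property
    def ratio_heights(self) -> float | None:
        """h2 / h1 (second peak over first)."""
        if self.h1 is None or self.h2 is None or self.h1 == 0:
            return None
        return self.h2 / self.h1

    @property
    def separation(self) -> float | None:
        if self.t1 is None or self.t2 is None:
            return None
        return self.t2 - self.t1

    @property
    def ratio_final_h1(self) -> float | None:
        if self.h1 is None or self.h1 == 0:
            return None
        return self.final_value / self.h1


def _candidate_maxima(y: np.ndarray) -> list[int]:
    """Interior local maxima; plateaus report their midpoint."""
    n = len(y)
    out = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[j]:
                j += 1
            if j < n - 1 and y[j + 1] < y[j]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def find_distinct_maxima(trace, prominence_frac: float = DEFAULT_PROMINENCE_FRAC
                         ) -> list[int]:
    """Indices of distinct interior local maxima of a 1-D trace.

    Successive maxima are merged (keeping the higher) whenever the
    valley between them fails to drop below both by
    ``prominence_frac * (max - min)`` of the whole trace.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("trace must be 1-D with at least 3 points")
    rng = float(y.max() - y.min())
    if rng == 0.0 or not np.isfinite(rng):
        return []
    delta = prominence_frac * rng
    peaks = _candidate_maxima(y)
    # also require each surviving peak to rise at least delta above the
    # lowest point separating it from the boundary/neighbors on each side
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        for a in range(len(peaks) - 1):
            i, j = peaks[a], peaks[a + 1]
            valley = float(y[i:j + 1].min())
            if valley > min(y[i], y[j]) - delta:
                drop = a if y[i] <= y[j] else a + 1
                del peaks[drop]
                changed = True
                break
    # prune peaks that barely rise above the trace edges
    kept = []
    for idx, p in enumerate(peaks):
        left = peaks[idx - 1] if idx > 0 else 0
        right = peaks[idx + 1] if idx + 1 < len(peaks) else len(y) - 1
        lmin = float(y[left:p + 1].min())
        rmin = float(y[p:right + 1].min())
        if y[p] - max(lmin, rmin) >= delta:
            kept.append(p)
    return kept


def count_local_maxima(trace, prominence_frac: float = DEFAULT_PROMINENCE_FRAC) -> int:
    """Number of distinct interior local maxima (see find_distinct_maxima)."""
    return len(find_distinct_maxima(trace, prominence_frac))


def extract_features(trace, times=None,
                     prominence_frac: float = DEFAULT_PROMINENCE_FRAC
                     ) -> PeakFeatureSet:
    """Peak count, heights, times, final value and derived ratios of a trace.

    When more than two maxima survive the prominence rule, the first two
    in time define (h1, t1, h2, t2).
    """
    y = np.asarray(trace, dtype=float)
    if times is None:
        times = np.arange(y.size, dtype=float)
    t = np.asarray(times, dtype=float)
    idx = find_distinct_maxima(y, prominence_frac)
    final = float(y[-1])
    if len(idx) == 0:
        return PeakFeatureSet(n_peaks=0, final_value=final)
    if len(idx) == 1:
        i = idx[0]
        return PeakFeatureSet(n_peaks=1, final_value=final,
                              h1=float(y[i]), t1=float(t[i]))
    i, j = idx[0], idx[1]
    return PeakFeatureSet(n_peaks=len(idx), final_value=final,
                          h1=float(y[i]), h2=float(y[j]),
                          t1=float(t[i]), t2=float(t[j]))


def fit_smoothing_spline(times, means, lam: float | None = None,
                         n_dense: int = 961,
                         prominence_frac: float = DEFAULT_PROMINENCE_FRAC):
    """Smoothing spline through a measured mean time course, plus its features.

    The smoothing parameter is chosen by generalized cross-validation
    unless ``lam`` overrides it.  Returns ``(t_dense, y_dense, spline,
    PeakFeatureSet)`` with features taken from the smooth curve on a
    dense grid.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(means, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 time points for a smoothing spline")
    order = np.argsort(t)
    t, y = t[order], y[order]
    spline = make_smoothing_spline(t, y, lam=lam)
    t_dense = np.linspace(t[0], t[-1], n_dense)
    y_dense = spline(t_dense)
    feats = extract_features(y_dense, t_dense, prominence_frac)
    return t_dense, y_dense, spline, feats
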