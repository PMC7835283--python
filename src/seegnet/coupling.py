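"""Nonlinear correlation coefficient h² between signal amplitude pairs.

h²(y|x) is the fraction of the amplitude variance of signal y explained by a
piecewise-linear regression curve of y on x: the x range is split into
equal-width bins, the mean of y in each bin defines a point at the bin
midpoint, and straight segments between those points (constant beyond the
outer midpoints) form the predictor f.  Then

    h²(y|x) = max(0, 1 - Σ(yᵢ - f(xᵢ))² / Σ(yᵢ - ȳ)²),  clamped to [0, 1].

Unlike the squared Pearson correlation, h² detects nonlinear (e.g. quadratic)
relationships; unlike coherence it works on amplitudes directly.  It is
asymmetric — h²(y|x) ≠ h²(x|y) in general — which, together with the sign of
the delay at which h² peaks, carries the directionality of coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_io import EventAnnotation, Recording, extract_event


@dataclass
class H2Config:
    """Estimation parameters for h².

    n_bins
        Number of equal-width amplitude bins for the regression curve.
    min_points_per_bin
        If the window is shorter than ``n_bins * min_points_per_bin`` samples,
        the bin count is reduced (with a warning) to keep bins populated.
    lag_range_ms
        Signed lag scan range in milliseconds; positive lag means the target
        signal trails the source.
    lag_step_samples
        Scan stride in samples.
    bin_mode
        "width" (equal-width on the observed x range, the classical choice) or
        "count" (equal-count/quantile bins).
    """

    n_bins: int = 10
    min_points_per_bin: int = 10
    lag_range_ms: tuple = (-100.0, 100.0)
    lag_step_samples: int = 1
    bin_mode: str = "width"

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.bin_mode not in ("width", "count"):
            raise ValueError("bin_mode must be 'width' or 'count'")


@dataclass
class RegressionCurve:
    """Piecewise-linear conditional-mean predictor of y given x."""

    midpoints: np.ndarray
    means: np.ndarray

    def __call__(self, x) -> np.ndarray:
        # np.interp is constant beyond the outer midpoints
        return np.interp(x, self.midpoints, self.means)


@dataclass
class CouplingEstimate:
    src: str
    dst: str
    h2: float
    lag_samples: int


@dataclass
class CouplingMatrix:
    """Per-event matrix of h² values: ``values[i, j] = h²(j | i)``.

    Rows index the predicting (source) channel, columns the predicted (target)
    channel; the diagonal is undefined (NaN).  ``lags[i, j]`` is the signed lag
    in samples at which the maximum was attained.
    """

    labels: list
    values: np.ndarray
    lags: np.ndarray
    event: EventAnnotation | None = None

    def value(self, src: str, dst: str) -> float:
        return float(self.values[self.labels.index(src), self.labels.index(dst)])

    def lag(self, src: str, dst: str) -> int:
        return int(self.lags[self.labels.index(src), self.labels.index(dst)])

    def offdiag_values(self) -> np.ndarray:
        n = len(self.labels)
        mask = ~np.eye(n, dtype=bool)
        return self.values[mask]

    def to_long_frame(self):
        import pandas as pd

        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                rows.append({
                    "src": self.labels[i],
                    "dst": self.labels[j],
                    "h2": self.values[i, j],
                    "lag_samples": int(self.lags[i, j]),
                    "seizure_id": self.event.seizure_id if self.event else None,
                    "phase": self.event.phase.value if self.event else None,
                })
        return pd.DataFrame(rows)

    def to_csv(self, path, fmt: str = "long") -> None:
        if fmt == "long":
            self.to_long_frame().to_csv(path, index=False, float_format="%.6f")
        elif fmt == "square":
            import pandas as pd

            pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
                path, float_format="%.6f")
        else:
            raise ValueError("fmt must be 'long' or 'square'")


# ---------------------------------------------------------------------------
# Core estimators
# ---------------------------------------------------------------------------

def _effective_bins(n: int, n_bins: int, min_points_per_bin: int) -> int:
    if n < n_bins * min_points_per_bin:
        reduced = max(2, n // max(min_points_per_bin, 1))
        warnings.warn(
            f"window of {n} samples too short for {n_bins} bins; using {reduced}")
        return reduced
    return n_bins


def regression_curve(x, y, n_bins: int = 10, min_points_per_bin: int = 10,
                     bin_mode: str = "width") -> RegressionCurve:
    """Fit the piecewise-linear regression curve of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("degenerate predictor: x is constant")
    n_bins = _effective_bins(x.size, n_bins, min_points_per_bin)
    if bin_mode == "width":
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        if edges.size < 3:
            raise ValueError("degenerate predictor: x has too few distinct values")
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=y, minlength=len(edges) - 1)
    nonempty = counts > 0
    mids = 0.5 * (edges[:-1] + edges[1:])[nonempty]
    means = sums[nonempty] / counts[nonempty]
    return RegressionCurve(midpoints=mids, means=means)


def h2(x, y, config: H2Config | None = None) -> float:
    """Explained-variance fraction of y under the regression curve on x, in [0, 1]."""
    config = config or H2Config()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot <= 0:
        raise ValueError("zero variance target")
    f = regression_curve(x, y, config.n_bins, config.min_points_per_bin,
                         config.bin_mode)
    ss_res = np.sum((y - f(x)) ** 2)
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def _lag_order(lags):
    # scan order: ties broken toward smallest |lag|, then negative lag
    return sorted(lags, key=lambda L: (abs(L), L))


def h2_lagged(x, y, config: H2Config | None = None, fs: float = 1000.0,
              src: str = "x", dst: str = "y") -> CouplingEstimate:
    """Maximise h²(y|x) over a scan of signed lags.

    Positive ``lag_samples`` means y trails x by that many samples (x drives y
    with a delay).  The overlapping portion of the two signals is used at each
    lag.  Ties are resolved toward the smallest |lag|, then the negative one.
    """
    config = config or H2Config()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    lo_ms, hi_ms = config.lag_range_ms
    lo = int(round(lo_ms * fs / 1000.0))
    hi = int(round(hi_ms * fs / 1000.0))
    max_abs = max(abs(lo), abs(hi))
    if n - max_abs < 2 * config.n_bins:
        raise ValueError("window shorter than max lag")
    best = (-1.0, 0)
    for L in _lag_order(range(lo, hi + 1, config.lag_step_samples)):
        if L >= 0:
            xs, ys = x[:n - L] if L else x, y[L:]
        else:
            xs, ys = x[-L:], y[:n + L]
        val = h2(xs, ys, config)
        if val > best[0]:
            best = (val, L)
    return CouplingEstimate(src=src, dst=dst, h2=best[0], lag_samples=best[1])


def event_coupling_matrix(rec: Recording, event: EventAnnotation,
                          config: H2Config | None = None) -> CouplingMatrix:
    """One h² per ordered channel pair over the whole event window.

    The temporal bin of an h² value is the full duration of the clinically
    defined event — no sub-windowing or averaging.
    """
    config = config or H2Config()
    win = extract_event(rec, event)
    n = win.n_channels
    values = np.full((n, n), np.nan)
    lags = np.zeros((n, n), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                est = h2_lagged(win.samples[i], win.samples[j], config, fs=win.fs,
                                src=win.channel_labels[i], dst=win.channel_labels[j])
                values[i, j] = est.h2
                lags[i, j] = est.lag_samples
    return CouplingMatrix(labels=list(win.channel_labels), values=values,
                          lags=lags, event=event)
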