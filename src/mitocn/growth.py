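"""Growth-kinetics fitting of per-frame nuclear counts.

Counts per field of view over a multi-day time-lapse are fitted with a
3-parameter exponential, count(t) = c + a * exp(k t), where k (1/h) is the
growth-rate constant and the doubling time is ln(2)/k.  The additive offset
c absorbs a non-dividing (or mis-segmented) baseline; a pure 2-parameter
exponential (c = 0) is available and is biased whenever a genuine offset
exists.  End-point comparisons use the relative growth (final/first count),
and conditioned-media protocols rebase curves at the media-change time.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["GrowthCurve", "GrowthFit", "GrowthModel", "fit_growth",
           "doubling_time", "relative_growth", "rebase_at_time"]

LN2 = float(np.log(2.0))


@dataclass
class GrowthCurve:
    """Nuclear counts over time for one field of view.

    ``time_h`` must be strictly increasing; counts are cells/field and must
    be non-negative.
    """

    time_h: np.ndarray
    count: np.ndarray
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, float)
        self.count = np.asarray(self.count, float)
        if self.time_h.ndim != 1 or self.time_h.shape != self.count.shape:
            raise ValueError("time and count must be 1-D and equal length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.count < 0):
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time_col="time_h", count_col="count",
                   **metadata) -> "GrowthCurve":
        return cls(df[time_col].to_numpy(float), df[count_col].to_numpy(float),
                   metadata=metadata)

    @classmethod
    def from_csv(cls, path, **kw) -> "GrowthCurve":
        return cls.from_frame(pd.read_csv(path), **kw)


@dataclass
class GrowthFit:
    """Fitted growth parameters and diagnostics.

    ``doubling_time_h`` is ln(2)/k when k > 0 and NaN otherwise (the
    ``negative_rate`` flag marks shrinking cultures).
    """

    amplitude: float
    rate: float
    offset: float
    model: str
    resid_norm: float
    r_squared: float
    converged: bool
    n_points: int
    flags: list = dc_field(default_factory=list)

    @property
    def doubling_time_h(self) -> float:
        return LN2 / self.rate if self.rate > 0 else float("nan")

    def predict(self, time_h) -> np.ndarray:
        t = np.asarray(time_h, float)
        return self.offset + self.amplitude * np.exp(self.rate * t)

    def plot(self, curve: "GrowthCurve" = None, ax=None):
        """Counts (when a curve is given) with the fitted exponential."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        if curve is not None:
            ax.plot(curve.time_h, curve.count, ".", ms=3, color="grey",
                    label="counts")
            tt = np.linspace(curve.time_h[0], curve.time_h[-1], 300)
        else:
            tt = np.linspace(0.0, 72.0, 300)
        label = f"fit: k={self.rate:.4g}/h"
        if np.isfinite(self.doubling_time_h):
            label += f", T_d={self.doubling_time_h:.3g} h"
        ax.plot(tt, self.predict(tt), "C3", label=label)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("cells / field")
        ax.legend()
        return ax

    def summary(self) -> str:
        td = self.doubling_time_h
        return (
            "Exponential growth fit\n"
            "======================\n"
            f"model:          {self.model}\n"
            f"n points:       {self.n_points}\n"
            f"amplitude a:    {self.amplitude:.4g} cells\n"
            f"rate k:         {self.rate:.5g} 1/h\n"
            f"offset c:       {self.offset:.4g} cells\n"
            f"doubling time:  {td:.3g} h" + ("" if np.isfinite(td) else " (undefined: k <= 0)") + "\n"
            f"R^2:            {self.r_squared:.5f}\n"
            f"converged:      {self.converged}"
            + (f"\nflags: {'; '.join(self.flags)}" if self.flags else ""))


class GrowthModel:
    """Least-squares exponential growth model for one curve.

    ``model`` is ``"offset_exponential"`` (c + a e^{kt}, default) or
    ``"pure_exponential"`` (c fixed at 0).  The rate is initialized from a
    log-linear regression of the tail of the series.

    Counts are Poisson-distributed, so the default fit is weighted least
    squares with sigma_i = sqrt(count_i) (``weighting="poisson"``;
    ``weighting="none"`` gives ordinary least squares).  The amplitude is
    constrained positive and the offset non-negative: the offset models a
    non-dividing (or mis-segmented) baseline population, which cannot be
    negative, and the unconstrained fit occasionally trades a spurious
    negative offset against a badly biased rate.
    """

    def __init__(self, curve: GrowthCurve, model: str = "offset_exponential",
                 weighting: str = "poisson"):
        if weighting not in ("poisson", "none"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.weighting = weighting
        if model not in ("offset_exponential", "pure_exponential"):
            raise ValueError(f"unknown model {model!r}")
        if curve.time_h.size < 8:
            raise ValueError("need >= 8 time points to fit growth")
        if np.ptp(curve.count) == 0:
            raise ValueError("counts are all equal; growth rate unidentifiable")
        self.curve = curve
        self.model = model

    def _initial_guess(self):
        t, y = self.curve.time_h, self.curve.count
        c0 = 0.0 if self.model == "pure_exponential" else 0.5 * y.min()
        tail = slice(t.size // 2, None)
        yy = np.clip(y[tail] - c0, 1e-6, None)
        k0, loga0 = np.polyfit(t[tail], np.log(yy), 1)
        a0 = float(np.exp(loga0))
        if not np.isfinite(k0) or k0 == 0:
            k0 = 1e-3
        return max(a0, 1e-6), float(k0), c0

    def fit(self) -> GrowthFit:
        t, y = self.curve.time_h, self.curve.count
        a0, k0, c0 = self._initial_guess()
        flags = []
        converged = True
        sigma = (np.sqrt(np.clip(y, 1.0, None)) if self.weighting == "poisson"
                 else None)
        if self.model == "offset_exponential":
            f = lambda tt, a, k, c: c + a * np.exp(k * tt)
            p0 = (a0, max(k0, -0.999), max(c0, 0.0))
            bounds = ([1e-12, -1.0, 0.0], [np.inf, 1.0, np.inf])
        else:
            f = lambda tt, a, k: a * np.exp(k * tt)
            p0 = (a0, max(k0, -0.999))
            bounds = ([1e-12, -1.0], [np.inf, 1.0])
        try:
            popt, _ = curve_fit(f, t, y, p0=p0, sigma=sigma, bounds=bounds,
                                maxfev=20000)
        except RuntimeError:
            popt = np.asarray(p0, float)
            converged = False
            flags.append("non-convergence: reporting the initial guess")
        a, k = float(popt[0]), float(popt[1])
        c = float(popt[2]) if self.model == "offset_exponential" else 0.0
        resid = y - f(t, *popt)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if k <= 0:
            flags.append("negative_rate")
        return GrowthFit(amplitude=a, rate=k, offset=c, model=self.model,
                         resid_norm=float(np.sqrt(ss_res)),
                         r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
                         converged=converged, n_points=t.size, flags=flags)


def fit_growth(curve: GrowthCurve, model: str = "offset_exponential") -> GrowthFit:
    """Convenience wrapper: ``GrowthModel(curve, model).fit()``."""
    return GrowthModel(curve, model=model).fit()


def doubling_time(k: float) -> float:
    """Doubling time ln(2)/k in hours; undefined (error) for k <= 0."""
    if k <= 0:
        raise ValueError("doubling time is undefined for k <= 0")
    return LN2 / k


def relative_growth(curve: GrowthCurve) -> float:
    """End-point relative growth: final count / first-frame count."""
    if curve.count[0] <= 0:
        raise ValueError("relative growth undefined with zero first-frame count")
    return float(curve.count[-1] / curve.count[0])


def rebase_at_time(curve: GrowthCurve, t0: float) -> GrowthCurve:
    """Normalize a curve to its (interpolated) count at time ``t0``.

    The rebased curve equals 1 at t0; an exponential stays exponential with
    the same rate constant.
    """
    t = curve.time_h
    if not (t[0] <= t0 <= t[-1]):
        raise ValueError("t0 outside the curve's time range")
    ref = float(np.interp(t0, t, curve.count))
    if ref <= 0:
        raise ValueError("count at t0 is zero; cannot rebase")
    return GrowthCurve(time_h=t.copy(), count=curve.count / ref,
                       metadata={**curve.metadata, "rebased_at_h": t0})
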