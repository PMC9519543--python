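"""Binding rates, calibration fits, and limits of detection.

Two calibration modes mirror the two assay formats:

* **Endpoint** (capture, label, wash, image once): particle counts follow a
  power law ``count = a * c**b``; the LOD is the classical
  ``3.3 * sigma / slope`` with the slope taken on the linear response scale.

* **Kinetic** (real-time tracking): binding rates (events/hour) follow the
  diffusion-limited law ``rate ∝ c**(2/3)`` at low concentration. The LOD is
  the concentration where the theoretical-slope line through the double-log
  points crosses ``blank mean + 3 SD``, bracketed by the crossings of the
  free best-fit line and of the steepest line consistent with the data
  (upper end of the free slope's 95% CI).

Both are exposed as model classes whose ``fit()`` returns a results object
with estimates, uncertainties and a ``summary()`` table, plus thin
functional wrappers.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AVOGADRO",
    "BindingRate",
    "BlankStats",
    "CalibrationFit",
    "LODEstimate",
    "estimate_rate",
    "KineticCalibration",
    "KineticCalibrationResults",
    "EndpointCalibration",
    "EndpointCalibrationResults",
    "fit_endpoint_calibration",
    "lod_endpoint",
    "lod_kinetic",
    "molarity_copies",
    "copies_molarity",
]

AVOGADRO = 6.02214076e23

THEORETICAL_SLOPE = 2.0 / 3.0


@dataclass(frozen=True)
class BindingRate:
    """OLS binding rate from one cumulative curve, events per hour."""

    probe_label: str
    concentration: float
    rate: float
    rate_se: float
    fit_window: tuple[float, float]


@dataclass(frozen=True)
class BlankStats:
    """Mean and SD of blank replicates (rates or endpoint counts)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n < 2 and self.sd > 0:
            raise ValueError("sd requires n >= 2 replicates")

    @classmethod
    def from_samples(cls, samples) -> "BlankStats":
        samples = np.asarray(samples, dtype=float)
        if samples.size < 2:
            raise ValueError("need >= 2 blank replicates")
        return cls(float(samples.mean()), float(samples.std(ddof=1)), samples.size)

    @property
    def threshold(self) -> float:
        """Decision threshold: mean + 3 SD."""
        return self.mean + 3.0 * self.sd


@dataclass(frozen=True)
class CalibrationFit:
    """Double-log line fit, free slope and theory-slope variants."""

    mode: str
    log_c: np.ndarray
    log_response: np.ndarray
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    theoretical_slope: float = THEORETICAL_SLOPE
    theoretical_intercept: float = float("nan")


@dataclass(frozen=True)
class LODEstimate:
    """Limit of detection (molar) with an interval when defined."""

    lod: float
    method: str
    interval: tuple[float, float] = (float("nan"), float("nan"))
    extrapolated: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (math.isnan(lo) or math.isnan(hi)):
            if not lo <= self.lod <= hi:
                raise ValueError("interval must bracket the LOD")


def estimate_rate(
    times_s,
    counts,
    window: tuple[float, float] | None = None,
    burn_in_s: float = 0.0,
    probe_label: str = "",
    concentration: float = float("nan"),
) -> BindingRate:
    """OLS slope of a cumulative binding curve, in events per hour.

    ``window`` restricts the fit to a time span (seconds); by default the
    whole incubation after ``burn_in_s`` is used. A flat curve yields rate 0
    with a finite (zero) standard error.

    The reported ``rate_se`` is the Poisson counting error
    ``sqrt(rate / window_hours)``: a cumulative event curve has strongly
    autocorrelated residuals, so the iid OLS standard error understates the
    true sampling variability several-fold, while counting noise dominates it.
    """
    times_s = np.asarray(times_s, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times_s.shape != counts.shape:
        raise ValueError("times and counts must have equal length")
    lo = burn_in_s if window is None else max(window[0], burn_in_s)
    hi = float(times_s[-1]) if window is None else window[1]
    sel = (times_s >= lo) & (times_s <= hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 time points in the fit window")
    t_h = times_s[sel] / 3600.0
    y = counts[sel]
    if np.ptp(y) == 0:
        return BindingRate(probe_label, concentration, 0.0, 0.0, (lo, hi))
    res = stats.linregress(t_h, y)
    window_h = (t_h[-1] - t_h[0]) or 1.0
    se = math.sqrt(max(float(res.slope), 0.0) / window_h)
    return BindingRate(probe_label, concentration, float(res.slope), se, (lo, hi))


def _loglog_points(concentrations, responses) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    keep = r > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} non-positive response(s) from the "
            "log-log fit", stacklevel=3,
        )
    c, r = c[keep], r[keep]
    if c.size < 2:
        raise ValueError("need at least 2 positive responses for a log-log fit")
    return np.log10(c), np.log10(r)


def _free_fit(x: np.ndarray, y: np.ndarray):
    """OLS slope/intercept with a 95% CI on the slope (degenerate at n=2)."""
    res = stats.linregress(x, y)
    n = x.size
    if n > 2 and np.isfinite(res.stderr) and res.stderr > 0:
        tcrit = stats.t.ppf(0.975, n - 2)
        ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    else:
        ci = (res.slope, res.slope)
    return float(res.slope), float(res.intercept), (float(ci[0]), float(ci[1]))


def _fixed_slope_intercept(x: np.ndarray, y: np.ndarray, slope: float) -> float:
    """Least-squares intercept with the slope held fixed."""
    return float(np.mean(y - slope * x))


class KineticCalibration:
    """Kinetic calibration model: binding rate vs concentration.

    Parameters
    ----------
    concentrations : array of float
        Molar concentrations (> 0) of the calibration points.
    rates : array of float
        Binding rates, events/hour. Non-positive rates are excluded from the
        log fit with a warning.
    blank : BlankStats
        Mean/SD of blank replicate rates; sets the detection threshold
        ``mean + 3 SD``.
    theoretical_slope : float
        Slope of the physical rate law on double-log axes (2/3).
    """

    def __init__(self, concentrations, rates, blank: BlankStats,
                 theoretical_slope: float = THEORETICAL_SLOPE):
        self.log_c, self.log_r = _loglog_points(concentrations, rates)
        self.blank = blank
        self.theoretical_slope = float(theoretical_slope)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, blank: BlankStats,
                       concentration: str = "concentration",
                       rate: str = "rate_per_h", **kw) -> "KineticCalibration":
        g = df.groupby(concentration)[rate].mean()
        return cls(g.index.to_numpy(), g.to_numpy(), blank, **kw)

    def fit(self, threshold_floor: float = 0.0) -> "KineticCalibrationResults":
        """Fit free and theory-slope lines and locate the LOD.

        ``threshold_floor`` substitutes a positive response floor when the
        blank threshold is zero (no blank signal at all).
        """
        x, y = self.log_c, self.log_r
        slope, intercept, slope_ci = _free_fit(x, y)
        a_th = _fixed_slope_intercept(x, y, self.theoretical_slope)
        threshold = self.blank.threshold
        if threshold <= 0:
            threshold = threshold_floor
        if threshold <= 0:
            raise ValueError(
                "blank threshold is zero and no threshold_floor given: "
                "LOD crossing undefined"
            )
        log_thr = math.log10(threshold)

        def crossing(s: float, a: float) -> float:
            if s <= 0:
                return float("nan")
            return 10.0 ** ((log_thr - a) / s)

        lod = crossing(self.theoretical_slope, a_th)
        lower = crossing(slope, intercept)
        s_hi = slope_ci[1]
        upper = crossing(s_hi, _fixed_slope_intercept(x, y, s_hi))
        extrapolated = bool(log_thr < y.min() or log_thr > y.max())
        cands = [v for v in (lower, upper, lod) if np.isfinite(v)]
        interval = (min(cands), max(cands))
        fitres = CalibrationFit(
            "kinetic", x, y, slope, intercept, slope_ci,
            self.theoretical_slope, a_th,
        )
        return KineticCalibrationResults(
            self, fitres,
            LODEstimate(lod, "kinetic_intersection", interval, extrapolated),
            threshold,
        )


@dataclass
class KineticCalibrationResults:
    model: KineticCalibration
    fit: CalibrationFit
    lod: LODEstimate
    threshold: float

    @property
    def slope(self) -> float:
        return self.fit.slope

    @property
    def slope_ci(self) -> tuple[float, float]:
        return self.fit.slope_ci

    def predict(self, concentrations, line: str = "theory") -> np.ndarray:
        """Rates predicted by the fitted theory-slope or free line."""
        c = np.asarray(concentrations, dtype=float)
        if line == "theory":
            s, a = self.fit.theoretical_slope, self.fit.theoretical_intercept
        elif line == "free":
            s, a = self.fit.slope, self.fit.intercept
        else:
            raise ValueError("line must be 'theory' or 'free'")
        return 10.0 ** (a + s * np.log10(c))

    def summary(self) -> str:
        f = self.fit
        lo, hi = self.lod.interval
        lines = [
            "Kinetic calibration (double-log rate vs concentration)",
            "=" * 58,
            f"points (positive rates)     {len(f.log_c):>12d}",
            f"free slope                  {f.slope:>12.4f}",
            f"free slope 95% CI           [{f.slope_ci[0]:.4f}, {f.slope_ci[1]:.4f}]",
            f"free intercept              {f.intercept:>12.4f}",
            f"theoretical slope           {f.theoretical_slope:>12.4f}",
            f"theory-line intercept       {f.theoretical_intercept:>12.4f}",
            f"blank threshold (events/h)  {self.threshold:>12.4g}",
            f"LOD (molar)                 {self.lod.lod:>12.4g}",
            f"LOD interval (molar)        [{lo:.4g}, {hi:.4g}]",
            f"extrapolated                {str(self.lod.extrapolated):>12s}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": "kinetic",
            "slope": self.fit.slope,
            "slope_ci": list(self.fit.slope_ci),
            "intercept": self.fit.intercept,
            "theoretical_slope": self.fit.theoretical_slope,
            "theoretical_intercept": self.fit.theoretical_intercept,
            "threshold": self.threshold,
            "lod_molar": self.lod.lod,
            "lod_interval_molar": list(self.lod.interval),
            "extrapolated": self.lod.extrapolated,
        }


class EndpointCalibration:
    """Endpoint calibration model: particle count vs concentration.

    Fits ``log10 count = b * log10 c + a`` by least squares; the measured
    exponent ``b`` is often below 1 (a softer dependence than linear).
    """

    def __init__(self, concentrations, counts):
        self.log_c, self.log_n = _loglog_points(concentrations, counts)
        if self.log_c.size < 2:
            raise ValueError("need at least 2 calibration points")

    def fit(self) -> "EndpointCalibrationResults":
        slope, intercept, ci = _free_fit(self.log_c, self.log_n)
        return EndpointCalibrationResults(
            self, CalibrationFit("endpoint_powerlaw", self.log_c, self.log_n,
                                 slope, intercept, ci)
        )


@dataclass
class EndpointCalibrationResults:
    model: EndpointCalibration
    fit: CalibrationFit

    @property
    def exponent(self) -> float:
        return self.fit.slope

    @property
    def amplitude(self) -> float:
        """Prefactor a in count = a * c**b."""
        return 10.0 ** self.fit.intercept

    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return self.amplitude * c**self.fit.slope

    def linear_slope(self, at: float | None = None, method: str = "local") -> float:
        """Calibration slope on the linear scale, counts per molar.

        ``method='local'``: derivative of the power-law fit,
        ``a*b*c**(b-1)``, evaluated at ``at`` (default: the lowest fitted
        concentration) — the 3.3 sigma/slope rule presumes a locally linear
        response. ``method='global'``: OLS slope of count vs concentration
        through the fitted points on linear axes.
        """
        if method == "local":
            c0 = 10.0 ** self.fit.log_c.min() if at is None else float(at)
            return self.amplitude * self.fit.slope * c0 ** (self.fit.slope - 1.0)
        if method == "global":
            c = 10.0**self.fit.log_c
            n = 10.0**self.fit.log_response
            return float(stats.linregress(c, n).slope)
        raise ValueError("method must be 'local' or 'global'")

    def lod(self, blank: BlankStats, method: str = "local",
            at: float | None = None) -> LODEstimate:
        """Endpoint LOD = 3.3 * sigma_blank / slope (linear scale)."""
        slope = self.linear_slope(at=at, method=method)
        if slope <= 0:
            raise ValueError("calibration slope <= 0: no sensitivity")
        return LODEstimate(3.3 * blank.sd / slope, "endpoint_3.3sigma")

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Endpoint calibration (double-log count vs concentration)",
            "=" * 58,
            f"points                      {len(f.log_c):>12d}",
            f"power-law exponent b        {f.slope:>12.4f}",
            f"exponent 95% CI             [{f.slope_ci[0]:.4f}, {f.slope_ci[1]:.4f}]",
            f"prefactor a (count @ 1 M)   {self.amplitude:>12.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": "endpoint_powerlaw",
            "exponent": self.fit.slope,
            "exponent_ci": list(self.fit.slope_ci),
            "intercept": self.fit.intercept,
        }


# -- functional wrappers ----------------------------------------------------

def fit_endpoint_calibration(concentrations, counts) -> EndpointCalibrationResults:
    """Power-law fit of endpoint particle counts (see EndpointCalibration)."""
    return EndpointCalibration(concentrations, counts).fit()


def lod_endpoint(blank: BlankStats,
                 fit: EndpointCalibrationResults | None = None,
                 slope: float | None = None) -> LODEstimate:
    """Endpoint LOD, 3.3 sigma/slope.

    Pass either a fitted endpoint calibration (the slope is its local linear
    derivative at the lowest fitted concentration) or an explicit linear
    slope in counts per molar.
    """
    if (fit is None) == (slope is None):
        raise ValueError("pass exactly one of fit or slope")
    if fit is not None:
        return fit.lod(blank)
    if slope <= 0:
        raise ValueError("calibration slope <= 0: no sensitivity")
    return LODEstimate(3.3 * blank.sd / slope, "endpoint_3.3sigma")


def lod_kinetic(concentrations, rates, blank: BlankStats,
                theoretical_slope: float = THEORETICAL_SLOPE,
                threshold_floor: float = 0.0) -> KineticCalibrationResults:
    """Kinetic LOD from (concentration, rate) points and blank statistics."""
    model = KineticCalibration(concentrations, rates, blank, theoretical_slope)
    return model.fit(threshold_floor=threshold_floor)


def molarity_copies(concentration: float, volume_l: float) -> float:
    """Number of molecule copies at a molarity in a sample volume (litres)."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    return concentration * volume_l * AVOGADRO


def copies_molarity(copies: float, volume_l: float) -> float:
    """Molarity corresponding to a copy number in a sample volume (litres)."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    return copies / (volume_l * AVOGADRO)
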