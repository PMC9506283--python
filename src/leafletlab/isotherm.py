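"""Static mechanics of Langmuir π–A isotherms.

A compressed monolayer resists area reduction; the quasi-static compression
modulus

    ε(π) = −A · dπ/dA

(the inverse of the in-plane area compressibility) quantifies that stiffness
as a function of surface pressure. This module also locates the lift-off
area — the molecular area at which π first rises above the sensor noise on
compression — and segments the post-lift-off region into piecewise-linear
gradients, which is how gradient changes (a signature of 2D phase
transitions) are usually reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "Isotherm",
    "CompressionModulusCurve",
    "GradientSegment",
    "compression_modulus",
    "liftoff_area",
    "segment_gradients",
]


@dataclass
class Isotherm:
    """A surface pressure–area record.

    Parameters
    ----------
    area : array
        Molecular area, Å²/molecule.
    pressure : array
        Surface pressure, mN/m. Small negative values (sensor offset down to
        −0.5 mN/m) are tolerated.
    temperature : float
        Subphase temperature, K.
    composition, subphase : str
        Free-text labels.
    """

    area: np.ndarray
    pressure: np.ndarray
    temperature: float = 293.0
    composition: str = ""
    subphase: str = "water"

    def __post_init__(self):
        self.area = np.asarray(self.area, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.area.ndim != 1 or self.area.shape != self.pressure.shape:
            raise ValueError("area and pressure must be 1D arrays of equal length")
        if self.area.size < 3:
            raise ValueError("need at least 3 points")
        d = np.diff(self.area)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("area must be strictly monotone")
        if np.any(self.pressure < -0.5):
            raise ValueError("pressure below -0.5 mN/m: not a physical isotherm")

    def compression_branch(self) -> "Isotherm":
        """Return the record ordered with area decreasing (compression)."""
        if self.area[0] < self.area[-1]:
            return Isotherm(self.area[::-1].copy(), self.pressure[::-1].copy(),
                            self.temperature, self.composition, self.subphase)
        return self


@dataclass
class CompressionModulusCurve:
    """ε(π) along the compression branch."""

    pressure: np.ndarray
    epsilon: np.ndarray
    area: np.ndarray
    smoothing: str = ""


@dataclass
class GradientSegment:
    """One linear segment of π(A): |dπ/dA| and the π range it covers."""

    slope: float                 # |dπ/dA|, mN m⁻¹ Å⁻²
    pressure_range: tuple = field(default=(0.0, 0.0))
    area_range: tuple = field(default=(0.0, 0.0))


def _local_poly_derivative(x: np.ndarray, y: np.ndarray, window: int,
                           polyorder: int) -> np.ndarray:
    """dy/dx by local polynomial fits (handles non-uniform x grids)."""
    n = x.size
    half = window // 2
    dy = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        xi, yi = x[lo:hi], y[lo:hi]
        # centre for conditioning
        c = np.polyfit(xi - x[i], yi, polyorder)
        dy[i] = c[-2]
    return dy


def compression_modulus(iso: Isotherm, window: int = 11,
                        polyorder: int = 2) -> CompressionModulusCurve:
    """Compute ε(π) = −A·dπ/dA with a smoothed derivative.

    The derivative is estimated by local polynomial (Savitzky–Golay-style)
    fits of order ``polyorder`` over ``window`` points, which also works on
    non-uniform area grids.
    """
    if window % 2 == 0 or window < polyorder + 2:
        raise ValueError("window must be odd and >= polyorder + 2")
    iso = iso.compression_branch()
    a, p = iso.area, iso.pressure
    if a.size < window:
        raise ValueError("too few points for the requested window")
    if np.ptp(a) == 0:
        raise ValueError("zero-variance area")
    dpda = _local_poly_derivative(a, p, window, polyorder)
    eps = -a * dpda
    return CompressionModulusCurve(pressure=p, epsilon=eps, area=a,
                                   smoothing=f"local_poly(window={window}, order={polyorder})")


def liftoff_area(iso: Isotherm, threshold: float = 0.5,
                 window: int = 5, polyorder: int = 1) -> float:
    """Largest molecular area at which the (lightly smoothed) π exceeds
    ``threshold``, located by linear interpolation.

    The default threshold of 0.5 mN/m sits above typical Wilhelmy-sensor
    noise while staying close to π = 0. ``window=1`` disables smoothing
    (appropriate for noiseless model curves).
    """
    iso = iso.compression_branch()
    a, p = iso.area, iso.pressure
    if a.size >= window > polyorder + 1:
        p = np.array([np.polyval(np.polyfit(a[max(0, i - window // 2):i + window // 2 + 1]
                                            - a[i],
                                            iso.pressure[max(0, i - window // 2):i + window // 2 + 1],
                                            polyorder), 0.0)
                      for i in range(a.size)])
    above = p > threshold
    if not above.any():
        raise ValueError(f"pressure never exceeds threshold {threshold} mN/m")
    if above.all():
        raise ValueError("isotherm does not span pressures below the threshold")
    # first crossing scanning from large area (start of compression)
    idx = int(np.argmax(above))          # first True along decreasing area
    if idx == 0:
        return float(a[0])
    a0, a1 = a[idx - 1], a[idx]
    p0, p1 = p[idx - 1], p[idx]
    return float(a0 + (threshold - p0) * (a1 - a0) / (p1 - p0))


def _piecewise_linear_lsq(a: np.ndarray, p: np.ndarray, breaks: np.ndarray):
    """Continuous piecewise-linear least squares of p(a) with fixed breaks.

    Basis: 1, a, (a − b_k)·1[a < b_k] for each break (area decreasing along
    compression, so the hinge opens on the low-area side).
    """
    cols = [np.ones_like(a), a]
    for b in breaks:
        cols.append(np.where(a < b, a - b, 0.0))
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, p, rcond=None)
    resid = p - X @ coef
    return coef, float(np.sum(resid**2))


def segment_gradients(iso: Isotherm, n_segments: int = 2,
                      liftoff_threshold: float = 0.5) -> list[GradientSegment]:
    """Continuous piecewise-linear fit of the post-lift-off π(A).

    Returns one :class:`GradientSegment` per segment, ordered along
    compression (decreasing area / increasing pressure); slopes are |dπ/dA|.
    Breakpoints are optimised by profiling the least-squares residual over
    candidate break positions.
    """
    if n_segments not in (1, 2, 3):
        raise ValueError("n_segments must be 1, 2 or 3")
    iso = iso.compression_branch()
    try:
        a_lift = liftoff_area(iso, threshold=liftoff_threshold)
    except ValueError:
        a_lift = iso.area[0]
    mask = iso.area <= a_lift
    a, p = iso.area[mask], iso.pressure[mask]
    n_params = 2 * n_segments
    if a.size < n_params + 2:
        raise ValueError("fewer points than fit parameters in the post-lift-off region")

    n_breaks = n_segments - 1
    if n_breaks == 0:
        coef, _ = _piecewise_linear_lsq(a, p, np.array([]))
        breaks = np.array([])
    else:
        lo, hi = a.min(), a.max()
        span = hi - lo
        bounds = [(lo + 0.05 * span, hi - 0.05 * span)] * n_breaks

        def cost(breaks):
            breaks = np.sort(np.asarray(breaks))
            return _piecewise_linear_lsq(a, p, breaks)[1]

        # coarse grid seed then local refinement
        grid = np.linspace(lo + 0.05 * span, hi - 0.05 * span, 25)
        if n_breaks == 1:
            seeds = [[g] for g in grid]
        else:
            seeds = [[g1, g2] for g1 in grid[::3] for g2 in grid[::3] if g1 < g2]
        best = min(seeds, key=cost)
        res = optimize.minimize(cost, best, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-12})
        breaks = np.sort(res.x)
        coef, _ = _piecewise_linear_lsq(a, p, breaks)

    # evaluate per-segment slopes; segments ordered high area → low area
    edges = np.concatenate([[a.max()], breaks[::-1], [a.min()]])
    segments = []
    for k in range(n_segments):
        hi_a, lo_a = edges[k], edges[k + 1]
        # slope in segment = base slope + hinges active there (a < b)
        mid = 0.5 * (hi_a + lo_a)
        slope = coef[1] + sum(coef[2 + j] for j, b in enumerate(breaks) if mid < b)
        p_hi = _piecewise_eval(coef, breaks, hi_a)
        p_lo = _piecewise_eval(coef, breaks, lo_a)
        segments.append(GradientSegment(slope=abs(slope),
                                        pressure_range=(float(p_hi), float(p_lo)),
                                        area_range=(float(hi_a), float(lo_a))))
    return segments


def _piecewise_eval(coef, breaks, a):
    val = coef[0] + coef[1] * a
    for j, b in enumerate(breaks):
        if a < b:
            val += coef[2 + j] * (a - b)
    return val
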