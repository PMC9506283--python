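"""Surface dilatational stress-relaxation rheology.

A monolayer held at a target pressure π₀ is subjected to a fast step
compression of relative magnitude u = |ΔA/A₀| ≤ 5%. The induced surface
pressure excess Δπ(t) then relaxes at constant area towards a new
equilibrium Δπ∞ and is well described by a sum of decaying exponentials,

    Δπ(t) = Δπ∞ + Σᵢ Aᵢ exp(−t/τᵢ).

For a step strain, the Fourier transform of the fitted relaxation modulus
E(t) = Δπ(t)/u has the closed form of a generalised Maxwell (Prony) model:

    G′(ω) = (Δπ∞ + Σᵢ Aᵢ ω²τᵢ² / (1 + ω²τᵢ²)) / u
    G″(ω) = (Σᵢ Aᵢ ωτᵢ / (1 + ω²τᵢ²)) / u,     ω = 2πν,

from which the loss tangent tanφ = G″/G′ and the dilatational viscosity
η_D = G″/(2πν) follow. A single Maxwell mode traces an exact semicircle in
the Cole–Cole plane (G″ vs G′); deviation from a semicircle diagnoses
multi-step relaxation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RelaxationTransient",
    "ExponentialFit",
    "ViscoelasticSpectrum",
    "ColeColeResult",
    "fit_relaxation",
    "spectrum_from_fit",
    "cole_cole",
    "plateau_modulus",
]


@dataclass
class RelaxationTransient:
    """Δπ(t) after a step area perturbation.

    ``rel_area_change`` is the magnitude |ΔA/A₀| of the step (compression
    gives Δπ > 0 and ΔA < 0; only the magnitude is stored).
    """

    time: np.ndarray              # s, ascending, time[0] = 0
    delta_pi: np.ndarray          # mN/m
    rel_area_change: float        # dimensionless, in (0, 0.05]
    target_pressure: float = 30.0 # π₀, mN/m

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.delta_pi = np.asarray(self.delta_pi, dtype=float)
        if self.time.shape != self.delta_pi.shape or self.time.ndim != 1:
            raise ValueError("time and delta_pi must be 1D arrays of equal length")
        if self.time[0] != 0.0 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must ascend from 0")
        if not (0.0 < self.rel_area_change <= 0.05):
            raise ValueError("rel_area_change must be in (0, 0.05]")
        if not np.all(np.isfinite(self.delta_pi)):
            raise ValueError("delta_pi must be finite")


@dataclass
class ExponentialFit:
    """Multi-exponential model of a relaxation transient.

    ``modes`` is a list of (amplitude Aᵢ in mN/m, relaxation time τᵢ in s),
    sorted by ascending τ.
    """

    delta_pi_inf: float
    modes: list = field(default_factory=list)
    goodness: float = 0.0         # residual SD, mN/m

    def __post_init__(self):
        self.modes = sorted([(float(a), float(t)) for a, t in self.modes],
                            key=lambda m: m[1])
        if any(t <= 0 for _, t in self.modes):
            raise ValueError("relaxation times must be positive")
        if any(a < 0 for a, _ in self.modes):
            raise ValueError("mode amplitudes must be non-negative")
        if self.delta_pi_inf < 0:
            raise ValueError("delta_pi_inf must be non-negative")

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.delta_pi_inf, dtype=float)
        for a, tau in self.modes:
            out += a * np.exp(-t / tau)
        return out


@dataclass
class ViscoelasticSpectrum:
    """G′, G″, tanφ and η_D on a frequency grid."""

    frequency: np.ndarray         # Hz
    storage: np.ndarray           # G′, mN/m
    loss: np.ndarray              # G″, mN/m
    tan_phi: np.ndarray = None
    eta_D: np.ndarray = None      # mN·s/m

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.storage = np.asarray(self.storage, dtype=float)
        self.loss = np.asarray(self.loss, dtype=float)
        if self.tan_phi is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                self.tan_phi = np.where(self.storage > 0,
                                        self.loss / self.storage, np.nan)
        if self.eta_D is None:
            self.eta_D = self.loss / (2.0 * np.pi * self.frequency)


def _model(t, params, n_modes):
    out = np.full_like(t, params[0])
    for i in range(n_modes):
        a, log_tau = params[1 + 2 * i], params[2 + 2 * i]
        out += a * np.exp(-t / np.exp(log_tau))
    return out


def _aicc(n, rss, k):
    # small-sample-corrected Akaike information criterion, Gaussian errors
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_relaxation(tr: RelaxationTransient, max_modes: int = 3) -> ExponentialFit:
    """Fit Δπ(t) with 0..max_modes decaying exponentials plus a plateau.

    Each candidate mode count is fitted by bounded nonlinear least squares
    with multi-start initial relaxation times log-spaced over the record;
    the returned model minimises the small-sample-corrected Akaike
    criterion. A flat transient yields n_modes = 0 with Δπ∞ = mean.
    """
    if max_modes not in (1, 2, 3):
        raise ValueError("max_modes must be 1, 2 or 3")
    t, y = tr.time, tr.delta_pi
    if t.size < 10:
        raise ValueError("need at least 10 samples")

    # Floor the RSS at numerical noise so that machine-precision fits of
    # different mode counts tie and the AICc penalty selects the simplest.
    scale = max(float(np.abs(y).max()), 1e-12)
    rss_floor = (1e-9 * scale) ** 2 * t.size

    candidates = []
    # 0-mode candidate
    rss0 = max(float(np.sum((y - y.mean()) ** 2)), rss_floor)
    candidates.append((_aicc(t.size, rss0, 1),
                       ExponentialFit(delta_pi_inf=max(y.mean(), 0.0), modes=[],
                                      goodness=float(np.std(y - y.mean())))))

    t_pos = t[t > 0]
    span_lo, span_hi = max(t_pos.min(), 1e-3), t.max()
    amp0 = max(y[0] - y[-1], 1e-6)
    for n_modes in range(1, max_modes + 1):
        best = None
        tau_seeds = np.exp(np.linspace(np.log(span_lo), np.log(span_hi), 4 + n_modes))
        starts = []
        if n_modes == 1:
            starts = [[ts] for ts in tau_seeds]
        elif n_modes == 2:
            starts = [[a, b] for i, a in enumerate(tau_seeds) for b in tau_seeds[i + 1:]]
        else:
            starts = [[tau_seeds[0], tau_seeds[len(tau_seeds) // 2], tau_seeds[-1]],
                      [tau_seeds[1], tau_seeds[2], tau_seeds[-2]]]
        for taus in starts:
            p0 = [max(y[-1], 0.0)]
            for tau in taus:
                p0 += [amp0 / n_modes, np.log(tau)]
            lb = [0.0] + [0.0, np.log(span_lo) - 7] * n_modes
            ub = [np.inf] + [np.inf, np.log(span_hi) + 7] * n_modes
            try:
                res = least_squares(lambda p: _model(t, p, n_modes) - y, p0,
                                    bounds=(lb, ub), method="trf")
            except Exception:
                continue
            rss = float(np.sum(res.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, res.x)
        if best is None:
            continue
        rss, p = best
        rss = max(rss, rss_floor)
        k = 1 + 2 * n_modes + 1  # parameters + noise variance
        modes = [(p[1 + 2 * i], np.exp(p[2 + 2 * i])) for i in range(n_modes)]
        # drop vanishing modes rather than report spurious ones
        modes = [(a, tau) for a, tau in modes if a > 1e-12]
        fit = ExponentialFit(delta_pi_inf=p[0], modes=modes,
                             goodness=float(np.sqrt(rss / t.size)))
        candidates.append((_aicc(t.size, rss, k), fit))

    if not candidates:
        raise RuntimeError("relaxation fit did not converge for any mode count")
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1]


def spectrum_from_fit(fit: ExponentialFit, rel_area_change: float,
                      nu_grid: np.ndarray) -> ViscoelasticSpectrum:
    """Closed-form complex dilatational modulus for a step strain.

    With u = rel_area_change and ω = 2πν:
    G′ = (Δπ∞ + Σ Aᵢ ω²τᵢ²/(1+ω²τᵢ²))/u, G″ = (Σ Aᵢ ωτᵢ/(1+ω²τᵢ²))/u.
    """
    if rel_area_change <= 0:
        raise ValueError("rel_area_change must be positive")
    nu = np.asarray(nu_grid, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("frequencies must be positive")
    u = rel_area_change
    omega = 2.0 * np.pi * nu
    gp = np.full_like(nu, fit.delta_pi_inf)
    gpp = np.zeros_like(nu)
    for a, tau in fit.modes:
        wt = omega * tau
        gp += a * wt**2 / (1.0 + wt**2)
        gpp += a * wt / (1.0 + wt**2)
    return ViscoelasticSpectrum(frequency=nu, storage=gp / u, loss=gpp / u)


@dataclass
class ColeColeResult:
    """Cole–Cole curve and its deviation from a single-Maxwell semicircle."""

    storage: np.ndarray
    loss: np.ndarray
    centre: float        # semicircle centre on the G′ axis, mN/m
    radius: float        # mN/m
    deviation: float     # RMS distance from circle / radius


def cole_cole(spec: ViscoelasticSpectrum) -> ColeColeResult:
    """Fit a semicircle centred on the G′ axis to the (G′, G″) curve.

    The best-fit circle (centre c on the real axis, radius r) solves the
    linear system G′² + G″² = 2c·G′ + (r² − c²) in least squares; the score
    is the RMS of the geometric distance to the circle, normalised by r.
    A single relaxation mode gives an exact semicircle (score ≈ 0).
    """
    gp, gpp = spec.storage, spec.loss
    if gp.size < 5:
        raise ValueError("need at least 5 spectrum points")
    nu = spec.frequency
    if np.log10(nu.max() / nu.min()) < 2:
        warnings.warn("spectrum spans fewer than 2 decades; Cole–Cole "
                      "diagnostics may be unreliable")
    if np.ptp(gp) < 1e-12 * max(abs(gp).max(), 1.0):
        raise ValueError("degenerate (purely elastic) spectrum: Cole–Cole "
                         "curve collapses to a point")
    X = np.column_stack([2.0 * gp, np.ones_like(gp)])
    b = gp**2 + gpp**2
    (c, d), *_ = np.linalg.lstsq(X, b, rcond=None)
    r2 = d + c**2
    if r2 <= 0:
        raise ValueError("semicircle fit failed (non-positive radius)")
    r = float(np.sqrt(r2))
    dist = np.sqrt((gp - c) ** 2 + gpp**2) - r
    return ColeColeResult(storage=gp, loss=gpp, centre=float(c), radius=r,
                          deviation=float(np.sqrt(np.mean(dist**2)) / r))


def plateau_modulus(spec: ViscoelasticSpectrum,
                    band: tuple[float, float] = (0.1, np.inf),
                    flag_spread: float = 0.05) -> tuple[float, bool]:
    """Mean G′ over a frequency band (default ν > 100 mHz).

    Returns (plateau value in mN/m, is_plateau). The band is flagged
    non-plateau when the relative spread of G′ exceeds ``flag_spread``.
    """
    lo, hi = band
    mask = (spec.frequency >= lo) & (spec.frequency <= hi)
    if not mask.any():
        raise ValueError("band contains no spectrum points")
    gp = spec.storage[mask]
    mean = float(gp.mean())
    spread = float(np.ptp(gp) / mean) if mean != 0 else np.inf
    return mean, spread <= flag_spread
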