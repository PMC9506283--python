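"""Specular X-ray reflectivity of a lipid monolayer as a slab stack.

The interface is modelled as air / acyl-tail slab / headgroup slab /
semi-infinite aqueous subphase. Each slab carries a thickness d (Å), an
electron density ρ_e (e⁻/Å³) and a Gaussian roughness σ (Å) on its upper
interface. Reflectivity is computed dynamically with the Parratt recursion
and Névot–Croce roughness factors, which is exact near the critical edge
where the kinematic (Born) approximation fails. The electron density maps
to the refractive index through δ = r_e λ² ρ_e / 2π; absorption is
negligible for an organic film at 8 keV and is not modelled.

Normalising the measured R(q_z) by the Fresnel reflectivity R_F(q_z) of the
bare, ideally sharp subphase isolates the film structure factor; the
position of the first minimum of R/R_F constrains the total film thickness
(approximately q_z(1) ≈ (3π/2)/(d_T + d_H/2) for a two-slab film).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.signal import argrelmin
from scipy.special import erf

from .constants import R_E, WATER_RHO_E

__all__ = [
    "Slab",
    "SlabModel",
    "ReflectivityCurve",
    "ElectronDensityProfile",
    "fresnel",
    "critical_qz",
    "slab_reflectivity",
    "first_minimum",
    "density_profile",
    "fit_reflectivity",
]


@dataclass
class Slab:
    """One layer: thickness (Å), electron density (e⁻/Å³), upper-interface
    roughness (Å)."""

    thickness: float
    rho_e: float
    roughness: float = 0.0

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("slab thickness must be positive")
        if self.rho_e < 0 or self.roughness < 0:
            raise ValueError("rho_e and roughness must be non-negative")


@dataclass
class SlabModel:
    """Layer stack ordered from air (first slab) to the subphase.

    For the canonical monolayer decomposition, slab 0 is the acyl-tail slab
    (thickness ``d_T``) and slab 1 the headgroup slab (``d_H``);
    ``subphase_roughness`` smears the deepest interface.
    """

    slabs: list = field(default_factory=list)
    subphase_rho_e: float = WATER_RHO_E
    wavelength: float = 1.55
    subphase_roughness: float = 0.0

    def __post_init__(self):
        if self.subphase_rho_e <= 0:
            raise ValueError("subphase electron density must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def d_T(self) -> float:
        return self.slabs[0].thickness if self.slabs else 0.0

    @property
    def d_H(self) -> float:
        return self.slabs[1].thickness if len(self.slabs) > 1 else 0.0

    @property
    def d_tot(self) -> float:
        return sum(s.thickness for s in self.slabs)


@dataclass
class ReflectivityCurve:
    """R(q_z), optionally with the Fresnel-normalised branch R/R_F."""

    qz: np.ndarray
    R: np.ndarray
    R_over_RF: np.ndarray = None

    def __post_init__(self):
        self.qz = np.asarray(self.qz, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if np.any(self.qz <= 0):
            raise ValueError("qz must be positive")
        if self.R_over_RF is not None:
            self.R_over_RF = np.asarray(self.R_over_RF, dtype=float)


@dataclass
class ElectronDensityProfile:
    """Laterally averaged ρ_e(z); z increases from air into the subphase."""

    z: np.ndarray
    rho: np.ndarray


def critical_qz(rho_e: float) -> float:
    """Critical wave-vector transfer q_c = 4·sqrt(π r_e ρ_e).

    For water (ρ_e = 0.334 e⁻/Å³) this gives 0.0218 Å⁻¹, matching the
    critical angle of 0.154° at λ = 1.55 Å via q_c = (4π/λ) sin α_cr.
    """
    if rho_e <= 0:
        raise ValueError("electron density must be positive")
    return 4.0 * np.sqrt(np.pi * R_E * rho_e)


def fresnel(qz: np.ndarray, subphase_rho_e: float = WATER_RHO_E,
            wavelength: float = 1.55) -> np.ndarray:
    """Fresnel reflectivity of the bare, ideally sharp subphase.

    R_F = |(q_z − sqrt(q_z² − q_c²)) / (q_z + sqrt(q_z² − q_c²))|², with
    total reflection (R_F = 1) below q_c.
    """
    qz = np.asarray(qz, dtype=float)
    qc = critical_qz(subphase_rho_e)
    # complex sqrt handles qz < qc (evanescent) giving |r| = 1
    root = np.sqrt(qz.astype(complex) ** 2 - qc**2)
    r = (qz - root) / (qz + root)
    return np.abs(r) ** 2


def _kz_layers(qz: np.ndarray, model: SlabModel):
    """Vertical wavevector in each medium (air, slabs..., subphase)."""
    kz0 = qz.astype(complex) / 2.0
    rhos = [0.0] + [s.rho_e for s in model.slabs] + [model.subphase_rho_e]
    return [np.sqrt(kz0**2 - 4.0 * np.pi * R_E * rho) for rho in rhos]


def slab_reflectivity(model: SlabModel, qz_grid: np.ndarray) -> ReflectivityCurve:
    """Dynamical reflectivity of the stack by the Parratt recursion.

    Interface roughness enters through Névot–Croce factors
    exp(−2 k_{z,i} k_{z,i+1} σ²) on each Fresnel coefficient. An empty
    stack reduces exactly to the Fresnel reflectivity of the subphase.
    """
    qz = np.asarray(qz_grid, dtype=float)
    if np.any(qz <= 0):
        raise ValueError("qz grid must be positive")
    kz = _kz_layers(qz, model)
    sigmas = [s.roughness for s in model.slabs] + [model.subphase_roughness]
    thicknesses = [s.thickness for s in model.slabs]

    n_interfaces = len(kz) - 1
    # recursion from the deepest interface upward
    X = np.zeros_like(kz[0])
    for i in range(n_interfaces - 1, -1, -1):
        ki, kj = kz[i], kz[i + 1]
        r = (ki - kj) / (ki + kj) * np.exp(-2.0 * ki * kj * sigmas[i] ** 2)
        if i == n_interfaces - 1:
            X = r
        else:
            phase = np.exp(2j * kj * thicknesses[i])
            X = (r + X * phase) / (1.0 + r * X * phase)
    R = np.abs(X) ** 2
    RF = fresnel(qz, model.subphase_rho_e, model.wavelength)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(RF > 0, R / RF, np.nan)
    return ReflectivityCurve(qz=qz, R=R, R_over_RF=norm)


def first_minimum(curve: ReflectivityCurve, subphase_rho_e: float = WATER_RHO_E,
                  refine: bool = True) -> float:
    """q_z of the first local minimum of R/R_F above the critical edge.

    The minimum is located on the discrete grid and refined by a parabola
    through the three bracketing points. Requires the normalised branch.
    """
    if curve.R_over_RF is None:
        raise ValueError("curve has no normalised R/R_F branch")
    qc = critical_qz(subphase_rho_e)
    mask = curve.qz > 1.5 * qc
    q, y = curve.qz[mask], curve.R_over_RF[mask]
    idx = argrelmin(y, order=2)[0]
    idx = idx[(idx > 0) & (idx < q.size - 1)]
    # reject numerical ripples on an essentially flat curve: the dip must be
    # at least 5% below the running maximum before it
    real = [i for i in idx if y[i] < 0.95 * y[:i + 1].max()]
    if not real:
        raise ValueError("no local minimum of R/R_F found above the critical edge")
    i = int(real[0])
    if not refine:
        return float(q[i])
    # parabolic refinement on log(y)
    x0, x1, x2 = q[i - 1], q[i], q[i + 1]
    y0, y1, y2 = np.log(y[i - 1]), np.log(y[i]), np.log(y[i + 1])
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a <= 0:
        return float(x1)
    return float(-b / (2 * a))


def density_profile(model: SlabModel, z_grid: np.ndarray) -> ElectronDensityProfile:
    """Error-function-smeared electron density profile of the stack.

    ρ(z) = Σ over interfaces of Δρ/2 · (1 + erf((z − z_i)/(σ_i√2))); the
    σ → 0 limit is the exact step profile. z = 0 is the air/tail interface
    and z increases into the subphase.
    """
    z = np.asarray(z_grid, dtype=float)
    rhos = [0.0] + [s.rho_e for s in model.slabs] + [model.subphase_rho_e]
    sigmas = [s.roughness for s in model.slabs] + [model.subphase_roughness]
    z_interfaces = np.concatenate([[0.0], np.cumsum([s.thickness for s in model.slabs])])
    rho = np.zeros_like(z)
    for i, (zi, sigma) in enumerate(zip(z_interfaces, sigmas)):
        drho = rhos[i + 1] - rhos[i]
        if sigma == 0:
            rho += drho * (z >= zi)
        else:
            rho += drho * 0.5 * (1.0 + erf((z - zi) / (sigma * np.sqrt(2.0))))
    return ElectronDensityProfile(z=z, rho=rho)


def fit_reflectivity(curve: ReflectivityCurve, initial: SlabModel,
                     bounds: dict | None = None,
                     fixed_fields: tuple = ()) -> tuple[SlabModel, dict]:
    """Weighted least squares of log R(q_z) against the slab forward model.

    Free parameters: per-slab thickness, electron density and roughness plus
    the subphase roughness; names follow ``d0, rho0, sig0, d1, ...`` and
    ``sig_sub``. Any of these can be pinned via ``fixed_fields`` or given
    (lo, hi) windows via ``bounds``. Returns the fitted model and a dict of
    parameter values with 1σ uncertainties; parameters at their bounds are
    flagged in the report.
    """
    n_free = 3 * len(initial.slabs) + 1 - len(fixed_fields)
    if curve.qz.size < 5 * n_free:
        raise ValueError("need at least 5 data points per free parameter")
    bounds = bounds or {}

    params = lmfit.Parameters()

    def add(name, value, lo, hi):
        b = bounds.get(name, (lo, hi))
        params.add(name, value=value, min=b[0], max=b[1],
                   vary=name not in fixed_fields)

    for i, s in enumerate(initial.slabs):
        add(f"d{i}", s.thickness, 0.5 * s.thickness, 2.0 * s.thickness)
        add(f"rho{i}", s.rho_e, 0.5 * s.rho_e, 2.0 * s.rho_e)
        add(f"sig{i}", max(s.roughness, 0.1), 0.0, 10.0)
    add("sig_sub", max(initial.subphase_roughness, 0.1), 0.0, 10.0)

    def build(p):
        slabs = [Slab(p[f"d{i}"].value, p[f"rho{i}"].value, p[f"sig{i}"].value)
                 for i in range(len(initial.slabs))]
        return SlabModel(slabs=slabs, subphase_rho_e=initial.subphase_rho_e,
                         wavelength=initial.wavelength,
                         subphase_roughness=p["sig_sub"].value)

    log_data = np.log(np.clip(curve.R, 1e-300, None))

    def residual(p):
        R = slab_reflectivity(build(p), curve.qz).R
        return np.log(np.clip(R, 1e-300, None)) - log_data

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise RuntimeError("reflectivity fit did not converge")
    fitted = build(result.params)

    report = {}
    for name, par in result.params.items():
        stderr = par.stderr if par.stderr is not None else np.nan
        at_bound = (np.isfinite(par.min) and np.isclose(par.value, par.min)) or \
                   (np.isfinite(par.max) and np.isclose(par.value, par.max))
        if at_bound and par.vary:
            warnings.warn(f"fitted parameter {name} is at its bound")
        report[name] = {"value": par.value, "stderr": stderr, "at_bound": at_bound}
    report["d_tot"] = {"value": fitted.d_tot,
                       "stderr": float(np.sqrt(np.nansum(
                           [report[f"d{i}"]["stderr"] ** 2
                            for i in range(len(fitted.slabs))])))}
    report["redchi"] = result.redchi
    return fitted, report
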