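"""Synthetic inputs with known ground truth for every analysis stage.

No raw monolayer data are deposited for this kind of experiment, so the
pipeline is exercised on generated inputs whose generating parameters are
known exactly: parametric equations of state for π–A isotherms,
multi-exponential Maxwell relaxation transients, slab-model reflectivity
with interfacial roughness, single Bragg peaks on a linear background, and
toy monolayers (lattice-placed lipids with explicit hydrogens, sterols and
a water slab at bulk density). Every generator is a pure function of its
parameters and seed; noiseless outputs are exact fixed points of the
corresponding analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import xrr
from .constants import WATER_NUMBER_DENSITY, kT_mN_A2
from .gixd import GIXDPattern, _peak_profile
from .isotherm import Isotherm
from .rheology import ExponentialFit, RelaxationTransient
from .topology import LipidTopology, SpeciesTopology
from .trajectory import MonolayerTrajectory

__all__ = [
    "IsothermParams",
    "ToyMonolayerSpec",
    "gen_isotherm",
    "gen_relaxation",
    "gen_reflectivity",
    "gen_gixd_peak",
    "gen_toy_monolayer",
    "toy_topology",
]


# ---------------------------------------------------------------------------
# isotherms

@dataclass
class IsothermParams:
    """Equation-of-state menu for synthetic π–A isotherms.

    Models
    ------
    ``ideal_gas``
        π = kT/A (no coefficients).
    ``vdw2d``
        π = kT/(A − A0) − a/A², a 2D van-der-Waals-like law with
        coefficients ``A0`` (excluded area, Å²) and ``a`` (cohesion,
        mN/m·Å⁴).
    ``piecewise_linear``
        π = 0 above ``liftoff_area``; below it π rises linearly with
        |dπ/dA| = slopes[0] until ``break_pressures[0]``, then slopes[1],
        … — the two-gradient phenomenology of condensed mixed films.
    """

    model_name: str = "ideal_gas"
    coefficients: dict = field(default_factory=dict)
    temperature: float = 293.0
    noise_sd: float = 0.0
    seed: int = 0


def gen_isotherm(params: IsothermParams,
                 area_grid: np.ndarray | None = None) -> Isotherm:
    """Sample an equation of state on a descending area grid (+ noise)."""
    if area_grid is None:
        area_grid = np.linspace(100.0, 20.0, 400)
    a = np.asarray(area_grid, dtype=float)
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    c = params.coefficients
    kT = kT_mN_A2(params.temperature)
    if params.model_name == "ideal_gas":
        p = kT / a
    elif params.model_name == "vdw2d":
        a0, coh = c.get("A0", 20.0), c.get("a", 0.0)
        if np.any(a <= a0):
            raise ValueError("areas must exceed the excluded area A0")
        p = kT / (a - a0) - coh / a**2
    elif params.model_name == "piecewise_linear":
        a_lift = c["liftoff_area"]
        slopes = list(c["slopes"])
        breaks = list(c.get("break_pressures", []))
        if len(breaks) != len(slopes) - 1:
            raise ValueError("need one break pressure per extra slope")
        p = np.zeros_like(a)
        a_ref, p_ref = a_lift, 0.0
        compress = a < a_ref
        p[compress] = p_ref + slopes[0] * (a_ref - a[compress])
        for s_prev, s_next, pb in zip(slopes, slopes[1:], breaks):
            a_break = a_ref - (pb - p_ref) / s_prev  # area at the break pressure
            seg = a < a_break
            p[seg] = pb + s_next * (a_break - a[seg])
            a_ref, p_ref = a_break, pb
    else:
        raise ValueError(f"unknown isotherm model {params.model_name!r}")
    if np.any(p < 0):
        raise RuntimeError("model produced negative pressure before noise")
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        p = p + rng.normal(scale=params.noise_sd, size=p.shape)
        p = np.maximum(p, -0.49)
    return Isotherm(area=a, pressure=p, temperature=params.temperature,
                    composition=params.model_name)


# ---------------------------------------------------------------------------
# relaxation transients

def gen_relaxation(fit: ExponentialFit, rel_area_change: float,
                   t_grid: np.ndarray, noise_sd: float = 0.0,
                   seed: int = 0) -> RelaxationTransient:
    """Δπ(t) = Δπ∞ + Σ Aᵢ e^(−t/τᵢ) + Gaussian noise."""
    t = np.asarray(t_grid, dtype=float)
    y = fit(t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(scale=noise_sd, size=y.shape)
    return RelaxationTransient(time=t, delta_pi=y,
                               rel_area_change=rel_area_change)


# ---------------------------------------------------------------------------
# reflectivity and diffraction

def gen_reflectivity(model: xrr.SlabModel, qz_grid: np.ndarray,
                     noise_rel: float = 0.0, seed: int = 0) -> xrr.ReflectivityCurve:
    """Forward-model reflectivity with multiplicative log-normal noise.

    Counting statistics on a curve spanning many decades act
    multiplicatively, hence the log-normal choice; ``noise_rel`` is the
    relative noise level. Noiseless output is identical to
    :func:`leafletlab.xrr.slab_reflectivity`.
    """
    qz = np.asarray(qz_grid, dtype=float)
    if np.any(np.diff(qz) <= 0) or np.any(qz <= 0):
        raise ValueError("qz grid must be positive ascending")
    curve = xrr.slab_reflectivity(model, qz)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        factor = rng.lognormal(mean=0.0, sigma=noise_rel, size=qz.shape)
        RF = xrr.fresnel(qz, model.subphase_rho_e, model.wavelength)
        R = curve.R * factor
        curve = xrr.ReflectivityCurve(qz=qz, R=R, R_over_RF=R / RF)
    return curve


def gen_gixd_peak(q0: float, fwhm: float, amplitude: float = 100.0,
                  background: float = 10.0, shape: str = "lorentzian",
                  noise_sd: float = 0.0, seed: int = 0,
                  q_grid: np.ndarray | None = None) -> GIXDPattern:
    """One Bragg peak of known position/width on a linear background."""
    if q0 <= 0 or fwhm <= 0:
        raise ValueError("q0 and fwhm must be positive")
    if q_grid is None:
        q_grid = np.linspace(max(q0 - 15 * fwhm, 0.2 * q0),
                             q0 + 15 * fwhm, 400)
    q = np.asarray(q_grid, dtype=float)
    if fwhm > q.max() - q.min():
        raise ValueError("fwhm wider than the q grid span")
    y = _peak_profile(q, q0, fwhm, amplitude, shape) + background
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(scale=noise_sd, size=y.shape)
    return GIXDPattern(qxy=q, intensity=np.maximum(y, 0.0))


# ---------------------------------------------------------------------------
# toy monolayers

@dataclass
class ToyMonolayerSpec:
    """Geometry of a synthetic two-leaflet monolayer system.

    Two leaflets of ``n_lipids_per_leaflet`` lipids each face a central
    water slab (heads toward the water, tails toward the vacuum), mirroring
    the standard monolayer-pair simulation cell. Chains are either ideal
    all-trans zig-zags (with C–H bonds perpendicular to the chain axis, so
    order-parameter closed forms are exact) or seeded random walks.
    """

    n_lipids_per_leaflet: int = 36
    species_fractions: dict = field(default_factory=lambda: {"PLA": 1.0})
    lattice: str = "hexagonal"
    chain_conformation: str = "all_trans"
    tilt_deg: float = 0.0
    box: tuple = (40.0, 40.0, 120.0)
    water_thickness: float = 30.0
    seed: int = 0
    n_frames: int = 1
    n_tail_carbons: int = 8

    def __post_init__(self):
        total = sum(self.species_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("species fractions must sum to 1")
        if self.lattice not in ("hexagonal", "square", "random"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if self.chain_conformation not in ("all_trans", "random_walk"):
            raise ValueError("chain_conformation must be all_trans or random_walk")


_CC_BOND = 1.54      # Å
_CH_BOND = 1.09      # Å
_CC_DZ = 1.27        # all-trans rise per carbon along the chain axis
_STEROL_LENGTH = 9.0 # C3→C17 axis length, Å


def _phospholipid_template(n_carbons: int) -> SpeciesTopology:
    """Toy phospholipid: N/P/C2 head triad, two tails with explicit H."""
    electrons = {"N": 7, "P": 15, "C2": 6, "O1": 8, "HN1": 1, "HN2": 1}
    tails = {}
    for tail_id, prefix in (("sn1", "C1"), ("sn2", "C3")):
        entries = []
        carbonyl = f"{prefix}0"
        electrons[carbonyl] = 6
        for i in range(1, n_carbons + 1):
            cname = f"{prefix}{i}"
            h1, h2 = f"H{prefix[1]}{i}A", f"H{prefix[1]}{i}B"
            electrons[cname] = 6
            electrons[h1] = electrons[h2] = 1
            entries.append((cname, [h1, h2]))
        tails[tail_id] = entries
    return SpeciesTopology(
        name="", electrons=electrons, ref_atoms=["N", "P", "C2"],
        tails=tails, head_atoms=["N", "P", "C2", "O1"],
        carbonyl="C10", terminal=f"C1{n_carbons}", phosphorus="P",
        donors={"N": ["HN1", "HN2"]}, acceptors=["O1"],
    )


def _sterol_template() -> SpeciesTopology:
    """Toy sterol: hydroxyl head (O3/HO3), rigid C3→C17 body axis."""
    electrons = {"O3": 8, "HO3": 1, "C3": 6, "C7": 6, "C17": 6}
    return SpeciesTopology(
        name="", electrons=electrons, ref_atoms=["O3"], tails={},
        head_atoms=["O3"], carbonyl=None, terminal=None, phosphorus=None,
        donors={"O3": ["HO3"]}, acceptors=["O3"],
        sterol_axis=("C3", "C17"), is_sterol=True,
    )


def _water_template() -> SpeciesTopology:
    electrons = {"O": 8, "H1": 1, "H2": 1}
    return SpeciesTopology(
        name="SOL", electrons=electrons, ref_atoms=[], tails={},
        head_atoms=[], donors={"O": ["H1", "H2"]}, acceptors=["O"],
        is_water=True,
    )


def toy_topology(spec: ToyMonolayerSpec) -> LipidTopology:
    """Topology matching :func:`gen_toy_monolayer` output."""
    species = {}
    for name in spec.species_fractions:
        st = _sterol_template() if name.startswith("STE") \
            else _phospholipid_template(spec.n_tail_carbons)
        st.name = name
        species[name] = st
    water = _water_template()
    species["SOL"] = water
    return LipidTopology(species=species, water_species="SOL")


def _lattice_sites(spec: ToyMonolayerSpec, rng) -> np.ndarray:
    n = spec.n_lipids_per_leaflet
    lx, ly = spec.box[0], spec.box[1]
    if spec.lattice == "random":
        return rng.uniform([0, 0], [lx, ly], size=(n, 2))
    # factor n into nx × ny columns/rows (ny even for a periodic hex lattice)
    best = None
    for nx in range(1, n + 1):
        if n % nx:
            continue
        ny = n // nx
        if spec.lattice == "hexagonal" and ny % 2:
            continue
        score = abs(nx / ny - lx / ly)
        if best is None or score < best[0]:
            best = (score, nx, ny)
    if best is None:
        raise ValueError(f"cannot place {n} lipids on a periodic "
                         f"{spec.lattice} lattice (no even row factor)")
    _, nx, ny = best
    ax, ay = lx / nx, ly / ny
    sites = []
    for j in range(ny):
        xoff = (ax / 2 if (spec.lattice == "hexagonal" and j % 2) else 0.0)
        for i in range(nx):
            sites.append([(i + 0.25) * ax + xoff, (j + 0.25) * ay])
    return np.mod(np.asarray(sites), [lx, ly])


def _assign_species(spec: ToyMonolayerSpec, rng) -> list:
    n = spec.n_lipids_per_leaflet
    names = list(spec.species_fractions)
    counts = [int(np.floor(spec.species_fractions[s] * n)) for s in names]
    # distribute remainder in order of largest fractional part
    rem = n - sum(counts)
    fracs = [spec.species_fractions[s] * n - c for s, c in zip(names, counts)]
    for i in np.argsort(fracs)[::-1][:rem]:
        counts[i] += 1
    labels = sum(([s] * c for s, c in zip(names, counts)), [])
    return [labels[i] for i in rng.permutation(n)]


def _build_phospholipid(head_z: float, direction: float,
                        tilt_deg: float, conformation: str, rng,
                        n_carbons: int):
    """Atom names/elements/coords of one toy phospholipid.

    ``direction`` = +1 places tails above the head (upper leaflet), −1
    below. Head triad (N, P, C2) sits near ``head_z``; both tails descend
    from their carbonyls along the (possibly tilted) chain axis.
    """
    names, elements, coords = [], [], []

    def put(name, xyz):
        names.append(name)
        elements.append("H" if name.startswith("H") else name[0])
        coords.append(np.asarray(xyz, dtype=float))

    put("N", [0.0, 0.8, head_z - 0.8 * direction])
    put("HN1", [0.6, 1.4, head_z - 1.4 * direction])
    put("HN2", [-0.6, 1.4, head_z - 1.4 * direction])
    put("P", [0.0, -0.8, head_z])
    put("O1", [0.9, -1.4, head_z - 0.5 * direction])
    put("C2", [0.0, 0.0, head_z + 0.8 * direction])

    tilt = np.deg2rad(tilt_deg)
    axis = np.array([np.sin(tilt), 0.0, np.cos(tilt) * direction])
    e1 = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(axis, e1)
    e2 /= np.linalg.norm(e2)
    phi = np.deg2rad(54.75)  # half the tetrahedral H–C–H angle

    for tail_id, xoff in (("sn1", -1.2), ("sn2", 1.2)):
        prefix = "C1" if tail_id == "sn1" else "C3"
        base = np.array([xoff, 0.0, head_z + 1.5 * direction])
        put(f"{prefix}0", base)  # carbonyl carbon
        pos = base.copy()
        prev_dir = axis.copy()
        for i in range(1, n_carbons + 1):
            if conformation == "all_trans":
                zig = (e2 if i % 2 else -e2) * 0.437
                pos = base + axis * _CC_DZ * i + zig
                u1, u2 = e1, e2
            else:
                step = prev_dir + 0.6 * rng.normal(size=3)
                step[2] = abs(step[2]) * direction
                step /= np.linalg.norm(step)
                pos = pos + step * _CC_BOND
                prev_dir = step
                u1 = np.cross(step, rng.normal(size=3))
                u1 /= np.linalg.norm(u1)
                u2 = np.cross(step, u1)
            put(f"{prefix}{i}", pos)
            h1 = pos + _CH_BOND * (np.cos(phi) * u1 + np.sin(phi) * u2)
            h2 = pos + _CH_BOND * (np.cos(phi) * u1 - np.sin(phi) * u2)
            put(f"H{prefix[1]}{i}A", h1)
            put(f"H{prefix[1]}{i}B", h2)
    return names, elements, np.asarray(coords)


def _build_sterol(head_z: float, direction: float, tilt_deg: float):
    tilt = np.deg2rad(tilt_deg)
    axis = np.array([np.sin(tilt), 0.0, np.cos(tilt) * direction])
    names, elements, coords = [], [], []
    o3 = np.array([0.0, 0.0, head_z])
    for name, pos in (("O3", o3),
                      ("HO3", o3 + np.array([0.6, 0.6, -0.5 * direction])),
                      ("C3", o3 + axis * 1.4),
                      ("C7", o3 + axis * (1.4 + 0.4 * _STEROL_LENGTH)),
                      ("C17", o3 + axis * (1.4 + _STEROL_LENGTH))):
        names.append(name)
        elements.append("H" if name.startswith("H") else name[0])
        coords.append(pos)
    return names, elements, np.asarray(coords)


def gen_toy_monolayer(spec: ToyMonolayerSpec) -> MonolayerTrajectory:
    """Build a two-leaflet toy monolayer system with a central water slab.

    Lipids are placed on the requested lattice in each leaflet; water is a
    slab of randomly positioned and oriented 3-site molecules at the bulk
    number density 0.0334 Å⁻³. Deterministic for a fixed spec (seed
    included). Use :func:`toy_topology` for the matching atom roles.
    """
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    zc = lz / 2.0
    z_w_lo, z_w_hi = zc - spec.water_thickness / 2, zc + spec.water_thickness / 2
    chain_extent = 2.0 + spec.n_tail_carbons * _CC_DZ + 3.0
    if z_w_hi + chain_extent > lz or z_w_lo - chain_extent < 0:
        raise ValueError("infeasible packing: box z too small for chains "
                         "plus the water slab")

    names, elements, species, mol_ids, coords = [], [], [], [], []
    mol_id = 0

    for direction, head_z in ((+1, z_w_hi + 1.0), (-1, z_w_lo - 1.0)):
        sites = _lattice_sites(spec, rng)
        labels = _assign_species(spec, rng)
        for (x, y), label in zip(sites, labels):
            if label.startswith("STE"):
                n_, e_, c_ = _build_sterol(head_z, direction, spec.tilt_deg)
            else:
                n_, e_, c_ = _build_phospholipid(
                    head_z, direction, spec.tilt_deg,
                    spec.chain_conformation, rng, spec.n_tail_carbons)
            c_ = c_ + np.array([x, y, 0.0])
            c_[:, 0] = np.mod(c_[:, 0], lx)
            c_[:, 1] = np.mod(c_[:, 1], ly)
            names.extend(n_)
            elements.extend(e_)
            species.extend([label] * len(n_))
            mol_ids.extend([mol_id] * len(n_))
            coords.append(c_)
            mol_id += 1

    n_water = int(round(WATER_NUMBER_DENSITY * lx * ly * spec.water_thickness))
    o_pos = rng.uniform([0, 0, z_w_lo], [lx, ly, z_w_hi], size=(n_water, 3))
    for o in o_pos:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v = np.cross(u, rng.normal(size=3))
        v /= np.linalg.norm(v)
        h1 = o + 0.96 * u
        h2 = o + 0.96 * (np.cos(np.deg2rad(104.5)) * u
                         + np.sin(np.deg2rad(104.5)) * v)
        h1[:2] = np.mod(h1[:2], [lx, ly])
        h2[:2] = np.mod(h2[:2], [lx, ly])
        names.extend(["O", "H1", "H2"])
        elements.extend(["O", "H", "H"])
        species.extend(["SOL"] * 3)
        mol_ids.extend([mol_id] * 3)
        coords.append(np.array([o, h1, h2]))
        mol_id += 1

    frame = np.concatenate(coords)
    frames = np.repeat(frame[None], spec.n_frames, axis=0)
    return MonolayerTrajectory(
        coords=frames, box=np.array([lx, ly, lz]),
        species=np.array(species), names=np.array(names),
        elements=np.array(elements), molecule_ids=np.array(mol_ids))
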