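"""Plain-text readers and writers shared by all stages.

Curves travel as TSV with ``# key: value`` metadata headers; trajectories
as multi-frame PDB (CRYST1 box record) via MDAnalysis; topologies as YAML.
Every writer records the metadata needed to regenerate the file (seed,
parameters), so outputs are self-describing.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .gixd import GIXDPattern
from .isotherm import Isotherm
from .rheology import RelaxationTransient, ViscoelasticSpectrum
from .trajectory import MonolayerTrajectory
from .xrr import ReflectivityCurve

__all__ = [
    "read_curve",
    "write_curve",
    "write_trajectory",
    "read_trajectory",
]

_KINDS = ("isotherm", "transient", "reflectivity", "gixd")


def _parse_headers(path) -> tuple[dict, int]:
    meta, n_header = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta, n_header


def _load_numeric(path, n_header, n_cols) -> np.ndarray:
    rows, bad = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= n_header or not line.strip():
                continue
            parts = line.split()
            if len(parts) != n_cols:
                bad.append(lineno)
                continue
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                bad.append(lineno)
    if bad:
        raise ValueError(f"{path}: malformed rows at lines {bad}")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows)


def read_curve(path, kind: str):
    """Read a typed curve from a TSV file with ``#`` metadata headers."""
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, n_header = _parse_headers(path)
    if kind == "isotherm":
        data = _load_numeric(path, n_header, 2)
        return Isotherm(area=data[:, 0], pressure=data[:, 1],
                        temperature=float(meta.get("temperature_K", 293.0)),
                        composition=meta.get("composition", ""),
                        subphase=meta.get("subphase", "water"))
    if kind == "transient":
        if "rel_area_change" not in meta:
            raise ValueError(f"{path}: missing required header key "
                             "'rel_area_change'")
        data = _load_numeric(path, n_header, 2)
        return RelaxationTransient(
            time=data[:, 0], delta_pi=data[:, 1],
            rel_area_change=float(meta["rel_area_change"]),
            target_pressure=float(meta.get("pi0", 30.0)))
    if kind == "reflectivity":
        data = _load_numeric(path, n_header, 2)
        return ReflectivityCurve(qz=data[:, 0], R=data[:, 1])
    data = _load_numeric(path, n_header, 2)
    return GIXDPattern(qxy=data[:, 0], intensity=data[:, 1],
                       wavelength=float(meta.get("wavelength_A", 1.55)))


def write_curve(obj, path, metadata: dict | None = None) -> None:
    """Write a typed curve as TSV with ``#`` metadata headers (lossless
    round trip with :func:`read_curve`)."""
    meta = dict(metadata or {})
    if isinstance(obj, Isotherm):
        meta.setdefault("temperature_K", obj.temperature)
        meta.setdefault("composition", obj.composition)
        meta.setdefault("subphase", obj.subphase)
        cols, data = ("area_A2", "pressure_mN_m"), np.column_stack(
            [obj.area, obj.pressure])
    elif isinstance(obj, RelaxationTransient):
        meta.setdefault("rel_area_change", obj.rel_area_change)
        meta.setdefault("pi0", obj.target_pressure)
        cols, data = ("time_s", "delta_pi_mN_m"), np.column_stack(
            [obj.time, obj.delta_pi])
    elif isinstance(obj, ReflectivityCurve):
        cols, data = ("qz_invA", "R"), np.column_stack([obj.qz, obj.R])
    elif isinstance(obj, GIXDPattern):
        meta.setdefault("wavelength_A", obj.wavelength)
        cols, data = ("qxy_invA", "intensity"), np.column_stack(
            [obj.qxy, obj.intensity])
    elif isinstance(obj, ViscoelasticSpectrum):
        cols = ("nu_Hz", "G_prime_mN_m", "G_dprime_mN_m", "tan_phi",
                "eta_D_mNs_m")
        data = np.column_stack([obj.frequency, obj.storage, obj.loss,
                                obj.tan_phi, obj.eta_D])
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# columns: " + "\t".join(cols) + "\n")
        np.savetxt(fh, data, delimiter="\t", fmt="%.12g")


def write_trajectory(traj: MonolayerTrajectory, path) -> None:
    """Write a multi-frame PDB (with CRYST1 box) via MDAnalysis."""
    import MDAnalysis as mda

    n_mols = int(traj.molecule_ids.max()) + 1
    u = mda.Universe.empty(n_atoms=traj.n_atoms, n_residues=n_mols,
                           atom_resindex=traj.molecule_ids,
                           trajectory=True)
    u.add_TopologyAttr("names", [str(n) for n in traj.names])
    u.add_TopologyAttr("elements", [str(e) for e in traj.elements])
    resnames = [""] * n_mols
    for i in range(traj.n_atoms):
        resnames[traj.molecule_ids[i]] = str(traj.species[i])[:4]
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", list(range(1, n_mols + 1)))
    u.dimensions = [*traj.box, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                u.dimensions = [*traj.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)


def read_trajectory(path, periodic_z: bool = False) -> MonolayerTrajectory:
    """Read a multi-frame PDB/GRO file back into a trajectory."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        box = u.dimensions[:3].copy()
    elements = (u.atoms.elements if hasattr(u.atoms, "elements")
                else [n[0] for n in u.atoms.names])
    return MonolayerTrajectory(
        coords=coords, box=box,
        species=np.array([str(r) for r in u.atoms.resnames]),
        names=np.array([str(n) for n in u.atoms.names]),
        elements=np.array([str(e) for e in elements]),
        molecule_ids=u.atoms.resindices.copy(),
        periodic_z=periodic_z)
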