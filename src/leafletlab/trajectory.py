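"""Structural operators on monolayer trajectories.

The trajectory model is deliberately minimal: a static atom table (name,
element, species, molecule id) plus per-frame coordinates and an
orthorhombic box, periodic in x and y (a monolayer at an interface is not
periodic along its normal; fully periodic test boxes can opt in via
``periodic_z``). Two leaflets sit on either side of a water slab; a lipid
belongs to the leaflet given by the sign of its z relative to the water
midplane.

Implemented operators: Voronoi area per lipid, deuterium order parameters
S_CD = −½⟨3cos²β − 1⟩, tail/head/total thickness, electron density
profiles, vector (e.g. sterol-axis) orientation, 4-Å contact heatmaps,
geometric hydrogen-bond detection (d < 3.5 Å, angle > 150°), radial
distribution functions, minimum-distance hydration histograms and per-atom
hydration maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi, cKDTree

from .constants import WATER_NUMBER_DENSITY
from .topology import LipidTopology

__all__ = [
    "MonolayerTrajectory",
    "OrderParameterProfile",
    "ContactHeatmap",
    "RDFResult",
    "HydrationMap",
    "area_per_lipid",
    "order_parameter",
    "thicknesses",
    "electron_density_profile",
    "vector_orientation",
    "contact_heatmap",
    "hydrogen_bonds",
    "rdf",
    "hydration_histogram",
    "hydration_map",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class MonolayerTrajectory:
    """Frames of typed atoms in an orthorhombic box.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``box`` is (3,) and
    shared by all frames (NVT). ``species``/``names``/``elements`` are
    per-atom labels and ``molecule_ids`` groups atoms into molecules.
    """

    coords: np.ndarray
    box: np.ndarray
    species: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    molecule_ids: np.ndarray
    periodic_z: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        self.box = np.asarray(self.box, dtype=float)
        for attr in ("species", "names", "elements"):
            setattr(self, attr, np.asarray(getattr(self, attr)))
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        n = self.coords.shape[1]
        for attr in ("species", "names", "elements", "molecule_ids"):
            if getattr(self, attr).shape != (n,):
                raise ValueError(f"{attr} must have one entry per atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def periodic(self) -> tuple:
        return (True, True, self.periodic_z)

    def atom_indices(self, species: str, name: str | None = None) -> np.ndarray:
        mask = self.species == species
        if name is not None:
            mask &= self.names == name
        return np.nonzero(mask)[0]

    def molecules(self, species: str) -> list:
        """Atom-index arrays of each molecule of a species, in id order."""
        idx = np.nonzero(self.species == species)[0]
        mids = self.molecule_ids[idx]
        order = np.argsort(mids, kind="stable")
        idx, mids = idx[order], mids[order]
        splits = np.nonzero(np.diff(mids))[0] + 1
        return np.split(idx, splits) if idx.size else []

    def water_midplane(self, topology: LipidTopology, frame: int = 0) -> float:
        w = self.atom_indices(topology.water_species)
        if w.size == 0:
            raise ValueError("no water in trajectory")
        return float(self.coords[frame, w, 2].mean())

    def leaflet_of(self, mol_atoms: np.ndarray, topology: LipidTopology,
                   frame: int = 0) -> int:
        """+1 above the water midplane, −1 below."""
        zm = self.water_midplane(topology, frame)
        return 1 if self.coords[frame, mol_atoms, 2].mean() >= zm else -1

    def tail_frames(self, fraction: float = 0.05) -> "MonolayerTrajectory":
        """Trailing analysis window (defaults to the final 5% of frames)."""
        n = max(1, int(round(self.n_frames * fraction)))
        return MonolayerTrajectory(self.coords[-n:], self.box, self.species,
                                   self.names, self.elements,
                                   self.molecule_ids, self.periodic_z)


@dataclass
class OrderParameterProfile:
    """S_CD per carbon index for one tail of one species."""

    species: str
    tail: str
    carbons: list
    s_cd: np.ndarray
    sem: np.ndarray
    flags: list = field(default_factory=list)   # carbons outside [-0.5, 1.0]


@dataclass
class ContactHeatmap:
    """Normalised sterol–partner atom-contact frequencies."""

    sterol_species: str
    partner_species: str
    sterol_atoms: list
    partner_atoms: list
    matrix: np.ndarray            # sums to 1


@dataclass
class RDFResult:
    label_alpha: str
    label_beta: str
    r: np.ndarray                 # bin centres, Å
    g: np.ndarray


@dataclass
class HydrationMap:
    species: str
    atoms: list                   # heavy atoms
    probability: np.ndarray       # sums to 1


# ---------------------------------------------------------------------------
# geometry helpers

def min_image(disp: np.ndarray, box: np.ndarray, periodic) -> np.ndarray:
    """Minimum-image displacement vectors for an orthorhombic box."""
    disp = np.array(disp, dtype=float)
    for ax in range(3):
        if periodic[ax]:
            disp[..., ax] -= box[ax] * np.round(disp[..., ax] / box[ax])
    return disp


def pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray,
                   periodic) -> np.ndarray:
    """(len(a), len(b)) distance matrix with minimum-image convention."""
    disp = a[:, None, :] - b[None, :, :]
    disp = min_image(disp, box, periodic)
    return np.sqrt(np.sum(disp**2, axis=-1))


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def periodic_voronoi_areas(points_xy: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Cell areas of a 2D periodic Voronoi tessellation.

    The points are replicated into the 8 neighbouring images and the
    tessellation of the 3×3 tile is clipped implicitly: every central-cell
    region is then bounded and exact for cells smaller than the box.
    """
    pts = np.mod(points_xy, box_xy)
    n = pts.shape[0]
    shifts = [(ix, iy) for ix in (-1, 0, 1) for iy in (-1, 0, 1)]
    tiled = np.concatenate([pts + np.array(s) * box_xy for s in shifts])
    central_offset = shifts.index((0, 0)) * n
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[central_offset + i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded Voronoi cell; box too small for "
                               "the point configuration")
        areas[i] = _polygon_area(vor.vertices[region])
    return areas


# ---------------------------------------------------------------------------
# operators

def area_per_lipid(traj: MonolayerTrajectory, topology: LipidTopology,
                   frame: int = 0):
    """Voronoi area per lipid from headgroup reference points.

    The reference points of every lipid in a leaflet are tessellated
    together (periodic in x, y); a lipid's area is the sum of its
    reference-point cell areas. Returns (per-species mean over both
    leaflets, per-lipid dict keyed by (species, molecule id)).
    """
    per_lipid = {}
    for leaflet in (+1, -1):
        points, owners = [], []
        for sp in topology.lipid_species():
            st = topology[sp]
            if not st.ref_atoms:
                continue
            for mol in traj.molecules(sp):
                if traj.leaflet_of(mol, topology, frame) != leaflet:
                    continue
                names = traj.names[mol]
                for ref in st.ref_atoms:
                    sel = mol[names == ref]
                    if sel.size != 1:
                        raise ValueError(f"{sp}: reference atom {ref} not "
                                         "uniquely present")
                    points.append(traj.coords[frame, sel[0], :2])
                    owners.append((sp, int(traj.molecule_ids[sel[0]])))
        if not points:
            continue
        pts = np.asarray(points)
        # jitter exact duplicates, which break the tessellation
        _, first = np.unique(np.round(pts, 9), axis=0, return_index=True)
        if first.size != pts.shape[0]:
            warnings.warn("coincident reference points jittered by 1e-6 Å")
            rng = np.random.default_rng(0)
            dup = np.setdiff1d(np.arange(pts.shape[0]), first)
            pts[dup] += rng.normal(scale=1e-6, size=(dup.size, 2))
        areas = periodic_voronoi_areas(pts, traj.box[:2])
        for (key, a) in zip(owners, areas):
            per_lipid[key] = per_lipid.get(key, 0.0) + a
    if not per_lipid:
        raise ValueError("no lipids with reference atoms found")
    species_mean = {}
    for sp in topology.lipid_species():
        vals = [v for (s, _), v in per_lipid.items() if s == sp]
        if vals:
            species_mean[sp] = float(np.mean(vals))
    return species_mean, per_lipid


def _block_sem(per_frame: np.ndarray, n_blocks: int = 10) -> float:
    """SEM by block averaging (10 blocks by default)."""
    n = per_frame.size
    if n < 2:
        return np.nan
    nb = min(n_blocks, n)
    blocks = np.array_split(per_frame, nb)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(nb)) if nb > 1 else np.nan


def order_parameter(traj: MonolayerTrajectory, topology: LipidTopology,
                    species: str, tail: str = "sn1") -> OrderParameterProfile:
    """Deuterium order parameter profile S_CD(carbon index) for one tail.

    S_CD = −½(3cos²β − 1) with β the C–H bond angle to +z, averaged over
    bonds, molecules and frames; the SEM comes from block averaging over
    frames. Carbons whose mean falls outside the physically admissible
    [−0.5, 1.0] band for methylene geometries are flagged.
    """
    st = topology[species]
    if tail not in st.tails:
        raise ValueError(f"{species} has no tail {tail!r}")
    mols = traj.molecules(species)
    if not mols:
        raise ValueError(f"no molecules of species {species}")
    carbons, values, sems, flags = [], [], [], []
    name_of = traj.names

    def gather(mol, atom, what):
        idx = mol[name_of[mol] == atom]
        if idx.size != 1:
            raise ValueError(f"{species}: {what} {atom} missing in trajectory")
        return int(idx[0])

    for carbon, hydrogens in st.tails[tail]:
        if not hydrogens:
            continue
        c_idx = np.array([gather(m, carbon, "carbon") for m in mols])
        s_per_frame = []
        for h in hydrogens:
            h_idx = np.array([gather(m, h, f"hydrogen of {carbon}")
                              for m in mols])
            bond = traj.coords[:, h_idx] - traj.coords[:, c_idx]
            cos_b = bond[..., 2] / np.linalg.norm(bond, axis=-1)
            s_per_frame.append(-0.5 * (3.0 * cos_b**2 - 1.0))
        # average over bonds and molecules within each frame
        per_frame = np.stack(s_per_frame).mean(axis=(0, 2))
        mean = float(per_frame.mean())
        carbons.append(carbon)
        values.append(mean)
        sems.append(_block_sem(per_frame))
        if not (-0.5 <= mean <= 1.0):
            flags.append(carbon)
    if flags:
        warnings.warn(f"S_CD outside [-0.5, 1.0] for {flags}: chemically "
                      "impossible methylene geometry")
    return OrderParameterProfile(species=species, tail=tail, carbons=carbons,
                                 s_cd=np.array(values), sem=np.array(sems),
                                 flags=flags)


def thicknesses(traj: MonolayerTrajectory, topology: LipidTopology) -> dict:
    """Per-species tail, head and total thickness (Å).

    tail = mean |z(terminal C) − z(carbonyl C)|, head = mean
    |z(carbonyl C) − z(P)|, total = tail + head, averaged over molecules
    and frames. Species without a phosphorus (sterols) are skipped.
    """
    out = {}
    for sp in topology.lipid_species():
        st = topology[sp]
        if st.phosphorus is None or st.carbonyl is None or st.terminal is None:
            continue
        tails_, heads_ = [], []
        for mol in traj.molecules(sp):
            names = traj.names[mol]
            def z_of(atom):
                sel = mol[names == atom]
                if sel.size != 1:
                    raise ValueError(f"{sp}: atom {atom} not uniquely present")
                return traj.coords[:, sel[0], 2]
            z_term, z_carb, z_p = z_of(st.terminal), z_of(st.carbonyl), z_of(st.phosphorus)
            tails_.append(np.abs(z_term - z_carb))
            heads_.append(np.abs(z_carb - z_p))
        tail = float(np.mean(tails_))
        head = float(np.mean(heads_))
        out[sp] = {"tail": tail, "head": head, "total": tail + head}
    if not out:
        raise ValueError("no species with a full head/tail marker set")
    return out


def electron_density_profile(traj: MonolayerTrajectory, topology: LipidTopology,
                             bins: int = 100, average_leaflets: bool = True):
    """Electron density ρ_e(z) (e⁻/Å³), frame-averaged.

    Electron counts come from the topology's per-atom tables; atoms of
    unknown species fall back to their element. With ``average_leaflets``
    the profile is symmetrised by reflection about the water midplane,
    which is how monolayer pairs sharing a water slab are reported.
    """
    from .constants import ELECTRONS
    if bins <= 0:
        raise ValueError("bins must be positive")
    weights = np.empty(traj.n_atoms)
    for i in range(traj.n_atoms):
        sp, name = str(traj.species[i]), str(traj.names[i])
        if sp in topology and name in topology[sp].electrons:
            weights[i] = topology[sp].electrons[name]
        else:
            weights[i] = ELECTRONS[str(traj.elements[i])]
    edges = np.linspace(0.0, traj.box[2], bins + 1)
    area = traj.box[0] * traj.box[1]
    bin_vol = np.diff(edges) * area
    hist = np.zeros(bins)
    for f in range(traj.n_frames):
        h, _ = np.histogram(traj.coords[f, :, 2], bins=edges, weights=weights)
        hist += h
    rho = hist / (bin_vol * traj.n_frames)
    z = 0.5 * (edges[:-1] + edges[1:])
    if average_leaflets:
        try:
            zm = traj.water_midplane(topology)
        except ValueError:
            zm = float(traj.box[2] / 2)
        # resample the reflected profile onto the same grid and average
        rho_ref = np.interp(2 * zm - z, z, rho, left=0.0, right=0.0)
        rho = 0.5 * (rho + rho_ref)
    return z, rho


def vector_orientation(traj: MonolayerTrajectory, topology: LipidTopology,
                       species: str, atom_pair: tuple | None = None,
                       bins: int = 36):
    """Angle of an intramolecular vector to +z, per molecule per frame.

    Defaults to the species' sterol axis (C3 → C17). Returns
    (angles_deg array, histogram counts, bin edges, mean angle).
    """
    st = topology[species]
    if atom_pair is None:
        if st.sterol_axis is None:
            raise ValueError(f"{species} has no default orientation axis")
        atom_pair = st.sterol_axis
    a_name, b_name = atom_pair
    a_idx, b_idx = [], []
    for mol in traj.molecules(species):
        names = traj.names[mol]
        a, b = mol[names == a_name], mol[names == b_name]
        if a.size != 1 or b.size != 1:
            raise ValueError(f"{species}: axis atoms {atom_pair} not present")
        a_idx.append(a[0])
        b_idx.append(b[0])
    vec = traj.coords[:, b_idx] - traj.coords[:, a_idx]
    norm = np.linalg.norm(vec, axis=-1)
    if np.any(norm == 0):
        raise ValueError("zero-length orientation vector")
    angles = np.degrees(np.arccos(np.clip(vec[..., 2] / norm, -1, 1))).ravel()
    hist, edges = np.histogram(angles, bins=bins, range=(0.0, 180.0))
    return angles, hist, edges, float(angles.mean())


def contact_heatmap(traj: MonolayerTrajectory, topology: LipidTopology,
                    sterol_species: str, partner_species: str,
                    cutoff: float = 4.0) -> ContactHeatmap:
    """Atom-pair contact frequencies between a sterol and a lipid species.

    Counts, over all frames and molecule pairs, how often each
    (sterol atom, partner atom) pair is within ``cutoff`` (minimum image),
    then normalises the matrix by the total number of contact events.
    """
    s_atoms = [a for a in topology[sterol_species].electrons]
    p_atoms = [a for a in topology[partner_species].electrons]
    s_order = {a: i for i, a in enumerate(s_atoms)}
    p_order = {a: i for i, a in enumerate(p_atoms)}
    counts = np.zeros((len(s_atoms), len(p_atoms)))
    s_mols = traj.molecules(sterol_species)
    p_mols = traj.molecules(partner_species)
    if not s_mols or not p_mols:
        raise ValueError("both species must be present")
    for f in range(traj.n_frames):
        for sm in s_mols:
            s_names = traj.names[sm]
            for pm in p_mols:
                if (sterol_species == partner_species
                        and traj.molecule_ids[sm[0]] == traj.molecule_ids[pm[0]]):
                    continue
                d = pair_distances(traj.coords[f, sm], traj.coords[f, pm],
                                   traj.box, traj.periodic)
                ii, jj = np.nonzero(d < cutoff)
                for i, j in zip(ii, jj):
                    counts[s_order[s_names[i]],
                           p_order[traj.names[pm][j]]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no contacts within the cutoff in any frame")
    return ContactHeatmap(sterol_species=sterol_species,
                          partner_species=partner_species,
                          sterol_atoms=s_atoms, partner_atoms=p_atoms,
                          matrix=counts / total)


def hydrogen_bonds(traj: MonolayerTrajectory, topology: LipidTopology,
                   d_max: float = 3.5, angle_min: float = 150.0) -> dict:
    """Geometric intermolecular hydrogen-bond counts per frame.

    A bond requires donor–acceptor distance < ``d_max`` Å and a
    donor–hydrogen–acceptor angle > ``angle_min``°. Keys of the returned
    dict are ("species:donor_atom", "species:acceptor_atom"); values are
    arrays of counts per frame.
    """
    donors = []   # (mol_id, donor_idx, [h_idx...], label)
    acceptors = []
    for sp in topology.species:
        st = topology[sp]
        for mol in traj.molecules(sp):
            names = traj.names[mol]
            mid = int(traj.molecule_ids[mol[0]])
            for d_name, h_names in st.donors.items():
                d_idx = mol[names == d_name]
                if d_idx.size != 1:
                    continue
                h_idx = [mol[names == h][0] for h in h_names
                         if (mol[names == h]).size == 1]
                if not h_idx:
                    raise ValueError(f"{sp}: donor {d_name} has no hydrogen "
                                     "in the trajectory")
                donors.append((mid, int(d_idx[0]), h_idx, f"{sp}:{d_name}"))
            for a_name in st.acceptors:
                a_idx = mol[names == a_name]
                if a_idx.size == 1:
                    acceptors.append((mid, int(a_idx[0]), f"{sp}:{a_name}"))
    out: dict = {}
    for f in range(traj.n_frames):
        for d_mid, d_idx, h_list, d_label in donors:
            for a_mid, a_idx, a_label in acceptors:
                if d_mid == a_mid:
                    continue
                da = min_image(traj.coords[f, a_idx] - traj.coords[f, d_idx],
                               traj.box, traj.periodic)
                if np.linalg.norm(da) >= d_max:
                    continue
                for h_idx in h_list:
                    hd = min_image(traj.coords[f, d_idx] - traj.coords[f, h_idx],
                                   traj.box, traj.periodic)
                    ha = min_image(traj.coords[f, a_idx] - traj.coords[f, h_idx],
                                   traj.box, traj.periodic)
                    cos_ang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                    angle = np.degrees(np.arccos(np.clip(cos_ang, -1, 1)))
                    if angle > angle_min:
                        key = (d_label, a_label)
                        if key not in out:
                            out[key] = np.zeros(traj.n_frames, dtype=int)
                        out[key][f] += 1
                        break
    return out


def rdf(traj: MonolayerTrajectory, sel_alpha: np.ndarray, sel_beta: np.ndarray,
        r_max: float, bins: int = 100,
        labels: tuple = ("alpha", "beta")) -> RDFResult:
    """Radial distribution function g(r) = ρ_{r,α,β} / ρ_β.

    ``sel_alpha``/``sel_beta`` are atom-index arrays. Shell-histogram
    estimator with minimum-image distances, normalised by the mean β
    density and the spherical shell volumes; for a homogeneous system
    g(r) → 1 at large r. Requires r_max ≤ half the smallest box edge.
    """
    sel_alpha = np.asarray(sel_alpha, dtype=int)
    sel_beta = np.asarray(sel_beta, dtype=int)
    if sel_alpha.size == 0 or sel_beta.size == 0:
        raise ValueError("selections must be non-empty")
    if r_max > traj.box.min() / 2:
        raise ValueError("r_max exceeds half the smallest box edge")
    edges = np.linspace(0.0, r_max, bins + 1)
    hist = np.zeros(bins)
    volume = float(np.prod(traj.box))
    rho_beta = sel_beta.size / volume
    same = np.array_equal(np.sort(sel_alpha), np.sort(sel_beta))
    use_tree = all(traj.periodic) and sel_alpha.size * sel_beta.size > 4_000_000
    for f in range(traj.n_frames):
        if use_tree:
            pos_b = np.mod(traj.coords[f, sel_beta], traj.box)
            tree = cKDTree(pos_b, boxsize=traj.box)
            pos_a = np.mod(traj.coords[f, sel_alpha], traj.box)
            pairs = tree.query_ball_point(pos_a, r_max)
            d_all = []
            for i, nbrs in enumerate(pairs):
                if not nbrs:
                    continue
                disp = min_image(pos_b[nbrs] - pos_a[i], traj.box, traj.periodic)
                d = np.sqrt((disp**2).sum(axis=1))
                d_all.append(d)
            d = np.concatenate(d_all) if d_all else np.empty(0)
            d = d[d > 1e-9]
        else:
            d = pair_distances(traj.coords[f, sel_alpha],
                               traj.coords[f, sel_beta],
                               traj.box, traj.periodic).ravel()
            if same:
                d = d[d > 1e-9]
            d = d[d <= r_max]
        h, _ = np.histogram(d, bins=edges)
        hist += h
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = traj.n_frames * sel_alpha.size * rho_beta * shell_vol
    g = hist / norm
    r = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(label_alpha=labels[0], label_beta=labels[1], r=r, g=g)


def hydration_histogram(traj: MonolayerTrajectory, topology: LipidTopology,
                        bins: int = 50, r_max: float = 20.0,
                        surface_atoms: dict | None = None):
    """Histogram of minimum water–surface distances, in bulk-density units.

    The monolayer surface defaults to the headgroup heavy atoms of every
    lipid species (configurable via ``surface_atoms``: species → atom-name
    list). Each water molecule contributes its oxygen's minimum distance to
    the surface set; counts are divided by the slab volume per bin
    (box xy-area × bin width) and by the bulk water number density, so the
    histogram plateaus at ≈ 1 in bulk water.
    """
    w_ox = traj.atom_indices(topology.water_species, "O")
    if w_ox.size == 0:
        w_ox = traj.atom_indices(topology.water_species)
    if w_ox.size == 0:
        raise ValueError("no water in trajectory")
    surf_idx = []
    for sp in topology.lipid_species():
        wanted = (surface_atoms or {}).get(
            sp, [a for a in topology[sp].head_atoms if not a.startswith("H")])
        for name in wanted:
            surf_idx.extend(traj.atom_indices(sp, name))
    surf_idx = np.asarray(sorted(set(surf_idx)), dtype=int)
    if surf_idx.size == 0:
        raise ValueError("empty monolayer surface set")
    edges = np.linspace(0.0, r_max, bins + 1)
    hist = np.zeros(bins)
    for f in range(traj.n_frames):
        d = pair_distances(traj.coords[f, w_ox], traj.coords[f, surf_idx],
                           traj.box, traj.periodic).min(axis=1)
        h, _ = np.histogram(d, bins=edges)
        hist += h
    area = traj.box[0] * traj.box[1]
    bin_width = edges[1] - edges[0]
    density = hist / (traj.n_frames * area * bin_width * WATER_NUMBER_DENSITY)
    return 0.5 * (edges[:-1] + edges[1:]), density


def hydration_map(traj: MonolayerTrajectory, topology: LipidTopology,
                  species: str, cutoff: float = 4.0) -> HydrationMap:
    """Per-heavy-atom hydration probability, normalised over the molecule.

    An atom counts as hydrated in a frame when a water oxygen lies within
    ``cutoff``. Events are summed over molecules and frames and normalised
    so the map sums to 1.
    """
    st = topology[species]
    heavy = st.heavy_atoms
    w_ox = traj.atom_indices(topology.water_species, "O")
    if w_ox.size == 0:
        raise ValueError("no water in trajectory")
    counts = np.zeros(len(heavy))
    for mol in traj.molecules(species):
        names = traj.names[mol]
        idx = []
        for a in heavy:
            sel = mol[names == a]
            if sel.size != 1:
                raise ValueError(f"{species}: heavy atom {a} missing")
            idx.append(sel[0])
        idx = np.asarray(idx)
        for f in range(traj.n_frames):
            d = pair_distances(traj.coords[f, idx], traj.coords[f, w_ox],
                               traj.box, traj.periodic)
            counts += (d.min(axis=1) < cutoff)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"{species} is never hydrated at cutoff {cutoff} Å")
    return HydrationMap(species=species, atoms=heavy,
                        probability=counts / total)
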