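"""Per-species atom-role definitions for trajectory analysis.

Every structural operator needs to know which atoms of a lipid play which
role: the headgroup reference atoms used for the Voronoi tessellation
(three per phospholipid, one per sterol, so the small sterol headgroup is
not over-weighted), the ordered tail carbons with their attached hydrogens
(order parameters), the carbonyl/terminal/phosphorus markers (thickness),
hydrogen-bond donors and acceptors, per-atom electron counts (density
profiles) and the sterol orientation axis (C3 → C17).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["SpeciesTopology", "LipidTopology"]


@dataclass
class SpeciesTopology:
    """Atom roles of one molecular species.

    ``tails`` maps a tail id ("sn1", "sn2") to an ordered list of
    ``[carbon_name, [hydrogen_names...]]`` entries from the carbonyl end to
    the terminal methyl. ``donors`` maps a donor heavy atom to its attached
    hydrogens.
    """

    name: str
    electrons: dict = field(default_factory=dict)   # atom name -> e⁻ count
    ref_atoms: list = field(default_factory=list)
    tails: dict = field(default_factory=dict)
    head_atoms: list = field(default_factory=list)
    carbonyl: str | None = None
    terminal: str | None = None
    phosphorus: str | None = None
    donors: dict = field(default_factory=dict)
    acceptors: list = field(default_factory=list)
    sterol_axis: tuple | None = None                # (C3, C17)
    is_sterol: bool = False
    is_water: bool = False

    def __post_init__(self):
        template = set(self.electrons)
        if not template:
            return
        named = set(self.ref_atoms) | set(self.head_atoms) | set(self.donors) \
            | set(self.acceptors)
        for entries in self.tails.values():
            for carbon, hydrogens in entries:
                named.add(carbon)
                named.update(hydrogens)
        for atom in (self.carbonyl, self.terminal, self.phosphorus):
            if atom is not None:
                named.add(atom)
        if self.sterol_axis:
            named.update(self.sterol_axis)
        for hs in self.donors.values():
            named.update(hs)
        missing = named - template
        if missing:
            raise ValueError(f"{self.name}: atoms {sorted(missing)} not in "
                             "the species template (electrons table)")
        n_ref = len(self.ref_atoms)
        if n_ref and not self.is_water:
            expected = 1 if self.is_sterol else 3
            if n_ref != expected:
                raise ValueError(
                    f"{self.name}: {n_ref} reference atoms; expected "
                    f"{expected} ({'sterol' if self.is_sterol else 'phospholipid'})")

    @property
    def heavy_atoms(self) -> list:
        return [a for a in self.electrons if not a.startswith("H")]


@dataclass
class LipidTopology:
    """Collection of species topologies plus the water species name."""

    species: dict = field(default_factory=dict)     # name -> SpeciesTopology
    water_species: str = "SOL"

    def __getitem__(self, name: str) -> SpeciesTopology:
        return self.species[name]

    def __contains__(self, name: str) -> bool:
        return name in self.species

    def lipid_species(self) -> list:
        return [s for s in self.species if s != self.water_species]

    def to_yaml(self, path) -> None:
        payload = {"water_species": self.water_species,
                   "species": {k: asdict(v) for k, v in self.species.items()}}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "LipidTopology":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        species = {}
        for name, spec in payload.get("species", {}).items():
            if spec.get("sterol_axis"):
                spec["sterol_axis"] = tuple(spec["sterol_axis"])
            spec["tails"] = {tid: [(c, list(hs)) for c, hs in entries]
                             for tid, entries in spec.get("tails", {}).items()}
            species[name] = SpeciesTopology(**spec)
        return cls(species=species,
                   water_species=payload.get("water_species", "SOL"))
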