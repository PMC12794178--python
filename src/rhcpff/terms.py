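"""Domain types for the additive potential and its topology.

The potential is the standard Amber functional form: harmonic bonds and
angles, periodic torsions, and pairwise 12-6 Lennard-Jones plus Coulomb
interactions with 1-2/1-3 exclusions and scaled 1-4 pairs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class AtomSpec:
    """One atom with its type-level parameters.

    vdw_radius is the Lennard-Jones R*/2 value (half the minimum-energy
    pair separation of the homo-pair), vdw_well_depth the well depth
    epsilon, both in the Amber frcmod convention.
    """

    index: int
    name: str
    element: str
    atom_type: str
    mass: float
    charge: float = 0.0
    vdw_radius: float = 0.0
    vdw_well_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")
        if self.vdw_well_depth < 0:
            raise ValueError(f"atom {self.name}: negative well depth")


@dataclass
class BondTerm:
    i: int
    j: int
    force_constant: float  # kcal mol^-1 A^-2
    equilibrium: float  # Angstrom

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond between an atom and itself")
        if self.force_constant < 0:
            raise ValueError("negative bond force constant")
        if self.equilibrium <= 0:
            raise ValueError("non-positive equilibrium bond length")


@dataclass
class AngleTerm:
    i: int
    j: int
    k: int
    force_constant: float  # kcal mol^-1 rad^-2
    equilibrium: float  # degrees

    def __post_init__(self) -> None:
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError("angle atoms must be distinct")
        if self.force_constant < 0:
            raise ValueError("negative angle force constant")
        if not 0.0 < self.equilibrium < 180.0 and self.force_constant > 0:
            raise ValueError("equilibrium angle outside (0, 180) degrees")


@dataclass
class DihedralTerm:
    i: int
    j: int
    k: int
    l: int
    barrier: float  # V_n, kcal/mol (before division by divider)
    multiplicity: int
    phase: float  # degrees
    divider: int = 1  # frcmod IDIVF

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("dihedral multiplicity must be >= 1")
        if self.divider < 1:
            raise ValueError("dihedral divider must be >= 1")


@dataclass
class NonbondedSettings:
    """Evaluation conventions for the pairwise terms.

    cutoff=None (the default) means no truncation, appropriate for
    gas-phase evaluation; periodic systems use plain truncation with the
    minimum-image convention.
    """

    cutoff: float | None = None
    dielectric: float = 1.0
    coulomb_constant: float = 332.0522
    scale_14_elec: float = 1.2
    scale_14_vdw: float = 2.0

    def __post_init__(self) -> None:
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive or None")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")


@dataclass
class EnergyBreakdown:
    bond: float
    angle: float
    dihedral: float
    vdw: float
    coulomb: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.vdw + self.coulomb

    def as_dict(self) -> dict[str, float]:
        return {
            "bond": self.bond,
            "angle": self.angle,
            "dihedral": self.dihedral,
            "vdw": self.vdw,
            "coulomb": self.coulomb,
            "total": self.total,
        }


@dataclass
class Topology:
    """A fully enumerated bonded topology plus nonbonded bookkeeping.

    exclusions are unordered 1-2/1-3 pairs; pairs14 the unordered 1-4
    pairs whose interactions are divided by the 1-4 scale factors.
    symmetry_classes partitions atom indices into graph-automorphism
    orbits (empty until assigned by the symmetry machinery).
    """

    atoms: list[AtomSpec]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    pairs14: set[tuple[int, int]] = field(default_factory=set)
    net_charge: float = 0.0
    symmetry_classes: list[list[int]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def set_charges(self, q: np.ndarray) -> None:
        if len(q) != self.n_atoms:
            raise ValueError("charge count does not match atom count")
        for a, qi in zip(self.atoms, q):
            a.charge = float(qi)

    def copy(self) -> "Topology":
        return Topology(
            atoms=[replace(a) for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            angles=[replace(a) for a in self.angles],
            dihedrals=[replace(d) for d in self.dihedrals],
            exclusions=set(self.exclusions),
            pairs14=set(self.pairs14),
            net_charge=self.net_charge,
            symmetry_classes=[list(c) for c in self.symmetry_classes],
        )

    def class_of(self) -> np.ndarray:
        """Map each atom index to its symmetry-class id (-1 if unassigned)."""
        out = np.full(self.n_atoms, -1, dtype=int)
        for cid, members in enumerate(self.symmetry_classes):
            for m in members:
                out[m] = cid
        return out


def angle_value(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees, arccos argument clamped away from +/-1."""
    a = coords[i] - coords[j]
    b = coords[k] - coords[j]
    c = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    c = max(-1.0 + 1e-12, min(1.0 - 1e-12, c))
    return math.degrees(math.acos(c))


def dihedral_value(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral i-j-k-l in degrees, IUPAC sign convention."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))
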