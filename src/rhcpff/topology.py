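"""Sigma-bonded topology construction for [(alpha-diimine)Rh(Cp*)(X)] complexes.

The eta-5 Rh-Cp* interaction is represented by five explicit Rh-C bonds.
To keep the five ring carbons interchangeable (free ring rotation), the
builder assigns one custom type to all of them (Y1), one to both
coordinating nitrogens (Y6), one to the chloride (Y8) and one to the 2,2'
carbons of the diimine (YC); the metal is M1.  Every other atom keeps a
standard general-force-field type, and parameters for custom types fall
back to their standard counterparts (Y1/YC -> ca, Y6 -> nb, Y8 -> cl)
whenever the custom tables carry no explicit entry.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .io import FrcmodTable, canonical_angle, canonical_bond, canonical_dihedral
from .terms import AngleTerm, AtomSpec, BondTerm, DihedralTerm, Topology

#: parameter fallback from custom to standard atom types
TYPE_ALIASES = {"Y1": "ca", "Y6": "nb", "Y8": "cl", "YC": "ca"}


class MissingParameterError(KeyError):
    """A bonded or nonbonded term has no parameter entry for its types."""


class StructureError(ValueError):
    """The complex violates the expected coordination pattern."""


@dataclass
class ComplexStructure:
    """Connectivity-level description of one complex.

    ligand_labels holds one of {"metal", "cp*", "diimine", "halide"} per
    atom. oxidation_state is "I" or "III" (the latter carries a chloride).
    """

    names: list[str]
    elements: list[str]
    bonds: list[tuple[int, int]]
    ligand_labels: list[str]
    oxidation_state: str

    def __post_init__(self) -> None:
        if self.oxidation_state not in ("I", "III"):
            raise StructureError("oxidation_state must be 'I' or 'III'")
        n = len(self.elements)
        if not (len(self.names) == len(self.ligand_labels) == n):
            raise StructureError("inconsistent per-atom list lengths")
        self.bonds = [(min(i, j), max(i, j)) for i, j in self.bonds]
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def metal_index(self) -> int:
        idx = [i for i, e in enumerate(self.elements) if e == "Rh"]
        if len(idx) != 1:
            raise StructureError("expected exactly one Rh atom")
        return idx[0]

    def validate(self) -> None:
        m = self.metal_index()
        adj = self.adjacency()
        ring_c = [
            j for j in adj[m] if self.elements[j] == "C" and self.ligand_labels[j] == "cp*"
        ]
        nitro = [j for j in adj[m] if self.elements[j] == "N"]
        chloro = [j for j in adj[m] if self.elements[j] == "Cl"]
        if len(ring_c) != 5:
            raise StructureError(f"Rh must bind 5 Cp* ring carbons, found {len(ring_c)}")
        if len(nitro) != 2:
            raise StructureError(f"Rh must bind 2 diimine nitrogens, found {len(nitro)}")
        want_cl = 1 if self.oxidation_state == "III" else 0
        if len(chloro) != want_cl:
            raise StructureError(
                f"Rh(+{self.oxidation_state}) must bind {want_cl} chloride(s), found {len(chloro)}"
            )
        # connectivity
        seen = {m}
        queue = deque([m])
        while queue:
            cur = queue.popleft()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        if len(seen) != self.n_atoms:
            raise StructureError("bond graph is not connected")


@dataclass
class ChargeSet:
    charges: np.ndarray
    provenance: str = "fixture"

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)

    @property
    def total(self) -> float:
        return float(self.charges.sum())


# ---------------------------------------------------------------------------
# atom typing
# ---------------------------------------------------------------------------


def assign_atom_types(structure: ComplexStructure) -> list[str]:
    """Atom types of the sigma-bonded model (M1/Y1/Y6/Y8/YC + standard)."""
    adj = structure.adjacency()
    el = structure.elements
    lab = structure.ligand_labels
    m = structure.metal_index()
    types = [""] * structure.n_atoms
    coord_n = {j for j in adj[m] if el[j] == "N"}

    # the YC pair: bonded carbons each adjacent to a different coordinating N
    yc: set[int] = set()
    for i, j in structure.bonds:
        if el[i] == "C" and el[j] == "C":
            ni = coord_n & set(adj[i])
            nj = coord_n & set(adj[j])
            if ni and nj and ni != nj:
                yc |= {i, j}

    for i in range(structure.n_atoms):
        if i == m:
            types[i] = "M1"
        elif el[i] == "Cl":
            types[i] = "Y8" if m in adj[i] else "cl"
        elif el[i] == "N":
            types[i] = "Y6" if i in coord_n else "nb"
        elif el[i] == "C":
            if lab[i] == "cp*":
                types[i] = "Y1" if m in adj[i] else "c3"
            else:
                types[i] = "YC" if i in yc else "ca"
        elif el[i] == "H":
            parent = adj[i][0]
            if lab[parent] == "cp*" and m not in adj[parent]:
                types[i] = "hc"
            elif any(el[k] == "N" for k in adj[parent]):
                types[i] = "h4"
            else:
                types[i] = "ha"
        elif el[i] == "O":
            types[i] = "ow"
        else:
            raise StructureError(f"no typing rule for element {el[i]}")
    return types


# ---------------------------------------------------------------------------
# term enumeration and parameter resolution
# ---------------------------------------------------------------------------


def _alias(t: str) -> str:
    return TYPE_ALIASES.get(t, t)


def lookup_bond(table: FrcmodTable, a: str, b: str) -> tuple[float, float]:
    for sig in (canonical_bond(a, b), canonical_bond(_alias(a), _alias(b))):
        if sig in table.bond:
            return table.bond[sig]
    raise MissingParameterError(f"no bond parameters for type pair {a}-{b}")


def lookup_angle(table: FrcmodTable, a: str, b: str, c: str) -> tuple[float, float]:
    for sig in (canonical_angle(a, b, c), canonical_angle(_alias(a), _alias(b), _alias(c))):
        if sig in table.angle:
            return table.angle[sig]
    raise MissingParameterError(f"no angle parameters for type triple {a}-{b}-{c}")


def lookup_dihedral(
    table: FrcmodTable, a: str, b: str, c: str, d: str
) -> list[tuple[int, float, float, int]]:
    """Fourier terms for a proper torsion; exact signature first, then the
    alias-substituted signature, then the X-b-c-X wildcard."""
    if "M1" in (a, b, c, d):
        return [(1, 0.0, 0.0, 2)]
    candidates = [
        canonical_dihedral(a, b, c, d),
        canonical_dihedral(_alias(a), _alias(b), _alias(c), _alias(d)),
        canonical_dihedral("X", b, c, "X"),
        canonical_dihedral("X", _alias(b), _alias(c), "X"),
    ]
    for sig in candidates:
        if sig in table.dihe:
            return table.dihe[sig]
    raise MissingParameterError(f"no dihedral parameters for {a}-{b}-{c}-{d}")


def lookup_nonbonded(table: FrcmodTable, t: str) -> tuple[float, float]:
    for typ in (t, _alias(t)):
        if typ in table.nonbon:
            return table.nonbon[typ]
    raise MissingParameterError(f"no van der Waals parameters for atom type {t}")


def lookup_mass(table: FrcmodTable, t: str) -> float:
    for typ in (t, _alias(t)):
        if typ in table.mass:
            return table.mass[typ][0]
    raise MissingParameterError(f"no mass entry for atom type {t}")


def enumerate_pairs(
    bonds: list[tuple[int, int]], n_atoms: int
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """(exclusions, pairs14) from shortest bond-graph distances 1-3 vs 4."""
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    exclusions: set[tuple[int, int]] = set()
    pairs14: set[tuple[int, int]] = set()
    for src in range(n_atoms):
        dist = {src: 0}
        queue = deque([src])
        while queue:
            cur = queue.popleft()
            if dist[cur] >= 3:
                continue
            for nb in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + 1
                    queue.append(nb)
        for other, d in dist.items():
            if other <= src:
                continue
            if d <= 2:
                exclusions.add((src, other))
            elif d == 3:
                pairs14.add((src, other))
    return exclusions, pairs14


def build_topology(
    structure: ComplexStructure,
    parameter_set: FrcmodTable,
    charges: ChargeSet | None = None,
) -> Topology:
    """Enumerate and parametrize every bonded term of the complex.

    All angle and dihedral terms implied by the bond graph are present;
    every torsion containing the metal carries a zero barrier.  1-2/1-3
    pairs are excluded from the nonbonded sum and 1-4 pairs scaled.
    """
    types = assign_atom_types(structure)
    n = structure.n_atoms
    atoms = []
    for i in range(n):
        r, eps = lookup_nonbonded(parameter_set, types[i])
        atoms.append(
            AtomSpec(
                index=i,
                name=structure.names[i],
                element=structure.elements[i],
                atom_type=types[i],
                mass=lookup_mass(parameter_set, types[i]),
                charge=0.0,
                vdw_radius=r,
                vdw_well_depth=eps,
            )
        )

    adj = structure.adjacency()
    bonds = []
    for i, j in sorted(structure.bonds):
        k, r0 = lookup_bond(parameter_set, types[i], types[j])
        bonds.append(BondTerm(i, j, k, r0))

    angles = []
    for j in range(n):
        nbrs = sorted(adj[j])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                kth, th0 = lookup_angle(parameter_set, types[i], types[j], types[k])
                angles.append(AngleTerm(i, j, k, kth, th0))

    dihedrals = []
    for j, k in sorted(structure.bonds):
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                fourier = lookup_dihedral(parameter_set, types[i], types[j], types[k], types[l])
                for idivf, pk, phase, pn in fourier:
                    dihedrals.append(DihedralTerm(i, j, k, l, pk, pn, phase, idivf))

    exclusions, pairs14 = enumerate_pairs(structure.bonds, n)
    topo = Topology(
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        exclusions=exclusions,
        pairs14=pairs14,
        net_charge=1.0 if structure.oxidation_state == "III" else 0.0,
    )
    topo.ligand_labels = list(structure.ligand_labels)  # type: ignore[attr-defined]
    topo.symmetry_classes = symmetry_classes(structure)
    if charges is not None:
        topo.set_charges(charges.charges)
    return topo


# ---------------------------------------------------------------------------
# symmetry machinery
# ---------------------------------------------------------------------------


def symmetry_classes(structure: ComplexStructure) -> list[list[int]]:
    """Automorphism orbits of the typed bond graph.

    Computed by iterative neighborhood color refinement seeded with the
    atom type; for this family of complexes the stable coloring coincides
    with the orbit partition (five ring carbons in one class, both
    coordinating nitrogens paired, diimine atoms mirrored across the
    ligand's vertical axis, metal and halide singletons).
    """
    types = assign_atom_types(structure)
    adj = structure.adjacency()
    colors = list(types)
    for _ in range(structure.n_atoms):
        signatures = [
            (colors[i], tuple(sorted(colors[j] for j in adj[i])))
            for i in range(structure.n_atoms)
        ]
        palette = {sig: f"c{k}" for k, sig in enumerate(sorted(set(signatures)))}
        new_colors = [palette[sig] for sig in signatures]
        if len(set(new_colors)) == len(set(colors)):
            colors = new_colors
            break
        colors = new_colors
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(colors):
        groups.setdefault(c, []).append(i)
    return sorted(groups.values())


def symmetrize_charges(charges: ChargeSet, classes: list[list[int]]) -> ChargeSet:
    """Replace every charge by the mean over its symmetry class."""
    q = np.array(charges.charges, dtype=float)
    n = len(q)
    for members in classes:
        if any(m < 0 or m >= n for m in members):
            raise IndexError("symmetry class index out of range")
        q[members] = q[members].mean()
    return ChargeSet(q, provenance="symmetrized")


def _class_signature(class_of: np.ndarray, idx: tuple[int, ...]) -> tuple[int, ...]:
    sig = tuple(int(class_of[i]) for i in idx)
    return min(sig, sig[::-1])


def average_equivalent_terms(topology: Topology) -> Topology:
    """Average (k, equilibrium) over symmetry-equivalent bonded terms.

    Terms whose atom tuples map to the same symmetry-class signature are
    given their group-mean force constant and equilibrium value, so that
    e.g. all five M1-Y1 bonds stay interchangeable.  Idempotent.
    """
    if not topology.symmetry_classes:
        raise ValueError("symmetry classes must be assigned before averaging")
    out = topology.copy()
    class_of = out.class_of()

    groups: dict[tuple[int, ...], list[BondTerm]] = {}
    for b in out.bonds:
        groups.setdefault(_class_signature(class_of, (b.i, b.j)), []).append(b)
    for terms in groups.values():
        k = float(np.mean([t.force_constant for t in terms]))
        r0 = float(np.mean([t.equilibrium for t in terms]))
        for t in terms:
            t.force_constant, t.equilibrium = k, r0

    agroups: dict[tuple[int, ...], list[AngleTerm]] = {}
    for a in out.angles:
        agroups.setdefault(_class_signature(class_of, (a.i, a.j, a.k)), []).append(a)
    for terms in agroups.values():
        k = float(np.mean([t.force_constant for t in terms]))
        th0 = float(np.mean([t.equilibrium for t in terms]))
        for t in terms:
            t.force_constant, t.equilibrium = k, th0
    return out


def cp_star_ring_indices(topology: Topology) -> list[int]:
    return [a.index for a in topology.atoms if a.atom_type == "Y1"]


def cp_star_centroid(topology: Topology, coords: np.ndarray) -> np.ndarray:
    """Unweighted mean of the five ring-carbon positions."""
    return coords[cp_star_ring_indices(topology)].mean(axis=0)
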