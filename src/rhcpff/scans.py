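"""Rigid-fragment displacement scans with term-decomposed energy profiles.

A named ligand (Cp* ring + methyls, the whole diimine, or the halide) is
translated along, or rotated about, axes defined by the metal-anchor
frame while every other atom stays fixed; the force-field energy of each
geometry is then decomposed per term class and reported relative to the
zero-displacement point.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import CompiledSystem
from .terms import NonbondedSettings, Topology
from .topology import cp_star_centroid

#: scan kinds: distances displace along the metal-anchor axis (A);
#: rotations turn about an axis through the anchor (degrees)
SCAN_KINDS = (
    "ring-distance",
    "diimine-distance",
    "halide-distance",
    "ring-inplane",
    "ring-outofplane",
    "ring-around",
    "diimine-inplane",
    "diimine-outofplane",
    "diimine-around",
)

_LIGAND_OF_KIND = {k: k.split("-")[0] for k in SCAN_KINDS}
_LIGAND_LABEL = {"ring": "cp*", "diimine": "diimine", "halide": "halide"}


@dataclass
class ScanMode:
    kind: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in SCAN_KINDS:
            raise ValueError(f"unknown scan kind {self.kind!r}")
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.any(np.isclose(self.grid, 0.0)):
            raise ValueError("scan grid must include the 0 (equilibrium) point")


@dataclass
class ScanProfile:
    displacements: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.components["total"]


def _rotation_matrix(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _ligand_atoms(topology: Topology, ligand: str) -> np.ndarray:
    labels = getattr(topology, "ligand_labels", None)
    if labels is None:
        raise ValueError("topology carries no ligand annotation")
    sel = [i for i, lab in enumerate(labels) if lab == _LIGAND_LABEL[ligand]]
    if not sel:
        raise ValueError(f"no atoms for ligand {ligand!r} (mode inapplicable)")
    return np.array(sel)


def _frame(topology: Topology, coords: np.ndarray, ligand: str):
    """(anchor point, metal->anchor axis, in-plane axis, plane normal)."""
    labels = topology.ligand_labels  # type: ignore[attr-defined]
    m1 = next(i for i, a in enumerate(topology.atoms) if a.atom_type == "M1")
    cp_anchor = cp_star_centroid(topology, coords)
    y6 = [i for i, a in enumerate(topology.atoms) if a.atom_type == "Y6"]
    dii_anchor = coords[y6].mean(axis=0)
    if ligand == "ring":
        anchor = cp_anchor
        other = dii_anchor
    elif ligand == "diimine":
        anchor = dii_anchor
        other = cp_anchor
    else:  # halide
        y8 = [i for i, a in enumerate(topology.atoms) if a.atom_type == "Y8"]
        if not y8:
            raise ValueError("halide scan inapplicable: no coordinated chloride")
        anchor = coords[y8[0]]
        other = cp_anchor
    axis = anchor - coords[m1]
    axis = axis / np.linalg.norm(axis)
    ref = other - coords[m1]
    normal = np.cross(axis, ref)
    normal /= np.linalg.norm(normal)
    inplane = np.cross(normal, axis)
    return anchor, axis, inplane, normal


def generate_scan_geometries(
    coords: np.ndarray, topology: Topology, mode: ScanMode
) -> list[np.ndarray]:
    """One geometry per grid point; all non-ligand atoms stay fixed.

    Distances translate the rigid ligand along the metal-anchor axis;
    around-axis rotations turn it about that axis; in-plane rotations
    turn about the normal of the metal-anchor-ligand reference plane and
    out-of-plane rotations about the third, mutually perpendicular axis
    (all through the anchor).
    """
    ligand = _LIGAND_OF_KIND[mode.kind]
    sel = _ligand_atoms(topology, ligand)
    anchor, axis, inplane, normal = _frame(topology, coords, ligand)
    geoms = []
    for disp in mode.grid:
        g = np.array(coords, dtype=float)
        if mode.kind.endswith("distance"):
            g[sel] += disp * axis
        else:
            if mode.kind.endswith("around"):
                rot_axis = axis
            elif mode.kind.endswith("inplane"):
                rot_axis = normal
            else:
                rot_axis = inplane
            R = _rotation_matrix(rot_axis, disp)
            g[sel] = (g[sel] - anchor) @ R.T + anchor
        geoms.append(g)
    return geoms


def scan_profile(
    topology: Topology,
    geometries: list[np.ndarray],
    settings: NonbondedSettings | None = None,
    displacements: np.ndarray | None = None,
) -> ScanProfile:
    """Decomposed gas-phase energies, shifted to zero at displacement 0."""
    settings = settings or NonbondedSettings(cutoff=None)
    system = CompiledSystem(topology, settings)
    keys = ("bond", "angle", "dihedral", "vdw", "coulomb", "total")
    raw = {k: [] for k in keys}
    for g in geometries:
        e = system.energy(g)
        d = e.as_dict()
        for k in keys:
            raw[k].append(d[k])
    if displacements is None:
        displacements = np.arange(len(geometries), dtype=float)
    displacements = np.asarray(displacements, dtype=float)
    zero = int(np.argmin(np.abs(displacements)))
    comps = {k: np.array(v) - v[zero] for k, v in raw.items()}
    return ScanProfile(displacements=displacements, components=comps)


def run_scan(
    topology: Topology,
    coords: np.ndarray,
    kind: str,
    grid: np.ndarray,
    settings: NonbondedSettings | None = None,
) -> ScanProfile:
    mode = ScanMode(kind=kind, grid=grid)
    geoms = generate_scan_geometries(coords, topology, mode)
    return scan_profile(topology, geoms, settings, displacements=mode.grid)
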