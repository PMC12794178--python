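"""Structural-distribution and solvation-shell analysis.

Covers the one-dimensional radial distribution function around a chosen
center, the solute-aligned three-dimensional spatial distribution
function on a 0.2 A voxel lattice with bulk-referenced high-density
cutoffs, the ten N-metal-ring-carbon angle distributions that diagnose
free Cp* rotation, and the planarity dihedrals of the diimine and the
Cp* methyls.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import WATER_NUMBER_DENSITY
from .terms import Topology, dihedral_value
from .trajectory import Trajectory


@dataclass
class RDFResult:
    bin_centers: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    bin_width: float
    n_centers: int
    n_targets: int


@dataclass
class SDFGrid:
    origin: np.ndarray
    cell_edge: float
    mean_counts: np.ndarray  # (nx, ny, nz) mean atoms per cell per frame
    bulk_expectation: float
    cutoff_multiplier: float
    n_frames: int

    @property
    def high_density_mask(self) -> np.ndarray:
        return self.mean_counts >= self.cutoff_multiplier * self.bulk_expectation


@dataclass
class DistributionSet:
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    samples: dict[str, np.ndarray] = field(default_factory=dict)


def bulk_expectation_per_cell(
    cell_edge: float = 0.2, number_density: float = WATER_NUMBER_DENSITY
) -> float:
    """Expected molecules (or atoms) per voxel in uniform bulk."""
    return number_density * cell_edge**3


def _min_image_diff(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def rdf(
    trajectory: Trajectory,
    center_selection: np.ndarray,
    target_selection: np.ndarray,
    bin_width: float = 0.05,
    r_max: float = 10.0,
) -> RDFResult:
    """Radial distribution function g(r), bulk-density normalized.

    Uses minimum-image distances; requires a periodic box.  The bulk
    density is the mean target density over the box, so g -> 1 at large
    r for a uniform system.
    """
    if trajectory.boxes is None:
        raise ValueError("RDF requires a periodic box")
    center_selection = np.asarray(center_selection, dtype=int)
    target_selection = np.asarray(target_selection, dtype=int)
    if center_selection.size == 0 or target_selection.size == 0:
        raise ValueError("empty selection")
    if r_max > trajectory.boxes.min() / 2.0:
        raise ValueError("r_max exceeds half the shortest box edge")
    nbins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    counts = np.zeros(nbins)
    shared = np.intersect1d(center_selection, target_selection).size > 0
    n_pair_frames = 0.0
    for f in range(trajectory.n_frames):
        box = trajectory.boxes[f]
        pos_c = trajectory.frames[f, center_selection]
        pos_t = trajectory.frames[f, target_selection]
        d = pos_t[None, :, :] - pos_c[:, None, :]
        d = _min_image_diff(d, box)
        r = np.linalg.norm(d, axis=-1).ravel()
        if shared:
            r = r[r > 1e-9]
        counts += np.histogram(r, bins=edges)[0]
        vol = float(np.prod(box))
        rho = len(target_selection) / vol
        n_pair_frames += len(center_selection) * rho
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (shell * n_pair_frames)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(centers, g, counts, bin_width, len(center_selection), len(target_selection))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto
    reference (apply as x @ R.T + t)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8:
        raise ValueError("degenerate (collinear) alignment selection")
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = rc - mc @ R.T
    return R, t


def sdf(
    trajectory: Trajectory,
    alignment_selection: np.ndarray,
    species_selection: np.ndarray,
    cell_edge: float = 0.2,
    cutoff_multiplier: float = 5.0,
    bulk_density: float = WATER_NUMBER_DENSITY,
    extent: float | None = None,
) -> SDFGrid:
    """Spatial distribution function on a solute-aligned voxel grid.

    Every frame is least-squares superposed onto the first frame using
    the alignment selection before the species atoms are binned.  The
    bulk expectation per cell is bulk_density * cell_edge^3 and the
    high-density mask marks cells whose mean per-frame count reaches
    cutoff_multiplier times that expectation.
    """
    alignment_selection = np.asarray(alignment_selection, dtype=int)
    species_selection = np.asarray(species_selection, dtype=int)
    ref = trajectory.frames[0, alignment_selection]
    center = ref.mean(axis=0)
    if extent is None:
        extent = 12.0
    ncell = int(round(2.0 * extent / cell_edge))
    origin = center - extent
    grid = np.zeros((ncell, ncell, ncell))
    for f in range(trajectory.n_frames):
        R, t = kabsch(trajectory.frames[f, alignment_selection], ref)
        pos = trajectory.frames[f, species_selection] @ R.T + t
        ijk = np.floor((pos - origin) / cell_edge).astype(int)
        ok = np.all((ijk >= 0) & (ijk < ncell), axis=1)
        np.add.at(grid, tuple(ijk[ok].T), 1.0)
    grid /= trajectory.n_frames
    return SDFGrid(
        origin=origin,
        cell_edge=cell_edge,
        mean_counts=grid,
        bulk_expectation=bulk_expectation_per_cell(cell_edge, bulk_density),
        cutoff_multiplier=cutoff_multiplier,
        n_frames=trajectory.n_frames,
    )


def _histogram(samples: np.ndarray, lo: float, hi: float, width: float):
    nbins = int(round((hi - lo) / width))
    counts, edges = np.histogram(samples, bins=nbins, range=(lo, hi))
    freq = counts / (len(samples) * width) if len(samples) else counts.astype(float)
    return 0.5 * (edges[1:] + edges[:-1]), freq


def angle_distribution_set(
    trajectory: Trajectory, topology: Topology, bin_width: float = 1.0
) -> DistributionSet:
    """The ten N-metal-ring-carbon angle distributions.

    With two coordinating nitrogens and five equivalent ring carbons the
    complex has ten such angles; freely rotating Cp* makes their
    long-time distributions indistinguishable.
    """
    types = [a.atom_type for a in topology.atoms]
    m1 = types.index("M1")
    y6 = [i for i, t in enumerate(types) if t == "Y6"]
    y1 = [i for i, t in enumerate(types) if t == "Y1"]
    out = DistributionSet()
    frames = trajectory.frames
    for n_i in y6:
        for c_i in y1:
            u = frames[:, n_i] - frames[:, m1]
            v = frames[:, c_i] - frames[:, m1]
            c = np.einsum("fa,fa->f", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
            name = f"Y6[{n_i}]-M1-Y1[{c_i}]"
            out.samples[name] = ang
            out.histograms[name] = _histogram(ang, 0.0, 180.0, bin_width)
    return out


def _quad_instances(topology: Topology, tokens: tuple[str, ...]) -> list[tuple[int, ...]]:
    types = [a.atom_type for a in topology.atoms]
    seen = set()
    out = []
    for d in topology.dihedrals:
        sig = (types[d.i], types[d.j], types[d.k], types[d.l])
        if sig == tokens or sig[::-1] == tokens:
            key = (d.i, d.j, d.k, d.l)
            if key not in seen and key[::-1] not in seen:
                seen.add(key)
                out.append(key)
    return out


def ring_plane_dihedrals(
    trajectory: Trajectory, topology: Topology, bin_width: float = 1.0
) -> DistributionSet:
    """Planarity dihedrals: the diimine inter-ring ca-YC-YC-ca torsion
    (0 degrees = coplanar pyridine rings, signed, reported on
    [-180, 180]) and the Cp* methyl out-of-plane Y1-Y1-Y1-c3 torsion
    (folded to [0, 180]; 180 = methyl in the ring plane).
    """
    out = DistributionSet()
    frames = trajectory.frames
    inter = _quad_instances(topology, ("ca", "YC", "YC", "ca"))
    vals = []
    for i, j, k, l in inter:
        phi = np.array([dihedral_value(f, i, j, k, l) for f in frames])
        # center on 0: wrap to [-180, 180) is already atan2's range
        vals.append(phi)
    if vals:
        x = np.concatenate(vals)
        out.samples["diimine-inter-ring"] = x
        out.histograms["diimine-inter-ring"] = _histogram(x, -180.0, 180.0, bin_width)
    methyl = _quad_instances(topology, ("Y1", "Y1", "Y1", "c3"))
    vals = []
    for i, j, k, l in methyl:
        phi = np.array([abs(dihedral_value(f, i, j, k, l)) for f in frames])
        vals.append(phi)
    if vals:
        x = np.concatenate(vals)
        out.samples["cp*-methyl-plane"] = x
        out.histograms["cp*-methyl-plane"] = _histogram(x, 0.0, 180.0, bin_width)
    return out
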