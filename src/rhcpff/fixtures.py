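"""Self-contained input generators: idealized complex geometries, fixture
charge sets, bundled parameter tables, water boxes and synthetic
calibration cases.

The ideal geometries are assembled from internal coordinates so that the
metal-proximal descriptors (M1-Cp*, M1-Y1, M1-Y6, Y6-M1-Y6, Y6-M1-Cp*,
and for Rh(III) M1-Y8 / Y8-M1-Cp*) reproduce the reference means exactly;
aromatic rings are planar by construction and remaining internal
coordinates use standard aromatic values.
"""
from __future__ import annotations

import math
from importlib import resources

import numpy as np

from .io import FrcmodTable, read_frcmod
from .topology import (
    ChargeSet,
    ComplexStructure,
    assign_atom_types,
    build_topology,
    symmetrize_charges,
    symmetry_classes,
)

#: reference structural means (distances in A, angles/dihedrals in degrees)
#: for the three alpha-diimine ligands in both oxidation states
REFERENCE_GEOMETRY = {
    ("bpy", "I"): {
        "M1-Cp*": 1.894, "M1-Y1": 2.251, "M1-Y6": 2.015, "Y1-Y1": 1.433,
        "Y6-YC": 1.385, "YC-YC": 1.444, "Y6-M1-Cp*": 140.5, "Y6-M1-Y6": 77.8,
        "M1-Y6-YC": 117.75, "Y1-Y1-Y1-c3": 174.3,
    },
    ("bpy", "III"): {
        "M1-Cp*": 1.820, "M1-Y1": 2.195, "M1-Y6": 2.106, "Y1-Y1": 1.443,
        "Y6-YC": 1.353, "YC-YC": 1.482, "M1-Y8": 2.409, "Y6-M1-Cp*": 130.4,
        "Y6-M1-Y6": 76.7, "M1-Y6-YC": 115.4, "Y8-M1-Cp*": 127.0,
        "Y8-M1-Y6": 87.7, "Y1-Y1-Y1-c3": 176.7,
    },
    ("phen", "I"): {
        "M1-Cp*": 1.888, "M1-Y1": 2.247, "M1-Y6": 2.027, "Y1-Y1": 1.433,
        "Y6-YC": 1.373, "YC-YC": 1.420, "Y6-M1-Cp*": 140.8, "Y6-M1-Y6": 77.4,
        "M1-Y6-YC": 117.2, "Y1-Y1-Y1-c3": 175.0,
    },
    ("phen", "III"): {
        "M1-Cp*": 1.819, "M1-Y1": 2.195, "M1-Y6": 2.128, "Y1-Y1": 1.444,
        "Y6-YC": 1.344, "YC-YC": 1.459, "M1-Y8": 2.405, "Y6-M1-Cp*": 130.6,
        "Y6-M1-Y6": 76.6, "M1-Y6-YC": 114.9, "Y8-M1-Cp*": 127.3,
        "Y8-M1-Y6": 87.1, "Y1-Y1-Y1-c3": 177.0,
    },
    ("dppz", "I"): {
        "M1-Cp*": 1.892, "M1-Y1": 2.250, "M1-Y6": 2.028, "Y1-Y1": 1.433,
        "Y6-YC": 1.376, "YC-YC": 1.421, "Y6-M1-Cp*": 140.8, "Y6-M1-Y6": 77.3,
        "M1-Y6-YC": 117.3, "Y1-Y1-Y1-c3": 174.9,
    },
    ("dppz", "III"): {
        "M1-Cp*": 1.819, "M1-Y1": 2.194, "M1-Y6": 2.120, "Y1-Y1": 1.444,
        "Y6-YC": 1.346, "YC-YC": 1.458, "M1-Y8": 2.409, "Y6-M1-Cp*": 130.4,
        "Y6-M1-Y6": 76.5, "M1-Y6-YC": 115.1, "Y8-M1-Cp*": 127.1,
        "Y8-M1-Y6": 87.5, "Y1-Y1-Y1-c3": 176.9,
    },
}

_LIGANDS = ("bpy", "phen", "dppz")


# ---------------------------------------------------------------------------
# parameter fixtures
# ---------------------------------------------------------------------------


def _read_data(name: str) -> str:
    return resources.files("rhcpff.data").joinpath(name).read_text()


def load_frcmod_fixture(name: str) -> FrcmodTable:
    """Load one of the bundled tables: 'rh1', 'rh3' or 'standard_subset'."""
    return read_frcmod(_read_data(f"{name}.frcmod"))


def load_parameters(state: str) -> FrcmodTable:
    """Standard subset merged with the custom Rh(state) overrides."""
    custom = load_frcmod_fixture("rh1" if state == "I" else "rh3")
    return load_frcmod_fixture("standard_subset").merged_with(custom)


# ---------------------------------------------------------------------------
# geometry helpers (2D in-plane construction of the diimine)
# ---------------------------------------------------------------------------


def _rot2(p: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * p[0] - s * p[1], s * p[0] + c * p[1]])


def _extend_ring(p_a: np.ndarray, p_b: np.ndarray) -> list[np.ndarray]:
    """Complete a planar six-ring from one mirror-symmetric bonded edge.

    p_a (y<0) and p_b (y>0) are bonded and mirrored across y=0; returns
    the four missing vertices ordered from the p_a side, lying on the
    circle through p_a/p_b on the +x side.
    """
    s = float(np.linalg.norm(p_a - p_b))
    yb = abs(p_a[1])
    xc = p_a[0] + math.sqrt(max(s * s - yb * yb, 1e-12))
    center = np.array([xc, 0.0])
    theta_a = math.atan2(p_a[1] - 0.0, p_a[0] - xc)
    out = []
    for k in range(1, 5):
        th = theta_a + math.radians(60.0 * k)
        out.append(center + s * np.array([math.cos(th), math.sin(th)]))
    return out


class _Builder:
    def __init__(self) -> None:
        self.names: list[str] = []
        self.elements: list[str] = []
        self.labels: list[str] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int]] = []
        self._counter: dict[str, int] = {}

    def add(self, element: str, label: str, xyz: np.ndarray) -> int:
        self._counter[element] = self._counter.get(element, 0) + 1
        name = "RH" if element == "Rh" else f"{element.upper()}{self._counter[element]}"
        if element == "Cl":
            name = "CL"
        self.names.append(name)
        self.elements.append(element)
        self.labels.append(label)
        self.coords.append(np.asarray(xyz, dtype=float))
        return len(self.names) - 1

    def bond(self, i: int, j: int) -> None:
        self.bonds.append((min(i, j), max(i, j)))


def build_ideal_complex(
    ligand: str = "bpy", state: str = "I"
) -> tuple[ComplexStructure, np.ndarray]:
    """Idealized [(diimine)Rh(Cp*)(Cl)] geometry and connectivity.

    The metal sits at the origin with the Cp* centroid on +z; the diimine
    points toward -x and, for Rh(III), the chloride toward +x.
    """
    if ligand not in _LIGANDS:
        raise ValueError(f"unknown ligand {ligand!r}")
    ref = REFERENCE_GEOMETRY[(ligand, state)]
    b = _Builder()
    rh = b.add("Rh", "metal", np.zeros(3))

    # --- Cp* ---
    d_cp = ref["M1-Cp*"]
    r_ring = math.sqrt(ref["M1-Y1"] ** 2 - d_cp**2)
    ring_idx, methyl_idx = [], []
    for k in range(5):
        # vertex at azimuth 0 keeps the complex mirror-symmetric about the
        # metal/Cp*-axis/diimine plane
        phi = math.radians(72.0 * k)
        pos = np.array([r_ring * math.cos(phi), r_ring * math.sin(phi), d_cp])
        ring_idx.append(b.add("C", "cp*", pos))
    for k in range(5):
        # vertex at azimuth 0 keeps the complex mirror-symmetric about the
        # metal/Cp*-axis/diimine plane
        phi = math.radians(72.0 * k)
        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        pos = b.coords[ring_idx[k]] + 1.51 * radial
        methyl_idx.append(b.add("C", "cp*", pos))
    for k in range(5):
        # vertex at azimuth 0 keeps the complex mirror-symmetric about the
        # metal/Cp*-axis/diimine plane
        phi = math.radians(72.0 * k)
        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        tangent = np.array([-math.sin(phi), math.cos(phi), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        c3 = b.coords[methyl_idx[k]]
        for az in (0.0, 120.0, 240.0):
            ar = math.radians(az)
            direction = math.cos(math.radians(70.53)) * radial + math.sin(
                math.radians(70.53)
            ) * (math.cos(ar) * zhat + math.sin(ar) * tangent)
            h = b.add("H", "cp*", c3 + 1.092 * direction)
            b.bond(methyl_idx[k], h)
    for k in range(5):
        b.bond(rh, ring_idx[k])
        b.bond(ring_idx[k], ring_idx[(k + 1) % 5])
        b.bond(ring_idx[k], methyl_idx[k])

    # --- diimine nitrogen placement ---
    th_n = math.radians(ref["Y6-M1-Cp*"])
    bite = math.radians(ref["Y6-M1-Y6"])
    cos2dphi = (math.cos(bite) - math.cos(th_n) ** 2) / math.sin(th_n) ** 2
    cos2dphi = max(-1.0, min(1.0, cos2dphi))
    dphi = 0.5 * math.acos(cos2dphi)
    d_n = ref["M1-Y6"]
    n_pos = []
    for sgn in (-1.0, +1.0):
        phi = math.pi + sgn * dphi
        n_pos.append(
            d_n
            * np.array(
                [math.sin(th_n) * math.cos(phi), math.sin(th_n) * math.sin(phi), math.cos(th_n)]
            )
        )

    # in-plane frame of the diimine (plane through the metal and both N)
    e2 = n_pos[1] - n_pos[0]
    e2 /= np.linalg.norm(e2)
    mid = 0.5 * (n_pos[0] + n_pos[1])
    e1 = mid - np.dot(mid, e2) * e2
    e1 /= np.linalg.norm(e1)

    def to3d(p2: np.ndarray) -> np.ndarray:
        return p2[0] * e1 + p2[1] * e2

    n1_2d = np.array([np.dot(n_pos[0], e1), np.dot(n_pos[0], e2)])

    # --- one pyridine ring in 2D (negative-y half), mirrored for the other ---
    r_nyc = ref["Y6-YC"]
    ang_mnc = ref["M1-Y6-YC"]
    u = -n1_2d / np.linalg.norm(n1_2d)  # direction N1 -> metal
    cands = [n1_2d + r_nyc * _rot2(u, s * ang_mnc) for s in (+1.0, -1.0)]
    c2_2d = min(cands, key=lambda p: abs(p[1]))
    ring2d = [n1_2d, c2_2d]
    lengths = [1.40, 1.39, 1.39, 1.39]
    d = (c2_2d - n1_2d) / np.linalg.norm(c2_2d - n1_2d)
    turn = None
    for L in lengths:
        if turn is None:
            c_plus = ring2d[-1] + L * _rot2(d, 60.0)
            c_minus = ring2d[-1] + L * _rot2(d, -60.0)
            turn = 60.0 if np.linalg.norm(c_plus) > np.linalg.norm(c_minus) else -60.0
        nxt = ring2d[-1] + L * _rot2(d, turn)
        d = (nxt - ring2d[-1]) / np.linalg.norm(nxt - ring2d[-1])
        ring2d.append(nxt)
    # ring2d: N1, C2, C3, C4, C5, C6
    centroid2d = np.mean(ring2d, axis=0)

    def outward(p2: np.ndarray, g: np.ndarray, dist: float) -> np.ndarray:
        v = p2 - g
        return p2 + dist * v / np.linalg.norm(v)

    n_idx, yc_idx, c3pos_idx = [], [], []
    for half in (0, 1):
        mirror = 1.0 if half == 0 else -1.0

        def place(p2: np.ndarray) -> np.ndarray:
            return to3d(np.array([p2[0], mirror * p2[1]]))

        ni = b.add("N", "diimine", place(ring2d[0]))
        c2i = b.add("C", "diimine", place(ring2d[1]))
        c3i = b.add("C", "diimine", place(ring2d[2]))
        c4i = b.add("C", "diimine", place(ring2d[3]))
        c5i = b.add("C", "diimine", place(ring2d[4]))
        c6i = b.add("C", "diimine", place(ring2d[5]))
        for i, j in ((ni, c2i), (c2i, c3i), (c3i, c4i), (c4i, c5i), (c5i, c6i), (c6i, ni)):
            b.bond(i, j)
        for ci in ((c4i, ring2d[3]), (c5i, ring2d[4]), (c6i, ring2d[5])):
            h = b.add("H", "diimine", place(outward(ci[1], centroid2d, 1.087)))
            b.bond(ci[0], h)
        if ligand == "bpy":
            h = b.add("H", "diimine", place(outward(ring2d[2], centroid2d, 1.087)))
            b.bond(c3i, h)
        b.bond(rh, ni)
        n_idx.append(ni)
        yc_idx.append(c2i)
        c3pos_idx.append(c3i)
    b.bond(yc_idx[0], yc_idx[1])

    if ligand in ("phen", "dppz"):
        # bridge carbons closing the central ring on the C3/C3' positions
        c3_2d = ring2d[2]
        yb = 0.68
        dy = -yb - (-abs(c3_2d[1]))
        xb = c3_2d[0] + math.sqrt(max(1.40**2 - dy * dy, 1e-12))
        cb_2d = np.array([xb, -yb])
        cb1 = b.add("C", "diimine", to3d(cb_2d))
        cb2 = b.add("C", "diimine", to3d(cb_2d * np.array([1.0, -1.0])))
        b.bond(c3pos_idx[0], cb1)
        b.bond(cb1, cb2)
        b.bond(cb2, c3pos_idx[1])
        mid_centroid = np.mean(
            [ring2d[1], c3_2d, cb_2d, cb_2d * np.array([1, -1]),
             c3_2d * np.array([1, -1]), ring2d[1] * np.array([1, -1])],
            axis=0,
        )
        if ligand == "phen":
            for ci, p2 in ((cb1, cb_2d), (cb2, cb_2d * np.array([1, -1]))):
                h = b.add("H", "diimine", to3d(outward(p2, mid_centroid, 1.087)))
                b.bond(ci, h)
        else:
            # pyrazine ring fused on the bridge edge, then the outer benzo ring
            pz = _extend_ring(cb_2d, cb_2d * np.array([1, -1]))
            n1p = b.add("N", "diimine", to3d(pz[0]))
            cj1 = b.add("C", "diimine", to3d(pz[1]))
            cj2 = b.add("C", "diimine", to3d(pz[2]))
            n2p = b.add("N", "diimine", to3d(pz[3]))
            for i, j in ((cb1, n1p), (n1p, cj1), (cj1, cj2), (cj2, n2p), (n2p, cb2)):
                b.bond(i, j)
            bz = _extend_ring(pz[1], pz[2])
            bz_center = np.mean([pz[1], pz[2]] + bz, axis=0)
            prev = cj1
            for p2 in bz:
                ci = b.add("C", "diimine", to3d(p2))
                h = b.add("H", "diimine", to3d(outward(p2, bz_center, 1.087)))
                b.bond(ci, h)
                b.bond(prev, ci)
                prev = ci
            b.bond(prev, cj2)

    if state == "III":
        th_cl = math.radians(ref["Y8-M1-Cp*"])
        pos = ref["M1-Y8"] * np.array([math.sin(th_cl), 0.0, math.cos(th_cl)])
        cl = b.add("Cl", "halide", pos)
        b.bond(rh, cl)

    structure = ComplexStructure(
        names=b.names,
        elements=b.elements,
        bonds=b.bonds,
        ligand_labels=b.labels,
        oxidation_state=state,
    )
    return structure, np.array(b.coords)


# ---------------------------------------------------------------------------
# fixture charges
# ---------------------------------------------------------------------------

#: aggregate targets (e): metal and halide values as reported; ligand totals
#: chosen so the net charge is exactly 0 (Rh I) or +1 (Rh III)
_CHARGE_AGGREGATES = {
    "I": {"metal": -0.7, "halide": 0.0, "cp*": 0.35, "diimine": 0.35},
    "III": {"metal": -0.3, "halide": -0.4, "cp*": 0.84, "diimine": 0.86},
}


def fixture_charges(ligand: str = "bpy", state: str = "I") -> ChargeSet:
    """Per-atom fixture charges honoring the reported aggregates.

    The metal carries -0.7 e (Rh I) or -0.3 e (Rh III), the chloride
    -0.4 e, methyl hydrogens +0.08/+0.10 e, and the ligand totals close
    the net charge exactly (0 or +1). Per-atom values within the diimine
    are a documented fixture choice, symmetrized over the automorphism
    classes.
    """
    structure, _ = build_ideal_complex(ligand, state)
    types = assign_atom_types(structure)
    agg = _CHARGE_AGGREGATES[state]
    hc = 0.08 if state == "I" else 0.10
    c3 = -0.12 if state == "I" else -0.14
    y1 = (agg["cp*"] - 15 * hc - 5 * c3) / 5.0
    base = {
        "M1": agg["metal"], "Y8": agg["halide"], "hc": hc, "c3": c3, "Y1": y1,
        "Y6": -0.40, "YC": 0.25, "h4": 0.085, "ha": 0.145, "nb": -0.50, "ca": -0.10,
    }
    q = np.array([base[t] for t in types], dtype=float)
    # close the diimine total exactly, spread uniformly over the ligand
    dii = [i for i, lab in enumerate(structure.ligand_labels) if lab == "diimine"]
    residual = agg["diimine"] - q[dii].sum()
    q[dii] += residual / len(dii)
    charges = symmetrize_charges(ChargeSet(q, provenance="fixture"), symmetry_classes(structure))
    charges.provenance = "fixture"
    return charges


def prepared_complex(ligand: str = "bpy", state: str = "I"):
    """(structure, coords, topology) with bundled parameters and charges."""
    structure, coords = build_ideal_complex(ligand, state)
    topo = build_topology(structure, load_parameters(state), fixture_charges(ligand, state))
    return structure, coords, topo


# ---------------------------------------------------------------------------
# water boxes
# ---------------------------------------------------------------------------

#: rigid 3-site water geometry and charges (TIP3P-class)
WATER_OH = 0.9572
WATER_ANGLE = 104.52
WATER_Q_O = -0.834
WATER_Q_H = 0.417


def water_geometry() -> np.ndarray:
    """One water molecule (O, H, H) with O at the origin, in-plane."""
    a = math.radians(WATER_ANGLE / 2.0)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [WATER_OH * math.sin(a), WATER_OH * math.cos(a), 0.0],
            [-WATER_OH * math.sin(a), WATER_OH * math.cos(a), 0.0],
        ]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    qv = rng.standard_normal(4)
    qv /= np.linalg.norm(qv)
    w, x, y, z = qv
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def water_box(
    edge: float, density: float = 0.0334, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Cubic box of rigid waters at the target number density.

    Oxygens are placed on a jittered lattice (minimum O-O separation
    2.4 A) with random molecular orientations; reproducible under seed.
    Returns (coordinates in molecule-major (O,H,H) order, molecule count).
    """
    n = int(round(density * edge**3))
    if n < 1:
        raise ValueError("box too small for a single water at this density")
    m = math.ceil(n ** (1.0 / 3.0))
    spacing = edge / m
    jitter = min(0.2, max(0.0, (spacing - 2.4) / 2.0 - 1e-3))
    if spacing < 2.4:
        raise ValueError(
            f"target density {density} unreachable: lattice spacing {spacing:.2f} A < 2.4 A"
        )
    rng = np.random.default_rng(seed)
    cells = [(i, j, k) for i in range(m) for j in range(m) for k in range(m)]
    chosen = rng.choice(len(cells), size=n, replace=False)
    mono = water_geometry()
    out = np.empty((3 * n, 3))
    for w, cell_id in enumerate(chosen):
        i, j, k = cells[cell_id]
        origin = (np.array([i, j, k]) + 0.5) * spacing
        origin += rng.uniform(-jitter, jitter, size=3)
        rot = _random_rotation(rng)
        out[3 * w : 3 * w + 3] = origin + mono @ rot.T
    return out, n


# ---------------------------------------------------------------------------
# synthetic calibration cases
# ---------------------------------------------------------------------------


def synthetic_calibration_case(seed: int = 0, sim_ps: float = 150.0):
    """Known-truth round-trip harness for the calibration loop.

    Simulates the Rh(I)-bpy ground-truth topology to produce target means,
    then perturbs the adjustable equilibrium parameters by up to +/-0.05 A
    and +/-5 degrees. Returns (truth_topology, targets, perturbed_topology,
    coords, ground_truth_parameters).
    """
    from .calibrate import DEFAULT_ADJUSTABLE_RH1, GeometryTarget, measure_structural_means
    from .sampler import SamplerConfig, minimize, run_langevin
    from .trajectory import Trajectory

    structure, coords, topo = prepared_complex("bpy", "I")
    coords, _ = minimize(topo, coords, n_steepest=300, n_conjugate=300)
    config = SamplerConfig(
        steps=int(sim_ps * 500), seed=seed % 2**31, snapshot_interval=100
    )
    traj = run_langevin(topo, coords, config)
    skip = traj.n_frames // 5
    prod = Trajectory(traj.frames[skip:], None, traj.frame_spacing)
    descriptors = list(DEFAULT_ADJUSTABLE_RH1)
    table = measure_structural_means(prod, descriptors, topo)
    targets = []
    for _, row in table.iterrows():
        is_bond = row["descriptor"].count("-") == 1
        targets.append(
            GeometryTarget(row["descriptor"], row["mean"], 0.01 if is_bond else 1.0)
        )
    rng = np.random.default_rng(seed + 1)
    perturbed = topo.copy()
    truth_params = {}
    for desc in descriptors:
        sig = tuple(desc.split("-"))
        if len(sig) == 2:
            delta = rng.uniform(-0.05, 0.05)
        else:
            delta = rng.uniform(-5.0, 5.0)
        terms = perturbed.bonds if len(sig) == 2 else perturbed.angles
        for t in terms:
            tsig = _term_type_signature(perturbed, t)
            if tsig == sig or tsig == sig[::-1]:
                truth_params[desc] = t.equilibrium
                t.equilibrium += delta
    return topo, targets, perturbed, coords, truth_params


def _term_type_signature(topo, term):
    types = [a.atom_type for a in topo.atoms]
    if hasattr(term, "l"):
        return (types[term.i], types[term.j], types[term.k], types[term.l])
    if hasattr(term, "k") and isinstance(term.k, int):
        return (types[term.i], types[term.j], types[term.k])
    return (types[term.i], types[term.j])
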