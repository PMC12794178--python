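"""Readers and writers: Amber frcmod parameter files, PDB structures, and
a plain-text multi-frame XYZ trajectory with optional orthorhombic box.

The frcmod dialect covers the MASS, BOND, ANGLE, DIHE and NONBON sections
with explicit IDIVF on torsion lines; sections this toolkit does not
interpret (e.g. IMPROPER) are preserved verbatim so that files written by
other tools survive a round trip.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

log = logging.getLogger(__name__)

_KNOWN_SECTIONS = ("MASS", "BOND", "ANGLE", "DIHE", "NONBON")

# widths of the fixed atom-type field for each bonded section
_TYPE_WIDTH = {"BOND": 5, "ANGLE": 8, "DIHE": 11}


class FrcmodParseError(ValueError):
    pass


def canonical_bond(a: str, b: str) -> tuple[str, str]:
    return (a, b) if (a,) <= (b,) else (b, a)


def canonical_angle(a: str, b: str, c: str) -> tuple[str, str, str]:
    return (a, b, c) if (a,) <= (c,) else (c, b, a)


def canonical_dihedral(a: str, b: str, c: str, d: str) -> tuple[str, str, str, str]:
    fwd = (a, b, c, d)
    rev = (d, c, b, a)
    return fwd if fwd <= rev else rev


@dataclass
class FrcmodTable:
    """In-memory frcmod content.

    mass: type -> (mass_amu, polarizability)
    bond: canonical pair -> (k_b, r0)
    angle: canonical triple -> (k_theta, theta0_deg)
    dihe: canonical quad -> list of (idivf, barrier, phase_deg, multiplicity)
    nonbon: type -> (vdw_radius, well_depth)
    extra_sections: section header -> raw lines, passed through untouched
    """

    title: str = "frcmod written by rhcpff"
    mass: dict[str, tuple[float, float]] = field(default_factory=dict)
    bond: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    angle: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    dihe: dict[tuple[str, str, str, str], list[tuple[int, float, float, int]]] = field(
        default_factory=dict
    )
    nonbon: dict[str, tuple[float, float]] = field(default_factory=dict)
    extra_sections: dict[str, list[str]] = field(default_factory=dict)

    def merged_with(self, other: "FrcmodTable") -> "FrcmodTable":
        """New table where entries of `other` override entries of self."""
        out = FrcmodTable(title=self.title)
        out.mass = {**self.mass, **other.mass}
        out.bond = {**self.bond, **other.bond}
        out.angle = {**self.angle, **other.angle}
        out.dihe = {**self.dihe, **other.dihe}
        out.nonbon = {**self.nonbon, **other.nonbon}
        out.extra_sections = {**self.extra_sections, **other.extra_sections}
        return out


def _split_types(token: str, lineno: int) -> list[str]:
    parts = [p.strip() for p in token.split("-")]
    if any(not p for p in parts):
        raise FrcmodParseError(f"line {lineno}: malformed atom-type field {token!r}")
    return parts


def _floats(fields: list[str], n: int, lineno: int) -> list[float]:
    if len(fields) < n:
        raise FrcmodParseError(f"line {lineno}: expected {n} numeric fields")
    try:
        return [float(f) for f in fields[:n]]
    except ValueError as exc:
        raise FrcmodParseError(f"line {lineno}: malformed numeric field ({exc})") from exc


def read_frcmod(text: str) -> FrcmodTable:
    table = FrcmodTable()
    section = None
    first = True
    pending_dihe: tuple[str, str, str, str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        stripped = line.strip()
        if first and stripped and stripped.split()[0] not in _KNOWN_SECTIONS:
            table.title = stripped
            first = False
            continue
        first = False
        if not stripped:
            continue
        head = stripped.split()[0].upper()
        if head in _KNOWN_SECTIONS or (head.isupper() and head.isalpha() and len(stripped.split()) == 1 and stripped == head):
            if head in _KNOWN_SECTIONS:
                section = head
            else:
                section = head
                table.extra_sections.setdefault(section, [])
            pending_dihe = None
            continue
        if section is None:
            continue
        if section not in _KNOWN_SECTIONS:
            table.extra_sections[section].append(line)
            continue
        if stripped.startswith("#"):
            continue
        if section == "MASS":
            fields = stripped.split()
            typ = fields[0]
            vals = _floats(fields[1:], 1, lineno)
            pol = 0.0
            if len(fields) >= 3:
                try:
                    pol = float(fields[2])
                except ValueError:
                    pol = 0.0
            table.mass[typ] = (vals[0], pol)
        elif section == "NONBON":
            fields = stripped.split()
            typ = fields[0]
            r, eps = _floats(fields[1:], 2, lineno)
            table.nonbon[typ] = (r, eps)
        elif section == "BOND":
            w = _TYPE_WIDTH["BOND"]
            types = _split_types(line[:w], lineno)
            if len(types) != 2:
                raise FrcmodParseError(f"line {lineno}: bond needs two atom types")
            k, r0 = _floats(line[w:].split(), 2, lineno)
            table.bond[canonical_bond(*types)] = (k, r0)
        elif section == "ANGLE":
            w = _TYPE_WIDTH["ANGLE"]
            types = _split_types(line[:w], lineno)
            if len(types) != 3:
                raise FrcmodParseError(f"line {lineno}: angle needs three atom types")
            k, th0 = _floats(line[w:].split(), 2, lineno)
            table.angle[canonical_angle(*types)] = (k, th0)
        elif section == "DIHE":
            w = _TYPE_WIDTH["DIHE"]
            types = _split_types(line[:w], lineno)
            if len(types) != 4:
                raise FrcmodParseError(f"line {lineno}: dihedral needs four atom types")
            idivf, pk, phase, pn = _floats(line[w:].split(), 4, lineno)
            sig = canonical_dihedral(*types)
            if pending_dihe != sig:
                table.dihe[sig] = []
            table.dihe[sig].append((int(round(idivf)), pk, phase, abs(int(round(pn)))))
            # negative multiplicity marks a continuation line in Amber files
            pending_dihe = sig if pn < 0 else None
    return table


def _fmt_types(types: tuple[str, ...], width: int) -> str:
    return "-".join(f"{t:<2s}" for t in types).ljust(width)


def write_frcmod(table: FrcmodTable) -> str:
    out = [table.title, "MASS"]
    for typ, (m, pol) in table.mass.items():
        out.append(f"{typ:<2s}  {m:10.4f}  {pol:8.4f}")
    out += ["", "BOND"]
    for sig, (k, r0) in table.bond.items():
        out.append(f"{_fmt_types(sig, 5)}  {k:10.4f}  {r0:10.4f}")
    out += ["", "ANGLE"]
    for sig, (k, th0) in table.angle.items():
        out.append(f"{_fmt_types(sig, 8)}  {k:10.4f}  {th0:10.4f}")
    out += ["", "DIHE"]
    for sig, terms in table.dihe.items():
        for t, (idivf, pk, phase, pn) in enumerate(terms):
            pn_out = -pn if t < len(terms) - 1 else pn
            out.append(
                f"{_fmt_types(sig, 11)}  {idivf:3d}  {pk:10.4f}  {phase:10.4f}  {pn_out:4d}"
            )
    out += ["", "NONBON"]
    for typ, (r, eps) in table.nonbon.items():
        out.append(f"  {typ:<2s}  {r:10.4f}  {eps:10.4f}")
    for header, lines in table.extra_sections.items():
        out += ["", header] + lines
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {"CL", "RH", "BR", "NA", "MG", "ZN", "FE"}


def infer_element(name: str) -> str:
    """Guess the element from an atom name when the element column is blank."""
    alpha = "".join(ch for ch in name if ch.isalpha()).upper()
    if alpha[:2] in _TWO_LETTER_ELEMENTS:
        return alpha[:2].capitalize()
    return alpha[:1]


def write_pdb(
    names: list[str],
    elements: list[str],
    coords: np.ndarray,
    bonds: list[tuple[int, int]] | None = None,
    resnames: list[str] | None = None,
    resids: list[int] | None = None,
) -> str:
    coords = np.asarray(coords, dtype=float)
    n = len(names)
    resnames = resnames or ["RHC"] * n
    resids = resids or [1] * n
    lines = []
    for i in range(n):
        el = elements[i]
        name = names[i]
        # PDB v3.3: element right-justified in 77-78, name in 13-16
        name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"HETATM{i + 1:5d} {name_f:<4s}{resnames[i]:>4s}  {resids[i]:4d}    "
            f"{coords[i, 0]:8.3f}{coords[i, 1]:8.3f}{coords[i, 2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
        )
    if bonds:
        neigh: dict[int, list[int]] = {}
        for i, j in bonds:
            neigh.setdefault(i, []).append(j)
            neigh.setdefault(j, []).append(i)
        for i in sorted(neigh):
            partners = sorted(neigh[i])
            for chunk in range(0, len(partners), 4):
                rec = "".join(f"{p + 1:5d}" for p in partners[chunk : chunk + 4])
                lines.append(f"CONECT{i + 1:5d}{rec}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_pdb(text: str) -> dict:
    """Parse ATOM/HETATM and CONECT records.

    Returns a dict with names, elements, coords (A), resnames, resids and
    bonds (0-based unordered pairs from CONECT, deduplicated). A missing
    element column is inferred from the atom name with a logged warning.
    """
    names: list[str] = []
    elements: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    xyz: list[list[float]] = []
    bonds: set[tuple[int, int]] = set()
    serial_to_index: dict[int, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise ValueError(f"line {lineno}: truncated coordinate record")
            try:
                serial = int(line[6:11])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: column misalignment ({exc})") from exc
            name = line[12:16].strip()
            el = line[76:78].strip() if len(line) >= 78 else ""
            if not el:
                el = infer_element(name)
                log.warning("line %d: element column missing, inferred %s from %r", lineno, el, name)
            serial_to_index[serial] = len(names)
            names.append(name)
            elements.append(el if len(el) == 1 else el.capitalize())
            resnames.append(line[17:21].strip() or "UNK")
            try:
                resids.append(int(line[22:26]))
            except ValueError:
                resids.append(1)
            xyz.append([x, y, z])
        elif rec == "CONECT":
            fields = line[6:].split()
            if not fields:
                continue
            try:
                serials = [int(f) for f in fields]
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad CONECT record ({exc})") from exc
            base = serial_to_index[serials[0]]
            for s in serials[1:]:
                j = serial_to_index[s]
                bonds.add((min(base, j), max(base, j)))
    return {
        "names": names,
        "elements": elements,
        "coords": np.array(xyz, dtype=float),
        "resnames": resnames,
        "resids": resids,
        "bonds": sorted(bonds),
    }


# ---------------------------------------------------------------------------
# Trajectory: multi-frame XYZ with optional box comment
# ---------------------------------------------------------------------------


def write_traj(traj: Trajectory, elements: list[str] | None = None) -> str:
    """Serialize a trajectory.

    Format per frame: natoms line, then a comment line
    `frame <k> dt_ps=<spacing> box=<Lx>,<Ly>,<Lz>` (box=none in gas phase),
    then one `element x y z` line per atom at full float precision.
    """
    n = traj.n_atoms
    elements = elements or ["X"] * n
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(str(n))
        if traj.boxes is not None:
            b = traj.boxes[f]
            box = f"{float(b[0])!r},{float(b[1])!r},{float(b[2])!r}"
        else:
            box = "none"
        lines.append(f"frame {f} dt_ps={float(traj.frame_spacing)!r} box={box}")
        for a in range(n):
            x, y, z = traj.frames[f, a]
            lines.append(f"{elements[a]:<2s} {float(x)!r} {float(y)!r} {float(z)!r}")
    return "\n".join(lines) + "\n"


def read_traj(text: str) -> Trajectory:
    lines = text.splitlines()
    pos = 0
    frames = []
    boxes = []
    spacing = 0.0
    has_box = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos])
        comment = lines[pos + 1].split()
        meta = dict(kv.split("=", 1) for kv in comment if "=" in kv)
        spacing = float(meta.get("dt_ps", "0.0"))
        boxval = meta.get("box", "none")
        if boxval == "none":
            if has_box is True:
                raise ValueError("mixed periodic and aperiodic frames")
            has_box = False
        else:
            has_box = True
            boxes.append([float(v) for v in boxval.split(",")])
        frame = np.empty((n, 3))
        for a in range(n):
            parts = lines[pos + 2 + a].split()
            frame[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(frame)
        pos += 2 + n
    return Trajectory(
        frames=np.array(frames),
        boxes=np.array(boxes) if has_box else None,
        frame_spacing=spacing,
    )
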