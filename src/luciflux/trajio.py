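"""Structure/trajectory containers and plain-text I/O.

Internal units are Angstrom for coordinates, nanoseconds for time and
kcal/mol for energies, throughout the package; nothing converts units
implicitly.

Residue identity is ``(chain, residue_number, insertion_code)`` taken
verbatim from the input file — residues are never renumbered, so selections
quoted in crystallographic numbering (e.g. the luciferase active-site
residues N17, T79) resolve directly.

Supported formats are text-only: fixed-column PDB (single- and multi-MODEL),
XYZ (xmol), and a CSV array container with a one-line JSON header carrying
shape, frame spacing and atom count.  Binary trajectory formats (DCD, XTC,
NetCDF) are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "ParseError",
    "read_structure",
    "write_trajectory",
    "read_trajectory",
    "export_nri_features",
]


class ParseError(ValueError):
    """Raised when a structure file fails fixed-column parsing."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain: str
    insertion_code: str = ""


@dataclass
class Topology:
    """Ordered atom list plus residue bookkeeping shared by all observables."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        self._calpha: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            if a.name == "CA" and a.element != "CA":  # exclude calcium ions
                self._calpha.setdefault((a.chain, a.residue_number, a.insertion_code), i)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def calpha_index(self, residue_number: int, chain: str | None = None,
                     insertion_code: str = "") -> int:
        """Atom index of the Cα of a residue; raises KeyError if absent."""
        if chain is None:
            for (ch, num, ins), idx in self._calpha.items():
                if num == residue_number and ins == insertion_code:
                    return idx
            raise KeyError(f"no C-alpha atom for residue {residue_number}")
        try:
            return self._calpha[(chain, residue_number, insertion_code)]
        except KeyError:
            raise KeyError(
                f"no C-alpha atom for residue {residue_number} chain {chain!r}"
            ) from None

    def calpha_indices(self, residue_numbers=None) -> np.ndarray:
        """Cα atom indices for the given residue numbers (all residues if None)."""
        if residue_numbers is None:
            return np.array(sorted(self._calpha.values()), dtype=int)
        return np.array([self.calpha_index(r) for r in residue_numbers], dtype=int)

    def atom_index(self, residue_number: int, atom_name: str) -> int | None:
        for i, a in enumerate(self.atoms):
            if a.residue_number == residue_number and a.name == atom_name:
                return i
        return None

    @classmethod
    def point_sites(cls, n: int) -> "Topology":
        """Placeholder topology of n pseudo-Cα sites (synthetic ensembles)."""
        return cls([Atom("CA", "C", i + 1, "GLY", "A") for i in range(n)])


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (Angstrom) over a shared topology."""

    topology: Topology
    coords: np.ndarray
    frame_spacing_ns: float = 0.1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# PDB fixed-column reading

def _parse_float(line: str, lo: int, hi: int, lineno: int, what: str) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"line {lineno}: malformed {what} field {text!r}"
        ) from None


def read_structure(path, fmt: str = "pdb") -> Trajectory:
    """Read a PDB structure; multi-MODEL files become multi-frame trajectories.

    ATOM and HETATM records are kept; for alternate locations only the
    highest-occupancy conformer of each atom is retained (ties keep the
    first encountered).  Insertion codes are preserved in residue identity.
    """
    if fmt != "pdb":
        raise ValueError(f"unsupported structure format {fmt!r}; supported: pdb")
    models: list[list[tuple[Atom, float, tuple[float, float, float]]]] = []
    current: list[tuple[Atom, float, tuple[float, float, float]]] = []
    seen_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if seen_model and current:
                    models.append(current)
                    current = []
                seen_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                name = line[12:16].strip()
                altloc = line[16:17].strip()
                resname = line[17:20].strip()
                chain = line[21:22].strip()
                try:
                    resnum = int(line[22:26])
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: malformed residue number {line[22:26]!r}"
                    ) from None
                icode = line[26:27].strip()
                x = _parse_float(line, 30, 38, lineno, "x coordinate")
                y = _parse_float(line, 38, 46, lineno, "y coordinate")
                z = _parse_float(line, 46, 54, lineno, "z coordinate")
                occ_text = line[54:60].strip()
                occ = float(occ_text) if occ_text else 1.0
                element = line[76:78].strip() or name[:1]
                atom = Atom(name, element.capitalize(), resnum, resname, chain, icode)
                # altloc policy: keep highest occupancy per (residue, atom name)
                if altloc:
                    key = (chain, resnum, icode, name)
                    for k, (a0, occ0, _) in enumerate(current):
                        if (a0.chain, a0.residue_number, a0.insertion_code, a0.name) == key:
                            if occ > occ0:
                                current[k] = (atom, occ, (x, y, z))
                            break
                    else:
                        current.append((atom, occ, (x, y, z)))
                else:
                    current.append((atom, occ, (x, y, z)))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    atoms = [a for a, _, _ in models[0]]
    coords = np.array([[xyz for _, _, xyz in m] for m in models], dtype=float)
    if any(len(m) != len(atoms) for m in models):
        raise ParseError(f"{path}: MODELs differ in atom count")
    return Trajectory(Topology(atoms), coords)


# ---------------------------------------------------------------------------
# Writing

_FORMATS = ("pdb", "xyz", "csv-array")


def write_trajectory(traj: Trajectory, path, fmt: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB, XYZ (xmol) or CSV array.

    PDB and XYZ round-trip within printed precision (1e-3 Å); the CSV
    array container round-trips floats bit-identically (repr precision).
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; supported: {', '.join(_FORMATS)}")
    if traj.n_frames == 0:
        raise ValueError("empty trajectories are unwritable")
    if fmt == "pdb":
        _write_pdb(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    else:
        _write_csv_array(traj, path)


def _write_pdb(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, a in enumerate(traj.topology.atoms):
                x, y, z = traj.coords[f, i]
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {i + 1 % 100000:5d} {name}{'':1s}{a.residue_name:>3s} "
                    f"{a.chain:1s}{a.residue_number:4d}{a.insertion_code:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {f} spacing_ns {traj.frame_spacing_ns}\n")
            for i, a in enumerate(traj.topology.atoms):
                x, y, z = traj.coords[f, i]
                fh.write(f"{a.element:<2s} {x:.6f} {y:.6f} {z:.6f}\n")


def _write_csv_array(traj: Trajectory, path) -> None:
    header = json.dumps(
        {
            "n_frames": traj.n_frames,
            "n_atoms": traj.n_atoms,
            "frame_spacing_ns": traj.frame_spacing_ns,
        }
    )
    with open(path, "w") as fh:
        fh.write("# " + header + "\n")
        flat = traj.coords.reshape(traj.n_frames, -1)
        for row in flat:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_trajectory(path, fmt: str, topology: Topology | None = None) -> Trajectory:
    """Read back a trajectory written by :func:`write_trajectory`."""
    if fmt == "pdb":
        return read_structure(path)
    if fmt == "xyz":
        return _read_xyz(path, topology)
    if fmt == "csv-array":
        return _read_csv_array(path, topology)
    raise ValueError(f"unsupported format {fmt!r}; supported: {', '.join(_FORMATS)}")


def _read_xyz(path, topology: Topology | None) -> Trajectory:
    frames = []
    spacing = 0.1
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    elements: list[str] = []
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1].split()
        if "spacing_ns" in comment:
            spacing = float(comment[comment.index("spacing_ns") + 1])
        block = lines[i + 2 : i + 2 + n]
        elements = [ln.split()[0] for ln in block]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    coords = np.array(frames)
    if topology is None:
        topology = Topology(
            [Atom(e, e, k + 1, "UNK", "A") for k, e in enumerate(elements)]
        )
    return Trajectory(topology, coords, frame_spacing_ns=spacing)


def _read_csv_array(path, topology: Topology | None) -> Trajectory:
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("# "))
        flat = np.array(
            [[float(v) for v in ln.split(",")] for ln in fh if ln.strip()]
        )
    coords = flat.reshape(header["n_frames"], header["n_atoms"], 3)
    if topology is None:
        topology = Topology.point_sites(header["n_atoms"])
    return Trajectory(topology, coords, frame_spacing_ns=header["frame_spacing_ns"])


# ---------------------------------------------------------------------------
# Feature export for relational-inference models

def export_nri_features(traj: Trajectory) -> np.ndarray:
    """Per-node position+velocity features for graph dynamics models.

    Returns an array of shape ``(n_frames - 1, n_atoms, 6)``: columns are
    (x, y, z, vx, vy, vz) with velocity the forward finite difference
    ``(r[t+1] - r[t]) / frame_spacing_ns`` (Å/ns).  Each node therefore
    carries a six-dimensional feature vector.
    """
    if traj.n_frames < 2:
        raise ValueError("velocity by finite difference needs >= 2 frames")
    pos = traj.coords[:-1]
    vel = np.diff(traj.coords, axis=0) / traj.frame_spacing_ns
    return np.concatenate([pos, vel], axis=2)
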