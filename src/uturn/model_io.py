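"""Coordinate-ensemble and tabular I/O.

Atom addressing follows the deposition conventions of solution-NMR RNA
entries: author residue numbering (1-based, e.g. 1-27 for the neomycin
sensing riboswitch), PDB atom names with ribose primes accepted in
apostrophe (O2'), prime (O2′) and star (O2*) spellings, waters as
HOH/WAT residues and monovalent/divalent cations as single-atom residues
(K/K+/NA/NA+/MG).

Units are fixed package-wide: coordinates in Å, times in ps,
concentrations in mM, scalar couplings in Hz.
"""

from __future__ import annotations

import json
import math
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRef", "AtomTable", "StructureFrame", "Ensemble", "NOERestraint",
    "TitrationSeries", "CTIntensitySeries", "EnsembleFormatError",
    "AtomResolutionError", "normalize_atom_name", "read_ensemble",
    "write_ensemble", "read_noe_table", "fetch_rcsb",
]

WATER_RESNAMES = {"HOH", "WAT"}
ION_RESNAMES = {"K": "K", "K+": "K", "NA": "NA", "NA+": "NA", "MG": "MG",
                "MG2": "MG", "CL": "CL", "CL-": "CL"}

_PRIME = "′"


class EnsembleFormatError(ValueError):
    """Raised for malformed or internally inconsistent coordinate files."""


class AtomResolutionError(KeyError):
    """Raised when an AtomRef does not resolve to exactly one atom."""


def normalize_atom_name(name: str) -> str:
    """Collapse prime/star dialects to a single apostrophe spelling.

    O2', O2′ and O2* all denote the ribose 2'-oxygen; one internal
    spelling (apostrophe) is used for every lookup.
    """
    if not name:
        raise ValueError("atom name must be nonempty")
    return name.strip().replace(_PRIME, "'").replace("*", "'")


@dataclass(frozen=True)
class AtomRef:
    """Reference to one atom by author residue number and atom name.

    ``residue_name`` is optional; when given it is checked at resolution
    time, otherwise the (residue number, atom name) pair must be unique.
    """

    residue_number: int
    atom_name: str
    residue_name: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "atom_name", normalize_atom_name(self.atom_name))

    @classmethod
    def parse(cls, text: str) -> "AtomRef":
        """Parse ``"14:H3"`` or ``"U14:H3"`` into an AtomRef."""
        res_part, _, atom = text.strip().partition(":")
        if not atom:
            raise ValueError(f"cannot parse atom reference {text!r}; expected 'res:atom'")
        m = re.fullmatch(r"([A-Za-z]*)(-?\d+)", res_part.strip())
        if not m:
            raise ValueError(f"cannot parse residue part of atom reference {text!r}")
        resname = m.group(1) or None
        return cls(int(m.group(2)), atom, resname)

    def __str__(self) -> str:
        if self.residue_name:
            return f"{self.residue_name}{self.residue_number}:{self.atom_name}"
        return f"{self.residue_number}:{self.atom_name}"


class AtomTable:
    """Immutable table of atoms shared by every frame of an ensemble."""

    def __init__(self, residue_numbers: Sequence[int], residue_names: Sequence[str],
                 atom_names: Sequence[str], elements: Sequence[str] | None = None):
        n = len(residue_numbers)
        if not (len(residue_names) == len(atom_names) == n):
            raise ValueError("atom table columns must have equal length")
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = [r.strip().upper() for r in residue_names]
        self.atom_names = [normalize_atom_name(a) for a in atom_names]
        if elements is None:
            elements = [_guess_element(a) for a in self.atom_names]
        self.elements = [e.strip().upper() for e in elements]
        self._index: dict[tuple[int, str], int] = {}
        for i, (num, aname) in enumerate(zip(self.residue_numbers, self.atom_names)):
            key = (int(num), aname)
            if key in self._index:
                raise EnsembleFormatError(
                    f"duplicate atom {num}:{aname} in atom table (altloc duplicates "
                    "must be stripped before analysis)")
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.atom_names)

    def index(self, ref: AtomRef) -> int:
        """Resolve an AtomRef to its row, raising if absent or mismatched."""
        key = (ref.residue_number, ref.atom_name)
        try:
            i = self._index[key]
        except KeyError:
            raise AtomResolutionError(
                f"atom {ref} not found in atom table") from None
        if ref.residue_name is not None and \
                self.residue_names[i] != ref.residue_name.upper():
            raise AtomResolutionError(
                f"atom {ref}: residue {ref.residue_number} is "
                f"{self.residue_names[i]}, not {ref.residue_name}")
        return i

    def residues(self) -> list[tuple[int, str]]:
        """Ordered unique (residue number, residue name) pairs."""
        seen: dict[int, str] = {}
        out = []
        for num, name in zip(self.residue_numbers, self.residue_names):
            if int(num) not in seen:
                seen[int(num)] = name
                out.append((int(num), name))
        return out

    def residue_name(self, residue_number: int) -> str:
        mask = self.residue_numbers == residue_number
        if not mask.any():
            raise AtomResolutionError(f"no residue numbered {residue_number}")
        return self.residue_names[int(np.argmax(mask))]

    def residue_atom_indices(self, residue_number: int) -> np.ndarray:
        return np.nonzero(self.residue_numbers == residue_number)[0]

    def water_residues(self) -> list[int]:
        return [num for num, name in self.residues() if name in WATER_RESNAMES]

    def ion_indices(self, species: str) -> np.ndarray:
        """Atom rows of single-atom cation/anion residues of one species."""
        species = ION_RESNAMES.get(species.strip().upper(), species.strip().upper())
        rows = [i for i, name in enumerate(self.residue_names)
                if ION_RESNAMES.get(name) == species]
        return np.asarray(rows, dtype=int)

    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e != "H" for e in self.elements], dtype=bool)

    def keys(self) -> Iterable[tuple[int, str]]:
        return self._index.keys()


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in {"CL", "BR", "MG", "NA", "MN", "ZN", "FE"}:
        return two
    return stripped[0].upper()


@dataclass
class StructureFrame:
    """One coordinate set over a shared atom table (coordinates in Å)."""

    atoms: AtomTable
    xyz: np.ndarray  # (n_atoms, 3)
    frame_index: int = 0
    time_ps: float | None = None

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom table")
        if not np.isfinite(self.xyz).all():
            raise ValueError("coordinates must be finite")

    def pos(self, ref: AtomRef) -> np.ndarray:
        return self.xyz[self.atoms.index(ref)]


class Ensemble:
    """Ordered frames sharing one atom table; optional time step dt (ps)."""

    def __init__(self, atoms: AtomTable, coords: np.ndarray,
                 dt: float | None = None, label: str = "",
                 aligned: bool = False):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (len(atoms), 3):
            raise ValueError(
                f"coords must be (n_frames, {len(atoms)}, 3); got {coords.shape}")
        if not np.isfinite(coords).all():
            raise ValueError("coordinates must be finite")
        if dt is not None and dt <= 0:
            raise ValueError("dt must be positive when given")
        self.atoms = atoms
        self.coords = coords
        self.dt = dt
        self.label = label
        self.aligned = aligned

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> StructureFrame:
        t = None if self.dt is None else i * self.dt
        return StructureFrame(self.atoms, self.coords[i], i, t)

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    def index(self, ref: AtomRef) -> int:
        return self.atoms.index(ref)

    def positions(self, ref: AtomRef) -> np.ndarray:
        """Per-frame positions of one atom, shape (n_frames, 3)."""
        return self.coords[:, self.atoms.index(ref), :]

    def with_coords(self, coords: np.ndarray, aligned: bool | None = None) -> "Ensemble":
        return Ensemble(self.atoms, coords, dt=self.dt, label=self.label,
                        aligned=self.aligned if aligned is None else aligned)


# ---------------------------------------------------------------------------
# Restraint / NMR-table containers
# ---------------------------------------------------------------------------

@dataclass
class NOERestraint:
    """Two equivalent-proton groups with an upper-bound distance (Å)."""

    group_a: list[AtomRef]
    group_b: list[AtomRef]
    upper_bound: float

    def __post_init__(self):
        if not self.group_a or not self.group_b:
            raise ValueError("proton groups must be nonempty")
        if self.upper_bound <= 0:
            raise ValueError("upper bound must be positive")
        keys_a = {(r.residue_number, r.atom_name) for r in self.group_a}
        keys_b = {(r.residue_number, r.atom_name) for r in self.group_b}
        if keys_a & keys_b:
            raise ValueError("proton groups must be disjoint")


@dataclass
class TitrationSeries:
    """Chemical-shift changes vs titrant concentration (mM, ppm)."""

    concentrations: list[float]
    delta_shift: list[float]
    nucleus: str = ""
    model: str = "single-site"

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        d = np.asarray(self.delta_shift, dtype=float)
        if c.shape != d.shape or c.ndim != 1:
            raise ValueError("concentrations and shifts must be equal-length vectors")
        if len(c) < 4:
            raise ValueError("need at least 4 titration points")
        if (c < 0).any():
            raise ValueError("concentrations must be nonnegative")
        if not (np.diff(c) > 0).all():
            raise ValueError("concentrations must be strictly increasing")
        if self.model not in ("single-site", "cooperative2"):
            raise ValueError(f"unknown model tag {self.model!r}")
        self.concentrations = c.tolist()
        self.delta_shift = d.tolist()


@dataclass
class CTIntensitySeries:
    """Constant-time intensity ratios I_cross/I_ref vs delay tau_m (s)."""

    tau_m: list[float]
    ratio: list[float]
    replicate: str = "1"
    clip: bool = False

    def __post_init__(self):
        t = np.asarray(self.tau_m, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("tau_m and ratio must be equal-length vectors")
        if (t <= 0).any():
            raise ValueError("delays must be positive")
        if self.clip:
            r = np.clip(r, -1.0, 1.0)
        elif ((r < -1) | (r > 1)).any():
            raise ValueError("intensity ratios outside [-1, 1]; pass clip=True to clip")
        self.tau_m = t.tolist()
        self.ratio = r.tolist()


# ---------------------------------------------------------------------------
# Ensemble readers / writers
# ---------------------------------------------------------------------------

def read_ensemble(path: str | Path, format: str | None = None,
                  dt: float | None = None, label: str | None = None) -> Ensemble:
    """Read a coordinate ensemble.

    Parameters
    ----------
    path
        Input file. ``pdb-multimodel``: a standard PDB with MODEL/ENDMDL
        records (a single-model file yields a length-1 ensemble).
        ``xyz-frames``: the package's plain frame-series text format (see
        :func:`write_ensemble`).
    format
        ``"pdb-multimodel"`` or ``"xyz-frames"``; inferred from the file
        suffix when omitted (``.pdb``/``.ent`` vs anything else).
    dt
        Frame time step in ps (optional; xyz-frames files may carry their own).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "pdb-multimodel" if path.suffix.lower() in (".pdb", ".ent") \
            else "xyz-frames"
    if format == "pdb-multimodel":
        ens = _read_pdb_multimodel(path)
    elif format == "xyz-frames":
        ens = _read_xyz_frames(path)
    else:
        raise ValueError(f"unknown ensemble format {format!r}")
    if dt is not None:
        ens.dt = float(dt)
    ens.label = label if label is not None else path.stem
    return ens


def _read_pdb_multimodel(path: Path) -> Ensemble:
    import gemmi

    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise EnsembleFormatError(f"{path}: no models found")
    ref_keys: list[tuple[int, str, str]] = []
    frames = []
    for imodel, model in enumerate(st):
        keys = []
        xyz = []
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("", "A", "\0"):
                        continue  # keep the first alternate location only
                    keys.append((res.seqid.num, res.name.strip().upper(),
                                 normalize_atom_name(atom.name)))
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if imodel == 0:
            ref_keys = keys
        elif keys != ref_keys:
            raise EnsembleFormatError(
                f"{path}: model {model.num} has a different atom table than "
                f"model {st[0].num} ({len(keys)} vs {len(ref_keys)} atoms or "
                "different names/order)")
        frames.append(np.asarray(xyz, dtype=float))
    elements = None
    table = AtomTable([k[0] for k in ref_keys], [k[1] for k in ref_keys],
                      [k[2] for k in ref_keys], elements)
    return Ensemble(table, np.stack(frames))


_FRAMES_MAGIC = "# uturn-frames 1"


def _read_xyz_frames(path: Path) -> Ensemble:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _FRAMES_MAGIC:
        raise EnsembleFormatError(
            f"{path}: line 1: expected header {_FRAMES_MAGIC!r}")
    dt = None
    natoms = None
    i = 1
    nums: list[int] = []
    names: list[str] = []
    anames: list[str] = []
    elements: list[str] = []
    # header section
    while i < len(lines):
        ln = lines[i].strip()
        i += 1
        if not ln or ln.startswith("#"):
            continue
        if ln.startswith("dt "):
            dt = float(ln.split()[1])
        elif ln.startswith("natoms "):
            natoms = int(ln.split()[1])
        elif ln == "atoms":
            break
        else:
            raise EnsembleFormatError(f"{path}: line {i}: unexpected {ln!r}")
    if natoms is None:
        raise EnsembleFormatError(f"{path}: missing 'natoms' header")
    for _ in range(natoms):
        if i >= len(lines):
            raise EnsembleFormatError(f"{path}: truncated atom table")
        parts = lines[i].split()
        if len(parts) not in (3, 4):
            raise EnsembleFormatError(
                f"{path}: line {i + 1}: expected 'resnum resname atom [element]'")
        nums.append(int(parts[0]))
        names.append(parts[1])
        anames.append(parts[2])
        elements.append(parts[3] if len(parts) == 4 else _guess_element(
            normalize_atom_name(parts[2])))
        i += 1
    table = AtomTable(nums, names, anames, elements)
    frames = []
    while i < len(lines):
        ln = lines[i].strip()
        if not ln:
            i += 1
            continue
        if not ln.startswith("frame"):
            raise EnsembleFormatError(
                f"{path}: line {i + 1}: expected 'frame' record, got {ln!r}")
        i += 1
        block = np.empty((natoms, 3), dtype=float)
        for j in range(natoms):
            if i >= len(lines):
                raise EnsembleFormatError(
                    f"{path}: frame {len(frames)} truncated at line {i + 1}")
            parts = lines[i].split()
            if len(parts) != 3:
                raise EnsembleFormatError(
                    f"{path}: line {i + 1}: expected 3 coordinates")
            try:
                block[j] = [float(p) for p in parts]
            except ValueError:
                raise EnsembleFormatError(
                    f"{path}: line {i + 1}: non-numeric coordinate") from None
            i += 1
        frames.append(block)
    if not frames:
        raise EnsembleFormatError(f"{path}: no frames")
    return Ensemble(table, np.stack(frames), dt=dt)


def write_ensemble(ensemble: Ensemble, path: str | Path,
                   format: str | None = None, precision: int = 3) -> Path:
    """Write an ensemble as multi-model PDB or as plain frame-series text."""
    path = Path(path)
    if format is None:
        format = "pdb-multimodel" if path.suffix.lower() in (".pdb", ".ent") \
            else "xyz-frames"
    if format == "pdb-multimodel":
        _write_pdb_multimodel(ensemble, path)
    elif format == "xyz-frames":
        _write_xyz_frames(ensemble, path, precision)
    else:
        raise ValueError(f"unknown ensemble format {format!r}")
    return path


def _write_pdb_multimodel(ensemble: Ensemble, path: Path) -> None:
    import gemmi

    st = gemmi.Structure()
    st.name = ensemble.label or "ensemble"
    table = ensemble.atoms
    for iframe in range(ensemble.n_frames):
        model = gemmi.Model(iframe + 1)
        chain = gemmi.Chain("A")
        cur_res = None
        cur_key = None
        for j in range(len(table)):
            key = (int(table.residue_numbers[j]), table.residue_names[j])
            if key != cur_key:
                cur_res = gemmi.Residue()
                cur_res.name = table.residue_names[j]
                cur_res.seqid = gemmi.SeqId(key[0], " ")
                chain.add_residue(cur_res)
                cur_key = key
            atom = gemmi.Atom()
            atom.name = table.atom_names[j]
            atom.element = gemmi.Element(table.elements[j])
            x, y, z = ensemble.coords[iframe, j]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            chain[-1].add_atom(atom)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    path.write_text(doc)


def _write_xyz_frames(ensemble: Ensemble, path: Path, precision: int) -> None:
    table = ensemble.atoms
    out = [_FRAMES_MAGIC, f"natoms {len(table)}"]
    if ensemble.dt is not None:
        out.append(f"dt {ensemble.dt:g}")
    out.append("atoms")
    for j in range(len(table)):
        out.append(f"{table.residue_numbers[j]} {table.residue_names[j]} "
                   f"{table.atom_names[j]} {table.elements[j]}")
    fmt = f"{{:.{precision}f}}"
    for i in range(ensemble.n_frames):
        out.append(f"frame {i}")
        for j in range(len(table)):
            out.append(" ".join(fmt.format(v) for v in ensemble.coords[i, j]))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# NOE tables
# ---------------------------------------------------------------------------

def _parse_group(cell: str, row: int) -> list[AtomRef]:
    refs = []
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            refs.append(AtomRef.parse(token))
        except ValueError as exc:
            raise ValueError(f"row {row}: {exc}") from None
    if not refs:
        raise ValueError(f"row {row}: empty proton group")
    return refs


def read_noe_table(path: str | Path) -> list[NOERestraint]:
    """Read tab-separated NOE restraints.

    Columns: group_a, group_b (semicolon-joined ``res:atom`` references)
    and upper_bound_A. A header line starting with ``group_a`` is skipped.
    """
    restraints = []
    for irow, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cells = [c.strip() for c in line.split("\t")]
        if irow == 1 and cells[0].lower() in ("group_a", "groupa"):
            continue
        if len(cells) < 3:
            raise ValueError(f"row {irow}: expected 3 tab-separated columns")
        try:
            bound = float(cells[2])
        except ValueError:
            raise ValueError(
                f"row {irow}: non-numeric upper bound {cells[2]!r}") from None
        try:
            restraints.append(NOERestraint(_parse_group(cells[0], irow),
                                           _parse_group(cells[1], irow), bound))
        except ValueError as exc:
            msg = str(exc)
            raise ValueError(msg if msg.startswith("row") else
                             f"row {irow}: {exc}") from None
    return restraints


def write_noe_table(restraints: Sequence[NOERestraint], path: str | Path) -> Path:
    path = Path(path)
    lines = ["group_a\tgroup_b\tupper_bound_A"]
    for r in restraints:
        a = ";".join(f"{x.residue_number}:{x.atom_name}" for x in r.group_a)
        b = ";".join(f"{x.residue_number}:{x.atom_name}" for x in r.group_b)
        lines.append(f"{a}\t{b}\t{r.upper_bound:g}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Remote fetch (requires network; analyses themselves are offline)
# ---------------------------------------------------------------------------

def fetch_rcsb(pdb_id: str, dest_dir: str | Path = ".",
               timeout: float = 60.0) -> Path:
    """Download a PDB-format entry from RCSB into ``dest_dir`` (cached).

    Returns the local path ``<dest_dir>/<id>.pdb``. Raises URLError /
    OSError when offline.
    """
    pdb_id = pdb_id.lower()
    if not re.fullmatch(r"[0-9][a-z0-9]{3}", pdb_id):
        raise ValueError(f"invalid PDB id {pdb_id!r}")
    dest = Path(dest_dir) / f"{pdb_id}.pdb"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    dest.write_bytes(data)
    return dest
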