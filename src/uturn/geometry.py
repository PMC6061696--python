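"""Elementary geometric operators on frames and ensembles.

Hydrogen bonds use the strict geometric criterion common in RNA
simulation analysis: donor-acceptor heavy-atom distance < 3.5 Å and
donor-hydrogen-acceptor angle > 120 deg (both strict, so counts at the
boundary are reproducible). Base planes are least-squares (SVD) planes
through the ring atoms; plane-atom distances are unsigned perpendicular
distances, summarized as median +/- sd across frames. Superposition is
iterative Kabsch alignment onto the evolving coordinate average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from uturn.model_io import AtomRef, Ensemble, StructureFrame

__all__ = [
    "HBondCriteria", "HBondObservation", "Plane", "detect_hbond",
    "hbond_series", "detect_water_bridge", "fit_base_plane",
    "plane_atom_distance_series", "superpose_and_rmsd",
    "PYRIMIDINE_RING", "PURINE_RING",
]

PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
# exocyclic additions for the optional extended plane definition
_EXOCYCLIC = {
    "U": ("O2", "O4"), "T": ("O2", "O4"), "C": ("O2", "N4"),
    "A": ("N6",), "G": ("O6", "N2"),
}
_PURINES = {"A", "G"}
_PYRIMIDINES = {"U", "C", "T", "DT", "DC"}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond acceptance thresholds (strict inequalities)."""

    d_max: float = 3.5       # heavy-atom donor-acceptor distance, Å
    angle_min: float = 120.0  # donor-hydrogen-acceptor angle, degrees

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0 <= self.angle_min < 180):
            raise ValueError("angle_min must lie in [0, 180)")


@dataclass
class HBondObservation:
    donor: AtomRef
    hydrogen: AtomRef
    acceptor: AtomRef
    distance: float  # heavy-atom donor-acceptor distance, Å
    angle: float     # D-H-A angle, degrees
    satisfied: bool


@dataclass
class Plane:
    """Least-squares plane: centroid, unit normal, rms perpendicular residual."""

    centroid: np.ndarray
    normal: np.ndarray
    rms_residual: float

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("normal must be a unit vector")
        if self.rms_residual < 0:
            raise ValueError("residual must be nonnegative")

    def signed_distance(self, point: np.ndarray) -> float:
        return float(np.dot(np.asarray(point) - self.centroid, self.normal))

    def distance(self, point: np.ndarray) -> float:
        return abs(self.signed_distance(point))


def _angle_deg(a: np.ndarray, apex: np.ndarray, b: np.ndarray) -> float:
    u = a - apex
    v = b - apex
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def detect_hbond(frame: StructureFrame, donor: AtomRef, hydrogen: AtomRef,
                 acceptor: AtomRef,
                 criteria: HBondCriteria = HBondCriteria()) -> HBondObservation:
    """Evaluate one candidate H-bond; geometry is recorded even when unmet."""
    d = frame.pos(donor)
    h = frame.pos(hydrogen)
    a = frame.pos(acceptor)
    if np.linalg.norm(h - d) > 1.2:
        warnings.warn(
            f"hydrogen {hydrogen} is {np.linalg.norm(h - d):.2f} Å from donor "
            f"{donor}; not covalently plausible", stacklevel=2)
    dist = float(np.linalg.norm(a - d))
    ang = _angle_deg(d, h, a)
    return HBondObservation(donor, hydrogen, acceptor, dist, ang,
                            dist < criteria.d_max and ang > criteria.angle_min)


def hbond_series(ensemble: Ensemble, donor: AtomRef, hydrogen: AtomRef,
                 acceptor: AtomRef,
                 criteria: HBondCriteria = HBondCriteria()
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-frame (distance, angle, satisfied) for one triple."""
    d = ensemble.positions(donor)
    h = ensemble.positions(hydrogen)
    a = ensemble.positions(acceptor)
    dist = np.linalg.norm(a - d, axis=1)
    u = d - h
    v = a - h
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    denom = np.where(nu * nv == 0, 1.0, nu * nv)
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / denom, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    sat = (dist < criteria.d_max) & (ang > criteria.angle_min)
    return dist, ang, sat


def _water_atoms(frame_atoms, water_resnum: int) -> tuple[int, list[int]]:
    """(oxygen row, hydrogen rows) of one water residue."""
    rows = frame_atoms.residue_atom_indices(water_resnum)
    o_row = None
    h_rows = []
    for r in rows:
        if frame_atoms.elements[r] == "O":
            o_row = int(r)
        elif frame_atoms.elements[r] == "H":
            h_rows.append(int(r))
    if o_row is None:
        raise ValueError(f"water residue {water_resnum} has no oxygen")
    return o_row, h_rows


def detect_water_bridge(frame: StructureFrame,
                        partner_a: tuple[AtomRef, AtomRef],
                        partner_b: AtomRef,
                        criteria: HBondCriteria = HBondCriteria()
                        ) -> AtomRef | None:
    """Find a water bridging a donor group and an acceptor atom.

    ``partner_a`` is the (donor heavy atom, its hydrogen) pair that must
    donate to the water oxygen; the water must in turn donate, via either
    of its hydrogens, to the acceptor ``partner_b``. The first qualifying
    water by ascending residue number is returned (documented tie-break),
    or None.
    """
    table = frame.atoms
    donor, hydrogen = partner_a
    d = frame.pos(donor)
    h = frame.pos(hydrogen)
    b = frame.pos(partner_b)
    for wnum in sorted(table.water_residues()):
        o_row, h_rows = _water_atoms(table, wnum)
        ow = frame.xyz[o_row]
        # leg 1: partner_a donates to the water oxygen
        if not (np.linalg.norm(ow - d) < criteria.d_max
                and _angle_deg(d, h, ow) > criteria.angle_min):
            continue
        # leg 2: the water donates to partner_b via either hydrogen
        if np.linalg.norm(b - ow) >= criteria.d_max:
            continue
        for hr in h_rows:
            if _angle_deg(ow, frame.xyz[hr], b) > criteria.angle_min:
                return AtomRef(wnum, table.atom_names[o_row],
                               table.residue_names[o_row])
    return None


def default_ring_atoms(residue_name: str, include_exocyclic: bool = False
                       ) -> tuple[str, ...]:
    name = residue_name.strip().upper().lstrip("DR")
    base = name[-1] if name else ""
    if base in _PURINES:
        ring = PURINE_RING
    elif base in _PYRIMIDINES or name in _PYRIMIDINES:
        ring = PYRIMIDINE_RING
    else:
        raise ValueError(f"no default ring for residue {residue_name!r}")
    if include_exocyclic:
        ring = ring + _EXOCYCLIC.get(base, ())
    return ring


def fit_base_plane(frame: StructureFrame, residue_number: int,
                   ring_atoms: Sequence[str] | None = None,
                   include_exocyclic: bool = False) -> Plane:
    """Least-squares plane through a base ring (SVD of centered coordinates).

    The normal sign is fixed along the glycosidic N -> C1' direction when
    those atoms are present (otherwise toward positive determinant of the
    leading components), so repeated fits are reproducible.
    """
    table = frame.atoms
    resname = table.residue_name(residue_number)
    if ring_atoms is None:
        ring_atoms = default_ring_atoms(resname, include_exocyclic)
    pts = []
    for aname in ring_atoms:
        pts.append(frame.pos(AtomRef(residue_number, aname)))
    pts = np.asarray(pts)
    if len(pts) < 3:
        raise ValueError("need at least 3 ring atoms")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError(
            f"ring atoms of residue {residue_number} are collinear")
    normal = vt[2]
    residual = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    # orient the normal
    sign_ref = None
    base = resname.strip().upper().lstrip("DR")[-1:]
    n_gly = "N9" if base in _PURINES else "N1"
    try:
        gly = frame.pos(AtomRef(residue_number, "C1'")) - \
            frame.pos(AtomRef(residue_number, n_gly))
        sign_ref = float(np.dot(normal, gly))
    except KeyError:
        pass
    if sign_ref is None:
        nz = normal[np.argmax(np.abs(normal))]
        sign_ref = float(nz)
    if sign_ref < 0:
        normal = -normal
    return Plane(centroid, normal, residual)


@dataclass
class PlaneDistanceSeries:
    """Per-frame unsigned plane-atom distances with median +/- sd summary."""

    base_residue: int
    target: AtomRef
    distances: np.ndarray
    median: float
    sd: float


def plane_atom_distance_series(ensemble: Ensemble, base_residue: int,
                               target: AtomRef,
                               ring_atoms: Sequence[str] | None = None,
                               include_exocyclic: bool = False
                               ) -> PlaneDistanceSeries:
    """Unsigned perpendicular distance from an atom to a base plane, per frame.

    The summary median uses the midpoint convention for even frame counts
    (numpy median); the spread is the population standard deviation.
    """
    dists = np.empty(ensemble.n_frames)
    for i, frame in enumerate(ensemble):
        plane = fit_base_plane(frame, base_residue, ring_atoms,
                               include_exocyclic)
        dists[i] = plane.distance(frame.pos(target))
    return PlaneDistanceSeries(base_residue, target, dists,
                               float(np.median(dists)), float(np.std(dists)))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and translations mapping mobile onto target.

    Returns (R, mobile_centroid, target_centroid); apply as
    ``(x - mc) @ R.T + tc``.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, mc, tc


@dataclass
class SuperpositionResult:
    aligned: Ensemble
    average: np.ndarray                 # (n_atoms, 3) final average structure
    per_residue_rmsd: dict[int, float]  # heavy-atom RMSD vs average, Å
    atom_rmsd: np.ndarray               # per-atom RMSD vs average, Å
    iterations: int


def superpose_and_rmsd(ensemble: Ensemble,
                       subset: Sequence[AtomRef] | None = None,
                       tol: float = 1e-4, max_iter: int = 100
                       ) -> SuperpositionResult:
    """Iteratively superpose all frames onto their evolving average.

    Frames are first aligned (optimal rigid rotation + translation over
    the fit subset) onto frame 1, averaged, re-aligned onto the average
    and re-averaged until the average moves less than ``tol`` Å (max
    per-atom displacement). Per-residue heavy-atom RMSD is computed
    against the final average.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames to superpose")
    if subset is not None and len(subset) == 0:
        raise ValueError("fit subset must be nonempty")
    if subset is None:
        fit_rows = np.nonzero(ensemble.atoms.heavy_mask())[0]
        if len(fit_rows) == 0:
            fit_rows = np.arange(len(ensemble.atoms))
    else:
        fit_rows = np.asarray([ensemble.atoms.index(r) for r in subset])
    coords = ensemble.coords.copy()

    def align_all(reference: np.ndarray) -> None:
        for i in range(coords.shape[0]):
            r, mc, tc = _kabsch(coords[i, fit_rows], reference[fit_rows])
            coords[i] = (coords[i] - mc) @ r.T + tc

    align_all(coords[0])
    average = coords.mean(axis=0)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        align_all(average)
        new_average = coords.mean(axis=0)
        shift = np.abs(new_average - average).max()
        average = new_average
        if shift < tol:
            break
    sq = ((coords - average) ** 2).sum(axis=2)   # (frames, atoms)
    atom_rmsd = np.sqrt(sq.mean(axis=0))
    heavy = ensemble.atoms.heavy_mask()
    per_res: dict[int, float] = {}
    for resnum, _ in ensemble.atoms.residues():
        rows = ensemble.atoms.residue_atom_indices(resnum)
        rows = rows[heavy[rows]]
        if len(rows) == 0:
            continue
        per_res[resnum] = float(np.sqrt(sq[:, rows].mean()))
    aligned = ensemble.with_coords(coords, aligned=True)
    return SuperpositionResult(aligned, average, per_res, atom_rmsd, iterations)
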