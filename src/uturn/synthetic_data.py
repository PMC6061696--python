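"""Synthetic inputs with declared statistical structure.

Every analyzer in the package can be exercised without external data:

* conformer ensembles — two pyrimidine-like toy residues whose rigid
  placement realizes each base-pair state's H-bond predicate exactly
  (required bonds at 2.9 Å with donor angles of ~136 deg, the optimum
  the regular-hexagon template admits for the doubly-bonded pair;
  non-required contacts pushed beyond 4.2 Å; a bridging water placed
  collinearly for mediated states), switching between states via a
  discrete Markov chain;
* a cation alternating between a binding site and bulk with a
  prescribed bound fraction and geometric (memoryless) dwell times;
* titration curves and constant-time cosine decays with Gaussian noise.

The toy coordinates make no claim to real RNA chemistry: the templates
only guarantee the logical truth of each state's geometric predicate,
which is what the classifiers test. Every generator is a pure function
of its spec and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from uturn.model_io import (AtomRef, AtomTable, CTIntensitySeries, Ensemble,
                            TitrationSeries)
from uturn.geometry import HBondCriteria
from uturn.basepair_states import StateScheme, classify_frame, builtin_schemes

__all__ = ["ConformerSimSpec", "IonSimSpec", "IonTrack",
           "gen_conformer_ensemble", "gen_ion_trajectory", "gen_ion_ensemble",
           "gen_titration", "gen_ct_series", "stationary_distribution"]

_HBOND_LEN = 2.9       # donor-acceptor distance realized for required bonds, Å
_EXCLUDE = 4.2         # minimum distance for non-required contacts, Å
_BRIDGE_SPAN = 5.4     # donor-acceptor distance for water-mediated contacts, Å
_WATER_OH = 0.97       # water O-H bond length, Å


# ---------------------------------------------------------------------------
# Toy residue template and rigid pair placement
# ---------------------------------------------------------------------------

def _residue_template() -> dict[str, np.ndarray]:
    """Flat pyrimidine-like residue in the z=0 plane.

    A regular hexagon (radius 1.40 Å) carries the ring names; exocyclic
    O2/O4, the imino H3 and the glycosidic C1' extend radially, which
    keeps the imino hydrogen on the C2-N3-C4 bisector as in a real base.
    """
    ring = {}
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    for i, name in enumerate(names):
        a = math.radians(60 * i)
        ring[name] = np.array([1.40 * math.cos(a), 1.40 * math.sin(a), 0.0])

    def radial(base: str, bond: float) -> np.ndarray:
        v = ring[base]
        return v * (1.0 + bond / np.linalg.norm(v))

    ring["O2"] = radial("C2", 1.22)
    ring["O4"] = radial("C4", 1.22)
    ring["H3"] = radial("N3", 1.01)
    ring["C1'"] = radial("N1", 1.47)
    return ring

_TEMPLATE_ATOMS = ["N1", "C2", "N3", "C4", "C5", "C6", "O2", "O4", "H3", "C1'"]


def _rot2(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _angle(a, apex, b) -> float:
    u = a - apex
    v = b - apex
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _circle_intersections(c1, r1, c2, r2):
    """Intersection points of two circles in the z=0 plane."""
    d = np.linalg.norm((c2 - c1)[:2])
    if d == 0 or d > r1 + r2 or d < abs(r1 - r2):
        return []
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h2 = r1 * r1 - a * a
    if h2 < 0:
        return []
    h = math.sqrt(h2)
    ex = (c2 - c1) / d
    ey = np.array([-ex[1], ex[0], 0.0])
    base = c1 + a * ex
    return [base + h * ey, base - h * ey]


@dataclass(frozen=True)
class _PairState:
    """Canonical form of one state: which oxygens each imino bonds to."""
    label: str
    # (donor_res_slot, acceptor_atom) for direct bonds; slot 0 = residue a
    direct: tuple[tuple[int, str], ...]
    bridge: tuple[int, str] | None   # donor slot + acceptor atom, or None


def _canonicalize_state(state, res_a: int, res_b: int) -> _PairState:
    slot = {res_a: 0, res_b: 1}

    def check(donor: AtomRef, hydrogen: AtomRef, acceptor: AtomRef):
        if donor.residue_number not in slot or \
                acceptor.residue_number not in slot or \
                donor.residue_number == acceptor.residue_number:
            raise ValueError(f"state {state.label!r}: unsupported bond topology")
        if donor.atom_name != "N3" or hydrogen.atom_name != "H3" or \
                acceptor.atom_name not in ("O2", "O4"):
            raise ValueError(
                f"state {state.label!r}: generator supports N3-H3 -> O2/O4 "
                "bonds only")
        return slot[donor.residue_number], acceptor.atom_name

    direct = tuple(check(d, h, a) for d, h, a in state.direct)
    bridge = None
    if state.bridges:
        if len(state.bridges) > 1:
            raise ValueError(
                f"state {state.label!r}: at most one water bridge supported")
        (donor, hydrogen), acceptor = state.bridges[0]
        bridge = check(donor, hydrogen, acceptor)
    if len(direct) + (1 if bridge else 0) != 2:
        raise ValueError(
            f"state {state.label!r}: generator realizes exactly two "
            "inter-residue contacts per state")
    return _PairState(state.label, direct, bridge)


def _place_pair(ps: _PairState, tmpl: dict[str, np.ndarray]
                ) -> tuple[np.ndarray, np.ndarray | None]:
    """Rigidly place residue b so the state's contacts are realized.

    Scans the in-plane orientation of residue b; for each orientation the
    two contact-distance constraints define two circles whose
    intersections give candidate translations. Candidates are scored by
    the smaller donor angle, subject to clash and state-exclusivity
    constraints. Returns (coords of residue b atoms, water oxygen or None).
    """
    contacts = list(ps.direct)
    radii = [_HBOND_LEN] * len(ps.direct)
    if ps.bridge is not None:
        contacts.append(ps.bridge)
        radii.append(_BRIDGE_SPAN)
    assert len(contacts) == 2

    def contact_anchor(slot_atoms_b, which):
        (dslot, acc) = contacts[which]
        if dslot == 0:   # residue a donates to an oxygen of residue b
            return tmpl["N3"], slot_atoms_b[acc]
        return slot_atoms_b["N3"], tmpl[acc]

    best = None
    a_pts = np.array([tmpl[n] for n in _TEMPLATE_ATOMS])
    # The partner may face the first residue either way; flipping is the
    # 180-degree rotation about an in-plane axis (still a proper rigid
    # motion of the planar residue).
    flip = np.diag([1.0, -1.0, 1.0])
    orientations = [(theta, use_flip)
                    for use_flip in (False, True)
                    for theta in np.linspace(0.0, 2 * math.pi, 720,
                                             endpoint=False)]
    for theta, use_flip in orientations:
        rot = _rot2(theta)
        if use_flip:
            rot = rot @ flip
        rb = {n: rot @ tmpl[n] for n in _TEMPLATE_ATOMS}
        # circle centers for the translation t of residue b
        centers = []
        for (dslot, acc) in contacts:
            if dslot == 0:
                centers.append(tmpl["N3"] - rb[acc])
            else:
                centers.append(tmpl[acc] - rb["N3"])
        for t in _circle_intersections(centers[0], radii[0],
                                       centers[1], radii[1]):
            b = {n: rb[n] + t for n in _TEMPLATE_ATOMS}
            score = _score_placement(ps, tmpl, b, a_pts)
            if score is not None and (best is None or score > best[0]):
                best = (score, b)
    if best is None:
        raise ValueError(
            f"state {ps.label!r} is not geometrically realizable by the "
            "generator templates")
    b = best[1]
    water = None
    if ps.bridge is not None:
        dslot, acc = ps.bridge
        donor = tmpl["N3"] if dslot == 0 else b["N3"]
        hydrogen = tmpl["H3"] if dslot == 0 else b["H3"]
        target = b[acc] if dslot == 0 else tmpl[acc]
        placed = _best_water(donor, hydrogen, target)
        if placed is None:
            raise ValueError(
                f"state {ps.label!r}: no bridging-water position satisfies "
                "both legs")
        water = placed[0]
    return np.array([b[n] for n in _TEMPLATE_ATOMS]), water


def _best_water(donor: np.ndarray, hydrogen: np.ndarray,
                target: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Water-oxygen position accepting from (donor, hydrogen) and within
    donating range of target; swung off the donor-target axis (in-plane)
    to maximize the donor-leg D-H-A angle. Returns (position, angle)."""
    axis = target - donor
    axis = axis / np.linalg.norm(axis)
    best = None
    # joint noise margin: ~4 deg of angle jitter trades against ~0.07 Å of
    # distance jitter for Å-scale coordinate noise, so both margins are
    # expressed in those units and the worst one is maximized
    for alpha in np.linspace(-math.pi / 4, math.pi / 4, 121):
        u = _rot2(alpha) @ axis
        ow = donor + _HBOND_LEN * u
        dist = np.linalg.norm(ow - target)
        if dist >= 3.5:
            continue
        ang = _angle(donor, hydrogen, ow)
        margin = min((ang - 120.0) / 4.0, (3.5 - dist) / 0.07)
        if best is None or margin > best[2]:
            best = (ow, ang, margin)
    if best is None or best[2] <= 1.5:
        return None
    return best[0], best[1]


def _score_placement(ps: _PairState, tmpl, b, a_pts) -> float | None:
    # donor D-H-A angles (apex at the hydrogen) for the realized contacts
    angles = []
    for (dslot, acc) in ps.direct:
        if dslot == 0:
            angles.append(_angle(tmpl["N3"], tmpl["H3"], b[acc]))
        else:
            angles.append(_angle(b["N3"], b["H3"], tmpl[acc]))
    if ps.bridge is not None:
        dslot, acc = ps.bridge
        donor = tmpl["N3"] if dslot == 0 else b["N3"]
        hydrogen = tmpl["H3"] if dslot == 0 else b["H3"]
        target = b[acc] if dslot == 0 else tmpl[acc]
        placed = _best_water(donor, hydrogen, target)
        if placed is None:
            return None
        angles.append(placed[1])
    if min(angles) < 125.0:
        return None
    # exclusivity: every imino-oxygen pairing not required by this state
    # stays beyond the exclusion distance
    required = set(ps.direct) | ({ps.bridge} if ps.bridge else set())
    for dslot in (0, 1):
        for acc in ("O2", "O4"):
            if (dslot, acc) in required:
                continue
            n3 = tmpl["N3"] if dslot == 0 else b["N3"]
            oxy = b[acc] if dslot == 0 else tmpl[acc]
            if np.linalg.norm(n3 - oxy) < _EXCLUDE:
                return None
    # no steric clash between the residues (floor below the ~1.9 Å
    # hydrogen-acceptor distance of a near-linear 2.9 Å H-bond)
    b_pts = np.array([b[n] for n in _TEMPLATE_ATOMS])
    dmin = np.linalg.norm(a_pts[:, None, :] - b_pts[None, :, :], axis=2).min()
    if dmin < 1.75:
        return None
    return min(angles)


@lru_cache(maxsize=8)
def _scheme_templates(scheme: StateScheme) -> tuple[AtomTable, dict[str, np.ndarray]]:
    """Atom table + per-state coordinate templates for a two-residue scheme."""
    resnums = sorted({ref.residue_number
                      for st in scheme.states
                      for d, h, a in st.direct
                      for ref in (d, h, a)} |
                     {ref.residue_number
                      for st in scheme.states
                      for (dh, acc) in st.bridges
                      for ref in (dh[0], dh[1], acc)})
    if len(resnums) != 2:
        raise ValueError("generator supports two-residue schemes")
    res_a, res_b = resnums
    tmpl = _residue_template()
    water_num = 9001
    park = np.array([50.0, 50.0, 50.0])

    nums, names, anames = [], [], []
    for resnum in (res_a, res_b):
        for aname in _TEMPLATE_ATOMS:
            nums.append(resnum)
            names.append("U")
            anames.append(aname)
    for aname in ("O", "H1", "H2"):
        nums.append(water_num)
        names.append("HOH")
        anames.append(aname)
    table = AtomTable(nums, names, anames)

    a_coords = np.array([tmpl[n] for n in _TEMPLATE_ATOMS])
    templates: dict[str, np.ndarray] = {}
    for state in scheme.states:
        ps = _canonicalize_state(state, res_a, res_b)
        b_coords, water_o = _place_pair(ps, tmpl)
        if water_o is None:
            wat = np.array([park, park + [0.8, 0.5, 0.0],
                            park + [-0.6, 0.7, 0.0]])
        else:
            # orient one O-H toward the bridge acceptor so the water donates
            dslot, acc = ps.bridge
            target = dict(zip(_TEMPLATE_ATOMS, b_coords))[acc] if dslot == 0 \
                else tmpl[acc]
            u = (target - water_o) / np.linalg.norm(target - water_o)
            perp = np.array([-u[1], u[0], 0.0])
            h1 = water_o + _WATER_OH * u
            h2 = water_o + _WATER_OH * (-0.5 * u + 0.87 * perp)
            wat = np.array([water_o, h1, h2])
        templates[state.label] = np.vstack([a_coords, b_coords, wat])
    return table, templates


# ---------------------------------------------------------------------------
# Conformer ensemble generator
# ---------------------------------------------------------------------------

@dataclass
class ConformerSimSpec:
    """Markov-switching conformer ensemble specification.

    ``transition`` is a row-stochastic per-frame matrix over the scheme's
    state labels (order = scheme label order). ``sigma`` is isotropic
    Gaussian coordinate noise in Å.
    """

    scheme: StateScheme | str
    transition: np.ndarray
    n_frames: int
    dt: float = 10.0
    sigma: float = 0.05
    seed: int = 0
    start_state: str | None = None

    def __post_init__(self):
        if isinstance(self.scheme, str):
            self.scheme = builtin_schemes()[self.scheme]
        p = np.asarray(self.transition, dtype=float)
        k = len(self.scheme.labels)
        if p.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k} "
                             f"for scheme {self.scheme.name}")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if (p < 0).any():
            raise ValueError("transition probabilities must be nonnegative")
        if self.sigma < 0:
            raise ValueError("coordinate noise sigma must be nonnegative")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        self.transition = p


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    p = np.asarray(transition, dtype=float)
    w, v = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _sample_markov(transition: np.ndarray, n: int, rng: np.random.Generator,
                   start: int | None = None) -> np.ndarray:
    cum = np.cumsum(transition, axis=1)
    states = np.empty(n, dtype=int)
    if start is None:
        pi = stationary_distribution(transition)
        states[0] = int(np.searchsorted(np.cumsum(pi), rng.random()))
    else:
        states[0] = start
    u = rng.random(n)
    for i in range(1, n):
        states[i] = int(np.searchsorted(cum[states[i - 1]], u[i]))
    return states


def gen_conformer_ensemble(spec: ConformerSimSpec) -> tuple[Ensemble, list[str]]:
    """Generate a Markov-switching conformer ensemble.

    Returns the ensemble and the true per-frame state labels. With
    ``sigma = 0`` the classifier recovers the true labels exactly
    (verified once per scheme at template-construction time).
    """
    scheme: StateScheme = spec.scheme
    table, templates = _scheme_templates(scheme)
    _verify_templates(scheme, table, templates)
    rng = np.random.default_rng(spec.seed)
    start = None
    if spec.start_state is not None:
        start = scheme.labels.index(spec.start_state)
    seq = _sample_markov(spec.transition, spec.n_frames, rng, start)
    stack = np.stack([templates[lab] for lab in scheme.labels])
    coords = stack[seq].astype(float)
    if spec.sigma > 0:
        coords = coords + rng.normal(0.0, spec.sigma, size=coords.shape)
    ens = Ensemble(table, coords, dt=spec.dt,
                   label=f"synthetic-{scheme.name}")
    return ens, [scheme.labels[i] for i in seq]


@lru_cache(maxsize=8)
def _verified(scheme: StateScheme) -> bool:
    table, templates = _scheme_templates(scheme)
    from uturn.model_io import StructureFrame
    for label, coords in templates.items():
        got = classify_frame(StructureFrame(table, coords), scheme,
                             HBondCriteria())
        if got != label:
            raise ValueError(
                f"state {label!r} template classifies as {got!r}; "
                "state definition not realizable")
    return True


def _verify_templates(scheme, table, templates):
    _verified(scheme)


# ---------------------------------------------------------------------------
# Ion trajectory generator
# ---------------------------------------------------------------------------

@dataclass
class IonSimSpec:
    """Two-state (site-bound vs bulk) cation trajectory specification.

    Dwell times are geometric (discrete-time memoryless): bound dwells
    have mean ``mean_residence_ps``; unbound dwells are derived from the
    prescribed bound fraction ``p``.
    """

    p: float                     # stationary bound fraction
    mean_residence_ps: float
    dt: float = 10.0
    n_frames: int = 1000
    bound_sigma: float = 0.15    # Å scatter around the contact position;
    # kept small enough (>3 sigma inside a 3.4 Å inner shell from the
    # 2.8 Å contact distance) that shell-crossing noise does not
    # fragment bound episodes
    contact_distance: float = 2.8  # Å mean ion-primary-atom distance
    box_size: float = 40.0       # Å cubic box edge for bulk placement
    exclusion: float = 6.0       # Å bulk positions stay beyond this radius
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("bound fraction must lie in [0, 1]")
        if self.mean_residence_ps < self.dt:
            raise ValueError("mean residence must be at least one frame (dt)")
        if self.box_size <= 2 * self.exclusion:
            raise ValueError("box too small for the bulk exclusion radius")


@dataclass
class IonTrack:
    coords: np.ndarray   # (n_frames, 3) ion position, Å
    bound: np.ndarray    # (n_frames,) bool
    dt: float


def gen_ion_trajectory(spec: IonSimSpec,
                       site_position=(0.0, 0.0, 0.0)) -> IonTrack:
    """Alternating bound/bulk ion track around a site position."""
    rng = np.random.default_rng(spec.seed)
    site = np.asarray(site_position, dtype=float)
    n = spec.n_frames
    m_bound = spec.mean_residence_ps / spec.dt
    if spec.p >= 1.0:
        if np.isfinite(spec.mean_residence_ps):
            warnings.warn("bound fraction 1 with finite mean residence: the "
                          "trajectory is a single uninterrupted episode",
                          stacklevel=2)
        bound = np.ones(n, dtype=bool)
    elif spec.p <= 0.0:
        bound = np.zeros(n, dtype=bool)
    else:
        m_unbound = m_bound * (1.0 - spec.p) / spec.p
        exit_b = min(1.0, 1.0 / m_bound)
        exit_u = min(1.0, 1.0 / m_unbound)
        bound = np.empty(n, dtype=bool)
        state = rng.random() < spec.p
        u = rng.random(n)
        for i in range(n):
            bound[i] = state
            if state and u[i] < exit_b:
                state = False
            elif not state and u[i] < exit_u:
                state = True
    coords = np.empty((n, 3))
    nb = int(bound.sum())
    if nb:
        directions = rng.normal(size=(nb, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        coords[bound] = site + spec.contact_distance * directions + \
            rng.normal(0.0, spec.bound_sigma, size=(nb, 3))
    nu = n - nb
    if nu:
        pts = np.empty((nu, 3))
        need = np.ones(nu, dtype=bool)
        while need.any():
            k = int(need.sum())
            cand = site + rng.uniform(-spec.box_size / 2, spec.box_size / 2,
                                      size=(k, 3))
            ok = np.linalg.norm(cand - site, axis=1) > spec.exclusion
            rows = np.nonzero(need)[0][ok]
            pts[rows] = cand[ok]
            need[rows] = False
        coords[~bound] = pts
    return IonTrack(coords, bound, spec.dt)


def gen_ion_ensemble(spec: IonSimSpec, site_position=(0.0, 0.0, 0.0),
                     species: str = "K") -> tuple[Ensemble, np.ndarray]:
    """Minimal ensemble realizing an ion track: one site atom + one ion.

    The primary coordinating atom is modelled as the O4 of a uridine
    numbered 14, fixed at ``site_position``; the cation is a single-atom
    residue of the requested species.
    """
    track = gen_ion_trajectory(spec, site_position)
    table = AtomTable([14, 9000], ["U", species], ["O4", species],
                      ["O", species])
    coords = np.empty((spec.n_frames, 2, 3))
    coords[:, 0, :] = np.asarray(site_position, dtype=float)
    coords[:, 1, :] = track.coords
    ens = Ensemble(table, coords, dt=spec.dt, label="synthetic-ion-site")
    return ens, track.bound


# ---------------------------------------------------------------------------
# NMR observable generators
# ---------------------------------------------------------------------------

def gen_titration(model: str, kd: float, ddelta_max: float,
                  concentrations, sigma: float = 0.0,
                  seed: int = 0, nucleus: str = "") -> TitrationSeries:
    """Exact isotherm curve plus Gaussian shift noise (ppm), seeded."""
    from uturn.nmr_models import _isotherm

    c = np.asarray(concentrations, dtype=float)
    d = _isotherm(model)(c, kd, ddelta_max)
    if sigma > 0:
        d = d + np.random.default_rng(seed).normal(0.0, sigma, size=c.shape)
    return TitrationSeries(c.tolist(), d.tolist(), nucleus, model)


def gen_ct_series(j: float, delays, sigma: float = 0.0, replicates: int = 2,
                  seed: int = 0) -> list[CTIntensitySeries]:
    """cos(pi J tau) intensity ratios with noise, one series per replicate."""
    tau = np.asarray(delays, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(replicates):
        r = np.cos(np.pi * j * tau)
        if sigma > 0:
            r = r + rng.normal(0.0, sigma, size=tau.shape)
        out.append(CTIntensitySeries(tau.tolist(), r.tolist(),
                                     replicate=str(rep + 1), clip=True))
    return out
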