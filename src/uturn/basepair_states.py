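"""Conformer classification for cWW U/U base pairs.

A cis Watson-Crick U/U pair can realize two isosteric two-H-bond
arrangements (labelled 2a and 2b) that differ in which carbonyl oxygen
(O4 or O2) each imino group contacts, plus variants (1a and 1b) where
the H-bond involving the O2 atom is water-mediated instead of direct.
In the neomycin-sensing riboswitch, the loop-closing U13/U18 pair is
sterically restricted to 2a and 1a, while the helix pair U10/U21 can in
principle access all four arrangements.

Frames are labelled by the highest-priority state whose required direct
H-bonds are all satisfied and whose water bridges are all present; a
frame meeting a two-direct-bond state is assigned to it even if a
bridging water also happens to qualify (direct beats mediated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from uturn.model_io import AtomRef, Ensemble, StructureFrame
from uturn.geometry import HBondCriteria, detect_hbond, detect_water_bridge, \
    hbond_series, _angle_deg

__all__ = ["StateDefinition", "StateScheme", "StateTrace", "builtin_schemes",
           "classify_frame", "trace_populations", "UNASSIGNED"]

UNASSIGNED = "unassigned"

# (donor heavy atom, donor hydrogen, acceptor)
HBondTriple = tuple[AtomRef, AtomRef, AtomRef]
# ((donor heavy atom, donor hydrogen), acceptor)
BridgePair = tuple[tuple[AtomRef, AtomRef], AtomRef]


@dataclass(frozen=True)
class StateDefinition:
    """One conformer: required direct H-bonds plus required water bridges."""

    label: str
    direct: tuple[HBondTriple, ...]
    bridges: tuple[BridgePair, ...] = ()

    def __post_init__(self):
        if not self.direct and not self.bridges:
            raise ValueError(f"state {self.label!r} has no requirements")


@dataclass(frozen=True)
class StateScheme:
    """Ordered conformer states for one base pair.

    Priority: states with more direct H-bonds are evaluated first; ties
    follow list order (so 2a precedes 2b).
    """

    name: str
    states: tuple[StateDefinition, ...]

    def __post_init__(self):
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique within a scheme")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def by_priority(self) -> list[StateDefinition]:
        order = sorted(range(len(self.states)),
                       key=lambda i: (-len(self.states[i].direct), i))
        return [self.states[i] for i in order]


def _imino(res: int) -> tuple[AtomRef, AtomRef]:
    return AtomRef(res, "N3"), AtomRef(res, "H3")


def _uu_scheme(name: str, res_a: int, res_b: int, mirror: bool) -> StateScheme:
    """Build a cWW U/U scheme for residues (res_a < res_b).

    2a: a(N3-H3) -> b(O4) and b(N3-H3) -> a(O2);
    1a: the a(O2) contact becomes water-mediated.
    With ``mirror`` the O2/O4-swapped states 2b/1b are added.
    """
    n3a, h3a = _imino(res_a)
    n3b, h3b = _imino(res_b)

    def pair_states(suffix: str, o_to_b: str, o_to_a: str
                    ) -> tuple[StateDefinition, StateDefinition]:
        direct2 = ((n3a, h3a, AtomRef(res_b, o_to_b)),
                   (n3b, h3b, AtomRef(res_a, o_to_a)))
        # the H-bond involving the O2 atom is the one that becomes
        # water-mediated in the single-direct-bond variant
        if o_to_a == "O2":
            keep, bridge = direct2[0], ((n3b, h3b), AtomRef(res_a, "O2"))
        else:
            keep, bridge = direct2[1], ((n3a, h3a), AtomRef(res_b, "O2"))
        two = StateDefinition("2" + suffix, direct2)
        one = StateDefinition("1" + suffix, (keep,), (bridge,))
        return two, one

    two_a, one_a = pair_states("a", "O4", "O2")
    states = [two_a]
    if mirror:
        two_b, one_b = pair_states("b", "O2", "O4")
        states += [two_b, one_a, one_b]
    else:
        states += [one_a]
    return StateScheme(name, tuple(states))


def builtin_schemes() -> dict[str, StateScheme]:
    """The two U/U pair schemes of the neomycin-sensing riboswitch.

    ``U13U18``: the loop-closing pair; only the 2a arrangement
    (U13 N3->U18 O4 plus U18 N3->U13 O2) and its water-mediated variant
    1a are sterically accessible.
    ``U10U21``: the helix pair, with both symmetry-related two-bond
    arrangements (2a, 2b) and both water-mediated variants (1a, 1b).
    """
    return {
        "U13U18": _uu_scheme("U13U18", 13, 18, mirror=False),
        "U10U21": _uu_scheme("U10U21", 10, 21, mirror=True),
    }


def _state_met(frame: StructureFrame, state: StateDefinition,
               criteria: HBondCriteria) -> bool:
    for donor, hydrogen, acceptor in state.direct:
        if not detect_hbond(frame, donor, hydrogen, acceptor, criteria).satisfied:
            return False
    for partner_a, partner_b in state.bridges:
        if detect_water_bridge(frame, partner_a, partner_b, criteria) is None:
            return False
    return True


def classify_frame(frame: StructureFrame, scheme: StateScheme,
                   criteria: HBondCriteria = HBondCriteria()) -> str:
    """Label one frame, or ``"unassigned"`` if no state's requirements hold."""
    for state in scheme.by_priority():
        if _state_met(frame, state, criteria):
            return state.label
    return UNASSIGNED


@dataclass
class StateTrace:
    """Per-frame labels with populations and first-order transition counts."""

    scheme: str
    labels: list[str]                     # per frame, includes "unassigned"
    fractions: dict[str, float]           # over all frames (sums to 1)
    assigned_fractions: dict[str, float]  # renormalized over assigned frames
    unassigned_fraction: float
    transition_counts: "np.ndarray"       # (n_labels+1)^2, order labels+[unassigned]
    transition_labels: list[str]
    water_states_available: bool


def _bridge_series(ensemble: Ensemble, partner_a, partner_b,
                   criteria: HBondCriteria) -> np.ndarray:
    """Vectorized per-frame presence of a qualifying bridging water."""
    table = ensemble.atoms
    donor, hydrogen = partner_a
    d = ensemble.positions(donor)
    h = ensemble.positions(hydrogen)
    b = ensemble.positions(partner_b)
    found = np.zeros(ensemble.n_frames, dtype=bool)
    for wnum in sorted(table.water_residues()):
        rows = table.residue_atom_indices(wnum)
        o_rows = [r for r in rows if table.elements[r] == "O"]
        h_rows = [r for r in rows if table.elements[r] == "H"]
        if not o_rows:
            continue
        ow = ensemble.coords[:, o_rows[0], :]
        leg1 = (np.linalg.norm(ow - d, axis=1) < criteria.d_max) & \
            (_angles(d, h, ow) > criteria.angle_min)
        leg2_dist = np.linalg.norm(b - ow, axis=1) < criteria.d_max
        leg2 = np.zeros_like(leg1)
        for hr in h_rows:
            hw = ensemble.coords[:, hr, :]
            leg2 |= _angles(ow, hw, b) > criteria.angle_min
        found |= leg1 & leg2_dist & leg2
        if found.all():
            break
    return found


def _angles(a: np.ndarray, apex: np.ndarray, b: np.ndarray) -> np.ndarray:
    u = a - apex
    v = b - apex
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    denom = np.where(nu * nv == 0, 1.0, nu * nv)
    c = np.clip(np.einsum("ij,ij->i", u, v) / denom, -1.0, 1.0)
    return np.degrees(np.arccos(c))


def trace_populations(ensemble: Ensemble, scheme: StateScheme,
                      criteria: HBondCriteria = HBondCriteria()) -> StateTrace:
    """Classify every frame and tabulate populations and transitions.

    Populations over all frames (with the unassigned fraction reported
    separately) and renormalized over assigned frames are both returned;
    published population tables typically use the latter. When the
    ensemble carries no explicit waters, water-mediated states are
    structurally unobservable; this is flagged via
    ``water_states_available`` rather than reported as population zero.
    """
    if ensemble.n_frames < 1:
        raise ValueError("need at least one frame")
    n = ensemble.n_frames
    has_waters = bool(ensemble.atoms.water_residues())
    # vectorized satisfaction per state
    met = {}
    for state in scheme.states:
        ok = np.ones(n, dtype=bool)
        for donor, hydrogen, acceptor in state.direct:
            ok &= hbond_series(ensemble, donor, hydrogen, acceptor, criteria)[2]
            if not ok.any():
                break
        if ok.any():
            for partner_a, partner_b in state.bridges:
                if not has_waters:
                    ok[:] = False
                    break
                ok &= _bridge_series(ensemble, partner_a, partner_b, criteria)
        met[state.label] = ok
    labels_arr = np.full(n, UNASSIGNED, dtype=object)
    for state in reversed(scheme.by_priority()):
        labels_arr[met[state.label]] = state.label
    labels = list(labels_arr)

    all_labels = scheme.labels + [UNASSIGNED]
    counts = {lab: 0 for lab in all_labels}
    for lab in labels:
        counts[lab] += 1
    fractions = {lab: counts[lab] / n for lab in all_labels}
    n_assigned = n - counts[UNASSIGNED]
    assigned_fractions = {
        lab: (counts[lab] / n_assigned if n_assigned else float("nan"))
        for lab in scheme.labels}
    idx = {lab: i for i, lab in enumerate(all_labels)}
    tmat = np.zeros((len(all_labels), len(all_labels)), dtype=int)
    for a, b in zip(labels[:-1], labels[1:]):
        tmat[idx[a], idx[b]] += 1
    return StateTrace(scheme.name, labels, fractions, assigned_fractions,
                      fractions[UNASSIGNED], tmat, all_labels, has_waters)
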