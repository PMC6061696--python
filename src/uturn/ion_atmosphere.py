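"""Cation-atmosphere analysis: RDFs, site occupancy, residence, densities.

A binding site is keyed to one primary coordinating atom (e.g. the O4
carbonyl of the conserved U-turn uridine): a frame counts as occupied
when any ion of the site's species sits within the inner-shell cutoff
of that atom. Auxiliary atoms are descriptive — the nearest bound ion
is classified per frame as inner-shell (direct contact), outer-shell
(solvent-separated distance range) or absent. Residence episodes are
maximal runs of occupied frames, with an optional gap tolerance that
absorbs short unbound interruptions.

Ensembles are assumed imaged/whole; periodic boundaries are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from uturn.model_io import AtomRef, Ensemble

__all__ = ["IonSite", "RDFProfile", "ResidenceEpisode", "ResidenceSummary",
           "DensityRegion", "compute_rdf", "site_occupancy",
           "residence_statistics", "density_maxima", "SiteOccupancy"]


@dataclass(frozen=True)
class IonSite:
    """A cation-binding site keyed to one primary coordinating atom."""

    site_id: str
    primary: AtomRef
    auxiliary: tuple[AtomRef, ...] = ()
    inner_cutoff: float = 3.4   # Å; direct (inner-shell) contact
    outer_cutoff: float = 6.0   # Å; solvent-separated (outer-shell) range
    species: str = "K"

    def __post_init__(self):
        if not (0 < self.inner_cutoff < self.outer_cutoff):
            raise ValueError("need 0 < inner cutoff < outer cutoff")


@dataclass
class RDFProfile:
    bin_centers: np.ndarray
    g: np.ndarray
    bin_width: float
    bulk_density: float   # mean ion number density over the analysis sphere
    counts: np.ndarray    # raw pair counts per bin, summed over frames
    n_frames: int

    def __post_init__(self):
        if (self.g < 0).any():
            raise ValueError("g(r) must be nonnegative")


def compute_rdf(ensemble: Ensemble, species: str, reference: AtomRef,
                r_max: float = 10.0, bin_width: float = 0.1) -> RDFProfile:
    """Normalized radial distribution of ion-reference pair distances.

    g(r) is the observed shell count divided by the count expected for
    the same mean number of ions spread uniformly over the analysis
    sphere of radius ``r_max`` around the reference atom, so an
    ideal-gas ion cloud gives g -> 1.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    rows = ensemble.atoms.ion_indices(species)
    if len(rows) == 0:
        raise ValueError(f"ensemble contains no {species} ions")
    ref = ensemble.positions(reference)                  # (F, 3)
    ions = ensemble.coords[:, rows, :]                   # (F, I, 3)
    dist = np.linalg.norm(ions - ref[:, None, :], axis=2).ravel()
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, edges = np.histogram(dist, bins=edges)
    inside = float((dist <= r_max).sum()) / ensemble.n_frames  # mean ions in sphere
    sphere_vol = 4.0 / 3.0 * np.pi * r_max ** 3
    rho = inside / sphere_vol
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = rho * shell_vol * ensemble.n_frames
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFProfile(centers, g, bin_width, rho, counts, ensemble.n_frames)


@dataclass
class SiteOccupancy:
    site: IonSite
    occupied: np.ndarray            # bool per frame
    occupancy: float                # fraction of occupied frames
    aux_labels: dict[str, np.ndarray]   # per aux atom: 'inner'/'outer'/'none'
    aux_fractions: dict[str, dict[str, float]]


def site_occupancy(ensemble: Ensemble, site: IonSite) -> SiteOccupancy:
    """Per-frame occupancy of a site plus auxiliary-atom shell labels."""
    rows = ensemble.atoms.ion_indices(site.species)
    n = ensemble.n_frames
    primary = ensemble.positions(site.primary)
    if len(rows) == 0:
        occupied = np.zeros(n, dtype=bool)
        dist_primary = np.full((n, 0), np.inf)
    else:
        ions = ensemble.coords[:, rows, :]
        dist_primary = np.linalg.norm(ions - primary[:, None, :], axis=2)
        occupied = (dist_primary < site.inner_cutoff).any(axis=1)
    aux_labels: dict[str, np.ndarray] = {}
    aux_fractions: dict[str, dict[str, float]] = {}
    for aux in site.auxiliary:
        labels = np.full(n, "none", dtype=object)
        if len(rows):
            bound_mask = dist_primary < site.inner_cutoff       # (F, I)
            aux_pos = ensemble.positions(aux)
            dist_aux = np.linalg.norm(
                ensemble.coords[:, rows, :] - aux_pos[:, None, :], axis=2)
            dist_aux = np.where(bound_mask, dist_aux, np.inf)
            nearest = dist_aux.min(axis=1)
            labels[nearest < site.outer_cutoff] = "outer"
            labels[nearest < site.inner_cutoff] = "inner"
        key = str(aux)
        aux_labels[key] = labels
        aux_fractions[key] = {lab: float((labels == lab).mean())
                              for lab in ("inner", "outer", "none")}
    return SiteOccupancy(site, occupied, float(occupied.mean()),
                         aux_labels, aux_fractions)


@dataclass(frozen=True)
class ResidenceEpisode:
    start: int      # first occupied frame (inclusive)
    end: int        # last occupied frame (inclusive)
    duration: float  # ps, (end - start + 1) * dt


@dataclass
class ResidenceSummary:
    episodes: list[ResidenceEpisode]
    mean_duration: float    # ps; nan when no episodes
    max_duration: float     # ps; nan when no episodes
    dt: float
    tolerance: int


def residence_statistics(occupied: np.ndarray, dt: float,
                         tolerance: int = 0) -> ResidenceSummary:
    """Episode statistics of a boolean occupancy trace.

    Maximal runs of occupied frames form episodes; unoccupied gaps of at
    most ``tolerance`` frames between two episodes are absorbed into a
    single episode (default 0 = strict).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    occ = np.asarray(occupied, dtype=bool)
    runs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(occ):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(occ) - 1))
    if tolerance > 0 and runs:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe - 1 <= tolerance:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged
    episodes = [ResidenceEpisode(s, e, (e - s + 1) * dt) for s, e in runs]
    durations = [ep.duration for ep in episodes]
    mean_d = float(np.mean(durations)) if durations else float("nan")
    max_d = float(np.max(durations)) if durations else float("nan")
    return ResidenceSummary(episodes, mean_d, max_d, dt, tolerance)


@dataclass
class DensityRegion:
    centroid: np.ndarray     # occupancy-weighted center of the merged cells, Å
    occupancy: float         # ion observations in the region / n_frames
    peak_count: int          # raw count of the peak cell


def density_maxima(ensemble: Ensemble, species: str, spacing: float = 0.5,
                   k: int = 5, merge_radius: float = 2.0
                   ) -> list[DensityRegion]:
    """Top-k ion density regions on a grid over an aligned ensemble.

    Ion positions from all frames are binned on a cubic grid; occupied
    cells are merged greedily (descending count) into regions whose
    peaks are at least ``merge_radius`` Å apart; each region's centroid
    is the count-weighted mean of its cells. The ensemble must have been
    superposed first (``Ensemble.aligned``), otherwise densities smear.
    """
    if not ensemble.aligned:
        raise ValueError(
            "ensemble is not aligned; run geometry.superpose_and_rmsd first "
            "and pass the aligned ensemble")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    rows = ensemble.atoms.ion_indices(species)
    if len(rows) == 0:
        raise ValueError(f"ensemble contains no {species} ions")
    pts = ensemble.coords[:, rows, :].reshape(-1, 3)
    origin = pts.min(axis=0) - spacing
    idx = np.floor((pts - origin) / spacing).astype(int)
    cells: dict[tuple[int, int, int], int] = {}
    for key in map(tuple, idx):
        cells[key] = cells.get(key, 0) + 1
    ordered = sorted(cells.items(), key=lambda kv: (-kv[1], kv[0]))
    centers = {key: origin + (np.asarray(key) + 0.5) * spacing
               for key, _ in ordered}
    regions: list[dict] = []
    for key, count in ordered:
        c = centers[key]
        placed = False
        for reg in regions:
            if np.linalg.norm(c - reg["peak"]) <= merge_radius:
                reg["weight"] += count
                reg["moment"] += count * c
                placed = True
                break
        if not placed:
            regions.append({"peak": c, "weight": count,
                            "moment": count * c.astype(float),
                            "peak_count": count})
    regions.sort(key=lambda r: -r["weight"])
    out = []
    for reg in regions[:k]:
        out.append(DensityRegion(reg["moment"] / reg["weight"],
                                 reg["weight"] / ensemble.n_frames,
                                 reg["peak_count"]))
    return out
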