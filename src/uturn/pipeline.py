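"""End-to-end analysis runs from a structured config file.

A run config is a flat TOML file; every section beyond ``[run]`` and
``[ensemble]`` is optional and enables one analysis section. The report
bundle contains ``report.json`` (deterministic: sorted keys, no
timestamps), per-section CSV tables (each with a header row and a units
row) and ``run.log`` recording package version, config hash and seeds.

Example config::

    [run]
    output_dir = "out"
    seed = 1

    [ensemble]
    path = "ensemble.pdb"       # or: synthetic_scheme = "U13U18", ...
    dt = 10.0                   # ps, optional

    [criteria]
    d_max = 3.5
    angle_min = 120.0

    [states]
    schemes = ["U13U18", "U10U21"]

    [planes]
    pairs = [[14, "16:OP2"], [16, "18:O4'"]]

    [noe]
    restraints = "restraints.tsv"
    threshold = 0.3

    [ions]
    species = "K"
    primary = "14:O4"
    auxiliary = ["13:O4", "17:OP2", "18:O4"]

    [rmsd]
    enabled = true
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import uturn
from uturn.model_io import AtomRef, Ensemble, read_ensemble, read_noe_table
from uturn.geometry import (HBondCriteria, plane_atom_distance_series,
                            superpose_and_rmsd)
from uturn.basepair_states import builtin_schemes, trace_populations
from uturn.noe_validation import count_violations
from uturn.ion_atmosphere import IonSite, residence_statistics, site_occupancy
from uturn.synthetic_data import ConformerSimSpec, gen_conformer_ensemble

__all__ = ["RunConfig", "run_analysis", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run config is missing required fields."""


@dataclass
class RunConfig:
    raw: dict
    path: Path | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            return cls(tomllib.load(fh), path)

    def validate(self) -> None:
        missing = []
        run = self.raw.get("run", {})
        if "output_dir" not in run:
            missing.append("run.output_dir")
        ens = self.raw.get("ensemble", {})
        if not ens:
            missing.append("ensemble (section)")
        elif "path" not in ens and "synthetic_scheme" not in ens:
            missing.append("ensemble.path or ensemble.synthetic_scheme")
        if "path" in ens:
            base = self.path.parent if self.path else Path(".")
            if not (base / ens["path"]).exists():
                missing.append(f"ensemble.path (file {ens['path']} not found)")
        noe = self.raw.get("noe", {})
        if noe and "restraints" not in noe:
            missing.append("noe.restraints")
        if missing:
            raise ConfigError("invalid run config; missing or bad fields: "
                              + ", ".join(missing))

    def _resolve(self, rel: str) -> Path:
        base = self.path.parent if self.path else Path(".")
        return base / rel

    def load_ensemble(self) -> Ensemble:
        ens = self.raw["ensemble"]
        if "path" in ens:
            return read_ensemble(self._resolve(ens["path"]),
                                 format=ens.get("format"),
                                 dt=ens.get("dt"))
        seed = int(self.raw.get("run", {}).get("seed", 0))
        scheme = builtin_schemes()[ens["synthetic_scheme"]]
        k = len(scheme.labels)
        transition = np.asarray(ens.get("transition",
                                        np.full((k, k), 1.0 / k)), dtype=float)
        spec = ConformerSimSpec(scheme, transition,
                                n_frames=int(ens.get("n_frames", 1000)),
                                dt=float(ens.get("dt", 10.0)),
                                sigma=float(ens.get("sigma", 0.05)),
                                seed=seed)
        ensemble, _ = gen_conformer_ensemble(spec)
        return ensemble

    def criteria(self) -> HBondCriteria:
        c = self.raw.get("criteria", {})
        return HBondCriteria(d_max=float(c.get("d_max", 3.5)),
                             angle_min=float(c.get("angle_min", 120.0)))


def _write_csv(path: Path, header: list[str], units: list[str],
               rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        fh.write(",".join(units) + "\n")
        for row in rows:
            fh.write(",".join(str(v) for v in row) + "\n")


def run_analysis(config: RunConfig | str | Path) -> dict:
    """Run every configured analysis section; write the report bundle.

    Section failures are recorded per section in the report under
    ``errors`` and do not abort other sections; the returned report dict
    mirrors ``report.json``.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_toml(config)
    config.validate()
    run = config.raw["run"]
    outdir = (config.path.parent if config.path else Path(".")) / run["output_dir"]
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(run.get("seed", 0))
    criteria = config.criteria()
    cfg_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()).hexdigest()

    report: dict = {
        "package_version": uturn.__version__,
        "config_hash": cfg_hash,
        "seed": seed,
        "criteria": {"d_max_A": criteria.d_max,
                     "angle_min_deg": criteria.angle_min},
        "sections": {},
        "errors": {},
    }
    log_lines = [f"uturn {uturn.__version__}", f"config sha256 {cfg_hash}",
                 f"seed {seed}"]

    ensemble = config.load_ensemble()
    report["ensemble"] = {"label": ensemble.label,
                          "n_frames": ensemble.n_frames,
                          "n_atoms": len(ensemble.atoms),
                          "dt_ps": ensemble.dt}

    def section(name, fn):
        try:
            report["sections"][name] = fn()
            log_lines.append(f"section {name}: ok")
        except Exception as exc:  # recorded, not fatal to other sections
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            log_lines.append(f"section {name}: FAILED ({exc})")

    if "states" in config.raw:
        def _states():
            out = {}
            rows = []
            for name in config.raw["states"].get(
                    "schemes", list(builtin_schemes())):
                scheme = builtin_schemes()[name]
                trace = trace_populations(ensemble, scheme, criteria)
                out[name] = {
                    "fractions_all_frames": trace.fractions,
                    "fractions_assigned": trace.assigned_fractions,
                    "unassigned_fraction": trace.unassigned_fraction,
                    "water_states_available": trace.water_states_available,
                }
                for i, lab in enumerate(trace.labels):
                    if len(rows) <= i:
                        rows.append([i])
                    rows[i].append(lab)
            _write_csv(outdir / "state_labels.csv",
                       ["frame"] + list(config.raw["states"].get(
                           "schemes", list(builtin_schemes()))),
                       ["index"] + ["label"] * (len(rows[0]) - 1 if rows else 0),
                       rows)
            return out
        section("states", _states)

    if "planes" in config.raw:
        def _planes():
            out = {}
            for base, target in config.raw["planes"]["pairs"]:
                series = plane_atom_distance_series(
                    ensemble, int(base), AtomRef.parse(str(target)))
                key = f"base{base}_to_{target}"
                out[key] = {"median_A": series.median, "sd_A": series.sd}
                _write_csv(outdir / f"plane_{base}_{str(target).replace(':', '_').replace(chr(39), 'p')}.csv",
                           ["frame", "distance"], ["index", "A"],
                           [[i, f"{d:.4f}"] for i, d in
                            enumerate(series.distances)])
            return out
        section("planes", _planes)

    if "noe" in config.raw:
        def _noe():
            restraints = read_noe_table(
                config._resolve(config.raw["noe"]["restraints"]))
            rep = count_violations(
                ensemble, restraints,
                threshold=float(config.raw["noe"].get("threshold", 0.3)))
            _write_csv(outdir / "noe_report.csv",
                       ["group_a", "group_b", "upper_bound", "distance",
                        "excess", "violated"],
                       ["res:atom", "res:atom", "A", "A", "A", "bool"],
                       [[";".join(map(str, r.restraint.group_a)),
                         ";".join(map(str, r.restraint.group_b)),
                         r.restraint.upper_bound,
                         f"{r.ensemble_distance:.3f}",
                         f"{r.excess:.3f}", r.violated]
                        for r in rep.results])
            return {"violated": rep.violated_count,
                    "applicable": rep.applicable_count,
                    "summary": rep.summary(),
                    "threshold_A": rep.threshold,
                    "averaging_exponent": rep.exponent,
                    "unresolvable": len(rep.unresolvable)}
        section("noe", _noe)

    if "ions" in config.raw:
        def _ions():
            ion_cfg = config.raw["ions"]
            site = IonSite(
                site_id=ion_cfg.get("site_id", "site1"),
                primary=AtomRef.parse(str(ion_cfg["primary"])),
                auxiliary=tuple(AtomRef.parse(str(a))
                                for a in ion_cfg.get("auxiliary", [])),
                inner_cutoff=float(ion_cfg.get("inner", 3.4)),
                outer_cutoff=float(ion_cfg.get("outer", 6.0)),
                species=ion_cfg.get("species", "K"))
            occ = site_occupancy(ensemble, site)
            out = {"occupancy": occ.occupancy,
                   "aux_shell_fractions": occ.aux_fractions,
                   "inner_cutoff_A": site.inner_cutoff,
                   "outer_cutoff_A": site.outer_cutoff}
            if ensemble.dt is not None:
                res = residence_statistics(
                    occ.occupied, ensemble.dt,
                    tolerance=int(ion_cfg.get("residence_tolerance", 0)))
                out["residence"] = {
                    "n_episodes": len(res.episodes),
                    "mean_ps": res.mean_duration,
                    "max_ps": res.max_duration,
                    "tolerance_frames": res.tolerance}
            return out
        section("ions", _ions)

    if config.raw.get("rmsd", {}).get("enabled", False):
        def _rmsd():
            sup = superpose_and_rmsd(ensemble)
            _write_csv(outdir / "per_residue_rmsd.csv",
                       ["residue", "rmsd"], ["number", "A"],
                       [[num, f"{val:.4f}"]
                        for num, val in sorted(sup.per_residue_rmsd.items())])
            return {"per_residue_rmsd_A": {str(k): v for k, v in
                                           sorted(sup.per_residue_rmsd.items())},
                    "iterations": sup.iterations}
        section("rmsd", _rmsd)

    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2, default=float) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
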