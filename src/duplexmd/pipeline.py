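"""Config-driven full-pipeline runner.

One RunConfig names the inputs, selections, cutoffs and outputs; the
pipeline executes descriptors (RMSD / RMSF / Rg) -> contact census (with
population filter) -> base-pair traces and opening detection -> 2D energy
landscape -> Qb decay and exponential fit, writing one TSV per product plus
a JSON manifest that fully determines reproduction.  Stages are
independently skippable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import (ContactConfig, census_frame, electrostatic_contacts,
                       filter_by_population, hydrogen_bonds, hydrophobic_contacts)
from .duplex import PairMap, basepair_distances, detect_opening
from .geometry import average_structure, rg_series, rmsd_series, rmsf
from .kinetics import fit_exponential, native_contacts, qb_series
from .landscape import basin_summary, energy_landscape
from .output import write_tsv
from .structure_io import Selection, Trajectory, read_pdb, select

logger = logging.getLogger(__name__)

ALL_STAGES = ("descriptors", "contacts", "basepairs", "landscape", "kinetics")


@dataclass
class RunConfig:
    trajectory: str
    dt_ps: float = 10.0
    reference: str | None = None          # native-contact reference (default: frame 1)
    second_trajectory: str | None = None  # apo ensemble for comparisons
    selection: dict = field(default_factory=lambda: {"names": ["C5'"], "molecule_class": "rna"})
    contacts: dict = field(default_factory=dict)
    pairs: list | None = None             # [[chain1, resid1, chain2, resid2], ...]
    antiparallel_chains: list | None = None
    landscape_bins: int = 8
    kinetics: dict = field(default_factory=lambda: {"cutoff": 4.5, "tolerance_factor": 1.2})
    opening: dict = field(default_factory=lambda: {"delta": 3.0, "sustain": 50})
    t_start: float | None = None
    t_end: float | None = None
    outdir: str = "out"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**data)

    def build_selection(self) -> Selection:
        return Selection(**self.selection)

    def build_pair_map(self, traj: Trajectory) -> PairMap:
        if self.pairs:
            return PairMap(tuple(((c1, int(r1)), (c2, int(r2)))
                                 for c1, r1, c2, r2 in self.pairs))
        chains = self.antiparallel_chains or [
            c for c, cls in traj.topology.molecule_class.items() if cls == "rna"]
        if len(chains) != 2:
            raise ValueError(f"cannot infer base pairing from chains {chains}")
        return PairMap.antiparallel(traj.topology, chains[0], chains[1])


def time_window(traj: Trajectory, t_start: float | None, t_end: float | None) -> Trajectory:
    """Restrict a trajectory to frames with t_start <= t <= t_end."""
    if t_start is None and t_end is None:
        return traj
    t = traj.times
    mask = np.ones(traj.n_frames, dtype=bool)
    if t_start is not None:
        mask &= t >= t_start
    if t_end is not None:
        mask &= t <= t_end
    if not mask.any():
        raise ValueError(f"analysis window [{t_start}, {t_end}] contains no frames")
    kept = np.flatnonzero(mask)
    return Trajectory(traj.topology, traj.coords[kept],
                      dt=traj.dt, t0=float(t[kept[0]]))


def _provenance(cfg: RunConfig, **extra) -> dict:
    base = {"duplexmd_version": __version__, "seed": cfg.seed,
            "trajectory": cfg.trajectory}
    base.update(extra)
    return base


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        "stages": {},
        "outputs": {},
    }

    traj = read_pdb(cfg.trajectory, dt=cfg.dt_ps)
    traj = time_window(traj, cfg.t_start, cfg.t_end)
    sel = cfg.build_selection()
    ccfg = ContactConfig(**cfg.contacts)
    second = None
    if cfg.second_trajectory:
        second = time_window(read_pdb(cfg.second_trajectory, dt=cfg.dt_ps),
                             cfg.t_start, cfg.t_end)

    def record(stage: str, status: str, files: dict | None = None, error: str | None = None):
        manifest["stages"][stage] = {"status": status, **({"error": error} if error else {})}
        if files:
            manifest["outputs"].update({k: str(v) for k, v in files.items()})

    rmsd_ds = rg_ds = None

    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            record(stage, "skipped")
            continue
        try:
            if stage == "descriptors":
                mean = average_structure(traj, sel)
                rmsd_ds = rmsd_series(traj, mean, sel, label="rmsd")
                rg_ds = rg_series(traj, sel, label="rg")
                prof = rmsf(traj, sel) if traj.n_frames >= 2 else None
                files = {
                    "rmsd": write_tsv(outdir / "rmsd.tsv",
                                      pd.DataFrame({"time_ps": rmsd_ds.times,
                                                    "rmsd_A": rmsd_ds.values}),
                                      _provenance(cfg, selection=cfg.selection)),
                    "rg": write_tsv(outdir / "rg.tsv",
                                    pd.DataFrame({"time_ps": rg_ds.times,
                                                  "rg_A": rg_ds.values}),
                                    _provenance(cfg, selection=cfg.selection)),
                }
                if prof is not None:
                    files["rmsf"] = write_tsv(
                        outdir / "rmsf.tsv",
                        pd.DataFrame({"chain": [k[0] for k in prof.keys],
                                      "resid": [k[1] for k in prof.keys],
                                      "name": [k[2] for k in prof.keys],
                                      "rmsf_A": prof.values}),
                        _provenance(cfg, selection=cfg.selection))
                record(stage, "ok", files)

            elif stage == "contacts":
                census = (hydrophobic_contacts(traj, ccfg)
                          + electrostatic_contacts(traj, ccfg)
                          + hydrogen_bonds(traj, ccfg))
                kept = filter_by_population(census, ccfg.population_threshold)
                prov = _provenance(cfg, hydrophobic_cutoff=ccfg.hydrophobic_cutoff,
                                   electrostatic_cutoff=ccfg.electrostatic_cutoff,
                                   hbond_da_cutoff=ccfg.hbond_da_cutoff,
                                   population_threshold=ccfg.population_threshold)
                files = {
                    "contacts_all": write_tsv(outdir / "contacts_all.tsv",
                                              census_frame(census), prov),
                    "contacts_filtered": write_tsv(outdir / "contacts_filtered.tsv",
                                                   census_frame(kept), prov),
                }
                record(stage, "ok", files)

            elif stage == "basepairs":
                pmap = cfg.build_pair_map(traj)
                series = basepair_distances(traj, pmap)
                rows = [{"time_ps": t, "pair_index": s.pair_index, "distance_A": d}
                        for s in series for t, d in zip(s.times, s.distances)]
                baseline = [s.distances[0] for s in series]
                report = detect_opening(series, baseline, **cfg.opening)
                op_rows = [{"pair_index": s.pair_index, "opened": o,
                            "opening_time_ps": (t if t is not None else "none"),
                            "threshold_A": thr}
                           for s, o, t, thr in zip(series, report.opened,
                                                   report.opening_times, report.threshold)]
                prov = _provenance(cfg, **cfg.opening,
                                   ordered_from_terminus=report.ordered_from_terminus)
                files = {
                    "basepairs": write_tsv(outdir / "basepairs.tsv",
                                           pd.DataFrame(rows), prov),
                    "opening": write_tsv(outdir / "opening.tsv",
                                         pd.DataFrame(op_rows), prov),
                }
                record(stage, "ok", files)
                manifest["stages"][stage]["ordered_from_terminus"] = report.ordered_from_terminus

            elif stage == "landscape":
                if rmsd_ds is None or rg_ds is None:
                    raise RuntimeError("landscape stage needs the descriptors stage")
                ls = energy_landscape(rmsd_ds, rg_ds, bins_per_axis=cfg.landscape_bins)
                basin = basin_summary(ls)
                rows = []
                for i in range(ls.P.shape[0]):
                    for j in range(ls.P.shape[1]):
                        rows.append({"x_lo": ls.x_edges[i], "x_hi": ls.x_edges[i + 1],
                                     "y_lo": ls.y_edges[j], "y_hi": ls.y_edges[j + 1],
                                     "P": ls.P[i, j], "G": ls.G[i, j]})
                prov = _provenance(cfg, bins=cfg.landscape_bins,
                                   x=ls.x_label, y=ls.y_label,
                                   basin_x=basin.x_ranges, basin_y=basin.y_ranges)
                files = {"landscape": write_tsv(outdir / "landscape.tsv",
                                                pd.DataFrame(rows), prov)}
                record(stage, "ok", files)
                manifest["stages"][stage]["basin"] = {
                    "x_ranges": basin.x_ranges, "y_ranges": basin.y_ranges,
                    "p_basin": basin.p_basin}

            elif stage == "kinetics":
                ref = (read_pdb(cfg.reference, dt=cfg.dt_ps).coords[0]
                       if cfg.reference else traj.coords[0])
                native = native_contacts(traj.topology, ref,
                                         cutoff=cfg.kinetics.get("cutoff", 4.5))
                qb = qb_series(traj, native,
                               tolerance_factor=cfg.kinetics.get("tolerance_factor", 1.2))
                fit = fit_exponential(qb)
                prov = _provenance(cfg, n_native=len(native), **cfg.kinetics)
                files = {"qb": write_tsv(outdir / "qb.tsv",
                                         pd.DataFrame({"time_ps": qb.times, "qb": qb.qb}),
                                         prov)}
                fit_path = outdir / "qb_fit.json"
                fit_path.write_text(json.dumps({
                    "A": fit.A, "tau_ns": fit.tau, "t_half_ns": fit.t_half,
                    "B": fit.B, "rss": fit.rss, "converged": fit.converged,
                    "n_obs": fit.n_obs}, indent=2) + "\n")
                files["qb_fit"] = fit_path
                record(stage, "ok", files)
                manifest["stages"][stage]["tau_ns"] = fit.tau

        except Exception as exc:  # noqa: BLE001 - recorded per stage
            logger.error("stage %s failed: %s", stage, exc)
            record(stage, "failed", error=str(exc))
            manifest_path = outdir / "manifest.json"
            manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
            raise

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
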