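"""End-to-end orchestration: simulate -> kinematics -> gait -> coordination
-> circular stats -> inference, as a configurable, logged, reproducible run.

A :class:`PipelineConfig` either points at existing footfall/swim/marker CSV
tables or embeds a pair of simulation configs (control + silenced).  The
``run`` entry point executes the enabled stages in dependency order, writes
tidy CSV/JSON outputs under the output directory, and records a
:class:`RunManifest` (config hash, per-stage row counts, warnings) before
and after each stage.  Identical config + seed yields byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circstats, coordination, gait_events, inference
from .synthetic import SimulationConfig, simulate_footfalls, simulate_markers

__all__ = ["PipelineConfig", "RunManifest", "run", "report"]

log = logging.getLogger("quadgait")

STAGES = ("simulate", "kinematics", "gait", "coordination", "circstats",
          "stats", "report")


@dataclass
class PipelineConfig:
    outdir: str = "quadgait_out"
    seed: int = 0
    # either input paths ...
    footfall_csv: str | None = None
    swim_csv: str | None = None
    marker_csv: str | None = None
    # ... or simulation configs (dicts of SimulationConfig overrides)
    simulate_control: dict | None = None
    simulate_silenced: dict | None = None
    stages: tuple[str, ...] = STAGES
    # analysis thresholds
    k_sd: float = 2.0
    outlier_k_sd: float = 3.0
    speed_cutoff_cm_s: float = 90.0
    n_permutations: int = 2000
    circular_change: bool = False
    reference_limb: str = "RH"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    started: str = ""
    finished: str = ""
    stages: dict = field(default_factory=dict)   # stage -> {rows, status}
    warnings: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _default_sim(config: PipelineConfig, condition: str) -> SimulationConfig:
    overrides = (config.simulate_control if condition == "control"
                 else config.simulate_silenced) or {}
    base = {"condition": condition, "seed": config.seed
            if condition == "control" else config.seed + 1}
    if condition == "silenced":
        base["hind_kappa"] = overrides.get("hind_kappa", 1.0)
    base.update(overrides)
    base["condition"] = condition
    return SimulationConfig(**base)


def run(config: PipelineConfig) -> RunManifest:
    """Execute the enabled pipeline stages; returns the final manifest."""
    outdir = Path(config.outdir)
    for name in ("footfall_csv", "swim_csv", "marker_csv"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name} path does not exist: {p}")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest_path = outdir / "manifest.json"
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=1)

    footfalls = swim = markers = None
    truth = {}

    def checkpoint(stage: str, **counts):
        manifest.stages[stage] = {"status": "done", **counts}
        manifest.write(manifest_path)
        log.info("stage %s done: %s", stage, counts)

    try:
        if "simulate" in config.stages and config.footfall_csv is None:
            dsets = []
            for condition in ("control", "silenced"):
                sim = _default_sim(config, condition)
                ds = simulate_footfalls(sim)
                if "kinematics" in config.stages:
                    ds = simulate_markers(sim, ds)
                dsets.append(ds)
            footfalls = pd.concat([d.footfalls for d in dsets],
                                  ignore_index=True)
            swim = pd.concat([d.swim for d in dsets], ignore_index=True)
            if dsets[0].markers is not None:
                markers = pd.concat([d.markers for d in dsets],
                                    ignore_index=True)
            truth = {"control": dsets[0].truth, "silenced": dsets[1].truth}
            footfalls.to_csv(outdir / "footfalls.csv", index=False)
            swim.to_csv(outdir / "swim.csv", index=False)
            if markers is not None:
                markers.to_csv(outdir / "markers.csv", index=False)
            checkpoint("simulate", footfall_rows=len(footfalls),
                       swim_rows=len(swim))
        else:
            if config.footfall_csv is None:
                raise ValueError("no input: provide footfall_csv or enable "
                                 "the simulate stage")
            footfalls = pd.read_csv(config.footfall_csv)
            swim = pd.read_csv(config.swim_csv) if config.swim_csv else \
                pd.DataFrame()
            if config.marker_csv:
                markers = pd.read_csv(config.marker_csv)
            checkpoint("load", footfall_rows=len(footfalls),
                       swim_rows=len(swim))

        if "kinematics" in config.stages and markers is not None \
                and not markers.empty:
            from . import kinematics as km
            angle_rows, phase_rows = [], []
            for key, ang in km.angles_from_marker_table(markers).items():
                animal, pass_id, side = key
                peaks = km.detect_angle_peaks(ang)
                try:
                    ip = km.intralimb_phase(peaks["proximal"]["peaks"],
                                            peaks["distal"]["peaks"])
                except ValueError:
                    continue
                ip.insert(0, "animal_id", animal)
                ip.insert(1, "pass_id", pass_id)
                ip.insert(2, "side", side)
                phase_rows.append(ip)
                angle_rows.append(pd.DataFrame({
                    "animal_id": animal, "pass_id": pass_id, "side": side,
                    "time_s": ang.time, "proximal_deg": ang.proximal_deg,
                    "distal_deg": ang.distal_deg}))
            if angle_rows:
                pd.concat(angle_rows, ignore_index=True).to_csv(
                    outdir / "angles.csv", index=False)
                pd.concat(phase_rows, ignore_index=True).to_csv(
                    outdir / "intralimb_phase.csv", index=False)
            checkpoint("kinematics", limb_series=len(angle_rows))

        strides = passes = ssp = None
        if "gait" in config.stages:
            strides = gait_events.extract_strides(footfalls)
            strides.to_csv(outdir / "strides.csv", index=False)
            rejected = strides.attrs.get("rejected")
            if rejected is not None and len(rejected):
                manifest.warnings.append(
                    f"{len(rejected)} stride record(s) rejected")
            passes = gait_events.pass_summaries(
                footfalls, reference_limb=config.reference_limb)
            passes.to_csv(outdir / "pass_summary.csv", index=False)
            ssp = gait_events.ssp_tally(
                footfalls, group_cols=("condition", "timepoint"))
            ssp.to_csv(outdir / "ssp_tally.csv", index=False)
            checkpoint("gait", strides=len(strides), passes=len(passes))

        phases = {}
        rules = {}
        counts = {}
        if "coordination" in config.stages:
            phases["hind"] = coordination.phase_series_from_footfalls(
                footfalls, pair="hindlimbs")
            phases["fore"] = coordination.phase_series_from_footfalls(
                footfalls, pair="forelimbs")
            if swim is not None and not swim.empty:
                phases["swim"] = coordination.phase_series_from_swim(swim)
            for name, ser in phases.items():
                if ser.empty:
                    continue
                ctrl = ser[(ser.condition == "control") &
                           ser.phase_transformed.notna()]
                scope = {"hind": "step_hind", "fore": "step_fore",
                         "swim": "swim"}[name]
                if len(ctrl) >= 2:
                    keep, dropped = coordination.remove_outliers(
                        ctrl, value_col="phase_transformed",
                        group_cols=("timepoint",), k_sd=config.outlier_k_sd)
                    if len(dropped):
                        manifest.warnings.append(
                            f"{len(dropped)} control outlier(s) removed "
                            f"({name})")
                    rule = coordination.control_threshold(
                        ctrl.phase_transformed.to_numpy()[keep],
                        k_sd=config.k_sd, scope=scope)
                    rules[name] = rule
                    ser["irregular"] = (ser.phase_transformed > rule.cutoff)
                    counts[name] = coordination.classify_irregular(
                        ser, rule, by=("condition", "timepoint"))
                ser.to_csv(outdir / f"phase_{name}.csv", index=False)
                chg = coordination.per_step_change(
                    ser, circular=config.circular_change)
                chg.to_csv(outdir / f"change_{name}.csv", index=False)
                coordination.poincare(ser).to_csv(
                    outdir / f"poincare_{name}.csv", index=False)
            if counts:
                pd.concat(counts, names=["series"]).reset_index(0).to_csv(
                    outdir / "irregular_counts.csv", index=False)
            cov_res = coordination.cov(phases["hind"]) if "hind" in phases \
                and not phases["hind"].empty else None
            if cov_res is not None:
                cov_res.per_animal.to_csv(outdir / "cov_per_animal.csv",
                                          index=False)
                cov_res.group.to_csv(outdir / "cov_group.csv", index=False)
            checkpoint("coordination",
                       **{f"{k}_steps": len(v) for k, v in phases.items()})

        circ = {}
        if "circstats" in config.stages and phases.get("hind") is not None:
            hind = phases["hind"]
            for name, ser in phases.items():
                ok = ser[ser.phase.notna()]
                ctrl = ok[ok.condition == "control"].phase.to_numpy()
                sil = ok[ok.condition == "silenced"].phase.to_numpy()
                entry = {}
                for lab, vals in (("control", ctrl), ("silenced", sil)):
                    if len(vals):
                        mu, r = circstats.circular_summary(
                            circstats.phase_to_angle(vals))
                        entry[lab] = {"mean_direction_rad": mu,
                                      "resultant_length": r, "n": len(vals)}
                if len(ctrl) >= 4 and len(sil) >= 4:
                    res = circstats.watson_u2(
                        circstats.phase_to_angle(ctrl),
                        circstats.phase_to_angle(sil),
                        n_permutations=config.n_permutations,
                        seed=config.seed)
                    entry["watson_u2"] = dataclasses.asdict(res)
                circ[name] = entry
            with open(outdir / "circstats.json", "w") as fh:
                json.dump(circ, fh, indent=1)
            checkpoint("circstats", comparisons=len(circ))

        stat_results = {}
        if "stats" in config.stages and counts:
            for name, table in counts.items():
                pooled = table.groupby("condition")[
                    ["n_irregular", "n_total"]].sum()
                if {"control", "silenced"} <= set(pooled.index):
                    res = inference.two_proportion_z(
                        int(pooled.loc["control", "n_irregular"]),
                        int(pooled.loc["control", "n_total"]),
                        int(pooled.loc["silenced", "n_irregular"]),
                        int(pooled.loc["silenced", "n_total"]))
                    stat_results[f"proportion_{name}"] = dataclasses.asdict(res)
            hind = phases.get("hind")
            if hind is not None and not hind.empty and strides is not None:
                ctrl = hind[hind.condition == "control"]
                sil = hind[hind.condition == "silenced"]
                if len(ctrl) and len(sil):
                    d, p = inference.ks_compare(
                        ctrl.phase_transformed.dropna(),
                        sil.phase_transformed.dropna())
                    stat_results["ks_transformed_hind"] = {"D": d, "p": p}
                ref = strides[strides.limb == config.reference_limb]
                merged = hind.merge(
                    ref[["animal_id", "pass_id", "stride_index",
                         "instantaneous_speed_cm_s", "step_frequency_hz",
                         "stride_length_cm", "stride_time_s", "stance_s",
                         "swing_s"]],
                    left_on=["animal_id", "pass_id", "cycle_index"],
                    right_on=["animal_id", "pass_id", "stride_index"],
                    how="inner")
                assoc = inference.phase_speed_association(merged)
                stat_results["phase_associations"] = [
                    dataclasses.asdict(a) for a in assoc]
                if "irregular" in merged.columns:
                    tab = inference.speed_category_counts(
                        merged, cutoff=config.speed_cutoff_cm_s)
                    stat_results["speed_categories"] = {
                        "table": tab.to_dict(),
                        "fraction_irregular_at_or_below_cutoff":
                            tab.attrs["fraction_irregular_at_or_below_cutoff"],
                    }
            with open(outdir / "stats.json", "w") as fh:
                json.dump(stat_results, fh, indent=1, default=_jsonable)
            checkpoint("stats", results=len(stat_results))

        if "report" in config.stages:
            rep = report(outdir)
            with open(outdir / "report.json", "w") as fh:
                json.dump(rep, fh, indent=1, default=_jsonable)
            checkpoint("report", sections=len(rep))
    except Exception as exc:
        manifest.stages["failed"] = {"status": "error", "error": str(exc)}
        manifest.write(manifest_path)
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(manifest_path)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def report(outdir: str | Path) -> dict:
    """Summarise a pipeline run from its written outputs.

    Sections mirror the analysis surfaces: irregular-step proportions,
    step-sequence-pattern tallies, COV, circular summaries, and pass
    summaries; a missing stage output is marked ``"absent"``.  Row counts in
    the report equal sums over the stage CSVs.
    """
    outdir = Path(outdir)
    rep: dict = {}

    def section(name, path, fn):
        p = outdir / path
        rep[name] = fn(p) if p.exists() else "absent"

    section("irregular_counts", "irregular_counts.csv",
            lambda p: pd.read_csv(p).to_dict(orient="records"))
    section("ssp_tally", "ssp_tally.csv",
            lambda p: pd.read_csv(p).to_dict(orient="records"))
    section("cov", "cov_group.csv",
            lambda p: pd.read_csv(p).to_dict(orient="records"))
    section("circstats", "circstats.json",
            lambda p: json.loads(p.read_text()))
    section("stats", "stats.json", lambda p: json.loads(p.read_text()))
    section("pass_summary", "pass_summary.csv",
            lambda p: {"n_passes": len(pd.read_csv(p)),
                       "mean_step_ratio":
                           float(pd.read_csv(p).step_ratio.mean())})
    for name in ("hind", "fore", "swim"):
        p = outdir / f"phase_{name}.csv"
        rep[f"n_{name}_steps"] = len(pd.read_csv(p)) if p.exists() else "absent"
    return rep
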