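"""Interlimb coordination: phase series, transformation, irregularity.

The interlimb phase of a step is the time of the left limb's initial contact
divided by the duration of the enclosing stride cycle of the reference right
limb: 0.5 means strict left-right alternation, values near 0/1 mean
synchrony (hopping).  To remove lead-limb ambiguity, raw phases are
*transformed* onto the linear scale [0.5, 1.0] by mirroring values below 0.5
about 0.5 (x -> 1 - x).  "Reciprocal >0.50" is implemented as this mirror:
it is the only reading that lands in [0.5, 1.0]; a multiplicative reciprocal
would leave the unit interval.

Irregularity is control-referenced: pooled control transformed phases define
mean and sample s.d.; any phase strictly greater than mean + k*sd (k = 2 by
default, hindlimb cutoff 0.63 with the calibrated defaults) is an irregular
step.  A value exactly at the cutoff is regular (strict ">").

The same machinery serves stepping (contact events), swimming (peak
downward toe-extension events), per-step absolute phase changes, coefficient
of variation, and Poincare lag-1 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IrregularityRule",
    "CovResult",
    "interlimb_phase",
    "swim_phase",
    "phase_series_from_footfalls",
    "phase_series_from_swim",
    "transform_phase",
    "control_threshold",
    "remove_outliers",
    "classify_irregular",
    "per_step_change",
    "match_stride_changes",
    "cov",
    "poincare",
]

SCOPES = ("step_hind", "step_fore", "swim", "per_step_change_hind",
          "per_step_change_fore")


@dataclass(frozen=True)
class IrregularityRule:
    """Control-referenced cutoff: values > control_mean + k*sd are irregular."""

    control_mean: float
    control_sd: float
    scope: str
    k_sd: float = 2.0

    def __post_init__(self):
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.control_sd < 0:
            raise ValueError("control_sd must be >= 0")

    @property
    def cutoff(self) -> float:
        return self.control_mean + self.k_sd * self.control_sd


@dataclass
class CovResult:
    """Per-animal coefficient of variation (percent) and group summary."""

    per_animal: pd.DataFrame     # animal_id, pool, mean, sd, cov_pct
    group: pd.DataFrame          # pool, mean_cov_pct, sd_cov_pct, n_animals


def _phase_in_reference_cycles(event_times: np.ndarray,
                               ref_times: np.ndarray) -> pd.DataFrame:
    """Phase of each event within consecutive reference cycles.

    For each reference interval [r_k, r_{k+1}) containing exactly one event
    t, phase = (t - r_k)/(r_{k+1} - r_k).  Intervals with zero or multiple
    events are flagged (missed / double step) and carry NaN phase.
    """
    ref_times = np.sort(np.asarray(ref_times, dtype=float))
    event_times = np.sort(np.asarray(event_times, dtype=float))
    if len(ref_times) < 2:
        raise ValueError("need at least one reference cycle")
    if np.any(np.diff(ref_times) <= 0):
        raise ValueError("zero-length reference cycle")
    rows = []
    for k in range(len(ref_times) - 1):
        r0, r1 = ref_times[k], ref_times[k + 1]
        inside = event_times[(event_times >= r0) & (event_times < r1)]
        phase = (inside[0] - r0) / (r1 - r0) if len(inside) == 1 else np.nan
        rows.append({"cycle_index": k, "phase": phase, "n_events": len(inside),
                     "ref_start_s": r0, "ref_duration_s": r1 - r0})
    return pd.DataFrame(rows)


def interlimb_phase(left_contacts: np.ndarray,
                    right_contacts: np.ndarray) -> pd.DataFrame:
    """Left-contact phase within each reference right stride cycle."""
    return _phase_in_reference_cycles(left_contacts, right_contacts)


def swim_phase(left_peaks: np.ndarray, right_peaks: np.ndarray) -> pd.DataFrame:
    """Left peak-extension phase within each reference right stroke cycle."""
    return _phase_in_reference_cycles(left_peaks, right_peaks)


def phase_series_from_footfalls(footfalls: pd.DataFrame, pair: str = "hindlimbs",
                                swap_reference: bool = False) -> pd.DataFrame:
    """Tidy per-step phase table for a limb pair across all passes.

    By convention the left limb is the moving limb and the right limb the
    reference; ``swap_reference`` flips this.  Strides with a missed or
    double left contact are excluded from the phase column (NaN) but kept in
    the table for diagnostics.
    """
    if pair == "hindlimbs":
        mov, ref = "LH", "RH"
    elif pair == "forelimbs":
        mov, ref = "LF", "RF"
    else:
        raise ValueError("pair must be 'hindlimbs' or 'forelimbs'")
    if swap_reference:
        mov, ref = ref, mov
    frames = []
    for (animal, pass_id), grp in footfalls.groupby(["animal_id", "pass_id"],
                                                    sort=True):
        left = grp.loc[grp.limb == mov, "contact_time_s"].to_numpy()
        right = grp.loc[grp.limb == ref, "contact_time_s"].to_numpy()
        if len(right) < 2 or len(left) == 0:
            continue
        ph = interlimb_phase(left, right)
        ph.insert(0, "animal_id", animal)
        ph.insert(1, "pass_id", pass_id)
        ph["condition"] = grp.condition.iloc[0] if "condition" in grp else ""
        ph["timepoint"] = grp.timepoint.iloc[0] if "timepoint" in grp else ""
        frames.append(ph)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    out["pair"] = pair
    out["task"] = "step"
    out["phase_transformed"] = transform_phase(out.phase.to_numpy())
    return out


def phase_series_from_swim(swim: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-stroke phase table from a swim-event table."""
    frames = []
    for (animal, pass_id), grp in swim.groupby(["animal_id", "pass_id"],
                                               sort=True):
        left = grp.loc[grp.side == "left", "peak_extension_time_s"].to_numpy()
        right = grp.loc[grp.side == "right", "peak_extension_time_s"].to_numpy()
        if len(right) < 2 or len(left) == 0:
            continue
        ph = swim_phase(left, right)
        ph.insert(0, "animal_id", animal)
        ph.insert(1, "pass_id", pass_id)
        ph["condition"] = grp.condition.iloc[0] if "condition" in grp else ""
        ph["timepoint"] = grp["timepoint"].iloc[0] if "timepoint" in grp else \
            (grp.condition.iloc[0] if "condition" in grp else "")
        frames.append(ph)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    out["pair"] = "hindlimbs"
    out["task"] = "swim"
    out["phase_transformed"] = transform_phase(out.phase.to_numpy())
    return out


def transform_phase(raw):
    """Fold raw phase in [0, 1) onto the linear scale [0.5, 1.0].

    Values below 0.5 map to their mirror 1 - x; values >= 0.5 are unchanged.
    Idempotent, and transform(x) == transform(1 - x).  NaN passes through.
    """
    arr = np.asarray(raw, dtype=float)
    finite = np.isfinite(arr)
    # accept the closed interval: 0 maps to 1, itself a fixed point
    if np.any((arr[finite] < 0) | (arr[finite] > 1)):
        raise ValueError("raw phase must lie in [0, 1]")
    out = np.where(arr < 0.5, 1.0 - arr, arr)
    out = np.where(finite, out, np.nan)
    return float(out) if np.isscalar(raw) else out


def control_threshold(control_transformed: np.ndarray, k_sd: float = 2.0,
                      scope: str = "step_hind") -> IrregularityRule:
    """Pooled control mean and sample s.d. -> irregularity cutoff mean+k*sd."""
    vals = np.asarray(control_transformed, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise ValueError("need at least two control values")
    return IrregularityRule(control_mean=float(np.mean(vals)),
                            control_sd=float(np.std(vals, ddof=1)),
                            scope=scope, k_sd=k_sd)


def remove_outliers(values: pd.DataFrame | np.ndarray, value_col: str = "value",
                    group_cols: tuple[str, ...] = ("timepoint",),
                    k_sd: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively drop values beyond k s.d. of their group mean.

    Within each group, values with |x - mean| > k*sd are removed, mean and
    s.d. recomputed, and the rule reapplied until no additional outliers
    remain.  Accepts a bare array (single group) or a DataFrame with group
    columns.  Returns (kept_mask, dropped_indices) aligned to the input rows.
    """
    if isinstance(values, pd.DataFrame):
        df = values
        groups = df.groupby([c for c in group_cols if c in df.columns]).groups \
            if group_cols else {None: df.index}
        x = df[value_col].to_numpy(dtype=float)
        index_sets = [np.asarray(ix) for ix in groups.values()] or [df.index.to_numpy()]
        positions = {ix: pos for pos, ix in enumerate(df.index)}
        index_sets = [np.array([positions[i] for i in ixs]) for ixs in index_sets]
    else:
        x = np.asarray(values, dtype=float)
        index_sets = [np.arange(len(x))]
    keep = np.ones(len(x), dtype=bool)
    for idx in index_sets:
        while True:
            active = idx[keep[idx]]
            if len(active) < 3:
                break
            m, s = np.mean(x[active]), np.std(x[active], ddof=1)
            if s == 0:
                break
            bad = active[np.abs(x[active] - m) > k_sd * s]
            if len(bad) == 0:
                break
            keep[bad] = False
    dropped = np.flatnonzero(~keep)
    return keep, dropped


def classify_irregular(series: pd.DataFrame, rule: IrregularityRule,
                       value_col: str = "phase_transformed",
                       by: tuple[str, ...] = ("timepoint",)) -> pd.DataFrame:
    """Count transformed phases strictly above the cutoff, per group.

    The series' pair/task must match the rule scope (step_hind expects
    hindlimb stepping data, etc.).  Returns (x=n_irregular, n=n_total) per
    group for the proportion tests.
    """
    expected = {"step_hind": ("hindlimbs", "step"),
                "step_fore": ("forelimbs", "step"),
                "swim": ("hindlimbs", "swim")}
    if rule.scope in expected and {"pair", "task"} <= set(series.columns):
        pair, task = expected[rule.scope]
        if not ((series.pair == pair) & (series.task == task)).all():
            raise ValueError(
                f"rule scope {rule.scope!r} does not match series pair/task")
    vals = series[value_col]
    ok = vals.notna()
    grouped = series.loc[ok].assign(
        _irr=vals[ok].to_numpy() > rule.cutoff)
    gb = [c for c in by if c in grouped.columns]
    if gb:
        out = (grouped.groupby(gb)
               .agg(n_irregular=("_irr", "sum"), n_total=("_irr", "size"))
               .reset_index())
    else:
        out = pd.DataFrame([{"n_irregular": int(grouped._irr.sum()),
                             "n_total": int(len(grouped))}])
    out["proportion"] = out.n_irregular / out.n_total
    out["cutoff"] = rule.cutoff
    return out


def per_step_change(series: pd.DataFrame, circular: bool = False,
                    value_col: str = "phase") -> pd.DataFrame:
    """Absolute change in phase between successive steps within each pass.

    Uses raw phases by default; with ``circular=True`` the wrap-around
    distance min(|d|, 1 - |d|) is used instead.  Changes never span pass
    boundaries.  Steps with missing phase are skipped (no change computed
    across them).
    """
    rows = []
    for (animal, pass_id), grp in series.groupby(["animal_id", "pass_id"],
                                                 sort=True):
        grp = grp.sort_values("cycle_index")
        vals = grp[value_col].to_numpy(dtype=float)
        cyc = grp.cycle_index.to_numpy()
        good = np.isfinite(vals)
        vals, cyc = vals[good], cyc[good]
        meta = {c: grp[c].iloc[0]
                for c in ("condition", "timepoint", "pair", "task")
                if c in grp.columns}
        for i in range(len(vals) - 1):
            if cyc[i + 1] != cyc[i] + 1:
                continue        # gap (flagged stride) between the steps
            d = abs(vals[i + 1] - vals[i])
            if circular:
                d = min(d, 1.0 - d)
            rows.append({"animal_id": animal, "pass_id": pass_id, **meta,
                         "cycle_index": int(cyc[i]), "change": d})
    return pd.DataFrame(rows)


def match_stride_changes(series: pd.DataFrame, strides: pd.DataFrame,
                         reference_limb: str = "RH") -> pd.DataFrame:
    """Pair per-step phase changes with reference-limb stride-time changes.

    For each successive step pair within a pass, emits |delta phase| and
    |delta stride time| of the reference limb, so coordination changes can
    be checked against timing changes (uncoupled coordination with preserved
    rhythm shows large phase changes at near-zero stride-time changes).
    """
    ref = strides[strides.limb == reference_limb]
    rows = []
    for (animal, pass_id), grp in series.groupby(["animal_id", "pass_id"],
                                                 sort=True):
        grp = grp.sort_values("cycle_index")
        st = ref[(ref.animal_id == animal) & (ref.pass_id == pass_id)] \
            .sort_values("stride_index")
        times = dict(zip(st.stride_index, st.stride_time_s))
        vals = grp.phase.to_numpy(dtype=float)
        cyc = grp.cycle_index.to_numpy()
        for i in range(len(grp) - 1):
            if cyc[i + 1] != cyc[i] + 1:
                continue
            if not (np.isfinite(vals[i]) and np.isfinite(vals[i + 1])):
                continue
            if cyc[i] not in times or cyc[i + 1] not in times:
                continue
            rows.append({
                "animal_id": animal, "pass_id": pass_id,
                "cycle_index": int(cyc[i]),
                "dphase": abs(vals[i + 1] - vals[i]),
                "dstride_time_s": abs(times[cyc[i + 1]] - times[cyc[i]]),
            })
    return pd.DataFrame(rows)


def cov(series: pd.DataFrame, pools: dict[str, list[str]] | None = None,
        use_transformed: bool = False) -> CovResult:
    """Per-animal coefficient of variation of phase, by condition pool.

    Each animal's mean and sample s.d. are computed across all steps in the
    pool; COV% = 100 * sd / mean.  ``pools`` maps pool name -> list of
    timepoint labels (default: one pool per condition label).
    """
    col = "phase_transformed" if use_transformed else "phase"
    df = series[series[col].notna()].copy()
    if pools is None:
        pools = {c: sorted(df.loc[df.condition == c, "timepoint"].unique())
                 for c in df.condition.unique()}
    rows = []
    for pool, tps in pools.items():
        sub = df[df.timepoint.isin(tps)]
        for animal, grp in sub.groupby("animal_id"):
            if len(grp) < 2:
                continue
            m = float(grp[col].mean())
            if m == 0:
                raise ValueError("zero mean phase; COV undefined")
            s = float(grp[col].std(ddof=1))
            rows.append({"animal_id": animal, "pool": pool, "mean": m,
                         "sd": s, "cov_pct": 100.0 * s / m,
                         "n_steps": len(grp)})
    per_animal = pd.DataFrame(rows)
    group = (per_animal.groupby("pool")
             .agg(mean_cov_pct=("cov_pct", "mean"),
                  sd_cov_pct=("cov_pct", lambda s: s.std(ddof=1)),
                  n_animals=("cov_pct", "size"))
             .reset_index())
    return CovResult(per_animal=per_animal, group=group)


def poincare(series: pd.DataFrame, value_col: str = "phase") -> pd.DataFrame:
    """Lag-1 pairs (step n, step n+1) of phase within each pass.

    Pairs never span pass boundaries; an n-step pass yields n-1 pairs.
    """
    rows = []
    for (animal, pass_id), grp in series.groupby(["animal_id", "pass_id"],
                                                 sort=True):
        grp = grp.sort_values("cycle_index")
        vals = grp[value_col].to_numpy(dtype=float)
        meta = {c: grp[c].iloc[0] for c in ("condition", "timepoint")
                if c in grp.columns}
        for i in range(len(vals) - 1):
            rows.append({"animal_id": animal, "pass_id": pass_id, **meta,
                         "phase_n": vals[i], "phase_n1": vals[i + 1]})
    return pd.DataFrame(rows)
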