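"""Stride cycles, spatiotemporal gait indices, and step-sequence patterns.

A stride cycle is one stance phase (paw contact -> liftoff) plus the
following swing phase (liftoff -> next contact of the same limb).  From
footfall-event tables this module derives, per stride: stance and swing
durations, stride time, stride length, step frequency, instantaneous speed,
and stance/swing percentages (identities stance + swing = stride time and
stance% + swing% = 100 hold exactly by construction).

The step-sequence pattern (SSP) is the categorical footfall order of the
four limbs over one locomotor cycle, independent of phase durations: three
main patterns (alternate, cruciate, rotate), each with subtype "a"/"b" by
whether the right or left forelimb initiates the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SSPLabel",
    "extract_strides",
    "swing_stance_percent",
    "overall_speed",
    "classify_ssp",
    "ssp_tally",
    "step_ratio",
    "pass_summaries",
    "SSP_ORDERS",
]

HIND = {"LH", "RH"}
FORE = {"LF", "RF"}

# canonical footfall orders; rotate follows the standard quadruped taxonomy
SSP_ORDERS: dict[tuple[str, str, str, str], tuple[str, str]] = {
    ("RF", "LH", "LF", "RH"): ("alternate", "a"),
    ("LF", "RH", "RF", "LH"): ("alternate", "b"),
    ("RF", "LF", "RH", "LH"): ("cruciate", "a"),
    ("LF", "RF", "LH", "RH"): ("cruciate", "b"),
    ("RF", "LF", "LH", "RH"): ("rotate", "a"),
    ("LF", "RF", "RH", "LH"): ("rotate", "b"),
}


@dataclass(frozen=True)
class SSPLabel:
    pattern: str            # alternate | cruciate | rotate | unclassified
    subtype: str            # a | b | none
    initiating_limb: str

    def __post_init__(self):
        if (self.subtype == "none") != (self.pattern == "unclassified"):
            raise ValueError("subtype is 'none' iff pattern is unclassified")


def extract_strides(footfalls: pd.DataFrame) -> pd.DataFrame:
    """Pair consecutive same-limb contacts into strides with derived indices.

    Expects the footfall schema (animal_id, condition, timepoint, pass_id,
    limb, contact_time_s, liftoff_time_s, contact_x_cm).  The last contact of
    a limb in a pass yields no stride.  Records with liftoff at or after the
    next contact (non-positive swing) are rejected with a diagnostic column
    in the attribute ``.attrs["rejected"]``.
    """
    required = {"animal_id", "pass_id", "limb", "contact_time_s",
                "liftoff_time_s", "contact_x_cm"}
    missing = required - set(footfalls.columns)
    if missing:
        raise ValueError(f"footfall table missing columns: {sorted(missing)}")
    if (footfalls.liftoff_time_s <= footfalls.contact_time_s).any():
        raise ValueError("every event must have contact < liftoff")
    rows, rejected = [], []
    keys = ["animal_id", "pass_id", "limb"]
    extra = [c for c in ("condition", "timepoint") if c in footfalls.columns]
    for key, grp in footfalls.groupby(keys, sort=True):
        grp = grp.sort_values("contact_time_s")
        c = grp.contact_time_s.to_numpy()
        lo = grp.liftoff_time_s.to_numpy()
        x = grp.contact_x_cm.to_numpy()
        if np.any(np.diff(c) <= 0):
            raise ValueError(f"contacts not strictly increasing for {key}")
        for i in range(len(grp) - 1):
            stance = lo[i] - c[i]
            swing = c[i + 1] - lo[i]
            rec = dict(zip(keys, key))
            for col in extra:
                rec[col] = grp[col].iloc[i]
            rec.update(stride_index=i, start_contact_s=c[i],
                       next_contact_s=c[i + 1])
            if swing <= 0:
                rec["reason"] = "liftoff at/after next contact"
                rejected.append(rec)
                continue
            stride = stance + swing
            length = x[i + 1] - x[i]
            rec.update(
                stance_s=stance, swing_s=swing, stride_time_s=stride,
                stride_length_cm=length, step_frequency_hz=1.0 / stride,
                instantaneous_speed_cm_s=length / stride,
                stance_pct=100.0 * stance / stride,
                swing_pct=100.0 * swing / stride,
            )
            rows.append(rec)
    strides = pd.DataFrame(rows)
    strides.attrs["rejected"] = pd.DataFrame(rejected)
    return strides


def swing_stance_percent(strides: pd.DataFrame,
                         speed_cutoff: float = 90.0) -> pd.DataFrame:
    """Mean +/- s.d. swing% and stance% within speed classes.

    Classes are instantaneous speed <= cutoff ("low", walk-trot range) and
    > cutoff ("high", gallop-bound range); an empty class is simply absent
    from the result.
    """
    if strides.empty:
        raise ValueError("no strides")
    df = strides.copy()
    df["speed_class"] = np.where(
        df.instantaneous_speed_cm_s <= speed_cutoff, "low", "high")
    out = (df.groupby("speed_class")
           .agg(n=("swing_pct", "size"),
                mean_swing_pct=("swing_pct", "mean"),
                sd_swing_pct=("swing_pct", lambda s: s.std(ddof=1)),
                mean_stance_pct=("stance_pct", "mean"),
                sd_stance_pct=("stance_pct", lambda s: s.std(ddof=1)))
           .reset_index())
    return out


def overall_speed(pass_events: pd.DataFrame,
                  reference_limb: str = "RH") -> float:
    """Speed of one complete locomotor bout, start to finish (cm/s).

    Uses the reference limb's first and last contacts:
    (last contact_x - first contact_x) / (last time - first time).
    """
    ev = pass_events[pass_events.limb == reference_limb].sort_values(
        "contact_time_s")
    if len(ev) < 2:
        raise ValueError("need at least two contacts of the reference limb")
    dt = ev.contact_time_s.iloc[-1] - ev.contact_time_s.iloc[0]
    if dt <= 0:
        raise ValueError("zero elapsed time in pass")
    return float((ev.contact_x_cm.iloc[-1] - ev.contact_x_cm.iloc[0]) / dt)


def classify_ssp(footfall_order: list[str] | tuple[str, ...]) -> SSPLabel:
    """Classify a 4-footfall window into a step-sequence pattern.

    The six canonical orders map to alternate/cruciate/rotate subtype a/b;
    any other order, a repeated limb, or fewer than four footfalls is
    unclassified.
    """
    seq = tuple(footfall_order)
    if len(seq) != 4 or len(set(seq)) != 4 or not set(seq) <= (HIND | FORE):
        init = seq[0] if seq else ""
        return SSPLabel("unclassified", "none", init)
    if seq in SSP_ORDERS:
        pattern, subtype = SSP_ORDERS[seq]
        return SSPLabel(pattern, subtype, seq[0])
    return SSPLabel("unclassified", "none", seq[0])


def ssp_tally(footfalls: pd.DataFrame,
              group_cols: tuple[str, ...] = ("timepoint",)) -> pd.DataFrame:
    """Tally step-sequence patterns per pass, reported as percent of total.

    Within each pass, footfalls are ordered by contact time; consecutive
    non-overlapping 4-footfall windows are classified, each window starting
    at a forelimb footfall (the taxonomy defines subtypes by the initiating
    forelimb, so hindlimb footfalls between windows are skipped).  Emits
    both subtype-resolved and pooled-per-main-pattern percentages.
    """
    rows = []
    for (animal, pass_id), grp in footfalls.groupby(["animal_id", "pass_id"],
                                                    sort=True):
        grp = grp.sort_values("contact_time_s")
        limbs = grp.limb.tolist()
        meta = {c: grp[c].iloc[0] for c in group_cols if c in grp.columns}
        i = next((k for k, l in enumerate(limbs) if l in FORE), len(limbs))
        while i + 4 <= len(limbs):
            lab = classify_ssp(limbs[i:i + 4])
            rows.append({"animal_id": animal, "pass_id": pass_id, **meta,
                         "pattern": lab.pattern, "subtype": lab.subtype})
            # a classified window is consumed whole; after a failed window
            # the sequence re-initiates at the next forelimb footfall
            i += 4 if lab.pattern != "unclassified" else 1
            while i < len(limbs) and limbs[i] not in FORE:
                i += 1
    calls = pd.DataFrame(rows)
    if calls.empty:
        return calls
    gb = [c for c in group_cols if c in calls.columns]
    out = []
    for key, grp in calls.groupby(gb, sort=True) if gb else [((), calls)]:
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        sub = (grp.groupby(["pattern", "subtype"]).size() / n * 100.0)
        for (pat, subty), pct in sub.items():
            out.append({**dict(zip(gb, key)), "pattern": pat,
                        "subtype": subty, "percent": pct, "n_patterns": n})
        pooled = (grp.groupby("pattern").size() / n * 100.0)
        for pat, pct in pooled.items():
            out.append({**dict(zip(gb, key)), "pattern": pat,
                        "subtype": "pooled", "percent": pct, "n_patterns": n})
    return pd.DataFrame(out)


def step_ratio(pass_events: pd.DataFrame) -> float:
    """Hindlimb strides divided by forelimb strides within one pass."""
    strides = extract_strides(pass_events)
    if strides.empty:
        raise ValueError("no strides in pass")
    n_hind = int(strides.limb.isin(HIND).sum())
    n_fore = int(strides.limb.isin(FORE).sum())
    if n_fore == 0:
        raise ValueError("no forelimb strides in pass")
    if n_hind == 0:
        raise ValueError("no hindlimb strides in pass")
    return n_hind / n_fore


def pass_summaries(footfalls: pd.DataFrame,
                   reference_limb: str = "RH") -> pd.DataFrame:
    """Per-pass overall speed, stride counts, and hind:fore step ratio."""
    rows = []
    for (animal, pass_id), grp in footfalls.groupby(["animal_id", "pass_id"],
                                                    sort=True):
        strides = extract_strides(grp)
        n_hind = int(strides.limb.isin(HIND).sum()) if not strides.empty else 0
        n_fore = int(strides.limb.isin(FORE).sum()) if not strides.empty else 0
        rows.append({
            "animal_id": animal, "pass_id": pass_id,
            "condition": grp.condition.iloc[0] if "condition" in grp else "",
            "timepoint": grp.timepoint.iloc[0] if "timepoint" in grp else "",
            "overall_speed_cm_s": overall_speed(grp, reference_limb),
            "n_hind_steps": n_hind, "n_fore_steps": n_fore,
            "step_ratio": n_hind / n_fore if n_fore else np.nan,
        })
    return pd.DataFrame(rows)
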