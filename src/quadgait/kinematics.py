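"""Hindlimb kinematics: the 3-segment / 2-angle model.

Four skin landmarks -- iliac crest (I), hip (H), ankle (A), toe (T) -- define
three segments (I-H, H-A, A-T) and two interior joint angles:

* proximal: the angle at the hip vertex of I-H-A,
* distal: the angle at the ankle vertex of H-A-T,

both in degrees in (0, 180].  From the angle time series this module extracts
peak/trough events, per-cycle range of motion, and the *intralimb phase*: the
timing of the proximal-angle peak expressed as a fraction of the enclosing
distal peak-to-peak interval (0/1 = in-phase multi-joint coordination, 0.5 =
out-of-phase).

Angles are computed in the sagittal plane (2-D); 3-D capture is reduced to
its sagittal projection.  Angle computation is invariant to global
translation, rotation, and uniform scaling of the marker coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "AngleSeries",
    "ExcursionStats",
    "compute_angles",
    "detect_angle_peaks",
    "intralimb_phase",
    "range_of_motion",
    "angles_from_marker_table",
]

MARKER_NAMES = ("iliac_crest", "hip", "ankle", "toe")


@dataclass
class AngleSeries:
    """Per-frame proximal and distal joint angles (degrees)."""

    time: np.ndarray
    proximal_deg: np.ndarray
    distal_deg: np.ndarray
    side: str = ""
    valid: np.ndarray | None = None   # frames with well-defined angles

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.proximal_deg = np.asarray(self.proximal_deg, dtype=float)
        self.distal_deg = np.asarray(self.distal_deg, dtype=float)
        if not (len(self.time) == len(self.proximal_deg) == len(self.distal_deg)):
            raise ValueError("time and angle series must have equal length")
        if self.valid is None:
            self.valid = np.ones(len(self.time), dtype=bool)


def _interior_angle_deg(p: np.ndarray, vertex: np.ndarray,
                        q: np.ndarray) -> np.ndarray:
    """Interior angle at `vertex` between rays vertex->p and vertex->q."""
    u = p - vertex
    v = q - vertex
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    bad = (nu == 0) | (nv == 0)
    nu = np.where(bad, 1.0, nu)
    nv = np.where(bad, 1.0, nv)
    cosang = np.clip(np.einsum("...i,...i->...", u, v) / (nu * nv), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return np.where(bad, np.nan, ang)


def compute_angles(time: np.ndarray, iliac_crest: np.ndarray, hip: np.ndarray,
                   ankle: np.ndarray, toe: np.ndarray,
                   side: str = "") -> AngleSeries:
    """Compute proximal (I-H-A at hip) and distal (H-A-T at ankle) angles.

    Marker arrays are (n_frames, 2|3) positions in cm.  Frames with a
    zero-length segment are flagged invalid (NaN angle) with a warning rather
    than raising; downstream peak detection ignores them.
    """
    time = np.asarray(time, dtype=float)
    if len(time) < 3:
        raise ValueError("need at least 3 frames")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    arrs = [np.asarray(a, dtype=float) for a in (iliac_crest, hip, ankle, toe)]
    for a in arrs:
        if a.shape[0] != len(time):
            raise ValueError("marker arrays must match time length")
    iliac_crest, hip, ankle, toe = arrs
    proximal = _interior_angle_deg(iliac_crest, hip, ankle)
    distal = _interior_angle_deg(hip, ankle, toe)
    valid = np.isfinite(proximal) & np.isfinite(distal)
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} frame(s) with coincident adjacent markers "
            "excluded from angle series", stacklevel=2)
    return AngleSeries(time=time, proximal_deg=proximal, distal_deg=distal,
                       side=side, valid=valid)


def angles_from_marker_table(markers: pd.DataFrame) -> dict[tuple, AngleSeries]:
    """Compute angle series per (animal_id, pass_id, side) from a marker table.

    Expects the long-format marker CSV schema: animal_id, pass_id, frame,
    time_s, side, marker, x_cm, y_cm.
    """
    out: dict[tuple, AngleSeries] = {}
    for key, grp in markers.groupby(["animal_id", "pass_id", "side"], sort=True):
        wide = grp.pivot_table(index=["frame", "time_s"], columns="marker",
                               values=["x_cm", "y_cm"])
        time = wide.index.get_level_values("time_s").to_numpy()
        pos = {m: np.stack([wide[("x_cm", m)].to_numpy(),
                            wide[("y_cm", m)].to_numpy()], axis=1)
               for m in MARKER_NAMES}
        out[key] = compute_angles(time, pos["iliac_crest"], pos["hip"],
                                  pos["ankle"], pos["toe"], side=key[2])
    return out


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="same")
    return sm[pad:pad + len(x)] if pad else sm


def _enforce_alternation(times: np.ndarray, values: np.ndarray,
                         kinds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge runs of same-sign extrema, keeping the more extreme one."""
    keep_t, keep_k = [], []
    i = 0
    n = len(times)
    while i < n:
        j = i
        while j + 1 < n and kinds[j + 1] == kinds[i]:
            j += 1
        run = slice(i, j + 1)
        vals = values[run]
        best = np.argmax(vals) if kinds[i] == 1 else np.argmin(vals)
        keep_t.append(times[run][best])
        keep_k.append(kinds[i])
        i = j + 1
    return np.asarray(keep_t), np.asarray(keep_k)


def detect_angle_peaks(angles: AngleSeries, smoothing_window: int = 5,
                       prominence_deg: float = 5.0) -> dict[str, dict[str, np.ndarray]]:
    """Detect peak and trough times of each angle after smoothing.

    Moving-average smoothing (default 5 frames) precedes prominence-gated
    extremum detection; runs of same-sign extrema are merged keeping the
    larger, so peaks and troughs strictly alternate.  Returns
    ``{"proximal": {"peaks": t, "troughs": t}, "distal": {...}}``.
    A flat series yields empty arrays.
    """
    out = {}
    for name in ("proximal", "distal"):
        y = getattr(angles, f"{name}_deg").copy()
        good = angles.valid & np.isfinite(y)
        if good.sum() < 3:
            out[name] = {"peaks": np.array([]), "troughs": np.array([])}
            continue
        yv = np.interp(angles.time, angles.time[good], y[good])
        ys = _moving_average(yv, smoothing_window)
        pk, _ = find_peaks(ys, prominence=prominence_deg)
        tr, _ = find_peaks(-ys, prominence=prominence_deg)
        if len(pk) + len(tr) == 0:
            out[name] = {"peaks": np.array([]), "troughs": np.array([])}
            continue
        times = np.concatenate([angles.time[pk], angles.time[tr]])
        values = np.concatenate([ys[pk], ys[tr]])
        kinds = np.concatenate([np.ones(len(pk), int), -np.ones(len(tr), int)])
        order = np.argsort(times)
        t2, k2 = _enforce_alternation(times[order], values[order], kinds[order])
        out[name] = {"peaks": t2[k2 == 1], "troughs": t2[k2 == -1]}
    return out


def intralimb_phase(proximal_peaks: np.ndarray,
                    distal_peaks: np.ndarray) -> pd.DataFrame:
    """Proximal-peak timing as a fraction of each distal peak-to-peak interval.

    For each consecutive distal-peak interval [d_k, d_{k+1}) containing
    exactly one proximal peak t, phase = (t - d_k) / (d_{k+1} - d_k), in
    [0, 1).  Intervals with zero or multiple proximal peaks are flagged
    (``n_proximal``) and carry NaN phase; callers drop them from statistics.
    """
    distal_peaks = np.sort(np.asarray(distal_peaks, dtype=float))
    proximal_peaks = np.sort(np.asarray(proximal_peaks, dtype=float))
    if len(distal_peaks) < 2:
        raise ValueError("need at least two distal peaks")
    if np.any(np.diff(distal_peaks) <= 0):
        raise ValueError("distal peak intervals must have positive length")
    rows = []
    for k in range(len(distal_peaks) - 1):
        d0, d1 = distal_peaks[k], distal_peaks[k + 1]
        inside = proximal_peaks[(proximal_peaks >= d0) & (proximal_peaks < d1)]
        phase = (inside[0] - d0) / (d1 - d0) if len(inside) == 1 else np.nan
        rows.append({"cycle_index": k, "phase": phase,
                     "n_proximal": len(inside)})
    return pd.DataFrame(rows)


@dataclass
class ExcursionStats:
    """Per-cycle peak/trough/range of motion plus summary mean +/- s.d."""

    per_cycle: pd.DataFrame        # angle, cycle_index, peak_deg, trough_deg, range_deg
    summary: pd.DataFrame          # angle, mean_peak, mean_trough, mean_range, sd_range


def range_of_motion(angles: AngleSeries,
                    cycles: list[tuple[float, float]]) -> ExcursionStats:
    """Peak-to-trough excursion of each angle within each cycle interval."""
    if not cycles:
        raise ValueError("need at least one cycle interval")
    rows = []
    for name in ("proximal", "distal"):
        y = getattr(angles, f"{name}_deg")
        for k, (t0, t1) in enumerate(cycles):
            mask = (angles.time >= t0) & (angles.time < t1) & angles.valid
            if mask.sum() < 2:
                continue
            peak = float(np.nanmax(y[mask]))
            trough = float(np.nanmin(y[mask]))
            rows.append({"angle": name, "cycle_index": k, "peak_deg": peak,
                         "trough_deg": trough, "range_deg": peak - trough})
    per_cycle = pd.DataFrame(rows)
    summary = (per_cycle.groupby("angle")
               .agg(mean_peak=("peak_deg", "mean"),
                    mean_trough=("trough_deg", "mean"),
                    mean_range=("range_deg", "mean"),
                    sd_range=("range_deg", lambda s: s.std(ddof=1)))
               .reset_index())
    return ExcursionStats(per_cycle=per_cycle, summary=summary)
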