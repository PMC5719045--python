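"""Synthetic quadruped gait generator.

Produces footfall tables, swim-event tables, and hindlimb marker trajectories
with the statistical structure the downstream analysis assumes, together with
full ground truth, so every stage of the pipeline can be tested without any
recorded animal data.

The generative model
--------------------
Left-right interlimb coordination is expressed as a *phase*: the fraction of
the reference (right) limb's stride cycle at which the contralateral (left)
limb makes initial contact.  Phase 0.5 is strict alternation (walk/trot);
phase 0/1 is synchrony (hop/bound).

Phase noise is von Mises on the circle (angle = 2*pi*phase), the standard
circular analogue of a Gaussian.  Two condition regimes are modelled:

* ``control`` -- phases concentrated at alternation.  Each animal carries a
  small, fixed lead-limb bias (random sign, magnitude ``lead_bias``) on top
  of per-step von Mises noise.  The bias structure matters: the analysis
  folds phases onto [0.5, 1.0] to remove lead-limb ambiguity, and folding a
  distribution centred *exactly* at 0.5 would produce a half-normal rather
  than the roughly Gaussian transformed distribution the irregularity
  thresholds assume.  With the default bias 0.06 and within-animal circular
  s.d. ~0.035 (``hind_kappa`` = 21) the transformed phases have mean ~0.56,
  s.d. ~0.03, and a tail beyond the 0.63 cutoff of ~2.3%.
* ``silenced`` -- a low-concentration von Mises at alternation mixed (weight
  ``synchrony_weight``) with a component at synchrony, plus an optional
  per-step random-walk drift, reproducing a coordination continuum from
  alternating stepping to hopping.

Forelimb coupling uses a high concentration in both conditions (the
manipulation modelled here leaves the forelimbs untouched), and swimming
phase is condition-independent.

Stride timing follows a sublinear cadence law ``T(v) = stride_time_mean *
(cadence_ref_speed / v) ** cadence_exponent`` so faster passes take quicker,
longer steps; per-step stride-time jitter is small (consistent stride
durations).  Contact positions advance at the pass speed exactly, so
``stride_length = speed * stride_time`` holds per step by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_footfalls",
    "simulate_markers",
    "stance_fraction",
]

HIND_LIMBS = ("LH", "RH")
FORE_LIMBS = ("LF", "RF")
ALL_LIMBS = ("LF", "RF", "LH", "RH")

FOOTFALL_COLUMNS = [
    "animal_id", "condition", "timepoint", "pass_id", "limb",
    "contact_time_s", "liftoff_time_s", "contact_x_cm",
]
SWIM_COLUMNS = [
    "animal_id", "condition", "pass_id", "side", "peak_extension_time_s",
]
MARKER_COLUMNS = [
    "animal_id", "pass_id", "frame", "time_s", "side", "marker", "x_cm", "y_cm",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic gait model.

    Phases are fractions in [0, 1); concentrations are von Mises kappa on the
    angle scale (2*pi*phase); times are seconds, positions centimetres.
    """

    n_animals: int = 6
    passes_per_animal: int = 4
    steps_per_pass: int = 12          # hindlimb cycles per pass (10-14 typical)
    condition: str = "control"        # {"control", "silenced"}
    timepoint: str | None = None      # label; defaults to condition

    # hindlimb interlimb phase
    hind_phase_mean: float = 0.5
    hind_kappa: float = 21.0          # control concentration (circ. sd ~0.035 phase)
    lead_bias: float = 0.06           # per-animal lead-limb offset magnitude (phase)
    silenced_kappa: float = 1.0
    synchrony_weight: float = 0.2     # stationary weight at phase 0/1 (silenced)
    synchrony_persistence: float = 0.7  # bout stickiness of the synchrony state
    synchrony_phase: float = 0.03     # hop component centre: left trails slightly
    drift_sd: float = 0.02            # per-step random-walk sd on phase (silenced)

    # forelimb interlimb phase (high concentration in both conditions)
    fore_phase_mean: float = 0.5
    fore_kappa: float = 28.0
    fore_lead_bias: float = 0.04

    # stride timing / geometry
    stride_time_mean: float = 0.35    # s, at cadence_ref_speed
    stride_time_sd: float = 0.02      # s, per-step jitter
    speed_range: tuple[float, float] = (40.0, 100.0)   # cm/s, spans 90
    cadence_ref_speed: float = 60.0   # cm/s
    cadence_exponent: float = 0.4     # T(v) = T_ref * (v_ref/v)**exponent
    walkway_length_cm: float = 150.0  # caps steps per pass
    stance_fraction_ref: float = 0.55     # stance fraction of stride at ref speed
    stance_ref_speed: float = 40.0        # cm/s
    stance_speed_slope: float = 0.001     # fraction decrease per cm/s above ref
    fore_hind_offset_cm: float = 12.0     # forelimb contact positions lead by this

    # swimming (condition-independent)
    swim_passes_per_animal: int = 4
    strokes_per_pass: int = 10
    swim_stroke_time_mean: float = 0.33
    swim_stroke_time_sd: float = 0.02
    swim_phase_mean: float = 0.5
    swim_kappa: float = 10.0

    # marker simulation
    frame_rate_hz: float = 100.0
    proximal_mean_deg: float = 105.0
    proximal_amp_deg: float = 15.0
    distal_mean_deg: float = 100.0
    distal_amp_deg: float = 25.0
    intralimb_lag: float = 0.0        # proximal peak lag, fraction of distal cycle
    marker_noise_cm: float = 0.0
    hip_osc_amp_cm: float = 0.3
    hip_osc_amp_silenced_cm: float = 0.8
    segment_upper_cm: float = 4.0     # iliac crest - hip
    segment_thigh_cm: float = 5.0     # hip - ankle (composite segment)
    segment_foot_cm: float = 4.0      # ankle - toe

    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("control", "silenced"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.stride_time_mean <= 0:
            raise ValueError("stride_time_mean must be positive")
        if self.swim_stroke_time_mean <= 0:
            raise ValueError("swim_stroke_time_mean must be positive")
        for name in ("hind_kappa", "silenced_kappa", "fore_kappa", "swim_kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (von Mises concentration)")
        if not 0.0 <= self.synchrony_weight <= 1.0:
            raise ValueError("synchrony_weight must lie in [0, 1]")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        lo, hi = self.speed_range
        if not 0 < lo <= hi:
            raise ValueError("speed_range must be a positive interval")
        if self.timepoint is None:
            self.timepoint = self.condition

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["speed_range"] = list(d["speed_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "speed_range" in d:
            d["speed_range"] = tuple(d["speed_range"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth used to generate them."""

    footfalls: pd.DataFrame
    swim: pd.DataFrame
    markers: pd.DataFrame | None
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write CSV tables and the truth JSON; returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["footfalls"] = outdir / "footfalls.csv"
        self.footfalls.to_csv(paths["footfalls"], index=False)
        paths["swim"] = outdir / "swim.csv"
        self.swim.to_csv(paths["swim"], index=False)
        if self.markers is not None:
            paths["markers"] = outdir / "markers.csv"
            self.markers.to_csv(paths["markers"], index=False)
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_json_default)
        return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def stance_fraction(speed_cm_s: float | np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Stance fraction of the stride as a function of pass speed.

    Defaults to 0.55 at the reference speed, decreasing linearly with speed
    (stance occupies less of the stride as animals move faster); clipped to
    [0.2, 0.75] to keep both stance and swing strictly positive.
    """
    frac = config.stance_fraction_ref - config.stance_speed_slope * (
        np.asarray(speed_cm_s, dtype=float) - config.stance_ref_speed
    )
    return np.clip(frac, 0.2, 0.75)


def _draw_phases(rng: np.random.Generator, n: int, config: SimulationConfig,
                 bias: float) -> np.ndarray:
    """Draw n hindlimb phases for one pass under the configured condition."""
    if config.condition == "control":
        kappa = config.hind_kappa
        mu = 2 * np.pi * (config.hind_phase_mean + bias)
        if np.isinf(kappa):
            theta = np.full(n, mu)
        else:
            theta = rng.vonmises(mu, kappa, size=n)
        return np.mod(theta / (2 * np.pi), 1.0)
    # silenced: mixture of low-kappa alternation and synchrony, plus drift.
    # Synchrony arrives in persistent bouts (sticky two-state chain with
    # stationary weight synchrony_weight), emulating consistent hop bouts.
    kappa = config.silenced_kappa
    w, rho = config.synchrony_weight, config.synchrony_persistence
    sync = np.zeros(n, dtype=bool)
    u = rng.random(n)
    state = u[0] < w
    sync[0] = state
    for i in range(1, n):
        p_sync = w + rho * (1.0 - w) if state else w * (1.0 - rho)
        state = u[i] < p_sync
        sync[i] = state
    mu_alt = 2 * np.pi * config.hind_phase_mean
    theta = np.where(
        sync,
        rng.vonmises(2 * np.pi * config.synchrony_phase, max(kappa, 2.0),
                     size=n),
        rng.vonmises(mu_alt, kappa, size=n) if not np.isinf(kappa)
        else np.full(n, mu_alt),
    )
    if config.drift_sd > 0:
        drift = np.cumsum(rng.normal(0.0, config.drift_sd, size=n))
        theta = theta + 2 * np.pi * drift
    return np.mod(theta / (2 * np.pi), 1.0)


def _draw_fore_phases(rng: np.random.Generator, n: int, config: SimulationConfig,
                      bias: float) -> np.ndarray:
    mu = 2 * np.pi * (config.fore_phase_mean + bias)
    if np.isinf(config.fore_kappa):
        theta = np.full(n, mu)
    else:
        theta = rng.vonmises(mu, config.fore_kappa, size=n)
    return np.mod(theta / (2 * np.pi), 1.0)


def simulate_footfalls(config: SimulationConfig) -> SyntheticDataset:
    """Generate footfall and swim tables for one condition.

    Right-hindlimb contacts are laid down from cumulative stride times; each
    left-hindlimb contact is placed at a drawn phase within the enclosing
    right stride.  Forelimb contacts are placed analogously (right forelimb
    offset a quarter cycle after the right hindlimb, left forelimb at the
    drawn forelimb phase within the right-forelimb stride), which yields the
    alternate step-sequence pattern under control phases.  Contact positions
    advance at the pass speed exactly, so ``stride_length = speed *
    stride_time`` per step; stance/swing split follows :func:`stance_fraction`.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[tuple] = []
    swim_rows: list[tuple] = []
    truth_passes: list[dict] = []

    for a in range(config.n_animals):
        animal = f"rat{a + 1:02d}"
        # per-animal lead-limb biases: fixed magnitude, random sign
        hind_bias = config.lead_bias * rng.choice([-1.0, 1.0])
        fore_bias = config.fore_lead_bias * rng.choice([-1.0, 1.0])
        for p in range(config.passes_per_animal):
            pass_id = f"{animal}_{config.timepoint}_p{p + 1}"
            speed = rng.uniform(*config.speed_range)
            t_mean = config.stride_time_mean * (
                config.cadence_ref_speed / speed) ** config.cadence_exponent
            # walkway length caps the number of cycles in a pass
            cap = max(2, int(config.walkway_length_cm // (speed * t_mean)))
            n_steps = min(config.steps_per_pass, cap)
            stride_times = np.maximum(
                rng.normal(t_mean, config.stride_time_sd, size=n_steps),
                0.25 * t_mean,
            )
            r = np.concatenate([[0.0], np.cumsum(stride_times)])  # RH contacts
            phases = _draw_phases(rng, n_steps, config, hind_bias)
            l = r[:-1] + phases * stride_times                    # LH contacts
            # lead-in LH contact so every limb has n_steps strides
            l = np.concatenate([[r[0] - (1.0 - phases[0]) * stride_times[0]], l])
            # forelimbs: RF a quarter cycle after RH, LF at fore phase in RF stride
            rf = r + 0.25 * np.concatenate([stride_times, stride_times[-1:]])
            fore_phases = _draw_fore_phases(rng, n_steps, config, fore_bias)
            rf_strides = np.diff(rf)
            lf = rf[:-1] + fore_phases * rf_strides
            lf = np.concatenate([[rf[0] - (1.0 - fore_phases[0]) * rf_strides[0]], lf])

            t0 = -min(l[0], lf[0]) + 0.05     # shift pass start to t >= 0
            stance = stance_fraction(speed, config)
            for limb, contacts in (("RH", r), ("LH", l), ("RF", rf), ("LF", lf)):
                contacts = contacts + t0
                gaps = np.diff(contacts)
                gaps = np.concatenate([gaps, gaps[-1:]])   # last: extrapolate
                liftoffs = contacts + stance * gaps
                offset = config.fore_hind_offset_cm if limb in FORE_LIMBS else 0.0
                xs = speed * contacts + offset
                for c, lo, x in zip(contacts, liftoffs, xs):
                    rows.append((animal, config.condition, config.timepoint,
                                 pass_id, limb, c, lo, x))
            truth_passes.append({
                "animal_id": animal, "pass_id": pass_id,
                "condition": config.condition, "speed_cm_s": speed,
                "stride_times_s": stride_times, "hind_phases": phases,
                "fore_phases": fore_phases, "hind_bias": hind_bias,
                "fore_bias": fore_bias,
                "kappa": (config.hind_kappa if config.condition == "control"
                          else config.silenced_kappa),
            })
        # swimming: condition-independent alternation
        for p in range(config.swim_passes_per_animal):
            pass_id = f"{animal}_{config.timepoint}_s{p + 1}"
            n_strokes = config.strokes_per_pass
            stroke_times = np.maximum(
                rng.normal(config.swim_stroke_time_mean,
                           config.swim_stroke_time_sd, size=n_strokes),
                0.25 * config.swim_stroke_time_mean,
            )
            r_peaks = np.concatenate([[0.1], 0.1 + np.cumsum(stroke_times)])
            theta = rng.vonmises(2 * np.pi * config.swim_phase_mean,
                                 config.swim_kappa, size=n_strokes)
            sphase = np.mod(theta / (2 * np.pi), 1.0)
            l_peaks = r_peaks[:-1] + sphase * stroke_times
            for t in r_peaks:
                swim_rows.append((animal, config.condition, pass_id, "right", t))
            for t in l_peaks:
                swim_rows.append((animal, config.condition, pass_id, "left", t))

    footfalls = pd.DataFrame(rows, columns=FOOTFALL_COLUMNS)
    footfalls = footfalls.sort_values(
        ["animal_id", "pass_id", "contact_time_s"], kind="stable"
    ).reset_index(drop=True)
    swim = pd.DataFrame(swim_rows, columns=SWIM_COLUMNS)
    truth = {
        "config": config.to_dict(),
        "passes": truth_passes,
    }
    return SyntheticDataset(footfalls=footfalls, swim=swim, markers=None,
                            truth=truth)


def _limb_angle_series(t: np.ndarray, contacts: np.ndarray,
                       config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Proximal/distal angle templates phase-locked to a limb's stride cycle.

    The distal angle peaks at stride phase 0 (contact); the proximal peak
    lags it by ``intralimb_lag`` of the cycle (0 = in-phase coordination).
    Outside the recorded contacts the last stride period is extrapolated.
    """
    if len(contacts) < 2:
        raise ValueError("need at least two contacts to define a stride cycle")
    idx = np.clip(np.searchsorted(contacts, t, side="right") - 1, 0,
                  len(contacts) - 2)
    starts = contacts[idx]
    periods = contacts[idx + 1] - contacts[idx]
    phase = (t - starts) / periods                     # may exceed [0,1) at edges
    distal = config.distal_mean_deg + config.distal_amp_deg * np.cos(
        2 * np.pi * phase)
    proximal = config.proximal_mean_deg + config.proximal_amp_deg * np.cos(
        2 * np.pi * (phase - config.intralimb_lag))
    return proximal, distal


def _markers_from_angles(x_crest: np.ndarray, y_crest: np.ndarray,
                         proximal_deg: np.ndarray, distal_deg: np.ndarray,
                         config: SimulationConfig) -> dict[str, np.ndarray]:
    """Place I, H, A, T so the interior angles at H and A equal the templates."""
    prox = np.deg2rad(proximal_deg)
    dist = np.deg2rad(distal_deg)
    ih_dir = np.deg2rad(-80.0)        # crest->hip direction, near vertical down
    ix, iy = x_crest, y_crest
    hx = ix + config.segment_upper_cm * np.cos(ih_dir)
    hy = iy + config.segment_upper_cm * np.sin(ih_dir)
    # hip->ankle: rotate hip->crest direction by -proximal (limb hangs forward)
    hi_dir = ih_dir + np.pi
    ha_dir = hi_dir - prox
    ax = hx + config.segment_thigh_cm * np.cos(ha_dir)
    ay = hy + config.segment_thigh_cm * np.sin(ha_dir)
    ah_dir = ha_dir + np.pi
    at_dir = ah_dir + dist
    tx = ax + config.segment_foot_cm * np.cos(at_dir)
    ty = ay + config.segment_foot_cm * np.sin(at_dir)
    return {
        "iliac_crest": np.stack([ix, iy], axis=1),
        "hip": np.stack([hx, hy], axis=1),
        "ankle": np.stack([ax, ay], axis=1),
        "toe": np.stack([tx, ty], axis=1),
    }


def simulate_markers(config: SimulationConfig,
                     footfalls: SyntheticDataset) -> SyntheticDataset:
    """Add 100-Hz marker trajectories phase-locked to each hindlimb's strides.

    For each pass, smooth periodic proximal/distal angle templates are
    evaluated against the hindlimb contact times, markers are placed so the
    interior angles reproduce the templates exactly, Gaussian position noise
    (``marker_noise_cm``) is added, and the iliac crest oscillates vertically
    with condition-dependent amplitude (raised hip excursion when silenced).
    """
    if footfalls.footfalls.empty:
        raise ValueError("footfall table is empty")
    rng = np.random.default_rng(config.seed + 1_000_003)
    dt = 1.0 / config.frame_rate_hz
    hip_amp = (config.hip_osc_amp_silenced_cm if config.condition == "silenced"
               else config.hip_osc_amp_cm)
    rows = []
    truth_angles = []
    ff = footfalls.footfalls
    pass_speeds = {p["pass_id"]: p["speed_cm_s"]
                   for p in footfalls.truth.get("passes", [])}
    for (animal, pass_id), grp in ff.groupby(["animal_id", "pass_id"], sort=True):
        speed = float(pass_speeds.get(pass_id, np.nan))
        if np.isnan(speed):
            # fall back to pass-level displacement speed
            rh = grp[grp.limb == "RH"]
            speed = ((rh.contact_x_cm.iloc[-1] - rh.contact_x_cm.iloc[0]) /
                     (rh.contact_time_s.iloc[-1] - rh.contact_time_s.iloc[0]))
        for side, limb in (("left", "LH"), ("right", "RH")):
            contacts = grp.loc[grp.limb == limb, "contact_time_s"].to_numpy()
            if len(contacts) < 2:
                continue
            t = np.arange(contacts[0], contacts[-1], dt)
            frames = np.arange(len(t))
            proximal, distal = _limb_angle_series(t, contacts, config)
            # crest advances at pass speed; vertical oscillation at stride rate
            mean_period = np.diff(contacts).mean()
            x_crest = speed * t
            y_crest = 12.0 + hip_amp * np.sin(2 * np.pi * t / mean_period)
            markers = _markers_from_angles(x_crest, y_crest, proximal, distal,
                                           config)
            for name, xy in markers.items():
                noisy = xy + rng.normal(0.0, config.marker_noise_cm, xy.shape) \
                    if config.marker_noise_cm > 0 else xy
                for fr, tt, (mx, my) in zip(frames, t, noisy):
                    rows.append((animal, pass_id, int(fr), tt, side, name,
                                 mx, my))
            truth_angles.append({
                "animal_id": animal, "pass_id": pass_id, "side": side,
                "time_s": t, "proximal_deg": proximal, "distal_deg": distal,
                "intralimb_lag": config.intralimb_lag,
            })
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    truth = dict(footfalls.truth)
    truth["marker_angles"] = truth_angles
    return SyntheticDataset(footfalls=footfalls.footfalls, swim=footfalls.swim,
                            markers=markers, truth=truth)
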