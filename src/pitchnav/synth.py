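"""Synthetic swim-behavior generator with known ground truth.

Every downstream stage (segmentation, kinematics, model fits, resolution)
can be validated against data generated here, with every latent per-bout
value logged.  The generator emulates 166 Hz epochs containing discrete
speed bouts with posture dynamics:

* bout onsets follow a posture-dependent renewal process whose expected
  bout frequency is the timing parabola ``a (pitch - b)^2 + c``: after each
  bout, a target frequency is drawn from the parabola (plus noise) at the
  current pitch, and the next sub-threshold gap is set to the matching
  duration (including the two 100 ms detection buffers);
* each bout carries a Gaussian speed bump (peak drawn from a lognormal
  matching the observed 12.90 +/- 4.91 mm/s, floored at 6 mm/s for
  detectability) and a smooth pre-peak steering rotation whose angular
  velocity peaks 50 ms before peak speed;
* attack angle is coupled to the realized pre-peak body rotation through an
  increasing sigmoid (the fin-body relation), and the bout's displacement
  direction realizes trajectory = pitch at peak + attack angle + thrust
  noise;
* after peak speed the fish rights: the post-peak rotation is
  ``-gain * (initial pitch - set point)`` plus noise, which also makes the
  pitch distribution stationary (mean ~ set point, SD set by the steering
  rotation spread);
* slow baseline pitch drift (random walk) and per-frame measurement noise
  are added on top.

Because attack angle is *defined* as trajectory minus pitch at peak speed,
the steering gain cannot be dialed independently of the fin-body coupling:
the generator instead records the latent-population regression slope as
``steering_gain_true`` (and can approximate a requested gain by inflating
the thrust-direction noise).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter
from scipy.stats import norm

from .io import DLM_COLUMNS, RunMetadata, write_dlm, write_metadata

__all__ = [
    "GeneratorParams",
    "generate_epoch",
    "simulate_dataset",
    "generate_dataset",
    "SimulatedDataset",
]

SPEED_THRESHOLD = 5.0  # mm/s, must match the analysis bout threshold


@dataclass
class GeneratorParams:
    """Ground-truth parameters of the synthetic behavior.

    Defaults are the study conditions: 166 Hz acquisition, peak speeds
    matching the observed 12.90 +/- 4.91 mm/s, pitch distribution with
    ~8.5 deg mean and ~15 deg SD, and model coefficients in the observed
    range for 7 dpf larvae.
    """

    frame_rate: float = 166.0
    mm_per_pixel: float = 60.0 / 1200.0
    # bout speed profile
    peak_speed_mean: float = 12.9  # mm/s, lognormal target mean
    peak_speed_sd: float = 4.9  # mm/s, lognormal target SD
    peak_speed_floor: float = 6.0  # redraw below this (detectability)
    speed_profile_sd_ms: float = 60.0  # Gaussian bump width
    # bout timing parabola: frequency = a*(pitch-b)^2 + c
    timing_a: float = 0.003  # Hz/deg^2 (sensitivity)
    timing_b: float = 8.5  # deg (baseline posture)
    timing_c: float = 1.25  # Hz (base rate)
    freq_noise_sd: float = 0.3  # Hz
    freq_min: float = 0.3
    freq_max: float = 8.0
    # steering rotation and its time course
    steer_sd: float = 8.4  # deg, per-bout steering rotation spread
    t_maxangvel_ms: float = -50.0  # angular-velocity peak, rel. peak speed
    angvel_bump_sd_ms: float = 40.0
    # fin-body sigmoid: attack = a0 + h / (1 + exp(-k*(body_rot + b)))
    finbody_k: float = 0.4  # 1/deg
    finbody_h: float = 8.0  # deg
    finbody_b: float = 2.0  # deg, sigmoid center at body rotation -b
    finbody_a0: float = -1.5  # deg
    attack_noise_sd: float = 1.5  # deg
    # trajectory (thrust direction) noise; replaced by a calibrated value
    # when steering_gain is requested explicitly
    traj_noise_sd: float = 1.5  # deg
    steering_gain: float | None = None  # None -> emergent
    # righting: rotation = -gain*(p_init - set_point) + noise
    righting_gain: float = 0.18
    set_point: float = 8.5  # deg
    righting_noise_sd: float = 1.5  # deg
    # baseline drift and measurement noise
    pitch_walk_sd: float = 0.5  # deg / sqrt(s) random walk
    pitch_noise_sd: float = 0.25  # deg, per-frame measurement noise
    jitter_speed_sd: float = 0.25  # mm/s per axis between bouts
    jitter_tau_s: float = 1.0  # drift-velocity correlation time
    start_pitch_sd: float = 15.0
    pitch_limit: float = 75.0
    # bookkeeping
    epoch_duration_s: float = 30.0
    animal_length_px: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timing_a < 0:
            raise ValueError("timing_a must be >= 0")
        if self.timing_c <= 0:
            raise ValueError("timing_c must be > 0 (bout rate)")
        for name in ("peak_speed_mean", "peak_speed_sd", "speed_profile_sd_ms",
                     "steer_sd", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_speed_floor <= SPEED_THRESHOLD:
            raise ValueError("peak_speed_floor must exceed the 5 mm/s bout threshold")

    @property
    def fin_body_ratio(self) -> float:
        return self.finbody_k * self.finbody_h / 4.0

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying normal for the peak-speed lognormal."""
        cv2 = (self.peak_speed_sd / self.peak_speed_mean) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.log(self.peak_speed_mean) - sigma2 / 2.0
        return mu, float(np.sqrt(sigma2))


# ---------------------------------------------------------------------------
# epoch planning


@dataclass
class _EpochPlan:
    t: np.ndarray
    pitch_latent: np.ndarray
    bouts: pd.DataFrame  # latent per-bout values (no trajectory yet)
    bump_segments: list[tuple[slice, np.ndarray]]  # speed bump per bout
    heading: int


def _steer_profile(params: GeneratorParams, fr: float) -> np.ndarray:
    """Normalized steering time course on frames [-250 ms, 0] rel. peak.

    Truncated-Gaussian CDF whose derivative (the angular velocity) peaks at
    ``t_maxangvel_ms``; 0 at -250 ms, 1 at peak speed.
    """
    n_pre = int(round(250.0 * fr / 1000.0))
    t = np.arange(-n_pre, 1) / fr
    mu = params.t_maxangvel_ms / 1000.0
    sd = params.angvel_bump_sd_ms / 1000.0
    cdf = norm.cdf((t - mu) / sd)
    return (cdf - cdf[0]) / (cdf[-1] - cdf[0])


def _righting_profile(fr: float) -> np.ndarray:
    """Smoothstep 0 -> 1 over [0, +100 ms]."""
    n = int(round(100.0 * fr / 1000.0))
    u = np.arange(n + 1) / n
    return 3 * u**2 - 2 * u**3


def _plan_epoch(
    params: GeneratorParams,
    duration_s: float,
    rng: np.random.Generator,
) -> _EpochPlan:
    fr = params.frame_rate
    dt = 1.0 / fr
    n = int(round(duration_s * fr))
    t = np.arange(n) * dt
    walk = np.cumsum(rng.normal(0.0, params.pitch_walk_sd * np.sqrt(dt), n))
    p_start = float(
        np.clip(
            rng.normal(params.set_point, params.start_pitch_sd),
            -params.pitch_limit * 0.8,
            params.pitch_limit * 0.8,
        )
    )
    inc = np.zeros(n)
    sprof = _steer_profile(params, fr)
    rprof = _righting_profile(fr)
    n_steer, n_right = len(sprof) - 1, len(rprof) - 1
    bump_sd = params.speed_profile_sd_ms / 1000.0
    mu_ln, sd_ln = params.lognormal_params()

    offset = 0.0
    t_down_prev: float | None = None
    rows = []
    segments: list[tuple[slice, np.ndarray]] = []
    while True:
        # peak speed (redraw below the detectability floor)
        for _ in range(100):
            A = float(rng.lognormal(mu_ln, sd_ln))
            if A >= params.peak_speed_floor:
                break
        w_half = bump_sd * np.sqrt(2.0 * np.log(A / SPEED_THRESHOLD))
        # posture-dependent bout timing
        i_cursor = min(int(round((t_down_prev or 0.0) / dt)), n - 1)
        hazard_pitch = p_start + walk[i_cursor] + offset
        f = params.timing_a * (hazard_pitch - params.timing_b) ** 2 + params.timing_c
        f = float(np.clip(f + rng.normal(0.0, params.freq_noise_sd),
                          params.freq_min, params.freq_max))
        # the gap (time between threshold crossings) carries the measured
        # IBI: buffer-corrected duration 1/f; subtract one dt so the
        # frame-sampled crossing times are centered on the target
        gap = 0.2 + 1.0 / f - dt
        if t_down_prev is None:
            t_peak = max(0.52, gap) + w_half
        else:
            t_peak = t_down_prev + gap + w_half
        if t_peak + 0.35 > duration_s:
            break
        i_peak = int(round(t_peak / dt))
        i0 = i_peak - n_steer

        steer = float(rng.normal(0.0, params.steer_sd))
        p_init = p_start + walk[i0] + offset
        righting = float(
            -params.righting_gain * (p_init - params.set_point)
            + rng.normal(0.0, params.righting_noise_sd)
        )
        inc[i0 : i_peak + 1] += steer * sprof
        inc[i_peak + 1 :] += steer
        inc[i_peak : i_peak + n_right + 1] += righting * rprof
        inc[i_peak + n_right + 1 :] += righting

        lo = max(0, i_peak - int(round(4 * bump_sd / dt)))
        hi = min(n, i_peak + int(round(4 * bump_sd / dt)) + 1)
        bump = A * np.exp(-((t[lo:hi] - t_peak) ** 2) / (2 * bump_sd**2))
        segments.append((slice(lo, hi), bump))

        rows.append(
            {
                "i_peak": i_peak,
                "t_peak": t_peak,
                "peak_speed": A,
                "f_target": f,
                "hazard_pitch": hazard_pitch,
                "steer": steer,
                "righting": righting,
                "gap_s": gap,
            }
        )
        offset += steer + righting
        t_down_prev = t_peak + w_half

    pitch_latent = p_start + walk + inc
    bouts = pd.DataFrame(
        rows,
        columns=["i_peak", "t_peak", "peak_speed", "f_target", "hazard_pitch",
                 "steer", "righting", "gap_s"],
    )
    if len(bouts):
        fr_ms = fr / 1000.0
        i_pk = bouts["i_peak"].to_numpy(int)
        i_init = i_pk - n_steer
        i_mav = i_pk + int(round(params.t_maxangvel_ms * fr_ms))
        i_post = i_pk + n_right
        bouts["pitch_initial"] = pitch_latent[i_init]
        bouts["pitch_peak"] = pitch_latent[i_pk]
        bouts["pitch_post"] = pitch_latent[i_post]
        bouts["body_rotation"] = pitch_latent[i_mav] - pitch_latent[i_init]
        bouts["residual_rotation"] = pitch_latent[i_pk] - pitch_latent[i_mav]
        x = bouts["body_rotation"].to_numpy()
        bouts["attack_angle"] = (
            params.finbody_a0
            + params.finbody_h / (1.0 + np.exp(-params.finbody_k * (x + params.finbody_b)))
            + rng.normal(0.0, params.attack_noise_sd, len(bouts))
        )
    heading = int(rng.integers(0, 2)) * 2 - 1
    return _EpochPlan(t=t, pitch_latent=pitch_latent, bouts=bouts,
                      bump_segments=segments, heading=heading)


def _assemble_epoch(
    plan: _EpochPlan,
    params: GeneratorParams,
    rng: np.random.Generator,
    traj_noise_sd: float,
    epoch_id: int,
    t_offset: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn a plan into raw-trace frames (trajectory realized here)."""
    fr = params.frame_rate
    dt = 1.0 / fr
    n = len(plan.t)
    bouts = plan.bouts.copy()
    traj_noise = rng.normal(0.0, traj_noise_sd, len(bouts))
    bouts["traj_noise"] = traj_noise
    bouts["trajectory"] = bouts["pitch_peak"] + bouts["attack_angle"] + traj_noise

    # slow drift velocity: AR(1) with correlation time jitter_tau_s, so the
    # baseline speed is smooth and never chops a threshold crossing into
    # multiple runs
    rho = float(np.exp(-dt / params.jitter_tau_s))
    innov = rng.normal(0.0, params.jitter_speed_sd, (2, n))
    scale = np.sqrt(1.0 - rho**2)
    innov[:, 1:] *= scale  # first sample keeps the stationary variance
    drift = lfilter([1.0], [1.0, -rho], innov, axis=1)
    vx, vz = drift[0], drift[1]
    for (sl, bump), traj in zip(plan.bump_segments, bouts["trajectory"]):
        th = np.radians(traj)
        vx[sl] += bump * np.cos(th) * plan.heading
        vz[sl] += bump * np.sin(th)
    x_mm = np.cumsum(vx) * dt
    z_mm = np.cumsum(vz) * dt

    pitch_meas = plan.pitch_latent + rng.normal(0.0, params.pitch_noise_sd, n)
    mpp = params.mm_per_pixel
    body_x = 600.0 + x_mm / mpp
    body_z = 608.0 + z_mm / mpp
    L = params.animal_length_px + rng.normal(0.0, 2.0, n)
    half = L / 2.0
    th = np.radians(pitch_meas)
    head_x = body_x + half * np.cos(th) * plan.heading
    head_z = body_z + half * np.sin(th)

    trace = pd.DataFrame(
        {
            "time_stamp": plan.t + t_offset,
            "body_x": body_x,
            "body_z": body_z,
            "head_x": head_x,
            "head_z": head_z,
            "pitch": pitch_meas,
            "epoch_id": np.full(n, epoch_id, dtype=np.int64),
            "animal_length": L,
        }
    )[DLM_COLUMNS]
    bouts.insert(0, "epoch_id", epoch_id)
    bouts["t_peak"] += t_offset
    return trace, bouts


def generate_epoch(
    params: GeneratorParams,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    epoch_id: int = 0,
    t_offset: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one epoch; returns ``(trace, ground_truth_bouts)``.

    The trace is a raw-trace DataFrame (``.dlm`` schema) and the ground
    truth has one row per emitted bout with every latent value (steering,
    body/residual rotation, attack angle, trajectory, righting, target
    bout frequency, peak speed).
    """
    if duration_s < 2.5:
        raise ValueError("epoch duration must be at least 2.5 s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    plan = _plan_epoch(params, duration_s, rng)
    return _assemble_epoch(plan, params, rng, params.traj_noise_sd, epoch_id, t_offset)


# ---------------------------------------------------------------------------
# dataset-level generation


@dataclass
class SimulatedDataset:
    """In-memory synthetic dataset: one trace + truth table per repeat."""

    params: GeneratorParams
    repeats: list[tuple[pd.DataFrame, pd.DataFrame]]
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_bouts(self) -> int:
        return sum(len(truth) for _, truth in self.repeats)

    def metadata(self) -> RunMetadata:
        return RunMetadata(
            frame_rate=self.params.frame_rate,
            mm_per_pixel=self.params.mm_per_pixel,
            start_time=datetime(2000, 1, 1, 9, 0, 0),
        )


def _calibrated_traj_sd(
    params: GeneratorParams, pp: np.ndarray, att: np.ndarray
) -> float:
    """Thrust-noise SD that makes the population steering gain hit the target.

    With trajectory = pitch_peak + attack + eps, the regression slope of
    pitch_peak on trajectory is (Spp + C) / (Spp + Sa + 2C + var(eps));
    solve for var(eps).  Falls back to 0 (with a warning) if the requested
    gain exceeds the gain the latent structure already implies.
    """
    if params.steering_gain is None:
        return params.traj_noise_sd
    spp = float(np.var(pp))
    sa = float(np.var(att))
    c = float(np.cov(pp, att)[0, 1])
    var_eps = (spp + c) / params.steering_gain - (spp + sa + 2 * c)
    if var_eps < 0:
        warnings.warn(
            f"requested steering_gain={params.steering_gain} exceeds the "
            "latent-structure maximum; using zero trajectory noise"
        )
        return 0.0
    return float(np.sqrt(var_eps))


def simulate_dataset(
    params: GeneratorParams,
    n_repeats: int,
    bouts_per_repeat: int,
    seed: int | None = None,
) -> SimulatedDataset:
    """Simulate a multi-repeat dataset with a ground-truth manifest.

    Epochs of ``params.epoch_duration_s`` are generated until each repeat
    holds at least ``bouts_per_repeat`` bouts.  Planning (pitch dynamics,
    bout latents) is completed for the whole dataset first so the
    trajectory-noise calibration — and hence ``steering_gain_true`` — is
    computed on the pooled latent population.
    """
    if n_repeats <= 0 or bouts_per_repeat <= 0:
        raise ValueError("n_repeats and bouts_per_repeat must be positive")
    master = params.seed if seed is None else seed
    plans: list[list[_EpochPlan]] = []
    for rep in range(n_repeats):
        rep_plans: list[_EpochPlan] = []
        total = 0
        ep = 0
        while total < bouts_per_repeat:
            rng = np.random.default_rng([master, 11, rep, ep])
            plan = _plan_epoch(params, params.epoch_duration_s, rng)
            if len(plan.bouts):
                rep_plans.append(plan)
                total += len(plan.bouts)
            ep += 1
        plans.append(rep_plans)

    all_pp = np.concatenate(
        [p.bouts["pitch_peak"].to_numpy() for rp in plans for p in rp]
    )
    all_att = np.concatenate(
        [p.bouts["attack_angle"].to_numpy() for rp in plans for p in rp]
    )
    traj_sd = _calibrated_traj_sd(params, all_pp, all_att)

    repeats = []
    for rep, rep_plans in enumerate(plans):
        traces, truths = [], []
        t_offset = 0.0
        for ep, plan in enumerate(rep_plans):
            rng = np.random.default_rng([master, 12, rep, ep])
            trace, truth = _assemble_epoch(plan, params, rng, traj_sd, ep, t_offset)
            traces.append(trace)
            truths.append(truth)
            t_offset += params.epoch_duration_s + 5.0
        repeats.append(
            (pd.concat(traces, ignore_index=True), pd.concat(truths, ignore_index=True))
        )

    all_traj = np.concatenate([tr["trajectory"].to_numpy() for _, tr in repeats])
    all_pp2 = np.concatenate([tr["pitch_peak"].to_numpy() for _, tr in repeats])
    slope = float(np.polyfit(all_traj, all_pp2, 1)[0])
    ground_truth = {
        "sensitivity": params.timing_a,
        "baseline_posture": params.timing_b,
        "base_rate": params.timing_c,
        "steering_gain_true": slope,
        "fin_body_ratio": params.fin_body_ratio,
        "finbody_k": params.finbody_k,
        "finbody_h": params.finbody_h,
        "righting_gain": params.righting_gain,
        "set_point": params.set_point,
        "t_maxangvel_ms": params.t_maxangvel_ms,
        "traj_noise_sd_used": traj_sd,
    }
    return SimulatedDataset(params=params, repeats=repeats, ground_truth=ground_truth)


def generate_dataset(
    params: GeneratorParams,
    n_repeats: int,
    bouts_per_repeat: int,
    out_dir: str | Path,
    seed: int | None = None,
) -> SimulatedDataset:
    """Simulate and write a dataset: one ``.dlm`` per repeat + manifest.

    Writes ``repeat_<k>.dlm``, one shared ``metadata.txt``, a
    ``manifest.yaml`` holding the generator parameters and dataset-level
    ground truths, and ``ground_truth_bouts.csv`` with every latent
    per-bout value.  Byte-identical output for identical seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(params, n_repeats, bouts_per_repeat, seed)
    files = []
    truth_all = []
    for rep, (trace, truth) in enumerate(ds.repeats):
        name = f"repeat_{rep:03d}.dlm"
        write_dlm(trace, out / name)
        files.append(name)
        t = truth.copy()
        t.insert(0, "repeat_id", rep)
        truth_all.append(t)
    write_metadata(ds.metadata(), out / "metadata.txt")
    pd.concat(truth_all, ignore_index=True).to_csv(
        out / "ground_truth_bouts.csv", index=False
    )
    manifest = {
        "params": dataclasses.asdict(ds.params),
        "ground_truth": ds.ground_truth,
        "files": files,
        "n_bouts": ds.n_bouts,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return ds
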