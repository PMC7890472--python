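"""Synthetic dyadic-motion studies with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without external data:

* Body movement is a smooth, stationary, unit-variance process: each body
  site's latent angular-velocity signal is an Ornstein–Uhlenbeck (OU)
  process (mean reversion θ = 1 s⁻¹) sampled at the device rate.
* Coordination is a lagged linear coupling: the interviewee's latent signal
  is ``κ·leader(t − τ(t)) + sqrt(1 − κ²)·independent`` with a slowly
  drifting lag ``τ(t) = τ0 + lag_drift·sin(2πt/60)``; the construction
  preserves unit variance for every coupling strength κ ∈ [0, 1].
* Device capture adds Gaussian sensor noise, integer quantization to device
  counts, a ~0.5% rate of out-of-range recording errors, and per-device
  recording-start offsets (timestamps share the capture host clock, but a
  device that starts late contributes no samples before its offset).
* Veracity judgements are drawn directly at a target coded-accuracy level
  per task, on the 7-point truthfulness scale.

Per-dyad randomness is derived from a counter-based seed sequence, so
adding dyads never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import DyadwarpError
from .sensor_io import SITES, DyadSession

__all__ = [
    "CouplingSpec",
    "GroundTruth",
    "simulate_leader",
    "simulate_follower",
    "inject_artifacts",
    "simulate_study",
    "DEFAULT_KAPPA_BY_TASK",
    "DEFAULT_ACCURACY",
]

# Coupling strengths per task. These are generator defaults chosen so that
# the qualitative ordering of coordination with lie difficulty is detectable
# at the study's sample size; they are not measured quantities.
DEFAULT_KAPPA_BY_TASK = {
    "easy_lie": 0.20,
    "truth": 0.30,
    "difficult_lie": 0.45,
    "very_difficult_lie": 0.60,
}

# Target probabilities that a veracity judgement is coded correct, by design
# and task (observed detection rates of the two experiments).
DEFAULT_ACCURACY = {
    "exp1": {"easy_lie": 0.16, "difficult_lie": 0.32, "very_difficult_lie": 0.57, "truth": 0.63},
    "exp2": {"easy_lie": 0.29, "very_difficult_lie": 0.52, "truth": 0.74},
}

DESIGN_TASKS = {
    "exp1": ("truth", "easy_lie", "difficult_lie", "very_difficult_lie"),
    "exp2": ("truth", "easy_lie", "very_difficult_lie"),
}

DEVICE_SCALE = 100.0  # device counts per unit of latent signal
TASK_GAP_S = 5.0      # pause between questioning segments


@dataclass(frozen=True)
class CouplingSpec:
    """Parameters of one simulated stream pair."""

    kappa: float = 0.3
    tau0: float = 0.5              # base lag, s
    lag_drift: float = 0.2         # slow lag modulation amplitude, s
    dyad_effect_sd: float = 0.1    # between-dyad SD on kappa
    noise_sd: float = 0.05         # sensor noise SD, latent units
    artifact_rate: float = 0.005   # out-of-range spike probability per sample
    clock_offset_ms: int = 0       # recording-start delay of the device
    rate_hz: float = 120.0
    duration_s: float = 30.0   # length of the simulated questioning excerpt per task

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise DyadwarpError(f"kappa must be in [0, 1], got {self.kappa}")
        if not 0.0 <= self.artifact_rate <= 0.05:
            raise DyadwarpError("artifact_rate must be in [0, 0.05]")
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise DyadwarpError("rate and duration must be positive")
        if self.clock_offset_ms < 0 or self.noise_sd < 0:
            raise DyadwarpError("offsets and noise SD must be non-negative")


@dataclass
class GroundTruth:
    """Generating values behind a simulated study (the recovery oracle)."""

    kappa: pd.DataFrame                 # dyad_id, task, kappa (post dyad effect)
    dyad_effect: Dict[str, float]
    clock_offsets: Dict[Tuple[str, str, str], int]   # (dyad, role, site) -> ms
    spike_rows: Dict[Tuple[str, str, str], np.ndarray]
    lag: Dict[str, float]               # tau0 / lag_drift actually used


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def _ou(rng: np.random.Generator, n: int, dt: float, theta: float, sd: float) -> np.ndarray:
    """Exact discretization of a stationary OU process with stationary SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    a = math.exp(-theta * dt)
    innov_sd = sd * math.sqrt(1.0 - a * a)
    u = rng.normal(size=n) * innov_sd
    u[0] = rng.normal() * sd  # draw x0 from the stationary law
    return lfilter([1.0], [1.0, -a], u)


def _t_ms(n: int, rate_hz: float, start_ms: int = 0) -> np.ndarray:
    return (np.round(np.arange(n) * 1000.0 / rate_hz) + start_ms).astype(np.int64)


def _latent_frame(t_ms: np.ndarray, vals: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"t_ms": t_ms, "gx": vals[:, 0], "gy": vals[:, 1], "gz": vals[:, 2]}
    )


def simulate_leader(
    duration_s: float,
    rate_hz: float = 120.0,
    seed: int = 0,
    theta: float = 1.0,
    stationary_sd: float = 1.0,
    start_s: float = 0.0,
) -> pd.DataFrame:
    """Latent 3-axis leader movement: independent OU processes per axis.

    Returns a stream DataFrame (``t_ms, gx, gy, gz``) in latent units
    (unit stationary SD by default).  ``start_s`` may be negative to
    provide lead-in history for a lagged follower.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise DyadwarpError("duration and rate must be positive")
    rng = _rng(seed, 0)
    dt = 1.0 / rate_hz
    n = int(round(duration_s * rate_hz))
    vals = np.column_stack([_ou(rng, n, dt, theta, stationary_sd) for _ in range(3)])
    t = np.round((np.arange(n) * dt + start_s) * 1000.0).astype(np.int64)
    return _latent_frame(t, vals)


def simulate_follower(
    leader: pd.DataFrame, spec: CouplingSpec, seed: int = 0, theta: float = 1.0
) -> pd.DataFrame:
    """Latent follower stream coupled to ``leader`` with strength κ.

    ``follower(t) = κ·leader(t − τ(t)) + sqrt(1 − κ²)·OU(t) + ε(t)`` with
    ``τ(t) = τ0 + lag_drift·sin(2πt/60)`` and sensor noise SD
    ``spec.noise_sd``.  The follower is emitted on the non-negative part of
    the leader's time grid; leader history before its first sample (when no
    lead-in was generated) is extrapolated as its first value.
    """
    if leader.empty:
        raise DyadwarpError("leader stream is empty")
    tL = leader["t_ms"].to_numpy() / 1000.0
    if spec.tau0 + spec.lag_drift >= tL[-1]:
        raise DyadwarpError("lag exceeds the leader's duration")
    mask = tL >= 0.0
    t = tL[mask]
    rng = _rng(seed, 1)
    dt = float(np.median(np.diff(tL)))
    tau = spec.tau0 + spec.lag_drift * np.sin(2.0 * np.pi * t / 60.0)
    k = spec.kappa
    vals = np.empty((t.size, 3))
    for ax, col in enumerate(("gx", "gy", "gz")):
        lead = np.interp(t - tau, tL, leader[col].to_numpy())
        indep = _ou(rng, t.size, dt, theta, 1.0)
        vals[:, ax] = k * lead + math.sqrt(1.0 - k * k) * indep
    if spec.noise_sd > 0:
        vals += rng.normal(scale=spec.noise_sd, size=vals.shape)
    return _latent_frame(np.round(t * 1000.0).astype(np.int64), vals)


def inject_artifacts(
    samples: pd.DataFrame,
    spec: CouplingSpec,
    seed: int = 0,
    valid_range: Tuple[float, float] = (-500.0, 500.0),
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Device-capture defects: out-of-range spikes and a recording-start offset.

    Each sample is independently replaced by an out-of-range reading with
    probability ``spec.artifact_rate``; samples before the device's
    recording-start offset are absent from its file.  Returns the defective
    stream and the row indices (into the returned frame) of injected spikes.
    """
    rng = _rng(seed, 2)
    df = samples.copy(deep=True)
    keep = df["t_ms"].to_numpy() >= spec.clock_offset_ms
    df = df.loc[keep].reset_index(drop=True)
    n = len(df)
    spikes = np.nonzero(rng.random(n) < spec.artifact_rate)[0]
    if spikes.size:
        lo, hi = valid_range
        mag = rng.uniform(1.1, 2.0, size=(spikes.size, 3)) * max(abs(lo), abs(hi))
        sign = rng.choice([-1.0, 1.0], size=(spikes.size, 3))
        spike_vals = sign * mag
        vals = df[["gx", "gy", "gz"]].to_numpy()
        if np.issubdtype(vals.dtype, np.integer):
            # keep device streams integer-valued (they are ADC counts)
            spike_vals = np.round(spike_vals)
        vals = vals.astype(float)
        vals[spikes] = spike_vals
        out = vals.astype(np.int64) if np.array_equal(vals, vals.astype(np.int64)) else vals
        df[["gx", "gy", "gz"]] = out
    return df, spikes


def _exp2_instructions(n: int) -> List[str]:
    # instruction-group allocation 12:14:16 of 42, scaled to n
    n_nv = int(round(n * 12 / 42))
    n_v = int(round(n * 14 / 42))
    return ["nonverbal"] * n_nv + ["verbal"] * n_v + ["none"] * (n - n_nv - n_v)


def _draw_rating(rng, veracity: str, p_correct: float) -> int:
    correct = rng.random() < p_correct
    if veracity == "truth":
        choices = (5, 6, 7) if correct else (1, 2, 3, 4)
    else:
        choices = (1, 2, 3) if correct else (4, 5, 6, 7)
    return int(rng.choice(choices))


def simulate_study(
    n_dyads: int = 43,
    design: str = "exp1",
    kappa_by_task: Optional[Dict[str, float]] = None,
    judgement_accuracy_by_task: Optional[Dict[str, float]] = None,
    seed: int = 0,
    spec: CouplingSpec = CouplingSpec(),
    sites: Iterable[str] = SITES,
) -> Tuple[List[DyadSession], pd.DataFrame, GroundTruth]:
    """Generate a full synthetic study.

    ``design`` mirrors the two experiments: ``exp1`` (all dyads do truth and
    easy lie; half the difficult lie, half the very difficult lie; order
    counterbalanced) or ``exp2`` (truth, easy and very difficult lie for
    everyone; between-dyad attention instruction allocated 12:14:16).
    Judgement ratings are drawn so that the coded accuracy matches
    ``judgement_accuracy_by_task``.  Everything is a pure function of
    (parameters, seed).
    """
    if design not in DESIGN_TASKS:
        raise DyadwarpError(f"unknown design {design!r}; use 'exp1' or 'exp2'")
    sites = tuple(sites)
    kappa_by_task = dict(kappa_by_task or DEFAULT_KAPPA_BY_TASK)
    acc = dict(judgement_accuracy_by_task or DEFAULT_ACCURACY[design])
    n_difficult = int(math.ceil(n_dyads / 2))
    instructions = _exp2_instructions(n_dyads) if design == "exp2" else None

    sessions: List[DyadSession] = []
    judgement_rows = []
    kappa_rows = []
    dyad_effect: Dict[str, float] = {}
    clock_offsets: Dict[Tuple[str, str, str], int] = {}
    spike_rows: Dict[Tuple[str, str, str], np.ndarray] = {}

    dt = 1.0 / spec.rate_hz
    seg_n = int(round(spec.duration_s * spec.rate_hz))
    gap_n = int(round(TASK_GAP_S * spec.rate_hz))
    pad_s = spec.tau0 + spec.lag_drift + 0.5
    pad_n = int(round(pad_s * spec.rate_hz))

    for d in range(n_dyads):
        dyad_id = f"dyad{d:03d}"
        rng = _rng(seed, 10, d)
        b_dyad = float(rng.normal(scale=spec.dyad_effect_sd))
        dyad_effect[dyad_id] = b_dyad

        if design == "exp1":
            third = "difficult_lie" if d < n_difficult else "very_difficult_lie"
            tasks = ["truth", "easy_lie", third]
        else:
            tasks = list(DESIGN_TASKS["exp2"])
        order_variant = "forward" if d % 2 == 0 else "reverse"
        if order_variant == "reverse":
            tasks = tasks[::-1]

        # session timeline: gap, task, gap, task, ...
        marks = []
        t_cursor = gap_n
        task_slices = {}
        for task in tasks:
            task_slices[task] = (t_cursor, t_cursor + seg_n)
            marks.append((task, "start", int(round(t_cursor * dt * 1000.0))))
            marks.append((task, "end", int(round((t_cursor + seg_n - 1) * dt * 1000.0))))
            t_cursor += seg_n + gap_n
        n_total = t_cursor
        t_grid = _t_ms(n_total, spec.rate_hz)
        t_s = np.arange(n_total) * dt

        kappa_t = np.zeros(n_total)
        for task, (i0, i1) in task_slices.items():
            k = float(np.clip(kappa_by_task[task] + b_dyad, 0.0, 1.0))
            kappa_t[i0:i1] = k
            kappa_rows.append({"dyad_id": dyad_id, "task": task, "kappa": k})

        streams = {}
        for s_idx, site in enumerate(sites):
            srng = _rng(seed, 20, d, s_idx)
            # leader latent with lead-in history for the lagged copy
            lead_full = np.column_stack(
                [_ou(srng, n_total + pad_n, dt, 1.0, 1.0) for _ in range(3)]
            )
            leader = lead_full[pad_n:]
            tau = spec.tau0 + spec.lag_drift * np.sin(2.0 * np.pi * t_s / 60.0)
            pos = np.arange(n_total) - tau * spec.rate_hz + pad_n
            vals_f = np.empty((n_total, 3))
            root = np.sqrt(1.0 - kappa_t**2)
            for ax in range(3):
                lagged = np.interp(pos, np.arange(n_total + pad_n), lead_full[:, ax])
                indep = _ou(srng, n_total, dt, 1.0, 1.0)
                vals_f[:, ax] = kappa_t * lagged + root * indep
            for role, vals in (("interviewer", leader), ("interviewee", vals_f)):
                # device capture: sensor noise, integer counts, start offset,
                # out-of-range spikes (same defect model as inject_artifacts)
                drng = _rng(seed, 30, d, s_idx, 0 if role == "interviewer" else 1)
                noisy = vals + drng.normal(scale=spec.noise_sd, size=vals.shape)
                counts = np.round(noisy * DEVICE_SCALE).astype(np.int64)
                offset = int(drng.integers(0, 1501))
                i0 = int(np.searchsorted(t_grid, offset, side="left"))
                t_dev = t_grid[i0:]
                counts = counts[i0:].copy()
                spikes = np.nonzero(drng.random(len(t_dev)) < spec.artifact_rate)[0]
                if spikes.size:
                    mag = drng.uniform(1.1, 2.0, size=(spikes.size, 3)) * 500.0
                    sign = drng.choice([-1.0, 1.0], size=(spikes.size, 3))
                    counts[spikes] = np.round(sign * mag).astype(np.int64)
                streams[(role, site)] = pd.DataFrame(
                    {
                        "t_ms": t_dev,
                        "gx": counts[:, 0],
                        "gy": counts[:, 1],
                        "gz": counts[:, 2],
                    }
                )
                clock_offsets[(dyad_id, role, site)] = offset
                spike_rows[(dyad_id, role, site)] = spikes

        conditions = {
            "order_variant": order_variant,
            "attention_instruction": instructions[d] if instructions else "n/a",
            "nominal_rate_hz": spec.rate_hz,
        }
        markers = pd.DataFrame(marks, columns=["task", "boundary", "t_ms"])
        sessions.append(
            DyadSession(dyad_id=dyad_id, streams=streams, markers=markers, conditions=conditions)
        )

        jrng = _rng(seed, 40, d)
        for task in tasks:
            veracity = "truth" if task == "truth" else "lie"
            p = float(acc.get(task, 0.5))
            judgement_rows.append(
                {
                    "dyad_id": dyad_id,
                    "task": task,
                    "veracity": veracity,
                    "rating": _draw_rating(jrng, veracity, p),
                    "p_correct": p,
                    "suspicion": 0,
                }
            )

    judgements = pd.DataFrame(judgement_rows)
    # interviewer suspicion: inverse of the truthfulness rating
    judgements["suspicion"] = 8 - judgements["rating"]
    truth = GroundTruth(
        kappa=pd.DataFrame(kappa_rows),
        dyad_effect=dyad_effect,
        clock_offsets=clock_offsets,
        spike_rows=spike_rows,
        lag={"tau0": spec.tau0, "lag_drift": spec.lag_drift},
    )
    return sessions, judgements, truth
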