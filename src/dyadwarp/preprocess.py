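"""Four-step screening of raw gyroscope segments.

The screening turns a pair of raw task segments into aligned, down-sampled,
standardized streams:

1. **Remove impossible values** — samples with any axis outside the
   sensor's representable range are electronic recording errors (~0.5% of
   samples) and are dropped.
2. **Align** — devices do not start recording simultaneously; both streams
   are cut to start at the first timestamp covered by both recordings.
3. **Down-sample to 5 frames/s** — per-axis means over 200 ms bins, which
   keeps the streams aligned after error samples have been removed.
4. **Standardize** — per-axis z-scores (device placement makes absolute
   units incomparable across body parts), multiplied by 1000 and rounded to
   integers.

Defaults live in :data:`DEFAULT_CONFIG`; ``valid_range`` is the device's
representable gyro range and is deployment-specific.  The public functions
take and return stream DataFrames; the array helpers underneath are shared
with the batch path in :func:`preprocess_pair`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import PreprocessError
from .sensor_io import DyadSession

logger = logging.getLogger("dyadwarp.preprocess")

DEFAULT_CONFIG = {
    "valid_range": (-500.0, 500.0),
    "target_rate_hz": 5.0,
    "zscore_scale": 1000,
    "max_empty_bin_fraction": 0.10,
}

GYRO_COLS = ["gx", "gy", "gz"]


@dataclass
class CleanSegment:
    """One screened body-site stream for one task.

    ``frames`` is an (n, 3) integer array of z-scores x 1000 at
    ``rate_hz`` frames per second; ``t0_common`` is the offset of the first
    frame on the common capture clock, in ms.
    """

    site: str
    role: str
    task: str
    frames: np.ndarray
    rate_hz: float = 5.0
    t0_common: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.size == 0:
            raise PreprocessError("empty CleanSegment")
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise PreprocessError("CleanSegment frames must be integers")


# --- array core -------------------------------------------------------------

def _stream_arrays(df: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    return df["t_ms"].to_numpy(np.int64), df[GYRO_COLS].to_numpy(dtype=float)


def _remove_arrays(t, v, valid_range):
    lo, hi = valid_range
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise PreprocessError("valid_range must be finite")
    keep = np.all((v >= lo) & (v <= hi), axis=1)
    removed = int(len(t) - keep.sum())
    if removed == len(t):
        raise PreprocessError("all samples out of range; segment unusable")
    if removed:
        t, v = t[keep], v[keep]
    return t, v, removed


def _align_arrays(ta, va, tb, vb):
    if len(ta) == 0 or len(tb) == 0:
        raise PreprocessError("cannot align an empty stream")
    t0 = int(max(ta[0], tb[0]))
    if t0 > min(ta[-1], tb[-1]):
        raise PreprocessError("streams have no overlapping time support")
    ia = int(np.searchsorted(ta, t0, side="left"))
    ib = int(np.searchsorted(tb, t0, side="left"))
    return ta[ia:], va[ia:], tb[ib:], vb[ib:], t0


def _downsample_arrays(t, v, t0, target_rate_hz, nominal_rate_hz, max_empty_bin_fraction):
    if len(t) == 0:
        raise PreprocessError("cannot down-sample an empty stream")
    w = 1000.0 / target_rate_hz
    period = 1000.0 / nominal_rate_hz
    duration = t[-1] - t0 + period
    n_frames = int(np.floor(duration / w))
    if n_frames < 1:
        raise PreprocessError("segment shorter than one down-sampling bin")
    idx = np.floor((t - t0) / w).astype(np.int64)
    keep = (idx >= 0) & (idx < n_frames)
    idx, vals = idx[keep], v[keep]
    counts = np.bincount(idx, minlength=n_frames)
    frames = np.empty((n_frames, 3))
    for ax in range(3):
        sums = np.bincount(idx, weights=vals[:, ax], minlength=n_frames)
        with np.errstate(invalid="ignore"):
            frames[:, ax] = sums / counts
    empty = counts == 0
    if empty.any():
        frac = empty.mean()
        if frac > max_empty_bin_fraction:
            raise PreprocessError(
                f"{frac:.1%} of down-sampling bins empty "
                f"(> {max_empty_bin_fraction:.0%}); segment unusable"
            )
        logger.warning(
            "%d empty bin(s) of %d filled by interpolation", int(empty.sum()), n_frames
        )
        good = np.nonzero(~empty)[0]
        bad = np.nonzero(empty)[0]
        for ax in range(3):
            frames[bad, ax] = np.interp(bad, good, frames[good, ax])
    return frames


# --- public operations ------------------------------------------------------

def remove_impossible_values(
    samples: pd.DataFrame, valid_range: Tuple[float, float]
) -> Tuple[pd.DataFrame, int]:
    """Drop samples with any gyro axis outside the closed ``valid_range``."""
    lo, hi = valid_range
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise PreprocessError("valid_range must be finite")
    vals = samples[GYRO_COLS].to_numpy()
    keep = np.all((vals >= lo) & (vals <= hi), axis=1)
    removed = int(len(samples) - keep.sum())
    if removed == len(samples):
        raise PreprocessError("all samples out of range; segment unusable")
    if removed == 0:
        return samples.reset_index(drop=True), 0
    return samples.loc[keep].reset_index(drop=True), removed


def align_streams(
    a: pd.DataFrame, b: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    """Cut both streams to the first timestamp covered by both recordings.

    Returns (a', b', t0_common).  Fatal when the streams share no time
    support.
    """
    if a.empty or b.empty:
        raise PreprocessError("cannot align an empty stream")
    ta = a["t_ms"].to_numpy()
    tb = b["t_ms"].to_numpy()
    t0 = int(max(ta[0], tb[0]))
    if t0 > min(ta[-1], tb[-1]):
        raise PreprocessError("streams have no overlapping time support")
    a2 = a.iloc[np.searchsorted(ta, t0, side="left"):].reset_index(drop=True)
    b2 = b.iloc[np.searchsorted(tb, t0, side="left"):].reset_index(drop=True)
    return a2, b2, t0


def downsample_5hz(
    samples: pd.DataFrame,
    t0: Optional[int] = None,
    target_rate_hz: float = 5.0,
    nominal_rate_hz: float = 120.0,
    max_empty_bin_fraction: float = 0.10,
) -> np.ndarray:
    """Per-axis bin means over (1000 / ``target_rate_hz``) ms bins.

    Frame k summarizes the bin [t0 + k*w, t0 + (k+1)*w) with w = 200 ms at
    the default 5 Hz.  The trailing partial bin is dropped; interior bins
    emptied by error removal are filled by linear interpolation of the
    neighbouring bin means (fatal when more than ``max_empty_bin_fraction``
    of bins are empty).
    """
    if samples.empty:
        raise PreprocessError("cannot down-sample an empty stream")
    t, v = _stream_arrays(samples)
    if t0 is None:
        t0 = int(t[0])
    return _downsample_arrays(
        t, v, t0, target_rate_hz, nominal_rate_hz, max_empty_bin_fraction
    )


def standardize_z1000(frames: np.ndarray, scale: int = 1000) -> np.ndarray:
    """Per-axis z-scores (sample SD) scaled by 1000, rounded half away from zero."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2 or frames.shape[0] < 3:
        raise PreprocessError("standardization needs at least 3 frames")
    sd = frames.std(axis=0, ddof=1)
    if np.any(sd == 0):
        ax = int(np.nonzero(sd == 0)[0][0])
        raise PreprocessError(
            f"zero variance on axis {ax} (frozen or faulty sensor); segment excluded"
        )
    z = (frames - frames.mean(axis=0)) / sd * scale
    return np.copysign(np.floor(np.abs(z) + 0.5), z).astype(np.int64)


def preprocess_pair(
    session: DyadSession,
    task: str,
    site: str,
    valid_range: Tuple[float, float] = DEFAULT_CONFIG["valid_range"],
    site_b: Optional[str] = None,
    target_rate_hz: float = 5.0,
    zscore_scale: int = 1000,
    max_empty_bin_fraction: float = 0.10,
) -> Tuple[CleanSegment, CleanSegment]:
    """Apply the four screening steps to one (task, site) stream pair.

    ``site`` is the interviewer's site; ``site_b`` (default: same) the
    interviewee's, which allows the exploratory cross-hand pairings.  Both
    outputs have equal frame counts (the longer stream is truncated after
    down-sampling).
    """
    site_b = site_b or site
    spans = session.task_spans()
    if task not in spans:
        raise PreprocessError(f"task {task!r} not marked in session {session.dyad_id}")
    t0_task, t1_task = spans[task]
    a = session.streams.get(("interviewer", site))
    b = session.streams.get(("interviewee", site_b))
    if a is None or b is None:
        raise PreprocessError(
            f"session {session.dyad_id}: missing stream for site pair "
            f"({site}, {site_b})"
        )
    rate = float(session.conditions.get("nominal_rate_hz", 120))

    def seg(df):
        t, v = _stream_arrays(df)
        lo = int(np.searchsorted(t, t0_task, side="left"))
        hi = int(np.searchsorted(t, t1_task, side="right"))
        return t[lo:hi], v[lo:hi]

    ta, va = seg(a)
    tb, vb = seg(b)
    if len(ta) == 0 or len(tb) == 0:
        raise PreprocessError(
            f"session {session.dyad_id} task {task}: empty segment for site "
            f"pair ({site}, {site_b})"
        )
    ta, va, _ = _remove_arrays(ta, va, valid_range)
    tb, vb, _ = _remove_arrays(tb, vb, valid_range)
    ta, va, tb, vb, t0 = _align_arrays(ta, va, tb, vb)
    fa = _downsample_arrays(ta, va, t0, target_rate_hz, rate, max_empty_bin_fraction)
    fb = _downsample_arrays(tb, vb, t0, target_rate_hz, rate, max_empty_bin_fraction)
    n = min(len(fa), len(fb))
    za = standardize_z1000(fa[:n], scale=zscore_scale)
    zb = standardize_z1000(fb[:n], scale=zscore_scale)
    mk = lambda role, s, z: CleanSegment(
        site=s, role=role, task=task, frames=z, rate_hz=target_rate_hz, t0_common=t0
    )
    return mk("interviewer", site, za), mk("interviewee", site_b, zb)
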