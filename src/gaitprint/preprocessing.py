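"""From raw trials to 1x1200 stride patterns.

Processing order (per trial, then per participant within a day split):

1. stance segmentation from the vertical GRF (15 N threshold);
2. zero-phase lowpass filtering (15 Hz angles, 50 Hz forces);
3. time normalization of every channel to 100 samples (shape-preserving
   piecewise cubic / PCHIP);
4. per-participant standardization: subtract the participant's average
   trajectory and divide by the participant's per-sample SD;
5. rescaling of every channel to [-1, 1] over the dataset split;
6. concatenation into the 1x1200 feature vector.

Standardization and rescaling statistics are computed per day split (day-1
trials use day-1 statistics, day-2 trials day-2 statistics), mirroring the
per-participant normalization of both datasets before classification.  The
per-participant step intentionally removes body-size effects (constant
offsets and gains); see the package methods note for the identity-leakage
caveat this implies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

from .channels import ANGLE_CHANNELS, CHANNELS, GRF_CHANNELS, N_FEATURES, N_SAMPLES
from .kinematics import trial_joint_angles
from .synthetic import RawTrial, TrialRecord

logger = logging.getLogger(__name__)

#: SD floor used when a participant's across-trial variance vanishes at a sample
EPS_SD = 1e-8


@dataclass(frozen=True)
class StanceSegment:
    """Half-open stance interval [heel_strike, toe_off) in force samples."""

    heel_strike_index: int
    toe_off_index: int
    threshold: float = 15.0

    def __len__(self) -> int:
        return self.toe_off_index - self.heel_strike_index


@dataclass(frozen=True)
class FilterConfig:
    """Zero-phase lowpass settings: -3 dB at the stated cutoffs."""

    angle_cutoff: float = 15.0
    grf_cutoff: float = 50.0
    order: int = 5


@dataclass(frozen=True)
class PipelineConfig:
    """Switches of the stride-pattern pipeline.

    sd_mode
        ``"pointwise"`` divides by the per-sample across-trial SD (default;
        the participant's 'standard deviation' is a trajectory, like the
        average), ``"scalar"`` by one SD per channel.
    rescale_scope
        ``"per-channel"`` (default) divides each channel by its maximum
        absolute standardized value over the split; ``"per-trial"``
        rescales each trial's channel independently.
    """

    filter: FilterConfig = field(default_factory=FilterConfig)
    stance_threshold: float = 15.0
    min_stance_s: float = 0.05
    sd_mode: Literal["pointwise", "scalar"] = "pointwise"
    rescale_scope: Literal["per-channel", "per-trial"] = "per-channel"


@dataclass(frozen=True)
class StridePattern:
    """One stance phase as the network sees it: a 1x1200 feature vector."""

    features: np.ndarray
    subject_id: int
    day: int
    trial_id: str

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.shape != (N_FEATURES,):
            raise ValueError(f"features must have shape ({N_FEATURES},), got {f.shape}")
        if not np.all(np.isfinite(f)):
            raise ValueError("features contain non-finite values")
        object.__setattr__(self, "features", f)


# --------------------------------------------------------------------------
# stance segmentation
# --------------------------------------------------------------------------


def detect_stance(
    vertical_grf: np.ndarray,
    rate: float,
    threshold: float = 15.0,
    min_duration_s: float = 0.05,
    strict: bool = True,
) -> StanceSegment:
    """Locate the stance phase as the above-threshold run of the vertical GRF.

    Heel strike is the first sample at or above ``threshold`` of the
    qualifying run, toe off the first sample after it (half-open interval).
    Runs shorter than ``min_duration_s`` are rejected as threshold-crossing
    noise.  With ``strict=True`` (the default, matching a protocol that
    guarantees a single step on the force plate), more than one qualifying
    run is an error; otherwise the longest run is returned.
    """
    v = np.asarray(vertical_grf, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("vertical GRF must be a non-empty 1-D series")
    if not np.all(np.isfinite(v)):
        raise ValueError("vertical GRF contains non-finite values")
    above = v >= threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        stops = np.concatenate([stops, [v.size]])
    min_len = int(np.ceil(min_duration_s * rate))
    runs = [(a, b) for a, b in zip(starts, stops) if b - a >= min_len]
    if not runs:
        raise ValueError(
            f"no stance found: no run >= {threshold} N lasting >= {min_duration_s} s"
        )
    if strict and len(runs) > 1:
        raise ValueError(
            f"{len(runs)} qualifying contact intervals found; expected a single "
            "step on the force plate (use strict=False to take the longest)"
        )
    a, b = max(runs, key=lambda r: r[1] - r[0])
    return StanceSegment(heel_strike_index=int(a), toe_off_index=int(b), threshold=threshold)


# --------------------------------------------------------------------------
# filtering and time normalization
# --------------------------------------------------------------------------


def lowpass(signal: np.ndarray, rate: float, cutoff: float, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth lowpass with -3 dB at ``cutoff``.

    The filter is applied forward and backward (``filtfilt``), which
    squares the magnitude response and removes the phase shift; the design
    cutoff is pre-warped so the *two-pass* response is -3 dB at the nominal
    cutoff.  DC gain is exactly 1.
    """
    x = np.asarray(signal, dtype=float)
    nyq = rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    # single pass must be -1.5 dB at the nominal cutoff:
    # (f_c / f_design)^(2 order) = sqrt(2) - 1
    f_design = cutoff / (np.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * order))
    b, a = butter(order, min(f_design, 0.99 * nyq) / nyq)
    padlen = min(3 * (max(len(a), len(b)) - 1), x.size - 1)
    return filtfilt(b, a, x, padlen=padlen)


def time_normalize(signal: np.ndarray, n_out: int = N_SAMPLES) -> np.ndarray:
    """Resample onto ``n_out`` equally spaced points over [first, last].

    Uses shape-preserving (monotone) piecewise cubic interpolation, which
    reproduces endpoints exactly and does not overshoot on monotone
    stretches.
    """
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError(f"need a 1-D signal of length >= 4, got shape {y.shape}")
    x = np.arange(y.size, dtype=float)
    interp = PchipInterpolator(x, y)
    return interp(np.linspace(0.0, y.size - 1.0, n_out))


# --------------------------------------------------------------------------
# standardization and rescaling
# --------------------------------------------------------------------------


def standardize_participant(
    trajectories: np.ndarray, sd_mode: str = "pointwise"
) -> np.ndarray:
    """Standardize one participant's trials of one channel.

    Subtracts the participant's average trajectory and divides by the
    participant's standard deviation (across-trial, per sample by default;
    ``sd_mode="scalar"`` uses one SD per channel).  SDs below
    :data:`EPS_SD` are floored and logged — the affected samples come out
    as zeros.

    Parameters
    ----------
    trajectories : (n_trials, n_samples) ndarray
    """
    t = np.asarray(trajectories, dtype=float)
    if t.ndim != 2:
        raise ValueError(f"expected (n_trials, n_samples), got shape {t.shape}")
    if t.shape[0] < 2:
        raise ValueError("standardization needs >= 2 trials per participant")
    mean = t.mean(axis=0)
    centered = t - mean
    if sd_mode == "pointwise":
        sd = centered.std(axis=0, ddof=1)
    elif sd_mode == "scalar":
        sd = np.full(t.shape[1], centered.std(ddof=1))
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    floored = sd < EPS_SD
    if floored.any():
        logger.warning(
            "standardization: %d/%d samples had zero across-trial variance; "
            "SD floored at %.0e (values come out as 0)",
            int(floored.sum()),
            sd.size,
            EPS_SD,
        )
    return centered / np.where(floored, EPS_SD, sd)


def rescale_unit(trajectories: np.ndarray) -> np.ndarray:
    """Symmetric rescale of one channel's standardized data into [-1, 1].

    Divides by the maximum absolute value over everything passed in (one
    channel across the dataset split), so zero maps to zero and at least
    one value lands on +-1.  An all-zero channel is left at zero and
    logged.
    """
    t = np.asarray(trajectories, dtype=float)
    m = np.max(np.abs(t)) if t.size else 0.0
    if m == 0.0:
        logger.warning("rescale: all-zero channel left unscaled")
        return t.copy()
    return t / m


def assemble(
    channel_trajectories: Mapping[str, np.ndarray],
    subject_id: int,
    day: int,
    trial_id: str,
) -> StridePattern:
    """Concatenate 12 normalized 100-sample trajectories into a StridePattern.

    The concatenation order is the fixed channel order; the public mapping
    between flat indices and (channel, sample) pairs is
    :func:`gaitprint.channels.feature_index` /
    :func:`gaitprint.channels.feature_unindex`.
    """
    extra = set(channel_trajectories) - set(CHANNELS)
    missing = [c for c in CHANNELS if c not in channel_trajectories]
    if missing or extra:
        raise ValueError(
            f"need exactly the 12 channels; missing={missing}, extra={sorted(extra)}"
        )
    parts = []
    for c in CHANNELS:
        v = np.asarray(channel_trajectories[c], dtype=float)
        if v.shape != (N_SAMPLES,):
            raise ValueError(f"channel {c!r} must have {N_SAMPLES} samples, got {v.shape}")
        parts.append(v)
    return StridePattern(
        features=np.concatenate(parts), subject_id=subject_id, day=day, trial_id=trial_id
    )


# --------------------------------------------------------------------------
# whole-pipeline drivers
# --------------------------------------------------------------------------


def _trial_to_normalized(
    trial: TrialRecord,
    kinematic_rate: float,
    force_rate: float,
    config: PipelineConfig,
) -> dict[str, np.ndarray]:
    """Filter + time-normalize one processed trial to 12 x 100."""
    out = {}
    for c in CHANNELS:
        rate = kinematic_rate if c in ANGLE_CHANNELS else force_rate
        cutoff = (
            config.filter.angle_cutoff if c in ANGLE_CHANNELS else config.filter.grf_cutoff
        )
        out[c] = time_normalize(
            lowpass(trial.channels[c], rate, cutoff, config.filter.order)
        )
    return out


def raw_to_trial(
    raw: RawTrial,
    standing: Mapping[str, np.ndarray],
    config: PipelineConfig = PipelineConfig(),
    trial_id: str = "",
) -> TrialRecord:
    """Turn a raw trial into a processed 12-channel record.

    Detects stance on the vertical force channel, cuts the GRF channels to
    it, and recovers the joint-angle channels from the marker clusters
    relative to the standing trial.
    """
    stance = detect_stance(
        raw.grf[2],
        raw.force_rate,
        threshold=config.stance_threshold,
        min_duration_s=config.min_stance_s,
    )
    sl = slice(stance.heel_strike_index, stance.toe_off_index)
    angles = trial_joint_angles(raw.marker_blocks, dict(standing))
    channels = {c: angles[c] for c in ANGLE_CHANNELS}
    for row, c in enumerate(GRF_CHANNELS):
        channels[c] = raw.grf[row, sl].copy()
    return TrialRecord(
        subject_id=raw.subject_id, day=raw.day, trial_id=trial_id, channels=channels
    )


def build_stride_patterns(
    trials: Sequence[TrialRecord],
    kinematic_rate: float = 240.0,
    force_rate: float = 2400.0,
    config: PipelineConfig = PipelineConfig(),
) -> list[StridePattern]:
    """Run the full normalization pipeline over a set of processed trials.

    Each day split is normalized independently: per participant and
    channel, trials are standardized against that participant's own
    statistics within the split, then each channel is rescaled to [-1, 1]
    across the split, and the 12 channels are concatenated per trial.
    Returns patterns in the input trial order.
    """
    normalized = [
        _trial_to_normalized(t, kinematic_rate, force_rate, config) for t in trials
    ]
    features = {i: {} for i in range(len(trials))}
    for day in sorted({t.day for t in trials}):
        day_idx = [i for i, t in enumerate(trials) if t.day == day]
        for c in CHANNELS:
            std = np.empty((len(day_idx), N_SAMPLES))
            by_subject: dict[int, list[int]] = {}
            for pos, i in enumerate(day_idx):
                by_subject.setdefault(trials[i].subject_id, []).append(pos)
            for subject, positions in by_subject.items():
                block = np.stack([normalized[day_idx[p]][c] for p in positions])
                std[positions] = standardize_participant(block, config.sd_mode)
            if config.rescale_scope == "per-channel":
                scaled = rescale_unit(std)
            elif config.rescale_scope == "per-trial":
                scaled = np.stack([rescale_unit(row) for row in std])
            else:
                raise ValueError(f"unknown rescale_scope {config.rescale_scope!r}")
            for pos, i in enumerate(day_idx):
                features[i][c] = scaled[pos]
    return [
        assemble(features[i], trials[i].subject_id, trials[i].day, trials[i].trial_id)
        for i in range(len(trials))
    ]


def patterns_matrix(patterns: Sequence[StridePattern]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patterns into (n_trials, 1200) features and a label vector."""
    X = np.stack([p.features for p in patterns])
    y = np.array([p.subject_id for p in patterns])
    return X, y


def save_stride_patterns(patterns: Sequence[StridePattern], path) -> None:
    """Write a trials x 1200 matrix as CSV plus a JSON label sidecar.

    The sidecar (``<path>.json``) records subject/day/trial labels and the
    flat-index -> (channel, sample) map of the feature columns.
    """
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    X, _ = patterns_matrix(patterns)
    cols = [f"{CHANNELS[i // N_SAMPLES]}_{i % N_SAMPLES:02d}" for i in range(N_FEATURES)]
    pd.DataFrame(X, columns=cols).to_csv(path, index=False)
    sidecar = {
        "trials": [
            {"trial_id": p.trial_id, "subject_id": int(p.subject_id), "day": int(p.day)}
            for p in patterns
        ],
        "channels": list(CHANNELS),
        "n_samples_per_channel": N_SAMPLES,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_stride_patterns(path) -> list[StridePattern]:
    """Read back a matrix written by :func:`save_stride_patterns`."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    X = pd.read_csv(path).to_numpy()
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return [
        StridePattern(
            features=row,
            subject_id=entry["subject_id"],
            day=entry["day"],
            trial_id=entry["trial_id"],
        )
        for row, entry in zip(X, meta["trials"])
    ]
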