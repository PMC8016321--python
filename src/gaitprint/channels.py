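"""Channel registry and feature-vector index bookkeeping.

A stride pattern concatenates 12 time-normalized trajectories (9 joint-angle
channels and 3 ground-reaction-force channels), 100 samples each, into a
single 1200-element feature vector.  The concatenation order below is fixed
and shared by every module: index ``i`` of the feature vector maps to
``(channel = i // 100, sample = i % 100)``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

#: Samples per time-normalized trajectory.
N_SAMPLES = 100

#: Fixed channel order of the 1x1200 feature vector.
CHANNELS: tuple[str, ...] = (
    "hip_flex_ext",
    "hip_ab_ad",
    "hip_int_ext_rot",
    "knee_flex_ext",
    "knee_ab_ad",
    "knee_int_ext_rot",
    "ankle_dorsi_plantar",
    "ankle_ab_ad",
    "ankle_in_eversion",
    "grf_anterior_posterior",
    "grf_medio_lateral",
    "grf_vertical",
)

N_CHANNELS = len(CHANNELS)
N_FEATURES = N_CHANNELS * N_SAMPLES

#: The 9 joint-angle channels (sampled at the kinematic rate).
ANGLE_CHANNELS: tuple[str, ...] = CHANNELS[:9]
#: The 3 force channels (sampled at the force-plate rate).
GRF_CHANNELS: tuple[str, ...] = CHANNELS[9:]


def channel_index(channel: str) -> int:
    """Position of ``channel`` in the fixed concatenation order."""
    try:
        return CHANNELS.index(channel)
    except ValueError:
        raise KeyError(f"unknown channel {channel!r}; valid: {CHANNELS}") from None


def feature_index(channel: int | str, sample: int) -> int:
    """Map (channel, sample) to the flat feature-vector index (0-based)."""
    c = channel_index(channel) if isinstance(channel, str) else int(channel)
    if not 0 <= c < N_CHANNELS:
        raise IndexError(f"channel index {c} out of range [0, {N_CHANNELS})")
    if not 0 <= sample < N_SAMPLES:
        raise IndexError(f"sample index {sample} out of range [0, {N_SAMPLES})")
    return c * N_SAMPLES + sample


def feature_unindex(index: int) -> tuple[int, int]:
    """Inverse of :func:`feature_index`: flat index -> (channel, sample)."""
    if not 0 <= index < N_FEATURES:
        raise IndexError(f"feature index {index} out of range [0, {N_FEATURES})")
    return divmod(index, N_SAMPLES)


def window_samples(window: tuple[float, float]) -> range:
    """Sample indices covered by a fractional stance window.

    The half-open convention maps the fraction pair ``(w0, w1)`` to samples
    ``round(w0 * 100) .. round(w1 * 100) - 1``; e.g. the early-stance window
    (0.0, 0.3) covers samples 0-29.
    """
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"window must satisfy 0 <= lo < hi <= 1, got {window}")
    return range(round(lo * N_SAMPLES), round(hi * N_SAMPLES))


def planted_indices(
    channels: Iterable[str], window: tuple[float, float]
) -> Sequence[int]:
    """Flat feature indices of ``channels`` x fractional ``window`` (sorted)."""
    samples = window_samples(window)
    idx = [feature_index(c, s) for c in channels for s in samples]
    return tuple(sorted(idx))
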