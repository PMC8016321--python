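"""Synthetic multi-subject running datasets with planted identity structure.

The generator emulates the statistical shape of a two-day overground-running
study: each subject contributes 29-40 force-plate stance phases split over
two days, recorded as 9 joint-angle channels at the kinematic rate (240 Hz)
and 3 ground-reaction-force (GRF) channels at the force-plate rate
(2400 Hz).  Identity information is *planted* in a known subset of channels
and a known fractional stance window, which gives every downstream stage an
exact oracle.

Identity is planted in two complementary forms, both confined to
``planted_channels`` x ``planted_window`` and both scaled by
``effect_size`` relative to the within-subject trial noise:

1. **Template offsets** — each subject's mean curve deviates from the
   population curve by a smooth bump pattern.  Any analysis that compares
   trials *across* subjects sees this directly (it drives the per-variable
   discriminability oracle).
2. **Fluctuation signatures** — each subject owns a private smooth
   "strategy contrast" curve (an orthonormalized harmonic wave confined to
   the window) added to every trial with a +-1 coefficient plus jitter,
   emulating discrete trial-to-trial coordination variation.  This
   component survives the classification pipeline's per-participant
   standardization, which removes all per-sample mean and variance
   differences but not the *shape* of the fluctuations.

Trial noise shared by all subjects has two smooth correlated components
(Gaussian white noise convolved with Gaussian kernels): a dominant slow
drift and a small fast measurement-like part, so the pipeline's lowpass
stage neither trivially erases it nor lets it mimic the oscillatory
signatures.

All randomness flows from explicit integer seeds; dataset generation is a
pure function of ``(spec, spec.seed)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .channels import (
    ANGLE_CHANNELS,
    CHANNELS,
    GRF_CHANNELS,
    N_CHANNELS,
    planted_indices,
)
from .kinematics import JOINT_CHANNELS, JOINT_SEGMENTS, SEGMENTS, compose_zxy

# --------------------------------------------------------------------------
# defaults: the stated world
# --------------------------------------------------------------------------

#: the five channels reported as most identity-bearing (frontal/transverse
#: plane angles and the medio-lateral force)
DEFAULT_PLANTED_CHANNELS: tuple[str, ...] = (
    "hip_ab_ad",
    "hip_int_ext_rot",
    "knee_ab_ad",
    "ankle_in_eversion",
    "grf_medio_lateral",
)

#: within-subject trial-noise SD per channel (degrees for angles, newtons
#: for forces); sagittal-plane angles move and vary more than
#: frontal/transverse ones, vertical force more than shear forces
DEFAULT_NOISE_SIGMA: Mapping[str, float] = {
    "hip_flex_ext": 1.5,
    "hip_ab_ad": 0.8,
    "hip_int_ext_rot": 0.8,
    "knee_flex_ext": 1.5,
    "knee_ab_ad": 0.8,
    "knee_int_ext_rot": 0.8,
    "ankle_dorsi_plantar": 1.5,
    "ankle_ab_ad": 0.8,
    "ankle_in_eversion": 0.8,
    "grf_anterior_posterior": 8.0,
    "grf_medio_lateral": 4.0,
    "grf_vertical": 10.0,
}


#: share of trial-noise variance in the fast (measurement-like) component
FAST_NOISE_FRACTION = 0.15
#: correlation length (seconds) of the fast noise component
FAST_NOISE_CORR_S = 0.005


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic gait world.

    Defaults mirror the study layout: 50 subjects, 29-40 stance trials per
    subject over two days (at most 20 per day), 240 Hz kinematics, 2400 Hz
    forces, identity planted in five frontal/transverse-plane channels
    during early stance (first 30%).

    Parameters
    ----------
    trials_per_day : int or (int, int)
        An int means exactly that many trials on each day; a pair
        ``(lo, hi)`` means each subject's *total* trial count is drawn
        uniformly from that inclusive range and split across the days with
        a 20-per-day cap.
    effect_size : float or mapping
        Ratio of between-subject template spread (and of the
        subject-specific fluctuation-mode amplitude) to the within-subject
        trial-noise SD; scalar or per-channel mapping.
    noise_corr_s : float
        Correlation length (seconds) of the smooth trial noise.
    day2_drift : float
        RMS amplitude, as a fraction of each channel's noise SD, of a
        smooth systematic per-subject template perturbation applied on
        day 2 only.
    stance_mean, stance_sd : float
        Mean and SD (seconds) of the stance duration distribution
        (truncated to [0.15 s, 0.32 s]; running at ~3.5 m/s).
    """

    n_subjects: int = 50
    trials_per_day: int | tuple[int, int] = (29, 40)
    channels: tuple[str, ...] = CHANNELS
    planted_channels: tuple[str, ...] = DEFAULT_PLANTED_CHANNELS
    planted_window: tuple[float, float] = (0.0, 0.3)
    effect_size: float | Mapping[str, float] = 3.0
    noise_sigma: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SIGMA)
    )
    noise_corr_s: float = 0.15
    day2_drift: float = 0.25
    kinematic_rate: float = 240.0
    force_rate: float = 2400.0
    stance_mean: float = 0.22
    stance_sd: float = 0.015
    n_modes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.channels) != CHANNELS or len(self.channels) != 12:
            raise ValueError(
                "channels must be the fixed 12-entry concatenation order "
                f"{CHANNELS}"
            )
        unknown = set(self.planted_channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown planted channels: {sorted(unknown)}")
        lo, hi = self.planted_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"planted_window must lie in [0, 1], got {self.planted_window}")
        if any(e < 0 for e in self._effect_by_channel().values()):
            raise ValueError("effect_size must be >= 0")
        if min(self.kinematic_rate, self.force_rate) <= 0:
            raise ValueError("sampling rates must be strictly positive")
        if self.stance_mean <= 0 or self.stance_sd < 0:
            raise ValueError("stance duration parameters must be positive")
        if isinstance(self.trials_per_day, int):
            if self.trials_per_day < 1:
                raise ValueError("trials_per_day must be >= 1")
        else:
            lo_t, hi_t = self.trials_per_day
            if not 1 <= lo_t <= hi_t:
                raise ValueError("trials_per_day range must satisfy 1 <= lo <= hi")

    def _effect_by_channel(self) -> dict[str, float]:
        if isinstance(self.effect_size, Mapping):
            return {c: float(self.effect_size.get(c, 0.0)) for c in CHANNELS}
        return {
            c: (float(self.effect_size) if c in self.planted_channels else 0.0)
            for c in CHANNELS
        }


def desk_scale_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The reduced 'desk-scale' world used by tests and examples.

    10 subjects with 30 trials on each day, default effect size, identity
    planted in the default five channels during the first 30% of stance.
    """
    params = dict(n_subjects=10, trials_per_day=30, seed=seed)
    params.update(overrides)
    return SyntheticSpec(**params)


# --------------------------------------------------------------------------
# smooth curve primitives
# --------------------------------------------------------------------------


def _raised_cosine(s: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth compact bump: 0.5*(1 + cos(2*pi*(s-center)/width)) on its support."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    mask = np.abs(s - center) < width / 2.0
    out[mask] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (s[mask] - center) / width))
    return out


# population mean curves per channel, phase s in [0, 1] (documented
# constants: degrees for angles, newtons for forces; shapes are stylized,
# only their role as distinct channels matters)
def _common_template(channel: str, s: np.ndarray) -> np.ndarray:
    rc = _raised_cosine
    if channel == "hip_flex_ext":
        return 25.0 * np.cos(np.pi * s) - 5.0
    if channel == "hip_ab_ad":
        return 6.0 * np.sin(2 * np.pi * s) + 3.0 * rc(s, 0.2, 0.3)
    if channel == "hip_int_ext_rot":
        return 5.0 * np.sin(np.pi * s) - 3.0 * rc(s, 0.7, 0.4)
    if channel == "knee_flex_ext":
        return 12.0 + 22.0 * rc(s, 0.35, 0.7)
    if channel == "knee_ab_ad":
        return 4.0 * np.sin(2 * np.pi * s) + 2.0 * rc(s, 0.5, 0.4)
    if channel == "knee_int_ext_rot":
        return 5.0 * rc(s, 0.3, 0.5) - 2.0
    if channel == "ankle_dorsi_plantar":
        return 15.0 * rc(s, 0.4, 0.8) - 18.0 * rc(s, 0.95, 0.35)
    if channel == "ankle_ab_ad":
        return 3.0 * np.sin(2 * np.pi * s)
    if channel == "ankle_in_eversion":
        return -6.0 * rc(s, 0.25, 0.5) + 3.0 * rc(s, 0.8, 0.4)
    if channel == "grf_anterior_posterior":
        return -250.0 * np.sin(2 * np.pi * s)
    if channel == "grf_medio_lateral":
        return 15.0 * np.sin(3 * np.pi * s) + 10.0 * np.sin(np.pi * s)
    if channel == "grf_vertical":
        # double-hump vertical force with a 60 N floor so the whole stance
        # sits above the 15 N contact threshold (see render_raw)
        return 60.0 + 1500.0 * np.sin(np.pi * s) ** 1.2 + 250.0 * rc(s, 0.12, 0.18)
    raise KeyError(f"unknown channel {channel!r}")


@dataclass(frozen=True)
class _BumpCurve:
    """Sum of raised-cosine bumps; supports exact evaluation at any phase."""

    centers: np.ndarray
    widths: np.ndarray
    amps: np.ndarray

    def __call__(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        for c, w, a in zip(self.centers, self.widths, self.amps):
            out += a * _raised_cosine(s, c, w)
        return out


@dataclass(frozen=True)
class _WindowWave:
    """Tapered random harmonic wave supported inside a stance window.

    A raised-cosine envelope over the window times a random combination of
    the first ``n_harmonics`` cosine harmonics: a random direction in the
    window's smooth (filter-surviving) function subspace.
    """

    window: tuple[float, float]
    coeffs: np.ndarray
    scale: float

    def __call__(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        lo, hi = self.window
        span = hi - lo
        u = (s - lo) / span
        mask = (u > 0.0) & (u < 1.0)
        out = np.zeros_like(s)
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[mask]))
        wave = np.zeros_like(env)
        # harmonics start at k=1: the k=0 term (the bare envelope) is the
        # same shape for every subject and mimics smooth trial noise
        for k, a in enumerate(self.coeffs, start=1):
            wave += a * np.cos(k * np.pi * u[mask])
        out[mask] = self.scale * env * wave
        return out


_FINE = np.linspace(0.0, 1.0, 2001)  # grid for RMS normalization of curves


def _ortho_mixer(window: tuple[float, float], n_harmonics: int) -> np.ndarray:
    """Coefficient mixing matrix that orthonormalizes the harmonic basis.

    The enveloped harmonics ``env * cos(k pi u)`` are far from orthogonal
    in window L2 (the envelope couples odd harmonics); this returns the
    symmetric inverse square root of their Gram matrix, so coefficient
    vectors that are orthogonal map to window-orthogonal curves.
    """
    lo, hi = window
    mask = (_FINE >= lo) & (_FINE < hi)
    B = []
    for k in range(n_harmonics):
        coeffs = np.zeros(n_harmonics)
        coeffs[k] = 1.0
        B.append(_WindowWave(window=window, coeffs=coeffs, scale=1.0)(_FINE[mask]))
    B = np.stack(B)
    G = (B @ B.T) / B.shape[1]
    vals, vecs = np.linalg.eigh(G)
    return vecs @ np.diag(1.0 / np.sqrt(np.maximum(vals, 1e-12))) @ vecs.T


def _make_wave(window: tuple[float, float], coeffs: np.ndarray, rms: float) -> _WindowWave:
    """Harmonic window wave with the realized window-RMS scaled to ``rms``."""
    wave = _WindowWave(window=window, coeffs=np.asarray(coeffs, dtype=float), scale=1.0)
    lo, hi = window
    mask = (_FINE >= lo) & (_FINE < hi)
    cur = float(np.sqrt(np.mean(wave(_FINE[mask]) ** 2)))
    return _WindowWave(window=window, coeffs=wave.coeffs, scale=rms / max(cur, 1e-12))


def _random_window_wave(
    rng: np.random.Generator,
    window: tuple[float, float],
    n_harmonics: int,
    rms: float,
) -> _WindowWave:
    return _make_wave(window, rng.standard_normal(n_harmonics), rms)


def _mode_harmonics(channel: str) -> int:
    """Window harmonics that survive the channel's lowpass stage.

    A ~30% stance window spans only ~70 ms: the 15 Hz angle filter passes
    about 2 in-window harmonics, the 50 Hz force filter about 6.
    """
    return 2 if channel in ANGLE_CHANNELS else 6



def _random_bump_curve(
    rng: np.random.Generator,
    window: tuple[float, float],
    n_bumps: int,
    rms: float,
    margin: float = 0.1,
    width_range: tuple[float, float] = (0.5, 1.0),
) -> _BumpCurve:
    """Random smooth curve supported strictly inside ``window``.

    Bump supports are kept inside the window, so 100% of the curve's energy
    lies there; the curve is rescaled to the requested RMS over the window.
    ``margin`` keeps bump centers away from the window edges and
    ``width_range`` scales widths relative to the widest bump that still
    fits (wide bumps survive the downstream lowpass filters).
    """
    lo, hi = window
    span = hi - lo
    centers = rng.uniform(lo + margin * span, hi - margin * span, size=n_bumps)
    max_w = 2.0 * np.minimum(centers - lo, hi - centers)
    widths = max_w * rng.uniform(*width_range, size=n_bumps)
    amps = rng.standard_normal(n_bumps)
    curve = _BumpCurve(centers=centers, widths=widths, amps=amps)
    mask = (_FINE >= lo) & (_FINE < hi)
    cur_rms = float(np.sqrt(np.mean(curve(_FINE[mask]) ** 2)))
    if cur_rms < 1e-12:  # pathological draw; fall back to a single unit bump
        curve = _BumpCurve(
            centers=np.array([(lo + hi) / 2]),
            widths=np.array([span / 2]),
            amps=np.array([1.0]),
        )
        cur_rms = float(np.sqrt(np.mean(curve(_FINE[mask]) ** 2)))
    scale = rms / cur_rms if rms > 0 else 0.0
    return _BumpCurve(curve.centers, curve.widths, curve.amps * scale)


def _smooth_noise(rng: np.random.Generator, n: int, sigma: float, corr_samples: float) -> np.ndarray:
    """Stationary smooth noise with per-sample SD ``sigma``.

    White Gaussian noise circularly convolved with a Gaussian kernel of SD
    ``corr_samples`` (samples), normalized analytically so the marginal
    per-sample SD equals ``sigma`` exactly.
    """
    if sigma == 0.0:
        return np.zeros(n)
    if corr_samples < 1e-9:
        return sigma * rng.standard_normal(n)
    radius = max(1, int(np.ceil(4.0 * corr_samples)))
    t = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (t / corr_samples) ** 2)
    # unit output variance under *circular* convolution: when the kernel is
    # wider than the record, overlapping wraps add coherently, so normalize
    # by the folded (mod-n) kernel's power
    folded = np.zeros(n)
    np.add.at(folded, t % n, kernel)
    kernel /= np.sqrt(np.sum(folded**2))
    white = rng.standard_normal(n)
    padded = white[np.arange(-radius, n + radius) % n]  # circular
    return sigma * np.convolve(padded, kernel, mode="valid")


# --------------------------------------------------------------------------
# ground truth and trial generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows and the analysis must rediscover."""

    spec: SyntheticSpec
    #: subject -> channel -> smooth deviation curve added to the common template
    template_deviation: dict[int, dict[str, _BumpCurve]]
    #: subject -> channel -> tuple of fluctuation-mode curves (window RMS 1)
    fluctuation_modes: dict[int, dict[str, tuple[_BumpCurve, ...]]]
    #: subject -> channel -> smooth day-2 drift curve
    day2_drift_curve: dict[int, dict[str, _BumpCurve]]
    #: flat feature indices where identity was planted
    planted_variable_set: tuple[int, ...]

    def subject_template(self, subject_id: int, channel: str, s: np.ndarray) -> np.ndarray:
        """Subject mean curve = common template + planted deviation."""
        base = _common_template(channel, s)
        dev = self.template_deviation[subject_id].get(channel)
        return base + dev(s) if dev is not None else base


def generate_templates(spec: SyntheticSpec) -> GroundTruth:
    """Draw the per-subject templates, fluctuation modes and day-2 drifts.

    Deterministic given ``spec.seed``.  For non-planted channels all
    subjects share the common template exactly; for planted channels each
    subject deviates by a smooth bump curve whose energy lies entirely
    inside ``planted_window`` and whose RMS equals
    ``effect_size * noise_sigma`` for that channel.
    """
    effect = spec._effect_by_channel()
    if all(e == 0 for e in effect.values()) and spec.planted_channels:
        warnings.warn(
            "effect_size is 0 with non-empty planted_channels: subjects are "
            "identical by construction and the dataset is unidentifiable",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)

    # Subject "strategy" signatures are directions in the joint
    # (planted channel x surviving harmonic) coefficient space.  When the
    # subject count allows, the directions are drawn orthonormal, so
    # subjects are maximally distinct by construction (each individual has
    # a unique preferred coordination pattern); beyond that, random unit
    # directions are used.
    planted = tuple(spec.planted_channels)
    dims = {c: _mode_harmonics(c) for c in planted}
    D = sum(dims.values())
    if planted:
        A = rng.standard_normal((D, spec.n_subjects))
        if spec.n_subjects <= D:
            A = np.linalg.qr(A)[0][:, : spec.n_subjects]
        else:
            A = A / np.linalg.norm(A, axis=0, keepdims=True)
        offsets = dict(zip(planted, np.cumsum([0] + [dims[c] for c in planted[:-1]])))
        mixers = {c: _ortho_mixer(spec.planted_window, dims[c]) for c in planted}

    template_dev: dict[int, dict[str, _BumpCurve]] = {}
    modes: dict[int, dict[str, tuple]] = {}
    drifts: dict[int, dict[str, _BumpCurve]] = {}
    for subject in range(spec.n_subjects):
        template_dev[subject] = {}
        modes[subject] = {}
        drifts[subject] = {}
        for channel in planted:
            sigma = spec.noise_sigma[channel]
            rms = effect[channel] * sigma
            template_dev[subject][channel] = _random_bump_curve(
                rng, spec.planted_window, n_bumps=3, rms=rms
            )
            sub = A[offsets[channel] : offsets[channel] + dims[channel], subject]
            # channel RMS proportional to the signature's weight on this
            # channel; sqrt(D/dim) makes the expected RMS 1
            strategy = _make_wave(
                spec.planted_window,
                mixers[channel] @ sub,
                rms=float(np.linalg.norm(sub)) * np.sqrt(D / dims[channel]),
            )
            secondary = tuple(
                _make_wave(
                    spec.planted_window,
                    mixers[channel] @ rng.standard_normal(dims[channel]),
                    rms=1.0,
                )
                for _ in range(spec.n_modes - 1)
            )
            modes[subject][channel] = (strategy, *secondary)
        for channel in CHANNELS:
            drifts[subject][channel] = _random_bump_curve(
                rng, (0.0, 1.0), n_bumps=3, rms=spec.day2_drift * spec.noise_sigma[channel]
            )
    return GroundTruth(
        spec=spec,
        template_deviation=template_dev,
        fluctuation_modes=modes,
        day2_drift_curve=drifts,
        planted_variable_set=tuple(
            planted_indices(spec.planted_channels, spec.planted_window)
        ),
    )


def generate_trial(
    truth: GroundTruth, subject_id: int, day: int, trial_seed: int
) -> dict[str, np.ndarray]:
    """One stance trial: channel -> trajectory at its native rate.

    The 9 angle channels are sampled at the kinematic rate and the 3 GRF
    channels at the force rate over the same stance duration (drawn from
    the spec's distribution).  trajectory = subject template
    (+ day-2 drift on day 2) + subject fluctuation modes + shared smooth
    noise.  Reproducible from ``trial_seed``.
    """
    spec = truth.spec
    if subject_id not in truth.template_deviation:
        raise KeyError(f"unknown subject {subject_id}")
    if day not in (1, 2):
        raise ValueError(f"day must be 1 or 2, got {day}")
    rng = np.random.default_rng(trial_seed)

    duration = float(
        np.clip(rng.normal(spec.stance_mean, spec.stance_sd), 0.15, 0.32)
    )
    n_kin = max(4, round(duration * spec.kinematic_rate))
    n_force = n_kin * round(spec.force_rate / spec.kinematic_rate)

    effect = spec._effect_by_channel()
    # one coefficient per fluctuation mode, shared across channels (the
    # whole stride adopts one coordination state).  The leading mode is the
    # subject's "strategy contrast": a discrete +-1 trial-to-trial flip
    # (with a little mixing jitter) emulating alternation between two
    # preferred coordination patterns, e.g. strike-style variation.  Higher
    # modes carry Gaussian coefficients.
    z = rng.standard_normal(max(1, spec.n_modes))
    z[0] = rng.choice([-1.0, 1.0]) + 0.15 * z[0]

    out: dict[str, np.ndarray] = {}
    for channel in CHANNELS:
        n = n_kin if channel in ANGLE_CHANNELS else n_force
        rate = spec.kinematic_rate if channel in ANGLE_CHANNELS else spec.force_rate
        s = np.linspace(0.0, 1.0, n)
        traj = truth.subject_template(subject_id, channel, s)
        if day == 2:
            traj = traj + truth.day2_drift_curve[subject_id][channel](s)
        mode_curves = truth.fluctuation_modes[subject_id].get(channel)
        if mode_curves:
            # the discrete strategy mode carries most of the planted
            # variance; secondary Gaussian modes add within-subject richness
            w = np.array([1.0] + [0.5] * (len(mode_curves) - 1))
            w *= effect[channel] * spec.noise_sigma[channel] / np.linalg.norm(w)
            for m, mode in enumerate(mode_curves):
                traj = traj + w[m] * z[m] * mode(s)
        # two-component trial noise: a dominant very smooth drift (slow
        # neuromotor variability, ~1-2 degrees of freedom per stance) plus
        # a small fast component (measurement noise); per-sample SD is
        # noise_sigma exactly
        sigma = spec.noise_sigma[channel]
        traj = traj + _smooth_noise(
            rng, n, sigma * np.sqrt(1.0 - FAST_NOISE_FRACTION), spec.noise_corr_s * rate
        )
        traj = traj + _smooth_noise(
            rng, n, sigma * np.sqrt(FAST_NOISE_FRACTION), FAST_NOISE_CORR_S * rate
        )
        out[channel] = traj
    return out


# --------------------------------------------------------------------------
# raw-mode rendering (forward kinematics + force-plate embedding)
# --------------------------------------------------------------------------

#: standing-pose marker coordinates (metres, lab frame) per segment cluster
DEFAULT_CLUSTER_GEOMETRY: Mapping[str, np.ndarray] = {
    "pelvis": np.array(
        [[0.10, 0.12, 1.00], [0.10, -0.12, 1.00], [-0.12, 0.10, 1.02], [-0.12, -0.10, 1.02]]
    ),
    "thigh": np.array([[0.05, 0.05, 0.75], [0.03, -0.06, 0.68], [-0.04, 0.02, 0.60]]),
    "shank": np.array([[0.04, 0.04, 0.40], [0.02, -0.05, 0.33], [-0.03, 0.03, 0.25]]),
    "foot": np.array([[0.12, 0.03, 0.03], [0.05, -0.04, 0.02], [-0.03, 0.00, 0.05]]),
}

#: contact threshold (newtons) the rendered record crosses exactly at the
#: intended stance boundaries
CONTACT_THRESHOLD_N = 15.0


@dataclass(frozen=True)
class RawTrial:
    """Marker-cluster trajectories plus an untrimmed force-plate record.

    Marker blocks are already cut to the stance interval at the kinematic
    rate; the force record includes sub-threshold padding before heel
    strike and after toe off, with the vertical channel crossing the 15 N
    threshold exactly at ``intended_stance`` (half-open sample interval at
    the force rate).
    """

    subject_id: int
    day: int
    marker_blocks: dict[str, np.ndarray]  # segment -> (frames, k, 3)
    grf: np.ndarray  # (3, T): anterior-posterior, medio-lateral, vertical
    kinematic_rate: float
    force_rate: float
    intended_stance: tuple[int, int]


def standing_blocks(
    geometry: Mapping[str, np.ndarray] = DEFAULT_CLUSTER_GEOMETRY,
) -> dict[str, np.ndarray]:
    """Standing-trial marker positions (the kinematics reference)."""
    return {seg: np.array(geometry[seg], dtype=float) for seg in SEGMENTS}


def render_raw(
    trajectories: Mapping[str, np.ndarray],
    geometry: Mapping[str, np.ndarray] = DEFAULT_CLUSTER_GEOMETRY,
    *,
    subject_id: int = 0,
    day: int = 1,
    kinematic_rate: float = 240.0,
    force_rate: float = 2400.0,
    pad_pre_s: float = 0.15,
    pad_post_s: float = 0.12,
    pad_noise_amp: float = 5.0,
    seed: int = 0,
) -> RawTrial:
    """Render a processed 12-channel trial into raw markers + force plate.

    Marker positions are the standing-pose cluster coordinates rotated
    about each cluster centroid by the composed segment rotations implied
    by the angle channels (Z-X-Y per joint, chained pelvis -> thigh ->
    shank -> foot with the pelvis fixed at its standing pose).  The GRF
    channels are embedded in a longer force record padded with
    sub-threshold noise; the rendered vertical force is clipped to at
    least ``CONTACT_THRESHOLD_N + 1`` inside stance and below the
    threshold outside, so the 15 N contact rule recovers the intended
    boundaries exactly.

    Raises
    ------
    ValueError
        If an ab-adduction (middle-rotation) channel enters the
        gimbal-degenerate zone (|angle| >= 89.9 deg).
    """
    missing = [c for c in ANGLE_CHANNELS if c not in trajectories]
    if missing:
        raise ValueError(f"trajectories missing angle channels: {missing}")
    n_frames = len(np.asarray(trajectories[ANGLE_CHANNELS[0]]))

    for joint, (_, ch_abad, _) in JOINT_CHANNELS.items():
        ax = np.asarray(trajectories[ch_abad], dtype=float)
        bad = np.abs(ax) >= 89.9
        if bad.any():
            raise ValueError(
                f"{joint} ab-adduction channel reaches {np.max(np.abs(ax)):.2f} deg "
                "at frame(s) "
                f"{np.flatnonzero(bad)[:5].tolist()}: Z-X-Y rendering is "
                "gimbal-degenerate near |middle rotation| = 90 deg"
            )

    ref = standing_blocks(geometry)
    marker_blocks = {
        seg: np.empty((n_frames, ref[seg].shape[0], 3)) for seg in SEGMENTS
    }
    for t in range(n_frames):
        R_seg = {"pelvis": np.eye(3)}
        for joint in ("hip", "knee", "ankle"):
            prox, dist = JOINT_SEGMENTS[joint]
            ch_flex, ch_abad, ch_rot = JOINT_CHANNELS[joint]
            R_joint = compose_zxy(
                float(trajectories[ch_rot][t]),
                float(trajectories[ch_abad][t]),
                float(trajectories[ch_flex][t]),
            )
            R_seg[dist] = R_seg[prox] @ R_joint
        for seg in SEGMENTS:
            centroid = ref[seg].mean(axis=0)
            marker_blocks[seg][t] = (ref[seg] - centroid) @ R_seg[seg].T + centroid

    # force-plate embedding
    rng = np.random.default_rng(seed)
    thr = CONTACT_THRESHOLD_N
    n_stance = len(np.asarray(trajectories["grf_vertical"]))
    n_pre = round(pad_pre_s * force_rate)
    n_post = round(pad_post_s * force_rate)
    total = n_pre + n_stance + n_post
    grf = np.zeros((3, total))
    amp = min(pad_noise_amp, thr - 1.0)
    for row, channel in enumerate(GRF_CHANNELS):
        stance = np.asarray(trajectories[channel], dtype=float)
        pre = _smooth_noise(rng, n_pre, amp / 2.0, 0.01 * force_rate)
        post = _smooth_noise(rng, n_post, amp / 2.0, 0.01 * force_rate)
        if channel == "grf_vertical":
            pre = np.clip(np.abs(pre), 0.0, thr - 1.0)
            post = np.clip(np.abs(post), 0.0, thr - 1.0)
            stance = np.maximum(stance, thr + 1.0)
        grf[row] = np.concatenate([pre, stance, post])
    return RawTrial(
        subject_id=subject_id,
        day=day,
        marker_blocks=marker_blocks,
        grf=grf,
        kinematic_rate=kinematic_rate,
        force_rate=force_rate,
        intended_stance=(n_pre, n_pre + n_stance),
    )


# --------------------------------------------------------------------------
# whole datasets
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialRecord:
    subject_id: int
    day: int
    trial_id: str
    channels: dict[str, np.ndarray]


@dataclass(frozen=True)
class GaitDataset:
    """A full two-day synthetic dataset in processed-trajectory form."""

    spec: SyntheticSpec
    truth: GroundTruth
    trials: tuple[TrialRecord, ...]

    @property
    def true_labels(self) -> np.ndarray:
        return np.array([t.subject_id for t in self.trials])

    def day_trials(self, day: int) -> list[TrialRecord]:
        return [t for t in self.trials if t.day == day]


def _trial_counts(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Per subject, trials on (day 1, day 2)."""
    counts = []
    for _ in range(spec.n_subjects):
        if isinstance(spec.trials_per_day, int):
            counts.append((spec.trials_per_day, spec.trials_per_day))
        else:
            lo, hi = spec.trials_per_day
            total = int(rng.integers(lo, hi + 1))
            d1 = min(20, total - total // 2)
            counts.append((d1, total - d1))
    return counts


def generate_dataset(spec: SyntheticSpec) -> GaitDataset:
    """Generate the full dataset; pure function of ``(spec, spec.seed)``."""
    truth = generate_templates(spec)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    trials: list[TrialRecord] = []
    for subject, (n1, n2) in enumerate(_trial_counts(spec, rng)):
        for day, n_day in ((1, n1), (2, n2)):
            for i in range(n_day):
                trial_seed = int(rng.integers(0, 2**31 - 1))
                channels = generate_trial(truth, subject, day, trial_seed)
                trials.append(
                    TrialRecord(
                        subject_id=subject,
                        day=day,
                        trial_id=f"S{subject:03d}_D{day}_T{i:02d}",
                        channels=channels,
                    )
                )
    return GaitDataset(spec=spec, truth=truth, trials=tuple(trials))


def write_dataset(dataset: GaitDataset, out_dir: str | Path) -> Path:
    """Write one delimited table per trial plus a JSON manifest.

    Each trial becomes two CSV files (angle channels at the kinematic rate,
    GRF channels at the force rate); ``manifest.json`` records labels,
    rates, paths and a spec echo, and ``ground_truth.json`` the planted
    feature indices and per-trial labels.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in dataset.trials:
        angles = pd.DataFrame({c: trial.channels[c] for c in ANGLE_CHANNELS})
        grf = pd.DataFrame({c: trial.channels[c] for c in GRF_CHANNELS})
        a_path = out / f"{trial.trial_id}_angles.csv"
        g_path = out / f"{trial.trial_id}_grf.csv"
        angles.to_csv(a_path, index=False)
        grf.to_csv(g_path, index=False)
        entries.append(
            {
                "trial_id": trial.trial_id,
                "subject_id": trial.subject_id,
                "day": trial.day,
                "angles_file": a_path.name,
                "grf_file": g_path.name,
            }
        )
    spec = dataset.spec
    manifest = {
        "kinematic_rate": spec.kinematic_rate,
        "force_rate": spec.force_rate,
        "seed": spec.seed,
        "spec": {
            "n_subjects": spec.n_subjects,
            "trials_per_day": spec.trials_per_day,
            "planted_channels": list(spec.planted_channels),
            "planted_window": list(spec.planted_window),
            "effect_size": spec.effect_size
            if not isinstance(spec.effect_size, Mapping)
            else dict(spec.effect_size),
            "day2_drift": spec.day2_drift,
        },
        "trials": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "planted_variable_set": list(dataset.truth.planted_variable_set),
                "labels": {t.trial_id: t.subject_id for t in dataset.trials},
            },
            indent=1,
        )
    )
    return out


def load_dataset_tables(data_dir: str | Path) -> tuple[list[TrialRecord], dict]:
    """Read back trials written by :func:`write_dataset` (or user-supplied
    tables in the same layout).  Returns the trial records and the manifest."""
    data = Path(data_dir)
    manifest = json.loads((data / "manifest.json").read_text())
    trials = []
    for entry in manifest["trials"]:
        angles = pd.read_csv(data / entry["angles_file"])
        grf = pd.read_csv(data / entry["grf_file"])
        channels = {c: angles[c].to_numpy() for c in ANGLE_CHANNELS}
        channels.update({c: grf[c].to_numpy() for c in GRF_CHANNELS})
        trials.append(
            TrialRecord(
                subject_id=int(entry["subject_id"]),
                day=int(entry["day"]),
                trial_id=entry["trial_id"],
                channels=channels,
            )
        )
    return trials, manifest
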