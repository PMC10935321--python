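"""Synthetic bio-radar session generator.

Emulates the measurement scenario of a continuous-wave Doppler radar
(5.8 GHz carrier) monitoring a seated subject together with a contact
reference system (chest band + ECG at 1 kHz): chest displacement is the sum
of a smooth respiratory excursion and a small cardiac micro-motion, and the
radar perceives that displacement as a phase modulation,

    s(t) = A * exp(j*(theta0 + 4*pi*d(t)/lambda)) + dc(t) + n(t),

with a complex DC offset from static scene reflections and additive complex
noise.  Sessions are fully labeled: ground-truth displacement, beat times,
interbeat intervals and breath boundaries are returned alongside the raw
channels, so every downstream stage (demodulation, peak detection, HRV,
features, classification) is testable without laboratory data.

Emotion-conditioned parameter draws give the classifier stage a dataset with
the right *structure* (one emotion per subject-day, baseline + induction
segments, class-dependent shifts in rate/variability/motion); the shift
magnitudes are fixture choices, not physiological estimates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

SPEED_OF_LIGHT = 299_792_458.0
CARRIER_HZ = 5.8e9
#: Free-space wavelength of the 5.8 GHz carrier, metres (~51.7 mm).
WAVELENGTH_M = SPEED_OF_LIGHT / CARRIER_HZ

#: Working sampling rate of the radar branch after decimation, Hz.
RADAR_FS = 100.0
#: Sampling rate of the contact reference system, Hz.
REFERENCE_FS = 1000.0

EMOTIONS = ("neutral", "happy", "fear")


class SpecValidationError(ValueError):
    """Raised when a :class:`SessionSpec` field violates its constraints."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass
class SessionSpec:
    """Parameters of one synthetic monitoring session.

    A session is a 5-min baseline followed by an emotion-induction period;
    one emotion per subject-day.  ``dc_offset`` may be a complex constant or
    a ``(start, end)`` pair for a linear drift across the session.
    """

    subject_id: str = "S01"
    day_index: int = 1
    emotion: str = "neutral"
    baseline_duration: float = 300.0
    induction_duration: float = 1500.0
    resp_rate: float = 15.0          # breaths/min
    resp_amp: float = 0.004          # metres, chest excursion
    heart_rate: float = 70.0         # beats/min
    ibi_jitter_sd: float = 40.0      # ms, Gaussian IBI jitter (sets HRV)
    dc_offset: complex | tuple[complex, complex] = 0.4 + 0.3j
    noise_sd: float = 0.01
    motion_burst_rate: float = 0.0   # events/min
    rng_seed: int = 0
    # secondary shape parameters (fixture choices, see methods note)
    resp_cycle_var: float = 0.03     # fractional SD of breath duration
    inhale_fraction: float = 0.4     # inhale shorter than exhale
    cardiac_amp: float = 0.0003      # metres (~0.3 mm pulse)
    cardiac_width: float = 0.030     # s, Gaussian pulse sigma (~80 ms FWHM)
    motion_burst_amp: float = 0.002  # metres
    motion_burst_duration: float = 1.0  # s
    amplitude: float = 1.0           # arc radius in the complex plane
    theta0: float = 0.3              # rad, static phase of the arc centre
    fs: float = RADAR_FS
    fs_reference: float = REFERENCE_FS

    def validate(self) -> None:
        if self.baseline_duration <= 0:
            raise SpecValidationError("baseline_duration", "must be > 0")
        if self.induction_duration <= 0:
            raise SpecValidationError("induction_duration", "must be > 0")
        if not (4.0 < self.resp_rate < 60.0):
            raise SpecValidationError("resp_rate", "must lie in (4, 60) breaths/min")
        if not (40.0 < self.heart_rate < 180.0):
            raise SpecValidationError("heart_rate", "must lie in (40, 180) BPM")
        if self.resp_amp <= 0:
            raise SpecValidationError("resp_amp", "must be > 0")
        if self.ibi_jitter_sd < 0:
            raise SpecValidationError("ibi_jitter_sd", "must be >= 0")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")
        if self.motion_burst_rate < 0:
            raise SpecValidationError("motion_burst_rate", "must be >= 0")
        if self.emotion not in EMOTIONS:
            raise SpecValidationError("emotion", f"must be one of {EMOTIONS}")
        if not (0 < self.inhale_fraction < 1):
            raise SpecValidationError("inhale_fraction", "must lie in (0, 1)")
        if not (1 <= int(self.day_index) <= 3):
            raise SpecValidationError("day_index", "must be 1, 2 or 3")

    @property
    def duration(self) -> float:
        return self.baseline_duration + self.induction_duration

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["dc_offset"], complex):
            d["dc_offset"] = [d["dc_offset"].real, d["dc_offset"].imag]
        else:
            d["dc_offset"] = [[c.real, c.imag] for c in d["dc_offset"]]
        return d


@dataclass
class PhysioGroundTruth:
    """Ground-truth physiology of a synthetic session (for recovery tests)."""

    displacement: np.ndarray        # metres, at ``fs``
    fs: float
    true_resp_rate: np.ndarray      # breaths/min, per sample
    true_peak_times_cardiac: np.ndarray  # s
    true_ibi: np.ndarray            # ms
    inhale_onset_times: np.ndarray  # s (breath valleys / cycle starts)
    exhale_onset_times: np.ndarray  # s (breath peaks)


@dataclass
class RadarBaseband:
    """Complex quadrature baseband samples with their sampling context."""

    samples: np.ndarray
    fs: float = RADAR_FS
    wavelength: float = WAVELENGTH_M
    dc_truth: np.ndarray | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if not np.all(np.isfinite(self.samples.view(float))):
            raise ValueError("baseband samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class ReferenceRecording:
    """Contact-system channels: chest band and ECG at 1 kHz, with R peaks."""

    chest_band: np.ndarray
    ecg: np.ndarray
    fs: float = REFERENCE_FS
    r_peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.chest_band = np.asarray(self.chest_band, float)
        self.ecg = np.asarray(self.ecg, float)
        if self.chest_band.size != self.ecg.size:
            raise ValueError("chest_band and ecg must cover the same duration")
        self.r_peak_times = np.asarray(self.r_peak_times, float)
        if self.r_peak_times.size > 1 and np.any(np.diff(self.r_peak_times) <= 0):
            raise ValueError("r_peak_times must be strictly increasing")


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _breath_cycles(duration: float, resp_rate: float, cycle_var: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Breath-cycle onset times covering [0, duration] (first at t=0)."""
    mean_t = 60.0 / resp_rate
    onsets = [0.0]
    while onsets[-1] < duration:
        t = mean_t * (1.0 + cycle_var * rng.standard_normal())
        t = max(t, 0.3 * mean_t)
        onsets.append(onsets[-1] + t)
    return np.asarray(onsets)


def respiration_displacement(t: np.ndarray, onsets: np.ndarray, amp: float,
                             inhale_fraction: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raised-cosine breathing displacement.

    Each cycle rises 0 -> amp over ``inhale_fraction`` of its duration and
    decays back over the remainder; valleys sit at cycle onsets.  Returns
    (displacement, per-sample rate in breaths/min, exhale-onset times).
    """
    d = np.zeros_like(t)
    rate = np.zeros_like(t)
    exhale_onsets = []
    for k in range(len(onsets) - 1):
        t0, t1 = onsets[k], onsets[k + 1]
        period = t1 - t0
        tp = t0 + inhale_fraction * period
        exhale_onsets.append(tp)
        sel = (t >= t0) & (t < t1)
        u = (t[sel] - t0) / period
        phase = np.where(
            u < inhale_fraction,
            u / inhale_fraction * 0.5,
            0.5 + (u - inhale_fraction) / (1 - inhale_fraction) * 0.5,
        )
        d[sel] = amp * 0.5 * (1 - np.cos(2 * np.pi * phase))
        rate[sel] = 60.0 / period
    # trailing samples past the last complete onset keep the last rate
    if len(onsets) >= 2:
        rate[rate == 0] = 60.0 / (onsets[-1] - onsets[-2])
    return d, rate, np.asarray(exhale_onsets)


def cardiac_beat_times(duration: float, heart_rate: float, jitter_sd_ms: float,
                       rng: np.random.Generator, floor_ms: float = 300.0) -> np.ndarray:
    """Beat times from an IBI renewal process.

    IBI_k = 60000/heart_rate + N(0, jitter_sd_ms), floored at ``floor_ms``;
    the floor keeps the process physiological at high jitter.
    """
    mean_ibi = 60000.0 / heart_rate
    times = [0.4]
    while times[-1] < duration:
        ibi = mean_ibi + jitter_sd_ms * rng.standard_normal()
        ibi = max(ibi, floor_ms)
        times.append(times[-1] + ibi / 1000.0)
    return np.asarray([x for x in times if x <= duration])


def cardiac_displacement(t: np.ndarray, beat_times: np.ndarray, amp: float,
                         width: float) -> np.ndarray:
    """Gaussian micro-motion pulse per beat (mechanical, MCG-like)."""
    d = np.zeros_like(t)
    if beat_times.size == 0 or amp == 0:
        return d
    dt = t[1] - t[0] if t.size > 1 else 0.01
    half = int(np.ceil(4 * width / dt))
    for tb in beat_times:
        i0 = max(int((tb - 4 * width) / dt), 0)
        i1 = min(i0 + 2 * half + 1, t.size)
        d[i0:i1] += amp * np.exp(-0.5 * ((t[i0:i1] - tb) / width) ** 2)
    return d


def motion_bursts(t: np.ndarray, rate_per_min: float, amp: float,
                  duration: float, rng: np.random.Generator) -> np.ndarray:
    """Hann-windowed displacement bumps at Poisson times (frights/laughs)."""
    d = np.zeros_like(t)
    if rate_per_min <= 0:
        return d
    span = t[-1] - t[0] if t.size else 0.0
    n = rng.poisson(rate_per_min * span / 60.0)
    dt = t[1] - t[0] if t.size > 1 else 0.01
    width = max(int(duration / dt), 3)
    window = np.hanning(width)
    for _ in range(n):
        i0 = rng.integers(0, max(t.size - width, 1))
        d[i0:i0 + width] += amp * rng.uniform(0.5, 1.5) * window
    return d


def sync_preamble_displacement(fs: float, amp: float = 0.008,
                               resp_rate: float = 15.0) -> np.ndarray:
    """Scripted synchronization pattern performed before each session.

    Three deep breaths, a 10-s apnea, then a slow exhale; the useful signal
    starts at the valley immediately before the next inhale.  Returned as a
    displacement trace ready to prepend to a session.
    """
    t_breath = np.arange(int(3 * 4.0 * fs)) / fs          # 3 deep breaths, 4 s each
    deep = amp * 0.5 * (1 - np.cos(2 * np.pi * t_breath / 4.0))
    apnea = np.full(int(10.0 * fs), amp * 0.6)            # hold at partial inflation
    # ramp into the hold so the pattern is continuous
    deep[-1] = amp * 0.6
    t_ex = np.arange(int(4.0 * fs)) / fs
    exhale = amp * 0.6 * 0.5 * (1 + np.cos(np.pi * t_ex / 4.0))
    return np.concatenate([deep, apnea, exhale])


# ---------------------------------------------------------------------------
# baseband synthesis
# ---------------------------------------------------------------------------

def displacement_to_baseband(displacement: np.ndarray, wavelength: float = WAVELENGTH_M,
                             amplitude: float = 1.0, theta0: float = 0.0,
                             dc: complex | np.ndarray = 0.0, noise_sd: float = 0.0,
                             seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """Map chest displacement to complex quadrature baseband.

    ``sample_i = amplitude * exp(j*(theta0 + 4*pi*d_i/wavelength)) + dc_i + n_i``
    with circularly symmetric complex Gaussian noise of RMS ``noise_sd``.
    """
    d = np.asarray(displacement, float)
    if not np.all(np.isfinite(d)):
        raise ValueError("displacement must be finite")
    dc_arr = np.broadcast_to(np.asarray(dc, complex), d.shape)
    if np.asarray(dc).ndim > 0 and np.asarray(dc).shape != d.shape:
        raise ValueError("dc trace length must match displacement length")
    phase = theta0 + 4.0 * np.pi * d / wavelength
    s = amplitude * np.exp(1j * phase) + dc_arr
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n = rng.standard_normal(d.size) + 1j * rng.standard_normal(d.size)
        s = s + noise_sd * n / np.sqrt(2.0)
    return s


def _dc_trace(dc_offset, n: int) -> np.ndarray:
    if isinstance(dc_offset, (tuple, list)):
        c0, c1 = complex(dc_offset[0]), complex(dc_offset[1])
        frac = np.linspace(0.0, 1.0, n)
        return c0 + (c1 - c0) * frac
    return np.full(n, complex(dc_offset))


def _synthetic_ecg(t: np.ndarray, beat_times: np.ndarray,
                   rng: np.random.Generator, noise_sd: float = 0.02) -> np.ndarray:
    """ECG-like trace: sharp R spike + small T wave per beat."""
    ecg = np.zeros_like(t)
    dt = t[1] - t[0] if t.size > 1 else 1e-3
    for tb in beat_times:
        i0 = max(int((tb - 0.05) / dt), 0)
        i1 = min(int((tb + 0.4) / dt), t.size)
        tt = t[i0:i1] - tb
        ecg[i0:i1] += np.exp(-0.5 * (tt / 0.008) ** 2)            # R
        ecg[i0:i1] += 0.25 * np.exp(-0.5 * ((tt - 0.25) / 0.05) ** 2)  # T
    return ecg + noise_sd * rng.standard_normal(t.size)


def generate_session(spec: SessionSpec) -> tuple[RadarBaseband, ReferenceRecording,
                                                 PhysioGroundTruth, str]:
    """Generate one labeled session (radar + reference + ground truth).

    Deterministic for a fixed ``spec.rng_seed``.  The radar and reference
    channels share one ground-truth physiology; the baseline occupies the
    first ``baseline_duration`` seconds.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    duration = spec.duration
    t = np.arange(int(round(duration * spec.fs))) / spec.fs

    onsets = _breath_cycles(duration, spec.resp_rate, spec.resp_cycle_var, rng)
    d_resp, rate_trace, exhale_onsets = respiration_displacement(
        t, onsets, spec.resp_amp, spec.inhale_fraction)
    beats = cardiac_beat_times(duration, spec.heart_rate, spec.ibi_jitter_sd, rng)
    d_card = cardiac_displacement(t, beats, spec.cardiac_amp, spec.cardiac_width)
    d_burst = motion_bursts(t, spec.motion_burst_rate, spec.motion_burst_amp,
                            spec.motion_burst_duration, rng)
    displacement = d_resp + d_card + d_burst

    dc = _dc_trace(spec.dc_offset, t.size)
    samples = displacement_to_baseband(
        displacement, WAVELENGTH_M, spec.amplitude, spec.theta0, dc,
        spec.noise_sd, rng)
    radar = RadarBaseband(samples, fs=spec.fs, dc_truth=dc)

    t_ref = np.arange(int(round(duration * spec.fs_reference))) / spec.fs_reference
    d_resp_ref, _, _ = respiration_displacement(
        t_ref, onsets, spec.resp_amp, spec.inhale_fraction)
    chest = d_resp_ref * 1000.0 + 0.02 * spec.resp_amp * 1000.0 * rng.standard_normal(t_ref.size)
    ecg = _synthetic_ecg(t_ref, beats, rng)
    reference = ReferenceRecording(chest, ecg, fs=spec.fs_reference, r_peak_times=beats)

    truth = PhysioGroundTruth(
        displacement=displacement,
        fs=spec.fs,
        true_resp_rate=rate_trace,
        true_peak_times_cardiac=beats,
        true_ibi=np.diff(beats) * 1000.0,
        inhale_onset_times=onsets[onsets <= duration],
        exhale_onset_times=exhale_onsets,
    )
    return radar, reference, truth, spec.emotion


# ---------------------------------------------------------------------------
# emotion-conditioned cohort draws
# ---------------------------------------------------------------------------

#: Class-conditional parameter distributions (means).  Directionality only:
#: fear raises heart/breathing rate, lowers beat-to-beat jitter (lower RMSSD)
#: and adds frights; happiness adds laugh-like motion bursts and breath
#: variability.  Magnitudes are fixture choices.
EMOTION_PARAMS = {
    "neutral": dict(resp_rate=14.0, resp_rate_sd=1.2, heart_rate=66.0, heart_rate_sd=4.0,
                    ibi_jitter_sd=45.0, jitter_sd_sd=6.0, motion_burst_rate=0.2,
                    resp_cycle_var=0.03),
    "happy": dict(resp_rate=15.5, resp_rate_sd=1.8, heart_rate=72.0, heart_rate_sd=4.0,
                  ibi_jitter_sd=40.0, jitter_sd_sd=6.0, motion_burst_rate=2.0,
                  resp_cycle_var=0.06),
    "fear": dict(resp_rate=18.0, resp_rate_sd=1.8, heart_rate=84.0, heart_rate_sd=5.0,
                 ibi_jitter_sd=25.0, jitter_sd_sd=4.0, motion_burst_rate=1.2,
                 resp_cycle_var=0.04),
}

#: Between-subject trait SDs (added to every session of a subject).
SUBJECT_EFFECT_SD = dict(resp_rate=1.0, heart_rate=4.0, ibi_jitter_sd=5.0)


def subject_effects(rng: np.random.Generator, scale: float = 1.0) -> dict:
    """Draw stable per-subject trait offsets."""
    return {k: scale * sd * rng.standard_normal() for k, sd in SUBJECT_EFFECT_SD.items()}


def draw_session_spec(emotion: str, subject_id: str, day_index: int,
                      rng: np.random.Generator, effects: dict | None = None,
                      baseline_duration: float = 300.0,
                      induction_duration: float = 1500.0) -> SessionSpec:
    """Draw a session parameterization for one subject-day-emotion."""
    if emotion not in EMOTION_PARAMS:
        raise SpecValidationError("emotion", f"must be one of {EMOTIONS}")
    p = EMOTION_PARAMS[emotion]
    eff = effects or {}
    resp_rate = np.clip(p["resp_rate"] + eff.get("resp_rate", 0.0)
                        + p["resp_rate_sd"] * rng.standard_normal(), 6.0, 40.0)
    heart_rate = np.clip(p["heart_rate"] + eff.get("heart_rate", 0.0)
                         + p["heart_rate_sd"] * rng.standard_normal(), 45.0, 160.0)
    jitter = np.clip(p["ibi_jitter_sd"] + eff.get("ibi_jitter_sd", 0.0)
                     + p["jitter_sd_sd"] * rng.standard_normal(), 5.0, 120.0)
    dc = complex(rng.uniform(0.2, 0.6), rng.uniform(-0.4, 0.4))
    return SessionSpec(
        subject_id=subject_id,
        day_index=day_index,
        emotion=emotion,
        baseline_duration=baseline_duration,
        induction_duration=induction_duration,
        resp_rate=float(resp_rate),
        heart_rate=float(heart_rate),
        ibi_jitter_sd=float(jitter),
        motion_burst_rate=p["motion_burst_rate"],
        resp_cycle_var=p["resp_cycle_var"],
        dc_offset=dc,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort_specs(n_subjects: int = 20, seed: int = 0,
                          baseline_duration: float = 300.0,
                          induction_duration: float = 1500.0) -> list[SessionSpec]:
    """Specs for a cohort: each subject does one emotion per day (3 days)."""
    rng = np.random.default_rng(seed)
    specs = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        eff = subject_effects(rng)
        order = list(EMOTIONS)
        rng.shuffle(order)
        for day, emotion in enumerate(order, start=1):
            specs.append(draw_session_spec(
                emotion, sid, day, rng, eff,
                baseline_duration=baseline_duration,
                induction_duration=induction_duration))
    return specs


# ---------------------------------------------------------------------------
# synthetic feature matrices (for selection/classification fixtures)
# ---------------------------------------------------------------------------

def planted_feature_matrix(n_informative: int = 5, n_redundant: int = 5,
                           n_noise: int = 50, n_obs: int = 600,
                           effect: float = 1.0, redundancy_r: float = 0.95,
                           seed: int = 0):
    """Feature matrix with planted class structure and redundancy.

    ``n_informative`` features carry class-shifted means (3 balanced emotion
    classes), each of the first ``n_redundant`` informative features gets a
    near-duplicate (correlation > ``redundancy_r``), and ``n_noise`` features
    are label-independent Gaussian noise.  Returns a
    :class:`bioradar.features.FeatureMatrix`; feature ids follow the F-number
    convention so the selection machinery runs unchanged.
    """
    from bioradar.features import FeatureMatrix

    rng = np.random.default_rng(seed)
    n_classes = 3
    labels = np.array([EMOTIONS[i % n_classes] for i in range(n_obs)])
    shifts = {"neutral": 0.0, "happy": 1.0, "fear": -1.0}
    class_shift = np.array([shifts[l] for l in labels])

    cols = []
    for i in range(n_informative):
        direction = 1.0 if i % 2 == 0 else -1.0
        cols.append(direction * effect * class_shift + rng.standard_normal(n_obs))
    informative = np.column_stack(cols)
    dup_noise_sd = np.sqrt(1.0 / redundancy_r**2 - 1.0)
    redundant = np.column_stack([
        informative[:, i % n_informative]
        + dup_noise_sd * np.sqrt(np.var(informative[:, i % n_informative]))
        * rng.standard_normal(n_obs)
        for i in range(n_redundant)
    ])
    noise = rng.standard_normal((n_obs, n_noise))
    values = np.column_stack([informative, redundant, noise])
    n_features = values.shape[1]
    feature_ids = [f"F{i + 1}" for i in range(n_features)]
    roles = (["informative"] * n_informative + ["redundant"] * n_redundant
             + ["noise"] * n_noise)
    subjects = np.array([f"S{(i % 10) + 1:02d}" for i in range(n_obs)])
    fm = FeatureMatrix.from_arrays(
        values, feature_ids, labels, subject_id=subjects,
        day_index=np.ones(n_obs, int), is_baseline=np.zeros(n_obs, bool))
    fm.meta["roles"] = dict(zip(feature_ids, roles))
    return fm


def cohort_feature_matrix(n_subjects: int = 10, obs_per_emotion: int = 10,
                          n_features: int = 12, class_sep: float = 3.0,
                          noise_sd: float = 1.0, subject_shift_sd: float = 0.0,
                          shifted_subject: str | None = None,
                          shift_magnitude: float = 6.0, seed: int = 0):
    """Feature matrix with subject structure for classifier protocol tests.

    Class centroids are placed ``class_sep`` apart along random directions;
    optionally one subject's observations are displaced by
    ``shift_magnitude`` to emulate an out-of-distribution individual.
    """
    from bioradar.features import FeatureMatrix

    rng = np.random.default_rng(seed)
    centroids = {}
    for e in EMOTIONS:
        u = rng.standard_normal(n_features)
        centroids[e] = class_sep * u / np.linalg.norm(u)
    rows, labels, subjects, days = [], [], [], []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        subj_off = subject_shift_sd * rng.standard_normal(n_features)
        if shifted_subject is not None and sid == shifted_subject:
            subj_off = subj_off + shift_magnitude * rng.standard_normal(n_features)
        for day, emotion in enumerate(EMOTIONS, start=1):
            for _ in range(obs_per_emotion):
                rows.append(centroids[emotion] + subj_off
                            + noise_sd * rng.standard_normal(n_features))
                labels.append(emotion)
                subjects.append(sid)
                days.append(day)
    values = np.asarray(rows)
    fids = [f"F{i + 1}" for i in range(n_features)]
    return FeatureMatrix.from_arrays(
        values, fids, np.asarray(labels), subject_id=np.asarray(subjects),
        day_index=np.asarray(days), is_baseline=np.zeros(len(labels), bool))


# ---------------------------------------------------------------------------
# session I/O (delimited text + JSON sidecar)
# ---------------------------------------------------------------------------

def write_session(outdir: str | Path, spec: SessionSpec, radar: RadarBaseband,
                  reference: ReferenceRecording, truth: PhysioGroundTruth) -> Path:
    """Write a session as per-channel delimited text + a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = radar.times
    np.savetxt(outdir / "radar_iq.csv",
               np.column_stack([t, radar.samples.real, radar.samples.imag]),
               delimiter=",", header="time,i,q", comments="")
    t_ref = np.arange(reference.chest_band.size) / reference.fs
    np.savetxt(outdir / "chest_band.csv",
               np.column_stack([t_ref, reference.chest_band]),
               delimiter=",", header="time,value", comments="")
    np.savetxt(outdir / "ecg.csv", np.column_stack([t_ref, reference.ecg]),
               delimiter=",", header="time,value", comments="")
    sidecar = {
        "spec": spec.to_dict(),
        "label": spec.emotion,
        "ground_truth": {
            "true_peak_times_cardiac": truth.true_peak_times_cardiac.tolist(),
            "true_ibi_ms": truth.true_ibi.tolist(),
            "inhale_onset_times": truth.inhale_onset_times.tolist(),
            "exhale_onset_times": truth.exhale_onset_times.tolist(),
        },
        "r_peak_times": reference.r_peak_times.tolist(),
    }
    (outdir / "session.json").write_text(json.dumps(sidecar, indent=1))
    return outdir


def read_session(indir: str | Path) -> tuple[RadarBaseband, ReferenceRecording, dict]:
    """Read a session written by :func:`write_session`."""
    indir = Path(indir)
    sidecar = json.loads((indir / "session.json").read_text())
    iq = np.loadtxt(indir / "radar_iq.csv", delimiter=",", skiprows=1)
    chest = np.loadtxt(indir / "chest_band.csv", delimiter=",", skiprows=1)
    ecg = np.loadtxt(indir / "ecg.csv", delimiter=",", skiprows=1)
    spec = sidecar["spec"]
    radar = RadarBaseband(iq[:, 1] + 1j * iq[:, 2], fs=spec["fs"])
    reference = ReferenceRecording(
        chest[:, 1], ecg[:, 1], fs=spec["fs_reference"],
        r_peak_times=np.asarray(sidecar["r_peak_times"]))
    return radar, reference, sidecar
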