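"""Respiratory/cardiac signal separation and event detection.

The demodulated radar phase carries respiration and the cardiac
micro-motion mixed together.  The cardiac branch follows the two-stage
scheme that works best for mechanical (MCG-like) heart signals: a 100th
order FIR band-pass at 0.7-2 Hz to attenuate the dominant respiratory
component, then a shift-invariant wavelet decomposition (MODWT-style, db4,
7 levels) keeping the detail levels 5 and 6 - at a 100 Hz working rate
those dyadic bands span roughly 0.78-3.13 Hz, the cardiac fundamental and
its first harmonic.  The respiratory branch is a zero-phase low-pass below
the cardiac band.  The contact reference's ECG gets a 15th order FIR
band-pass at 6-20 Hz to highlight the R peak.

All FIR stages are group-delay compensated so event times are comparable
across channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage, signal

FS = 100.0

#: cardiac extraction pre-filter: 100th order FIR, 0.7-2 Hz pass-band
PRE_BPF_ORDER = 100
PRE_BPF_BAND = (0.7, 2.0)
#: wavelet decomposition: db4 (4 vanishing moments), 7 levels, keep D5+D6
WAVELET = "db4"
WAVELET_LEVELS = 7
CARDIAC_LEVELS = (5, 6)
#: ECG R-peak filter: 15th order FIR, 6-20 Hz
ECG_ORDER = 15
ECG_BAND = (6.0, 20.0)
#: respiratory low-pass (below the 0.7 Hz cardiac band edge); the order is
#: high enough that the transition band stays clear of breathing rates
RS_CUTOFF = 0.5
RS_ORDER = 800

#: minimum inter-event distance, seconds
MIN_DISTANCE = {"cardiac": 0.33, "resp_peak": 1.5, "resp_valley": 1.5}


@dataclass
class VitalSigns:
    """Paired respiratory/cardiac series with detected event times."""

    rs: np.ndarray
    cs: np.ndarray
    fs: float = FS
    cardiac_peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    breath_peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    breath_valleys: np.ndarray = field(default_factory=lambda: np.empty(0))
    source: str = "bR"
    pre_bpf: np.ndarray | None = None   # band-passed signal before wavelets
    aux: np.ndarray | None = None       # bP: raw ECG (for energy-ratio use)

    def __post_init__(self):
        if len(self.rs) != len(self.cs):
            raise ValueError("rs and cs must be equal length")
        for name in ("cardiac_peak_times", "breath_peaks", "breath_valleys"):
            t = np.asarray(getattr(self, name), float)
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            span = len(self.rs) / self.fs
            if t.size and (t.min() < 0 or t.max() > span):
                raise ValueError(f"{name} outside signal span")
            setattr(self, name, t)


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with exact group-delay compensation.

    Works for odd and even tap counts (fractional delays handled by
    interpolating the full convolution).
    """
    full = np.convolve(x, taps, mode="full")
    delay = (taps.size - 1) / 2.0
    idx = np.arange(x.size) + delay
    return np.interp(idx, np.arange(full.size), full)


def extract_rs(phase: np.ndarray, fs: float = FS) -> np.ndarray:
    """Respiratory signal: zero-phase FIR low-pass (0.5 Hz), mean removed."""
    x = np.asarray(phase, float)
    if x.size < int(30 * fs):
        raise ValueError("need at least 30 s of signal for RS extraction")
    taps = signal.firwin(RS_ORDER + 1, RS_CUTOFF, fs=fs)
    y = _zero_phase_fir(x, taps)
    return y - y.mean()


def _modwt_detail_reconstruction(x: np.ndarray, levels: tuple[int, ...],
                                 wavelet: str = WAVELET,
                                 n_levels: int = WAVELET_LEVELS) -> np.ndarray:
    """Sum of detail reconstructions at ``levels`` via the undecimated WT.

    The stationary (a trous) transform is shift-invariant like the MODWT
    and shares its dyadic detail bands, level j ~ fs/2^(j+1) .. fs/2^j.
    Input is reflection-padded to the required power-of-two multiple.
    """
    n = x.size
    block = 2 ** n_levels
    pad = (-n) % block
    xp = np.pad(x, (0, pad), mode="reflect") if pad else x
    coeffs = pywt.swt(xp, wavelet, level=n_levels)
    # coeffs[k] corresponds to decomposition level n_levels - k
    kept = []
    for k, (ca, cd) in enumerate(coeffs):
        level = n_levels - k
        kept.append((np.zeros_like(ca),
                     cd if level in levels else np.zeros_like(cd)))
    rec = pywt.iswt(kept, wavelet)
    return np.asarray(rec)[:n]


def extract_cs(phase: np.ndarray, fs: float = FS
               ) -> tuple[np.ndarray, np.ndarray]:
    """Cardiac signal from the demodulated phase.

    Returns ``(cs, pre_bpf)``: the 0.7-2 Hz pre-filtered signal is retained
    because the RS/CS energy-ratio feature is defined against it (it keeps
    all high-frequency spectral content the wavelet stage would discard).
    """
    x = np.asarray(phase, float)
    if x.size < 4 * (PRE_BPF_ORDER + 1):
        raise ValueError("signal too short for cardiac extraction")
    taps = signal.firwin(PRE_BPF_ORDER + 1, PRE_BPF_BAND, fs=fs,
                         pass_zero=False)
    pre = _zero_phase_fir(x - x.mean(), taps)
    cs = _modwt_detail_reconstruction(pre, CARDIAC_LEVELS)
    return cs, pre


def filter_ecg(ecg: np.ndarray, fs: float = FS) -> np.ndarray:
    """Highlight the R peak: 15th order FIR band-pass, 6-20 Hz, zero lag."""
    x = np.asarray(ecg, float)
    taps = signal.firwin(ECG_ORDER + 1, ECG_BAND, fs=fs, pass_zero=False)
    return _zero_phase_fir(x - x.mean(), taps)


def normalize_unit(x: np.ndarray) -> np.ndarray:
    """Mean-removed, peak-normalised copy (max absolute value = 1)."""
    y = np.asarray(x, float) - np.mean(x)
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def detect_peaks(x: np.ndarray, fs: float = FS, kind: str = "cardiac"
                 ) -> np.ndarray:
    """Event times (s) by local-extremum detection.

    Minimum inter-event distance: 0.33 s cardiac, 1.5 s respiratory.  The
    prominence threshold adapts to the signal: 30% of the 90th-percentile
    absolute deviation from the median.
    """
    if kind not in MIN_DISTANCE:
        raise ValueError(f"kind must be one of {tuple(MIN_DISTANCE)}")
    y = np.asarray(x, float)
    if kind == "resp_valley":
        y = -y
    dev = np.abs(y - np.median(y))
    prom = 0.3 * np.percentile(dev, 90)
    if prom == 0:
        warnings.warn(f"no {kind} events found (flat signal)")
        return np.empty(0)
    idx, _ = signal.find_peaks(y, distance=max(int(MIN_DISTANCE[kind] * fs), 1),
                               prominence=prom)
    if idx.size == 0:
        warnings.warn(f"no {kind} events found")
    return idx / fs


def detect_r_peaks(ecg_filtered: np.ndarray, fs: float = FS) -> np.ndarray:
    """R-peak times: threshold at half the rolling 95th percentile,
    0.33 s refractory period."""
    x = np.asarray(ecg_filtered, float)
    win = max(int(2.0 * fs), 3)
    thresh = 0.5 * ndimage.percentile_filter(x, 95, size=win)
    idx, _ = signal.find_peaks(x, distance=max(int(0.33 * fs), 1))
    idx = idx[x[idx] >= thresh[idx]]
    if idx.size == 0:
        warnings.warn("no R peaks found")
    return idx / fs


def vitals_from_phase(phase: np.ndarray, fs: float = FS,
                      source: str = "bR") -> VitalSigns:
    """Full radar branch: RS + CS extraction and event detection."""
    rs = extract_rs(phase, fs)
    cs, pre = extract_cs(phase, fs)
    return VitalSigns(
        rs=rs, cs=cs, fs=fs,
        cardiac_peak_times=detect_peaks(cs, fs, "cardiac"),
        breath_peaks=detect_peaks(rs, fs, "resp_peak"),
        breath_valleys=detect_peaks(rs, fs, "resp_valley"),
        source=source, pre_bpf=pre)


def vitals_from_reference(chest_band: np.ndarray, ecg: np.ndarray,
                          fs_in: float = 1000.0, fs: float = FS) -> VitalSigns:
    """Contact-system branch: decimate to the working rate, filter the ECG,
    detect R peaks and breath cycles."""
    from bioradar.radar_dsp import decimate

    rs = decimate(np.asarray(chest_band, float), fs_in, fs)
    rs = rs - rs.mean()
    ecg_d = decimate(np.asarray(ecg, float), fs_in, fs)
    ecg_f = filter_ecg(ecg_d, fs)
    n = min(rs.size, ecg_f.size)
    rs, ecg_f, ecg_d = rs[:n], ecg_f[:n], ecg_d[:n]
    return VitalSigns(
        rs=rs, cs=ecg_f, fs=fs,
        cardiac_peak_times=detect_r_peaks(ecg_f, fs),
        breath_peaks=detect_peaks(rs, fs, "resp_peak"),
        breath_valleys=detect_peaks(rs, fs, "resp_valley"),
        source="bP", aux=ecg_d)
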