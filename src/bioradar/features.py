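"""The 60-feature physiological catalogue and observation matrix.

Sessions are divided into one-minute segments; one observation = one
minute.  Waveform, statistical and spectral features are computed directly
on each minute.  Cardiac HRV features instead honour the 5-min gold
standard: they are computed on sliding 5-min windows moving at a 1-min
pace, and each observation receives the value of the window whose central
minute it is (edge observations use the nearest valid window and are
flagged).  Respiratory-interval HRV (F47/F49) stays on one-minute segments
since breath peaks are sparse but slow.

Feature groups (ids follow the catalogue convention):

==========  ================================================================
F1-F2       signal rate of CS and RS (events/min from detected peaks)
F3-F4       approximate entropy of CS and RS (m=2, r=0.2*SD)
F5-F10      mean |1st / 2nd derivative| of RS, normalised RS, IBI-CS
F11         RS/CS energy ratio (radar: RS vs pre-band-pass output;
            contact: chest band vs ECG)
F12-F14     kurtosis, mean peak/valley width, variance of RS
F15-F38     skewness / median / IQR / mean of IBI-CS, IBI-RS, CS, RS,
            inhale times, exhale times
F39-F44     RS band power: 0-0.1, 0.1-0.2, 0.2-0.3, 0.3-0.4, 0.4-0.9,
            0.9-1.5 Hz
F45         RS band-power ratio (0.1-0.4 Hz) / (0.5-1.5 Hz)
F46-F49     SDNN and RMSSD of IBI-CS and IBI-RS (log-transformed)
F50         pNN50 of IBI-CS
F51-F52     DFA2 alpha1 (20-60 beats) and alpha2 (10-100 beats),
            quadratic detrending
F53-F60     Poincare SD1, SD2, SD12, SDRR at lags m=1 and m=10
==========  ================================================================

To remove individual and day dependencies, the mean of each subject-day's
baseline features is subtracted from that day's condition features
(baseline normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy import stats

from bioradar import hrv as hrv_mod
from bioradar.vitals import VitalSigns, normalize_unit

LOG_EPS = 1e-6          # ms, floor inside the log transform of F46-F49
PSD_SEGMENT_S = 30.0    # Welch segment length
PSD_BANDS = [(0.0, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4),
             (0.4, 0.9), (0.9, 1.5)]
PSD_RATIO_BANDS = ((0.1, 0.4), (0.5, 1.5))
APEN_FS = 10.0          # regularity statistics run on a decimated copy
DFA_SHORT = (20, 60)    # beats, alpha1
DFA_LONG = (10, 100)    # beats, alpha2
HRV_WINDOW_MIN = 5      # minutes per cardiac-HRV window

_STAT_NAMES = ("Sk", "Med", "IQR", "Av")


@dataclass(frozen=True)
class FeatureSpec:
    id: str
    category: str         # waveform | statistical | spectral | HRV
    input_signal: str
    description: str
    windowed: bool = False  # 5-min sliding-window cardiac HRV feature


def _registry() -> dict[str, FeatureSpec]:
    r: dict[str, FeatureSpec] = {}

    def add(fid, cat, sig, desc, windowed=False):
        r[fid] = FeatureSpec(fid, cat, sig, desc, windowed)

    add("F1", "waveform", "CS", "Signal rate of CS (beats/min)")
    add("F2", "waveform", "RS", "Signal rate of RS (breaths/min)")
    add("F3", "waveform", "CS", "Approximate entropy of CS")
    add("F4", "waveform", "RS", "Approximate entropy of RS")
    for fid, sig in zip(("F5", "F6", "F7"), ("RS", "RS-N", "IBI-CS")):
        add(fid, "waveform", sig, f"Mean |first derivative| of {sig}")
    for fid, sig in zip(("F8", "F9", "F10"), ("RS", "RS-N", "IBI-CS")):
        add(fid, "waveform", sig, f"Mean |second derivative| of {sig}")
    add("F11", "waveform", "RS", "Energy ratio RS/CS")
    add("F12", "waveform", "RS", "Kurtosis of RS")
    add("F13", "waveform", "RS", "Mean width of RS peaks and valleys (s)")
    add("F14", "waveform", "RS", "Variance of RS")
    blocks = [("F15", "IBI-CS", True), ("F19", "IBI-RS", False),
              ("F23", "CS", False), ("F27", "RS", False),
              ("F31", "inhale", False), ("F35", "exhale", False)]
    for start, sig, win in blocks:
        base = int(start[1:])
        for k, stat in enumerate(_STAT_NAMES):
            add(f"F{base + k}", "statistical", sig, f"{stat} of {sig}", win)
    for k, (lo, hi) in enumerate(PSD_BANDS):
        add(f"F{39 + k}", "spectral", "RS", f"PSD of RS in {lo}-{hi} Hz")
    add("F45", "spectral", "RS",
        "PSD ratio of RS (0.1-0.4 Hz)/(0.5-1.5 Hz)")
    add("F46", "HRV", "IBI-CS", "log SDNN of IBI-CS", True)
    add("F47", "HRV", "IBI-RS", "log SDNN of IBI-RS (1-min)")
    add("F48", "HRV", "IBI-CS", "log RMSSD of IBI-CS", True)
    add("F49", "HRV", "IBI-RS", "log RMSSD of IBI-RS (1-min)")
    add("F50", "HRV", "IBI-CS", "pNN50 of IBI-CS (%)", True)
    add("F51", "HRV", "IBI-CS", "DFA2 alpha1 (20-60 beats)", True)
    add("F52", "HRV", "IBI-CS", "DFA2 alpha2 (10-100 beats)", True)
    for fid, name in zip(("F53", "F54", "F55", "F56"),
                         ("SD1", "SD2", "SD12", "SDRR")):
        add(fid, "HRV", "IBI-CS", f"Poincare {name}, m=1", True)
    for fid, name in zip(("F57", "F58", "F59", "F60"),
                         ("SD1", "SD2", "SD12", "SDRR")):
        add(fid, "HRV", "IBI-CS", f"Poincare {name}, m=10", True)
    return r


#: the full catalogue, F1..F60
FEATURE_REGISTRY: dict[str, FeatureSpec] = _registry()
FEATURE_IDS: list[str] = [f"F{i}" for i in range(1, 61)]
WINDOWED_IDS: list[str] = [f for f in FEATURE_IDS if FEATURE_REGISTRY[f].windowed]


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------

def apen(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy (regularity statistic), Chebyshev distance,
    self-matches included; default tolerance r = 0.2*SD."""
    x = np.asarray(x, float)
    n = x.size
    if n < m + 2:
        return np.nan
    if r is None:
        r = 0.2 * float(np.std(x))

    def phi(mm: int) -> float:
        emb = sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        c = np.mean(d <= r, axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def _stats4(x: np.ndarray) -> tuple[float, float, float, float]:
    """(skewness, median, IQR, mean); skewness NaN-flagged if degenerate."""
    x = np.asarray(x, float)
    sk = float(stats.skew(x)) if x.size >= 3 and np.std(x) > 0 else np.nan
    med = float(np.median(x)) if x.size else np.nan
    iqr = float(np.subtract(*np.percentile(x, [75, 25]))) if x.size else np.nan
    av = float(np.mean(x)) if x.size else np.nan
    return sk, med, iqr, av


def welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD: 30-s mean-removed segments, 50% overlap."""
    x = np.asarray(x, float)
    nperseg = min(int(PSD_SEGMENT_S * fs), x.size)
    return sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2,
                     detrend="constant")


def band_power(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    sel = (f >= lo) & (f < hi)
    if not np.any(sel):
        return 0.0
    df = f[1] - f[0] if f.size > 1 else 1.0
    return float(np.sum(p[sel]) * df)


def dfa2(ibi: np.ndarray, range_short: tuple[int, int] = DFA_SHORT,
         range_long: tuple[int, int] = DFA_LONG) -> tuple[float, float]:
    """Detrended fluctuation analysis with quadratic (order-2) detrending.

    Returns (alpha1, alpha2): slopes of log F(n) vs log n over the short
    (20-60 beats) and long (10-100 beats) box-size ranges.  NaN when too
    few beats support a range (alpha2 needs >= 100 IBIs).
    """
    x = np.asarray(ibi, float)
    return (_dfa_alpha(x, range_short), _dfa_alpha(x, range_long))


def _dfa_alpha(x: np.ndarray, n_range: tuple[int, int], order: int = 2) -> float:
    n_tot = x.size
    if n_tot < max(n_range[1], 4 * n_range[0]):
        return np.nan
    y = np.cumsum(x - x.mean())
    ns = np.unique(np.round(np.geomspace(n_range[0], n_range[1], 12)).astype(int))
    ns = ns[(ns >= order + 2) & (ns <= n_tot // 4)]
    if ns.size < 2:
        return np.nan
    fl = []
    for n in ns:
        k = n_tot // n
        t = np.arange(n)
        vand = np.vander(t, order + 1)
        resids = []
        for boxes in (y[:k * n].reshape(k, n), y[-k * n:].reshape(k, n)):
            coef, *_ = np.linalg.lstsq(vand, boxes.T, rcond=None)
            res = boxes.T - vand @ coef
            resids.append(np.mean(res**2, axis=0))
        fl.append(np.sqrt(np.mean(np.concatenate(resids))))
    fl = np.asarray(fl)
    if np.any(fl <= 0):
        return np.nan
    return float(np.polyfit(np.log(ns), np.log(fl), 1)[0])


def poincare(ibi: np.ndarray, m: int = 1
             ) -> tuple[float, float, float, float]:
    """Poincare plot dispersions of the lagged pairs (IBI_k, IBI_{k+m}).

    SD1 = SD of (x - y)/sqrt(2) (crosswise), SD2 = SD of (x + y)/sqrt(2)
    (lengthwise), SD12 = SD1/SD2 (NaN when SD2 = 0), SDRR = SD of the IBIs.
    """
    v = np.asarray(ibi, float)
    if v.size < m + 2:
        return (np.nan,) * 4
    x, y = v[:-m], v[m:]
    sd1 = float(np.std((x - y) / np.sqrt(2.0)))
    sd2 = float(np.std((x + y) / np.sqrt(2.0)))
    sd12 = sd1 / sd2 if sd2 > 0 else np.nan
    return sd1, sd2, sd12, float(np.std(v))


def _log_eps(x: float) -> float:
    return float(np.log(x + LOG_EPS))


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

@dataclass
class Observation:
    index: int        # minute index within the session
    t0: float
    t1: float
    is_baseline: bool


def segment_observations(duration: float, baseline_duration: float
                         ) -> list[Observation]:
    """Non-overlapping one-minute observations; trailing partial dropped."""
    if duration < 60.0:
        raise ValueError("session shorter than one minute")
    n = int(duration // 60)
    out = []
    for i in range(n):
        t0 = 60.0 * i
        out.append(Observation(i, t0, t0 + 60.0,
                               is_baseline=t0 + 60.0 <= baseline_duration + 1e-9))
    return out


@dataclass
class SessionRecord:
    """One subject-day session ready for feature extraction."""

    vit: VitalSigns
    subject_id: str
    day_index: int
    emotion: str
    baseline_duration: float = 300.0
    ibi_method: str | None = None  # default: window_median for bR else conventional

    @property
    def method(self) -> str:
        if self.ibi_method:
            return self.ibi_method
        return "window_median" if self.vit.source == "bR" else "conventional"


def _events_in(times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    t = np.asarray(times, float)
    return t[(t >= t0) & (t < t1)]


def _breath_phases(peaks: np.ndarray, valleys: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Inhale (valley->peak) and exhale (peak->valley) durations."""
    events = sorted([(t, "p") for t in peaks] + [(t, "v") for t in valleys])
    inhale, exhale = [], []
    for (t_prev, k_prev), (t_cur, k_cur) in zip(events, events[1:]):
        if k_prev == "v" and k_cur == "p":
            inhale.append(t_cur - t_prev)
        elif k_prev == "p" and k_cur == "v":
            exhale.append(t_cur - t_prev)
    return np.asarray(inhale), np.asarray(exhale)


def _mean_extremum_width(x: np.ndarray, fs: float) -> float:
    """Mean width (s) of RS peaks and valleys at half prominence."""
    widths = []
    for y in (x, -x):
        idx, _ = sps.find_peaks(y, distance=int(1.5 * fs))
        if idx.size:
            w = sps.peak_widths(y, idx, rel_height=0.5)[0]
            widths.extend(w / fs)
    return float(np.mean(widths)) if widths else np.nan


def _decimated(x: np.ndarray, fs: float, target_fs: float = APEN_FS) -> np.ndarray:
    q = max(int(round(fs / target_fs)), 1)
    return x[::q] if q == 1 else sps.decimate(x, q, ftype="fir", zero_phase=True)


def compute_minute_features(rec: SessionRecord, t0: float, t1: float) -> dict:
    """All per-minute (non-windowed) features of one observation.

    Values that cannot be computed (too few events, degenerate statistics)
    are returned as NaN and later flagged/imputed.
    """
    v = rec.vit
    fs = v.fs
    i0, i1 = int(t0 * fs), int(t1 * fs)
    rs = v.rs[i0:i1]
    cs = v.cs[i0:i1]
    rs_n = normalize_unit(rs)
    minutes = (t1 - t0) / 60.0
    pk_c = _events_in(v.cardiac_peak_times, t0, t1)
    pk_r = _events_in(v.breath_peaks, t0, t1)
    vl_r = _events_in(v.breath_valleys, t0, t1)
    ibi_cs = np.diff(pk_c) * 1000.0 if pk_c.size >= 2 else np.empty(0)
    ibi_rs = np.diff(pk_r) * 1000.0 if pk_r.size >= 2 else np.empty(0)

    out: dict[str, float] = {}
    out["F1"] = pk_c.size / minutes
    out["F2"] = pk_r.size / minutes
    out["F3"] = apen(_decimated(cs, fs))
    out["F4"] = apen(_decimated(rs, fs))
    out["F5"] = float(np.mean(np.abs(np.diff(rs))))
    out["F6"] = float(np.mean(np.abs(np.diff(rs_n))))
    out["F7"] = float(np.mean(np.abs(np.diff(ibi_cs)))) if ibi_cs.size >= 2 else np.nan
    out["F8"] = float(np.mean(np.abs(np.diff(rs, 2))))
    out["F9"] = float(np.mean(np.abs(np.diff(rs_n, 2))))
    out["F10"] = float(np.mean(np.abs(np.diff(ibi_cs, 2)))) if ibi_cs.size >= 3 else np.nan

    if v.source == "bR":
        denom = v.pre_bpf[i0:i1] if v.pre_bpf is not None else cs
    else:
        denom = v.aux[i0:i1] if v.aux is not None else cs
    e_den = float(np.sum(np.square(denom)))
    out["F11"] = float(np.sum(rs**2)) / e_den if e_den > 0 else np.nan

    out["F12"] = float(stats.kurtosis(rs, fisher=False)) if np.std(rs) > 0 else np.nan
    out["F13"] = _mean_extremum_width(rs, fs)
    out["F14"] = float(np.var(rs))

    inhale, exhale = _breath_phases(pk_r, vl_r)
    for base, series in (("F19", ibi_rs), ("F23", cs), ("F27", rs),
                         ("F31", inhale), ("F35", exhale)):
        sk, med, iqr, av = _stats4(series)
        b = int(base[1:])
        out[f"F{b}"], out[f"F{b+1}"], out[f"F{b+2}"], out[f"F{b+3}"] = sk, med, iqr, av

    f, p = welch_psd(rs, fs)
    for k, (lo, hi) in enumerate(PSD_BANDS):
        out[f"F{39 + k}"] = band_power(f, p, lo, hi)
    num = band_power(f, p, *PSD_RATIO_BANDS[0])
    den = band_power(f, p, *PSD_RATIO_BANDS[1])
    out["F45"] = num / den if den > 0 else np.nan

    if ibi_rs.size >= 2:
        h = hrv_mod.hrv_params(ibi_rs)
        out["F47"] = _log_eps(h.sdnn)
        out["F49"] = _log_eps(h.rmssd)
    else:
        out["F47"] = out["F49"] = np.nan
    return out


def hrv_feature_windows(rec: SessionRecord, observations: list[Observation]
                        ) -> tuple[list[dict], list[bool]]:
    """Cardiac HRV features on 5-min sliding windows at a 1-min pace.

    Each observation receives the window centred on it; the first/last two
    observations of a session use the nearest valid window and are flagged.
    Sessions shorter than 5 min flag every cardiac HRV feature.
    """
    n = len(observations)
    results, edge_flags = [], []
    if n < HRV_WINDOW_MIN:
        return [dict.fromkeys(WINDOWED_IDS, np.nan) for _ in observations], [True] * n
    half = HRV_WINDOW_MIN // 2
    for obs in observations:
        c = min(max(obs.index, half), n - 1 - half)
        edge_flags.append(c != obs.index)
        w0 = observations[c - half].t0
        w1 = observations[c + half].t1
        peaks = _events_in(rec.vit.cardiac_peak_times, w0, w1) - w0
        vals: dict[str, float] = {}
        ibi = np.empty(0)
        if peaks.size >= 2:
            try:
                if rec.method == "window_median":
                    ibi = hrv_mod.window_median_ibi(peaks).values
                else:
                    ibi = hrv_mod.conventional_ibi(peaks).values
            except ValueError:
                ibi = np.empty(0)
        sk, med, iqr, av = _stats4(ibi)
        vals["F15"], vals["F16"], vals["F17"], vals["F18"] = sk, med, iqr, av
        if ibi.size >= 2:
            h = hrv_mod.hrv_params(ibi)
            vals["F46"] = _log_eps(h.sdnn)
            vals["F48"] = _log_eps(h.rmssd)
            vals["F50"] = h.pnn50
        else:
            vals["F46"] = vals["F48"] = vals["F50"] = np.nan
        vals["F51"], vals["F52"] = dfa2(ibi)
        vals["F53"], vals["F54"], vals["F55"], vals["F56"] = poincare(ibi, 1)
        vals["F57"], vals["F58"], vals["F59"], vals["F60"] = poincare(ibi, 10)
        results.append(vals)
    return results, edge_flags


def session_feature_table(rec: SessionRecord
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Feature values, flags and metadata for every minute of one session."""
    duration = rec.vit.rs.size / rec.vit.fs
    observations = segment_observations(duration, rec.baseline_duration)
    rows = [compute_minute_features(rec, o.t0, o.t1) for o in observations]
    win_rows, edge = hrv_feature_windows(rec, observations)
    for r, w in zip(rows, win_rows):
        r.update(w)
    values = pd.DataFrame(rows, columns=FEATURE_IDS)
    flags = values.isna()
    for i, e in enumerate(edge):
        if e:
            flags.loc[i, WINDOWED_IDS] = True
    meta = pd.DataFrame({
        "subject_id": rec.subject_id,
        "day_index": rec.day_index,
        "label": rec.emotion,
        "is_baseline": [o.is_baseline for o in observations],
        "minute_index": [o.index for o in observations],
        "source": rec.vit.source,
    })
    return values, flags, meta


# ---------------------------------------------------------------------------
# the observation matrix
# ---------------------------------------------------------------------------

META_COLUMNS = ["subject_id", "day_index", "label", "is_baseline",
                "minute_index", "source"]


class FeatureMatrix:
    """N-features x M-observations table with labels and subject metadata.

    Stored observation-major (rows = observations) as a pandas DataFrame;
    ``flags`` marks imputed/edge-window cells.
    """

    def __init__(self, df: pd.DataFrame, obs: pd.DataFrame,
                 flags: pd.DataFrame | None = None, meta: dict | None = None):
        if len(df) != len(obs):
            raise ValueError("df and obs must have one row per observation")
        self.df = df.reset_index(drop=True)
        self.obs = obs.reset_index(drop=True)
        self.flags = (flags.reset_index(drop=True) if flags is not None
                      else pd.DataFrame(False, index=self.df.index,
                                        columns=self.df.columns))
        self.meta = meta or {}

    @classmethod
    def from_arrays(cls, values, feature_ids, labels, subject_id=None,
                    day_index=None, is_baseline=None):
        values = np.asarray(values, float)
        m = values.shape[0]
        obs = pd.DataFrame({
            "subject_id": subject_id if subject_id is not None else ["S01"] * m,
            "day_index": day_index if day_index is not None else np.ones(m, int),
            "label": np.asarray(labels),
            "is_baseline": is_baseline if is_baseline is not None
            else np.zeros(m, bool),
            "minute_index": np.arange(m),
            "source": "synthetic",
        })
        return cls(pd.DataFrame(values, columns=list(feature_ids)), obs)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def labels(self) -> np.ndarray:
        return self.obs["label"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def condition_rows(self) -> "FeatureMatrix":
        keep = ~self.obs["is_baseline"].to_numpy(bool)
        return FeatureMatrix(self.df[keep], self.obs[keep], self.flags[keep],
                             dict(self.meta))

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.df.copy(), self.obs.copy(),
                             self.flags.copy(), dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.obs[META_COLUMNS].reset_index(drop=True),
                         self.df.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureMatrix":
        raw = pd.read_csv(path)
        obs = raw[[c for c in META_COLUMNS if c in raw.columns]].copy()
        df = raw[[c for c in raw.columns if c not in META_COLUMNS]]
        return cls(df, obs)


def impute_flagged(fm: FeatureMatrix) -> FeatureMatrix:
    """Replace NaNs with the per-subject median of the same feature.

    Falls back to the overall feature median when a subject has no valid
    value; flags are raised on every imputed cell.  Keeps the matrix
    complete without leaking information across subjects.
    """
    out = fm.copy()
    subj = out.obs["subject_id"].to_numpy()
    for col in out.df.columns:
        x = out.df[col]
        nan = x.isna()
        if not nan.any():
            continue
        out.flags.loc[nan, col] = True
        med_by_subj = x.groupby(subj).transform("median")
        x = x.fillna(med_by_subj)
        x = x.fillna(x.median())
        out.df[col] = x.fillna(0.0)
    return out


def build_feature_matrix(records: list[SessionRecord]) -> FeatureMatrix:
    """Extract, assemble and impute the observation matrix for a cohort."""
    vals, flags, metas = [], [], []
    for rec in records:
        v, f, m = session_feature_table(rec)
        vals.append(v)
        flags.append(f)
        metas.append(m)
    fm = FeatureMatrix(pd.concat(vals), pd.concat(metas),
                       pd.concat(flags))
    return impute_flagged(fm)


def baseline_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Subtract each subject-day's baseline feature mean from that day's
    condition observations (user- and day-independence).  Baseline rows are
    normalized too (hence ~zero-mean) and stay flagged via ``is_baseline``.
    """
    out = fm.copy()
    groups = out.obs.groupby(["subject_id", "day_index"]).groups
    for (subj, day), idx in groups.items():
        rows = out.obs.loc[idx]
        base_idx = rows.index[rows["is_baseline"].astype(bool)]
        if len(base_idx) == 0:
            raise ValueError(f"no baseline observations for subject {subj} "
                             f"day {day}")
        base_mean = out.df.loc[base_idx].mean(axis=0)
        out.df.loc[idx] = out.df.loc[idx] - base_mean
    out.meta["baseline_normalized"] = True
    return out


def zscore_fit(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature z-score parameters from a training partition only."""
    mu = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def zscore_apply(values: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (values - mu) / sd
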