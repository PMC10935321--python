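"""Phase recovery from complex quadrature radar baseband.

Chest-wall motion traces an arc in the complex plane; static scene
reflections add a complex DC offset that displaces the arc's centre away
from the origin.  Correct arctangent demodulation requires the arc to
oscillate around the complex origin, so the chain is:

    decimate -> synchronize -> windowed DC-offset estimation/removal
             -> dynamic arc rotation to 0 degrees -> arctangent -> phase

The DC-offset estimator minimises a radial-variance cost over candidate
circle centres with the search region constrained to lie *outside* the
sample cloud.  A plain algebraic circle fit collapses to the cloud centroid
when a weak signal degenerates from an arc into a dispersed cluster; the
outside-the-cloud constraint prevents exactly that failure mode.  Estimates
from overlapped windows are interpolated so every radar sample gets its own
DC-offset coordinate, accommodating slow drifts from body motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal


class DegenerateCloudError(ValueError):
    """No arc: the sample cloud has (near-)zero spread."""


@dataclass
class DcOffsetTrack:
    """Windowed complex DC-offset estimates and their per-sample interpolation."""

    window_centers: np.ndarray   # s
    estimates: np.ndarray        # complex, one per window
    per_sample: np.ndarray       # complex, one per radar sample


@dataclass
class PhaseSignal:
    """Unwrapped demodulated phase in radians at the working rate."""

    values: np.ndarray
    fs: float = 100.0
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


# ---------------------------------------------------------------------------
# decimation
# ---------------------------------------------------------------------------

def decimate(samples: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias filter and subsample ``fs_in`` -> ``fs_out``.

    The ratio must be an integer.  Implemented as a zero-phase polyphase
    FIR decimator with linear edge extension (no start-up transient on
    slowly varying signals).  Output length is ``floor(n * fs_out / fs_in)``.
    """
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs_in/fs_out must be an integer, got {ratio:g}")
    q = int(round(ratio))
    x = np.asarray(samples)
    n_out = int(np.floor(x.shape[-1] * fs_out / fs_in))
    if q == 1:
        return x.copy()
    y = signal.resample_poly(x, 1, q, padtype="line")
    return y[:n_out]


# ---------------------------------------------------------------------------
# DC-offset estimation
# ---------------------------------------------------------------------------

def _kasa_center(z: np.ndarray) -> complex:
    """Algebraic least-squares circle fit (exact on noiseless circles)."""
    x, y = z.real, z.imag
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return complex(sol[0] / 2.0, sol[1] / 2.0)


def _radial_variance(z: np.ndarray, c: complex) -> float:
    r = np.abs(z - c)
    return float(np.var(r))


def estimate_dc_window(window: np.ndarray) -> complex:
    """Estimate the complex DC offset (arc centre) of one sample window.

    Minimises the radial-variance cost ``Var_i |s_i - c|`` over candidate
    centres ``c`` constrained to lie outside the sample cloud
    (``|c - centroid| >= cloud RMS radius``, enforced as a penalty).  When
    the samples cover most of a circle the interior is sample-free and the
    constraint is waived, so closed circles recover their exact centre.
    """
    z = np.asarray(window, complex)
    if z.size < 8:
        raise ValueError("DC estimation needs at least 8 samples")
    centroid = complex(np.mean(z))
    r_rms = float(np.sqrt(np.mean(np.abs(z - centroid) ** 2)))
    if r_rms < 1e-12 * max(1.0, abs(centroid)):
        raise DegenerateCloudError("no arc: sample cloud has zero spread")

    c0 = _kasa_center(z)
    # The outside-the-cloud constraint is waived only when the samples form
    # a tight ring covering most of a circle: then the interior is
    # sample-free and the centre legitimately sits "outside the samples".
    # A dispersed blob also surrounds its fitted centre, but with a large
    # relative radial spread, and must stay constrained.
    radii = np.abs(z - c0)
    coverage = _angular_extent(np.angle(z - c0))
    ring_cv = float(np.std(radii) / np.mean(radii)) if np.mean(radii) > 0 else np.inf
    constrained = not (coverage > 1.5 * np.pi and ring_cv < 0.2)

    # cost evaluated on at most 256 samples: the radial-variance surface is
    # smooth and a uniform subsample estimates it to ample accuracy
    zc = z[:: max(z.size // 256, 1)]
    scale = max(_radial_variance(zc, centroid), 1e-30)

    def cost(p):
        c = complex(p[0], p[1])
        val = _radial_variance(zc, c)
        if constrained:
            short = r_rms - abs(c - centroid)
            if short > 0:
                val += scale * (1.0 + (short / r_rms) ** 2) * 1e3
        return val

    starts = [(np.array([c0.real, c0.imag]), 400)]
    if constrained and abs(c0 - centroid) < r_rms:
        # Kasa collapsed into the cloud: seed a ring of exterior candidates
        # (coarser optimizer budget; precision is meaningless for blobs).
        for theta in np.linspace(0, 2 * np.pi, 4, endpoint=False):
            starts.append((np.array([centroid.real + 2 * r_rms * np.cos(theta),
                                     centroid.imag + 2 * r_rms * np.sin(theta)]),
                           120))
    best = None
    for p0, maxiter in starts:
        res = optimize.minimize(cost, p0, method="Nelder-Mead",
                                options=dict(xatol=1e-9, fatol=1e-18,
                                             maxiter=maxiter))
        if best is None or res.fun < best.fun:
            best = res
    return complex(best.x[0], best.x[1])


def _angular_extent(angles: np.ndarray) -> float:
    """Extent of a set of angles: 2*pi minus the largest empty gap."""
    a = np.sort(np.mod(angles, 2 * np.pi))
    if a.size < 2:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 2 * np.pi]]))
    return float(2 * np.pi - gaps.max())


def estimate_dc_track(samples: np.ndarray, fs: float, window_len: float = 10.0,
                      overlap: float = 0.5) -> DcOffsetTrack:
    """Overlapped-window DC-offset estimation, interpolated per sample.

    Windows of ``window_len`` seconds with fractional ``overlap``; the
    per-window estimates are linearly interpolated (real and imaginary parts
    independently) onto every sample, with nearest-estimate extension at the
    edges.  A signal shorter than one window yields a single broadcast
    estimate.
    """
    z = np.asarray(samples, complex)
    n = z.size
    wlen = int(round(window_len * fs))
    if wlen < 8:
        raise ValueError("window_len * fs must be >= 8 samples")
    if n <= wlen:
        est = estimate_dc_window(z)
        return DcOffsetTrack(np.array([n / (2 * fs)]), np.array([est]),
                             np.full(n, est))
    hop = max(int(round(wlen * (1.0 - overlap))), 1)
    starts = list(range(0, n - wlen + 1, hop))
    if starts[-1] + wlen < n:
        starts.append(n - wlen)
    centers, ests = [], []
    for s0 in starts:
        ests.append(estimate_dc_window(z[s0:s0 + wlen]))
        centers.append((s0 + wlen / 2.0) / fs)
    centers = np.asarray(centers)
    ests = np.asarray(ests)
    t = np.arange(n) / fs
    per_sample = (np.interp(t, centers, ests.real)
                  + 1j * np.interp(t, centers, ests.imag))
    return DcOffsetTrack(centers, ests, per_sample)


# ---------------------------------------------------------------------------
# centering, rotation, demodulation
# ---------------------------------------------------------------------------

#: rotation-reference window, seconds; spans many respiratory cycles so the
#: reference tracks only slow arc drift, not the respiration itself
ROTATION_WINDOW_S = 60.0


def remove_dc_and_rotate(samples: np.ndarray, track: DcOffsetTrack,
                         fs: float = 100.0,
                         rotation_window_s: float = ROTATION_WINDOW_S
                         ) -> np.ndarray:
    """Subtract the interpolated DC track and rotate the arc onto 0 degrees.

    The rotation reference is the circular-mean angle of the centred
    samples over sliding windows of ``rotation_window_s`` (much longer than
    a breath, so respiratory motion averages out of the reference),
    unwrapped across windows and interpolated per sample.  Rotating
    dynamically keeps the arc oscillating about 0 degrees and avoids phase
    wraps when the raw arc straddles +/-pi.
    """
    z = np.asarray(samples, complex)
    if z.size != track.per_sample.size:
        raise ValueError("samples and DC track lengths differ")
    centered = z - track.per_sample
    t = np.arange(z.size) / fs
    half = rotation_window_s / 2.0
    if t[-1] <= rotation_window_s:
        centers = np.array([t[-1] / 2.0])
    else:
        centers = np.arange(half, t[-1] - half + 1e-9, half)
    angles = []
    for tc in centers:
        sel = (t >= tc - half) & (t <= tc + half) if centers.size > 1 else slice(None)
        w = centered[sel]
        w = w[np.abs(w) > 0]
        angles.append(float(np.angle(np.mean(w / np.abs(w)))) if w.size else 0.0)
    phi = np.unwrap(np.asarray(angles))
    phi_ref = (np.interp(t, centers, phi) if centers.size > 1
               else np.full(z.size, phi[0]))
    return centered * np.exp(-1j * phi_ref)


def arctangent_demodulate(centered: np.ndarray, wavelength: float,
                          fs: float = 100.0, t0: float = 0.0
                          ) -> tuple[PhaseSignal, np.ndarray]:
    """Four-quadrant phase demodulation.

    ``phase = unwrap(angle(s))``; displacement follows from the two-way path
    modulation, ``d = phase * wavelength / (4*pi)`` (metres).
    """
    z = np.asarray(centered, complex)
    if np.any(np.abs(z) == 0):
        raise ValueError("zero-magnitude sample: phase undefined")
    phase = np.unwrap(np.angle(z))
    displacement = phase * wavelength / (4.0 * np.pi)
    return PhaseSignal(phase, fs=fs, t0=t0), displacement


def demodulate(radar, window_len: float = 10.0, overlap: float = 0.5
               ) -> tuple[PhaseSignal, np.ndarray, DcOffsetTrack]:
    """Full chain on a :class:`~bioradar.synth.RadarBaseband`: DC track ->
    centre+rotate -> arctangent.  Returns (phase, displacement, dc_track)."""
    track = estimate_dc_track(radar.samples, radar.fs, window_len, overlap)
    centered = remove_dc_and_rotate(radar.samples, track, radar.fs)
    return (*arctangent_demodulate(centered, radar.wavelength, fs=radar.fs), track)


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

def _find_apnea_valley(x: np.ndarray, fs: float, min_flat: float = 8.0
                       ) -> int | None:
    """Index of the valley ending the scripted apnea pattern, if present.

    Looks for a flat segment (rolling SD below 15% of the overall SD)
    lasting at least ``min_flat`` seconds, followed by a fall to a local
    minimum before breathing resumes.
    """
    x = np.asarray(x, float)
    sd = float(np.std(x))
    if sd == 0:
        return None
    w = max(int(1.0 * fs), 2)
    kernel = np.ones(w) / w
    mean = np.convolve(x, kernel, mode="same")
    var = np.convolve(x**2, kernel, mode="same") - mean**2
    rolling_sd = np.sqrt(np.maximum(var, 0.0))
    flat = rolling_sd < 0.15 * sd
    # longest-first runs of flat samples
    runs = []
    i = 0
    while i < flat.size:
        if flat[i]:
            j = i
            while j < flat.size and flat[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    runs = [r for r in runs if (r[1] - r[0]) / fs >= min_flat]
    if not runs:
        return None
    end = runs[0][1]
    # search the slow exhale after the hold for its terminal minimum
    horizon = min(end + int(10 * fs), x.size)
    if horizon - end < int(0.5 * fs):
        return None
    seg = x[end:horizon]
    return end + int(np.argmin(seg))


def synchronize(a: np.ndarray, b: np.ndarray, fs: float,
                max_lag: float = 30.0, min_corr: float = 0.3
                ) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Align two respiration-bearing channels.

    Primary method: detect the valley that ends the scripted pre-session
    breathing pattern (three deep breaths, 10-s apnea, slow exhale) in each
    channel and truncate both to start there.  Fallback: cross-correlation
    lag.  If neither works, a warning is issued and the channels are
    returned unshifted with zero lag.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if min(a.size, b.size) < int(30 * fs):
        raise ValueError("synchronization needs at least 30 s of signal")
    ia = _find_apnea_valley(a, fs)
    ib = _find_apnea_valley(b, fs)
    if ia is not None and ib is not None:
        lag = (ia - ib) / fs
        return (a[ia:], b[ib:]), float(lag)

    # cross-correlation fallback
    am = a - a.mean()
    bm = b - b.mean()
    n = min(am.size, bm.size)
    am, bm = am[:n], bm[:n]
    maxshift = int(max_lag * fs)
    corr = signal.correlate(am, bm, mode="full")
    lags = signal.correlation_lags(n, n, mode="full")
    sel = np.abs(lags) <= maxshift
    corr, lags = corr[sel], lags[sel]
    denom = np.sqrt(np.sum(am**2) * np.sum(bm**2))
    if denom == 0 or corr.max() / denom < min_corr:
        warnings.warn("synchronization pattern absent and correlation weak; "
                      "assuming zero lag")
        return (a, b), 0.0
    shift = int(lags[np.argmax(corr)])
    if shift >= 0:
        return (a[shift:], b), float(shift / fs)
    return (a, b[-shift:]), float(shift / fs)
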