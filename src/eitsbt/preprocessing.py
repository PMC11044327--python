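"""Signal cleaning, breath segmentation and stable-period selection.

Long EIT recordings around a spontaneous breathing trial are riddled
with spikes (electrode contact glitches), sudden baseline steps (belt
re-gelling, posture changes) and a cardiac-frequency oscillation riding
on the respiratory signal.  This module turns a raw pixel sequence into
a list of detected breaths and the stable tidal-breathing periods on
which all parameters are computed:

1. :func:`remove_artifacts` — spike frames are found on the global
   signal as deviations from a short rolling median exceeding ``k`` MADs
   and repaired by temporal interpolation; sustained baseline steps are
   detected and recorded as segment boundaries across which
   end-expiratory impedance must not be compared (steps are *not*
   corrected).
2. :func:`filter_cardiac` — zero-phase low-pass with the cutoff midway
   between the respiratory and cardiac fundamentals (spectral peaks, or
   a caller-supplied heart-rate estimate).
3. :func:`segment_breaths` — alternating prominence-gated troughs
   (end-expiration) and peaks (end-inspiration).
4. :func:`select_stable_periods` — maximal runs of consecutive breaths
   with low variation in amplitude and duration, free of step
   boundaries and nearly free of artifact frames.

All thresholds are relative to the signal's own tidal swing, so the
whole screen is invariant under rescaling of the impedance units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_core import EITSequence, LungMask

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessingConfig",
    "GlobalSignal",
    "Breath",
    "StablePeriod",
    "ArtifactReport",
    "global_signal",
    "remove_artifacts",
    "estimate_bands",
    "notch_cardiac",
    "filter_cardiac",
    "segment_breaths",
    "select_stable_periods",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessingConfig:
    """Tunable thresholds of the cleaning and stability screen.

    ``mad_k``: spike threshold in MADs of the detrended global signal.
    ``step_thresh_au``: absolute step-detection threshold; ``None`` means
    1.5x the robust tidal swing.  ``cv_max`` bounds the coefficient of
    variation of both amplitude and duration inside a stable period.
    """

    mad_k: float = 6.0
    step_thresh_au: Optional[float] = None
    cv_max: float = 0.25
    min_breaths: int = 5
    prominence_frac: float = 0.3
    breath_min_s: float = 1.0
    breath_max_s: float = 15.0
    artifact_frac_max: float = 0.05


@dataclass
class GlobalSignal:
    """Sum of lung-pixel impedance per frame."""

    z: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 1:
            raise ValueError("global signal must be 1-D")

    @property
    def n(self) -> int:
        return self.z.size


@dataclass
class Breath:
    """One detected respiratory cycle on the global signal."""

    i_exp_start: int
    i_insp_peak: int
    i_exp_end: int
    eeli: float
    dz: float
    duration_s: float

    def __post_init__(self) -> None:
        if not (self.i_exp_start < self.i_insp_peak < self.i_exp_end):
            raise ValueError("breath indices must satisfy start < peak < end")
        if self.dz <= 0:
            raise ValueError("tidal impedance swing must be positive")

    @property
    def rr(self) -> float:
        """Instantaneous respiratory rate [breaths/min]."""
        return 60.0 / self.duration_s


@dataclass
class StablePeriod:
    """A run of consecutive breaths passing the stability screen."""

    i_start: int
    i_end: int
    breaths: list[Breath]
    cv_dz: float
    cv_duration: float
    artifact_fraction: float

    @property
    def n_breaths(self) -> int:
        return len(self.breaths)


@dataclass
class ArtifactReport:
    """Everything the artifact stage altered or flagged."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["frame", "kind", "magnitude"])
    )

    @property
    def spike_frames(self) -> np.ndarray:
        return self.table.loc[self.table["kind"] == "spike", "frame"].to_numpy(dtype=int)

    @property
    def step_frames(self) -> np.ndarray:
        """Segment boundaries across which EELI comparison is forbidden."""
        return self.table.loc[self.table["kind"] == "step", "frame"].to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Global signal & artifact removal
# ---------------------------------------------------------------------------

def global_signal(seq: EITSequence, mask: LungMask) -> GlobalSignal:
    """Sum of impedance over lung pixels, per frame."""
    mask.check_compatible(seq)
    return GlobalSignal(z=seq.frames[:, mask.mask].sum(axis=1), fs=seq.fs)


def _robust_swing(z: np.ndarray) -> float:
    """Robust estimate of the tidal peak-to-trough swing."""
    lo, hi = np.percentile(z, [10, 90])
    return float(hi - lo)


def _rolling_median(z: np.ndarray, win: int) -> np.ndarray:
    win = max(3, win | 1)  # odd
    return (
        pd.Series(z).rolling(win, center=True, min_periods=1).median().to_numpy()
    )


def _interpolate_frames(frames: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Replace whole frames by linear temporal interpolation between the
    nearest good frames (edges: nearest good frame)."""
    n = frames.shape[0]
    good = np.ones(n, dtype=bool)
    good[bad] = False
    if good.all() or not good.any():
        return frames
    idx = np.arange(n)
    out = frames.copy()
    flat = out.reshape(n, -1)
    gi = idx[good]
    for j in range(flat.shape[1]):
        flat[~good, j] = np.interp(idx[~good], gi, flat[good, j])
    return out


def remove_artifacts(
    seq: EITSequence,
    mask: LungMask,
    mad_k: float = 6.0,
    step_thresh_au: Optional[float] = None,
) -> tuple[EITSequence, ArtifactReport]:
    """Repair spike frames and flag baseline step events.

    Spikes are frames whose global signal deviates from a short (0.1 s)
    rolling median by more than ``mad_k`` MADs of the detrended signal
    (with a floor of 5% of the tidal swing, so smooth clean recordings
    produce zero flags); they are replaced by temporal interpolation.
    Steps are sustained shifts of a 2 s rolling median exceeding
    ``step_thresh_au`` (default: 1.5x the robust tidal swing); they are
    *recorded*, not corrected — end-expiratory impedance must never be
    compared across a step boundary.
    """
    gs = global_signal(seq, mask)
    z, fs = gs.z, gs.fs
    n = z.size

    # short window: long enough to bridge a single-frame spike, short
    # enough that cardiac-frequency curvature does not leak into the
    # residual
    short = _rolling_median(z, int(round(0.10 * fs)))
    resid = z - short
    mad = float(np.median(np.abs(resid - np.median(resid))))
    # tidal swing estimated on the baseline-detrended signal, so step
    # artifacts cannot inflate it
    detrended = z - _rolling_median(z, int(round(4.0 * fs)))
    swing = _robust_swing(detrended)
    # 1.4826 makes the MAD a consistent sigma estimate; the floor keeps
    # smooth clean recordings at zero flags
    thresh = max(mad_k * 1.4826 * mad, 0.05 * swing)
    spike = np.abs(resid) > thresh
    spike_idx = np.nonzero(spike)[0]

    if spike_idx.size > 0.5 * n:
        raise ValueError(
            f"{spike_idx.size}/{n} frames flagged as artifacts; recording unusable"
        )

    frames = _interpolate_frames(np.asarray(seq.frames, dtype=float), spike_idx)

    # step detection on the spike-repaired global signal
    z_rep = frames[:, mask.mask].sum(axis=1)
    w = max(3, int(round(2.0 * fs)))
    fwd = pd.Series(z_rep).rolling(w, min_periods=w // 2).median().to_numpy()
    bwd = pd.Series(z_rep[::-1]).rolling(w, min_periods=w // 2).median().to_numpy()[::-1]
    jump = np.full(n, 0.0)
    valid = slice(w, n - w)
    jump[valid] = bwd[valid] - fwd[valid]
    s_thresh = step_thresh_au if step_thresh_au is not None else 1.5 * swing
    over = np.abs(jump) > s_thresh
    step_idx = []
    if over.any():
        bounds = np.nonzero(np.diff(over.astype(int)))[0] + 1
        segments = np.split(np.arange(n), bounds)
        for seg in segments:
            if seg.size and over[seg[0]]:
                step_idx.append(int(seg[np.argmax(np.abs(jump[seg]))]))

    rows = [
        {"frame": int(i), "kind": "spike", "magnitude": float(resid[i])}
        for i in spike_idx
    ] + [{"frame": i, "kind": "step", "magnitude": float(jump[i])} for i in step_idx]
    report = ArtifactReport(
        table=pd.DataFrame(rows, columns=["frame", "kind", "magnitude"]).sort_values(
            "frame", ignore_index=True
        )
        if rows
        else ArtifactReport().table
    )
    if spike_idx.size or step_idx:
        logger.info(
            "artifact removal: %d spike frame(s) repaired, %d step boundary(ies)",
            spike_idx.size, len(step_idx),
        )
    cleaned = EITSequence(
        frames=frames, fs=seq.fs, t0=seq.t0, channels=seq.channels,
        nonfinite_frames=seq.nonfinite_frames,
    )
    return cleaned, report


# ---------------------------------------------------------------------------
# Cardiac filtering
# ---------------------------------------------------------------------------

def _spectral_peak(z: np.ndarray, fs: float, f_lo: float, f_hi: float,
                   exclude: tuple[float, ...] = (), guard: float = 0.15,
                   min_power_frac: float = 0.0) -> Optional[float]:
    """Largest Welch-spectrum peak in [f_lo, f_hi], skipping guard bands
    around the ``exclude`` frequencies (e.g. respiratory harmonics).

    ``min_power_frac`` rejects peaks below that fraction of the overall
    spectral maximum, so leakage floors do not masquerade as a real
    component.
    """
    nper = min(z.size, int(round(60 * fs)))
    f, p = sps.welch(z - z.mean(), fs=fs, nperseg=nper)
    band = (f >= f_lo) & (f <= f_hi)
    for fx in exclude:
        band &= np.abs(f - fx) > guard
    if not band.any() or not np.any(p[band] > 0):
        return None
    i = np.argmax(p[band])
    if p[band][i] < min_power_frac * p.max():
        return None
    return float(f[band][i])


def estimate_bands(
    gs: GlobalSignal, hr_estimate: Optional[float] = None
) -> tuple[Optional[float], Optional[float]]:
    """Estimate the respiratory and cardiac fundamental frequencies [Hz]
    from spectral peaks of the global signal (``None`` where absent)."""
    z, fs = gs.z, gs.fs
    f_resp = _spectral_peak(z, fs, 0.08, 0.8)
    if f_resp is None:
        return None, None
    if hr_estimate is not None:
        if hr_estimate <= f_resp:
            raise ValueError(
                f"cardiac frequency estimate {hr_estimate:.3f} Hz must exceed the "
                f"respiratory fundamental {f_resp:.3f} Hz"
            )
        return f_resp, float(hr_estimate)
    # guard only the strong low respiratory harmonics; higher ones are
    # far weaker than any real cardiac peak and fail the power gate,
    # and a heart rate may legitimately sit on a high harmonic
    harmonics = tuple(k * f_resp for k in range(1, 4))
    f_card = _spectral_peak(z, fs, max(0.8, 1.3 * f_resp), 3.5,
                            exclude=harmonics, min_power_frac=1e-3)
    return f_resp, f_card


def notch_cardiac(gs: GlobalSignal, f_card: float, bandwidth: float = 0.25,
                  noise_cutoff_hz: float = 3.5) -> GlobalSignal:
    """Zero-phase narrowband suppression of the cardiac component.

    Notches the cardiac fundamental (and its second harmonic when below
    Nyquist) while leaving the respiratory harmonics untouched, so tidal
    amplitudes read off the result are undistorted; a generous low-pass
    at ``noise_cutoff_hz`` (far above any meaningful respiratory
    harmonic) then suppresses wideband pixel noise.  Used for breath
    *values*; breath *timing* uses the broader low-pass of
    :func:`filter_cardiac`.
    """
    z, fs = gs.z, gs.fs
    out = z.copy()
    for f0 in (f_card, 2.0 * f_card):
        if f0 < 0.45 * fs:
            b, a = sps.iirnotch(f0, Q=f0 / bandwidth, fs=fs)
            out = sps.filtfilt(b, a, out)
    if noise_cutoff_hz < 0.45 * fs:
        sos = sps.butter(4, noise_cutoff_hz, btype="low", fs=fs, output="sos")
        out = sps.sosfiltfilt(sos, out)
    return GlobalSignal(z=out, fs=fs)


def filter_cardiac(
    gs: GlobalSignal, hr_estimate: Optional[float] = None, order: int = 8
) -> GlobalSignal:
    """Zero-phase low-pass removing the cardiac oscillation.

    The cutoff is placed midway between the respiratory and cardiac
    fundamental frequencies (both estimated from spectral peaks when
    ``hr_estimate`` [Hz] is not supplied).  A high-order Butterworth
    applied forward-backward keeps the respiratory fundamental and its
    low harmonics essentially untouched (<5% amplitude loss) while
    suppressing the cardiac band.  If the two fundamentals are closer
    than 0.2 Hz a warning is issued and the cutoff falls back to their
    geometric mean.
    """
    z, fs = gs.z, gs.fs
    f_resp, f_card = estimate_bands(gs, hr_estimate)
    if f_resp is None:
        logger.info("no respiratory spectral peak found; signal returned unfiltered")
        return GlobalSignal(z=z.copy(), fs=fs)
    if f_card is None:
        logger.info("no cardiac spectral peak found; signal returned unfiltered")
        return GlobalSignal(z=z.copy(), fs=fs)
    if fs <= 2 * f_card:
        raise ValueError("sampling rate must exceed twice the cardiac frequency")
    if f_card - f_resp < 0.2:
        warnings.warn(
            "respiratory and cardiac fundamentals closer than 0.2 Hz; "
            "cutoff placed at their geometric mean",
            stacklevel=2,
        )
        cutoff = float(np.sqrt(f_resp * f_card))
    else:
        cutoff = 0.5 * (f_resp + f_card)
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, z)
    logger.debug("cardiac filter: f_resp=%.3f Hz f_card=%.3f Hz cutoff=%.3f Hz",
                 f_resp, f_card, cutoff)
    return GlobalSignal(z=filtered, fs=fs)


# ---------------------------------------------------------------------------
# Breath segmentation
# ---------------------------------------------------------------------------

def segment_breaths(
    gs: GlobalSignal,
    prominence_frac: float = 0.3,
    breath_min_s: float = 1.0,
    breath_max_s: float = 15.0,
) -> list[Breath]:
    """Detect breaths as alternating troughs (end-expiration) and peaks
    (end-inspiration) on the filtered global signal.

    Extremum detection is prominence-gated at ``prominence_frac`` times a
    rolling median of the detected tidal swings (bootstrapped from the
    signal's robust swing), so the gate adapts to slow amplitude trends
    and is invariant under rescaling.  Breaths shorter than
    ``breath_min_s`` or longer than ``breath_max_s`` are discarded.
    """
    z, fs = gs.z, gs.fs
    swing = _robust_swing(z)
    if swing <= 0:
        return []
    dist = max(1, int(round(0.5 * breath_min_s * fs)))
    base_prom = prominence_frac * 0.5 * swing
    peaks, pprops = sps.find_peaks(z, prominence=base_prom, distance=dist)
    troughs, tprops = sps.find_peaks(-z, prominence=base_prom, distance=dist)
    if peaks.size == 0 or troughs.size == 0:
        return []

    # refine the gate: prominence relative to a rolling median of local swings
    prom_med = np.median(np.concatenate([pprops["prominences"], tprops["prominences"]]))
    gate = prominence_frac * prom_med
    peaks = peaks[pprops["prominences"] >= gate]
    troughs = troughs[tprops["prominences"] >= gate]
    if peaks.size == 0:
        return []

    # recover end-expiratory troughs at the recording boundaries, which
    # find_peaks cannot mark (a breath starting at frame 0 would be lost)
    trough_list = list(troughs)
    if troughs.size == 0 or peaks[0] < troughs[0]:
        cand = int(np.argmin(z[: peaks[0] + 1]))
        if z[peaks[0]] - z[cand] >= gate and cand < peaks[0]:
            trough_list.insert(0, cand)
    if trough_list and peaks[-1] > trough_list[-1]:
        cand = peaks[-1] + int(np.argmin(z[peaks[-1]:]))
        if z[peaks[-1]] - z[cand] >= gate and cand > peaks[-1]:
            trough_list.append(cand)
    troughs = np.asarray(trough_list, dtype=int)
    if troughs.size < 2:
        return []

    breaths: list[Breath] = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        inside = peaks[(peaks > a) & (peaks < b)]
        if inside.size == 0:
            continue
        pk = inside[np.argmax(z[inside])]
        duration = (b - a) / fs
        dz = z[pk] - z[a]
        if dz <= 0 or not (breath_min_s <= duration <= breath_max_s):
            continue
        breaths.append(
            Breath(i_exp_start=int(a), i_insp_peak=int(pk), i_exp_end=int(b),
                   eeli=float(z[a]), dz=float(dz), duration_s=float(duration))
        )
    return breaths


# ---------------------------------------------------------------------------
# Stable-period selection
# ---------------------------------------------------------------------------

def _cv(x: np.ndarray) -> float:
    m = np.mean(x)
    if m == 0:
        return np.inf
    return float(np.std(x) / abs(m))


def select_stable_periods(
    breaths: list[Breath],
    report: ArtifactReport,
    min_breaths: int = 5,
    cv_max: float = 0.25,
    artifact_frac_max: float = 0.05,
) -> list[StablePeriod]:
    """Maximal runs of consecutive breaths forming stable tidal breathing.

    A run qualifies when the coefficients of variation of both tidal
    swing and breath duration stay at or below ``cv_max``, it contains at
    least ``min_breaths`` breaths, it does not span a step-event
    boundary, and at most ``artifact_frac_max`` of its frames were
    flagged.  Runs are returned longest-first.
    """
    if not breaths:
        return []
    step_frames = report.step_frames
    spike_frames = report.spike_frames

    # split at step boundaries and at temporal gaps between breaths
    segments: list[list[Breath]] = [[breaths[0]]]
    for prev, cur in zip(breaths, breaths[1:]):
        gap = cur.i_exp_start - prev.i_exp_end
        crosses_step = np.any(
            (step_frames > prev.i_exp_start) & (step_frames <= cur.i_exp_end)
        )
        if gap > 2 or crosses_step:
            segments.append([cur])
        else:
            segments[-1].append(cur)

    def window_ok(seg: list[Breath], i: int, j: int) -> bool:
        win = seg[i:j]
        dz = np.array([b.dz for b in win])
        dur = np.array([b.duration_s for b in win])
        if _cv(dz) > cv_max or _cv(dur) > cv_max:
            return False
        lo, hi = win[0].i_exp_start, win[-1].i_exp_end
        n_frames = hi - lo + 1
        n_art = int(np.count_nonzero((spike_frames >= lo) & (spike_frames <= hi)))
        return n_art / n_frames <= artifact_frac_max

    periods: list[StablePeriod] = []
    for seg in segments:
        n = len(seg)
        i = 0
        while i < n:
            j = i + 1
            while j < n and window_ok(seg, i, j + 1):
                j += 1
            if j - i >= min_breaths:
                win = seg[i:j]
                dz = np.array([b.dz for b in win])
                dur = np.array([b.duration_s for b in win])
                lo, hi = win[0].i_exp_start, win[-1].i_exp_end
                n_art = int(np.count_nonzero((spike_frames >= lo) & (spike_frames <= hi)))
                periods.append(
                    StablePeriod(
                        i_start=lo, i_end=hi, breaths=win,
                        cv_dz=_cv(dz), cv_duration=_cv(dur),
                        artifact_fraction=n_art / (hi - lo + 1),
                    )
                )
                i = j
            else:
                i += 1
    periods.sort(key=lambda p: p.n_breaths, reverse=True)
    return periods


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

def preprocess(
    seq: EITSequence,
    mask: LungMask,
    cfg: PreprocessingConfig = PreprocessingConfig(),
    hr_estimate: Optional[float] = None,
) -> tuple[EITSequence, GlobalSignal, list[Breath], list[StablePeriod], ArtifactReport]:
    """Run the full cleaning chain on one sequence.

    Breath *timing* comes from the low-pass cardiac filter (robust
    extremum detection); breath *values* (EELI, tidal swing) are then
    read off a narrowband cardiac-notched signal at those extrema, which
    preserves the respiratory harmonics and hence the true amplitudes.
    Returns the spike-repaired sequence, the cardiac-filtered global
    signal, the detected breaths, the stable periods and the artifact
    report.
    """
    cleaned, report = remove_artifacts(seq, mask, mad_k=cfg.mad_k,
                                       step_thresh_au=cfg.step_thresh_au)
    gs = global_signal(cleaned, mask)
    filtered = filter_cardiac(gs, hr_estimate=hr_estimate)
    breaths = segment_breaths(
        filtered, prominence_frac=cfg.prominence_frac,
        breath_min_s=cfg.breath_min_s, breath_max_s=cfg.breath_max_s,
    )
    _, f_card = estimate_bands(gs, hr_estimate)
    if f_card is not None and breaths:
        amp_sig = notch_cardiac(gs, f_card)
        breaths = _remeasure_breaths(breaths, amp_sig.z, gs.fs)
    periods = select_stable_periods(
        breaths, report, min_breaths=cfg.min_breaths, cv_max=cfg.cv_max,
        artifact_frac_max=cfg.artifact_frac_max,
    )
    return cleaned, filtered, breaths, periods, report


def _extremum_value(z: np.ndarray, idx: int, half: int, kind: str) -> float:
    """Extremum value near ``idx`` via a local quadratic fit.

    The low-pass used for timing can displace an extremum by a few
    frames; a parabola fitted to the amplitude-faithful signal recovers
    the true extremum value while averaging out residual noise.
    """
    lo, hi = max(idx - half, 0), min(idx + half + 1, z.size)
    seg = z[lo:hi]
    if seg.size < 5:
        return float(seg.max() if kind == "max" else seg.min())
    x = np.arange(seg.size, dtype=float)
    a, b, c = np.polyfit(x, seg, 2)
    concave_ok = a < 0 if kind == "max" else a > 0
    if concave_ok and a != 0:
        xv = -b / (2 * a)
        if 0 <= xv <= seg.size - 1:
            return float(a * xv * xv + b * xv + c)
    fitted = np.polyval((a, b, c), x)
    return float(fitted.max() if kind == "max" else fitted.min())


def _remeasure_breaths(breaths: list[Breath], z_amp: np.ndarray, fs: float) -> list[Breath]:
    """Re-evaluate EELI and tidal swing on an amplitude-faithful signal at
    the detected extrema."""
    out = []
    for b in breaths:
        half = max(3, int(round(0.06 * b.duration_s * fs)))
        eeli = _extremum_value(z_amp, b.i_exp_start, half, "min")
        pk = _extremum_value(z_amp, b.i_insp_peak, half, "max")
        if pk - eeli <= 0:
            continue
        out.append(Breath(i_exp_start=b.i_exp_start, i_insp_peak=b.i_insp_peak,
                          i_exp_end=b.i_exp_end, eeli=eeli, dz=pk - eeli,
                          duration_s=b.duration_s))
    return out
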