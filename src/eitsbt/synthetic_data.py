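"""Synthetic EIT session generator with known ground truth.

No public EIT recordings around spontaneous breathing trials exist, so
every downstream stage of this package is validated against sequences
generated here.  The generator emulates the features that matter for a
breath-by-breath SBT analysis:

* tidal breathing inside a two-lung elliptical mask, with a per-pixel
  amplitude map whose spatial inhomogeneity is controlled by a single
  exponent ``gamma`` (``gamma=0`` gives perfectly uniform ventilation,
  larger values give heavier-tailed amplitude spreads and hence larger
  global inhomogeneity indices),
* a cardiac-frequency oscillation concentrated in a mediastinal blob,
* a slow end-expiratory (baseline) impedance track with per-phase
  offsets — the SBT scenario drops EELI at trial start and recovers it
  only partially after reconnection, while the tidal amplitude recovers
  fully,
* spike artifacts (single-frame pixel outliers) and step artifacts
  (sudden sustained baseline shifts, as after belt re-gelling), both
  logged in the ground truth so detector recall is measurable,
* a 1 Hz ventilator log tied to the tidal impedance by an exact,
  recorded ml-per-AU conversion (absent during the T-piece phase, when
  the patient is disconnected), and an optional transcutaneous CO2-like
  scalar channel.

All randomness flows from one :class:`numpy.random.Generator` seeded in
the config; identical configs produce bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_core import AuxChannel, EITSequence, LungMask, SBTAnnotation, VentilatorLog

__all__ = [
    "PhaseSpec",
    "ScenarioConfig",
    "GroundTruth",
    "generate_scenario",
    "true_gi_of_map",
    "elliptical_lung_mask",
    "amplitude_map",
    "sbt_recovery_scenario",
    "success_scenario",
    "failure_scenario",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSpec:
    """One phase of the recording script (pre-SBT, SBT, post-SBT).

    Overrides are multiplicative/relative to the scenario-wide values:
    ``eeli_offset_frac`` shifts the end-expiratory baseline by that
    fraction of the scenario EELI, ``vt_scale`` and ``rr_scale`` scale
    tidal amplitude and respiratory rate, ``gamma_scale`` scales the
    inhomogeneity exponent of the amplitude map.
    """

    name: str
    duration_s: float
    eeli_offset_frac: float = 0.0
    vt_scale: float = 1.0
    rr_scale: float = 1.0
    gamma_scale: float = 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic SBT session.

    Defaults describe a typical adult weaning candidate: 32x32
    reconstruction grid at 50.2 Hz, 15 breaths/min on pressure support,
    ~400 ml tidal volumes (4 AU at 100 ml/AU), heart rate 90/min with a
    cardiac oscillation 20% of the tidal swing, and an end-expiratory
    impedance ten times the tidal swing.
    """

    n_rows: int = 32
    n_cols: int = 32
    fs: float = 50.2
    rr: float = 15.0            # breaths/min
    vt_au: float = 4.0          # global tidal swing [AU]
    eeli_au: float = 40.0       # end-expiratory baseline [AU]
    hr: float = 90.0            # beats/min
    cardiac_amp: float = 0.2    # fraction of vt_au
    gamma: float = 0.6          # amplitude-map inhomogeneity exponent
    noise_sd: float = 0.0       # per-pixel white noise [AU]
    spike_rate: float = 0.0     # fraction of frames carrying a spike artifact
    spike_amp_factor: float = 5.0   # global spike magnitude in units of vt_au
    steps: Sequence[tuple[float, float]] = ()  # (time [s], global shift [AU])
    drift_au_per_min: float = 0.0   # slow linear EELI drift
    transition_s: float = 10.0  # EELI ramp length at phase changes
    insp_frac: float = 0.40     # inspiratory fraction of the breath cycle
    pause_frac: float = 0.0     # end-expiratory pause fraction
    ml_per_au: float = 100.0    # exact ventilator calibration constant
    phases: tuple[PhaseSpec, ...] = (
        PhaseSpec("pre", 120.0),
        PhaseSpec("sbt", 300.0),
        PhaseSpec("post", 120.0),
    )
    tcco2: Optional[tuple[float, float]] = None  # (baseline, end-of-SBT) [mmHg]
    outcome: str = "unknown"
    seed: int = 0

    def validate(self) -> None:
        if self.rr <= 0:
            raise ValueError("respiratory rate must be positive")
        if self.hr <= self.rr:
            raise ValueError("cardiac rate must exceed respiratory rate")
        if self.noise_sd < 0 or self.gamma < 0 or self.cardiac_amp < 0:
            raise ValueError("noise_sd, gamma and cardiac_amp must be non-negative")
        if not (0 < self.insp_frac and self.insp_frac + self.pause_frac < 1):
            raise ValueError("need 0 < insp_frac and insp_frac + pause_frac < 1")
        if any(p.duration_s <= 0 for p in self.phases):
            raise ValueError("phase durations must be positive")
        if not (0 <= self.spike_rate < 1):
            raise ValueError("spike_rate must be in [0, 1)")
        if self.vt_au <= 0 or self.ml_per_au <= 0 or self.fs <= 0:
            raise ValueError("vt_au, ml_per_au and fs must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration_s for p in self.phases))


@dataclass
class GroundTruth:
    """Oracle values recorded while generating a scenario."""

    eeli_track: np.ndarray          # clean global EELI per frame [AU]
    z_clean: np.ndarray             # clean global signal per frame [AU]
    breaths: pd.DataFrame           # i_start, i_peak, i_end, t_start, duration_s,
                                    # eeli, dz, rr, vt_ml, mv_l_min, phase
    amplitude_maps: dict[str, np.ndarray]   # per-phase per-pixel tidal amplitude
    gi: dict[str, float]            # per-phase GI of the amplitude map
    c_true: float                   # exact ml-per-AU conversion
    spike_frames: np.ndarray        # frames carrying injected spikes
    step_frames: np.ndarray         # frames at which step artifacts occur

    def __post_init__(self) -> None:
        starts = self.breaths["i_start"].to_numpy()
        if starts.size and np.any(np.diff(starts) <= 0):
            raise ValueError("breath boundaries must be strictly increasing")


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def elliptical_lung_mask(n_rows: int = 32, n_cols: int = 32) -> LungMask:
    """Two elliptical lung fields on the reconstruction grid.

    Row 0 is ventral (anterior), the last row dorsal; the two ellipses sit
    left and right of the mediastinum.
    """
    r, c = np.mgrid[0:n_rows, 0:n_cols].astype(float)
    cy = 0.52 * (n_rows - 1)
    ry, rx = 0.33 * n_rows, 0.19 * n_cols
    left = ((r - cy) / ry) ** 2 + ((c - 0.28 * (n_cols - 1)) / rx) ** 2 <= 1.0
    right = ((r - cy) / ry) ** 2 + ((c - 0.72 * (n_cols - 1)) / rx) ** 2 <= 1.0
    return LungMask(mask=(left | right).astype(int))


def amplitude_map(
    mask: LungMask,
    gamma: float,
    total_au: float,
    rng: np.random.Generator,
    smooth_sigma: float = 2.5,
) -> np.ndarray:
    """Per-pixel tidal amplitude map with controllable inhomogeneity.

    A spatially smooth positive random field is raised to the power
    ``gamma`` and renormalised so the lung-pixel sum equals ``total_au``.
    ``gamma = 0`` yields identical amplitudes on every lung pixel; larger
    ``gamma`` spreads the amplitudes further from their median, which
    monotonically increases the global inhomogeneity index.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    field_ = gaussian_filter(rng.standard_normal(mask.shape), smooth_sigma)
    inside = field_[mask.mask]
    # map to a positive field in (~0.1, ~1.1) before exponentiation
    lo, hi = inside.min(), inside.max()
    span = hi - lo if hi > lo else 1.0
    pos = 0.1 + (field_ - lo) / span
    amp = np.zeros(mask.shape)
    amp[mask.mask] = pos[mask.mask] ** gamma
    amp[mask.mask] *= total_au / amp[mask.mask].sum()
    return amp


def true_gi_of_map(amp: np.ndarray, mask: LungMask) -> float:
    """Global inhomogeneity index of a noiseless amplitude map.

    Direct evaluation of the defining formula: the sum over lung pixels of
    the absolute deviation from the lung-pixel median, divided by the sum
    of the pixel values.  Serves as the independent oracle for the
    pipeline's GI computation.
    """
    vals = np.asarray(amp, dtype=float)[mask.mask]
    if vals.size == 0:
        raise ValueError("mask contains no lung pixels")
    total = vals.sum()
    if total <= 0:
        raise ValueError("amplitude map must have positive lung-pixel sum")
    return float(np.abs(vals - np.median(vals)).sum() / total)


def _resp_wave(phi: np.ndarray, insp_frac: float, pause_frac: float) -> np.ndarray:
    """Smooth 0-to-1 breath cycle: raised-cosine inspiration and expiration
    followed by an optional end-expiratory pause."""
    exp_frac = 1.0 - insp_frac - pause_frac
    w = np.zeros_like(phi)
    insp = phi < insp_frac
    w[insp] = 0.5 * (1.0 - np.cos(np.pi * phi[insp] / insp_frac))
    expi = (phi >= insp_frac) & (phi < insp_frac + exp_frac)
    w[expi] = 0.5 * (1.0 + np.cos(np.pi * (phi[expi] - insp_frac) / exp_frac))
    return w


def _eeli_track(cfg: ScenarioConfig, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear EELI target with ramped phase transitions."""
    knots_t = [0.0]
    knots_v = [cfg.eeli_au * (1.0 + cfg.phases[0].eeli_offset_frac)]
    cursor = 0.0
    for prev, nxt in zip(cfg.phases, cfg.phases[1:]):
        cursor += prev.duration_s
        v_prev = cfg.eeli_au * (1.0 + prev.eeli_offset_frac)
        v_next = cfg.eeli_au * (1.0 + nxt.eeli_offset_frac)
        ramp_end = min(cursor + cfg.transition_s, cursor + nxt.duration_s)
        knots_t += [cursor, ramp_end]
        knots_v += [v_prev, v_next]
    knots_t.append(cfg.total_duration)
    knots_v.append(cfg.eeli_au * (1.0 + cfg.phases[-1].eeli_offset_frac))
    track = np.interp(t, knots_t, knots_v)
    track += cfg.drift_au_per_min * t / 60.0
    return track


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_scenario(
    cfg: ScenarioConfig,
) -> tuple[EITSequence, LungMask, VentilatorLog, SBTAnnotation, GroundTruth]:
    """Generate one synthetic SBT session plus its ground truth.

    The pixel signal is built as

        ``share(x,y) * EELI(t) + amp_phase(x,y) * wave(t) + cardiac(x,y,t)
        + noise + artifacts``

    where ``wave`` is a smooth 0-to-1 cycle at the phase's respiratory
    rate, ``amp_phase`` sums to the phase's tidal amplitude over lung
    pixels, and ``share`` distributes the baseline across the lung.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mask = elliptical_lung_mask(cfg.n_rows, cfg.n_cols)

    n_frames = int(np.floor(cfg.total_duration * cfg.fs))
    t = np.arange(n_frames) / cfg.fs

    # per-phase amplitude maps share one base field (same rng draw)
    field_rng = np.random.default_rng(rng.integers(2**31))
    base_state = field_rng.bit_generator.state
    amp_maps: dict[str, np.ndarray] = {}
    gi_true: dict[str, float] = {}
    phase_starts = np.cumsum([0.0] + [p.duration_s for p in cfg.phases])
    for p in cfg.phases:
        field_rng.bit_generator.state = base_state
        amp_maps[p.name] = amplitude_map(
            mask, cfg.gamma * p.gamma_scale, cfg.vt_au * p.vt_scale, field_rng
        )
        gi_true[p.name] = true_gi_of_map(amp_maps[p.name], mask)

    share = amp_maps[cfg.phases[0].name].copy()
    share /= share[mask.mask].sum()

    # ---- breath schedule -------------------------------------------------
    eeli = _eeli_track(cfg, t)
    wave = np.zeros(n_frames)
    frame_phase = np.zeros(n_frames, dtype=int)  # index into cfg.phases
    breath_rows = []
    cursor = 0.0
    while True:
        p_idx = int(np.searchsorted(phase_starts[1:], cursor, side="right"))
        p_idx = min(p_idx, len(cfg.phases) - 1)
        phase = cfg.phases[p_idx]
        period = 60.0 / (cfg.rr * phase.rr_scale)
        if cursor + period > cfg.total_duration + 1e-9:
            break
        i0 = int(np.ceil(cursor * cfg.fs - 1e-9))
        i1 = int(np.ceil((cursor + period) * cfg.fs - 1e-9))
        i1 = min(i1, n_frames)
        phi = (t[i0:i1] - cursor) / period
        wave[i0:i1] = _resp_wave(phi, cfg.insp_frac, cfg.pause_frac)
        frame_phase[i0:i1] = p_idx
        i_peak = i0 + int(np.argmax(wave[i0:i1])) if i1 > i0 else i0
        breath_rows.append(
            dict(i_start=i0, i_peak=i_peak, i_end=min(i1, n_frames - 1),
                 t_start=cursor, duration_s=period, phase=phase.name,
                 vt_scale=phase.vt_scale)
        )
        cursor += period

    breaths = pd.DataFrame(breath_rows)

    # ---- clean global signal & per-breath truth --------------------------
    vt_frame = np.array([cfg.vt_au * cfg.phases[k].vt_scale for k in frame_phase])
    z_clean = eeli + vt_frame * wave
    if not breaths.empty:
        i_s = breaths["i_start"].to_numpy()
        i_p = breaths["i_peak"].to_numpy()
        breaths["eeli"] = z_clean[i_s]
        breaths["dz"] = z_clean[i_p] - z_clean[i_s]
        breaths["rr"] = 60.0 / breaths["duration_s"]
        breaths["vt_ml"] = cfg.ml_per_au * breaths["dz"]
        breaths["mv_l_min"] = breaths["rr"] * breaths["vt_ml"] / 1000.0

    # ---- pixel stack ------------------------------------------------------
    frames = share[None, :, :] * eeli[:, None, None]
    amp_stack = np.stack([amp_maps[p.name] for p in cfg.phases])
    frames += amp_stack[frame_phase] * wave[:, None, None]

    if cfg.cardiac_amp > 0:
        rr_, cc_ = np.mgrid[0:cfg.n_rows, 0:cfg.n_cols].astype(float)
        heart = np.exp(
            -(((rr_ - 0.45 * cfg.n_rows) / (0.18 * cfg.n_rows)) ** 2
              + ((cc_ - 0.5 * cfg.n_cols) / (0.18 * cfg.n_cols)) ** 2)
        )
        heart[~mask.mask] = 0.0
        total = heart.sum()
        if total > 0:
            heart *= cfg.cardiac_amp * cfg.vt_au / total
            cardiac_t = np.sin(2 * np.pi * (cfg.hr / 60.0) * t)
            frames += heart[None, :, :] * cardiac_t[:, None, None]

    if cfg.noise_sd > 0:
        frames += rng.normal(0.0, cfg.noise_sd, frames.shape)

    # ---- artifacts ---------------------------------------------------------
    spike_frames = np.empty(0, dtype=int)
    if cfg.spike_rate > 0:
        n_spikes = int(round(cfg.spike_rate * n_frames))
        spike_frames = np.sort(
            rng.choice(n_frames, size=min(n_spikes, n_frames), replace=False)
        )
        lung_idx = np.argwhere(mask.mask)
        n_hit = min(24, len(lung_idx))
        for fi in spike_frames:
            hit = lung_idx[rng.choice(len(lung_idx), size=n_hit, replace=False)]
            sign = rng.choice((-1.0, 1.0))
            # global deviation of the spiked frame is spike_amp_factor * vt_au
            frames[fi, hit[:, 0], hit[:, 1]] += sign * cfg.spike_amp_factor * cfg.vt_au / n_hit

    step_frames = []
    for t_step, mag in cfg.steps:
        idx = int(round(t_step * cfg.fs))
        if 0 <= idx < n_frames:
            frames[idx:] += mag * share[None, :, :]
            step_frames.append(idx)
    step_frames = np.asarray(sorted(step_frames), dtype=int)

    # ---- channels ----------------------------------------------------------
    if len(cfg.phases) >= 3:
        t_pre, t_sbt_start, t_sbt_end = phase_starts[0], phase_starts[1], phase_starts[2]
    else:
        # single- or two-phase test scenarios: nominal thirds, so the
        # annotation stays well-formed
        t_pre = 0.0
        t_sbt_start = cfg.total_duration / 3.0
        t_sbt_end = 2.0 * cfg.total_duration / 3.0
    annotation = SBTAnnotation(
        t_pre_start=float(t_pre),
        t_sbt_start=float(t_sbt_start),
        t_sbt_end=float(t_sbt_end),
        t_post_end=float(cfg.total_duration),
        outcome=cfg.outcome,
    )

    # 1 Hz ventilator log, only while connected (pre and post phases)
    vt_sec = np.arange(0.0, cfg.total_duration, 1.0)
    on_vent = (vt_sec < t_sbt_start) | (vt_sec >= t_sbt_end)
    vt_sec = vt_sec[on_vent]
    vt_ml = np.zeros_like(vt_sec)
    if not breaths.empty:
        b_start = breaths["t_start"].to_numpy()
        which = np.clip(np.searchsorted(b_start, vt_sec, side="right") - 1, 0, len(breaths) - 1)
        vt_ml = breaths["vt_ml"].to_numpy()[which]
    vent = VentilatorLog(timestamps=vt_sec, tidal_volume=vt_ml)

    channels: dict[str, AuxChannel] = {}
    if cfg.tcco2 is not None:
        base, end = cfg.tcco2
        tc_t = np.arange(0.0, cfg.total_duration, 1.0)
        tc_v = np.interp(tc_t, [0.0, t_sbt_start, t_sbt_end, cfg.total_duration],
                         [base, base, end, end])
        channels["tcco2"] = AuxChannel("tcco2", tc_t, tc_v, units="mmHg")

    seq = EITSequence(frames=frames, fs=cfg.fs, t0=0.0, channels=channels)
    truth = GroundTruth(
        eeli_track=eeli,
        z_clean=z_clean,
        breaths=breaths,
        amplitude_maps=amp_maps,
        gi=gi_true,
        c_true=cfg.ml_per_au,
        spike_frames=spike_frames,
        step_frames=step_frames,
    )
    return seq, mask, vent, annotation, truth


# ---------------------------------------------------------------------------
# Packaged scenarios
# ---------------------------------------------------------------------------

def sbt_recovery_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The reference SBT scenario: RR 15 -> 25/min, EELI -20% during the
    trial with incomplete (-10%) recovery after reconnection, tidal swing
    -15% with full recovery, cardiac oscillation at 90/min at 20% of the
    tidal swing, 1% spike frames."""
    cfg = ScenarioConfig(
        phases=(
            PhaseSpec("pre", 120.0),
            PhaseSpec("sbt", 300.0, eeli_offset_frac=-0.20, vt_scale=0.85,
                      rr_scale=25.0 / 15.0),
            PhaseSpec("post", 120.0, eeli_offset_frac=-0.10),
        ),
        hr=90.0,
        cardiac_amp=0.2,
        spike_rate=0.01,
        noise_sd=0.003,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def success_scenario(seed: int = 0) -> ScenarioConfig:
    """A patient passing the trial: homogeneous lungs (low gamma), GI rising
    moderately on the T-piece and recovering, moderate RR increase, stable
    transcutaneous CO2."""
    return ScenarioConfig(
        gamma=0.4,
        phases=(
            PhaseSpec("pre", 120.0),
            PhaseSpec("sbt", 300.0, eeli_offset_frac=-0.20, vt_scale=0.85,
                      rr_scale=20.0 / 15.0, gamma_scale=1.3),
            PhaseSpec("post", 120.0, eeli_offset_frac=-0.10),
        ),
        hr=90.0,
        cardiac_amp=0.2,
        spike_rate=0.005,
        noise_sd=0.003,
        tcco2=(40.0, 42.0),
        outcome="success",
        seed=seed,
    )


def failure_scenario(seed: int = 0) -> ScenarioConfig:
    """A patient failing the trial: markedly inhomogeneous lungs at every
    phase (higher gamma), rapid shallow breathing on the T-piece, rising
    transcutaneous CO2."""
    return ScenarioConfig(
        gamma=1.4,
        phases=(
            PhaseSpec("pre", 120.0),
            PhaseSpec("sbt", 300.0, eeli_offset_frac=-0.20, vt_scale=0.70,
                      rr_scale=30.0 / 15.0, gamma_scale=1.1),
            PhaseSpec("post", 120.0, eeli_offset_frac=-0.10),
        ),
        hr=100.0,
        cardiac_amp=0.2,
        spike_rate=0.005,
        noise_sd=0.003,
        tcco2=(40.0, 55.0),
        outcome="failure",
        seed=seed,
    )
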