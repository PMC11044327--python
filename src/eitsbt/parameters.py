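"""Breath-by-breath EIT parameters.

Everything here is computed on lung pixels only, from the per-pixel
inspiratory impedance change ("tidal image") of a detected breath:

* **GI** — global inhomogeneity index, the sum over lung pixels of the
  absolute deviation of the pixel tidal change from the lung-pixel
  median, divided by the summed tidal change.  Zero means perfectly
  homogeneous ventilation; larger values mean more inhomogeneous
  distributions.  Scale-invariant by construction.
* **CoV** — impedance-weighted centroid of the tidal image, expressed in
  percent of the lung bounding box along each axis (0% ventral/left,
  100% dorsal/right, supine orientation by default).
* **Silent spaces** — lung pixels whose tidal change is below 10% of the
  maximum tidal change; split at the gravity-axis CoV line into
  nondependent (ventral of the line) and dependent (dorsal) silent
  spaces.  The functional lung space is 100% minus the silent-space
  percentage, so NSS + DSS + FLS = 100 exactly.
* **Volume calibration** — a single-point (or averaged multi-point)
  ml-per-AU factor from ventilator tidal volumes during stable pre-SBT
  breathing, giving calibrated tidal volume, minute volume and the rapid
  shallow breathing index RSBI = RR / VT[L].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .io_core import EITSequence, LungMask, VentilatorLog
from .preprocessing import Breath, StablePeriod

logger = logging.getLogger(__name__)

__all__ = [
    "TidalImage",
    "CalibrationFactor",
    "BreathParameters",
    "tidal_image",
    "period_tidal_image",
    "compute_gi",
    "compute_cov",
    "compute_silent_spaces",
    "calibrate_volume",
    "breath_parameters",
    "period_parameters",
    "parameters_table",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TidalImage:
    """Per-pixel inspiratory impedance change of one breath (or the mean
    over a stable period), restricted to lung pixels.

    ``di`` is a full-grid array; values outside the mask are undefined
    and never consulted.  Negative lung-pixel values (paradoxical pixels)
    are retained.
    """

    di: np.ndarray
    mask: LungMask
    source: str = ""
    n_breaths: int = 1

    def __post_init__(self) -> None:
        self.di = np.asarray(self.di, dtype=float)
        if self.di.shape != self.mask.shape:
            raise ValueError("tidal image and mask shapes differ")

    @property
    def lung_values(self) -> np.ndarray:
        return self.di[self.mask.mask]


@dataclass(frozen=True)
class CalibrationFactor:
    """Individualized ml-per-AU conversion from pre-SBT stable breaths."""

    c: float  # ml per AU
    n_points: int
    method: Literal["single_point", "mean_of_points"]

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ValueError(f"calibration factor must be positive, got {self.c}")


@dataclass
class BreathParameters:
    """All EIT parameters of one breath (NaN marks a flagged-missing value)."""

    eeli: float                     # [AU]
    dz: float                       # [AU]
    rr: float                       # [breaths/min]
    vt_ml: float                    # [ml]
    mv_l_min: float                 # [L/min]
    rsbi: float                     # [breaths/min/L]
    gi: float                       # [-]
    cov_x: float                    # [% of lung extent, left->right]
    cov_y: float                    # [% of lung extent, ventral->dorsal]
    nss: float                      # [% of lung pixels]
    dss: float                      # [% of lung pixels]
    fls: float                      # [% of lung pixels]
    frac_left: float                # [fraction of tidal change]
    frac_right: float
    frac_ventral: float
    frac_dorsal: float
    t_start: float = np.nan         # [s] breath start time
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _PARAM_FIELDS}
        d["t_start"] = self.t_start
        return d


_PARAM_FIELDS = (
    "eeli", "dz", "rr", "vt_ml", "mv_l_min", "rsbi", "gi",
    "cov_x", "cov_y", "nss", "dss", "fls",
    "frac_left", "frac_right", "frac_ventral", "frac_dorsal",
)


# ---------------------------------------------------------------------------
# Tidal images
# ---------------------------------------------------------------------------

def tidal_image(seq: EITSequence, breath: Breath, mask: LungMask) -> TidalImage:
    """Per-pixel end-inspiration minus end-expiration impedance change.

    Computed from the (artifact-repaired, unfiltered) frames at the
    breath's detected extrema; negative pixels are retained.
    """
    mask.check_compatible(seq)
    if not (0 <= breath.i_exp_start < breath.i_insp_peak < seq.n_frames):
        raise ValueError("breath indices fall outside the sequence")
    di = seq.frames[breath.i_insp_peak].astype(float) - seq.frames[breath.i_exp_start]
    return TidalImage(di=di, mask=mask, source=f"breath@{breath.i_exp_start}")


def period_tidal_image(seq: EITSequence, period: StablePeriod, mask: LungMask) -> TidalImage:
    """Mean tidal image over all breaths of a stable period."""
    if not period.breaths:
        raise ValueError("stable period contains no breaths")
    acc = np.zeros(seq.shape, dtype=float)
    for b in period.breaths:
        acc += tidal_image(seq, b, mask).di
    acc /= len(period.breaths)
    return TidalImage(di=acc, mask=mask, source=f"period@{period.i_start}",
                      n_breaths=len(period.breaths))


# ---------------------------------------------------------------------------
# Distribution indices
# ---------------------------------------------------------------------------

def compute_gi(ti: TidalImage) -> float:
    """Global inhomogeneity index of a tidal image.

    Sum over lung pixels of ``|di - median(di_lung)|`` divided by the sum
    of ``di`` over lung pixels; the median is taken over lung pixels only
    (even counts: mean of the central order statistics).  A non-positive
    denominator is flagged as a missing value (NaN) with a diagnostic,
    since the index is undefined there.
    """
    vals = ti.lung_values
    total = vals.sum()
    if total <= 0:
        warnings.warn(
            f"GI undefined: summed tidal impedance change is {total:.3g} <= 0",
            stacklevel=2,
        )
        return float("nan")
    return float(np.abs(vals - np.median(vals)).sum() / total)


def _bounding_box(mask: LungMask) -> tuple[int, int, int, int]:
    rows, cols = np.nonzero(mask.mask)
    return rows.min(), rows.max(), cols.min(), cols.max()


def compute_cov(ti: TidalImage) -> tuple[float, float]:
    """Center of ventilation: impedance-weighted centroid of the tidal
    image in percent of the lung bounding box.

    ``cov_x`` runs left (0%) to right (100%), ``cov_y`` ventral (0%) to
    dorsal (100%) for a supine patient.  Negative pixels are clipped to
    zero for weighting only; if no positive weight remains both
    coordinates are missing (NaN).
    """
    w = np.clip(ti.di, 0.0, None) * ti.mask.mask
    total = w.sum()
    if total <= 0:
        warnings.warn("CoV undefined: no positive tidal change in the lung", stacklevel=2)
        return float("nan"), float("nan")
    r0, r1, c0, c1 = _bounding_box(ti.mask)
    rows, cols = np.mgrid[0:ti.di.shape[0], 0:ti.di.shape[1]]
    cy = (w * rows).sum() / total
    cx = (w * cols).sum() / total
    cov_y = 50.0 if r1 == r0 else 100.0 * (cy - r0) / (r1 - r0)
    cov_x = 50.0 if c1 == c0 else 100.0 * (cx - c0) / (c1 - c0)
    return float(cov_x), float(cov_y)


def compute_silent_spaces(
    ti: TidalImage, cov_y: Optional[float] = None
) -> tuple[float, float, float]:
    """Nondependent/dependent silent spaces and functional lung space.

    Lung pixels with a tidal change below 10% of the maximum tidal change
    are silent.  Silent pixels dorsal of the gravity-axis CoV line are
    dependent (DSS), ventral of it nondependent (NSS); pixels exactly on
    the line split evenly, remainder to DSS.  All three are percent of
    lung pixels and ``nss + dss + fls == 100`` exactly (FLS is computed
    as the complement of the silent percentage).
    """
    vals = ti.lung_values
    n_lung = vals.size
    vmax = np.clip(vals, 0.0, None).max() if n_lung else 0.0
    if vmax <= 0:
        warnings.warn("no ventilated pixels: maximum tidal change <= 0", stacklevel=2)
        return 50.0, 50.0, 0.0
    if cov_y is None:
        cov_y = compute_cov(ti)[1]
    r0, r1, _, _ = _bounding_box(ti.mask)
    cov_row = r0 + cov_y / 100.0 * (r1 - r0)

    silent = (ti.di < 0.10 * vmax) & ti.mask.mask
    rows = np.nonzero(silent)[0]
    eps = 1e-9
    n_above = int(np.count_nonzero(rows < cov_row - eps))   # ventral -> NSS
    n_below = int(np.count_nonzero(rows > cov_row + eps))   # dorsal  -> DSS
    n_on = int(rows.size - n_above - n_below)
    n_nss = n_above + n_on // 2
    n_dss = n_below + (n_on - n_on // 2)

    nss = 100.0 * n_nss / n_lung
    dss = 100.0 * n_dss / n_lung
    fls = 100.0 - (nss + dss)
    return nss, dss, fls


def _half_fractions(ti: TidalImage, axis: int) -> tuple[float, float]:
    """Share of summed positive tidal change in each half of the lung grid,
    split at the mask bounding-box midline (a middle line of odd extent
    contributes half to each side)."""
    w = np.clip(ti.di, 0.0, None) * ti.mask.mask
    total = w.sum()
    if total <= 0:
        return float("nan"), float("nan")
    r0, r1, c0, c1 = _bounding_box(ti.mask)
    lo, hi = (r0, r1) if axis == 0 else (c0, c1)
    center = 0.5 * (lo + hi)
    coord = np.mgrid[0:ti.di.shape[0], 0:ti.di.shape[1]][axis]
    first = w[coord < center].sum() + 0.5 * w[coord == center].sum()
    return float(first / total), float(1.0 - first / total)


# ---------------------------------------------------------------------------
# Volume calibration
# ---------------------------------------------------------------------------

def calibrate_volume(
    breaths: Iterable[Breath],
    vent: VentilatorLog,
    fs: float,
    t0: float = 0.0,
    method: Literal["single_point", "mean_of_points"] = "mean_of_points",
    match_window_s: float = 1.0,
) -> CalibrationFactor:
    """Individualized ml-per-AU factor from stable pre-SBT breaths.

    Each breath is matched to ventilator samples whose timestamps fall
    within the breath interval padded by ``match_window_s``; the breath's
    reference volume is the median of the matched samples.  The factor is
    the mean of ``vt_ml / dz`` over calibration breaths (``single_point``
    uses the first matched breath only).  Breaths without a match are
    skipped; matched non-positive volumes are excluded with a warning.
    """
    points = []
    for b in breaths:
        lo = t0 + b.i_exp_start / fs - match_window_s
        hi = t0 + b.i_exp_end / fs + match_window_s
        sel = (vent.timestamps >= lo) & (vent.timestamps <= hi)
        if not sel.any():
            continue
        vt = float(np.median(vent.tidal_volume[sel]))
        if vt <= 0:
            warnings.warn(
                f"calibration point at t={t0 + b.i_exp_start / fs:.1f}s has "
                f"non-positive tidal volume; excluded",
                stacklevel=2,
            )
            continue
        points.append(vt / b.dz)
        if method == "single_point":
            break
    if not points:
        raise ValueError("no breath could be matched to a ventilator tidal volume")
    c = float(np.mean(points))
    logger.info("volume calibration: c=%.3f ml/AU from %d point(s)", c, len(points))
    return CalibrationFactor(c=c, n_points=len(points), method=method)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def breath_parameters(
    seq: EITSequence,
    breath: Breath,
    mask: LungMask,
    cal: Optional[CalibrationFactor] = None,
) -> BreathParameters:
    """All EIT parameters of one breath.

    ``rr = 60/duration``; with a calibration, ``vt_ml = c * dz``,
    ``mv = rr * vt / 1000`` [L/min] and ``rsbi = rr / (vt/1000)``
    [breaths/min/L]; without one the volume-derived parameters are NaN.
    """
    ti = tidal_image(seq, breath, mask)
    gi = compute_gi(ti)
    cov_x, cov_y = compute_cov(ti)
    nss, dss, fls = compute_silent_spaces(ti, cov_y=cov_y)
    frac_left, frac_right = _half_fractions(ti, axis=1)
    frac_ventral, frac_dorsal = _half_fractions(ti, axis=0)
    rr = breath.rr
    if cal is not None:
        vt_ml = cal.c * breath.dz
        mv = rr * vt_ml / 1000.0
        rsbi = rr / (vt_ml / 1000.0) if vt_ml > 0 else float("nan")
    else:
        vt_ml = mv = rsbi = float("nan")
    return BreathParameters(
        eeli=breath.eeli, dz=breath.dz, rr=rr, vt_ml=vt_ml, mv_l_min=mv,
        rsbi=rsbi, gi=gi, cov_x=cov_x, cov_y=cov_y, nss=nss, dss=dss, fls=fls,
        frac_left=frac_left, frac_right=frac_right,
        frac_ventral=frac_ventral, frac_dorsal=frac_dorsal,
        t_start=seq.t0 + breath.i_exp_start / seq.fs,
    )


def parameters_table(
    seq: EITSequence,
    breaths: Iterable[Breath],
    mask: LungMask,
    cal: Optional[CalibrationFactor] = None,
) -> pd.DataFrame:
    """Tidy per-breath parameter table (one row per breath)."""
    rows = [breath_parameters(seq, b, mask, cal).as_dict() for b in breaths]
    return pd.DataFrame(rows)


def period_parameters(
    seq: EITSequence,
    period: StablePeriod,
    mask: LungMask,
    cal: Optional[CalibrationFactor] = None,
    gi_mode: Literal["per_breath", "period_image"] = "per_breath",
    agg: Literal["mean", "median"] = "mean",
) -> dict:
    """Aggregate parameters over one stable period.

    Per-breath values are averaged (mean by default, median via ``agg``);
    with ``gi_mode='period_image'`` the distribution indices are instead
    computed once on the period-averaged tidal image.
    """
    df = parameters_table(seq, period.breaths, mask, cal)
    agg_fn = np.nanmean if agg == "mean" else np.nanmedian
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        out = {k: float(agg_fn(df[k].to_numpy())) for k in _PARAM_FIELDS}
    if gi_mode == "period_image":
        ti = period_tidal_image(seq, period, mask)
        out["gi"] = compute_gi(ti)
        out["cov_x"], out["cov_y"] = compute_cov(ti)
        out["nss"], out["dss"], out["fls"] = compute_silent_spaces(ti, cov_y=out["cov_y"])
    out["n_breaths"] = period.n_breaths
    out["t_start"] = seq.t0 + period.i_start / seq.fs
    out["t_end"] = seq.t0 + period.i_end / seq.fs
    return out
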