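"""Epoch-wise SBT trend assembly and the end-to-end pipeline.

Because trial length varies between patients, the SBT span of every
session is divided into five equal time intervals ("epochs"); the pre-
and post-SBT phases form one epoch each.  Breath-by-breath parameters
from stable tidal-breathing periods are averaged per epoch, and the
end-expiratory impedance and tidal swing are additionally expressed as
percent change from the pre-SBT baseline.  Multi-session results are
stacked into a tidy long table ready for external mixed-model
statistics; no significance testing is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_core, parameters, preprocessing
from .io_core import SBTAnnotation
from .parameters import _PARAM_FIELDS, CalibrationFactor
from .preprocessing import Breath, PreprocessingConfig, StablePeriod

logger = logging.getLogger(__name__)

__all__ = [
    "PHASES",
    "EpochAssignment",
    "SessionResult",
    "RunConfig",
    "PipelineError",
    "divide_epochs",
    "summarize_epochs",
    "cohort_table",
    "run_pipeline",
]

PHASES = ("pre", "sbt_1", "sbt_2", "sbt_3", "sbt_4", "sbt_5", "post")
N_SBT_EPOCHS = 5
POST_EARLY_S = 30.0  # breaths this soon after reconnection are flagged


# ---------------------------------------------------------------------------
# Epoch division
# ---------------------------------------------------------------------------

@dataclass
class EpochAssignment:
    """Phase edges and the stable breaths assigned to each phase.

    ``edges`` maps each phase to its half-open time interval
    ``[t_lo, t_hi)``; ``breaths`` maps each phase to the stable breaths
    whose end-expiration start time falls inside it.
    """

    edges: dict[str, tuple[float, float]]
    breaths: dict[str, list[Breath]]
    mode: str = "duration"

    def epoch_of(self, t: float) -> Optional[str]:
        for phase, (lo, hi) in self.edges.items():
            if lo <= t < hi:
                return phase
        return None


def divide_epochs(
    ann: SBTAnnotation,
    periods: Sequence[StablePeriod],
    fs: float,
    t0: float = 0.0,
    mode: Literal["duration", "count"] = "duration",
) -> EpochAssignment:
    """Cut the SBT span into five epochs and assign stable breaths.

    ``duration`` mode (default) cuts ``[t_sbt_start, t_sbt_end)`` into
    five equal-length half-open intervals; a breath belongs to the
    interval containing its end-expiration start time (boundary breaths
    go to the later interval).  ``count`` mode instead splits the stable
    SBT breaths into five consecutive groups of near-equal size.  Empty
    epochs are reported, never an error.
    """
    if ann.t_sbt_end <= ann.t_sbt_start:
        raise ValueError("SBT end must come after SBT start")
    cuts = np.linspace(ann.t_sbt_start, ann.t_sbt_end, N_SBT_EPOCHS + 1)
    edges: dict[str, tuple[float, float]] = {"pre": (ann.t_pre_start, ann.t_sbt_start)}
    for k in range(N_SBT_EPOCHS):
        edges[f"sbt_{k + 1}"] = (float(cuts[k]), float(cuts[k + 1]))
    edges["post"] = (ann.t_sbt_end, ann.t_post_end)

    stable = sorted(
        (b for p in periods for b in p.breaths), key=lambda b: b.i_exp_start
    )
    by_phase: dict[str, list[Breath]] = {ph: [] for ph in PHASES}
    sbt_breaths: list[Breath] = []
    for b in stable:
        t = t0 + b.i_exp_start / fs
        if edges["pre"][0] <= t < edges["pre"][1]:
            by_phase["pre"].append(b)
        elif edges["post"][0] <= t < edges["post"][1]:
            by_phase["post"].append(b)
        elif ann.t_sbt_start <= t < ann.t_sbt_end:
            sbt_breaths.append(b)

    if mode == "duration":
        for b in sbt_breaths:
            t = t0 + b.i_exp_start / fs
            k = min(int((t - ann.t_sbt_start) / (cuts[1] - cuts[0])), N_SBT_EPOCHS - 1)
            # robust against float edge effects: honour the half-open rule
            while k + 1 < N_SBT_EPOCHS and t >= cuts[k + 1]:
                k += 1
            while k > 0 and t < cuts[k]:
                k -= 1
            by_phase[f"sbt_{k + 1}"].append(b)
    elif mode == "count":
        groups = np.array_split(np.arange(len(sbt_breaths)), N_SBT_EPOCHS)
        for k, grp in enumerate(groups):
            by_phase[f"sbt_{k + 1}"] = [sbt_breaths[i] for i in grp]
    else:
        raise ValueError(f"unknown epoch mode {mode!r}")

    empty = [ph for ph in PHASES if not by_phase[ph]]
    if empty:
        logger.warning("empty epoch(s): %s", ", ".join(empty))
    return EpochAssignment(edges=edges, breaths=by_phase, mode=mode)


# ---------------------------------------------------------------------------
# Epoch summaries
# ---------------------------------------------------------------------------

def summarize_epochs(assignment: EpochAssignment, params: pd.DataFrame) -> pd.DataFrame:
    """Per-epoch means and dispersions, with percent change from baseline.

    ``params`` is a tidy per-breath table (one row per stable breath,
    including ``t_start``).  For EELI and the tidal swing the epoch mean
    is additionally expressed as percent change from the pre-SBT epoch,
    ``100 * (mean - mean_pre) / |mean_pre|`` (the pre epoch is 0 by
    definition).  An empty pre epoch is an error: without a baseline no
    trend can be anchored.  Missing values propagate as NaN with
    per-parameter counts.
    """
    if "t_start" not in params.columns:
        raise ValueError("parameter table must carry a t_start column")
    rows = []
    for phase in PHASES:
        lo, hi = assignment.edges[phase]
        sub = params[(params["t_start"] >= lo) & (params["t_start"] < hi)]
        row: dict = {"phase": phase, "n_breaths": len(sub),
                     "t_lo": lo, "t_hi": hi}
        for p in _PARAM_FIELDS:
            vals = sub[p].to_numpy(dtype=float) if p in sub else np.empty(0)
            ok = np.isfinite(vals)
            row[f"{p}_mean"] = float(np.mean(vals[ok])) if ok.any() else np.nan
            row[f"{p}_sd"] = float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else np.nan
            row[f"{p}_n"] = int(ok.sum())
        if phase == "post":
            row["n_breaths_first30s"] = int(
                ((sub["t_start"] >= lo) & (sub["t_start"] < lo + POST_EARLY_S)).sum()
            ) if len(sub) else 0
        rows.append(row)
    out = pd.DataFrame(rows)
    pre = out.loc[out["phase"] == "pre"].iloc[0]
    if pre["n_breaths"] == 0:
        raise ValueError("pre-SBT epoch contains no stable breaths; no baseline")
    for p in ("eeli", "dz"):
        base = pre[f"{p}_mean"]
        out[f"pct_change_{p}"] = 100.0 * (out[f"{p}_mean"] - base) / abs(base)
    return out


# ---------------------------------------------------------------------------
# Session & cohort
# ---------------------------------------------------------------------------

@dataclass
class SessionResult:
    """Everything the pipeline produced for one session."""

    patient_id: str
    outcome: str
    epochs: pd.DataFrame
    calibration: Optional[CalibrationFactor]
    breaths: pd.DataFrame
    periods: pd.DataFrame
    qc: preprocessing.ArtifactReport


def cohort_table(
    sessions: Sequence[SessionResult],
    parameters_: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack session epoch means into a tidy long table.

    Returns ``(values, group_means)``: one row per (patient, outcome,
    phase, parameter) — epochs without breaths keep their row with a NaN
    value and ``missing=True`` rather than being dropped — plus group
    means per (outcome, phase, parameter), ready for external
    mixed-model fitting.
    """
    if not sessions:
        raise ValueError("cohort requires at least one session")
    params = tuple(parameters_) if parameters_ is not None else _PARAM_FIELDS
    rows = []
    for s in sessions:
        for _, ep in s.epochs.iterrows():
            for p in params:
                val = ep.get(f"{p}_mean", np.nan)
                rows.append(
                    {"patient": s.patient_id, "outcome": s.outcome,
                     "phase": ep["phase"], "parameter": p,
                     "value": float(val) if np.isfinite(val) else np.nan,
                     "missing": not np.isfinite(val)}
                )
    values = pd.DataFrame(rows)
    group_means = (
        values.groupby(["outcome", "phase", "parameter"], sort=False)["value"]
        .mean()
        .reset_index(name="group_mean")
    )
    return values, group_means


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable, flat keys)."""

    session: str = ""
    outdir: str = "results"
    patient_id: str = "anon"
    gi_mode: Literal["per_breath", "period_image"] = "per_breath"
    epoch_mode: Literal["duration", "count"] = "duration"
    agg: Literal["mean", "median"] = "mean"
    calibration_method: Literal["single_point", "mean_of_points"] = "mean_of_points"
    hr_estimate_hz: Optional[float] = None
    mad_k: float = 6.0
    step_thresh_au: Optional[float] = None
    cv_max: float = 0.25
    min_breaths: int = 5
    prominence_frac: float = 0.3
    breath_min_s: float = 1.0
    breath_max_s: float = 15.0
    artifact_frac_max: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in dc_fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(
                f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def preprocessing(self) -> PreprocessingConfig:
        return PreprocessingConfig(
            mad_k=self.mad_k, step_thresh_au=self.step_thresh_au,
            cv_max=self.cv_max, min_breaths=self.min_breaths,
            prominence_frac=self.prominence_frac,
            breath_min_s=self.breath_min_s, breath_max_s=self.breath_max_s,
            artifact_frac_max=self.artifact_frac_max,
        )


def _periods_frame(periods: list[StablePeriod], fs: float, t0: float) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"i_start": p.i_start, "i_end": p.i_end,
             "t_start": t0 + p.i_start / fs, "t_end": t0 + p.i_end / fs,
             "n_breaths": p.n_breaths, "cv_dz": p.cv_dz,
             "cv_duration": p.cv_duration,
             "artifact_fraction": p.artifact_fraction}
            for p in periods
        ],
        columns=["i_start", "i_end", "t_start", "t_end", "n_breaths",
                 "cv_dz", "cv_duration", "artifact_fraction"],
    )


def run_pipeline(config: RunConfig, write: bool = True) -> SessionResult:
    """Execute the whole analysis on one session container.

    io -> preprocessing -> calibration -> parameters -> epochs; writes
    ``breaths.csv``, ``periods.csv``, ``epochs.csv``, ``qc_report.csv``
    and ``session.log`` into the output directory.  Each stage failure is
    re-raised as :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    log_handler = None
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(outdir / "session.log", mode="w")
        log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logging.getLogger("eitsbt").addHandler(log_handler)
    try:
        try:
            seq, mask, vent, ann = io_core.read_session_container(config.session)
            session = io_core.align_channels(seq, vent, ann, mask=mask)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("io", str(exc)) from exc

        try:
            cleaned, filtered, breaths, periods, report = preprocessing.preprocess(
                session.seq, session.mask, config.preprocessing(),
                hr_estimate=config.hr_estimate_hz,
            )
        except Exception as exc:
            raise PipelineError("preprocessing", str(exc)) from exc

        try:
            # calibration breaths must lie fully inside the pre-SBT phase —
            # a breath straddling the SBT start is no steady ventilated breath
            pre_breaths = [
                b for p in periods for b in p.breaths
                if ann.t_pre_start <= seq.t0 + b.i_exp_start / seq.fs
                and seq.t0 + b.i_exp_end / seq.fs <= ann.t_sbt_start
            ]
            cal: Optional[CalibrationFactor] = None
            if pre_breaths and session.vent.n_samples:
                cal = parameters.calibrate_volume(
                    pre_breaths, session.vent, fs=seq.fs, t0=seq.t0,
                    method=config.calibration_method,
                )
            stable = sorted(
                (b for p in periods for b in p.breaths), key=lambda b: b.i_exp_start
            )
            params_df = parameters.parameters_table(cleaned, stable, session.mask, cal)
        except Exception as exc:
            raise PipelineError("parameters", str(exc)) from exc

        try:
            assignment = divide_epochs(ann, periods, fs=seq.fs, t0=seq.t0,
                                       mode=config.epoch_mode)
            if config.gi_mode == "period_image" and periods:
                # distribution indices from period-averaged tidal images
                for p in periods:
                    pp = parameters.period_parameters(
                        cleaned, p, session.mask, cal, gi_mode="period_image",
                    )
                    sel = (params_df["t_start"] >= seq.t0 + p.i_start / seq.fs) & (
                        params_df["t_start"] <= seq.t0 + p.i_end / seq.fs
                    )
                    for k in ("gi", "cov_x", "cov_y", "nss", "dss", "fls"):
                        params_df.loc[sel, k] = pp[k]
            epochs = summarize_epochs(assignment, params_df)
        except Exception as exc:
            raise PipelineError("trend_analysis", str(exc)) from exc

        result = SessionResult(
            patient_id=config.patient_id, outcome=ann.outcome, epochs=epochs,
            calibration=cal, breaths=params_df,
            periods=_periods_frame(periods, seq.fs, seq.t0), qc=report,
        )
        if write:
            params_df.to_csv(outdir / "breaths.csv", index=False)
            result.periods.to_csv(outdir / "periods.csv", index=False)
            epochs.to_csv(outdir / "epochs.csv", index=False)
            report.to_csv(outdir / "qc_report.csv")
            logger.info("session %s: %d breaths, %d stable periods, c=%s",
                        config.patient_id, len(params_df), len(periods),
                        "n/a" if cal is None else f"{cal.c:.2f} ml/AU")
        return result
    finally:
        if log_handler is not None:
            logging.getLogger("eitsbt").removeHandler(log_handler)
            log_handler.close()
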