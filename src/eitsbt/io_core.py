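"""Data model and I/O for EIT spontaneous-breathing-trial sessions.

The pipeline consumes four kinds of input:

* a time-ordered stack of reconstructed 2-D pixel impedance maps
  (:class:`EITSequence`, typically sampled at ~50.2 Hz),
* a binary lung-contour mask (:class:`LungMask`) restricting every image
  index to lung pixels,
* a 1 Hz ventilator log with tidal volumes in ml (:class:`VentilatorLog`),
* timestamps delimiting the pre-SBT, SBT and post-SBT phases
  (:class:`SBTAnnotation`).

Two on-disk dialects are supported: a plain-text ``frame-csv`` layout
(one row per frame, row-major pixel order, ``# key=value`` header lines)
and an HDF5 ``container`` holding a whole session in one file.

All times are seconds from recording start; frame ``i`` lives at
``t0 + i / fs``.  Timestamps map to frame indices by nearest frame with
ties broken toward the earlier frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EITSequence",
    "LungMask",
    "VentilatorLog",
    "SBTAnnotation",
    "AuxChannel",
    "AlignedSession",
    "read_eit_sequence",
    "write_eit_sequence",
    "read_lung_mask",
    "write_lung_mask",
    "read_ventilator_log",
    "write_ventilator_log",
    "read_session_container",
    "write_session_container",
    "align_channels",
    "time_to_frame",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AuxChannel:
    """An auxiliary scalar channel (e.g. transcutaneous CO2) with its own clock."""

    name: str
    timestamps: np.ndarray  # [s]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError(f"channel {self.name!r}: timestamps/values length mismatch")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError(f"channel {self.name!r}: timestamps must be strictly increasing")


@dataclass
class EITSequence:
    """Time-ordered stack of 2-D pixel impedance maps.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, n_rows, n_cols)`` in arbitrary units.
    fs
        Sampling frequency in Hz.
    t0
        Time of the first frame, seconds.
    channels
        Optional auxiliary scalar channels keyed by name.
    nonfinite_frames
        Indices of frames that contained non-finite pixels on ingestion
        (repaired by temporal interpolation, never propagated).
    """

    frames: np.ndarray
    fs: float
    t0: float = 0.0
    channels: dict[str, AuxChannel] = field(default_factory=dict)
    nonfinite_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, n_rows, n_cols) stack with n_frames >= 1")
        if not (self.fs > 0):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        self.nonfinite_frames = np.asarray(self.nonfinite_frames, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of each frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return self.t0 + np.arange(self.n_frames) / self.fs

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.fs


@dataclass
class LungMask:
    """Binary lung-contour mask on the reconstruction grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.all(np.isin(m, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.mask = m.astype(bool)
        if self.n_lung_pixels < 1:
            raise ValueError("mask contains no lung pixels")

    @property
    def n_lung_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def check_compatible(self, seq: EITSequence) -> None:
        if self.shape != seq.shape:
            raise ValueError(f"mask shape {self.shape} does not match frame shape {seq.shape}")


@dataclass
class VentilatorLog:
    """1 Hz ventilator samples: tidal volume [ml], optional RR and PEEP."""

    timestamps: np.ndarray  # [s]
    tidal_volume: np.ndarray  # [ml]
    respiratory_rate: Optional[np.ndarray] = None  # [breaths/min]
    peep: Optional[np.ndarray] = None  # [cmH2O]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.tidal_volume = np.asarray(self.tidal_volume, dtype=float)
        if self.timestamps.shape != self.tidal_volume.shape:
            raise ValueError("timestamps and tidal_volume must have equal length")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("ventilator timestamps must be strictly increasing")
        if np.any(self.tidal_volume < 0):
            raise ValueError("tidal volumes must be non-negative")
        for name in ("respiratory_rate", "peep"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.timestamps.shape:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    @property
    def n_samples(self) -> int:
        return self.timestamps.size


_OUTCOMES = ("success", "failure", "unknown")


@dataclass
class SBTAnnotation:
    """Phase timestamps of one spontaneous breathing trial."""

    t_pre_start: float
    t_sbt_start: float
    t_sbt_end: float
    t_post_end: float
    outcome: str = "unknown"

    def __post_init__(self) -> None:
        ts = (self.t_pre_start, self.t_sbt_start, self.t_sbt_end, self.t_post_end)
        if not (ts[0] < ts[1] < ts[2] < ts[3]):
            raise ValueError(f"annotation timestamps must be strictly ordered, got {ts}")
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"outcome must be one of {_OUTCOMES}, got {self.outcome!r}")

    @property
    def sbt_duration(self) -> float:
        return self.t_sbt_end - self.t_sbt_start


@dataclass
class AlignedSession:
    """All channels of one session on the EIT frame clock."""

    seq: EITSequence
    mask: LungMask
    vent: VentilatorLog
    annotation: SBTAnnotation
    vent_frame_idx: np.ndarray  # frame index of each vent sample
    annotation_frame_idx: dict[str, int]  # keys: pre_start, sbt_start, sbt_end, post_end


# ---------------------------------------------------------------------------
# Non-finite repair
# ---------------------------------------------------------------------------

def _repair_nonfinite(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace non-finite pixels by temporal interpolation of that pixel.

    Returns the repaired stack and the indices of affected frames.
    """
    finite = np.isfinite(frames)
    if finite.all():
        return frames, np.empty(0, dtype=int)
    bad_frames = np.unique(np.nonzero(~finite)[0])
    frames = np.array(frames, dtype=float, copy=True)
    n = frames.shape[0]
    t = np.arange(n)
    flat = frames.reshape(n, -1)
    flat_finite = finite.reshape(n, -1)
    for j in np.nonzero(~flat_finite.all(axis=0))[0]:
        good = flat_finite[:, j]
        if not good.any():
            raise ValueError(f"pixel {j} has no finite samples; cannot repair")
        flat[~good, j] = np.interp(t[~good], t[good], flat[good, j])
    logger.warning("repaired non-finite pixels in %d frame(s)", bad_frames.size)
    return flat.reshape(frames.shape), bad_frames


# ---------------------------------------------------------------------------
# frame-csv dialect
# ---------------------------------------------------------------------------

def _parse_frame_csv_headers(path: Path) -> tuple[dict[str, float], int]:
    headers: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                headers[key.strip()] = float(val.strip())
    return headers, n_header


def _read_grid_rows(path: Path, skip: int, rows: int, cols: int) -> np.ndarray:
    data = []
    with open(path) as fh:
        for _ in range(skip):
            next(fh)
        for lineno, line in enumerate(fh, start=skip + 1):
            line = line.strip()
            if not line:
                continue
            vals = line.split(",")
            if len(vals) != rows * cols:
                raise ValueError(
                    f"{path}: line {lineno} has {len(vals)} values, expected {rows * cols}"
                )
            data.append(np.array(vals, dtype=float))
    return np.asarray(data)


def read_eit_sequence(path: str | Path, dialect: str = "frame-csv") -> EITSequence:
    """Read an EIT frame sequence.

    ``frame-csv``: plain text with ``# fs=``, ``# rows=``, ``# cols=``,
    ``# t0=`` headers and one comma-separated row per frame (row-major).
    ``container``: the HDF5 session container (frames/fs/t0 only).
    """
    path = Path(path)
    if dialect == "container":
        session = read_session_container(path)
        return session[0]
    if dialect != "frame-csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    headers, n_header = _parse_frame_csv_headers(path)
    for key in ("fs", "rows", "cols"):
        if key not in headers:
            raise ValueError(f"{path}: missing required header '# {key}='")
    fs = headers["fs"]
    if fs <= 0:
        raise ValueError(f"{path}: fs must be positive, got {fs}")
    rows, cols = int(headers["rows"]), int(headers["cols"])
    flat = _read_grid_rows(path, n_header, rows, cols)
    if flat.size == 0:
        raise ValueError(f"{path}: no frame rows found")
    frames, bad = _repair_nonfinite(flat.reshape(-1, rows, cols))
    return EITSequence(frames=frames, fs=fs, t0=headers.get("t0", 0.0), nonfinite_frames=bad)


def write_eit_sequence(seq: EITSequence, path: str | Path) -> None:
    """Write a sequence in the frame-csv dialect (full float precision)."""
    path = Path(path)
    rows, cols = seq.shape
    with open(path, "w") as fh:
        fh.write(f"# fs={seq.fs!r}\n# rows={rows}\n# cols={cols}\n# t0={seq.t0!r}\n")
        for frame in seq.frames:
            fh.write(",".join(repr(float(v)) for v in frame.ravel()) + "\n")


def read_lung_mask(path: str | Path) -> LungMask:
    """Read a lung mask in frame-csv grid layout (no fs header needed)."""
    path = Path(path)
    headers, n_header = _parse_frame_csv_headers(path)
    if "rows" in headers and "cols" in headers:
        rows, cols = int(headers["rows"]), int(headers["cols"])
        grid = _read_grid_rows(path, n_header, rows, cols).reshape(-1, rows, cols)
        if grid.shape[0] != 1:
            raise ValueError(f"{path}: mask file must contain exactly one grid row")
        m = grid[0]
    else:
        # headerless: one text row per grid row
        with open(path) as fh:
            rows_txt = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        parsed = [np.array(r.split(","), dtype=float) for r in rows_txt]
        widths = {p.size for p in parsed}
        if len(widths) != 1:
            raise ValueError(f"{path}: ragged mask rows (widths {sorted(widths)})")
        m = np.asarray(parsed)
    return LungMask(mask=m)


def write_lung_mask(mask: LungMask, path: str | Path) -> None:
    rows, cols = mask.shape
    with open(path, "w") as fh:
        fh.write(f"# rows={rows}\n# cols={cols}\n")
        fh.write(",".join(str(int(v)) for v in mask.mask.ravel()) + "\n")


def read_ventilator_log(path: str | Path) -> VentilatorLog:
    """Read a ventilator log CSV with columns ``t_s, vt_ml[, rr_bpm, peep_cmh2o]``."""
    df = pd.read_csv(path)
    for col in ("t_s", "vt_ml"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return VentilatorLog(
        timestamps=df["t_s"].to_numpy(),
        tidal_volume=df["vt_ml"].to_numpy(),
        respiratory_rate=df["rr_bpm"].to_numpy() if "rr_bpm" in df.columns else None,
        peep=df["peep_cmh2o"].to_numpy() if "peep_cmh2o" in df.columns else None,
    )


def write_ventilator_log(vent: VentilatorLog, path: str | Path) -> None:
    data = {"t_s": vent.timestamps, "vt_ml": vent.tidal_volume}
    if vent.respiratory_rate is not None:
        data["rr_bpm"] = vent.respiratory_rate
    if vent.peep is not None:
        data["peep_cmh2o"] = vent.peep
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# container dialect (HDF5)
# ---------------------------------------------------------------------------

def write_session_container(
    path: str | Path,
    seq: EITSequence,
    mask: LungMask,
    vent: VentilatorLog,
    annotation: SBTAnnotation,
) -> None:
    """Write a whole session into one HDF5 container.

    Layout: ``/frames`` (n x r x c), ``/fs``, ``/t0``, ``/mask``,
    ``/vent/t``, ``/vent/vt``, ``/annotation`` (4 phase timestamps, with
    an ``outcome`` attribute). Auxiliary channels go under
    ``/channels/<name>/{t,v}``.
    """
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=seq.frames)
        h5.create_dataset("fs", data=float(seq.fs))
        h5.create_dataset("t0", data=float(seq.t0))
        h5.create_dataset("mask", data=mask.mask.astype(np.uint8))
        h5.create_dataset("vent/t", data=vent.timestamps)
        h5.create_dataset("vent/vt", data=vent.tidal_volume)
        ann = h5.create_dataset(
            "annotation",
            data=np.array(
                [annotation.t_pre_start, annotation.t_sbt_start,
                 annotation.t_sbt_end, annotation.t_post_end]
            ),
        )
        ann.attrs["outcome"] = annotation.outcome
        for name, ch in seq.channels.items():
            h5.create_dataset(f"channels/{name}/t", data=ch.timestamps)
            h5.create_dataset(f"channels/{name}/v", data=ch.values)
            h5[f"channels/{name}"].attrs["units"] = ch.units


def read_session_container(
    path: str | Path,
) -> tuple[EITSequence, LungMask, VentilatorLog, SBTAnnotation]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as h5:
        frames, bad = _repair_nonfinite(np.asarray(h5["frames"], dtype=float))
        channels = {}
        if "channels" in h5:
            for name in h5["channels"]:
                grp = h5[f"channels/{name}"]
                channels[name] = AuxChannel(
                    name=name,
                    timestamps=np.asarray(grp["t"]),
                    values=np.asarray(grp["v"]),
                    units=grp.attrs.get("units", ""),
                )
        seq = EITSequence(
            frames=frames,
            fs=float(h5["fs"][()]),
            t0=float(h5["t0"][()]),
            channels=channels,
            nonfinite_frames=bad,
        )
        mask = LungMask(mask=np.asarray(h5["mask"]))
        vent = VentilatorLog(
            timestamps=np.asarray(h5["vent/t"]),
            tidal_volume=np.asarray(h5["vent/vt"]),
        )
        ann_ds = h5["annotation"]
        t = np.asarray(ann_ds, dtype=float)
        annotation = SBTAnnotation(*t, outcome=str(ann_ds.attrs.get("outcome", "unknown")))
    return seq, mask, vent, annotation


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def time_to_frame(t: float | np.ndarray, seq: EITSequence, clip: bool = True):
    """Map timestamps to frame indices: nearest frame, ties toward earlier.

    With ``clip=False``, out-of-range timestamps raise.
    """
    rel = (np.asarray(t, dtype=float) - seq.t0) * seq.fs
    idx = np.ceil(rel - 0.5).astype(int)  # nearest; exact halves go down
    if clip:
        idx = np.clip(idx, 0, seq.n_frames - 1)
    elif np.any(idx < 0) or np.any(idx > seq.n_frames - 1):
        raise ValueError("timestamp outside recording")
    return idx if np.ndim(t) else int(idx)


def align_channels(seq: EITSequence, vent: VentilatorLog, ann: SBTAnnotation,
                   mask: LungMask | None = None) -> AlignedSession:
    """Express ventilator and annotation channels on the EIT frame clock.

    Vent samples outside the recording are dropped; annotation timestamps
    are clipped to the recording but must overlap it.
    """
    t_start, t_end = seq.t0, seq.t0 + (seq.n_frames - 1) / seq.fs
    if ann.t_post_end <= t_start or ann.t_pre_start >= t_end:
        raise ValueError("annotation window does not overlap the EIT recording")
    in_rec = (vent.timestamps >= t_start) & (vent.timestamps <= t_end)
    vent_idx = time_to_frame(vent.timestamps[in_rec], seq)
    kept = VentilatorLog(
        timestamps=vent.timestamps[in_rec],
        tidal_volume=vent.tidal_volume[in_rec],
        respiratory_rate=None if vent.respiratory_rate is None else vent.respiratory_rate[in_rec],
        peep=None if vent.peep is None else vent.peep[in_rec],
    )
    ann_idx = {
        "pre_start": time_to_frame(ann.t_pre_start, seq),
        "sbt_start": time_to_frame(ann.t_sbt_start, seq),
        "sbt_end": time_to_frame(ann.t_sbt_end, seq),
        "post_end": time_to_frame(ann.t_post_end, seq),
    }
    if mask is not None:
        mask.check_compatible(seq)
    else:
        mask = LungMask(mask=np.ones(seq.shape, dtype=int))
    return AlignedSession(
        seq=seq, mask=mask, vent=kept, annotation=ann,
        vent_frame_idx=np.atleast_1d(vent_idx),
        annotation_frame_idx=ann_idx,
    )
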