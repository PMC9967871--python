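"""Reading, writing and derivation of analysis-ready signals.

Three input classes are supported, all as plain-text/TIFF artifacts:

* fluorescence time series (two-channel 340/380 nm Fura-2 or single-channel
  Rhod-2) as CSV with a ``time_s`` column and a JSON sidecar for stimulus
  and event metadata;
* oxygraph recordings (O2 concentration, safranine-O signal, event markers)
  as CSV;
* 2-D microscopy frames as TIFF with the pixel size in a JSON sidecar.

Derived signals are the 340/380 ratio (`compute_ratio`) and the
baseline-normalised fluorescence change dF/F0 (`compute_dff`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

#: relative tolerance on the uniformity of the acquisition time grid
TIME_GRID_RTOL = 1e-6

#: event labels understood by the oxygraph reader, in protocol order
OXYGRAPH_EVENT_LABELS = ("GMP", "ADP_HEX", "CACL2", "FCCP")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValidationError(f"{name} contains a non-finite value at index {bad}")
    return arr


def _check_uniform_time(time: np.ndarray) -> float:
    """Validate a strictly increasing uniform grid; return the median step."""
    if time.size < 2:
        raise ValidationError("time grid needs at least two samples")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise ValidationError("non-uniform time grid: time is not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > TIME_GRID_RTOL * med:
        raise ValidationError("non-uniform time grid: step deviates beyond tolerance")
    return med


@dataclass
class FluorescenceTrace:
    """Raw acquired fluorescence channels plus stimulus metadata for one cell.

    ``channels`` holds either ``{"F340", "F380"}`` (ratiometric Fura-2) or
    ``{"F"}`` (single-wavelength Rhod-2), all on the common ``time`` grid.
    ``stim_freq`` is the field-stimulation frequency in Hz (0 = unpaced);
    explicit ``stim_times`` override the frequency when present.  ``events``
    are ``(label, time_s)`` pairs, e.g. ``("caffeine", 30.0)``.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    sampling_rate: float
    modality: str  # "ratiometric" | "single"
    stim_freq: float = 0.0
    stim_times: np.ndarray | None = None
    events: list[tuple[str, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        dt = _check_uniform_time(self.time)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if not math.isclose(self.sampling_rate, 1.0 / dt, rel_tol=1e-6):
            raise ValidationError(
                f"sampling_rate {self.sampling_rate} inconsistent with grid step {dt}"
            )
        if self.modality not in ("ratiometric", "single"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        expected = {"F340", "F380"} if self.modality == "ratiometric" else {"F"}
        if set(self.channels) != expected:
            raise ValidationError(
                f"modality {self.modality!r} requires channels {sorted(expected)}, "
                f"got {sorted(self.channels)}"
            )
        for name in self.channels:
            ch = _as_float_array(self.channels[name], name)
            if ch.size != self.time.size:
                raise ValidationError(f"channel {name} length differs from time grid")
            self.channels[name] = ch
        if self.stim_times is not None:
            st = _as_float_array(self.stim_times, "stim_times")
            if st.size and (st[0] < self.time[0] - dt / 2 or st[-1] > self.time[-1] + dt / 2):
                raise ValidationError("stim_times fall outside the recording")
            self.stim_times = st

    @property
    def duration(self) -> float:
        """Span of the time grid, ``(n_samples - 1) / sampling_rate``."""
        return float(self.time[-1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return int(self.time.size)


@dataclass
class RatioTrace:
    """A dimensionless analysis-ready signal: 340/380 ratio or dF/F0."""

    time: np.ndarray
    signal: np.ndarray
    kind: str  # "ratio" | "dff"
    f0: float | None = None
    provenance: str = ""
    sampling_rate: float = 0.0
    stim_freq: float = 0.0
    stim_times: np.ndarray | None = None
    events: list[tuple[str, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        dt = _check_uniform_time(self.time)
        if not self.sampling_rate:
            self.sampling_rate = 1.0 / dt
        self.signal = _as_float_array(self.signal, "signal")
        if self.signal.size != self.time.size:
            raise ValidationError("signal length differs from time grid")
        if self.kind not in ("ratio", "dff"):
            raise ValidationError(f"unknown kind {self.kind!r}")
        if self.kind == "dff":
            if self.f0 is None or self.f0 <= 0:
                raise ValidationError("kind='dff' requires f0 > 0")


@dataclass
class OxygraphEvent:
    label: str
    time: float
    dose: str = ""


@dataclass
class OxygraphRecording:
    """Event-marked O2 + safranine-O time series from one oxygraph chamber.

    ``free_ca_ladder`` maps cumulative CaCl2 added (mM) to the resulting free
    [Ca2+] (uM); it is supplied externally (speciation is not computed here).
    """

    time: np.ndarray
    o2_conc: np.ndarray  # uM
    safranine: np.ndarray  # uM-equivalent signal
    events: list[OxygraphEvent]
    chamber_volume_ml: float = 2.0
    tissue_mass_mg: float = 2.0
    free_ca_ladder: dict[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        _check_uniform_time(self.time)
        self.o2_conc = _as_float_array(self.o2_conc, "o2_conc")
        self.safranine = _as_float_array(self.safranine, "safranine")
        if not (self.o2_conc.size == self.safranine.size == self.time.size):
            raise ValidationError("channel lengths differ from time grid")
        if np.any(self.o2_conc < 0):
            raise ValidationError("o2_conc must be non-negative")
        if self.chamber_volume_ml <= 0 or self.tissue_mass_mg <= 0:
            raise ValidationError("chamber_volume_ml and tissue_mass_mg must be positive")
        self.events = [
            e if isinstance(e, OxygraphEvent) else OxygraphEvent(*e) for e in self.events
        ]
        for e in self.events:
            if e.label not in OXYGRAPH_EVENT_LABELS:
                raise ValidationError(
                    f"unknown event label {e.label!r}; allowed: {OXYGRAPH_EVENT_LABELS}"
                )
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValidationError("events out of time order")


@dataclass
class LabelImage:
    """A single-channel 2-D microscopy frame with physical pixel size."""

    pixels: np.ndarray
    pixel_size_nm: float
    channel_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be a 2-D array")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")

    @property
    def frame_um(self) -> tuple[float, float]:
        """Physical extent (width, height) in um."""
        h, w = self.pixels.shape
        s = self.pixel_size_nm / 1000.0
        return (w * s, h * s)


# ---------------------------------------------------------------------------
# trace I/O

_TRACE_TIME = "time_s"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_trace(path, schema: Mapping[str, str] | None = None) -> FluorescenceTrace:
    """Read a delimited-text fluorescence trace plus optional JSON sidecar.

    ``schema`` maps canonical names (``time_s``, ``F340``, ``F380``, ``F``)
    to the column names actually present in the file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    schema = dict(schema or {})
    cols = {canon: schema.get(canon, canon) for canon in (_TRACE_TIME, "F340", "F380", "F")}
    if cols[_TRACE_TIME] not in df.columns:
        raise FormatError(f"missing required column {cols[_TRACE_TIME]!r} in {path.name}")
    have = {c for c in ("F340", "F380", "F") if cols[c] in df.columns}
    if {"F340", "F380"} <= have:
        modality, names = "ratiometric", ("F340", "F380")
    elif "F" in have:
        modality, names = "single", ("F",)
    else:
        raise FormatError(
            f"missing intensity columns in {path.name}: need F340+F380 or F "
            f"(after schema mapping {schema or '{}'})"
        )
    time = df[cols[_TRACE_TIME]].to_numpy(dtype=float)
    channels = {n: df[cols[n]].to_numpy(dtype=float) for n in names}

    stim_freq, stim_times, events, meta = 0.0, None, [], {}
    sc = _sidecar_path(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        stim_freq = float(side.get("stim_freq", 0.0))
        if side.get("stim_times") is not None:
            stim_times = np.asarray(side["stim_times"], dtype=float)
        events = [(str(l), float(t)) for l, t in side.get("events", [])]
        meta = dict(side.get("meta", {}))

    dt = _check_uniform_time(_as_float_array(time, "time"))
    return FluorescenceTrace(
        time=time,
        channels=channels,
        sampling_rate=1.0 / dt,
        modality=modality,
        stim_freq=stim_freq,
        stim_times=stim_times,
        events=events,
        meta=meta,
    )


def write_trace(trace: FluorescenceTrace, path) -> Path:
    """Write a trace as CSV plus JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {_TRACE_TIME: trace.time, **trace.channels}
    header = ",".join(cols)
    data = np.column_stack(list(cols.values()))
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.12g")
    side = {
        "stim_freq": trace.stim_freq,
        "stim_times": None if trace.stim_times is None else list(map(float, trace.stim_times)),
        "events": [[l, t] for l, t in trace.events],
        "meta": trace.meta,
        "modality": trace.modality,
    }
    _sidecar_path(path).write_text(json.dumps(side, indent=1))
    return path


# ---------------------------------------------------------------------------
# derived signals


def compute_ratio(trace: FluorescenceTrace) -> RatioTrace:
    """Pointwise 340/380 ratio of a ratiometric trace.

    Optional per-channel constant dark backgrounds may be stored in
    ``trace.meta["background"]`` as ``{"F340": b1, "F380": b2}`` (default 0).
    """
    if trace.modality != "ratiometric":
        raise ValidationError("compute_ratio requires a ratiometric trace")
    bg = trace.meta.get("background", {})
    f340 = trace.channels["F340"] - float(bg.get("F340", 0.0))
    f380 = trace.channels["F380"] - float(bg.get("F380", 0.0))
    nonpos = np.flatnonzero(f380 <= 0)
    if nonpos.size:
        raise ValidationError(
            f"F380 non-positive at sample index {int(nonpos[0])}; cannot form ratio"
        )
    return RatioTrace(
        time=trace.time.copy(),
        signal=f340 / f380,
        kind="ratio",
        provenance=str(trace.meta.get("cell_id", "")),
        sampling_rate=trace.sampling_rate,
        stim_freq=trace.stim_freq,
        stim_times=None if trace.stim_times is None else trace.stim_times.copy(),
        events=list(trace.events),
        meta=dict(trace.meta),
    )


def compute_dff(trace: FluorescenceTrace, f0_window: tuple[float, float]) -> RatioTrace:
    """dF/F0 of a single-channel trace; F0 = mean F over ``[start, end)``."""
    if trace.modality != "single":
        raise ValidationError("compute_dff requires a single-channel trace")
    start, end = f0_window
    sel = (trace.time >= start) & (trace.time < end)
    if start < trace.time[0] - 0.5 / trace.sampling_rate or end > trace.time[-1] + 1.0 / trace.sampling_rate:
        raise ValidationError("f0_window extends outside the recording")
    if int(sel.sum()) < 10:
        raise ValidationError("f0_window must contain at least 10 samples")
    f = trace.channels["F"]
    f0 = float(np.mean(f[sel]))
    if f0 <= 0:
        raise ValidationError(f"baseline F0 must be positive, got {f0}")
    return RatioTrace(
        time=trace.time.copy(),
        signal=(f - f0) / f0,
        kind="dff",
        f0=f0,
        provenance=str(trace.meta.get("cell_id", "")),
        sampling_rate=trace.sampling_rate,
        stim_freq=trace.stim_freq,
        stim_times=None if trace.stim_times is None else trace.stim_times.copy(),
        events=list(trace.events),
        meta=dict(trace.meta),
    )


# ---------------------------------------------------------------------------
# oxygraph I/O


def read_oxygraph(path) -> OxygraphRecording:
    """Read an oxygraph CSV (time_s, o2_uM, safranine_uM, event).

    The ``event`` column is empty except at event onsets, where it holds
    ``LABEL`` or ``LABEL:dose`` (e.g. ``CACL2:0.3mM``).  Chamber volume,
    tissue mass and the free-Ca ladder come from the JSON sidecar.
    """
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("time_s", "o2_uM", "safranine_uM", "event"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    events = []
    for t, cell in zip(df["time_s"], df["event"]):
        s = str(cell).strip()
        if not s:
            continue
        label, _, dose = s.partition(":")
        events.append(OxygraphEvent(label=label, time=float(t), dose=dose))

    kwargs: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        kwargs["chamber_volume_ml"] = float(side.get("chamber_volume_ml", 2.0))
        kwargs["tissue_mass_mg"] = float(side.get("tissue_mass_mg", 2.0))
        if side.get("free_ca_ladder") is not None:
            kwargs["free_ca_ladder"] = {
                float(k): float(v) for k, v in side["free_ca_ladder"].items()
            }
        kwargs["meta"] = dict(side.get("meta", {}))
    return OxygraphRecording(
        time=df["time_s"].to_numpy(dtype=float),
        o2_conc=df["o2_uM"].to_numpy(dtype=float),
        safranine=df["safranine_uM"].to_numpy(dtype=float),
        events=events,
        **kwargs,
    )


def write_oxygraph(rec: OxygraphRecording, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    event_col = [""] * rec.time.size
    for e in rec.events:
        i = int(np.argmin(np.abs(rec.time - e.time)))
        event_col[i] = f"{e.label}:{e.dose}" if e.dose else e.label
    df = pd.DataFrame(
        {
            "time_s": rec.time,
            "o2_uM": rec.o2_conc,
            "safranine_uM": rec.safranine,
            "event": event_col,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    side = {
        "chamber_volume_ml": rec.chamber_volume_ml,
        "tissue_mass_mg": rec.tissue_mass_mg,
        "free_ca_ladder": rec.free_ca_ladder,
        "meta": rec.meta,
    }
    _sidecar_path(path).write_text(json.dumps(side, indent=1))
    return path


# ---------------------------------------------------------------------------
# image I/O


def read_image(path, pixel_size_nm: float | None = None, channel: int | None = None) -> LabelImage:
    """Read a TIFF frame; pixel size from argument or JSON sidecar.

    Multi-channel TIFFs (channel-first) require ``channel`` to select a plane.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    channel_label, meta = "", {}
    sc = _sidecar_path(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        if pixel_size_nm is None and side.get("pixel_size_nm") is not None:
            pixel_size_nm = float(side["pixel_size_nm"])
        channel_label = str(side.get("channel_label", ""))
        meta = dict(side.get("meta", {}))
    if pixel_size_nm is None:
        raise FormatError(f"pixel size missing for {path.name}: pass pixel_size_nm or a sidecar")
    if arr.ndim == 3:
        if channel is None:
            raise FormatError(f"{path.name} has {arr.shape[0]} channels; pass channel index")
        arr = arr[channel]
    return LabelImage(pixels=arr, pixel_size_nm=pixel_size_nm, channel_label=channel_label, meta=meta)


def write_image(img: LabelImage, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, img.pixels)  # dtype preserved so round trips are lossless
    _sidecar_path(path).write_text(
        json.dumps(
            {"pixel_size_nm": img.pixel_size_nm, "channel_label": img.channel_label, "meta": img.meta},
            indent=1,
        )
    )
    return path
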