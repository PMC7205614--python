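"""FCS 3.0 I/O and the compensation → ArcSinh pipeline.

All registration arithmetic happens on ArcSinh-transformed, compensated
intensities.  This module owns the :class:`Sample` container and the state
machine ``raw → compensated → transformed`` (and back), plus reading and
writing list-mode FCS 3.0 files ($DATATYPE F, float32).

Scatter channels (FSC*/SSC*/Time) are never compensated and are linearly
rescaled — rather than ArcSinh-transformed — so that they live on a scale
comparable to transformed fluorescence values.
"""

from __future__ import annotations

import re
import struct
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Sample",
    "SpilloverMatrix",
    "FCSParseError",
    "UnsupportedFormatError",
    "read_fcs",
    "write_fcs",
    "compensate",
    "arcsinh_transform",
    "inverse_transform",
    "concatenate",
    "save_registered",
    "default_cofactors",
    "is_scatter_channel",
]

#: default ArcSinh cofactor for fluorescence channels (community convention)
FLUOR_COFACTOR = 150.0
#: default ArcSinh cofactor for mass-cytometry (metal isotope) channels
MASS_COFACTOR = 5.0
#: default linear divisor applied to scatter channels instead of ArcSinh
SCATTER_SCALE = 1.0e4

_SCATTER_RE = re.compile(r"^(FSC|SSC|TIME)", re.IGNORECASE)


class FCSParseError(ValueError):
    """Malformed FCS header or segment; message names the byte offset."""


class UnsupportedFormatError(ValueError):
    """FCS file uses a datatype/mode this reader does not support."""


def is_scatter_channel(name: str) -> bool:
    return bool(_SCATTER_RE.match(name))


@dataclass
class SpilloverMatrix:
    """Square spillover matrix over a subset of fluorescence channels."""

    matrix: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.channels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"spillover matrix shape {self.matrix.shape} does not match "
                f"{n} channels"
            )

    @classmethod
    def identity(cls, channels: list[str]) -> "SpilloverMatrix":
        return cls(np.eye(len(channels)), list(channels))

    def inverse(self) -> np.ndarray:
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("spillover matrix is singular")
        return np.linalg.inv(self.matrix)


@dataclass
class Sample:
    """Event × channel intensity matrix with channel metadata and provenance.

    ``transform_state`` moves only along raw → compensated → transformed
    (and back via :func:`inverse_transform`).
    """

    events: np.ndarray
    channels: list[str]
    markers: list[str | None] = None  # type: ignore[assignment]
    transform_state: str = "raw"
    cofactor_map: dict[str, float] = field(default_factory=dict)
    source_id: str = ""
    spillover: SpilloverMatrix | None = None
    event_sources: np.ndarray | None = None
    keywords: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.atleast_2d(np.asarray(self.events, dtype=float))
        if self.events.size == 0:
            self.events = self.events.reshape(0, len(self.channels))
        if self.events.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.events.shape[1]} event columns but "
                f"{len(self.channels)} channel names"
            )
        if self.markers is None:
            self.markers = [None] * len(self.channels)
        if np.isnan(self.events).any():
            raise ValueError("event matrix contains missing values")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return self.events.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in sample {self.source_id!r}")

    def scatter_channels(self) -> list[str]:
        return [c for c in self.channels if is_scatter_channel(c)]

    def fluorescence_channels(self) -> list[str]:
        return [c for c in self.channels if not is_scatter_channel(c)]

    def copy(self) -> "Sample":
        return replace(
            self,
            events=self.events.copy(),
            channels=list(self.channels),
            markers=list(self.markers),
            cofactor_map=dict(self.cofactor_map),
            keywords=dict(self.keywords),
            event_sources=None if self.event_sources is None else self.event_sources.copy(),
        )


def default_cofactors(sample: Sample, mass: bool = False) -> dict[str, float]:
    """Per-channel ArcSinh cofactors: 150 (fluorescence) or 5 (mass)."""
    cf = MASS_COFACTOR if mass else FLUOR_COFACTOR
    return {c: cf for c in sample.fluorescence_channels()}


# ---------------------------------------------------------------------------
# FCS 3.0 reading


def _parse_text_segment(raw: bytes, offset: int) -> dict[str, str]:
    if not raw:
        raise FCSParseError(f"empty TEXT segment at offset {offset}")
    delim = raw[:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    # Escaped delimiters (doubled) show up as empty parts; rejoin them.
    fields: list[str] = []
    i = 0
    while i < len(parts):
        part = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == b"" and i + 2 < len(parts):
            part = part + delim + parts[i + 2]
            i += 2
        fields.append(part.decode("latin-1"))
        i += 1
    kv = {}
    for j in range(0, len(fields) - 1, 2):
        kv[fields[j].strip().upper()] = fields[j + 1]
    return kv


def _parse_spillover(value: str) -> SpilloverMatrix | None:
    tokens = [t.strip() for t in value.split(",")]
    try:
        n = int(tokens[0])
    except (ValueError, IndexError):
        return None
    names = tokens[1 : 1 + n]
    vals = [float(t) for t in tokens[1 + n : 1 + n + n * n]]
    if len(vals) != n * n:
        return None
    return SpilloverMatrix(np.array(vals).reshape(n, n), names)


def read_fcs(path) -> Sample:
    """Read a list-mode FCS 2.0/3.0/3.1 file into a raw-scale :class:`Sample`.

    Supports $DATATYPE F (float32) and D (float64), $MODE L, and spillover
    stored under $SPILLOVER, SPILL or $COMP.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FCSParseError(f"file too short ({len(blob)} bytes) for an FCS header at offset 0")
    version = blob[:6].decode("latin-1", "replace")
    if not version.startswith("FCS"):
        raise FCSParseError(f"bad magic {version!r} at offset 0; not an FCS file")
    if version not in ("FCS2.0", "FCS3.0", "FCS3.1"):
        raise UnsupportedFormatError(f"unsupported FCS version {version!r}")

    def _hdr_int(lo: int, hi: int) -> int:
        txt = blob[lo:hi].decode("latin-1").strip()
        if not txt:
            return 0
        try:
            return int(txt)
        except ValueError:
            raise FCSParseError(f"non-numeric header field at offset {lo}: {txt!r}")

    text_beg, text_end = _hdr_int(10, 18), _hdr_int(18, 26)
    data_beg, data_end = _hdr_int(26, 34), _hdr_int(34, 42)
    if text_end <= text_beg:
        raise FCSParseError(f"invalid TEXT segment bounds at offset 10: {text_beg}..{text_end}")
    kw = _parse_text_segment(blob[text_beg : text_end + 1], text_beg)

    if data_beg == 0 or data_end == 0:
        data_beg = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    tot = int(kw["$TOT"])
    if tot > 0 and data_end <= data_beg:
        raise FCSParseError(f"invalid DATA segment bounds at offset 26: {data_beg}..{data_end}")

    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise UnsupportedFormatError(f"$MODE {mode!r} not supported (list mode only)")
    datatype = kw.get("$DATATYPE", "").upper()
    if datatype not in ("F", "D"):
        raise UnsupportedFormatError(f"$DATATYPE {datatype!r} not supported (F or D only)")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    npdt = np.dtype(f"{endian}f4" if datatype == "F" else f"{endian}f8")

    par = int(kw["$PAR"])
    channels = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, par + 1)]
    markers = [kw.get(f"$P{i}S") for i in range(1, par + 1)]

    raw = blob[data_beg : data_end + 1]
    need = tot * par * npdt.itemsize
    if len(raw) < need:
        raise FCSParseError(
            f"DATA segment at offset {data_beg} holds {len(raw)} bytes, "
            f"need {need} for {tot}x{par} events"
        )
    events = np.frombuffer(raw[:need], dtype=npdt).reshape(tot, par).astype(float)

    spill = None
    for key in ("$SPILLOVER", "SPILL", "$COMP"):
        if key in kw:
            spill = _parse_spillover(kw[key])
            if spill is not None:
                break

    state = "raw"
    if kw.get("CYTOREG_STATE", "").lower() == "compensated":
        state = "compensated"
    return Sample(
        events=events,
        channels=channels,
        markers=markers,
        transform_state=state,
        source_id=str(path),
        spillover=spill,
        keywords=kw,
    )


# ---------------------------------------------------------------------------
# FCS 3.0 writing


def _spillover_keyword(spill: SpilloverMatrix) -> str:
    vals = ",".join(f"{v:g}" for v in spill.matrix.ravel())
    return f"{len(spill.channels)},{','.join(spill.channels)},{vals}"


def write_fcs(sample: Sample, path, extra_keywords: dict[str, str] | None = None) -> None:
    """Write a compensated, linear-scale sample as FCS 3.0 ($DATATYPE F).

    Refuses non-finite values.  The written TEXT segment records
    ``CYTOREG_STATE/compensated`` so round trips restore the state machine.
    """
    if sample.transform_state not in ("compensated", "raw"):
        raise ValueError(
            "write_fcs expects linear-scale events (raw or compensated); "
            f"got transform_state={sample.transform_state!r} — inverse_transform first"
        )
    ev = np.asarray(sample.events, dtype=np.float32)
    if ev.size and not np.isfinite(ev).all():
        bad = np.unique(np.nonzero(~np.isfinite(ev))[0])[:20]
        raise ValueError(f"non-finite values in events {bad.tolist()}; refusing to write")

    tot, par = ev.shape if ev.ndim == 2 else (0, len(sample.channels))
    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(tot),
        "$PAR": str(par),
        "CYTOREG_STATE": sample.transform_state,
    }
    for i, name in enumerate(sample.channels, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        rng = float(np.nanmax(ev[:, i - 1])) if tot else 0.0
        kw[f"$P{i}R"] = str(int(max(1024, np.ceil(abs(rng)) + 1)))
        marker = sample.markers[i - 1]
        if marker:
            kw[f"$P{i}S"] = marker
    if sample.spillover is not None:
        kw["$SPILLOVER"] = _spillover_keyword(sample.spillover)
    if extra_keywords:
        kw.update(extra_keywords)

    delim = b"/"

    def render(data_beg: int, data_end: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = str(data_beg)
        items["$ENDDATA"] = str(data_end)
        out = [delim]
        for k, v in items.items():
            vv = str(v).replace("/", "//") or " "
            out.append(k.encode("latin-1") + delim + vv.encode("latin-1") + delim)
        return b"".join(out)

    # offsets depend on TEXT length, which depends on the offsets: iterate.
    data_beg = data_end = 0
    for _ in range(4):
        text = render(data_beg, data_end)
        new_beg = 58 + len(text)
        new_end = new_beg + ev.nbytes - 1 if ev.nbytes else new_beg
        if (new_beg, new_end) == (data_beg, data_end):
            break
        data_beg, data_end = new_beg, new_end
    text = render(data_beg, data_end)
    text_beg, text_end = 58, 58 + len(text) - 1

    def fmt(n: int) -> bytes:
        s = str(n) if n <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.0    " + fmt(text_beg) + fmt(text_end) + fmt(data_beg) + fmt(data_end) + fmt(0) + fmt(0)
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(ev.astype("<f4").tobytes())


def save_registered(sample: Sample, path) -> None:
    """Inverse-transform a registered sample and write it as standard FCS 3.0.

    Values are stored compensated and linear, with an identity spillover and a
    keyword noting that compensation has already been applied, so downstream
    tools do not compensate twice.
    """
    if sample.transform_state != "transformed":
        raise ValueError("save_registered expects a transformed sample")
    linear = inverse_transform(sample)
    linear.spillover = SpilloverMatrix.identity(linear.fluorescence_channels())
    write_fcs(linear, path, extra_keywords={"CYTOREG_COMP_APPLIED": "TRUE"})


# ---------------------------------------------------------------------------
# Compensation and transform


def compensate(sample: Sample, spillover: SpilloverMatrix | None = None) -> Sample:
    """Apply spillover unmixing: events ← events · spillover⁻¹ (fluorescence only)."""
    if sample.transform_state != "raw":
        raise ValueError(f"compensate requires raw events, got {sample.transform_state!r}")
    spill = spillover if spillover is not None else sample.spillover
    out = sample.copy()
    if spill is not None:
        missing = [c for c in spill.channels if c not in sample.channels]
        if missing:
            raise ValueError(f"spillover channels absent from sample: {missing}")
        idx = [sample.channel_index(c) for c in spill.channels]
        out.events[:, idx] = sample.events[:, idx] @ spill.inverse()
    out.transform_state = "compensated"
    return out


def arcsinh_transform(
    sample: Sample,
    cofactor_map: dict[str, float] | None = None,
    scatter_scale: float = SCATTER_SCALE,
) -> Sample:
    """Per-channel x' = asinh(x / cofactor); scatter channels divided by
    ``scatter_scale`` instead."""
    if sample.transform_state != "compensated":
        raise ValueError(
            f"arcsinh_transform requires compensated events, got {sample.transform_state!r}"
        )
    cof = dict(default_cofactors(sample))
    if cofactor_map:
        cof.update(cofactor_map)
    for c, v in cof.items():
        if v <= 0:
            raise ValueError(f"nonpositive cofactor {v} for channel {c!r}")
    if scatter_scale <= 0:
        raise ValueError("scatter_scale must be positive")
    out = sample.copy()
    for j, c in enumerate(sample.channels):
        if is_scatter_channel(c):
            out.events[:, j] = sample.events[:, j] / scatter_scale
        else:
            out.events[:, j] = np.arcsinh(sample.events[:, j] / cof[c])
    out.cofactor_map = cof
    out.keywords["CYTOREG_SCATTER_SCALE"] = str(scatter_scale)
    out.transform_state = "transformed"
    return out


def inverse_transform(sample: Sample) -> Sample:
    """Undo :func:`arcsinh_transform`, returning compensated linear events."""
    if sample.transform_state != "transformed":
        raise ValueError(
            f"inverse_transform requires transformed events, got {sample.transform_state!r}"
        )
    scatter_scale = float(sample.keywords.get("CYTOREG_SCATTER_SCALE", SCATTER_SCALE))
    out = sample.copy()
    for j, c in enumerate(sample.channels):
        if is_scatter_channel(c):
            out.events[:, j] = sample.events[:, j] * scatter_scale
        else:
            out.events[:, j] = np.sinh(sample.events[:, j]) * sample.cofactor_map[c]
    out.transform_state = "compensated"
    return out


# ---------------------------------------------------------------------------
# Consensus construction


def concatenate(samples: list[Sample], n_per_sample: int, seed: int,
                replace_events: bool = False) -> Sample:
    """Consensus sample: a seeded, per-input subsample of equal size.

    Used to build consensus references ("concatenation of multiple files")
    when no single sample contains all subpopulations, and batch consensus
    samples when internal standards are missing.
    """
    if not samples:
        raise ValueError("no samples to concatenate")
    channels = samples[0].channels
    states = {s.transform_state for s in samples}
    if len(states) > 1:
        raise ValueError(f"mixed transform states {sorted(states)}")
    for s in samples[1:]:
        if s.channels != channels:
            extra = sorted(set(s.channels) ^ set(channels))
            raise ValueError(f"channel mismatch between inputs: {extra}")
    rng = np.random.default_rng(seed)
    chunks, sources = [], []
    for s in samples:
        if n_per_sample > s.n_events and not replace_events:
            raise ValueError(
                f"n_per_sample={n_per_sample} exceeds {s.n_events} events in "
                f"{s.source_id!r}; pass replace_events=True to bootstrap"
            )
        idx = rng.choice(s.n_events, size=n_per_sample, replace=replace_events)
        chunks.append(s.events[idx])
        sources.extend([s.source_id] * n_per_sample)
    out = samples[0].copy()
    out.events = np.vstack(chunks)
    out.event_sources = np.array(sources)
    out.source_id = f"consensus({len(samples)}x{n_per_sample},seed={seed})"
    out.keywords["CYTOREG_CONSENSUS_SEED"] = str(seed)
    return out
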