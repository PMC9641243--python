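"""Event-table I/O, spillover compensation, manifests and run configuration.

Two on-disk encodings are supported: a plain CSV dialect (header row of
channel roles, one event per row, time in seconds) and FCS 3.0/3.1 with
float or integer data.  The FCS reader honors the $TIMESTEP keyword; when it
is absent the time channel is assumed to already be in seconds.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

REQUIRED_CHANNELS = ("Fluo4", "CD19", "IgD", "CD27", "CD25")

__all__ = [
    "SpilloverMatrix",
    "SchemaError",
    "FormatError",
    "REQUIRED_CHANNELS",
    "read_event_table",
    "write_event_table",
    "read_fcs",
    "write_fcs",
    "apply_compensation",
    "read_manifest",
    "load_config",
]


class SchemaError(ValueError):
    """A required channel is missing from an event table."""


class FormatError(ValueError):
    """The file cannot be parsed in any supported encoding."""


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square spillover matrix over named fluorescence channels.

    ``matrix[i, j]`` is the fraction of channel ``i``'s signal observed in
    channel ``j``; the diagonal is 1.  Compensation multiplies observed
    intensities by the inverse.
    """

    channels: tuple[str, ...]
    matrix: np.ndarray
    unit_diagonal: bool = True  # set False for derived matrices (e.g. inverses)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        k = len(self.channels)
        if m.shape != (k, k):
            raise ValueError("spillover matrix must be square over its channels")
        if self.unit_diagonal and not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover matrix diagonal must be 1")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, channels) -> "SpilloverMatrix":
        channels = tuple(channels)
        return cls(channels, np.eye(len(channels)))

    def inverse(self) -> np.ndarray:
        try:
            inv = np.linalg.inv(self.matrix)
        except np.linalg.LinAlgError as exc:
            raise ValueError("spillover matrix is singular") from exc
        return inv


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def write_event_table(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table in the CSV dialect (deterministic byte output)."""
    path = Path(path)
    events.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _resolve_channels(df: pd.DataFrame, channel_map: dict[str, str] | None):
    if channel_map:
        rename = {src: role for role, src in channel_map.items() if src in df.columns}
        df = df.rename(columns=rename)
    return df


def read_event_table(
    path: str | Path,
    channel_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read an event table from CSV or FCS, resolving instrument channel names.

    ``channel_map`` maps panel roles (``time``, ``Fluo4``, ``CD19``, ...) to
    the channel names used in the file.  Unknown extra channels are preserved.
    Raises :class:`SchemaError` naming any missing required channel and
    :class:`FormatError` for unparseable files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".fcs":
        df = read_fcs(path)
    else:
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc

    df = _resolve_channels(df, channel_map)
    missing = [c for c in ("time", *REQUIRED_CHANNELS) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required channel(s): {', '.join(missing)}")
    df = df.copy()
    df["time"] = df["time"].astype(float)
    df.attrs["sample_id"] = path.stem
    return df


# ---------------------------------------------------------------------------
# Minimal FCS 3.0 / 3.1 support
# ---------------------------------------------------------------------------

_DELIM = "/"


def write_fcs(events: pd.DataFrame, path: str | Path, timestep: float = 1.0) -> None:
    """Write numeric columns of an event table as a single-precision FCS 3.1 file.

    The time column is stored as ``time / timestep`` ticks with a $TIMESTEP
    keyword, so a round trip through :func:`read_fcs` restores seconds.
    """
    cols = [c for c in events.columns if pd.api.types.is_numeric_dtype(events[c])]
    data = events[cols].to_numpy(dtype="<f4").copy()
    if "time" in cols and timestep != 1.0:
        data[:, cols.index("time")] /= timestep
    n_events, n_par = data.shape

    kw: dict[str, str] = {
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
        "$TIMESTEP": repr(timestep),
    }
    for i, name in enumerate(cols, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"

    databytes = data.tobytes()

    def render(begin_data, end_data):
        items = dict(kw)
        items["$BEGINDATA"] = str(begin_data)
        items["$ENDDATA"] = str(end_data)
        items["$BEGINANALYSIS"] = "0"
        items["$ENDANALYSIS"] = "0"
        text = _DELIM + _DELIM.join(
            f"{k}{_DELIM}{v}" for k, v in sorted(items.items())
        ) + _DELIM
        return text.encode("ascii")

    text_start = 58
    # iterate: text length depends on the data offsets it encodes
    begin_data = 0
    for _ in range(5):
        text = render(begin_data, begin_data + len(databytes) - 1)
        new_begin = text_start + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text = render(begin_data, begin_data + len(databytes) - 1)
    text_end = text_start + len(text) - 1
    end_data = begin_data + len(databytes) - 1

    header = (
        f"FCS3.1    "
        f"{text_start:>8d}{text_end:>8d}"
        f"{begin_data if begin_data <= 99_999_999 else 0:>8d}"
        f"{end_data if end_data <= 99_999_999 else 0:>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == 58

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(databytes)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    txt = raw.decode("latin-1")
    delim = txt[0]
    parts = txt[1:].split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 list-mode file (float32/float64/integer data)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 58 or not raw[:3] == b"FCS":
        raise FormatError(f"{path} is not an FCS file")
    version = raw[3:10].decode("ascii", "replace").strip()
    if not version.startswith("3"):
        raise FormatError(f"unsupported FCS version {version!r}")

    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise FormatError("malformed FCS header offsets") from exc
    kw = _parse_text_segment(raw[text_start : text_end + 1])

    def offset(primary, begin_key):
        try:
            return int(raw[primary[0] : primary[1]])
        except ValueError:
            return int(kw.get(begin_key, 0))

    data_start = offset((26, 34), "$BEGINDATA")
    data_end = offset((34, 42), "$ENDDATA")
    if data_start == 0:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    widths = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    names = [
        kw.get(f"$P{i}S") or kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)
    ]

    blob = raw[data_start : data_end + 1]
    if datatype == "F":
        arr = np.frombuffer(blob, dtype=f"{order}f4", count=n_tot * n_par)
    elif datatype == "D":
        arr = np.frombuffer(blob, dtype=f"{order}f8", count=n_tot * n_par)
    elif datatype == "I":
        if len(set(widths)) != 1 or widths[0] not in (16, 32):
            raise FormatError("only uniform 16/32-bit integer FCS data supported")
        arr = np.frombuffer(
            blob, dtype=f"{order}u{widths[0] // 8}", count=n_tot * n_par
        )
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")
    data = arr.reshape(n_tot, n_par).astype(float)

    df = pd.DataFrame(data, columns=names)
    # honor $TIMESTEP when present; otherwise the channel is taken as seconds
    time_cols = [c for c in df.columns if c.lower() == "time"]
    if time_cols:
        ts = float(kw.get("$TIMESTEP", "1.0"))
        df[time_cols[0]] = df[time_cols[0]] * ts
        if time_cols[0] != "time":
            df = df.rename(columns={time_cols[0]: "time"})
    return df


# ---------------------------------------------------------------------------
# Compensation
# ---------------------------------------------------------------------------


def apply_compensation(events: pd.DataFrame, m: SpilloverMatrix) -> pd.DataFrame:
    """Replace fluorescence channels by observed intensities times ``m``-inverse.

    The time column and channels outside ``m`` are untouched.
    """
    missing = [c for c in m.channels if c not in events.columns]
    if missing:
        raise SchemaError(f"compensation channels absent from events: {missing}")
    inv = m.inverse()
    out = events.copy()
    observed = events[list(m.channels)].to_numpy(dtype=float)
    out[list(m.channels)] = observed @ inv
    return out


# ---------------------------------------------------------------------------
# Manifest and config
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV: sample_id, group, subject_id, path, ...

    Relative ``path`` entries are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"sample_id", "group", "subject_id", "path"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"manifest missing column(s): {sorted(missing)}")
    base = path.parent
    df["path"] = [
        str(p) if Path(p).is_absolute() else str(base / p) for p in df["path"]
    ]
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("configuration must be a YAML mapping")
    return cfg
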