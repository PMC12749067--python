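"""Containers and I/O for multistatic microwave S21 scans.

A scan is the complex forward-transmission (S21) response of one breast,
measured by a vector network analyser over a rotating transmitter/receiver
pair: ``n_tx`` transmitter positions, ``n_rx`` receiver positions per
transmitter and ``n_freq`` frequency points, stored as an
``(n_tx * n_rx, n_freq)`` complex matrix whose rows are transmitter-major
(each consecutive group of ``n_rx`` rows shares one transmitter angle).

Two on-disk containers are provided: a line-oriented text format
(``# key=value`` header, then one ``tx,rx,f,re,im`` record per matrix cell)
and a binary ``.npz`` container holding the matrix plus a JSON metadata
block.  No standard interchange format exists for multistatic scans of this
shape; Touchstone files are per-port-pair and would fragment one scan into
hundreds of files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GeometryError",
    "ScanGeometry",
    "S21Scan",
    "TxBlock",
    "LabelTable",
    "DENSITY_LABELS",
    "HEALTH_LABELS",
    "DEFAULT_TX_ANGLES_DEG",
    "split_by_transmitter",
    "read_scan",
    "write_scan",
    "read_labels",
    "write_labels",
]

FORMAT_VERSION = 1

DENSITY_LABELS = ("LD", "HD", "unknown")
HEALTH_LABELS = ("healthy", "non-healthy", "unknown")

# Five transmitter pairs 72 degrees apart, the members of each pair 9 degrees
# apart -- the 10-position rotation pattern of the scanning prototype.
DEFAULT_TX_ANGLES_DEG = (0.0, 9.0, 72.0, 81.0, 144.0, 153.0, 216.0, 225.0, 288.0, 297.0)


class FormatError(ValueError):
    """A scan or label file violates its declared container format."""


class GeometryError(ValueError):
    """Data are inconsistent with the declared scan geometry."""


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry of a multistatic scan.

    Defaults describe the clinical prototype: 10 transmitter angles,
    80 receiver positions every 4.5 degrees (a full 360 degree sweep) and
    1601 frequency points from 1 GHz to 9 GHz in 5 MHz steps.
    """

    n_tx: int = 10
    n_rx: int = 80
    rx_step_deg: float = 4.5
    tx_angles_deg: tuple[float, ...] = DEFAULT_TX_ANGLES_DEG
    f_start_hz: float = 1.0e9
    f_step_hz: float = 5.0e6
    n_freq: int = 1601

    def __post_init__(self) -> None:
        object.__setattr__(self, "tx_angles_deg", tuple(float(a) for a in self.tx_angles_deg))
        if self.n_tx < 1 or self.n_rx < 1 or self.n_freq < 1:
            raise GeometryError("n_tx, n_rx and n_freq must all be >= 1")
        if len(self.tx_angles_deg) != self.n_tx:
            raise GeometryError(
                f"{len(self.tx_angles_deg)} transmitter angles given for n_tx={self.n_tx}"
            )
        angles = self.tx_angles_deg
        if sorted(set(angles)) != list(angles):
            raise GeometryError("tx_angles_deg must be sorted and unique")
        if any(a < 0.0 or a >= 360.0 for a in angles):
            raise GeometryError("tx_angles_deg must lie in [0, 360)")
        if abs(self.rx_step_deg * self.n_rx - 360.0) > 1e-6:
            raise GeometryError("receiver positions must cover 360 degrees: rx_step_deg * n_rx != 360")
        if self.f_step_hz <= 0 or self.f_start_hz <= 0:
            raise GeometryError("frequency grid must have positive start and step")

    @property
    def n_pairs(self) -> int:
        return self.n_tx * self.n_rx

    @property
    def frequencies_hz(self) -> np.ndarray:
        return self.f_start_hz + self.f_step_hz * np.arange(self.n_freq)

    @property
    def rx_angles_deg(self) -> np.ndarray:
        return self.rx_step_deg * np.arange(self.n_rx)

    def freq_index(self, f_hz: float) -> int:
        """Column index of frequency ``f_hz``; raises if off-grid."""
        x = (f_hz - self.f_start_hz) / self.f_step_hz
        i = int(round(x))
        if abs(x - i) > 1e-6 or not 0 <= i < self.n_freq:
            raise GeometryError(f"frequency {f_hz} Hz is not on the scan grid")
        return i

    def freq_indices(self, f_hz) -> np.ndarray:
        """Vectorized :meth:`freq_index` for an array of frequencies."""
        x = (np.asarray(f_hz, dtype=float) - self.f_start_hz) / self.f_step_hz
        i = np.rint(x).astype(np.int64)
        bad = (np.abs(x - i) > 1e-6) | (i < 0) | (i >= self.n_freq)
        if np.any(bad):
            f_bad = np.atleast_1d(np.asarray(f_hz, dtype=float))[np.flatnonzero(bad)[0]]
            raise GeometryError(f"frequency {f_bad} Hz is not on the scan grid")
        return i

    def to_dict(self) -> dict:
        return {
            "n_tx": self.n_tx,
            "n_rx": self.n_rx,
            "rx_step_deg": self.rx_step_deg,
            "tx_angles_deg": list(self.tx_angles_deg),
            "f_start_hz": self.f_start_hz,
            "f_step_hz": self.f_step_hz,
            "n_freq": self.n_freq,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            n_tx=int(d["n_tx"]),
            n_rx=int(d["n_rx"]),
            rx_step_deg=float(d["rx_step_deg"]),
            tx_angles_deg=tuple(float(a) for a in d["tx_angles_deg"]),
            f_start_hz=float(d["f_start_hz"]),
            f_step_hz=float(d["f_step_hz"]),
            n_freq=int(d["n_freq"]),
        )


@dataclass
class S21Scan:
    """One breast scan: complex S21 matrix plus geometry and labels."""

    matrix: np.ndarray
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    sample_id: str = ""
    density_label: str = "unknown"
    health_label: str = "unknown"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.complex128)
        expected = (self.geometry.n_pairs, self.geometry.n_freq)
        if self.matrix.shape != expected:
            raise GeometryError(f"matrix shape {self.matrix.shape} != geometry shape {expected}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("scan matrix contains non-finite entries")
        if self.density_label not in DENSITY_LABELS:
            raise ValueError(f"unknown density label {self.density_label!r}")
        if self.health_label not in HEALTH_LABELS:
            raise ValueError(f"unknown health label {self.health_label!r}")


@dataclass
class TxBlock:
    """Per-transmitter sub-matrix: ``n_rx`` receiver rows by frequency columns.

    ``tx_index`` is 0-based.  ``column_freqs_hz`` tracks which frequency each
    column corresponds to, so sub-band-sliced blocks stay self-describing.
    """

    values: np.ndarray
    tx_index: int
    column_freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.column_freqs_hz = np.asarray(self.column_freqs_hz, dtype=float)
        if self.values.ndim != 2:
            raise GeometryError("TxBlock values must be a 2-D matrix")
        if self.tx_index < 0:
            raise GeometryError("tx_index must be >= 0")
        if self.column_freqs_hz.shape != (self.values.shape[1],):
            raise GeometryError("one column frequency required per column")
        if self.values.shape[1] > 1 and not np.all(np.diff(self.column_freqs_hz) > 0):
            raise GeometryError("column frequencies must be strictly increasing")

    @property
    def n_rx(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


def split_by_transmitter(scan: S21Scan) -> list[TxBlock]:
    """Restructure the scan matrix into one block per transmitter position.

    Block ``t`` holds rows ``t*n_rx .. (t+1)*n_rx - 1``; concatenating the
    blocks in order reproduces the scan matrix exactly.
    """
    n_rx = scan.geometry.n_rx
    if scan.matrix.shape[0] % n_rx != 0:
        raise GeometryError("scan row count is not divisible by n_rx")
    freqs = scan.geometry.frequencies_hz
    return [
        TxBlock(values=scan.matrix[t * n_rx : (t + 1) * n_rx], tx_index=t, column_freqs_hz=freqs)
        for t in range(scan.geometry.n_tx)
    ]


# ---------------------------------------------------------------------------
# scan containers
# ---------------------------------------------------------------------------


def _scan_meta(scan: S21Scan) -> dict:
    meta = scan.geometry.to_dict()
    meta.update(
        format_version=FORMAT_VERSION,
        sample_id=scan.sample_id,
        density=scan.density_label,
        health=scan.health_label,
    )
    return meta


def write_scan(scan: S21Scan, path: str | Path, format: str = "binary") -> None:
    """Write a scan to ``path`` in the text or binary container format."""
    path = Path(path)
    if format == "binary":
        with open(path, "wb") as fh:
            np.savez(fh, matrix=scan.matrix, meta=json.dumps(_scan_meta(scan)))
    elif format == "text":
        geom = scan.geometry
        with open(path, "w") as fh:
            for key, val in _scan_meta(scan).items():
                if key == "tx_angles_deg":
                    val = ",".join(f"{a:.17g}" for a in val)
                fh.write(f"# {key}={val}\n")
            for t in range(geom.n_tx):
                for r in range(geom.n_rx):
                    row = scan.matrix[t * geom.n_rx + r]
                    for f in range(geom.n_freq):
                        z = row[f]
                        fh.write(f"{t},{r},{f},{z.real:.17g},{z.imag:.17g}\n")
    else:
        raise ValueError(f"unknown scan format {format!r}")


def _parse_text_header(path: Path) -> dict:
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" not in body:
                raise FormatError(f"malformed header line: {line.strip()!r}")
            key, val = body.split("=", 1)
            header[key.strip()] = val.strip()
    required = ("n_tx", "n_rx", "rx_step_deg", "tx_angles_deg", "f_start_hz", "f_step_hz", "n_freq")
    missing = [k for k in required if k not in header]
    if missing:
        raise FormatError(f"scan header missing geometry field(s): {', '.join(missing)}")
    return header


def _read_text_scan(path: Path) -> S21Scan:
    header = _parse_text_header(path)
    geom = ScanGeometry.from_dict(
        {**header, "tx_angles_deg": [a for a in header["tx_angles_deg"].split(",") if a != ""]}
    )
    try:
        data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"malformed scan record in {path}: {exc}") from exc
    n_cells = geom.n_pairs * geom.n_freq
    if data.size == 0:
        raise FormatError(f"scan file {path} declares {n_cells} cells but contains none")
    if data.shape[1] != 5:
        raise FormatError("scan records must have 5 fields: tx,rx,f,re,im")
    tx = data[:, 0].astype(np.int64)
    rx = data[:, 1].astype(np.int64)
    fi = data[:, 2].astype(np.int64)
    bad = (tx < 0) | (tx >= geom.n_tx) | (rx < 0) | (rx >= geom.n_rx) | (fi < 0) | (fi >= geom.n_freq)
    if np.any(bad):
        b = int(np.flatnonzero(bad)[0])
        raise GeometryError(
            f"record (tx={tx[b]}, rx={rx[b]}, f={fi[b]}) is outside the declared geometry"
        )
    flat = (tx * geom.n_rx + rx) * geom.n_freq + fi
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    dup = np.flatnonzero(np.diff(sorted_flat) == 0)
    if dup.size:
        b = int(order[dup[0] + 1])
        raise FormatError(f"duplicate cell (tx={tx[b]}, rx={rx[b]}, f={fi[b]})")
    if flat.size != n_cells:
        present = np.zeros(n_cells, dtype=bool)
        present[flat] = True
        m = int(np.flatnonzero(~present)[0])
        t, rem = divmod(m, geom.n_rx * geom.n_freq)
        r, f = divmod(rem, geom.n_freq)
        raise FormatError(f"missing cell (tx={t}, rx={r}, f={f})")
    matrix = np.empty((geom.n_pairs, geom.n_freq), dtype=np.complex128)
    matrix.reshape(-1)[flat] = data[:, 3] + 1j * data[:, 4]
    return S21Scan(
        matrix=matrix,
        geometry=geom,
        sample_id=header.get("sample_id", ""),
        density_label=header.get("density", "unknown"),
        health_label=header.get("health", "unknown"),
    )


def _read_binary_scan(path: Path) -> S21Scan:
    with np.load(path, allow_pickle=False) as npz:
        if "matrix" not in npz or "meta" not in npz:
            raise FormatError(f"{path} is not a scan container (missing matrix/meta)")
        matrix = npz["matrix"]
        meta = json.loads(str(npz["meta"]))
    geom = ScanGeometry.from_dict(meta)
    if matrix.shape != (geom.n_pairs, geom.n_freq):
        raise GeometryError(
            f"stored matrix shape {matrix.shape} does not match declared geometry "
            f"({geom.n_pairs}, {geom.n_freq})"
        )
    return S21Scan(
        matrix=matrix,
        geometry=geom,
        sample_id=meta.get("sample_id", ""),
        density_label=meta.get("density", "unknown"),
        health_label=meta.get("health", "unknown"),
    )


def read_scan(path: str | Path, format: str = "binary") -> S21Scan:
    """Read a scan container written by :func:`write_scan`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "binary":
        return _read_binary_scan(path)
    if format == "text":
        return _read_text_scan(path)
    raise ValueError(f"unknown scan format {format!r}")


# ---------------------------------------------------------------------------
# label tables
# ---------------------------------------------------------------------------

LABEL_COLUMNS = ("sample_id", "density", "health")


@dataclass
class LabelTable:
    """Per-sample density and health labels."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LABEL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"label table missing column(s): {', '.join(missing)}")
        self.frame = self.frame.loc[:, list(LABEL_COLUMNS)].reset_index(drop=True)
        ids = self.frame["sample_id"].astype(str)
        dup = ids[ids.duplicated()]
        if not dup.empty:
            raise FormatError(f"duplicate sample_id {dup.iloc[0]!r}")
        bad_d = ~self.frame["density"].isin(DENSITY_LABELS)
        if bad_d.any():
            raise FormatError(f"unknown density label {self.frame['density'][bad_d].iloc[0]!r}")
        bad_h = ~self.frame["health"].isin(HEALTH_LABELS)
        if bad_h.any():
            raise FormatError(f"unknown health label {self.frame['health'][bad_h].iloc[0]!r}")

    def __len__(self) -> int:
        return len(self.frame)

    def lookup(self, sample_id: str) -> tuple[str, str]:
        row = self.frame[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["density"].iloc[0]), str(row["health"].iloc[0])

    @classmethod
    def from_records(cls, records) -> "LabelTable":
        return cls(pd.DataFrame(records, columns=list(LABEL_COLUMNS)))


def read_labels(path: str | Path) -> LabelTable:
    """Read a ``sample_id,density,health`` CSV into a :class:`LabelTable`."""
    frame = pd.read_csv(path, dtype=str, comment="#")
    return LabelTable(frame)


def write_labels(table: LabelTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# format_version={FORMAT_VERSION}\n")
        table.frame.to_csv(fh, index=False)
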