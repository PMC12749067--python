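"""DC-bias removal and 1 GHz sub-band selection on per-transmitter blocks.

The 1-9 GHz measurement band is divided into eight contiguous 1 GHz
sub-bands SB1..SB8.  Band b covers [b GHz, (b+1) GHz) -- half-open, so on the
canonical 1601-point grid each band holds 200 columns, except SB8 which also
receives the 9 GHz endpoint (201 columns).  A :class:`SubBandMask` selects a
subset of bands; its canonical printed form puts a space after the fourth
bit, e.g. ``"1011 1100"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .s21_io import GeometryError, TxBlock

__all__ = ["SubBandMask", "N_BANDS", "remove_dc_bias", "subband_slice", "band_column_indices"]

N_BANDS = 8
_BAND_EDGE_HZ = 1.0e9  # SB1 starts here; each band is 1 GHz wide


@dataclass(frozen=True)
class SubBandMask:
    """Selection of the eight 1 GHz sub-bands SB1..SB8."""

    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", tuple(bool(b) for b in self.bits))
        if len(self.bits) != N_BANDS:
            raise ValueError(f"a sub-band mask has exactly {N_BANDS} bits, got {len(self.bits)}")

    @classmethod
    def parse(cls, text: str) -> "SubBandMask":
        """Parse ``"1011 1100"`` or ``"10111100"``."""
        compact = text.replace(" ", "")
        if len(compact) != N_BANDS or set(compact) - {"0", "1"}:
            raise ValueError(f"invalid sub-band mask {text!r}")
        return cls(tuple(c == "1" for c in compact))

    @classmethod
    def from_bands(cls, bands) -> "SubBandMask":
        """Build from 1-based band numbers, e.g. ``[1, 3, 4, 5, 6]``."""
        bands = set(int(b) for b in bands)
        if not bands <= set(range(1, N_BANDS + 1)):
            raise ValueError(f"band numbers must be in 1..{N_BANDS}")
        return cls(tuple(b in bands for b in range(1, N_BANDS + 1)))

    @classmethod
    def all_bands(cls) -> "SubBandMask":
        return cls((True,) * N_BANDS)

    @classmethod
    def coerce(cls, value) -> "SubBandMask":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            return cls.parse(value)
        return cls(tuple(value))

    @property
    def selected_bands(self) -> tuple[int, ...]:
        """1-based numbers of the selected bands, ascending."""
        return tuple(b + 1 for b, on in enumerate(self.bits) if on)

    @property
    def n_selected(self) -> int:
        return sum(self.bits)

    def to_string(self) -> str:
        s = "".join("1" if b else "0" for b in self.bits)
        return s[:4] + " " + s[4:]

    def __str__(self) -> str:
        return self.to_string()


def remove_dc_bias(block: TxBlock) -> TxBlock:
    """Subtract each receiver row's mean across frequency.

    Removes the receiver-wise average (uninformative background / system
    bias), so every row has exactly zero complex mean afterwards.  The
    operation is idempotent.
    """
    if block.n_cols < 2:
        raise ValueError("DC removal needs at least 2 frequency columns per row")
    centred = block.values - block.values.mean(axis=1, keepdims=True)
    return TxBlock(values=centred, tx_index=block.tx_index, column_freqs_hz=block.column_freqs_hz)


def band_column_indices(column_freqs_hz: np.ndarray) -> dict[int, np.ndarray]:
    """Map 1-based band number -> column indices, for a full 1-9 GHz grid.

    Band b selects f in [b GHz, (b+1) GHz); the 9 GHz endpoint belongs
    to SB8.
    """
    f = np.asarray(column_freqs_hz, dtype=float)
    if f.size == 0 or abs(f[0] - _BAND_EDGE_HZ) > 1e-3 or abs(f[-1] - 9.0e9) > 1e-3:
        raise GeometryError("sub-band slicing requires columns covering the full 1-9 GHz grid")
    band_of = np.minimum((f / 1.0e9).astype(int), N_BANDS)
    return {b: np.flatnonzero(band_of == b) for b in range(1, N_BANDS + 1)}


def subband_slice(block: TxBlock, mask: SubBandMask) -> list[TxBlock]:
    """Slice a full-band block into one block per selected sub-band, ascending."""
    mask = SubBandMask.coerce(mask)
    if mask.n_selected == 0:
        raise ValueError("empty sub-band mask")
    indices = band_column_indices(block.column_freqs_hz)
    out = []
    for b in mask.selected_bands:
        cols = indices[b]
        out.append(
            TxBlock(
                values=block.values[:, cols],
                tx_index=block.tx_index,
                column_freqs_hz=block.column_freqs_hz[cols],
            )
        )
    return out
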