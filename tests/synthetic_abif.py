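"""Minimal synthetic ABIF (.ab1) writer for exercising the optional ABI reader.

Real chromatogram files are binary and cannot be shipped; this helper
constructs the smallest ABIF container (header, data blocks, directory)
that carries the four processed channels (DATA9-12), the filter-wheel
order (FWO_1), basecalls (PBAS2), and peak locations (PLOC2).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_DIR_ENTRY = struct.Struct(">4sI2H3I")  # name, number, etype, esize, nelem, dsize, offset
_HEAD = struct.Struct(">H4sI2H3I")


def write_synthetic_abif(
    path: str | Path,
    channels: dict[str, np.ndarray],
    called_bases: str,
    peak_positions: np.ndarray,
    channel_order: str = "GATC",
    omit: tuple[str, ...] = (),
) -> None:
    """Write an ABIF file with the given channels, basecalls and peaks.

    ``omit`` drops named tags (e.g. ``("PLOC2",)``) to produce malformed
    files for error-path tests.
    """
    entries: list[tuple[bytes, int, int, int, int, bytes]] = []

    def add(name: str, number: int, etype: int, esize: int, nelem: int, data: bytes) -> None:
        tag = f"{name}{number}"
        if tag in omit:
            return
        entries.append((name.encode(), number, etype, esize, nelem, data))

    add("FWO_", 1, 2, 1, 4, channel_order.encode())
    for i, base in enumerate(channel_order):
        arr = np.asarray(channels[base], dtype=">i2")
        add("DATA", 9 + i, 4, 2, len(arr), arr.tobytes())
    add("PBAS", 2, 2, 1, len(called_bases), called_bases.encode())
    ploc = np.asarray(peak_positions, dtype=">i2")
    add("PLOC", 2, 4, 2, len(ploc), ploc.tobytes())

    header_size = 4 + _HEAD.size  # "ABIF" marker + header struct
    blob = bytearray()
    offsets: list[int] = []
    for _, _, _, _, _, data in entries:
        if len(data) > 4:
            offsets.append(header_size + len(blob))
            blob.extend(data)
        else:
            offsets.append(-1)  # inline
    dir_offset = header_size + len(blob)

    out = bytearray()
    out += b"ABIF"
    out += _HEAD.pack(101, b"tdir", 1, 1023, 28, len(entries), 28 * len(entries), dir_offset)
    out += blob
    for (name, number, etype, esize, nelem, data), off in zip(entries, offsets):
        if off < 0:
            inline = data.ljust(4, b"\x00")
            out += struct.pack(">4sI2H2I", name, number, etype, esize, nelem, len(data))
            out += inline
            out += struct.pack(">I", 0)
        else:
            out += _DIR_ENTRY.pack(name, number, etype, esize, nelem, len(data), off)
            out += struct.pack(">I", 0)
    Path(path).write_bytes(bytes(out))
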