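"""Four-channel sequencing-trace data model and on-disk formats.

The primary on-disk format is a documented plain-text TSV dialect (no
binary chromatogram is required anywhere in the pipeline); standard ABI
``.ab1`` files are supported as an optional reader behind the same
:class:`TraceSignal` contract, via Biopython's ABIF parser.

TSV dialect
-----------
A UTF-8, tab-separated file with two blocks::

    pos	A	C	G	T
    0	12.0	3.0	800.5	0.0
    ...
    # basecalls
    0	G	5
    1	T	15
    ...

The first block holds one row per scan index with the four channel
intensities; the ``# basecalls`` block holds one row per called base with
its 0-based basecall index, base label, and 0-based peak position into the
intensity arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import TraceFormatError, ValidationError

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class TraceSignal:
    """A four-channel fluorescence trace with called peak positions.

    Parameters
    ----------
    intensities
        Array of shape ``(4, L)``; row order follows ``channel_order``.
        All values must be >= 0.
    called_bases
        One base label per called base.
    peak_positions
        Strictly increasing 0-based indices into ``[0, L)``, one per
        called base.
    channel_order
        The four base labels naming the intensity rows (default A,C,G,T).
    """

    intensities: np.ndarray
    called_bases: tuple[str, ...]
    peak_positions: np.ndarray
    channel_order: tuple[str, ...] = BASES

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        object.__setattr__(self, "called_bases", tuple(self.called_bases))
        object.__setattr__(
            self, "peak_positions", np.asarray(self.peak_positions, dtype=int)
        )
        object.__setattr__(self, "channel_order", tuple(self.channel_order))
        self.validate()

    def validate(self) -> None:
        if sorted(self.channel_order) != sorted(BASES):
            raise ValidationError(
                f"channel_order must be a permutation of {BASES}, got {self.channel_order}"
            )
        if self.intensities.ndim != 2 or self.intensities.shape[0] != 4:
            raise ValidationError(
                f"intensities must have shape (4, L), got {self.intensities.shape}"
            )
        if self.length == 0:
            raise ValidationError("trace length must be > 0")
        if np.any(self.intensities < 0):
            raise ValidationError("negative intensity values are not allowed")
        if len(self.peak_positions) != len(self.called_bases):
            raise ValidationError(
                "peak_positions and called_bases must have equal length "
                f"({len(self.peak_positions)} vs {len(self.called_bases)})"
            )
        if len(self.peak_positions) > 0:
            if self.peak_positions.min() < 0 or self.peak_positions.max() >= self.length:
                raise ValidationError("peak positions out of range [0, L)")
            if np.any(np.diff(self.peak_positions) <= 0):
                raise ValidationError("peak positions must be strictly increasing")
        for b in self.called_bases:
            if b not in BASES and b != "N":
                raise ValidationError(f"unknown called base {b!r}")

    @property
    def length(self) -> int:
        """Number of scan indices L."""
        return self.intensities.shape[1]

    def channel(self, base: str) -> np.ndarray:
        """Return the intensity array for one base channel."""
        try:
            i = self.channel_order.index(base)
        except ValueError:
            raise ValidationError(f"no channel for base {base!r}") from None
        return self.intensities[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceSignal):
            return NotImplemented
        return (
            self.channel_order == other.channel_order
            and self.called_bases == other.called_bases
            and np.array_equal(self.peak_positions, other.peak_positions)
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass(frozen=True)
class SNPLocus:
    """Descriptor of the diagnostic SNP and its sequence context.

    ``flank_left`` and ``flank_right`` give the expected called bases on
    either side of the variable position; the SNP itself is a wildcard.
    """

    allele_primary: str
    allele_secondary: str
    flank_left: str
    flank_right: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.allele_primary == self.allele_secondary:
            raise ValidationError("SNP alleles must differ")
        for a in (self.allele_primary, self.allele_secondary):
            if a not in BASES:
                raise ValidationError(f"allele {a!r} is not a base")
        if not self.flank_left or not self.flank_right:
            raise ValidationError("flanks must be nonempty")


# ---------------------------------------------------------------------------
# TSV dialect


def write_trace(trace: TraceSignal, path: str | Path) -> None:
    """Write a trace in the TSV dialect. Refuses invalid traces."""
    trace.validate()
    path = Path(path)
    lines = ["pos\t" + "\t".join(trace.channel_order)]
    for i in range(trace.length):
        vals = "\t".join(repr(float(v)) for v in trace.intensities[:, i])
        lines.append(f"{i}\t{vals}")
    lines.append("# basecalls")
    for j, (base, pos) in enumerate(zip(trace.called_bases, trace.peak_positions)):
        lines.append(f"{j}\t{base}\t{int(pos)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_tsv(path: Path) -> TraceSignal:
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TraceFormatError(f"{path}: empty trace file")
    header = lines[0].split("\t")
    if len(header) != 5 or header[0] != "pos":
        raise TraceFormatError(
            f"{path}: header must be 'pos' plus 4 channel names, got {header!r}"
        )
    channel_order = tuple(header[1:])
    if sorted(channel_order) != sorted(BASES):
        raise TraceFormatError(
            f"{path}: channel columns must name the 4 bases, got {channel_order!r}"
        )
    rows: list[list[float]] = []
    basecalls: list[tuple[str, int]] = []
    in_basecalls = False
    for ln in lines[1:]:
        if ln.startswith("#"):
            if ln.strip() == "# basecalls":
                in_basecalls = True
                continue
            raise TraceFormatError(f"{path}: unexpected comment line {ln!r}")
        fields = ln.split("\t")
        if not in_basecalls:
            if len(fields) != 5:
                raise TraceFormatError(
                    f"{path}: intensity row needs 5 columns, got {ln!r}"
                )
            try:
                idx = int(fields[0])
                vals = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise TraceFormatError(f"{path}: bad intensity row {ln!r}") from exc
            if idx != len(rows):
                raise TraceFormatError(
                    f"{path}: scan indices must be consecutive from 0, got {ln!r}"
                )
            if any(v < 0 for v in vals):
                raise TraceFormatError(f"{path}: negative intensity in row {ln!r}")
            rows.append(vals)
        else:
            if len(fields) != 3:
                raise TraceFormatError(f"{path}: basecall row needs 3 columns, got {ln!r}")
            try:
                j = int(fields[0])
                base = fields[1]
                pos = int(fields[2])
            except ValueError as exc:
                raise TraceFormatError(f"{path}: bad basecall row {ln!r}") from exc
            if j != len(basecalls):
                raise TraceFormatError(
                    f"{path}: basecall indices must be consecutive from 0, got {ln!r}"
                )
            basecalls.append((base, pos))
    if not rows:
        raise TraceFormatError(f"{path}: no intensity rows")
    positions = [p for _, p in basecalls]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise TraceFormatError(f"{path}: peak positions are not strictly increasing")
    try:
        return TraceSignal(
            intensities=np.asarray(rows, dtype=float).T,
            called_bases=tuple(b for b, _ in basecalls),
            peak_positions=np.asarray(positions, dtype=int),
            channel_order=channel_order,
        )
    except ValidationError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# ABI (.ab1) dialect — optional, via Biopython


def _read_abi(path: Path) -> TraceSignal:
    # ABIF stores raw channels in DATA9..DATA12; FWO_1 names the base order.
    from Bio import SeqIO

    record = SeqIO.read(str(path), "abi")
    raw = record.annotations["abif_raw"]
    try:
        order_bytes = raw["FWO_1"]
        order = order_bytes.decode() if isinstance(order_bytes, bytes) else str(order_bytes)
        channels = {
            base: np.asarray(raw[f"DATA{9 + i}"], dtype=float)
            for i, base in enumerate(order)
        }
        ploc = raw.get("PLOC2", raw.get("PLOC1"))
        pbas = raw.get("PBAS2", raw.get("PBAS1"))
    except KeyError as exc:
        raise TraceFormatError(f"{path}: missing ABIF tag {exc}") from exc
    if ploc is None or pbas is None:
        raise TraceFormatError(f"{path}: missing basecall/peak-location tags")
    bases = pbas.decode() if isinstance(pbas, bytes) else str(pbas)
    lengths = {len(v) for v in channels.values()}
    if len(lengths) != 1:
        raise TraceFormatError(f"{path}: unequal channel lengths {sorted(lengths)}")
    if sorted(channels) != sorted(BASES):
        raise TraceFormatError(f"{path}: FWO_1 does not name the 4 bases: {order!r}")
    try:
        return TraceSignal(
            intensities=np.stack([channels[b] for b in BASES]),
            called_bases=tuple(bases),
            peak_positions=np.asarray(list(ploc), dtype=int),
            channel_order=BASES,
        )
    except ValidationError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


def read_trace(path: str | Path, dialect: str = "tsv") -> TraceSignal:
    """Read a trace file in the named dialect (``tsv`` or ``abi``)."""
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"{path}: no such file")
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "abi":
        return _read_abi(path)
    raise ValueError(f"unknown trace dialect {dialect!r}")


def read_locus(path: str | Path) -> SNPLocus:
    """Read a SNP-locus descriptor from a small key-value text file.

    Lines are ``key = value``; keys are the SNPLocus field names.
    """
    fields: dict[str, str] = {}
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if "=" not in ln:
            raise TraceFormatError(f"locus file line without '=': {ln!r}")
        key, _, value = ln.partition("=")
        fields[key.strip()] = value.strip()
    try:
        return SNPLocus(
            allele_primary=fields["allele_primary"],
            allele_secondary=fields["allele_secondary"],
            flank_left=fields["flank_left"],
            flank_right=fields["flank_right"],
            label=fields.get("label", ""),
        )
    except KeyError as exc:
        raise TraceFormatError(f"locus file missing key {exc}") from exc


def write_locus(locus: SNPLocus, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(
            [
                f"allele_primary = {locus.allele_primary}",
                f"allele_secondary = {locus.allele_secondary}",
                f"flank_left = {locus.flank_left}",
                f"flank_right = {locus.flank_right}",
                f"label = {locus.label}",
            ]
        )
        + "\n",
        encoding="utf-8",
    )
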