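"""Reading Sanger trace signals.

Two input routes feed the same in-memory representation:

* ABIF ``.ab1`` chromatograms (read through Biopython's ``abi`` parser),
  carrying the four analyzed fluorescence channels, the called sequence and
  the per-base peak locations;
* a plain-text TSV "peak table" holding the four channel intensities already
  extracted at each interrogated SNP site, so the whole downstream pipeline
  runs on portable text files.

Intensities are arbitrary fluorescence units; only ratios of intensities are
interpreted downstream, so the absolute scale never matters.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from struct import error as struct_error
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    EmptyReadError,
    ParameterError,
    SchemaError,
    TraceParseError,
    ValidationError,
)

NUCLEOTIDES = ("A", "C", "G", "T")

#: Columns of the peak-table dialect, in order. ``transcript`` is optional.
PEAK_TABLE_COLUMNS = (
    "sample_id",
    "molecule",
    "tissue",
    "site_id",
    "base_index",
    "A",
    "C",
    "G",
    "T",
)

#: ABIF tags required to reconstruct the analyzed trace. DATA9-12 are the
#: processed channels underlying the displayed chromatogram; FWO_1 gives the
#: base order of those channels; PLOC holds per-base peak locations.
_REQUIRED_ABIF_TAGS = ("DATA9", "DATA10", "DATA11", "DATA12", "FWO_1")


@dataclass
class ChromatogramRecord:
    """One sequencing read: called bases plus four channel intensity arrays.

    ``base_calls`` is an ordered list of ``(called_base, trace_index)`` pairs;
    every ``trace_index`` addresses a sample in the channel arrays.
    """

    sample_id: str
    molecule: str  # "gDNA" or "cDNA"
    tissue: str
    base_calls: list[tuple[str, int]]
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {len(self.channels[n]) for n in NUCLEOTIDES}
        if len(lengths) != 1:
            raise ValidationError(f"channel arrays differ in length: {lengths}")
        L = lengths.pop()
        if not self.base_calls:
            raise EmptyReadError(f"{self.sample_id}: no called bases")
        for base, idx in self.base_calls:
            if not 0 <= idx < L:
                raise ValidationError(
                    f"trace index {idx} outside channel length {L}"
                )
        for n in NUCLEOTIDES:
            if np.any(np.asarray(self.channels[n]) < 0):
                raise ValidationError(f"negative intensity in channel {n}")

    @property
    def sequence(self) -> str:
        return "".join(b for b, _ in self.base_calls)


@dataclass
class SiteSignal:
    """Per-channel intensities at one interrogated SNP site in one sample."""

    site_id: str
    base_index: int
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.intensities) != set(NUCLEOTIDES):
            raise ValidationError(
                f"intensities must have exactly the keys A,C,G,T, "
                f"got {sorted(self.intensities)}"
            )
        for n, v in self.intensities.items():
            if v < 0:
                raise ValidationError(f"negative intensity {v} for channel {n}")


@dataclass
class PeakRecord:
    """One peak-table row: sample metadata plus the site signal."""

    sample_id: str
    molecule: str
    tissue: str
    signal: SiteSignal
    transcript: str | None = None


def _infer_metadata(sample_field: str, path: str) -> tuple[str, str, str]:
    # SMPL1 convention "sample|molecule|tissue"; fall back to the file stem.
    parts = sample_field.split("|")
    if len(parts) == 3:
        return parts[0], parts[1], parts[2]
    sid = sample_field or os.path.splitext(os.path.basename(path))[0]
    return sid, "gDNA", "unknown"


def read_chromatogram(
    path: str,
    format_hint: Literal["abif", "auto"] = "auto",
    *,
    sample_id: str | None = None,
    molecule: str | None = None,
    tissue: str | None = None,
) -> ChromatogramRecord:
    """Read an ABIF ``.ab1`` chromatogram into a :class:`ChromatogramRecord`.

    Sample metadata is taken from the SMPL1 tag when it follows the
    ``sample|molecule|tissue`` convention, and can be overridden with the
    keyword arguments.  ``format_hint="auto"`` sniffs the ABIF magic bytes.
    """
    if format_hint not in ("abif", "auto"):
        raise ParameterError(f"unknown format hint {format_hint!r}")
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic != b"ABIF":
        raise TraceParseError(f"{path}: not an ABIF file (magic {magic!r})")
    try:
        rec = SeqIO.read(path, "abi")
    except (ValueError, struct_error) as exc:  # pragma: no cover - re-raised
        raise TraceParseError(f"{path}: {exc}") from exc
    raw = rec.annotations["abif_raw"]

    for tag in _REQUIRED_ABIF_TAGS:
        if tag not in raw:
            raise TraceParseError(f"{path}: missing required ABIF tag {tag}")
    base_order = raw["FWO_1"]
    if isinstance(base_order, bytes):
        base_order = base_order.decode()
    channels = {
        base: np.asarray(raw[f"DATA{9 + i}"], dtype=float)
        for i, base in enumerate(base_order)
    }
    if set(channels) != set(NUCLEOTIDES):
        raise TraceParseError(f"{path}: unexpected base order {base_order!r}")

    seq = None
    for tag in ("PBAS2", "PBAS1"):
        if tag in raw:
            seq = raw[tag]
            break
    if seq is None:
        raise TraceParseError(f"{path}: missing required ABIF tag PBAS2")
    if isinstance(seq, bytes):
        seq = seq.decode()
    ploc = None
    for tag in ("PLOC2", "PLOC1"):
        if tag in raw:
            ploc = raw[tag]
            break
    if ploc is None:
        raise TraceParseError(f"{path}: missing required ABIF tag PLOC2")
    if isinstance(ploc, int):
        ploc = (ploc,)
    if not seq:
        raise EmptyReadError(f"{path}: empty called sequence")
    if len(seq) != len(ploc):
        raise TraceParseError(
            f"{path}: {len(seq)} called bases but {len(ploc)} peak locations"
        )

    smpl = raw.get("SMPL1", "")
    if isinstance(smpl, bytes):
        smpl = smpl.decode()
    sid, mol, tis = _infer_metadata(smpl, path)
    return ChromatogramRecord(
        sample_id=sample_id or sid,
        molecule=molecule or mol,
        tissue=tissue or tis,
        base_calls=list(zip(seq, (int(p) for p in ploc))),
        channels=channels,
    )


def extract_site_signal(
    record: ChromatogramRecord, base_index: int, window: int = 4
) -> SiteSignal:
    """Extract the four channel intensities at one called base.

    For each channel the intensity is the maximum channel value within
    ``±window`` trace samples of the base's peak location (``window=0`` reads
    the value exactly at the peak).  The window is clipped to the trace ends.
    """
    if window < 0:
        raise ParameterError(f"window must be >= 0, got {window}")
    if not 0 <= base_index < len(record.base_calls):
        raise IndexError(
            f"base_index {base_index} outside 0..{len(record.base_calls) - 1}"
        )
    _, trace_index = record.base_calls[base_index]
    lo = max(0, trace_index - window)
    hi = trace_index + window + 1
    intensities = {
        n: float(np.max(record.channels[n][lo:hi])) for n in NUCLEOTIDES
    }
    return SiteSignal(
        site_id=f"{record.sample_id}:{base_index}",
        base_index=base_index,
        intensities=intensities,
    )


def _require_columns(df: pd.DataFrame, path: str) -> None:
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing peak-table columns {missing}")


def read_peak_table(path: str | io.TextIOBase) -> list[PeakRecord]:
    """Read the TSV peak-table dialect into a list of :class:`PeakRecord`.

    The table must carry the header columns ``sample_id  molecule  tissue
    site_id  base_index  A  C  G  T``; an optional ``transcript`` column is
    attached when present.  Negative intensities are rejected.
    """
    df = read_peak_frame(path)
    records = []
    for row in df.itertuples(index=False):
        signal = SiteSignal(
            site_id=row.site_id,
            base_index=int(row.base_index),
            intensities={n: float(getattr(row, n)) for n in NUCLEOTIDES},
        )
        records.append(
            PeakRecord(
                sample_id=row.sample_id,
                molecule=row.molecule,
                tissue=row.tissue,
                signal=signal,
                transcript=getattr(row, "transcript", None),
            )
        )
    return records


def read_peak_frame(path: str | io.TextIOBase) -> pd.DataFrame:
    """Read and validate a peak table as a DataFrame (pipeline-internal)."""
    name = path if isinstance(path, str) else getattr(path, "name", "<stream>")
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "tissue": str},
        float_precision="round_trip",
    )
    _require_columns(df, name)
    for n in NUCLEOTIDES:
        if (df[n] < 0).any():
            bad = df.loc[df[n] < 0].index[0]
            raise ValidationError(
                f"{name}: negative intensity in column {n} (data row {bad})"
            )
    if (df["base_index"] < 0).any():
        raise ValidationError(f"{name}: negative base_index")
    return df


def write_peak_table(
    records: Iterable[PeakRecord], path: str | io.TextIOBase
) -> None:
    """Write :class:`PeakRecord` rows as the TSV peak-table dialect.

    Intensities round-trip exactly through :func:`read_peak_table` (Python
    ``repr`` floats).
    """
    rows = []
    any_transcript = False
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "molecule": r.molecule,
            "tissue": r.tissue,
            "site_id": r.signal.site_id,
            "base_index": r.signal.base_index,
            **{n: r.signal.intensities[n] for n in NUCLEOTIDES},
        }
        if r.transcript is not None:
            row["transcript"] = r.transcript
            any_transcript = True
        rows.append(row)
    cols = list(PEAK_TABLE_COLUMNS) + (["transcript"] if any_transcript else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
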