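"""Comparative locus architecture: intergenic gaps, repeats, CpG density.

Utilities for asking how far apart two syntenic genes sit across species,
what the intervening DNA is made of (RepeatMasker classes), and how CpG
density varies along a sequence — the comparative-genomics side of an
imprinted-locus analysis.

Coordinate conventions: GFF3 and RepeatMasker query coordinates are 1-based
inclusive and are kept that way throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .errors import (
    AmbiguityError,
    GeneLookupError,
    ParameterError,
    RepeatMaskerParseError,
    ValidationError,
)

#: Repeat classes reported in composition summaries; RepeatMasker
#: class/family strings are mapped here by their prefix before "/"
#: (e.g. "LTR/ERVK" -> "LTR"); anything else falls into "Other".
REPEAT_CLASSES = (
    "SINE",
    "LINE",
    "LTR",
    "DNA",
    "Simple_repeat",
    "Low_complexity",
    "Other",
)


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic footprint (1-based inclusive, as in GFF3)."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class DistanceRecord:
    """Gap between two genes in one species.

    ``gap_bp`` is signed: negative means the gene bodies overlap.  It is
    ``None`` (and ``linked`` false) when the genes sit on different
    sequences, as for the teleost case where synteny is broken.
    """

    species: str
    gene_a: str
    gene_b: str
    linked: bool
    gap_bp: int | None
    overlap: bool
    divergence_mya: float | None = None


@dataclass
class RepeatSummary:
    """Repeat composition of one interval.

    ``per_class`` maps each class to ``(bp, percent)`` where bp counts the
    union of same-class hits (overlaps merged) clipped to the interval;
    ``per_element`` holds raw clipped bp per repeat element name.
    """

    seq_id: str
    start: int
    end: int
    total_bp: int
    per_class: dict[str, tuple[int, float]]
    per_element: dict[str, int]


@dataclass
class CpGTrack:
    """CpG density (percent) over successive non-overlapping windows."""

    seq_id: str
    window_bp: int
    values: list[float]


def parse_gene_intervals(
    annotation: str, gene_ids: Sequence[str]
) -> list[GeneInterval]:
    """Look up gene-level features in a GFF3 file by ID or Name.

    Returns one :class:`GeneInterval` per requested id, in request order.
    A missing gene raises :class:`GeneLookupError`; a gene id matching more
    than one feature raises :class:`AmbiguityError`.
    """
    db = gffutils.create_db(
        annotation,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    by_key: dict[str, list[gffutils.Feature]] = {}
    for feat in db.features_of_type("gene"):
        keys = set(feat.attributes.get("ID", [])) | set(
            feat.attributes.get("Name", [])
        ) | {feat.id}
        for key in keys:
            by_key.setdefault(key, []).append(feat)
    out = []
    for gid in gene_ids:
        hits = by_key.get(gid, [])
        uniq = {(f.seqid, f.start, f.end, f.strand) for f in hits}
        if not hits:
            raise GeneLookupError(f"gene {gid!r} not found in {annotation}")
        if len(uniq) > 1:
            raise AmbiguityError(
                f"gene id {gid!r} matches {len(uniq)} distinct features"
            )
        f = hits[0]
        out.append(GeneInterval(gid, f.seqid, f.start, f.end, f.strand))
    return out


def compute_gene_gap(
    a: GeneInterval, b: GeneInterval, species: str = ""
) -> DistanceRecord:
    """Signed gap between two gene intervals, symmetric in its arguments.

    On the same sequence the gap is ``start(later) − end(earlier)`` where
    "later" is the interval with the greater start; a negative value flags
    overlapping gene bodies.  On different sequences the genes are reported
    unlinked with no gap.
    """
    if a.seq_id != b.seq_id:
        return DistanceRecord(
            species, a.gene_id, b.gene_id, linked=False, gap_bp=None, overlap=False
        )
    earlier, later = sorted((a, b), key=lambda g: (g.start, g.end))
    gap = later.start - earlier.end
    return DistanceRecord(
        species,
        a.gene_id,
        b.gene_id,
        linked=True,
        gap_bp=gap,
        overlap=gap < 0,
    )


def repeat_class_of(class_family: str) -> str:
    """Map a RepeatMasker class/family string to the summary class set."""
    prefix = class_family.split("/")[0]
    return prefix if prefix in REPEAT_CLASSES else "Other"


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def parse_repeatmasker_out(path: str) -> pd.DataFrame:
    """Parse a RepeatMasker ``.out`` file (standard 15-column annotation).

    The three header lines are skipped; each hit row yields query sequence,
    1-based inclusive begin/end, repeat element name and class/family.
    Malformed rows raise :class:`RepeatMaskerParseError` with the line
    number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            # header lines start with the "SW"/"score" banner
            if stripped.startswith(("SW", "score")):
                continue
            fields = stripped.split()
            if len(fields) < 14:
                raise RepeatMaskerParseError(
                    lineno, f"expected >= 14 columns, got {len(fields)}"
                )
            try:
                rows.append(
                    {
                        "seq_id": fields[4],
                        "begin": int(fields[5]),
                        "end": int(fields[6]),
                        "strand": fields[8],
                        "element": fields[9],
                        "class_family": fields[10],
                    }
                )
            except ValueError as exc:
                raise RepeatMaskerParseError(lineno, str(exc)) from exc
    return pd.DataFrame(
        rows,
        columns=["seq_id", "begin", "end", "strand", "element", "class_family"],
    )


def summarize_repeats(
    rm_out: str, interval: tuple[str, int, int]
) -> RepeatSummary:
    """Repeat composition of one interval from RepeatMasker output.

    Hits are clipped to the interval; same-class hits are merged before the
    class bp is counted, so nested or overlapping annotations are not double
    counted.  Per-element totals use the raw clipped lengths.  Percentages
    are relative to the interval length.
    """
    seq_id, start, end = interval
    if start > end:
        raise ParameterError(f"empty interval {seq_id}:{start}-{end}")
    total_bp = end - start + 1
    hits = parse_repeatmasker_out(rm_out)
    per_class_ivs: dict[str, list[tuple[int, int]]] = {
        c: [] for c in REPEAT_CLASSES
    }
    per_element: dict[str, int] = {}
    for row in hits.itertuples(index=False):
        if row.seq_id != seq_id:
            continue
        s, e = max(row.begin, start), min(row.end, end)
        if s > e:
            continue
        cls = repeat_class_of(row.class_family)
        per_class_ivs[cls].append((s, e))
        per_element[row.element] = per_element.get(row.element, 0) + (e - s + 1)
    per_class = {}
    for cls in REPEAT_CLASSES:
        bp = sum(e - s + 1 for s, e in _merge_intervals(per_class_ivs[cls]))
        per_class[cls] = (bp, 100.0 * bp / total_bp)
    return RepeatSummary(
        seq_id=seq_id,
        start=start,
        end=end,
        total_bp=total_bp,
        per_class=per_class,
        per_element=per_element,
    )


def compute_cpg_density(
    sequence: str, window_bp: int, seq_id: str = ""
) -> CpGTrack:
    """CpG density as a percentage over non-overlapping windows.

    Per window the density is ``100 × (# CG dinucleotides) / window length``
    with an overlapping dinucleotide scan; a dinucleotide straddling a window
    boundary is assigned to the window holding its first base.  Dinucleotides
    containing N (or any non-ACGT base) are not counted.  The final partial
    window is normalized by its own length.
    """
    if window_bp < 2:
        raise ParameterError(f"window_bp must be >= 2, got {window_bp}")
    seq = sequence.upper()
    L = len(seq)
    values = []
    for w_start in range(0, L, window_bp):
        w_len = min(window_bp, L - w_start)
        count = 0
        for i in range(w_start, min(w_start + w_len, L - 1)):
            if seq[i] == "C" and seq[i + 1] == "G":
                count += 1
        values.append(100.0 * count / w_len)
    return CpGTrack(seq_id=seq_id, window_bp=window_bp, values=values)


def join_divergence(
    distances: Iterable[DistanceRecord], divergence_table: str | Mapping[str, float]
) -> pd.DataFrame:
    """Left-join distance records to species divergence times (mya).

    ``divergence_table`` is a TSV with columns ``species`` and ``mya`` (or an
    equivalent mapping); matching is case-insensitive.  Unmatched species
    keep a missing divergence.  Output is sorted by divergence then species.
    """
    if isinstance(divergence_table, Mapping):
        table = {str(k): float(v) for k, v in divergence_table.items()}
        keys = [k.lower() for k in table]
        if len(set(keys)) != len(keys):
            raise AmbiguityError("duplicate species in divergence mapping")
        lookup = {k.lower(): v for k, v in table.items()}
    else:
        df = pd.read_csv(divergence_table, sep="\t")
        missing = {"species", "mya"} - set(df.columns)
        if missing:
            raise ValidationError(
                f"divergence table missing columns {sorted(missing)}"
            )
        lowered = df["species"].str.lower()
        if lowered.duplicated().any():
            dup = df["species"][lowered.duplicated()].iloc[0]
            raise AmbiguityError(f"duplicate species {dup!r} in divergence table")
        lookup = dict(zip(lowered, df["mya"].astype(float)))
    rows = []
    for d in distances:
        mya = lookup.get(d.species.lower())
        rows.append(
            {
                "species": d.species,
                "gene_a": d.gene_a,
                "gene_b": d.gene_b,
                "linked": d.linked,
                "gap_bp": d.gap_bp,
                "overlap": d.overlap,
                "divergence_mya": mya,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "species",
            "gene_a",
            "gene_b",
            "linked",
            "gap_bp",
            "overlap",
            "divergence_mya",
        ],
    )
    return out.sort_values(
        ["divergence_mya", "species"], na_position="last"
    ).reset_index(drop=True)
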