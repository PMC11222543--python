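"""Synthetic trio signals, chromatograms and locus fixtures with known truth.

Every downstream stage of the package is testable against data generated
here, because each generator records the ground truth it used:

* :func:`simulate_trio_dataset` emits peak tables for mother gDNA, offspring
  gDNA and offspring cDNA at SNP sites where the true maternal expression
  fraction θ is known.  Mothers are homozygous and offspring heterozygous at
  every simulated site (the informative configuration); a flag adds
  non-informative sites to exercise filtering.
* :func:`simulate_chromatogram` writes a minimal ABIF (.ab1) file whose
  analyzed channels carry specified peak heights, for exercising the trace
  reader end to end.
* :func:`simulate_locus_fixture` writes FASTA + GFF3 + RepeatMasker ``.out``
  files for a locus with known gene gaps and repeat composition.

Noise model: each emitted intensity is multiplied by a lognormal factor with
mean 1 and coefficient of variation ``noise_cv`` — fluorescence signal is
positive and its dispersion scales with the mean, which a multiplicative
model captures; the mat:pat ratio's scale invariance makes results
insensitive to the absolute ``total_signal``.
"""

from __future__ import annotations

import math
import struct
import textwrap
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .trace_io import NUCLEOTIDES

# --------------------------------------------------------------------------
# trio signal datasets
# --------------------------------------------------------------------------


@dataclass
class TrioSimulationConfig:
    """Study conditions for a simulated trio dataset.

    ``theta_true`` is the maternal expression fraction the cDNA signal is
    split by; ``total_signal`` the mean summed parental intensity in
    fluorescence units; ``baseline`` the mean intensity of channels carrying
    no allele (instrument noise floor, about 1% of signal by default).
    """

    theta_true: float
    n_animals: int = 10
    n_snps: int = 3
    total_signal: float = 1000.0
    noise_cv: float = 0.1
    baseline: float = 10.0
    seed: int = 0
    transcript: str = "TX1"
    tissue: str = "liver"
    n_noninformative: int = 0  # extra mother-het sites per animal

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_true <= 1.0:
            raise ParameterError(f"theta_true {self.theta_true} outside [0,1]")
        if self.noise_cv < 0:
            raise ParameterError(f"noise_cv {self.noise_cv} must be >= 0")
        if self.total_signal <= 0:
            raise ParameterError("total_signal must be positive")
        if self.n_animals < 1 or self.n_snps < 1:
            raise ParameterError("n_animals and n_snps must be >= 1")
        if self.baseline < 0:
            raise ParameterError("baseline must be >= 0")


@dataclass
class TrioDataset:
    """Simulated peak tables plus the truth they were generated from."""

    mother_gdna: pd.DataFrame
    offspring_gdna: pd.DataFrame
    offspring_cdna: pd.DataFrame
    pairs: pd.DataFrame
    truth: pd.DataFrame
    config: TrioSimulationConfig

    def peaks(self) -> pd.DataFrame:
        """All three peak tables stacked into one frame."""
        return pd.concat(
            [self.mother_gdna, self.offspring_gdna, self.offspring_cdna],
            ignore_index=True,
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write peaks.tsv, pairs.tsv and truth.tsv; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks": out / "peaks.tsv",
            "pairs": out / "pairs.tsv",
            "truth": out / "truth.tsv",
        }
        self.peaks().to_csv(paths["peaks"], sep="\t", index=False)
        self.pairs.to_csv(paths["pairs"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _noise(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal factor with mean 1 and sd/mean = cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def simulate_trio_dataset(config: TrioSimulationConfig) -> TrioDataset:
    """Simulate mother/offspring peak tables at a known θ.

    Per SNP: the mother is homozygous for the maternal allele (its channel
    near ``total_signal``); the offspring gDNA splits the signal 50/50
    between the maternal and paternal alleles; the offspring cDNA splits it
    θ/(1−θ).  Channels carrying no allele fluctuate around ``baseline``.
    Identical config and seed give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    c = config
    mother_rows, off_g_rows, off_c_rows, pair_rows, truth_rows = (
        [],
        [],
        [],
        [],
        [],
    )

    def row(sample, molecule, tissue, site, base_index, channel_values):
        r = {
            "sample_id": sample,
            "molecule": molecule,
            "tissue": tissue,
            "site_id": site,
            "base_index": base_index,
            "transcript": c.transcript,
        }
        r.update({n: float(channel_values.get(n, 0.0)) for n in NUCLEOTIDES})
        return {
            k: r[k]
            for k in (
                "sample_id",
                "molecule",
                "tissue",
                "site_id",
                "base_index",
                "A",
                "C",
                "G",
                "T",
                "transcript",
            )
        }

    for a in range(c.n_animals):
        off_id, mot_id = f"off{a + 1}", f"mot{a + 1}"
        pair_rows.append({"offspring_id": off_id, "mother_id": mot_id})
        n_sites = c.n_snps + c.n_noninformative
        for s in range(n_sites):
            informative = s < c.n_snps
            site = f"{c.transcript}_snp{s + 1}"
            mat, pat = rng.choice(list(NUCLEOTIDES), size=2, replace=False)
            off = {
                n: c.baseline * _noise(rng, c.noise_cv) for n in NUCLEOTIDES
            }
            if informative:
                mother = dict(off)
                mother[mat] = c.total_signal * _noise(rng, c.noise_cv)
            else:
                # mother heterozygous: site carries no parental information
                mother = dict(off)
                mother[mat] = c.total_signal / 2 * _noise(rng, c.noise_cv)
                mother[pat] = c.total_signal / 2 * _noise(rng, c.noise_cv)
            off_g = {
                n: c.baseline * _noise(rng, c.noise_cv) for n in NUCLEOTIDES
            }
            off_g[mat] = c.total_signal / 2 * _noise(rng, c.noise_cv)
            off_g[pat] = c.total_signal / 2 * _noise(rng, c.noise_cv)
            off_c = {
                n: c.baseline * _noise(rng, c.noise_cv) for n in NUCLEOTIDES
            }
            off_c[mat] = c.theta_true * c.total_signal * _noise(rng, c.noise_cv)
            off_c[pat] = (
                (1.0 - c.theta_true) * c.total_signal * _noise(rng, c.noise_cv)
            )
            mother_rows.append(row(mot_id, "gDNA", c.tissue, site, s, mother))
            off_g_rows.append(row(off_id, "gDNA", c.tissue, site, s, off_g))
            off_c_rows.append(row(off_id, "cDNA", c.tissue, site, s, off_c))
            truth_rows.append(
                {
                    "animal_id": off_id,
                    "site_id": site,
                    "maternal_allele": mat,
                    "paternal_allele": pat,
                    "informative": informative,
                    "theta_true": c.theta_true,
                }
            )
    return TrioDataset(
        mother_gdna=pd.DataFrame(mother_rows),
        offspring_gdna=pd.DataFrame(off_g_rows),
        offspring_cdna=pd.DataFrame(off_c_rows),
        pairs=pd.DataFrame(pair_rows),
        truth=pd.DataFrame(truth_rows),
        config=c,
    )


# --------------------------------------------------------------------------
# ABIF chromatogram fixtures
# --------------------------------------------------------------------------

# ABIF binary layout constants: 128-byte header (magic + packed fields +
# padding), directory entries of 28 bytes, big-endian throughout.
_HEADER_FMT = ">H4sI2H3I"
_DIR_FMT = ">4sI2H4I"
_HEADER_SIZE = 128


@dataclass
class ChromatogramSpec:
    """Specification for a synthetic chromatogram fixture.

    ``site_heights`` maps a 0-based base index to channel heights placed at
    that base's peak location; bases without an entry get a single peak of
    ``default_height`` on the called base's channel.
    """

    sample_id: str
    sequence: str
    site_heights: dict[int, dict[str, float]] = field(default_factory=dict)
    molecule: str = "gDNA"
    tissue: str = "unknown"
    peak_spacing: int = 12
    default_height: int = 800

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError("sequence must be non-empty")
        if any(b not in NUCLEOTIDES for b in self.sequence.upper()):
            raise ParameterError("sequence must be plain A/C/G/T")
        for idx, heights in self.site_heights.items():
            if not 0 <= idx < len(self.sequence):
                raise ParameterError(f"site index {idx} outside sequence")
            for n, h in heights.items():
                if n not in NUCLEOTIDES:
                    raise ParameterError(f"unknown channel {n!r}")
                if not 0 <= h <= 32767:
                    raise ParameterError(
                        f"height {h} outside the 16-bit trace range"
                    )


def _pack_abif(tags: list[tuple[str, int, int, int, int, bytes]]) -> bytes:
    """Assemble an ABIF file from (name, number, type, elem_size, n, payload)."""
    blob = bytearray()
    entries = []
    data_start = _HEADER_SIZE
    for name, number, code, elem_size, n_elem, payload in tags:
        size = len(payload)
        if size <= 4:
            offset_field = int.from_bytes(payload.ljust(4, b"\x00"), "big")
        else:
            offset_field = data_start + len(blob)
            blob.extend(payload)
        entries.append(
            struct.pack(
                _DIR_FMT,
                name.encode(),
                number,
                code,
                elem_size,
                n_elem,
                size,
                offset_field,
                0,
            )
        )
    dir_offset = data_start + len(blob)
    header = b"ABIF" + struct.pack(
        _HEADER_FMT,
        101,  # file version
        b"tdir",
        1,
        1023,
        28,
        len(entries),
        28 * len(entries),
        dir_offset,
    )
    header = header.ljust(_HEADER_SIZE, b"\x00")
    return bytes(header) + bytes(blob) + b"".join(entries)


def simulate_chromatogram(
    spec: ChromatogramSpec, path: str | Path, seed: int = 0
) -> Path:
    """Write a minimal ABIF file realizing ``spec``; returns the path.

    The analyzed channels (DATA9-12, base order GATC) hold a single-sample
    peak per called base at regularly spaced trace indices (PLOC2).  The
    SMPL1 tag encodes ``sample|molecule|tissue`` so the reader can recover
    the metadata.  Output is deterministic for a given spec and seed.
    """
    seq = spec.sequence.upper()
    spacing = spec.peak_spacing
    L = spacing * len(seq)
    channels = {n: np.zeros(L, dtype=np.int16) for n in NUCLEOTIDES}
    ploc = []
    for i, base in enumerate(seq):
        t = i * spacing + spacing // 2
        ploc.append(t)
        heights = spec.site_heights.get(i, {base: spec.default_height})
        for n, h in heights.items():
            channels[n][t] = int(round(h))

    def shorts(values) -> bytes:
        return struct.pack(f">{len(values)}h", *[int(v) for v in values])

    smpl = f"{spec.sample_id}|{spec.molecule}|{spec.tissue}".encode()
    tags = []
    for i, base in enumerate("GATC"):  # FWO_1 base order
        payload = shorts(channels[base])
        tags.append(("DATA", 9 + i, 4, 2, L, payload))
    tags.append(("FWO_", 1, 2, 1, 4, b"GATC"))
    tags.append(("PBAS", 2, 2, 1, len(seq), seq.encode()))
    tags.append(("PLOC", 2, 4, 2, len(ploc), shorts(ploc)))
    tags.append(("SMPL", 1, 18, 1, len(smpl) + 1, bytes([len(smpl)]) + smpl))
    out = Path(path)
    out.write_bytes(_pack_abif(tags))
    return out


# --------------------------------------------------------------------------
# locus fixtures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePlacement:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class RepeatPlacement:
    element: str
    class_family: str  # RepeatMasker style, e.g. "LTR/ERVK"
    start: int
    end: int


@dataclass
class LocusFixtureSpec:
    """A synthetic locus: genes, repeats and CpG islands on one sequence."""

    seq_length: int
    genes: list[GenePlacement] = field(default_factory=list)
    repeats: list[RepeatPlacement] = field(default_factory=list)
    cpg_islands: list[tuple[int, int, float]] = field(default_factory=list)
    seq_id: str = "locus1"
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.genes:
            if not 1 <= g.start <= g.end <= self.seq_length:
                raise ParameterError(f"gene {g.gene_id} outside sequence bounds")
        for r in self.repeats:
            if not 1 <= r.start <= r.end <= self.seq_length:
                raise ParameterError(f"repeat {r.element} outside sequence bounds")
        for s, e, d in self.cpg_islands:
            if not 1 <= s <= e <= self.seq_length:
                raise ParameterError("CpG island outside sequence bounds")
            if not 0 <= d <= 50:
                raise ParameterError(
                    "island density must be 0-50% (non-overlapping CpGs)"
                )


@dataclass
class LocusTruth:
    """Ground truth recorded at construction time.

    ``gaps`` maps an ordered gene-id pair (by start coordinate) to the
    signed gap ``start(later) − end(earlier)``.  ``intergenic_repeats`` maps
    the same pair to the per-class repeat bp inside the intergenic interval
    (positions counted once, computed by position masks independent of the
    interval-merging parser).
    """

    gaps: dict[tuple[str, str], int]
    intergenic_intervals: dict[tuple[str, str], tuple[int, int]]
    intergenic_repeats: dict[tuple[str, str], dict[str, int]]


@dataclass
class LocusFixture:
    fasta: Path
    gff3: Path
    rm_out: Path
    truth: LocusTruth
    spec: LocusFixtureSpec


def _island_block(length: int, density_pct: float) -> str:
    """A block of given length whose CG-dinucleotide density ≈ density_pct."""
    k = int(round(density_pct * length / 100.0))
    block = ["T"] * length
    if k > 0:
        step = length / k
        for j in range(k):
            p = min(int(j * step), length - 2)
            block[p], block[p + 1] = "C", "G"
    return "".join(block)


def simulate_locus_fixture(
    spec: LocusFixtureSpec, out_dir: str | Path
) -> LocusFixture:
    """Write FASTA + GFF3 + RepeatMasker .out for a locus with known truth."""
    from .locus_architecture import repeat_class_of  # local: avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # background sequence avoids C-before-G so islands dominate CpG density
    seq = rng.choice(list("ACGT"), size=spec.seq_length)
    cg = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
    seq[cg] = "T"
    seq = list("".join(seq))
    for s, e, d in spec.cpg_islands:
        seq[s - 1 : e] = list(_island_block(e - s + 1, d))
    sequence = "".join(seq)

    fasta = out / f"{spec.seq_id}.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{spec.seq_id}\n")
        fh.write("\n".join(textwrap.wrap(sequence, 60)) + "\n")

    gff3 = out / f"{spec.seq_id}.gff3"
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {spec.seq_id} 1 {spec.seq_length}\n")
        for g in spec.genes:
            fh.write(
                f"{spec.seq_id}\tsangerase\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};Name={g.gene_id}\n"
            )

    rm_out = out / f"{spec.seq_id}.out"
    with open(rm_out, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           "
            "matching       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)    "
            "repeat         class/family         begin  end (left)     ID\n"
            "\n"
        )
        for i, r in enumerate(spec.repeats, start=1):
            rep_len = r.end - r.start + 1
            fh.write(
                f"  {1000 + i:4d}  10.0  1.0  1.0  {spec.seq_id} "
                f"{r.start:8d} {r.end:8d} ({spec.seq_length - r.end}) + "
                f"{r.element} {r.class_family} {1:6d} {rep_len:4d} (0) {i:6d}\n"
            )

    # ground truth by construction
    ordered = sorted(spec.genes, key=lambda g: (g.start, g.end))
    gaps: dict[tuple[str, str], int] = {}
    intervals: dict[tuple[str, str], tuple[int, int]] = {}
    repeats_truth: dict[tuple[str, str], dict[str, int]] = {}
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            earlier, later = ordered[i], ordered[j]
            key = (earlier.gene_id, later.gene_id)
            gaps[key] = later.start - earlier.end
            if gaps[key] > 1:
                iv = (earlier.end + 1, later.start - 1)
                intervals[key] = iv
                mask_len = iv[1] - iv[0] + 1
                per_class: dict[str, int] = {}
                for cls in {repeat_class_of(r.class_family) for r in spec.repeats}:
                    mask = np.zeros(mask_len, dtype=bool)
                    for r in spec.repeats:
                        if repeat_class_of(r.class_family) != cls:
                            continue
                        s = max(r.start, iv[0]) - iv[0]
                        e = min(r.end, iv[1]) - iv[0]
                        if s <= e:
                            mask[s : e + 1] = True
                    per_class[cls] = int(mask.sum())
                repeats_truth[key] = per_class
    return LocusFixture(
        fasta=fasta,
        gff3=gff3,
        rm_out=rm_out,
        truth=LocusTruth(gaps, intervals, repeats_truth),
        spec=spec,
    )
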