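"""End-to-end orchestration: peaks → trios → ratios → summary table.

The pipeline consumes one peak table holding mother gDNA, offspring gDNA and
offspring cDNA rows plus a pairs table mapping each offspring to its mother,
and produces a per-transcript × per-tissue imprinting summary with
per-animal detail and an exclusion log that accounts for every animal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ase_quant, genotyping, trace_io
from .errors import (
    MendelianInconsistencyError,
    NoInformativeSitesError,
    SchemaError,
    TranscriptNotDetectedError,
    UncallableSiteError,
)
from .trace_io import NUCLEOTIDES, SiteSignal

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and parameters for one pipeline run."""

    peaks: str | Path
    pairs: str | Path
    het_threshold: float = genotyping.DEFAULT_HET_THRESHOLD
    out_dir: str | Path | None = None


@dataclass
class PipelineResult:
    """Summary rows, per-animal detail, and the exclusion log."""

    summaries: list[ase_quant.AseSummary]
    per_animal: pd.DataFrame
    per_snp: pd.DataFrame
    exclusions: pd.DataFrame

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for s in sorted(self.summaries, key=lambda s: (s.transcript, s.tissue)):
            rows.append(
                {
                    "transcript": s.transcript,
                    "tissue": s.tissue,
                    "n": s.n_animals,
                    "mean_ratio": s.mean_ratio,
                    "sem": s.sem,
                    "class": str(s.classification) if s.detected else "n.d.",
                }
            )
        return pd.DataFrame(
            rows, columns=["transcript", "tissue", "n", "mean_ratio", "sem", "class"]
        )


def _signal_from_row(row) -> SiteSignal:
    return SiteSignal(
        site_id=row["site_id"],
        base_index=int(row["base_index"]),
        intensities={n: float(row[n]) for n in NUCLEOTIDES},
    )


def _transcript_of(row) -> str:
    if "transcript" in row.index and pd.notna(row["transcript"]):
        return str(row["transcript"])
    site = str(row["site_id"])
    return site.split(":", 1)[0] if ":" in site else "unknown"


def run_ase_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run genotyping, informative-site selection and ASE quantification.

    Raises :class:`NoInformativeSitesError` when no mother-offspring pair
    yields an informative site.  Mendelian-inconsistent sites are flagged in
    the exclusion log rather than aborting the run.
    """
    peaks = trace_io.read_peak_frame(str(config.peaks))
    pairs = pd.read_csv(config.pairs, sep="\t")
    missing = {"offspring_id", "mother_id"} - set(pairs.columns)
    if missing:
        raise SchemaError(f"pairs table missing columns {sorted(missing)}")

    gdna = peaks[peaks["molecule"] == "gDNA"]
    cdna = peaks[peaks["molecule"] == "cDNA"]

    exclusions: list[dict] = []
    measurements: list[ase_quant.AseMeasurement] = []
    n_informative = 0

    for pair in pairs.itertuples(index=False):
        off_id, mot_id = str(pair.offspring_id), str(pair.mother_id)
        off_g = gdna[gdna["sample_id"] == off_id]
        mot_g = gdna[gdna["sample_id"] == mot_id]
        shared_sites = sorted(
            set(off_g["site_id"]) & set(mot_g["site_id"])
        )
        if not shared_sites:
            exclusions.append(
                {"animal_id": off_id, "site_id": "", "reason": "no_shared_gdna_sites"}
            )
            continue
        trios: dict[str, genotyping.TrioSite] = {}
        for site in shared_sites:
            mrow = mot_g[mot_g["site_id"] == site].iloc[0]
            orow = off_g[off_g["site_id"] == site].iloc[0]
            try:
                mgt = genotyping.call_genotype(
                    _signal_from_row(mrow), config.het_threshold
                )
                ogt = genotyping.call_genotype(
                    _signal_from_row(orow), config.het_threshold
                )
            except UncallableSiteError:
                exclusions.append(
                    {"animal_id": off_id, "site_id": site, "reason": "uncallable"}
                )
                continue
            try:
                trio = genotyping.classify_trio_site(mgt, ogt, site)
            except MendelianInconsistencyError:
                exclusions.append(
                    {
                        "animal_id": off_id,
                        "site_id": site,
                        "reason": "mendelian_inconsistency",
                    }
                )
                continue
            if not trio.informative:
                exclusions.append(
                    {"animal_id": off_id, "site_id": site, "reason": "not_informative"}
                )
                continue
            trios[site] = trio
            n_informative += 1
        if not trios:
            continue
        off_c = cdna[cdna["sample_id"] == off_id]
        for _, crow in off_c.iterrows():
            site = crow["site_id"]
            if site not in trios:
                continue
            try:
                m = ase_quant.compute_mat_pat_ratio(
                    _signal_from_row(crow),
                    trios[site],
                    animal_id=off_id,
                    tissue=str(crow["tissue"]),
                    transcript=_transcript_of(crow),
                )
            except TranscriptNotDetectedError:
                exclusions.append(
                    {"animal_id": off_id, "site_id": site, "reason": "not_detected"}
                )
                continue
            measurements.append(m)

    if n_informative == 0:
        raise NoInformativeSitesError(
            "no informative mother-offspring site in the dataset"
        )

    per_snp = pd.DataFrame(
        [
            {
                "animal_id": m.animal_id,
                "transcript": m.transcript,
                "tissue": m.tissue,
                "site_id": m.site_id,
                "ratio": m.ratio,
                "class": str(ase_quant.classify_ratio(m.ratio)),
            }
            for m in measurements
        ],
        columns=["animal_id", "transcript", "tissue", "site_id", "ratio", "class"],
    )

    animal_rows = []
    group_means: dict[tuple[str, str], list[float]] = {}
    by_animal: dict[tuple[str, str, str], list[ase_quant.AseMeasurement]] = {}
    for m in measurements:
        by_animal.setdefault((m.transcript, m.tissue, m.animal_id), []).append(m)
    for (transcript, tissue, animal), ms in sorted(by_animal.items()):
        mean = ase_quant.aggregate_animal(ms)
        animal_rows.append(
            {
                "animal_id": animal,
                "transcript": transcript,
                "tissue": tissue,
                "n_snps": len(ms),
                "mean_ratio": mean,
                "class": str(ase_quant.classify_ratio(mean)),
            }
        )
        group_means.setdefault((transcript, tissue), []).append(mean)
    per_animal = pd.DataFrame(
        animal_rows,
        columns=["animal_id", "transcript", "tissue", "n_snps", "mean_ratio", "class"],
    )

    # summary universe: every transcript × tissue seen anywhere in the input,
    # so an assayed tissue with no detectable transcript renders as "n.d."
    transcripts = {
        _transcript_of(row) for _, row in peaks.iterrows()
    }
    tissues = set(peaks["tissue"].astype(str))
    summaries = []
    for transcript in sorted(transcripts):
        for tissue in sorted(tissues):
            means = group_means.get((transcript, tissue))
            if means:
                summaries.append(
                    ase_quant.aggregate_group(means, transcript, tissue)
                )
            else:
                summaries.append(
                    ase_quant.AseSummary.not_detected(transcript, tissue)
                )

    logger.info(
        "pipeline: %d peak rows, %d informative sites, %d measurements, "
        "%d exclusions",
        len(peaks),
        n_informative,
        len(measurements),
        len(exclusions),
    )
    result = PipelineResult(
        summaries=summaries,
        per_animal=per_animal,
        per_snp=per_snp,
        exclusions=pd.DataFrame(
            exclusions, columns=["animal_id", "site_id", "reason"]
        ),
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.summary_frame().to_csv(out / "summary.tsv", sep="\t", index=False)
        result.per_animal.to_csv(out / "per_animal.tsv", sep="\t", index=False)
        result.per_snp.to_csv(out / "per_snp.tsv", sep="\t", index=False)
        result.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
        (out / "summary.txt").write_text(render_summary(result.summaries))
    return result


def format_summary_value(s: ase_quant.AseSummary) -> str:
    """Render one summary cell, e.g. ``0.24 ± 0.04 (4)`` or ``n.d.``."""
    if not s.detected:
        return "n.d."
    if s.n_animals == 1:
        return f"{s.mean_ratio:.2f} (1)"
    return f"{s.mean_ratio:.2f} ± {s.sem:.2f} ({s.n_animals})"


def render_summary(summaries: list[ase_quant.AseSummary]) -> str:
    """Human-readable summary table, one row per transcript × tissue.

    Values are rounded to two decimals here only; the TSV outputs keep full
    precision.
    """
    header = f"{'transcript':<14}{'tissue':<12}{'mat:pat ratio':<22}{'class'}"
    lines = [header, "-" * len(header)]
    for s in sorted(summaries, key=lambda s: (s.transcript, s.tissue)):
        cls = str(s.classification) if s.detected else "n.d."
        lines.append(
            f"{s.transcript:<14}{s.tissue:<12}{format_summary_value(s):<22}{cls}"
        )
    return "\n".join(lines) + "\n"
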