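"""The mat:pat ratio: quantification and classification of allele use.

The statistic is ``maternal signal / (maternal signal + paternal signal)``
computed from the offspring cDNA channel intensities of the two parental
alleles at an informative site.  It ranges from 0 (paternal-only expression)
through 0.5 (biallelic) to 1 (maternal-only expression), and is invariant to
the overall fluorescence scale.

Classification intervals
------------------------
The ratio is binned as monoallelic / skewed / biallelic on each parental
side.  The bin edges 0.20, 0.35, 0.65 and 0.80 are assigned to the
monoallelic and biallelic bins (closed endpoints), leaving the skewed bins
open:

=====================  ======================
interval               class
=====================  ======================
[0.00, 0.20]           paternal_monoallelic
(0.20, 0.35)           paternal_skewed
[0.35, 0.65]           biallelic
(0.65, 0.80)           maternal_skewed
[0.80, 1.00]           maternal_monoallelic
=====================  ======================

Aggregation is per-SNP ratios → per-animal mean → group mean ± SEM across
animals (sample SD, n−1 denominator; SEM undefined at n = 1).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

from .errors import TranscriptNotDetectedError, ValidationError
from .genotyping import TrioSite
from .trace_io import SiteSignal


class AllelicClass(enum.Enum):
    """Five-way classification of a mat:pat ratio."""

    PATERNAL_MONOALLELIC = "paternal_monoallelic"
    PATERNAL_SKEWED = "paternal_skewed"
    BIALLELIC = "biallelic"
    MATERNAL_SKEWED = "maternal_skewed"
    MATERNAL_MONOALLELIC = "maternal_monoallelic"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class AseMeasurement:
    """mat:pat ratio for one SNP in one animal/tissue/transcript."""

    animal_id: str
    tissue: str
    transcript: str
    site_id: str
    ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise ValidationError(f"ratio {self.ratio} outside [0,1]")


@dataclass(frozen=True)
class AseSummary:
    """Group summary for one transcript × tissue.

    ``detected=False`` rows carry no numeric fields and render as "n.d.".
    ``sem`` is ``None`` when only one animal contributed.
    """

    transcript: str
    tissue: str
    detected: bool
    n_animals: int | None = None
    mean_ratio: float | None = None
    sem: float | None = None
    classification: AllelicClass | None = None

    @classmethod
    def not_detected(cls, transcript: str, tissue: str) -> "AseSummary":
        return cls(transcript=transcript, tissue=tissue, detected=False)


def compute_mat_pat_ratio(
    cdna_signal: SiteSignal,
    trio: TrioSite,
    *,
    animal_id: str = "",
    tissue: str = "",
    transcript: str = "",
) -> AseMeasurement:
    """Compute the mat:pat ratio at an informative site from cDNA intensities.

    Only the two parental-allele channels enter the ratio; the other two
    channels carry baseline noise and are ignored.  Raises
    :class:`TranscriptNotDetectedError` when both parental channels are zero
    (no transcript signal at the site).
    """
    if not trio.informative:
        raise ValidationError(
            f"site {trio.site_id!r} is not informative; no parental assignment"
        )
    mat = cdna_signal.intensities[trio.maternal_allele]
    pat = cdna_signal.intensities[trio.paternal_allele]
    total = mat + pat
    if total == 0:
        raise TranscriptNotDetectedError(
            f"site {trio.site_id!r}: no signal on either parental allele"
        )
    return AseMeasurement(
        animal_id=animal_id,
        tissue=tissue,
        transcript=transcript,
        site_id=trio.site_id,
        ratio=mat / total,
    )


def classify_ratio(ratio: float) -> AllelicClass:
    """Map a mat:pat ratio in [0,1] to its allelic class (see module docs)."""
    if not 0.0 <= ratio <= 1.0:
        raise ValidationError(f"ratio {ratio} outside [0,1]")
    if ratio <= 0.20:
        return AllelicClass.PATERNAL_MONOALLELIC
    if ratio < 0.35:
        return AllelicClass.PATERNAL_SKEWED
    if ratio <= 0.65:
        return AllelicClass.BIALLELIC
    if ratio < 0.80:
        return AllelicClass.MATERNAL_SKEWED
    return AllelicClass.MATERNAL_MONOALLELIC


def aggregate_animal(measurements: Sequence[AseMeasurement]) -> float:
    """Mean ratio over the SNPs of one animal/tissue/transcript."""
    if not measurements:
        raise ValidationError("no measurements to aggregate")
    keys = {(m.animal_id, m.tissue, m.transcript) for m in measurements}
    if len(keys) > 1:
        raise ValidationError(
            f"measurements span multiple animal/tissue/transcript groups: {keys}"
        )
    return sum(m.ratio for m in measurements) / len(measurements)


def aggregate_group(
    per_animal_means: Sequence[float], transcript: str, tissue: str
) -> AseSummary:
    """Mean ± SEM of per-animal ratios; classification applied to the mean."""
    n = len(per_animal_means)
    if n == 0:
        raise ValidationError("no per-animal means to aggregate")
    mean = sum(per_animal_means) / n
    if n > 1:
        var = sum((x - mean) ** 2 for x in per_animal_means) / (n - 1)
        sem = math.sqrt(var) / math.sqrt(n)
    else:
        sem = None
    return AseSummary(
        transcript=transcript,
        tissue=tissue,
        detected=True,
        n_animals=n,
        mean_ratio=mean,
        sem=sem,
        classification=classify_ratio(mean),
    )
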