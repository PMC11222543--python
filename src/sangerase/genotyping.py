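"""Genotype calling from channel intensities and informative-trio logic.

A site is *informative* for parent-of-origin analysis when the offspring is
heterozygous and the mother is homozygous there: the offspring allele shared
with the mother must be the maternally inherited one, so the other allele is
paternal.  Informativeness is evaluated per mother-offspring pair; the same
SNP can be informative in one trio and not in another, and different trios
may inherit different maternal alleles at the same SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import MendelianInconsistencyError, UncallableSiteError
from .trace_io import NUCLEOTIDES, SiteSignal

#: Default secondary-peak cutoff for calling a Sanger heterozygote: the
#: minor-allele channel must reach 20% of the major one.  Conservative
#: against baseline noise while tolerant of unequal dye efficiencies.
DEFAULT_HET_THRESHOLD = 0.2


@dataclass(frozen=True)
class Genotype:
    """Called genotype at one site.

    ``minor_fraction`` is the second-highest channel intensity divided by the
    highest — the quantity thresholded to separate heterozygotes from
    homozygotes with baseline noise.
    """

    alleles: frozenset[str]
    zygosity: str  # "homozygous" | "heterozygous"
    minor_fraction: float

    @property
    def is_het(self) -> bool:
        return self.zygosity == "heterozygous"


@dataclass(frozen=True)
class TrioSite:
    """Mother and offspring genotypes at one site, with parental assignment.

    When ``informative`` is true, ``maternal_allele`` is the mother's
    homozygous allele and ``paternal_allele`` the other offspring allele;
    otherwise both are ``None``.
    """

    site_id: str
    mother: Genotype
    offspring: Genotype
    informative: bool
    maternal_allele: str | None = None
    paternal_allele: str | None = None


def call_genotype(
    signal: SiteSignal, het_threshold: float = DEFAULT_HET_THRESHOLD
) -> Genotype:
    """Call a genotype from the four channel intensities at a site.

    Heterozygous iff the minor fraction (second/top intensity) reaches
    ``het_threshold``; the alleles are the top one (hom) or top two (het)
    channels.  Exact intensity ties are broken in fixed A<C<G<T order, which
    only matters for picking *which* channels are reported, never for
    zygosity.
    """
    if not 0 < het_threshold < 1:
        raise ValueError(f"het_threshold must be in (0,1), got {het_threshold}")
    # stable sort on fixed nucleotide order makes ties deterministic
    ranked = sorted(
        NUCLEOTIDES, key=lambda n: signal.intensities[n], reverse=True
    )
    top, second = ranked[0], ranked[1]
    top_i = signal.intensities[top]
    if top_i <= 0:
        raise UncallableSiteError(
            f"site {signal.site_id!r}: all channel intensities zero"
        )
    minor_fraction = signal.intensities[second] / top_i
    if minor_fraction >= het_threshold:
        return Genotype(frozenset((top, second)), "heterozygous", minor_fraction)
    return Genotype(frozenset((top,)), "homozygous", minor_fraction)


def classify_trio_site(
    mother: Genotype, offspring: Genotype, site_id: str
) -> TrioSite:
    """Evaluate informativeness and assign parental alleles for one trio site.

    Raises :class:`MendelianInconsistencyError` when the configuration is the
    informative one (mother hom, offspring het) but the offspring does not
    carry the maternal allele — flagged explicitly rather than silently
    dropped, since it indicates a sample swap or genotyping failure.
    """
    informative_shape = (not mother.is_het) and offspring.is_het
    if not informative_shape:
        return TrioSite(site_id, mother, offspring, informative=False)
    (maternal,) = mother.alleles
    if maternal not in offspring.alleles:
        raise MendelianInconsistencyError(site_id, maternal, offspring.alleles)
    (paternal,) = offspring.alleles - {maternal}
    return TrioSite(
        site_id,
        mother,
        offspring,
        informative=True,
        maternal_allele=maternal,
        paternal_allele=paternal,
    )
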