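# Methods

## Signal model and the mat:pat ratio

A Sanger chromatogram carries four analyzed fluorescence channels (A, C, G,
T) and per-base peak locations. At an interrogated SNP the signal of each
nucleotide is read from its channel at the called base's trace index; by
default the maximum within ±4 trace samples is taken (`window` parameter)
to tolerate slightly mis-registered peaks, a common chromatogram-
quantification practice. `window=0` reads the single sample at the peak
location exactly. Enlarging the window can only increase the extracted
intensity (it is a running maximum), which the tests assert as a property.

At an informative site the maternal expression fraction is estimated as

    r = I_mat / (I_mat + I_pat)

using only the two parental-allele channels; the other two channels carry
baseline noise and are ignored. The statistic is scale-invariant (any
common gain cancels) and antisymmetric under swapping the parental roles
(`r -> 1 - r`). Both properties are asserted by tests. No background
subtraction is applied: with a baseline near 1% of peak signal its effect
on `r` is well below the classification resolution.

## Genotyping and informativeness

A genotype is called from the ranked channel intensities: heterozygous iff
the second-highest channel reaches `het_threshold` (default **0.2**) of the
highest. The threshold is a package decision — a standard secondary-peak
cutoff for Sanger heterozygote detection, conservative against baseline
noise; it is configurable everywhere it appears. Exact intensity ties are
broken in fixed A<C<G<T order, which can only affect which tied channel is
named, never the zygosity.

A trio site is *informative* when the mother is homozygous and the
offspring heterozygous; the offspring allele shared with the mother is
assigned maternal, the other paternal. Assignment is per-trio, never
per-allele-identity, so different animals may inherit different maternal
alleles at the same SNP. If the informative configuration holds but the
offspring lacks the maternal allele, a Mendelian-inconsistency error is
raised and the pipeline logs the site rather than silently dropping it —
such sites indicate sample swaps or genotyping failure and must be audited.

## Classification intervals

The published interval descriptions overlap at their shared endpoints
(0.20, 0.35, 0.65, 0.80). This package closes the monoallelic and biallelic
intervals and leaves the skewed intervals open:

    [0, 0.20] pat-mono | (0.20, 0.35) pat-skew | [0.35, 0.65] biallelic |
    (0.65, 0.80) mat-skew | [0.80, 1] mat-mono

This convention reproduces every reported per-animal call we encode in the
tests (0.20 → monoallelic, 0.34 → skewed, 0.62 → biallelic, 0.75 →
skewed) and makes the classification a true partition of [0,1]: total,
single-valued and monotone, asserted by a property test.

## Aggregation

Per-SNP ratios are averaged per animal ("mean of multiple SNPs"), then the
per-animal means are summarized as mean ± SEM across n animals, with SEM =
sample standard deviation (n−1 denominator) / √n, undefined (omitted) at
n = 1. Classification is applied both to each per-animal mean and to the
group mean; both tables are emitted. Whether per-SNP ratios should instead
be pooled at the signal level before averaging is an open choice;
per-SNP-then-average is implemented because it weights SNPs equally and
keeps each SNP auditable. Rendered summaries round to 2 decimals
("0.24 ± 0.04 (4)"); the TSV outputs keep full precision. A transcript ×
tissue combination that was assayed but yielded no parental-allele signal
is reported as "n.d." rather than dropped.

## Synthetic trio data

`simulate_trio_dataset` emulates the study design: per SNP, a homozygous
mother (one channel near `total_signal`), an offspring gDNA heterozygote
with a 50/50 split, and offspring cDNA split θ/(1−θ) between the maternal
and paternal alleles. Defaults: 10 animals × 3 SNPs, `total_signal` 1000
fluorescence units, `noise_cv` 0.1, `baseline` 10 (≈1% of signal, a
realistic Sanger noise floor). Noise is multiplicative lognormal with mean
1 and sd/mean = `noise_cv` — fluorescence is positive and its dispersion
scales with the mean — and the ratio's scale invariance makes results
insensitive to `total_signal`. Only informative sites are generated by
default; `n_noninformative` adds mother-heterozygous sites to exercise
filtering.

What the generator does **not** emulate: base-calling errors, dye blobs,
mobility shifts, primer-proximal intensity decay, PCR allelic drop-out or
amplification bias, and RT efficiency differences between alleles. Passing
recovery tests therefore demonstrates correctness of the quantification
arithmetic and plumbing under a realistic noise magnitude, not robustness
to every artefact of real traces.

`simulate_chromatogram` writes a minimal ABIF file (analyzed channels
DATA9–12 in GATC order, PBAS2/PLOC2 base calls and peak locations, SMPL1
metadata) with single-sample peaks at regular spacing; it exists so the
trace reader is exercised end to end without storing binary fixtures.

## Locus architecture

* **Gap**: for two genes on one sequence, `gap_bp = start(later) −
  end(earlier)` where "later" has the greater start. The orientation-free
  formulation keeps the published magnitudes regardless of which gene sits
  first on an assembly and is symmetric in its arguments; a negative gap
  flags overlapping gene bodies rather than being clamped. No −1
  "bases strictly between" correction is applied — the value is the simple
  coordinate difference. Genes on different sequences are reported
  unlinked with no gap.
* **Repeats**: RepeatMasker `.out` hits (standard 15-column layout, 1-based
  inclusive query coordinates) are clipped to the interval; same-class hits
  are merged before class bp is counted, so nested/overlapping annotations
  are not double counted (per-element totals deliberately use raw clipped
  lengths). Class/family strings map to the summary classes {SINE, LINE,
  LTR, DNA, Simple_repeat, Low_complexity, Other} by their prefix before
  "/". Percentages are relative to the interval length. Counting merged
  rather than raw bp is a documented package choice.
* **CpG density**: per non-overlapping window, 100 × (overlapping-scan CG
  dinucleotide count) / window length; a dinucleotide straddling a boundary
  belongs to the window of its first base; dinucleotides containing N are
  not counted; the final partial window is normalized by its own length.
  This is the simplest reading of "CpG density as a percentage"; the
  definition is documented so tracks are comparable across runs. CG is its
  own reverse complement, so whole-sequence density is strand-symmetric
  (property-tested on full windows).
* **Divergence join**: case-insensitive left join of species onto a
  user-supplied TSV of divergence times (mya); duplicates in the table are
  an error, unmatched species keep a missing value; rows sort by divergence
  then species.

## Numerical and degenerate-input choices

* All-zero channel intensities: uncallable site (error, logged by the
  pipeline), since 0/0 has no genotype interpretation.
* Both parental cDNA channels zero: "transcript not detected", propagated
  to an `n.d.` summary row rather than a ratio.
* Empty measurement sets are errors, never silent zeros.
* Peak tables round-trip floats exactly (`float_precision="round_trip"` on
  read).
* Pipeline runs are deterministic: re-running on identical inputs produces
  byte-identical output files.

## Problem sizes

Recovery checks use 10 animals × 3 SNPs per θ at `noise_cv` 0.1 with fixed
seeds — at that size the group-mean ratio concentrates well within ±0.05 of
θ, the tolerance the tests assert, while the whole suite stays fast. The
acceptance script uses the same sizes, plus single noiseless trios for the
exact θ = 0 and θ = 1 boundary cases.

## Known limitations

* Peak-height ASE is semi-quantitative; dye- and context-dependent
  incorporation biases can shift ratios by several percent, which the
  classification bins absorb but the raw ratios inherit.
* The het-calling threshold trades sensitivity against baseline noise; at
  very low minor fractions (<0.2) true heterozygotes are called homozygous
  by design.
* The CLI `pipeline` command covers extract→genotype→ASE→summary in one
  step; the staged `genotype`/`report` commands exchange TSVs, with the
  per-SNP ratio table (`per_snp.tsv`) serving as the intermediate ASE
  table.
* Statistical tests against 0.5 are out of scope; the package reports
  means, SEMs and interval classes only.
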