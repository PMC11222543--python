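# sangerase

Parent-of-origin allele-specific expression (ASE) from Sanger chromatogram
peak heights, plus comparative locus-architecture utilities.

## The problem

Genomic imprinting — parent-of-origin-dependent monoallelic expression — is
classically assayed without RNA-seq: genotype a mother and her offspring at
transcribed SNPs, find *informative* sites (offspring heterozygous where the
mother is homozygous, so the maternally inherited allele is known), then
Sanger-sequence the offspring cDNA and compare the fluorescence peak heights
of the two alleles. This package turns that procedure into a tested,
reusable pipeline, aimed at developmental and evolutionary biologists
studying imprinted loci (e.g. the *TH*/*INS* region) in species without
inbred crosses.

## The statistic

At an informative SNP the maternal expression fraction is estimated by the
**mat:pat ratio**

```
r = I_mat / (I_mat + I_pat)
```

where `I_mat` and `I_pat` are the cDNA channel intensities of the maternal
and paternal alleles. `r = 0` is paternal-only expression, `0.5` biallelic,
`1` maternal-only. Ratios are averaged per animal across SNPs, then
summarized across `n` animals as mean ± SEM and classified:

| interval       | class                 |
|----------------|-----------------------|
| [0.00, 0.20]   | paternal monoallelic  |
| (0.20, 0.35)   | paternal skewed       |
| [0.35, 0.65]   | biallelic             |
| (0.65, 0.80)   | maternal skewed       |
| [0.80, 1.00]   | maternal monoallelic  |

The locus-architecture side computes intergenic gaps between orthologue
pairs from GFF3, repeat-class composition of the intervening DNA from
RepeatMasker `.out` files, CpG density tracks, and joins gaps to species
divergence times — the comparative context in which imprinting of a locus
is usually interpreted.

A synthetic-data module generates trio peak tables with a known true
maternal fraction θ (and ABIF `.ab1` chromatogram fixtures, and locus
fixtures with known gaps/repeats), so every stage is testable without
animal samples or genome downloads.

## Worked example

Simulate 10 mother–offspring pairs with 3 transcribed SNPs each at a true
maternal fraction θ = 0.25 (paternally skewed expression), then run the
full pipeline:

```
$ sangerase simulate trio --theta 0.25 --seed 3 --out d
$ sangerase pipeline --peaks d/peaks.tsv --pairs d/pairs.tsv --out out
transcript    tissue      mat:pat ratio         class
-----------------------------------------------------
TX1           liver       0.26 ± 0.01 (10)      paternal_skewed
```

The summary row reads: across 10 animals the group-mean mat:pat ratio is
0.26 with SEM 0.01 — the maternal allele contributes about a quarter of the
transcript signal, a paternally skewed pattern, recovering the simulated
θ = 0.25. `out/` also holds `per_animal.tsv`, `per_snp.tsv` (full
precision) and `exclusions.tsv`, which accounts for every animal that
contributed no measurement (not informative, not detected, Mendelian
inconsistency).

Locus architecture on a synthetic fixture:

```
$ sangerase locus-gap --gff loc/locus1.gff3 --genes TH,INS
TH  INS  linked=True  gap_bp=2400  overlap=False
$ sangerase repeats --rmout loc/locus1.out --interval locus1:11001-13399
class   bp    percent
LTR     601   25.05
...
```

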