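# Methods

## Coordinates and formats

All in-memory coordinates are 0-based half-open (BED convention); every
tab-separated dialect that exposes 1-based positions (variant tables,
per-base coverage files, gene-model TSVs, SNP catalogs) converts exactly
once, at the I/O boundary in `retpanel.io`. The variant-table dialect is a
headered TSV (`>` header line) with ref/alt alleles, total and
variant-supporting read counts; the coverage dialect carries per-base
average quality in column 4 and unique depth in column 5, and enumerates
every targeted base including depth-0 rows.

## Panel design

Each exon is extended by `flank_bp` (default 50) on both sides so splice
donor/acceptor context is sequenced; a `promoter_bp` window (default 1000)
is placed immediately 5′ of the transcription-start-most exon — lower
coordinates on the plus strand, higher on the minus strand — covering the
proximal promoter and 5′-UTR. The 3′-UTR lies within the last exon of the
gene model and is covered by construction. Intervals are clipped at contig
bounds (with a warning when clipped at zero) and merged per contig into a
minimal disjoint sorted cover; origin labels and gene symbols are unioned
on merge, including across genes — the alternative (keeping per-gene
duplicates) would double-count shared bases in panel size. Genes may carry
exons from several transcripts; the loader merges them into their union
before model construction. Panel statistics count genes and per-gene exons
(promoter windows count toward total target bp but are not exons).

The packaged panel table records exon counts and whole-gene spans, not exon
coordinates, so `gene_models_from_panel_table` synthesizes fixed-width
placeholder exons spread evenly over each span. Gene and exon counts are
exact; the synthetic coordinates support interval arithmetic but are not
genomic truth, and the panel's true genomic footprint in bp is therefore
not a quantity this package reproduces.

## Simulator

The simulator works at pileup level: it generates the mapper's *outputs*
(per-base unique depth and called sequence differences), not reads or
alignments, because that is the layer the downstream pipeline consumes.

- **Read lengths**: Normal(408, 48²) bp truncated at 50 bp (by resampling;
  the truncated mass at the defaults is ~10⁻¹³) and rounded to integer bp.
  These feed run-level summaries only; depth is modeled directly.
- **Depth**: per-base i.i.d. Poisson(λ) within each target, λ = 17 by
  default. If a target's GC fraction exceeds 0.70, λ is multiplied by a
  dropout factor (default 0.2), emulating failed probe design in GC-rich
  context. An optional dispersion parameter gamma-mixes λ for
  overdispersion; the default is pure Poisson.
- **Allele fractions**: at a truth-variant site with depth *n*, the
  variant-supporting count is Binomial(n, 0.5) for heterozygotes and
  Binomial(n, 0.99) for homozygotes; hemizygous X-linked variants in males
  use the homozygous fraction since a single allele is present. A row is
  emitted only when at least one supporting read is drawn, as a mapper
  reports only observed differences.
- **Errors**: spurious substitution rows appear at `sub_error_rate` per
  target base (default 10⁻⁴, a post-mapping call rate) with low allele
  balance (Binomial(depth, 0.1), floored at one read). Homopolymer indel
  rows — the dominant pyrosequencing artifact — are emitted per reference
  run of length L with probability min(0.5, a·(L−1)), a = 0.01 by default;
  the functional form is our own (monotone in run length, bounded), as only
  the error *mode* is characteristic of the platform, not a published rate
  curve. Error fractions use Binomial(depth, 0.15).
- **Multi-exon deletions**: carriers get zero depth across the deleted
  exons and no variant row — exactly the signature that motivates
  coverage-based deletion detection.
- **Reproducibility**: one master seed; sample *i* draws from
  `default_rng([seed, i])`, so per-sample output is independent of cohort
  composition and order.

The simulator emulates the statistical structure of a panel run (depth
levels, allele balance, error modes, family genotype sharing). It does not
emulate flowgrams, quality-score distributions (column 4 is a constant
placeholder, as no per-base quality model is available), alignment
ambiguity, or PCR duplicates — so passing tests demonstrate correct
*pipeline logic* under realistic statistics, not performance on real
454 data.

## Consequence annotation

A variant inside the CDS is classified by splicing the reference CDS,
applying the allele (reverse-complemented for minus-strand genes),
translating both sequences with the standard genetic code, and diffing the
proteins. This single code path handles SNVs, multi-base substitutions,
and indels on both strands; common-prefix/suffix trimming of the protein
diff right-aligns repeats, so a tandem duplication is named `dup`
naturally. Length changes not divisible by 3 are frameshifts. Variants
whose genomic span crosses an exon boundary are classified
`intronic_flank` with no protein effect (splice prediction is out of
scope). Known-SNP filtering requires an exact (contig, position, ref, alt)
match: positional matching would throw away novel alleles at polymorphic
sites. Repeat context is flagged when a variant lies in or immediately
adjoins a single-base run of ≥ 6 bp — our operationalization of
"repetitive sequence", chosen because ≥ 6 bp homopolymers are where
pyrosequencing indel errors concentrate. The deleteriousness score is
pluggable; the default is Grantham distance for missense and the scale
maximum (215) for truncating changes, standing in for external predictors
that cannot be a library dependency.

## Triage cascade

Stage order: coding → known-SNP removal → protein-changing → fraction
threshold → prioritization. The fraction step follows the consequence step
because prioritization operates on "remaining coding sequence variants";
the earlier stages are pure set filters, so the recorded survivor counts —
not the survivor set — are all the ordering affects. Frameshifts and
in-frame indels are retained alongside missense and nonsense because
validated panel findings include duplications and insertions. Thresholds
compare with ≥, so a 22.6% call passes the 20% policy and fails the 35%
one. The dynamic policy descends 0.50, 0.45, …, 0.20 and stops at the
first threshold with ≥ 1 survivor (target band 1–2); if a step jumps from
0 survivors straight past 2, the first non-empty threshold still wins,
since no grid point yields the band. The 5% step is a design choice, not a
published value. Prioritization sorts by (known-reported flag,
inheritance compatibility, deleteriousness, fraction), descending, with
positional tie-breaks; under an AR hint a variant is compatible when
homozygous or when its gene carries ≥ 2 heterozygous survivors (compound
heterozygosity, phase unknowable from the assay), and under AD/XL when
het/hemi. The known-reported lookup is an optional user-supplied table,
empty by default.

## Coverage analysis

Exon summaries exclude the ±50 bp flanks so exon-level statements match
gene-model exons; exons are numbered 1..n in transcription order
(strand-aware). Missing target bases count as depth 0 with a warning. The
cumulative curve reports, for every integer fold x from 0 to max+1, the
percentage of targeted bases with depth ≥ x. Both pooled-bases and
median-of-patient-medians cohort medians are provided (`pooled_median_depth`,
`median_of_patient_medians`) since either reading of "cohort median" is
defensible. Deletion detection: an exon zero-covered in the focal sample is
a candidate iff ≥ 80% of the *other* samples have median exon depth ≥ 5
there (both thresholds are our own; the distinction between deletion and
technical failure is narrative in the source workflow); consecutive
candidate exons in one gene merge into one candidate, and exons zero in
*all* samples are panel technical failures, never candidates. At default
depth (λ = 17 per base), a spurious all-zero 120 bp exon has probability
e^(−17·120), so false positives are effectively impossible under the study
conditions; the acceptance suite verifies exact-span recovery in ≥ 48 of 50
seeded cohorts with zero false positives.

## Segregation and diagnostic classes

Cosegregation assumes full penetrance and no phenocopies: AD — every
genotyped affected carries, no genotyped unaffected does; AR — affected
are homozygous, unaffected are not (healthy het carriers expected); XL —
affected males hemizygous, unaffected males reference, females may carry
unaffected but not be homozygous. With no informative (non-proband)
genotypes the answer is `unknown`. Clear-cut Mendelian impossibilities are
flagged with a warning, not silently absorbed. A compound-heterozygote
check is provided separately for AR pairs. The patient-level decision
table maps evidence categories to classes: cosegregates → definite; family
unavailable or a digenic two-gene hypothesis → potential; a
previously-reported dominant allele without confirming relatives, or a
healthy carrier relative → questionable; non-segregation, a single het in
a recessive-only gene, or nothing found → unsolved. The
`reported_dominant_unconfirmed` category exists because a prior literature
report is evidence that family absence alone is not — no computable rule
separates the two situations, so the category is an explicit input flag.
Percentages round half away from zero. Note that 12 definite of 23 is 52%;
the packaged cohort's potential and unsolved percentages are 13% and 26%.

## Problem sizes and numerical choices

Statistical tests on the simulator use 10⁵ draws and 3-standard-error
bands. Deletion-recovery evaluation uses 50 cohorts (seeds 1–50) of 10
samples over a 50-exon gene with one implanted 2–5-exon deletion each —
large enough that recovery failures would be visible, small enough that
the whole suite runs in well under a minute of simulation time. Dynamic
thresholds are rounded to 10 decimals to keep the 0.05 grid exact in
floating point. Fixture files are verified against packaged SHA-256
checksums at load.

## Known limitations

- Consequence annotation covers one transcript per gene and no splice-site
  or regulatory prediction; promoter/UTR variants are located but not
  scored.
- Segregation assumes full penetrance; reduced-penetrance dominant disease
  will be misclassified as non-segregating.
- The simulator's constant-quality column and i.i.d. per-base depth ignore
  alignment mappability structure and within-exon depth correlation.
- Deletion detection targets homozygous/complete dropout; heterozygous
  deletions (≈ half depth) need read-depth CNV segmentation, which is out
  of scope.
- Gene models synthesized from the packaged panel table have placeholder
  exon coordinates; any analysis needing true genomic positions must load
  real gene models via the TSV interface.
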