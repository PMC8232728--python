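# Methods

This note documents the models, parameter choices and limitations of
the package; the README gives the usage-level overview.

## Gene fixture and panel geometry

The packaged gene model is synthetic by design: real reference
coordinates are deliberately not used, so nothing in the package can be
mistaken for calls against a genome assembly (the VCF header declares
the contig as a pseudo-genome).  Its shape mirrors a very large
recessive deafness–blindness locus: 73 exons, total span exactly
800,503 nt, coding length 15,606 nt (5,202 codons).  Exon boundaries on
the coding axis are a fixed hand-designed table chosen so that every
variant position the worked examples use falls where its nomenclature
implies — e.g. exon 43 is c.8559–8681 (123 nt, in frame), exon 38
starts at c.7121, exon 57 at c.11048, and the four deep-intronic loci
sit in introns long enough that their nearest-boundary offset notation
is unambiguous (each such intron is at least twice its deepest offset).
The seed passed to `build_fixture_gene_model` redistributes only the
spare intronic length (Dirichlet-weighted multinomial, favouring a few
large introns as in real multi-hundred-kb loci); exon structure and
total span are seed-invariant.

Panel tiling places a new 112-nt probe every 90 nt across each exon
± 20 nt of flank, right-anchoring the final probe, so interior
positions are double-covered (22-nt overlap) — the probe-edge artifact
rule needs an overlapping probe to adjudicate — plus one centered probe
per deep-intronic locus: 224 probes in total.  The real panel the
design emulates used a proprietary external design pipeline whose
overlap geometry is not published; the 90-nt step is this package's own
choice and is configurable.

## Coverage model

Counts for sample *s*, probe *m* are negative binomial with mean
`depth × eff_m × copy/2` and size parameter *r* (`dispersion`):

- `depth` defaults to 1488 (the emulated study's mean per-sample
  coverage);
- `eff_m` is a per-probe capture efficiency drawn log-normally
  (σ = 1.0, mean 1), fixed per panel and shared across samples — the
  cohort-median normalization requires this sharing, and the σ = 1.0
  spread reproduces the orders-of-magnitude range (tens to >10⁴×) seen
  in real MIP data;
- `copy/2` is 0.5 for a heterozygous deletion, 1.5 for a single-copy
  duplication; homozygous loss retains a 2% residual capture background
  rather than exact zero (off-target and barcode bleed-through);
  structural dropout probes are exact zero columns;
- *r* defaults to 150, i.e. a normalized-cell coefficient of variation
  of ≈ 8.5% at full depth.  At this dispersion ≈ 0.05–0.1% of diploid
  normalized cells fall below the 0.7 deletion threshold.  A markedly
  noisier calibration (≈ 1% of diploid cells below 0.7, *r* ≈ 55) was
  considered and rejected: under the all-points run rule it caps
  heterozygous-deletion sensitivity for 7-probe events near 95%,
  incompatible with the ≥ 99% recovery the caller is validated against.

No noise model is published for the emulated assay; negative
binomial over log-normal efficiencies is this package's stated
assumption, and both knobs are exposed in `CoverageSimSpec`.

## Normalization

Four median steps: (1) scale each sample row by its median raw count
over included probes; (2) divide each probe column by its cohort
median; (3) re-scale each sample by the median of its ratios — this
polish pass matters because a multi-exon CNV spanning ~25% of the panel
biases the raw-count median of its carrier, which would otherwise
inflate the rest of the row by ~30% for a homozygous event; (4) a final
per-probe cohort-median division makes the included-cell cohort median
exactly 1.0 by construction.  The scheme is scale-invariant per sample.
Probes whose cohort-median raw count is below 20 reads are excluded
from calling (NaN cells).  A fully zero sample is an error naming the
sample.

## CNV calling

Per sample, maximal runs of consecutive *included* probes with
normalized coverage ≤ 0.7 (deletion) or ≥ 1.3 (duplication) — both
thresholds inclusive — are collected; excluded probes are transparent
(bridged) so a structural dropout cannot split a true event.  Runs of
≥ 7 qualifying probes are auto-called; runs of 2–6 are reported as the
qPCR follow-up tier; singletons are ignored as noise (logged at debug
level).  Same-type runs separated by at most one discordant included
probe are merged (`merge_gap=1`): in a 50-probe event a single probe
fluctuating back across the threshold is expected every few carriers at
the default dispersion and must not fragment the call.  `merge_gap=0`
restores strict maximal runs, and the caller is verified against a
brute-force interval-enumeration oracle in both modes.  `n_mips` counts
qualifying probes only, so a bridged or merged call can span more
panel indices than `n_mips`.

Zygosity is never asserted from depth: a mean ratio ≤ 0.15 sets a
`likely_homozygous` hint, and an allele counts twice only when an
explicit flag (wet-lab knowledge, carried in the cohort manifest /
CNV-flags table) confirms it.  Likewise, follow-up-tier calls enter
case resolution only with an explicit qPCR-confirmation flag, mirroring
how sub-threshold signals are handled in practice.  Exon spans and the
in-frame consequence are annotated from the probe footprint at exon
granularity (appropriate for events with intronic breakpoints); the
frame check uses the summed coding length of the overlapped exons.

Known limitation: duplication detection at the ≥ 1.3 all-points
threshold is Poisson-limited — for probes with efficiency below ~¼ of
the mean, a triploid cell falls under 1.3 too often for reliable
7-probe runs at any dispersion.  The statistical recovery study
therefore plants deletions (heterozygous and homozygous, 8–20 probes
for the auto-call tier and 3–6 probes for the follow-up tier);
duplication calling is verified by rule traces and the oracle.  The
2-probe minimum (a 123-nt exon at this tiling) is exercised by the
mirror cohort's single-exon deletion.

## Variant triage

The three drop filters (frequency, read fraction, probe edge) are pure
predicates, so the kept/dropped partition is order-invariant; the
recorded `drop_reason` follows the canonical order frequency → read
fraction → edge → database-benign.  Missing annotations are treated
conservatively: a missing population frequency keeps the variant
(novel), a missing in-silico score fails its criterion.  The 4-of-5
missense rule is applied as the qualifying-VUS criterion for all
phenotypes, not only the arRP inclusion context it originated in —
one consistent rule, threshold configurable.  The splice-assay gate
follows the 2-of-4 ≥ 0.2 rule exactly; variants with exactly one delta
at threshold are logged as near-misses for manual review
(`splice_near_miss`), since assay practice is sometimes more lenient
than the written rule.

Tier assignment (operational, not ACMG): stop-gain / frameshift /
canonical-splice → pathogenic; database P/LP → that tier;
splice-gate-positive **and** functionally confirmed (minigene assay
flag, an input like the in-cis flag) → pathogenic; criteria-passing
missense without database support → qualifying VUS; everything else
kept → VUS.  Database benign/likely-benign → excluded.  The
`functionally_confirmed` input exists because a synonymous variant with
a demonstrated splice effect is classified by the assay result, which
the pipeline consumes but cannot produce.

## Case resolution and summaries

`solved_PLP` (≥ 2 P/LP allele count), `solved_with_VUS` (exactly one
P/LP plus ≥ 1 qualifying VUS), `monoallelic`, `unsolved` partition the
cohort; both solved tiers count toward the solve rate, and the strict
biallelic-P/LP count is always reported alongside (the two published
headline counts differ in exactly whether VUS-containing cases are
included).  Alleles are deduplicated by description so a pre-screened
allele re-detected by the panel is not double-counted; phase is assumed
trans absent an explicit cis flag.  Integer percentages take the
convention as a parameter: round-half-up reproduces 26/29 → 90 and
32/40 → 80, truncation reproduces 6/11 → 54; published yields mix both,
so neither is hard-coded.

## Synthetic cohorts

The study-mirror cohort plants a fixed 40-case genotype plan
(29 USH2 + 11 arRP): 29 biallelic-P/LP cases, 3 P/LP + qualifying-VUS
cases, 7 monoallelic, 1 with no allele in the gene (solved externally);
9 CNV alleles across 4 distinct events (one recurrent 19-exon deletion
on 6 alleles including one homozygote; three sub-threshold events
carrying qPCR-confirmation flags).  SNV alleles come from a catalog of
recurrent/known variants with fixed annotations; the three
qualifying-VUS missense entries are synthetic stand-ins (marked as such
in the catalog) because the study's own VUS are not reproducible
without its appendix data.  Read fractions are drawn ~N(0.5, 0.05)
clipped to [0.3, 0.7] for heterozygous calls (≈ 0.97 for homozygous);
three catalog variants carry fixed sub-15% read fractions to exercise
the database-rescue rule.  `inject_annotation_noise` appends labelled
decoys — common variants (MAF 2–30%), low-read-fraction artifacts,
probe-edge artifacts unsupported in the overlapping probe, and
database-benign variants — whose planted drop reason the cascade must
reproduce exactly.

What the generator does **not** emulate: read-level errors and
alignment artifacts (annotations are planted, not computed), linkage
between variants (phase is an input flag), population structure in
allele frequencies, batch effects between sample pools, and the
coverage correlation structure of shared capture chemistry.  Passing
tests therefore validate the decision logic and the depth-signal
statistics, not robustness to upstream bioinformatics noise.

## Numerical and degenerate-input choices

Thresholds are compared inclusively exactly as printed (≤ 0.7, ≥ 1.3,
MAF ≤ 1%, read fraction ≥ 15%, delta ≥ 0.2, Grantham ≥ 80, CADD ≥ 15,
PhyloP ≥ 2.7).  Normalization requires ≥ 3 samples (the cohort
reference is a median).  `deleted_aa_count` is a closed-form inclusive
span; deletions with unknown intronic breakpoints report their exon
span as the event length.  The Grantham matrix is embedded as static
data; tests cross-check the transcription against the
composition/polarity/volume formula (one pair, Asp–Trp, is known to
deviate from recomputation by ~10 units in the canonical printed table
and is allowed for explicitly).  Study sizes used by the validation
suite — 100 cohorts × 40 samples × 224 probes, 200 random oracle
matrices — were chosen to give tight binomial bounds on the recovery
rates while keeping the default test run fast.
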