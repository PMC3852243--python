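# Methods

## Exonic regions

All coordinates are internally 0-based half-open; GFF3/GTF input (1-based
inclusive, both `ID`/`Parent` and `gene_id`/`transcript_id` dialects, parsed
with gffutils) is converted on read. Exons from every isoform of every gene
are pooled regardless of strand and merged into connected components under
strict interval overlap: two exons overlap iff they share at least one base,
so bookended (touching) exons do **not** merge. Each component becomes one
maximal exonic region spanning the component union.

`n_source_exons` counts *distinct* exon intervals: an exon annotated
identically in five isoforms is still a single-exon (`S`) region. Region ids
are assigned after sorting by (chromosome, start): `S####_SI` for
single-distinct-exon regions, `F####_SI` otherwise, `####` a 1-based index
zero-padded to at least four digits, `_SI` an opaque literal tag. The
partition singleton + alternate-start/end + cross-gene always equals the
region total.

Within one gene, a region is *constitutive* when it derives from one
identical exon present in every isoform, *common* when every isoform
overlaps it but boundaries differ (or several exons merged), and
*alternative* otherwise. Cross-gene regions (exons of more than one gene)
are reported but classified `unclassified` and excluded from differential
testing and enrichment.

## Quantification and filters

A read increments every region any of its aligned blocks overlaps by ≥ 1
base, at most once per region (spliced alignments contribute each `N`-split
block separately). Unmapped, secondary and supplementary records are
ignored; duplicates are not removed. Expression is
`RPKM = count × 1e9 / (length_bases × total_mapped_reads)` on the natural
log scale. Zero-count observations are missing values, not pseudocounted —
the model simply drops them.

Filtering: regions with no reads in any sample are dropped; a region is
untestable for a design when some treatment group has no detected sample,
or some group's detected values (≥ 2 observations) show zero variance.

## The per-region model and calling

Each testable region gets a one-way fixed-effect cell-means model over its
(genotype, sex) cells. A contrast (difference of two cell means) is tested
with the pooled residual variance across *all* cells of that region
(t-statistic, residual df = observations − occupied cells). Fitting one
model per region and expressing every comparison as a contrast within it is
what gives the test its power: with the full design (12 cells × 3
replicates) the residual df per region is ~24 instead of the 4–6 a
two-group test would have. Benjamini–Hochberg is
applied once to the pooled raw-p vector across all regions *and* all
contrasts (statsmodels' `fdr_bh`).

Fold change is `exp(estimate)`, so the ≥ 2-fold gate is
`|estimate| ≥ ln 2`. The over-expression gate requires significance
(FDR p < 0.20), the fold gate, and sign agreement against **both** wild-type
strains of the matching sex; the loss-of-function gate requires significance
and sign agreement in all four null-vs-wild-type comparisons with no fold
gate (absolute expression differences are smaller in loss-of-function than
under GAL4/UAS over-expression). Sign agreement is enforced in both
families. A gene is induced (repressed) for a condition when at least one of
its regions is; genes carrying both calls through different regions keep
both memberships and are flagged ambivalent.

Defaults (FDR 0.20, fold 2.0) are arguments, not constants.

## Gibbs site sampler

The SELEX clone inserts are modelled as one binding site per sequence
(OOPS): inserts are 26 nt and each sequenced clone is one selected binder.
The sampler initialises one (position, strand) site per sequence uniformly,
then iterates: withhold one sequence; build the 4×W count matrix from the
others' sites with pseudocounts (default 0.25/cell) and the background from
the others' non-site positions; sample the withheld sequence's site among
all windows on both strands with probability proportional to the
PWM/background likelihood ratio. After each sweep a phase-shift move tries
sliding every site by ±1–2 positions and keeps the best — without it the
sampler visibly locks into off-by-one local optima. The best configuration
across sweeps and restarts (default 3 restarts × ≤ 100 sweeps, early stop
after 30 sweeps without improvement) is kept, scored by the information
content of the site alignment (bits, uniform reference); the tracked best
is monotone non-decreasing by construction.

Both strands are sampled because an inferred motif's orientation is
arbitrary; the final model is reported in the orientation read on the
forward strand by the majority of sites, which makes the consensus
deterministic and, for directionally cloned inserts, recovers the planted
orientation. Consensus ties break alphabetically. Runs are bit-reproducible
given a seed. A width-scan helper reruns the sampler over a width range and
reports IC per free parameter (IC / 3W) for width choice; the three Fru
motif widths (6, 7, 10) are otherwise taken as given.

Two independent selections are compared with `consensus_agreement`: the
best per-column match fraction over all offsets and both orientations,
normalised by the larger width so only a full-width agreement scores 1.0.

## Scanning and enrichment

A gene's scan region is its annotated span ± 2 kb, clipped to the
chromosome — introns included, hits counted wherever they fall in that
window, unnormalised. Exact-word mode requires equality with the consensus
(or its reverse complement, reported on the minus strand); PWM mode
thresholds the log-odds score at a fraction (default 0.85) of the maximum
achievable score. Windows containing N are skipped. Neither mode is
MAST-equivalent (MAST's E-value machinery is deliberately out of scope);
both are verified against an exhaustive window-scoring oracle.

Every enrichment question is a 2×2 table over a fixed gene universe:
expected counts are `row × column / N`; the chi-square is Pearson's without
continuity correction (df = 1, verified against the closed form
`N(ad−bc)² / (r₁r₂c₁c₂)`), with its tail probability from the χ²₁
distribution; the Fisher p is the two-tailed point-probability sum (scipy),
verified against margin-fixed hypergeometric enumeration. Published
enrichment rows can be rebuilt from their printed margins because the
expected count inverts to the genome-wide motif-positive total
`M = expected × N / set_size`; a trustworthy row inverts to an integer.
Chromosome-arm enrichment runs one such table per arm (X, 2L, 2R, 3L, 3R, 4)
and flags arms at Fisher p < 0.05 with an enriched/depleted direction;
per-arm tests are deliberately not multiplicity-corrected, matching the
convention of flagging individual arms at 0.05.

## Synthetic data: what it emulates, and what it does not

`generate_gene_models` places genes along the six arms with master exon
chains and derived isoforms (skipped exons, shifted first/last boundaries, a
controlled fraction of cross-gene overlaps). Its truth record computes the
expected regions with an independently coded pairwise union-find oracle,
not the production sweep. `generate_counts` draws negative-binomial counts
(variance μ + φμ², default φ = 0.1; φ = 0 degenerates to rounded means)
around per-region lognormal baselines, per-genotype lognormal strain
factors (default scale 0.1), and planted per-condition folds.
`generate_selex_clones` plants a word at a random offset in each insert
(the published selection oligo's 26-nt random core and constant flanks are
available as constants), mutating planted bases at a given rate; the word
is planted in insert orientation by default because the clones were
directionally ligated. `generate_genome_with_sites` builds a GC-controlled
background scrubbed of accidental exact motif matches on both strands, then
plants consensus words in chosen genes' scan regions — so in exact-word
mode the scanner's gene × motif table equals the planting truth exactly;
the per-gene truth is evaluated against every gene's scan region, so sites
falling in overlapping flanks are attributed to all genes that see them.

Recovery studies use the conditions they state: the differential-expression
study plants fold 4 in 100 of 2,000 single-region genes across the three
over-expressor male cells of the full design, with total residual noise
σ(ln) ≈ 0.3 (φ = 0.08 plus count noise at ~100 reads/region) and equal
strain means, then applies the full gating; the binding-site study plants
sites at probability 0.9 in 100 of 500 widely spaced, non-overlapping genes
versus 0.3 elsewhere, which makes per-gene presence independent and the
null table exactly multinomial. Simulation sizes (2,000 regions, 500 genes,
20–50 seeded replicates) were chosen as the smallest that estimate the
rates stably.

What passing these tests shows is that the implementation recovers what the
generator plants under the stated noise; it does not show robustness to
features the generator omits: real read-mapping artifacts (multireads,
positional bias), correlated biological replicates, overdispersion varying
with expression, motif degeneracy beyond per-base mutation of a fixed word,
or a realistic base-composition landscape (the background is i.i.d. at a
fixed GC).

## Numerical and degenerate-input conventions

Missing observations propagate as NaN and are dropped per region; a
contrast with an all-missing group is skipped with a recorded reason, as is
a region with zero residual df. A region whose fit has zero residual
variance gets p = 1 for zero estimates and p = 0 otherwise. BH-adjusted
values are capped at 1 and never below the raw p. The chi-square refuses
tables with a zero expected cell (the Fisher test has no such restriction).
Consensus and argmax tie-breaks are alphabetical; scan hits are ordered by
position with plus before minus. All samplers take an explicit seed and are
reproducible bit-for-bit.

## Known limitations

- The exact Gibbs variant, iteration counts and convergence rule of the
  original SELEX analysis are unpublished; the classic site sampler with
  the documented defaults stands in, and only seeded-recovery behaviour is
  claimed.
- The scanner is not MAST; published genome-wide site counts for specific
  genes are not reproducible without the original annotation build and
  scoring threshold, and are not attempted.
- The linear model assumes homoscedastic cells within a region
  (one pooled variance); no automatic model-assumption rejection is
  implemented, matching the absence of a stated criterion.
- Whether loss-of-function calling required direction agreement across its
  four comparisons was implied but not stated; it is enforced here.
- The over-expression/loss-of-function overlap-association test is provided
  both pooled and per direction, since the original conditioning is
  unstated.
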