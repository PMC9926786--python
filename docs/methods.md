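# Methods

## Data model and coordinates

All intervals are held internally as 0-based half-open `[start, end)`.
CpG count tables arrive 1-based (bedGraph / CX-report convention) and are
converted on read; written reports restore 1-based coordinates. A CpG is
identified by the `+`-strand cytosine of its dyad: a record on the `-`
strand is folded onto the paired cytosine one base to the left and its
counts summed, so one record per dyad results (symmetric-CpG pooling).
Whether the upstream methylation caller merged strands is a convention
this package fixes, not something the input format encodes — inputs that
are already dyad-merged pass through unchanged.

Chromosome names are compared as exact strings; no `chr` normalization
is applied, to avoid silently mixing assemblies.

## DMC calling

Replicate samples of a group are pooled by summing counts; the pooled
fraction is then the coverage-weighted mean of the per-sample fractions.
Only CpGs with coverage ≥ `min_coverage` (default 3) in *both* groups
are tested. A site is a DMC when

* |Δβ| = |m_A/n_A − m_B/n_B| **strictly** exceeds `delta_threshold`
  (default 0.2), and
* the two-sided Fisher exact p-value is **strictly** below
  `p_threshold` (default 0.05).

Both inequalities are strict because that is the natural reading of
"> 0.2" and "< 0.05" thresholds; a Δβ of exactly 0.2 is not called.
p-values are *not* multiplicity-adjusted at the DMC stage (the raw
threshold is the operative definition); the run log notes this.

Pooling rather than replicate-level modelling is deliberate: the
replicate structure enters only through the pooled coverage and,
optionally, through the credible statistic below. A full hierarchical
beta-binomial treatment (as in MOABS-style callers) is out of scope; on
data with strong replicate-level dispersion the Fisher test on pooled
counts is anti-conservative, which is a known limitation.

### Credible difference option

With `statistic="credible"` the effect statistic is derived from
independent Beta(m + ½, n − m + ½) (Jeffreys) posteriors for the two
group fractions: the central 95% interval of β_A − β_B is formed, and
the statistic is the distance from zero to the nearer endpoint, or zero
when the interval spans zero. It never exceeds the raw |Δβ| and shrinks
noisy low-coverage effects toward zero. The interval is computed
deterministically from the product of 512 posterior quantiles per group
(grid product, no Monte Carlo), so results carry no seed dependence.
The Fisher p-value is retained as the significance component.

## DMR assembly

Within one direction (hyper and hypo are processed independently — an
intervening opposite-direction DMC does not break a run), every run of
`min_dmcs` (default 3) consecutive DMCs whose positional span
(last − first) is ≤ `window_bp` (default 300, inclusive) seeds a region;
seeds sharing a DMC merge transitively, and each merged component is one
DMR spanning its outermost DMCs (end = last position + 1). The inclusive
span reading matches a 300-bp window slid at 1-nt steps with inclusive
endpoints; the test suite holds the assembler equal to that literal
window-enumeration oracle on randomized layouts. Same-direction DMRs in
one catalog can therefore never overlap.

## Cross-contrast classification

*Shared* always means ≥ `min_overlap_bp` (default 1) overlapping base
pairs on the same chromosome.

* **Temporal aging categories.** Each early-contrast (8 vs 2 months) DMR
  is classified against the late contrast (16 vs 8 months):
  `inverse` if any opposite-direction late partner exists, else
  `progressive` if any same-direction partner exists, else
  `early_single`; unpartnered late DMRs are `late_single`. Inverse takes
  precedence over progressive when partners of both directions exist —
  the categories must be exclusive and the inverse pattern is the
  biologically interesting one; the partner list still records every
  overlap, so the choice is auditable.
* **Aging × regeneration.** Every overlapping (regenerative, aging) DMR
  pair yields one record labelled `synchronous` (equal directions) or
  `inverse`; a DMR may appear in several records.
* **Three-way Venn.** DMRs of one direction from the three regeneration
  catalogs are clustered into connected components under cross-catalog
  overlap; all Venn quantities count components, and a component belongs
  to every catalog contributing a DMR. Counting components (not raw
  records) prevents double-counting when one DMR overlaps two partners
  and makes |A∪B∪C| = Σ|sets| − Σ|pairs| + |triple| an identity, with
  pairwise intersections including triple members.

## Genomic annotation

The hotspot vocabulary (Gene, ExtGene, Genf, ExtGenf, 1stExon,
1stIntron, Exon, Intron, FpUTR, TpUTR, Prom1k, TSSup1k, TSSdn1k, TTS1k,
TTSup1k, TTSdn1k, Center30ct, TSS-7k, plus pass-through rmsk / cgi /
SINE / LINE / LTR / Simple_repeat) is derived from refFlat-like gene
models. All upstream/downstream and "first" notions are strand-aware:
for a `-` gene the TSS is the transcript end and upstream means larger
coordinates. Center30ct is the central 60% of the transcript span with
boundaries rounded toward the center. FpUTR/TpUTR require CDS
coordinates and are emitted empty (with a warning) without them.
Windows are clipped to `[0, chrom length)` when a sizes file is given,
else clipped at zero with a warning. Multi-isoform inputs are treated
row-by-row; gene-level maps deduplicate by gene id.

A DMR counts toward a region class when it overlaps any interval of the
class ≥ 1 bp; classes are intentionally not mutually exclusive, and
percentages are per-direction (count / direction total × 100).

DMR→gene mapping uses the promoter window −7 kb/+3 kb of the TSS
(strand-aware) and the gene body `[tx_start, tx_end)`; one row per
(gene, DMR, zone). `TSS-7k` (the 7-kb-upstream-only hotspot class) is a
distinct track from the mapping window, since the two serve different
reporting surfaces.

## DEG filtering and linkage

Genes are classified up/down/ns by corrected p ≤ 0.05 (inclusive) and
|fold change| ≥ 2 (inclusive), with log2fc > 0 meaning higher expression
in the treated/later condition. When the table lacks corrected values,
Benjamini–Hochberg q-values are computed over all raw p-values
(statsmodels step-up); supplied q-values are used as-is without
re-adjustment. Linkage keeps direction-matched pairs only (promoter
hypo-DMR ↔ up-DEG, hyper ↔ down), defaulting to the promoter-only zone
with `promoter+gBody` available; summaries report DMR-level and
gene-level counts separately since one DEG may collect several DMRs.
Flip genes are DEGs with ≥ 1 early-aging promoter DMR synchronous with
the expression direction *and* ≥ 1 mid-to-late-aging promoter DMR
inverse to it; the set equals the gene-level intersection of a
synchronous early pass and an inverse late pass, which the tests assert
as an identity.

## Synthetic methylomes

The generator emulates replicate WGBS count data for six conditions:
baseline ages A2R0/A8R0/A16R0 and post-hepatectomy days A2R1/A2R2/A2R4,
four replicates each, with regeneration contrasts sharing the A2R0
reference.

* **Positions** — irregular, drawn uniformly without replacement on even
  coordinates (dyads never collide); irregular spacing is what actually
  exercises the 300-bp window rule.
* **Baseline** — per-CpG β ~ Beta(0.7, 0.25), a U-shaped landscape with
  mean ≈ 73.7%, matching the ~74% bulk-liver global methylation level.
  Only *shifted* fractions are clipped (to [0.02, 0.98]); the untouched
  baseline keeps its distribution, which the KS-distance test checks.
* **Coverage** — Poisson with mean 10 per sample (negative binomial
  optional); methylated counts Binomial(coverage, condition β).
* **Planted regions** — condition fractions are built cumulatively
  (A16 = A8 + late shift, A8 = A2 + early shift; each regeneration day
  adds its own shift to A2R0), so an early-only region persists into
  A16 as an *early single* event rather than silently reverting.
  Planted-region baselines are drawn with headroom so every condition
  stays inside (0.05, 0.95). Default effect Δβ = 0.3 with 10 CpGs inside
  ≤ 280 bp — a realistic CpG-island-like density comfortably above the
  3-DMC recovery floor.
* **Default layout** — 12 single regions per contrast-direction across
  the five called contrasts, 20 progressive + 20 inverse aging regions,
  6 + 6 aging×regeneration shared regions (synchronous ones in early
  aging, inverse ones in mid-to-late aging, mirroring the liver
  biology), four flip genes (with promoter-planted early/late regions at
  ≥ 20 bp margin inside the −7k/+3k window) plus sync-only and
  pattern-free DEGs, each DEG also carrying a direction-matched
  regenerative promoter region. Totals ≈ 240 planted region-contrast
  pairs on 2 × 1.2 Mb chromosomes with ~30,000 background CpGs — sized
  so a full pipeline run takes seconds while leaving >100 planted
  regions per recovery measurement.
* **DEG table** — planted DEGs get |log2fc| = 1.5 and p ~ U(10⁻⁸, 10⁻⁵)
  (survives BH at any sane table size); background genes get
  log2fc ~ N(0, 0.3) and p ~ U(0, 1), so the BH path is genuinely
  exercised.

Everything is driven by one `numpy` Generator seeded from the config;
identical configs give byte-identical outputs, which the suite asserts.

### What the generator does *not* emulate

Replicate-level biological dispersion beyond binomial sampling, chromatin
domain structure, CpG-density coupling to CGIs, non-CpG methylation,
sex-chromosome effects, and read-level artifacts (conversion failure,
mapping bias). Passing recovery tests therefore demonstrates correctness
of the calling/classification logic under the stated noise model, not
performance on real WGBS libraries — on real data with overdispersed
replicates the pooled Fisher test will call more sites than the planted
truth suggests.

## Numerical and degenerate-input choices

* Fisher p-values are cached per 2×2 table within a call, and only
  computed for sites whose raw |Δβ| passes the effect threshold (valid
  for the credible statistic too, since it never exceeds |Δβ|).
* Venn components use union-find; the test oracle uses an independent
  graph-traversal implementation.
* Empty catalogs: hotspot percentages are defined as 0; an empty BED is
  written without a header.
* Single-exon genes: Genf spans the sole exon, 1stIntron is empty.
* Ties at interval boundaries: all intervals are half-open, so abutting
  regions ([100,300) vs [300,400)) do not overlap.
* Degenerate planted configs fail fast with the offending region named
  (too few CpG positions; no baseline headroom for the cumulative shifts).

## Scoring recovery

A planted region counts as recovered when a called DMR of the same
contrast and direction overlaps it ≥ 1 bp; a called DMR is a true
positive when it overlaps any such region. Temporal recovery asks the
temporal classifier to reproduce the planted progressive/inverse
category on an overlapping early DMR; flip recovery compares the
reported flip-gene set with the planted one and also counts spurious
calls. The acceptance script reports all of these from a fresh seeded
run, alongside exact worked arithmetic on the published per-timepoint
set sizes (inputs) pushed through the same Venn/cross/linkage machinery.

Known bookkeeping note: the published hypo-DMR marginals imply a
"day 1 and/or day 2 only" count of 1,201 by inclusion–exclusion, while
the corresponding narrative figure differs; the hyper marginals are
self-consistent. This package reports only what inclusion–exclusion
yields and asserts the self-consistent hyper quantities.
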