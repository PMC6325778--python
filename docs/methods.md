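# Methods

This note documents the models, conventions and numerical choices behind
`mrith`, the open design decisions it had to settle, and what its validation
on simulated cohorts does and does not demonstrate about real data.

## Variant identity and input conventions

Variants are matched across regions and between tissue and plasma by a
canonical key: `chrom:pos:ref:alt` for SNVs/indels (1-based, VCF-style
coordinates) and `gene:class:event` for copy-number and fusion records,
which have no single base-pair coordinate in MAF-like tables. Exact
genomic-coordinate identity is the strictest reproducible matching rule;
gene+protein-change matching would be laxer and annotation-dependent.
Panel BED files are 0-based half-open; the conversion lives only in
`filter_to_panel`, which keeps an SNV/indel iff its position falls in a
target interval and a CNV/fusion iff its gene is a panel gene name.

Inputs are pre-called variants: alignment, variant calling and
quality-filtering are upstream of this package. Consequently the default
*presence rule* is permissive — a variant is present in a region iff it has
≥ 1 supporting read there (rows without read counts, i.e. CNV/fusion
records, always count). Re-thresholding calls that already passed an
upstream caller would silently change trunk/branch labels; the threshold is
still exposed (`min_alt_reads`) for sensitivity analyses. CNV and fusion
records participate in trunk/branch classification, ITHi and trees exactly
like SNVs.

## Trunk/branch and the ITH index

The classification is the literal all-regions rule: TRUNK iff the presence
row is all ones. Patients with a single sampled region have only trunk
mutations by this rule; they carry no heterogeneity information and are
excluded from subtype ITHi comparisons (but retained everywhere else).

ITHi is defined as the branch fraction, `n_branch / (n_trunk + n_branch)`.
Any statistic that is monotone-decreasing in the trunk fraction and bounded
in [0, 1] would order patients identically; the branch fraction is the
simplest such statistic and the one this package commits to. It is
undefined (an error) for zero classified mutations.

Subtype comparisons use the two-sided Mann-Whitney U test: ITHi is a bounded,
typically non-normal fraction, so a rank test is the conservative default.
The exact no-tie null is used when total n ≤ 20 and there are no ties,
otherwise the normal approximation with tie correction — without the
continuity correction, so that identical groups yield p = 1 exactly (the
correction's effect is negligible at the sample sizes where the
approximation is used). Raw p-values are reported without multiple-testing
correction; with one pre-specified contrast per analysis there is nothing
to correct over.

## Maximum-parsimony phylogenies

The tree model: leaves are tumor regions, plus a germline outgroup fixed to
the all-zero state at the root; characters are the binary presence rows.
The reconstruction minimizes total state changes (Fitch parsimony). Because
branch lengths are defined as mutation counts per edge, the parsimony tree
is exactly the object whose trunk and branch lengths are "proportional to
the numbers of detected mutations".

The search is exact, not heuristic: rooted leaf-labeled topologies are
enumerated by stepwise leaf insertion with branch-and-bound pruning — the
parsimony score of a leaf subset never exceeds that of a superset, so any
partial tree scoring worse than the incumbent can be discarded without
losing optima (ties are kept). At ≤ 10 regions ((2n−3)!! ≤ 34 M topologies,
and far fewer after pruning and the collapsing below) this is tractable;
more than 10 regions raises an error suggesting subsampling. Regions with
identical mutation profiles are collapsed before the search and re-attached
as zero-length cherries; identical mutation rows are collapsed into weighted
characters. Ties between equally parsimonious topologies are broken by the
lexicographically smallest canonical Newick string (children sorted by their
canonical form), making every output deterministic.

Mutation-to-edge assignment treats somatic mutations as effectively
irreversible: among assignments achieving the minimal number of changes,
the one with the fewest losses (back-mutations) is chosen, computed by a
small Sankoff-style dynamic program minimizing the pair (changes, losses)
lexicographically, with remaining ties resolved by keeping the parent's
state. A perfect-phylogeny-compatible character therefore gets exactly one
gain, on the edge above its minimal clade; in particular every all-ones
(trunk) character lands on the single germline edge, so the trunk edge
length equals `n_trunk` and `trunk_fraction_from_tree` equals 1 − ITHi on
compatible matrices. Incompatible characters (homoplasy from calling noise)
are placed on every edge where their state changes — gains and losses both
count toward edge lengths, preserving "edge lengths sum to the parsimony
score". When homoplasy *forces* a loss (no gains-only assignment attains the
minimum), a subclonal character can legitimately gain on the trunk edge, so
on incompatible matrices the trunk length can exceed `n_trunk`; this is a
property of parsimony itself, not of the implementation.

The evolution pattern is topology-free: LINEAR iff the distinct subclonal
presence patterns are pairwise nested (a chain under inclusion), BRANCHED
otherwise; patients without branch mutations are LINEAR. This matches the
intuition of a single dominant lineage vs divergent subclones and is
independent of how ties in the tree search are broken.

## Driver analysis

Driver status comes entirely from the supplied catalog (genes absent are
passengers); no de novo driver discovery is attempted. Composition tables
test each dichotomy (driver vs passenger within a compartment; oncogene vs
TSG among its drivers) with the exact two-sided binomial test against 0.5 —
each printed contrast is a single proportion against an even split, which is
what a binomial test measures; compartments with zero mutations are omitted
rather than reported as 0/0.

The dominance score is not given a closed form in the literature this
package follows; the implemented definition — the mean over carriers of the
reciprocal of the number of distinct mutated driver genes in that carrier —
was chosen because it is exactly 1 iff the gene is the sole mutated driver
in every carrier ("self-sufficient"), strictly decreases as co-drivers
accumulate, and is monotone under removing a co-driver. Co-drivers are
counted at gene level, across all regions, trunk or branch alike, because
"co-driver" is a gene-level notion.

## ctDNA concordance

A tumor-derived mutation is a tissue-confirmed mutation looked up in the
matched plasma sample; detection means ≥ 1 high-quality mutant read, where
"high-quality" filtering is assumed upstream of the input counts (the
threshold is configurable). Tissue mutations with no plasma row are counted
as assayed-but-undetected when the patient has a plasma sample at all, and
excluded when the patient has none; a flag (`count_uncovered`) switches to
excluding them, since published denominators are often ambiguous on this
point. Plasma-only variants are logged and excluded — inferring their
tumor origin is out of scope. Detection rates are pooled over mutations
(not averaged over patients): a stratum is a single binomial count, so the
pooled rate is the mutation-count-weighted mean of per-patient rates. The
trunk-vs-branch contrast is Fisher's exact test on the 2×2
detected/undetected table, exact at any count; a patient is ctDNA-positive
iff ≥ 1 tumor-derived mutation is detected.

## The simulator

The generator emulates a 32-patient NSCLC cohort: 9 EGFR-mutant LUAD,
6 KRAS-mutant LUAD, 11 EGFR&KRAS-wild-type LUAD, 5 LUSC, 1 LELC, each with
3–7 regions and Poisson(14) mutations (≈ 440 variants per cohort, of which
roughly 87% SNV, 9% indel, 3% CNV, 1% fusion). Per patient a uniform random
rooted bifurcating tree over the regions is drawn; a mutation is trunk
(root edge, all regions) with per-subtype probability θ — defaults 0.30 for
EGFR-mutant LUAD (the least clonal subtype), 0.55 for KRAS-mutant and
wild-type LUAD and LELC, 0.60 for LUSC — otherwise it lands uniformly on a
subclonal edge and is present in exactly the regions below it. Presence is
noiseless by default, so matrices are perfect-phylogeny compatible and the
pipeline must recover clonality exactly; an optional per-(mutation, region)
`dropout` rate introduces homoplasy to exercise the incompatible-matrix
code path (ground truth then remains the pre-dropout clonality).

Placements are redrawn until every region carries at least one mutation:
a sampled region with zero somatic calls would simply not appear in a
MAF-like table (region lists are derived from rows), which would otherwise
silently shrink the denominator of the all-regions rule. This conditioning
is the generative counterpart of a QC rule that discards regions without
any somatic call. Each subtype's canonical driver (EGFR, KRAS) is added as
a forced trunk oncogene SNV in its subtype — except in the degenerate θ = 0
limit, where forcing a clonal mutation would contradict the configured
trunk fraction — and EGFR/KRAS are excluded from the driver draw of other
subtypes so that simulated subtype labels agree with mutation-based subtype
inference. Driver probability and oncogene/TSG split are per-subtype
(oncogene-heavy in EGFR-mutant LUAD, TSG-heavy in LUSC); driver genes come
from a bundled ~20-gene lung-cancer catalog, passengers from a synthetic
panel-like namespace (`GENE0001`…), and coordinates are sequential on a
synthetic contig `chrS`.

Plasma counts are drawn as `Binomial(depth, q)` at constant depth 1000,
with q solved from `1 − (1 − q)^depth = p_detect` for the mutation's
(subtype × clonality) stratum, so pooled detection rates are directly
controllable. Defaults follow the trunk-detection ordering
LUSC 0.81 > WT 0.53 > EGFR 0.30 > KRAS 0.22 (LELC, for which no published
stratum rate exists, is set to 0.40) with branch detection 0.13–0.25.
Tissue read counts are cosmetic (VAF uniform on 0.05–0.5 at depth 800);
no purity/ploidy/CCF modeling is attempted. Identical seed and
configuration give byte-identical output files.

What passing on simulated data shows — and does not. The simulator makes
presence calls noiseless and regions exchangeable, so exact trunk/branch
recovery and score = mutation count are *correctness* checks of the
algorithms, not evidence about miscalled or undersampled real data. Real
multi-region data add region-dependent false negatives (purity, coverage),
which move mutations from trunk to branch and inflate ITHi; the `dropout`
knob models only the simplest version of this.

## Problem sizes and numerical notes

The test suite and acceptance script run cohorts of 32–200 patients and
parsimony searches at ≤ 7 regions (after profile collapsing, usually far
fewer leaves), sizes at which the exact search completes in milliseconds
per patient and the whole validation in well under a minute; the
statistical calibration checks use ~2000 pooled mutations, where 3 binomial
standard errors is a ±3% band. Exact-test p-values (binomial, Fisher,
Mann-Whitney) are delegated to scipy and cross-checked in the test suite
against independent exhaustive-enumeration oracles over all small
configurations (2×2 margins ≤ 12, n ≤ 12 binomials, rank splits with
n ≤ 8). Degenerate inputs have defined behavior throughout: empty matrices,
zero-mutation patients, single-region patients, empty strata and empty
groups either take a documented convention or raise a specific error, as
listed in the module docstrings.

## Known limitations

- ITHi uses presence/absence only; no cancer-cell-fraction clustering or
  VAF-based clonal deconvolution.
- The parsimony search is exact but exponential; > 10 regions are rejected
  rather than approximated.
- The dominance-score and ITHi formulas are this package's committed
  definitions of quantities whose published descriptions are directional
  only; alternative normalizations would need their own validation.
- Plasma analysis ignores CHIP, tumor-fraction estimation and plasma-only
  variants.
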