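# Methods

## Overview

`epromoter` implements an end-to-end procedure for identifying *Epromoters*
— gene promoters that also act as enhancers on distal genes — from
(Cap)STARR-seq reporter data, and for quantifying the pleiotropic
association of their variants with GWAS traits. The chain runs:

1. **STARR activity** — fragment extension, FPKM normalization, input
   filtering, fold-change ranking, knee thresholding, replicate merging;
2. **Epromoter calling** — 500-bp upstream promoters intersected with
   active enhancers under the ≥50%-of-either-feature rule, merged at ≥1 nt;
3. **Control matching** — tau tissue-specificity and expression-nearest
   control promoters;
4. **Variant pleiotropy** — LD expansion of GWAS leads (r² > 0.8, ±1 Mb),
   non-redundant trait counting, hypergeometric and chi-squared enrichment;
5. **Target linking** — eQTL proximal/distal classification (2-kb
   boundary), promoter–promoter (P–P) interaction consistency, CRISPRi
   distal-regulation screen, and the four-layer evidence intersection;
6. **Feature statistics** — CGI/G4/conservation/TFBS/CAGE/chromatin-state
   comparisons between Epromoters and controls.

Every stage is driven by a synthetic-data generator that emulates all the
inputs with planted ground truth, so the whole chain is testable offline.

## Models and procedures

### Activity calling

Coverage of a captured region is FPKM = fragments overlapping the region
(≥1 bp, `bedtools coverage` semantics) / (region kb × mapped fragments /
10⁶). Reads are first extended from their 5′ start to 314 nt, the mean
captured-fragment length. Regions with input FPKM < 1 are removed; fold
change = output FPKM / input FPKM. On the descending fold-change curve,
both axes are min–max normalized and the threshold is the value at the rank
with maximal perpendicular distance to the chord joining the first and last
points; ties break toward the smaller rank (fewer actives) and a flat curve
yields no actives. Regions strictly above the threshold are active. The
estimator is deliberately simple and is exposed as a pluggable strategy
(`threshold_fn`); its exact equivalence to exhaustive enumeration is a
tested property. Replicates are merged by keeping regions present in all
replicates (identical keys for captured regions, ≥1 bp overlap for
peak-style inputs), averaging activity, and re-thresholding.

A knee threshold always leaves the top tail of a *noise* curve above it;
on a null input (no true enhancers) the active set is therefore small but
not empty. This is intrinsic to inflection-point thresholding, not a
defect, and is why recovery is scored against planted truth rather than
against an expectation of emptiness.

### Promoters and Epromoters

A promoter is the 500-bp window upstream of a coding transcript's TSS
(strand-aware, clipped at chromosome bounds; window configurable). A
promoter is flagged when a single enhancer overlap covers ≥50% of the
promoter *or* ≥50% of the enhancer (the `-f 0.5 -F 0.5 -e` convention).
Flagged promoter regions merge by single linkage at ≥1 nt overlap, so
merging is transitive and idempotent. A gene is Epromoter-associated when
any of its transcript promoters is flagged.

### tau and control matching

tau = Σᵢ(1 − xᵢ)/(N − 1) with xᵢ the profile max-normalized: 0 for uniform,
1 for single-tissue expression; all-zero rows are undefined (NaN with a
warning). Controls are chosen greedily in lexicographic gene order: each
Epromoter gene takes the still-unassigned candidate with minimal Euclidean
distance over the tissue profile (raw values by default, `log1p`
optionally), giving an injective, one-to-one control set. Direct
nearest-neighbor distance replaces dendrogram-leaf adjacency: leaf order is
an accident of linkage, while the well-defined target of "nearest gene in
the cluster results" is the expression-nearest gene.

### LD, pleiotropy and enrichment

r² between two sites is computed from phased haplotype frequencies,
(p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B)); monomorphic sites are
undefined and rejected. Every panel variant within ±1 Mb of a GWAS lead and
r² strictly above 0.8 inherits the lead's traits (unique EFO ids) and
parent categories; leads always annotate themselves, and multi-lead proxies
union their traits. Traits per promoter are the non-redundant union over
member SNPs; ≥2 traits defines a pleiotropic element. Enrichment per trait
uses the upper-tail hypergeometric test against the genome-wide GWAS-SNP
background and a chi-squared 2×2 test between Epromoters and controls
(no continuity correction by default, exposed as a flag); BH-FDR columns
are reported alongside the raw p-values.

### Target linking

eQTLs are merged non-redundantly across tissues by (SNP, target); a SNP is
proximal when every target TSS is within 2 kb (the exact boundary counts
as proximal), distal when all are beyond, otherwise "both" — a complete
partition. A distal target is P–P consistent when an interaction anchored
in the Epromoter has its partner anchor on *any* promoter of the target
gene (alternative TSSs count); consistency is tissue-agnostic. In the
CRISPRi screen a promoter is efficiently inactivated when its own gene
ranks in the 2 most repressed genes of its perturbation profile; its 30
most repressed genes are its regulated set, and it is a distal regulator
when a regulated gene other than its own lies within 1 Mb. The
hypergeometric universe is the efficiently inactivated set (configurable,
since the universe choice is a genuinely open design point). The final
variant list is the strict intersection of four flags: consistent distal
eQTL, P–P support, MPRA allelic skew, and TF-binding skew (the last two
consumed as pre-thresholded tables).

### Feature statistics

CGI: any-overlap boolean. G4: merged coverage as % of region length
(invariant to splitting annotations). Conservation: sum of per-base scores.
TFBS: sites with score strictly above 400 only; density = retained sites,
diversity = distinct TF families. ChIP: distinct (TF, interval) peaks and
distinct biotypes. CAGE: TSS ± 500 bp window, orientation relative to the
gene strand; divergent = sense and antisense peaks, unidirectional = sense
only; signal is the strand-partitioned sum (sum rather than mean, exposed
as the aggregation choice). Chromatin states: fold(s) =
[overlap bp in s / total bp of s] / [region bp / genome bp], compared
between sets as log2 ratios.

## The synthetic world

`generate_world(SyntheticConfig)` produces a complete input bundle plus
`PlantedTruth`. Defaults (the conditions all end-to-end results refer to):

| parameter | default | meaning |
| --- | --- | --- |
| n_genes / n_chromosomes | 2000 / 4 | one gene per ~150 kb, human-like density |
| chrom_length_bp | 75 Mb | keeps the 1-Mb cis window sparse |
| frac_epromoters | 0.10 | planted Epromoter genes |
| epromoter_fold_effect | 5.0 | expected output/input enrichment of planted regions |
| background_fold_mean / sigma | 1.0 / 0.15 | region-level background activity (lognormal) |
| mean_depth / nb_dispersion | 40 / 20 | negative-binomial fragment counts per region |
| n_replicates | 2 | input and output libraries each |
| fragment_length_nt / read_length_nt | 314 / 50 | extension target and raw read length |
| n_haplotypes / ld_block_bp | 200 / 50 kb | block-copy LD panel |
| n_gwas_leads / pleiotropy_boost | 400 / 2 | planted leads carry 1 + boost traits |

Fragment counts are negative-binomial around depth × fold — overdispersed
coverage is the realistic stress case for the knee threshold. The
background noise level (σ = 0.15, dispersion 20) is the generator's
calibrated operating point: at fold effect ≥ 4 and ≥40× depth the planted
active set is recoverable at sensitivity ≥ 0.9 and precision ≥ 0.8, which
is the regime the pipeline is specified to operate in.

Gene density matters: at much denser spacing the CRISPRi top-30 rule
saturates (almost every promoter has some random cis gene among its 30
most-repressed), so the default grid keeps ~13 genes per cis-window as in
the human genome.

Expression profiles are smooth exponential-family shapes organized in 20
co-expression modules (a shared tissue program per module plus per-gene
jitter), with a per-gene temperature spanning the tau range and a
log-normal gene scale. The module structure mirrors real co-expression and
is what makes expression-nearest matching meaningful; with independent
per-gene peaks, nearest-neighbor matching systematically pairs peaked genes
with flatter ones and the matched controls are *not* neutral.

The haplotype panel is built by block-copy: four founder patterns per LD
block, random founder assignment per haplotype, 2% per-site mutation.
Planted promoter SNPs get a clean ~50%-frequency column and their proxies
copy it exactly (r² = 1 > 0.8 by construction); rare variants carry exactly
one haplotype (MAF 0.005 < 1%). Planted pleiotropic SNPs sit inside planted
Epromoter promoters; each planted gene regulates its nearest neighbor
(< 1 Mb), and that pair is consistently wired through the eQTL table, the
P–P anchors, the CRISPRi z-matrix (own gene z ≈ −8, target z ≈ −6 versus
N(0,1) noise) and the MPRA/TF-skew lists.

What the generator does *not* emulate: real sequence content, mapping
artifacts, population LD structure beyond block-copy, correlated eQTL
effect sizes, trait ontologies beyond the fixed 17-category vocabulary,
and batch effects. Passing recovery tests therefore show that the
implementation is correct and well-calibrated under these idealized
conditions, not that the thresholds are optimal on any particular real
dataset.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open throughout; VCF positions convert at
  the reader boundary. Abutting intervals share zero bases and never merge.
- Knee: flat curves return the common value (no actives); ties toward the
  smaller rank; fewer than 3 points is an error.
- Fewer than 3 regions after the input filter is an error (knee
  undefined); an empty replicate intersection warns and returns empty.
- Exact r² = 0.8 is excluded (strict inequality), exact 2,000 bp is
  proximal, TFBS score exactly 400 is dropped (strict), MAF exactly 1% is
  common (inclusive ≥).
- Monomorphic sites, all-zero expression rows, zero-bp states and zero
  no-stimulation allelic baselines are reported as errors, NaN, skips and
  missing values respectively, never silently imputed.
- The greedy control matcher breaks distance ties lexicographically and
  errors when the candidate pool is exhausted.

## Problem sizes

Unit tests run on miniature worlds (≈120 genes, 2 × 1.5-Mb chromosomes);
the end-to-end recovery and control-neutrality checks use the default
2000-gene worlds (10 seeds and 1 seed respectively), chosen so the entire
suite completes in a few minutes on one CPU while keeping every planted
effect at the default study conditions.

## Known limitations

- The knee estimator is one of several in use (the R `inflection` package
  offers ESE/EDE); results near the threshold boundary depend on the
  estimator, which is why it is pluggable.
- Control matching ignores chromatin context; it matches expression only.
- The CRISPRi universe and the tissue-agnostic P–P consistency rule are
  documented choices where the underlying procedure is underdetermined.
- `enrichment_tests` recomputes per-trait membership by scanning the
  background; for very large catalogs a sparse indicator matrix would be
  preferable.
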