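# epromoter

Identification of **Epromoters** — gene promoters that also act as
enhancers on distal genes — from (Cap)STARR-seq reporter assays, and
quantification of the pleiotropic association of their variants with GWAS
traits.

The package is aimed at regulatory genomicists who want a tested,
reusable implementation of the full analysis chain: enhancer-activity
calling, promoter/enhancer intersection, expression-matched controls, LD
expansion of GWAS leads, eQTL target classification, 3D-interaction
consistency, CRISPRi validation, and comparative feature statistics — all
exercisable end-to-end on a synthetic-data generator with planted ground
truth, so no external download is needed to develop against it or test it.

## The method in brief

**Activity.** STARR-seq regulatory activity of a captured region is the
fold change FC = FPKM_out / FPKM_in, with FPKM = n_frag / (L_kb · N/10⁶)
and fragments extended to 314 nt. Regions with FPKM_in < 1 are removed;
on the descending ranked FC curve, both axes min–max normalized, the
activity threshold is the value at the rank maximizing the perpendicular
distance to the chord between the first and last points (the
inflection/knee point); regions strictly above it are active. Replicates
are merged by intersection, averaging, and re-thresholding.

**Epromoters.** A promoter is the 500-bp window upstream of a coding
transcript's TSS. It is an Epromoter when an active enhancer overlap
covers ≥50% of the promoter *or* ≥50% of the enhancer
(`bedtools intersect -f 0.5 -F 0.5 -e` semantics); flagged regions merge
at ≥1 nt overlap.

**Controls.** Tissue specificity is
τ = Σᵢ(1 − xᵢ)/(N − 1), xᵢ = expression / max over N tissues. Each
Epromoter gene is matched to the expression-nearest non-Epromoter gene
(Euclidean distance, greedy, without replacement).

**Pleiotropy.** GWAS lead SNPs are expanded to all panel variants within
±1 Mb at r² > 0.8, r² = (p_AB − p_A p_B)²/(p_A q_A p_B q_B); proxies
inherit the lead's traits (unique EFO ids, 17 parent categories). Traits
per promoter are counted non-redundantly; ≥2 traits = pleiotropic.
Enrichment per trait: upper-tail hypergeometric vs the genome-wide
GWAS-SNP background, plus chi-squared between Epromoters and controls.

**Targets.** eQTLs are proximal (all targets within 2 kb of the TSS),
distal (all beyond), or both; distal targets are consistent when a
promoter–promoter interaction links the Epromoter to a promoter of the
target gene. A CRISPRi perturbation validates distal regulation when the
promoter's own gene ranks in its top-2 repressed genes and another gene
< 1 Mb away is among its top-30. The final variant list is the strict
intersection of four evidence layers: consistent distal eQTL, P–P
support, MPRA allelic skew, TF-binding skew.

See `docs/methods.md` for assumptions, parameter defaults, numerical
conventions, and what the synthetic generator does and does not emulate.

## Worked example

Run the whole chain on a generated world (400 genes, 10% planted
Epromoters, fold effect 5, 40× depth) and score recovery against the
planted truth:

```bash
eprom demo --seed 1 --outdir demo/ --n-genes 400 \
    --n-chromosomes 2 --chrom-length-bp 30000000
```

Output (abridged):

```json
{
 "n_active_regions": 45,
 "n_epromoter_genes": 45,
 "epromoter_sensitivity": 1.0,
 "epromoter_precision": 0.833,
 "control_expr_wilcoxon_p": 0.687,
 "control_tau_wilcoxon_p": 0.675,
 "n_gwas_snps": 442,
 "n_pleiotropic_epromoters": 40,
 "traits_per_promoter_wilcoxon_p": 1.38e-14,
 "eqtl_class_counts": {"both": 40, "distal": 25, "proximal": 50},
 "evidence": {"n_final": 40, "n_3plus_traits": 40},
 "crispri_tests": {
  "epromoters": {"n_distal": 45, "n_in_universe": 45, "p_hyper": 8.7e-10},
  "controls":   {"n_distal": 28, "n_in_universe": 45, "p_hyper": 0.72}
 }
}
```

Reading this: the knee threshold called 45 active regions, recovering all
40 planted Epromoter genes (sensitivity 1.0) with 5 noise regions
(precision 0.83). Matched control genes are statistically
indistinguishable from Epromoter genes in mean expression and τ
(p ≈ 0.69/0.67, as they should be). Epromoters carry significantly more
GWAS traits per promoter than controls (rank-sum p ≈ 1e-14), the 40
planted pleiotropic variants classify as proximal+distal eQTLs and
assemble all four evidence layers (`n_final` = 40, all with ≥3 traits),
and the CRISPRi screen finds distal regulation enriched at Epromoters
(p ≈ 9e-10) but not at controls.

`eprom demo --write-world` also serializes every generated input
(GTF, BED fragment libraries, phased VCF panel, TSV tables) so the same
analysis can be re-run from files:

```bash
eprom run --config cfg.yaml   # cfg.yaml: {indir: demo/world, outdir: out/}
```

Single stages are exposed as `eprom starr-call`, `eprom epcall`,
`eprom match-controls`, `eprom pleiotropy` and `eprom features`, and the
whole library is importable (`epromoter.call_active_regions`,
`epromoter.expand_ld`, ...).

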