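"""Synthetic miniature "world" with planted Epromoters and pleiotropic SNPs.

The generator emulates every input of the pipeline — gene annotation,
(Cap)STARR-seq fragment libraries with replicates, a gene x tissue
expression matrix, a phased haplotype panel with block LD, a GWAS catalog,
eQTL credible sets, promoter-promoter interaction anchors, a CRISPRi
perturbation z-matrix, allelic reporter reads, and feature annotation
tracks — together with the ground truth that was planted, so every
downstream stage can be scored with no external download.

What is planted and how:

* A fraction of genes become Epromoters: their captured promoter region gets
  an output/input fold effect of ``epromoter_fold_effect`` while background
  regions fluctuate around ``background_fold_mean``; fragment counts are
  negative-binomially overdispersed around depth x fold.
* Every planted Epromoter carries a common promoter SNP that is (directly or
  through a perfect-LD proxy within the same haplotype block) a GWAS lead
  with 1 + ``pleiotropy_boost`` traits, i.e. pleiotropic.
* Each planted Epromoter regulates the nearest neighboring gene (< 1 Mb):
  the pair appears as a distal eQTL target, a promoter-promoter interaction,
  a strong repression entry in the CRISPRi z-matrix, and the planted SNP is
  listed in the MPRA allelic-skew and TF-binding-skew tables.

Genes are laid out on a regular grid with spacing far exceeding the promoter
window, so promoters of different genes never interfere; within a gene,
alternative TSSs may produce overlapping promoters that merge downstream.
"""

from __future__ import annotations


import json
from dataclasses import dataclass


import numpy as np
import pandas as pd

from .epcall import define_promoters
from .intervals import GenomicInterval
from .starr import FragmentSet

#: The 17 parent trait categories (EFO-style vocabulary).
TRAIT_CATEGORIES = (
    "Biological process",
    "Body measurement",
    "Cancer",
    "Cardiovascular disease",
    "Cardiovascular measurement",
    "Digestive system disorder",
    "Hematological measurement",
    "Immune system disorder",
    "Inflammatory measurement",
    "Lipid or lipoprotein measurement",
    "Liver enzyme measurement",
    "Metabolic disorder",
    "Neurological disorder",
    "Other disease",
    "Other measurement",
    "Other trait",
    "Response to drug",
)

CHIP_BIOTYPES = tuple(f"biotype_{i:02d}" for i in range(1, 19))
TF_FAMILIES = tuple(f"family_{i:02d}" for i in range(1, 21))
STATE_LABELS = ("TSS", "Enh", "Tx", "ReprPC", "Quies")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the generated world; the seed fully determines it."""

    n_chromosomes: int = 4
    chrom_length_bp: int = 75_000_000
    n_genes: int = 2000
    n_tissues: int = 30
    frac_epromoters: float = 0.10
    epromoter_fold_effect: float = 5.0
    background_fold_mean: float = 1.0
    background_fold_sigma: float = 0.15
    n_replicates: int = 2
    fragment_length_nt: int = 314
    read_length_nt: int = 50
    mean_depth: float = 40.0
    nb_dispersion: float = 20.0
    n_haplotypes: int = 200
    ld_block_bp: int = 50_000
    n_gwas_leads: int = 400
    pleiotropy_boost: int = 2
    promoter_window: int = 500
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_genes": self.n_genes,
            "n_tissues": self.n_tissues,
            "n_replicates": self.n_replicates,
            "fragment_length_nt": self.fragment_length_nt,
            "read_length_nt": self.read_length_nt,
            "n_haplotypes": self.n_haplotypes,
            "ld_block_bp": self.ld_block_bp,
            "promoter_window": self.promoter_window,
        }
        for name, val in counts.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if not 0 <= self.frac_epromoters <= 1:
            raise ValueError("frac_epromoters must lie in [0, 1]")
        if self.epromoter_fold_effect <= self.background_fold_mean:
            raise ValueError("epromoter_fold_effect must exceed background_fold_mean")
        if self.fragment_length_nt > self.chrom_length_bp:
            raise ValueError("fragments cannot tile a chromosome shorter than a fragment")
        if self.read_length_nt > self.promoter_window:
            raise ValueError("reads must fit inside a captured promoter region")
        if self.n_haplotypes < 4:
            raise ValueError("n_haplotypes < 4 leaves r^2 degenerate")
        if self.genes_per_chrom_spacing() < 3 * (self.promoter_window + 1500):
            raise ValueError(
                "gene spacing too tight: promoters of neighboring genes would interfere"
            )
        if self.frac_epromoters > 0 and self.genes_per_chrom_spacing() >= 1_000_000:
            raise ValueError(
                "gene spacing >= 1 Mb leaves planted Epromoters without cis-distal targets"
            )

    def genes_per_chrom(self) -> list[int]:
        base = self.n_genes // self.n_chromosomes
        extra = self.n_genes % self.n_chromosomes
        return [base + (1 if i < extra else 0) for i in range(self.n_chromosomes)]

    def genes_per_chrom_spacing(self) -> int:
        most = max(self.genes_per_chrom())
        return self.chrom_length_bp // (most + 1)

    def chrom_sizes(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)
        }


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for recovery scoring."""

    true_epromoter_promoter_ids: frozenset
    true_epromoter_gene_ids: frozenset
    planted_active_regions: list  # list[GenomicInterval]
    true_distal_targets: dict  # gene_id -> list[gene_id], all < 1 Mb away
    true_pleiotropic_snp_ids: dict  # snp_id -> planted trait count
    true_eqtl_classes: dict  # snp_id -> proximal | distal | both

    def to_json(self) -> str:
        payload = {
            "true_epromoter_promoter_ids": sorted(self.true_epromoter_promoter_ids),
            "true_epromoter_gene_ids": sorted(self.true_epromoter_gene_ids),
            "planted_active_regions": [
                [r.chrom, r.start, r.end] for r in self.planted_active_regions
            ],
            "true_distal_targets": {k: sorted(v) for k, v in self.true_distal_targets.items()},
            "true_pleiotropic_snp_ids": dict(sorted(self.true_pleiotropic_snp_ids.items())),
            "true_eqtl_classes": dict(sorted(self.true_eqtl_classes.items())),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            true_epromoter_promoter_ids=frozenset(d["true_epromoter_promoter_ids"]),
            true_epromoter_gene_ids=frozenset(d["true_epromoter_gene_ids"]),
            planted_active_regions=[
                GenomicInterval(c, s, e) for c, s, e in d["planted_active_regions"]
            ],
            true_distal_targets=d["true_distal_targets"],
            true_pleiotropic_snp_ids=d["true_pleiotropic_snp_ids"],
            true_eqtl_classes=d["true_eqtl_classes"],
        )


@dataclass
class SyntheticWorld:
    """Bundle of all generated inputs plus the planted truth."""

    config: SyntheticConfig
    annotation: pd.DataFrame
    captured_regions: list  # list[GenomicInterval], one per gene, disjoint
    fragment_sets: dict  # (library, replicate) -> FragmentSet
    expression: pd.DataFrame  # genes x tissues
    variants: pd.DataFrame  # snp_id, chrom, pos (1-based), col, maf, kind, gene_id
    panel: np.ndarray  # haplotypes x sites, 0/1
    gwas: pd.DataFrame
    eqtls: pd.DataFrame
    pp_interactions: pd.DataFrame
    crispri_genes: list
    crispri_z: np.ndarray
    mpra_snps: pd.DataFrame
    tfskew_snps: pd.DataFrame
    tracks: dict  # kind -> DataFrame
    allelic_fragments: dict  # condition -> DataFrame
    truth: PlantedTruth


def _negbin(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate a deterministic world from ``config`` (seeded RNG only)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    win = config.promoter_window
    chrom_sizes = config.chrom_sizes()

    # ---- annotation: genes on a grid, 1-6 transcripts each -----------------
    ann_rows = []
    gene_meta = []  # (gene_id, chrom, anchor_tss, strand)
    gid = 0
    for ci, n_chrom_genes in enumerate(config.genes_per_chrom()):
        chrom = f"chr{ci + 1}"
        spacing = config.chrom_length_bp // (n_chrom_genes + 1)
        for k in range(n_chrom_genes):
            gid += 1
            gene_id = f"G{gid:05d}"
            anchor = spacing * (k + 1)
            strand = "+" if rng.random() < 0.5 else "-"
            n_tx = int(rng.integers(1, 7))
            tss_list = [anchor]
            for t in range(1, n_tx):
                off = int(rng.integers(-1500, 1501))
                tss_list.append(anchor + off)
            gene_meta.append((gene_id, chrom, anchor, strand))
            for t, tss in enumerate(tss_list, start=1):
                ann_rows.append(
                    {
                        "gene_id": gene_id,
                        "transcript_id": f"{gene_id}T{t}",
                        "chrom": chrom,
                        "strand": strand,
                        "tss": int(tss),
                    }
                )
    annotation = pd.DataFrame(ann_rows)
    meta = pd.DataFrame(
        gene_meta, columns=["gene_id", "chrom", "tss", "strand"]
    ).set_index("gene_id")

    promoters = define_promoters(annotation, window=win, chrom_sizes=chrom_sizes)
    canonical = promoters[
        promoters["transcript_id"].str.endswith("T1")
    ].set_index("gene_id")

    # ---- plant Epromoters --------------------------------------------------
    all_genes = sorted(meta.index)
    n_ep = int(round(config.frac_epromoters * config.n_genes))
    planted_genes = sorted(
        rng.choice(all_genes, size=n_ep, replace=False)
    ) if n_ep else []
    planted_regions = [
        GenomicInterval(
            canonical.at[g, "chrom"],
            int(canonical.at[g, "start"]),
            int(canonical.at[g, "end"]),
        )
        for g in planted_genes
    ]
    region_by_gene = dict(zip(planted_genes, planted_regions))

    # truth at promoter level: the >=50%-either overlap arithmetic, inline
    true_prom_ids = set()
    for p in promoters.itertuples():
        reg = region_by_gene.get(p.gene_id)
        if reg is None:
            continue
        ov = max(0, min(p.end, reg.end) - max(p.start, reg.start))
        plen = p.end - p.start
        if 2 * ov >= plen or 2 * ov >= reg.length:
            true_prom_ids.add(p.promoter_id)

    # ---- STARR fragment libraries ------------------------------------------
    captured = sorted(
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in canonical.iterrows()
    )
    captured_gene = {
        GenomicInterval(
            canonical.at[g, "chrom"],
            int(canonical.at[g, "start"]),
            int(canonical.at[g, "end"]),
        ): g
        for g in all_genes
    }
    planted_set = set(planted_genes)
    fold = np.array(
        [
            config.epromoter_fold_effect
            if captured_gene[r] in planted_set
            else rng.lognormal(
                np.log(config.background_fold_mean)
                - config.background_fold_sigma**2 / 2.0,
                config.background_fold_sigma,
            )
            for r in captured
        ]
    )
    fragment_sets = {}
    for rep in range(1, config.n_replicates + 1):
        for lib in ("input", "output"):
            mean = config.mean_depth * (fold if lib == "output" else 1.0)
            counts = _negbin(rng, np.broadcast_to(mean, (len(captured),)),
                             config.nb_dispersion)
            counts = np.maximum(counts, 0)
            starts0 = np.repeat([r.start for r in captured], counts)
            span = np.repeat(
                [r.length - config.read_length_nt for r in captured], counts
            )
            offs = rng.integers(0, np.maximum(span, 0) + 1)
            chroms = np.repeat([r.chrom for r in captured], counts)
            frag_start = starts0 + offs
            df = pd.DataFrame(
                {
                    "chrom": chroms,
                    "start": frag_start,
                    "end": frag_start + config.read_length_nt,
                    "strand": "+",
                }
            )
            fragment_sets[(lib, rep)] = FragmentSet(
                library_label=lib, replicate=rep, fragments=df, condition="NS"
            )

    # ---- expression matrix --------------------------------------------------
    # smooth multi-tissue profiles organized in co-expression modules: genes
    # of a module share a tissue program, and a per-gene temperature controls
    # how peaked the profile is, spanning the whole tau range from ubiquitous
    # (temperature 0) toward single-tissue expression
    n_t = config.n_tissues
    n_modules = 20
    scale = rng.lognormal(1.0, 1.0, size=config.n_genes)
    temperature = rng.uniform(0.0, 3.0, size=config.n_genes)
    module_program = rng.normal(0.0, 1.0, size=(n_modules, n_t))
    module_of = rng.integers(0, n_modules, size=config.n_genes)
    gene_program = module_program[module_of] + 0.3 * rng.normal(
        0.0, 1.0, size=(config.n_genes, n_t)
    )
    shape = np.exp(temperature[:, None] * gene_program)
    shape /= shape.max(axis=1, keepdims=True)
    noise = rng.lognormal(0.0, 0.05, size=(config.n_genes, n_t))
    expr = scale[:, None] * shape * noise
    expression = pd.DataFrame(
        expr, index=all_genes, columns=[f"T{j + 1:02d}" for j in range(n_t)]
    )
    expression.index.name = "gene_id"

    # ---- variants + haplotype panel -----------------------------------------
    site_rows = []  # chrom, pos0, kind, gene_id
    for g in all_genes:
        start = int(canonical.at[g, "start"])
        off = int(rng.integers(50, win - 50))
        site_rows.append((canonical.at[g, "chrom"], start + off, "promoter", g))
    proxy_of: dict[int, int] = {}
    for g in planted_genes:
        # proxy SNP for the planted promoter variant, 5-50 kb away
        chrom = canonical.at[g, "chrom"]
        prom_idx = next(
            i for i, s in enumerate(site_rows) if s[3] == g and s[2] == "promoter"
        )
        shift = int(rng.integers(5_000, 50_000)) * (1 if rng.random() < 0.5 else -1)
        pos = min(max(site_rows[prom_idx][1] + shift, 10), config.chrom_length_bp - 10)
        site_rows.append((chrom, pos, "proxy", g))
        proxy_of[len(site_rows) - 1] = prom_idx
    n_intergenic = max(config.n_genes // 2, 4)
    for _ in range(n_intergenic):
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        site_rows.append(
            (chrom, int(rng.integers(1000, config.chrom_length_bp - 1000)), "intergenic", "")
        )
    n_rare = max(config.n_genes // 4, 2)
    for _ in range(n_rare):
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        site_rows.append(
            (chrom, int(rng.integers(1000, config.chrom_length_bp - 1000)), "rare", "")
        )

    order = sorted(range(len(site_rows)), key=lambda i: (site_rows[i][0], site_rows[i][1], i))
    col_of_site = {old: new for new, old in enumerate(order)}
    sites = [site_rows[i] for i in order]
    n_sites = len(sites)
    n_hap = config.n_haplotypes

    panel = np.zeros((n_hap, n_sites), dtype=np.int8)
    # block-copy haplotypes: founders per LD block, then per-site mutation
    block_key = [(s[0], s[1] // config.ld_block_bp) for s in sites]
    blocks: dict[tuple, list[int]] = {}
    for j, key in enumerate(block_key):
        blocks.setdefault(key, []).append(j)
    founder_assign_by_block = {}
    for key in sorted(blocks):
        cols = blocks[key]
        founders = rng.integers(0, 2, size=(4, len(cols)))
        flat = founders.sum(axis=0)
        founders[0, flat == 0] = 1  # keep every site polymorphic among founders
        founders[0, flat == 4] = 0
        assign = rng.integers(0, 4, size=n_hap)
        founder_assign_by_block[key] = assign
        panel[:, cols] = founders[assign][:, :]
        flips = rng.random((n_hap, len(cols))) < 0.02
        panel[:, cols] = np.where(flips, 1 - panel[:, cols], panel[:, cols])

    # overrides: planted promoter SNPs get a clean ~50% column; proxies copy it
    planted_prom_cols = {}
    for g in planted_genes:
        old = next(
            i for i, s in enumerate(site_rows) if s[3] == g and s[2] == "promoter"
        )
        j = col_of_site[old]
        assign = founder_assign_by_block[block_key[j]]
        col = (assign % 2).astype(np.int8)
        if col.min() == col.max():  # pathological assignment; force polymorphism
            col[: n_hap // 2] = 1 - col[: n_hap // 2]
        panel[:, j] = col
        planted_prom_cols[g] = j
    for old_proxy, old_prom in proxy_of.items():
        panel[:, col_of_site[old_proxy]] = panel[:, col_of_site[old_prom]]
    # rare sites: exactly one carrier
    for j, s in enumerate(sites):
        if s[2] == "rare":
            panel[:, j] = 0
            panel[int(rng.integers(0, n_hap)), j] = 1

    freq = panel.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1:06d}" for j in range(n_sites)],
            "chrom": [s[0] for s in sites],
            "pos": [s[1] + 1 for s in sites],  # VCF dialect, 1-based
            "col": np.arange(n_sites),
            "maf": maf,
            "is_common": maf >= 0.01,
            "kind": [s[2] for s in sites],
            "gene_id": [s[3] for s in sites],
        }
    )
    snp_by_gene = {
        s[3]: f"rs{j + 1:06d}"
        for j, s in enumerate(sites)
        if s[2] == "promoter" and s[3]
    }
    proxy_by_gene = {
        s[3]: f"rs{j + 1:06d}" for j, s in enumerate(sites) if s[2] == "proxy"
    }

    # ---- GWAS catalog --------------------------------------------------------
    n_trait_pool = max(17 * 15, config.n_gwas_leads)
    trait_pool = [
        (
            f"EFO:{i + 1:07d}",
            f"trait_{i + 1:04d}",
            TRAIT_CATEGORIES[i % len(TRAIT_CATEGORIES)],
        )
        for i in range(n_trait_pool)
    ]
    gwas_rows = []
    pleio_traits: dict[str, int] = {}
    var_pos = variants.set_index("snp_id")
    for g in planted_genes:
        snp = snp_by_gene[g]
        n_traits = 1 + config.pleiotropy_boost
        lead = snp if rng.random() < 0.5 else proxy_by_gene[g]
        chosen = rng.choice(len(trait_pool), size=n_traits, replace=False)
        for t in chosen:
            efo, label, cat = trait_pool[t]
            gwas_rows.append(
                {
                    "lead_snp_id": lead,
                    "chrom": var_pos.at[lead, "chrom"],
                    "pos": int(var_pos.at[lead, "pos"]),
                    "trait_efo_id": efo,
                    "trait_label": label,
                    "parent_category": cat,
                }
            )
        pleio_traits[snp] = n_traits
    n_background = max(config.n_gwas_leads - len(planted_genes), 0)
    bg_candidates = [
        snp_by_gene[g] for g in all_genes if g not in planted_set
    ] + sorted(
        variants.loc[variants["kind"] == "intergenic", "snp_id"]
    )
    if n_background and bg_candidates:
        picks = rng.choice(
            len(bg_candidates), size=min(n_background, len(bg_candidates)), replace=False
        )
        for p in sorted(picks):
            lead = bg_candidates[int(p)]
            efo, label, cat = trait_pool[int(rng.integers(0, len(trait_pool)))]
            gwas_rows.append(
                {
                    "lead_snp_id": lead,
                    "chrom": var_pos.at[lead, "chrom"],
                    "pos": int(var_pos.at[lead, "pos"]),
                    "trait_efo_id": efo,
                    "trait_label": label,
                    "parent_category": cat,
                }
            )
    gwas = pd.DataFrame(
        gwas_rows,
        columns=["lead_snp_id", "chrom", "pos", "trait_efo_id", "trait_label",
                 "parent_category"],
    )

    # ---- eQTLs + planted distal targets --------------------------------------
    gene_order = {
        chrom: list(grp.sort_values("tss").index)
        for chrom, grp in meta.groupby("chrom")
    }
    distal_targets: dict[str, list[str]] = {}
    eqtl_rows = []
    eqtl_classes: dict[str, str] = {}
    tissues = list(expression.columns)

    def _neighbor(g: str) -> str:
        chrom = meta.at[g, "chrom"]
        order_ = gene_order[chrom]
        i = order_.index(g)
        return order_[i + 1] if i + 1 < len(order_) else order_[i - 1]

    for g in planted_genes:
        target = _neighbor(g)
        distal_targets[g] = [target]
        snp = snp_by_gene[g]
        pos0 = int(var_pos.at[snp, "pos"]) - 1
        d_own = pos0 - int(meta.at[g, "tss"])
        d_target = pos0 - int(meta.at[target, "tss"])
        assert abs(d_target) < 1_000_000, "planted distal target beyond 1 Mb"
        for tis in rng.choice(tissues, size=2, replace=False):
            eqtl_rows.append(
                {"snp_id": snp, "target_gene_id": g, "tissue": tis,
                 "effect_z": float(-abs(rng.normal(4.0, 1.0))),
                 "tss_distance_bp": d_own}
            )
            eqtl_rows.append(
                {"snp_id": snp, "target_gene_id": target, "tissue": tis,
                 "effect_z": float(-abs(rng.normal(3.0, 1.0))),
                 "tss_distance_bp": d_target}
            )
        eqtl_classes[snp] = "both"
    non_planted = [g for g in all_genes if g not in planted_set]
    n_prox = min(len(non_planted), max(config.n_genes // 8, 2))
    for g in (non_planted[i] for i in sorted(
        rng.choice(len(non_planted), size=n_prox, replace=False)
    )):
        snp = snp_by_gene[g]
        pos0 = int(var_pos.at[snp, "pos"]) - 1
        eqtl_rows.append(
            {"snp_id": snp, "target_gene_id": g,
             "tissue": tissues[int(rng.integers(0, len(tissues)))],
             "effect_z": float(rng.normal(0.0, 2.0)),
             "tss_distance_bp": pos0 - int(meta.at[g, "tss"])}
        )
        eqtl_classes[snp] = "proximal"
    inter = variants[variants["kind"] == "intergenic"]
    n_dist = min(len(inter), max(config.n_genes // 16, 2))
    for rec in inter.iloc[
        sorted(rng.choice(len(inter), size=n_dist, replace=False))
    ].itertuples():
        # nearest gene on the chromosome, guaranteed > 2 kb by re-distancing
        chrom_genes = gene_order[rec.chrom]
        tss_arr = np.array([meta.at[g, "tss"] for g in chrom_genes])
        gi = int(np.argmin(np.abs(tss_arr - (rec.pos - 1))))
        g = chrom_genes[gi]
        d = int(rec.pos - 1 - tss_arr[gi])
        if abs(d) <= 2000:
            d = 2500 if d >= 0 else -2500
        eqtl_rows.append(
            {"snp_id": rec.snp_id, "target_gene_id": g,
             "tissue": tissues[int(rng.integers(0, len(tissues)))],
             "effect_z": float(rng.normal(0.0, 2.0)),
             "tss_distance_bp": d}
        )
        eqtl_classes[rec.snp_id] = "distal"
    eqtls = pd.DataFrame(
        eqtl_rows,
        columns=["snp_id", "target_gene_id", "tissue", "effect_z", "tss_distance_bp"],
    )

    # ---- P-P interactions -----------------------------------------------------
    pp_rows = []
    for g, targets in distal_targets.items():
        for t in targets:
            pp_rows.append(
                {
                    "chrom_a": canonical.at[g, "chrom"],
                    "start_a": int(canonical.at[g, "start"]),
                    "end_a": int(canonical.at[g, "end"]),
                    "chrom_b": canonical.at[t, "chrom"],
                    "start_b": int(canonical.at[t, "start"]),
                    "end_b": int(canonical.at[t, "end"]),
                    "source": "planted",
                }
            )
    n_decoy = max(config.n_genes // 20, 2)
    for _ in range(n_decoy):
        g = non_planted[int(rng.integers(0, len(non_planted)))]
        t = _neighbor(g)
        pp_rows.append(
            {
                "chrom_a": canonical.at[g, "chrom"],
                "start_a": int(canonical.at[g, "start"]),
                "end_a": int(canonical.at[g, "end"]),
                "chrom_b": canonical.at[t, "chrom"],
                "start_b": int(canonical.at[t, "start"]),
                "end_b": int(canonical.at[t, "end"]),
                "source": "decoy",
            }
        )
    pp_interactions = pd.DataFrame(pp_rows)

    # ---- CRISPRi z-matrix ------------------------------------------------------
    n = config.n_genes
    z = rng.normal(0.0, 1.0, size=(n, n))
    idx = {g: i for i, g in enumerate(all_genes)}
    z[np.arange(n), np.arange(n)] = -8.0 + rng.normal(0.0, 0.3, size=n)
    for g, targets in distal_targets.items():
        for t in targets:
            z[idx[g], idx[t]] = -6.0 + rng.normal(0.0, 0.3)

    # ---- MPRA / TF-binding skew tables ----------------------------------------
    planted_snps = sorted(pleio_traits)
    other_snps = sorted(set(variants["snp_id"]) - set(planted_snps))
    n_noise = max(len(planted_snps) // 4, 2)
    mpra = pd.DataFrame(
        {"snp_id": planted_snps
         + [other_snps[i] for i in sorted(
             rng.choice(len(other_snps), size=n_noise, replace=False))]}
    )
    tfskew = pd.DataFrame(
        {"snp_id": planted_snps
         + [other_snps[i] for i in sorted(
             rng.choice(len(other_snps), size=n_noise, replace=False))]}
    )

    # ---- feature tracks ---------------------------------------------------------
    tracks = _feature_tracks(rng, config, canonical, all_genes, planted_set, meta)

    # ---- allelic reporter reads (one exemplar planted SNP) ----------------------
    allelic = {}
    if planted_genes:
        g = planted_genes[0]
        snp = snp_by_gene[g]
        chrom = var_pos.at[snp, "chrom"]
        pos0 = int(var_pos.at[snp, "pos"]) - 1
        means = {"NS": {"C": 30, "T": 30}, "IFNa": {"C": 60, "T": 30}}
        for cond, per_allele in means.items():
            rows = []
            for rep in (1, 2):
                for allele, mu in per_allele.items():
                    k = int(rng.poisson(mu))
                    for _ in range(k):
                        s = pos0 - int(rng.integers(0, config.read_length_nt))
                        rows.append(
                            {"chrom": chrom, "start": s,
                             "end": s + config.read_length_nt,
                             "replicate": rep, "allele": allele}
                        )
            allelic[cond] = pd.DataFrame(rows)

    truth = PlantedTruth(
        true_epromoter_promoter_ids=frozenset(true_prom_ids),
        true_epromoter_gene_ids=frozenset(planted_genes),
        planted_active_regions=planted_regions,
        true_distal_targets=distal_targets,
        true_pleiotropic_snp_ids=pleio_traits,
        true_eqtl_classes=eqtl_classes,
    )
    return SyntheticWorld(
        config=config,
        annotation=annotation,
        captured_regions=captured,
        fragment_sets=fragment_sets,
        expression=expression,
        variants=variants,
        panel=panel,
        gwas=gwas,
        eqtls=eqtls,
        pp_interactions=pp_interactions,
        crispri_genes=all_genes,
        crispri_z=z,
        mpra_snps=mpra,
        tfskew_snps=tfskew,
        tracks=tracks,
        allelic_fragments=allelic,
        truth=truth,
    )


def _feature_tracks(rng, config, canonical, all_genes, planted_set, meta):
    """Annotation tracks with mild enrichment at planted Epromoters."""
    cgi_rows, g4_rows, tfbs_rows, chip_rows, cage_rows, sig_rows = [], [], [], [], [], []
    cons_chrom, cons_pos, cons_score = [], [], []
    for g in all_genes:
        chrom = canonical.at[g, "chrom"]
        start = int(canonical.at[g, "start"])
        end = int(canonical.at[g, "end"])
        strand = meta.at[g, "strand"]
        tss = int(meta.at[g, "tss"])
        is_ep = g in planted_set
        if rng.random() < (0.7 if is_ep else 0.35):
            cgi_rows.append({"chrom": chrom, "start": start + 50, "end": end - 20})
        if rng.random() < (0.5 if is_ep else 0.25):
            for _ in range(int(rng.integers(1, 4))):
                s = start + int(rng.integers(0, 440))
                g4_rows.append({"chrom": chrom, "start": s,
                                "end": s + int(rng.integers(20, 61))})
        for _ in range(int(rng.poisson(6.0 if is_ep else 3.0))):
            s = start + int(rng.integers(0, 490))
            tfbs_rows.append(
                {"chrom": chrom, "start": s, "end": s + 10,
                 "family": TF_FAMILIES[int(rng.integers(0, len(TF_FAMILIES)))],
                 "score": int(rng.integers(300, 601))}
            )
        for _ in range(int(rng.poisson(5.0 if is_ep else 2.5))):
            s = start + int(rng.integers(0, 450))
            chip_rows.append(
                {"chrom": chrom, "start": s, "end": s + int(rng.integers(30, 120)),
                 "tf": TF_FAMILIES[int(rng.integers(0, len(TF_FAMILIES)))],
                 "biotype": CHIP_BIOTYPES[int(rng.integers(0, len(CHIP_BIOTYPES)))]}
            )
        cage_rows.append(
            {"chrom": chrom, "start": max(tss - 50, 0), "end": tss + 50,
             "strand": strand}
        )
        if rng.random() < (0.6 if is_ep else 0.2):
            cage_rows.append(
                {"chrom": chrom, "start": max(tss - 150, 0), "end": tss - 50,
                 "strand": "-" if strand == "+" else "+"}
            )
        for s_off in range(-100, 100, 10):
            sig_rows.append(
                {"chrom": chrom, "pos": tss + s_off, "strand": strand,
                 "score": float(rng.poisson(8.0 if is_ep else 5.0))}
            )
        mu = 0.5 if is_ep else 0.2
        scores = rng.normal(mu, 0.2, size=end - start)
        cons_chrom.append(np.full(end - start, chrom, dtype=object))
        cons_pos.append(np.arange(start, end))
        cons_score.append(scores)
    state_rows = []
    seg = 2000
    tss_segments = {
        (canonical.at[g, "chrom"], int(meta.at[g, "tss"]) // seg) for g in all_genes
    }
    probs = np.array([0.03, 0.07, 0.2, 0.1, 0.6])
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n_seg = config.chrom_length_bp // seg
        draws = rng.choice(len(STATE_LABELS), size=n_seg, p=probs)
        for si in range(n_seg):
            label = "TSS" if (chrom, si) in tss_segments else STATE_LABELS[draws[si]]
            state_rows.append(
                {"chrom": chrom, "start": si * seg, "end": (si + 1) * seg,
                 "state": label}
            )
    return {
        "cgi": pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]),
        "g4": pd.DataFrame(g4_rows, columns=["chrom", "start", "end"]),
        "tfbs": pd.DataFrame(tfbs_rows,
                             columns=["chrom", "start", "end", "family", "score"]),
        "chip_peak": pd.DataFrame(chip_rows,
                                  columns=["chrom", "start", "end", "tf", "biotype"]),
        "cage_peak": pd.DataFrame(cage_rows,
                                  columns=["chrom", "start", "end", "strand"]),
        "cage_signal": pd.DataFrame(sig_rows,
                                    columns=["chrom", "pos", "strand", "score"]),
        "conservation": pd.DataFrame(
            {"chrom": np.concatenate(cons_chrom) if cons_chrom else [],
             "pos": np.concatenate(cons_pos) if cons_pos else [],
             "score": np.concatenate(cons_score) if cons_score else []}
        ),
        "states": pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state"]),
    }
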