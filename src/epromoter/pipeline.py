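"""End-to-end pipeline: activity calling -> Epromoter calling -> control
matching -> GWAS pleiotropy -> target linking -> feature statistics.

``run_on_world`` executes the whole chain on a (generated or loaded) world
and, when the world carries planted truth, scores the recovery of planted
Epromoters. ``demo`` generates a world from a seed and runs the chain; the
pipeline itself draws no random numbers, so a seed fully determines the
report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path


import pandas as pd
import yaml
from scipy import stats

from . import controls, epcall, features, linking, pleiotropy, starr
from .intervals import GenomicInterval
from .synthetic import SyntheticConfig, SyntheticWorld, generate_world

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Analysis thresholds; defaults are the method's published settings."""

    promoter_window: int = 500
    min_input_fpkm: float = 1.0
    overlap_frac: float = 0.5
    either: bool = True
    ld_window_kb: float = 1000.0
    r2_min: float = 0.8
    proximal_bp: int = 2000
    crispri_top_inactivated: int = 2
    crispri_top_regulated: int = 30
    cis_window_bp: int = 1_000_000
    fragment_length: int = 314
    maf_common: float = 0.01

    def validate(self) -> None:
        for name in (
            "promoter_window", "min_input_fpkm", "overlap_frac", "ld_window_kb",
            "r2_min", "proximal_bp", "crispri_top_inactivated",
            "crispri_top_regulated", "cis_window_bp", "fragment_length",
            "maf_common",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    summary: dict
    promoters: pd.DataFrame
    active_calls: list
    epromoters: "epcall.EpromoterSet"
    control_assignment: pd.DataFrame
    annotated_variants: pd.DataFrame
    evidence: pd.DataFrame
    feature_table: pd.DataFrame


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # abort with the stage name attached
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
    return out


def run_on_world(
    world: SyntheticWorld, params: PipelineParams | None = None
) -> PipelineResult:
    params = params or PipelineParams()
    params.validate()
    cfg = world.config
    chrom_sizes = cfg.chrom_sizes()
    summary: dict = {"seed": cfg.seed}

    # --- STARR activity -----------------------------------------------------
    def _starr() -> list:
        per_rep = []
        for rep in range(1, cfg.n_replicates + 1):
            fin = starr.extend_fragments(
                world.fragment_sets[("input", rep)], params.fragment_length, chrom_sizes
            )
            fout = starr.extend_fragments(
                world.fragment_sets[("output", rep)], params.fragment_length, chrom_sizes
            )
            fpkm_in = starr.compute_fpkm(world.captured_regions, fin)
            fpkm_out = starr.compute_fpkm(world.captured_regions, fout)
            per_rep.append(
                starr.call_active_regions(
                    fpkm_in, fpkm_out, min_input_fpkm=params.min_input_fpkm
                )
            )
        if len(per_rep) == 1:
            return per_rep[0]
        return starr.merge_replicate_calls(per_rep, match="key")

    calls = _stage("starr_activity", _starr)
    active_regions = [a.region for a in calls if a.active]
    summary["n_regions_retained"] = len(calls)
    summary["n_active_regions"] = len(active_regions)

    # --- Epromoter calling ---------------------------------------------------
    def _epcall():
        promoters = epcall.define_promoters(
            world.annotation, window=params.promoter_window, chrom_sizes=chrom_sizes
        )
        flagged = epcall.call_epromoters(
            promoters, active_regions, min_frac=params.overlap_frac,
            either=params.either,
        )
        return flagged, epcall.merge_epromoters(flagged)

    flagged, epset = _stage("epromoter_caller", _epcall)
    ep_genes = sorted(epset.gene_ids())
    summary["n_epromoter_promoters"] = int(flagged["is_epromoter"].sum())
    summary["n_epromoters_merged"] = len(epset.regions)
    summary["n_epromoter_genes"] = len(ep_genes)

    # recovery against planted truth
    truth = world.truth
    called = set(flagged.loc[flagged["is_epromoter"], "promoter_id"])
    true_ids = set(truth.true_epromoter_promoter_ids)
    tp = len(called & true_ids)
    summary["epromoter_sensitivity"] = tp / len(true_ids) if true_ids else float("nan")
    summary["epromoter_precision"] = tp / len(called) if called else (
        1.0 if not true_ids else 0.0
    )

    # --- control matching ----------------------------------------------------
    def _controls():
        tau = controls.tau_table(world.expression)
        if not ep_genes:
            return tau, pd.DataFrame(columns=["epromoter_gene", "control_gene", "distance"])
        return tau, controls.match_controls(world.expression, ep_genes)

    tau, assignment = _stage("control_matching", _controls)
    ctrl_genes = sorted(assignment["control_gene"]) if len(assignment) else []
    if ep_genes:
        ep_expr = world.expression.loc[ep_genes].mean(axis=1)
        ct_expr = world.expression.loc[ctrl_genes].mean(axis=1)
        summary["control_expr_wilcoxon_p"] = float(
            stats.mannwhitneyu(ep_expr, ct_expr, alternative="two-sided").pvalue
        )
        summary["control_tau_wilcoxon_p"] = float(
            stats.mannwhitneyu(
                tau.loc[ep_genes].dropna(), tau.loc[ctrl_genes].dropna(),
                alternative="two-sided",
            ).pvalue
        )

    # --- GWAS pleiotropy ------------------------------------------------------
    promoters_all = flagged
    canon_idx = (
        promoters_all.sort_values("promoter_id")
        .drop_duplicates("gene_id", keep="first")
        .set_index("gene_id")
    )
    ctrl_regions = pd.DataFrame(
        {
            "region_id": [f"CTRL_{g}" for g in ctrl_genes],
            "chrom": [canon_idx.at[g, "chrom"] for g in ctrl_genes],
            "start": [canon_idx.at[g, "start"] for g in ctrl_genes],
            "end": [canon_idx.at[g, "end"] for g in ctrl_genes],
        }
    )
    ep_regions = epset.regions.rename(columns={"merged_id": "region_id"})

    def _pleio():
        annotated = pleiotropy.expand_ld(
            world.gwas, world.variants, world.panel,
            window_kb=params.ld_window_kb, r2_min=params.r2_min,
        )
        ep_hits = pleiotropy.overlap_variants(annotated, ep_regions)
        ctrl_hits = pleiotropy.overlap_variants(annotated, ctrl_regions)
        snp_counts, ep_counts = pleiotropy.pleiotropy_counts(ep_hits, annotated)
        _, ctrl_counts = pleiotropy.pleiotropy_counts(ctrl_hits, annotated)
        return annotated, ep_hits, ctrl_hits, snp_counts, ep_counts, ctrl_counts

    annotated, ep_hits, ctrl_hits, snp_counts, ep_counts, ctrl_counts = _stage(
        "variant_pleiotropy", _pleio
    )
    summary["n_gwas_snps"] = len(annotated)
    ep_snps = sorted({s for v in ep_hits.values() for s in v})
    ctrl_snps = sorted({s for v in ctrl_hits.values() for s in v})
    summary["n_gwas_snps_in_epromoters"] = len(ep_snps)
    summary["n_epromoters_with_snps"] = int((ep_counts["n_snps"] > 0).sum())
    summary["n_pleiotropic_epromoters"] = int(ep_counts["pleiotropic"].sum())
    if len(ep_counts) and len(ctrl_counts):
        res = stats.mannwhitneyu(
            ep_counts["n_traits"], ctrl_counts["n_traits"], alternative="greater"
        )
        summary["traits_per_promoter_wilcoxon_p"] = float(res.pvalue)
        summary["traits_per_promoter_direction"] = float(
            ep_counts["n_traits"].mean() - ctrl_counts["n_traits"].mean()
        )
    if ep_snps and ctrl_snps:
        cat_enrich = pleiotropy.enrichment_tests(
            ep_snps, ctrl_snps, annotated, key="categories"
        )
        trait_enrich = pleiotropy.enrichment_tests(ep_snps, ctrl_snps, annotated)
        summary["n_traits_enriched_vs_genome"] = int(
            (trait_enrich["p_hyper_a"] < 0.001).sum()
        )
        summary["n_traits_differential_vs_controls"] = int(
            (trait_enrich["p_chi2"] < 0.05).sum()
        )
        summary["n_categories_enriched_vs_genome"] = int(
            (cat_enrich["p_hyper_a"] < 0.001).sum()
        )

    # --- target linking --------------------------------------------------------
    def _linking():
        eqtl_class = linking.classify_eqtls(world.eqtls, proximal_bp=params.proximal_bp)
        merged_eqtls = world.eqtls.drop_duplicates(["snp_id", "target_gene_id"])
        distal = merged_eqtls[
            merged_eqtls["tss_distance_bp"].abs() > params.proximal_bp
        ]
        ep_snp_set = set(ep_snps)
        region_of_snp: dict[str, str] = {}
        for rid, snps in ep_hits.items():
            for s in snps:
                region_of_snp.setdefault(s, rid)
        regions_by_id = {
            r.region_id: GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in ep_regions.itertuples()
        }
        pp_ok: set[str] = set()
        distal_snps: set[str] = set()
        for snp, grp in distal.groupby("snp_id"):
            if snp not in ep_snp_set:
                continue
            distal_snps.add(snp)
            region = regions_by_id[region_of_snp[snp]]
            flags = linking.pp_consistency(
                region, sorted(grp["target_gene_id"].unique()), promoters_all,
                world.pp_interactions,
            )
            if any(flags.values()):
                pp_ok.add(snp)
        tss_by_gene = {
            r.gene_id: (r.chrom, int(r.tss))
            for r in world.annotation.drop_duplicates("gene_id").itertuples()
        }
        screen = linking.crispri_screen(
            world.crispri_z, world.crispri_genes, world.crispri_genes, tss_by_gene,
            query_sets={"epromoters": ep_genes, "controls": ctrl_genes},
            top_inactivated=params.crispri_top_inactivated,
            top_regulated=params.crispri_top_regulated,
            cis_window_bp=params.cis_window_bp,
        )
        snp_traits = snp_counts[snp_counts["snp_id"].isin(ep_snp_set)]
        evidence, ev_summary = linking.integrate_evidence(
            snp_traits,
            distal_snps,
            pp_ok,
            set(world.mpra_snps["snp_id"]),
            set(world.tfskew_snps["snp_id"]),
        )
        return eqtl_class, screen, evidence, ev_summary

    eqtl_class, screen, evidence, ev_summary = _stage("target_linking", _linking)
    summary["eqtl_class_counts"] = eqtl_class.value_counts().to_dict()
    summary["crispri_tests"] = screen["tests"]
    summary["evidence"] = ev_summary

    # --- feature statistics ------------------------------------------------------
    def _features():
        ep_r = ep_regions
        ct_r = ctrl_regions
        rows = {}
        for name, regions in (("epromoter", ep_r), ("control", ct_r)):
            if regions.empty:
                continue
            cgi = features.region_feature_stats(regions, world.tracks["cgi"], "cgi")
            g4 = features.region_feature_stats(regions, world.tracks["g4"], "g4")
            cons = features.region_feature_stats(
                regions, world.tracks["conservation"], "conservation_base"
            )
            tf = features.tfbs_density_diversity(regions, world.tracks["tfbs"])
            rows[name] = {
                "cgi_frac": float(cgi["cgi_overlap"].mean()),
                "g4_pct_mean": float(g4["g4_pct"].mean()),
                "conservation_sum_mean": float(cons["conservation_sum"].mean()),
                "tfbs_density_mean": float(tf["density"].mean()),
                "tfbs_diversity_mean": float(tf["diversity"].mean()),
            }
        table = pd.DataFrame(rows).T
        genome = cfg.n_chromosomes * cfg.chrom_length_bp
        if not ep_r.empty and not ct_r.empty:
            comp = features.compare_state_enrichment(
                ep_r, ct_r, world.tracks["states"], genome
            )
            state_log2 = comp["log2_ratio"].to_dict()
        else:
            state_log2 = {}
        return table, state_log2

    feature_table, state_log2 = _stage("promoter_features", _features)
    summary["state_log2_ratio"] = {k: float(v) for k, v in state_log2.items()}
    if not feature_table.empty:
        summary["features"] = {
            k: {c: float(v) for c, v in row.items()}
            for k, row in feature_table.iterrows()
        }

    return PipelineResult(
        summary=summary,
        promoters=flagged,
        active_calls=calls,
        epromoters=epset,
        control_assignment=assignment,
        annotated_variants=annotated,
        evidence=evidence,
        feature_table=feature_table,
    )


def demo(
    seed: int,
    config: SyntheticConfig | None = None,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
    write_world: bool = False,
) -> PipelineResult:
    """Generate a world from ``seed`` and run the full chain on it."""
    cfg = config or SyntheticConfig()
    cfg = dataclasses.replace(cfg, seed=seed)
    world = generate_world(cfg)
    result = run_on_world(world, params)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=1, sort_keys=True, default=str)
        result.promoters.to_csv(out / "promoters.tsv", sep="\t", index=False)
        result.epromoters.regions.to_csv(out / "epromoters.tsv", sep="\t", index=False)
        result.control_assignment.to_csv(out / "controls.tsv", sep="\t", index=False)
        result.evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
        if write_world:
            from .io import write_world as _ww

            _ww(world, out / "world")
    return result


def run_pipeline(config_path: str | Path) -> PipelineResult:
    """Run on a serialized world described by a YAML config file.

    The config carries ``indir`` (a directory written by
    :func:`epromoter.io.write_world`), optionally ``outdir`` and a
    ``params`` block overriding :class:`PipelineParams` defaults.
    """
    from .io import load_world

    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if "indir" not in cfg:
        raise ValueError("pipeline config must name an input directory 'indir'")
    params = PipelineParams(**cfg.get("params", {}))
    world = load_world(cfg["indir"])
    result = run_on_world(world, params)
    outdir = cfg.get("outdir")
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=1, sort_keys=True, default=str)
        result.promoters.to_csv(out / "promoters.tsv", sep="\t", index=False)
        result.evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
    return result
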