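"""Target-gene linking: eQTL distance classes, 3D-interaction consistency,
CRISPRi distal-regulation screen, and evidence integration.

eQTLs are merged non-redundantly across tissues and classified by the
distance of the variant to its target TSSs: proximal when every target is
within 2 kb, distal when every target is beyond 2 kb, "both" otherwise
(exactly 2 kb counts as proximal). A distal eQTL target is consistent with
the 3D data when a promoter-promoter interaction links the Epromoter to any
promoter of the target gene. The CRISPRi screen keeps promoters whose own
gene ranks in the 2 most repressed genes of their perturbation profile,
takes the 30 most repressed genes as the regulated set, and calls distal
regulators when a regulated gene other than the own gene lies within 1 Mb.
The final pleiotropic-variant list is the strict intersection of four
evidence layers: consistent distal eQTL, P-P interaction, allelic-skewed
MPRA activity, and skewed TF binding.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .pleiotropy import hypergeom_upper

EQTL_COLUMNS = ["snp_id", "target_gene_id", "tissue", "effect_z", "tss_distance_bp"]


def classify_eqtls(eqtls: pd.DataFrame, proximal_bp: int = 2000) -> pd.Series:
    """Proximal / distal / both label per SNP.

    Records are first merged non-redundantly across tissues by
    (snp, target gene); a target is proximal when |distance| <= proximal_bp
    (the exact boundary counts as proximal), distal otherwise.
    """
    missing = [c for c in ("snp_id", "target_gene_id", "tss_distance_bp")
               if c not in eqtls.columns]
    if missing:
        raise ValueError(f"eQTL table lacks columns {missing}")
    merged = eqtls.drop_duplicates(subset=["snp_id", "target_gene_id"])
    labels = {}
    for snp, grp in merged.groupby("snp_id"):
        prox = grp["tss_distance_bp"].abs() <= proximal_bp
        if prox.all():
            labels[snp] = "proximal"
        elif (~prox).all():
            labels[snp] = "distal"
        else:
            labels[snp] = "both"
    return pd.Series(labels, name="eqtl_class").sort_index()


def pp_consistency(
    epromoter: GenomicInterval,
    target_gene_ids: Iterable[str],
    promoters: pd.DataFrame,
    interactions: pd.DataFrame,
) -> dict[str, bool]:
    """Is each distal eQTL target supported by a promoter-promoter contact?

    A target is consistent iff some interaction has one anchor overlapping
    the Epromoter and the partner anchor overlapping *any* promoter of the
    target gene (alternative TSSs count).
    """
    partners: list[GenomicInterval] = []
    for rec in interactions.itertuples():
        a = GenomicInterval(rec.chrom_a, int(rec.start_a), int(rec.end_a))
        b = GenomicInterval(rec.chrom_b, int(rec.start_b), int(rec.end_b))
        if epromoter.overlaps(a):
            partners.append(b)
        if epromoter.overlaps(b):
            partners.append(a)
    out = {}
    for gene in target_gene_ids:
        proms = promoters[promoters["gene_id"] == gene]
        hit = False
        for p in proms.itertuples():
            piv = GenomicInterval(p.chrom, int(p.start), int(p.end))
            if any(piv.overlaps(anchor) for anchor in partners):
                hit = True
                break
        out[gene] = hit
    return out


def crispri_screen(
    z_matrix: np.ndarray,
    row_gene_ids: Sequence[str],
    col_gene_ids: Sequence[str],
    tss_by_gene: Mapping[str, tuple[str, int]],
    query_sets: Mapping[str, Iterable[str]] | None = None,
    top_inactivated: int = 2,
    top_regulated: int = 30,
    cis_window_bp: int = 1_000_000,
) -> dict:
    """CRISPRi perturbation screen for distal regulation.

    ``z_matrix[i, j]`` is the expression z-score of gene j after perturbing
    the promoter of gene i; lower means more repressed. A promoter is
    *efficiently inactivated* when its own gene ranks among the
    ``top_inactivated`` most repressed genes of its row; its
    ``top_regulated`` most repressed genes form the regulated set, and the
    promoter is a *distal regulator* when a regulated gene other than its
    own has a TSS within ``cis_window_bp`` on the same chromosome.

    ``query_sets`` (e.g. Epromoter and control gene sets) are each tested by
    an upper-tail hypergeometric overlap with the distal regulators inside
    the universe of efficiently inactivated promoters.
    """
    n_rows, n_cols = z_matrix.shape
    if n_rows != len(row_gene_ids) or n_cols != len(col_gene_ids):
        raise ValueError("z-matrix shape does not match the gene id lists")
    col_index = {g: j for j, g in enumerate(col_gene_ids)}
    k = min(top_regulated, n_cols)
    if n_cols < top_regulated:
        warnings.warn(
            f"only {n_cols} genes per row; regulated set is the full row",
            stacklevel=2,
        )
    inactivated: list[str] = []
    regulated: dict[str, list[str]] = {}
    distal: list[str] = []
    for i, gene in enumerate(row_gene_ids):
        row = z_matrix[i]
        order = np.argsort(row, kind="stable")[:k]
        own_j = col_index.get(gene)
        if own_j is None or own_j not in order[:top_inactivated]:
            continue
        inactivated.append(gene)
        reg = [col_gene_ids[j] for j in order]
        regulated[gene] = reg
        own_chrom, own_tss = tss_by_gene[gene]
        for g in reg:
            if g == gene:
                continue
            chrom, tss = tss_by_gene[g]
            if chrom == own_chrom and abs(tss - own_tss) < cis_window_bp:
                distal.append(gene)
                break
    result = {
        "inactivated": sorted(inactivated),
        "regulated": regulated,
        "distal_regulators": sorted(distal),
        "tests": {},
    }
    if query_sets:
        universe = set(inactivated)
        hits = set(distal)
        for name, genes in query_sets.items():
            q = set(genes) & universe
            obs = len(q & hits)
            result["tests"][name] = {
                "n_in_universe": len(q),
                "n_distal": obs,
                "p_hyper": hypergeom_upper(len(universe), len(hits), len(q), obs),
            }
    return result


def integrate_evidence(
    snp_traits: pd.DataFrame,
    distal_eqtl_snps: Iterable[str],
    pp_consistent_snps: Iterable[str],
    mpra_skew_snps: Iterable[str],
    tf_skew_snps: Iterable[str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Intersect the four evidence layers into the final variant list.

    ``snp_traits`` provides the candidate SNPs (snp_id, n_traits). A SNP
    enters the final list iff all four flags hold; members with >= 2 traits
    are pleiotropic. Returns the per-SNP evidence profile plus summary counts
    of final-list members in trait bins 1 / 2 / >= 3.
    """
    d, p = set(distal_eqtl_snps), set(pp_consistent_snps)
    m, t = set(mpra_skew_snps), set(tf_skew_snps)
    prof = snp_traits[["snp_id", "n_traits"]].drop_duplicates("snp_id").copy()
    prof["has_distal_eqtl"] = prof["snp_id"].isin(d)
    prof["has_pp_consistent_target"] = prof["snp_id"].isin(p)
    prof["has_mpra_skew"] = prof["snp_id"].isin(m)
    prof["has_tf_binding_skew"] = prof["snp_id"].isin(t)
    prof["in_final_list"] = (
        prof["has_distal_eqtl"]
        & prof["has_pp_consistent_target"]
        & prof["has_mpra_skew"]
        & prof["has_tf_binding_skew"]
    )
    prof["pleiotropic"] = prof["n_traits"] >= 2
    final = prof[prof["in_final_list"]]
    summary = {
        "n_final": int(len(final)),
        "n_1_trait": int((final["n_traits"] == 1).sum()),
        "n_2_traits": int((final["n_traits"] == 2).sum()),
        "n_3plus_traits": int((final["n_traits"] >= 3).sum()),
    }
    return prof.sort_values("snp_id").reset_index(drop=True), summary
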