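"""GWAS lead expansion through LD and pleiotropy/enrichment statistics.

Lead SNPs from a GWAS catalog are expanded to all panel variants within a
1-Mb window in high linkage disequilibrium (r^2 > 0.8); proxies inherit the
lead's traits (unique EFO ids) and parent categories. Variants are
intersected with promoter sets; pleiotropy is the count of non-redundant
traits per SNP and per region, and enrichment is tested per trait with an
upper-tail hypergeometric test against the genome-wide GWAS-SNP background
and a chi-squared contingency test between two promoter sets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats



logger = logging.getLogger(__name__)

GWAS_COLUMNS = ["lead_snp_id", "chrom", "pos", "trait_efo_id", "trait_label", "parent_category"]


def compute_r2(panel: np.ndarray, snp_a: int, snp_b: int) -> float:
    """LD r^2 between two panel columns from phased haplotype frequencies.

    r^2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B)). Monomorphic sites
    are undefined and raise.
    """
    a = np.asarray(panel[:, snp_a], dtype=float)
    b = np.asarray(panel[:, snp_b], dtype=float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("r^2 undefined for a monomorphic site")
    pab = np.mean(a * b)
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))


def _r2_one_vs_many(panel: np.ndarray, lead_col: int, cols: np.ndarray) -> np.ndarray:
    """Vectorized r^2 of one column against many; NaN for monomorphic sites."""
    a = panel[:, lead_col].astype(float)
    B = panel[:, cols].astype(float)
    pa = a.mean()
    pb = B.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = (a[:, None] * B).mean(axis=0) - pa * pb
        r2 = cov**2 / (pa * (1 - pa) * pb * (1 - pb))
    r2[(pb == 0) | (pb == 1)] = np.nan
    if pa in (0.0, 1.0):
        r2[:] = np.nan
    return r2


def expand_ld(
    leads: pd.DataFrame,
    variants: pd.DataFrame,
    panel: np.ndarray,
    window_kb: float = 1000.0,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """Annotate panel variants with the traits of nearby high-LD leads.

    ``leads`` is the GWAS catalog (one row per lead x trait, columns
    ``GWAS_COLUMNS``); ``variants`` maps snp_id -> chrom, pos (1-based),
    panel column ``col`` and ``maf``. Every variant within +-window and
    r^2 strictly above ``r2_min`` of a lead inherits that lead's traits; the
    lead itself always does; multi-lead proxies union their traits. Leads
    absent from the panel are logged and skipped.

    Returns one row per annotated variant: snp_id, chrom, pos, maf,
    is_common, traits / categories (frozensets), lead_links
    (list of (lead_snp_id, r2)).
    """
    var = variants.set_index("snp_id", drop=False)
    window = int(window_kb * 1000)
    traits_by_lead: dict[str, set] = {}
    cats_by_lead: dict[str, set] = {}
    for rec in leads.itertuples():
        traits_by_lead.setdefault(rec.lead_snp_id, set()).add(rec.trait_efo_id)
        cats_by_lead.setdefault(rec.lead_snp_id, set()).add(rec.parent_category)

    hits: dict[str, dict] = {}

    def _annotate(snp_id: str, lead_id: str, r2: float) -> None:
        rec = var.loc[snp_id]
        entry = hits.setdefault(
            snp_id,
            {
                "snp_id": snp_id,
                "chrom": rec["chrom"],
                "pos": int(rec["pos"]),
                "maf": float(rec["maf"]),
                "traits": set(),
                "categories": set(),
                "lead_links": [],
            },
        )
        entry["traits"] |= traits_by_lead[lead_id]
        entry["categories"] |= cats_by_lead[lead_id]
        entry["lead_links"].append((lead_id, round(float(r2), 6)))

    chrom_groups = {
        chrom: grp.sort_values("pos") for chrom, grp in var.groupby("chrom")
    }
    for lead_id in sorted(traits_by_lead):
        if lead_id not in var.index:
            logger.warning("lead SNP %s absent from the panel; skipped", lead_id)
            continue
        lead = var.loc[lead_id]
        _annotate(lead_id, lead_id, 1.0)
        grp = chrom_groups[lead["chrom"]]
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, lead["pos"] - window, side="left")
        hi = np.searchsorted(pos, lead["pos"] + window, side="right")
        cand = grp.iloc[lo:hi]
        cand = cand[cand["snp_id"] != lead_id]
        if cand.empty:
            continue
        r2 = _r2_one_vs_many(panel, int(lead["col"]), cand["col"].to_numpy())
        for snp_id, val in zip(cand["snp_id"], r2):
            if np.isfinite(val) and val > r2_min:
                _annotate(snp_id, lead_id, val)

    rows = []
    for snp_id in sorted(hits):
        e = hits[snp_id]
        rows.append(
            {
                "snp_id": e["snp_id"],
                "chrom": e["chrom"],
                "pos": e["pos"],
                "maf": e["maf"],
                "is_common": e["maf"] >= 0.01,
                "traits": frozenset(e["traits"]),
                "categories": frozenset(e["categories"]),
                "lead_links": sorted(e["lead_links"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chrom", "pos", "maf", "is_common",
            "traits", "categories", "lead_links",
        ],
    )


def overlap_variants(
    variants: pd.DataFrame, regions: pd.DataFrame
) -> dict[str, list[str]]:
    """SNPs falling inside each region (half-open; VCF pos converted to
    0-based before the membership test).

    ``regions`` needs region_id/chrom/start/end columns. Every region is
    reported, possibly with an empty list.
    """
    out: dict[str, list[str]] = {str(r.region_id): [] for r in regions.itertuples()}
    if variants.empty:
        return out
    by_chrom = {
        chrom: grp.sort_values("pos") for chrom, grp in variants.groupby("chrom")
    }
    for r in regions.itertuples():
        grp = by_chrom.get(r.chrom)
        if grp is None:
            continue
        pos0 = grp["pos"].to_numpy() - 1
        lo = np.searchsorted(pos0, r.start, side="left")
        hi = np.searchsorted(pos0, r.end - 1, side="right")
        out[str(r.region_id)] = sorted(grp["snp_id"].iloc[lo:hi])
    return out


def pleiotropy_counts(
    region_variants: Mapping[str, Sequence[str]], annotated: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-redundant trait/category counts per SNP and per region.

    Per SNP: the sizes of its trait and category sets. Per region: the sizes
    of the unions over member SNPs; regions with >= 2 traits are labeled
    pleiotropic.
    """
    ann = annotated.set_index("snp_id")
    snp_rows = [
        {
            "snp_id": s,
            "n_traits": len(ann.at[s, "traits"]),
            "n_categories": len(ann.at[s, "categories"]),
        }
        for s in sorted(ann.index)
    ]
    region_rows = []
    for region_id in sorted(region_variants):
        traits: set = set()
        cats: set = set()
        n_snps = 0
        for s in region_variants[region_id]:
            if s in ann.index:
                traits |= set(ann.at[s, "traits"])
                cats |= set(ann.at[s, "categories"])
                n_snps += 1
        region_rows.append(
            {
                "region_id": region_id,
                "n_snps": n_snps,
                "n_traits": len(traits),
                "n_categories": len(cats),
                "pleiotropic": len(traits) >= 2,
            }
        )
    return pd.DataFrame(snp_rows), pd.DataFrame(region_rows)


def hypergeom_upper(population: int, successes: int, draws: int, observed: int) -> float:
    """Upper-tail hypergeometric probability P(X >= observed)."""
    return float(stats.hypergeom.sf(observed - 1, population, successes, draws))


def enrichment_tests(
    set_a_snps: Iterable[str],
    set_b_snps: Iterable[str],
    background: pd.DataFrame,
    key: str = "traits",
    yates: bool = False,
) -> pd.DataFrame:
    """Per-trait (or per-category) enrichment of two SNP sets.

    For each trait: hypergeometric upper tail of the set's trait-SNP count
    against the genome-wide GWAS-SNP background, for both sets; plus a
    chi-squared test (no continuity correction by default) on the 2x2 table
    trait/not-trait x set A/set B. A Benjamini-Hochberg FDR column is
    appended to each raw p-value column.
    """
    ann = background.set_index("snp_id")
    a = sorted(set(set_a_snps) & set(ann.index))
    b = sorted(set(set_b_snps) & set(ann.index))
    if not a and not b:
        return pd.DataFrame(
            columns=[key[:-1] if key.endswith("s") else key, "k_background",
                     "k_a", "k_b", "p_hyper_a", "p_hyper_b", "chi2", "p_chi2",
                     "fdr_hyper_a", "fdr_hyper_b", "fdr_chi2"]
        )
    all_terms = sorted({t for ts in ann[key] for t in ts})
    pop = len(ann)
    rows = []
    for term in all_terms:
        has = ann[key].apply(lambda ts: term in ts)
        K = int(has.sum())
        k_a = int(has.loc[a].sum()) if a else 0
        k_b = int(has.loc[b].sum()) if b else 0
        table = np.array(
            [[k_a, len(a) - k_a], [k_b, len(b) - k_b]], dtype=float
        )
        if table.sum() > 0 and (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            chi2, p_chi2, _, _ = stats.chi2_contingency(table, correction=yates)
        else:
            chi2, p_chi2 = 0.0, 1.0
        rows.append(
            {
                key[:-1] if key.endswith("s") else key: term,
                "k_background": K,
                "k_a": k_a,
                "k_b": k_b,
                "p_hyper_a": hypergeom_upper(pop, K, len(a), k_a),
                "p_hyper_b": hypergeom_upper(pop, K, len(b), k_b),
                "chi2": float(chi2),
                "p_chi2": float(p_chi2),
            }
        )
    out = pd.DataFrame(rows)
    for col in ("p_hyper_a", "p_hyper_b", "p_chi2"):
        out["fdr_" + col[2:]] = stats.false_discovery_control(out[col], method="bh")
    return out
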