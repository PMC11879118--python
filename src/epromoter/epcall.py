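"""Promoter definition and Epromoter calling.

A promoter is the 500-bp region upstream of a protein-coding transcript's
TSS. A promoter is an Epromoter when it overlaps an active enhancer with the
either-fraction rule of ``bedtools intersect -f 0.5 -F 0.5 -e``: the overlap
covers at least half of the promoter OR at least half of the enhancer.
Flagged promoter regions overlapping by >= 1 nt are merged (single linkage)
into non-redundant Epromoters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, interval_trees, merge_intervals, query_overlaps

ANNOTATION_COLUMNS = ["gene_id", "transcript_id", "chrom", "strand", "tss"]
PROMOTER_COLUMNS = [
    "promoter_id",
    "gene_id",
    "transcript_id",
    "chrom",
    "start",
    "end",
    "strand",
]


def define_promoters(
    annotation: pd.DataFrame,
    window: int = 500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """One promoter record per coding transcript: ``window`` bp upstream of
    the TSS, strand-aware, clipped at chromosome boundaries.

    ``annotation`` needs gene_id/transcript_id/chrom/strand/tss columns with
    0-based TSS. Records with an identical (gene, region) are collapsed,
    keeping the lexicographically smallest transcript id as the promoter id.
    """
    if window <= 0:
        raise ValueError("promoter window must be positive")
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation lacks columns {missing}")
    bad = ~annotation["strand"].isin(["+", "-"])
    if bad.any():
        tx = annotation.loc[bad, "transcript_id"].iloc[0]
        raise ValueError(f"transcript {tx} has no valid strand")
    rows = []
    for rec in annotation.sort_values("transcript_id").itertuples():
        tss = int(rec.tss)
        if rec.strand == "+":
            start, end = tss - window, tss
        else:
            start, end = tss, tss + window
        start = max(start, 0)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[rec.chrom])
        if end <= start:
            continue  # TSS at the very chromosome edge leaves no promoter
        rows.append(
            {
                "promoter_id": rec.transcript_id,
                "gene_id": rec.gene_id,
                "transcript_id": rec.transcript_id,
                "chrom": rec.chrom,
                "start": start,
                "end": end,
                "strand": rec.strand,
            }
        )
    out = pd.DataFrame(rows, columns=PROMOTER_COLUMNS)
    out = out.drop_duplicates(subset=["gene_id", "chrom", "start", "end"], keep="first")
    return out.sort_values(["chrom", "start", "promoter_id"]).reset_index(drop=True)


def promoter_intervals(promoters: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in promoters.itertuples()
    ]


def call_epromoters(
    promoters: pd.DataFrame,
    enhancers: Sequence[GenomicInterval],
    min_frac: float = 0.5,
    either: bool = True,
) -> pd.DataFrame:
    """Flag promoters overlapping an enhancer under the fraction rule.

    With ``either`` (the -e semantics) a single overlap must cover
    ``min_frac`` of the promoter OR of the enhancer; without it, both
    fractions are required.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    flags = []
    trees = interval_trees(enhancers) if len(enhancers) else {}
    for rec in promoters.itertuples():
        piv = GenomicInterval(rec.chrom, int(rec.start), int(rec.end))
        hit = False
        for idx in query_overlaps(trees, piv):
            e = enhancers[idx]
            ov = piv.overlap_len(e)
            f_prom = ov >= min_frac * piv.length
            f_enh = ov >= min_frac * e.length
            if (f_prom or f_enh) if either else (f_prom and f_enh):
                hit = True
                break
        flags.append(hit)
    return promoters.assign(is_epromoter=flags)


@dataclass
class EpromoterSet:
    """Non-redundant merged Epromoter regions with their member promoters."""

    regions: pd.DataFrame  # merged_id, chrom, start, end
    members: pd.DataFrame  # merged_id, promoter_id, gene_id, dataset

    @property
    def region_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in self.regions.itertuples()
        ]

    def gene_ids(self) -> set[str]:
        return set(self.members["gene_id"])


def merge_epromoters(flagged: pd.DataFrame, dataset: str = "default") -> EpromoterSet:
    """Merge flagged promoter regions overlapping by >= 1 nt (single linkage,
    hence transitive) and union the member promoter/gene ids."""
    sub = flagged[flagged["is_epromoter"]] if "is_epromoter" in flagged.columns else flagged
    if sub.empty:
        return EpromoterSet(
            regions=pd.DataFrame(columns=["merged_id", "chrom", "start", "end"]),
            members=pd.DataFrame(
                columns=["merged_id", "promoter_id", "gene_id", "dataset"]
            ),
        )
    ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in sub.itertuples()
    ]
    merged, assignment = merge_intervals(ivs)
    ids = [f"EP{i + 1:05d}" for i in range(len(merged))]
    regions = pd.DataFrame(
        {
            "merged_id": ids,
            "chrom": [m.chrom for m in merged],
            "start": [m.start for m in merged],
            "end": [m.end for m in merged],
        }
    )
    members = pd.DataFrame(
        {
            "merged_id": [ids[a] for a in assignment],
            "promoter_id": sub["promoter_id"].to_numpy(),
            "gene_id": sub["gene_id"].to_numpy(),
            "dataset": dataset,
        }
    ).sort_values(["merged_id", "promoter_id"]).reset_index(drop=True)
    return EpromoterSet(regions=regions, members=members)


def sharing_stats(
    per_dataset: Mapping[str, EpromoterSet],
) -> tuple[pd.DataFrame, pd.Series]:
    """Cross-dataset sharing of Epromoters.

    All datasets' merged regions are union-merged; each union region is
    scored by the number of datasets containing an overlapping Epromoter.
    Returns the per-region table and the fraction of regions found in
    exactly k datasets.
    """
    if len(per_dataset) < 2:
        raise ValueError("sharing requires at least 2 datasets")
    names = sorted(per_dataset)
    all_ivs: list[GenomicInterval] = []
    owners: list[str] = []
    for name in names:
        ivs = per_dataset[name].region_intervals
        all_ivs.extend(ivs)
        owners.extend([name] * len(ivs))
    if not all_ivs:
        return (
            pd.DataFrame(columns=["chrom", "start", "end", "n_datasets", "datasets"]),
            pd.Series(dtype=float),
        )
    merged, assignment = merge_intervals(all_ivs)
    present: list[set[str]] = [set() for _ in merged]
    for owner, a in zip(owners, assignment):
        present[a].add(owner)
    table = pd.DataFrame(
        {
            "chrom": [m.chrom for m in merged],
            "start": [m.start for m in merged],
            "end": [m.end for m in merged],
            "n_datasets": [len(p) for p in present],
            "datasets": [",".join(sorted(p)) for p in present],
        }
    )
    frac = table["n_datasets"].value_counts(normalize=True).sort_index()
    return table, frac


def define_distal_enhancers(
    starr_enhancers: Sequence[GenomicInterval],
    reference_enhancers: Sequence[GenomicInterval],
    epromoters: Sequence[GenomicInterval],
    min_frac: float = 0.5,
    center_bp: int = 500,
) -> list[GenomicInterval]:
    """Distal (non-promoter) enhancer comparison set.

    STARR enhancers overlapping any Epromoter are discarded; the remainder is
    intersected with the reference (e.g. ENCODE candidate) enhancers at the
    >= 50%-either rule, and the central ``center_bp`` of each retained
    reference enhancer is emitted (the whole region when shorter).
    """
    ep_trees = interval_trees(epromoters) if len(epromoters) else {}
    candidates = [
        e for e in starr_enhancers if not query_overlaps(ep_trees, e)
    ]
    cand_trees = interval_trees(candidates) if candidates else {}
    out = []
    for ref in reference_enhancers:
        keep = False
        for idx in query_overlaps(cand_trees, ref):
            c = candidates[idx]
            ov = ref.overlap_len(c)
            if ov >= min_frac * ref.length or ov >= min_frac * c.length:
                keep = True
                break
        if not keep:
            continue
        if ref.length <= center_bp:
            out.append(GenomicInterval(ref.chrom, ref.start, ref.end))
        else:
            mid = (ref.start + ref.end) // 2
            out.append(
                GenomicInterval(ref.chrom, mid - center_bp // 2, mid + center_bp // 2)
            )
    return sorted(out)
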