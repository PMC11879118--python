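"""Comparative genomic/epigenomic feature statistics of promoter sets.

Per-region statistics against annotation tracks: CpG-island overlap
(boolean), G-quadruplex coverage (% of bases), per-base conservation sums,
TF binding-site density and family diversity (sites with score > 400 only),
ChIP peak and biotype counts, CAGE directionality around the TSS, and
chromatin-state fold enrichment relative to the genome.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, interval_trees, merge_intervals, query_overlaps


def _region_ivs(regions: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in regions.itertuples()
    ]


def _ids(regions: pd.DataFrame) -> list[str]:
    if "region_id" in regions.columns:
        return [str(x) for x in regions["region_id"]]
    return [f"{r.chrom}:{r.start}-{r.end}" for r in regions.itertuples()]


def region_feature_stats(
    regions: pd.DataFrame, track: pd.DataFrame, kind: str
) -> pd.DataFrame:
    """Per-region statistic for an interval or per-base feature track.

    kinds: ``cgi`` -> any-overlap boolean; ``g4`` -> merged coverage as % of
    region length; ``conservation_base`` -> sum of per-base scores (track
    columns chrom/pos/score, one row per base); ``chip_peak`` -> counts of
    distinct (tf, interval) peaks and of distinct biotypes.
    """
    ids = _ids(regions)
    ivs = _region_ivs(regions)
    if kind == "cgi":
        trees = interval_trees(_track_ivs(track)) if len(track) else {}
        vals = [bool(query_overlaps(trees, iv)) for iv in ivs]
        return pd.DataFrame({"region_id": ids, "cgi_overlap": vals})
    if kind == "g4":
        merged, _ = merge_intervals(_track_ivs(track)) if len(track) else ([], [])
        trees = interval_trees(merged) if merged else {}
        vals = []
        for iv in ivs:
            cov = sum(iv.overlap_len(merged[i]) for i in query_overlaps(trees, iv))
            vals.append(100.0 * cov / iv.length)
        return pd.DataFrame({"region_id": ids, "g4_pct": vals})
    if kind == "conservation_base":
        sums = _per_base_sums(ivs, track)
        return pd.DataFrame({"region_id": ids, "conservation_sum": sums})
    if kind == "chip_peak":
        peaks = track.drop_duplicates(subset=["tf", "chrom", "start", "end"])
        trees = interval_trees(_track_ivs(peaks)) if len(peaks) else {}
        n_peaks, n_biotypes = [], []
        for iv in ivs:
            hits = query_overlaps(trees, iv)
            n_peaks.append(len(hits))
            n_biotypes.append(peaks.iloc[hits]["biotype"].nunique() if hits else 0)
        return pd.DataFrame(
            {"region_id": ids, "n_peaks": n_peaks, "n_biotypes": n_biotypes}
        )
    raise ValueError(f"unknown track kind {kind!r}")


def _track_ivs(track: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(t.chrom, int(t.start), int(t.end)) for t in track.itertuples()
    ]


def _per_base_sums(
    ivs: Sequence[GenomicInterval], track: pd.DataFrame
) -> list[float]:
    """Sum per-base scores over each region (track: chrom/pos/score)."""
    sums = [0.0] * len(ivs)
    for chrom, grp in track.groupby("chrom"):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(grp["score"].to_numpy(dtype=float))])
        for i, iv in enumerate(ivs):
            if iv.chrom != chrom:
                continue
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end - 1, side="right")
            sums[i] += float(csum[hi] - csum[lo])
    return sums


def tfbs_density_diversity(
    regions: pd.DataFrame, tfbs: pd.DataFrame, min_score: float = 400.0
) -> pd.DataFrame:
    """TF binding-site density and family diversity per region.

    Sites with score <= ``min_score`` are dropped (strictly-greater filter);
    density is the retained sites overlapping the region, diversity the
    number of distinct TF families among them.
    """
    kept = tfbs[tfbs["score"] > min_score].reset_index(drop=True)
    trees = interval_trees(_track_ivs(kept)) if len(kept) else {}
    rows = []
    for rid, iv in zip(_ids(regions), _region_ivs(regions)):
        hits = query_overlaps(trees, iv)
        fams = kept.iloc[hits]["family"] if hits else pd.Series(dtype=object)
        rows.append(
            {"region_id": rid, "density": len(hits), "diversity": int(fams.nunique())}
        )
    return pd.DataFrame(rows)


def cage_directionality(
    promoters: pd.DataFrame,
    cage_peaks: pd.DataFrame,
    cage_signal: pd.DataFrame | None = None,
    window: int = 500,
) -> pd.DataFrame:
    """CAGE directionality and strand-partitioned signal around each TSS.

    The window is TSS +- ``window`` bp. Orientation is relative to the gene:
    a peak (or signal base) on the gene's strand is *sense/forward*, the
    opposite strand *antisense/reverse*. A promoter is ``divergent`` when
    both a sense and an antisense peak overlap the window, ``unidirectional``
    with a sense peak only, else ``unclassified``.
    """
    if "strand" not in promoters.columns or promoters["strand"].isna().any():
        raise ValueError("promoters must carry the gene strand")
    peak_trees: dict[str, dict] = {}
    for strand in ("+", "-"):
        sub = cage_peaks[cage_peaks["strand"] == strand].reset_index(drop=True)
        peak_trees[strand] = interval_trees(_track_ivs(sub)) if len(sub) else {}
    sig_by = {}
    if cage_signal is not None and len(cage_signal):
        for (chrom, strand), grp in cage_signal.groupby(["chrom", "strand"]):
            grp = grp.sort_values("pos")
            sig_by[(chrom, strand)] = (
                grp["pos"].to_numpy(),
                np.concatenate([[0.0], np.cumsum(grp["score"].to_numpy(dtype=float))]),
            )
    rows = []
    for rec in promoters.itertuples():
        tss = int(rec.tss) if hasattr(rec, "tss") else (
            int(rec.end) if rec.strand == "+" else int(rec.start)
        )
        win = GenomicInterval(rec.chrom, max(tss - window, 0), tss + window)
        sense_strand = rec.strand
        anti_strand = "-" if sense_strand == "+" else "+"
        has_sense = bool(query_overlaps(peak_trees[sense_strand], win))
        has_anti = bool(query_overlaps(peak_trees[anti_strand], win))
        if has_sense and has_anti:
            cls = "divergent"
        elif has_sense:
            cls = "unidirectional"
        else:
            cls = "unclassified"

        def _signal(strand: str) -> float:
            got = sig_by.get((rec.chrom, strand))
            if got is None:
                return 0.0
            pos, csum = got
            lo = np.searchsorted(pos, win.start, side="left")
            hi = np.searchsorted(pos, win.end - 1, side="right")
            return float(csum[hi] - csum[lo])

        rows.append(
            {
                "promoter_id": rec.promoter_id,
                "class": cls,
                "forward_signal": _signal(sense_strand),
                "reverse_signal": _signal(anti_strand),
            }
        )
    return pd.DataFrame(rows)


def state_fold_enrichment(
    regions: pd.DataFrame, states: pd.DataFrame, genome_size: int
) -> pd.Series:
    """Chromatin-state fold enrichment of a region set.

    fold(s) = [overlap_bp(s, regions) / total_bp(s)] /
              [bp(regions) / genome_size]; states with zero genomic bp are
    skipped with a warning. States are assumed to tile the genome uniquely.
    """
    ivs = _region_ivs(regions)
    region_bp = sum(iv.length for iv in ivs)
    if region_bp == 0 or genome_size <= 0:
        raise ValueError("regions and genome size must be non-empty")
    trees = interval_trees(_track_ivs(states))
    overlap = {}
    total = states.assign(length=states["end"] - states["start"]).groupby("state")[
        "length"
    ].sum()
    for iv in ivs:
        for idx in query_overlaps(trees, iv):
            seg = states.iloc[idx]
            ov = iv.overlap_len(
                GenomicInterval(seg["chrom"], int(seg["start"]), int(seg["end"]))
            )
            overlap[seg["state"]] = overlap.get(seg["state"], 0) + ov
    folds = {}
    for state, tot in total.items():
        if tot == 0:
            warnings.warn(f"state {state} covers zero bases; skipped", stacklevel=2)
            continue
        folds[state] = (overlap.get(state, 0) / tot) / (region_bp / genome_size)
    return pd.Series(folds, name="fold").sort_index()


def compare_state_enrichment(
    regions_a: pd.DataFrame,
    regions_b: pd.DataFrame,
    states: pd.DataFrame,
    genome_size: int,
) -> pd.DataFrame:
    """log2 ratio of per-state fold enrichments of two region sets."""
    fa = state_fold_enrichment(regions_a, states, genome_size)
    fb = state_fold_enrichment(regions_b, states, genome_size)
    out = pd.DataFrame({"fold_a": fa, "fold_b": fb})
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_ratio"] = np.log2(out["fold_a"] / out["fold_b"])
    return out
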