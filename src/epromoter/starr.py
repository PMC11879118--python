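"""(Cap)STARR-seq activity quantification and enhancer calling.

The assay transfects a library of candidate fragments (the *input*) and
sequences transcribed reporter RNA (the *output*); regulatory activity of a
region is the fold change of output over input coverage, both normalized as
FPKM. Regions are called active when their fold change exceeds the knee
(inflection point) of the ranked fold-change curve.

Reads are extended to the mean captured-fragment size (314 nt) before
coverage is computed; fragment-region membership is >= 1 bp overlap, matching
`bedtools coverage` defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, count_overlapping

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass
class FragmentSet:
    """Mapped fragments of one sequencing library.

    ``fragments`` is a DataFrame with columns chrom/start/end/strand
    (0-based half-open). ``total_mapped`` defaults to the fragment count but
    may be larger when the table is a filtered subset of the library.
    """

    library_label: str  # "input" or "output"
    replicate: int
    fragments: pd.DataFrame
    condition: str = "NS"
    total_mapped: int | None = None

    def __post_init__(self) -> None:
        if self.library_label not in ("input", "output"):
            raise ValueError(f"library_label must be input/output, got {self.library_label!r}")
        missing = [c for c in ("chrom", "start", "end") if c not in self.fragments.columns]
        if missing:
            raise ValueError(f"fragment table lacks columns {missing}")
        if "strand" not in self.fragments.columns:
            self.fragments = self.fragments.assign(strand="+")
        n = len(self.fragments)
        if self.total_mapped is None:
            self.total_mapped = n
        if n == 0 or self.total_mapped < n:
            raise ValueError("total_mapped >= number of fragments > 0 required")
        self.fragments = self.fragments.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)


@dataclass(frozen=True)
class RegionActivity:
    """Activity call for one captured/tiled region."""

    region: GenomicInterval
    fpkm_input: float
    fpkm_output: float
    fold_change: float
    rank: int = -1
    active: bool = False


def extend_fragments(
    fragset: FragmentSet, target_length: int, chrom_sizes: Mapping[str, int]
) -> FragmentSet:
    """Extend each fragment from its 5' start to ``target_length``.

    Plus-strand fragments grow rightward from ``start``; minus-strand
    fragments grow leftward from ``end``. Extensions are clipped at
    chromosome bounds; the fragment count is unchanged.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    df = fragset.fragments
    unknown = set(df["chrom"]) - set(chrom_sizes)
    if unknown:
        bad = df[df["chrom"].isin(unknown)].iloc[0]
        raise ValueError(
            f"fragment {bad['chrom']}:{bad['start']}-{bad['end']} on unknown chromosome"
        )
    sizes = df["chrom"].map(chrom_sizes).to_numpy()
    plus = df["strand"].to_numpy() != "-"
    start = df["start"].to_numpy().copy()
    end = df["end"].to_numpy().copy()
    end[plus] = np.minimum(start[plus] + target_length, sizes[plus])
    start[~plus] = np.maximum(end[~plus] - target_length, 0)
    out = df.assign(start=start, end=end)
    return replace(fragset, fragments=out)


def compute_fpkm(
    regions: Sequence[GenomicInterval], fragset: FragmentSet
) -> dict[GenomicInterval, float]:
    """Fragments per kilobase of region per million mapped fragments.

    A fragment counts toward a region if it overlaps it by >= 1 bp.
    """
    if fragset.total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    for r in regions:
        if r.length <= 0:
            raise ValueError(f"zero-length region: {r}")
    df = fragset.fragments
    counts = count_overlapping(
        regions,
        df["chrom"].to_numpy(),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
    )
    scale = fragset.total_mapped / 1e6
    return {
        r: c / ((r.length / 1000.0) * scale) for r, c in zip(regions, counts)
    }


def find_inflection_point(
    sorted_values: Sequence[float],
) -> float:
    """Knee of a descending curve: the value at the rank with maximal
    perpendicular distance to the chord joining the first and last points,
    after min-max normalizing both axes.

    Ties break toward the smaller rank (larger value, fewer actives). A flat
    curve degenerates to the common value, leaving nothing strictly above it.
    """
    y = np.asarray(sorted_values, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 values to locate a knee")
    if np.any(np.diff(y) > 0):
        raise ValueError("values must be sorted in descending order")
    lo, hi = y[-1], y[0]
    if hi == lo:
        return float(hi)
    yn = (y - lo) / (hi - lo)
    xn = np.linspace(0.0, 1.0, y.size)
    # chord runs (0,1) -> (1,0); |x + y - 1| / sqrt(2) is the distance
    dist = np.abs(xn + yn - 1.0)
    knee = int(np.argmax(dist))  # argmax returns the first (smallest) rank on ties
    return float(y[knee])


def call_active_regions(
    input_fpkm: Mapping[GenomicInterval, float],
    output_fpkm: Mapping[GenomicInterval, float],
    min_input_fpkm: float = 1.0,
    threshold_fn: Callable[[Sequence[float]], float] = find_inflection_point,
) -> list[RegionActivity]:
    """Filter on input coverage, compute fold changes, and call actives.

    Regions with input FPKM below ``min_input_fpkm`` are removed before
    ranking. Active regions are those with fold change strictly greater than
    the knee threshold of the descending fold-change curve.
    """
    if set(input_fpkm) != set(output_fpkm):
        raise ValueError("input and output FPKM maps must share identical regions")
    retained = [
        (r, fin, output_fpkm[r])
        for r, fin in input_fpkm.items()
        if fin >= min_input_fpkm
    ]
    if len(retained) < 3:
        raise ValueError(
            f"only {len(retained)} regions pass the input filter; knee undefined"
        )
    records = [
        RegionActivity(region=r, fpkm_input=fin, fpkm_output=fout, fold_change=fout / fin)
        for r, fin, fout in retained
    ]
    return _rank_and_threshold(records, threshold_fn)


def _rank_and_threshold(
    records: list[RegionActivity],
    threshold_fn: Callable[[Sequence[float]], float] = find_inflection_point,
) -> list[RegionActivity]:
    records = sorted(records, key=lambda a: (-a.fold_change, a.region))
    threshold = threshold_fn([a.fold_change for a in records])
    return [
        replace(a, rank=i, active=a.fold_change > threshold)
        for i, a in enumerate(records)
    ]


def merge_replicate_calls(
    replicate_calls: Sequence[Sequence[RegionActivity]],
    match: str = "key",
    threshold_fn: Callable[[Sequence[float]], float] = find_inflection_point,
) -> list[RegionActivity]:
    """Common regions across replicates with averaged activity, re-thresholded.

    ``match="key"`` (captured-region libraries) keeps regions whose interval is
    identical in every replicate; ``match="overlap"`` (peak-style inputs) keeps
    first-replicate regions overlapping >= 1 bp with some region of every other
    replicate and averages over the overlapping partners.
    """
    if len(replicate_calls) < 2:
        raise ValueError("need at least 2 replicates to merge")
    if match == "key":
        maps = [{a.region: a for a in calls} for calls in replicate_calls]
        common = set(maps[0])
        for m in maps[1:]:
            common &= set(m)
        merged = [
            RegionActivity(
                region=r,
                fpkm_input=float(np.mean([m[r].fpkm_input for m in maps])),
                fpkm_output=float(np.mean([m[r].fpkm_output for m in maps])),
                fold_change=float(np.mean([m[r].fold_change for m in maps])),
            )
            for r in common
        ]
    elif match == "overlap":
        from .intervals import interval_trees, query_overlaps

        others = [
            (calls, interval_trees([a.region for a in calls]))
            for calls in replicate_calls[1:]
        ]
        merged = []
        for a in replicate_calls[0]:
            partner_folds = [a.fold_change]
            partner_in = [a.fpkm_input]
            partner_out = [a.fpkm_output]
            ok = True
            for calls, trees in others:
                hits = query_overlaps(trees, a.region)
                if not hits:
                    ok = False
                    break
                partner_folds.extend(calls[h].fold_change for h in hits)
                partner_in.extend(calls[h].fpkm_input for h in hits)
                partner_out.extend(calls[h].fpkm_output for h in hits)
            if ok:
                merged.append(
                    RegionActivity(
                        region=a.region,
                        fpkm_input=float(np.mean(partner_in)),
                        fpkm_output=float(np.mean(partner_out)),
                        fold_change=float(np.mean(partner_folds)),
                    )
                )
    else:
        raise ValueError(f"unknown match mode {match!r}")
    if not merged:
        warnings.warn("no regions are common to all replicates", stacklevel=2)
        return []
    if len(merged) < 3:
        warnings.warn(
            "fewer than 3 common regions; knee undefined, all calls inactive",
            stacklevel=2,
        )
        return [
            replace(a, rank=i, active=False)
            for i, a in enumerate(
                sorted(merged, key=lambda a: (-a.fold_change, a.region))
            )
        ]
    return _rank_and_threshold(merged, threshold_fn)


def allelic_read_counts(
    fragments_by_condition: Mapping[str, pd.DataFrame],
    snp_chrom: str | None = None,
    snp_pos: int | None = None,
    baseline_condition: str = "NS",
) -> pd.DataFrame:
    """Allele-partitioned read counts at a SNP, per stimulation condition.

    Each condition's table carries one row per read with ``replicate`` and
    ``allele`` columns (plus chrom/start/end when a SNP position is given, in
    which case only reads overlapping the SNP are counted). Per condition and
    allele the replicate mean is computed, then normalized to the
    no-stimulation condition for that allele; the baseline condition is 1 by
    construction, and alleles with zero baseline reads report NaN.
    """
    if baseline_condition not in fragments_by_condition:
        raise ValueError(f"baseline condition {baseline_condition!r} missing")
    alleles = sorted(
        {a for df in fragments_by_condition.values() for a in df["allele"].unique()}
    )
    rows = []
    for condition, df in fragments_by_condition.items():
        if snp_pos is not None:
            df = df[
                (df["chrom"] == snp_chrom)
                & (df["start"] <= snp_pos)
                & (df["end"] > snp_pos)
            ]
        n_reps = max(df["replicate"].nunique(), 1)
        for allele in alleles:
            counts = df[df["allele"] == allele].groupby("replicate").size()
            mean = counts.reindex(sorted(df["replicate"].unique()), fill_value=0).mean()
            rows.append(
                {
                    "condition": condition,
                    "allele": allele,
                    "mean_count": 0.0 if n_reps == 0 or np.isnan(mean) else float(mean),
                }
            )
    out = pd.DataFrame(rows)
    base = out[out["condition"] == baseline_condition].set_index("allele")["mean_count"]
    norm = []
    for _, row in out.iterrows():
        b = base.get(row["allele"], 0.0)
        norm.append(row["mean_count"] / b if b > 0 else np.nan)
    out["normalized"] = norm
    return out.sort_values(["condition", "allele"]).reset_index(drop=True)
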