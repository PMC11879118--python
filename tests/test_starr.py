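"""STARR-seq activity quantification: extension, FPKM, knee threshold,
replicate merging and allelic read partitioning."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epromoter import (
    FragmentSet,
    GenomicInterval,
    allelic_read_counts,
    call_active_regions,
    compute_fpkm,
    extend_fragments,
    find_inflection_point,
    merge_replicate_calls,
)
from epromoter.starr import RegionActivity, _rank_and_threshold

CHROMS = {"chr1": 10_000, "chr2": 10_000}


def _fragset(rows, label="input", **kw):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return FragmentSet(library_label=label, replicate=1, fragments=df, **kw)


def knee_oracle(vals):
    """Exhaustive max-perpendicular-distance-to-chord enumeration."""
    y = np.asarray(vals, dtype=float)
    lo, hi = y[-1], y[0]
    if hi == lo:
        return float(hi)
    best_d, best_i = -1.0, 0
    for i in range(y.size):
        x = i / (y.size - 1)
        yn = (y[i] - lo) / (hi - lo)
        d = abs(x + yn - 1.0) / math.sqrt(2)
        if d > best_d + 1e-15:
            best_d, best_i = d, i
    return float(y[best_i])


class TestExtendFragments:
    def test_plus_strand_extends_to_target(self):
        fs = _fragset([("chr1", 1000, 1050, "+")])
        out = extend_fragments(fs, 314, CHROMS)
        assert out.fragments.iloc[0][["start", "end"]].tolist() == [1000, 1314]

    def test_already_at_target_unchanged(self):
        fs = _fragset([("chr1", 1000, 1314, "+")])
        out = extend_fragments(fs, 314, CHROMS)
        assert out.fragments.iloc[0][["start", "end"]].tolist() == [1000, 1314]

    def test_clipped_at_chromosome_end(self):
        fs = _fragset([("chr1", 9900, 9950, "+")])
        out = extend_fragments(fs, 314, CHROMS)
        row = out.fragments.iloc[0]
        assert (row["start"], row["end"]) == (9900, 10000)

    def test_minus_strand_extends_from_three_prime_end(self):
        fs = _fragset([("chr1", 1000, 1050, "-")])
        out = extend_fragments(fs, 314, CHROMS)
        row = out.fragments.iloc[0]
        assert (row["start"], row["end"]) == (1050 - 314, 1050)

    def test_unknown_chromosome_names_fragment(self):
        fs = _fragset([("chrX", 0, 50, "+")])
        with pytest.raises(ValueError, match="chrX"):
            extend_fragments(fs, 314, CHROMS)


class TestComputeFpkm:
    def test_direct_formula(self):
        # 10 fragments on a 500-bp region, one million mapped -> 20.0
        frags = [("chr1", 1000 + i, 1050 + i, "+") for i in range(10)]
        fs = _fragset(frags, total_mapped=1_000_000)
        region = GenomicInterval("chr1", 1000, 1500)
        assert compute_fpkm([region], fs)[region] == pytest.approx(20.0)

    def test_no_overlap_is_zero(self):
        fs = _fragset([("chr1", 9000, 9050, "+")])
        region = GenomicInterval("chr1", 0, 500)
        assert compute_fpkm([region], fs)[region] == 0.0

    def test_hand_computed_case(self):
        # 7 fragments, 700-bp region, 2e6 mapped -> 7 / (0.7 * 2) = 5.0
        frags = [("chr1", 100 + i, 150 + i, "+") for i in range(7)]
        fs = _fragset(frags, total_mapped=2_000_000)
        region = GenomicInterval("chr1", 0, 700)
        assert compute_fpkm([region], fs)[region] == pytest.approx(5.0)

    def test_zero_length_region_rejected(self):
        fs = _fragset([("chr1", 0, 50, "+")])
        with pytest.raises(ValueError, match="zero-length"):
            compute_fpkm([GenomicInterval("chr1", 5, 5)], fs)

    def test_scale_equivariance(self):
        # doubling all counts and total_mapped leaves FPKM unchanged
        frags = [("chr1", i * 10, i * 10 + 50, "+") for i in range(8)]
        region = GenomicInterval("chr1", 0, 300)
        one = compute_fpkm([region], _fragset(frags, total_mapped=10_000))[region]
        two = compute_fpkm([region], _fragset(frags * 2, total_mapped=20_000))[region]
        assert one == pytest.approx(two)


class TestInflectionPoint:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([10, 9, 8, 1.05, 1.0, 0.95, 0.9], 1.05),
            ([100, 90, 80, 70, 5, 4, 3, 2, 1], 5.0),
            ([5, 5, 5, 5], 5.0),
        ],
    )
    def test_frozen_oracle_values(self, values, expected):
        assert find_inflection_point(values) == pytest.approx(expected)
        assert find_inflection_point(values) == pytest.approx(knee_oracle(values))

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            find_inflection_point([1.0, 3.0, 2.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_inflection_point([2.0, 1.0])

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=3, max_size=12),
        st.floats(0.1, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_scaling_preserves_knee_rank_and_active_set(self, vals, c):
        vals = sorted(vals, reverse=True)
        thr = find_inflection_point(vals)
        thr_scaled = find_inflection_point([v * c for v in vals])
        assert thr_scaled == pytest.approx(thr * c, rel=1e-9)
        # strict-threshold membership, with float equality treated as "at knee"
        active = [i for i, v in enumerate(vals)
                  if v > thr and not math.isclose(v, thr, rel_tol=1e-9)]
        active_scaled = [i for i, v in enumerate(vals)
                         if v * c > thr_scaled
                         and not math.isclose(v * c, thr_scaled, rel_tol=1e-9)]
        assert active == active_scaled


class TestCallActiveRegions:
    def _maps(self, folds, fin=2.0):
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(len(folds))]
        return (
            {r: fin for r in regions},
            {r: fin * f for r, f in zip(regions, folds)},
        )

    def test_low_input_region_removed(self):
        fin, fout = self._maps([10, 9, 8, 1.0])
        weak = GenomicInterval("chr1", 99_000, 99_500)
        fin[weak] = 0.5
        fout[weak] = 50.0  # high output cannot rescue a low-input region
        calls = call_active_regions(fin, fout)
        assert weak not in {a.region for a in calls}

    def test_flat_curve_has_no_actives(self):
        fin, fout = self._maps([3.0, 3.0, 3.0, 3.0])
        calls = call_active_regions(fin, fout)
        assert not any(a.active for a in calls)

    def test_top_three_active_on_example_curve(self):
        fin, fout = self._maps([10, 9, 8, 1.05, 1.0, 0.95, 0.9])
        calls = call_active_regions(fin, fout)
        active_folds = sorted(
            (a.fold_change for a in calls if a.active), reverse=True
        )
        assert np.allclose(active_folds, [10, 9, 8])

    def test_too_few_regions_rejected(self):
        fin, fout = self._maps([2.0, 1.0])
        with pytest.raises(ValueError, match="knee undefined"):
            call_active_regions(fin, fout)


class TestMergeReplicates:
    def _call(self, region, fold):
        return RegionActivity(
            region=region, fpkm_input=2.0, fpkm_output=2.0 * fold, fold_change=fold
        )

    def test_region_in_one_replicate_excluded(self):
        shared = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(4)]
        only1 = GenomicInterval("chr1", 90_000, 90_500)
        rep1 = [self._call(r, f) for r, f in zip(shared + [only1], [9, 8, 1, 1, 7])]
        rep2 = [self._call(r, f) for r, f in zip(shared, [9, 8, 1, 1])]
        merged = merge_replicate_calls([rep1, rep2])
        assert only1 not in {a.region for a in merged}

    def test_identical_replicates_idempotent(self):
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(5)]
        rep = [self._call(r, f) for r, f in zip(regions, [9, 8, 7, 1, 0.9])]
        merged = merge_replicate_calls([rep, rep])
        single = _rank_and_threshold(list(rep))
        assert {(a.region, a.active, a.fold_change) for a in merged} == {
            (a.region, a.active, a.fold_change) for a in single
        }

    def test_activity_is_arithmetic_mean(self):
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(3)]
        rep1 = [self._call(r, f) for r, f in zip(regions, [4.0, 1.0, 0.5])]
        rep2 = [self._call(r, f) for r, f in zip(regions, [6.0, 1.0, 0.5])]
        merged = {a.region: a for a in merge_replicate_calls([rep1, rep2])}
        assert merged[regions[0]].fold_change == pytest.approx(5.0)

    def test_empty_intersection_warns_not_raises(self):
        a = [self._call(GenomicInterval("chr1", 0, 500), 2.0)] * 1
        b = [self._call(GenomicInterval("chr2", 0, 500), 2.0)] * 1
        with pytest.warns(UserWarning, match="common"):
            assert merge_replicate_calls([a, b]) == []


class TestAllelicReadCounts:
    def _frame(self, spec):
        # spec: list of (replicate, allele, n_reads)
        rows = []
        for rep, allele, n in spec:
            rows.extend(
                {"chrom": "chr1", "start": 100, "end": 150, "replicate": rep,
                 "allele": allele}
                for _ in range(n)
            )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "replicate", "allele"])

    def test_replicate_mean_and_normalization(self):
        data = {
            "NS": self._frame([(1, "C", 10), (2, "C", 20), (1, "T", 15), (2, "T", 15)]),
            "IFNa": self._frame([(1, "C", 30), (2, "C", 30), (1, "T", 15), (2, "T", 15)]),
        }
        out = allelic_read_counts(data, snp_chrom="chr1", snp_pos=120)
        out = out.set_index(["condition", "allele"])
        assert out.at[("NS", "C"), "mean_count"] == pytest.approx(15.0)
        assert out.at[("NS", "C"), "normalized"] == pytest.approx(1.0)
        assert out.at[("IFNa", "C"), "normalized"] == pytest.approx(2.0)
        assert out.at[("IFNa", "T"), "normalized"] == pytest.approx(1.0)

    def test_zero_baseline_allele_reported_missing(self):
        data = {
            "NS": self._frame([(1, "C", 10), (2, "C", 10)]),
            "IFNa": self._frame([(1, "C", 10), (1, "T", 5)]),
        }
        out = allelic_read_counts(data).set_index(["condition", "allele"])
        assert np.isnan(out.at[("IFNa", "T"), "normalized"])
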