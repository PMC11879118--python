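"""Promoter definition, either-fraction Epromoter calling, merging,
cross-dataset sharing and the distal-enhancer comparison set."""

import pandas as pd
import pytest

from epromoter import (
    GenomicInterval,
    call_epromoters,
    define_distal_enhancers,
    define_promoters,
    merge_epromoters,
    sharing_stats,
)


def _ann(rows):
    return pd.DataFrame(rows, columns=["gene_id", "transcript_id", "chrom", "strand", "tss"])


class TestDefinePromoters:
    def test_plus_strand_upstream_window(self):
        out = define_promoters(_ann([("G1", "T1", "chr1", "+", 10_000)]))
        assert out.iloc[0][["start", "end"]].tolist() == [9_500, 10_000]

    def test_minus_strand_mirrored(self):
        out = define_promoters(_ann([("G1", "T1", "chr1", "-", 10_000)]))
        assert out.iloc[0][["start", "end"]].tolist() == [10_000, 10_500]

    def test_clipped_at_chromosome_start(self):
        out = define_promoters(_ann([("G1", "T1", "chr1", "+", 200)]))
        assert out.iloc[0][["start", "end"]].tolist() == [0, 200]

    def test_missing_strand_is_error(self):
        with pytest.raises(ValueError, match="T1"):
            define_promoters(_ann([("G1", "T1", "chr1", ".", 1_000)]))

    def test_identical_region_and_gene_collapsed(self):
        out = define_promoters(
            _ann([("G1", "T1", "chr1", "+", 10_000), ("G1", "T2", "chr1", "+", 10_000)])
        )
        assert len(out) == 1
        assert out.iloc[0]["promoter_id"] == "T1"


class TestCallEpromoters:
    PROM = define_promoters(_ann([("G1", "T1", "chr1", "+", 10_000)]))

    def _flagged(self, enh):
        return bool(call_epromoters(self.PROM, enh)["is_epromoter"].iloc[0])

    def test_half_of_promoter_covered(self):
        assert self._flagged([GenomicInterval("chr1", 9_750, 10_900)])

    def test_half_of_enhancer_covered(self):
        # 200-bp enhancer, 150-bp overlap: 30% of promoter but 75% of enhancer
        assert self._flagged([GenomicInterval("chr1", 9_850, 10_050)])

    def test_small_mutual_overlap_not_flagged(self):
        # 100-bp overlap of a 500-bp promoter and 300-bp enhancer (20% / 33%)
        assert not self._flagged([GenomicInterval("chr1", 9_900, 10_200)])

    def test_both_fractions_required_without_either(self):
        out = call_epromoters(
            self.PROM, [GenomicInterval("chr1", 9_850, 10_050)], either=False
        )
        assert not out["is_epromoter"].iloc[0]

    def test_monotone_in_enhancer_set(self):
        base = [GenomicInterval("chr1", 9_850, 10_050)]
        more = base + [GenomicInterval("chr1", 9_000, 9_100)]
        assert self._flagged(base) and self._flagged(more)


class TestMergeEpromoters:
    def _prom(self, pid, start, end):
        return {
            "promoter_id": pid, "gene_id": f"g_{pid}", "transcript_id": pid,
            "chrom": "chr1", "start": start, "end": end, "strand": "+",
            "is_epromoter": True,
        }

    def test_overlapping_regions_merge(self):
        df = pd.DataFrame([self._prom("a", 100, 600), self._prom("b", 550, 1050)])
        out = merge_epromoters(df)
        assert out.regions[["start", "end"]].values.tolist() == [[100, 1050]]

    def test_disjoint_regions_unchanged(self):
        df = pd.DataFrame([self._prom("a", 100, 600), self._prom("b", 700, 1200)])
        assert len(merge_epromoters(df).regions) == 2

    def test_abutting_regions_share_zero_nt_and_stay_apart(self):
        df = pd.DataFrame([self._prom("a", 100, 600), self._prom("b", 600, 1100)])
        assert len(merge_epromoters(df).regions) == 2

    def test_transitive_chain_merges(self):
        df = pd.DataFrame(
            [self._prom("a", 0, 500), self._prom("b", 400, 900), self._prom("c", 800, 1300)]
        )
        out = merge_epromoters(df)
        assert out.regions[["start", "end"]].values.tolist() == [[0, 1300]]
        assert set(out.members["promoter_id"]) == {"a", "b", "c"}

    def test_merge_idempotent(self):
        df = pd.DataFrame(
            [self._prom("a", 0, 500), self._prom("b", 400, 900), self._prom("c", 2000, 2500)]
        )
        once = merge_epromoters(df)
        again = merge_epromoters(
            once.regions.assign(
                promoter_id=once.regions["merged_id"],
                gene_id=once.regions["merged_id"],
                is_epromoter=True,
            )
        )
        assert once.regions[["chrom", "start", "end"]].values.tolist() == \
            again.regions[["chrom", "start", "end"]].values.tolist()


class TestSharing:
    def _set(self, spans):
        df = pd.DataFrame(
            [
                {"promoter_id": f"p{i}", "gene_id": f"g{i}", "transcript_id": f"p{i}",
                 "chrom": "chr1", "start": s, "end": e, "strand": "+",
                 "is_epromoter": True}
                for i, (s, e) in enumerate(spans)
            ]
        )
        return merge_epromoters(df)

    def test_private_and_shared_counts(self):
        per = {
            "A": self._set([(0, 500), (5_000, 5_500)]),
            "B": self._set([(0, 500)]),
            "C": self._set([(9_000, 9_500)]),
        }
        table, frac = sharing_stats(per)
        by_start = table.set_index("start")["n_datasets"]
        assert by_start[0] == 2 and by_start[5_000] == 1 and by_start[9_000] == 1
        assert frac[1] == pytest.approx(2 / 3)

    def test_identical_datasets_fully_shared(self):
        per = {"A": self._set([(0, 500)]), "B": self._set([(0, 500)])}
        table, frac = sharing_stats(per)
        assert (table["n_datasets"] == 2).all()
        assert frac[2] == pytest.approx(1.0)


class TestDistalEnhancers:
    def test_epromoter_overlapping_starr_excluded(self):
        out = define_distal_enhancers(
            starr_enhancers=[GenomicInterval("chr1", 0, 1_000)],
            reference_enhancers=[GenomicInterval("chr1", 0, 1_000)],
            epromoters=[GenomicInterval("chr1", 900, 1_400)],
        )
        assert out == []

    def test_center_500_of_retained_reference(self):
        out = define_distal_enhancers(
            starr_enhancers=[GenomicInterval("chr1", 0, 1_000)],
            reference_enhancers=[GenomicInterval("chr1", 0, 1_000)],
            epromoters=[],
        )
        assert out == [GenomicInterval("chr1", 250, 750)]

    def test_short_reference_emitted_whole(self):
        out = define_distal_enhancers(
            starr_enhancers=[GenomicInterval("chr1", 0, 400)],
            reference_enhancers=[GenomicInterval("chr1", 0, 400)],
            epromoters=[],
        )
        assert out == [GenomicInterval("chr1", 0, 400)]

    def test_disjoint_sets_empty(self):
        out = define_distal_enhancers(
            starr_enhancers=[GenomicInterval("chr1", 0, 500)],
            reference_enhancers=[GenomicInterval("chr2", 0, 500)],
            epromoters=[],
        )
        assert out == []


def test_true_active_set_recovers_planted_epromoters_exactly(small_world):
    """Feeding the planted active regions through the caller reproduces the
    planted promoter set exactly (the >=50%-either and merge rules agree)."""
    from epromoter import define_promoters as dp

    promoters = dp(
        small_world.annotation,
        window=small_world.config.promoter_window,
        chrom_sizes=small_world.config.chrom_sizes(),
    )
    flagged = call_epromoters(promoters, small_world.truth.planted_active_regions)
    called = set(flagged.loc[flagged["is_epromoter"], "promoter_id"])
    assert called == set(small_world.truth.true_epromoter_promoter_ids)
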