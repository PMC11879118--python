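"""LD r-squared, GWAS lead expansion, trait counting and enrichment tests."""


import math

import numpy as np
import pandas as pd
import pytest

from epromoter import (
    compute_r2,
    enrichment_tests,
    expand_ld,
    hypergeom_upper,
    overlap_variants,
    pleiotropy_counts,
)


def r2_brute_force(panel, i, j):
    """Haplotype-class counting, independent of the implementation."""
    n = panel.shape[0]
    n_ab = sum(1 for h in range(n) if panel[h, i] == 1 and panel[h, j] == 1)
    p_a = sum(panel[:, i]) / n
    p_b = sum(panel[:, j]) / n
    d = n_ab / n - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


def _panel_from_counts(ab, aB, Ab, ab_):
    """Panel with given counts of haplotype classes (1,1), (0,1), (1,0), (0,0)."""
    rows = (
        [[1, 1]] * ab + [[0, 1]] * aB + [[1, 0]] * Ab + [[0, 0]] * ab_
    )
    return np.array(rows, dtype=np.int8)


class TestR2:
    def test_identical_columns_are_perfect_ld(self):
        panel = _panel_from_counts(3, 0, 0, 5)
        assert compute_r2(panel, 0, 1) == pytest.approx(1.0)

    def test_independent_sites_are_zero(self):
        panel = _panel_from_counts(2, 2, 2, 2)
        assert compute_r2(panel, 0, 1) == pytest.approx(0.0)

    def test_hand_computed_intermediate_case(self):
        # counts AB, Ab, aB, ab = 3, 1, 1, 3 -> r2 = (3/8 - 1/4)^2 / (1/4 * 1/4)
        panel = _panel_from_counts(3, 1, 1, 3)
        assert compute_r2(panel, 0, 1) == pytest.approx(0.25)

    def test_monomorphic_site_rejected(self):
        panel = np.array([[1, 1], [1, 0], [1, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            compute_r2(panel, 0, 1)

    def test_symmetry_and_brute_force_equivalence(self):
        rng = np.random.default_rng(5)
        done = 0
        while done < 100:
            n = int(rng.integers(4, 17))
            panel = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
            if panel[:, 0].min() == panel[:, 0].max() or panel[:, 1].min() == panel[:, 1].max():
                continue
            done += 1
            a = compute_r2(panel, 0, 1)
            assert a == pytest.approx(compute_r2(panel, 1, 0))
            assert a == pytest.approx(r2_brute_force(panel, 0, 1), abs=1e-12)


class TestExpandLd:
    def _inputs(self):
        # three sites on chr1: lead (col 0), perfect proxy (col 1), distant noise
        panel = np.array(
            [[1, 1, 0], [1, 1, 1], [0, 0, 0], [0, 0, 1], [1, 1, 0], [0, 0, 1]],
            dtype=np.int8,
        )
        variants = pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2", "rs3"],
                "chrom": ["chr1"] * 3,
                "pos": [100_000, 150_000, 190_000],
                "col": [0, 1, 2],
                "maf": [0.5, 0.5, 0.5],
            }
        )
        leads = pd.DataFrame(
            [
                {"lead_snp_id": "rs1", "chrom": "chr1", "pos": 100_000,
                 "trait_efo_id": "EFO:1", "trait_label": "t1",
                 "parent_category": "Cancer"},
            ]
        )
        return panel, variants, leads

    def test_proxy_inherits_lead_traits(self):
        panel, variants, leads = self._inputs()
        out = expand_ld(leads, variants, panel).set_index("snp_id")
        assert set(out.index) == {"rs1", "rs2"}
        assert out.at["rs2", "traits"] == frozenset({"EFO:1"})

    def test_boundary_r2_is_strictly_excluded(self):
        panel, variants, leads = self._inputs()
        r2 = compute_r2(panel, 0, 1)  # 1.0 for the perfect proxy
        out = expand_ld(leads, variants, panel, r2_min=r2)
        assert set(out["snp_id"]) == {"rs1"}  # r2 > r2_min is strict

    def test_window_excludes_distal_proxy(self):
        panel, variants, leads = self._inputs()
        out = expand_ld(leads, variants, panel, window_kb=10)
        assert set(out["snp_id"]) == {"rs1"}

    def test_multi_lead_proxy_unions_traits(self):
        panel, variants, leads = self._inputs()
        leads2 = pd.concat(
            [
                leads,
                pd.DataFrame(
                    [{"lead_snp_id": "rs2", "chrom": "chr1", "pos": 150_000,
                      "trait_efo_id": "EFO:2", "trait_label": "t2",
                      "parent_category": "Cancer"}]
                ),
            ]
        )
        out = expand_ld(leads2, variants, panel).set_index("snp_id")
        assert out.at["rs1", "traits"] == frozenset({"EFO:1", "EFO:2"})

    def test_absent_lead_skipped(self, caplog):
        panel, variants, leads = self._inputs()
        leads = leads.assign(lead_snp_id="rs_missing")
        out = expand_ld(leads, variants, panel)
        assert out.empty


class TestOverlapAndCounts:
    REGIONS = pd.DataFrame(
        [
            {"region_id": "R1", "chrom": "chr1", "start": 1_000, "end": 1_500},
            {"region_id": "R2", "chrom": "chr1", "start": 9_000, "end": 9_500},
        ]
    )

    def _variants(self, positions):
        return pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(len(positions))],
                "chrom": "chr1",
                "pos": positions,  # 1-based
                "traits": [frozenset({"T1"})] * len(positions),
                "categories": [frozenset({"C1"})] * len(positions),
            }
        )

    def test_half_open_membership(self):
        # 1-based pos 1001 is 0-based 1000 = region start -> member;
        # pos 1501 is 0-based 1500 = region end -> not a member
        hits = overlap_variants(self._variants([1_001, 1_501]), self.REGIONS)
        assert hits["R1"] == ["rs0"] and hits["R2"] == []

    def test_counts_per_region(self):
        hits = overlap_variants(self._variants([1_100, 1_200, 5_000]), self.REGIONS)
        assert len(hits["R1"]) == 2 and len(hits["R2"]) == 0

    def test_trait_counts_are_set_semantics(self):
        ann = pd.DataFrame(
            {
                "snp_id": ["a", "b"],
                "traits": [frozenset({"T1", "T2"}), frozenset({"T2", "T3"})],
                "categories": [frozenset({"C1"}), frozenset({"C1"})],
            }
        )
        snps, regions = pleiotropy_counts({"R1": ["a", "b"], "R2": []}, ann)
        assert snps.set_index("snp_id").at["a", "n_traits"] == 2
        r = regions.set_index("region_id")
        assert r.at["R1", "n_traits"] == 3  # non-redundant union
        assert bool(r.at["R1", "pleiotropic"]) and not bool(r.at["R2", "pleiotropic"])

    def test_region_count_bounded_by_member_counts(self):
        rng = np.random.default_rng(7)
        traits = [frozenset(rng.choice(10, size=rng.integers(1, 5), replace=False))
                  for _ in range(6)]
        ann = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(6)], "traits": traits,
             "categories": [frozenset({"C"})] * 6}
        )
        snps, regions = pleiotropy_counts({"R": [f"s{i}" for i in range(6)]}, ann)
        total = regions.set_index("region_id").at["R", "n_traits"]
        assert snps["n_traits"].max() <= total <= snps["n_traits"].sum()


def hypergeom_enumeration(population, successes, draws, observed):
    """P(X >= observed) by exhaustive combinatorics (small populations)."""
    total = math.comb(population, draws)
    acc = 0
    for k in range(observed, min(successes, draws) + 1):
        acc += math.comb(successes, k) * math.comb(population - successes, draws - k)
    return acc / total


class TestEnrichment:
    def test_hypergeometric_against_enumeration(self):
        assert hypergeom_upper(10, 5, 4, 4) == pytest.approx(5 / 210)
        rng = np.random.default_rng(9)
        for _ in range(200):
            pop = int(rng.integers(2, 21))
            succ = int(rng.integers(0, pop + 1))
            draws = int(rng.integers(1, pop + 1))
            obs = int(rng.integers(0, min(succ, draws) + 1))
            assert hypergeom_upper(pop, succ, draws, obs) == pytest.approx(
                hypergeom_enumeration(pop, succ, draws, obs), abs=1e-12
            )

    def test_zero_observed_is_certain(self):
        assert hypergeom_upper(10, 5, 4, 0) == pytest.approx(1.0)

    def _background(self):
        rows = []
        for i in range(12):
            traits = {"T1"} if i < 6 else {"T2"}
            rows.append(
                {"snp_id": f"rs{i}", "traits": frozenset(traits),
                 "categories": frozenset({"C1"})}
            )
        return pd.DataFrame(rows)

    def test_identical_sets_give_null_chi_squared(self):
        bg = self._background()
        sel = [f"rs{i}" for i in range(0, 8)]
        out = enrichment_tests(sel, sel, bg).set_index("trait")
        assert out.at["T1", "chi2"] == pytest.approx(0.0)
        assert out.at["T1", "p_chi2"] == pytest.approx(1.0)

    def test_enriched_set_has_small_hypergeometric_p(self):
        bg = self._background()
        out = enrichment_tests(
            [f"rs{i}" for i in range(5)], [f"rs{i}" for i in range(6, 11)], bg
        ).set_index("trait")
        assert out.at["T1", "k_a"] == 5
        assert out.at["T1", "p_hyper_a"] == pytest.approx(
            hypergeom_enumeration(12, 6, 5, 5), abs=1e-12
        )
        assert set(out.columns) >= {"fdr_hyper_a", "fdr_chi2"}
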