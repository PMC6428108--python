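"""eUTR and RUD estimators, delta classification, the Welch comparison and
set overlaps; includes the independent weighted-mean oracle and the
estimator-monotonicity properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apakit import (CoverageTrack, GeneAPAProfile, GeneModel,
                    build_gene_profiles, compute_eutr, compute_rud,
                    delta_eutr, delta_rud, overlap_sets, two_sample_test)
from apakit.metrics import shortened_genes


def profile(sites, gene_id="g", condition="ctrl"):
    return GeneAPAProfile(gene_id=gene_id, condition=condition, sites=sites)


def eutr_oracle(sites):
    """Independent weighted mean using exact summation."""
    total = sum(c for _, c in sites)
    return math.fsum(d * (c / total) for d, c in sites)


class TestComputeEutr:
    def test_single_site_returns_its_distance(self):
        assert compute_eutr(profile([(500, 7)])) == 500

    def test_hand_arithmetic(self):
        assert compute_eutr(profile([(200, 30), (800, 10)])) == pytest.approx(350)

    def test_symmetric_mean(self):
        assert compute_eutr(profile([(100, 5), (300, 5)])) == pytest.approx(200)

    def test_zero_tags_undefined(self):
        with pytest.raises(ValueError, match="zero tags"):
            compute_eutr(profile([(100, 0), (300, 0)]))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 5000), st.integers(0, 1000)),
                    min_size=1, max_size=6, unique_by=lambda t: t[0]))
    def test_matches_oracle_and_bounds(self, raw):
        sites = sorted((d, c) for d, c in raw)
        if sum(c for _, c in sites) == 0:
            sites[0] = (sites[0][0], 1)
        e = compute_eutr(profile(sites))
        assert e == pytest.approx(eutr_oracle(sites), rel=1e-9)
        dists = [d for d, c in sites if c > 0]
        assert min(dists) <= e <= max(dists)

    def test_invariant_to_uniform_count_scaling(self):
        sites = [(150, 3), (600, 9), (900, 2)]
        scaled = [(d, 10 * c) for d, c in sites]
        assert compute_eutr(profile(sites)) == pytest.approx(
            compute_eutr(profile(scaled)), rel=1e-12)

    def test_moving_mass_proximal_strictly_decreases_eutr(self):
        before = compute_eutr(profile([(200, 10), (800, 10)]))
        after = compute_eutr(profile([(200, 15), (800, 5)]))
        assert after < before


class TestDeltaEutr:
    def test_shortening_classes_across_cutoffs(self):
        rec = delta_eutr(profile([(300, 1), (500, 1)]),          # eutr 400
                         profile([(300, 2), (600, 1)], condition="kd"))  # eutr 400 -> 400
        assert rec.delta_eutr == pytest.approx(0.0)
        rec = delta_eutr(profile([(400, 1)]), profile([(300, 1)], condition="kd"))
        assert rec.delta_eutr == -100
        assert rec.classes[50.0] == "shortened"
        assert rec.classes[100.0] == "shortened"   # boundary inclusive
        assert rec.classes[200.0] == "unchanged"

    def test_identical_profiles_unchanged_everywhere(self):
        p = profile([(200, 30), (800, 10)])
        rec = delta_eutr(p, profile(p.sites, condition="kd"))
        assert rec.delta_eutr == 0
        assert set(rec.classes.values()) == {"unchanged"}

    def test_lengthening_at_all_cutoffs(self):
        rec = delta_eutr(profile([(300, 1)]), profile([(800, 1)], condition="kd"))
        assert rec.delta_eutr == 500
        assert set(rec.classes.values()) == {"lengthened"}

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            delta_eutr(profile([(100, 1)], gene_id="a"),
                       profile([(100, 1)], gene_id="b"))


def plus_gene(stop=1000, utr_len=1000, gene_id="g"):
    return GeneModel(gene_id=gene_id, chrom="c1", strand="+", stop_pos=stop,
                     utr_len=utr_len, exons=((0, stop + utr_len),),
                     tx_start=0, tx_end=stop + utr_len)


class TestComputeRud:
    def track(self, total_len=3000):
        return CoverageTrack({"c1": total_len})

    def test_density_ratio_arithmetic(self):
        g = plus_gene()
        t = self.track()
        t.add("c1", 1000, np.full(400, 50.0))   # cUTR: 400 nt, summed 20000
        t.add("c1", 1400, np.full(600, 15.0))   # aUTR: 600 nt, summed 9000
        res = compute_rud(g, g.pos_at(400), g.pos_at(1000), t)
        assert res.density_c == pytest.approx(50.0)
        assert res.density_a == pytest.approx(15.0)
        assert res.rud == pytest.approx(0.3)

    def test_zero_autr_coverage_gives_zero(self):
        g = plus_gene()
        t = self.track()
        t.add("c1", 1000, np.full(400, 10.0))
        res = compute_rud(g, g.pos_at(400), g.pos_at(1000), t)
        assert res.rud == 0.0

    def test_equal_densities_give_one(self):
        g = plus_gene()
        t = self.track()
        t.add("c1", 1000, np.full(1000, 20.0))
        res = compute_rud(g, g.pos_at(400), g.pos_at(1000), t)
        assert res.rud == pytest.approx(1.0)

    def test_minus_strand_equivalent(self):
        g = GeneModel(gene_id="m", chrom="c1", strand="-", stop_pos=1999,
                      utr_len=1000, exons=((0, 3000),), tx_start=0, tx_end=3000)
        t = self.track()
        # cUTR genomic [1600, 2000), aUTR [1000, 1600)
        t.add("c1", 1600, np.full(400, 50.0))
        t.add("c1", 1000, np.full(600, 15.0))
        res = compute_rud(g, g.pos_at(400), g.pos_at(1000), t)
        assert res.rud == pytest.approx(0.3)

    def test_short_cutr_excluded_with_reason(self):
        g = plus_gene()
        res = compute_rud(g, g.pos_at(50), g.pos_at(1000), self.track())
        assert res.exclude_reason == "cutr_too_short"

    def test_low_cutr_coverage_excluded(self):
        g = plus_gene()
        res = compute_rud(g, g.pos_at(400), g.pos_at(1000), self.track())
        assert res.exclude_reason == "cutr_low_coverage"

    def test_bad_site_order_rejected(self):
        g = plus_gene()
        with pytest.raises(ValueError, match="proximal"):
            compute_rud(g, g.pos_at(800), g.pos_at(400), self.track())


class TestDeltaRud:
    def test_classes_across_cutoffs(self):
        rec = delta_rud(0.62, 0.50, gene_id="g")
        assert rec.delta_rud == pytest.approx(-0.12)
        assert rec.classes[0.05] == "shortened"
        assert rec.classes[0.1] == "shortened"
        assert rec.classes[0.2] == "unchanged"

    def test_zero_delta_unchanged(self):
        rec = delta_rud(0.5, 0.5)
        assert set(rec.classes.values()) == {"unchanged"}

    def test_boundary_is_inclusive(self):
        rec = delta_rud(0.50, 0.45)
        assert rec.classes[0.05] == "shortened"

    def test_undefined_value_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            delta_rud(np.nan, 0.5, gene_id="g")


class TestTwoSampleTest:
    def test_identical_samples(self):
        t, p = two_sample_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == pytest.approx(1.0)

    def test_welch_reference_values(self):
        t, p = two_sample_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224744871, rel=1e-6)
        assert p == pytest.approx(0.2878641, rel=1e-4)

    def test_separated_samples_give_tiny_p(self):
        a = [1.0, 1.01, 0.99, 1.0]
        _, p = two_sample_test(a, [x + 100 for x in a])
        assert p < 1e-10

    def test_log2_requires_positive(self):
        with pytest.raises(ValueError, match="positive"):
            two_sample_test([1, 2], [0, 3], log2_transform=True)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="2 values"):
            two_sample_test([1], [1, 2])


class TestOverlapSets:
    def test_pairwise(self):
        df = overlap_sets({"a": {"g1", "g2", "g3"}, "b": {"g2", "g3", "g4"}})
        both = df[(df["region"] == "a&b") & (df["kind"] == "exclusive")]
        assert both["count"].iloc[0] == 2
        totals = df[df["kind"] == "total"].set_index("region")["count"]
        assert totals["a"] == 3 and totals["b"] == 3

    def test_identical_sets(self):
        df = overlap_sets({"a": {"x", "y"}, "b": {"x", "y"}})
        assert df[(df["region"] == "a&b")]["count"].iloc[0] == 2

    def test_triple_intersection(self):
        df = overlap_sets({"a": {"g1", "g2"}, "b": {"g1", "g3"}, "c": {"g1", "g4"}})
        assert df[df["region"] == "a&b&c"]["count"].iloc[0] == 1

    def test_requires_two_sets(self):
        with pytest.raises(ValueError, match="2 sets"):
            overlap_sets({"a": {"x"}})


class TestBuildProfiles:
    def clusters(self, rows):
        df = pd.DataFrame(rows)
        df["internal_priming"] = df.get("internal_priming", False)
        df["category"] = df.get("category", "UTR3")
        return df

    def crow(self, mode_pos, n, strand="+", chrom="c1"):
        return {"chrom": chrom, "strand": strand, "start": mode_pos - 1,
                "end": mode_pos + 1, "mode_pos": mode_pos, "n_ctrl": n,
                "total": n}

    def test_direct_assembly(self):
        g = plus_gene()
        cl = self.clusters([self.crow(g.pos_at(200), 30), self.crow(g.pos_at(800), 10)])
        profs = build_gene_profiles(cl, [g], "ctrl", min_gene_tags=20)
        assert profs["g"].sites == [(200, 30), (800, 10)]
        assert profs["g"].total_tags == 40

    def test_single_site_gene_excluded(self):
        g = plus_gene()
        cl = self.clusters([self.crow(g.pos_at(200), 30)])
        assert build_gene_profiles(cl, [g], "ctrl") == {}

    def test_low_tag_gene_excluded(self):
        g = plus_gene()
        cl = self.clusters([self.crow(g.pos_at(200), 3), self.crow(g.pos_at(800), 4)])
        assert build_gene_profiles(cl, [g], "ctrl", min_gene_tags=20) == {}

    def test_minus_strand_distance_convention(self):
        g = GeneModel(gene_id="m", chrom="c1", strand="-", stop_pos=5000,
                      utr_len=1000, exons=((3000, 6000),), tx_start=3000, tx_end=6000)
        cl = self.clusters([self.crow(4801, 15, strand="-"),   # 200 nt upstream in genome
                            self.crow(4001, 15, strand="-")])
        profs = build_gene_profiles(cl, [g], "ctrl", min_gene_tags=20)
        assert profs["m"].sites == [(200, 15), (1000, 15)]

    def test_internal_priming_clusters_skipped(self):
        g = plus_gene()
        rows = [self.crow(g.pos_at(200), 30), self.crow(g.pos_at(800), 10)]
        cl = self.clusters(rows)
        cl.loc[1, "internal_priming"] = True
        assert build_gene_profiles(cl, [g], "ctrl") == {}  # one site left

    def test_ambiguous_gene_assignment_rejected(self):
        g1 = plus_gene(gene_id="a")
        g2 = plus_gene(gene_id="b")      # identical locus: overlapping UTRs
        cl = self.clusters([self.crow(g1.pos_at(200), 30)])
        with pytest.raises(ValueError, match="multiple genes"):
            build_gene_profiles(cl, [g1, g2], "ctrl")


def test_shortened_gene_set_extraction():
    recs = [delta_rud(0.7, 0.4, gene_id="a"), delta_rud(0.7, 0.69, gene_id="b")]
    assert shortened_genes(recs, 0.05) == {"a"}
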