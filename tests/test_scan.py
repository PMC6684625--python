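"""Genome-scan filtering, FDR, centromere flags, intersections and hotspots."""

import numpy as np
import pandas as pd
import pytest

import lrldscan as L


def _tiny_panels(positions, seed=0, n=100, pops=("AFR", "EUR")):
    """Independent uniform-frequency panels over explicit positions."""
    rng = np.random.default_rng(seed)
    m = len(positions)
    variants = pd.DataFrame(
        {"chrom": "1", "pos": list(positions), "id": [f"v{i}" for i in range(m)],
         "ref": "A", "alt": "C"}
    )
    out = {}
    for pop in pops:
        hap = (rng.random((2 * n, m)) < 0.4).astype(np.uint8)
        out[pop] = L.HaplotypePanel(pop, [f"{pop}{i}" for i in range(n)], variants, hap)
    return out


def _records(rows):
    df = pd.DataFrame(
        rows, columns=["population", "chromosome", "pos_a", "pos_b"]
    )
    df["centromeric_flag"] = False
    return df


class TestPairEnumeration:
    def test_distance_threshold_inclusive(self):
        panels = _tiny_panels([1_000_000, 5_999_999, 6_000_000])
        res = L.scan_pairs(panels, L.ScanConfig(), keep_all=True)
        tested = set(zip(res.all_tests["pos_a"], res.all_tests["pos_b"]))
        assert (1_000_000, 5_999_999) not in tested  # distance 4,999,999
        assert (1_000_000, 6_000_000) in tested      # distance exactly 5 Mb
        assert res.tested_pairs["1"] == 1

    def test_maf_filter_is_per_population(self):
        panels = _tiny_panels([1, 6_000_001, 12_000_001], n=50)
        # make one variant rare in one population only -> drops from the universe
        panels["EUR"].haplotypes[:, 1] = 0
        panels["EUR"].haplotypes[:3, 1] = 1
        res = L.scan_pairs(panels, L.ScanConfig(), keep_all=True)
        assert 6_000_001 not in set(res.all_tests["pos_a"]) | set(res.all_tests["pos_b"])

    def test_empty_universe_raises(self):
        panels = _tiny_panels([1, 6_000_001])
        for pop in panels:
            panels[pop].haplotypes[:] = 0
            panels[pop].haplotypes[0, :] = 1  # frequency 1/200 < maf_min
        with pytest.raises(ValueError, match="frequency filter"):
            L.scan_pairs(panels, L.ScanConfig())

    def test_worker_count_invariance(self, planted_panels):
        one = L.scan_pairs(planted_panels, L.ScanConfig(workers=1))
        four = L.scan_pairs(planted_panels, L.ScanConfig(workers=4))
        pd.testing.assert_frame_equal(one.records, four.records)


class TestPlantedRecovery:
    def test_planted_pair_has_smallest_p_on_chromosome(self, planted_scan, planted_pairs):
        planted_keys = {(p.pos_a, p.pos_b) for p in planted_pairs}
        tests = planted_scan.all_tests
        for pop in ("AFR", "EUR", "EAS"):
            sub = tests[tests["population"] == pop]
            best = sub.loc[sub["p_raw"].idxmin()]
            assert (best["pos_a"], best["pos_b"]) in planted_keys

    def test_sensitivity_at_fdr(self, planted_scan, planted_pairs):
        """Planted D'=1 pairs (MAF 0.3, n=500) are recovered at FDR < 0.05."""
        sig = set(
            zip(planted_scan.records["population"],
                planted_scan.records["pos_a"], planted_scan.records["pos_b"])
        )
        expected = [
            (pop, p.pos_a, p.pos_b)
            for p in planted_pairs for pop in ("AFR", "EUR", "EAS")
        ]
        sensitivity = np.mean([k in sig for k in expected])
        assert sensitivity >= 0.9

    def test_population_specific_plant_stays_specific(self, base_panels):
        first = next(iter(base_panels.values()))
        pos = first.variants["pos"].to_numpy()
        plant = L.PlantedLRLD(int(pos[5]), int(pos[200]), 1.0, ("EAS",), (0.3, 0.3))
        panels = L.plant_lrld(base_panels, [plant], seed=99)
        res = L.scan_pairs(panels, L.ScanConfig())
        rec = res.records
        hits = rec[(rec["pos_a"] == plant.pos_a) & (rec["pos_b"] == plant.pos_b)]
        assert set(hits["population"]) == {"EAS"}


class TestBHAdjust:
    def test_worked_example(self):
        q = L.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert L.bh_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(L.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=200))
        q = L.bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all(q >= p - 1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            L.bh_adjust([0.5, 1.5])


class TestCentromereFilter:
    CEN = {"1": (98_000_000, 102_000_000)}

    def test_boundary_is_closed(self):
        pad = 5_000_000
        recs = _records([
            ("AFR", "1", 98_000_000 - pad, 150_000_000),   # exactly at the pad edge
            ("AFR", "1", 50_000_000, 102_000_000 + pad),   # other side edge
            ("AFR", "1", 92_999_999, 150_000_000),         # 1 bp outside
        ])
        out = L.apply_centromere_filter(recs, self.CEN, pad)
        assert out["centromeric_flag"].tolist() == [True, True, False]

    def test_missing_chromosome_raises(self):
        recs = _records([("AFR", "2", 1, 6_000_001)])
        with pytest.raises(KeyError, match="chromosome 2"):
            L.apply_centromere_filter(recs, self.CEN)

    def test_plants_far_from_centromere_not_flagged(self, planted_scan, planted_pairs):
        cen = {"1": (98_500_000, 101_500_000)}
        out = L.apply_centromere_filter(planted_scan.records, cen)
        keys = {(p.pos_a, p.pos_b) for p in planted_pairs}
        planted_far = out[
            out.apply(lambda r: (r.pos_a, r.pos_b) in keys, axis=1)
            & (abs(out.pos_a - 100_000_000) > 8_500_000)
            & (abs(out.pos_b - 100_000_000) > 8_500_000)
        ]
        assert not planted_far["centromeric_flag"].any()


class TestIntersections:
    def test_counting_rules(self):
        recs = _records([
            ("EAS", "1", 1, 6_000_001),                    # EAS only
            ("AFR", "1", 2, 7_000_001), ("EUR", "1", 2, 7_000_001),
            ("EAS", "1", 2, 7_000_001),                    # shared by all three
        ])
        s = L.population_intersections(recs, populations=["AFR", "EUR", "EAS"])
        row = s.counts["total"].loc["1"]
        assert row["EAS"] == 2 and row["AFR"] == 1
        assert row["AFR&EUR"] == row["AFR&EAS"] == row["EUR&EAS"] == 1
        assert row["ALL"] == 1

    def test_symmetric_in_population_order(self):
        recs = _records([
            ("AFR", "1", 2, 7_000_001), ("EUR", "1", 2, 7_000_001),
            ("EAS", "1", 9, 9_000_001),
        ])
        a = L.population_intersections(recs, populations=["AFR", "EUR", "EAS"])
        b = L.population_intersections(recs, populations=["EAS", "EUR", "AFR"])
        assert (
            a.counts["total"].loc["1", "AFR&EUR"]
            == b.counts["total"].loc["1", "EUR&AFR"]
        )
        assert a.counts["total"].loc["1", "ALL"] == b.counts["total"].loc["1", "ALL"]

    def test_shared_plants_do_not_cross_populations(self, base_panels):
        first = next(iter(base_panels.values()))
        pos = first.variants["pos"].to_numpy()
        plants = [
            L.PlantedLRLD(int(pos[k]), int(pos[220 + k]), 1.0, ("EUR", "EAS"), (0.3, 0.3))
            for k in range(3)
        ]
        panels = L.plant_lrld(base_panels, plants, seed=8)
        res = L.scan_pairs(panels, L.ScanConfig())
        s = L.population_intersections(res.records, populations=["AFR", "EUR", "EAS"])
        keys = {(p.pos_a, p.pos_b) for p in plants}
        rec = res.records
        afr_eur = set(
            zip(rec.loc[rec.population == "AFR", "pos_a"],
                rec.loc[rec.population == "AFR", "pos_b"])
        ) & keys
        assert not afr_eur  # plants absent from AFR
        assert s.counts["total"].loc["1", "EUR&EAS"] >= 2

    def test_expected_counts(self):
        counts = pd.DataFrame({"AFR": [10], "EUR": [20], "EAS": [0]}, index=["1"])
        tested = pd.Series({"1": 1000})
        exp = L.expected_intersections(counts, tested)
        assert exp.loc["1", "AFR&EUR"] == pytest.approx(0.2)
        assert exp.loc["1", "AFR&EAS"] == 0.0
        assert exp.loc["1", "ALL"] == 0.0

    def test_expected_triple_below_pairwise(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(1, 500, size=3)
            N = int(rng.integers(500, 5000))
            counts = pd.DataFrame(
                {"A": [n[0]], "B": [n[1]], "C": [n[2]]}, index=["1"]
            )
            exp = L.expected_intersections(counts, pd.Series({"1": N}))
            pairwise = [exp.loc["1", c] for c in ("A&B", "A&C", "B&C")]
            assert exp.loc["1", "ALL"] <= min(pairwise) + 1e-12

    def test_zero_tested_pairs_raises(self):
        counts = pd.DataFrame({"AFR": [1], "EUR": [1]}, index=["1"])
        with pytest.raises(ValueError, match="zero tested"):
            L.expected_intersections(counts, pd.Series({"1": 0}))


class TestHotspots:
    def test_counting_and_threshold(self):
        recs = _records([
            ("AFR", "1", 100, 6_000_100),
            ("AFR", "1", 100, 7_000_100),
            ("AFR", "1", 100, 8_000_100),
            ("AFR", "1", 200, 9_000_100),
        ])
        hot = L.find_hotspots(recs, min_pairs=2)
        assert len(hot) == 1
        assert hot.iloc[0]["pos"] == 100 and hot.iloc[0]["n_pairs"] == 3

    def test_planted_hotspot_variant(self, base_panels):
        first = next(iter(base_panels.values()))
        pos = first.variants["pos"].to_numpy()
        anchor = int(pos[0])
        partners = [int(pos[150 + k]) for k in range(5)]
        plants = [
            L.PlantedLRLD(anchor, pb, 1.0, ("AFR",), (0.3, 0.3)) for pb in partners
        ]
        panels = L.plant_lrld(base_panels, plants, seed=21)
        res = L.scan_pairs(panels, L.ScanConfig())
        hot = L.find_hotspots(res.records, min_pairs=3)
        afr = hot[hot["population"] == "AFR"]
        assert anchor in set(afr["pos"])
        assert int(afr.loc[afr["pos"] == anchor, "n_pairs"].iloc[0]) >= 5

    def test_min_pairs_validation(self):
        with pytest.raises(ValueError):
            L.find_hotspots(_records([]), min_pairs=1)
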