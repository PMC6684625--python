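"""Synthetic panel generation, LD planting, admixture, and annotation tracks."""

import numpy as np
import pytest

import lrldscan as L


class TestGeneratePanel:
    def test_deterministic_given_seed(self):
        spec = L.PanelSpec(n_individuals=30, n_variants=40, seed=7)
        a = L.generate_panel(spec)
        b = L.generate_panel(spec)
        for pop in spec.populations:
            assert np.array_equal(a[pop].haplotypes, b[pop].haplotypes)
            assert a[pop].variants.equals(b[pop].variants)

    def test_realized_frequencies_stay_in_band(self, base_panels):
        for panel in base_panels.values():
            f = panel.allele_frequencies()
            assert f.min() >= 0.05 and f.max() <= 0.95

    def test_positions_strictly_increasing_unique(self, base_panels):
        pos = next(iter(base_panels.values())).variants["pos"].to_numpy()
        assert np.all(np.diff(pos) > 0)

    def test_zero_block_dprime_gives_independence(self):
        """With no founder copying, block-mates are uncorrelated (|D'| small)."""
        spec = L.PanelSpec(
            n_individuals=500, n_variants=150, chromosome_length=20_000_000,
            block_length=5_000_000, within_block_dprime=0.0,
            populations=("AFR",), seed=3,
        )
        panel = L.generate_panel(spec)["AFR"]
        block = panel.variants["pos"].to_numpy() // spec.block_length
        dprimes = []
        for b in np.unique(block):
            idx = np.flatnonzero(block == b)
            for i in range(len(idx)):
                for j in range(i + 1, min(i + 6, len(idx))):
                    t = L.build_two_locus_table(panel, idx[i], idx[j])
                    dprimes.append(abs(L.estimate_ld(t).dprime))
        assert np.mean(dprimes) < 0.15

    def test_high_block_dprime_creates_local_ld(self):
        spec_hi = L.PanelSpec(
            n_individuals=500, n_variants=150, chromosome_length=20_000_000,
            block_length=5_000_000, within_block_dprime=1.0,
            populations=("AFR",), seed=3,
        )
        panel = L.generate_panel(spec_hi)["AFR"]
        block = panel.variants["pos"].to_numpy() // spec_hi.block_length
        dprimes = []
        for b in np.unique(block)[:2]:
            idx = np.flatnonzero(block == b)
            for i, j in zip(idx[:-1], idx[1:]):
                t = L.build_two_locus_table(panel, i, j)
                dprimes.append(abs(L.estimate_ld(t).dprime))
        assert np.mean(dprimes) > 0.3

    def test_incompatible_spec_rejected(self):
        with pytest.raises(ValueError):
            L.PanelSpec(n_variants=100, chromosome_length=50)
        with pytest.raises(ValueError):
            L.PanelSpec(n_individuals=1)
        with pytest.raises(ValueError):
            L.PanelSpec(maf_range=(0.9, 0.1))


class TestPlantLRLD:
    def test_target_dprime_realized(self, planted_panels, planted_pairs):
        plant = planted_pairs[0]
        for pop in ("AFR", "EUR", "EAS"):
            panel = planted_panels[pop]
            i = panel.variant_index("1", plant.pos_a)
            j = panel.variant_index("1", plant.pos_b)
            est = L.estimate_ld(L.build_two_locus_table(panel, i, j))
            assert abs(est.dprime) >= 0.9

    def test_zero_target_blends_into_background(self, base_panels):
        first = next(iter(base_panels.values()))
        pos = first.variants["pos"].to_numpy()
        plant = L.PlantedLRLD(int(pos[10]), int(pos[210]), 0.0, ("AFR",), (0.3, 0.3))
        panels = L.plant_lrld(base_panels, [plant], seed=4)
        panel = panels["AFR"]
        i = panel.variant_index("1", plant.pos_a)
        j = panel.variant_index("1", plant.pos_b)
        est = L.estimate_ld(L.build_two_locus_table(panel, i, j))
        assert est.p_chi2 > 0.01  # indistinguishable from an independent pair

    def test_other_columns_untouched(self, base_panels, planted_pairs, planted_panels):
        touched = set()
        for p in planted_pairs:
            first = next(iter(base_panels.values()))
            touched.add(first.variant_index("1", p.pos_a))
            touched.add(first.variant_index("1", p.pos_b))
        keep = [k for k in range(next(iter(base_panels.values())).n_variants)
                if k not in touched]
        for pop in base_panels:
            assert np.array_equal(
                base_panels[pop].haplotypes[:, keep],
                planted_panels[pop].haplotypes[:, keep],
            )

    def test_unnamed_population_keeps_independence(self):
        """A pair planted only in EAS stays null in AFR/EUR across seeds."""
        spec = L.PanelSpec(
            n_individuals=200, n_variants=10, chromosome_length=100_000_000,
            populations=("AFR", "EUR", "EAS"),
        )
        n_null = {"AFR": 0, "EUR": 0}
        n_seeds = 100
        for s in range(n_seeds):
            panels = L.generate_panel(L.PanelSpec(**{**spec.__dict__, "seed": 1000 + s}))
            pos = panels["AFR"].variants["pos"].to_numpy()
            lo, hi = int(pos[0]), int(pos[-1])
            if hi - lo < L.MIN_LRLD_DISTANCE_BP:
                n_seeds -= 1
                continue
            plant = L.PlantedLRLD(lo, hi, 1.0, ("EAS",), (0.3, 0.3))
            planted = L.plant_lrld(panels, [plant], seed=s)
            for pop in ("AFR", "EUR"):
                panel = planted[pop]
                t = L.build_two_locus_table(
                    panel, panel.variant_index("1", lo), panel.variant_index("1", hi)
                )
                n_null[pop] += L.estimate_ld(t).p_chi2 > 0.05
        for pop in ("AFR", "EUR"):
            assert n_null[pop] >= 0.9 * n_seeds

    def test_unachievable_target_names_bound(self, base_panels):
        first = next(iter(base_panels.values()))
        pos = first.variants["pos"].to_numpy()
        with pytest.raises(ValueError, match="strictly inside"):
            plant = L.PlantedLRLD(int(pos[0]), int(pos[-1]), 1.0, ("AFR",), (1.0, 0.3))
            L.plant_lrld(base_panels, [plant], seed=0)

    def test_short_distance_rejected(self):
        with pytest.raises(ValueError, match="long-range threshold"):
            L.PlantedLRLD(1_000_000, 2_000_000, 1.0, ("AFR",))


class TestAdmixture:
    def test_identical_subpopulations_no_spurious_ld(self):
        spec = L.AdmixtureSpec(0.5, ((0.3, 0.3), (0.3, 0.3)))
        ds = []
        for s in range(50):
            panel = L.generate_admixed_panel(spec, 500, seed=s)
            ds.append(L.estimate_ld(L.build_two_locus_table(panel, 0, 1)).d_hat)
        mc_se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds)) < 3 * mc_se + 1e-4

    def test_worked_mixture_mean_d(self):
        """Pooling 0.1 vs 0.5 at both loci (w=0.5) gives D close to 0.04."""
        spec = L.AdmixtureSpec(0.5, ((0.1, 0.1), (0.5, 0.5)))
        ds = []
        for s in range(400):
            panel = L.generate_admixed_panel(spec, 500, seed=s)
            ds.append(L.estimate_ld(L.build_two_locus_table(panel, 0, 1)).d_hat)
        assert np.mean(ds) == pytest.approx(0.04, abs=0.005)

    def test_thin_mixture_approaches_single_population(self):
        diverged = ((0.1, 0.1), (0.9, 0.9))
        d_thin, d_half = [], []
        for s in range(30):
            thin = L.generate_admixed_panel(L.AdmixtureSpec(0.002, diverged), 500, seed=s)
            half = L.generate_admixed_panel(L.AdmixtureSpec(0.5, diverged), 500, seed=s)
            d_thin.append(abs(L.estimate_ld(L.build_two_locus_table(thin, 0, 1)).d_hat))
            d_half.append(abs(L.estimate_ld(L.build_two_locus_table(half, 0, 1)).d_hat))
        assert np.mean(d_thin) < np.mean(d_half) / 3

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            L.AdmixtureSpec(1.5, ((0.1,), (0.5,)))
        with pytest.raises(ValueError):
            L.AdmixtureSpec(0.5, ((0.1,), (1.5,)))
        with pytest.raises(ValueError, match="equilibrium"):
            L.AdmixtureSpec(0.5, ((0.1,), (0.5,)), within_subpop_equilibrium=False)


class TestAnnotationTracks:
    def test_zero_gene_density_all_nongenic(self, base_spec, base_panels):
        tracks = L.generate_annotation_tracks(base_spec, gene_density=0.0, seed=1)
        pos = next(iter(base_panels.values())).variants["pos"].to_numpy()
        codes = {tracks.annotation.classify("1", int(p)) for p in pos[:50]}
        assert codes == {10}

    def test_single_centromere_per_chromosome(self, base_spec):
        tracks = L.generate_annotation_tracks(base_spec, seed=1)
        assert list(tracks.centromeres) == [base_spec.chromosome]

    def test_sv_track_deterministic_and_length_bounded(self, base_spec):
        a = L.generate_annotation_tracks(base_spec, seed=5)
        b = L.generate_annotation_tracks(base_spec, seed=5)
        assert a.sv_intervals == b.sv_intervals
        for sv in a.sv_intervals:
            if sv.sv_type != "insertion":
                assert 310 <= sv.length <= 60_000

    def test_genes_do_not_overlap(self, base_spec):
        tracks = L.generate_annotation_tracks(base_spec, seed=5)
        genes = sorted(tracks.genes, key=lambda g: g.start)
        for g1, g2 in zip(genes[:-1], genes[1:]):
            assert g1.end < g2.start
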