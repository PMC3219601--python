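"""Generator determinism and planted ground truth."""

import numpy as np
import pytest

from pioneerscan import expression as ex
from pioneerscan.intervals import IntervalSet
from pioneerscan.motif import screen_cistrome, threshold_for_pvalue
from pioneerscan.synthetic import (
    SyntheticDesign,
    default_pwm,
    gen_cistromes,
    gen_cohort,
    gen_expression,
    gen_genes,
    gen_genome,
    gen_track,
    genome_as_strings,
    plant_motifs,
)

SMALL = dict(chrom_lengths={"chr1": 3_000_000},
             venn_counts={"ERa": 5, "FoxA1": 8, "PBX1": 8, "ERa&FoxA1": 5,
                          "ERa&PBX1": 5, "FoxA1&PBX1": 8, "ERa&FoxA1&PBX1": 6})


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        d1 = SyntheticDesign(seed=9, **SMALL)
        d2 = SyntheticDesign(seed=9, **SMALL)
        g1, g2 = gen_genome(d1), gen_genome(d2)
        assert bytes(g1["chr1"]) == bytes(g2["chr1"])
        c1, c2 = gen_cistromes(d1), gen_cistromes(d2)
        for label in c1.cistromes:
            assert [iv.sort_key() for iv in c1.cistromes[label]] == [
                iv.sort_key() for iv in c2.cistromes[label]
            ]
        e1 = gen_expression(d1, gen_genes(d1, c1.class_sites))
        e2 = gen_expression(d2, gen_genes(d2, c2.class_sites))
        np.testing.assert_array_equal(e1.matrix.to_numpy(), e2.matrix.to_numpy())
        np.testing.assert_array_equal(
            gen_cohort(d1).table["expression"], gen_cohort(d2).table["expression"]
        )

    def test_different_seeds_differ(self):
        g1 = gen_genome(SyntheticDesign(seed=1, **SMALL))
        g2 = gen_genome(SyntheticDesign(seed=2, **SMALL))
        assert bytes(g1["chr1"]) != bytes(g2["chr1"])


class TestGenome:
    def test_gc_content_concentrates(self):
        design = SyntheticDesign(seed=3, gc_content=0.6, **SMALL)
        genome = gen_genome(design)
        seq = bytes(genome["chr1"])
        gc = (seq.count(b"G"[0]) + seq.count(b"C"[0])) / len(seq)
        assert abs(gc - 0.6) < 0.01

    def test_gc_zero_is_at_only(self):
        design = SyntheticDesign(seed=3, gc_content=0.0, **SMALL)
        seq = bytes(gen_genome(design)["chr1"])
        assert set(seq) <= set(b"AT")


class TestCistromes:
    def test_shared_class_identical_across_factors(self):
        design = SyntheticDesign(seed=5, **SMALL)
        truth = gen_cistromes(design)
        triple = {iv.sort_key() for iv in truth.class_sites["ERa&FoxA1&PBX1"]}
        for factor in ("ERa", "FoxA1", "PBX1"):
            keys = {iv.sort_key() for iv in truth.cistromes[factor]}
            assert triple <= keys

    def test_domain_too_small_raises(self):
        design = SyntheticDesign(
            seed=5, chrom_lengths={"chr1": 100_000},
            venn_counts={"PBX1": 50},
        )
        with pytest.raises(ValueError, match="too small"):
            gen_cistromes(design)


class TestPlantMotifs:
    def _setup(self, seed, prob, n=60):
        design = SyntheticDesign(seed=seed, motif_plant_prob=prob, **SMALL)
        genome = gen_genome(design)
        truth = gen_cistromes(design)
        sites = IntervalSet(
            [iv for s in truth.class_sites.values() for iv in s], "all"
        )
        pwm = default_pwm()
        table = plant_motifs(genome, sites, pwm, prob, design.rng(7))
        return design, genome, sites, pwm, table

    def test_prob_one_every_site_hits_at_consensus_score(self):
        design, genome, sites, pwm, table = self._setup(seed=1, prob=1.0)
        assert table["planted"].all()
        res = screen_cistrome(sites, genome_as_strings(genome), pwm)
        assert res.fraction == 1.0

    def test_prob_zero_fraction_near_background(self):
        design, genome, sites, pwm, table = self._setup(seed=2, prob=0.0)
        assert not table["planted"].any()
        res = screen_cistrome(sites, genome_as_strings(genome), pwm)
        # two-strand scan of ~193-window peaks at per-window p<=1e-4
        n_windows = 2 * (design.peak_width - len(pwm) + 1)
        background_rate = 1 - (1 - 1e-4) ** n_windows
        assert res.fraction <= background_rate * 5 + 0.05


class TestGenesAndExpression:
    def test_linked_genes_have_sites_unlinked_do_not(self):
        design = SyntheticDesign(seed=4, n_genes=400, n_responsive=100, **SMALL)
        truth = gen_cistromes(design)
        gt = gen_genes(design, truth.class_sites)
        from pioneerscan.tss_enrichment import genes_with_site

        linked = gt.table[gt.table.linked_class != ""]
        unlinked = gt.table[gt.table.linked_class == ""]
        all_sites = IntervalSet(
            [iv for s in truth.class_sites.values() for iv in s], "all"
        )
        with_site = genes_with_site(all_sites, gt.genes, design.tss_window)
        assert set(linked.gene_id) <= with_site
        assert not (set(unlinked.gene_id) & with_site)

    def test_expression_truth_recovered_with_strong_effect(self):
        design = SyntheticDesign(seed=6, n_genes=500, n_responsive=50,
                                 effect_size=4.0, noise_sd=0.3, **SMALL)
        truth = gen_cistromes(design)
        gt = gen_genes(design, truth.class_sites)
        study = gen_expression(design, gt)
        resp, _, _ = ex.estrogen_response_analysis(study, direction="up")
        planted = gt.responsive
        recovered = resp.responsive_all
        assert len(planted & recovered) / len(planted) > 0.95

    def test_dependent_fraction_limits(self):
        design = SyntheticDesign(seed=7, n_genes=300, n_responsive=60,
                                 dependent_fraction=1.0, effect_size=4.0,
                                 noise_sd=0.3, **SMALL)
        truth = gen_cistromes(design)
        gt = gen_genes(design, truth.class_sites)
        study = gen_expression(design, gt)
        resp, _, _ = ex.estrogen_response_analysis(study, direction="up")
        assert resp.dependent_fraction > 0.9


class TestTrackAndCohort:
    def test_zero_amplitudes_flat_noise(self):
        design = SyntheticDesign(
            seed=8, openness_amplitudes={}, track_noise_sd=0.1, **SMALL
        )
        truth = gen_cistromes(design)
        track = gen_track(design, truth.class_sites)
        vec = track.values["chr1"]
        assert abs(vec.mean() - design.track_baseline) < 0.01

    def test_amplitude_ordering_in_profiles(self):
        design = SyntheticDesign(seed=9, **SMALL)
        truth = gen_cistromes(design)
        track = gen_track(design, truth.class_sites)
        from pioneerscan.signal import aggregate_profile

        heights = {
            label: aggregate_profile(track, truth.class_sites[label], 1000).peak_height
            for label in ("FoxA1&PBX1", "PBX1", "FoxA1")
        }
        assert heights["FoxA1&PBX1"] > heights["PBX1"] > heights["FoxA1"]

    def test_zero_event_probabilities_no_events(self):
        design = SyntheticDesign(seed=10, event_prob_high=0.0,
                                 event_prob_low=0.0, **SMALL)
        cohort = gen_cohort(design)
        for y in (1, 3, 5):
            assert (cohort.table[f"status_y{y}"] == "event-free").all()

    def test_high_stratum_has_more_events(self):
        design = SyntheticDesign(seed=11, **SMALL)
        cohort = gen_cohort(design)
        from pioneerscan.outcome import stratify

        high, low = stratify(cohort, design.high_fraction)
        ev_h = (cohort.table.loc[high, "status_y5"] == "event").mean()
        ev_l = (cohort.table.loc[low, "status_y5"] == "event").mean()
        assert ev_h > ev_l
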