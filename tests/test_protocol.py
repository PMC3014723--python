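"""Three-phase protocol: thinning, selection uniformity, enumeration oracle."""

import itertools
import math

import numpy as np
import pytest

from subtray import (CommunityConfig, SampleRealization, TaxonSpec,
                     TrayGeometry, draw_sample, phase1_sieve,
                     phase2_subsample, phase3_scan, preset, run_protocol)


def _sample(cells, large, taxa, geometry):
    return SampleRealization(taxa=taxa, geometry=geometry,
                             cell_counts=np.asarray(cells),
                             large_counts=np.asarray(large))


@pytest.fixture
def two_taxa():
    return (TaxonSpec("Carabidae", 1.0, large_fraction=0.8),
            TaxonSpec("Aphidae", 1.0, p_detect_cell=0.7,
                      p_detect_scan_per_individual=0.05))


class TestPhase1:
    def test_identity_passthrough(self, two_taxa, tiny_geometry):
        s = _sample(np.zeros((5, 2), int), [3, 0], two_taxa, tiny_geometry)
        np.testing.assert_array_equal(phase1_sieve(s), [3, 0])
        # phase-2 ground truth excludes the sieve pool
        assert s.true_phase2_total == s.true_total - 3

    def test_zero_pool(self, two_taxa, tiny_geometry):
        s = _sample(np.zeros((5, 2), int), [0, 0], two_taxa, tiny_geometry)
        assert phase1_sieve(s).sum() == 0


class TestPhase2:
    def test_exhaustive_perfect_detection(self, rng, default_geometry):
        taxa = (TaxonSpec("a", 1.0),)
        sample = draw_sample(
            CommunityConfig(taxa=taxa, total_abundance=("fixed", 400)),
            default_geometry, rng)
        sub = phase2_subsample(sample, k=45, rng=rng)
        assert sub.observed_counts.sum() == sample.cell_counts[:45].sum()

    def test_zero_detection_taxon_never_observed(self, rng, default_geometry):
        taxa = (TaxonSpec("ghost", 1.0, p_detect_cell=0.0),)
        sample = draw_sample(
            CommunityConfig(taxa=taxa, total_abundance=("fixed", 300)),
            default_geometry, rng)
        sub = phase2_subsample(sample, k=16, rng=rng)
        assert sub.observed_counts.sum() == 0

    def test_k_out_of_range(self, rng, default_geometry):
        taxa = (TaxonSpec("a", 1.0),)
        sample = draw_sample(
            CommunityConfig(taxa=taxa, total_abundance=("fixed", 10)),
            default_geometry, rng)
        for k in (0, 46):
            with pytest.raises(ValueError):
                phase2_subsample(sample, k=k, rng=rng)

    def test_thinning_never_exceeds_truth(self, default_geometry):
        cfg = preset("pitfall_low")
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sample = draw_sample(cfg, default_geometry, rng)
            sub = phase2_subsample(sample, k=16, rng=rng)
            truth = sample.cell_counts[sub.selected_cells]
            assert (sub.observed_counts <= truth).all()

    def test_cell_selection_uniform(self, default_geometry):
        rng = np.random.default_rng(99)
        taxa = (TaxonSpec("a", 1.0),)
        sample = draw_sample(
            CommunityConfig(taxa=taxa, total_abundance=("fixed", 1)),
            default_geometry, rng)
        n_draws = 50_000
        hits = np.zeros(45)
        for _ in range(n_draws):
            cells = phase2_subsample(sample, k=16, rng=rng).selected_cells
            hits[cells] += 1
        p = 16 / 45
        sd = math.sqrt(n_draws * p * (1 - p))
        # 4-SD band: Bonferroni-safe for 45 simultaneous inclusion checks
        assert np.all(np.abs(hits - n_draws * p) < 4 * sd)


def _enumerate_detection_probability(m, C, k, p_detect):
    """Brute force: place m individuals uniformly over C cells, select k,
    thin each individual in a selected cell with p_detect; probability the
    taxon is observed at least once."""
    p_missed = 0.0
    placements = list(itertools.product(range(C), repeat=m))
    selections = list(itertools.combinations(range(C), k))
    for placement in placements:
        for sel in selections:
            in_sel = sum(1 for c in placement if c in sel)
            p_missed += (1 - p_detect) ** in_sel / (
                len(placements) * len(selections))
    return 1.0 - p_missed


class TestPhase2Oracle:
    @pytest.mark.parametrize("m, C, k, p_detect", [
        (2, 4, 2, 1.0),    # closed form: 1 - (2/4)^2 = 0.75
        (3, 5, 2, 1.0),
        (2, 6, 3, 0.7),
        (3, 4, 1, 0.5),
    ])
    def test_detection_probability_matches_enumeration(self, m, C, k, p_detect):
        expected = _enumerate_detection_probability(m, C, k, p_detect)
        geometry = TrayGeometry(inner_diameter=30.0, cell_side=2.0,
                                n_complete_cells=C, equivalent_cells=float(C))
        taxa = (TaxonSpec("t", 1.0, p_detect_cell=p_detect),)
        cfg = CommunityConfig(taxa=taxa, total_abundance=("fixed", m))
        rng = np.random.default_rng(12345)
        reps = 20_000
        hits = 0
        for _ in range(reps):
            sample = draw_sample(cfg, geometry, rng)
            sub = phase2_subsample(sample, k=k, rng=rng)
            hits += sub.observed_counts.sum() > 0
        p_hat = hits / reps
        sd = math.sqrt(expected * (1 - expected) / reps)
        assert abs(p_hat - expected) < 3 * sd

    def test_two_in_four_closed_form(self):
        assert _enumerate_detection_probability(2, 4, 2, 1.0) == \
            pytest.approx(0.75)


class TestPhase3:
    def test_already_detected_never_rescanned(self, two_taxa, tiny_geometry,
                                              rng):
        cells = np.zeros((5, 2), int)
        cells[0, 0] = 4
        s = _sample(cells, [0, 0], two_taxa, tiny_geometry)
        found = phase3_scan(s, {"Carabidae"}, rng)
        assert "Carabidae" not in found

    def test_certain_detection(self, tiny_geometry, rng):
        taxa = (TaxonSpec("t", 1.0, p_detect_scan_per_individual=1.0),)
        cells = np.zeros((5, 1), int)
        cells[2, 0] = 1
        s = _sample(cells, [0], taxa, tiny_geometry)
        assert phase3_scan(s, set(), rng) == {"t"}

    def test_three_individuals_half_q(self):
        # m=3, q=0.5: detection probability 1 - 0.5^3 = 0.875
        taxa = (TaxonSpec("t", 1.0, p_detect_scan_per_individual=0.5),)
        geometry = TrayGeometry(inner_diameter=8.0, cell_side=2.0,
                                n_complete_cells=4, equivalent_cells=4.0)
        cells = np.zeros((5, 1), int)
        cells[1, 0] = 3
        s = _sample(cells, [0], taxa, geometry)
        rng = np.random.default_rng(777)
        reps = 20_000
        hits = sum(bool(phase3_scan(s, set(), rng)) for _ in range(reps))
        expected = 0.875
        sd = math.sqrt(expected * (1 - expected) / reps)
        assert abs(hits / reps - expected) < 3 * sd


class TestRunProtocol:
    def test_empty_sample(self, two_taxa, tiny_geometry, rng):
        s = _sample(np.zeros((5, 2), int), [0, 0], two_taxa, tiny_geometry)
        result = run_protocol(s, k=2, rng=rng)
        assert result.large_counts.sum() == 0
        assert result.subsample.observed_total == 0
        assert result.scan_taxa == frozenset()

    def test_exhaustive_perfect_detection_recovers_truth(self, rng,
                                                         default_geometry):
        cfg = preset("pan_moderate", perfect_detection=True)
        sample = draw_sample(cfg, default_geometry, rng)
        # place no edge individuals: move them into cell 0
        cells = sample.cell_counts.copy()
        cells[0] += cells[-1]
        cells[-1] = 0
        sample = SampleRealization(taxa=sample.taxa, geometry=default_geometry,
                                   cell_counts=cells,
                                   large_counts=sample.large_counts)
        result = run_protocol(sample, k=45, rng=rng)
        assert result.subsample.observed_total == sample.true_phase2_total

    def test_scan_partition_no_duplicates(self, default_geometry):
        cfg = preset("pitfall_high")
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sample = draw_sample(cfg, default_geometry, rng)
            result = run_protocol(sample, k=16, rng=rng)
            assert not (result.scan_taxa & result.detected_taxa_phase12)
            assert result.detected_taxa <= sample.true_taxa

    def test_prefix_nesting(self, rng, default_geometry):
        sample = draw_sample(preset("pan_high"), default_geometry, rng)
        result = run_protocol(sample, k=16, rng=rng)
        p8 = result.subsample.prefix(8)
        np.testing.assert_array_equal(
            p8.selected_cells, result.subsample.selected_cells[:8])
        np.testing.assert_array_equal(
            p8.observed_counts, result.subsample.observed_counts[:8])
        with pytest.raises(ValueError):
            result.subsample.prefix(0)
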