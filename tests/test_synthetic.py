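"""Generators: determinism, planted truth agrees with direct inspection,
composition converges to the requested frequencies."""

import numpy as np
import pytest
from scipy.stats import chisquare

from phytkit.anchors import (
    CATALYTIC_OFFSETS,
    CATALYTIC_RESIDUES,
    I9_ANCHOR,
    S8_ANCHOR,
)
from phytkit.synthetic import (
    BackgroundSpec,
    LeafImageSpec,
    PlantedSbtSpec,
    TraceSpec,
    make_background_proteome,
    make_leaf_image,
    make_planted_sbt,
    make_trace,
)
from phytkit.types import AMINO_ACIDS, GenerationError


class TestBackgroundProteome:
    def test_empty(self):
        assert make_background_proteome(BackgroundSpec(n_proteins=0)) == []

    def test_deterministic(self):
        spec = BackgroundSpec(n_proteins=3, seed=1)
        a = make_background_proteome(spec)
        b = make_background_proteome(spec)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_invalid_freqs_rejected(self):
        with pytest.raises(ValueError):
            BackgroundSpec(n_proteins=1, aa_freqs=tuple([0.1] * 20))

    def test_composition_binomial_oracle(self):
        """Observed Asp fraction within 3 binomial SDs of its frequency."""
        spec = BackgroundSpec(n_proteins=1000, length_range=(80, 120), seed=5)
        proteome = make_background_proteome(spec)
        residues = "".join(r.sequence for r in proteome)
        n = len(residues)
        p = 0.05
        observed = residues.count("D") / n
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * sd

    def test_composition_chisquare_calibration(self):
        """Chi-square GOF at alpha=0.01 over 20 seeds: at most 2 rejections
        (expected false alarms ~0.2 at 1e5+ residues per seed)."""
        rejections = 0
        for seed in range(20):
            spec = BackgroundSpec(
                n_proteins=250, length_range=(400, 400), seed=seed
            )
            residues = "".join(
                r.sequence for r in make_background_proteome(spec)
            )
            counts = [residues.count(a) for a in AMINO_ACIDS]
            _, p = chisquare(counts)
            if p < 0.01:
                rejections += 1
        assert rejections <= 2


class TestPlantedSbt:
    def test_truth_matches_string_inspection(self, planted_candidate):
        rec, truth = planted_candidate
        j = truth.junction_index
        assert rec.sequence[j - 6:j + 6] == truth.window_residues
        assert rec.sequence[j - 1] == truth.p1_residue == "D"
        assert rec.sequence[truth.residue331_index] == truth.residue331_analog
        s, e = truth.s8_span
        expected_s8 = list(S8_ANCHOR)
        expected_s8[65] = truth.residue331_analog
        assert rec.sequence[s:e] == "".join(expected_s8)
        i, k = truth.i9_span
        assert rec.sequence[i:k] == I9_ANCHOR
        for pos, res in zip(truth.catalytic_positions, CATALYTIC_RESIDUES):
            assert rec.sequence[pos] == res

    def test_his_p1_is_noncandidate_truth(self, planted_noncandidate):
        _, truth = planted_noncandidate
        assert truth.p1_residue == "H"
        assert not truth.is_candidate

    def test_deterministic(self):
        spec = PlantedSbtSpec(id="x", total_length=700, junction_index=100, seed=3)
        a, _ = make_planted_sbt(spec)
        b, _ = make_planted_sbt(spec)
        assert a.sequence == b.sequence

    def test_missing_flags_remove_anchors(self):
        spec = PlantedSbtSpec(
            id="x", total_length=700, junction_index=100,
            has_i9=False, has_catalytic=False, seed=3,
        )
        rec, truth = make_planted_sbt(spec)
        assert truth.i9_span is None and I9_ANCHOR not in rec.sequence
        assert truth.catalytic_positions == ()
        s = truth.s8_span[0]
        for off in CATALYTIC_OFFSETS:
            assert rec.sequence[s + off] == "A"

    def test_window_collision_raises(self):
        with pytest.raises(GenerationError):
            make_planted_sbt(PlantedSbtSpec(
                id="x", total_length=700, junction_index=40, seed=0,
            ))
        with pytest.raises(GenerationError):
            make_planted_sbt(PlantedSbtSpec(
                id="x", total_length=250, junction_index=100, seed=0,
            ))

    def test_window_p1_consistency_enforced(self):
        with pytest.raises(ValueError):
            PlantedSbtSpec(
                id="x", total_length=700, junction_index=100,
                p1_residue="D", window_residues="STQAVHTTHGAA",
            )


class TestTrace:
    def test_noiseless_line(self):
        trace = make_trace(TraceSpec(intercept=10, slope=50, noise_sd=0,
                                     n_points=10, dt=1))
        v = np.asarray(trace.values)
        t = np.asarray(trace.times)
        assert np.allclose(v, 10 + 50 * t)

    def test_constant(self):
        trace = make_trace(TraceSpec(intercept=7, slope=0, noise_sd=0, n_points=5))
        assert set(trace.values) == {7.0}

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            TraceSpec(n_points=1)

    def test_monte_carlo_slope_recovery(self):
        """Mean fitted slope over 200 replicate seeds within 2 SE of truth."""
        from phytkit.activity import initial_rate

        slopes = []
        for seed in range(200):
            trace = make_trace(TraceSpec(
                intercept=0, slope=50, noise_sd=5, n_points=100, dt=1, seed=seed,
            ))
            slopes.append(initial_rate(trace, window_policy="full").slope)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 50) < 2 * se + 1e-9


class TestLeafImage:
    def test_no_necrosis_no_dark(self):
        img, truth = make_leaf_image(LeafImageSpec(necrotic_fraction=0))
        assert truth.n_dark == 0
        assert (img <= 40).sum() == 0

    def test_exact_planted_count(self):
        img, truth = make_leaf_image(LeafImageSpec(
            width=100, height=100, leaf_fraction=1.0, necrotic_fraction=0.05,
        ))
        assert truth.n_leaf == 10000
        assert truth.n_dark == 500
        assert int((img <= 40).sum()) == 500
        assert int((img >= 250).sum()) == 0  # leaf covers everything

    def test_pixel_classes(self):
        img, truth = make_leaf_image(LeafImageSpec(
            width=60, height=40, leaf_fraction=0.5, necrotic_fraction=0.1, seed=2,
        ))
        n_bg = (img == 255).sum()
        n_leafish = ((img >= 100) & (img <= 160)).sum()
        n_dark = (img <= 40).sum()
        assert n_bg + n_leafish + n_dark == 60 * 40
        assert n_dark == truth.n_dark

    def test_deterministic(self):
        spec = LeafImageSpec(necrotic_fraction=0.2, seed=9)
        a, _ = make_leaf_image(spec)
        b, _ = make_leaf_image(spec)
        assert np.array_equal(a, b)
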