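"""Window placement, terminal normalization, aggregation and contrast."""

import math

import numpy as np
import pytest

from readthrough import (
    AnnotationSet,
    GenomicInterval,
    PipelineConfig,
    StrandedCoverage,
    TranscriptProfile,
    compare_conditions,
    expected_metagene,
    metagene_profile,
    place_windows,
    simulate_annotation,
    simulate_coverage,
    transcript_profile,
    SimulationParams,
)

from conftest import coverage_from_dict, make_transcript, mirror_annotation, mirror_coverage


def _cfg(**kw):
    kw.setdefault("window_size", 250)
    kw.setdefault("n_windows", 2)
    return PipelineConfig(**kw)


class TestPlaceWindows:
    def test_plus_strand_downstream_windows(self):
        t = make_transcript(exons=((0, 1000),))
        wins = place_windows(t, _cfg())
        assert [(w.start, w.end) for w in wins] == [(1000, 1250), (1250, 1500)]

    def test_minus_strand_windows_walk_leftward(self):
        t = make_transcript(strand="-", exons=((1000, 2000),))
        wins = place_windows(t, _cfg())
        assert [(w.start, w.end) for w in wins] == [(750, 1000), (500, 750)]

    def test_terminal_window_sits_inside_span(self):
        t = make_transcript(exons=((0, 1000),))
        (term,) = place_windows(t, _cfg(), side="terminal")
        assert (term.start, term.end) == (750, 1000)
        t_minus = make_transcript(strand="-", exons=((1000, 2000),))
        (term,) = place_windows(t_minus, _cfg(), side="terminal")
        assert (term.start, term.end) == (1000, 1250)

    def test_short_span_flagged_invalid_for_terminal(self):
        t = make_transcript(exons=((0, 100),))
        assert place_windows(t, _cfg(), side="terminal") is None

    def test_windows_beyond_chromosome_bounds_flagged(self):
        t_minus = make_transcript(strand="-", exons=((100, 1000),))
        assert place_windows(t_minus, _cfg()) is None  # would cross position 0
        t_plus = make_transcript(exons=((0, 1000),))
        assert place_windows(t_plus, _cfg(), chrom_length=1200) is None


class TestTranscriptProfile:
    def test_normalization_by_terminal_signal(self):
        t = make_transcript(exons=((0, 1000),))
        values = {("chr1", "+", 999): 100.0, ("chr1", "+", 1000): 44.0, ("chr1", "+", 1300): 20.0}
        prof = transcript_profile(t, coverage_from_dict(values), _cfg())
        assert prof.terminal_signal == 100.0
        assert prof.normalized == pytest.approx([0.44, 0.20])

    def test_zero_terminal_signal_hits_floor(self):
        t = make_transcript(exons=((0, 1000),))
        prof = transcript_profile(t, StrandedCoverage(), _cfg())
        assert not prof.valid and prof.reason == "terminal-floor"

    def test_terminal_window_self_normalizes_to_one(self):
        # substituting the terminal window for window 1 must give exactly 1
        t = make_transcript(exons=((0, 1000),))
        values = {("chr1", "+", p): float(1 + p % 5) for p in range(600, 1000)}
        cov = coverage_from_dict(values)
        cfg = _cfg()
        (term,) = place_windows(t, cfg, side="terminal")
        prof = transcript_profile(t, cov, cfg)
        assert cov.interval_sum(term) / prof.terminal_signal == 1.0

    def test_noiseless_simulation_matches_analytic_oracle(self):
        params = SimulationParams(
            n_transcripts=12,
            chrom_length=400_000,
            readthrough_fraction=0.5,
            decay_length=1000.0,
            seed=3,
        )
        ann, truth = simulate_annotation(params)
        cov = simulate_coverage(ann, truth, noiseless=True)
        cfg = PipelineConfig(window_size=250, n_windows=4)
        for t in ann:
            prof = transcript_profile(t, cov, cfg, chrom_length=params.chrom_length)
            assert prof.valid
            assert prof.normalized[0] == pytest.approx(0.4424, abs=1e-3)


class TestMetaGeneProfile:
    def _profiles(self, normalized_rows, terminals=None, windows=None):
        out = []
        for i, norm in enumerate(normalized_rows):
            norm = np.asarray(norm, dtype=float)
            term = terminals[i] if terminals else 1.0
            win = np.asarray(windows[i], dtype=float) if windows else norm * term
            out.append(
                TranscriptProfile(
                    transcript_id=f"T{i}",
                    terminal_signal=term,
                    window_signals=win,
                    normalized=norm,
                    valid=True,
                )
            )
        return out

    def test_mean_of_ratios_means(self):
        profiles = self._profiles([[1, 0], [0, 0], [2, 1]])
        mg = metagene_profile(profiles, _cfg())
        assert mg.mean == pytest.approx([1.0, 1 / 3])
        assert mg.n_transcripts == 3

    def test_single_profile_is_identity(self):
        profiles = self._profiles([[0.7, 0.2]])
        mg = metagene_profile(profiles, _cfg())
        assert mg.mean == pytest.approx([0.7, 0.2])

    def test_modes_differ_as_hand_computed(self):
        # terminals 100, 300; window-1 signals 100, 0:
        # mean_of_ratios = (1 + 0)/2 = 0.5; pooled = 100/400 = 0.25
        profiles = self._profiles(
            [[1.0, 0.0], [0.0, 0.0]],
            terminals=[100.0, 300.0],
            windows=[[100.0, 0.0], [0.0, 0.0]],
        )
        mor = metagene_profile(profiles, _cfg(aggregation="mean_of_ratios"))
        pr = metagene_profile(profiles, _cfg(aggregation="pooled_ratio"))
        assert mor.mean[0] == pytest.approx(0.5)
        assert pr.mean[0] == pytest.approx(0.25)

    def test_pooled_ratio_invariant_to_transcript_duplication(self):
        profiles = self._profiles(
            [[0.5, 0.1], [0.2, 0.0]], terminals=[100.0, 50.0],
            windows=[[50.0, 10.0], [10.0, 0.0]],
        )
        pr1 = metagene_profile(profiles, _cfg(aggregation="pooled_ratio"))
        pr2 = metagene_profile(profiles + profiles, _cfg(aggregation="pooled_ratio"))
        assert pr1.mean == pytest.approx(pr2.mean)

    def test_no_valid_profiles_errors(self):
        invalid = TranscriptProfile("T0", 0.0, np.zeros(2), None, False, "terminal-floor")
        with pytest.raises(ValueError, match="no analyzable"):
            metagene_profile([invalid], _cfg())


class TestCompareConditions:
    def _sim_profiles(self, alpha, seed, n=60):
        params = SimulationParams(
            n_transcripts=n,
            chrom_length=1_500_000,
            readthrough_fraction=alpha,
            seed=5,
        )
        ann, truth = simulate_annotation(params)
        cov = simulate_coverage(ann, truth, condition_alpha=alpha, replicate_seed=seed)
        cfg = PipelineConfig(n_windows=8, seed=42)
        return [
            transcript_profile(t, cov, cfg, chrom_length=params.chrom_length)
            for t in ann
        ], cfg

    def test_identical_collections_give_zero_difference(self):
        profiles, cfg = self._sim_profiles(0.3, seed=1)
        cmp = compare_conditions(profiles, profiles, cfg)
        assert np.all(cmp.diff == 0.0)
        assert np.all(cmp.ci_lo <= cmp.diff) and np.all(cmp.diff <= cmp.ci_hi)

    def test_deterministic_given_seed(self):
        pa, cfg = self._sim_profiles(0.05, seed=1)
        pb, _ = self._sim_profiles(0.6, seed=2)
        c1 = compare_conditions(pa, pb, cfg)
        c2 = compare_conditions(pa, pb, cfg)
        assert np.array_equal(c1.ci_lo, c2.ci_lo)
        assert np.array_equal(c1.ci_hi, c2.ci_hi)

    def test_contrast_detected_between_low_and_high_alpha(self):
        pa, cfg = self._sim_profiles(0.05, seed=1)
        pb, _ = self._sim_profiles(0.6, seed=2)
        cmp = compare_conditions(pa, pb, cfg)
        assert np.all(cmp.diff > 0)
        assert np.all(cmp.ci_lo > 0)

    def test_empty_condition_errors(self):
        pa, cfg = self._sim_profiles(0.3, seed=1)
        with pytest.raises(ValueError):
            compare_conditions(pa, [], cfg)


class TestInvariances:
    def _metagene_from(self, ann, cov, cfg, chrom_length):
        profiles = [
            transcript_profile(t, cov, cfg, chrom_length=chrom_length) for t in ann
        ]
        return metagene_profile(profiles, cfg)

    def test_depth_invariance(self):
        params = SimulationParams(n_transcripts=40, chrom_length=1_000_000, seed=9)
        ann, truth = simulate_annotation(params)
        cov = simulate_coverage(ann, truth, condition_alpha=0.4, replicate_seed=4)
        cfg = PipelineConfig(n_windows=10)
        mg1 = self._metagene_from(ann, cov, cfg, params.chrom_length)
        mg3 = self._metagene_from(ann, cov.scaled(3.0), cfg, params.chrom_length)
        assert mg3.mean == pytest.approx(mg1.mean, abs=1e-9)
        assert mg3.n_transcripts == mg1.n_transcripts

    def test_strand_mirror_invariance(self):
        params = SimulationParams(n_transcripts=30, chrom_length=800_000, seed=21)
        ann, truth = simulate_annotation(params)
        cov = simulate_coverage(ann, truth, condition_alpha=0.5, replicate_seed=8)
        cfg = PipelineConfig(n_windows=10)
        L = params.chrom_length
        mg = self._metagene_from(ann, cov, cfg, L)
        mg_mirror = self._metagene_from(
            mirror_annotation(ann, L), mirror_coverage(cov, params.chrom, L), cfg, L
        )
        assert mg_mirror.mean == pytest.approx(mg.mean, abs=1e-12)
        assert mg_mirror.n_transcripts == mg.n_transcripts


class TestExpectedMetagene:
    def test_reference_value(self):
        assert expected_metagene(0.5, 1000, 250, 1) == pytest.approx(
            0.5 * 4 * (1 - math.exp(-0.25)), abs=1e-12
        )
        assert expected_metagene(0.5, 1000, 250, 1) == pytest.approx(0.4424, abs=1e-4)

    def test_zero_alpha_is_zero_everywhere(self):
        assert all(expected_metagene(0.0, 1000, 250, k) == 0.0 for k in range(1, 10))

    def test_large_lambda_limit_approaches_alpha(self):
        # deviation from the limit is O(kW/lam)
        assert expected_metagene(0.37, 1e9, 250, 1) == pytest.approx(0.37, rel=1e-5)
        assert expected_metagene(0.37, 1e9, 250, 5) == pytest.approx(0.37, rel=1e-5)
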