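"""Ground-truth generators: determinism, composition, planted recoverability."""

import numpy as np
import pytest

import triplexkit as tk
from triplexkit.synthetic import CapacityError, place_nonoverlapping
from triplexkit import qpcr


class TestMakeGenome:
    def test_gc_fraction_within_binomial_bound(self):
        genome, manifest = tk.make_genome(1, 10_000, 0.5, seed=7)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02
        assert manifest["seed"] == 7

    def test_zero_gc_forces_at_only(self):
        genome, _ = tk.make_genome(1, 100, 0.0, seed=1)
        assert set(genome["chr1"]) <= {"A", "T"}

    def test_seeded_determinism(self):
        a, _ = tk.make_genome(2, 500, 0.4, seed=11)
        b, _ = tk.make_genome(2, 500, 0.4, seed=11)
        assert a == b

    def test_input_validation(self):
        with pytest.raises(ValueError):
            tk.make_genome(0, 1000, 0.5)
        with pytest.raises(ValueError):
            tk.make_genome(1, 10, 0.5)
        with pytest.raises(ValueError):
            tk.make_genome(1, 1000, 1.5)


class TestPlantTts:
    def test_zero_sites_is_identity(self, ga_tfo):
        genome, _ = tk.make_genome(1, 1000, 0.5, seed=3)
        planted, truth = tk.plant_tts(genome, ga_tfo, 0, seed=4)
        assert planted == genome and truth == []

    def test_sites_disjoint_and_in_bounds(self):
        from triplexkit import sequences as sq
        genome, _ = tk.make_genome(1, 10_000, 0.5, seed=7)
        _, truth = tk.plant_tts(genome, sq.TFO2_23, 5, 0.1, seed=3)
        assert len(truth) == 5
        intervals = sorted((s, e) for _, s, e, _ in truth)
        assert all(e - s == 23 for s, e in intervals)
        assert all(intervals[i][1] <= intervals[i + 1][0]
                   for i in range(len(intervals) - 1))

    def test_perfect_sites_found_with_zero_mismatches(self, ga_tfo):
        """A motif-pure TFO's planted sites are exact full-length hits."""
        genome, _ = tk.make_genome(1, 5000, 0.5, seed=5)
        planted, truth = tk.plant_tts(genome, ga_tfo, 4, 0.0, seed=6)
        hits = tk.find_tts(ga_tfo, tk.NucleicSeq("chr1", "DNA", planted["chr1"]))
        perfect = {(h.start, h.end, h.strand) for h in hits
                   if h.mismatches == 0 and h.length == len(ga_tfo)}
        assert {(s, e, st) for _, s, e, st in truth} <= perfect

    def test_requested_mismatches_are_written(self, ga_tfo):
        genome, _ = tk.make_genome(1, 5000, 0.5, seed=5)
        rate = 0.2
        planted, truth = tk.plant_tts(genome, ga_tfo, 3, rate, seed=8)
        n_planted_mm = int(np.floor(rate * len(ga_tfo)))
        hits = tk.find_tts(ga_tfo, tk.NucleicSeq("chr1", "DNA", planted["chr1"]),
                           max_error_rate=rate)
        for chrom, s, e, strand in truth:
            site_hits = [h for h in hits if h.start >= s and h.end <= e
                         and h.strand == strand]
            assert site_hits, f"planted site {s}-{e} not recovered"
            assert min(h.mismatches for h in site_hits) <= n_planted_mm

    def test_capacity_error(self, ga_tfo):
        genome, _ = tk.make_genome(1, 100, 0.5, seed=1)
        with pytest.raises(CapacityError):
            tk.plant_tts(genome, ga_tfo, 20, seed=2)

    def test_strict_motif_rejects_incompatible_base(self):
        from triplexkit import sequences as sq
        genome, _ = tk.make_genome(1, 1000, 0.5, seed=1)
        with pytest.raises(ValueError, match="no partner"):
            tk.plant_tts(genome, sq.TFO2_23, 1, motif="antiparallel_purine")

    def test_determinism(self, ga_tfo):
        genome, _ = tk.make_genome(1, 2000, 0.5, seed=9)
        a = tk.plant_tts(genome, ga_tfo, 3, 0.1, seed=10)
        b = tk.plant_tts(genome, ga_tfo, 3, 0.1, seed=10)
        assert a == b


class TestPlacement:
    @pytest.mark.parametrize("seed", range(10))
    def test_placements_never_overlap(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(5, 40, size=8).tolist()
        starts = place_nonoverlapping(lengths, 400, rng)
        spans = sorted(zip(starts, lengths))
        for (s1, l1), (s2, _) in zip(spans, spans[1:]):
            assert s1 + l1 <= s2
        assert all(s >= 0 and s + l <= 400 for s, l in zip(starts, lengths))

    def test_capacity(self):
        rng = np.random.default_rng(0)
        with pytest.raises(CapacityError):
            place_nonoverlapping([60, 60], 100, rng)
        # exact fit is allowed
        assert place_nonoverlapping([50, 50], 100, rng) == [0, 50]


class TestPeakTable:
    def test_background_matches_poisson_mean(self):
        peaks, truth = tk.make_peak_table(4000, 0, background_lambda=5.0, seed=2)
        assert not truth["is_enriched"].any()
        mean = peaks["observed_reads"].mean()
        # mean of 4000 Poisson(5) draws: sd of mean ~ 0.035
        assert abs(mean - 5.0) < 0.15
        assert (peaks["expected_reads"] == 5.0).all()

    def test_enriched_rows_carry_fold(self):
        peaks, truth = tk.make_peak_table(500, 50, 5.0, 20.0, seed=3)
        enriched = peaks[truth["is_enriched"].to_numpy()]
        background = peaks[~truth["is_enriched"].to_numpy()]
        assert enriched["observed_reads"].mean() > 10 * background["observed_reads"].mean()

    def test_determinism_and_validation(self):
        a = tk.make_peak_table(100, 5, seed=4)[0]
        b = tk.make_peak_table(100, 5, seed=4)[0]
        assert a.equals(b)
        with pytest.raises(ValueError):
            tk.make_peak_table(10, 11)
        with pytest.raises(ValueError):
            tk.make_peak_table(10, 1, background_lambda=0)


class TestMeltingCurveGenerator:
    def test_sigmoid_midpoint_value(self):
        curve = tk.make_melting_curve(a=0.8, x0=50.0, b=3.0, c=0.0, x2=80.0,
                                      d=3.0, t_min=5, t_max=95, step=0.5,
                                      noise_sd=0.0)
        i = int(np.argmin(np.abs(curve.temperatures - 50.0)))
        assert curve.values[i] == pytest.approx(0.4, abs=1e-9)

    def test_noiseless_curve_monotone(self):
        curve = tk.make_melting_curve(noise_sd=0.0)
        assert np.all(np.diff(curve.values) >= 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            tk.make_melting_curve(t_min=50, t_max=40)
        with pytest.raises(ValueError):
            tk.make_melting_curve(b=-1.0)


class TestCtTable:
    def test_fold_four_lowers_target_by_two_cycles(self):
        table, _ = tk.make_ct_table([4.0], base_ct=25.0, noise_sd=0.0,
                                    n_replicates=1)
        ctrl = table[table["condition"] == "control"]["target_ct"].iloc[0]
        trt = table[table["condition"] == "treated"]["target_ct"].iloc[0]
        assert ctrl - trt == pytest.approx(2.0)

    def test_noiseless_folds_recovered_exactly(self):
        folds = [1.0, 2.0, 4.0, 0.5]
        table, truth = tk.make_ct_table(folds, noise_sd=0.0, seed=1)
        out = qpcr.analyze_ct_table(table)
        assert np.allclose(out["fold_change"].to_numpy(),
                           truth["true_fold"].to_numpy())

    def test_noisy_folds_recovered_in_expectation(self):
        # many replicates at sd 0.2 cycles: mean recovered fold within 5%
        table, _ = tk.make_ct_table([2.0], noise_sd=0.2, seed=5,
                                    n_replicates=1000)
        out = qpcr.analyze_ct_table(table)
        assert abs(out["fold_change"].iloc[0] - 2.0) / 2.0 < 0.05


class TestTruthManifest:
    def test_round_trip(self, tmp_path):
        truth = tk.SyntheticTruth(
            genome_id="g", seed=3,
            planted_tts=[("chr1", 10, 33, "+"), ("chr1", 100, 123, "-")],
            planted_tfr=("rna", 5, 21),
            peak_truth=[("LNC1", 5.0, 5.0, False)],
            melt_truth=[("c1", 0.5, 49.52, 3.0, 0.5, 70.0, 3.0, 0.02)],
            ct_truth=[("S1", 2.0)],
        )
        path = tmp_path / "truth.json"
        truth.write(path)
        assert tk.SyntheticTruth.read(path) == truth

    def test_validation(self):
        bad = tk.SyntheticTruth(planted_tts=[("chr1", 10, 5, "+")])
        with pytest.raises(ValueError):
            bad.validate()
        out_of_bounds = tk.SyntheticTruth(planted_tts=[("chr1", 10, 50, "+")])
        with pytest.raises(ValueError):
            out_of_bounds.validate({"chr1": "A" * 20})
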