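"""Synthetic read/event generator: distributions, effects, determinism."""

import numpy as np
import pytest

from gravseq.errors import InputError
from gravseq.events import read_quality
from gravseq.segmentation import PhasePeriod
from gravseq.simulate import ReadModel, simulate_genome, simulate_reads
from gravseq.simulate.reads import Effects, TranslocationDist

ONE_PERIOD = [PhasePeriod(0.0, 60.0, "other")]


class TestGenome:
    def test_deterministic_and_right_length(self):
        a = simulate_genome(10, seed=1)
        b = simulate_genome(10, seed=1)
        assert str(a.seq) == str(b.seq)
        assert len(a.seq) == 10
        assert set(str(a.seq)) <= set("ACGT")

    def test_header_records_length(self):
        rec = simulate_genome(48502, seed=0)
        assert "48502" in rec.description or "48502" in rec.id

    def test_zero_length_rejected(self):
        with pytest.raises(InputError):
            simulate_genome(0)


class TestTranslocationDist:
    def test_lognormal_median_mean_parameterisation(self, rng):
        d = TranslocationDist(median_ms=1.8, mean_ms=2.2786)
        x = d.sample(rng, 400000)
        assert np.median(x) == pytest.approx(1.8, rel=0.01)
        assert np.mean(x) == pytest.approx(2.2786, rel=0.01)

    def test_inverse_gaussian_alternative(self, rng):
        d = TranslocationDist(median_ms=1.8, mean_ms=2.2786,
                              family="inverse_gaussian")
        x = d.sample(rng, 400000)
        assert np.mean(x) == pytest.approx(2.2786, rel=0.01)
        assert np.median(x) == pytest.approx(1.8, rel=0.02)

    def test_invalid_params_rejected(self):
        with pytest.raises(InputError):
            TranslocationDist(median_ms=2.0, mean_ms=1.0)


class TestSimulateReads:
    def test_mean_translocation_matches_model(self):
        """With ~1e5 bases, the sample mean dwell lands within 1% of the
        configured mean (law of large numbers + discretisation)."""
        model = ReadModel(read_rate=40.0, read_len_mean=500.0,
                          trans_dist=TranslocationDist(1.8, 2.3))
        _, bases, _ = simulate_reads(model, ONE_PERIOD, 60.0, seed=3)
        assert len(bases) > 1e5
        assert bases["trans_ms"].mean() == pytest.approx(2.3, rel=0.01)

    def test_degenerate_quality_gives_exact_q_pbar(self):
        model = ReadModel(read_rate=5.0, read_len_mean=200.0, qual_sd=0.0,
                          qual_mean=9.0)
        reads, bases, _ = simulate_reads(model, ONE_PERIOD, 60.0, seed=0)
        assert (bases["qual"] == 9).all()
        np.testing.assert_allclose(reads["q_pbar"], 9.0)

    def test_q_pbar_matches_read_quality_recomputation(self):
        model = ReadModel(read_rate=3.0, read_len_mean=300.0)
        reads, bases, _ = simulate_reads(model, ONE_PERIOD, 60.0, seed=1)
        rid = reads["read_id"].iloc[0]
        quals = bases.loc[bases["read_id"] == rid, "qual"].to_numpy()
        assert reads["q_pbar"].iloc[0] == pytest.approx(
            read_quality(quals), abs=1e-9
        )

    def test_determinism(self):
        model = ReadModel(read_rate=5.0, read_len_mean=200.0)
        a = simulate_reads(model, ONE_PERIOD, 60.0, seed=9)
        b = simulate_reads(model, ONE_PERIOD, 60.0, seed=9)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_mux_window_flagging(self):
        model = ReadModel(read_rate=5.0, read_len_mean=100.0,
                          mux_window_s=30.0)
        reads, _, _ = simulate_reads(model, ONE_PERIOD, 60.0, seed=2)
        assert (reads.loc[reads["start_s"] < 30.0, "is_mux"]).all()
        assert (~reads.loc[reads["start_s"] >= 30.0, "is_mux"]).all()

    def test_genome_positions_contiguous_and_in_range(self):
        model = ReadModel(read_rate=3.0, read_len_mean=500.0)
        reads, bases, _ = simulate_reads(model, ONE_PERIOD, 60.0, seed=4)
        assert bases["genome_pos"].between(0, 48501).all()
        for rid, grp in bases.groupby("read_id"):
            pos = grp["genome_pos"].to_numpy()
            assert (np.diff(pos) == 1).all()

    def test_uncovered_session_rejected(self):
        with pytest.raises(InputError):
            simulate_reads(ReadModel(), ONE_PERIOD, 120.0, seed=0)
        with pytest.raises(InputError):
            simulate_reads(ReadModel(), [], 10.0, seed=0)

    def test_planted_phase_effect_shifts_noise(self):
        periods = [
            PhasePeriod(0, 30, "other"),
            PhasePeriod(30, 60, "hypergravity"),
        ]
        eff = Effects(noise_phase={"hypergravity": -0.05})
        model = ReadModel(read_rate=20.0, read_len_mean=300.0, effects=eff)
        _, bases, truth = simulate_reads(model, periods, 60.0, seed=5)
        in_hyper = bases["t_s"].between(31, 59)
        in_other = bases["t_s"].between(1, 29)
        delta = (bases.loc[in_hyper, "norm_std"].mean()
                 - bases.loc[in_other, "norm_std"].mean())
        assert delta == pytest.approx(-0.05, abs=0.01)
        assert truth["effects"]["noise_phase"] == {"hypergravity": -0.05}

    def test_planted_time_trend_recovered_by_stepwise(self, small_flight):
        """Parameter recovery: a linear time trend planted on per-base
        quality is selected by the stepwise regression of binned median
        q_pbar on time, and the fitted slope brackets the planted one."""
        from gravseq.accel import FilterSpec, process_vibration
        from gravseq.integration import build_bins
        from gravseq.stats import stepwise_lm

        trace, truth = small_flight
        slope = -0.01  # Phred units per second
        eff = Effects(qual_per_s=slope)
        model = ReadModel(read_rate=4.0, read_len_mean=400.0, effects=eff)
        reads, bases, _ = simulate_reads(model, truth, trace.duration_s,
                                         seed=6)
        vib = process_vibration(trace, FilterSpec(sample_rate=500.0))
        run = reads[~reads["is_mux"]]
        bins = build_bins(run, bases[bases["read_id"].isin(run["read_id"])],
                          vib, truth)
        res = stepwise_lm(
            bins["median_q_pbar"],
            {"elapsed_s": bins["elapsed_s"].to_numpy(),
             "rms_g": bins["rms_g"].to_numpy(),
             "mean_g": bins["mean_g"].to_numpy()},
        )
        assert "elapsed_s" in res.terms
        fitted = res.coefficients["elapsed_s"]
        # q_pbar responds to a shift of the per-base Phred mean nearly 1:1
        assert fitted == pytest.approx(slope, rel=0.35)
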