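"""Trace simulation, processivity, lifetime MLE and bulk quantifications."""

import collections
import math

import numpy as np
import pandas as pd
import pytest

from sortramp import elongation as elo
from sortramp.errors import ConfigurationError, GapError, TraceFormatError


def model(q=(0.0, 0.4, 0.3, 0.0), **kw):
    return elo.ElongationModel(abort_probs=tuple(q), **kw)


class TestSimulateTraces:
    def test_no_abort_probability_completes_everything(self):
        traces = elo.simulate_traces(model(q=(0.0, 0.0)), 8, 200, seed=0)
        assert all(t.outcome == "completed" for t in traces)
        # codons 3..8 each contribute one elongation cycle
        assert all(t.n_elongation_cycles == 6 for t in traces)

    def test_certain_abort_at_codon_four(self):
        traces = elo.simulate_traces(model(q=(0.0, 1.0)), 8, 100, seed=0)
        assert all(t.outcome == "aborted_at:4" for t in traces)
        assert all(t.dwells[-1][0] == elo.NON_ROTATED for t in traces)

    def test_completion_matches_survival_product(self):
        m = model(q=(0.0, 0.4, 0.3, 0.0))
        traces = elo.simulate_traces(m, 10, 1000, seed=3)
        frac = sum(t.outcome == "completed" for t in traces) / 1000
        expected = m.expected_completion
        sd = math.sqrt(expected * (1 - expected) / 1000)
        assert expected == pytest.approx(0.42)
        assert abs(frac - expected) <= 3 * sd

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            elo.simulate_traces(model(), 10, 0, seed=0)
        with pytest.raises(ConfigurationError):
            elo.simulate_traces(model(), 2, 10, seed=0)

    def test_dwells_sit_on_the_frame_grid(self):
        traces = elo.simulate_traces(model(q=(0.0,)), 6, 50, seed=1)
        for t in traces:
            for _, dur in t.dwells:
                frames = dur * t.frame_rate
                assert frames >= 1 - 1e-9
                assert abs(frames - round(frames)) < 1e-9

    def test_abort_profile_recovers_branch_probabilities(self):
        q = (0.0, 0.35, 0.2, 0.1)
        traces = elo.simulate_traces(model(q=q), 10, 1000, seed=8)
        prof = elo.abort_profile(traces, 10).set_index("codon")
        for codon, q_true in zip(range(3, 7), q):
            n = prof.loc[codon, "n_reached"]
            sd = math.sqrt(max(q_true * (1 - q_true), 1e-9) / n)
            assert abs(prof.loc[codon, "q_hat"] - q_true) <= 3 * sd + 1e-9


class TestClassifyTrace:
    def make_aborted(self, bindings):
        dwells = [(elo.NON_ROTATED, 0.2), (elo.ROTATED, 0.3)] * 2
        dwells.append((elo.NON_ROTATED, 30.0))
        return elo.Trace(
            dwells=dwells,
            trna_events=[(5, b) for b in bindings],
            outcome="aborted_at:5",
        )

    def test_full_traversal_is_completed(self):
        t = elo.Trace(dwells=[(elo.NON_ROTATED, 0.1), (elo.ROTATED, 0.2)] * 4)
        assert elo.classify_trace(t, 6) == "completed"

    def test_long_binding_marks_sampling(self):
        assert (
            elo.classify_trace(self.make_aborted([0.15]), 8)
            == "aborted_with_sampling"
        )

    def test_threshold_is_strict(self):
        assert (
            elo.classify_trace(self.make_aborted([0.1, 0.05]), 8)
            == "aborted_no_sampling"
        )

    def test_malformed_alternation_rejected(self):
        t = elo.Trace(dwells=[(elo.ROTATED, 0.1)])
        with pytest.raises(TraceFormatError):
            elo.classify_trace(t, 6)

    def test_simulated_sampling_classes_are_rare(self):
        m = model(q=(0.0, 0.5), sampling_event_rate=0.002, sampling_mean_s=0.04)
        traces = elo.simulate_traces(m, 8, 500, seed=5)
        classes = collections.Counter(
            elo.classify_trace(t, 8) for t in traces
        )
        assert classes["aborted_with_sampling"] < classes["aborted_no_sampling"]


class TestProcessivity:
    @pytest.mark.parametrize(
        "completed, total, p, se",
        [
            (50, 100, 0.50, 0.05),
            (100, 100, 1.0, 0.0),
            (150, 179, 0.8379888268, 0.0275400727),
        ],
    )
    def test_closed_forms(self, completed, total, p, se):
        got_p, got_se = elo.processivity(completed, total)
        assert got_p == pytest.approx(p)
        assert got_se == pytest.approx(se, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            elo.processivity(1, 0)
        with pytest.raises(ConfigurationError):
            elo.processivity(5, 4)

    def test_presets_reproduce_their_completion_fractions(self):
        for name, target in elo.PROCESSIVITY_PRESETS.items():
            m = elo.ElongationModel.from_preset(name)
            assert m.expected_completion == pytest.approx(target, abs=1e-9)


class TestExponentialMLE:
    def test_mean_is_the_sample_mean(self):
        mean, (lo, hi) = elo.fit_exponential_mle([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert lo < 2.0 < hi

    def test_repeated_value(self):
        mean, (lo, hi) = elo.fit_exponential_mle([2.0, 2.0, 2.0])
        assert mean == pytest.approx(2.0)
        assert lo < mean < hi

    def test_ci_covers_truth_for_exponential_draws(self):
        rng = np.random.default_rng(0)
        mean, (lo, hi) = elo.fit_exponential_mle(rng.exponential(0.5, 1000))
        assert lo <= 0.5 <= hi

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError):
            elo.fit_exponential_mle([1.0, 0.0])
        with pytest.raises(ConfigurationError):
            elo.fit_exponential_mle([1.0])

    def test_discretization_bias_low_and_correction(self):
        rng = np.random.default_rng(12)
        tau, dt = 0.3, 0.1
        x = rng.exponential(tau, 50_000)
        xd = np.maximum(1, np.floor(x / dt)) * dt
        raw, _ = elo.fit_exponential_mle(xd)
        corrected, _ = elo.fit_exponential_mle(xd, frame_rate=10)
        assert raw < tau  # floored dwells bias the plain MLE low
        assert tau - raw <= dt  # ...by at most one frame
        assert abs(corrected - tau) <= 0.2 * dt

    def test_pooled_state_lifetimes_recover_rates(self):
        m = model(q=(0.0,), nonrotated_rate=4.0, rotated_rate=1.5)
        traces = elo.simulate_traces(m, 10, 400, seed=6)
        fits = elo.pooled_state_lifetimes(traces, frame_rate=10).set_index("state")
        assert fits.loc[elo.NON_ROTATED, "lifetime_s"] == pytest.approx(0.25, rel=0.1)
        assert fits.loc[elo.ROTATED, "lifetime_s"] == pytest.approx(1 / 1.5, rel=0.1)

    def test_per_codon_mode_restricts_to_requested_codons(self):
        traces = elo.simulate_traces(model(q=(0.0,)), 10, 50, seed=7)
        fits = elo.pooled_state_lifetimes(traces, per_codon=True, codon_range=(3, 7))
        assert set(fits["codon"]) <= set(range(3, 8))


class TestTraceIO:
    def test_jsonl_roundtrip(self, tmp_path):
        traces = elo.simulate_traces(model(), 8, 20, seed=9)
        path = tmp_path / "traces.jsonl"
        assert elo.write_traces(traces, path) == 20
        back = elo.read_traces(path)
        assert [t.outcome for t in back] == [t.outcome for t in traces]
        assert back[0].dwells == traces[0].dwells


class TestRelativeAccumulation:
    def make_table(self, intensities):
        rows = []
        for species, series in intensities.items():
            for t, v in zip((60, 120, 180, 240, 300), series):
                rows.append({"species": species, "time_s": t, "intensity": v})
        return pd.DataFrame(rows)

    def test_identical_species_all_ratio_one(self):
        table = self.make_table({"tetra": [5, 5, 5, 5, 5], "hexa": [5, 5, 5, 5, 5]})
        ratios = elo.relative_accumulation(table, "tetra")
        assert ratios["tetra"] == pytest.approx(1.0)
        assert ratios["hexa"] == pytest.approx(1.0)

    def test_five_fold_accumulation_by_hand(self):
        # at the last three time points A carries 5x the normalized
        # intensity of B regardless of lane totals
        table = self.make_table({"A": [1, 1, 10, 20, 30], "B": [9, 9, 2, 4, 6]})
        ratios = elo.relative_accumulation(table, "B")
        assert ratios["A"] == pytest.approx(5.0)
        assert ratios["B"] == pytest.approx(1.0)

    def test_missing_time_point_raises_gap_error(self):
        table = self.make_table({"A": [1, 1, 1, 1, 1], "B": [1, 1, 1, 1, 1]})
        table = table[~((table.species == "B") & (table.time_s == 240))]
        with pytest.raises(GapError):
            elo.relative_accumulation(table, "A")

    def test_unknown_reference_rejected(self):
        table = self.make_table({"A": [1, 1, 1, 1, 1]})
        with pytest.raises(GapError):
            elo.relative_accumulation(table, "Z")


class TestQuantumYield:
    def test_identity_when_equal_to_reference(self):
        assert elo.relative_quantum_yield(2.0, 2.0, 1.33, 1.33, 0.925) == 0.925

    def test_linear_in_gradient(self):
        q1 = elo.relative_quantum_yield(1.0, 2.0, 1.33, 1.33, 0.9)
        q2 = elo.relative_quantum_yield(2.0, 2.0, 1.33, 1.33, 0.9)
        assert q2 == pytest.approx(2 * q1)

    def test_closed_form_value(self):
        q = elo.relative_quantum_yield(0.778, 1.0, 1.33, 1.33, 0.925)
        assert q == pytest.approx(0.7197, abs=5e-5)

    def test_bad_reference_rejected(self):
        with pytest.raises(ValueError):
            elo.relative_quantum_yield(1.0, 0.0, 1.33, 1.33, 0.9)
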