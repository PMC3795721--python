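"""Normalization, 2-sigma calling, concordance and quantitative binding."""

import numpy as np
import pandas as pd
import pytest

from dpiscreen import (
    BinderModel,
    NoiseModel,
    analyze_readout,
    call_positives,
    normalize_plate,
    quantify_binding,
    replicate_concordance,
    simulate_readout,
)
from dpiscreen.plate import all_wells


class TestNormalizePlate:
    def test_uniform_plate_normalizes_to_one(self):
        out = normalize_plate({f"A{i}": 0.5 for i in range(1, 11)})
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_hand_computed_example(self):
        out = normalize_plate({"A1": 1.0, "A2": 1.0, "A3": 4.0})
        assert out == pytest.approx({"A1": 0.5, "A2": 0.5, "A3": 2.0})

    def test_mean_is_one_for_random_plates(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            values = {w: float(v) for w, v in
                      zip(all_wells(), rng.uniform(0.01, 3.0, 384))}
            out = normalize_plate(values)
            assert np.mean(list(out.values())) == pytest.approx(1.0)

    def test_degenerate_plates_raise(self):
        with pytest.raises(ValueError):
            normalize_plate({"A1": 0.0, "A2": 0.0})
        with pytest.raises(ValueError):
            normalize_plate({"A1": 1.0})


class TestCallPositives:
    def test_two_strong_wells_are_the_only_positives(self):
        values = {w: 1.0 for w in all_wells()}
        values["B2"] = 3.0
        values["C3"] = 3.0
        norm = normalize_plate(values)
        result = call_positives(norm)
        assert norm["B2"] > result.threshold  # sd is small, 3.0 clears 2-sigma
        assert result.positives == ["B2", "C3"]

    def test_constant_plate_yields_no_positives(self):
        with pytest.warns(UserWarning):
            result = call_positives({f"A{i}": 1.0 for i in range(1, 21)})
        assert result.positives == []
        assert result.sigma == 0.0

    def test_ranking_is_total_with_well_order_tie_break(self):
        norm = {"A2": 1.0, "A1": 1.0, "B1": 2.0, "A10": 0.5}
        result = call_positives(norm)
        assert result.ranking == ["B1", "A1", "A2", "A10"]

    def test_scale_invariance_of_threshold_and_calls(self):
        rng = np.random.default_rng(2)
        raw = {w: float(v) for w, v in zip(all_wells(), rng.uniform(0.05, 1.0, 384))}
        res1 = call_positives(normalize_plate(raw))
        res5 = call_positives(normalize_plate({w: 5.0 * v for w, v in raw.items()}))
        assert res1.threshold == pytest.approx(res5.threshold)
        assert res1.positives == res5.positives
        assert res1.ranking == res5.ranking

    def test_raising_a_well_never_removes_it_from_positives(self):
        rng = np.random.default_rng(3)
        raw = {w: float(v) for w, v in zip(all_wells(), rng.normal(1.0, 0.1, 384))}
        for bump in (1.5, 2.0, 4.0, 8.0):
            raw_b = dict(raw)
            raw_b["H17"] = raw["H17"] * bump
            result = call_positives(normalize_plate(raw_b))
            if "H17" in result.positives:
                for more in (2.0, 10.0):
                    raw_c = dict(raw_b)
                    raw_c["H17"] *= more
                    assert "H17" in call_positives(normalize_plate(raw_c)).positives
                break
        else:
            pytest.fail("bumped well never became positive")

    def test_noise_free_binder_positives_match_consensus_windows(
        self, default_library, default_layout
    ):
        from dpiscreen.core import forward_windows, iupac_match, reverse_complement

        binder = BinderModel(consensus="TTGACY")
        readout = simulate_readout(default_layout, binder, NoiseModel(sd=0.0))
        result = analyze_readout(readout, default_layout)
        expected = set()
        for p in default_library.probes:
            for w in forward_windows(p.variable_region, 6):
                if iupac_match("TTGACY", w) or iupac_match(
                    "TTGACY", reverse_complement(w)
                ):
                    expected.add(default_layout.well_of(p.probe_id))
        assert set(result.positives) == expected


class TestReplicateConcordance:
    def test_identical_replicates_correlate_perfectly(self, default_layout):
        binder = BinderModel(consensus="TTGACY")
        readout = simulate_readout(default_layout, binder, NoiseModel(sd=0.0))
        result = analyze_readout(readout, default_layout)
        r, reproducible = replicate_concordance(result, result)
        assert r == pytest.approx(1.0)
        assert reproducible == sorted(result.positives, key=lambda w: (w[0],
                                                                       int(w[1:])))

    def test_noisy_replicates_fall_in_predicted_band(self, default_layout):
        # with signal sd_s across wells and independent noise sd_n per
        # replicate, expected r ~ var_s / (var_s + var_n)
        binder = BinderModel(consensus="TTGACY")
        clean = simulate_readout(default_layout, binder, NoiseModel(sd=0.0))
        arr = np.array(list(clean.values.values()))
        var_s = arr.var()
        sd_n = 0.05
        expected_r = var_s / (var_s + sd_n**2)
        rs = []
        for seed in range(5):
            ra = analyze_readout(
                simulate_readout(default_layout, binder, NoiseModel(sd=sd_n,
                                                                    seed=seed)),
                default_layout,
            )
            rb = analyze_readout(
                simulate_readout(default_layout, binder,
                                 NoiseModel(sd=sd_n, seed=100 + seed)),
                default_layout,
            )
            rs.append(replicate_concordance(ra, rb)[0])
        assert np.mean(rs) == pytest.approx(expected_r, abs=0.05)

    def test_too_few_shared_wells(self):
        a = call_positives({"A1": 1.0, "A2": 1.1})
        b = call_positives({"A1": 1.0, "A3": 1.1})
        with pytest.raises(ValueError):
            replicate_concordance(a, b)


class TestQuantifyBinding:
    @staticmethod
    def table():
        return pd.DataFrame(
            {
                "rep1": {"probe38": 1.0, "probe38m": 0.8, "empty1": 1.0,
                         "empty2": 1.0},
                "rep2": {"probe38": 1.0, "probe38m": 1.2, "empty1": 1.0,
                         "empty2": 1.0},
            }
        )

    def test_reference_probe_is_100_percent(self):
        result = quantify_binding(self.table(), ["empty1", "empty2"], "probe38")
        row = result.table.set_index("probe").loc["probe38"]
        assert row["relative_binding_pct"] == pytest.approx(100.0)

    def test_empty_vector_normalizes_to_one(self):
        result = quantify_binding(self.table(), ["empty1", "empty2"], "probe38")
        row = result.table.set_index("probe").loc["empty1"]
        assert row["normalized_abs"] == pytest.approx(1.0)

    def test_half_range_error_for_two_replicates(self):
        result = quantify_binding(self.table(), ["empty1", "empty2"], "probe38")
        row = result.table.set_index("probe").loc["probe38m"]
        assert row["relative_binding_pct"] == pytest.approx(100.0)
        assert row["abs_error_pct"] == pytest.approx(20.0)

    def test_max_deviation_error_for_three_replicates(self):
        df = pd.DataFrame(
            {
                "rep1": {"p": 0.7, "empty": 1.0},
                "rep2": {"p": 1.0, "empty": 1.0},
                "rep3": {"p": 1.0, "empty": 1.0},
            }
        )
        result = quantify_binding(df, ["empty"], "p")
        row = result.table.set_index("probe").loc["p"]
        assert row["abs_error_pct"] == pytest.approx(
            np.abs(np.array([0.7, 1.0, 1.0]) / 0.9 - 1.0).max() * 100
        )

    def test_missing_reference_or_controls(self):
        with pytest.raises(ValueError):
            quantify_binding(self.table(), ["empty1"], "nope")
        with pytest.raises(ValueError):
            quantify_binding(self.table(), ["missing"], "probe38")
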