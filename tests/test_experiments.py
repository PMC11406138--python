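"""Grid designs, aggregation arithmetic and repolarisation failure."""

import math

import numpy as np
import pandas as pd
import pytest

from popneuron._engine import ModelRunner
from popneuron.experiments import (GridDesign, GridResult,
                                   collapse_over_conductance,
                                   detect_repolarisation_failure,
                                   four_parameter_design, mean_firing_rate,
                                   rapid_firing_split, run_grid)
from popneuron.population import (SamplingRanges, build_population,
                                  evaluate_candidate)
from popneuron.protocols import step_protocol
from popneuron.synthetic import (SyntheticSpikeSpec, generate_trace,
                                 synthetic_calibration_ranges)
from popneuron.trace import Trace


@pytest.fixture(scope="module")
def toy_population(toy_model, fast_protocols):
    centre = evaluate_candidate(toy_model, {}, fast_protocols)
    calibration = synthetic_calibration_ranges(centre, rel_sd=0.3)
    ranges = SamplingRanges.uniform(toy_model.current_names, 0.7, 1.3)
    pop = build_population(toy_model, ranges, calibration, n_candidates=10,
                           seed=4, protocols=fast_protocols)
    assert len(pop) >= 2
    return pop


def fake_result(table: pd.DataFrame, design: GridDesign, population) -> GridResult:
    return GridResult(table=table, design=design, population=population)


class TestDesignBookkeeping:
    def test_four_parameter_design_has_875_cells(self):
        design = four_parameter_design()
        assert design.n_cells == 875  # 7 amplitudes x 5 x 5 x 5 scalings
        cells = design.cells()
        assert len(cells) == 875
        assert len({tuple(sorted(c.items())) for c in cells}) == 875
        amps = {c["amp_pA"] for c in cells}
        assert amps == {0.0, 1000.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0}
        for name in ("Nav1.8", "Kdr", "KM"):
            assert {c[name] for c in cells} == {0.0, 0.5, 1.0, 1.5, 2.0}

    def test_design_size_is_product_of_level_counts(self):
        design = GridDesign(scalings={"a": [0.0, 1.0, 2.0], "b": [1.0, 2.0]},
                            amplitudes=[100.0, 200.0])
        assert design.n_cells == 3 * 2 * 2


class TestAggregation:
    def make_two_model_result(self):
        design = GridDesign(scalings={"g": [0.5, 1.0]},
                            amplitudes=[100.0, 200.0])
        rows = []
        rates = {(0.5, 100.0): (10.0, 20.0), (0.5, 200.0): (0.0, 0.0),
                 (1.0, 100.0): (30.0, 10.0), (1.0, 200.0): (5.0, 15.0)}
        for (g, amp), (r1, r2) in rates.items():
            for mid, rate in ((0, r1), (1, r2)):
                rows.append({"model_id": mid, "amp_pA": amp, "g": g,
                             "firing_rate": rate, "half_width": 1.0,
                             "repol_failure": False, "failed": False})
        pop = type("P", (), {"params": pd.DataFrame({"g": [1.0, 1.0]},
                                                    index=[0, 1])})
        return fake_result(pd.DataFrame(rows), design, pop)

    def test_mean_firing_rate_matches_brute_force(self):
        result = self.make_two_model_result()
        means = mean_firing_rate(result)
        lookup = {(row["g"], row["amp_pA"]): row["firing_rate"]
                  for _, row in means.iterrows()}
        assert lookup[(0.5, 100.0)] == pytest.approx(15.0)
        assert lookup[(1.0, 100.0)] == pytest.approx(20.0)
        assert lookup[(1.0, 200.0)] == pytest.approx(10.0)

    def test_failed_models_excluded_from_cell_mean(self):
        result = self.make_two_model_result()
        tab = result.table
        tab.loc[(tab["model_id"] == 0) & (tab["amp_pA"] == 100.0)
                & (tab["g"] == 0.5), "failed"] = True
        means = mean_firing_rate(result)
        row = means[(means["g"] == 0.5) & (means["amp_pA"] == 100.0)].iloc[0]
        assert row["firing_rate"] == pytest.approx(20.0)  # model 1 only
        assert row["n_models"] == 1

    def test_collapse_over_conductance_2x2(self):
        result = self.make_two_model_result()
        curve = collapse_over_conductance(result, "g", over_amplitude=False)
        lookup = dict(zip(curve["amp_pA"], curve["firing_rate"]))
        assert lookup[100.0] == pytest.approx((15.0 + 20.0) / 2)
        assert lookup[200.0] == pytest.approx((0.0 + 10.0) / 2)
        total = collapse_over_conductance(result, "g", over_amplitude=True)
        assert total["firing_rate"].iloc[0] == pytest.approx(
            np.mean([15.0, 0.0, 20.0, 10.0]))

    def test_collapse_single_level_is_identity(self):
        design = GridDesign(scalings={"g": [1.0], "h": [0.5, 1.5]},
                            amplitudes=[100.0])
        rows = [{"model_id": 0, "amp_pA": 100.0, "g": 1.0, "h": h,
                 "firing_rate": r, "half_width": 1.0, "repol_failure": False,
                 "failed": False} for h, r in ((0.5, 4.0), (1.5, 8.0))]
        pop = type("P", (), {"params": pd.DataFrame(index=[0])})
        res = fake_result(pd.DataFrame(rows), design, pop)
        curve = collapse_over_conductance(res, "g", over_amplitude=True)
        assert dict(zip(curve["h"], curve["firing_rate"])) == {0.5: 4.0, 1.5: 8.0}


class TestRapidFiringSplit:
    def make_counts_result(self, counts):
        """One-conductance design where model i exceeds 20 AP/s in counts[i] cells."""
        n_cells = max(counts) + 1
        design = GridDesign(scalings={"g": [1.0]},
                            amplitudes=[float(100 * (k + 1)) for k in range(n_cells)])
        rows = []
        for mid, c in enumerate(counts):
            for cell in range(n_cells):
                rows.append({"model_id": mid, "amp_pA": float(100 * (cell + 1)),
                             "g": 1.0, "firing_rate": 25.0 if cell < c else 1.0,
                             "half_width": 1.0, "repol_failure": False,
                             "failed": False})
        params = pd.DataFrame({"g": np.linspace(0.5, 1.5, len(counts))},
                              index=range(len(counts)))
        pop = type("P", (), {"params": params})
        return fake_result(pd.DataFrame(rows), design, pop)

    def test_hand_ranking(self):
        result = self.make_counts_result([5, 4, 3, 2, 1, 0, 0, 0])
        top, rest, stats = rapid_firing_split(result)
        assert top == [0, 1]  # ceil(0.25 * 8) = 2
        assert rest == [2, 3, 4, 5, 6, 7]

    def test_tie_break_by_stable_model_order(self):
        result = self.make_counts_result([3, 3, 3, 3])
        top, rest, _ = rapid_firing_split(result)
        assert top == [0] and rest == [1, 2, 3]

    def test_group_means_match_brute_force(self):
        result = self.make_counts_result([5, 4, 3, 2, 1, 0, 0, 0])
        top, rest, stats = rapid_firing_split(result)
        params = result.population.params
        rapid_mean = stats[(stats["group"] == "rapid")
                           & (stats["conductance"] == "g")]["mean"].iloc[0]
        assert rapid_mean == pytest.approx(params.loc[top, "g"].mean())


class TestRepolarisationFailure:
    def test_locked_depolarised_trace(self):
        proto = step_protocol(amplitude=500.0, delay=100.0, duration=800.0)
        t = np.arange(0.0, 1200.0, 0.05)
        v = np.where(t < 150.0, -65.0, 10.0)  # crosses up at 150, never back
        assert detect_repolarisation_failure(Trace(t=t, v=v), proto) is True

    def test_normal_spiking_trace(self):
        proto = step_protocol(amplitude=500.0, delay=100.0, duration=800.0,
                              t_stop=1500.0)
        spec = SyntheticSpikeSpec(spike_times=(200.0, 500.0, 800.0),
                                  t_stop=1500.0)
        trace, _ = generate_trace(spec, protocol=proto)
        assert detect_repolarisation_failure(trace, proto) is False

    def test_no_ap_trace(self):
        proto = step_protocol(amplitude=100.0, delay=100.0, duration=800.0)
        t = np.arange(0.0, 1200.0, 0.05)
        assert detect_repolarisation_failure(
            Trace(t=t, v=np.full_like(t, -65.0)), proto) is False

    def test_potassium_blocked_toy_model_fails_to_repolarise(self, toy_model):
        """Blocking K currents produces depolarisation block under drive."""
        proto = step_protocol(amplitude=2000.0, delay=20.0, duration=200.0,
                              t_stop=250.0)
        blocked = toy_model.scaled({"Kdr": 0.0, "leak": 0.2})
        trace = ModelRunner(blocked).run(proto)
        assert detect_repolarisation_failure(trace, proto) is True
        normal = ModelRunner(toy_model).run(proto)
        assert detect_repolarisation_failure(normal, proto) is False


class TestRunGrid:
    def test_single_cell_at_rheobase_fires(self, toy_population, toy_model,
                                           fast_protocols):
        """At each model's own rheobase every accepted model fires >= 1 AP."""
        pop = toy_population
        proto = fast_protocols.step
        model_id = pop.params.index[0]
        amp = pop.biomarkers.loc[model_id, "rheobase"]
        design = GridDesign(
            scalings={n: [1.0] for n in toy_model.current_names},
            amplitudes=[float(amp)], protocol=proto)
        res = run_grid(pop, toy_model, design)
        row = res.table[res.table["model_id"] == model_id].iloc[0]
        assert row["firing_rate"] >= 1.0 / (proto.duration / 1000.0) - 1e-9

    def test_scaling_composition_exact(self, toy_population, toy_model,
                                       fast_protocols):
        """Cell factor f on stored factor s equals direct factor f*s."""
        pop = toy_population
        model_id = pop.params.index[0]
        factors = pop.params.loc[model_id].to_dict()
        proto = fast_protocols.step.with_amplitude(400.0)
        f = 0.8
        via_grid = toy_model.scaled(factors, compose=False).scaled(
            {"NaT": f}, compose=True)
        direct_factors = dict(factors)
        direct_factors["NaT"] *= f
        direct = toy_model.scaled(direct_factors, compose=False)
        tr1 = ModelRunner(via_grid).run(proto)
        tr2 = ModelRunner(direct).run(proto)
        assert np.array_equal(tr1.v, tr2.v)

    def test_grid_order_and_workers_invariant(self, toy_population, toy_model,
                                              fast_protocols):
        design = GridDesign(scalings={"NaT": [0.8, 1.2]},
                            amplitudes=[300.0, 600.0],
                            protocol=fast_protocols.step)
        serial = run_grid(toy_population, toy_model, design, n_jobs=1)
        parallel = run_grid(toy_population, toy_model, design, n_jobs=2)
        pd.testing.assert_frame_equal(serial.table, parallel.table)

    def test_sodium_block_cell_reduces_firing(self, toy_population, toy_model,
                                              fast_protocols):
        design = GridDesign(scalings={"NaT": [0.0, 1.0]},
                            amplitudes=[600.0], protocol=fast_protocols.step)
        result = run_grid(toy_population, toy_model, design)
        means = mean_firing_rate(result)
        rate = dict(zip(means["NaT"], means["firing_rate"]))
        assert rate[1.0] > 0.0
        assert rate[0.0] < rate[1.0]
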