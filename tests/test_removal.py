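import math

import numpy as np
import pytest

from swdreduce import (
    CellPair,
    DesignConfig,
    build_complete_sw,
    enumerate_pairs,
    remove_pair,
    run_removal,
    select_min_pair,
    ic_map,
)

from .oracles import stacked_gls_variance


class TestTraceStructure:
    def test_exchangeable_trace_runs_to_the_four_cell_design(self, trial_4x5_exchangeable_trace):
        """20 cells down to the minimally viable 4-cell design in 8 removals."""
        trace = trial_4x5_exchangeable_trace
        assert len(trace) == 9
        counts = [s.design.n_observed for s in trace.steps]
        assert counts == list(range(20, 3, -2))
        assert trace.steps[0].design.observed.all()
        assert trace.final_design.n_observed == 4

    def test_first_removal_is_distant_from_the_switch(self, trial_4x5_exchangeable_trace):
        """The lowest-IC pair of the complete exchangeable design is
        {(1,4),(4,2)} — cells far from their clusters' treatment switches
        leave first, while switch-adjacent and corner cells persist."""
        assert trial_4x5_exchangeable_trace.steps[0].removed_pair == CellPair((1, 4), (4, 2))

    def test_middle_pair_is_removed_last(self, trial_4x5_exchangeable_trace):
        trace = trial_4x5_exchangeable_trace
        six = trace.steps[7].design
        assert six.n_observed == 6
        assert trace.steps[7].removed_pair == CellPair((2, 3), (3, 3))

    def test_consecutive_designs_differ_by_one_pair(self, trial_4x5_decay_trace):
        for a, b in zip(trial_4x5_decay_trace.steps, trial_4x5_decay_trace.steps[1:]):
            diff = a.design.observed & ~b.design.observed
            assert diff.sum() == 2
            assert np.array_equal(diff, diff[::-1, ::-1])

    def test_every_design_keeps_structural_invariants(self, large_decay_trace):
        for step in large_decay_trace.steps:
            assert step.design.is_centrosymmetric()
            assert step.design.is_skew_symmetric()

    def test_variances_and_precision_loss_non_decreasing(
        self, trial_4x5_exchangeable_trace, trial_4x5_decay_trace, large_decay_trace
    ):
        for trace in (trial_4x5_exchangeable_trace, trial_4x5_decay_trace, large_decay_trace):
            v = trace.variances
            assert np.all(np.diff(v) >= -1e-12 * v[:-1])
            loss = [s.precision_loss_pct for s in trace.steps]
            assert np.all(np.diff(loss) >= -1e-9)

    def test_two_period_design_is_not_estimable(self):
        """T=2 leaves two cell means for three fixed effects; the complete
        design cannot estimate the treatment effect at all."""
        from swdreduce import ConfigurationError

        with pytest.raises(ConfigurationError):
            run_removal(DesignConfig(T=2, m=10, rho=0.1))

    def test_smallest_reducible_design_has_three_periods(self):
        trace = run_removal(DesignConfig(T=3, m=10, rho=0.05))
        assert len(trace) == 3
        assert trace.final_design.n_observed == 2
        assert trace.steps[-1].removed_pair is None

    def test_deterministic(self, trial_4x5_decay):
        a = run_removal(trial_4x5_decay).to_frame()
        b = run_removal(trial_4x5_decay).to_frame()
        assert a.equals(b)


class TestGreedySelection:
    def test_selected_pair_attains_brute_force_minimum(self, trial_4x5_exchangeable_trace):
        """At every iteration the removed pair's IC matches the minimum over
        an independent recomputation of each candidate's variance ratio."""
        config = trial_4x5_exchangeable_trace.config
        for step in trial_4x5_exchangeable_trace.steps[:-1]:
            design = step.design
            base = stacked_gls_variance(design, config)
            brute = {}
            for pair in enumerate_pairs(design):
                try:
                    brute[pair] = stacked_gls_variance(remove_pair(design, pair), config) / base
                except np.linalg.LinAlgError:
                    brute[pair] = math.inf
            finite = {p: v for p, v in brute.items() if v < 1e12}
            assert step.icmap.pair_ic[step.removed_pair] == pytest.approx(
                min(finite.values()), rel=1e-9
            )

    def test_tie_break_prefers_smallest_cluster_then_period(self, trial_4x5_exchangeable):
        """Pairs {(2,1),(3,5)} and {(2,5),(3,1)} tie exactly by symmetry of
        the exchangeable structure; the smaller (cluster, period) wins."""
        design = build_complete_sw(trial_4x5_exchangeable)
        icm = ic_map(design, trial_4x5_exchangeable)
        tied = [CellPair((2, 5), (3, 1)), CellPair((2, 1), (3, 5))]
        assert icm.pair_ic[tied[0]] == pytest.approx(icm.pair_ic[tied[1]], rel=1e-10)
        assert select_min_pair(icm, tied) == CellPair((2, 1), (3, 5))

    def test_single_finite_pair_is_selected(self):
        from swdreduce import ICMap

        a, b = CellPair((1, 1), (2, 3)), CellPair((1, 2), (2, 2))
        icm = ICMap(np.full((2, 3), np.nan), 1.0, {a: math.inf, b: 2.0})
        assert select_min_pair(icm, [a, b]) == b

    def test_strictly_smaller_ic_wins_regardless_of_position(self, trial_4x5_decay):
        design = build_complete_sw(trial_4x5_decay)
        icm = ic_map(design, trial_4x5_decay)
        ics = icm.pair_ic
        strict_min = min(ics.values())
        chosen = select_min_pair(icm, list(ics))
        assert ics[chosen] <= strict_min * (1 + 1e-9)

    def test_all_infinite_signals_termination(self, trial_4x5_exchangeable_trace):
        final_step = trial_4x5_exchangeable_trace.steps[-1]
        pairs = list(final_step.icmap.pair_ic)
        assert pairs  # pairs remain, but none is removable
        assert select_min_pair(final_step.icmap, pairs) is None


class TestLargeDesign:
    def test_midpoint_design_resembles_a_staircase(self, large_decay_trace):
        """After 23 removals (51.11% of cells) measurements concentrate in a
        band around each cluster's treatment switch."""
        step = large_decay_trace.step_at_removed_pairs(23)
        design = step.design
        assert design.n_observed == 44
        assert design.pct_removed == pytest.approx(51.11, abs=0.005)
        # every cluster still observes at least one cell adjacent to its switch
        for k in range(1, design.K + 1):
            switch_cols = [k - 1, k]  # 0-based periods k and k+1
            assert design.observed[k - 1, switch_cols].any()

    def test_trace_export_columns(self, large_decay_trace):
        frame = large_decay_trace.to_frame()
        assert list(frame.columns) == [
            "iteration",
            "removed_cluster",
            "removed_period",
            "partner_cluster",
            "partner_period",
            "n_cells_remaining",
            "pct_removed",
            "variance",
            "precision_loss_pct",
            "power_pct",
        ]
        assert frame["iteration"].tolist() == list(range(len(large_decay_trace)))
        assert frame["removed_cluster"].isna().tolist() == [False] * (len(frame) - 1) + [True]

    def test_json_bundle_round_trips_designs(self, trial_4x5_exchangeable_trace):
        import json

        from swdreduce import Design

        bundle = json.loads(json.dumps(trial_4x5_exchangeable_trace.to_dict()))
        assert len(bundle["steps"]) == len(trial_4x5_exchangeable_trace)
        d = Design.from_dict(bundle["steps"][-1]["design"])
        assert d.n_observed == 4
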