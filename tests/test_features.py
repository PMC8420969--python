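"""Feature extraction: arcsinh medians, frequencies, responses, assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import immunoclock as ic
from immunoclock.errors import (
    EmptyPopulationError,
    IncompleteSampleError,
    UndefinedFrequencyError,
)
from immunoclock.panel import DEFAULT_PANEL, PROTEINS, STIMULI, UNSTIM

from conftest import make_events


class TestArcsinhMedian:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0, 0, 0], 0.0),
            ([5, 5, 5], math.log(1 + math.sqrt(2))),  # asinh(1)
            ([10, 20, 30], math.log(4 + math.sqrt(17))),  # asinh(4)
        ],
    )
    def test_closed_form(self, values, expected):
        assert ic.arcsinh_median(values) == pytest.approx(expected, abs=1e-9)

    def test_even_length_median_is_midpoint(self):
        # median of [10, 20] is 15 -> asinh(3)
        assert ic.arcsinh_median([20, 10]) == pytest.approx(np.arcsinh(3.0))

    def test_empty_population_raises(self):
        with pytest.raises(EmptyPopulationError):
            ic.arcsinh_median([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e4), min_size=1, max_size=30),
        st.floats(0.5, 50),
    )
    def test_scale_equivariance(self, values, cofactor):
        """Doubling the cofactor and all intensities leaves the value fixed."""
        a = ic.arcsinh_median(values, cofactor=cofactor)
        b = ic.arcsinh_median([2 * v for v in values], cofactor=2 * cofactor)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


class TestFrequency:
    def _mono_mix(self):
        rows = [("s1", UNSTIM, "cMC", {})] * 4 + [("s1", UNSTIM, "B_naive", {})] * 4
        return rows

    def test_mononuclear_denominator(self):
        ev = make_events(self._mono_mix())
        assert ic.compute_frequency(ev, "s1", "cMC") == pytest.approx(50.0)

    def test_granulocyte_uses_leukocyte_denominator(self):
        # 2 granulocytes among 10 leukocytes (8 mononuclear)
        rows = [("s1", UNSTIM, "granulocytes", {})] * 2 + self._mono_mix()
        ev = make_events(rows)
        assert ic.compute_frequency(ev, "s1", "granulocytes") == pytest.approx(20.0)
        # mononuclear subsets are unaffected by the granulocytes
        assert ic.compute_frequency(ev, "s1", "cMC") == pytest.approx(50.0)

    def test_absent_subset_is_zero(self):
        ev = make_events(self._mono_mix())
        assert ic.compute_frequency(ev, "s1", "Treg") == 0.0

    def test_zero_denominator_raises(self):
        ev = make_events([("s1", UNSTIM, "granulocytes", {})])
        with pytest.raises(UndefinedFrequencyError):
            ic.compute_frequency(ev, "s1", "Treg")  # no mononuclear events

    def test_stimulated_events_are_ignored(self):
        ev = make_events(self._mono_mix() + [("s1", "LPS", "cMC", {})] * 50)
        assert ic.compute_frequency(ev, "s1", "cMC") == pytest.approx(50.0)


class TestBasalAndResponse:
    def test_basal_constant_five(self):
        ev = make_events([("s1", UNSTIM, "cMC", {"pS6": 5.0})] * 3)
        assert ic.compute_basal(ev, "s1", "cMC", "pS6") == pytest.approx(
            0.881374, abs=1e-5
        )

    def test_basal_ignores_stimulated_conditions(self):
        rows = [("s1", UNSTIM, "cMC", {"pS6": 5.0})] * 3
        ev1 = make_events(rows)
        ev2 = make_events(rows + [("s1", "IFNa", "cMC", {"pS6": 500.0})] * 5)
        assert ic.compute_basal(ev1, "s1", "cMC", "pS6") == ic.compute_basal(
            ev2, "s1", "cMC", "pS6"
        )

    def test_response_difference_and_antisymmetry(self):
        def build(lo, hi):
            return make_events(
                [("s1", UNSTIM, "cMC", {"pS6": lo})] * 3
                + [("s1", "LPS", "cMC", {"pS6": hi})] * 3
            )

        up = ic.compute_response(build(5, 15), "s1", "cMC", "pS6", "LPS")
        down = ic.compute_response(build(15, 5), "s1", "cMC", "pS6", "LPS")
        assert up == pytest.approx(0.937072, abs=1e-5)
        assert down == pytest.approx(-up, abs=1e-12)

    def test_identical_distributions_give_zero(self):
        ev = make_events(
            [("s1", UNSTIM, "cMC", {"pS6": 7.0})] * 4
            + [("s1", "IL", "cMC", {"pS6": 7.0})] * 4
        )
        assert ic.compute_response(ev, "s1", "cMC", "pS6", "IL") == 0.0


def _complete_sample(sample_id, n_per_condition=2):
    rows = []
    for cond in (UNSTIM,) + STIMULI:
        for subset in DEFAULT_PANEL.subsets:
            rows += [(sample_id, cond, subset, {"pS6": 5.0})] * n_per_condition
    return rows


class TestAssemble:
    def test_feature_counts_default_mask(self):
        ev = make_events(_complete_sample("s1") + _complete_sample("s2"))
        fm = ic.assemble_features(ev)
        classes = fm.classes().value_counts()
        assert classes["frequency"] == 34
        assert classes["basal"] == 34 * 11
        mask = ic.default_penalization_mask()
        assert classes["response"] == sum(mask.values())

    def test_all_allowed_mask_emits_full_grid(self):
        ev = make_events(_complete_sample("s1"))
        mask = {k: True for k in ic.default_penalization_mask()}
        fm = ic.assemble_features(ev, mask=mask)
        assert (fm.classes() == "response").sum() == 34 * 11 * 3
        # disallowing k triples removes exactly k response features
        k = 17
        for key in list(mask)[:k]:
            mask[key] = False
        fm2 = ic.assemble_features(ev, mask=mask)
        assert (fm2.classes() == "response").sum() == 34 * 11 * 3 - k

    def test_missing_condition_raises_with_sample_listed(self):
        rows = _complete_sample("s1")
        rows += [("s2", UNSTIM, "cMC", {})]  # s2 lacks stimulated conditions
        with pytest.raises(IncompleteSampleError, match="s2"):
            ic.assemble_features(make_events(rows))

    def test_column_order_deterministic_and_mask_sample_independent(self):
        ev1 = make_events(_complete_sample("s1") + _complete_sample("s2"))
        ev2 = make_events(_complete_sample("s2") + _complete_sample("s1"))
        fm1, fm2 = ic.assemble_features(ev1), ic.assemble_features(ev2)
        assert fm1.feature_ids == fm2.feature_ids

    def test_oracle_equivalence_on_toy(self):
        """Every assembled value matches a naive per-feature recomputation."""
        rng = np.random.default_rng(7)
        rows = []
        for sid in ("a", "b", "c"):
            for cond in (UNSTIM,) + STIMULI:
                for subset in DEFAULT_PANEL.subsets:
                    for _ in range(3):
                        rows.append(
                            (sid, cond, subset,
                             {p: rng.uniform(0, 30) for p in PROTEINS})
                        )
        ev = make_events(rows)
        fm = ic.assemble_features(ev)
        defs = fm.defs
        for fid in rng.choice(fm.feature_ids, size=40, replace=False):
            d = defs.loc[fid]
            if d["feature_class"] == "frequency":
                expected = ic.compute_frequency(ev, "b", d["cell_type"])
            elif d["feature_class"] == "basal":
                expected = ic.compute_basal(ev, "b", d["cell_type"], d["protein"])
            else:
                expected = ic.compute_response(
                    ev, "b", d["cell_type"], d["protein"], d["stimulus"]
                )
            assert fm.values.loc["b", fid] == pytest.approx(expected, abs=1e-9)

    def test_frequency_closure_of_mononuclear_subsets(self):
        ev = make_events(_complete_sample("s1", n_per_condition=3))
        fm = ic.assemble_features(ev)
        mono = [
            f"freq_{s}" for s in DEFAULT_PANEL.subsets if s != "granulocytes"
        ]
        assert fm.values.loc["s1", mono].sum() == pytest.approx(100.0)

    def test_empty_population_yields_missing_then_policy(self):
        # Treg present for s1 but absent for s2 in all conditions
        rows = _complete_sample("s1")
        rows += [
            r for r in _complete_sample("s2") if r[2] != "Treg" or r[1] != UNSTIM
        ]
        fm = ic.assemble_features(make_events(rows), max_missing_frac=0.6)
        # basal Treg features missing for s2 -> imputed from s1 median
        assert "basal_Treg_pS6" in fm.imputed
        fm2 = ic.assemble_features(make_events(rows), max_missing_frac=0.2)
        assert "basal_Treg_pS6" in fm2.dropped
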