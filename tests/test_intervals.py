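"""Intervals' method binning, convergence, and Box-Cox pre-processing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from taloco.fea import StressField
from taloco.intervals import (
    FeatureMatrix,
    boxcox_center_scale,
    choose_intervals,
    default_ft_upper,
    interval_profile,
    profiles_to_frame,
)
from taloco.synthetic import SynthConfig, simulate_stress_field


class TestIntervalProfile:
    def test_binning_hand_example(self):
        fld = StressField(sigma=[0.5, 1.5, 2.5], vol=[1.0, 1.0, 2.0])
        prof = interval_profile(fld, FT_upper=3.0, N=3)
        assert prof.values == pytest.approx([25.0, 25.0, 50.0])

    def test_all_below_first_edge(self):
        fld = StressField(sigma=[0.1, 0.2], vol=[1.0, 3.0])
        prof = interval_profile(fld, FT_upper=10.0, N=5)
        assert prof.values == pytest.approx([100.0, 0, 0, 0, 0])

    def test_overflow_accumulates_in_top_interval(self):
        fld = StressField(sigma=[1.0, 50.0], vol=[1.0, 1.0])
        prof = interval_profile(fld, FT_upper=10.0, N=5)
        assert prof.values[-1] == pytest.approx(50.0)
        assert prof.values.sum() == pytest.approx(100.0)

    def test_discard_variant_drops_overflow(self):
        fld = StressField(sigma=[1.0, 50.0], vol=[1.0, 1.0])
        prof = interval_profile(fld, FT_upper=10.0, N=5, discard_above=True)
        assert prof.values.sum() == pytest.approx(50.0)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_order_invariance(self, data):
        n = data.draw(st.integers(1, 12))
        sigma = np.array(
            data.draw(st.lists(st.floats(0, 20, allow_nan=False), min_size=n, max_size=n))
        )
        vol = np.array(data.draw(st.lists(st.floats(0.1, 5), min_size=n, max_size=n)))
        fld = StressField(sigma=sigma, vol=vol)
        prof = interval_profile(fld, FT_upper=7.0, N=6)
        assert prof.values.sum() == pytest.approx(100.0, abs=1e-9)
        perm = np.random.default_rng(0).permutation(n)
        prof2 = interval_profile(StressField(sigma=sigma[perm], vol=vol[perm]), 7.0, 6)
        assert prof.values == pytest.approx(prof2.values)
        doubled = interval_profile(StressField(sigma=sigma, vol=2 * vol), 7.0, 6)
        assert prof.values == pytest.approx(doubled.values)

    def test_nested_bins_collapse_exactly(self, rng):
        fld = StressField(sigma=rng.uniform(0, 12, 40), vol=rng.uniform(0.1, 3, 40))
        fine = interval_profile(fld, FT_upper=10.0, N=8).values
        coarse = interval_profile(fld, FT_upper=10.0, N=4).values
        assert fine.reshape(4, 2).sum(axis=1) == pytest.approx(coarse)


class TestChooseIntervals:
    def make_fields(self, seed, n=8):
        cfg = SynthConfig(n_elements=200, seed=seed)
        groups = ["leaper", "arboreal_quadruped", "clamber_suspensory"]
        return [
            simulate_stress_field(groups[i % 3], cfg, 1000 + seed * 100 + i, f"s{i}")
            for i in range(n)
        ]

    def test_identical_fields_return_first_candidate(self):
        fld = StressField(sigma=[1.0, 2.0], vol=[1.0, 1.0])
        fields = [StressField(sigma=fld.sigma, vol=fld.vol, specimen_id=str(i)) for i in range(4)]
        assert choose_intervals(fields, 5.0, (4, 8, 16)) == 4

    def test_deterministic_given_seed(self):
        a = choose_intervals(self.make_fields(3), 20.0, (5, 10, 15, 25, 50))
        b = choose_intervals(self.make_fields(3), 20.0, (5, 10, 15, 25, 50))
        assert a == b

    def test_zero_tolerance_never_converges(self):
        fields = self.make_fields(5)
        with pytest.warns(UserWarning):
            n = choose_intervals(fields, 20.0, (5, 10, 15), tol=0.0)
        assert n == 15

    def test_requires_two_candidates(self):
        with pytest.raises(ValueError):
            choose_intervals(self.make_fields(1), 20.0, (10,))

    def test_ft_upper_rule_is_max_m95_ceiling(self):
        fields = [
            StressField(sigma=[1.0, 2.3], vol=[1.0, 1.0], specimen_id="a"),
            StressField(sigma=[0.5, 4.2], vol=[1.0, 1.0], specimen_id="b"),
        ]
        assert default_ft_upper(fields) == 5.0


class TestBoxCoxCenterScale:
    def test_lognormal_column_becomes_symmetric(self, rng):
        df = pd.DataFrame({"a": np.exp(rng.normal(0, 1, size=500))})
        out = boxcox_center_scale(df)
        assert abs(stats.skew(out.data["a"])) < 0.2
        assert out.data["a"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out.data["a"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_warns_and_centres(self):
        df = pd.DataFrame({"a": [3.0, 3.0, 3.0], "b": [1.0, 2.0, 4.0]})
        with pytest.warns(UserWarning):
            out = boxcox_center_scale(df)
        assert out.data["a"].tolist() == [0.0, 0.0, 0.0]
        assert out.lambdas["a"] is None

    def test_zero_entries_are_offset_not_dropped(self, rng):
        values = np.concatenate([[0.0, 0.0], rng.uniform(1, 5, 20)])
        out = boxcox_center_scale(pd.DataFrame({"a": values}))
        assert np.isfinite(out.data["a"]).all()
        assert out.offsets["a"] == pytest.approx(values[values > 0].min() / 2)

    def test_stored_transform_reproduces_training_rows(self, rng):
        df = pd.DataFrame(
            {f"I{i}": rng.uniform(0, 30, size=25) for i in range(1, 4)}
        )
        out = boxcox_center_scale(df)
        again = out.transform_new(df)
        assert np.allclose(again.to_numpy(), out.data.to_numpy(), atol=1e-10)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            boxcox_center_scale(pd.DataFrame({"a": [-1.0, 2.0]}))


def test_profiles_to_frame_layout():
    flds = [
        StressField(sigma=[0.5, 1.5], vol=[1.0, 1.0], specimen_id=s) for s in ("a", "b")
    ]
    profs = [interval_profile(f, 2.0, 4) for f in flds]
    df = profiles_to_frame(profs)
    assert list(df.columns) == ["I1", "I2", "I3", "I4"]
    assert list(df.index) == ["a", "b"]
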