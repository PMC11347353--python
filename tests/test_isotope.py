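"""Unit and property tests for the isotope arithmetic chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsechase import isotope as iso

RC = iso.VPDB_RATIO
C = iso.IsotopeConstants()


class TestDeltaRatioConversion:
    @pytest.mark.parametrize(
        "rs, expected",
        [
            (RC, 0.0),  # sample at the standard ratio
            (0.0, -1000.0),  # no 13C at all
            (RC * 1.15226, 152.26),  # enriched leaf at end of labeling
        ],
    )
    def test_delta_from_ratio(self, rs, expected):
        assert iso.delta_from_ratio(rs) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "delta, expected",
        [
            (0.0, RC),
            (1000.0, 2 * RC),
            (175.50, RC * 1.1755),  # peak leaf enrichment 6 h after labeling
        ],
    )
    def test_ratio_from_delta(self, delta, expected):
        assert iso.ratio_from_delta(delta) == pytest.approx(expected, rel=1e-12)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            iso.delta_from_ratio(-0.001)

    def test_delta_at_floor_rejected(self):
        with pytest.raises(ValueError):
            iso.ratio_from_delta(-1000.0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_round_trip(self, rs):
        assert iso.ratio_from_delta(iso.delta_from_ratio(rs)) == pytest.approx(
            rs, rel=1e-12
        )


class TestAtomPercent:
    @pytest.mark.parametrize(
        "delta, expected",
        [
            # frozen from direct evaluation of ((d+1000)Rc)/(((d+1000)Rc)+1000)*100
            (0.0, 1.1112328541711083),  # = 11.2372 / 1011.2372 * 100
            (175.50, 1.3037117037060804),  # = 13.2093286 / 1013.2093286 * 100
        ],
    )
    def test_values(self, delta, expected):
        assert iso.atom_percent(delta) == pytest.approx(expected, rel=1e-12)

    def test_limit_at_floor_is_zero(self):
        assert iso.atom_percent(-1000 + 1e-9) == pytest.approx(0.0, abs=1e-10)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=-999.999, max_value=1e6))
    def test_bounded(self, delta):
        ap = iso.atom_percent(delta)
        assert 0.0 < ap < 100.0

    def test_strictly_increasing(self):
        deltas = np.linspace(-999, 5000, 400)
        assert np.all(np.diff(iso.atom_percent(deltas)) > 0)

    def test_inverse(self):
        deltas = np.linspace(-500, 500, 50)
        back = iso.delta_from_atom_percent(iso.atom_percent(deltas))
        np.testing.assert_allclose(back, deltas, rtol=1e-10, atol=1e-9)


class TestMassBalance:
    @pytest.mark.parametrize(
        "cf, w, expected",
        [(0.50, 10.0, 5.0), (0.0, 7.0, 0.0), (0.45, 2.0, 0.9)],
    )
    def test_total_carbon(self, cf, w, expected):
        pool = iso.OrganPool("x", "Jul", w, cf, 1.1)
        assert iso.total_carbon(pool) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ci, ap, fn, expected",
        [
            (3.0, 1.5, 1.5, 0.0),  # unlabeled organ
            (1.0, 2.1113, 1.1113, 10.0),
            (0.0, 99.0, 1.1, 0.0),
        ],
    )
    def test_excess_mass(self, ci, ap, fn, expected):
        assert iso.excess_13c_mass(ci, ap, fn) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=0.1, max_value=10),
    )
    def test_excess_linear_in_ci_and_enrichment(self, ci, diff, scale):
        base = iso.excess_13c_mass(ci, 1.2 + diff, 1.2)
        assert iso.excess_13c_mass(ci * scale, 1.2 + diff, 1.2) == pytest.approx(
            base * scale, rel=1e-9, abs=1e-9
        )
        assert iso.excess_13c_mass(ci, 1.2 + diff * scale, 1.2) == pytest.approx(
            base * scale, rel=1e-9, abs=1e-9
        )

    def test_transport_rate_arithmetic(self):
        assert iso.transport_rate(0.072, 10.0, 6.0) == pytest.approx(1.2)
        assert iso.transport_rate(0.0, 5.0, 24.0) == 0.0
        assert iso.transport_rate(1.0, 2.0, 48.0) == pytest.approx(
            iso.transport_rate(1.0, 2.0, 24.0) / 2
        )

    def test_transport_rate_rejects_bad_denominators(self):
        with pytest.raises(ValueError):
            iso.transport_rate(1.0, 10.0, 0.0)
        with pytest.raises(ValueError):
            iso.transport_rate(1.0, 0.0, 6.0)


class TestAllocationRatios:
    def test_symmetry(self):
        out = iso.allocation_ratios({"a": 1, "b": 1, "c": 1, "d": 1})
        assert all(v == pytest.approx(25.0) for v in out.values())

    def test_single_positive(self):
        out = iso.allocation_ratios({"a": 2, "b": 0, "c": 0})
        assert out == {"a": 100.0, "b": 0.0, "c": 0.0}

    def test_august_partition_is_scale_invariant(self):
        # the monthly partition depends only on proportions
        shares = {"branches": 7.70, "leaves": 54.55, "peels": 16.54, "seed_kernels": 21.21}
        masses = {k: v * 0.0584 for k, v in shares.items()}  # arbitrary rescale
        out = iso.allocation_ratios(masses)
        for organ, pct in shares.items():
            assert out[organ] == pytest.approx(pct, abs=1e-9)

    def test_error_when_no_net_label(self):
        with pytest.raises(ValueError, match="no net labeled carbon"):
            iso.allocation_ratios({"a": -1.0, "b": 0.5})

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1e3), min_size=1, max_size=8),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_sums_to_100_and_scale_invariant(self, masses, scale):
        named = {f"o{i}": m for i, m in enumerate(masses)}
        out = iso.allocation_ratios(named)
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)
        scaled = iso.allocation_ratios({k: v * scale for k, v in named.items()})
        for k in named:
            assert scaled[k] == pytest.approx(out[k], rel=1e-9)


class TestAllocationTable:
    def _pool(self, organ, month="Aug", fn=1.08):
        return iso.OrganPool(organ, month, 10.0, 0.45, fn)

    def test_single_organ_gets_everything(self):
        readings = [iso.IsotopeReading("leaves", "Aug", 72.0, delta13C=100.0)]
        table = iso.allocation_table(readings, [self._pool("leaves")])
        assert table.loc[0, "allocation_percent"] == pytest.approx(100.0)

    def test_equal_excess_split_evenly(self):
        organs = ["a", "b", "c", "d"]
        readings = [iso.IsotopeReading(o, "Aug", 72.0, delta13C=50.0) for o in organs]
        table = iso.allocation_table(readings, [self._pool(o) for o in organs])
        np.testing.assert_allclose(table["allocation_percent"], 25.0)

    def test_missing_pool_names_the_organ(self):
        readings = [iso.IsotopeReading("peels", "Aug", 72.0, delta13C=50.0)]
        with pytest.raises(KeyError, match="peels"):
            iso.allocation_table(readings, [self._pool("leaves")])

    def test_latest_timepoint_wins(self):
        readings = [
            iso.IsotopeReading("leaves", "Aug", 6.0, delta13C=175.5),
            iso.IsotopeReading("leaves", "Aug", 72.0, delta13C=70.98),
        ]
        table = iso.allocation_table(readings, [self._pool("leaves")])
        assert table.loc[0, "time_h"] == 72.0
        assert table.loc[0, "delta13c"] == pytest.approx(70.98)

    def test_dataframe_input_prefers_delta_when_both_given(self):
        readings = pd.DataFrame(
            dict(organ=["leaves"], month=["Aug"], time_h=[72.0], rs=[0.02], delta13c=[100.0])
        )
        pools = pd.DataFrame(
            dict(organ=["leaves"], month=["Aug"], biomass_g=[10.0],
                 carbon_fraction=[0.45], fn_atom_percent=[1.08])
        )
        table = iso.allocation_table(readings, pools)
        assert table.loc[0, "delta13c"] == pytest.approx(100.0)

    def test_negative_excess_preserved_and_flagged(self):
        # reading below the unlabeled background: label has left the organ
        readings = [
            iso.IsotopeReading("leaves", "Oct", 72.0, delta13C=-40.0),
            iso.IsotopeReading("seeds", "Oct", 72.0, delta13C=100.0),
        ]
        pools = [self._pool("leaves", "Oct"), self._pool("seeds", "Oct")]
        table = iso.allocation_table(readings, pools).set_index("organ")
        assert table.loc["leaves", "excess13c_mg"] < 0
        assert bool(table.loc["leaves", "negative_excess"])
        assert not bool(table.loc["seeds", "negative_excess"])


class TestReadingValidation:
    def test_exactly_one_of_rs_delta(self):
        with pytest.raises(ValueError):
            iso.IsotopeReading("leaves", "Aug", 0.0)
        with pytest.raises(ValueError):
            iso.IsotopeReading("leaves", "Aug", 0.0, Rs=0.01, delta13C=5.0)

    def test_pool_invariants(self):
        with pytest.raises(ValueError):
            iso.OrganPool("x", "Jul", -1.0, 0.5, 1.1)
        with pytest.raises(ValueError):
            iso.OrganPool("x", "Jul", 1.0, 1.5, 1.1)
        with pytest.raises(ValueError):
            iso.OrganPool("x", "Jul", 1.0, 0.5, 100.0)
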