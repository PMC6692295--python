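import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filadyn.hdx import (
    HDXPeptide,
    LabelingConditions,
    UptakeTable,
    compare_states,
    count_exchangeable,
    deuterium_fraction,
    peptide_uptake_model,
    relative_fractional_uptake,
)
from filadyn.synth import make_hdx_tables, make_peptide_map


class TestDeuteriumFraction:
    def test_printed_volumes(self):
        assert round(100 * deuterium_fraction(15, 55), 1) == 78.6

    def test_equal_volumes(self):
        assert deuterium_fraction(7.0, 7.0) == 0.5

    def test_zero_volume_errors(self):
        with pytest.raises(ValueError):
            deuterium_fraction(0.0, 55)

    @given(a=st.floats(0.1, 1000), b=st.floats(0.1, 1000))
    @settings(max_examples=40, deadline=None)
    def test_in_open_interval(self, a, b):
        f = deuterium_fraction(a, b)
        assert 0 < f < 1


class TestCountExchangeable:
    def test_proline_handling(self):
        assert count_exchangeable("PGPLG") == 3
        assert count_exchangeable("AA") == 1
        assert count_exchangeable("APPP") == 0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            count_exchangeable("")

    def test_first_two_variant(self):
        assert count_exchangeable("AAAAA", skip_n_terminal=2) == 3


class TestPeptideUptakeModel:
    COND = LabelingConditions()

    def test_zero_time(self):
        pep = HDXPeptide(1, 5, "AAAAA")
        rates = np.full(5, 0.3)
        assert peptide_uptake_model(pep, rates, self.COND, 0.0) == 0.0

    def test_saturation(self):
        pep = HDXPeptide(1, 5, "AAAAA")
        rates = np.full(5, 1e9)
        u = peptide_uptake_model(pep, rates, self.COND, 1.0)
        assert np.isclose(u, 4 * deuterium_fraction(15, 55), rtol=1e-12)

    def test_single_residue_closed_form(self):
        pep = HDXPeptide(1, 2, "AA")
        rates = np.array([0.0, 0.1])
        u = peptide_uptake_model(pep, rates, self.COND, 10.0)
        assert np.isclose(u, (55 / 70) * (1 - np.exp(-1.0)), rtol=1e-12)

    def test_negative_rate_errors(self):
        pep = HDXPeptide(1, 3, "AAA")
        with pytest.raises(ValueError):
            peptide_uptake_model(pep, np.array([0, -0.1, 0.2]), self.COND, 1.0)

    def test_monotone_in_time(self):
        rng = np.random.default_rng(0)
        pep = HDXPeptide(3, 12, "ACDEFGHIKL")
        rates = np.concatenate([np.zeros(2), 10 ** rng.uniform(-3, 1, 10)])
        times = np.linspace(0, 200, 40)
        vals = [peptide_uptake_model(pep, rates, self.COND, t) for t in times]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_additivity_over_partition(self):
        # two peptides partitioning the exchangeable amides of a span
        rng = np.random.default_rng(1)
        rates = 10 ** rng.uniform(-2, 0, 20)
        seq = "ACDEFGHIKLMNQRSTVWYA"
        whole = HDXPeptide(1, 20, seq)
        left = HDXPeptide(1, 10, seq[:10])
        right = HDXPeptide(10, 20, seq[9:])  # residue 10 is right's non-exchanging first
        u_whole = peptide_uptake_model(whole, rates, self.COND, 30.0)
        u_left = peptide_uptake_model(left, rates, self.COND, 30.0)
        u_right = peptide_uptake_model(right, rates, self.COND, 30.0)
        # left covers 2..10, right covers 11..20; whole covers 2..20
        assert np.isclose(u_left + u_right, u_whole, rtol=1e-10)


class TestRelativeFractionalUptake:
    COND = LabelingConditions()

    def test_saturated_is_one(self):
        pep = HDXPeptide(1, 8, "AAAAAAAA")
        u = pep.n_exchangeable * self.COND.d_fraction
        frac, clipped = relative_fractional_uptake(u, pep, self.COND)
        assert np.isclose(frac, 1.0) and not clipped

    def test_zero(self):
        pep = HDXPeptide(1, 8, "AAAAAAAA")
        frac, _ = relative_fractional_uptake(0.0, pep, self.COND)
        assert frac == 0.0

    def test_direct_evaluation(self):
        pep = HDXPeptide(1, 8, "AAAAAAAA")  # 7 exchangeable
        frac, _ = relative_fractional_uptake(2.75, pep, self.COND)
        assert np.isclose(frac, 2.75 / (7 * 55 / 70), rtol=1e-12)

    def test_no_exchangeable_errors(self):
        pep = HDXPeptide(1, 2, "AP")
        with pytest.raises(ValueError):
            relative_fractional_uptake(0.5, pep, self.COND)


def _two_state_tables(seed=7, slow_lo=30, slow_hi=45, noise=0.05, n_res=134,
                      factor=20.0):
    rng = np.random.default_rng(5)
    seq = "".join(np.random.default_rng(12345).choice(list("ACDEFGHIKLMNQRSTVWY"), n_res))
    pm = make_peptide_map(seq, seed=0)
    k_a = 10 ** rng.uniform(-2, 0.5, n_res)
    k_b = k_a.copy()
    k_b[slow_lo - 1 : slow_hi] /= factor
    return make_hdx_tables({"A": k_a, "B": k_b}, pm, noise_sd=noise, seed=seed), pm


class TestCompareStates:
    def test_identical_tables_nothing_significant(self):
        tables, _ = _two_state_tables(factor=1.0)
        ta = tables["A"]
        tb = UptakeTable(data=ta.data.copy(), state="B")  # literally identical values
        cmp_ = compare_states(ta, tb)
        assert not cmp_.peptide_table["significant"].any()
        assert (cmp_.peptide_table["class"] == "none").all()

    def test_slowed_region_detected_major(self):
        tables, pm = _two_state_tables()
        cmp_ = compare_states(tables["A"], tables["B"], alpha=0.01)
        pt = cmp_.peptide_table
        for _, row in pt.iterrows():
            if row["start"] >= 30 and row["end"] <= 45:
                assert row["significant"]
                assert row["class"] == "major"
            if row["end"] < 26 or row["start"] > 49:
                assert not row["significant"]

    def test_minor_class_thresholds(self):
        # significant peptide with max |dRFU| 0.07 -> minor
        import pandas as pd

        from filadyn.hdx import MAJOR_THRESHOLD, MINOR_THRESHOLD

        assert MINOR_THRESHOLD < 0.07 < MAJOR_THRESHOLD
        rng = np.random.default_rng(3)
        pep = HDXPeptide(1, 12, "ACDEFGHIKLMN")
        records_a, records_b = [], []
        denom = pep.n_exchangeable * LabelingConditions().d_fraction
        for t in LabelingConditions().time_points:
            for rep in range(1, 4):
                base = 3.0 + 0.001 * t
                records_a.append(dict(start=1, end=12, sequence=pep.sequence,
                                      time_min=t, replicate=rep,
                                      uptake_Da=base + rng.normal(0, 0.005)))
                records_b.append(dict(start=1, end=12, sequence=pep.sequence,
                                      time_min=t, replicate=rep,
                                      uptake_Da=base - 0.065 * denom + rng.normal(0, 0.005)))
        ta = UptakeTable.from_records(records_a, state="A")
        tb = UptakeTable.from_records(records_b, state="B")
        cmp_ = compare_states(ta, tb)
        row = cmp_.peptide_table.iloc[0]
        assert row["significant"]
        assert row["class"] == "minor"

    def test_statsmodels_wald_oracle(self):
        # independent OLS + Wald route through statsmodels formula API
        import pandas as pd
        import statsmodels.formula.api as smf

        tables, _ = _two_state_tables()
        ta, tb = tables["A"], tables["B"]
        cmp_ = compare_states(ta, tb)
        pep = cmp_.peptide_table.iloc[5]
        sel_a = ta.data[(ta.data["start"] == pep["start"]) & (ta.data["end"] == pep["end"])].copy()
        sel_b = tb.data[(tb.data["start"] == pep["start"]) & (tb.data["end"] == pep["end"])].copy()
        sel_a["state"] = -1.0
        sel_b["state"] = 1.0
        df = pd.concat([sel_a, sel_b])
        model = smf.ols("uptake_Da ~ state * C(time_min, Sum)", data=df).fit()
        p_mag = float(model.wald_test("state", use_f=True, scalar=True).pvalue)
        inter = [n for n in model.params.index if "state:" in n]
        p_kin = float(model.wald_test(inter, use_f=True, scalar=True).pvalue)
        assert np.isclose(pep["p_magnitude"], p_mag, rtol=1e-6, atol=1e-12)
        assert np.isclose(pep["p_kinetics"], p_kin, rtol=1e-6, atol=1e-12)

    def test_swap_states_preserves_pvalues_negates_delta(self):
        tables, _ = _two_state_tables()
        c1 = compare_states(tables["A"], tables["B"])
        c2 = compare_states(tables["B"], tables["A"])
        assert np.allclose(c1.peptide_table["p_magnitude"], c2.peptide_table["p_magnitude"])
        assert np.allclose(c1.peptide_table["mean_delta_rfu"],
                           -c2.peptide_table["mean_delta_rfu"])

    def test_mismatched_maps_error(self):
        tables, _ = _two_state_tables()
        ta = tables["A"]
        tb = tables["B"]
        trimmed = UptakeTable(data=tb.data[tb.data["start"] > 5].copy(), state="B")
        with pytest.raises(ValueError, match="peptide maps"):
            compare_states(ta, trimmed)

    def test_residue_aggregation_most_severe(self):
        tables, _ = _two_state_tables()
        cmp_ = compare_states(tables["A"], tables["B"])
        rt = cmp_.residue_table.set_index("residue")["class"]
        pt = cmp_.peptide_table
        for _, row in pt.iterrows():
            if row["class"] == "major":
                for rid in range(int(row["start"]), int(row["end"]) + 1):
                    assert rt.loc[rid] == "major"

    def test_null_type_one_error_small(self):
        # identical generating processes: few significant calls
        rng = np.random.default_rng(0)
        n_sig = n_tot = 0
        for trial in range(40):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNQRSTVWY"), 40))
            pm = make_peptide_map(seq, seed=trial)
            k = 10 ** np.random.default_rng(1000 + trial).uniform(-2, 0.5, 40)
            tables = make_hdx_tables({"A": k, "B": k}, pm, noise_sd=0.05,
                                     seed=2000 + trial)
            cmp_ = compare_states(tables["A"], tables["B"])
            n_sig += int(cmp_.peptide_table["significant"].sum())
            n_tot += len(cmp_.peptide_table)
        assert n_sig / n_tot <= 0.02
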