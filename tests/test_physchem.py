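"""Embedded VIP data, stacking energies, trimer aggregation and log-linear fits."""

import numpy as np
import pandas as pd
import pytest

import mutmotif as mm
from mutmotif.physchem import VIP_FREE_GUANINE_EXPERIMENTAL_EV

DGN_TRIMERS = [f"{d}G{n}" for d in "AGT" for n in "ACGT"]


class TestVipTable:
    @pytest.mark.parametrize(
        "trimer,ev", [("GGG", 5.39), ("TGC", 5.97), ("G", 8.02)]
    )
    def test_lookup(self, trimer, ev):
        assert mm.vip_lookup(trimer) == ev

    def test_experimental_reference(self):
        assert VIP_FREE_GUANINE_EXPERIMENTAL_EV == 8.26

    def test_cgn_rejected(self):
        with pytest.raises(KeyError, match="DGN"):
            mm.vip_lookup("CGA")

    def test_twelve_entries(self):
        assert sorted(mm.VIP_TRIMER_EV) == sorted(DGN_TRIMERS)

    def test_ggg_is_global_minimum(self):
        assert min(mm.VIP_TRIMER_EV, key=mm.VIP_TRIMER_EV.get) == "GGG"

    def test_gg_doublets_below_single_g_trimers(self):
        doublet = [t for t in DGN_TRIMERS if "GG" in t]
        single = [t for t in DGN_TRIMERS if "GG" not in t]
        assert max(mm.VIP_TRIMER_EV[t] for t in doublet) < min(
            mm.VIP_TRIMER_EV[t] for t in single
        )

    def test_three_prime_purine_below_pyrimidine(self):
        for d in "AGT":
            purine_max = max(mm.VIP_TRIMER_EV[f"{d}G{n}"] for n in "AG")
            pyrimidine_min = min(mm.VIP_TRIMER_EV[f"{d}G{n}"] for n in "CT")
            assert purine_max < pyrimidine_min

    def test_all_trimers_well_below_free_guanine(self):
        assert max(mm.VIP_TRIMER_EV.values()) < mm.VIP_FREE_GUANINE_EV


class TestStacking:
    def test_toy_table_mean(self):
        steps = {f"{a}{b}": 0.0 for a in "ACGT" for b in "ACGT"}
        steps.update({"AG": 1.0, "GT": 2.0, "TT": 3.0})
        table = mm.StackingStepTable(steps, source="toy")
        assert mm.mean_stacking_energy("AGTT", table) == pytest.approx(2.0)

    def test_uniform_table_is_constant(self):
        table = mm.StackingStepTable(
            {f"{a}{b}": 1.5 for a in "ACGT" for b in "ACGT"}
        )
        for motif in mm.SUBSETS["DGNN"]:
            assert mm.mean_stacking_energy(motif, table) == pytest.approx(1.5)

    def test_equal_step_multisets_get_equal_means(self):
        rng = np.random.default_rng(7)
        table = mm.StackingStepTable(
            {f"{a}{b}": float(v) for (a, b), v in zip(
                [(a, b) for a in "ACGT" for b in "ACGT"], rng.random(16)
            )}
        )
        by_multiset = {}
        for motif in mm.SUBSETS["DGNN"]:
            key = frozenset(
                [(motif[0:2]), (motif[1:3]), (motif[2:4])]
            ), tuple(sorted([motif[0:2], motif[1:3], motif[2:4]]))
            by_multiset.setdefault(key[1], []).append(
                mm.mean_stacking_energy(motif, table)
            )
        for vals in by_multiset.values():
            assert np.allclose(vals, vals[0])

    def test_cgnn_rejected_without_flag(self):
        table = mm.StackingStepTable.synthetic_default()
        with pytest.raises(ValueError, match="CGNN"):
            mm.mean_stacking_energy("CGAA", table)
        assert mm.mean_stacking_energy("CGAA", table, allow_cgnn=True) > 0

    def test_synthetic_default_honors_class_ordering(self):
        steps = mm.StackingStepTable.synthetic_default().steps
        cls = {
            "RR": [v for s, v in steps.items() if s[0] in "AG" and s[1] in "AG"],
            "RY": [v for s, v in steps.items() if s[0] in "AG" and s[1] in "CT"],
            "YR": [v for s, v in steps.items() if s[0] in "CT" and s[1] in "AG"],
            "YY": [v for s, v in steps.items() if s[0] in "CT" and s[1] in "CT"],
        }
        assert min(cls["RR"]) > max(cls["RY"])
        assert min(cls["RY"]) > max(cls["YR"])
        assert min(cls["YR"]) > max(cls["YY"])

    def test_missing_step_is_error(self):
        steps = {f"{a}{b}": 1.0 for a in "ACGT" for b in "ACGT"}
        del steps["GT"]
        with pytest.raises(ValueError, match="GT"):
            mm.StackingStepTable(steps)


class TestTrimerAggregation:
    def test_sum_over_p4(self):
        m = pd.Series(0, index=list(mm.MOTIFS))
        for p4 in "ACGT":
            m[f"AGT{p4}"] = 1
        t = pd.Series(100, index=list(mm.MOTIFS))
        tri = mm.aggregate_to_trimers(mm.motif_fractions(m, t))
        assert tri.loc["AGT", "m"] == 4
        assert tri.loc["AGT", "t"] == 400
        assert tri.loc["AGT", "f"] == pytest.approx(0.01)

    def test_counts_conserved(self, sim_small_fractions):
        tri = mm.aggregate_to_trimers(sim_small_fractions)
        assert tri["m"].sum() == sim_small_fractions.m.sum()
        assert tri["t"].sum() == sim_small_fractions.t.sum()
        dgn = tri.loc[[t for t in tri.index if t[0] != "C"]]
        dgnn = sim_small_fractions.subset("DGNN")
        assert dgn["m"].sum() == dgnn["m"].sum()


class TestCombineFractions:
    def _table(self, scale):
        m = pd.Series(0, index=list(mm.MOTIFS))
        m["AGAA"], m["TGTT"] = 2 * scale, 6 * scale
        t = pd.Series(1000, index=list(mm.MOTIFS))
        return mm.motif_fractions(m, t)

    def test_per_dataset_normalization_weights_datasets_equally(self):
        # same spectrum at 10x the burden: combination is burden-invariant
        combined = mm.combine_fractions(
            {"small": self._table(1), "large": self._table(10)}
        )
        assert combined["AGAA"] == pytest.approx(0.25)
        assert combined["TGTT"] == pytest.approx(0.75)

    def test_raw_averaging_keeps_burden_weighting(self):
        combined = mm.combine_fractions(
            {"small": self._table(1), "large": self._table(10)},
            normalize_first=False,
        )
        assert combined["AGAA"] == pytest.approx((0.002 + 0.02) / 2)


class TestLogLinearFit:
    def test_perfect_exponential(self):
        x = np.arange(5.0)
        res = mm.fit_log_linear(np.exp(2 * x), x, bootstrap_b=200, seed=0)
        assert res["slope"] == pytest.approx(2.0)
        assert res["r2"] == pytest.approx(1.0)
        assert res["p_alpha"] == 1.0

    def test_null_has_low_persistence(self):
        rng = np.random.default_rng(5)
        x = rng.random(48)
        y = np.exp(rng.normal(size=48))  # independent of x
        res = mm.fit_log_linear(y, x, bootstrap_b=400, seed=1)
        assert res["r2"] < 0.15
        assert res["p_alpha"] < 0.5

    def test_rescaling_y_only_shifts_intercept(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 20)
        y = np.exp(1.3 * x + rng.normal(scale=0.1, size=20))
        a = mm.fit_log_linear(y, x, bootstrap_b=100, seed=9)
        b = mm.fit_log_linear(1000 * y, x, bootstrap_b=100, seed=9)
        assert a["slope"] == pytest.approx(b["slope"], rel=1e-12)
        assert a["r2"] == pytest.approx(b["r2"], rel=1e-12)
        assert a["p"] == pytest.approx(b["p"], rel=1e-9)
        assert b["intercept"] - a["intercept"] == pytest.approx(np.log(1000))

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(11)
        x = rng.random(30)
        y = np.exp(-x + rng.normal(scale=0.3, size=30))
        r1 = mm.fit_log_linear(y, x, bootstrap_b=300, seed=42)
        r2 = mm.fit_log_linear(y, x, bootstrap_b=300, seed=42)
        assert r1 == r2

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            mm.fit_log_linear([1.0, 2.0], [0.0, 1.0], bootstrap_b=10, seed=0)
        with pytest.raises(ValueError, match="constant"):
            mm.fit_log_linear([1.0, 2.0, 3.0], [1.0, 1.0, 1.0],
                              bootstrap_b=10, seed=0)

    def test_nonpositive_y_excluded_with_warning(self):
        x = np.arange(6.0)
        y = np.exp(x)
        y[0] = 0.0
        with pytest.warns(UserWarning, match="excluding 1"):
            res = mm.fit_log_linear(y, x, bootstrap_b=50, seed=2)
        assert res["n_used"] == 5 and res["n_excluded"] == 1
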