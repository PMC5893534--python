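"""WPR / GER / PRE arithmetic, treatment comparison and ANOVA power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathfabric import (
    anova_power,
    anova_sample_size,
    compare_treatments,
    ger,
    pathway_percentages,
    pre,
    read_gmt,
    score_table,
    wpr,
)
from pathfabric.calls import TransitionTable
from pathfabric.scores import write_gmt


def contrast_frame(rows: dict) -> pd.DataFrame:
    """rows: gene -> (mu_ref, x, p[, call])"""
    df = pd.DataFrame.from_dict(
        {g: list(v) for g, v in rows.items()},
        orient="index",
        columns=["mu_ref", "x", "p", "call"][: len(next(iter(rows.values())))],
    )
    return df


class TestPercentages:
    def test_mixed_calls(self):
        calls = pd.Series(["U"] * 3 + ["D"] * 2 + ["X"] * 5,
                          index=[f"g{i}" for i in range(10)])
        assert pathway_percentages(calls, calls.index) == (30.0, 20.0)

    def test_all_unregulated(self):
        calls = pd.Series(["X"] * 4, index=list("abcd"))
        assert pathway_percentages(calls, list("abcd")) == (0.0, 0.0)

    def test_single_quantified_gene(self):
        calls = pd.Series(["D"], index=["a"])
        assert pathway_percentages(calls, ["a", "not_quantified"]) == (0.0, 100.0)

    def test_no_quantified_gene_rejected(self):
        calls = pd.Series(["U"], index=["a"])
        with pytest.raises(ValueError):
            pathway_percentages(calls, ["zzz"])


class TestWPR:
    def test_unit_fold_changes_give_zero(self):
        df = contrast_frame({"a": (5.0, 1.0, 0.2), "b": (2.0, -1.0, 0.9)})
        assert wpr(df, ["a", "b"]) == 0.0

    def test_single_gene_substitution(self):
        df = contrast_frame({"a": (2.0, -3.0, 0.01)})
        assert wpr(df, ["a"]) == pytest.approx(3.96)

    def test_two_gene_average(self):
        df = contrast_frame({"a": (1.0, 2.0, 0.0), "b": (1.0, 1.0, 1.0)})
        assert wpr(df, ["a", "b"]) == pytest.approx(0.5)

    def test_empty_intersection_rejected(self):
        df = contrast_frame({"a": (1.0, 2.0, 0.0)})
        with pytest.raises(ValueError):
            wpr(df, ["zzz"])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        df = contrast_frame(
            {f"g{i}": (rng.uniform(0.5, 5), rng.uniform(1, 4), rng.uniform(0, 1))
             for i in range(20)}
        )
        base = wpr(df, df.index)
        scaled = df.copy()
        scaled["mu_ref"] *= 7.0
        assert wpr(scaled, df.index) == pytest.approx(7.0 * base, rel=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        sign = rng.choice([-1, 1], 50)
        df = contrast_frame(
            {f"g{i}": (rng.uniform(0.1, 9), sign[i] * rng.uniform(1, 5),
                       rng.uniform(0, 1)) for i in range(50)}
        )
        assert wpr(df, df.index) >= 0.0


class TestGER:
    def test_full_restoration(self):
        assert ger(TransitionTable(counts={"DX": 10, "UX": 5})) == 100.0

    def test_pure_side_effects(self):
        assert ger(TransitionTable(counts={"XD": 4, "XU": 6})) == -100.0

    def test_hand_example(self):
        t = TransitionTable(counts={"DX": 3, "XU": 1, "DD": 4})
        assert ger(t) == pytest.approx(25.0)

    def test_all_xx_not_applicable(self):
        assert np.isnan(ger(TransitionTable(counts={"XX": 100})))

    def test_bounds_and_attainment(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            counts = {c: int(rng.integers(0, 20)) for c in
                      ("DX", "UX", "XD", "XU", "DD", "DU", "UD", "UU")}
            if sum(counts.values()) == 0:
                continue
            g = ger(TransitionTable(counts=counts))
            assert -100.0 <= g <= 100.0
            at_max = all(counts[c] == 0 for c in ("XD", "XU", "DD", "DU", "UD", "UU"))
            assert (g == 100.0) == (at_max and counts["DX"] + counts["UX"] > 0)


class TestPRE:
    @pytest.mark.parametrize(
        "treated,untreated,expected",
        [(0.0, 5.0, 100.0), (5.0, 5.0, 0.0), (10.0, 5.0, -100.0)],
    )
    def test_printed_outcomes(self, treated, untreated, expected):
        assert pre(treated, untreated) == pytest.approx(expected)

    def test_positive_effect_band(self):
        assert 0.0 < pre(2.0, 5.0) < 100.0

    def test_untreated_zero_not_applicable(self):
        assert np.isnan(pre(1.0, 0.0))

    def test_negative_wpr_rejected(self):
        with pytest.raises(ValueError):
            pre(-1.0, 2.0)


class TestCompareTreatments:
    def test_identical_vectors(self):
        assert compare_treatments([90] * 5, [90] * 5) == 1.0

    def test_separated_vectors(self):
        rng = np.random.default_rng(0)
        a = 90 + rng.normal(0, 0.1, 5)
        b = 10 + rng.normal(0, 0.1, 5)
        assert compare_treatments(a, b) < 0.001

    def test_matches_reference(self):
        a = np.array([58.0, 61.0, 70.0, 55.0, 66.0])
        b = np.array([69.0, 72.0, 66.0, 75.0, 68.0])
        assert compare_treatments(a, b) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue, abs=1e-10
        )
        assert compare_treatments(a, b, paired=True) == pytest.approx(
            stats.ttest_rel(a, b).pvalue, abs=1e-10
        )

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            compare_treatments([1.0], [2.0, 3.0])


class TestAnovaSampleSize:
    def test_study_worked_example(self):
        assert anova_sample_size(f=0.7972, k=3, alpha=0.05, power=0.80) == 7

    def test_huge_effect_minimal_n(self):
        assert anova_sample_size(f=10.0, k=3) == 2

    def test_power_monotone_in_n(self):
        powers = [anova_power(0.5, 3, n) for n in range(2, 30)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_unreachable_power_raises(self):
        with pytest.raises(ValueError):
            anova_sample_size(f=0.001, k=3, power=0.99, max_n=50)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            anova_power(0.0, 3, 5)
        with pytest.raises(ValueError):
            anova_sample_size(0.5, 3, alpha=1.5)


class TestGMTAndScoreTable:
    def test_gmt_round_trip(self, tmp_path):
        sets = {"GABA": ["g1", "g2", "g3"], "GLU": ["g2", "g4"]}
        write_gmt(sets, tmp_path / "p.gmt")
        assert read_gmt(tmp_path / "p.gmt") == sets

    def test_malformed_gmt_rejected(self, tmp_path):
        (tmp_path / "bad.gmt").write_text("onlyname\n")
        with pytest.raises(ValueError):
            read_gmt(tmp_path / "bad.gmt")

    def test_shipped_synapse_fixture(self):
        from pathlib import Path

        sets = read_gmt(Path(__file__).resolve().parent.parent / "data" / "synapse_pathways.gmt")
        assert set(sets) == {"ACH", "GLU", "GABA", "DA", "5HT"}
        assert all(len(g) >= 5 for g in sets.values())

    def test_score_table_structure(self, sim_norm):
        from pathfabric import contrast_genes

        _, cohort, truth = sim_norm
        contrasts = {
            c: contrast_genes(cohort, "male", c) for c in ("BYS", "BYA", "BYP")
        }
        table = score_table(contrasts, truth.pathways)
        assert set(table["pathway"]) == set(truth.pathways) | {"ALL"}
        assert set(table["condition"]) == {"BYS", "BYA", "BYP"}
        bys = table[table["condition"] == "BYS"]
        assert bys["ger"].isna().all() and bys["pre"].isna().all()
        treated = table[table["condition"].isin(["BYA", "BYP"])]
        assert treated["ger"].notna().all() and treated["pre"].notna().all()
        assert (table["wpr"] >= 0).all()
        assert ((table["pct_up"] + table["pct_down"]) <= 100.0 + 1e-9).all()
        # genes shared between pathways count fully in each
        all_row = table[(table["pathway"] == "ALL") & (table["condition"] == "BYS")]
        assert int(all_row["n_genes"].iloc[0]) == len(contrasts["BYS"])
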