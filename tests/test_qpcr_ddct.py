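import math

import numpy as np
import pandas as pd
import pytest

from surreg.qpcr_ddct import (
    ddct_fold,
    expression_ratio,
    induction_response,
    reference_stability,
)
from surreg.synthetic_data import simulate_ct


def ct_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "strain",
            "pressure_MPa",
            "sulfur",
            "sulfur_conc_g_per_L",
            "bio_replicate",
            "tech_replicate",
            "ct",
        ],
    )


def group(strain, pressure=0.1, sulfur="present", conc=0.25):
    return {
        "strain": strain,
        "pressure_MPa": pressure,
        "sulfur": sulfur,
        "sulfur_conc_g_per_L": conc,
    }


def make_table(gene_cts, strain="d517", pressure=0.1, n_bio=1):
    rows = []
    for gene, ct in gene_cts.items():
        for b in range(1, n_bio + 1):
            rows.append(
                (gene, strain, pressure, "present", 0.25, f"b{b}", "t1", ct)
            )
    return ct_frame(rows)


class TestReferenceStability:
    def test_constant_candidate_ranks_first(self):
        rows = []
        for pressure, ct_s13 in [(0.1, 20.0), (40.0, 23.0), (70.0, 18.5)]:
            rows.append(("pcna", "d517", pressure, "present", 0.25, "b1", "t1", 21.0))
            rows.append(("S13", "d517", pressure, "present", 0.25, "b1", "t1", ct_s13))
        ranking = reference_stability(ct_frame(rows), ["S13", "pcna"])
        assert list(ranking["gene"]) == ["pcna", "S13"]
        assert ranking["ct_sd"].iloc[0] == 0.0

    def test_planted_stability_ordering_recovered(self, rng):
        rows = []
        for i, pressure in enumerate([0.1, 40.0, 70.0, 0.1, 40.0, 70.0]):
            sulfur = "present" if i < 3 else "absent"
            rows.append(
                ("pcna", "d517", pressure, sulfur, 0.25, "b1", "t1",
                 20 + rng.normal(0, 0.2))
            )
            rows.append(
                ("S13", "d517", pressure, sulfur, 0.25, "b1", "t1",
                 18 + rng.normal(0, 1.5))
            )
        ranking = reference_stability(ct_frame(rows), ["S13", "pcna"])
        assert ranking["gene"].iloc[0] == "pcna"

    def test_exact_tie_breaks_alphabetically_and_flags(self):
        rows = []
        for pressure in (0.1, 40.0):
            for gene in ("S19", "S13"):
                rows.append((gene, "d517", pressure, "present", 0.25, "b1", "t1", 20.0))
        ranking = reference_stability(ct_frame(rows), ["S19", "S13"])
        assert list(ranking["gene"]) == ["S13", "S19"]
        assert ranking["tied"].all()

    def test_absent_candidate_named_in_error(self):
        table = make_table({"pcna": 20.0})
        with pytest.raises(ValueError, match="S19"):
            reference_stability(table, ["S19"])


class TestExpressionRatio:
    def test_two_cycles_behind_reference(self):
        table = make_table({"mbh1": 22.0, "pcna": 20.0})
        er = expression_ratio(table, "mbh1", "pcna", group("d517"))
        assert er.ratio == pytest.approx(0.25)
        assert er.n_bio == 1

    def test_equal_ct_gives_unit_ratio_zero_sd(self):
        table = make_table({"shII": 21.5, "pcna": 21.5}, n_bio=3)
        er = expression_ratio(table, "shII", "pcna", group("d517"))
        assert er.ratio == pytest.approx(1.0)
        assert er.sd == pytest.approx(0.0)

    def test_missing_reference_replicate_dropped(self):
        table = make_table({"mbh1": 22.0, "pcna": 20.0}, n_bio=2)
        table = table[
            ~((table["gene"] == "pcna") & (table["bio_replicate"] == "b2"))
        ]
        er = expression_ratio(table, "mbh1", "pcna", group("d517"))
        assert (er.ratio, er.n_bio) == (pytest.approx(0.25), 1)

    def test_all_replicates_dropped_is_error(self):
        table = make_table({"mbh1": 22.0}, n_bio=2)
        with pytest.raises(ValueError):
            expression_ratio(table, "mbh1", "pcna", group("d517"))

    def test_uniform_ct_shift_leaves_ratio_unchanged(self):
        table = make_table({"mbh1": 24.0, "pcna": 20.0}, n_bio=3)
        shifted = table.copy()
        shifted["ct"] += 3.7
        a = expression_ratio(table, "mbh1", "pcna", group("d517"))
        b = expression_ratio(shifted, "mbh1", "pcna", group("d517"))
        assert a.ratio == pytest.approx(b.ratio)

    def test_recovery_under_realistic_noise(self):
        # planted ratio 0.1; estimate within [0.07, 0.14] in >= 95% of draws
        truth = pd.DataFrame(
            [{"gene": "mbs", "strain": "d517", "pressure_MPa": 0.1,
              "sulfur": "present", "sulfur_conc_g_per_L": 0.25,
              "true_ratio": 0.1}]
        )
        inside = 0
        n = 200
        for seed in range(n):
            table, _ = simulate_ct(truth, sd_bio=0.3, sd_tech=0.15, seed=seed)
            er = expression_ratio(table, "mbs", "pcna", group("d517"))
            inside += 0.07 <= er.ratio <= 0.14
        assert inside / n >= 0.95


class TestDdctFold:
    def test_identical_groups_unchanged(self):
        rows = make_table({"shII": 22.0, "pcna": 20.0})
        rows2 = make_table({"shII": 22.0, "pcna": 20.0}, strain="dsurR")
        table = pd.concat([rows, rows2])
        fc = ddct_fold(table, "shII", "pcna", group("d517"), group("dsurR"))
        assert (fc.fold, fc.direction) == (pytest.approx(1.0), "unchanged")

    def test_three_cycle_advantage_is_eightfold_up(self):
        num = make_table({"shII": 19.0, "pcna": 20.0})
        den = make_table({"shII": 22.0, "pcna": 20.0}, strain="dsurR")
        fc = ddct_fold(pd.concat([num, den]), "shII", "pcna",
                       group("d517"), group("dsurR"))
        assert (fc.fold, fc.direction) == (pytest.approx(8.0), "up")

    def test_reciprocity_exact_on_noiseless_data(self):
        a = make_table({"mbh2": 21.3, "pcna": 19.9})
        b = make_table({"mbh2": 23.8, "pcna": 20.4}, strain="dsurR")
        table = pd.concat([a, b])
        ab = ddct_fold(table, "mbh2", "pcna", group("d517"), group("dsurR"))
        ba = ddct_fold(table, "mbh2", "pcna", group("dsurR"), group("d517"))
        assert ab.fold * ba.fold == pytest.approx(1.0)

    def test_efficiency_changes_fold_base(self):
        num = make_table({"shII": 19.0, "pcna": 20.0})
        den = make_table({"shII": 20.0, "pcna": 20.0}, strain="dsurR")
        table = pd.concat([num, den])
        fc = ddct_fold(table, "shII", "pcna", group("d517"), group("dsurR"),
                       efficiency=0.9)
        assert fc.fold == pytest.approx(1.9)


class TestInductionResponse:
    def test_null_data_all_unchanged(self):
        pre = make_table({"mbh1": 21.0, "shI": 22.0, "pcna": 20.0})
        post = make_table({"mbh1": 21.0, "shI": 22.0, "pcna": 20.0},
                          pressure=40.0)
        table = pd.concat([pre, post])
        out = induction_response(
            table, ["mbh1", "shI"], group("d517"), group("d517", 40.0)
        )
        assert (out["direction"] == "unchanged").all()

    def test_planted_repression_after_sulfur(self):
        # ddCt +4 for hydrogenogenic genes: folds near 1/16, labelled down
        pre = make_table({"mbh1": 20.0, "shII": 21.0, "pcna": 20.0})
        post = make_table({"mbh1": 24.0, "shII": 25.0, "pcna": 20.0},
                          pressure=40.0)
        table = pd.concat([pre, post])
        out = induction_response(
            table, ["mbh1", "shII"], group("d517"), group("d517", 40.0)
        )
        assert out["fold"].tolist() == pytest.approx([1 / 16, 1 / 16])
        assert (out["direction"] == "down").all()

    def test_missing_gene_yields_na_row_and_run_continues(self):
        pre = make_table({"mbh1": 20.0, "pcna": 20.0})
        post = make_table({"mbh1": 21.0, "pcna": 20.0}, pressure=40.0)
        table = pd.concat([pre, post])
        out = induction_response(
            table, ["mbh1", "ghost"], group("d517"), group("d517", 40.0)
        )
        assert out.loc[out["gene"] == "ghost", "direction"].iloc[0] == "NA"
        assert math.isnan(out.loc[out["gene"] == "ghost", "fold"].iloc[0])
        assert math.isfinite(out.loc[out["gene"] == "mbh1", "fold"].iloc[0])


class TestZeroNoiseIdentifiability:
    def test_simulated_ratios_recovered_exactly(self):
        truth = pd.DataFrame(
            [
                {"gene": g, "strain": "d517", "pressure_MPa": 0.1,
                 "sulfur": "present", "sulfur_conc_g_per_L": 0.25,
                 "true_ratio": r}
                for g, r in [("mbh1", 0.25), ("shII", 1.0), ("mbs", 3.5)]
            ]
        )
        table, _ = simulate_ct(truth, sd_bio=0.0, sd_tech=0.0, seed=0)
        for g, r in [("mbh1", 0.25), ("shII", 1.0), ("mbs", 3.5)]:
            er = expression_ratio(table, g, "pcna", group("d517"))
            assert er.ratio == pytest.approx(r, abs=1e-12)
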