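"""Fold-change computation and the genetic-dependency rule table."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rdrnascan.depclass import (
    ClassifierConfig,
    classify_all,
    classify_locus,
    log2_fold_change,
    summarize_classes,
)

CFG = ClassifierConfig()


def rpm_row(wt=100.0, **kwargs):
    row = {
        "WT": wt,
        "dcl1": wt,
        "dcl2": wt,
        "dcl1dcl2": wt,
        "rdrp1": wt,
        "rdrp2": wt,
        "r3b2": wt,
    }
    row.update(kwargs)
    return row


class TestLog2FoldChange:
    def test_exact_fourfold(self):
        assert log2_fold_change(25, 100) == pytest.approx(-2.0)

    def test_identity(self):
        assert log2_fold_change(100, 100) == 0.0

    def test_zero_mutant_is_minus_infinity_and_depleted(self):
        fc = log2_fold_change(0, 80)
        assert fc == -math.inf
        call = classify_locus(rpm_row(rdrp1=0.0), CFG)
        assert call.depleted["rdrp1"]

    def test_both_zero_is_nan(self):
        assert math.isnan(log2_fold_change(0, 0))

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            log2_fold_change(-1, 10)

    def test_pseudocount(self):
        assert log2_fold_change(0, 80, pseudocount=1) == pytest.approx(
            math.log2(1 / 81)
        )


class TestClassifyLocus:
    def test_rdrna_both_example(self):
        # WT 100; dcl contrasts ~100; rdrp1 20; rdrp2 15 (fourfold = <= 25)
        call = classify_locus(rpm_row(rdrp1=20, rdrp2=15), CFG)
        assert call.class_label == "rdRNA-both"

    def test_wt_floor_excludes(self):
        call = classify_locus(rpm_row(wt=40, rdrp1=5), CFG)
        assert call.class_label == "unclassified"

    def test_exsirna_ii_example(self):
        call = classify_locus(
            rpm_row(wt=200, dcl1=190, dcl2=30, dcl1dcl2=35, rdrp1=40, rdrp2=210), CFG
        )
        assert call.class_label == "exsiRNA-II"

    def test_missing_contrast_errors(self):
        with pytest.raises(ValueError, match="rdrp2"):
            classify_locus({"WT": 100, "dcl1": 100, "dcl2": 100, "dcl1dcl2": 100,
                            "rdrp1": 100, "r3b2": 100}, CFG)

    def test_r3b2_and_ago1_flags(self):
        call = classify_locus(
            {**rpm_row(rdrp1=10), "r3b2": 5, "WT_ago1ip": 500, "ago1_ago1ip": 100},
            CFG,
        )
        assert call.r3b2_dependent
        assert call.ago1_bound
        weak = classify_locus(
            {**rpm_row(), "WT_ago1ip": 150, "ago1_ago1ip": 100}, CFG
        )
        assert not weak.ago1_bound

    def test_rule_table_oracle_over_all_flag_combinations(self):
        """Exhaustive check against an independent statement of the rules.

        Each of the five informative contrasts takes one of three states:
        depleted (RPM 10, log2 FC ~ -3.3), unchanged (100), or increased
        (500); all 3^5 combinations are classified and compared with a
        direct transcription of the class definitions.
        """
        state_rpm = {"dep": 10.0, "unch": 100.0, "inc": 500.0}

        def oracle(s):
            dicer_dep = "dep" in (s["dcl1"], s["dcl2"], s["dcl1dcl2"])
            if dicer_dep:
                if s["dcl1"] == "dep" and s["dcl2"] == "unch":
                    return "exsiRNA-IV"
                if (
                    s["dcl1"] == "unch"
                    and s["dcl2"] == "unch"
                    and s["dcl1dcl2"] == "dep"
                    and s["rdrp1"] == "dep"
                    and s["rdrp2"] == "dep"
                ):
                    return "exsiRNA-III"
                if s["dcl2"] == "dep" and s["rdrp1"] == "dep":
                    return "exsiRNA-II"
                if s["dcl2"] == "dep" and s["rdrp1"] == "unch":
                    return "exsiRNA-I"
                return "unclassified"
            if {s["dcl1"], s["dcl2"], s["dcl1dcl2"]} == {"unch"}:
                if s["rdrp1"] == "dep" and s["rdrp2"] == "dep":
                    return "rdRNA-both"
                if s["rdrp1"] == "dep":
                    return "rdRNA-rdrp1"
                if s["rdrp2"] == "dep":
                    return "rdRNA-rdrp2"
            return "unclassified"

        contrasts = ["dcl1", "dcl2", "dcl1dcl2", "rdrp1", "rdrp2"]
        for combo in itertools.product(["dep", "unch", "inc"], repeat=5):
            s = dict(zip(contrasts, combo))
            row = rpm_row(**{c: state_rpm[st] for c, st in s.items()})
            call = classify_locus(row, CFG)
            assert call.class_label == oracle(s), s

    def test_classified_implies_wt_above_floor(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            row = rpm_row(
                wt=float(rng.uniform(0, 200)),
                **{c: float(rng.uniform(0, 400))
                   for c in ("dcl1", "dcl2", "dcl1dcl2", "rdrp1", "rdrp2", "r3b2")},
            )
            call = classify_locus(row, CFG)
            if call.class_label != "unclassified":
                assert row["WT"] > CFG.wt_min_rpm

    def test_raising_floor_never_classifies_more(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(
            rng.uniform(0, 300, size=(100, 7)),
            columns=["WT", "dcl1", "dcl2", "dcl1dcl2", "rdrp1", "rdrp2", "r3b2"],
        )
        prev = None
        for floor in (0, 25, 50, 100, 200):
            cfg = ClassifierConfig(wt_min_rpm=floor)
            n = (classify_all(mat, config=cfg)["class_label"] != "unclassified").sum()
            if prev is not None:
                assert n <= prev
            prev = n


class TestSummarizeClasses:
    def _calls(self, rows):
        recs = []
        for i, (label, r3b2_dep, fc_r3b2, category) in enumerate(rows):
            recs.append(
                {
                    "locus_id": f"L{i}",
                    "class_label": label,
                    "r3b2_dependent": r3b2_dep,
                    "ago1_bound": False,
                    "wt_rpm": 100.0,
                    "log2fc_r3b2": fc_r3b2,
                    "depleted_rdrp1": label in ("rdRNA-rdrp1", "rdRNA-both", "exsiRNA-II"),
                    "depleted_rdrp2": label in ("rdRNA-rdrp2", "rdRNA-both"),
                    "_category": category,
                }
            )
        calls = pd.DataFrame(recs)
        loci = pd.DataFrame(
            {"locus_id": calls["locus_id"], "category": calls["_category"]}
        )
        return calls.drop(columns="_category"), loci

    def test_direct_counts(self):
        calls, loci = self._calls(
            [("rdRNA-both", True, -5.0, "exon")] * 3
            + [("exsiRNA-II", True, -2.5, "exon")]
        )
        tables = summarize_classes(calls, loci)
        t1 = tables["dependency_by_category"]
        assert t1.loc["exon", "both_total"] == 3
        assert t1.loc["exon", "both_dicer_independent"] == 3
        t2 = tables["r3b2_by_class"].set_index("class_label")
        assert t2.loc["exsiRNA-II", "n_loci"] == 1
        assert t2.loc["rdRNA-both", "n_loci"] == 3

    def test_r3b2_percentage_and_mean_fc(self):
        rows = [("exsiRNA-II", True, -3.0, "exon")] * 2 + [
            ("exsiRNA-II", False, -0.5, "exon")
        ]
        calls, loci = self._calls(rows)
        t2 = summarize_classes(calls, loci)["r3b2_by_class"].set_index("class_label")
        assert t2.loc["exsiRNA-II", "pct_r3b2_dependent"] == pytest.approx(66.7)
        assert t2.loc["exsiRNA-II", "mean_log2fc_r3b2"] == pytest.approx(
            (-3.0 - 3.0 - 0.5) / 3
        )

    def test_infinite_fold_changes_excluded_from_mean(self):
        rows = [
            ("rdRNA-rdrp1", True, -4.0, "exon"),
            ("rdRNA-rdrp1", True, -math.inf, "exon"),
        ]
        calls, loci = self._calls(rows)
        t2 = summarize_classes(calls, loci)["r3b2_by_class"].set_index("class_label")
        assert t2.loc["rdRNA-rdrp1", "mean_log2fc_r3b2"] == pytest.approx(-4.0)

    def test_empty_calls_full_headers(self):
        calls = pd.DataFrame(
            columns=[
                "locus_id", "class_label", "r3b2_dependent", "ago1_bound",
                "wt_rpm", "log2fc_r3b2", "depleted_rdrp1", "depleted_rdrp2",
            ]
        )
        tables = summarize_classes(calls, None)
        assert (tables["dependency_by_category"].to_numpy() == 0).all()
        assert (tables["r3b2_by_class"]["n_loci"] == 0).all()


def test_classification_recovers_expected_rpm_truth(small_dataset, small_libraries):
    """Classifying the simulator's own expected-RPM table reproduces the
    planted class labels exactly (no sampling noise on this path)."""
    _, expected_rpm = small_libraries
    calls = classify_all(expected_rpm)
    merged = calls.merge(
        small_dataset.truth[["locus_id", "class_label"]].rename(
            columns={"class_label": "true_label"}
        ),
        on="locus_id",
    )
    planted = merged[merged["true_label"] != "background"]
    # expected RPM for planted loci is well above the floor in this design
    above = planted[planted["wt_rpm"] > 50]
    assert (above["class_label"] == above["true_label"]).all()
    bg = merged[merged["true_label"] == "background"]
    assert (bg["class_label"] == "unclassified").all()
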