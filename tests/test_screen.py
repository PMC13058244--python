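"""Screening pipeline: enumeration, filters, best-model choice, end-to-end."""

import math

import numpy as np
import pandas as pd
import pytest

from crkscreen import screen
from crkscreen.screen import (
    ScreenConfig,
    adaptive_interface_cutoff,
    combined_score,
    confidence_filter,
    enumerate_pairs,
    interface_filter,
    select_best_model,
    summarize_orientations,
)


class TestEnumeration:
    def test_38_with_self_pairs_gives_741(self):
        ids = [f"CRK{i}" for i in range(38)]
        assert len(enumerate_pairs(ids, include_self=True)) == 741

    def test_40_without_self_pairs_gives_780(self):
        ids = [f"CRK{i}" for i in range(40)]
        assert len(enumerate_pairs(ids, include_self=False)) == 780

    def test_two_ids_with_self(self):
        assert enumerate_pairs(["b", "a"], include_self=True) == [
            ("a", "a"),
            ("a", "b"),
            ("b", "b"),
        ]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs(["a", "a"])

    def test_canonical_lexicographic_order(self):
        pairs = enumerate_pairs(["c", "a", "b"], include_self=False)
        assert pairs == sorted(pairs)
        assert all(a <= b for a, b in pairs)


class TestConfidenceFilter:
    CFG = ScreenConfig()

    @pytest.mark.parametrize(
        "combined,ipae,expected",
        [
            (0.85, 5.0, True),
            (0.80, 5.0, False),  # strict >
            (0.90, 6.0, False),  # strict <
            (0.79, 7.0, False),
        ],
    )
    def test_strict_inequalities(self, combined, ipae, expected):
        ok, _ = confidence_filter(combined, ipae, self.CFG)
        assert ok is expected

    def test_missing_scores_fail_with_reason(self):
        ok, reason = confidence_filter(None, 5.0, self.CFG)
        assert not ok and reason == "missing"
        ok, reason = confidence_filter(float("nan"), 5.0, self.CFG)
        assert not ok and reason == "missing"

    def test_inclusive_mode(self):
        cfg = ScreenConfig(inclusive_cutoffs=True)
        assert confidence_filter(0.80, 6.0, cfg)[0]

    def test_combined_score_modes(self):
        assert combined_score(0.9, 0.5) == pytest.approx(0.8 * 0.9 + 0.2 * 0.5)
        assert combined_score(0.9, 0.5, mode="sum") == pytest.approx(1.4)


class TestBestModel:
    CFG = ScreenConfig()

    def frame(self, rows):
        return pd.DataFrame(rows, columns=["model_rank", "combined", "ipae", "iptm", "ptm"])

    def test_single_passing_model_selected(self):
        models = self.frame([(1, 0.5, 9.0, 0.5, 0.5), (2, 0.9, 3.0, 0.9, 0.9), (3, 0.6, 8.0, 0.6, 0.6)])
        assert select_best_model(models, self.CFG) == 2

    def test_none_pass_returns_none(self):
        models = self.frame([(1, 0.5, 9.0, 0.5, 0.5), (2, 0.7, 7.0, 0.7, 0.7)])
        assert select_best_model(models, self.CFG) is None

    def test_tie_breaks_to_lower_ipae_then_rank(self):
        models = self.frame([(1, 0.9, 4.0, 0.9, 0.9), (2, 0.9, 3.0, 0.9, 0.9)])
        assert select_best_model(models, self.CFG) == 2
        models = self.frame([(2, 0.9, 3.0, 0.9, 0.9), (1, 0.9, 3.0, 0.9, 0.9)])
        assert select_best_model(models, self.CFG) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_model(self.frame([]), self.CFG)


class TestAdaptiveCutoff:
    def test_printed_mean_and_sd_give_29(self):
        # a counts vector with mean 34 and sample SD 5.5 -> ceil(28.5) = 29
        counts = [34 - 5.5, 34 + 5.5]
        cutoff, mean, sd = adaptive_interface_cutoff(counts)
        assert (mean, sd) == (34.0, pytest.approx(5.5 * math.sqrt(2)))
        # construct exactly: a symmetric 3-point set with sample SD 5.5
        counts = [34.0, 34 - 5.5, 34 + 5.5]
        cutoff, mean, sd = adaptive_interface_cutoff(counts)
        assert mean == pytest.approx(34.0)
        assert sd == pytest.approx(5.5)
        assert cutoff == 29

    def test_equal_counts_sd_zero(self):
        assert adaptive_interface_cutoff([30, 30, 30])[0] == 30

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_mean_sd_ceil_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(10, 60, size=20).astype(float)
        cutoff, mean, sd = adaptive_interface_cutoff(counts)
        mu = sum(counts) / len(counts)
        var = sum((c - mu) ** 2 for c in counts) / (len(counts) - 1)
        assert cutoff == math.ceil(mu - math.sqrt(var))

    def test_too_few_counts_rejected(self):
        with pytest.raises(ValueError):
            adaptive_interface_cutoff([5])


class TestInterfaceFilter:
    @pytest.mark.parametrize(
        "a,b,cutoff,expected",
        [
            (30, 31, 29, True),
            (35, 20, 29, False),  # per-chain rule
            (29, 29, 29, True),  # inclusive ("or more")
        ],
    )
    def test_per_chain_rule(self, a, b, cutoff, expected):
        assert interface_filter(a, b, cutoff) is expected

    def test_total_mode(self):
        assert interface_filter(35, 20, 29, rule="total")


class TestSummarizeOrientations:
    def test_counting_matches_planted_cohort(self):
        records = pd.DataFrame(
            {
                "id1": ["a"] * 78 + ["b"] * 14 + ["c"] * 8,
                "id2": ["x"] * 100,
                "orientation": ["Standard"] * 78 + ["Flipped"] * 14 + ["FlippedShifted"] * 8,
                "passed_interface": [True] * 100,
            }
        )
        out = summarize_orientations(records)
        assert out["fractions"]["Standard"]["percent"] == 78
        assert out["fractions"]["Flipped"]["percent"] == 14
        assert out["fractions"]["FlippedShifted"]["percent"] == 8

    def test_single_record_is_total(self):
        records = pd.DataFrame(
            {"id1": ["a"], "id2": ["b"], "orientation": ["Flipped"], "passed_interface": [True]}
        )
        out = summarize_orientations(records)
        assert out["fractions"]["Flipped"]["percent"] == 100

    def test_group_tally_counts_dimers_in_both_groups(self):
        records = pd.DataFrame(
            {
                "id1": ["a", "a"],
                "id2": ["b", "a"],
                "orientation": ["Standard", "Flipped"],
                "passed_interface": [True, True],
            }
        )
        out = summarize_orientations(records, groups={"a": "I", "b": "II"})
        assert out["by_group"]["I"] == {"Standard": 1, "Flipped": 1}
        assert out["by_group"]["II"] == {"Standard": 1}


class TestRunScreen:
    def test_stage_counts_match_planted_ground_truth(self, cohort):
        out, man = cohort
        records, summary = screen.run_screen(
            out / "models", out / "pae", out / "scores.tsv", out / "annotations.tsv"
        )
        assert summary["n_enumerated"] == man.n_enumerated
        assert summary["n_confidence_passed"] == man.n_confidence
        assert summary["n_interface_passed"] == man.n_retained
        retained = {tuple(sorted((r.id1, r.id2))) for r in records[records.passed_interface].itertuples()}
        assert retained == set(man.pass_pairs)
        # planted orientations recovered on every retained pair
        for r in records[records.passed_interface].itertuples():
            assert r.orientation == man.orientations[(r.id1, r.id2)]

    def test_stage_counts_non_increasing(self, cohort):
        out, _ = cohort
        _, summary = screen.run_screen(
            out / "models", out / "pae", out / "scores.tsv", out / "annotations.tsv"
        )
        assert (
            summary["n_enumerated"]
            >= summary["n_confidence_passed"]
            >= summary["n_interface_passed"]
        )

    def test_fixed_cutoff_zero_is_no_op(self, cohort):
        out, _ = cohort
        cfg = ScreenConfig(adaptive_cutoff_mode="fixed", fixed_interface_cutoff=0)
        _, summary = screen.run_screen(
            out / "models", out / "pae", out / "scores.tsv", out / "annotations.tsv", cfg
        )
        assert summary["n_interface_passed"] == summary["n_confidence_passed"]

    def test_rerun_is_byte_identical(self, cohort, tmp_path):
        out, _ = cohort
        paths = []
        for run in (1, 2):
            records, summary = screen.run_screen(
                out / "models", out / "pae", out / "scores.tsv", out / "annotations.tsv"
            )
            dest = tmp_path / f"run{run}"
            screen.write_outputs(records, summary, dest)
            paths.append(dest)
        for name in ("screen_records.tsv", "screen_summary.json", "retained_pairs.tsv"):
            assert (paths[0] / name).read_bytes() == (paths[1] / name).read_bytes()

    def test_precision_and_recall_are_perfect_on_fixture(self, cohort):
        out, man = cohort
        records, _ = screen.run_screen(
            out / "models", out / "pae", out / "scores.tsv", out / "annotations.tsv"
        )
        predicted = {tuple(sorted((r.id1, r.id2))) for r in records[records.passed_interface].itertuples()}
        truth = set(man.pass_pairs)
        assert predicted == truth  # precision = recall = 1
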