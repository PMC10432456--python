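"""Comparison statistics: correlations, classes, agreement, RSA, calibration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from maskstack.core import ALPHABET, ValidationError
from maskstack.evaluation import (
    MAX_ASA_THEORETICAL,
    accuracy_correlation,
    add_call_columns,
    agreement_category,
    agreement_summary,
    calibration_curve,
    class_accuracy,
    confidence_rsa_profile,
    correct_prediction_aa_distribution,
    per_protein_accuracy,
    rsa_from_asa,
)

FAMILIES = {
    "struct_a": "structure",
    "struct_b": "structure",
    "seq_a": "sequence",
    "seq_b": "sequence",
}


def prediction_row(protein, site, wildtype, model, top, top_p=0.7):
    row = {"protein_id": protein, "site": site, "wildtype": wildtype, "model_id": model}
    rest = (1.0 - top_p) / 19
    for aa in ALPHABET:
        row[f"p_{aa}"] = top_p if aa == top else rest
    return row


def table(rows):
    return pd.DataFrame(rows)


class TestAccuracyCorrelation:
    def test_self_correlation_is_one(self):
        res = accuracy_correlation([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert res.r == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        res = accuracy_correlation([0.1, 0.5, 0.9], [0.9, 0.5, 0.1])
        assert res.r == pytest.approx(-1.0)

    def test_matches_textbook_product_moment_formula(self):
        a = np.array([0.2, 0.4, 0.9])
        b = np.array([0.3, 0.1, 0.8])
        # independent hand computation of the product-moment coefficient
        expected = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        res = accuracy_correlation(a, b)
        assert res.r == pytest.approx(expected)
        assert expected == pytest.approx(0.22 / 0.26)

    def test_zero_variance_flagged_not_zero(self):
        res = accuracy_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert res.degenerate
        assert np.isnan(res.r)

    def test_small_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValidationError):
            accuracy_correlation([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValidationError):
            accuracy_correlation([0.1, 0.2, 0.3], [0.3, 0.4])


class TestClassAccuracy:
    def test_all_correct_gives_ones(self):
        rows = [prediction_row("P1", i + 1, aa, "m", aa) for i, aa in enumerate("LKDG")]
        out = class_accuracy(table(rows))
        assert (out["accuracy"] == 1.0).all()

    def test_direct_count_example(self):
        rows = [
            prediction_row("P1", 1, "L", "m", "L"),   # aliphatic, correct
            prediction_row("P1", 2, "L", "m", "K"),   # aliphatic, wrong
            prediction_row("P1", 3, "D", "m", "D"),   # negative, correct
            prediction_row("P1", 4, "D", "m", "D"),   # negative, correct
        ]
        out = class_accuracy(table(rows)).set_index("aa_class")
        assert out.loc["aliphatic", "accuracy"] == 0.5
        assert out.loc["negative", "accuracy"] == 1.0
        assert "polar" not in out.index  # zero-site classes absent, not 0

    def test_matches_brute_force_recount(self, fixture_benchmarks):
        from maskstack.core import DEFAULT_CLASS_TABLE

        train, _ = fixture_benchmarks
        scored = add_call_columns(train.predictions_for("seq_a"))
        out = class_accuracy(scored).set_index("aa_class")
        # independent recount: python loop over rows
        counts: dict[str, list[int]] = {}
        for _, row in scored.iterrows():
            cls = DEFAULT_CLASS_TABLE[row["wildtype"]]
            c = counts.setdefault(cls, [0, 0])
            c[0] += int(row["correct"])
            c[1] += 1
        for cls, (ok, tot) in counts.items():
            assert out.loc[cls, "accuracy"] == pytest.approx(ok / tot)
            assert out.loc[cls, "n_sites"] == tot


class TestAgreementCategories:
    def test_scalar_category_assignments(self):
        base = {"struct_a": "K", "struct_b": "K", "seq_a": "K", "seq_b": "K"}
        assert agreement_category("K", base, FAMILIES) == "all_four"
        base = {"struct_a": "L", "struct_b": "V", "seq_a": "K", "seq_b": "K"}
        assert agreement_category("K", base, FAMILIES) == "sequence_only"
        base = {"struct_a": "K", "struct_b": "V", "seq_a": "K", "seq_b": "L"}
        assert agreement_category("K", base, FAMILIES) == "mixed"
        base = {"struct_a": "L", "struct_b": "V", "seq_a": "M", "seq_b": "N"}
        assert agreement_category("K", base, FAMILIES) == "none"
        with pytest.raises(ValidationError):
            agreement_category("K", base, {"struct_a": "structure"})

    def _combined(self, rows):
        return table([prediction_row(*r, "combined", r[3]) for r in rows])

    def test_unanimous_correct_gives_single_category(self):
        base_rows, comb_rows = [], []
        for site, aa in enumerate("LKDG", start=1):
            for m in FAMILIES:
                base_rows.append(prediction_row("P1", site, aa, m, aa))
            comb_rows.append(prediction_row("P1", site, aa, "combined", aa))
        summary = agreement_summary(table(base_rows), table(comb_rows), FAMILIES)
        out = summary.set_index("category")
        assert out.loc["all_four", "proportion"] == 1.0
        assert out.loc["all_four", "accuracy"] == 1.0
        assert summary["proportion"].sum() == pytest.approx(1.0)

    def test_partition_and_recount_on_benchmark(self, paper_run):
        """Category counts partition all sites and accuracies match an
        independent per-site recount."""
        base = add_call_columns(paper_run.eval_benchmark.predictions)
        comb = add_call_columns(paper_run.combined_predictions)
        summary = agreement_summary(base, comb, paper_run.eval_benchmark.families)
        n_sites = comb[["protein_id", "site"]].drop_duplicates().shape[0]
        assert summary["n_sites"].sum() == n_sites
        assert summary["proportion"].sum() == pytest.approx(1.0)

        # brute-force recount over every site of a few proteins, using the
        # scalar category function as the independent oracle
        proteins = sorted(comb["protein_id"].unique())[:5]
        sub_base = base[base["protein_id"].isin(proteins)]
        sub_comb = comb[comb["protein_id"].isin(proteins)]
        base_idx = sub_base.set_index(["protein_id", "site", "model_id"])["top1"]
        recount: dict[str, list[int]] = {}
        for _, row in sub_comb.iterrows():
            key = (row["protein_id"], row["site"])
            calls = {m: base_idx.loc[key + (m,)] for m in FAMILIES}
            cat = agreement_category(row["top1"], calls, FAMILIES)
            rec = recount.setdefault(cat, [0, 0])
            rec[0] += int(row["top1"] == row["wildtype"])
            rec[1] += 1
        sub_summary = agreement_summary(
            sub_base, sub_comb, paper_run.eval_benchmark.families
        ).set_index("category")
        for cat, (ok, tot) in recount.items():
            assert sub_summary.loc[cat, "n_sites"] == tot
            assert sub_summary.loc[cat, "accuracy"] == pytest.approx(ok / tot)


class TestRSA:
    def test_zero_asa_gives_zero_rsa(self):
        assert rsa_from_asa(0.0, "W") == 0.0

    def test_asa_equal_to_constant_gives_one(self):
        for aa, c in MAX_ASA_THEORETICAL.items():
            assert rsa_from_asa(c, aa) == pytest.approx(1.0)

    def test_half_alanine_constant(self):
        assert rsa_from_asa(MAX_ASA_THEORETICAL["A"] / 2, "A") == pytest.approx(0.5)

    def test_linear_in_asa(self, rng):
        asa = rng.uniform(0, 200, size=10)
        out = np.asarray(rsa_from_asa(asa, ["L"] * 10))
        np.testing.assert_allclose(out, asa / MAX_ASA_THEORETICAL["L"])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            rsa_from_asa(-1.0, "A")
        with pytest.raises(ValidationError):
            rsa_from_asa(10.0, "A", constants={"L": 201.0})

    def test_values_above_one_preserved(self):
        assert rsa_from_asa(2 * MAX_ASA_THEORETICAL["G"], "G") == pytest.approx(2.0)


class TestConfidenceRSAProfile:
    def test_single_cell_case(self):
        rows = [prediction_row("P1", i + 1, "A", "m", "A", top_p=0.5) for i in range(10)]
        ann = pd.DataFrame(
            {"protein_id": "P1", "site": range(1, 11), "rsa": [0.1] * 10}
        )
        prof = confidence_rsa_profile(table(rows), ann)
        assert prof.total == 10
        assert (prof.counts > 0).sum() == 1

    def test_counts_conserved_and_missing_rsa_excluded(self):
        rows = [prediction_row("P1", i + 1, "A", "m", "A") for i in range(10)]
        ann = pd.DataFrame(
            {"protein_id": "P1", "site": range(1, 9), "rsa": np.linspace(0, 0.9, 8)}
        )
        prof = confidence_rsa_profile(table(rows), ann)
        assert prof.total == 8
        assert prof.n_excluded == 2


class TestCalibration:
    def test_perfectly_calibrated_oracle(self, rng):
        """Confidence drawn equal to the correctness probability must track
        empirical accuracy bin by bin."""
        n = 20_000
        p = rng.uniform(0.25, 0.95, size=n)
        correct = rng.random(n) < p
        top = np.where(correct, "L", "K")
        rows = []
        frame = pd.DataFrame(
            {
                "protein_id": "P1",
                "site": np.arange(1, n + 1),
                "wildtype": "L",
                "model_id": "m",
            }
        )
        rest = (1.0 - p) / 19
        probs = np.tile(rest[:, None], (1, 20))
        for i, aa in enumerate(ALPHABET):
            frame[f"p_{aa}"] = probs[:, i]
        l_idx, k_idx = ALPHABET.index("L"), ALPHABET.index("K")
        pl = np.where(top == "L", p, rest)
        pk = np.where(top == "K", p, rest)
        frame["p_L"], frame["p_K"] = pl, pk
        # renormalize exactly
        cols = [f"p_{aa}" for aa in ALPHABET]
        vals = frame[cols].to_numpy()
        frame[cols] = vals / vals.sum(axis=1, keepdims=True)
        curve = calibration_curve(frame)
        for _, row in curve.iterrows():
            if row["n_sites"] < 100:
                continue
            se = np.sqrt(row["mean_confidence"] * (1 - row["mean_confidence"]) / row["n_sites"])
            assert abs(row["accuracy"] - row["mean_confidence"]) < 3 * se + 0.02

    def test_all_correct_gives_unit_accuracy(self):
        rows = [prediction_row("P1", i + 1, "A", "m", "A") for i in range(10)]
        curve = calibration_curve(table(rows))
        assert (curve["accuracy"] == 1.0).all()

    def test_bin_counts_conserved(self, fixture_benchmarks):
        train, _ = fixture_benchmarks
        sub = train.predictions_for("struct_a")
        curve = calibration_curve(sub)
        assert curve["n_sites"].sum() == len(sub)


class TestAADistributions:
    def test_two_residue_example(self):
        base_rows, comb_rows = [], []
        site = 0
        for aa in ("L", "V"):
            for _ in range(3):
                site += 1
                for m in FAMILIES:
                    base_rows.append(prediction_row("P1", site, aa, m, aa))
                comb_rows.append(prediction_row("P1", site, aa, "combined", aa))
        dist = correct_prediction_aa_distribution(
            table(base_rows), table(comb_rows), FAMILIES, "all_four"
        ).set_index("amino_acid")
        assert dist.loc["L", "frequency"] == pytest.approx(0.5)
        assert dist.loc["V", "frequency"] == pytest.approx(0.5)
        assert dist["frequency"].sum() == pytest.approx(1.0)

    def test_empty_category_returns_none(self):
        base_rows, comb_rows = [], []
        for m in FAMILIES:
            base_rows.append(prediction_row("P1", 1, "L", m, "L"))
        comb_rows.append(prediction_row("P1", 1, "L", "combined", "L"))
        out = correct_prediction_aa_distribution(
            table(base_rows), table(comb_rows), FAMILIES, "none"
        )
        assert out is None

    def test_structure_reliant_sites_skew_aliphatic(self, paper_run):
        """Sites where only structure-like models back the combined call are
        richer in aliphatic residues than sequence-only sites."""
        base = add_call_columns(paper_run.eval_benchmark.predictions)
        comb = add_call_columns(paper_run.combined_predictions)
        fam = paper_run.eval_benchmark.families
        aliphatic = set("AILMV")
        masses = {}
        for cat in ("structure_only", "sequence_only"):
            d = correct_prediction_aa_distribution(base, comb, fam, cat)
            masses[cat] = d[d["amino_acid"].isin(aliphatic)]["frequency"].sum()
        assert masses["structure_only"] > masses["sequence_only"]


def test_per_protein_accuracy_matches_direct_groupby(fixture_benchmarks):
    train, _ = fixture_benchmarks
    scored = add_call_columns(train.predictions)
    out = per_protein_accuracy(scored)
    one = scored[(scored["protein_id"] == "FTRAIN0000") & (scored["model_id"] == "seq_a")]
    assert out.loc["FTRAIN0000", "seq_a"] == pytest.approx(
        (one["top1"] == one["wildtype"]).mean()
    )
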