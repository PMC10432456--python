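"""The comparison statistics battery.

Given per-site predictions from the four base models and the combined
model, this module computes every summary used to compare them:

* per-protein top-1 accuracies and their cross-model Pearson correlations;
* accuracy within each biochemical amino-acid class;
* the agreement-category partition — for every site, which subset of base
  models' top-1 calls matches the combined call (all four / structure-only /
  sequence-only / mixed / none) — with per-category accuracy, proportion
  and count;
* relative solvent accessibility (RSA) handling: normalization of raw
  accessible-surface areas by per-residue maximum-ASA constants, and 2-D
  (RSA x confidence) profiles with per-RSA-bin mean confidence;
* confidence calibration curves;
* the distribution over amino acids of correctly predicted sites, overall
  and within each agreement category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ALPHABET,
    DEFAULT_CLASS_TABLE,
    PROB_COLUMNS,
    ValidationError,
    validate_class_table,
)
from .synthetic import BURIAL_THRESHOLD

AGREEMENT_CATEGORIES: tuple[str, ...] = (
    "all_four",
    "structure_only",
    "sequence_only",
    "mixed",
    "none",
)

#: Theoretical maximum accessible surface areas (A^2) per residue, used to
#: normalize raw ASA into RSA = ASA / maxASA.  Tien et al. (2013)
#: theoretical set; configurable, and echoed into every report.
MAX_ASA_THEORETICAL: dict[str, float] = {
    "A": 129.0, "C": 167.0, "D": 193.0, "E": 223.0, "F": 240.0,
    "G": 104.0, "H": 224.0, "I": 197.0, "K": 236.0, "L": 201.0,
    "M": 224.0, "N": 195.0, "P": 159.0, "Q": 225.0, "R": 274.0,
    "S": 155.0, "T": 172.0, "V": 174.0, "W": 285.0, "Y": 263.0,
}


def add_call_columns(predictions: pd.DataFrame) -> pd.DataFrame:
    """Append vectorized ``top1``, ``confidence`` and ``correct`` columns."""
    out = predictions.copy()
    probs = out[PROB_COLUMNS].to_numpy(dtype=float)
    top_idx = probs.argmax(axis=1)  # first max wins = alphabet-order tie rule
    out["top1"] = np.array(ALPHABET)[top_idx]
    out["confidence"] = probs.max(axis=1)
    out["correct"] = out["top1"] == out["wildtype"]
    return out


# --------------------------------------------------------------------------
# per-protein accuracy and correlations


def per_protein_accuracy(predictions: pd.DataFrame) -> pd.DataFrame:
    """Accuracy per (model, protein): wide frame, proteins x models."""
    scored = predictions if "correct" in predictions else add_call_columns(predictions)
    table = (
        scored.groupby(["protein_id", "model_id"], observed=True)["correct"]
        .mean()
        .unstack("model_id")
    )
    if table.isna().any().any():
        raise ValidationError("some proteins lack predictions for some models")
    return table


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of two models' per-protein accuracies."""

    model_a: str
    model_b: str
    r: float
    p_value: float
    n: int
    degenerate: bool = False  # zero variance in either accuracy vector


def accuracy_correlation(
    acc_a: Sequence[float],
    acc_b: Sequence[float],
    model_a: str = "A",
    model_b: str = "B",
) -> CorrelationResult:
    """Product-moment correlation between two aligned accuracy vectors.

    A zero-variance vector makes r undefined: the result is flagged
    ``degenerate`` with NaN statistics rather than silently reported as 0.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("accuracy vectors must be aligned over the same proteins")
    n = len(a)
    if n < 3:
        raise ValidationError("need at least 3 proteins for a defined p-value")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(model_a, model_b, float("nan"), float("nan"), n, True)
    res = stats.pearsonr(a, b)
    return CorrelationResult(model_a, model_b, float(res.statistic), float(res.pvalue), n)


def correlation_matrix(per_protein: pd.DataFrame) -> pd.DataFrame:
    """All pairwise accuracy correlations; long frame of CorrelationResults."""
    models = list(per_protein.columns)
    rows = []
    for i, ma in enumerate(models):
        for mb in models[i + 1 :]:
            res = accuracy_correlation(per_protein[ma], per_protein[mb], ma, mb)
            rows.append(
                {
                    "model_a": res.model_a,
                    "model_b": res.model_b,
                    "r": res.r,
                    "p_value": res.p_value,
                    "n": res.n,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# class accuracy


def class_accuracy(
    predictions: pd.DataFrame,
    class_table: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Accuracy per biochemical class of the *wildtype* residue.

    Sites are pooled over proteins.  Classes with zero sites are absent
    from the result (not reported as 0).
    """
    table = validate_class_table(
        DEFAULT_CLASS_TABLE if class_table is None else class_table
    )
    scored = predictions if "correct" in predictions else add_call_columns(predictions)
    scored = scored.assign(aa_class=scored["wildtype"].map(table))
    grouped = scored.groupby("aa_class", observed=True)["correct"].agg(["mean", "size"])
    grouped.columns = ["accuracy", "n_sites"]
    return grouped.reset_index()


# --------------------------------------------------------------------------
# agreement categories


def agreement_category(
    combined_top1: str,
    base_top1: Mapping[str, str],
    families: Mapping[str, str],
) -> str:
    """Category of one site from the combined call and the four base calls.

    Let S be the set of base models agreeing with the combined call:
    ``all_four`` if |S| = 4, ``none`` if S is empty, ``structure_only`` /
    ``sequence_only`` if S is non-empty and single-family, else ``mixed``.
    """
    missing = set(base_top1) - set(families)
    if missing:
        raise ValidationError(f"family map lacks models {sorted(missing)}")
    agreeing = {m for m, call in base_top1.items() if call == combined_top1}
    if len(agreeing) == len(base_top1):
        return "all_four"
    if not agreeing:
        return "none"
    fams = {families[m] for m in agreeing}
    if fams == {"structure"}:
        return "structure_only"
    if fams == {"sequence"}:
        return "sequence_only"
    return "mixed"


def _site_frame(
    base_predictions: pd.DataFrame,
    combined_predictions: pd.DataFrame,
    families: Mapping[str, str],
) -> pd.DataFrame:
    """Per-site frame with combined call, per-family agreement counts, category."""
    base = (
        base_predictions
        if "top1" in base_predictions
        else add_call_columns(base_predictions)
    )
    comb = (
        combined_predictions
        if "top1" in combined_predictions
        else add_call_columns(combined_predictions)
    )
    unknown = set(base["model_id"].unique()) - set(families)
    if unknown:
        raise ValidationError(f"family map lacks models {sorted(unknown)}")

    comb_idx = comb.set_index(["protein_id", "site"])
    wide = base.pivot(index=["protein_id", "site"], columns="model_id", values="top1")
    if wide.isna().any().any():
        raise ValidationError("agreement analysis requires all four base calls per site")
    aligned = comb_idx.reindex(wide.index)
    if aligned["top1"].isna().any():
        raise ValidationError("sites missing a combined prediction")

    models = list(wide.columns)
    agree = wide.to_numpy() == aligned["top1"].to_numpy()[:, None]
    struct_models = [m in [k for k, f in families.items() if f == "structure"] for m in models]
    struct_mask = np.array(struct_models)
    n_agree = agree.sum(axis=1)
    n_struct = agree[:, struct_mask].sum(axis=1)
    n_seq = n_agree - n_struct

    category = np.full(len(wide), "mixed", dtype=object)
    category[n_agree == len(models)] = "all_four"
    category[n_agree == 0] = "none"
    single_struct = (n_seq == 0) & (n_struct > 0) & (n_agree < len(models))
    single_seq = (n_struct == 0) & (n_seq > 0) & (n_agree < len(models))
    category[single_struct] = "structure_only"
    category[single_seq] = "sequence_only"

    out = wide.index.to_frame(index=False)
    out["combined_top1"] = aligned["top1"].to_numpy()
    out["combined_confidence"] = aligned["confidence"].to_numpy()
    out["wildtype"] = aligned["wildtype"].to_numpy()
    out["combined_correct"] = aligned["correct"].to_numpy()
    out["n_agreeing"] = n_agree
    out["n_structure_agreeing"] = n_struct
    out["n_sequence_agreeing"] = n_seq
    out["category"] = category
    return out


def agreement_summary(
    base_predictions: pd.DataFrame,
    combined_predictions: pd.DataFrame,
    families: Mapping[str, str],
) -> pd.DataFrame:
    """Per-category accuracy, proportion and count over all sites.

    The five categories partition the sites exactly, so the proportions sum
    to 1.  A per-|S| breakdown (how many base models agreed) is recoverable
    from :func:`_site_frame`'s ``n_agreeing`` column, which
    :func:`evaluate_models` also exports.
    """
    sites = _site_frame(base_predictions, combined_predictions, families)
    total = len(sites)
    rows = []
    for cat in AGREEMENT_CATEGORIES:
        sub = sites[sites["category"] == cat]
        rows.append(
            {
                "category": cat,
                "n_sites": len(sub),
                "proportion": len(sub) / total,
                "accuracy": sub["combined_correct"].mean() if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# RSA handling


def rsa_from_asa(
    asa: float | np.ndarray,
    wildtype: str | Sequence[str],
    constants: Mapping[str, float] | None = None,
) -> np.ndarray | float:
    """Normalize accessible surface area (A^2) to an RSA fraction.

    RSA = ASA / maxASA(residue).  Values above 1 are preserved (extended
    conformations can exceed the reference area); callers flag them.
    """
    table = MAX_ASA_THEORETICAL if constants is None else dict(constants)
    scalar = np.isscalar(asa) and isinstance(wildtype, str)
    asa_arr = np.atleast_1d(np.asarray(asa, dtype=float))
    wt_arr = np.atleast_1d(np.asarray([wildtype] if isinstance(wildtype, str) else wildtype))
    if np.any(asa_arr < 0):
        raise ValidationError("negative ASA values")
    missing = sorted(set(wt_arr) - set(table))
    if missing:
        raise ValidationError(f"no max-ASA constant for residues {missing}")
    denom = np.array([table[aa] for aa in wt_arr])
    rsa = asa_arr / denom
    return float(rsa[0]) if scalar else rsa


@dataclass
class RSAProfile:
    """2-D histogram over (RSA bin x confidence bin) for one model."""

    model_id: str
    rsa_edges: np.ndarray
    confidence_edges: np.ndarray
    counts: np.ndarray  # shape (n_rsa_bins, n_conf_bins)
    mean_confidence: pd.DataFrame = field(repr=False)  # per-RSA-bin mean
    n_excluded: int = 0  # sites lacking an RSA value

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confidence_rsa_profile(
    predictions: pd.DataFrame,
    rsa: pd.DataFrame,
    *,
    rsa_bin_width: float = 0.025,
    confidence_bin_width: float = 0.025,
    model_id: str | None = None,
) -> RSAProfile:
    """Joint (RSA, confidence) histogram plus per-RSA-bin mean confidence.

    ``rsa`` is an annotation frame (protein_id, site, rsa).  Sites lacking
    an RSA value are excluded and counted in ``n_excluded``.  Fine default
    bins (0.025) allow arbitrary coarser re-binning downstream.
    """
    scored = predictions if "confidence" in predictions else add_call_columns(predictions)
    if model_id is not None:
        scored = scored[scored["model_id"] == model_id]
    else:
        ids = scored["model_id"].unique()
        if len(ids) != 1:
            raise ValidationError(f"profile needs a single model, table has {list(ids)}")
        model_id = str(ids[0])
    merged = scored.merge(rsa[["protein_id", "site", "rsa"]], on=["protein_id", "site"], how="left")
    has_rsa = merged["rsa"].notna()
    n_excluded = int((~has_rsa).sum())
    merged = merged[has_rsa]

    max_rsa = max(1.0, float(merged["rsa"].max())) if len(merged) else 1.0
    rsa_edges = np.arange(0.0, max_rsa + rsa_bin_width, rsa_bin_width)
    conf_edges = np.arange(0.0, 1.0 + confidence_bin_width, confidence_bin_width)
    counts, rsa_edges, conf_edges = np.histogram2d(
        merged["rsa"], merged["confidence"], bins=[rsa_edges, conf_edges]
    )

    bin_idx = np.clip(
        np.digitize(merged["rsa"], rsa_edges) - 1, 0, len(rsa_edges) - 2
    )
    mean_conf = (
        pd.DataFrame({"rsa_bin": bin_idx, "confidence": merged["confidence"]})
        .groupby("rsa_bin")["confidence"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "mean_confidence", "size": "n_sites"})
        .reset_index()
    )
    mean_conf["rsa_lo"] = rsa_edges[mean_conf["rsa_bin"]]
    mean_conf["rsa_hi"] = rsa_edges[mean_conf["rsa_bin"] + 1]
    return RSAProfile(
        model_id=model_id,
        rsa_edges=rsa_edges,
        confidence_edges=conf_edges,
        counts=counts.astype(int),
        mean_confidence=mean_conf,
        n_excluded=n_excluded,
    )


def burial_confidence_gap(profile: RSAProfile) -> tuple[float, float]:
    """(mean confidence below the burial threshold, mean at/above it)."""
    mc = profile.mean_confidence
    buried = mc["rsa_hi"] <= BURIAL_THRESHOLD + 1e-12
    w = mc["n_sites"]
    lo = np.average(mc.loc[buried, "mean_confidence"], weights=w[buried])
    hi = np.average(mc.loc[~buried, "mean_confidence"], weights=w[~buried])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# calibration


def calibration_curve(
    predictions: pd.DataFrame,
    confidence_edges: np.ndarray | Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-confidence-bin mean confidence and empirical accuracy.

    Bins with zero sites are omitted.  Bin counts sum to the number of
    scored sites.
    """
    scored = predictions if "correct" in predictions else add_call_columns(predictions)
    if not len(scored):
        raise ValidationError("calibration_curve: empty input")
    edges = np.asarray(
        np.arange(0.0, 1.0500001, 0.05) if confidence_edges is None else confidence_edges,
        dtype=float,
    )
    bin_idx = np.clip(np.digitize(scored["confidence"], edges) - 1, 0, len(edges) - 2)
    out = (
        pd.DataFrame(
            {
                "bin": bin_idx,
                "confidence": scored["confidence"].to_numpy(),
                "correct": scored["correct"].to_numpy(),
            }
        )
        .groupby("bin")
        .agg(
            mean_confidence=("confidence", "mean"),
            accuracy=("correct", "mean"),
            n_sites=("correct", "size"),
        )
        .reset_index()
    )
    out["conf_lo"] = edges[out["bin"]]
    out["conf_hi"] = edges[out["bin"] + 1]
    return out


# --------------------------------------------------------------------------
# amino-acid distribution of correct predictions


def correct_prediction_aa_distribution(
    base_predictions: pd.DataFrame,
    combined_predictions: pd.DataFrame,
    families: Mapping[str, str],
    category: str = "overall",
) -> pd.DataFrame | None:
    """Wildtype amino-acid distribution of correctly combined-predicted sites.

    Restricted to one agreement category (or ``"overall"``); returned
    alongside the overall wildtype distribution for comparison.  Returns
    ``None`` when the category holds no correct site.
    """
    if category != "overall" and category not in AGREEMENT_CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    sites = _site_frame(base_predictions, combined_predictions, families)
    overall = sites["wildtype"].value_counts(normalize=True)
    sub = sites if category == "overall" else sites[sites["category"] == category]
    sub = sub[sub["combined_correct"]]
    if not len(sub):
        return None
    dist = sub["wildtype"].value_counts(normalize=True)
    frame = pd.DataFrame({"amino_acid": list(ALPHABET)})
    frame["frequency"] = frame["amino_acid"].map(dist).fillna(0.0)
    frame["overall_wildtype_frequency"] = frame["amino_acid"].map(overall).fillna(0.0)
    frame["n_sites"] = len(sub)
    return frame


# --------------------------------------------------------------------------
# full report


@dataclass
class EvaluationReport:
    """Bundle of every summary statistic, ready for serialization."""

    per_protein_accuracy: pd.DataFrame
    mean_accuracy: pd.Series
    correlations: pd.DataFrame
    class_accuracy: pd.DataFrame  # long: model_id, aa_class, accuracy, n_sites
    agreement: pd.DataFrame
    agreement_subcounts: pd.DataFrame  # per n_agreeing breakdown
    rsa_profiles: dict[str, RSAProfile]
    calibration: pd.DataFrame  # long: model_id + calibration columns
    aa_distributions: pd.DataFrame  # long: category + distribution columns
    config_echo: dict

    def summary(self) -> dict:
        """Scalar highlights as a plain dict (JSON-serializable)."""
        gaps = {
            m: burial_confidence_gap(p) for m, p in self.rsa_profiles.items()
        }
        return {
            "mean_accuracy": {k: float(v) for k, v in self.mean_accuracy.items()},
            "correlations": self.correlations.to_dict(orient="records"),
            "agreement": self.agreement.to_dict(orient="records"),
            "burial_confidence": {
                m: {"buried": lo, "exposed": hi} for m, (lo, hi) in gaps.items()
            },
        }


def evaluate_models(
    base_predictions: pd.DataFrame,
    combined_predictions: pd.DataFrame,
    families: Mapping[str, str],
    annotations: pd.DataFrame,
    *,
    class_table: Mapping[str, str] | None = None,
    config_echo: dict | None = None,
) -> EvaluationReport:
    """Run the complete battery over base + combined predictions."""
    table = validate_class_table(
        DEFAULT_CLASS_TABLE if class_table is None else class_table
    )
    base = add_call_columns(base_predictions)
    comb = add_call_columns(combined_predictions)
    everything = pd.concat([base, comb], ignore_index=True)

    per_prot = per_protein_accuracy(everything)
    correlations = correlation_matrix(per_prot)

    cls_rows = []
    for m, sub in everything.groupby("model_id", observed=True):
        ca = class_accuracy(sub, table)
        ca.insert(0, "model_id", m)
        cls_rows.append(ca)
    cls = pd.concat(cls_rows, ignore_index=True)

    agreement = agreement_summary(base, comb, families)
    sites = _site_frame(base, comb, families)
    sub = (
        sites.groupby("n_agreeing")["combined_correct"]
        .agg(["size", "mean"])
        .rename(columns={"size": "n_sites", "mean": "accuracy"})
        .reset_index()
    )

    profiles = {}
    for m, subp in everything.groupby("model_id", observed=True):
        profiles[str(m)] = confidence_rsa_profile(subp, annotations, model_id=str(m))

    cal_rows = []
    for m, subp in everything.groupby("model_id", observed=True):
        cc = calibration_curve(subp)
        cc.insert(0, "model_id", m)
        cal_rows.append(cc)
    calibration = pd.concat(cal_rows, ignore_index=True)

    dist_rows = []
    for cat in ("overall",) + AGREEMENT_CATEGORIES:
        d = correct_prediction_aa_distribution(base, comb, families, cat)
        if d is None:
            continue
        d.insert(0, "category", cat)
        dist_rows.append(d)
    aa_dist = pd.concat(dist_rows, ignore_index=True)

    echo = dict(config_echo or {})
    echo["class_table"] = dict(table)
    echo["max_asa_constants"] = dict(MAX_ASA_THEORETICAL)
    return EvaluationReport(
        per_protein_accuracy=per_prot,
        mean_accuracy=per_prot.mean(),
        correlations=correlations,
        class_accuracy=cls,
        agreement=agreement,
        agreement_subcounts=sub,
        rsa_profiles=profiles,
        calibration=calibration,
        aa_distributions=aa_dist,
        config_echo=echo,
    )


def write_report(report: EvaluationReport, outdir: str | Path) -> None:
    """Serialize a report as a directory of TSV tables plus a JSON summary."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.per_protein_accuracy.to_csv(outdir / "per_protein_accuracy.tsv", sep="\t")
    report.correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    report.class_accuracy.to_csv(outdir / "class_accuracy.tsv", sep="\t", index=False)
    report.agreement.to_csv(outdir / "agreement.tsv", sep="\t", index=False)
    report.agreement_subcounts.to_csv(
        outdir / "agreement_subcounts.tsv", sep="\t", index=False
    )
    report.calibration.to_csv(outdir / "calibration.tsv", sep="\t", index=False)
    report.aa_distributions.to_csv(
        outdir / "aa_distributions.tsv", sep="\t", index=False
    )
    for m, prof in report.rsa_profiles.items():
        prof.mean_confidence.to_csv(
            outdir / f"rsa_mean_confidence_{m}.tsv", sep="\t", index=False
        )
        np.savetxt(outdir / f"rsa_histogram_{m}.tsv", prof.counts, fmt="%d", delimiter="\t")
    (outdir / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    (outdir / "config_echo.json").write_text(json.dumps(report.config_echo, indent=2))
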