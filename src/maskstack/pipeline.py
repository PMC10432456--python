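"""End-to-end orchestration: simulate -> train -> evaluate -> report.

A :class:`RunConfig` bundles the protein simulation specs (separate train
and evaluation sets with disjoint identifier prefixes), the four oracle
profiles, the combiner training configuration and the evaluation options.
The default configuration is the "paper-like" setup: four complementary
oracles whose statistics echo the published comparison of two
structure-based and two sequence-based masked-residue predictors, scaled
to desk-size protein counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .combiner import (
    TrainedCombiner,
    TrainingConfig,
    assemble_feature_matrix,
    baseline_predictions,
    predict_combined,
    train_combiner,
)
from .core import PROB_COLUMNS, ValidationError
from .evaluation import EvaluationReport, evaluate_models, write_report
from .synthetic import (
    ConfidenceModel,
    OracleProfile,
    ProteinSimSpec,
    SyntheticBenchmark,
    generate_benchmark,
    paper_like_profiles,
)

COMBINED_MODEL_ID = "combined"


@dataclass
class RunConfig:
    """Full configuration of a paper-like run."""

    train_spec: ProteinSimSpec
    eval_spec: ProteinSimSpec
    profiles: list[OracleProfile]
    training: TrainingConfig
    seed: int = 0

    @classmethod
    def paper_like(
        cls,
        seed: int = 0,
        *,
        n_train: int = 300,
        n_eval: int = 150,
        epochs: int = 150,
    ) -> "RunConfig":
        """Default study conditions: 300 training / 150 evaluation proteins."""
        profiles = paper_like_profiles()
        return cls(
            train_spec=ProteinSimSpec(n_proteins=n_train, id_prefix="TRAIN"),
            eval_spec=ProteinSimSpec(n_proteins=n_eval, id_prefix="EVAL"),
            profiles=profiles,
            training=TrainingConfig(
                epochs=epochs,
                seed=seed,
                model_order=tuple(p.model_id for p in profiles),
            ),
            seed=seed,
        )

    @classmethod
    def fixture(cls, seed: int = 0, *, epochs: int = 5) -> "RunConfig":
        """Miniature configuration (5 proteins x 60 residues) for tests."""
        profiles = paper_like_profiles()
        return cls(
            train_spec=ProteinSimSpec(
                n_proteins=5, length_range=(60, 60), id_prefix="FTRAIN"
            ),
            eval_spec=ProteinSimSpec(
                n_proteins=5, length_range=(60, 60), id_prefix="FEVAL"
            ),
            profiles=profiles,
            training=TrainingConfig(
                epochs=epochs,
                seed=seed,
                model_order=tuple(p.model_id for p in profiles),
            ),
            seed=seed,
        )

    @property
    def families(self) -> dict[str, str]:
        return {p.model_id: p.family for p in self.profiles}

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        def spec_d(s: ProteinSimSpec) -> dict:
            d = dataclasses.asdict(s)
            d["composition"] = [float(x) for x in s.composition]
            d["length_range"] = list(s.length_range)
            d["buried_beta"] = list(s.buried_beta)
            d["exposed_beta"] = list(s.exposed_beta)
            return d

        def prof_d(p: OracleProfile) -> dict:
            d = dataclasses.asdict(p)
            d["accuracy"] = {c: dict(row) for c, row in p.accuracy.items()}
            return d

        t = dataclasses.asdict(self.training)
        t["model_order"] = list(self.training.model_order)
        return {
            "seed": self.seed,
            "train_spec": spec_d(self.train_spec),
            "eval_spec": spec_d(self.eval_spec),
            "profiles": [prof_d(p) for p in self.profiles],
            "training": t,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        def spec(sd: Mapping) -> ProteinSimSpec:
            sd = dict(sd)
            sd["length_range"] = tuple(sd["length_range"])
            sd["buried_beta"] = tuple(sd["buried_beta"])
            sd["exposed_beta"] = tuple(sd["exposed_beta"])
            sd["composition"] = np.asarray(sd["composition"], dtype=float)
            return ProteinSimSpec(**sd)

        def prof(pd_: Mapping) -> OracleProfile:
            pd_ = dict(pd_)
            pd_["confidence"] = ConfidenceModel(**pd_["confidence"])
            return OracleProfile(**pd_)

        t = dict(d["training"])
        t["model_order"] = tuple(t["model_order"])
        return cls(
            train_spec=spec(d["train_spec"]),
            eval_spec=spec(d["eval_spec"]),
            profiles=[prof(p) for p in d["profiles"]],
            training=TrainingConfig(**t),
            seed=int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# stages


def simulate(config: RunConfig) -> tuple[SyntheticBenchmark, SyntheticBenchmark]:
    """Generate the training and evaluation benchmarks.

    Disjoint seeds (derived from the master seed) and disjoint identifier
    prefixes keep the two protein sets separate.
    """
    train = generate_benchmark(config.train_spec, config.profiles, seed=config.seed)
    eval_seed = int(
        np.random.SeedSequence(config.seed, spawn_key=(999,)).generate_state(1)[0]
        % (2**31)
    )
    test = generate_benchmark(config.eval_spec, config.profiles, seed=eval_seed)
    return train, test


def write_benchmark(bench: SyntheticBenchmark, outdir: str | Path) -> None:
    """Write FASTA, annotation table and per-model prediction tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    msio.write_fasta(bench.proteins, outdir / "proteins.fasta")
    ann = pd.concat(
        [
            pd.DataFrame(
                {
                    "protein_id": rec.identifier,
                    "site": np.arange(1, len(rec) + 1),
                    "rsa": rec.rsa,
                }
            )
            for rec in bench.proteins
        ],
        ignore_index=True,
    )
    msio.write_annotations(ann, outdir / "annotations.tsv")
    for m in bench.model_ids:
        msio.write_predictions(
            bench.predictions_for(m), outdir / f"predictions_{m}.tsv"
        )
    (outdir / "provenance.json").write_text(
        json.dumps({**bench.provenance, "families": bench.families}, indent=2)
    )


def load_benchmark(indir: str | Path) -> SyntheticBenchmark:
    """Re-read a benchmark directory written by :func:`write_benchmark`."""
    indir = Path(indir)
    proteins = msio.read_fasta(indir / "proteins.fasta")
    ann = msio.read_annotations(indir / "annotations.tsv")
    rsa_by_protein = {
        pid: sub.sort_values("site")["rsa"].to_numpy()
        for pid, sub in ann.groupby("protein_id")
    }
    for rec in proteins:
        if rec.identifier in rsa_by_protein:
            rec.rsa = rsa_by_protein[rec.identifier]
            rec.__post_init__()
    prov = json.loads((indir / "provenance.json").read_text())
    families = prov.pop("families")
    tables = [
        msio.read_predictions(indir / f"predictions_{m}.tsv") for m in families
    ]
    return SyntheticBenchmark(
        proteins=proteins,
        predictions=pd.concat(tables, ignore_index=True),
        families=families,
        provenance=prov,
    )


def combined_prediction_table(
    combiner: TrainedCombiner, benchmark: SyntheticBenchmark
) -> pd.DataFrame:
    """Run the trained combiner over a benchmark; long prediction table."""
    X, _, sites = assemble_feature_matrix(benchmark.predictions, combiner.model_order)
    probs = predict_combined(combiner, X)
    out = sites.copy()
    out["model_id"] = COMBINED_MODEL_ID
    out[PROB_COLUMNS] = probs
    return out[["protein_id", "site", "wildtype", "model_id"] + PROB_COLUMNS]


def check_disjoint(train: SyntheticBenchmark, test: SyntheticBenchmark) -> None:
    """Hard guard against train/test protein overlap (dataset leakage)."""
    overlap = {r.identifier for r in train.proteins} & {
        r.identifier for r in test.proteins
    }
    if overlap:
        raise ValidationError(
            f"training and evaluation protein sets overlap: {sorted(overlap)[:10]} "
            "(pass an explicit override to evaluate on training proteins)"
        )


@dataclass
class PipelineResult:
    """Artifacts of a full simulate -> train -> evaluate run."""

    config: RunConfig
    train_benchmark: SyntheticBenchmark
    eval_benchmark: SyntheticBenchmark
    combiner: TrainedCombiner
    combined_predictions: pd.DataFrame
    report: EvaluationReport
    baseline_accuracy: dict[str, float]  # mean/max naive ensembles, overall


def run_paper_like(
    config: RunConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """The end-to-end paper-like run.

    Simulates both benchmarks, trains the stacking combiner on the training
    benchmark, predicts on the held-out evaluation benchmark, and computes
    the full evaluation battery (plus the two naive ensemble baselines).
    """
    config = RunConfig.paper_like(seed=seed) if config is None else config
    train_bench, eval_bench = simulate(config)
    check_disjoint(train_bench, eval_bench)

    combiner = train_combiner(train_bench.predictions, config.training)
    combined = combined_prediction_table(combiner, eval_bench)

    X, y, _ = assemble_feature_matrix(eval_bench.predictions, combiner.model_order)
    mean_top1, max_top1 = baseline_predictions(X)
    baselines = {
        "mean_ensemble": float((mean_top1 == y).mean()),
        "max_ensemble": float((max_top1 == y).mean()),
    }

    ann = pd.concat(
        [
            pd.DataFrame(
                {
                    "protein_id": rec.identifier,
                    "site": np.arange(1, len(rec) + 1),
                    "rsa": rec.rsa,
                }
            )
            for rec in eval_bench.proteins
        ],
        ignore_index=True,
    )
    report = evaluate_models(
        eval_bench.predictions,
        combined,
        eval_bench.families,
        ann,
        config_echo={"run_config": config.to_dict(), "baselines": baselines},
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.save(outdir / "config.yaml")
        write_benchmark(train_bench, outdir / "train")
        write_benchmark(eval_bench, outdir / "eval")
        combiner.save(outdir / "combiner.json")
        combiner.loss_history.to_csv(outdir / "loss_history.tsv", sep="\t", index=False)
        msio.write_predictions(combined, outdir / "predictions_combined.tsv")
        write_report(report, outdir / "report")

    return PipelineResult(
        config=config,
        train_benchmark=train_bench,
        eval_benchmark=eval_bench,
        combiner=combiner,
        combined_predictions=combined,
        report=report,
        baseline_accuracy=baselines,
    )
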