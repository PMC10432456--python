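"""Readers and writers for the package's on-disk formats.

Three plain-text formats are used throughout:

* FASTA for protein sequences (identifier = first whitespace-delimited
  token of the header line);
* prediction tables: tab-separated with columns ``protein_id``, ``site``
  (1-based), ``wildtype``, ``model_id``, then the 20 probability columns
  ``p_A`` ... ``p_Y`` in alphabet order, one row per (protein, site, model);
* annotation tables: tab-separated with columns ``protein_id``, ``site``
  and ``rsa`` and/or ``asa``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    NORMALIZATION_TOL,
    PROB_COLUMNS,
    ProteinRecord,
    ValidationError,
)

PREDICTION_KEY_COLUMNS = ["protein_id", "site", "wildtype", "model_id"]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences from a FASTA file."""
    records = [
        ProteinRecord(identifier=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.identifier, description="")
        for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def validate_prediction_frame(df: pd.DataFrame, *, where: str = "predictions") -> pd.DataFrame:
    """Validate a prediction table and renormalize in-tolerance rounding.

    Checks column layout, probability bounds and row normalization; rows off
    by more than :data:`~maskstack.core.NORMALIZATION_TOL` raise a
    :class:`~maskstack.core.ValidationError` naming the offending sites.
    """
    expected = PREDICTION_KEY_COLUMNS + PROB_COLUMNS
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{where}: missing columns {missing}")
    probs = df[PROB_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(probs)):
        raise ValidationError(f"{where}: non-finite probabilities")
    if np.any(probs < 0):
        bad = df.loc[(probs < 0).any(axis=1), PREDICTION_KEY_COLUMNS]
        raise ValidationError(f"{where}: negative probabilities at\n{bad.head(10)}")
    sums = probs.sum(axis=1)
    off = np.abs(sums - 1.0) > NORMALIZATION_TOL
    if np.any(off):
        bad = df.loc[off, PREDICTION_KEY_COLUMNS]
        raise ValidationError(
            f"{where}: {int(off.sum())} rows not normalized within "
            f"{NORMALIZATION_TOL}; first offenders:\n{bad.head(10)}"
        )
    out = df.copy()
    out[PROB_COLUMNS] = probs / sums[:, None]
    out["site"] = out["site"].astype(int)
    return out


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated prediction table."""
    df = pd.read_csv(path, sep="\t")
    return validate_prediction_frame(df, where=str(path))


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    expected = PREDICTION_KEY_COLUMNS + PROB_COLUMNS
    df[expected].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation table (per-site ``rsa`` and/or ``asa`` values)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "site"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if "rsa" not in df.columns and "asa" not in df.columns:
        raise ValidationError(f"{path}: need an 'rsa' or 'asa' column")
    df["site"] = df["site"].astype(int)
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
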