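"""Canonical data types and elementary per-site definitions.

The unit of analysis is a *site*: one residue position in one protein, for
which a predictor emits a 20-way probability distribution over the canonical
amino acids.  A prediction is *correct* when the amino acid receiving the
highest probability (the top-1 call) equals the wildtype residue that was
masked at that site.  *Confidence* is the probability of the top-1 call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Canonical amino-acid alphabet, alphabetical by one-letter code.  This
#: ordering is fixed for the lifetime of a dataset and encoded in the
#: p_A ... p_Y column order of every prediction table.
ALPHABET: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Column names of the 20 probability columns in prediction tables.
PROB_COLUMNS: list[str] = [f"p_{aa}" for aa in ALPHABET]

#: Non-canonical residue symbols excluded from all accuracy statistics.
NON_CANONICAL: frozenset[str] = frozenset("XBZUO")

#: Normalization slack tolerated on input probability vectors.  Deviations
#: within this bound are renormalized silently; larger ones are hard errors.
NORMALIZATION_TOL: float = 1e-6

#: Maximum sequence length accepted for a protein record (validation rule
#: mirroring the length restriction of transformer-based residue predictors).
MAX_PROTEIN_LENGTH: int = 1024

CLASS_NAMES: tuple[str, ...] = (
    "aliphatic",
    "aromatic",
    "polar",
    "positive",
    "negative",
    "unique",
)

#: Default biochemical partition of the 20 amino acids.  Glycine and proline
#: are "unique" for their conformational idiosyncrasies.  The table is
#: configurable; analyses echo the table they used into their reports.
DEFAULT_CLASS_TABLE: dict[str, str] = {
    "A": "aliphatic", "I": "aliphatic", "L": "aliphatic",
    "M": "aliphatic", "V": "aliphatic",
    "F": "aromatic", "W": "aromatic", "Y": "aromatic",
    "C": "polar", "N": "polar", "Q": "polar", "S": "polar", "T": "polar",
    "H": "positive", "K": "positive", "R": "positive",
    "D": "negative", "E": "negative",
    "G": "unique", "P": "unique",
}


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


def validate_class_table(table: Mapping[str, str]) -> dict[str, str]:
    """Check that ``table`` maps each of the 20 amino acids to exactly one class.

    Returns a plain dict copy.  Raises :class:`ValidationError` on missing or
    extra amino acids or unknown class labels.
    """
    extra = set(table) - set(ALPHABET)
    missing = set(ALPHABET) - set(table)
    if extra or missing:
        raise ValidationError(
            f"class table must cover exactly the 20 canonical amino acids; "
            f"missing={sorted(missing)} extra={sorted(extra)}"
        )
    bad = {aa: c for aa, c in table.items() if c not in CLASS_NAMES}
    if bad:
        raise ValidationError(f"unknown class labels: {bad}")
    return dict(table)


def validate_probability_vector(
    p: Sequence[float] | np.ndarray, *, where: str = "probability vector"
) -> np.ndarray:
    """Validate and return a 20-way probability vector as a float array.

    Entries must be non-negative and sum to 1 within ``NORMALIZATION_TOL``;
    a sum deviation inside the tolerance is corrected by renormalization so
    that serialization rounding never propagates.

    Parameters
    ----------
    p
        Candidate vector, length 20 in alphabet order.
    where
        Context string used in error messages (e.g. naming the offending
        protein and site).
    """
    arr = np.asarray(p, dtype=float)
    if arr.shape != (len(ALPHABET),):
        raise ValidationError(
            f"{where}: expected {len(ALPHABET)} probabilities, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{where}: non-finite entries")
    if np.any(arr < 0):
        raise ValidationError(f"{where}: negative entries")
    total = arr.sum()
    if abs(total - 1.0) > NORMALIZATION_TOL:
        raise ValidationError(
            f"{where}: probabilities sum to {total!r}, off by more than "
            f"{NORMALIZATION_TOL}"
        )
    return arr / total


def top1_prediction(p: Sequence[float] | np.ndarray) -> str:
    """Amino acid with the highest probability; ties go to alphabet order."""
    arr = validate_probability_vector(p)
    return ALPHABET[int(np.argmax(arr))]


def confidence(p: Sequence[float] | np.ndarray) -> float:
    """Probability of the top-1 call.  At least 0.05 for any valid vector."""
    arr = validate_probability_vector(p)
    return float(arr.max())


@dataclass(frozen=True)
class SitePrediction:
    """One model's 20-way probability vector for one residue position."""

    protein_id: str
    site: int  # 1-based along the sequence
    wildtype: str
    model_id: str
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ctx = f"{self.protein_id} site {self.site} ({self.model_id})"
        if self.wildtype not in AA_INDEX:
            raise ValidationError(f"{ctx}: wildtype {self.wildtype!r} not canonical")
        if self.site < 1:
            raise ValidationError(f"{ctx}: site index must be >= 1")
        object.__setattr__(
            self, "probs", validate_probability_vector(self.probs, where=ctx)
        )

    @property
    def top1(self) -> str:
        return ALPHABET[int(np.argmax(self.probs))]

    @property
    def confidence(self) -> float:
        return float(self.probs.max())


def is_correct(pred: SitePrediction) -> bool:
    """True iff the top-1 call equals the masked wildtype residue."""
    return pred.top1 == pred.wildtype


def protein_accuracy(predictions: Sequence[SitePrediction]) -> float:
    """Fraction of correct predictions across all residues of one protein.

    All predictions must come from the same protein and the same model;
    passing an empty or mixed collection is an error.
    """
    if not predictions:
        raise ValidationError("protein_accuracy: empty prediction list")
    proteins = {p.protein_id for p in predictions}
    models = {p.model_id for p in predictions}
    if len(proteins) != 1 or len(models) != 1:
        raise ValidationError(
            f"protein_accuracy: mixed identifiers (proteins={sorted(proteins)}, "
            f"models={sorted(models)})"
        )
    return sum(is_correct(p) for p in predictions) / len(predictions)


def classify_site(aa: str, table: Mapping[str, str] | None = None) -> str:
    """Biochemical class of an amino acid under ``table`` (default partition)."""
    table = DEFAULT_CLASS_TABLE if table is None else table
    try:
        return table[aa]
    except KeyError:
        raise ValidationError(f"amino acid {aa!r} not in class table") from None


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-site RSA and class annotations.

    RSA (relative solvent accessibility) is a unitless fraction; values above
    1 can legitimately occur for extended conformations and are kept but
    flagged via :attr:`rsa_flags`.
    """

    identifier: str
    sequence: str
    rsa: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValidationError(f"{self.identifier}: empty sequence")
        if len(self.sequence) > MAX_PROTEIN_LENGTH:
            raise ValidationError(
                f"{self.identifier}: length {len(self.sequence)} exceeds "
                f"{MAX_PROTEIN_LENGTH}-residue limit"
            )
        if self.rsa is not None:
            self.rsa = np.asarray(self.rsa, dtype=float)
            if self.rsa.shape != (len(self.sequence),):
                raise ValidationError(
                    f"{self.identifier}: RSA length {self.rsa.shape} does not "
                    f"match sequence length {len(self.sequence)}"
                )
            if np.any(self.rsa < 0):
                raise ValidationError(f"{self.identifier}: negative RSA values")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def rsa_flags(self) -> np.ndarray:
        """Boolean mask of sites whose RSA exceeds 1 (kept, not clamped)."""
        if self.rsa is None:
            return np.zeros(len(self.sequence), dtype=bool)
        return self.rsa > 1.0

    def canonical_sites(self) -> list[int]:
        """1-based indices of sites whose residue is a canonical amino acid."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa in AA_INDEX]

    def classes(self, table: Mapping[str, str] | None = None) -> list[str | None]:
        """Per-site class labels; ``None`` for non-canonical residues."""
        table = DEFAULT_CLASS_TABLE if table is None else table
        return [table.get(aa) for aa in self.sequence]


def split_canonical(
    records: Iterable[ProteinRecord],
) -> tuple[dict[str, list[int]], dict[str, list[int]]]:
    """Partition sites into canonical and excluded (non-canonical wildtype).

    Returns ``(kept, excluded)`` where each maps protein identifier to a list
    of 1-based site indices.  The excluded map is the per-protein exclusion
    log required when computing accuracy statistics.
    """
    kept: dict[str, list[int]] = {}
    excluded: dict[str, list[int]] = {}
    for rec in records:
        k = rec.canonical_sites()
        kept[rec.identifier] = k
        excluded[rec.identifier] = [
            i + 1 for i, aa in enumerate(rec.sequence) if aa not in AA_INDEX
        ]
    return kept, excluded
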