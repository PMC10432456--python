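"""Synthetic proteins and synthetic per-residue prediction oracles.

Real masked-residue predictors (protein language models, 3D convolutional
networks) emit a 20-way probability vector per site.  This module emulates
four such oracles — two "structure-like" and two "sequence-like" — with
controllable statistical structure:

* per-(amino-acid-class x burial) correctness probabilities, so the two
  families can be made complementary (structure-like strong on buried
  aliphatic/hydrophobic sites, sequence-like strong on exposed
  polar/charged sites);
* correlated errors within a family and nearly independent errors across
  families, via shared per-site latent draws and shared per-protein
  accuracy offsets;
* burial-dependent confidence (higher top probability below the RSA = 0.2
  burial threshold), mildly informative of correctness.

Everything is deterministic given a master seed: all randomness flows from
one :class:`numpy.random.SeedSequence` through named substreams, so any
artifact can be regenerated byte-identically from its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ALPHABET,
    CLASS_NAMES,
    DEFAULT_CLASS_TABLE,
    PROB_COLUMNS,
    ProteinRecord,
    ValidationError,
    validate_class_table,
)

#: Burial dichotomy: a site is "buried" when RSA < 0.2, "exposed" otherwise.
BURIAL_THRESHOLD: float = 0.2

BURIAL_LEVELS: tuple[str, str] = ("buried", "exposed")

FAMILIES: tuple[str, str] = ("structure", "sequence")

#: Approximate natural amino-acid frequencies (UniProt-scale composition),
#: alphabet order.  Used as the default sequence composition.
NATURAL_COMPOSITION: np.ndarray = np.array(
    [
        0.083, 0.014, 0.055, 0.067, 0.039, 0.071, 0.023, 0.059, 0.058, 0.097,
        0.024, 0.041, 0.047, 0.039, 0.055, 0.066, 0.053, 0.069, 0.011, 0.029,
    ]
)


@dataclass(frozen=True)
class ProteinSimSpec:
    """Parameters of the synthetic protein generator.

    Sequences are drawn i.i.d. from ``composition``; burial is drawn
    independently per site, with RSA for buried sites concentrated below the
    0.2 threshold and RSA for exposed sites at or above it.
    """

    n_proteins: int
    length_range: tuple[int, int] = (60, 300)
    composition: np.ndarray = field(default_factory=lambda: NATURAL_COMPOSITION.copy())
    p_buried: float = 0.45
    #: Beta(a, b) shape of RSA/0.2 for buried sites.
    buried_beta: tuple[float, float] = (1.2, 2.5)
    #: Beta(a, b) shape of (RSA - 0.2)/0.8 for exposed sites.
    exposed_beta: tuple[float, float] = (1.3, 2.2)
    id_prefix: str = "SYN"

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if not (1 <= lo <= hi <= 1024):
            raise ValidationError(
                f"length_range {self.length_range} must satisfy 1 <= min <= max <= 1024"
            )
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (20,) or np.any(comp < 0):
            raise ValidationError("composition must be 20 non-negative weights")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValidationError("composition weights must sum to 1")
        if not (0.0 <= self.p_buried <= 1.0):
            raise ValidationError("p_buried must be in [0, 1]")
        object.__setattr__(self, "composition", comp)


@dataclass(frozen=True)
class ConfidenceModel:
    """Top-probability model: Beta-distributed around a burial-level mean.

    ``correct_shift`` moves the mean up for correct calls and down for
    incorrect ones, so confidence carries information about accuracy (the
    empirical behavior that justifies confidence-based calibration curves).
    """

    buried_mean: float = 0.75
    exposed_mean: float = 0.60
    concentration: float = 14.0
    correct_shift: float = 0.08
    #: Linear response of the confidence mean to the shared per-site
    #: difficulty latent D ~ U(0,1): mean -= difficulty_slope * (D - 0.5).
    #: Hard sites make *every* oracle less confident at once.
    difficulty_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("buried_mean", "exposed_mean"):
            v = getattr(self, name)
            if not (0.05 < v <= 1.0):
                raise ValidationError(f"{name}={v} must lie in (0.05, 1]")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")


@dataclass(frozen=True)
class OracleProfile:
    """Parametric description of one synthetic predictor.

    ``accuracy`` maps every (amino-acid class, burial level) cell to the
    probability that the oracle's top-1 call equals the wildtype on such a
    site.  Error coupling has three layers:

    * ``shared_coupling`` / ``site_coupling``: probability that the per-site
      correctness draw uses the global / family latent uniform instead of an
      oracle-private one.  Sharing a latent correlates correctness site by
      site without changing any marginal accuracy.
    * ``protein_shared_sd`` / ``protein_common_sd`` / ``protein_own_sd``:
      standard deviations of mean-zero per-protein accuracy offsets drawn
      from the global, family and private streams, producing the spread of
      per-protein accuracies and their within-family correlation.
    * ``decoy_family_share``: probability that an incorrect call lands on
      the family's shared decoy proposal for the site, so family members
      tend to make the *same* mistake.
    """

    model_id: str
    family: str
    accuracy: Mapping[str, Mapping[str, float]]
    confidence: ConfidenceModel = field(default_factory=ConfidenceModel)
    decoy_class_bias: float = 0.5
    decoy_family_share: float = 0.5
    off_top_concentration: float = 0.35
    #: When the call is wrong, with probability ``wildtype_runnerup_prob``
    #: this fraction of the off-top mass is moved to the wildtype residue
    #: (real predictors often rank the true residue second).  The signal
    #: lets a stacker make correct predictions that agree with *no* base
    #: model's top-1 call.
    wildtype_runnerup_weight: float = 0.35
    wildtype_runnerup_prob: float = 0.3
    #: Mirror image of the wildtype leak: with probability ``confuser_prob``
    #: a wrong call puts the same runner-up fraction on the site's shared
    #: *confuser* residue (a chemically plausible wrong answer common to
    #: all oracles, e.g. R where the wildtype is K).  Because confuser and
    #: wildtype runner-up signals are indistinguishable row by row, a
    #: stacker's unique calls remain error-prone — as unique calls of real
    #: stacking models are — at a rate set by the two probabilities.
    confuser_weight: float = 0.35
    confuser_prob: float = 0.6
    site_coupling: float = 0.5
    shared_coupling: float = 0.1
    #: Linear response of the correctness probability to the shared
    #: per-site difficulty latent D ~ U(0,1): p += difficulty_slope*(0.5-D),
    #: clipped to [0, 1].  The term is mean-zero up to clipping, so
    #: the marginal accuracy stays at the profile's cell value (the exact
    #: clipped expectation is what :func:`expected_marginal_accuracy`
    #: reports); hard sites are hard for every oracle simultaneously.
    difficulty_slope: float = 0.0
    protein_shared_sd: float = 0.025
    protein_common_sd: float = 0.06
    protein_own_sd: float = 0.04

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"family must be one of {FAMILIES}")
        for cls in CLASS_NAMES:
            if cls not in self.accuracy:
                raise ValidationError(f"{self.model_id}: missing accuracy row {cls!r}")
            for level in BURIAL_LEVELS:
                if level not in self.accuracy[cls]:
                    raise ValidationError(
                        f"{self.model_id}: missing accuracy cell ({cls}, {level})"
                    )
                p = self.accuracy[cls][level]
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(
                        f"{self.model_id}: accuracy cell ({cls}, {level}) = {p} "
                        "outside [0, 1]"
                    )
        if not (0.0 <= self.site_coupling <= 1.0 and 0.0 <= self.shared_coupling <= 1.0):
            raise ValidationError("coupling weights must lie in [0, 1]")
        if self.site_coupling + self.shared_coupling > 1.0:
            raise ValidationError("site_coupling + shared_coupling must be <= 1")

    def cell(self, aa_class: str, buried: bool) -> float:
        return float(self.accuracy[aa_class]["buried" if buried else "exposed"])


@dataclass
class SyntheticBenchmark:
    """A complete synthetic dataset: proteins plus four prediction tables."""

    proteins: list[ProteinRecord]
    predictions: pd.DataFrame  # long format, all models stacked
    families: dict[str, str]  # model_id -> family
    provenance: dict

    @property
    def model_ids(self) -> list[str]:
        return list(self.families)

    def predictions_for(self, model_id: str) -> pd.DataFrame:
        return self.predictions[self.predictions["model_id"] == model_id]


# --------------------------------------------------------------------------
# named substreams

_STREAMS = {"proteins": 0, "shared": 1, "structure": 2, "sequence": 3}
_ORACLE_STREAM_BASE = 10


def _rng(master_seed: int, name: str, oracle_index: int | None = None) -> np.random.Generator:
    """Generator for a named substream of the master seed."""
    if oracle_index is None:
        key = _STREAMS[name]
    else:
        key = _ORACLE_STREAM_BASE + oracle_index
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


# --------------------------------------------------------------------------
# proteins


def generate_proteins(spec: ProteinSimSpec, seed: int) -> list[ProteinRecord]:
    """Draw synthetic proteins: sequence, per-site RSA, deterministic in seed."""
    rng = _rng(seed, "proteins")
    lo, hi = spec.length_range
    records: list[ProteinRecord] = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq_idx = rng.choice(20, size=length, p=spec.composition)
        buried = rng.random(length) < spec.p_buried
        rsa = np.empty(length)
        a, b = spec.buried_beta
        rsa[buried] = BURIAL_THRESHOLD * rng.beta(a, b, size=int(buried.sum()))
        a, b = spec.exposed_beta
        rsa[~buried] = BURIAL_THRESHOLD + (1.0 - BURIAL_THRESHOLD) * rng.beta(
            a, b, size=int((~buried).sum())
        )
        sequence = "".join(ALPHABET[j] for j in seq_idx)
        records.append(
            ProteinRecord(identifier=f"{spec.id_prefix}{i:04d}", sequence=sequence, rsa=rsa)
        )
    return records


# --------------------------------------------------------------------------
# latent difficulty draws


def draw_site_latents(n_sites: int, seed: int) -> dict[str, np.ndarray]:
    """Per-site latent difficulty uniforms shared across oracles.

    Returns the global latent plus one latent per family; an oracle with
    coupling weight w consumes the corresponding latent as its correctness
    uniform with probability w, which correlates correctness between
    oracles sharing a latent while leaving every marginal accuracy exactly
    at its profile value (the draw is uniform either way).
    """
    return {name: _rng(seed, name).random(n_sites) for name in ("shared",) + FAMILIES}


class _StreamCursor:
    """Sequential per-protein consumption of a named substream.

    Generating protein p's block requires drawing protein 0..p-1's blocks
    first; this object keeps a live generator so a full benchmark pass costs
    one sweep per stream instead of quadratic redraws.
    """

    def __init__(self, seed: int, name: str, oracle_index: int | None = None):
        self.rng = _rng(seed, name, oracle_index)

    def uniforms(self, shape) -> np.ndarray:
        return self.rng.random(shape)

    def normal(self, shape=None) -> np.ndarray:
        return self.rng.normal(size=shape)

    def beta(self, a, b) -> np.ndarray:
        return self.rng.beta(a, b)

    def gamma(self, shape_param, size) -> np.ndarray:
        return self.rng.gamma(shape_param, size=size)


# --------------------------------------------------------------------------
# oracle prediction generation


def _inverse_cdf_choice(weights: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw by inverse CDF over rows of ``weights``."""
    cdf = np.cumsum(weights, axis=1)
    cdf /= cdf[:, -1:]
    return (u[:, None] > cdf).sum(axis=1)


def _draw_decoys(
    wt_idx: np.ndarray,
    classes: np.ndarray,
    class_bias: float,
    composition: np.ndarray,
    u_mode: np.ndarray,
    u_pick: np.ndarray,
    class_members: dict[str, np.ndarray],
) -> np.ndarray:
    """Decoy (wrong top-1) amino-acid index per site.

    With probability ``class_bias`` the decoy is drawn from the wildtype's
    own biochemical class (excluding the wildtype), making errors
    chemically plausible; otherwise from the global composition excluding
    the wildtype.
    """
    n = len(wt_idx)
    weights = np.tile(composition, (n, 1))
    use_class = u_mode < class_bias
    for cls, members in class_members.items():
        rows = use_class & (classes == cls)
        if not rows.any():
            continue
        mask = np.zeros(20, dtype=bool)
        mask[members] = True
        w = weights[rows]
        w[:, ~mask] = 0.0
        weights[rows] = w
    weights[np.arange(n), wt_idx] = 0.0
    # degenerate rows (single-member class): fall back to global composition
    dead = weights.sum(axis=1) <= 0
    if dead.any():
        weights[dead] = composition
        weights[dead, wt_idx[dead]] = 0.0
    return _inverse_cdf_choice(weights, u_pick)


def _spread_off_top(
    top_p: np.ndarray,
    gammas: np.ndarray,
    boost: np.ndarray | None = None,
) -> np.ndarray:
    """Distribute 1 - top_p over the 19 non-top amino acids.

    Off-top mass follows a symmetric Dirichlet draw (``gammas`` are the
    unnormalized components).  ``boost`` is an optional (n, 19) matrix of
    per-slot mass fractions (row sums < 1): each row's Dirichlet share is
    scaled down by its boost total and the boost is added, concentrating
    runner-up mass on designated residues.  Rows whose largest off-top
    entry would rival the top probability are mixed toward uniform so the
    intended top-1 call always remains the argmax.
    """
    d = gammas / gammas.sum(axis=1, keepdims=True)
    if boost is not None:
        total = boost.sum(axis=1, keepdims=True)
        d = d * (1.0 - total) + boost
    others = (1.0 - top_p)[:, None] * d
    max_other = others.max(axis=1)
    cap = 0.95 * top_p
    bad = max_other >= cap
    if bad.any():
        uni = (1.0 - top_p[bad]) / 19.0
        lam = (cap[bad] - uni) / (max_other[bad] - uni)
        lam = np.clip(lam, 0.0, 1.0)
        others[bad] = lam[:, None] * others[bad] + (1 - lam[:, None]) * (
            (1.0 - top_p[bad]) / 19.0
        )[:, None]
    return others


def generate_oracle_predictions(
    protein: ProteinRecord,
    profile: OracleProfile,
    seed: int,
    *,
    composition: np.ndarray | None = None,
    class_table: Mapping[str, str] | None = None,
    _streams: dict | None = None,
    _protein_index: int = 0,
) -> pd.DataFrame:
    """Emit one prediction table row per site of ``protein`` for one oracle.

    Convenience single-protein entry point; :func:`generate_benchmark` runs
    the same machinery over a whole protein set with shared substreams.
    """
    bench = _generate_for_proteins(
        [protein], [profile], seed, composition=composition, class_table=class_table
    )
    return bench[0]



def _generate_for_proteins(
    proteins: Sequence[ProteinRecord],
    profiles: Sequence[OracleProfile],
    seed: int,
    *,
    composition: np.ndarray | None = None,
    class_table: Mapping[str, str] | None = None,
) -> list[pd.DataFrame]:
    """Core generator: one prediction frame per profile over ``proteins``."""
    class_table = validate_class_table(DEFAULT_CLASS_TABLE if class_table is None else class_table)
    comp = NATURAL_COMPOSITION if composition is None else np.asarray(composition, float)
    class_members = {
        cls: np.array([i for i, aa in enumerate(ALPHABET) if class_table[aa] == cls])
        for cls in CLASS_NAMES
    }

    shared = _StreamCursor(seed, "shared")
    family_streams = {fam: _StreamCursor(seed, fam) for fam in FAMILIES}
    oracle_streams = [_StreamCursor(seed, "oracle", i) for i in range(len(profiles))]

    frames: list[list[pd.DataFrame]] = [[] for _ in profiles]
    for rec in proteins:
        n = len(rec)
        wt_idx = np.array([ALPHABET.index(aa) for aa in rec.sequence])
        classes = np.array([class_table[aa] for aa in rec.sequence])
        buried = (rec.rsa if rec.rsa is not None else np.full(n, np.nan)) < BURIAL_THRESHOLD

        # shared stream: global site latent, per-protein global accuracy
        # offset, and the per-site difficulty latent common to all oracles
        z_shared = shared.uniforms(n)
        d_shared = float(shared.normal())
        difficulty = shared.uniforms(n)
        # per-site confuser residue: the biochemically plausible wrong
        # answer that *all* oracles rank highly when they miss the site
        confuser = _draw_decoys(
            wt_idx, classes, 0.5, comp,
            shared.uniforms(n), shared.uniforms(n), class_members,
        )
        # family streams: site latent, protein offset, shared decoy proposal draws
        z_fam, d_fam, fam_decoy_u = {}, {}, {}
        for fam in FAMILIES:
            cur = family_streams[fam]
            z_fam[fam] = cur.uniforms(n)
            d_fam[fam] = float(cur.normal())
            fam_decoy_u[fam] = (cur.uniforms(n), cur.uniforms(n), cur.uniforms(n))

        for k, prof in enumerate(profiles):
            cur = oracle_streams[k]
            cell = np.array([prof.cell(c, b) for c, b in zip(classes, buried)])
            d_own = float(cur.normal())
            p_site = np.clip(
                cell
                + prof.difficulty_slope * (0.5 - difficulty)
                + prof.protein_shared_sd * d_shared
                + prof.protein_common_sd * d_fam[prof.family]
                + prof.protein_own_sd * d_own,
                0.0,
                1.0,
            )
            # correctness uniform: global latent, family latent, or private
            selector = cur.uniforms(n)
            z_own = cur.uniforms(n)
            z = np.where(
                selector < prof.shared_coupling,
                z_shared,
                np.where(selector < prof.shared_coupling + prof.site_coupling,
                         z_fam[prof.family], z_own),
            )
            correct = z < p_site

            # decoy for incorrect sites: family proposal or private draw
            u_share, u_mode_f, u_pick_f = fam_decoy_u[prof.family]
            fam_decoy = _draw_decoys(
                wt_idx, classes, prof.decoy_class_bias, comp, u_mode_f, u_pick_f,
                class_members,
            )
            own_decoy = _draw_decoys(
                wt_idx, classes, prof.decoy_class_bias, comp,
                cur.uniforms(n), cur.uniforms(n), class_members,
            )
            decoy = np.where(u_share < prof.decoy_family_share, fam_decoy, own_decoy)
            top_idx = np.where(correct, wt_idx, decoy)

            # confidence: Beta around burial-level mean, shifted by correctness
            cm = prof.confidence
            mean = np.where(buried, cm.buried_mean, cm.exposed_mean)
            mean = mean - cm.difficulty_slope * (difficulty - 0.5)
            mean = np.clip(mean + np.where(correct, cm.correct_shift, -cm.correct_shift),
                           0.10, 0.97)
            a = mean * cm.concentration
            b = (1.0 - mean) * cm.concentration
            top_p = np.clip(cur.beta(a, b), 0.22, 0.995)

            gammas = cur.gamma(prof.off_top_concentration, size=(n, 19))
            gammas = np.maximum(gammas, 1e-12)
            # runner-up boosts on the 19 off-top slots of wrong rows: the
            # wildtype (intermittently) and the shared confuser residue
            boost = np.zeros((n, 19))
            rows = np.arange(n)
            leak_on = (~correct) & (cur.uniforms(n) < prof.wildtype_runnerup_prob)
            wt_slot = wt_idx - (wt_idx > top_idx).astype(int)
            boost[rows[leak_on], wt_slot[leak_on]] += prof.wildtype_runnerup_weight
            conf_on = (
                (~correct)
                & (confuser != top_idx)
                & (cur.uniforms(n) < prof.confuser_prob)
            )
            conf_slot = confuser - (confuser > top_idx).astype(int)
            boost[rows[conf_on], conf_slot[conf_on]] += prof.confuser_weight
            others = _spread_off_top(top_p, gammas, boost)

            probs = np.empty((n, 20))
            rows = np.arange(n)
            mask = np.ones((n, 20), dtype=bool)
            mask[rows, top_idx] = False
            probs[mask] = others.ravel()
            probs[rows, top_idx] = top_p
            probs /= probs.sum(axis=1, keepdims=True)

            frame = pd.DataFrame(
                {
                    "protein_id": rec.identifier,
                    "site": np.arange(1, n + 1),
                    "wildtype": list(rec.sequence),
                    "model_id": prof.model_id,
                }
            )
            frame[PROB_COLUMNS] = probs
            frames[k].append(frame)

    return [pd.concat(fl, ignore_index=True) for fl in frames]


# --------------------------------------------------------------------------
# benchmark assembly


def expected_marginal_accuracy(
    profile: OracleProfile,
    proteins: Sequence[ProteinRecord],
    class_table: Mapping[str, str] | None = None,
) -> float:
    """Profile-weighted mean correctness over the realized sites.

    This is the analytic target that an oracle's observed top-1 accuracy
    converges to: per-protein offsets are mean-zero, and the mean-zero
    difficulty term is integrated exactly, including its clipping at the
    [0, 1] bounds.
    """
    table = DEFAULT_CLASS_TABLE if class_table is None else class_table
    cells = np.array(
        [
            profile.cell(table[aa], rsa < BURIAL_THRESHOLD)
            for rec in proteins
            for aa, rsa in zip(rec.sequence, rec.rsa)
        ]
    )
    s = profile.difficulty_slope
    if s == 0.0:
        return float(cells.mean())
    # E_D[clip(p + s(0.5 - D), 0, 1)] for D ~ U(0,1), on a fine grid
    grid = np.linspace(0.0, 1.0, 2001)
    clipped = np.clip(cells[:, None] + s * (0.5 - grid[None, :]), 0.0, 1.0)
    return float(clipped.mean())


def generate_benchmark(
    proteins_spec: ProteinSimSpec,
    profiles: Sequence[OracleProfile],
    seed: int,
    *,
    class_table: Mapping[str, str] | None = None,
) -> SyntheticBenchmark:
    """Generate proteins plus the four oracles' prediction tables.

    Exactly four profiles — two structure-like, two sequence-like — are
    required, matching the fixed input layer of the stacking combiner.
    """
    if len(profiles) != 4:
        raise ValidationError(
            f"exactly 4 oracle profiles required (got {len(profiles)}): the "
            "combiner's input layer is fixed at four models"
        )
    fam_counts = {fam: sum(p.family == fam for p in profiles) for fam in FAMILIES}
    if fam_counts != {"structure": 2, "sequence": 2}:
        raise ValidationError(
            f"need two structure-like and two sequence-like profiles, got {fam_counts}"
        )
    ids = [p.model_id for p in profiles]
    if len(set(ids)) != 4:
        raise ValidationError(f"duplicate model identifiers: {ids}")

    proteins = generate_proteins(proteins_spec, seed)
    frames = _generate_for_proteins(
        proteins, profiles, seed,
        composition=proteins_spec.composition, class_table=class_table,
    )
    predictions = pd.concat(frames, ignore_index=True)
    provenance = {
        "seed": seed,
        "spec": {
            "n_proteins": proteins_spec.n_proteins,
            "length_range": list(proteins_spec.length_range),
            "p_buried": proteins_spec.p_buried,
            "id_prefix": proteins_spec.id_prefix,
        },
        "profiles": [p.model_id for p in profiles],
    }
    return SyntheticBenchmark(
        proteins=proteins,
        predictions=predictions,
        families={p.model_id: p.family for p in profiles},
        provenance=provenance,
    )


# --------------------------------------------------------------------------
# shipped configurations


def paper_like_profiles() -> list[OracleProfile]:
    """The default four-oracle configuration.

    Cell probabilities and coupling weights were chosen by moment matching
    so the generated benchmark reproduces the qualitative structure reported
    for real predictor ensembles: per-model mean accuracies near 60-68%,
    structure-like oracles strongest on buried aliphatic/aromatic/unique
    sites, sequence-like oracles strongest on exposed polar/charged sites,
    strong within-structure-family correlation of per-protein accuracies
    (~0.7-0.8), moderate within-sequence-family correlation (~0.5), weak
    cross-family correlation (~0.1), wider accuracy spread for the
    sequence-like pair, and higher confidence for buried sites everywhere.
    Structure-like oracles stay fairly confident even when wrong on exposed
    sites, which is what defeats the naive mean/max ensembles.
    """
    struct_acc = {
        "aliphatic": {"buried": 0.84, "exposed": 0.58},
        "aromatic": {"buried": 0.80, "exposed": 0.54},
        "polar": {"buried": 0.62, "exposed": 0.45},
        "positive": {"buried": 0.58, "exposed": 0.43},
        "negative": {"buried": 0.58, "exposed": 0.43},
        "unique": {"buried": 0.80, "exposed": 0.62},
    }
    seq_acc = {
        "aliphatic": {"buried": 0.60, "exposed": 0.52},
        "aromatic": {"buried": 0.60, "exposed": 0.56},
        "polar": {"buried": 0.56, "exposed": 0.74},
        "positive": {"buried": 0.54, "exposed": 0.78},
        "negative": {"buried": 0.54, "exposed": 0.78},
        "unique": {"buried": 0.50, "exposed": 0.48},
    }

    def bump(acc: dict, delta: float) -> dict:
        return {
            cls: {lvl: min(0.97, p + delta) for lvl, p in row.items()}
            for cls, row in acc.items()
        }

    # The two families are deliberately *miscalibrated relative to each
    # other*: structure-like oracles emit high top probabilities even when
    # wrong (their exposed-site accuracy is poor but their confidence only
    # dips mildly), while sequence-like oracles are conservative.  Naive
    # mean/max ensembles take the probabilities at face value and are
    # dominated by the overconfident family; a trained stacker learns each
    # family's calibration, which is what gives stacking its edge.
    # Shared per-site difficulty (evolutionarily variable positions are
    # hard for every model at once) depresses both accuracy and confidence
    # everywhere, giving the stacker a population of genuinely ambiguous
    # sites on which its unique (agree-with-nobody) calls are error-prone.
    struct_conf = ConfidenceModel(buried_mean=0.88, exposed_mean=0.80,
                                  concentration=18.0, correct_shift=0.05,
                                  difficulty_slope=0.40)
    seq_conf = ConfidenceModel(buried_mean=0.62, exposed_mean=0.54,
                               concentration=12.0, correct_shift=0.08,
                               difficulty_slope=0.40)
    return [
        OracleProfile(
            model_id="struct_a", family="structure", accuracy=struct_acc,
            confidence=struct_conf, site_coupling=0.55, shared_coupling=0.10,
            difficulty_slope=0.40,
            protein_shared_sd=0.025, protein_common_sd=0.055, protein_own_sd=0.02,
        ),
        OracleProfile(
            model_id="struct_b", family="structure", accuracy=bump(struct_acc, 0.01),
            confidence=struct_conf, site_coupling=0.55, shared_coupling=0.10,
            difficulty_slope=0.40,
            protein_shared_sd=0.025, protein_common_sd=0.055, protein_own_sd=0.02,
        ),
        OracleProfile(
            model_id="seq_a", family="sequence", accuracy=seq_acc,
            confidence=seq_conf, site_coupling=0.35, shared_coupling=0.10,
            difficulty_slope=0.40,
            protein_shared_sd=0.025, protein_common_sd=0.07, protein_own_sd=0.07,
        ),
        OracleProfile(
            model_id="seq_b", family="sequence", accuracy=bump(seq_acc, 0.05),
            confidence=seq_conf, site_coupling=0.35, shared_coupling=0.10,
            difficulty_slope=0.40,
            protein_shared_sd=0.025, protein_common_sd=0.07, protein_own_sd=0.07,
        ),
    ]


def uniform_profile(model_id: str, family: str, p: float, **kwargs) -> OracleProfile:
    """Profile with a single correctness probability in every cell."""
    acc = {cls: {"buried": p, "exposed": p} for cls in CLASS_NAMES}
    return OracleProfile(model_id=model_id, family=family, accuracy=acc, **kwargs)

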