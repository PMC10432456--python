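# Methods

`maskstack` studies how to combine several masked-residue predictors — models
that, given a protein with one position hidden, emit a probability for each
of the 20 canonical amino acids at that position — into a single, more
accurate *stacked* predictor, and how to characterize where the individual
predictors succeed and fail.  Because running the real pretrained predictors
(protein language models and 3D convolutional networks over voxelized
structure) is outside the package's scope, a parametric generator emulates
their *output statistics*; every downstream stage (feature assembly,
stacking network, evaluation battery) consumes only the standard prediction
tables and works unchanged on real model output.

## Elementary definitions

For a site with probability vector **p** ∈ Δ¹⁹ (alphabet order
A,C,D,…,Y):

* **top-1 call**: argmax **p**, ties broken toward the alphabetically first
  residue (deterministic across platforms);
* **confidence**: max **p** (≥ 1/20 for any valid vector);
* a call is **correct** when the top-1 equals the wildtype (the masked
  residue);
* **protein accuracy**: fraction of correct calls over a protein's scored
  sites.  Sites with non-canonical wildtype symbols (X, B, Z, U, O) are
  excluded from all accuracy statistics and tallied in an exclusion log.

Probability rows whose sum deviates from 1 by ≤ 1e-6 are renormalized
silently (serialization rounding); larger deviations are hard errors.

Amino acids are partitioned into six biochemical classes — aliphatic
{A,I,L,M,V}, aromatic {F,W,Y}, polar {C,N,Q,S,T}, positive {H,K,R},
negative {D,E}, unique {G,P} — used for per-class accuracy and for
class-biased decoy sampling.  The table is configurable and echoed into
every report.

Relative solvent accessibility (RSA) is accessible surface area divided by
the residue's maximum reference area; the shipped constants are the
theoretical maximum-ASA set of Tien et al. (2013).  RSA > 1 (extended
conformations) is preserved, not clamped, and flagged.  A site is *buried*
when RSA < 0.2 and *exposed* otherwise — the only burial threshold used
anywhere.

## The synthetic oracle generator

The generator draws proteins (sequence i.i.d. from a natural-frequency
composition; burial Bernoulli(0.45); RSA from Beta distributions scaled
below/above 0.2) and then, per oracle, per site:

1. **Correctness probability** starts at the profile's (class × burial)
   accuracy cell, then receives three mean-zero adjustments, clipped to
   [0, 1]:
   a shared per-site *difficulty* term `s·(0.5 − D)` with `D ~ U(0,1)`
   drawn once per site for all oracles (evolutionarily variable positions
   are hard for every model at once); per-protein Gaussian offsets drawn
   from a global stream, a family stream and a private stream (producing
   the spread of per-protein accuracies and their within-family
   correlation); nothing else.
2. **Correctness draw**: the uniform variate compared against that
   probability is, with probability `shared_coupling`, the global site
   latent; with probability `site_coupling`, the family latent; otherwise
   private.  Selecting the *source* of the uniform (rather than shifting
   the threshold) correlates errors between oracles sharing a latent while
   leaving every marginal accuracy exactly at its profile value — a
   threshold shift would not.
3. **Decoy**: a wrong call's top residue is sampled from the composition
   excluding the wildtype, biased (probability 0.5) toward the wildtype's
   own class; with probability `decoy_family_share` the oracle adopts its
   family's shared proposal for that site, so family members tend to make
   the same mistake.
4. **Confidence**: the top probability is Beta-distributed around a
   burial-level mean, shifted up/down by `correct_shift` according to
   correctness (so confidence is informative, which calibration curves
   measure) and depressed by the difficulty latent.
5. **Off-top mass**: the remaining 1 − top\_p follows a sparse symmetric
   Dirichlet over the 19 other residues.  On wrong rows two intermittent
   runner-up boosts are applied: a fraction of the off-top mass moves to
   the *wildtype* (probability 0.3 — real predictors often rank the true
   residue second) or to the site's shared *confuser* residue (probability
   0.6 — a chemically plausible wrong answer common to all oracles, e.g. R
   where the wildtype is K).  Rows whose largest off-top entry would rival
   the top probability are mixed toward uniform so the intended call stays
   the argmax.

All randomness flows from one master seed through named `SeedSequence`
substreams (proteins, shared, per-family, per-oracle), so every artifact
regenerates byte-identically from its provenance.

### The paper-like configuration

The shipped default emulates a benchmark of two structure-based and two
sequence-based (language-model-like) predictors.  Its parameters were set
by moment calculations before any end-to-end run, to land in the regime
such comparisons report:

* accuracy cells make the structure-like pair strongest on buried
  aliphatic/aromatic/unique sites and the sequence-like pair strongest on
  exposed polar/charged sites, with overall means near 60–65%;
* coupling weights (`site_coupling` 0.55/0.35, family protein-offset SDs
  0.055/0.07, private SDs 0.02/0.07, global SD 0.025) give within-family
  per-protein accuracy correlations ≈ 0.7 (structure) and ≈ 0.5
  (sequence), cross-family ≈ 0.1, and a wider accuracy spread for the
  sequence-like pair — e.g. for the structure pair,
  r ≈ σ²fam/(σ²fam + σ²own + p(1−p)/L̄ + σ²site/L̄) ≈
  0.0030/0.0042 ≈ 0.7 at mean length L̄ ≈ 180;
* the two families are deliberately miscalibrated relative to each other:
  structure-like oracles emit high top probabilities even when wrong
  (buried mean 0.88, exposed 0.80), sequence-like oracles are conservative
  (0.62/0.54).  Naive ensembles take the probabilities at face value and
  are dominated by the overconfident family; a trained stacker learns each
  family's calibration.  This is what reproduces the observation that
  averaging or copy-the-most-confident yields no meaningful improvement
  while stacking does;
* every oracle's confidence declines above RSA 0.2 (buried mean exceeds
  exposed mean) and declines with the shared difficulty latent
  (slope 0.4 on both accuracy and confidence).

## The stacking combiner

The combined model is a fully-connected network: 80 inputs (the four
oracles' 20-way vectors concatenated in a fixed, serialized model order —
structure-like first), hidden layers of 120 and 60 rectified-linear units,
and a 20-way softmax output.  Training minimizes categorical cross-entropy
against the wildtype with Adam at a fixed learning rate of 1e-4 for exactly
150 epochs — no early stopping.  Choices the recipe leaves open and how
this implementation fixes them:

* batch size 256 with per-epoch reshuffling (standard for ~10⁵-site
  training sets; configurable);
* weight initialization uniform fan-in scaled, U(±1/√fan\_in), derived
  from the training seed; biases zero;
* a 10% *protein-level* validation split monitors generalization only and
  never gates training (site-level splits would leak protein identity);
* forward/backward pass and the Adam update are explicit numpy, so
  training is bit-for-bit reproducible given the seed.

The naive baselines it is compared against are the elementwise mean of the
four vectors and copy-the-single-highest-probability across all 80 entries
(ties to alphabet order in both).

## Evaluation battery

Per-protein accuracies; pairwise Pearson correlations of per-protein
accuracy (SciPy's product-moment r with two-sided p; zero-variance inputs
are flagged as degenerate, never silently reported as r = 0); per-class
accuracy over pooled sites (classes with zero sites are absent, not 0);
the agreement partition — for each site, the set S of base models whose
top-1 matches the combined top-1 yields categories all\_four (|S| = 4),
none (S empty), structure\_only / sequence\_only (non-empty,
single-family), mixed — with per-category accuracy, proportion and count,
plus a per-|S| sub-count table so finer partitions can be recovered; 2-D
(RSA × confidence) histograms with 0.025-wide bins (fine enough for any
coarser re-binning) and per-RSA-bin mean confidence; calibration curves
(per-confidence-bin empirical accuracy); and the wildtype amino-acid
distribution of correctly predicted sites per agreement category, next to
the overall wildtype distribution.

Sites missing any model's prediction are excluded from agreement analyses
(the partition requires complete rows) but retained in single-model
accuracy; sites missing RSA are excluded from RSA profiles and counted.
Train/evaluation protein overlap is a hard error with an explicit override
flag, since dataset leakage is the chief threat to validity for this kind
of comparison.

## Problem sizes and what the tests show

The default study conditions are 300 training and 150 evaluation proteins
of 60–300 residues (~54,000 / ~26,000 scored sites), a desk-scale stand-in
for the thousands-of-structures training sets such comparisons use; the
unit-test fixture is 5 proteins × 60 residues.  Under these conditions the
end-to-end run reproduces the qualitative findings the generator encodes:
the stacked model beats every oracle and both naive ensembles by well over
two percentage points; within-family correlations exceed cross-family;
unanimous sites are the most accurate category and unique combined calls
the least accurate yet clearly above the 5% chance floor; and every oracle
is more confident on buried sites.

Because the generator draws sequence and burial independently and reduces
a predictor to a (class × burial × difficulty) correctness law with a
parametric confidence model, passing tests demonstrate that the pipeline's
machinery is correct and that the stacking advantage follows from
complementarity plus miscalibration — they do not certify accuracy levels
on real proteins, where composition–burial coupling, autocorrelation along
the chain, and richer error structure all matter.

## Known limitations

* The stacking network cannot represent an exact 20-way argmax: with one
  perfect and three uninformative oracles it plateaus near 96% held-out
  accuracy (errors concentrate at low-confidence sites), a capacity limit
  of the 80-120-60-20 architecture rather than undertraining.
* Pearson p-values are descriptive; no multiple-testing correction is
  applied, and no bootstrap intervals are provided.
* The generator emulates output distributions only — no embeddings,
  attention maps or structural microenvironments — and its per-site draws
  are independent along the sequence.
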