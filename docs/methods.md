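# Methods

This note records the modeling choices behind `loxqsar`, the parameters
that matter, and what the synthetic rehearsal does and does not
demonstrate.

## Molecular graphs

Structures are plain undirected graphs: atoms carry element, formal charge
and a ring flag; bonds carry order 1/2/3/aromatic. Stereochemistry, 3D
geometry, tautomers and protonation states are out of scope — every
descriptor downstream is a pure graph descriptor. Parsing goes through
RDKit; multi-fragment inputs (salts) are reduced to the largest connected
component with a logged warning, since the models describe single
structures.

Hydrogen completion uses per-atom counts captured at parse time when
available (RDKit's aromatic perception handles cases like pyrrole N–H
correctly); synthetic graphs built without a parser fall back to a valence
table (effective valence = default + formal charge, aromatic bonds
counting 1.5 with the total rounded). Ring perception flags an atom
exactly when it is incident to a non-bridge edge, which coincides with
membership in at least one cycle; the test suite checks this against an
explicit simple-cycle enumeration oracle on all fixture graphs.

## Descriptors

**MNA.** The atom mark is the element symbol, `-`-prefixed for acyclic
atoms; charges and isotopes are excluded from the mark by default. The
level-k descriptor concatenates the neighbors' level-(k−1) strings in
lexicographic order inside parentheses, which makes the string canonical
under atom relabeling (property-tested over random permutations). Default
maximum level 2: level 3+ descriptors are nearly unique per molecule at
n ≈ 100 and contribute only unidentifiable columns.

**QNA.** Per heavy atom, with B = IP − EA and A = ½(IP + EA) from a
shipped table of experimental atomic values (eV), the matrix
M = D_B^(−1/2)·exp(−½C)·D_B^(−1/2) over the heavy-atom adjacency C yields
P = row sums and Q = M·A. `scipy.linalg.expm` computes the exponential;
tests cross-check it against an independent Taylor-series oracle to 1e-10
and against closed forms (single atom: P = 1/B; homonuclear diatomic:
P = e^(−1/2)/B). Hydrogens are excluded — their large B would otherwise
dominate the coupling. The (P, Q) cloud becomes a fixed-length vector of
atom-averaged Chebyshev products T_a(p̂)T_b(q̂), 0 ≤ a,b ≤ 3 (16
features), after affinely mapping the training P/Q ranges onto [−1, 1];
prediction-time values outside the range are clipped to ±1, and such
clipping is exactly what the applicability-domain range rule flags. The
exact functional basis used by the proprietary reference implementation is
unpublished; the Chebyshev featurization is this package's pinned choice
of the same family and is recorded in every model archive.

**Whole-molecule.** Topological length = heavy-atom graph diameter in
bonds; topological volume = Σ (4/3)πr³ over covalent radii (additive
spheres, no overlap correction — the simplest convention consistent with a
"topological" volume); lipophilicity = Σ of coarse per-element additive
logP contributions. All three always enter the candidate pool. The three
property tables (IP/EA, radii, logP contributions) ship as TSV data so
conventions can be swapped without code changes.

**Vocabulary pruning.** MNA design matrices keep descriptors present in at
least 3 training molecules, capped at the 150 most frequent. Rare
substructure counts are unidentifiable at n ≤ 84 and quadratically slow
the elimination loop; the cap is a package choice, recorded in the model
archive.

## Self-consistent regression

Columns are standardized, the response centered. The ridge value is chosen
per fit by maximizing closed-form leave-one-out Q² over the grid
{1e-8, 1e-5, 1e-3, 1e-2, 1e-1}·n. Two numerical guards matter:

* near-interpolating fits (effective degrees of freedom > 0.9(n−1)) are
  scored −∞ — the LOO shortcut becomes 0/0-unstable there because the
  intercept is fit outside the identity;
* duplicated rows (bootstrap resamples) make plain LOO optimistic, since
  the twin of a held-out point stays in the fit; Q² is therefore assessed
  on the deduplicated design.

Elimination then drops the variable with the smallest |coefficient|/SE
below |t| = 2.0, one per refit, until all retained variables are
significant; SEs come from σ²·diag((XᵀX+λI)⁻¹) with σ² = RSS/(n − tr H − 1).
If everything is eliminated the result is a flagged intercept-only model.
The procedure contains no randomness. On an orthonormal design it reduces
to |t|-threshold selection, verified against an independent OLS
backward-elimination oracle.

**RBF-SCR** reuses the SCR-selected subspace (standardized), places a
Gaussian center on every training point with width = the median pairwise
distance (fallback to the mean, then to 1, when degenerate), and solves
(K + εI)w = y − ȳ. With ε → 0 this interpolates the training data; the
default ε = 1e-2 deliberately trades training fit for generalization —
with near-zero ε the leave-many-out Q² of RBF partials collapses
(ill-conditioned kernel weights oscillate wildly off the training set),
while ε = 1e-2 reproduces the expected qualitative ordering: RBF partials
fit closest and generalize worst (stability A ≈ 0.2), SCR partials are the
most stable (A < 0.1).

## Consensus models

Partial-model diversity: partial *i* draws a bootstrap resample of
compounds and a uniform-random 50–90% subset of the family's descriptor
columns from a counter-derived seed (`SeedSequence(seed, spawn_key=(i,))`);
the three whole-molecule descriptors are always candidates. Mixed-family
pools alternate QNA/MNA partials (160 + 160 at the default 320); the
"Both" method alternates SCR and RBF-SCR so every family × method
combination appears. Predictions are unweighted means over partials, with
the per-partial spread reported.

Summary statistics are arithmetic means over partials. R̄² and F̄ come
from each partial's own training sample. Q̄²_LMO and SD̄ come from
leave-many-out cross-validation (20 rounds, 20% held out) run per partial
over the full training set with the partial's *selected variables held
fixed* and its weights refit per round; the standalone
`lmo_cross_validation` function instead re-runs the entire fit including
selection each round and is what the noiseless-Q² and pure-noise property
tests exercise. The fixed-selection variant is what keeps the 18-model
grid (including two 320-partial cells) at desk scale — about 3 minutes on
one CPU at n = 100 — and is the package's reading of summary statistics
that "average over the partial models". SD̄ is consequently a
cross-validated prediction error, not a training residual: a training
residual would be near zero for RBF partials and carry no information.

Applicability domain: Tanimoto similarity of the compound's MNA descriptor
set to the nearest training compound ≥ 0.3, and every whole-molecule
descriptor within the training min/max expanded by 10% of the range.
Compounds with descriptors that cannot be computed (unseen element) are
out of domain unconditionally. Out-of-domain compounds get no numeric
prediction unless extrapolation is forced, and forced predictions are
flagged.

Stability A = R̄² − Q̄²_LMO, banded: < 0.1 high, ≤ 0.2 acceptable,
≤ 0.3 low, > 0.3 unstable.

## Dataset machinery

pIC50 = −log₁₀(IC50·10⁻⁶) for IC50 in µmol/L; records carrying both values
must agree within 5e-4. Ranked splitting sorts ascending by pIC50 (stable,
so ties preserve input order) and transfers every 6th compound (1-based)
to the test set: 100 → 84/16, and re-splitting the 84 gives 70/14.
Modeling requires the training activity range to exceed 3 log-units
(strict). Reported pIC50 values and thresholds are rounded to 3 decimals,
thresholds at 0.10/0.15/0.20/0.25 of the range.

## Validation statistics

All formulas are implemented directly and tested to 1e-10 against a
brute-force loop-coded oracle. Conventions pinned here:

* rm² = r²(1 − √|r² − r0²|): the absolute value keeps the metric real when
  the through-origin fit exceeds the ordinary one; both directions are
  computed, with their mean and absolute difference.
* CCC and the SD of absolute errors use population (n-denominator)
  moments; B = MAE + 3·SD is computed from the report's own MAE and SD at
  full precision, rounding last.
* QF1² normalizes by deviations from the training mean, QF2² by the test
  mean; the two coincide exactly when those means agree (property-tested).
* 95% coverage removes round(0.05·n) pairs, at least one, with the largest
  absolute errors; ties break by observation order.
* Ability bands: MAE against 0.10/0.15 of the training range and B against
  0.20/0.25 (boundary values inclusive in the better band), combined with
  r² > 0.8 / > 0.6, CCC > 0.8 / > 0.7 and QF² > 0.7 / > 0.6; the overall
  level is the worst band triggered. The published threshold table this
  follows is internally inconsistent in places; the clean conventional
  reading above is used.
* Systematic error is flagged when |mean signed error| > 0.5·MAE or more
  than 80% of residuals share a sign.
* The external confidence window is ±2·RMSEP, boundary inclusive.

## Assay arithmetic

I = (D_c − D_t)/D_c·100; replicate rows are averaged per concentration;
IC50 is the abscissa of the 50% crossing on the segment between the last
point below 50 and the next at or above it (a point exactly at 50 returns
its concentration; multiple crossings pick the jointly closest pair with a
warning). Replicate SDs are carried in reports but never enter the
interpolation. No Hill/4PL fitting: with four measured concentrations per
compound the two-point interpolation is the method. The bundled
eight-compound panel reproduces its reported IC50s exactly for compounds 3
and 7 and within 0.7 µmol/L for the rest — the reported values were
interpolated upstream from unrounded replicate means, while the panel
stores rounded means.

## Synthetic data

The generator emulates the *statistics* of the modeled inhibitor
collection, not its chemistry: valence-correct random attachment trees
(8–22 heavy atoms over C/N/O/S at 70/10/15/5%, single bonds) with up to
two probabilistic ring closures; activities are a planted linear
combination (unit-scale random weights on the three whole-molecule
descriptors plus the two most frequent MNA counts, standardized) plus
Gaussian noise, affinely rescaled so the set's mean (5.308) and range
(3.873) are exact. Rescaling happens after noise, so the advertised range
is exact by construction; the effective post-rescale coefficients are
recorded for recovery tests. The default noise for the grid rehearsal
(SD 1.0 before rescaling) puts linear-model training R² in the 0.8–0.9
band typical of heterogeneous inhibitor series; recovery experiments use
SD 0.1.

One identifiability caveat shapes the recovery tests: topological volume
and lipophilicity are exactly linear in the per-element atom counts, which
the level-0 MNA counts span — so in the *full* MNA design the planted
coefficients are structurally unidentifiable, and recovery is assessed on
the planted columns plus independent noise columns instead.

What passing tests show: the descriptor, selection, consensus and
validation machinery is correct, deterministic and recovers planted
structure at realistic noise. What they do not show: predictive
performance on real 15-LOX chemistry — random trees have no scaffold
structure, no activity cliffs, and descriptor–activity relationships far
tamer than real SAR.

## Problem sizes and runtime

The rehearsal grid uses the 100-compound synthetic set (84/70-compound
training sets), 20 partials per single-family cell and 320 per mixed cell,
20 LMO rounds at 20% — the full study design — and completes in about
3 minutes on one CPU; the test suite adds property checks and runs in
about 4 minutes total.

## Known limitations

* The QNA featurization and the partial-model diversification scheme are
  pinned package choices where the reference implementation's internals
  are unpublished; both are serialized into model archives for
  provenance.
* Ridge t-statistics are approximate (σ²·diag((XᵀX+λI)⁻¹)); at the chosen
  grid this matters only for strongly regularized fits.
* The additive volume and lipophilicity tables are element-level; a
  hybridization-aware scheme would de-collinearize them from the MNA
  level-0 counts.
* IC50 interpolation requires the curve to cross 50% within the tested
  concentration range; no extrapolation is attempted.
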