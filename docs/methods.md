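# Methods

## The correlation-weight model

The model treats a molecule as a multiset of attribute keys and its
predicted activity as an additive function of them.  Attribute extraction is
conformation-independent: nothing beyond the canonical SMILES string and the
hydrogen-suppressed molecular graph is used, so no geometry optimization or
alignment enters the pipeline.

Canonicalization is delegated to one fixed engine (RDKit's canonical SMILES
writer).  Any single fixed, idempotent canonicalizer is acceptable; what
matters is that every molecule in a study passes through the same one,
because the local SMILES attributes are read off the canonical string
directly.

### Attribute dialect

All keys are 12 characters, '.'-padded.  Local keys:

* **S** — one token, left-justified (`F...........`).  Tokens are single
  characters except the digraphs `Cl`, `Br`, `@@` and `%NN` ring closures;
  a closing parenthesis is rewritten to `(` so branch boundaries carry no
  direction.
* **SS** — adjacent token pair, the two texts in descending byte order,
  each left-justified in a 4-character dotted field (`c...F.......`).
* **SSS** — adjacent triple; the middle token keeps the middle field, the
  end tokens are written in descending byte order (`F...c...1...`).

The descending-byte-order normalization makes pair/triple keys direction
independent, and re-normalizing an emitted key is a no-op.

Global keys: `NOSP` + presence bits for N/O/S/P; `HALO` + bits for
F/Cl/Br; `BOND` + bits for double/triple/stereo bonds; one `ATOMPAIR` key
per co-occurring pair from {F, Cl, Br, N, O, S, P, B2, B3} (B2/B3 mark
double/triple-bond presence), rendered `++++X---Y===`; four element
statistics `Xmax.n`; and an 11-bit `HARD` composite presence fingerprint.
The default element-statistic rule counts terminal methyl groups for C and
non-aromatic atoms for N/O/S (capped at 9); it reproduces the
`Cmax.2/Nmax.1/Omax.1/Smax.0` codes of the reference worked example but is
pluggable because the convention is not fully determined by one example.
The `HARD` feature list (heteroatoms, halogens, unsaturation, aromaticity,
rings) is likewise a documented, configurable package convention.

Graph invariants are computed per atom on the hydrogen-suppressed graph:
EC0 is the degree (zero-order Morgan connectivity), VS2/VS3 count atoms at
shortest-path distance exactly 2/3, PT2/PT3 count simple paths (no repeated
vertices) of 2/3 edges starting at the atom, and NNC encodes the pair
(carbon neighbours, non-carbon neighbours).  A walk-based path variant was
considered and rejected as the default: simple paths are the standard
path-number definition in the descriptor literature.  Keys render as
`KIND-Ev.....` with lowercase element symbols for aromatic atoms, keeping
aromatic and aliphatic environments distinct, mirroring SMILES case
sensitivity.

### Optimization

Keys occurring in fewer than T training molecules are blocked: their weight
is pinned at 0 for the whole run, and unknown keys at prediction time
contribute 0.  Active weights start at 1.0 (a deterministic start aids
reproducibility; a seeded uniform start is available).  Each of the N_epoch
epochs visits the active keys in seeded random order; at each visit a short
sequence of perturbations δ ~ U(−move_scale, +move_scale) is proposed one
at a time, each accepted iff the training target does not decrease (greedy
hill climbing; the accepted-target trace is monotone by construction).  The
default of 10 proposals per visit makes one epoch comparable in optimization
work to the published correlation-weight methodology, whose models converge
within roughly 7–12 epochs; with single proposals an order of magnitude
more epochs is needed for the same target value.  The target is the
training r² by default; an IIC-blended target is available (weight 0 by
default) since IIC is part of the validation repertoire but its use inside
the objective is a methodological variant, not a given.  move_scale
defaults to 0.1 activity-contribution units.  After the final epoch the
calibration line pKi = C0 + C1·DCW is refit by OLS and both coefficient
standard errors are reported.

Weight multiplicity follows per-occurrence summation: a key occurring k
times contributes k·CW, matching worked examples in which repeated tokens
appear as repeated rows.

Reproducibility is bit-exact: identical data, settings and seed give an
identical weight map, and model JSON serialization round-trips weights at
full double precision.

## Validation statistics

r² is the squared Pearson correlation; s is the residual standard error of
the one-predictor calibration line (n−2 denominator); F is that line's
regression F-ratio.  q²(LOO) refits the line on every leave-one-out subset
(1 − PRESS/SS_tot).  CCC uses sample (1/n) moments.  IIC splits residuals
(observed − predicted) by sign and scales the Pearson correlation by
min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺); zero residuals count to the positive
group, and an empty group yields IIC = 0 with a warning flag.  IIC is
computed on the set being reported (training statistics from training
residuals, test from test): with a two-way split there is no separate
calibration set to reference.  Roy's r²m pair comes from through-origin
regressions in both axis orientations; the average and absolute difference
are reported.  The MAE-based class uses thresholds expressed as fractions
of the training activity range — GOOD when MAE ≤ 0.10·range and
MAE + 3σ ≤ 0.20·range, BAD when MAE > 0.15·range or MAE + 3σ > 0.25·range,
MODERATE between, boundaries resolving to the better class; the criterion's
5% trimming step presumes larger sets than an 8-molecule external set and
is off by default.  Y-randomization permutes training activities (identity
permutations are redrawn), reruns the full optimize-and-calibrate cycle per
permutation at a reduced epoch count, and reports the mean and maximum
scrambled test r² with cRp² = √(r²·(r² − mean scrambled r²)), clamped to 0
when the excess is negative.

Statistics tables always recompute averages from run rows rather than
trusting any pre-averaged input.

## Applicability domains

For the correlation-weight model, the statistical-defect domain: d(key) =
|P_tr − P_te| / (N_tr + N_te) with P the fraction of molecules in a set
containing the key and N the count of such molecules (per-molecule
presence by default; a per-occurrence variant is behind a flag).  A
molecule's defect D sums d over its attribute occurrences; it is inside the
domain iff D < 2 × (mean training D).  Tie rules are explicit: D equal to a
positive threshold is outside; D = 0 with threshold 0 is inside.  The
multiplier 2.0 is the conventional choice and is configurable.  On a random
75/25 split of a homogeneous congeneric series an occasional molecule can
exceed the threshold through a rare substitution pattern; the no-outlier
outcome holds when attribute frequencies are matched between the sets, and
the tests construct exactly that scenario.

For GA-MLR, the Williams plot: leverage from the hat matrix of the
training design (intercept included), warning leverage h* = 3(k+1)/n,
standardized residuals as residuals over the training residual standard
error; membership requires h < h* and |standardized residual| < 3, both
strict.

## GA-MLR

Columns whose modal value covers ≥ 80% of rows are dropped; of each pair
with |r| ≥ 0.95 the member with weaker absolute response correlation is
dropped — which member of a pair goes is an open choice, and keeping the
response-correlated one guards the signal; survivors are autoscaled with
stored parameters.
Chromosomes are descriptor subsets of exactly the configured size (5 by
default); fitness is the leave-one-out q² of the OLS fit, computed exactly
through the PRESS identity e_i/(1−h_ii) rather than n refits.  LOO fitness
rather than training r² guards against selection bias; it is switchable.
Selection is tournament (size 2), crossover uniform with repair back to
exact size, per-gene mutation at the configured rate (20% default),
elitism 1 — GA internals the method's descriptions leave open, fixed here
as documented defaults.  Ill-conditioned candidate designs (condition
number > 1e10) are rejected and resampled.  Final coefficients are refit on
the raw descriptor scale so the printed equation applies to unscaled
descriptor values.  On pools of ≤ 15 descriptors the GA result is verified
against exhaustive enumeration of all subsets.

## Analogue design

Fragment verdicts classify an attribute key as an activity promoter only
when its weight sign is stable across all independent runs (positive in
every run: promoter of increase; negative in every run: of decrease;
anything else, or blocked in any run: undefined).  The designer grafts
substituents by molecular-graph surgery — combine, bond, sanitize,
re-canonize — never by string concatenation, because attribute extraction
depends on the canonical form.  The template must carry a monosubstituted
phenyl ring; ortho/meta/para sites are located by walking the ring from the
ipso atom, taking the lower-index member of each symmetric pair (the
canonical product is identical for either).  Predicted activity increments
obey ΔpKi = C1·ΔDCW exactly, by linearity.  The default substituent set
{methyl, ethyl, isopropyl} × {ortho, meta, para} yields nine analogues.

A planted substituent maps to many attribute keys at once, so "the sign of
a fragment's effect" under the model is taken as the sign of
C1·(DCW(scaffold+fragment) − DCW(scaffold)) — the aggregate weight delta
the graft introduces — averaged over the three attachment positions, since
the planted effects are position-independent.

## Synthetic data

The congeneric generator emulates the study system: one scaffold (the
fluorinated imidazo[1,2-a]pyridine acetamide template by default),
substituents sampled over the phenyl ortho/meta/para sites without
repeating patterns, and activity = baseline + additive fragment effects +
Gaussian noise.  Defaults: baseline 6.7, effects methyl +0.5, ethyl −0.3,
isopropyl +0.8 pKi units, σ = 0.05, n = 40, matching the activity spread
the reference analogue series exhibits (6.75–8.02) with mixed effect signs
so that sign recovery is a real test.  Gaussian noise is appropriate for a
log-scale endpoint.  The ground-truth effect map and per-molecule
substitution patterns are always emitted with the data.

What the generator does not emulate: experimental activity measurement
error structure, scaffold diversity, tautomers/charge states, and any
relationship between the fabricated descriptor matrix and real
physicochemical descriptors.  Passing recovery tests therefore demonstrates
correctness of the machinery (attribute extraction, optimization,
calibration, design logic) on additive ground truth — not predictive
validity on real receptor pharmacology.

The descriptor-matrix generator plants a known linear signal in its first
k columns and engineers two filter baits: a 96%-constant column and a
sample-correlation-0.97 near-duplicate of the first signal column whose
noise component is orthogonalized against the signal span, so the duplicate
is deterministically the weaker-to-response member of its pair.

## Problem sizes and numerical choices

Tests and the acceptance script run the synthetic series at n = 40 with one
optimization run of 15 epochs (plus shorter 4-epoch runs inside the
20-permutation Y-randomization), and GA-versus-exhaustive checks on pools
of 10–15 descriptors with 25 molecules — sizes at which every oracle
(brute-force LOO, exhaustive subset enumeration, BFS/path enumeration on
random graphs) is exact and fast.  Metric implementations are required to
match their oracles to at least 10 decimal places.  Degenerate inputs are
errors, not silent results: constant vectors in correlations, constant DCW
in calibration, all-filtered descriptor matrices, templates without a
suitable phenyl ring.

## Known limitations

The exact semantics of two global codes (`HARD`, and the element-statistic
rule beyond the one reproduced instance) are package conventions behind
configurable interfaces.  Bracket-atom SMILES (`[nH]`, `[O-]`) are
tokenized character-wise with `[`/`]` as tokens — a documented convention;
the reference molecules contain none.  The correlation-weight optimizer is
a greedy stochastic search: different seeds give different weight maps of
similar quality, which is why fragment verdicts demand sign stability
across runs rather than trusting any single run.
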