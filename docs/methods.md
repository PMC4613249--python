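# Methods

This note documents the models, conventions and design choices behind
`afp_ensemble`, in the order the pipeline runs.

## Inputs and dataset filtering

Proteins enter as FASTA records; the identifier is the first
whitespace-delimited token of the header, and duplicate identifiers are
an error because all annotation tables join on them.  Dataset filtering
removes sequences shorter than 50 residues and sequences containing any
of the ambiguous codes B, J, O, U, X, Z.  Both rules are total and
idempotent, and every rejection is reported with its reason.

The train/test split is performed per class so the severe AFP:non-AFP
imbalance is preserved on both sides.  The per-class test count is
round-half-up(fraction × class size); with the published benchmark
counts (464 positives, 9083 negatives, fraction 0.2) this reproduces
the reference partition of 93 + 1817 test and 371 + 7266 training
proteins, which is why half-up rather than banker's rounding was chosen.

PSSM files are read in the PSI-BLAST `-out_ascii_pssm` dialect (only
the first 20 log-odds columns are used) or as headerless L×20 numeric
matrices, auto-detected.  The amino-acid column order everywhere is
PSI-BLAST's native `ARNDCQEGHILKMFPSTWYV`, recorded on the profile
object rather than assumed.  Disorder tables are `(id, position,
score)` rows with scores validated into [0, 1]; domain tables are
`(id, InterPro-entry)` pairs with set semantics.  All readers reject
malformed numeric fields rather than coercing them.

## Descriptor families (329 features)

**Composition (110).**  The 20 residues are partitioned into 10
functional groups by side-chain chemistry: phenyl {F,W,Y}, carboxyl
{D,E}, imidazole {H}, primary amine {K}, guanidino {R}, thiol {C},
sulfur {M}, amido {Q,N}, hydroxyl {S,T}, non-polar {A,G,I,L,V,P}.
Group AAC is f(gᵢ) = N(gᵢ)/L; group DPC counts the L−1 overlapping
dipeptides, f(gᵢgⱼ) = N(gᵢgⱼ)/(L−1), row-major over ordered pairs.
Both blocks sum to one per protein.

**Global physicochemistry (6).**  Theoretical pI (Bjellqvist pKa set,
charge-curve bisection, via biopython's ProtParam), counts of D+E and
R+K, the instability index (dipeptide weight sum × 10/(L−1), so L ≥ 2
is required), Ikai's aliphatic index X_A + 2.9·X_V + 3.9·(X_I + X_L)
in mole percent, and GRAVY (mean Kyte–Doolittle hydropathy).

**Auto-covariance (70).**  For each of seven residue scales
(hydrophobicity, hydrophilicity, net charge, van der Waals volume,
free energy of solution in water, side-chain interaction parameter,
accessible surface area — shipped in `data/physchem_properties.csv`,
transcribed from published AAindex scales, user-overridable) and lags
λ = 1..10:

    AC(j, λ) = (1/(L−λ)) Σᵢ (Pᵢʲ − P̄ʲ)(Pᵢ₊λʲ − P̄ʲ)

Each scale is standardized to zero mean / unit variance over the 20
residues before encoding (`standardize=False` disables this).  The
centering in AC makes the encoding location-invariant but not
scale-invariant, and the seven scales differ by orders of magnitude in
raw units, so standardization prevents any one scale from dominating.
The feature is property-major: `ac_<property>_<λ>`.

**Disorder (28).**  From a per-residue disorder score vector: mean and
population standard deviation (divide by L); counts of disordered and
ordered segments; min/max lengths of each segment class; and the mean
score of each of the 20 residue types.  A residue is disordered when
score ≥ threshold; the default threshold is 0.5, the conventional
decision boundary of disorder predictors.  An absent segment class has
min = max = 0; a residue type absent from the sequence has mean score
0 (a sentinel, not a measurement).

**Domains (15).**  Binary presence of each entry of a fixed InterPro
panel; the default panel is the 15 entries observed in ≥ 10 AFPs of the
original benchmark's training data, in rank order, so prediction works
without re-deriving it.  `derive_panel` rebuilds a panel from new
annotated data (entries in ≥ `min_count` positives, ordered by
descending count then lexicographic id for determinism).

**PSSM (100).**  Every PSSM entry is squashed by the logistic sigmoid
f(x) = 1/(1+e⁻ˣ) *before* aggregation; rows are grouped by the
functional group of the sequence residue, columns by the group of the
target amino acid; the scaled scores are summed within each of the
10×10 group pairs and divided by L.  Grouping rows by sequence residue
and columns by target residue is the only reading consistent with a
10×10 output; scaling-first is the presentation order of the method and
is the fixed convention here.

Assembly concatenates composition → physicochemistry → disorder →
domain → PSSM (10+100+6+70+28+15+100 = 329 columns).  Any family can be
disabled; missing PSSM or disorder annotations raise with the offending
protein ids (a missing domain annotation is a legitimate empty hit
set).  No scaling is applied at assembly time: random forests are
scale-invariant and the ANOVA F ranking is unchanged by affine
per-feature maps.

## Undersampling ensemble

With P training positives, G·P negatives are drawn without replacement
and partitioned into G groups of P; subset k is the full positive set
plus group k (2P rows).  One base classifier per subset; prediction is
positive iff strictly more than G/2 members vote positive.  G is odd by
default (validated set {1, 3, 5, 7, 9, 11, 13, 15}; default 9, the
optimum reported for the original benchmark) so ties cannot occur; an
explicitly configured even G resolves ties to the negative class, the
prior majority.  The base learner defaults to a 100-tree random forest
with √d features per split and unlimited depth — the classical forest
defaults — with member k seeded deterministically from (ensemble seed,
k); any sklearn-style fit/predict classifier can substitute.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total, and
BAcc = (Sn+Sp)/2.  BAcc is the headline metric: the all-majority
classifier has BAcc = 0.5 at any imbalance while its Acc approaches 1.
If a class is absent the corresponding rate and BAcc are NaN with an
explicit flag, never a silent zero.  Cross-validation is stratified
K-fold (per-class partition, fold sizes differing by ≤ 1); per-fold
predictions are pooled into one confusion matrix before the formulas
are applied, because fold-level Sn is unstable with few positives per
fold — the per-fold reports are also retained.  Negative sampling is
re-drawn independently inside every training fold.

## ANOVA-IFS

The per-feature one-way F statistic is computed from the exact sum
decomposition (SSB + SSW = SST is asserted in tests).  Conventions for
degenerate features: SSW = 0 with SSB > 0 gives F = +∞ (a
constant-within-groups feature separates the classes perfectly and
ranks first); SSB = SSW = 0 gives F = 0.  Ties in F break by ascending
original column index.  IFS evaluates each prefix of the ranking with
the same ensemble configuration used for final training, scored by
pooled CV BAcc; the optimum is the *smallest* prefix attaining the
maximum (parsimony — the tie rule is otherwise arbitrary).  A `stride`
option evaluates every s-th prefix plus the full set to bound the O(d)
pipeline evaluations; it never alters the metrics of evaluated
prefixes.

## Synthetic generator

The generator stands in for the unshippable benchmark (curated
sequences plus PSI-BLAST/nr PSSMs, disorder-predictor output and
InterPro annotations).  Sequences are drawn per position from
functional-group frequency profiles: negatives from group frequencies
proportional to group sizes (uniform over residues), positives from a
mixture (1−signal)·base + signal·shifted, where the shifted profile
moves mass toward the hydroxyl, amido and non-polar groups — ice-binding
surfaces are enriched in such residues, and injecting signal at the
group level makes the reduced-alphabet features the natural detectors,
so descriptor bugs show up as lost BAcc.  PSSMs are integer noise in
[−5, 5] plus a conservation bias on the columns of each residue's own
group, larger for positives; disorder scores are window-5 moving
averages of uniforms (bounded in [0, 1] with realistic run structure);
domain annotations hit panel entries with probability `enrichment` for
positives and a lower rate for negatives.  Everything is a pure
function of (parameters, seed).

What the generator does **not** emulate: real PSSM statistics from
large database searches, sequence homology and family structure,
length/composition correlations, or genuine AFP biology.  Passing
trend tests therefore demonstrates that the machinery behaves as
designed under controlled signal, not field performance on real
proteomes.

## Simulation experiments

Four named experiments mirror the benchmark's designs: `g_sweep`
(G ∈ {3,...,15}), `imbalance_sweep` (a single forest on training ratios
1:1..1:8, no sampling), `ensemble_vs_none` (single forest on full 1:9
data vs the G = 9 ensemble, paired per replicate) and `size_sweep`
(10%..80% of a 1:9 pool, G = 9 ensemble).  Each replicate generates a
fresh training set and an independent balanced test set of 150 per
class and reports test-set Sn/Sp/Acc/BAcc; with a generator available,
independent test data is statistically cleaner than cross-validating a
single fixed sample and an order of magnitude cheaper, so the
experiments use holdout evaluation while the `cv` command and IFS keep
true stratified 10-fold CV.  Study conditions, chosen once: signal 0.4,
lengths 50–150, 40 training positives (80-positive pool for the size
sweep), composition-only features, 100-tree forests, 10 replicates.
The expected qualitative results — specificity rising and sensitivity
falling with the imbalance ratio, the ensemble beating the single
forest at 1:9, BAcc non-decreasing in training size — are asserted in
the test suite with a one-replicate-SD slack per step.

## Numerical conventions and edge cases

* Round-half-up for split sizes (see above); all other rounding is
  whatever IEEE double arithmetic gives.
* The sigmoid is evaluated in the numerically stable split form, so
  extreme PSSM scores cannot overflow.
* Auto-covariance of a homopolymer is zero only up to rounding in the
  mean subtraction (~1e−30); tests assert it below 1e−20.
* Descriptor implementations are vectorized but are required by the
  test suite to agree with naive brute-force loop oracles to 1e−10
  relative tolerance on random fixtures.
* Model archives are joblib bundles carrying members, configuration,
  training column order and a format version; prediction refuses any
  feature matrix whose column names differ from training.
* CLI outputs are written to a temporary file and renamed, so a failed
  run never leaves partial output; commands with randomness require an
  explicit seed.

## Known limitations

* The seven property scales ship with this package's chosen AAindex
  accessions; the original method cites the database without naming
  entries, so other choices are defensible — the table is
  config-overridable and standardization makes results robust to
  affine differences.
* The 15-entry domain panel is frozen from the original benchmark;
  retraining on new data should use `derive_panel`.
* Holdout-based experiments (above) trade exact procedural fidelity for
  statistical cleanliness; absolute synthetic-data metrics are not
  comparable to benchmark values, only directions of change are.
* No probability calibration, ROC/AUC, or boosting variants; the
  voting ensemble outputs hard labels plus vote counts.
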