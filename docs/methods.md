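# Methods

This note documents the statistical conventions, numerical choices and
limitations behind `fip`. The README defines the quantities (CORM,
COPRM, PMIRM, ZPMIRM, RFT/ZRFT); here we state exactly how the edge
cases are resolved, what the synthetic generator does and does not
emulate, and which design decisions were genuinely open.

## Model and conventions

**Feature model.** A compound is a binary feature vector; a compound set
is a corpus in which each compound is a "sentence" and each fingerprint
bit a "word". PMI of a feature pair compares its co-occurrence
probability within one compound against the product of the features'
marginal probabilities, in log base 2 throughout: PMI = +1 means the
pair appears together twice as often as independence predicts, −1 half
as often, 0 exactly as often. All bit indices are 0-based.

**Diagonal.** Applying the PMI formula literally to a diagonal cell
would give −log₂ pᵢᵢ. We instead define the PMIRM diagonal of every
observed feature as 0: the "pair" (i, i) carries no interrelation
information, and a zero diagonal keeps tightness scores driven by
genuine pairs. The choice is recorded in the matrix container.

**Undefined cells.** A cell is defined iff its pair co-occurrence
probability is strictly positive. This covers both never-observed
features and pairs of observed features that never co-occur (literal
PMI −∞). Undefined cells are masked (stored as NaN) and never smoothed:
no pseudocounts or priors are applied anywhere. Consequences ripple
through the stack deliberately: masked cells are excluded from
standardization and from profile histograms, and contribute a
configurable constant (default 0) to tightness scores.

**Standardization (ZPMIRM).** μ and σ are computed over the *defined
off-diagonal* cells only, each unordered pair counted once (symmetry
duplicates would not change either value); σ is the population standard
deviation. The zeroed diagonal is a convention, not data, so it is
excluded from μ/σ but is itself standardized, mapping to −μ/σ. A profile
whose defined off-diagonal values are all equal has σ = 0 and is
rejected with a hard error naming the degenerate profile. The (μ, σ)
pair is stored with the matrix so ZRFT scores are reproducible from the
container alone.

**Tightness (RFT/ZRFT).** The product in RFT = μ(COPRM(S) × PMIRM(S′))
is element-wise (Hadamard); only this reading matches the intended
interpretation — query co-occurrence probabilities weighting the
reference's pairwise interrelation ratings — and keeps the score scale
independent of matrix dimension. Two conventions are exposed and
recorded on every score:

- `mean_over` — default `"all"`: the mean divides by D² regardless of
  how many reference cells are defined, so scores are comparable across
  queries against one reference; `"defined"` divides by the defined-cell
  count instead.
- `missing_pair` — default 0.0: the value substituted for reference
  cells with undefined PMI/Z before the product. A negative constant
  turns "this pair was never seen in the reference" into an explicit
  penalty.

Under the defaults, COPRM(S) is exactly the average of singleton outer
products, so a set's ZRFT equals the mean of its compounds' singleton
ZRFTs; the test suite asserts this as an identity. Per-compound scoring
uses the equivalent quadratic form kᵀZk / D², vectorized over compounds.

**Chemistry standardization contract.** The ingestion path strips all
stereochemistry (tetrahedral and double-bond), keeps the largest organic
fragment (desalting), and neutralizes charges where valence permits;
tautomers are *not* canonicalized. Duplicates are removed by InChIKey
computed after standardization, first occurrence kept. Parse,
standardization and encoding failures are counted and reported per
record (TSV of id + reason), never silently dropped, and are tallied
separately from deduplication counts.

**Fingerprints.** MACCS is exposed as its 166 semantic bits (the
toolkit's raw array carries a placeholder bit 0, which is dropped);
PubChem-style keys are 881 bits; ECFP is the folded Morgan fingerprint
(radius 2 = ECFP4, radius 3 = ECFP6, default 1024 bits). No installed
toolkit generates the 881 PubChem key definitions, and reimplementing
the dictionary is out of scope by design: `pubchemkey` is therefore a
first-class spec for pre-encoded FPS input and all downstream math, but
`encode()` refuses it with a clear error. ECFP bit semantics depend on
the toolkit version, so every FPS file and matrix container embeds the
toolkit name+version and loaders refuse mismatches rather than warn.

**Containers.** FPS (chemfp dialect, hex with LSB-first bit order
within bytes) is the fingerprint interchange format. Relation matrices
are single-file zip containers holding a JSON metadata block (variant,
spec, |S|, μ/σ, toolkit, creation command) plus the packed upper
triangle of values and defined-mask; counts are 64-bit integers
(database-scale set sizes overflow 32 bits). Round-trips are exact for
counts and masks and within 1e-12 for floats.

## Synthetic data: what it emulates and what it does not

The generator draws independent Bernoulli(pᵢ) feature columns, except
for feature-disjoint planted pairs (i, j, e) drawn jointly from the 2×2
table with joint on-probability e·pᵢ·pⱼ — so the population PMI of a
planted pair is exactly log₂ e, and every estimator can be validated
against a closed-form truth. Feasibility (e·pᵢ·pⱼ ≤ min(pᵢ, pⱼ), all
four cell probabilities non-negative) is checked at design time.
Disjointness keeps the joint law exactly specifiable without copula
machinery. `scramble_columns` permutes each column independently,
conserving marginals exactly while destroying all co-occurrence — the
surrogate for a structurally incoherent (hard-to-synthesize-like) set.

Real fingerprints are *not* like this: bits are hierarchically
correlated (substructures imply superstructures), marginals are heavily
skewed, and co-occurrence structure is dense rather than confined to
disjoint pairs. Passing tests therefore demonstrate estimator
correctness and the internal consistency of the PMI→ZRFT pipeline, not
chemical realism; the bundled 42-compound drug-like SMILES fixture
exercises the chemistry path end-to-end but is far too small to yield a
meaningful interrelation profile (realistic ECFP profiles need ~10⁵–10⁶
compounds).

**Study conditions used by tests and the acceptance script** (chosen
once as representative, at sizes a workstation handles in seconds):
parameter recovery uses p = 0.2, enrichments e ∈ {0.5, 1, 2, 4},
n = 50,000 compounds, 20 seeds. The ES/HS classification property uses
64 features fully covered by 32 disjoint planted pairs with e = 4 at
p = 0.2 (joint 0.16, within the feasibility bound 0.2), a 2000-compound
reference, and 200 coherent vs 200 scrambled query compounds per seed,
20 seeds, scored by singleton-set ZRFT. The Tanimoto protocol samples
5000 compounds and enumerates all 12,497,500 unordered pairs via one
Gram matrix.

## Numerical choices

- Log base 2 everywhere; natural-log or base-10 readings of PMI are not
  offered.
- Histogram bins are half-open [lo, lo + w) with edges at integer
  multiples of the bin width (default 0.1 PMI units); exported as CSV.
- Exclusive-pair mining treats the PMI range [lo, hi] as closed. "Not
  present in other sets" defaults to *undefined-or-out-of-range* in every
  other matrix; the stricter *never co-occurs elsewhere* reading is the
  `absent` mode.
- Youden threshold candidates are midpoints of consecutive distinct
  scores plus ±∞; ties break toward the lowest threshold; the decision
  rule is score ≥ threshold ⇒ ES; ES is the positive class and higher
  scores indicate ES. AUC is trapezoidal (equivalently the Mann–Whitney
  probability with ties counted ½).
- Multi-instance evaluation averages AUC/Acc/SN/SP arithmetically across
  instances; both a per-instance Youden policy and a fixed shared
  threshold are exposed, since averaged reports are meaningful under
  either.
- Subset ladders are nested by prefix-slicing a single seeded
  permutation, so each larger subset contains the smaller ones; the
  default ladder is ×4 geometric, 8000 → 2,048,000.
- Tanimoto of two all-zero vectors is defined as 0.

## Known limitations

- No sparse on-disk matrix formats beyond the packed triangle; dense
  D×D memory is assumed (fine for D ≤ a few thousand bits).
- No tautomer canonicalization; compounds differing only by tautomer
  state deduplicate to different InChIKeys exactly when their keys
  differ.
- RFT/ZRFT significance is not assessed; the scores are descriptive.
- The `pubchemkey` encoder gap means the full four-fingerprint protocol
  requires externally encoded FPS input for that key set.
- Per-compound ZRFT of an empty (all-zero) feature vector is 0 by
  construction, which places featureless records at the profile average
  rather than flagging them; callers should screen empty encodings via
  the rejects report.
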