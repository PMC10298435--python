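# Methods

## Scores

Both risk scores are integer-valued and exact; no floating point enters the
scoring path, so every scored value is bit-reproducible.

**WARS.** Each drug in the patient's standardised set contributes its
Anticholinergic Cognitive Burden class score (class 1 → 1, class 2 → 2,
class 3 → 3); drugs without an ACB listing contribute 0. The score is a sum
over *distinct* drugs: repeat prescriptions of the same drug within the
active window count once, because the score model counts drugs, not
prescribing events. WARS is additive over disjoint drug sets and monotone
under adding a drug.

**WIRS.** The patient's drugs index a symmetric interaction matrix with zero
diagonal; each off-diagonal cell holds the listed severity of that unordered
pair (1 mild, 2 moderate, 3 severe) or 0. WIRS is half the matrix sum,
equivalently the severity-weighted count of interacting unordered pairs; the
implementation computes both and errors if they ever disagree (they cannot
while the matrix invariants hold — the check guards against invariant
corruption upstream). A pair listed under several interaction mechanisms
carries one severity: the tables store at most one value per unordered pair
and conflicting duplicates are a validation error.

The two lookups are independent: a drug missing from the interaction table
still contributes to WARS wherever it has an ACB class, and vice versa. The
scores are never combined into a composite, since reviewers prioritise by
whichever clinically recognised measure fits the question; the joint analysis
keeps them as a 2-D feature vector instead.

**Name standardisation.** Medicine names are case-folded, trimmed, and
internal whitespace is collapsed; combination medicines expand through a
user-supplied component map. No fuzzy matching is attempted — prescription
extracts and the reference tables are expected to share a referencing form,
and deterministic matching keeps every score auditable. Names that resolve
against neither reference table are retained (they score 0 on both axes),
flagged in the audit log, and never raise.

## Cohorts

Patients with at least one active prescription row are scored; the rest are
excluded before scoring. Active status is a flag column with configurable
truthy values (default `active`) — date-window reconstruction of activity is
out of scope. Three cohorts are analysed after excluding zero scores:
WARS > 0 (1-D), WIRS > 0 (1-D), and their intersection on the joint 2-D
vector. Patients whose drugs are all unknown to both tables receive (0, 0)
and fall under the zero-score exclusion, with a count in the audit log.

## Mean-shift clustering

**Kernel.** Flat (uniform window of radius = bandwidth): each seed moves to
the arithmetic mean of all points within one bandwidth. This is the simplest
kernel consistent with merging all points in each other's vicinity; no
Gaussian weighting.

**Bandwidth.** With `k = max(1, floor(n·quantile))`, the bandwidth is the
mean over all points of the Euclidean distance to their k-th nearest
neighbour, self included. Default quantile 0.3. Because scores are small
integers with heavy ties, the estimate can be 0 (k = 1, or coincident
points); the fallback substitutes 10⁻³ × the maximum pairwise distance, and
if that is also 0 all points coincide and form a single trivial cluster.

**Iteration.** Every data point is a seed. Duplicate coordinates are
collapsed into weighted unique points before iterating — identical seeds have
identical flat-kernel trajectories, so this is exact, and it makes each
iteration quadratic in the number of *distinct* score vectors rather than
patients (cohorts of tens of thousands of integer-scored patients typically
have well under a few hundred distinct vectors). A seed stops when its
displacement falls below 10⁻³ × bandwidth, or after 300 iterations.

**Mode merging and labels.** Converged modes are sorted by within-bandwidth
support (number of points, with duplicate multiplicity, inside one bandwidth
of the mode), descending, ties broken by lexicographic coordinate order; a
mode is kept iff no already-kept mode lies within one bandwidth. Every point
is labelled with its nearest kept centre, so the labels always partition the
cohort — no orphans. All tie-breaks are deterministic, and the unique-row
preprocessing makes the result independent of input order.

**Ranking and tiers.** Groups are re-indexed 1..G by non-increasing mean
risk. In 1-D the key is the group's feature mean. In 2-D no published
ordering formula exists, so the package's choice is the Euclidean norm of the
group centroid after dividing each axis by its population maximum; without
the normalisation the interaction score's much larger numeric range would
dominate the hierarchy. Tiering colours the top `ceil(G/3)` groups red, the
next `ceil(G/3)` amber, and the rest green by default; the two fractions are
configurable, and rank 1 is always red.

## Pipeline

`run_pipeline` executes load → active filter → standardise → score → cohort
construction → per-cohort bandwidth estimation, mean shift, ranking, tiering
→ report. Per-patient scores are persisted to `scores.csv`, which doubles as
a cache: clustering can be re-run from it (different quantile, different
cohort) without re-scoring, and reproduces the end-to-end result exactly.
Every run re-asserts that group sizes sum to the cohort size. The pipeline
is a pure function of (inputs, config, seed): reruns are byte-identical. Any
stage failure removes partial outputs and reports the failing stage.

## Synthetic populations

Real prescription records cannot be distributed, so the generator emulates
the relevant marginals of a primary-care population:

- about 6.2% of patients WARS-positive (`anticholinergic_prevalence`,
  enforced exactly: flagged patients receive one ACB-listed drug plus a small
  Poisson(0.6) excess, unflagged patients draw only non-ACB drugs, so the
  positive count is exactly Binomial(n, p));
- about 3% WIRS-positive at defaults: drug counts are 1 + Poisson(3)
  (median 4, right-skewed, occasional extreme polypharmacy), giving on
  average E[m(m−1)/2] = 7.5 candidate pairs per patient, so the default
  listed-pair density 0.004 yields ≈ 7.5 × 0.004 = 3% of patients with a
  listed pair;
- right-skewed score distributions with heavy mass at the lowest scores —
  the regime the clustering must handle.

Every generator operation draws from its own stream seeded by
`(spec.seed, crc32(op_name))`, so outputs are byte-reproducible and adding
operations never perturbs existing ones. Drug names are synthetic tokens
(`drug_0041`); the only real medicine names in the package are the bundled
twelve-medicine worked example, whose tables are version-pinned constants.

What the generator does **not** emulate: comorbidity and demographic
structure, correlated prescribing (drugs are sampled independently within a
patient), dose/duration, and the extreme interaction-score tail of real
populations (synthetic WIRS rarely exceeds ~10, whereas real extracts show
rare patients an order of magnitude higher). Passing tests therefore
demonstrate the algorithmic contracts — exact scoring, partition, mode
recovery, determinism — not clinical validity on real data.

## Test and script problem sizes

The acceptance properties run at synthetic scale chosen for a laptop-class
single core: 100 random populations of 100–2,000 patients for the partition
invariant, 20 seeds × 150 points for mixture recovery, 50 instances of
n ≤ 20 for the exhaustive 1-D oracle, and 1,000 random patients of ≤ 8 drugs
for the scoring oracle. The worked-example quantities recomputed by
`scripts/acceptance.py` are deterministic and independent of scale.

## Known limitations

- The 2-D ranking key is a package design choice (max-normalised centroid
  norm); other hierarchies (e.g. per-axis lexicographic) are defensible.
- Bandwidth quality degrades when a cohort is dominated by one repeated
  score; the fallback keeps the algorithm defined but such cohorts often
  yield one group per distinct score, which is the honest answer at that
  resolution.
- Dose, weight, age and treatment duration are not modelled; age, if
  present, is passthrough metadata only.
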