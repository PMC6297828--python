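# Methods

`tcranet` represents a longitudinal T-cell receptor repertoire as a set of
**Clone-Attractors** (CAs): clusters of highly similar CDR3 amino-acid
sequences treated as single dynamical units.  A CA's *amplitude* in a
(sample, time point) is the summed abundance of its member sequences; its
*basin size* K is the number of distinct members.  This note records the
model, the defaults, and the numerical and design choices, in the order the
pipeline runs.

## Weighted edit metric

Sequence similarity is a Levenshtein distance with per-operation costs
`deletion = 1.1`, `insertion = 1.1`, `substitution = 1.9`, evaluated by a
Wagner–Fischer dynamic programme (no transpositions).  With the association
threshold `lambda = 3` this admits, relative to a cluster representative, at
most two pure indels (2.2) or one substitution plus one indel (3.0), while
two substitutions (3.8) are excluded.  Because the one-substitution-plus-
one-indel case sits exactly on the boundary, all threshold comparisons use
`<=` with an absolute tolerance of 1e-9.

`distance_within(a, b, w, cutoff)` returns the exact distance when it does
not exceed the cutoff and an infinite sentinel otherwise.  Two exact lower
bounds skip most DP work: the length difference costs at least that many
indels, and any edit script contains at least as many operations as the
unit-cost Levenshtein distance (computed by edlib's banded bit-vector
algorithm with early exit), so the weighted cost is at least
`unit_distance * min(op cost)`.

## Greedy clustering

Unique sequences, pooled across all samples and time points (one shared
attractor space), are sorted by ascending length, ties broken
lexicographically — the published sort order fixes only the length; the
lexicographic tie-break makes runs reproducible.  Each sequence joins an
existing cluster whose representative lies within `lambda`, or founds a new
cluster.  Two association strategies are shipped because the method's
narrative ("first cluster that is found close enough, winner takes all")
and its pseudocode ("find the nearest cluster") differ: `first_fit`
(default) scans clusters in creation order and stops at the first hit;
`nearest_fit` takes the closest, ties to the oldest.  `nearest_fit` can
never produce more clusters than `first_fit` on the same input order.

After every association the representative is refreshed to the **medoid**
— the member with the smallest summed distance to all other members, ties
broken by shorter length then lexicographic order.  Distance sums are
cached, so an association costs one distance evaluation per existing member
and the medoid never has to be recomputed from scratch.  Association uses
the distance to the representative only (not complete linkage), and an
association log records (sequence, cluster, distance at association) so the
within-lambda property can be audited after the fact.  `lambda = 0`
degenerates to one cluster per unique sequence.

## Repertoire graphs

Attractors survive filtering when they have at least `min_members = 10`
member sequences **and** are active (amplitude > 0 in at least one sample)
in strictly more than `min_timepoint_fraction = 0.6` of the time points;
activity is pooled over samples because the filter defines one shared node
set before any per-sample graph is built.  Each (sample, time point) then
gets a graph over the filtered attractors with positive amplitude there;
an edge joins two nodes when their representatives are within
`max_edge_distance = 8` on the same weighted scale as clustering.  The
pairwise representative distances are computed once per attractor space
and shared across the (up to) samples x time points graphs.

Two statistics summarise a graph:

* **MTI** (molecular topological index): `sum_i sum_j d_i (A_ij + D_ij)`
  with degree vector `d`, adjacency `A` and shortest-path edge counts `D`.
  `D` is undefined across components of a disconnected graph, so the index
  is evaluated per connected component and summed — unreachable pairs
  contribute nothing, and on a connected graph this is the plain double
  sum.  The index falls as a fixed-size graph becomes more branched:
  at n = 6, complete (300) > path (128) > star (100).
* **sBWC**: per node, the unnormalised betweenness
  `BWC(i) = sum_{j<k} g_jk(i)/g_jk` (no `2/((n-1)(n-2))` scaling, which the
  pooled threshold makes irrelevant); per graph, the sum of components
  *strictly* above a threshold, by default the median (`th50`) of the BWC
  values pooled over every graph of the run.  Empty graphs contribute no
  values to the pool.  The group ordering is insensitive to replacing the
  median by the 40th or 60th pooled percentile.

Per-sample summaries are the median and standard deviation of each measure
over that sample's own time points (std over a single time point is 0, with
a warning).  Graphs export to GraphML/GEXF with CA size and amplitude as
node attributes and distance as edge weight.  No decision rule converting
per-sample medians into a class call is part of the method; the group
comparison is by rank statistics.

## Cluster-size power law

Basin sizes are modelled as `P(K) ~ K^-alpha`.  The fitted exponent is the
least-squares slope of log count versus log K over the distinct integer
sizes observed at least `min_count = 4` times.  For a discrete power law
the per-size counts evaluate the density exactly, so this slope is
unbiased where counts are informative, while wide logarithmic bins
systematically distort steep discrete laws (the aggregated bin density is
assigned to a single abscissa whose correct position itself depends on the
exponent); the minimum-count guard drops the Poisson-dominated tail.  Logarithmic binning remains available
(`mode="logbin"`), and a discrete maximum-likelihood estimate (zeta
likelihood, Brent minimisation on alpha in [1.01, 20]) is reported as a
diagnostic.  Degenerate inputs (< 5 distinct sizes) are an error.

## Classification pipeline

Features are CA amplitudes per (sample, time point) data point, raw counts
by default with opt-in per-data-point relative abundance.  CAs active in
strictly more than 95% of the data points form the feature pool ("active"
= at least one member sequence observed).  A per-mouse interpretation of
the 95% rule is available but not default, matching the per-data-point
feature definition.

*Selection.*  Gaussian-kernel soft-margin SVMs (penalty C = 1; bandwidth
by the median heuristic on the full feature subset, which keeps scoring
deterministic) are trained on every feature pair and ranked by
leave-one-out cross-validation accuracy; the top 50 survive.  Each
retained d-subset is extended by every unused feature, deduplicated as
sets, rescored, and truncated to the top 50, until the best score stops
improving by more than 1e-6 or dimension 8 is reached.  Ties rank by
(score descending, subset lexicographic).  LOOCV leaves out a single data
point by default; points from the same mouse remain in training, which can
flatter the score when a mouse's time points are correlated — mouse-level
hold-out is available via `loocv_unit="sample"`.  Two exact shortcuts keep
the scan fast: the kernel matrix is computed once per subset, and folds
containing no support vector of the full-data solution reuse it unchanged
(removing a point with zero Lagrange multiplier leaves the SVM solution
intact), so only support-vector folds refit.

*Ensemble.*  A committee of m = 10 machines, the i-th trained on the i-th
ranked subset; the ensemble output is the mean of the members' decision
values squashed to [0, 1] by a logistic link (no Platt scaling, which
would introduce internal cross-validation randomness).

*Noise robustness.*  Evaluation data are perturbed multiplicatively,
`x -> x (1 + v)` with `v ~ N(0, sigma^2)` drawn independently per element,
over amplitudes 0 to 0.25 in steps of 0.05; one noisy copy of the feature
matrix is drawn per amplitude from the run seed, shared by all machines.
Every data point is scored by machines trained *without* it (leave-one-out
at the same unit as above), with the noise applied to the held-out copy.
Held-out scoring is deliberate: resubstitution scores of an RBF-SVM on
~10^2 points are optimistic enough to make a no-signal dataset look
separable, whereas held-out scores keep the no-signal benchmark near
chance.  A residual optimism from selecting features on the full data
remains — the no-signal benchmark test bounds it by asserting a mean AUC
within 0.5 +/- 0.15 over seeds — and is the reason a selection-free
evaluation on independent data should be preferred whenever more data
exist.  ROC curves are computed per amplitude over thresholds of
the ensemble output; the noise-averaged curve averages (FPR, TPR) over
amplitudes on a fixed threshold grid (201 points in [0, 1]).  The reported
model is the dimension with the highest noise-averaged AUC, ties going to
the smaller dimension; an operating point is read off the noise-averaged
curve at the requested FPR (default 0.1).

*Two stages.*  Stage 1 separates control from transgenic data points;
stage 2 reruns the identical pipeline on the transgenic points labelled
pre-cancer or cancer.  The two selected feature lists are reported with
their Jaccard overlap; stage 2 is skipped with a warning when a class is
absent.

## Synthetic repertoire generator

The generator emits clone tables with the statistical structure the method
assumes, with known ground truth.  Defaults mirror the reference design:
5 control and 10 transgenic samples over 8 time points.

* **Sizes**: basin sizes drawn from a discrete power law with exponent 3
  truncated to 1..1000.  400 attractors by default (a desk-scale stand-in
  for the ~57k of a full repertoire); tests that fit the exponent use
  2000–4000 so the tail is populated.
* **Sequences**: seeds on a `CASS...F` scaffold (lengths 10–17); the
  K−1 members apply mutations within the association radius (one
  substitution 40%, one insertion 30%, one deletion 10%, substitution +
  insertion 15%, two indels 10%/5% split).  The mix leans towards
  substitutions and insertions deliberately: deletion variants sort before
  their seed in the length-ordered greedy pass and can found off-centre
  clusters, so a deletion-heavy ball would fragment under the exact
  algorithm being tested.  All sequences are globally unique.
* **Hubs**: 25 attractors with basin >= 10 whose seeds form chains of 5
  (consecutive seeds differ in a sliding 3-position window: >= 2
  substitutions apart, so clustering never merges them, but <= 4, so the
  graph connects consecutive hubs).  Hub activity persists at 0.95 per
  data point in the transgenic group and decays by a factor 0.7 per time
  step in the control group — the minimal mechanism producing the
  dense-vs-diluted divergence of the two groups' late graphs; no
  immunological kinetics is claimed.
* **Features and signals**: 24 small "ubiquitous" attractors are active in
  99% of data points and form the classifier's feature pool; 3 of them
  carry a 4-fold amplitude signal in transgenic points (stage 1) and a
  disjoint 3 carry a 3-fold signal in cancer-labelled points (stage 2).
  Member counts are log-normal (location 1.0, scale 1.0 on the log scale,
  minimum 1) when an attractor is active; background attractors are active
  with probability 0.3.
* **Phenotypes**: each transgenic mouse gets an onset time drawn uniformly
  from time points 5–8; the point before onset is pre-cancer, later points
  are cancer.

What the generator does **not** emulate: V(D)J recombination statistics
and generation probabilities, nucleotide-level errors, public/shared
clones between animals, mouse-level random effects (amplitudes are
independent across data points, so point-level LOOCV has no leakage *in
the synthetic setting* — real repertoires are another matter), sequencing
depth variation, and time-point dropout.  Passing tests therefore
demonstrate the machinery is correct under the method's own assumptions,
not that the biological claims transfer to any particular dataset.

## Problem sizes and runtimes

The test suite runs the full benchmark (about 1,100 unique sequences,
120 data points) for clustering, graph and recovery checks; 3,600–4,000
attractor runs for the size-law checks; and a reduced 12-feature pool for
the repeated-seed classification checks, keeping the whole suite within
minutes on one core.  The acceptance script clusters a 4,000-attractor
repertoire (~5,500 sequences) and fits the size law; these sizes are the
package's chosen desk-scale study conditions.

## Known limitations

* The greedy pass is order-dependent by construction; determinism comes
  from the documented sort and tie-breaks, not from order-independence.
* The medoid tie-break (shorter, then lexicographic) can keep a deletion
  variant as representative of a two-member cluster; recovery of a ball's
  centre needs a handful of members.
* Feature selection and ROC evaluation share the data set; the resulting
  optimism is bounded by the no-signal benchmark test, as documented above.
* The unnormalised BWC scales with graph size; comparisons across runs
  with very different node counts should pool thresholds per run, as
  `sbwc_scores` does.
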