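# Methods

This note documents the models and procedures implemented in
`mi-remodel`, the assumptions behind them, the parameters that matter,
and what the synthetic-data tests do and do not establish about real
data.

## The propagation model

The interactome is a directed graph whose edges carry a sign
(+1 activation, −1 inhibition) and, once fitted, a weight in [0, 1].
Protein activity is a real number in [−1, 1] with 0 meaning
"unperturbed". A stimulus clamps a subset of nodes; all other nodes
update synchronously:

    x_v ← tanh( Σ_{(u→v)} sign_uv · w_uv · x_u )

The hyperbolic tangent is the squashing map: odd, bounded, monotone, so
a single path propagates the product of its edge signs and attenuates
with small weights. Iteration runs until the maximum state change falls
below `tol = 1e-6` or `max_iter = 100` sweeps have elapsed; a trajectory
still moving at the cap (which happens on sign-frustrated cycles that
oscillate) is replaced by the time-average of its last 10 states, which
maps a symmetric oscillation to its neutral midpoint rather than an
arbitrary phase. Clamped fixed points are stable under further sweeps,
so batching many stimuli into one matrix iteration (done for speed) is
numerically identical to running them separately. One consequence of the
stopping rule: a downstream signal whose fixed-point magnitude is below
`tol` (e.g. after many strongly attenuating edges) can be reported as
exactly 0; analyses that care about such vanishing signals should pass a
tighter tolerance.

These propagation semantics — clamped-stimulus synchronous fixed-point
iteration with a tanh squash — are the package's own operationalization
of bounded signal flow on a signed interactome; they were chosen because
they are deterministic, reproducible, and make single-path behaviour
exactly solvable (the nested-squash closed form used in tests).

## Truth-table fitting

A truth table is a list of rules (stimulus activities → expected
response signs, with a positive rule weight). A weight assignment is
scored by the rule-weighted fraction of response proteins whose
propagated activity lies strictly on the expected side of zero; an
activity of exactly 0 (signal never arrives) satisfies nothing.

Fitting is simulated annealing, run as `n_solutions` independent chains
to expose the degeneracy of the weight space:

* initialisation: the topology prior w(u→v) = 1/indegree(v) (each node
  divides its attention over its inputs) plus Gaussian jitter
  (sd 0.05, clipped to [0, 1]);
* proposal: one edge weight perturbed by Gaussian noise (sd 0.1,
  clipped);
* acceptance: Metropolis on the score with geometric temperature
  T_k = T0 · 0.995^k, T0 = 1;
* each chain reports its best-so-far weights and stops early at
  accuracy 1.0; ties between solutions resolve to the earlier chain.

Ensemble size, step count and the acceptance threshold for using
solutions downstream are configuration, not constants; the defaults
(10 solutions, 2000 steps) reliably reach accuracy 1.0 on satisfiable
tables of ~10 rules over ~50-node networks within seconds.

## Relation scoring ("is this protein linked to remodeling?")

For a differential protein p with observed direction d, every ensemble
solution clamps p to d, propagates, and takes the mean sign agreement
between the propagated activities of the signature effectors and their
expected signs (an unreached effector contributes 0). The
ensemble-averaged agreement a ∈ [−1, 1] maps to the predictive value
(a + 1)/2, so "no influence on any effector" lands exactly at the 0.5
chance level, and the inclusion rule is strictly greater than 0.5. This
realizes the declared contract — a [0, 1] relationship probability
against an effector signature computed from the fitted models — as an
ensemble-propagation statistic; it is deliberately not a trained
multilayer network, whose training data the problem does not provide.
`calibrate_fpr` estimates the false-positive rate of the 0.5 threshold
empirically (randomly-signed non-signature proteins, Wilson 95% CI).

## Triggering (source) proteins

Protein u *explains* protein v when some directed path u ⇒ v of length
≤ `max_path_len` (default 3; mechanisms of interest are short cascades)
has composed sign equal to direction(u) · direction(v). Arcs are found
by breadth-first search over (node, accumulated sign) states, so a pair
reachable with both signs is handled correctly. A protein never explains
itself. The per-cohort report rows are: proteins available, % with at
least one explainer ("max explainable"), number of sources, and % of
explainable proteins the sources cover. Source selection is greedy set
cover (largest uncovered gain; ties by total out-coverage then
lexicographic ID), which is deterministic and never picks a zero-gain
node.

## Identifiability of planted sources

Source recovery is only a well-posed question when one source's
downstream cone cannot sign-consistently explain another's. On dense
networks (mean degree ≈ 3) with path length 3 the explain relation
saturates — nearly every differential protein explains nearly every
other — and "the" sources are not identifiable from the data at all.
The synthetic generator therefore supports an identifiable planting
regime used by the recovery tests: a preferential-attachment tree
(mean degree 1), sources restricted to nodes with at least two
downstream proteins within the planting depth, a pairwise
undirected-distance separation between sources (`min_separation=6` for
depth-3 planting), and a perturbation budget split evenly across
sources. Under these conditions each planted cone is private, the greedy
cover provably prefers the cone's root, and recovery plus 100% coverage
held on every feasible instance of a 50-seed scan. Real interactomes sit
between the two regimes; the published-scale observation that only about
half of differential proteins are explainable at all corresponds to the
sparse side.

## Biomarker panels

Panels of 2, 3 or 5 proteins are enumerated exhaustively (the candidate
pool is capped, default 30, by descending predictive value before the
combinatorially expensive sizes). The classifier is nearest centroid on
z-scored features: parameter-free, deterministic, and cheap enough for
leave-one-out validation inside an exhaustive scan. Standardisation is
refit on each training fold; zero-variance features get unit scale and a
degenerate all-constant panel warns and scores at chance. Two metrics
are kept: resubstitution accuracy and LOO accuracy ("generalization"),
and ranking is by (generalization, accuracy, smaller panel,
lexicographic IDs). Note that duplicating a *single* sample can change
both the standardisation and a class centroid, so resubstitution
accuracy is not monotone under sample duplication; duplicating the whole
dataset is exactly invariant, and that is the invariance the tests
assert. The four strategies differ only in which candidate list gates
the stream: `models` and `HT` scan everything (classifying model
solutions or measured samples respectively); `models/HT` keeps panels
fully inside the HT-significant set; `HT/models` keeps panels fully
inside the model-related set.

## Enrichment score and bookkeeping

The ES walks a list of genes ranked by descending phenotype correlation,
adding |correlation|^p (normalised over the set's members; p defaults
to 1, with 0 giving the unweighted Kolmogorov–Smirnov form) on hits and
subtracting 1/(N−K) on misses; the ES is the signed maximum deviation of
the running sum. Ties in correlation keep input order (stable sort). A
set covering the whole list has no decrements and degenerates to ES = 1.
Overlap accounting is exact set algebra per annotation category
(categories are an input column, not an ontology lookup); network
summary statistics use the undirected conventions of interaction-
database reports (average degree 2|E|/|V| over all nodes; local
clustering of degree-<2 nodes counts 0), deliberately separate from the
directed model network; reported percentages use half-up rounding.

## The synthetic generator

The generator emulates the study design: a scale-free signed directed
network (random-oriented preferential attachment; inhibitory fraction
0.3 by default), six cohorts of log2 ratios against an implicit control,
three core cohorts whose differential sets are driven by ~3 planted
sources to roughly 40% of the network, and remote cohorts two orders of
magnitude smaller (1–3% of the core count), matching the strong
core-vs-remote asymmetry of infarct transcriptomes. Perturbed proteins
draw log2 ratios from effect_size · state + N(0, noise_sd) (defaults 1.0
and 0.1 — chosen so that sign recovery is reliable but the BH filter at
FDR 0.01 still does real work) and p-values from Beta(0.05, 1);
unperturbed proteins draw pure noise and Uniform(0, 1) p-values. The
ortholog matrix plants true pairs in [0.6, 1] over decoys in
[0, decoy_level], making RBH recovery exact by construction. Truth
tables are read off the network itself by propagating unit weights, so
the all-ones assignment satisfies every rule and satisfiability is
guaranteed rather than asserted.

What the generator does **not** emulate: probe-level intensities and
normalisation, batch effects, correlated noise across cohorts,
RNA-vs-protein discordance, or literature-curation noise in the effector
signatures. Passing tests therefore establish the *internal* correctness
and recovery properties of the chain, not its performance on real
arrays.

## Orchestration and problem sizes

The pipeline runner derives per-stage seeds from the master seed by a
documented counter (master · 1009 + stage index, mod 2^31) and writes a
manifest with the configuration hash and per-output checksums; reruns
with the same configuration are byte-identical. The bundled run uses
scaled problem sizes chosen to keep a full end-to-end execution in the
seconds range — 200-node networks, ensembles of 6 solutions × 400 steps,
8 truth-table rules, panel sizes (2, 3) with a 30-candidate cap —
while the library itself supports the full {2, 3, 5} panel scan and
arbitrarily larger ensembles. All randomness flows through explicit
integer seeds; there is no hidden global state.

## Known limitations

* The propagation map is one of several defensible semantics (asynchronous
  update, linear-threshold, ODE-based); conclusions that depend on
  oscillation handling should be checked against the time-average rule.
* The annealer offers no optimality guarantee on unsatisfiable or large
  tables; it returns best-effort ensembles whose accuracies say how far
  the constraints were met.
* Predictive values are calibrated only by the empirical FPR estimator;
  they are not posterior probabilities.
* Greedy set cover is an approximation to minimum cover; the *number* of
  sources reported is an upper bound on the minimum.
* The secreted/plasma annotation of biomarker panels is pass-through
  metadata, not computed.
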