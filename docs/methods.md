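# Methods

## The model

`cocktailnet` analyses pairwise drug combinations as a graph problem. The
**drug cocktail network** has one node per drug and an undirected edge
between two drugs that appear together in an effective combination;
combinations with more than two members are split into all C(k, 2)
member pairs before edges are added, and duplicate pairs collapse to a
single edge. Records with unclear or absent efficacy, and drugs without
ATC annotation, are excluded at load time (the loader reports every
exclusion it makes).

### Therapeutic similarity

The WHO ATC system classifies a drug at five nested levels, encoded as
prefixes of its 7-character code (prefix lengths 1/3/4/5/7). For two
drugs d1, d2 with level-k code sets ATC_k(d), the level similarity is
the Jaccard index

    S_k(d1, d2) = |ATC_k(d1) ∩ ATC_k(d2)| / |ATC_k(d1) ∪ ATC_k(d2)|

and the therapeutic similarity is the mean over the first n levels

    TS(d1, d2) = (1/n) Σ_{k=1..n} S_k(d1, d2)

with n = 3 by default: the substance level (5) is so sparse that almost
no drug pair shares it, and level 4 adds little discrimination beyond
level 3. Drugs may carry several ATC codes; S_k is the Jaccard of the
induced *sets* of level-k prefixes, deduplicated — the only reading
consistent with the set notation. TS is symmetric, lies in [0, 1], and
equals 1 on identically annotated drugs. "Similar" drugs are those with
TS > 0, i.e. sharing at least an anatomical main group.

### The shared-neighbor statistic

The prediction model assumes that two drugs sharing unexpectedly many
combination partners are themselves likely to combine effectively. For
a pair with n1 and n2 partners, m of them shared, in a network of N
drugs, the probability of exactly m shared partners under independent
uniform random neighborhoods is

    P(m, n1, n2, N) = C(N,m) C(N−m, n1−m) C(N−n1, n2−m) / [C(N,n1) C(N,n2)]
                    = C(n1,m) C(N−n1, n2−m) / C(N,n2)

— the hypergeometric point probability (the two forms are algebraically
identical: choosing m shared then n1−m private partners equals choosing
n1 partners then m of them). It is strictly decreasing in m for fixed
(n1, n2, N), symmetric in (n1, n2), and sums to 1 over m.

Reference worked values at N = 215 (a published cocktail network's node
count): P(2,2,2) = 4.35e−05, P(2,2,3) = 1.30406e−04, P(2,2,4) =
2.60813e−04. The point-probability reading (rather than an upper tail)
reproduces the published low-degree values exactly; in every published
case m = min(n1, n2), where point and tail coincide. The remaining
published value 4.83e−05 also inverts under this formula, at
(m=3, n1=4, n2=6, N=215) → 4.8286e−05, further supporting the reading.
An upper-tail variant (`tail=True`) is provided for users who prefer a
genuine p-value; it changes nothing when m = min(n1, n2).

### Ranking models

* **DCPred1** — candidates are all similar (TS > 0) pairs of network
  drugs; ranked by descending TS.
* **DCPred2 / DCPred3** — candidates additionally require both drugs to
  have at least 2 / 3 neighbors; ranked by ascending P(m, n1, n2, N).

N defaults to the number of nodes in the loaded network. Neighbor
counts are the full network degrees; when a candidate pair is itself an
edge its own edge contributes 1 to each degree (no correction), which
matches how published rankings score known combinations alongside novel
pairs — `exclude_pair_edge=True` offers the conservative alternative.
Ties are broken by descending TS, then lexicographic pair id, so
rankings are deterministic and invariant to input order.

### Null model for network-level similarity

The observed network mean TS (arithmetic mean of edge TS values) is
compared against degree-preserving randomizations: repeated double-edge
swaps (pick two disjoint edges (a,b), (c,d); rewire to (a,d), (c,b) if
that creates no loop or parallel edge). Each replicate attempts
`ceil(swap_factor × |E|)` swaps with `swap_factor = 10`, a standard
mixing allowance. The empirical p-value is the fraction of replicates
with mean TS ≥ observed — ties count toward the numerator, the
conservative convention, so p = 1 on networks rewiring cannot change
and p ≥ 1/R is the smallest resolvable value at R replicates. The
analysis is run at ATC depths k = 1..4; by default the pair score at
depth k is the TS aggregated over levels 1..k (`agg="mean"`), with the
single-level Jaccard available via `agg="single-level"`. Depth 5 is
omitted: essentially no pairs share full substance codes, so the
statistic degenerates there.

Component enrichment: for each level-1 ATC class in a connected
component, the one-sided hypergeometric tail of drawing at least the
observed number of class carriers in a component-sized sample from the
drug universe, with Benjamini–Hochberg adjustment across classes. A
drug carrying several level-1 classes counts once toward each. Raw
carrier counts are emitted alongside the test so frequency-style tables
can be rebuilt without any test.

### Target proximity

A STRING-style PPI table is loaded keeping edges with combined score ≥
700 (the usual high-confidence cutoff; the threshold is inclusive,
duplicates keep the maximum score). The distance between two drugs'
target sets is the minimum unweighted shortest-path length over all
cross pairs — 0 iff the sets intersect, and the named sentinel
`UNREACHABLE` (never an arbitrary large number) when no path exists.
Hub drugs (degree ≥ 7, i.e. "more than six partners"; threshold
configurable) are compared on two distributions: distances to their
combination partners vs. to therapeutically similar non-partners; both
distributions and their medians are reported, as is a per-localization
tally of target proteins.

## Synthetic data

The generator produces inputs with the statistical structure the
analyses assume, under a fabricated ATC alphabet (level-1 letters
E, F, I, K, O, Q, … that the real system does not use) so fixtures can
never be mistaken for real annotations.

* **Drugs** — each drug gets a primary class and a therapeutic family
  (a level-3 prefix); 1–3 codes are sampled mostly within the family
  (70%), sometimes elsewhere in the class (20%) or in another class
  (10%). Same-family drugs therefore score high TS; cross-class pairs
  score 0.
* **Combination network** — grown by degree-preferential attachment:
  each new drug brings 1–3 edges (probabilities 0.5/0.3/0.2); with
  probability `ts_assortativity = 0.7` an endpoint is drawn from the
  TS-similar drugs, and each extra edge closes a triangle through a
  partner-of-partner with probability `triadic_closure = 0.6`. The
  result is scale-free (log–log OLS slope ≈ 2, the regime reported for
  real cocktail networks), therapeutically assortative, and locally
  clustered so that combinable pairs share partners. A
  `planted_fraction = 0.1` of true pairs — sampled only where both
  endpoints retain degree ≥ 2 — is withheld from the emitted table and
  returned as evaluation positives. One 2-member effective combination
  is emitted per kept edge, with approved/clinical/preclinical status
  drawn at 0.40/0.33/0.27, the approximate mix in curated combination
  data.
* **PPI** — a connected Watts–Strogatz small-world graph (k = 6,
  p = 0.1) with 2 proteins per drug; partners' targets are placed
  within two hops with probability 0.8; all scores ≥ 700.

What the generator does **not** emulate: multi-drug (>2 member)
combinations, dosage, heterogeneous annotation quality, the long tail
of isolated drugs in real databases, or biologically structured PPI
modules. Passing tests therefore demonstrate that the statistics and
rankings behave as designed under the assumed structure, not that the
method will reach any particular accuracy on curated pharmacological
data.

## Numerical choices

* The shared-neighbor probability is evaluated in log-gamma space and
  exponentiated, stable for any realistic N; (n1, n2) are canonicalized
  to n1 ≤ n2 first so the symmetry P(m,n1,n2,N) = P(m,n2,n1,N) is exact
  in floating point, not just to rounding.
* Power-law fits are ordinary least squares on (log10 k, log10 P(k))
  over observed degrees with P(k) > 0 — matching how degree
  distributions are conventionally presented — with α = −slope and
  c = 10^intercept; an MLE fit is deliberately not the default. At
  least three distinct degrees are required.
* TS values are exact rationals conceptually; comparisons in tests use
  absolute tolerance 1e−12.
* ROC curves group tied scores (all equally scored candidates cross a
  threshold together); AUC is the trapezoid area, identical to the
  tie-corrected rank-sum statistic.
* All randomness flows from explicit integer seeds; replicate seeds are
  `seed + replicate index`, so null ensembles are reproducible and
  shared across ATC depths within a run.

## Problem sizes

The test suite exercises the full pipeline at 300–500 drugs (5 seeds
for the ranking benchmark, 200 null replicates for the significance
run) and the generator's degree-structure check at 2000 drugs; these
sizes give stable statistics for every property asserted while keeping
the suite quick to run.

## Quantities that require the original databases

Several published counts are properties of specific releases of DCDB
and DrugBank, not of the method: the 215-node / 239-edge network, the
194 effective combinations (76 approved / 64 clinical / 54
preclinical), the 74 known positives among 1181 similar candidate
pairs, 102 star drugs, 14 hubs, the 82% similar star-neighbor edges,
and the 22/35 known-effective top predictions, as well as the AUC
values 0.75/0.88/0.92 computed on that data. These are documented here
as external-data-dependent reference points; the package reproduces the
*mechanisms* behind them (and the analytic worked values above
exactly), and its benchmark asserts the model *ordering* — the
shared-neighbor ranking beating the TS-only ranking — on synthetic data
with planted ground truth.

## Known limitations

* Only pairwise combinations are scored; triples are split into pairs
  at load and never scored jointly.
* The statistic conditions on degrees but not on the full degree
  sequence; in very dense networks the independence assumption under-
  estimates expected overlap.
* Component enrichment uses level-1 classes only, the resolution at
  which published component tables are reported.
* The default evaluation scores known edges with their own contribution
  to the degree counts included (see `exclude_pair_edge` /
  `holdout_evaluation` for the conservative alternatives).
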