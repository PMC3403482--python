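# cocktailnet

Network analysis and prediction of effective drug combinations.

Combining drugs is a standard strategy against complex diseases, but
the space of possible pairings is far too large to screen. This
package treats the known effective combinations as a graph — the
**drug cocktail network**, with a node per drug and an edge per
effective pairwise combination — and exploits two empirical
regularities of that graph: drugs in effective combinations tend to
have similar therapeutic effects, and they tend to share combination
partners. It is aimed at computational pharmacologists and systems
biologists who want to rank candidate pairs for follow-up, and at
methodologists who want a reproducible, fully synthetic benchmark for
combination-prediction statistics.

## What it computes

**Therapeutic similarity (TS).** The ATC system classifies a drug at
five nested levels (prefixes of length 1/3/4/5/7 of its 7-character
code). With `ATC_k(d)` the set of level-*k* prefixes of drug *d*'s
codes,

```
S_k(d1, d2) = |ATC_k(d1) ∩ ATC_k(d2)| / |ATC_k(d1) ∪ ATC_k(d2)|
TS(d1, d2)  = (1/n) Σ_{k=1..n} S_k(d1, d2)        (n = 3 by default)
```

**Network topology.** Degree distribution and its log–log power-law
fit `p(k) ∝ c·k^(−α)`, connected components with level-1 ATC class
enrichment (hypergeometric + BH), star drugs (≥ 2 partners) and hub
drugs (≥ 7 partners), and the TS structure around star drugs.

**Null model.** Degree-preserving double-edge-swap randomization; the
empirical p-value of the observed mean edge TS against the rewired
ensemble at ATC depths 1–4.

**DCPred ranking.** For a candidate pair with `n1` and `n2` partners,
`m` shared, in an `N`-drug network, the shared-neighbor probability

```
P(m, n1, n2, N) = C(n1,m) · C(N−n1, n2−m) / C(N,n2)
```

(the hypergeometric point probability — small values mean the pair
shares more partners than chance allows). DCPred1 ranks similar pairs
(TS > 0) by descending TS; DCPred2/DCPred3 restrict to drugs with ≥ 2/3
partners and rank by ascending `P`. ROC/AUC and
sensitivity/specificity/accuracy tables evaluate rankings against
known or withheld positives.

**Target proximity.** On a STRING-style PPI graph (score ≥ 700),
minimum shortest-path distances between drugs' target sets, comparing
hub drugs' combination partners against therapeutically similar
non-partners, plus a target-localization tally.

**Synthetic data.** A seeded generator for drugs with fabricated ATC
hierarchies, TS-assortative scale-free combination networks with
planted (withheld) true pairs, and toy small-world PPI graphs — so the
entire pipeline runs and is tested offline. See `docs/methods.md` for
model details, assumptions, and limitations.

## Worked example

`examples/04_predict_and_evaluate.py` generates a 500-drug synthetic
network with 10% of true pairs withheld, ranks candidates with the
TS-only and shared-neighbor models, and scores recovery:

```
764 known combinations, 85 withheld as truth
DCPred1: 23067 candidates, AUC = 0.500
DCPred2: 11536 candidates, AUC = 0.847
top DCPred2 candidate: SD0047+SD0048 (m=3 shared partners of n1=5, n2=3; p = 4.83e-07)
```

An AUC of 0.847 means a withheld true pair outranks a random non-pair
85% of the time under the shared-neighbor model, while therapeutic
similarity alone carries no ranking signal once every candidate is
already similar — sharing partners is the informative feature. The
other examples cover similarity scoring (`01`), topology
(`02` — power-law fit `p(k) ~ 0.63·k^−1.80`, star/hub detection) and
the null model (`03` — observed mean TS 0.62 against a rewired null of
0.17 ± 0.02, empirical p = 0.000 at every ATC depth).

The same operations are scriptable from the shell:

```sh
cocktailnet simulate --n-drugs 500 --seed 1 --out-dir fixtures/
cocktailnet build     --drugs fixtures/drugs.tsv --combos fixtures/combos.tsv --out-dir net/
cocktailnet randomize --drugs fixtures/drugs.tsv --combos fixtures/combos.tsv \
                      --reps 1000 --seed 1 --levels 1,2,3,4 --out-dir rand/
cocktailnet predict   --drugs fixtures/drugs.tsv --combos fixtures/combos.tsv \
                      --model dcpred2 --out ranking.tsv
cocktailnet evaluate  --ranking ranking.tsv --out-dir eval/
```

Every run echoes its parameters, input checksums and package version
to `run_config.yaml` in its output directory.

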