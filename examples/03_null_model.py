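"""Is the network's therapeutic similarity higher than chance?

Compares the mean edge TS of a synthetic cocktail network against 100
degree-preserving rewirings at ATC depths 1-4.  The empirical p-value
is the fraction of rewired networks at least as similar as the real one.
"""

from cocktailnet import (
    GeneratorConfig,
    build_network,
    combinations_from_frame,
    drug_records_from_frame,
    generate_cocktail_network,
    generate_drugs,
    ts_significance,
)

cfg = GeneratorConfig(n_drugs=300, seed=1)
drugs_df = generate_drugs(cfg)
combos_df, _ = generate_cocktail_network(cfg, drugs_df)
drugs = drug_records_from_frame(drugs_df)
net = build_network(combinations_from_frame(combos_df), drugs)

results = ts_significance(net, drugs, n_replicates=100, seed=7)
print("ATC depth | observed TS | null mean ± sd | empirical p")
for level, res in results.items():
    print(
        f"    {level}     |   {res.observed_ts:.4f}    | "
        f"{res.null_mean:.4f} ± {res.null_sd:.4f} | {res.empirical_p:.3f}"
    )

# Rewiring keeps every drug's partner count but scrambles who partners
# with whom. p = 0.000 means no rewired network matched the observed
# similarity - drugs in effective combinations are far more alike than
# their connectivity alone would predict.
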