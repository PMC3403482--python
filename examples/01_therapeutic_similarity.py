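"""Score therapeutic similarity between drugs from their ATC codes.

Three diuretics-like drugs sharing a chemical subgroup score high;
an analgesic from another anatomical group scores zero.
"""

from cocktailnet import DrugRecord, level_similarity, therapeutic_similarity

hydro = DrugRecord("D1", "thiazide-like A", frozenset({"C03AA03"}))
chloro = DrugRecord("D2", "thiazide-like B", frozenset({"C03AA01"}))
indap = DrugRecord("D3", "sulfonamide diuretic", frozenset({"C03BA11"}))
aspirin = DrugRecord("D4", "analgesic", frozenset({"N02BA01"}))

for a, b in [(hydro, chloro), (hydro, indap), (hydro, aspirin)]:
    per_level = [level_similarity(a, b, k) for k in (1, 2, 3)]
    ts = therapeutic_similarity(a, b, n=3)
    print(f"{a.name:22s} vs {b.name:22s}  S1..S3 = {per_level}  TS = {ts:.4f}")

# TS is the mean Jaccard similarity of the drugs' ATC prefix sets over
# levels 1-3: 1.0 means same pharmacological subgroup throughout, 0.0
# means not even the anatomical main group is shared.
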