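"""Rank candidate genes for a disease/process pair on a synthetic world.

Builds the standard planted-community fixture, treats a slice of the
planted positives (plus one extra gene) as the "process" positive set, and
runs the full PDP pipeline: f_D and f_P share the disease negatives, the
combined score is g = f_D * f_P, and the union predictor is the baseline.
"""

from pdprank import FixtureSpec, filter_candidates, make_fixture, pdp_scores

fx = make_fixture(FixtureSpec(seed=0))
disease_pos = sorted(fx.positives)
process_pos = set(disease_pos[:10]) | {sorted(fx.graph.meta["communities"][0])[-1]}

table = pdp_scores(
    fx.graph,
    disease_positives=fx.positives,
    disease_negatives=fx.negatives,
    process_positives=process_pos,
    lam=1.0,
)

print("Top 8 candidates by combined score g = f_D * f_P:")
cols = ["rank", "gene", "degree", "f_D", "f_P", "f_union", "g", "label_D", "label_P"]
print(table.head(8)[cols].to_string(index=False, float_format="%.3f"))

unl = filter_candidates(table, "unlabeled-both", top=5)
print("\nTop 5 genes unlabeled in BOTH positive sets (novel candidates):")
print(unl[cols].to_string(index=False, float_format="%.3f"))
print(
    "\nDual positives pin g=f_D*f_P near 1 and rank first; the union "
    "baseline instead\nfixes every pooled positive at f=1.00, hiding which "
    "ones are close to both sets."
)
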