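"""Assemble a disease-disease network from shared associated factors.

After several disease queries have each been categorized over the same
factor universe, two diseases are linked by the Jaccard overlap of their
associated factors (established + potential by default, since candidate
hypotheses live in the weakly-positive band).
"""

import literank as lr

universe = {
    "hypertension", "diabetes", "smoking", "depression", "vitamin e",
    "head trauma", "caffeine", "stress",
}
th = lr.Thresholds((0.1, 0.3), source="manual")


def bands(established, potential):
    return lr.AssociationCategories(
        established=set(established), potential=set(potential),
        unknown=universe - set(established) - set(potential), thresholds=th,
    )


categorized = {
    "stroke": bands({"hypertension", "smoking", "diabetes"}, {"depression", "stress"}),
    "parkinson": bands({"head trauma"}, {"depression", "caffeine"}),
    "dementia": bands({"hypertension", "head trauma"}, {"depression"}),
}

network = lr.build_network(categorized, rule="jaccard_assoc", min_weight=0.0)
print("edges (Jaccard overlap of established + potential factors):")
for (a, b), (w, shared) in sorted(network.edges.items()):
    print(f"  {a} -- {b}: weight {w:.3f}, shared: {', '.join(sorted(shared))}")
# A higher weight means the two diseases share a larger fraction of their
# positively associated factors — a candidate disease-disease interaction.
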