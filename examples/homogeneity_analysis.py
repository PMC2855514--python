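"""Quantify molecular homogeneity of outcome classes with silhouette widths.

Two cohorts are compared: one whose lethal class is molecularly uniform
(K=1: every lethal tumor expresses the same signal genes) and one whose
lethal class hides four latent subtypes with disjoint signal blocks (K=4,
inter-tumor heterogeneity).  In both, the class descriptors are chosen by
deliberately overfitting the full cohort (t-test, q < 0.05), and each
sample's homogeneity score s(i) = (b(i) - a(i)) / max(a(i), b(i)) compares
its mean distance to its own class (a) and to the other class (b).
"""

from progsig import (
    SimulationConfig, generate_cohort, group_homogeneity, overfit_signature,
    pairwise_distances, silhouette_widths, structure_category,
)

for k in (1, 4):
    cohort, _ = generate_cohort(SimulationConfig(
        n_lethal_subtypes=k, effect_size_delta=2.0,
        erg_effect_size=0.0, stroma_fraction=0.0, seed=20 + k,
    ))
    signature = overfit_signature(cohort, q_threshold=0.05)
    dist = pairwise_distances(cohort.expression, signature,
                              metric="one_minus_pearson")
    result = silhouette_widths(dist, cohort.phenotype.outcomes().to_numpy())
    averages, overall = group_homogeneity(result)
    print(f"K={k} lethal subtype(s), {len(signature)}-gene overfit signature:")
    for group in ("lethal", "indolent"):
        avg = averages[group]
        print(f"  {group:<9} average homogeneity {avg:+.3f} "
              f"({structure_category(avg)} structure)")
    print(f"  overall   average homogeneity {overall:+.3f}")

print("\nWith a heterogeneous lethal class the lethal average drops below "
      "the indolent one (and below zero): lethal samples sit closer to "
      "indolent profiles than to each other, which is exactly why a single "
      "lethal signature is hard to learn.")
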