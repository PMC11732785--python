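"""Recover a publication effect from a synthetic cohort.

Generates a cohort in which each 'publication' shares its own richness
range, connectance, taxon-aggregation level and link-detection probability,
then compares the mean pairwise GCD-11 within publications to the mean
between publications.  A between/within ratio well above 1 is the
publication-effect signature: same-source webs look alike.
"""

from webprint import (
    apply_inclusion_filters,
    pairwise_distances,
    partition_from_metadata,
    publication_effect,
    threshold_shares,
)
from webprint.synth import generate_cohort, strong_effect_profiles

cohort = generate_cohort(strong_effect_profiles(), master_seed=17)
by_id = {m.web_id: m for m in cohort.metadata}
webs, meta = [], []
for raw in cohort.webs:
    processed, _ = apply_inclusion_filters(raw)
    if processed is not None:
        webs.append(processed)
        meta.append(by_id[raw.web_id])

D = pairwise_distances(webs)
part = partition_from_metadata(meta, "publication", D.web_ids)
effect = publication_effect(D, part)
print(f"within-publication mean GCD-11:  {effect['within']:.3f}  "
      f"({effect['n_within_pairs']} pairs)")
print(f"between-publication mean GCD-11: {effect['between']:.3f}  "
      f"({effect['n_between_pairs']} pairs)")
print(f"between/within ratio:            {effect['ratio']:.2f}")

shares = threshold_shares(D, meta, cutoffs=[1.5, 2.5])
print("\nshare of pairs at or below each cutoff, by pair category:")
print(shares.round(3).to_string(index=False))
print("\nSame-publication pairs dominate the smallest distances: webs built")
print("under one protocol carry that protocol's structural fingerprint.")
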