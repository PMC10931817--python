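"""Normalized volume gradients and pre/post volume correlation.

Runs the full image pipeline on a small 16 kHz young-adult cohort and
summarises the median-normalized element volumes: the modiolar>pillar
volume gradient of both synaptic partners and the rank correlation
between pre- and postsynaptic volumes of a pair.
"""

from ihcsynapse import get_profile, run_cohort
from ihcsynapse.volumetry import volume_correlation

cells, pairs, cohort, prov = run_cohort(
    [get_profile("gerbil_16k_young")], n_animals_per_group=3,
    cells_per_animal=8, seed=5,
)

print(f"{len(pairs)} colocalized pairs from {len(cells)} cells")
med = pairs.groupby("side")[["pre_norm_volume", "post_norm_volume"]].median()
print("\nmedian normalized volumes by side:")
print(med.round(3).to_string())

corr = volume_correlation(pairs, groupby=["side"])
print("\nSpearman rho, pre vs post normalized volume:")
print(corr.round(3).to_string(index=False))
# Within each stack the median normalized volume of colocalized elements
# is 1 by construction; the modiolar side carries larger elements and
# pre/post volumes co-vary (target rank correlation 0.6).
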