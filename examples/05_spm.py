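"""Surface statistical parametric mapping on a planted-effect cohort.

Per-node thickness fields for 20 loaded vs 20 control subjects are drawn
on a fixed ~1000-node template with a +30% patch planted on the loaded
group's superior neck; node-wise linear models plus permutation
cluster-extent correction recover the patch.
"""

import numpy as np

import femurmap as fm
from femurmap.spm import (
    build_design,
    cluster_inference,
    percent_difference_summary,
)
from femurmap.synth import make_field_cohort

template, _, truth = fm.make_femur(fm.FemurSpec(n_vertices=1000))
region = fm.synth._region_mask(truth.depth, truth.theta, 40, 60, 0.8, 2.4)
print(f"planted region: {region.sum()} of {template.n_vertices} nodes, "
      "+30% thickness in the loaded group")

feats, table = make_field_cohort(template, 20, 20, region, 30.0, 0.10,
                                 np.random.default_rng(1))
design = build_design(table.group.values, "loaded", "control",
                      {"weight_kg": table.weight_kg.values})
res = cluster_inference(
    feats, design, np.ones(template.n_vertices, bool), template.edges,
    method="permutation", n_perm=500, seed=42,
)
res = percent_difference_summary(res, feats, np.arange(20, 40), np.arange(20))

for i, c in enumerate(res.clusters[:3]):
    print(f"cluster {i}: extent {c.extent} nodes, corrected p = "
          f"{c.p_value:.4f}, significant = {c.significant}")
sig = [c for c in res.clusters if c.significant]
if sig:
    inter = np.intersect1d(sig[0].nodes, np.flatnonzero(region))
    dice = 2 * len(inter) / (len(sig[0].nodes) + region.sum())
    print(f"largest significant cluster: Dice overlap with truth = "
          f"{dice:.2f}, mean thickness difference = "
          f"{sig[0].mean_percent_diff:.1f}% (planted: +30%)")
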