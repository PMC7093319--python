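"""How stable are the estimated edges and the betweenness ranking?

Nonparametric bootstrap: the fraction of resamples in which each edge
reappears (its inclusion proportion) separates robust edges from noise.
Case-drop bootstrap: the CS-coefficient is the largest fraction of
subjects that can be dropped while the betweenness profile still
correlates >= 0.7 with the full sample in >= 95% of resamples.
"""

import numpy as np

import prsnet

p = 6
pcor = np.zeros((p, p))
pcor[0, 1] = pcor[1, 0] = 0.40   # strong planted edge
pcor[2, 3] = pcor[3, 2] = 0.30
pcor[1, 5] = pcor[5, 1] = 0.15   # weak risk edge
net = prsnet.planted_network_from_pcor(
    pcor, ["V1", "V2", "V3", "V4", "V5", "PRS"], ["positive"] * 5 + ["risk"])
data = prsnet.sample_dataset(net, n=2000, seed=10)

boot = prsnet.nonparametric_bootstrap(
    data, B=200, estimator="modselect", settings={"start": "empty"}, seed=11)
report = prsnet.edge_inclusion_report(
    boot, [("V1", "V2"), ("V2", "PRS"), ("V1", "V4")])
print(f"bootstrap over B={boot.B} resamples ({boot.n_failed} failed):")
for _, row in report.iterrows():
    kind = ("strong planted" if row.node_j == "V2" else
            "weak risk" if row.node_j == "PRS" else "planted null")
    print(f"  {row.node_i}-{row.node_j} ({kind}): included in "
          f"{row.inclusion_proportion:.0%} of resamples, "
          f"median weight {row.q50:.3f}, robust flag {row.robust_ge_50pct}")

curve = prsnet.casedrop_bootstrap(
    data, proportions=(0.0, 0.25, 0.5, 0.75), B=30,
    estimator="threshold", seed=12)
print("\ncase-drop stability of predictive betweenness:")
for _, row in curve.summary().iterrows():
    print(f"  drop {row.drop_proportion:.0%}: mean correlation "
          f"{row.mean_correlation:.2f}")
print(f"CS-coefficient = {curve.cs_coefficient}")
print("-> edges above 50% inclusion are reported as robust; a CS-coefficient"
      "\n   of 0.5+ means the betweenness ranking tolerates halving the cohort.")
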