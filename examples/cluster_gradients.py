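"""Isoform-specific gradients between a secreting and a scavenging cluster.

Places a 100-cell CXCL12-secreting cluster and a 100-cell CXCR7+ cluster
100 um apart (no vessel, no circadian rhythm), runs each isoform to
steady state, and prints the inter-cluster gradient, the time it took to
form, and the total chemokine left on the grid.  Expected pattern: the
gamma isoform (highest ECM partition) forms the steepest gradient but
takes longest; alpha (highest secretion, weakest ECM binding) leaves the
most *free* chemokine but a shallower gradient.
"""

import cxclgrad as cg

for isoform in ("alpha", "beta", "gamma"):
    cfg = cg.scaled_cluster_config(isoform=isoform)
    res = cg.run_setup1(cfg, seed=1)
    steady = (
        f"{res.time_to_steady_s / 60:.0f} min" if res.steady else "not reached (cap)"
    )
    print(
        f"CXCL12-{isoform:<6} gradient {res.gradient[-1]:+.3e} nM/um  "
        f"steady after {steady:<18} total on grid {res.total[-1]:8.2f} nM*voxel"
    )

print(
    "\nThe gradient is the mean total (free+bound) concentration difference\n"
    "between the facing cluster faces over the 100-um separation; positive\n"
    "points from the secreting toward the scavenging cluster."
)
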