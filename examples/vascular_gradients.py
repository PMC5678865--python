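"""Endothelial CXCR7+ cells set the near-vessel gradient direction.

Runs the desk-scale vascularized tumor section (100-um cube, central
vessel, circadian forcing of secretion and blood) twice with identical
cell placements: once with 83%-coverage endothelial scavengers on the
vessel lining and once without.  Prints the signed maximum
endothelial-tissue gradient and the radial concentration profile.
Expected: scavengers deplete chemokine next to the wall, so the gradient
points into the tissue (+); without them blood delivery dominates near
the wall and the gradient points toward the vasculature (-).
"""

import cxclgrad as cg

cfg = cg.scaled_tumor_config()
with_endo = cg.run_setup2(cfg, seed=1)
without = cg.run_setup2(cfg, seed=1, n_endothelial=0)

for label, res in (("with endothelial CXCR7", with_endo), ("without", without)):
    rec = res.max_gradient("endothelial_tissue")
    arrow = "into tissue" if rec.sign > 0 else "toward vasculature"
    print(
        f"{label:>24}: max endothelial-tissue gradient "
        f"{rec.value:+.3e} nM/um ({arrow})"
    )

print("\nradial total-concentration profile at the end of the day stage (nM):")
print("  distance from wall:", "  ".join(f"{d:5.0f} um" for d in with_endo.profile_distances_um))
print("  with scavengers:   ", "  ".join(f"{c:8.4f}" for c in with_endo.profiles[-1]))
print("  without:           ", "  ".join(f"{c:8.4f}" for c in without.profiles[-1]))
print(
    "\nScavengers suppress concentrations near the vessel wall far more than\n"
    "deep in the tissue, which is what flips the local gradient direction."
)
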