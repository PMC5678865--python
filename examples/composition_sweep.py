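"""Tumor cellular composition sets blood-tissue gradient size and sign.

Sweeps secreting x scavenging cell counts in the desk-scale vascularized
section (single replicate to keep this example quick; the study protocol
averages five) and prints the signed maximum blood-tissue gradient over
the circadian stage.  Negative values: chemokine is higher in the blood
and the gradient points toward the vasculature.
"""

import cxclgrad as cg

cfg = cg.scaled_tumor_config()
result = cg.sweep_composition(
    cfg, n_secreting_list=[3, 25], n_scavenging_list=[3, 25],
    replicates=1, master_seed=1,
)
print("signed max |blood-tissue gradient| (nM/um), rows = secreting cells:")
print(result.matrix.to_string(float_format=lambda v: f"{v:+.3e}"))
print(
    "\nWith the alpha-isoform defaults the blood is the dominant source at\n"
    "this scale, so gradients point into the blood across compositions; the\n"
    "magnitude still tracks the secreting:scavenging balance."
)
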