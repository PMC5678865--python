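"""Unit conversions shared across the simulator.

Concentrations are carried in nM, lengths in micrometres, volumes in
litres, molecular amounts either as molecule counts (receptor pools) or
as nM within a known compartment volume.
"""

AVOGADRO = 6.02214076e23  # molecules / mol

UM3_TO_L = 1e-15  # 1 um^3 = 1e-15 L


def molecules_to_nM(n_molecules: float, volume_l: float) -> float:
    """Convert a molecule count in a compartment of ``volume_l`` litres to nM."""
    return n_molecules / (AVOGADRO * volume_l) * 1e9


def nM_to_molecules(conc_nm: float, volume_l: float) -> float:
    """Convert a concentration in nM to a molecule count in ``volume_l`` litres."""
    return conc_nm * 1e-9 * AVOGADRO * volume_l
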