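"""Random-coil Hα/Cα reference chemical shifts.

Static reference table of residue-specific random-coil shifts (ppm) in the
style of the Wishart peptide coil compilations (aqueous conditions, near-
neutral pH, no neighbour corrections).  Deviations of observed shifts from
these references (CSDs) report on secondary structure: persistent negative
Hα and positive Cα deviations indicate α-helix.

A live predictor with pH/temperature and sequence-neighbour corrections
would give slightly different absolute references; the analyses here only
use deviations relative to a consistent table, and the synthetic-data
generators build their inputs from this same table.
"""

import pandas as pd

# residue -> (HA, CA) random-coil shifts in ppm
_COIL = {
    "A": (4.32, 52.5), "C": (4.55, 58.2), "D": (4.64, 54.2),
    "E": (4.35, 56.6), "F": (4.62, 57.7), "G": (3.96, 45.1),
    "H": (4.73, 55.0), "I": (4.17, 61.1), "K": (4.32, 56.3),
    "L": (4.34, 55.1), "M": (4.48, 55.4), "N": (4.74, 52.8),
    "P": (4.42, 63.3), "Q": (4.34, 56.1), "R": (4.34, 56.0),
    "S": (4.47, 58.3), "T": (4.35, 61.8), "V": (4.12, 62.2),
    "W": (4.66, 57.5), "Y": (4.55, 57.9),
}

# amide proton random-coil reference (single nominal value; only used by
# the synthetic generators, the dispersion statistic is reference-free)
HN_COIL = 8.30


def random_coil_table() -> pd.DataFrame:
    """Reference table with columns residue_type, HA, CA (ppm)."""
    return pd.DataFrame(
        [(aa, ha, ca) for aa, (ha, ca) in sorted(_COIL.items())],
        columns=["residue_type", "HA", "CA"],
    )


def coil_shift(residue_type: str, atom: str) -> float:
    """Random-coil shift (ppm) for one residue type and atom (HA, CA, HN)."""
    if atom == "HN":
        return HN_COIL
    try:
        ha, ca = _COIL[residue_type.upper()]
    except KeyError:
        raise KeyError(f"no random-coil reference for residue {residue_type!r}")
    return ha if atom == "HA" else ca
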