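"""Fixed physical and geometric constants used across the pipeline.

Backbone geometry is idealized: the helix builder consumes only the two
Ramachandran dihedrals, so bond lengths and angles are frozen here to make
the forward model bit-exactly reproducible.  Values are standard peptide
geometry (Engh–Huber-style averages, rounded).
"""

# --- backbone internal coordinates (lengths in Å, angles in degrees) ---
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.02
BOND_CA_CB = 1.53

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_N_H = 119.0
ANGLE_N_CA_CB = 110.5
# improper dihedral C'(i)-N(i)-CA(i)-CB(i) fixing the L-configuration side-chain
# direction; any consistent value defines the same azimuth *differences*
DIHEDRAL_C_N_CA_CB = -122.0

# --- default amide 15N chemical shift tensor (ppm) ---
# Literature-standard backbone amide values; principal values ordered
# sigma11 <= sigma22 <= sigma33, sigma33 in the peptide plane at BETA_NH
# degrees from the N-H bond, sigma22 perpendicular to the peptide plane.
SIGMA11_DEFAULT = 57.0
SIGMA22_DEFAULT = 81.0
SIGMA33_DEFAULT = 227.0
BETA_NH_DEFAULT = 17.0

# --- motional model defaults (degrees) ---
WOBBLE_SD_DEFAULT = 10.0
AZIMUTH_SD_DEFAULT = 18.0
QUADRATURE_POINTS_DEFAULT = 21

# --- helix defaults (degrees) ---
PHI_DEFAULT = -65.0
PSI_DEFAULT = -45.0
OMEGA_DEFAULT = 180.0

# --- deuterium order parameters ---
# static quadrupole coupling constant e^2qQ/h for C-D bonds, kHz
QCC_DEFAULT_KHZ = 167.0

# --- secondary-structure calling thresholds (ppm) ---
HA_THRESHOLD_DEFAULT = 0.1
CA_THRESHOLD_DEFAULT = 0.7
MIN_HELIX_RUN_DEFAULT = 4

# --- topology classification bounds (degrees tilt) ---
IN_PLANE_TILT_RANGE = (75.0, 105.0)
TRANSMEMBRANE_TILT_MAX = 30.0

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CATIONIC_RESIDUES = frozenset("KR")

# SAAP-148, a 24-residue LL-37-derived antimicrobial peptide
# (N-terminally acetylated, C-terminally amidated in the experiments).
SAAP148_SEQUENCE = "LKRVWKRVFKLLKRYWRQLKKPVR"
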