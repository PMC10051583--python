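"""Ideal α-helix construction and helical geometry.

The helix is built by internal-coordinate chain extension from fixed bond
lengths/angles (:mod:`memtopo.constants`) and user-supplied backbone
dihedrals.  Because every residue repeats the same internal coordinates,
the rigid transform mapping one residue's backbone onto the next is exactly
the same screw motion for all residues; its axis *is* the helix axis, its
rotation angle the per-residue twist and its axial translation the rise.
Coordinates are re-expressed in a frame with the helix axis along +z and the
projection of residue 1's Cα→Cβ vector defining azimuth zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C


class HelixBuildError(ValueError):
    """Invalid input to the helix builder (unknown residue, bad dihedrals)."""


class AxisFitError(ValueError):
    """Too few residues to define a helix axis (twist/rise undefined)."""


BACKBONE_ATOMS = ("N", "CA", "C", "O", "H", "CB")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D.

    Returns D such that |C-D| = bond, angle(B,C,D) = angle_deg and
    dihedral(A,B,C,D) = dihedral_deg.
    """
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(chi),
        np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) minimizing |R p + t - q| over point rows."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, qc - r @ pc


@dataclass
class HelixModel:
    """Ideal helix with per-residue backbone coordinates in the axis frame.

    ``coords[atom]`` is an (n_res, 3) array in Å; the helix axis is +z and
    azimuth 0 is residue 1's Cα→Cβ projection.  Azimuths increase in the
    sense of the helical screw rotation, so consecutive residues differ by
    exactly ``twist_per_residue`` (mod 360).
    """

    sequence: str
    phi: float
    psi: float
    omega: float
    coords: dict = field(repr=False)
    twist_per_residue: float = 0.0
    rise_per_residue: float = 0.0
    residue_azimuth: np.ndarray = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def residues_per_turn(self) -> float:
        return 360.0 / self.twist_per_residue

    def atom(self, name: str, residue_index: int) -> np.ndarray:
        """Coordinates of ``name`` for 1-based ``residue_index``."""
        return self.coords[name][residue_index - 1]


def _build_chain(sequence: str, phi: float, psi: float, omega: float) -> dict:
    n_res = len(sequence)
    atoms = {name: np.zeros((n_res, 3)) for name in BACKBONE_ATOMS}

    # seed residue in an arbitrary frame
    atoms["N"][0] = (0.0, 0.0, 0.0)
    atoms["CA"][0] = (C.BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(C.ANGLE_N_CA_C)
    atoms["C"][0] = atoms["CA"][0] + C.BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_res):
        atoms["N"][i] = _place_atom(atoms["N"][i - 1], atoms["CA"][i - 1], atoms["C"][i - 1],
                                    C.BOND_C_N, C.ANGLE_CA_C_N, psi)
        atoms["CA"][i] = _place_atom(atoms["CA"][i - 1], atoms["C"][i - 1], atoms["N"][i],
                                     C.BOND_N_CA, C.ANGLE_C_N_CA, omega)
        atoms["C"][i] = _place_atom(atoms["C"][i - 1], atoms["N"][i], atoms["CA"][i],
                                    C.BOND_CA_C, C.ANGLE_N_CA_C, phi)

    for i in range(n_res):
        # carbonyl O: trans to the next N across the C'=O plane (dihedral psi+180)
        atoms["O"][i] = _place_atom(atoms["N"][i], atoms["CA"][i], atoms["C"][i],
                                    C.BOND_C_O, C.ANGLE_CA_C_O, psi + 180.0)
        # side-chain direction marker (pseudo-Cβ also for Gly)
        atoms["CB"][i] = _place_atom(atoms["C"][i], atoms["N"][i], atoms["CA"][i],
                                     C.BOND_CA_CB, C.ANGLE_N_CA_CB, C.DIHEDRAL_C_N_CA_CB)

    for i in range(n_res):
        if i == 0:
            # N-terminus: nominal H trans to the own carbonyl direction
            atoms["H"][0] = _place_atom(atoms["C"][0], atoms["CA"][0], atoms["N"][0],
                                        C.BOND_N_H, C.ANGLE_C_N_H, 180.0)
        else:
            # amide H trans to the preceding carbonyl O across the peptide bond
            atoms["H"][i] = _place_atom(atoms["O"][i - 1], atoms["C"][i - 1], atoms["N"][i],
                                        C.BOND_N_H, C.ANGLE_C_N_H, 180.0)
    return atoms


def _screw_axis(atoms: dict) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Screw axis of the per-residue transform.

    Returns (axis unit vector with positive rise, point on axis,
    twist degrees measured right-handedly about the axis, rise Å).
    """
    n_res = atoms["N"].shape[0]
    triads = np.stack([atoms["N"], atoms["CA"], atoms["C"]], axis=1)  # (n,3,3)
    rots, trans = [], []
    for i in range(n_res - 1):
        r, t = _kabsch(triads[i], triads[i + 1])
        rots.append(r)
        trans.append(t)
    r = rots[0]
    t = trans[0]

    # rotation axis and angle from the rotation matrix
    w, v = np.linalg.eig(r)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    cos_theta = (np.trace(r) - 1.0) / 2.0
    # signed angle about `axis` via the skew-symmetric part
    sin_vec = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]]) / 2.0
    sin_theta = sin_vec @ axis
    theta = np.degrees(np.arctan2(sin_theta, np.clip(cos_theta, -1.0, 1.0)))

    rise = t @ axis
    if rise < 0:
        axis, rise, theta = -axis, -rise, -theta
    twist = theta % 360.0
    if twist == 0.0:
        raise AxisFitError("degenerate geometry: zero twist")

    # point on the axis: (I - R) p = t_perp, solved in the plane ⟂ axis
    t_perp = t - rise * axis
    a_mat = np.eye(3) - r
    p, *_ = np.linalg.lstsq(a_mat, t_perp, rcond=None)
    p = p - (p @ axis) * axis
    return axis, p, twist, rise


def build_ideal_helix(sequence: str,
                      phi: float = C.PHI_DEFAULT,
                      psi: float = C.PSI_DEFAULT,
                      omega: float = C.OMEGA_DEFAULT) -> HelixModel:
    """Build an ideal helix from backbone dihedrals.

    Parameters
    ----------
    sequence
        One-letter amino-acid codes (standard 20).
    phi, psi, omega
        Backbone dihedrals in degrees, uniform along the chain.

    Returns
    -------
    HelixModel
        With coordinates in the axis frame (+z = helix axis), per-residue
        azimuths, twist and rise per residue.

    Raises
    ------
    HelixBuildError
        Unknown residue code or sequence shorter than 2.
    AxisFitError
        Fewer than 4 residues (twist/rise undefined).
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise HelixBuildError("sequence must have at least 2 residues")
    bad = sorted(set(sequence) - set(C.AMINO_ACIDS))
    if bad:
        raise HelixBuildError(f"unknown residue code(s): {''.join(bad)}")
    if len(sequence) < 4:
        raise AxisFitError("need at least 4 residues to define a helix axis")

    atoms = _build_chain(sequence, phi, psi, omega)
    axis, point, twist, rise = _screw_axis(atoms)

    # frame: z along the axis, x along residue 1's Cα→Cβ projection,
    # y chosen so the screw rotation is a positive rotation about +z
    cb_dir = atoms["CB"][0] - atoms["CA"][0]
    x_hat = cb_dir - (cb_dir @ axis) * axis
    x_hat /= np.linalg.norm(x_hat)
    y_hat = np.cross(axis, x_hat)
    frame = np.stack([x_hat, y_hat, axis])  # rows

    coords = {name: (arr - point) @ frame.T for name, arr in atoms.items()}

    v = coords["CB"] - coords["CA"]
    azimuth = np.degrees(np.arctan2(v[:, 1], v[:, 0])) % 360.0

    return HelixModel(sequence=sequence, phi=phi, psi=psi, omega=omega,
                      coords=coords, twist_per_residue=twist,
                      rise_per_residue=rise, residue_azimuth=azimuth)


def residue_azimuths(model: HelixModel) -> list[tuple[int, float]]:
    """Per-residue (1-based index, azimuth degrees) about the helix axis."""
    return [(i + 1, float(a)) for i, a in enumerate(model.residue_azimuth)]


# residue polarity classes for the helical wheel.  Histidine is grouped as
# polar (mostly neutral at the experimental pH); glycine as apolar.
_POLARITY = {
    "K": "cationic", "R": "cationic",
    "D": "anionic", "E": "anionic",
    "S": "polar", "T": "polar", "N": "polar", "Q": "polar",
    "Y": "polar", "W": "polar", "H": "polar", "C": "polar",
    "A": "apolar", "V": "apolar", "L": "apolar", "I": "apolar",
    "M": "apolar", "F": "apolar", "P": "apolar", "G": "apolar",
}


def helical_wheel(sequence: str, residues_per_turn: float = 3.6) -> list[dict]:
    """Helical-wheel table: per residue, the wheel angle and polarity class.

    angle_i = (i-1) * 360 / residues_per_turn  (mod 360), 1-based i.
    """
    if residues_per_turn <= 2:
        raise ValueError("residues_per_turn must exceed 2")
    step = 360.0 / residues_per_turn
    return [
        {"residue_index": i + 1, "residue_type": aa,
         "angle": (i * step) % 360.0, "polarity": _POLARITY[aa]}
        for i, aa in enumerate(sequence.upper())
    ]


def minimal_arc(angles_deg) -> float:
    """Width (degrees) of the smallest arc containing all given angles."""
    a = np.sort(np.asarray(angles_deg, dtype=float) % 360.0)
    if a.size <= 1:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return 360.0 - float(gaps.max())


def write_pdb(model: HelixModel, path) -> None:
    """Write backbone ATOM records (N, CA, C, O, H, CB) for visual checks."""
    lines = []
    serial = 1
    three = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
             "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
             "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
             "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR"}
    for i, aa in enumerate(model.sequence):
        for name in BACKBONE_ATOMS:
            x, y, z = model.coords[name][i]
            lines.append(
                f"ATOM  {serial:5d} {name:>4s} {three[aa]} A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n")
            serial += 1
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
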