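"""Forward calculation of oriented-sample ¹⁵N amide chemical shifts.

In a uniaxially oriented membrane sample the external field B₀ lies along
the membrane normal, and the observed shift of a ¹⁵N amide is the
projection b̂ᵀ·σ·b̂ of its chemical-shift tensor onto the field direction.
The tensor is anchored to the peptide plane: σ33 lies in the plane at
``beta_nh`` degrees from the N–H bond, σ22 is perpendicular to the plane.
The helix orientation is parametrized by a tilt (helix axis vs. membrane
normal) and a pitch (rotation about the helix axis); rigid-body motions are
modelled as independent Gaussian fluctuations of both angles and the
observed shift is the Gaussian-weighted average of the static resonance
over that ensemble, evaluated by Gauss–Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss

from . import constants as C
from .helix import HelixModel


@dataclass(frozen=True)
class CSATensor:
    """¹⁵N chemical-shift tensor: principal values (ppm) and N–H geometry."""

    sigma11: float = C.SIGMA11_DEFAULT
    sigma22: float = C.SIGMA22_DEFAULT
    sigma33: float = C.SIGMA33_DEFAULT
    beta_nh: float = C.BETA_NH_DEFAULT

    def __post_init__(self):
        if not (self.sigma11 <= self.sigma22 <= self.sigma33):
            raise ValueError("principal values must satisfy sigma11 <= sigma22 <= sigma33")

    @property
    def isotropic(self) -> float:
        return (self.sigma11 + self.sigma22 + self.sigma33) / 3.0


@dataclass(frozen=True)
class MotionModel:
    """Gaussian rigid-body motion: tilt wobble and axial-rotation SDs (deg)."""

    wobble_sd: float = C.WOBBLE_SD_DEFAULT
    azimuth_sd: float = C.AZIMUTH_SD_DEFAULT
    n_points: int = C.QUADRATURE_POINTS_DEFAULT

    def __post_init__(self):
        if self.wobble_sd < 0 or self.azimuth_sd < 0:
            raise ValueError("motion SDs must be non-negative")
        if self.n_points < 3:
            raise ValueError("need at least 3 quadrature nodes per dimension")


@dataclass(frozen=True)
class Orientation:
    """Helix orientation: tilt in [0, 180], pitch in [0, 360) degrees."""

    tilt: float
    pitch: float

    def __post_init__(self):
        if not 0.0 <= self.tilt <= 180.0:
            raise ValueError("tilt must be in [0, 180] degrees")
        object.__setattr__(self, "pitch", self.pitch % 360.0)


@dataclass(frozen=True)
class AmideFrame:
    """Orthonormal frame of one amide in helix-fixed coordinates.

    ``nh_unit`` points N→H, ``plane_normal`` is normal to the peptide plane
    and ``in_plane_perp`` completes the right-handed triad (it lies in the
    peptide plane, perpendicular to N–H).
    """

    residue_index: int
    origin: np.ndarray
    nh_unit: np.ndarray
    plane_normal: np.ndarray
    in_plane_perp: np.ndarray


def amide_frame(model: HelixModel, residue_index: int) -> AmideFrame:
    """Amide frame of ``residue_index`` (1-based, >= 2).

    The peptide plane is spanned by the N–H bond and the C'(i-1)→N(i) bond.
    """
    if residue_index < 2 or residue_index > len(model):
        raise ValueError("amide frame requires 2 <= residue_index <= n_res "
                         "(residue 1 has no preceding peptide plane)")
    i = residue_index - 1
    n_pos = model.coords["N"][i]
    nh = model.coords["H"][i] - n_pos
    nh /= np.linalg.norm(nh)
    cn = n_pos - model.coords["C"][i - 1]
    cn /= np.linalg.norm(cn)
    normal = np.cross(nh, cn)
    normal /= np.linalg.norm(normal)
    perp = np.cross(normal, nh)
    return AmideFrame(residue_index=residue_index, origin=n_pos,
                      nh_unit=nh, plane_normal=normal, in_plane_perp=perp)


def tensor_in_helix_frame(frame: AmideFrame, tensor: CSATensor) -> np.ndarray:
    """3×3 shift tensor of one amide expressed in helix-fixed coordinates."""
    # sigma33 is tilted from the N-H bond toward the N-C' bond (the standard
    # amide geometry), which in this frame is the -in_plane_perp sense
    beta = np.deg2rad(tensor.beta_nh)
    v33 = np.cos(beta) * frame.nh_unit - np.sin(beta) * frame.in_plane_perp
    v22 = frame.plane_normal
    v11 = np.cross(v22, v33)
    return (tensor.sigma11 * np.outer(v11, v11)
            + tensor.sigma22 * np.outer(v22, v22)
            + tensor.sigma33 * np.outer(v33, v33))


def _field_in_helix_frame(tilt_deg, pitch_deg):
    """Unit field vector(s) in helix coordinates for orientation (tilt, pitch).

    The lab configuration is M = Ry(tilt) · Rz(pitch) applied to the helix;
    with B₀ along lab z the field seen in the helix frame is Mᵀ ẑ.
    Broadcasts over array inputs; returns components (bx, by, bz).
    """
    t = np.deg2rad(tilt_deg)
    p = np.deg2rad(pitch_deg)
    return -np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)


def static_shift(frame: AmideFrame, tensor: CSATensor, orient: Orientation) -> float:
    """Static (motion-free) shift b̂ᵀ·σ·b̂ in ppm for one orientation."""
    sigma = tensor_in_helix_frame(frame, tensor)
    bx, by, bz = _field_in_helix_frame(orient.tilt, orient.pitch)
    b = np.array([bx, by, bz])
    return float(b @ sigma @ b)


def _gh_nodes(mean_deg, sd_deg, n_points):
    """Gauss–Hermite nodes/weights for a Gaussian in degrees."""
    x, w = hermgauss(n_points)
    return mean_deg + np.sqrt(2.0) * sd_deg * x, w / np.sqrt(np.pi)


def averaged_shift(frame: AmideFrame, tensor: CSATensor, orient: Orientation,
                   motion: MotionModel) -> float:
    """Motionally averaged shift in ppm.

    Gaussian-weighted mean of the static resonance over independent tilt
    (wobble) and axial-rotation fluctuations, by tensor-product
    Gauss–Hermite quadrature with ``motion.n_points`` nodes per dimension.
    Averaging acts on resonance values, not on tensor components.
    """
    sigma = tensor_in_helix_frame(frame, tensor)
    tilts, wt = _gh_nodes(orient.tilt, motion.wobble_sd, motion.n_points)
    pitches, wp = _gh_nodes(orient.pitch, motion.azimuth_sd, motion.n_points)
    bx, by, bz = _field_in_helix_frame(tilts[:, None], pitches[None, :])
    shifts = (sigma[0, 0] * bx ** 2 + sigma[1, 1] * by ** 2 + sigma[2, 2] * bz ** 2
              + 2.0 * (sigma[0, 1] * bx * by + sigma[0, 2] * bx * bz
                       + sigma[1, 2] * by * bz))
    return float(wt @ shifts @ wp)


def averaged_shift_surface(frame: AmideFrame, tensor: CSATensor,
                           tilt_grid: np.ndarray, pitch_grid: np.ndarray,
                           motion: MotionModel) -> np.ndarray:
    """Motionally averaged shift on a full (tilt × pitch) grid, ppm.

    Exploits the separable form of the static shift,
    ``shift = sin²τ·A(ρ) + cos²τ·σzz + sin2τ·C(ρ)``, so the tensor-product
    quadrature factorizes into independent tilt and pitch moments.  The
    result is identical (to rounding) to calling :func:`averaged_shift` at
    every grid point.
    """
    sigma = tensor_in_helix_frame(frame, tensor)
    tilt_grid = np.asarray(tilt_grid, dtype=float)
    pitch_grid = np.asarray(pitch_grid, dtype=float)

    x, w = hermgauss(motion.n_points)
    w = w / np.sqrt(np.pi)

    tau = np.deg2rad(tilt_grid[:, None] + np.sqrt(2.0) * motion.wobble_sd * x[None, :])
    e_sin2 = np.sin(tau) ** 2 @ w
    e_cos2 = 1.0 - e_sin2
    e_sin2t = np.sin(2.0 * tau) @ w

    rho = np.deg2rad(pitch_grid[:, None] + np.sqrt(2.0) * motion.azimuth_sd * x[None, :])
    cr, sr = np.cos(rho), np.sin(rho)
    a_rho = (sigma[0, 0] * cr ** 2 + sigma[1, 1] * sr ** 2
             - 2.0 * sigma[0, 1] * sr * cr) @ w
    c_rho = (-sigma[0, 2] * cr + sigma[1, 2] * sr) @ w

    return (np.outer(e_sin2, a_rho)
            + e_cos2[:, None] * sigma[2, 2]
            + np.outer(e_sin2t, c_rho))
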