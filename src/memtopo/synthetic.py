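"""Seed-controlled synthetic inputs for every pipeline stage.

Each generator returns a (table, ground_truth) pair: the table is a valid
input for the consuming analysis, the ground truth records the parameters
the analysis should recover.  Scenarios emulate the statistical structure
of real measurements on a 24-residue cationic amphipathic helix:

* ``coil`` / ``helix`` / ``helix_with_pro_break`` — Hα/Cα/HN shift tables
  with random-coil scatter, helical CSD offsets and a proline break;
* ``amphipathic_pre`` — cosine-periodic paramagnetic attenuation (period
  3.6 residues/turn) with reduced losses on cationic residues, encoded as
  cross-peak intensity pairs;
* ``in_plane_topology`` — ¹⁵N restraints forward-computed from a known
  (tilt, pitch) with Gaussian measurement noise;
* ``scd_perturbation`` — plateau-then-decay acyl-chain S_CD profiles with
  a peptide-induced reduction ramp growing toward the chain terminus.

Noise magnitudes are Gaussian with the defaults stated per generator,
chosen to match the visual scatter of typical published profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from .csa import CSATensor, MotionModel, Orientation, amide_frame, averaged_shift
from .deuterium import WITH, WITHOUT, simulate_splittings
from .helix import HelixModel
from .randomcoil import HN_COIL, coil_shift
from .solution import cationic_positions

SCENARIOS = ("coil", "helix", "helix_with_pro_break", "in_plane_topology",
             "amphipathic_pre", "scd_perturbation")


@dataclass
class GeneratorSpec:
    """Scenario + seed + per-scenario parameters; seed fixes outputs bit-exactly."""

    seed: int
    scenario: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------- shifts

def gen_shift_table(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Hα/Cα/HN shift table for coil or helix scenarios.

    Coil: random-coil references + Gaussian noise (SD 0.02 ppm Hα, 0.1 ppm
    Cα, 0.08 ppm HN).  Helix: adds ΔHα = −0.25, ΔCα = +2.0 ppm over the
    helix span and a periodic HN modulation (amplitude 0.35 ppm) that
    widens the amide dispersion.  ``helix_with_pro_break`` zeroes the
    deviation at the break residue (proline-like interruption).
    """
    if spec.scenario not in ("coil", "helix", "helix_with_pro_break"):
        raise ValueError(f"scenario {spec.scenario!r} is not a shift scenario")
    p = {"sequence": C.SAAP148_SEQUENCE, "helix_span": (1, 21), "break_at": 22,
         "dha": -0.25, "dca": 2.0, "noise_ha": 0.02, "noise_ca": 0.1,
         "noise_hn": 0.08, "hn_amp": 0.35, **spec.params}
    seq = p["sequence"]
    rng = spec.rng()
    helical = np.zeros(len(seq), dtype=bool)
    if spec.scenario != "coil":
        lo, hi = p["helix_span"]
        helical[lo - 1:hi] = True
        if spec.scenario == "helix_with_pro_break":
            helical[p["break_at"] - 1] = False

    rows = []
    for i, aa in enumerate(seq, start=1):
        h = helical[i - 1]
        ha = coil_shift(aa, "HA") + (p["dha"] if h else 0.0) + rng.normal(0, p["noise_ha"])
        ca = coil_shift(aa, "CA") + (p["dca"] if h else 0.0) + rng.normal(0, p["noise_ca"])
        hn = HN_COIL + rng.normal(0, p["noise_hn"])
        if h:
            hn += p["hn_amp"] * np.cos(2 * np.pi * (i - 1) / 3.6)
        rows.append((i, aa, "HA", ha))
        rows.append((i, aa, "CA", ca))
        if aa != "P":  # proline has no amide proton
            rows.append((i, aa, "HN", hn))
    table = pd.DataFrame(rows, columns=["residue_index", "residue_type",
                                        "atom", "shift_ppm"])
    truth = {"scenario": spec.scenario, "sequence": seq,
             "helix_span": list(p["helix_span"]) if spec.scenario != "coil" else None,
             "break_at": p["break_at"] if spec.scenario == "helix_with_pro_break" else None}
    return table, truth


# ------------------------------------------------------------------- PRE

def _apolar_face_phase(sequence: str, period: float) -> float:
    """Residue position i0 of the apolar-face centre on the helical wheel."""
    cat = set(cationic_positions(sequence))
    angles = [2 * np.pi * (i - 1) / period
              for i in range(1, len(sequence) + 1) if i not in cat]
    theta = np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))
    return 1.0 + theta * period / (2 * np.pi)


def gen_pre_profile(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Cross-peak intensity table emulating amphipathic PRE attenuation.

    loss_i = offset + amp·cos(2π(i − i0)/period), with the cosine maximum
    phased onto the apolar face; cationic residues' loss is multiplied by
    ``cationic_factor`` (< 1: the charged face stays out of the micelle
    core); Gaussian noise of SD ``noise_sd`` (percentage points) is added.
    Intensities: B fixed at ``b0`` with noise floor ``db``; C = B·(1 − loss/100).
    """
    if spec.scenario != "amphipathic_pre":
        raise ValueError("gen_pre_profile requires the amphipathic_pre scenario")
    p = {"sequence": C.SAAP148_SEQUENCE, "period": 3.6, "amp": 30.0,
         "offset": 50.0, "cationic_factor": 0.6, "noise_sd": 3.0,
         "b0": 100.0, "db": 2.0, "dc": 2.0, "i0": None, **spec.params}
    seq = p["sequence"]
    rng = spec.rng()
    i0 = p["i0"] if p["i0"] is not None else _apolar_face_phase(seq, p["period"])
    cat = set(cationic_positions(seq))

    idx = np.arange(1, len(seq) + 1)
    loss = p["offset"] + p["amp"] * np.cos(2 * np.pi * (idx - i0) / p["period"])
    factor = np.where([i in cat for i in idx], p["cationic_factor"], 1.0)
    loss = loss * factor
    if p["noise_sd"] > 0:
        loss = loss + rng.normal(0, p["noise_sd"], size=idx.size)
    loss = np.clip(loss, 0.0, 100.0)

    b = np.full(idx.size, p["b0"])
    c = b * (1.0 - loss / 100.0)
    table = pd.DataFrame({"residue_index": idx,
                          "residue_type": list(seq),
                          "intensity_ref": b, "intensity_para": c,
                          "noise_ref": p["db"], "noise_para": p["dc"]})
    truth = {"scenario": spec.scenario, "period": p["period"], "i0": i0,
             "amp": p["amp"], "offset": p["offset"],
             "cationic_factor": p["cationic_factor"],
             "cationic_positions": sorted(cat)}
    return table, truth


# ----------------------------------------------------------- 15N restraints

def gen_15n_restraints(spec: GeneratorSpec, model: HelixModel,
                       tensor: CSATensor | None = None,
                       motion: MotionModel | None = None) -> tuple[pd.DataFrame, dict]:
    """¹⁵N restraints forward-computed from a known orientation.

    observed = averaged_shift(true orientation) + N(0, error/2), per labeled
    residue.  Defaults: residues (11, 12) with errors (2.5, 4.0) ppm and a
    surface-bound truth (tilt 90°, pitch 130°).
    """
    if spec.scenario != "in_plane_topology":
        raise ValueError("gen_15n_restraints requires the in_plane_topology scenario")
    p = {"tilt": 90.0, "pitch": 130.0, "residues": (11, 12),
         "errors": (2.5, 4.0), **spec.params}
    if len(p["residues"]) < 1:
        raise ValueError("need at least one labeled residue")
    tensor = tensor or CSATensor()
    motion = motion or MotionModel()
    rng = spec.rng()
    truth_orient = Orientation(tilt=p["tilt"], pitch=p["pitch"])

    rows = []
    for res, err in zip(p["residues"], p["errors"]):
        clean = averaged_shift(amide_frame(model, res), tensor, truth_orient, motion)
        rows.append((res, clean + rng.normal(0, err / 2.0), err))
    table = pd.DataFrame(rows, columns=["residue_index", "shift_ppm", "error_ppm"])
    truth = {"scenario": spec.scenario, "tilt": p["tilt"], "pitch": p["pitch"],
             "residues": list(p["residues"]), "errors": list(p["errors"])}
    return table, truth


# ------------------------------------------------------------------- 2H

def gen_scd_tables(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Splitting tables (both conditions) for a palmitoyl-d31 chain.

    Without peptide: plateau S_CD = 0.20 for C2–C8 decaying linearly to
    0.05 at C16.  With peptide: multiplied by (1 − ramp), the ramp rising
    from 0 at the plateau end to ``max_reduction`` at C16.  Converted to
    kHz splittings; optional Gaussian noise (kHz) on the splittings.
    """
    if spec.scenario != "scd_perturbation":
        raise ValueError("gen_scd_tables requires the scd_perturbation scenario")
    p = {"carbons": tuple(range(2, 17)), "plateau": 0.20, "plateau_end": 8,
         "terminal": 0.05, "max_reduction": 0.30, "noise_khz": 0.0,
         "lipid": "POPG-d31", "qcc_khz": C.QCC_DEFAULT_KHZ, **spec.params}
    rng = spec.rng()
    carbons = np.asarray(p["carbons"])
    last = carbons.max()

    scd_wo = np.where(
        carbons <= p["plateau_end"], p["plateau"],
        p["plateau"] + (p["terminal"] - p["plateau"])
        * (carbons - p["plateau_end"]) / (last - p["plateau_end"]))
    ramp = np.clip((carbons - p["plateau_end"]) / (last - p["plateau_end"]), 0.0, 1.0)
    scd_w = scd_wo * (1.0 - p["max_reduction"] * ramp)

    rows = []
    for cond, scd in ((WITHOUT, scd_wo), (WITH, scd_w)):
        dv = simulate_splittings(scd, p["qcc_khz"])
        if p["noise_khz"] > 0:
            dv = np.clip(dv + rng.normal(0, p["noise_khz"], size=dv.size), 0, None)
        for ci, v in zip(carbons, dv):
            group = "CD3" if ci == last else "CD2"
            rows.append((int(ci), group, float(v), cond, p["lipid"]))
    table = pd.DataFrame(rows, columns=["carbon_index", "group",
                                        "splitting_khz", "condition", "lipid"])
    truth = {"scenario": spec.scenario, "max_reduction": p["max_reduction"],
             "max_reduction_carbon": int(last),
             "scd_without": scd_wo.tolist(), "scd_with": scd_w.tolist()}
    return table, truth
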