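"""Solution-NMR analyses: chemical-shift deviations, amide dispersion,
paramagnetic attenuation, helical periodicity and amphipathic faces.

All operations consume tidy tables (pandas DataFrames with the column
schemas of :mod:`memtopo.io`).  The PRE analysis follows the percentage-
loss definition with linear error propagation: with B the cross-peak
intensity without the paramagnetic agent, C the intensity with it, and
ΔB/ΔC the spectral noise,

    A = C/B,   loss = 100·(1 − A),   Δloss = 100·A·(ΔB/B + ΔC/C).

The linear (worst-case) propagation is used deliberately; Gaussian
quadrature-sum propagation would give a smaller error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import constants as C
from .randomcoil import coil_shift


def chemical_shift_deviation(shifts: pd.DataFrame,
                             reference=coil_shift) -> pd.DataFrame:
    """Per-residue deviations from random coil: columns dHA, dCA (ppm).

    ``shifts`` needs columns residue_index, residue_type, atom, shift_ppm
    with atom in {HA, CA, HN}; HN rows are ignored here.  ``reference`` is
    a callable (residue_type, atom) -> ppm.
    """
    sub = shifts[shifts["atom"].isin(["HA", "CA"])]
    missing = []
    rows = {}
    for _, r in sub.iterrows():
        try:
            ref = reference(r["residue_type"], r["atom"])
        except KeyError:
            missing.append((int(r["residue_index"]), r["residue_type"]))
            continue
        key = int(r["residue_index"])
        rows.setdefault(key, {"residue_index": key,
                              "residue_type": r["residue_type"],
                              "dHA": np.nan, "dCA": np.nan})
        rows[key]["d" + r["atom"]] = float(r["shift_ppm"]) - ref
    if missing:
        raise ValueError(f"no random-coil reference for residues: {missing}")
    out = pd.DataFrame(sorted(rows.values(), key=lambda d: d["residue_index"]))
    return out.reset_index(drop=True)


@dataclass
class HelixSegment:
    start: int  # 1-based, inclusive
    end: int    # inclusive

    def __len__(self) -> int:
        return self.end - self.start + 1


def call_secondary_structure(deviations: pd.DataFrame,
                             h_threshold: float = C.HA_THRESHOLD_DEFAULT,
                             c_threshold: float = C.CA_THRESHOLD_DEFAULT,
                             min_run: int = C.MIN_HELIX_RUN_DEFAULT,
                             ) -> tuple[pd.DataFrame, list[HelixSegment]]:
    """Per-residue helix/coil call plus maximal helix segments.

    A residue supports helix if dHA <= -h_threshold or dCA >= +c_threshold,
    unless the other atom crosses its threshold in the coil-opposing
    direction (the two criteria must not disagree).  Helix segments are
    maximal runs of >= ``min_run`` supporting residues.
    """
    if h_threshold <= 0 or c_threshold <= 0:
        raise ValueError("thresholds must be positive")
    dev = deviations.sort_values("residue_index").reset_index(drop=True)
    dha = dev["dHA"].to_numpy(dtype=float)
    dca = dev["dCA"].to_numpy(dtype=float)

    ha_helix = dha <= -h_threshold
    ca_helix = dca >= c_threshold
    ha_against = dha >= h_threshold
    ca_against = dca <= -c_threshold
    support = (np.where(np.isnan(dha), False, ha_helix)
               | np.where(np.isnan(dca), False, ca_helix))
    conflict = (np.where(np.isnan(dha), False, ha_against)
                | np.where(np.isnan(dca), False, ca_against))
    support &= ~conflict

    segments = []
    idx = dev["residue_index"].to_numpy(dtype=int)
    n = len(idx)
    k = 0
    while k < n:
        if not support[k]:
            k += 1
            continue
        j = k
        while j + 1 < n and support[j + 1] and idx[j + 1] == idx[j] + 1:
            j += 1
        if j - k + 1 >= min_run:
            segments.append(HelixSegment(int(idx[k]), int(idx[j])))
        k = j + 1

    state = pd.DataFrame({"residue_index": idx,
                          "state": np.where(support, "helix", "coil")})
    return state, segments


def amide_dispersion(shifts: pd.DataFrame, atom: str = "HN") -> float:
    """Chemical-shift dispersion (max − min, ppm) of the amide protons.

    A large dispersion indicates structure: random-coil peptides cluster
    their HN shifts tightly, folded helices spread them out.
    """
    vals = shifts.loc[shifts["atom"] == atom, "shift_ppm"].to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError(f"need at least 2 {atom} shifts for a dispersion")
    return float(vals.max() - vals.min())


def pre_attenuation(pre: pd.DataFrame) -> pd.DataFrame:
    """Percentage intensity loss per residue with propagated error.

    Input columns: residue_index, intensity_ref (B), intensity_para (C),
    noise_ref (ΔB), noise_para (ΔC).  Output adds loss_pct, loss_err_pct
    and a ``negative`` flag where C > B (apparent signal gain).
    """
    b = pre["intensity_ref"].to_numpy(dtype=float)
    c = pre["intensity_para"].to_numpy(dtype=float)
    db = pre["noise_ref"].to_numpy(dtype=float)
    dc = pre["noise_para"].to_numpy(dtype=float)
    if np.any(b <= 0):
        bad = pre.loc[b <= 0, "residue_index"].tolist()
        raise ValueError(f"reference intensity must be positive (residues {bad})")
    if np.any(c < 0) or np.any(db < 0) or np.any(dc < 0):
        raise ValueError("intensities and noises must be non-negative")
    a = c / b
    loss = 100.0 * (1.0 - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = 100.0 * a * (db / b + np.where(c > 0, dc / c, 0.0))
    out = pre[["residue_index"]].copy()
    out["loss_pct"] = loss
    out["loss_err_pct"] = err
    out["negative"] = loss < 0
    return out


@dataclass
class PeriodicityFit:
    period: float | None
    phase_deg: float | None
    amplitude: float
    offset: float
    residual_sd: float
    has_periodicity: bool


def _cosine_lsq(indices: np.ndarray, values: np.ndarray,
                period: float) -> tuple[float, float, float, float]:
    """Linear LSQ of a + b·cos(2π i/P) + c·sin(2π i/P); returns
    (offset, amplitude, phase_offset_residues, sse)."""
    theta = 2.0 * np.pi * indices / period
    design = np.column_stack([np.ones_like(theta), np.cos(theta), np.sin(theta)])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    a, b_cos, b_sin = coef
    amp = float(np.hypot(b_cos, b_sin))
    i0 = float(np.arctan2(b_sin, b_cos) * period / (2.0 * np.pi))
    sse = float(((design @ coef - values) ** 2).sum())
    return float(a), amp, i0, sse


def fit_periodicity(profile: pd.DataFrame,
                    p_min: float = 3.0, p_max: float = 4.5,
                    p_step: float = 0.05) -> PeriodicityFit:
    """Fit loss_i = a + b·cos(2π(i − i0)/P) to a per-residue profile.

    The period is seeded from a grid over [p_min, p_max] (linear LSQ at
    each candidate) and refined by nonlinear least squares.  If the fitted
    amplitude does not exceed twice the residual SD the profile is flagged
    as non-periodic and the period is undefined.
    """
    data = profile.dropna(subset=["loss_pct"])
    idx = data["residue_index"].to_numpy(dtype=float)
    y = data["loss_pct"].to_numpy(dtype=float)
    if idx.size < 8:
        raise ValueError("need at least 8 residues with finite loss")

    grid = np.arange(p_min, p_max + p_step / 2, p_step)
    seeds = [(p, *_cosine_lsq(idx, y, p)) for p in grid]
    p0, a0, amp0, i00, _ = min(seeds, key=lambda s: s[4])

    def model(i, a, b, i0, period):
        return a + b * np.cos(2.0 * np.pi * (i - i0) / period)

    try:
        popt, _ = optimize.curve_fit(
            model, idx, y, p0=[a0, amp0, i00, p0],
            bounds=([-np.inf, 0.0, -np.inf, p_min - 0.5],
                    [np.inf, np.inf, np.inf, p_max + 0.5]),
            maxfev=10000)
        a, b, i0, period = popt
    except RuntimeError:
        a, b, i0, period = a0, amp0, i00, p0

    resid = y - model(idx, a, b, i0, period)
    dof = max(idx.size - 4, 1)
    resid_sd = float(np.sqrt((resid ** 2).sum() / dof))
    periodic = b >= 2.0 * resid_sd and b > 0
    phase = float((360.0 * (i0 / period)) % 360.0) if periodic else None
    return PeriodicityFit(period=float(period) if periodic else None,
                          phase_deg=phase,
                          amplitude=float(b), offset=float(a),
                          residual_sd=resid_sd, has_periodicity=bool(periodic))


@dataclass
class FaceComparison:
    mean_cationic: float
    mean_other: float
    difference: float  # cationic − other
    p_value: float
    n_cationic: int
    n_other: int


def cationic_positions(sequence: str) -> list[int]:
    """1-based positions of Lys/Arg in a one-letter sequence."""
    return [i + 1 for i, aa in enumerate(sequence.upper())
            if aa in C.CATIONIC_RESIDUES]


def classify_faces(profile: pd.DataFrame, sequence: str) -> FaceComparison:
    """Compare attenuation of cationic (K/R) vs. all other residues.

    One-sided Wilcoxon rank-sum test of cationic < other: for a surface
    helix exposing its apolar face to the micelle core, the cationic face
    should be attenuated less by a core-buried paramagnetic probe.  Exact
    null distribution where feasible (small samples without ties), normal
    approximation otherwise.
    """
    cat = set(cationic_positions(sequence))
    data = profile.dropna(subset=["loss_pct"])
    is_cat = data["residue_index"].astype(int).isin(cat)
    x = data.loc[is_cat, "loss_pct"].to_numpy(dtype=float)
    y = data.loc[~is_cat, "loss_pct"].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both residue groups must be non-empty")
    if np.allclose(x.std(), 0) and np.allclose(y.std(), 0) and np.isclose(x.mean(), y.mean()):
        p = 1.0
    else:
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (min(x.size, y.size) <= 12 and not has_ties) else "asymptotic"
        p = float(stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue)
    return FaceComparison(mean_cationic=float(x.mean()), mean_other=float(y.mean()),
                          difference=float(x.mean() - y.mean()), p_value=p,
                          n_cationic=int(x.size), n_other=int(y.size))
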