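"""²H quadrupolar splittings → C–D bond order parameters (S_CD).

For a deuterated acyl-chain segment i, the quadrupolar splitting Δνᵢ
relates to the segmental order parameter through

    S_CD,i = (4/3) · Δνᵢ / (e²qQ/h),

with the static quadrupole coupling constant e²qQ/h = 167 kHz for C–D
bonds.  Profiles along the chain (plateau near the glycerol, decay toward
the terminal methyl) and with/without-peptide ratio profiles quantify how
much an inserted peptide disorders the membrane core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import constants as C

WITH, WITHOUT = "with_peptide", "without_peptide"


def scd_from_splitting(splitting_khz, qcc_khz: float = C.QCC_DEFAULT_KHZ):
    """Order parameter S_CD from a quadrupolar splitting (kHz).

    Raises if the implied S_CD exceeds 1 (unphysical splitting).
    """
    splitting = np.asarray(splitting_khz, dtype=float)
    if qcc_khz <= 0:
        raise ValueError("quadrupole coupling constant must be positive")
    if np.any(splitting < 0):
        raise ValueError("splittings must be non-negative")
    scd = (4.0 / 3.0) * splitting / qcc_khz
    if np.any(scd > 1.0):
        raise ValueError(
            f"splitting implies S_CD > 1 (max {scd.max():.3f}); "
            f"unphysical for qcc = {qcc_khz} kHz")
    return float(scd) if scd.ndim == 0 else scd


def simulate_splittings(scd, qcc_khz: float = C.QCC_DEFAULT_KHZ):
    """Inverse map: splitting (kHz) from S_CD; exact round trip."""
    s = np.asarray(scd, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("S_CD values must lie in [0, 1]")
    dv = 0.75 * qcc_khz * s
    return float(dv) if dv.ndim == 0 else dv


def build_profile(table: pd.DataFrame,
                  qcc_khz: float = C.QCC_DEFAULT_KHZ) -> pd.DataFrame:
    """Per-carbon S_CD profile from a splitting table.

    Input columns: carbon_index, group (CD2|CD3), condition
    (with_peptide|without_peptide), splitting_khz.  Output is one row per
    (carbon_index, condition), sorted, with the S_CD value.
    """
    required = {"carbon_index", "group", "condition", "splitting_khz"}
    miss = required - set(table.columns)
    if miss:
        raise ValueError(f"splitting table missing columns: {sorted(miss)}")
    dup = table.duplicated(subset=["carbon_index", "condition"])
    if dup.any():
        pairs = table.loc[dup, ["carbon_index", "condition"]].values.tolist()
        raise ValueError(f"duplicate (carbon, condition) rows: {pairs}")
    out = table.copy()
    out["scd"] = scd_from_splitting(out["splitting_khz"].to_numpy(), qcc_khz)
    return (out[["carbon_index", "group", "condition", "scd"]]
            .sort_values(["condition", "carbon_index"])
            .reset_index(drop=True))


def profile_ratio(profile: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """With/without-peptide S_CD ratio per carbon and a reduction summary.

    ratio_i = S_with,i / S_without,i; % reduction = 100·(1 − ratio).
    Carbons with S_without = 0 get an undefined (NaN) ratio and are
    flagged.  Returns (ratio table, summary dict with max_reduction_pct
    and its carbon position).
    """
    wide = profile.pivot(index="carbon_index", columns="condition", values="scd")
    if WITH not in wide.columns or WITHOUT not in wide.columns:
        raise ValueError("need both with_peptide and without_peptide conditions")
    both = wide.dropna(subset=[WITH, WITHOUT])
    if both.empty:
        raise ValueError("no carbon has both conditions measured")
    ratio = pd.DataFrame({"carbon_index": both.index.to_numpy()})
    s_wo = both[WITHOUT].to_numpy(dtype=float)
    s_w = both[WITH].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(s_wo > 0, s_w / s_wo, np.nan)
    ratio["ratio"] = r
    ratio["reduction_pct"] = 100.0 * (1.0 - r)
    ratio["undefined"] = s_wo <= 0
    valid = ratio.dropna(subset=["ratio"])
    if valid.empty:
        summary = {"max_reduction_pct": np.nan, "carbon_index": None}
    else:
        k = valid["reduction_pct"].idxmax()
        summary = {"max_reduction_pct": float(valid.loc[k, "reduction_pct"]),
                   "carbon_index": int(valid.loc[k, "carbon_index"])}
    return ratio, summary
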