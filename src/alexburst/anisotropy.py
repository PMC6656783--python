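"""Steady-state fluorescence anisotropy arithmetic.

Used to verify that the attached fluorophores rotate freely (low anisotropy),
a prerequisite for reading FRET efficiency as a distance: r is computed from
the polarized emission components as

    r = (I_VV - G I_VH) / (I_VV + 2 G I_VH),

with the instrument G factor obtained under horizontal excitation as
G = I_HV / I_HH. Intensities are assumed background-corrected by the caller.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["g_factor", "anisotropy", "anisotropy_table"]


def g_factor(I_HV: float, I_HH: float) -> float:
    """Polarization sensitivity correction G = I_HV / I_HH."""
    if I_HH <= 0:
        raise ValueError("I_HH must be positive")
    if I_HV < 0:
        raise ValueError("intensities must be >= 0")
    return I_HV / I_HH


def anisotropy(I_VV: float, I_VH: float, G: float) -> float:
    """Steady-state anisotropy r = (I_VV - G I_VH) / (I_VV + 2 G I_VH)."""
    if G <= 0:
        raise ValueError("G must be positive")
    if I_VV < 0 or I_VH < 0:
        raise ValueError("intensities must be >= 0")
    denom = I_VV + 2.0 * G * I_VH
    if denom <= 0:
        raise ValueError("I_VV + 2 G I_VH must be positive")
    return (I_VV - G * I_VH) / denom


def anisotropy_table(df: pd.DataFrame) -> pd.DataFrame:
    """Batch mode: per-sample G and r from columns
    (sample, I_VV, I_VH, I_HV, I_HH)."""
    out = df.copy()
    out["G"] = [g_factor(hv, hh) for hv, hh in zip(df["I_HV"], df["I_HH"])]
    out["r"] = [anisotropy(vv, vh, g)
                for vv, vh, g in zip(df["I_VV"], df["I_VH"], out["G"])]
    return out
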