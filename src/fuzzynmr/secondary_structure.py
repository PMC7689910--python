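"""Secondary chemical shifts, SSP profiles and amide temperature coefficients.

Secondary shifts are observed shifts minus sequence-corrected random-coil
references.  The SSP score of residue i averages the available CA/CB/HA
secondary shifts over a sliding window and normalises by the corresponding
full-structure magnitudes, yielding +1 for a fully formed helix, 0 for
random coil and -1 for fully extended structure.  Amide-proton temperature
coefficients (ppb/K) are fit by least squares across a temperature series
and classified into H-bonded (> -4.5), intermediate, and fast solvent
exchange (< -9) regimes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PeakList, Sequence, ShiftTable, ValidationError
from .reference_data import RandomCoilTable, full_secondary_shift

logger = logging.getLogger("fuzzynmr.secondary_structure")

__all__ = [
    "SSPProfile",
    "TempCoeffProfile",
    "secondary_shifts",
    "ssp_profile",
    "temp_coefficients",
    "HBOND_BOUNDARY",
    "FAST_EXCHANGE_BOUNDARY",
]

SSP_NUCLEI = ("CA", "CB", "HA")

HBOND_BOUNDARY = -4.5  # ppb/K; slopes above suggest intramolecular H-bonding
FAST_EXCHANGE_BOUNDARY = -9.0  # ppb/K; slopes below suggest fast solvent exchange


@dataclass
class SSPProfile:
    """Per-residue secondary structure propensity scores.

    ``per_residue`` columns: residue_index, residue_type, ssp, n_shifts
    (data points contributing within the window).  ``ssp`` is NaN where no
    nucleus has both an observed and a random-coil value in the window.
    """

    per_residue: pd.DataFrame
    window: int = 5
    nuclei: tuple = SSP_NUCLEI


@dataclass
class TempCoeffProfile:
    """Per-residue amide 1H temperature coefficients and their classes."""

    per_residue: pd.DataFrame  # residue_index, slope_ppb_per_K, intercept_ppm,
    #                            r_squared, stderr_ppb_per_K, tc_class


def secondary_shifts(
    obs: ShiftTable,
    seq: Sequence,
    rc: RandomCoilTable,
    temperature: float | None = None,
    nuclei: tuple = SSP_NUCLEI,
) -> pd.DataFrame:
    """Observed minus sequence-corrected coil shifts, wide per-residue frame.

    Residues whose coil entry is undefined for a nucleus (Gly CB) are skipped
    for that nucleus with a log entry.  A residue-type mismatch between the
    observed table and the sequence is a hard error.
    """
    recs = {}
    for r in obs.rows.itertuples():
        if r.nucleus not in nuclei:
            continue
        expected = seq.get(r.residue_index)
        if expected is None:
            raise ValidationError(
                f"observed residue {r.residue_index} outside the sequence"
            )
        if expected != r.residue_type:
            raise ValidationError(
                f"residue {r.residue_index}: table says {r.residue_type}, "
                f"sequence says {expected}"
            )
        coil = rc.coil_shift(seq, r.residue_index, r.nucleus, temperature)
        if coil is None:
            logger.info(
                "no coil reference for %s%d/%s; skipped",
                r.residue_type, r.residue_index, r.nucleus,
            )
            continue
        recs.setdefault(r.residue_index, {})[r.nucleus] = r.shift_ppm - coil
    rows = []
    for res in sorted(recs):
        row = {"residue_index": res, "residue_type": seq[res]}
        row.update(recs[res])
        rows.append(row)
    df = pd.DataFrame(rows)
    for nuc in nuclei:
        if nuc not in df.columns:
            df[nuc] = np.nan
    return df.set_index("residue_index")


def ssp_profile(
    sec: pd.DataFrame,
    window: int = 5,
    nuclei: tuple = SSP_NUCLEI,
) -> SSPProfile:
    """SSP scores from a secondary-shift frame (output of secondary_shifts).

    Within the window around residue i, each available secondary shift is
    weighted by the sign of its full-helix reference (CA positive, CB and HA
    negative) and summed; the sum is normalised by the summed magnitudes of
    the full helix (if the sum is positive) or full sheet (if negative)
    reference shifts, so an ideal helix scores +1 and an ideal strand -1.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be an odd integer >= 1")
    half = window // 2
    residues = sec.index.to_numpy()
    rows = []
    for res in residues:
        num = 0.0
        den_helix = 0.0
        den_sheet = 0.0
        n_shifts = 0
        for j in range(res - half, res + half + 1):
            if j not in sec.index:
                continue
            rtype = sec.loc[j, "residue_type"]
            for nuc in nuclei:
                val = sec.loc[j, nuc]
                if not np.isfinite(val):
                    continue
                helix_ref = full_secondary_shift(rtype, nuc, "helix")
                sheet_ref = full_secondary_shift(rtype, nuc, "sheet")
                if helix_ref is None or sheet_ref is None:
                    continue
                num += np.sign(helix_ref) * val
                den_helix += abs(helix_ref)
                den_sheet += abs(sheet_ref)
                n_shifts += 1
        if n_shifts == 0:
            rows.append((res, sec.loc[res, "residue_type"], np.nan, 0))
            continue
        den = den_helix if num >= 0 else den_sheet
        rows.append((res, sec.loc[res, "residue_type"], num / den, n_shifts))
    df = pd.DataFrame(
        rows, columns=["residue_index", "residue_type", "ssp", "n_shifts"]
    )
    return SSPProfile(per_residue=df, window=window, nuclei=tuple(nuclei))


def classify_temp_coefficient(slope_ppb_per_k: float) -> str:
    """Half-open boundaries: exactly -4.5 or -9 ppb/K fall in 'intermediate'."""
    if slope_ppb_per_k > HBOND_BOUNDARY:
        return "hbonded"
    if slope_ppb_per_k < FAST_EXCHANGE_BOUNDARY:
        return "fast_exchange"
    return "intermediate"


def temp_coefficients(series: list[PeakList]) -> TempCoeffProfile:
    """Amide 1H temperature coefficients from a temperature series of peak lists.

    Fits delta_H (ppb) versus temperature (K) per assigned residue by least
    squares; requires >= 3 temperatures spanning >= 10 K.  Residues observed
    at fewer than 3 temperatures are skipped with a log entry.
    """
    temps = [pl.condition.get("temperature") for pl in series]
    if any(t is None for t in temps):
        raise ValidationError("every peak list needs a temperature condition")
    if len(set(temps)) < 3:
        raise ValidationError("need peak lists at >= 3 distinct temperatures")
    if max(temps) - min(temps) < 10.0:
        raise ValidationError("temperature range must span >= 10 K")

    obs: dict[int, list[tuple[float, float]]] = {}
    for t, pl in zip(temps, series):
        for r in pl.assigned.itertuples():
            obs.setdefault(int(r.residue_index), []).append((t, float(r.w2)))
    rows = []
    for res in sorted(obs):
        pts = obs[res]
        if len(pts) < 3:
            logger.info("residue %d observed at only %d temperatures; skipped",
                        res, len(pts))
            continue
        t = np.array([p[0] for p in pts])
        d_ppb = np.array([p[1] for p in pts]) * 1e3
        fit = stats.linregress(t, d_ppb)
        rows.append(
            (
                res,
                fit.slope,
                fit.intercept * 1e-3,
                fit.rvalue**2,
                fit.stderr,
                classify_temp_coefficient(fit.slope),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["residue_index", "slope_ppb_per_K", "intercept_ppm",
                 "r_squared", "stderr_ppb_per_K", "tc_class"],
    )
    return TempCoeffProfile(per_residue=df)
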