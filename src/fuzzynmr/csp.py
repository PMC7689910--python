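"""Chemical-shift perturbation (CSP) mapping across a titration.

Combines amide 1H/15N shift changes into the cumulative perturbation
``sqrt(dH^2 + (alpha*dN)^2)``, classifies residues against a fixed limit,
detects residues broadened below the detection limit, estimates 1H line
widths, tracks peaks through a titration and counts doubled peaks on the
partner side of an asymmetric homodimer complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core_io import PeakList, ShiftTable, ValidationError

logger = logging.getLogger("fuzzynmr.csp")

__all__ = [
    "CSPProfile",
    "FitError",
    "cumulative_delta",
    "classify_perturbed",
    "contiguous_regions",
    "linewidth_fwhm",
    "track_titration",
    "detect_peak_doubling",
]

DEFAULT_ALPHA = 0.14
DEFAULT_THRESHOLD = 0.15

#: nearest-neighbour matching gate in scaled ppm (1H weight 1, 15N weight alpha)
DEFAULT_GATE = 0.05


class FitError(RuntimeError):
    """Raised when a lineshape or decay fit cannot be performed."""


@dataclass
class CSPProfile:
    """Per-residue cumulative shift perturbations.

    ``per_residue`` columns: residue_index, residue_type, delta_H, delta_N,
    delta_cum (all ppm), broadened (bool), perturbed (nullable bool until
    classified).
    """

    per_residue: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    threshold: float = DEFAULT_THRESHOLD


def cumulative_delta(
    free: ShiftTable, bound: ShiftTable, alpha: float = DEFAULT_ALPHA
) -> CSPProfile:
    """Cumulative amide shift change per residue between two states.

    delta_cum = sqrt(dH^2 + (alpha*dN)^2).  Residues whose amide is present
    in the free state but absent in the bound state are flagged broadened
    (their peak vanished below the detection limit); their delta_cum is NaN.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    fw = free.pivot(("H", "N")).dropna(subset=["H", "N"])
    bw = bound.pivot(("H", "N"))
    if "H" not in bw.columns:
        bw["H"] = np.nan
    if "N" not in bw.columns:
        bw["N"] = np.nan
    records = []
    for res, row in fw.iterrows():
        if res in bw.index and np.isfinite(bw.loc[res, ["H", "N"]].astype(float)).all():
            dh = float(bw.loc[res, "H"]) - float(row["H"])
            dn = float(bw.loc[res, "N"]) - float(row["N"])
            dcum = float(np.hypot(dh, alpha * dn))
            records.append((res, row["residue_type"], dh, dn, dcum, False))
        else:
            records.append((res, row["residue_type"], np.nan, np.nan, np.nan, True))
    if not records:
        raise ValidationError("free and bound tables share no amide residues")
    overlap = [r for r in records if not r[5]]
    if not overlap:
        raise ValidationError("no residue has amide shifts in both states")
    df = pd.DataFrame(
        records,
        columns=["residue_index", "residue_type", "delta_H", "delta_N",
                 "delta_cum", "broadened"],
    )
    df["perturbed"] = pd.array([pd.NA] * len(df), dtype="boolean")
    return CSPProfile(per_residue=df, alpha=alpha)


def classify_perturbed(
    profile: CSPProfile, threshold: float = DEFAULT_THRESHOLD
) -> CSPProfile:
    """Mark residues with delta_cum >= threshold (or broadened) as perturbed."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    df = profile.per_residue.copy()
    df["perturbed"] = pd.array(
        (df["delta_cum"] >= threshold) | df["broadened"], dtype="boolean"
    )
    return CSPProfile(per_residue=df, alpha=profile.alpha, threshold=threshold)


def contiguous_regions(profile: CSPProfile, min_len: int = 3) -> list[tuple[int, int]]:
    """Maximal runs of perturbed/broadened residues of length >= min_len.

    A single-residue gap inside a run is bridged only if that residue has no
    data at all (e.g. a proline without an amide probe).
    """
    df = profile.per_residue
    if df["perturbed"].isna().all():
        raise ValidationError("profile must be classified first")
    lo, hi = int(df.residue_index.min()), int(df.residue_index.max())
    status = {}
    flagged = df.set_index("residue_index")
    for res in range(lo, hi + 1):
        if res not in flagged.index:
            status[res] = "nodata"
        elif bool(flagged.loc[res, "perturbed"]):
            status[res] = "hit"
        else:
            status[res] = "miss"
    regions: list[tuple[int, int]] = []
    start = None
    prev_hit = None
    for res in range(lo, hi + 1):
        st = status[res]
        if st == "hit":
            if start is None:
                start = res
            prev_hit = res
        elif st == "nodata" and start is not None:
            # bridge only a single missing residue flanked by hits
            nxt = res + 1
            if res - prev_hit == 1 and nxt <= hi and status[nxt] == "hit":
                continue
            regions.append((start, prev_hit))
            start = None
        elif start is not None:
            regions.append((start, prev_hit))
            start = None
    if start is not None:
        regions.append((start, prev_hit))
    return [(a, b) for a, b in regions if b - a + 1 >= min_len]


def _lorentzian(f, amplitude, f0, fwhm, baseline):
    return amplitude * (fwhm / 2.0) ** 2 / ((f - f0) ** 2 + (fwhm / 2.0) ** 2) + baseline


def linewidth_fwhm(freq_hz: np.ndarray, intensity: np.ndarray) -> float:
    """FWHM (Hz) of a single dominant peak by Lorentzian least squares.

    The profile must contain one dominant peak sampled by >= 8 points; a
    flat or monotone profile is rejected rather than silently returning NaN.
    """
    freq_hz = np.asarray(freq_hz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if freq_hz.shape != intensity.shape or freq_hz.size < 8:
        raise ValidationError("need >= 8 samples across the peak")
    if np.max(intensity) <= 0:
        raise FitError("non-positive profile: no peak to fit")
    diffs = np.diff(intensity)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        raise FitError("monotone profile: no interior peak")
    imax = int(np.argmax(intensity))
    amp0 = float(intensity[imax] - np.min(intensity))
    half = np.min(intensity) + amp0 / 2.0
    above = freq_hz[intensity >= half]
    fwhm0 = max(float(above.max() - above.min()), float(np.ptp(freq_hz)) / 20.0)
    p0 = [amp0, float(freq_hz[imax]), fwhm0, float(np.min(intensity))]
    try:
        popt, _ = curve_fit(_lorentzian, freq_hz, intensity, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Lorentzian fit failed: {exc}") from exc
    fwhm = abs(float(popt[2]))
    if not np.isfinite(fwhm) or fwhm <= 0:
        raise FitError("Lorentzian fit returned a non-physical width")
    return fwhm


@dataclass
class Trajectory:
    """Path of one assigned peak through a titration series."""

    residue_index: int
    points: pd.DataFrame  # columns: titration_fraction, w1, w2, height
    status: str = "complete"  # complete | broadened | ambiguous

    def __len__(self) -> int:
        return len(self.points)


def _scaled_dist(w1a, w2a, w1b, w2b, alpha):
    return np.hypot(w2a - w2b, alpha * (w1a - w1b))


def track_titration(
    series: list[PeakList],
    alpha: float = DEFAULT_ALPHA,
    gate: float = DEFAULT_GATE,
) -> dict[int, Trajectory]:
    """Follow assigned peaks through an ordered titration series.

    Peaks are matched between consecutive points by nearest neighbour in
    scaled ppm distance (1H weight 1, 15N weight alpha) under a maximum-jump
    gate.  A trajectory that loses its peak terminates as 'broadened'; two
    trajectories claiming one target peak are both flagged 'ambiguous'.
    """
    if len(series) < 2:
        raise ValidationError("titration series needs >= 2 points")
    fracs = [pl.condition.get("titration_fraction") for pl in series]
    if any(f is None for f in fracs) or sorted(fracs) != fracs:
        raise ValidationError("series must be ordered by titration_fraction")
    first = series[0].assigned
    if len(first) == 0:
        raise ValidationError("first peak list carries no assignments")

    trajs: dict[int, Trajectory] = {}
    current: dict[int, tuple[float, float]] = {}
    for r in first.itertuples():
        res = int(r.residue_index)
        trajs[res] = Trajectory(
            residue_index=res,
            points=pd.DataFrame(
                [[fracs[0], r.w1, r.w2, r.height]],
                columns=["titration_fraction", "w1", "w2", "height"],
            ),
        )
        current[res] = (r.w1, r.w2)

    active = set(current)
    for frac, pl in zip(fracs[1:], series[1:]):
        pk = pl.peaks
        claims: dict[int, list[int]] = {}
        for res in sorted(active):
            w1, w2 = current[res]
            d = _scaled_dist(pk.w1.to_numpy(), pk.w2.to_numpy(), w1, w2, alpha)
            if len(d) == 0 or np.min(d) > gate:
                trajs[res].status = "broadened"
                continue
            claims.setdefault(int(np.argmin(d)), []).append(res)
        newly_active = set()
        for target, residues in claims.items():
            if len(residues) > 1:
                for res in residues:
                    trajs[res].status = "ambiguous"
                    logger.warning(
                        "titration point %.2f: residues %s claim one peak",
                        frac, residues,
                    )
                continue
            res = residues[0]
            row = pk.iloc[target]
            trajs[res].points.loc[len(trajs[res].points)] = [
                frac, row.w1, row.w2, row.height,
            ]
            current[res] = (row.w1, row.w2)
            newly_active.add(res)
        active = newly_active
    return trajs


def detect_peak_doubling(
    assigned: PeakList,
    reference: ShiftTable,
    gate: float = DEFAULT_GATE,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Count peaks near each reference amide position of one homodimer chain.

    A count of 2 marks chain asymmetry (the two chemically equivalent chains
    resolved); 0 marks a candidate for intermediate-exchange broadening.
    """
    ref = reference.pivot(("H", "N")).dropna(subset=["H", "N"])
    pk = assigned.peaks
    recs = []
    for res, row in ref.iterrows():
        d = _scaled_dist(
            pk.w1.to_numpy(), pk.w2.to_numpy(), float(row["N"]), float(row["H"]), alpha
        )
        count = int(np.sum(d <= gate))
        recs.append((res, row["residue_type"], count, count == 2))
    return pd.DataFrame(
        recs, columns=["residue_index", "residue_type", "n_peaks", "asymmetric"]
    )
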