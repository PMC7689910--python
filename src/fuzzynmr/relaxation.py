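"""15N backbone relaxation analysis and reduced spectral density mapping.

R1 and R2 are fit from single-exponential intensity decays; the steady-state
heteronuclear NOE is the saturated/unsaturated intensity ratio.  The three
rates are then inverted into the spectral density values J(0), J(omega_N)
and J(0.87*omega_H) under the standard reduced-mapping approximation that
the spectral density is flat enough near the proton frequency that the
J(omega_H +/- omega_N) and J(omega_H) terms can be replaced by a single
value at 0.87*omega_H.  Exchange broadening is deliberately not separated:
an Rex contribution inflates the apparent J(0), which is how conformational
exchange is diagnosed against the single-motion curve.

Dipolar and CSA interaction constants use r_NH = 1.02 A and
delta_sigma_N = -160 ppm; omega_N is negative (15N gyromagnetic ratio), so
J(omega_H + omega_N) is the sum term evaluated at ~0.9*omega_H.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core_io import GAMMA_1H, SpectrometerContext, ValidationError

logger = logging.getLogger("fuzzynmr.relaxation")

__all__ = [
    "DecaySeries",
    "RelaxationRecord",
    "SpectralDensityTriple",
    "T1_DELAY_SCHEDULE",
    "T2_DELAY_SCHEDULE",
    "dipolar_csa_constants",
    "fit_exponential_decay",
    "het_noe",
    "rates_from_spectral_density",
    "reduced_spectral_density",
    "single_motion_curve",
    "locus_j0",
    "group_residues",
]

MU0_OVER_4PI = 1e-7  # T^2 m^3 J^-1
HBAR = 1.054571817e-34  # J s

R_NH = 1.02e-10  # m
DELTA_SIGMA_N = -160e-6  # 15N CSA (axially symmetric)

#: default variable-delay schedules (s): 10 steps in 0.01-2 s for T1,
#: 11 steps in 0.03-1.36 s for T2; one delay recorded twice for
#: reproducibility checking.
T1_DELAY_SCHEDULE = (0.01, 0.05, 0.1, 0.2, 0.4, 0.6, 0.9, 1.2, 1.6, 2.0)
T2_DELAY_SCHEDULE = (0.03, 0.06, 0.1, 0.17, 0.25, 0.36, 0.5, 0.68, 0.9, 1.1, 1.36)
T1_DUPLICATE_DELAY = 0.1
T2_DUPLICATE_DELAY = 0.1


@dataclass
class DecaySeries:
    """Per-residue intensity decay curves for one relaxation experiment.

    ``data`` columns: residue_index, delay_s, intensity.  ``experiment`` is
    'T1' or 'T2'.  A delay occurring twice per residue acts as the
    reproducibility check.
    """

    experiment: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.experiment not in ("T1", "T2"):
            raise ValidationError("experiment must be 'T1' or 'T2'")
        required = {"residue_index", "delay_s", "intensity"}
        if required - set(self.data.columns):
            raise ValidationError(f"decay series needs columns {sorted(required)}")

    def residues(self) -> list[int]:
        return sorted(self.data.residue_index.unique().tolist())

    @classmethod
    def from_tsv(cls, path, experiment: str) -> "DecaySeries":
        df = pd.read_csv(
            path, sep=r"\s+", comment="#",
            names=["residue_index", "delay_s", "intensity"],
        )
        return cls(experiment=experiment, data=df)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# experiment={self.experiment}\n# residue delay_s intensity\n")
            for r in self.data.itertuples():
                fh.write(f"{int(r.residue_index)}\t{r.delay_s:.4f}\t{r.intensity:.6e}\n")


@dataclass
class RelaxationRecord:
    """Per-residue R1, R2 (s^-1) and hetNOE with uncertainties."""

    per_residue: pd.DataFrame  # residue_index, R1, sigma_R1, R2, sigma_R2,
    #                            hetNOE, sigma_hetNOE, flags
    context: SpectrometerContext


@dataclass
class SpectralDensityTriple:
    """Per-residue J(0), J(omega_N), J(0.87 omega_H) in s/rad."""

    per_residue: pd.DataFrame  # residue_index, J0, JwN, JwH087, sigmas, flags, group
    context: SpectrometerContext


def dipolar_csa_constants(ctx: SpectrometerContext) -> tuple[float, float]:
    """(d^2, c^2) in s^-2: squared N-H dipolar coupling and 15N CSA constants."""
    gamma_n = GAMMA_1H * ctx.gamma_ratio_NH
    d = MU0_OVER_4PI * HBAR * GAMMA_1H * gamma_n / R_NH**3
    c2 = (ctx.omega_15N * DELTA_SIGMA_N) ** 2 / 3.0
    return d * d, c2


def _decay(t, i0, rate):
    return i0 * np.exp(-rate * t)


def fit_exponential_decay(series: DecaySeries) -> pd.DataFrame:
    """Per-residue single-exponential fits I(t) = I0 exp(-R t).

    Returns columns residue_index, rate, sigma, i0, flag.  Residues whose
    intensities do not decay (fitted R <= 0) are flagged 'unfittable' and
    carry NaN rates; a duplicate-delay intensity discrepancy beyond 3x the
    fit-residual noise is flagged 'irreproducible' (rate retained).
    """
    rows = []
    for res, grp in series.data.groupby("residue_index"):
        t = grp.delay_s.to_numpy(dtype=float)
        y = grp.intensity.to_numpy(dtype=float)
        if len(t) < 5:
            rows.append((int(res), np.nan, np.nan, np.nan, "too_few_delays"))
            continue
        flag = ""
        try:
            pos = y > 0
            if pos.sum() >= 2:
                slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
                p0 = [float(np.max(y)), max(-slope, 1e-3)]
            else:
                p0 = [float(np.max(np.abs(y))), 1.0]
            popt, pcov = curve_fit(_decay, t, y, p0=p0, maxfev=10000)
        except RuntimeError:
            rows.append((int(res), np.nan, np.nan, np.nan, "unfittable"))
            continue
        i0, rate = popt
        if rate <= 0 or not np.isfinite(rate):
            rows.append((int(res), np.nan, np.nan, np.nan, "unfittable"))
            continue
        sigma = float(np.sqrt(np.diag(pcov))[1])
        resid = y - _decay(t, *popt)
        noise = float(np.std(resid)) if len(t) > 2 else 0.0
        dup_delays = pd.Series(t).value_counts()
        for delay, count in dup_delays.items():
            if count > 1:
                vals = y[np.isclose(t, delay)]
                if noise > 0 and np.ptp(vals) > 3.0 * noise:
                    flag = "irreproducible"
        rows.append((int(res), float(rate), sigma, float(i0), flag))
    return pd.DataFrame(rows, columns=["residue_index", "rate", "sigma", "i0", "flag"])


def het_noe(
    sat: pd.DataFrame, unsat: pd.DataFrame, noise_floor: float = 0.0
) -> pd.DataFrame:
    """Steady-state heteronuclear NOE = I_sat / I_unsat per residue.

    Inputs are frames with residue_index and intensity columns.  Residues
    whose unsaturated intensity magnitude is at or below ``noise_floor`` are
    reported NaN with a log entry (ratio undefined).
    """
    s = sat.set_index("residue_index")["intensity"]
    u = unsat.set_index("residue_index")["intensity"]
    rows = []
    for res in sorted(set(s.index) & set(u.index)):
        if abs(u[res]) <= noise_floor:
            logger.info("residue %d: unsaturated intensity below noise floor", res)
            rows.append((int(res), np.nan))
        else:
            rows.append((int(res), float(s[res] / u[res])))
    return pd.DataFrame(rows, columns=["residue_index", "hetNOE"])


def rates_from_spectral_density(
    j, ctx: SpectrometerContext, rex: float = 0.0
) -> tuple[float, float, float]:
    """(R1, R2, hetNOE) from a spectral density function J(|omega|) [s/rad].

    The full dipolar + CSA expressions; omega_N is signed (negative), so the
    sum frequency omega_H + omega_N lies below omega_H.
    """
    d2, c2 = dipolar_csa_constants(ctx)
    wh, wn = ctx.omega_1H, ctx.omega_15N
    j_wn = j(abs(wn))
    j_diff = j(abs(wh - wn))  # |omega_H - omega_N| = 1.101 omega_H
    j_sum = j(abs(wh + wn))  # |omega_H + omega_N| = 0.899 omega_H
    j_wh = j(wh)
    r1 = (d2 / 4.0) * (j_diff + 3.0 * j_wn + 6.0 * j_sum) + c2 * j_wn
    r2 = (
        (d2 / 8.0) * (4.0 * j(0.0) + j_diff + 3.0 * j_wn + 6.0 * j_wh + 6.0 * j_sum)
        + (c2 / 6.0) * (4.0 * j(0.0) + 3.0 * j_wn)
        + rex
    )
    sigma_nh = (d2 / 4.0) * (6.0 * j_sum - j_diff)
    noe = 1.0 + (sigma_nh / r1) / ctx.gamma_ratio_NH
    return float(r1), float(r2), float(noe)


def _invert_reduced(r1, r2, noe, d2, c2, gamma_ratio):
    sigma_nh = r1 * (noe - 1.0) * gamma_ratio
    j_wh = 4.0 * sigma_nh / (5.0 * d2)
    clamped = False
    if j_wh < 0:
        j_wh, clamped = 0.0, True
    j_wn = (r1 - (7.0 * d2 / 4.0) * j_wh) / (3.0 * d2 / 4.0 + c2)
    j0 = (
        r2 - (3.0 * d2 / 8.0 + c2 / 2.0) * j_wn - (13.0 * d2 / 8.0) * j_wh
    ) / (d2 / 2.0 + 2.0 * c2 / 3.0)
    return j0, j_wn, j_wh, clamped


def reduced_spectral_density(
    rec: RelaxationRecord,
    n_mc: int = 200,
    rng: np.random.Generator | None = None,
) -> SpectralDensityTriple:
    """Invert R1/R2/hetNOE into J(0), J(omega_N), J(0.87 omega_H).

    sigma_NH = R1 (NOE - 1) gamma_N/gamma_H;
    J(0.87wH) = 4 sigma_NH / (5 d^2);
    J(wN)     = [R1 - (7 d^2/4) J(0.87wH)] / (3 d^2/4 + c^2);
    J(0)      = [R2 - (3 d^2/8 + c^2/2) J(wN) - (13 d^2/8) J(0.87wH)]
                / (d^2/2 + 2 c^2/3).

    Rex is not separated, so exchange inflates the apparent J(0).  A hetNOE
    above 1 would give negative J(0.87wH); it is clamped to 0 and flagged.
    Uncertainties are propagated by Monte-Carlo resampling (``n_mc`` draws
    from the rate uncertainties) when sigmas are available.
    """
    ctx = rec.context
    d2, c2 = dipolar_csa_constants(ctx)
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for r in rec.per_residue.itertuples():
        if not all(np.isfinite([r.R1, r.R2, r.hetNOE])):
            continue
        if r.hetNOE > 1.1:
            logger.warning(
                "residue %d: hetNOE %.2f above the physical ceiling",
                r.residue_index, r.hetNOE,
            )
        j0, j_wn, j_wh, clamped = _invert_reduced(
            r.R1, r.R2, r.hetNOE, d2, c2, ctx.gamma_ratio_NH
        )
        flag = "noe_clamped" if clamped else ""
        s_j0 = s_jwn = s_jwh = np.nan
        sig = [getattr(r, "sigma_R1", np.nan), getattr(r, "sigma_R2", np.nan),
               getattr(r, "sigma_hetNOE", np.nan)]
        if n_mc > 0 and all(np.isfinite(sig)):
            draws = np.array(
                [
                    _invert_reduced(
                        rng.normal(r.R1, sig[0]),
                        rng.normal(r.R2, sig[1]),
                        rng.normal(r.hetNOE, sig[2]),
                        d2, c2, ctx.gamma_ratio_NH,
                    )[:3]
                    for _ in range(n_mc)
                ]
            )
            s_j0, s_jwn, s_jwh = draws.std(axis=0)
        rows.append(
            (int(r.residue_index), j0, j_wn, j_wh, s_j0, s_jwn, s_jwh, flag)
        )
    df = pd.DataFrame(
        rows,
        columns=["residue_index", "J0", "JwN", "JwH087",
                 "sigma_J0", "sigma_JwN", "sigma_JwH087", "flag"],
    )
    monotone = (df.J0 >= df.JwN - 1e-15) & (df.JwN >= df.JwH087 - 1e-15)
    if not monotone.all():
        logger.warning(
            "%d residue(s) violate J(0) >= J(wN) >= J(0.87wH) monotonicity "
            "(noise or exchange)", int((~monotone).sum()),
        )
    return SpectralDensityTriple(per_residue=df, context=ctx)


def single_motion_curve(
    ctx: SpectrometerContext, tau_range: np.ndarray
) -> pd.DataFrame:
    """Locus of (J(0), J(omega_N)) for single-correlation-time motion.

    J(0) = (2/5) tau;  J(omega_N) = (2/5) tau / (1 + (omega_N tau)^2).
    """
    tau = np.asarray(tau_range, dtype=float)
    j0 = 0.4 * tau
    jwn = 0.4 * tau / (1.0 + (ctx.omega_15N * tau) ** 2)
    return pd.DataFrame({"tau_s": tau, "J0": j0, "JwN": jwn})


def locus_j0(ctx: SpectrometerContext, jwn: float) -> float:
    """J(0) on the single-motion curve consistent with a given J(omega_N).

    Solves (2/5) tau / (1 + (wN tau)^2) = JwN for the slow-motion branch; if
    JwN exceeds the curve's maximum 1/(5|wN|), returns that apex value.
    """
    wn2 = ctx.omega_15N**2
    disc = 0.04 - jwn**2 * wn2  # (2/5)^2/4 - JwN^2 wN^2
    if disc <= 0:
        tau = 1.0 / abs(ctx.omega_15N)
    else:
        tau = (0.2 + np.sqrt(disc)) / (jwn * wn2)
    return 0.4 * tau


def _kmeans_1d(values: np.ndarray, k: int = 4, max_iter: int = 200) -> np.ndarray:
    """Deterministic 1-D k-means with quantile initialisation."""
    qs = (np.arange(k) + 0.5) / k
    centers = np.quantile(values, qs)
    labels = np.zeros(len(values), dtype=int)
    for _ in range(max_iter):
        labels_new = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        if np.array_equal(labels_new, labels) and _ > 0:
            break
        labels = labels_new
        for i in range(k):
            if np.any(labels == i):
                centers[i] = values[labels == i].mean()
    order = np.argsort(centers)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels]


GROUP_NAMES = ("I", "II", "III", "IV")


def group_residues(
    triples: SpectralDensityTriple,
    boundaries: tuple[float, float, float] | None = None,
    exchange_factor: float = 2.0,
) -> SpectralDensityTriple:
    """Partition residues into mobility groups I-IV by increasing J(0).

    Group I gathers the most mobile residues (lowest J(0), typically the
    termini), group IV the most rigid.  With explicit ``boundaries`` (three
    ascending J(0) values) the split is a binning; otherwise deterministic
    1-D k-means with quantile initialisation is used.  Residues whose J(0)
    exceeds the single-motion-curve value consistent with their J(omega_N)
    by ``exchange_factor`` or more are flagged exchange-suspect.
    """
    df = triples.per_residue.copy()
    ok = np.isfinite(df.J0.to_numpy())
    values = df.J0.to_numpy()[ok]
    if len(values) < 4:
        logger.warning("fewer than 4 residues with J(0); single-group fallback")
        df["group"] = pd.array(
            np.where(ok, "I", None), dtype="string"
        )
    else:
        if boundaries is not None:
            b = np.asarray(boundaries, dtype=float)
            if not np.all(np.diff(b) > 0):
                raise ValidationError("boundaries must be strictly ascending")
            labels = np.digitize(values, b)
        else:
            if np.ptp(values) == 0:
                logger.warning("all J(0) identical; one group replicated")
                labels = np.zeros(len(values), dtype=int)
            else:
                labels = _kmeans_1d(values, k=4)
        group = np.full(len(df), None, dtype=object)
        group[ok] = [GROUP_NAMES[i] for i in labels]
        df["group"] = pd.array(group, dtype="string")
    suspects = []
    for r in df.itertuples():
        if np.isfinite(r.J0) and np.isfinite(r.JwN) and r.JwN > 0:
            suspects.append(r.J0 >= exchange_factor * locus_j0(triples.context, r.JwN))
        else:
            suspects.append(False)
    df["exchange_suspect"] = suspects
    return SpectralDensityTriple(per_residue=df, context=triples.context)
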