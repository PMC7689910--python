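"""Ground-truth generators emulating the study's data shapes.

A :class:`GroundTruthModel` fixes, per residue, the helical fraction, the
Lipari-Szabo model-free parameters (S^2, global tau_c, local tau_e),
exchange contributions, the binding response (endpoint amide shift changes
and broadening flags) and amide temperature coefficients.  From one model
the generators emit every input the analysis stages consume — shift tables,
titration peak lists, relaxation decay series, hetNOE intensity pairs and
conformational ensembles — so each stage has a parameter-recovery test with
known truth.  All generators are deterministic under a fixed seed.

The shipped ``p53tad_like`` preset mirrors a ~60-residue disordered
transactivation domain bound to an EF-hand homodimer: mobile termini
(1-13, 56-60), helices at 18-29 / 36-47 / 50-55, binding regions at 20-29 /
39-44 / 48-55 with the 48-55 stretch exchange-broadened, and hydrophobic
anchor residues 26, 40 and 53 buried in partner pockets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    P53TAD_1_60,
    PeakList,
    Sequence,
    SpectrometerContext,
    ValidationError,
)
from .ensemble import Ensemble
from .reference_data import RandomCoilTable, default_random_coil_table, full_secondary_shift
from .relaxation import (
    DecaySeries,
    T1_DELAY_SCHEDULE,
    T1_DUPLICATE_DELAY,
    T2_DELAY_SCHEDULE,
    T2_DUPLICATE_DELAY,
    rates_from_spectral_density,
)

__all__ = [
    "GroundTruthModel",
    "p53tad_like",
    "modelfree_J",
    "simulate_relaxation",
    "simulate_shift_tables",
    "simulate_titration",
    "simulate_ensemble",
]


@dataclass
class GroundTruthModel:
    """Per-residue ground truth for every simulated observable.

    Arrays are indexed by sequence position (0-based internally; residue i
    of the sequence numbering maps to position i - offset).
    """

    sequence: Sequence
    helical_fraction: np.ndarray  # bound-state helicity f_i in [0, 1]
    helical_fraction_free: np.ndarray  # free-state (transient) helicity
    s2: np.ndarray  # model-free order parameters in [0, 1]
    tau_c_ns: float  # global correlation time
    tau_e_ps: float  # local correlation time
    rex: np.ndarray  # exchange contribution to R2, s^-1
    delta_h: np.ndarray  # endpoint amide 1H shift change, ppm
    delta_n: np.ndarray  # endpoint amide 15N shift change, ppm
    broadened: np.ndarray  # bool: vanishes from the bound spectrum
    tempco: np.ndarray  # amide 1H temperature coefficient, ppb/K
    noise_shift_ppm: float = 0.003  # carbon/proton shift noise
    noise_peak_ppm: float = 0.002  # 1H peak-position noise (15N scaled 5x)
    noise_intensity: float = 0.01  # relative intensity noise

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("helical_fraction", "helical_fraction_free", "s2", "rex",
                     "delta_h", "delta_n", "broadened", "tempco"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if np.any((self.s2 < 0) | (self.s2 > 1)):
            raise ValidationError("S^2 must lie in [0, 1]")
        if np.any((self.helical_fraction < 0) | (self.helical_fraction > 1)):
            raise ValidationError("helical fractions must lie in [0, 1]")
        if self.tau_c_ns <= 0:
            raise ValidationError("tau_c must be positive")

    def pos(self, residue_index: int) -> int:
        return residue_index - self.sequence.offset

    @property
    def helical_regions(self) -> list[tuple[int, int]]:
        return _runs(self.helical_fraction >= 0.5, self.sequence.offset)

    @property
    def binding_regions(self) -> list[tuple[int, int]]:
        responsive = (
            np.hypot(self.delta_h, 0.14 * self.delta_n) >= 0.15
        ) | self.broadened
        return _runs(responsive, self.sequence.offset)


def _runs(mask: np.ndarray, offset: int) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start + offset, i - 1 + offset))
            start = None
    if start is not None:
        out.append((start + offset, len(mask) - 1 + offset))
    return out


HELIX_REGIONS = ((18, 29), (36, 47), (50, 55))
BINDING_REGIONS = ((20, 29), (39, 44), (48, 55))
BROADENED_REGION = (48, 55)
ANCHORS = (26, 40, 53)
EXCHANGE_RESIDUES = (23, 24, 32, 51)
MOBILE_TERMINI = ((1, 13), (56, 60))
HBONDED_RESIDUES = (20, 21, 24, 25, 39, 40, 41, 42, 43, 44, 45, 55)
FAST_EXCHANGE_RESIDUES = (5, 6, 7, 11, 12, 13, 14, 28, 32, 33, 57)


def p53tad_like() -> GroundTruthModel:
    """Default ground truth: a 60-residue TAD-like IDP bound to a homodimer."""
    seq = Sequence(id="p53TAD_1-60", residues=P53TAD_1_60, offset=1)
    n = len(seq)
    idx = np.arange(1, n + 1)

    f_bound = np.zeros(n)
    for lo, hi in HELIX_REGIONS:
        f_bound[lo - 1:hi] = 0.9
    f_free = np.zeros(n)
    f_free[18:24] = 0.3  # transient helicity around 19-24 in the free state

    s2 = np.full(n, 0.45)
    for lo, hi in MOBILE_TERMINI:
        s2[lo - 1:hi] = 0.25
    for lo, hi in HELIX_REGIONS:
        s2[lo - 1:hi] = 0.85
    for a in ANCHORS:
        s2[a - 1] = 0.92
    # natural residue-to-residue variability (fixed, part of the preset):
    # real S^2 profiles are never flat plateaus
    s2 = np.clip(s2 + 0.03 * np.sin(1.7 * idx) + 0.02 * np.cos(0.9 * idx),
                 0.05, 0.98)

    rex = np.zeros(n)
    for r in EXCHANGE_RESIDUES:
        rex[r - 1] = 4.0

    delta_h = np.zeros(n)
    delta_n = np.zeros(n)
    for lo, hi in BINDING_REGIONS:
        for r in range(lo, hi + 1):
            # largest response at the anchors, tapering toward region edges
            # but staying clearly above the 0.15 ppm perturbation limit
            dist = min(abs(r - a) for a in ANCHORS)
            scale = max(0.5, 1.0 - 0.08 * dist)
            delta_h[r - 1] = 0.28 * scale
            delta_n[r - 1] = 1.6 * scale
    broadened = np.zeros(n, dtype=bool)
    lo, hi = BROADENED_REGION
    broadened[lo - 1:hi] = True

    tempco = np.full(n, -6.5)
    for r in HBONDED_RESIDUES:
        tempco[r - 1] = -3.0
    for r in FAST_EXCHANGE_RESIDUES:
        tempco[r - 1] = -10.0

    return GroundTruthModel(
        sequence=seq,
        helical_fraction=f_bound,
        helical_fraction_free=f_free,
        s2=s2,
        tau_c_ns=6.0,
        tau_e_ps=50.0,
        rex=rex,
        delta_h=delta_h,
        delta_n=delta_n,
        broadened=broadened,
        tempco=tempco,
    )


def modelfree_J(omega: float | np.ndarray, s2: float, tau_c: float, tau_e: float):
    """Lipari-Szabo model-free spectral density, SI units (s/rad).

    J(w) = (2/5) [S^2 tau_c / (1 + (w tau_c)^2)
                  + (1 - S^2) tau' / (1 + (w tau')^2)],
    1/tau' = 1/tau_c + 1/tau_e.  ``tau_c``/``tau_e`` in seconds.
    """
    if tau_c <= 0:
        raise ValidationError("tau_c must be positive")
    if not 0.0 <= s2 <= 1.0:
        raise ValidationError("S^2 must lie in [0, 1]")
    omega = np.asarray(omega, dtype=float)
    tau_p = tau_c if tau_e <= 0 else 1.0 / (1.0 / tau_c + 1.0 / tau_e)
    j = 0.4 * (
        s2 * tau_c / (1.0 + (omega * tau_c) ** 2)
        + (1.0 - s2) * tau_p / (1.0 + (omega * tau_p) ** 2)
    )
    return j if j.shape else float(j)


def true_rates(
    model: GroundTruthModel, ctx: SpectrometerContext
) -> pd.DataFrame:
    """Noise-free R1/R2/hetNOE per amide-bearing residue of a model."""
    rows = []
    for res in model.sequence.numbering:
        if model.sequence[res] == "P":
            continue
        i = model.pos(res)
        j = lambda w: modelfree_J(
            w, model.s2[i], model.tau_c_ns * 1e-9, model.tau_e_ps * 1e-12
        )
        r1, r2, noe = rates_from_spectral_density(j, ctx, rex=model.rex[i])
        rows.append((res, r1, r2, noe, model.rex[i]))
    return pd.DataFrame(rows, columns=["residue_index", "R1", "R2", "hetNOE", "Rex"])


def simulate_relaxation(
    model: GroundTruthModel,
    ctx: SpectrometerContext,
    seed: int = 0,
) -> tuple[DecaySeries, DecaySeries, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic relaxation inputs on the standard delay schedules.

    Returns (t1_series, t2_series, noe_sat, noe_unsat, truth) where truth
    holds the generating noise-free rates.  Decays start at unit intensity
    with Gaussian noise at the model's relative intensity sigma; one delay
    per schedule is recorded twice.
    """
    rng = np.random.default_rng(seed)
    truth = true_rates(model, ctx)
    sigma = model.noise_intensity
    t1_delays = list(T1_DELAY_SCHEDULE) + [T1_DUPLICATE_DELAY]
    t2_delays = list(T2_DELAY_SCHEDULE) + [T2_DUPLICATE_DELAY]
    t1_rows, t2_rows, sat_rows, unsat_rows = [], [], [], []
    for r in truth.itertuples():
        for t in t1_delays:
            t1_rows.append(
                (r.residue_index, t, math.exp(-r.R1 * t) + rng.normal(0, sigma))
            )
        for t in t2_delays:
            t2_rows.append(
                (r.residue_index, t, math.exp(-r.R2 * t) + rng.normal(0, sigma))
            )
        unsat_rows.append((r.residue_index, 1.0 + rng.normal(0, sigma)))
        sat_rows.append((r.residue_index, r.hetNOE + rng.normal(0, sigma)))
    t1 = DecaySeries(
        "T1", pd.DataFrame(t1_rows, columns=["residue_index", "delay_s", "intensity"])
    )
    t2 = DecaySeries(
        "T2", pd.DataFrame(t2_rows, columns=["residue_index", "delay_s", "intensity"])
    )
    sat = pd.DataFrame(sat_rows, columns=["residue_index", "intensity"])
    unsat = pd.DataFrame(unsat_rows, columns=["residue_index", "intensity"])
    return t1, t2, sat, unsat, truth


def _amide_coil(model: GroundTruthModel, rc: RandomCoilTable, res: int):
    """Free-state amide position: coil shift plus a fixed per-residue offset
    emulating sequence-context dispersion (an HSQC never stacks all residues
    of one type on a single point).  The offset is deterministic per residue
    and shared by every generator, so state differences cancel."""
    seq = model.sequence
    h = rc.coil_shift(seq, res, "H")
    n = rc.coil_shift(seq, res, "N")
    disp = np.random.default_rng(10_000 + res)
    return h + disp.normal(0.0, 0.08), n + disp.normal(0.0, 1.2)


def simulate_shift_tables(
    model: GroundTruthModel,
    rc: RandomCoilTable | None = None,
    seed: int = 0,
):
    """Free and bound shift tables from the ground truth.

    Carbon/HA shifts are coil + f_i * full-helix secondary shift + noise;
    amide H/N acquire the binding endpoint deltas in the bound state, and
    broadened residues lose their amide rows there entirely.
    """
    from .core_io import ShiftTable

    rc = rc or default_random_coil_table()
    rng = np.random.default_rng(seed)
    seq = model.sequence
    rows_free, rows_bound = [], []
    for res in seq.numbering:
        aa = seq[res]
        i = model.pos(res)
        for nuc in ("CA", "CB", "HA"):
            coil = rc.coil_shift(seq, res, nuc)
            full = full_secondary_shift(aa, nuc, "helix")
            if coil is None or full is None:
                continue
            noise_scale = model.noise_shift_ppm * (10 if nuc in ("CA", "CB") else 1)
            rows_free.append(
                (res, aa, nuc,
                 coil + model.helical_fraction_free[i] * full
                 + rng.normal(0, noise_scale))
            )
            rows_bound.append(
                (res, aa, nuc,
                 coil + model.helical_fraction[i] * full
                 + rng.normal(0, noise_scale))
            )
        if aa == "P":
            continue
        h, n = _amide_coil(model, rc, res)
        rows_free.append((res, aa, "H", h + rng.normal(0, model.noise_peak_ppm)))
        rows_free.append((res, aa, "N", n + rng.normal(0, 5 * model.noise_peak_ppm)))
        if not model.broadened[i]:
            rows_bound.append(
                (res, aa, "H",
                 h + model.delta_h[i] + rng.normal(0, model.noise_peak_ppm))
            )
            rows_bound.append(
                (res, aa, "N",
                 n + model.delta_n[i] + rng.normal(0, 5 * model.noise_peak_ppm))
            )
    cols = ["residue_index", "residue_type", "nucleus", "shift_ppm"]
    free = ShiftTable(seq.id, "free", pd.DataFrame(rows_free, columns=cols))
    bound = ShiftTable(seq.id, "bound", pd.DataFrame(rows_bound, columns=cols))
    return free, bound


def simulate_titration(
    model: GroundTruthModel,
    n_points: int = 5,
    seed: int = 0,
    fractions: np.ndarray | None = None,
    rc: RandomCoilTable | None = None,
    broadening_fraction: float = 0.5,
) -> list[PeakList]:
    """Titration peak-list series under fast exchange.

    Peaks move linearly with the bound fraction (clamped at 1 past
    stoichiometric equivalence) toward the endpoint shifts; broadened
    residues drop below detection once the titration fraction reaches
    ``broadening_fraction``.  The series covers 0 to 1.15 by default.
    """
    if n_points < 2:
        raise ValidationError("need >= 2 titration points")
    rc = rc or default_random_coil_table()
    rng = np.random.default_rng(seed)
    if fractions is None:
        fractions = np.concatenate([[0.0], np.linspace(0.3, 1.15, n_points - 1)])
    out = []
    for frac in fractions:
        bound_frac = min(float(frac), 1.0)
        rows = []
        for res in model.sequence.numbering:
            aa = model.sequence[res]
            if aa == "P":
                continue
            i = model.pos(res)
            if model.broadened[i] and frac >= broadening_fraction:
                continue
            h, n = _amide_coil(model, rc, res)
            w2 = h + bound_frac * model.delta_h[i] + rng.normal(0, model.noise_peak_ppm)
            w1 = n + bound_frac * model.delta_n[i] + rng.normal(
                0, 5 * model.noise_peak_ppm
            )
            height = 1.0
            if model.broadened[i]:
                height = max(0.05, 1.0 - frac / broadening_fraction)
            rows.append((f"{aa}{res}N-H", w1, w2, height))
        out.append(
            PeakList(
                spectrum_id=f"titration_{frac:.2f}",
                condition={"titration_fraction": float(frac)},
                peaks=pd.DataFrame(rows, columns=["assignment", "w1", "w2", "height"]),
            )
        )
    return out


def simulate_temperature_series(
    model: GroundTruthModel,
    temperatures: tuple = (288.0, 298.0, 308.0, 318.0),
    seed: int = 0,
    rc: RandomCoilTable | None = None,
    noise_ppb: float = 0.0,
) -> list[PeakList]:
    """Peak lists across temperatures with ground-truth amide 1H slopes."""
    rc = rc or default_random_coil_table()
    rng = np.random.default_rng(seed)
    out = []
    for t in temperatures:
        rows = []
        for res in model.sequence.numbering:
            aa = model.sequence[res]
            if aa == "P":
                continue
            i = model.pos(res)
            h, n = _amide_coil(model, rc, res)
            w2 = h + model.tempco[i] * 1e-3 * (t - 298.0) + rng.normal(
                0, noise_ppb * 1e-3
            )
            rows.append((f"{aa}{res}N-H", n, w2, 1.0))
        out.append(
            PeakList(
                spectrum_id=f"hsqc_{t:.0f}K",
                condition={"temperature": float(t)},
                peaks=pd.DataFrame(rows, columns=["assignment", "w1", "w2", "height"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# backbone construction

_B_N_CA, _B_CA_C, _B_C_N = 1.46, 1.52, 1.33
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.5, 121.5
_B_C_O, _A_CA_C_O = 1.23, 120.5
_B_CA_CB, _A_C_CA_CB, _D_N_C_CA_CB = 1.53, 110.5, -122.5

HELIX_PHI_MEAN, HELIX_PSI_MEAN = -57.0, -47.0


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """Position of atom D from internal coordinates w.r.t. atoms A-B-C."""
    angle = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dih),
            bond * math.sin(angle) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray, sequence: Sequence):
    """Backbone (+CB, +O) coordinates from phi/psi with ideal geometry.

    Returns (coords, atoms records) with atoms N, CA, C, O and CB (except
    glycine); omega fixed to 180 degrees.
    """
    n_res = len(sequence)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N,
                           psi[i - 1])
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])
    coords, records = [], []
    for i, res in enumerate(sequence.numbering):
        aa = sequence[res]
        for name, xyz, elem in (("N", N[i], "N"), ("CA", CA[i], "C"),
                                ("C", C[i], "C")):
            coords.append(xyz)
            records.append((res, aa, name, elem))
        o = _place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i] + 180.0)
        coords.append(o)
        records.append((res, aa, "O", "O"))
        if aa != "G":
            cb = _place_atom(N[i], C[i], CA[i], _B_CA_CB, _A_C_CA_CB,
                             _D_N_C_CA_CB)
            coords.append(cb)
            records.append((res, aa, "CB", "C"))
    return np.array(coords), records


POCKET_RESIDUES_I = ((42, "L"), (45, "F"), (58, "L"), (62, "L"),
                     (77, "V"), (78, "F"), (81, "C"), (82, "I"))
POCKET_RESIDUES_II = ((97, "Q"), (100, "K"), (101, "K"))


def simulate_ensemble(
    model: GroundTruthModel,
    n_snapshots: int = 50,
    seed: int = 0,
    two_family: bool = False,
    with_partner: bool = True,
    chain_id: str = "P",
) -> Ensemble:
    """Conformational ensemble with stable helices and flexible linkers.

    Helical residues (f >= 0.5) sample phi/psi tightly around the ideal
    alpha-helix; linker/termini residues sample broad coil distributions.
    ``two_family=True`` draws linker conformations from two well-separated
    mean conformations (for clustering tests).  ``with_partner=True`` adds
    pseudo-atoms of the two partner monomer chains 'A' and 'B' in every snapshot
    just outside the CB of the anchor residues, emulating persistent burial
    in the partner's hydrophobic pockets.
    """
    if n_snapshots < 2:
        raise ValidationError("need >= 2 snapshots")
    from .core_io import ONE_TO_THREE

    rng = np.random.default_rng(seed)
    seq = model.sequence
    n_res = len(seq)
    helical = model.helical_fraction >= 0.5
    family_means = [(-75.0, 150.0), (-75.0, -25.0)]

    all_coords = []
    atoms_records = None
    for snap in range(n_snapshots):
        family = snap % 2 if two_family else 0
        phi = np.empty(n_res)
        psi = np.empty(n_res)
        # two-family mode keeps intra-family spread tiny (dihedral jitter
        # accumulates down the chain) so families are compact vs. the cutoff
        jitter = 0.3 if two_family else 4.0
        for i in range(n_res):
            if helical[i]:
                phi[i] = rng.normal(HELIX_PHI_MEAN, jitter)
                psi[i] = rng.normal(HELIX_PSI_MEAN, jitter)
            elif two_family:
                mphi, mpsi = family_means[family]
                phi[i] = rng.normal(mphi, jitter)
                psi[i] = rng.normal(mpsi, jitter)
            else:
                phi[i] = rng.uniform(-150.0, -60.0)
                psi[i] = rng.uniform(60.0, 180.0)
        coords, records = build_backbone(phi, psi, seq)
        if with_partner:
            partner_coords, partner_records = _place_partner(
                coords, records, model
            )
            coords = np.vstack([coords, partner_coords])
            records = records + partner_records
        all_coords.append(coords)
        if atoms_records is None:
            atoms_records = records
    chain_col = []
    res_idx, res_type, atom_name, element, chains = [], [], [], [], []
    for rec in atoms_records:
        if len(rec) == 4:
            res, aa, name, elem = rec
            ch = chain_id
        else:
            ch, res, aa, name, elem = rec
        chains.append(ch)
        res_idx.append(res)
        res_type.append(aa)
        atom_name.append(name)
        element.append(elem)
    atoms = pd.DataFrame(
        {
            "chain": chains,
            "residue_index": res_idx,
            "residue_name": [ONE_TO_THREE.get(a, "UNK") for a in res_type],
            "residue_type": res_type,
            "atom_name": atom_name,
            "element": element,
        }
    )
    return Ensemble(coords=np.stack(all_coords), atoms=atoms)


def _anchor_frame(coords, records, residue):
    ca = cb = None
    for xyz, (res, _aa, name, _e) in zip(coords, records):
        if res == residue and name == "CA":
            ca = xyz
        if res == residue and name == "CB":
            cb = xyz
    if cb is None:  # glycine anchor: extend along N->CA instead
        raise ValidationError(f"anchor residue {residue} lacks a CB atom")
    return ca, cb


def _place_partner(coords, records, model):
    """Pocket pseudo-atoms riding just outside each anchor's CB.

    Anchors 1 and 3 face chain 'I' (the hydrophobic pocket), anchor 2 faces
    chain 'II' (the partner's C-terminal tail); every pocket atom sits
    2.6-3.8 A from the anchor CB along the CA->CB direction, so the anchor
    contacts persist in every snapshot while distant residues stay clear.
    """
    anchors = [r for r in ANCHORS]
    partner_coords, partner_records = [], []
    # single-character chain ids (PDB column width): A = first monomer's
    # hydrophobic pocket, B = second monomer's C-terminal tail
    chain_map = {anchors[0]: ("A", POCKET_RESIDUES_I[:4]),
                 anchors[2]: ("A", POCKET_RESIDUES_I[4:]),
                 anchors[1]: ("B", POCKET_RESIDUES_II)}
    for anchor, (chain, pocket) in chain_map.items():
        ca, cb = _anchor_frame(coords, records, anchor)
        u = cb - ca
        u /= np.linalg.norm(u)
        # two perpendicular directions to fan the pocket atoms out
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, u)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        for k, (p_res, p_aa) in enumerate(pocket):
            radial = 2.6 + 0.3 * (k % 3)
            lateral = 0.8 * ((k % 4) - 1.5)
            pos = cb + radial * u + lateral * (v if k % 2 else w)
            partner_coords.append(pos)
            partner_records.append((chain, p_res, p_aa, "CB", "C"))
    return np.array(partner_coords), partner_records
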