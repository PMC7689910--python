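"""Structural statistics over conformational ensembles.

Operates on ordered coordinate snapshots (MD frames or NMR-style models):
least-squares superposition, GROMOS-style (Daura) cutoff clustering,
crystallographic-convention B-factors, phi/psi helix assignment, hydrogen
bonds, inter-chain contact/anchor maps, and r^-6-averaged NOE distance
constraint checks.  Coordinates are in angstroms throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core_io import DistanceConstraint, ValidationError

logger = logging.getLogger("fuzzynmr.ensemble")

__all__ = [
    "Ensemble",
    "ClusterResult",
    "superpose",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "bfactors",
    "assign_helix",
    "helix_fraction",
    "detect_hbonds",
    "residue_contacts",
    "pocket_report",
    "check_noe_constraints",
    "dihedral",
    "parse_selection",
]

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")

#: phi/psi window (degrees) accepted as helical
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, 0.0)
MIN_HELIX_LEN = 4

HBOND_DIST_CUT = 3.5  # donor-acceptor heavy-atom distance, A
HBOND_ANGLE_CUT = 30.0  # deviation from linear D-H...A, degrees
CONTACT_CUTOFF = 4.5  # heavy-atom min distance, A
NH_BOND_LENGTH = 1.02  # A, for inferred amide protons


@dataclass
class Ensemble:
    """Ordered snapshots of atomic coordinates with shared atom metadata.

    ``coords``: (n_models, n_atoms, 3) in angstroms.  ``atoms`` columns:
    chain, residue_index, residue_name (3-letter), residue_type (1-letter),
    atom_name, element.
    """

    coords: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValidationError("coords second axis must match the atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(
        self,
        chain: str | list[str] | None = None,
        resid: int | list[int] | range | None = None,
        names: str | list[str] | None = None,
        heavy: bool = False,
    ) -> np.ndarray:
        """Boolean atom mask for simple chain/resid/name selections."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            chains = [chain] if isinstance(chain, str) else list(chain)
            mask &= self.atoms.chain.isin(chains).to_numpy()
        if resid is not None:
            if isinstance(resid, int):
                resid = [resid]
            mask &= self.atoms.residue_index.isin(list(resid)).to_numpy()
        if names is not None:
            if isinstance(names, str):
                names = [names]
            mask &= self.atoms.atom_name.isin(names).to_numpy()
        if heavy:
            mask &= (self.atoms.element != "H").to_numpy()
        return mask

    def subset(self, mask: np.ndarray) -> "Ensemble":
        return Ensemble(coords=self.coords[:, mask], atoms=self.atoms[mask])

    def main_chain_mask(self, chain: str | None = None) -> np.ndarray:
        return self.select(chain=chain, names=list(MAIN_CHAIN_ATOMS))


def parse_selection(expr: str) -> dict:
    """Parse 'chain A and resid 2-60 and name N CA C' into select() kwargs."""
    kwargs: dict = {}
    for clause in expr.split(" and "):
        tokens = clause.split()
        if not tokens:
            continue
        key, args = tokens[0], tokens[1:]
        if key == "chain":
            kwargs["chain"] = args if len(args) > 1 else args[0]
        elif key == "resid":
            resids: list[int] = []
            for a in args:
                if "-" in a and not a.startswith("-"):
                    lo, hi = a.split("-")
                    resids.extend(range(int(lo), int(hi) + 1))
                else:
                    resids.append(int(a))
            kwargs["resid"] = resids
        elif key == "name":
            kwargs["names"] = args
        elif key == "heavy":
            kwargs["heavy"] = True
        else:
            raise ValidationError(f"unknown selection keyword {key!r}")
    return kwargs


# ---------------------------------------------------------------------------
# superposition


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation matrix and translation mapping mobile onto reference."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, rc - rot @ mc


def _rmsd_fitted(a: np.ndarray, b: np.ndarray) -> float:
    rot, trans = _kabsch(a, b)
    moved = a @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))


def superpose(
    ens: Ensemble,
    selection: np.ndarray | None = None,
    reference: int | str = "mean",
) -> tuple[Ensemble, np.ndarray]:
    """Least-squares superposition of every snapshot onto a reference.

    ``selection`` is a boolean atom mask defining the fit atoms (all atoms
    are moved); ``reference`` is a snapshot index or 'mean' for iterative
    alignment onto the ensemble mean.  Returns the aligned ensemble and the
    per-snapshot RMSD of the selection.
    """
    if selection is None:
        selection = np.ones(ens.n_atoms, dtype=bool)
    if selection.sum() < 3:
        raise ValidationError("superposition needs >= 3 selected atoms")
    coords = ens.coords.copy()
    if reference == "mean":
        ref_sel = coords[0, selection]
        for _ in range(5):
            for m in range(ens.n_models):
                rot, trans = _kabsch(coords[m, selection], ref_sel)
                coords[m] = coords[m] @ rot.T + trans
            new_ref = coords[:, selection].mean(axis=0)
            if np.allclose(new_ref, ref_sel, atol=1e-10):
                break
            ref_sel = new_ref
    else:
        ref_sel = coords[int(reference), selection]
        for m in range(ens.n_models):
            rot, trans = _kabsch(coords[m, selection], ref_sel)
            coords[m] = coords[m] @ rot.T + trans
        ref_sel = coords[:, selection].mean(axis=0)
    rmsd = np.sqrt(
        np.mean(np.sum((coords[:, selection] - ref_sel) ** 2, axis=2), axis=1)
    )
    return Ensemble(coords=coords, atoms=ens.atoms), rmsd


def pairwise_rmsd_matrix(ens: Ensemble, selection: np.ndarray | None = None) -> np.ndarray:
    """All-against-all best-fit RMSD on a selection."""
    if selection is None:
        selection = np.ones(ens.n_atoms, dtype=bool)
    n = ens.n_models
    sel = ens.coords[:, selection]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _rmsd_fitted(sel[i], sel[j])
    return out


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    """GROMOS clustering outcome.

    ``membership`` maps snapshot index -> cluster id (0 = largest);
    ``mid_structures[k]`` is the max-neighbour member of cluster k;
    ``sizes`` are descending.
    """

    cutoff: float
    membership: np.ndarray
    mid_structures: list[int]
    sizes: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def coverage(self, top: int = 1) -> float:
        return sum(self.sizes[:top]) / len(self.membership)


def gromos_cluster(
    ens: Ensemble,
    selection: np.ndarray | None = None,
    cutoff: float = 1.0,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Daura-style iterative neighbour-count clustering under an RMSD cutoff.

    The snapshot with the most neighbours within ``cutoff`` becomes the mid
    structure of cluster 1 and is removed together with its neighbours; the
    procedure repeats on the remainder.  Ties break toward the lowest
    snapshot index, making the partition deterministic.
    """
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(ens, selection)
    n = rmsd_matrix.shape[0]
    neighbours = rmsd_matrix <= cutoff
    np.fill_diagonal(neighbours, True)
    remaining = np.ones(n, dtype=bool)
    membership = np.full(n, -1, dtype=int)
    mids: list[int] = []
    sizes: list[int] = []
    cluster_id = 0
    while remaining.any():
        counts = (neighbours & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centre = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = neighbours[centre] & remaining
        membership[members] = cluster_id
        mids.append(centre)
        sizes.append(int(members.sum()))
        remaining &= ~members
        cluster_id += 1
    order = np.argsort(-np.array(sizes), kind="stable")
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    return ClusterResult(
        cutoff=cutoff,
        membership=remap[membership],
        mid_structures=[mids[i] for i in order],
        sizes=[sizes[i] for i in order],
    )


# ---------------------------------------------------------------------------
# B-factors


def bfactors(ens: Ensemble, per_residue: bool = True) -> pd.DataFrame:
    """B = (8 pi^2 / 3) <|r - <r>|^2> per atom from an aligned ensemble.

    ``per_residue=True`` averages over main-chain atoms (N, CA, C, O) of
    each residue.  A static ensemble gives B = 0; a single snapshot is an
    error (no fluctuation is measurable).
    """
    if ens.n_models < 2:
        raise ValidationError("B-factors need >= 2 snapshots")
    mean = ens.coords.mean(axis=0)
    msd = np.mean(np.sum((ens.coords - mean[None]) ** 2, axis=2), axis=0)
    b_atom = (8.0 * np.pi**2 / 3.0) * msd
    df = ens.atoms.copy()
    df["B"] = b_atom
    if not per_residue:
        return df[["chain", "residue_index", "residue_type", "atom_name", "B"]]
    mc = df[df.atom_name.isin(MAIN_CHAIN_ATOMS)]
    out = (
        mc.groupby(["chain", "residue_index"], sort=True)
        .agg(residue_type=("residue_type", "first"), B=("B", "mean"))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# helix assignment


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone_index(ens: Ensemble, chain: str | None):
    """(residue -> {atom: coord index}) for N/CA/C of one chain."""
    mask = ens.select(chain=chain, names=["N", "CA", "C"])
    table: dict[int, dict[str, int]] = {}
    for idx in np.nonzero(mask)[0]:
        row = ens.atoms.iloc[idx]
        table.setdefault(int(row.residue_index), {})[row.atom_name] = int(idx)
    return table


def phi_psi(ens: Ensemble, model: int = 0, chain: str | None = None) -> pd.DataFrame:
    """Backbone phi/psi angles (degrees) for one snapshot; NaN at chain ends."""
    bb = _backbone_index(ens, chain)
    xyz = ens.coords[model]
    residues = sorted(bb)
    rows = []
    for res in residues:
        here = bb[res]
        prev = bb.get(res - 1, {})
        nxt = bb.get(res + 1, {})
        phi = psi = np.nan
        if {"N", "CA", "C"} <= set(here):
            if "C" in prev:
                phi = dihedral(xyz[prev["C"]], xyz[here["N"]],
                               xyz[here["CA"]], xyz[here["C"]])
            if "N" in nxt:
                psi = dihedral(xyz[here["N"]], xyz[here["CA"]],
                               xyz[here["C"]], xyz[nxt["N"]])
        rows.append((res, phi, psi))
    return pd.DataFrame(rows, columns=["residue_index", "phi", "psi"])


def assign_helix(
    ens: Ensemble, model: int = 0, chain: str | None = None
) -> list[tuple[int, int]]:
    """Helical segments of one snapshot by phi/psi windows.

    A residue is helical when phi is in [-100, -30] and psi in [-80, 0]
    degrees; segments are runs of >= 4 consecutive helical residues.
    Residues lacking either dihedral (chain termini, missing atoms) are
    unassigned.
    """
    angles = phi_psi(ens, model=model, chain=chain)
    helical = (
        angles.phi.between(*HELIX_PHI) & angles.psi.between(*HELIX_PSI)
    ).to_numpy()
    residues = angles.residue_index.to_numpy()
    segments = []
    start = prev = None
    for res, h in zip(residues, helical):
        if h and start is None:
            start = prev = res
        elif h and res == prev + 1:
            prev = res
        elif h:
            if prev - start + 1 >= MIN_HELIX_LEN:
                segments.append((int(start), int(prev)))
            start = prev = res
        elif start is not None:
            if prev - start + 1 >= MIN_HELIX_LEN:
                segments.append((int(start), int(prev)))
            start = prev = None
    if start is not None and prev - start + 1 >= MIN_HELIX_LEN:
        segments.append((int(start), int(prev)))
    return segments


def helix_fraction(ens: Ensemble, chain: str | None = None) -> pd.DataFrame:
    """Per-residue fraction of snapshots in which the residue is helical."""
    counts: dict[int, int] = {}
    for m in range(ens.n_models):
        for lo, hi in assign_helix(ens, model=m, chain=chain):
            for res in range(lo, hi + 1):
                counts[res] = counts.get(res, 0) + 1
    bb = _backbone_index(ens, chain)
    rows = [
        (res, counts.get(res, 0) / ens.n_models) for res in sorted(bb)
    ]
    return pd.DataFrame(rows, columns=["residue_index", "helix_fraction"])


# ---------------------------------------------------------------------------
# hydrogen bonds


def _infer_amide_h(ens: Ensemble, chain: str | None):
    """Amide H positions per (model, residue): along the bisector away from
    C(i-1) and CA, at 1.02 A from N.  Residues whose H is in the roster use
    the explicit atom instead."""
    bb = _backbone_index(ens, chain)
    h_mask = ens.select(chain=chain, names=["H", "HN"])
    explicit: dict[int, int] = {}
    for idx in np.nonzero(h_mask)[0]:
        explicit[int(ens.atoms.iloc[idx].residue_index)] = int(idx)
    out: dict[int, np.ndarray] = {}
    for res, here in bb.items():
        if res in explicit:
            out[res] = ens.coords[:, explicit[res]]
            continue
        prev = bb.get(res - 1, {})
        if "C" not in prev or not {"N", "CA"} <= set(here):
            continue
        n = ens.coords[:, here["N"]]
        u = n - ens.coords[:, prev["C"]]
        v = n - ens.coords[:, here["CA"]]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        d = u + v
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        out[res] = n + NH_BOND_LENGTH * d
    return out


def detect_hbonds(
    ens: Ensemble,
    donor_chain: str | None = None,
    acceptor_chain: str | None = None,
    d_cut: float = HBOND_DIST_CUT,
    angle_cut: float = HBOND_ANGLE_CUT,
) -> pd.DataFrame:
    """Backbone amide (N-H) to carbonyl/carboxyl oxygen hydrogen bonds.

    An H-bond requires donor-acceptor heavy-atom distance <= ``d_cut`` and a
    D-H...A angle within ``angle_cut`` degrees of linear.  Amide protons
    absent from the roster are inferred from backbone geometry.  Returns one
    row per (donor residue, acceptor residue, acceptor atom) with its
    occurrence frequency over snapshots.
    """
    h_pos = _infer_amide_h(ens, donor_chain)
    bb = _backbone_index(ens, donor_chain)
    acc_mask = ens.select(chain=acceptor_chain) & (
        ens.atoms.element.to_numpy() == "O"
    )
    acc_idx = np.nonzero(acc_mask)[0]
    if len(acc_idx) == 0 or not h_pos:
        return pd.DataFrame(
            columns=["donor_residue", "acceptor_chain", "acceptor_residue",
                     "acceptor_atom", "frequency"]
        )
    counts: dict[tuple, int] = {}
    for m in range(ens.n_models):
        acc_xyz = ens.coords[m, acc_idx]
        for res, h_traj in h_pos.items():
            n_xyz = ens.coords[m, bb[res]["N"]]
            h_xyz = h_traj[m]
            dist = np.linalg.norm(acc_xyz - n_xyz, axis=1)
            for k in np.nonzero(dist <= d_cut)[0]:
                a_xyz = acc_xyz[k]
                v1 = n_xyz - h_xyz
                v2 = a_xyz - h_xyz
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= 180.0 - angle_cut:
                    row = ens.atoms.iloc[acc_idx[k]]
                    if row.chain == (donor_chain or row.chain) and int(
                        row.residue_index
                    ) == res:
                        continue  # self
                    key = (res, row.chain, int(row.residue_index), row.atom_name)
                    counts[key] = counts.get(key, 0) + 1
    rows = [
        (*key, n / ens.n_models) for key, n in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["donor_residue", "acceptor_chain", "acceptor_residue",
                 "acceptor_atom", "frequency"],
    )


# ---------------------------------------------------------------------------
# contacts and anchors


def residue_contacts(
    ens: Ensemble,
    chain_a: str | list[str],
    chain_b: str | list[str],
    cutoff: float = CONTACT_CUTOFF,
) -> pd.DataFrame:
    """Inter-chain residue contact frequencies.

    Two residues are in contact in a snapshot when their minimum heavy-atom
    distance is <= ``cutoff``.  Frequencies are fractions of snapshots.
    """
    mask_a = ens.select(chain=chain_a, heavy=True)
    mask_b = ens.select(chain=chain_b, heavy=True)
    if not mask_a.any() or not mask_b.any():
        raise ValidationError("empty chain selection")
    ia, ib = np.nonzero(mask_a)[0], np.nonzero(mask_b)[0]
    res_a = ens.atoms.residue_index.to_numpy()[ia]
    res_b = ens.atoms.residue_index.to_numpy()[ib]
    ua, ub = np.unique(res_a), np.unique(res_b)
    pos_a = {r: np.nonzero(res_a == r)[0] for r in ua}
    pos_b = {r: np.nonzero(res_b == r)[0] for r in ub}
    counts = np.zeros((len(ua), len(ub)), dtype=int)
    for m in range(ens.n_models):
        d = cdist(ens.coords[m, ia], ens.coords[m, ib])
        for i, r_a in enumerate(ua):
            da = d[pos_a[r_a]]
            for j, r_b in enumerate(ub):
                if da[:, pos_b[r_b]].min() <= cutoff:
                    counts[i, j] += 1
    rows = []
    for i, r_a in enumerate(ua):
        for j, r_b in enumerate(ub):
            if counts[i, j]:
                rows.append((int(r_a), int(r_b), counts[i, j] / ens.n_models))
    return pd.DataFrame(rows, columns=["residue_a", "residue_b", "frequency"])


def pocket_report(
    contacts: pd.DataFrame, query_residue: int, min_freq: float = 0.5
) -> list[int]:
    """Partner residues contacting a query residue at >= min_freq."""
    sel = contacts[
        (contacts.residue_a == query_residue) & (contacts.frequency >= min_freq)
    ]
    return sorted(sel.residue_b.astype(int).tolist())


# ---------------------------------------------------------------------------
# NOE constraints


def check_noe_constraints(
    ens: Ensemble,
    constraints: list[DistanceConstraint],
    per_snapshot: bool = False,
) -> pd.DataFrame:
    """NOE upper-bound fulfilment with r^-6 ensemble averaging.

    The effective distance is <r^-6>^(-1/6) over snapshots (NOE intensities
    average as r^-6, so close approaches dominate).  Status is 'satisfied',
    'violated', or 'unresolvable' when an atom is missing from the roster.
    With ``per_snapshot=True`` the max per-snapshot distance is used instead.
    """
    def find(res, atom, chain):
        m = (ens.atoms.residue_index == res) & (ens.atoms.atom_name == atom)
        if chain is not None:
            m &= ens.atoms.chain == chain
        idx = np.nonzero(m.to_numpy())[0]
        return int(idx[0]) if len(idx) else None

    rows = []
    for c in constraints:
        i = find(c.residue_a, c.atom_a, c.chain_a)
        j = find(c.residue_b, c.atom_b, c.chain_b)
        if i is None or j is None:
            missing = f"{c.residue_a}/{c.atom_a}" if i is None else f"{c.residue_b}/{c.atom_b}"
            logger.warning("constraint atom %s not in roster", missing)
            rows.append(
                (c.residue_a, c.atom_a, c.residue_b, c.atom_b, c.upper_bound,
                 np.nan, "unresolvable")
            )
            continue
        r = np.linalg.norm(ens.coords[:, i] - ens.coords[:, j], axis=1)
        eff = float(np.max(r)) if per_snapshot else float(
            np.mean(r**-6.0) ** (-1.0 / 6.0)
        )
        status = "satisfied" if eff <= c.upper_bound else "violated"
        rows.append(
            (c.residue_a, c.atom_a, c.residue_b, c.atom_b, c.upper_bound, eff, status)
        )
    return pd.DataFrame(
        rows,
        columns=["residue_a", "atom_a", "residue_b", "atom_b", "upper_bound",
                 "effective_distance", "status"],
    )
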