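"""Shared data model, readers/writers and spectrometer context.

Everything downstream (CSP mapping, SSP, relaxation analysis, ensemble
statistics) consumes the containers defined here: per-residue chemical-shift
tables, 2D peak lists, sequences, distance constraints and the spectrometer
field context used to convert between proton and heteronuclear frequencies.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence as TySequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fuzzynmr.core_io")

__all__ = [
    "SpectrometerContext",
    "ShiftTable",
    "PeakList",
    "Sequence",
    "DistanceConstraint",
    "ValidationError",
    "larmor_frequencies",
    "average_mass",
    "read_shift_table",
    "write_shift_table",
    "read_peaklist_sparky",
    "write_peaklist_sparky",
    "read_ensemble_pdb",
    "read_sequence_fasta",
    "read_constraints_tsv",
    "P53TAD_1_60",
]


class ValidationError(ValueError):
    """Raised when an input container violates its structural contract."""


# DSS-referenced IUPAC frequency ratios Xi(X) = freq_X / freq_1H
XI_13C = 0.251449530
XI_15N = 0.101329118

#: gamma_N / gamma_H for 15N (negative gyromagnetic ratio)
GAMMA_RATIO_NH = -0.10136

#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_1H = 2.6752218744e8

WATER_MASS = 18.0153

VALID_NUCLEI = ("H", "N", "HA", "CA", "CB", "C")

AA_CODES = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Average (isotope-abundance weighted) residue masses, Da
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: UniProt P04637 (human p53), residues 1-60 (the TAD1+TAD2 construct)
P53TAD_1_60 = "MEEPQSDPSVEPPLSQETFSDLWKLLPENNVLSPLPSQAMDDLMLSPDDIEQWFTEDPGP"


def larmor_frequencies(freq_1h: float) -> tuple[float, float]:
    """Heteronuclear Larmor frequencies (MHz) from the 1H frequency.

    Uses the DSS-referenced IUPAC frequency ratios, i.e. the indirect
    referencing convention: freq_X = freq_1H * Xi(X).

    Returns
    -------
    (freq_13C, freq_15N) in MHz.
    """
    if freq_1h <= 0:
        raise ValidationError("freq_1H must be positive")
    return freq_1h * XI_13C, freq_1h * XI_15N


@dataclass(frozen=True)
class SpectrometerContext:
    """Static field context of one spectrometer.

    Parameters
    ----------
    freq_1H:
        1H Larmor frequency in MHz (e.g. 700.17 for a 16.4 T magnet).
    gamma_ratio_NH:
        gamma_N / gamma_H; negative for 15N.
    """

    freq_1H: float
    gamma_ratio_NH: float = GAMMA_RATIO_NH

    def __post_init__(self) -> None:
        if self.freq_1H <= 0:
            raise ValidationError("freq_1H must be positive")
        if self.gamma_ratio_NH >= 0:
            raise ValidationError("gamma_ratio_NH must be negative for 15N")
        if abs(abs(self.gamma_ratio_NH) - XI_15N) / XI_15N > 2e-3:
            raise ValidationError(
                "gamma_ratio_NH inconsistent with the 15N/1H frequency ratio"
            )

    @property
    def freq_13C(self) -> float:
        return larmor_frequencies(self.freq_1H)[0]

    @property
    def freq_15N(self) -> float:
        return larmor_frequencies(self.freq_1H)[1]

    @property
    def B0(self) -> float:
        """Static field in tesla."""
        return 2.0 * math.pi * self.freq_1H * 1e6 / GAMMA_1H

    @property
    def omega_1H(self) -> float:
        """1H angular frequency, rad/s (positive)."""
        return 2.0 * math.pi * self.freq_1H * 1e6

    @property
    def omega_15N(self) -> float:
        """15N angular frequency, rad/s; negative (negative gamma)."""
        return self.omega_1H * self.gamma_ratio_NH


@dataclass
class ShiftTable:
    """Per-residue, per-nucleus chemical shifts (ppm) of one protein state.

    ``rows`` columns: residue_index (1-based int), residue_type (1-letter),
    nucleus (one of H, N, HA, CA, CB, C), shift_ppm (float).

    Prolines carry no amide H/N rows; missing amide data is structurally
    absent, never NaN-filled.
    """

    protein_id: str
    state: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"residue_index", "residue_type", "nucleus", "shift_ppm"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValidationError(f"shift table missing columns: {sorted(missing)}")
        df = self.rows.copy()
        df["residue_index"] = df["residue_index"].astype(int)
        df["shift_ppm"] = df["shift_ppm"].astype(float)
        bad = set(df["nucleus"]) - set(VALID_NUCLEI)
        if bad:
            raise ValidationError(f"unknown nucleus code(s): {sorted(bad)}")
        dup = df.duplicated(subset=["residue_index", "nucleus"])
        if dup.any():
            r = df.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate shift for {r.residue_index}/{r.nucleus}"
            )
        pro_amide = df[(df.residue_type == "P") & df.nucleus.isin(["H", "N"])]
        if len(pro_amide):
            r = pro_amide.iloc[0]
            raise ValidationError(
                f"proline residue {r.residue_index} cannot carry an amide "
                f"{r.nucleus} shift"
            )
        df = df.sort_values(["nucleus", "residue_index"]).reset_index(drop=True)
        self.rows = df

    def get(self, residue_index: int, nucleus: str) -> float | None:
        m = self.rows[
            (self.rows.residue_index == residue_index)
            & (self.rows.nucleus == nucleus)
        ]
        if len(m) == 0:
            return None
        return float(m.shift_ppm.iloc[0])

    def residues(self, nucleus: str | None = None) -> list[int]:
        df = self.rows if nucleus is None else self.rows[self.rows.nucleus == nucleus]
        return sorted(df.residue_index.unique().tolist())

    def residue_type(self, residue_index: int) -> str | None:
        m = self.rows[self.rows.residue_index == residue_index]
        if len(m) == 0:
            return None
        return str(m.residue_type.iloc[0])

    def pivot(self, nuclei: TySequence[str] = ("H", "N")) -> pd.DataFrame:
        """Wide per-residue view with one column per requested nucleus."""
        df = self.rows[self.rows.nucleus.isin(nuclei)]
        wide = df.pivot(index="residue_index", columns="nucleus", values="shift_ppm")
        types = self.rows.drop_duplicates("residue_index").set_index(
            "residue_index"
        )["residue_type"]
        wide.insert(0, "residue_type", types.reindex(wide.index))
        return wide


@dataclass
class PeakList:
    """One 2D 1H,15N spectrum's peak positions.

    ``peaks`` columns: assignment (Sparky label or '?-?'), residue_index
    (nullable), residue_type (nullable), w1 (15N ppm), w2 (1H ppm), height,
    linewidth_hint (Hz, nullable).  ``condition`` holds either a
    ``titration_fraction`` (dimensionless) or a ``temperature`` (K).
    """

    spectrum_id: str
    condition: dict
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.peaks.copy()
        for col, default in (
            ("assignment", "?-?"),
            ("height", np.nan),
            ("linewidth_hint", np.nan),
        ):
            if col not in df.columns:
                df[col] = default
        if "residue_index" not in df.columns:
            parsed = df["assignment"].map(_parse_assignment)
            df["residue_type"] = [p[0] for p in parsed]
            df["residue_index"] = [p[1] for p in parsed]
        for col in ("w1", "w2"):
            if col not in df.columns:
                raise ValidationError(f"peak list missing column {col}")
            if not np.all(np.isfinite(df[col].astype(float))):
                raise ValidationError("peak coordinates must be finite")
        df["residue_index"] = df["residue_index"].astype("Int64")
        frac = self.condition.get("titration_fraction")
        if frac is not None and not (0.0 <= frac <= 1.5):
            raise ValidationError(
                f"titration_fraction {frac} outside the declared series range"
            )
        self.peaks = df.reset_index(drop=True)

    @property
    def assigned(self) -> pd.DataFrame:
        return self.peaks[self.peaks.residue_index.notna()]


_ASSIGNMENT_RE = re.compile(r"^([A-Z])(\d+)([A-Za-z0-9']+)-([A-Za-z0-9']+)$")


def _parse_assignment(label: str) -> tuple[str | None, int | None]:
    """Sparky assignment 'L26N-H' -> ('L', 26); '?-?' -> (None, None)."""
    if label is None or "?" in label:
        return None, None
    m = _ASSIGNMENT_RE.match(label)
    if m is None:
        return None, None
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class Sequence:
    """Protein sequence in 1-letter code with 1-based numbering.

    ``offset`` is the residue number of the first letter; p53TAD constructs
    such as the 2-60 fragment use offset 2.
    """

    id: str
    residues: str
    offset: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValidationError("empty sequence")
        bad = set(self.residues) - set(AA_CODES)
        if bad:
            raise ValidationError(f"non-canonical residue code(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def numbering(self) -> range:
        return range(self.offset, self.offset + len(self.residues))

    def __getitem__(self, residue_index: int) -> str:
        if residue_index not in self.numbering:
            raise KeyError(f"residue {residue_index} outside sequence numbering")
        return self.residues[residue_index - self.offset]

    def get(self, residue_index: int) -> str | None:
        try:
            return self[residue_index]
        except KeyError:
            return None


@dataclass(frozen=True)
class DistanceConstraint:
    """Upper-bound H-H (or heavy-atom) distance constraint from an NOE."""

    residue_a: int
    atom_a: str
    residue_b: int
    atom_b: str
    upper_bound: float = 5.0
    chain_a: str | None = None
    chain_b: str | None = None

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise ValidationError("upper_bound must be positive")
        if (self.residue_a, self.atom_a, self.chain_a) == (
            self.residue_b,
            self.atom_b,
            self.chain_b,
        ):
            raise ValidationError("constraint atoms must be distinct")


def average_mass(seq: Sequence | str) -> float:
    """Average molecular mass of a peptide in Da (residue masses + one water)."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if len(residues) == 0:
        raise ValidationError("empty sequence")
    return sum(AVERAGE_RESIDUE_MASS[a] for a in residues) + WATER_MASS


# ---------------------------------------------------------------------------
# shift table I/O


def read_shift_table(
    path: str | Path,
    dialect: str = "tsv",
    protein_id: str | None = None,
    state: str = "free",
) -> ShiftTable:
    """Read a per-residue shift table.

    ``dialect='tsv'``: whitespace-delimited columns
    ``residue_index residue_type nucleus shift_ppm`` with '#' comments.
    ``dialect='nmrstar-minimal'``: a bare NMR-STAR atom-chemical-shift loop.
    Unparseable rows are reported with their line numbers.
    """
    path = Path(path)
    if dialect == "tsv":
        rows = _read_shift_tsv(path)
    elif dialect == "nmrstar-minimal":
        rows = _read_shift_nmrstar(path)
    else:
        raise ValidationError(f"unknown shift-table dialect {dialect!r}")
    return ShiftTable(
        protein_id=protein_id or path.stem,
        state=state,
        rows=pd.DataFrame(
            rows, columns=["residue_index", "residue_type", "nucleus", "shift_ppm"]
        ),
    )


def _read_shift_tsv(path: Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 4:
                raise ValidationError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            try:
                rows.append((int(parts[0]), parts[1], parts[2], float(parts[3])))
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return rows


def _read_shift_nmrstar(path: Path) -> list[tuple]:
    """Minimal NMR-STAR: a single _Atom_chem_shift loop, no framecode nesting."""
    tags: list[str] = []
    rows: list[tuple] = []
    in_loop = False
    reading_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s == "loop_":
                in_loop, reading_data, tags = True, False, []
                continue
            if s == "stop_":
                in_loop = False
                continue
            if in_loop and s.startswith("_"):
                tags.append(s.split(".")[-1])
                continue
            if in_loop and tags:
                reading_data = True
            if reading_data:
                parts = s.split()
                if len(parts) != len(tags):
                    raise ValidationError(
                        f"{path}:{lineno}: {len(parts)} values for {len(tags)} tags"
                    )
                rec = dict(zip(tags, parts))
                try:
                    comp = rec["Comp_ID"].upper()
                    rows.append(
                        (
                            int(rec["Seq_ID"]),
                            THREE_TO_ONE.get(comp, comp),
                            rec["Atom_ID"],
                            float(rec["Val"]),
                        )
                    )
                except (KeyError, ValueError) as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_shift_table(table: ShiftTable, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# protein_id={table.protein_id} state={table.state}\n")
            fh.write("# residue_index residue_type nucleus shift_ppm\n")
            for r in table.rows.itertuples():
                fh.write(
                    f"{r.residue_index}\t{r.residue_type}\t{r.nucleus}\t"
                    f"{r.shift_ppm:.6f}\n"
                )
    elif dialect == "nmrstar-minimal":
        with open(path, "w") as fh:
            fh.write(f"data_{table.protein_id}\n\nloop_\n")
            for tag in ("ID", "Seq_ID", "Comp_ID", "Atom_ID", "Val"):
                fh.write(f"  _Atom_chem_shift.{tag}\n")
            for i, r in enumerate(table.rows.itertuples(), 1):
                fh.write(
                    f"  {i} {r.residue_index} {ONE_TO_THREE[r.residue_type]} "
                    f"{r.nucleus} {r.shift_ppm:.6f}\n"
                )
            fh.write("stop_\n")
    else:
        raise ValidationError(f"unknown shift-table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Sparky peak lists


def read_peaklist_sparky(
    path: str | Path,
    spectrum_id: str | None = None,
    condition: dict | None = None,
) -> PeakList:
    """Read a Sparky-style .list file: ``assignment w1 w2 [height [lw]]``.

    Unassigned markers ('?-?') are preserved; an 'Assignment' header line is
    tolerated.  Non-numeric coordinates are a hard error with the line number.
    """
    path = Path(path)
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.split()[0].lower() == "assignment":
                continue
            parts = s.split()
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                w1, w2 = float(parts[1]), float(parts[2])
                height = float(parts[3]) if len(parts) > 3 else np.nan
                lw = float(parts[4]) if len(parts) > 4 else np.nan
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric value: {exc}"
                ) from exc
            recs.append((parts[0], w1, w2, height, lw))
    if not recs:
        logger.warning("empty peak list %s", path)
    df = pd.DataFrame(
        recs, columns=["assignment", "w1", "w2", "height", "linewidth_hint"]
    )
    return PeakList(
        spectrum_id=spectrum_id or path.stem,
        condition=condition or {},
        peaks=df,
    )


def write_peaklist_sparky(peaklist: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{'Assignment':>12s} {'w1':>9s} {'w2':>9s} {'Height':>12s}\n")
        for r in peaklist.peaks.itertuples():
            h = f"{r.height:.4e}" if np.isfinite(r.height) else ""
            fh.write(f"{r.assignment:>12s} {r.w1:9.4f} {r.w2:9.4f} {h:>12s}\n")


# ---------------------------------------------------------------------------
# FASTA / constraints / ensembles


def read_sequence_fasta(path: str | Path, offset: int = 1) -> Sequence:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return Sequence(id=rec.id, residues=str(rec.seq).upper(), offset=offset)


def write_sequence_fasta(seq: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.id} offset={seq.offset}\n{seq.residues}\n")


def read_constraints_tsv(path: str | Path) -> list[DistanceConstraint]:
    """TSV columns: residue_a atom_a residue_b atom_b [upper_bound [chain_a chain_b]]."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            p = s.split()
            if len(p) < 4:
                raise ValidationError(f"{path}:{lineno}: expected >= 4 columns")
            try:
                out.append(
                    DistanceConstraint(
                        residue_a=int(p[0]),
                        atom_a=p[1],
                        residue_b=int(p[2]),
                        atom_b=p[3],
                        upper_bound=float(p[4]) if len(p) > 4 else 5.0,
                        chain_a=p[5] if len(p) > 6 else None,
                        chain_b=p[6] if len(p) > 6 else None,
                    )
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_ensemble_pdb(path: str | Path):
    """Read a multi-MODEL PDB into an :class:`fuzzynmr.ensemble.Ensemble`.

    Models must share an identical atom roster; a mismatch is a hard error
    naming the first offending atom.
    """
    import biotite.structure.io.pdb as pdb

    from .ensemble import Ensemble

    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    arrays = [pdb_file.get_structure(model=i) for i in range(1, n_models + 1)]
    ref = arrays[0]
    ref_roster = list(zip(ref.chain_id, ref.res_id, ref.atom_name))
    for i, arr in enumerate(arrays[1:], start=2):
        roster = list(zip(arr.chain_id, arr.res_id, arr.atom_name))
        if roster != ref_roster:
            for a, b in zip(ref_roster, roster):
                if a != b:
                    raise ValidationError(
                        f"atom roster mismatch in MODEL {i}: expected "
                        f"{a[0]}/{a[1]}/{a[2]}, found {b[0]}/{b[1]}/{b[2]}"
                    )
            off = ref_roster[len(roster)] if len(roster) < len(ref_roster) else roster[len(ref_roster)]
            raise ValidationError(
                f"atom roster mismatch in MODEL {i}: differing atom "
                f"{off[0]}/{off[1]}/{off[2]}"
            )
    coords = np.stack([arr.coord for arr in arrays])
    atoms = pd.DataFrame(
        {
            "chain": ref.chain_id,
            "residue_index": ref.res_id.astype(int),
            "residue_name": ref.res_name,
            "residue_type": [THREE_TO_ONE.get(rn, "X") for rn in ref.res_name],
            "atom_name": ref.atom_name,
            "element": ref.element,
        }
    )
    return Ensemble(coords=coords, atoms=atoms)


def write_ensemble_pdb(ensemble, path: str | Path, models: Iterable[int] | None = None) -> None:
    """Write snapshots of an Ensemble as a multi-MODEL PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    idx = list(models) if models is not None else list(range(ensemble.n_models))
    n_atoms = len(ensemble.atoms)
    stack = struc.AtomArrayStack(len(idx), n_atoms)
    stack.coord = ensemble.coords[idx]
    stack.chain_id = ensemble.atoms.chain.to_numpy(dtype="U4")
    stack.res_id = ensemble.atoms.residue_index.to_numpy()
    stack.res_name = ensemble.atoms.residue_name.to_numpy(dtype="U5")
    stack.atom_name = ensemble.atoms.atom_name.to_numpy(dtype="U6")
    stack.element = ensemble.atoms.element.to_numpy(dtype="U2")
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
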