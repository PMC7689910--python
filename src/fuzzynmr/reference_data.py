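"""Reference chemical-shift tables.

Random-coil shifts (ppm, ~pH 6, 298 K) for the backbone nuclei, a minimal
sequence-correction set (the dominant effect: the residue preceding a
proline), and full-structure secondary-shift magnitudes used to normalise
SSP scores.  Values follow widely used random-coil compilations; any table
with complete coverage can be substituted via the ``RandomCoilTable``
constructor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import AA_CODES, ValidationError

__all__ = [
    "RandomCoilTable",
    "default_random_coil_table",
    "FULL_SECONDARY_SHIFTS",
    "full_secondary_shift",
]

# residue -> (CA, CB, HA, H, N, C) random-coil shifts; None where undefined
_COIL = {
    #      CA     CB     HA     H      N       C
    "A": (52.5, 19.1, 4.32, 8.24, 123.8, 177.8),
    "R": (56.0, 30.9, 4.34, 8.23, 120.5, 176.3),
    "N": (53.1, 38.9, 4.74, 8.40, 118.7, 175.2),
    "D": (54.2, 41.1, 4.64, 8.34, 120.4, 176.3),
    "C": (58.2, 28.0, 4.55, 8.32, 118.8, 174.6),
    "Q": (55.7, 29.4, 4.34, 8.32, 119.8, 176.0),
    "E": (56.6, 29.9, 4.35, 8.42, 120.2, 176.6),
    "G": (45.1, None, 3.96, 8.33, 108.8, 174.9),
    "H": (55.0, 29.0, 4.73, 8.42, 118.2, 174.1),
    "I": (61.1, 38.8, 4.17, 8.00, 119.9, 176.4),
    "L": (55.1, 42.4, 4.34, 8.16, 121.8, 177.6),
    "K": (56.2, 33.1, 4.32, 8.29, 120.4, 176.6),
    "M": (55.4, 32.9, 4.48, 8.28, 119.6, 176.3),
    "F": (57.7, 39.6, 4.62, 8.30, 120.3, 175.8),
    "P": (63.3, 32.1, 4.42, None, None, 177.3),
    "S": (58.3, 63.8, 4.47, 8.31, 115.7, 174.6),
    "T": (61.8, 69.8, 4.35, 8.15, 113.6, 174.7),
    "W": (57.5, 29.6, 4.66, 8.25, 121.3, 176.1),
    "Y": (57.9, 38.8, 4.55, 8.12, 120.3, 175.9),
    "V": (62.2, 32.9, 4.12, 8.03, 119.2, 176.3),
}

_NUCLEI = ("CA", "CB", "HA", "H", "N", "C")

# correction (ppm) added to the coil shift of residue i when the residue at
# i+offset has the given type; proline at i+1 dominates in practice
_NEIGHBOUR_CORRECTIONS = {
    ("CA", +1, "P"): -1.90,
    ("HA", +1, "P"): +0.05,
    ("CB", +1, "P"): -0.20,
    ("C", +1, "P"): -1.50,
    ("N", +1, "P"): +0.50,
}


@dataclass(frozen=True)
class RandomCoilTable:
    """Sequence-corrected random-coil chemical shifts.

    ``coil[(residue_type, nucleus)]`` are base coil shifts at
    ``ref_temperature``; ``corrections[(nucleus, offset, neighbour_type)]``
    are additive neighbour terms for offsets in i-2..i+2;
    ``temp_coefficients[(residue_type, nucleus)]`` are linear corrections in
    ppb/K applied relative to the reference temperature.
    """

    coil: dict
    corrections: dict = field(default_factory=dict)
    ref_temperature: float = 298.0
    ref_ph: float = 6.0
    temp_coefficients: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aa in AA_CODES:
            for nuc in ("CA", "HA"):
                if (aa, nuc) not in self.coil:
                    raise ValidationError(f"coil table missing {aa}/{nuc}")
            if aa != "G" and (aa, "CB") not in self.coil:
                raise ValidationError(f"coil table missing {aa}/CB")

    def coil_shift(
        self,
        sequence,
        residue_index: int,
        nucleus: str,
        temperature: float | None = None,
    ) -> float | None:
        """Sequence- and temperature-corrected coil shift, or None if undefined."""
        aa = sequence.get(residue_index)
        if aa is None:
            raise ValidationError(f"residue {residue_index} outside sequence")
        base = self.coil.get((aa, nucleus))
        if base is None:
            return None
        value = base
        for offset in (-2, -1, 1, 2):
            nb = sequence.get(residue_index + offset)
            if nb is not None:
                value += self.corrections.get((nucleus, offset, nb), 0.0)
        if temperature is not None:
            coeff = self.temp_coefficients.get((aa, nucleus), 0.0)
            value += coeff * 1e-3 * (temperature - self.ref_temperature)
        return value


def default_random_coil_table() -> RandomCoilTable:
    coil = {}
    for aa, values in _COIL.items():
        for nuc, val in zip(_NUCLEI, values):
            if val is not None:
                coil[(aa, nuc)] = val
    return RandomCoilTable(coil=coil, corrections=dict(_NEIGHBOUR_CORRECTIONS))


# Full-structure secondary shifts (ppm): observed minus coil for a residue in
# ideal helix / ideal extended strand.  Helix moves CA downfield and CB/HA
# upfield; strand mirrors the signs.
FULL_SECONDARY_SHIFTS = {
    "CA": (3.1, -1.5),
    "CB": (-0.38, 2.16),
    "HA": (-0.39, 0.37),
}


def full_secondary_shift(residue_type: str, nucleus: str, structure: str) -> float | None:
    """Full helix/sheet secondary shift for one residue type and nucleus.

    The shipped table is uniform across residue types (per-nucleus averages
    from published compilations); Gly CB is undefined.
    """
    if residue_type == "G" and nucleus == "CB":
        return None
    try:
        helix, sheet = FULL_SECONDARY_SHIFTS[nucleus]
    except KeyError:
        return None
    if structure == "helix":
        return helix
    if structure == "sheet":
        return sheet
    raise ValidationError(f"unknown structure class {structure!r}")
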