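"""Mass arithmetic for uniform heavy-nitrogen (15N) metabolic labeling.

In a fully 15N-labeled culture every nitrogen atom of every residue —
backbone amide and side chain alike — carries the heavy isotope, so a
peptide's heavy channel is offset from its light counterpart by
(number of nitrogen atoms) x the 15N/14N mass difference. The per-nitrogen
shift is close to, but not exactly, 1 Da; the exact isotopic mass
difference is used throughout and the near-integer behavior falls out as
a property.
"""

from __future__ import annotations

from .errors import DomainError

#: Nitrogen atoms per residue (residue = amino acid minus water), including
#: the backbone amide nitrogen. Side-chain nitrogens: K/Q/N/W add one,
#: H adds two, R adds three.
RESIDUE_NITROGEN: dict[str, int] = {
    **{aa: 1 for aa in "GASPVTCLIMFYED"},
    **{aa: 2 for aa in "KQNW"},
    "H": 3,
    "R": 4,
}

#: m(15N) - m(14N) in Da, from standard atomic masses.
DELTA_M_15N = 0.9970349

#: Mass of a proton in Da (for m/z arithmetic).
PROTON_MASS = 1.007276466879


def nitrogen_count(peptide_seq: str) -> int:
    """Total nitrogen atoms in a peptide of canonical residues.

    Raises :class:`DomainError` naming the first offending position if the
    sequence contains a non-canonical letter.
    """
    total = 0
    for i, aa in enumerate(peptide_seq):
        try:
            total += RESIDUE_NITROGEN[aa]
        except KeyError:
            raise DomainError(
                f"non-canonical residue {aa!r} at position {i + 1} "
                f"in peptide {peptide_seq!r}"
            ) from None
    return total


def heavy_mass_shift(peptide_seq: str) -> float:
    """Mass offset (Da) of the uniformly 15N-labeled peptide vs. its light form."""
    return nitrogen_count(peptide_seq) * DELTA_M_15N


def heavy_mz(light_mz: float, charge: int, peptide_seq: str) -> float:
    """Predicted heavy-channel precursor m/z for a light precursor.

    The neutral mass shift is divided by the charge; the proton count is
    unchanged between channels, so no proton-mass term enters.
    """
    if charge < 1:
        raise DomainError(f"charge must be >= 1, got {charge}")
    if not light_mz > 0:
        raise DomainError(f"light_mz must be positive, got {light_mz}")
    return light_mz + heavy_mass_shift(peptide_seq) / charge
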