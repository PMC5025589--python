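"""Canonical amino-acid alphabet, residue classes and sequence encoding.

The 20-letter canonical alphabet is fixed in a stable order; every model
emission row is indexed against it.  Ambiguity codes (B, Z, X, U, O, J) are
accepted in input sequences but are emitted with probability 1/20 by every
state, so they contribute the same constant to every model's likelihood and
can never decide a classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}
N_SYMBOLS: int = len(ALPHABET)

#: Ambiguity codes tolerated in input; class-neutral emission 1/20 everywhere.
AMBIGUOUS: frozenset[str] = frozenset("BZXUOJ")

#: Sentinel symbol index for ambiguous residues.
AMBIGUOUS_CODE: int = -1

# Residue classes partition the alphabet (Kyte-Doolittle-positive letters are
# "hydrophobic"; histidine is grouped with the basic residues).
BASIC: frozenset[str] = frozenset("KRH")
HYDROPHOBIC: frozenset[str] = frozenset("ACFILMVW")
HYDROPHILIC: frozenset[str] = frozenset(ALPHABET) - BASIC - HYDROPHOBIC

RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "basic": BASIC,
    "hydrophobic": HYDROPHOBIC,
    "hydrophilic": HYDROPHILIC,
}


def residue_class(letter: str) -> str:
    """Return the class name of a canonical residue letter."""
    for name, members in RESIDUE_CLASSES.items():
        if letter in members:
            return name
    raise KeyError(f"not a canonical residue: {letter!r}")


class SequenceError(ValueError):
    """Raised for empty, non-canonical or otherwise invalid input sequences."""


@dataclass(frozen=True)
class AminoAcidSequence:
    """A validated, uppercase amino-acid sequence.

    Parameters
    ----------
    id : str
        Record identifier.
    residues : str
        Residue letters; canonicalised to uppercase.  Only the 20 canonical
        letters plus the ambiguity codes B, Z, X, U, O, J are accepted.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        canon = self.residues.upper()
        for pos, letter in enumerate(canon):
            if letter not in ALPHABET_INDEX and letter not in AMBIGUOUS:
                raise SequenceError(
                    f"sequence {self.id!r}: invalid residue {letter!r} "
                    f"at position {pos + 1}"
                )
        object.__setattr__(self, "residues", canon)

    def __len__(self) -> int:
        return len(self.residues)

    def encode(self) -> np.ndarray:
        """Integer codes, with :data:`AMBIGUOUS_CODE` for ambiguity letters."""
        return np.fromiter(
            (ALPHABET_INDEX.get(a, AMBIGUOUS_CODE) for a in self.residues),
            dtype=np.int64,
            count=len(self.residues),
        )

    def reversed(self) -> "AminoAcidSequence":
        """The same record read C-terminus first."""
        return AminoAcidSequence(self.id, self.residues[::-1])


def as_sequence(obj, id: str = "seq") -> AminoAcidSequence:
    """Coerce a plain string into an :class:`AminoAcidSequence`."""
    if isinstance(obj, AminoAcidSequence):
        return obj
    return AminoAcidSequence(id, str(obj))
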