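"""Sequence data model, alphabet normalization, and FASTA I/O.

The canonical internal alphabet is RNA ({A, C, G, U}); DNA is treated as a
presentation layer on read/write.  All coordinates in the toolkit are
0-based, half-open, plus-strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetConflictError,
    EmptyInputError,
    InvalidResidueError,
)

_RNA_RESIDUES = frozenset("ACGU")
_INPUT_RESIDUES = frozenset("ACGTU")


class Alphabet(str, Enum):
    """Source alphabet of a nucleotide record."""

    DNA = "dna"
    RNA = "rna"


@dataclass(frozen=True)
class NucleotideSequence:
    """A normalized RNA-alphabet sequence with provenance of its source alphabet.

    Attributes
    ----------
    id : str
        Record identifier (first whitespace-delimited FASTA header token).
    residues : str
        Uppercase residues over {A, C, G, U}.
    source_alphabet : Alphabet
        Alphabet of the original input (``dna`` or ``rna``).
    description : str
        Optional free-text description (rest of the FASTA header).
    """

    id: str
    residues: str
    source_alphabet: Alphabet = Alphabet.RNA
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidResidueError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - _RNA_RESIDUES
        if bad:
            raise InvalidResidueError(
                f"sequence {self.id!r}: non-RNA residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def to_source(self) -> str:
        """Residues rendered in the original source alphabet."""
        if self.source_alphabet is Alphabet.DNA:
            return to_dna(self)
        return self.residues

    def with_residues(self, residues: str, id: Union[str, None] = None) -> "NucleotideSequence":
        """Copy with new residues (and optionally a new id)."""
        return NucleotideSequence(
            id=self.id if id is None else id,
            residues=residues,
            source_alphabet=self.source_alphabet,
            description=self.description,
        )


def normalize_sequence(
    raw: str,
    alphabet_hint: str = "auto",
    *,
    id: str = "seq",
    description: str = "",
) -> NucleotideSequence:
    """Normalize a raw nucleotide string to the canonical RNA alphabet.

    Whitespace is stripped, case is folded to upper, and T is mapped to U.
    The source alphabet is recorded: with ``alphabet_hint="auto"`` it is
    ``dna`` if any T and no U occur, ``rna`` if any U and no T, and ``dna``
    when neither base appears.

    Raises
    ------
    AlphabetConflictError
        If the record mixes T and U, or contradicts an explicit hint.
    InvalidResidueError
        On any character outside {A, C, G, T, U} (case-insensitive).
    """
    if alphabet_hint not in ("auto", "dna", "rna"):
        raise ValueError(f"unknown alphabet hint {alphabet_hint!r}")
    stripped = "".join(raw.split()).upper()
    if not stripped:
        raise InvalidResidueError(f"sequence {id!r}: empty input")
    bad = set(stripped) - _INPUT_RESIDUES
    if bad:
        raise InvalidResidueError(
            f"sequence {id!r}: invalid residues {sorted(bad)!r}"
        )
    has_t = "T" in stripped
    has_u = "U" in stripped
    if has_t and has_u:
        raise AlphabetConflictError(
            f"sequence {id!r}: record mixes T and U"
        )
    if alphabet_hint == "dna":
        if has_u:
            raise AlphabetConflictError(
                f"sequence {id!r}: U present in a record declared as DNA"
            )
        source = Alphabet.DNA
    elif alphabet_hint == "rna":
        if has_t:
            raise AlphabetConflictError(
                f"sequence {id!r}: T present in a record declared as RNA"
            )
        source = Alphabet.RNA
    else:
        source = Alphabet.RNA if has_u else Alphabet.DNA
    return NucleotideSequence(
        id=id,
        residues=stripped.replace("T", "U"),
        source_alphabet=source,
        description=description,
    )


def to_dna(seq: NucleotideSequence) -> str:
    """Render a normalized sequence as DNA (U -> T); length-preserving."""
    return seq.residues.replace("U", "T")


def read_fasta(
    path: Union[str, Path],
    alphabet_hint: str = "auto",
) -> List[NucleotideSequence]:
    """Read a FASTA file into normalized sequences.

    Duplicate ids are kept but disambiguated with ``.2``, ``.3``, ... suffixes
    (with a warning).  A file containing zero records raises
    :class:`EmptyInputError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records found")
    seen: dict = {}
    out: List[NucleotideSequence] = []
    for rec in records:
        rec_id = rec.id
        seen[rec_id] = seen.get(rec_id, 0) + 1
        if seen[rec_id] > 1:
            new_id = f"{rec_id}.{seen[rec_id]}"
            warnings.warn(
                f"{path}: duplicate id {rec_id!r} renamed to {new_id!r}"
            )
            rec_id = new_id
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(
            normalize_sequence(
                str(rec.seq), alphabet_hint, id=rec_id, description=desc
            )
        )
    return out


def write_fasta(
    seqs: Iterable[NucleotideSequence],
    path: Union[str, Path],
    alphabet: str = "rna",
) -> None:
    """Write sequences as FASTA, 60-column wrapped, in the requested alphabet."""
    if alphabet not in ("dna", "rna"):
        raise ValueError(f"unknown output alphabet {alphabet!r}")
    records = []
    for s in seqs:
        residues = to_dna(s) if alphabet == "dna" else s.residues
        records.append(
            SeqRecord(Seq(residues), id=s.id, description=s.description)
        )
    if not records:
        raise EmptyInputError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
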