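"""DNA sequence container and FASTA ingestion.

Sequences are plain A/C/G/T strings; anything outside that alphabet is
rejected at construction time so downstream frequency normalisation is
never silently corrupted by ambiguity codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Union

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class InvalidSequenceError(ValueError):
    """Raised when a record contains characters outside A/C/G/T."""


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA sequence with an identifier.

    Residues are uppercased on ingest; any character outside {A, C, G, T}
    raises :class:`InvalidSequenceError` naming the record and character.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        for ch in residues:
            if ch not in _BASE_INDEX:
                raise InvalidSequenceError(
                    f"record {self.id!r} contains invalid character {ch!r}; "
                    f"only A/C/G/T are accepted"
                )
        if not residues:
            raise InvalidSequenceError(f"record {self.id!r} is empty")
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def indices(self) -> np.ndarray:
        """Residues as an integer array with A=0, C=1, G=2, T=3."""
        return np.frombuffer(
            self.residues.encode("ascii").translate(_TRANSLATE), dtype=np.uint8
        ).astype(np.intp)


_TRANSLATE = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))


def read_fasta(
    path: Union[str, Path], skip_invalid: bool = False
) -> List[DnaSequence]:
    """Read a multi-record FASTA file into validated :class:`DnaSequence` objects.

    Ids are taken from the header up to the first whitespace.  With
    ``skip_invalid`` records containing non-ACGT characters are dropped with
    a logged warning instead of raising.
    """
    path = Path(path)
    seqs: List[DnaSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            seqs.append(DnaSequence(id=record.id, residues=str(record.seq)))
        except InvalidSequenceError:
            if skip_invalid:
                logger.warning("skipping record %s: non-ACGT characters", record.id)
            else:
                raise
    if not seqs:
        raise InvalidSequenceError(f"no valid FASTA records found in {path}")
    return seqs


def write_fasta(path: Union[str, Path], seqs: Iterable[DnaSequence]) -> None:
    """Write sequences as unwrapped FASTA."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")
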