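"""Peptide and dataset containers, validation and FASTA / plain-text I/O.

Peptides are short (typically 5-30 residue) sequences over the 20 natural
amino acids in uppercase one-letter code.  Entries carrying non-natural
residues (selenocysteine ``U``, pyrrolysine ``O``), ambiguity codes
(``B``, ``J``, ``X``, ``Z``) or gap characters are rejected outright
rather than masked, because a single residue can change membrane-crossing
behaviour.  Duplicate sequences are deliberately permitted: alanine-scan
and truncation series are informative and are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyDatasetError, EmptySequenceError, InvalidResidueError

#: The 20 natural amino acids, alphabetical one-letter order.  All feature
#: encodings index residues in this fixed order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

Label = Literal["positive", "negative", "unknown"]


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with an identifier and optional class label."""

    sequence: str
    id: str = ""
    label: Label = "unknown"

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def validate_peptide(raw: str, id: str = "", label: Label = "unknown") -> Peptide:
    """Validate a raw sequence string and return a :class:`Peptide`.

    Input is stripped of surrounding whitespace and uppercased.  Any
    character outside the 20-letter alphabet raises
    :class:`~cppred.errors.InvalidResidueError` naming the character and
    its 1-based position; an empty string raises
    :class:`~cppred.errors.EmptySequenceError`.
    """
    seq = raw.strip().upper()
    if not seq:
        raise EmptySequenceError("empty sequence" + (f" ({id})" if id else ""))
    for pos, ch in enumerate(seq, start=1):
        if ch not in AA_SET:
            raise InvalidResidueError(ch, pos, context=id or None or "")
    return Peptide(sequence=seq, id=id, label=label)


@dataclass
class PeptideDataset:
    """An ordered collection of peptides.

    Duplicates are retained; balanced construction is the caller's
    responsibility.
    """

    entries: list[Peptide] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {"positive": 0, "negative": 0, "unknown": 0}
        for p in self.entries:
            counts[p.label] += 1
        return counts

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.entries]

    def subset(self, indices: Iterable[int], name: str = "") -> "PeptideDataset":
        return PeptideDataset([self.entries[i] for i in indices], name=name or self.name)


def read_sequences(path: str | Path, format: str = "fasta",
                   label: Label = "unknown") -> PeptideDataset:
    """Read peptides from ``path`` in ``fasta`` or ``plain`` format.

    FASTA headers (first whitespace-delimited token) become peptide ids.
    Plain format is one sequence per line; blank lines and lines starting
    with ``#`` are ignored and ids are assigned ``seq1..seqN``.
    Validation errors are re-raised with the record id / line number.
    """
    path = Path(path)
    entries: list[Peptide] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            entries.append(validate_peptide(str(rec.seq), id=rec.id, label=label))
    elif format == "plain":
        n = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                n += 1
                try:
                    entries.append(validate_peptide(line, id=f"seq{n}", label=label))
                except InvalidResidueError as e:
                    raise InvalidResidueError(e.residue, e.position,
                                              context=f"line {lineno}") from e
    else:
        raise ValueError(f"unknown format {format!r}: use 'fasta' or 'plain'")
    return PeptideDataset(entries, name=path.stem)


def write_fasta(dataset: PeptideDataset, path: str | Path) -> Path:
    """Write a dataset as standard FASTA; round-trips through read_sequences."""
    if len(dataset) == 0:
        raise EmptyDatasetError("refusing to write an empty dataset")
    path = Path(path)
    records = [SeqRecord(Seq(p.sequence), id=p.id or f"seq{i + 1}", description="")
               for i, p in enumerate(dataset)]
    SeqIO.write(records, str(path), "fasta")
    return path
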