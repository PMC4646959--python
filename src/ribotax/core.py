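"""Shared domain types, coordinate conventions and sequence/table I/O.

All positions on the 16S gene model are 1-based and inclusive, matching the
convention of HMMER tabular output. The default model length (1542) is the
length of the *E. coli* 16S gene, which serves as the positional reference
for the whole pipeline; it is carried as data and never assumed by logic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Model coordinates

#: Length of the E. coli 16S rRNA gene, the standard positional reference.
DEFAULT_MODEL_LENGTH = 1542

#: Recognised profile-HMM model identifiers.
MODEL_IDS = ("bacteria_16S", "archaea_16S")

Mate = Literal["single", "1", "2"]
MATES = ("single", "1", "2")


def check_interval(start: int, end: int, model_length: int = DEFAULT_MODEL_LENGTH) -> None:
    """Assert that ``[start, end]`` is a valid 1-based inclusive model interval.

    This single helper enforces the coordinate convention everywhere; any
    interval entering the system passes through it.
    """
    if not (1 <= start <= end <= model_length):
        raise ValueError(
            f"invalid model interval [{start}, {end}] for model length {model_length}"
        )


@dataclass(frozen=True)
class ModelCoordinates:
    """Coordinate system of a 16S profile model (1-based, inclusive)."""

    model_id: str = "bacteria_16S"
    model_length: int = DEFAULT_MODEL_LENGTH

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.model_length < 1:
            raise ValueError("model_length must be positive")

    def check(self, start: int, end: int) -> None:
        check_interval(start, end, self.model_length)


# ---------------------------------------------------------------------------
# Reads

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_ALPHABET = frozenset("ACGTN")


def reverse_complement(sequence: str) -> str:
    """Reverse-complement a DNA string over {A,C,G,T,N}; N maps to N.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if not _DNA_ALPHABET.issuperset(sequence):
        bad = sorted(set(sequence) - _DNA_ALPHABET)
        raise ValueError(f"sequence contains non-DNA characters: {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRead:
    """A single sequencing read, possibly one mate of a pair.

    ``mate`` is ``"single"`` for unpaired data, ``"1"`` or ``"2"`` for the
    forward/reverse mate of a pair; it is assigned from the file role the
    caller supplies (R1 vs R2), never parsed out of headers.
    """

    read_id: str
    sequence: str
    mate: Mate = "single"
    quality: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.mate not in MATES:
            raise ValueError(f"read {self.read_id!r}: invalid mate {self.mate!r}")
        if not _DNA_ALPHABET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _DNA_ALPHABET)
            raise ValueError(f"read {self.read_id!r}: non-DNA characters {bad}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.read_id, self.mate)

    def __len__(self) -> int:
        return len(self.sequence)


def read_sequences(path: str | os.PathLike, format: str = "fasta",
                   mate: Mate = "single") -> Iterator[SequenceRead]:
    """Stream reads from a FASTA or FASTQ (Sanger phred+33) file.

    ``mate`` labels every record in the file: the caller states the paired-
    file role (R1 -> "1", R2 -> "2"). An empty file yields an empty stream;
    a malformed record raises ``ValueError`` naming the record index.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    handle = "fastq-sanger" if format == "fastq" else "fasta"
    index = 0
    parser = SeqIO.parse(str(path), handle)
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except Exception as exc:  # malformed record
            raise ValueError(f"{path}: malformed {format} record #{index}: {exc}") from exc
        qual = rec.letter_annotations.get("phred_quality")
        try:
            yield SequenceRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                mate=mate,
                quality=list(qual) if qual is not None else None,
            )
        except ValueError as exc:
            raise ValueError(f"{path}: record #{index} ({rec.id}): {exc}") from exc
        index += 1


def write_sequences(reads: Iterable[SequenceRead], path: str | os.PathLike,
                    format: str = "fasta") -> int:
    """Write reads to FASTA/FASTQ; returns the number of records written."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if format == "fastq":
            qual = r.quality if r.quality is not None else [40] * len(r.sequence)
            rec.letter_annotations["phred_quality"] = list(qual)
        records.append(rec)
    handle = "fastq-sanger" if format == "fastq" else "fasta"
    return SeqIO.write(records, str(path), handle)


# ---------------------------------------------------------------------------
# Lineages

#: The six ranks handled by the classifier, most to least inclusive.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class Lineage:
    """Ranked taxon names from domain down to (at most) genus.

    The ranks present must form a contiguous prefix of
    domain > phylum > class > order > family > genus: a lineage may stop
    early (e.g. end at family) but never skip a rank.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names or len(self.names) > len(RANKS):
            raise ValueError(f"lineage must have 1..{len(RANKS)} names, got {self.names!r}")
        if any(not n for n in self.names):
            raise ValueError(f"lineage contains an empty name: {self.names!r}")

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "Lineage":
        names = []
        for rank in RANKS:
            v = d.get(rank, "")
            if not v:
                break
            names.append(v)
        lin = cls(tuple(names))
        # reject non-contiguous input (a named rank below a gap)
        for rank in RANKS[len(names):]:
            if d.get(rank, ""):
                raise ValueError(f"lineage skips a rank before {rank!r}: {d!r}")
        return lin

    @property
    def depth(self) -> int:
        return len(self.names)

    @property
    def genus(self) -> Optional[str]:
        return self.names[5] if len(self.names) == 6 else None

    def name_at(self, rank: str) -> Optional[str]:
        i = RANKS.index(rank)
        return self.names[i] if i < len(self.names) else None

    def path_to(self, rank: str) -> tuple[str, ...]:
        """Lineage path truncated at ``rank`` (inclusive)."""
        i = RANKS.index(rank)
        if i >= len(self.names):
            raise ValueError(f"lineage {self.names!r} has no rank {rank!r}")
        return self.names[: i + 1]

    def is_complete(self) -> bool:
        return len(self.names) == len(RANKS)


def read_lineages(path: str | os.PathLike) -> dict[str, Lineage]:
    """Read a lineage TSV: header ``seq_id<TAB>domain..genus``, one row per sequence."""
    lineages: dict[str, Lineage] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["seq_id", *RANKS]
        if header != expected:
            raise ValueError(f"{path}: bad lineage header {header!r}, expected {expected!r}")
        for lno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lno}: expected 7 tab-separated fields")
            seq_id = fields[0]
            if seq_id in lineages:
                raise ValueError(f"{path}:{lno}: duplicate seq_id {seq_id!r}")
            lineages[seq_id] = Lineage.from_dict(dict(zip(RANKS, fields[1:])))
    return lineages


def write_lineages(lineages: dict[str, Lineage], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\t" + "\t".join(RANKS) + "\n")
        for seq_id, lin in lineages.items():
            padded = list(lin.names) + [""] * (len(RANKS) - len(lin.names))
            fh.write(seq_id + "\t" + "\t".join(padded) + "\n")
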