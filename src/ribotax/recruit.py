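"""Recruitment of candidate 16S reads by profile-HMM search.

Each read is searched on both strands (the minus strand by searching its
reverse complement) against the bacterial and archaeal 16S profile HMMs and
thresholded on the per-domain independent E-value. The search engine sits
behind a small interface with two interchangeable implementations:

* :class:`PyhmmerEngine` — in-process, via the pyhmmer bindings (default);
* :class:`HmmsearchEngine` — external ``hmmsearch`` subprocess speaking the
  per-domain tabular (domtblout) dialect, for interoperability with a user's
  own HMMER runs.

Reads appear in the search as *targets* (the HMM is the query); the reverse-
complement copy of a read carries an ``_rc`` suffix on its target name, which
is how strand is recovered when parsing tabular output.
"""

from __future__ import annotations

import os
import subprocess
import tempfile
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Protocol, Union

import pyhmmer
from pyhmmer import easel, plan7

from .core import MATES, MODEL_IDS, Mate, SequenceRead, check_interval, reverse_complement

DEFAULT_EVALUE = 1e-5

HmmSource = Union[str, os.PathLike, plan7.HMM]


@dataclass(frozen=True)
class HmmHit:
    """One profile-HMM match of a read (one aligned domain).

    ``model_from``/``model_to`` are 1-based inclusive positions on the HMM;
    ``read_from``/``read_to`` are 1-based inclusive positions on the read *as
    given* (already mapped back from the reverse complement for minus-strand
    hits). ``read_length`` is carried so minus-strand coordinates and the
    minimum-length filter downstream need no lookup.
    """

    read_id: str
    mate: Mate
    model_id: str
    strand: str  # "+" or "-"
    evalue: float
    bit_score: float
    model_from: int
    model_to: int
    read_from: int
    read_to: int
    read_length: int

    def __post_init__(self) -> None:
        if self.mate not in MATES:
            raise ValueError(f"invalid mate {self.mate!r}")
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if not (1 <= self.model_from <= self.model_to):
            raise ValueError(f"invalid model interval [{self.model_from},{self.model_to}]")
        if not (1 <= self.read_from <= self.read_to <= self.read_length):
            raise ValueError(
                f"invalid read interval [{self.read_from},{self.read_to}] "
                f"for length {self.read_length}"
            )


# ---------------------------------------------------------------------------
# Target naming (read <-> search-target identity)

def encode_target_name(read_id: str, mate: Mate, strand: str) -> str:
    name = read_id if mate == "single" else f"{read_id}/{mate}"
    return name + "_rc" if strand == "-" else name


def decode_target_name(name: str) -> tuple[str, Mate, str]:
    strand = "+"
    if name.endswith("_rc"):
        strand = "-"
        name = name[:-3]
    if len(name) > 2 and name[-2] == "/" and name[-1] in ("1", "2"):
        return name[:-2], name[-1], strand  # type: ignore[return-value]
    return name, "single", strand


def _map_minus_coords(rc_from: int, rc_to: int, length: int) -> tuple[int, int]:
    """Map an interval on the reverse complement back onto the original read."""
    return length - rc_to + 1, length - rc_from + 1


# ---------------------------------------------------------------------------
# HMM loading

def load_hmm(source: HmmSource) -> plan7.HMM:
    """Load a profile HMM from a HMMER3 ``.hmm`` file (or pass one through)."""
    if isinstance(source, plan7.HMM):
        return source
    try:
        with plan7.HMMFile(str(source)) as fh:
            return fh.read()
    except Exception as exc:
        raise ValueError(f"cannot read HMM file {source}: {exc}") from exc


def _prepare_models(hmm_models: Mapping[str, HmmSource]) -> list[plan7.HMM]:
    alphabet = easel.Alphabet.dna()
    hmms = []
    for model_id, source in hmm_models.items():
        if model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {model_id!r}")
        hmm = load_hmm(source)
        if hmm.alphabet.type != alphabet.type:
            raise ValueError(f"model {model_id!r} is not a nucleotide HMM")
        hmm = hmm.copy()
        hmm.name = model_id
        hmms.append(hmm)
    return hmms


def _digitized_targets(reads: Iterable[SequenceRead]) -> list[easel.DigitalSequence]:
    """Both-strand digitized targets for every read, rc copies tagged ``_rc``."""
    alphabet = easel.Alphabet.dna()
    targets = []
    for read in reads:
        for strand, seq in (("+", read.sequence),
                            ("-", reverse_complement(read.sequence))):
            name = encode_target_name(read.read_id, read.mate, strand)
            targets.append(easel.TextSequence(name=name, sequence=seq).digitize(alphabet))
    return targets


# ---------------------------------------------------------------------------
# Engines

class SearchEngine(Protocol):
    def search(self, reads: Iterable[SequenceRead], hmm_models: Mapping[str, HmmSource],
               evalue_threshold: float) -> list[HmmHit]: ...


class PyhmmerEngine:
    """In-process profile-HMM search via pyhmmer (single worker by default)."""

    def __init__(self, cpus: int = 1) -> None:
        self.cpus = cpus

    def search(self, reads: Iterable[SequenceRead], hmm_models: Mapping[str, HmmSource],
               evalue_threshold: float = DEFAULT_EVALUE) -> list[HmmHit]:
        hmms = _prepare_models(hmm_models)
        targets = _digitized_targets(reads)
        hits: list[HmmHit] = []
        if not targets or not hmms:
            return hits
        for top in pyhmmer.hmmer.hmmsearch(hmms, targets, cpus=self.cpus):
            model_id = str(top.query.name)
            for hit in top:
                read_id, mate, strand = decode_target_name(str(hit.name))
                length = hit.length
                for dom in hit.domains:
                    if dom.i_evalue > evalue_threshold:
                        continue
                    ali = dom.alignment
                    rf, rt = ali.target_from, ali.target_to
                    if strand == "-":
                        rf, rt = _map_minus_coords(rf, rt, length)
                    hits.append(HmmHit(
                        read_id=read_id, mate=mate, model_id=model_id, strand=strand,
                        evalue=dom.i_evalue, bit_score=dom.score,
                        model_from=ali.hmm_from, model_to=ali.hmm_to,
                        read_from=rf, read_to=rt, read_length=length,
                    ))
        return hits


class HmmsearchEngine:
    """External-process engine: writes targets, runs ``hmmsearch --domtblout``."""

    def __init__(self, binary: str = "hmmsearch") -> None:
        self.binary = binary

    def search(self, reads: Iterable[SequenceRead], hmm_models: Mapping[str, HmmSource],
               evalue_threshold: float = DEFAULT_EVALUE) -> list[HmmHit]:
        hmms = _prepare_models(hmm_models)
        reads = list(reads)
        if not reads or not hmms:
            return []
        hits: list[HmmHit] = []
        with tempfile.TemporaryDirectory(prefix="ribotax_hmm_") as tmp:
            fasta = os.path.join(tmp, "targets.fa")
            with open(fasta, "w") as fh:
                for read in reads:
                    for strand, seq in (("+", read.sequence),
                                        ("-", reverse_complement(read.sequence))):
                        fh.write(f">{encode_target_name(read.read_id, read.mate, strand)}\n"
                                 f"{seq}\n")
            for hmm in hmms:
                hmm_path = os.path.join(tmp, str(hmm.name) + ".hmm")
                with open(hmm_path, "wb") as fh:
                    hmm.write(fh)
                tbl = os.path.join(tmp, str(hmm.name) + ".domtbl")
                proc = subprocess.run(
                    [self.binary, "--domtblout", tbl, "--noali", "--cpu", "1",
                     "-E", "10", hmm_path, fasta],
                    capture_output=True, text=True,
                )
                if proc.returncode != 0:
                    raise RuntimeError(
                        f"{self.binary} failed ({proc.returncode}): {proc.stderr.strip()}")
                hits.extend(h for h in parse_hit_table(tbl)
                            if h.evalue <= evalue_threshold)
        return hits


def search_reads(reads: Iterable[SequenceRead], hmm_models: Mapping[str, HmmSource],
                 evalue_threshold: float = DEFAULT_EVALUE,
                 engine: Optional[SearchEngine] = None) -> list[HmmHit]:
    """Search every read (both strands) against the given 16S models.

    Returns every per-domain match with independent E-value at or below the
    threshold; a read may contribute several hits (both models, both strands,
    several domains). No de-replication happens here.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be > 0")
    if engine is None:
        engine = PyhmmerEngine()
    return engine.search(reads, hmm_models, evalue_threshold)


# ---------------------------------------------------------------------------
# Tabular I/O (HMMER3 per-domain table dialect)

_DOMTBL_NCOLS = 22


def parse_hit_table(path: str | os.PathLike) -> list[HmmHit]:
    """Parse HMMER3 per-domain tabular output (domtblout dialect).

    The target-name suffix convention of this pipeline (``_rc`` for reverse-
    complement searches) recovers strand; minus-strand read coordinates are
    mapped back onto the original read. Comment lines are skipped; anything
    else unparseable is a hard error with its line number.
    """
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split(None, _DOMTBL_NCOLS)
            if len(fields) < _DOMTBL_NCOLS:
                raise ValueError(f"{path}:{lno}: expected ≥{_DOMTBL_NCOLS} columns, "
                                 f"got {len(fields)}")
            try:
                read_id, mate, strand = decode_target_name(fields[0])
                length = int(fields[2])
                model_id = fields[3]
                i_evalue = float(fields[12])
                score = float(fields[13])
                hmm_from, hmm_to = int(fields[15]), int(fields[16])
                ali_from, ali_to = int(fields[17]), int(fields[18])
                if strand == "-":
                    ali_from, ali_to = _map_minus_coords(ali_from, ali_to, length)
                hits.append(HmmHit(
                    read_id=read_id, mate=mate, model_id=model_id, strand=strand,
                    evalue=i_evalue, bit_score=score,
                    model_from=hmm_from, model_to=hmm_to,
                    read_from=ali_from, read_to=ali_to, read_length=length,
                ))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lno}: unparseable domain table line: {exc}") \
                    from exc
    return hits


def write_hit_table(hits: Iterable[HmmHit], path: str | os.PathLike) -> None:
    """Write hits in the per-domain tabular dialect ``parse_hit_table`` reads."""
    with open(path, "w") as fh:
        fh.write("# target name\taccession\ttlen\tquery name\taccession\tqlen\t"
                 "E-value\tscore\tbias\t#\tof\tc-Evalue\ti-Evalue\tscore\tbias\t"
                 "hmm_from\thmm_to\tali_from\tali_to\tenv_from\tenv_to\tacc\t"
                 "description\n".replace("\t", " "))
        for h in hits:
            rf, rt = h.read_from, h.read_to
            if h.strand == "-":
                rf, rt = _map_minus_coords(rf, rt, h.read_length)
            name = encode_target_name(h.read_id, h.mate, h.strand)
            fh.write(" ".join(map(str, [
                name, "-", h.read_length, h.model_id, "-", 0,
                format(h.evalue, ".17g"), format(h.bit_score, ".17g"), "0.0", 1, 1,
                format(h.evalue, ".17g"), format(h.evalue, ".17g"),
                format(h.bit_score, ".17g"), "0.0",
                h.model_from, h.model_to, rf, rt, rf, rt, "0.00", "-",
            ])) + "\n")
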