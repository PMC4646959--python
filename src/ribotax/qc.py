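"""Quality control and positioning of recruited reads.

Takes the raw profile-HMM hits, applies the four quality-control rules
(E-value, minimum read length, strand coherence, multiple-assignment
de-replication), orients every surviving read model-forward, annotates its
position on the 16S model in the FASTA header, and computes per-position
coverage of the gene.

Filtering is silent but fully accounted: every removal is attributed to a
reason in a :class:`FilterSummary` so recruitment-summary tables can be
produced for any dataset.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import (DEFAULT_MODEL_LENGTH, MATES, Mate, SequenceRead, check_interval,
                   reverse_complement)
from .recruit import DEFAULT_EVALUE, HmmHit

DEFAULT_MIN_LENGTH = 60

ReadKey = tuple[str, str]


@dataclass
class RibosomalRead:
    """A recruited read, oriented model-forward and positioned on the 16S gene."""

    read_id: str
    mate: Mate
    oriented_sequence: str
    model_id: str
    model_from: int
    model_to: int
    evalue: float

    def __post_init__(self) -> None:
        if self.mate not in MATES:
            raise ValueError(f"invalid mate {self.mate!r}")
        if not (1 <= self.model_from <= self.model_to):
            raise ValueError(f"invalid model interval [{self.model_from},{self.model_to}]")

    @property
    def key(self) -> ReadKey:
        return (self.read_id, self.mate)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.model_from, self.model_to)


@dataclass
class FilterSummary:
    """Removal accounting for one pass of hit filtering."""

    n_reads_in: int = 0
    n_kept: int = 0
    removed_evalue: int = 0        # all hits above the E-value threshold
    removed_short: int = 0         # read shorter than the minimum length
    removed_strand: int = 0        # passing hits on both strands (incongruent)

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_and_dereplicate(
    hits: Iterable[HmmHit],
    min_length: int = DEFAULT_MIN_LENGTH,
    evalue_threshold: float = DEFAULT_EVALUE,
    read_lengths: Optional[Mapping[ReadKey, int]] = None,
) -> tuple[dict[ReadKey, HmmHit], FilterSummary]:
    """Apply the four QC rules; keep exactly one hit per (read_id, mate).

    Rules, all applied to each read's hit set:

    1. hits with E-value above ``evalue_threshold`` are dropped;
    2. reads shorter than ``min_length`` are dropped (length from
       ``read_lengths`` when supplied, else the hit's recorded read length);
    3. a read with passing hits on *both* strands is incongruent and dropped;
    4. among the surviving hits of a read, exactly one is kept: lowest
       E-value, ties broken by higher bit score, then bacteria over archaea,
       then smaller model start.

    The surviving set is independent of the order the rules are stated in.
    Returns the per-read winning hit plus a removal-reason summary.
    """
    by_read: dict[ReadKey, list[HmmHit]] = {}
    for h in hits:
        by_read.setdefault((h.read_id, h.mate), []).append(h)

    summary = FilterSummary(n_reads_in=len(by_read))
    kept: dict[ReadKey, HmmHit] = {}
    for key, read_hits in by_read.items():
        passing = [h for h in read_hits if h.evalue <= evalue_threshold]
        if not passing:
            summary.removed_evalue += 1
            continue
        length = read_lengths[key] if read_lengths is not None \
            else max(h.read_length for h in passing)
        if length < min_length:
            summary.removed_short += 1
            continue
        if len({h.strand for h in passing}) > 1:
            summary.removed_strand += 1
            continue
        kept[key] = min(passing, key=_hit_rank)
    summary.n_kept = len(kept)
    return kept, summary


def _hit_rank(h: HmmHit) -> tuple:
    # lowest E-value; then highest bit score; then bacteria first; then leftmost
    return (h.evalue, -h.bit_score, h.model_id != "bacteria_16S", h.model_from)


# ---------------------------------------------------------------------------
# Orientation and header annotation

def orient_and_annotate(read: SequenceRead, hit: HmmHit) -> RibosomalRead:
    """Orient a read model-forward and attach its model position.

    Minus-strand reads are reverse-complemented so every output sequence runs
    in the 16S model's direction.
    """
    if (read.read_id, read.mate) != (hit.read_id, hit.mate):
        raise ValueError(
            f"read {read.key!r} does not match hit {(hit.read_id, hit.mate)!r}")
    seq = read.sequence if hit.strand == "+" else reverse_complement(read.sequence)
    return RibosomalRead(
        read_id=read.read_id, mate=read.mate, oriented_sequence=seq,
        model_id=hit.model_id, model_from=hit.model_from, model_to=hit.model_to,
        evalue=hit.evalue,
    )


def format_header(r: RibosomalRead) -> str:
    """Serialize a positioned read's annotation into its FASTA header."""
    return f"{r.read_id}|{r.mate}|{r.model_id}|{r.model_from}-{r.model_to}|" \
           f"{format(r.evalue, '.17g')}"


def parse_header(header: str, sequence: str) -> RibosomalRead:
    """Inverse of :func:`format_header`."""
    parts = header.rsplit("|", 4)
    if len(parts) != 5:
        raise ValueError(f"unparseable annotated header {header!r}")
    read_id, mate, model_id, span, evalue = parts
    mfrom, mto = span.split("-")
    return RibosomalRead(
        read_id=read_id, mate=mate, oriented_sequence=sequence,  # type: ignore[arg-type]
        model_id=model_id, model_from=int(mfrom), model_to=int(mto),
        evalue=float(evalue),
    )


def write_ribo_fasta(reads: Iterable[RibosomalRead], path: str | os.PathLike) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{format_header(r)}\n{r.oriented_sequence}\n")
            n += 1
    return n


def read_ribo_fasta(path: str | os.PathLike) -> list[RibosomalRead]:
    reads = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    reads.append(parse_header(header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
        if header is not None:
            reads.append(parse_header(header, "".join(chunks)))
    return reads


# ---------------------------------------------------------------------------
# Coverage

@dataclass
class CoverageProfile:
    """Per-position read depth along the 16S model (index 0 = position 1)."""

    depth: np.ndarray
    model_id: str = "bacteria_16S"

    @property
    def model_length(self) -> int:
        return len(self.depth)


def coverage(ribo_reads: Iterable[RibosomalRead],
             model_length: int = DEFAULT_MODEL_LENGTH,
             model_id: str = "bacteria_16S") -> CoverageProfile:
    """Depth at model position p = number of reads whose interval contains p.

    Computed with a difference array, so ``sum(depth)`` equals the summed
    interval lengths exactly.
    """
    diff = np.zeros(model_length + 1, dtype=np.int64)
    for r in ribo_reads:
        check_interval(r.model_from, r.model_to, model_length)
        diff[r.model_from - 1] += 1
        diff[r.model_to] -= 1
    return CoverageProfile(depth=np.cumsum(diff[:-1]), model_id=model_id)


def write_coverage(profile: CoverageProfile, path: str | os.PathLike) -> None:
    """Two-column TSV: 1-based position, depth."""
    with open(path, "w") as fh:
        fh.write("position\tdepth\n")
        for pos, d in enumerate(profile.depth, start=1):
            fh.write(f"{pos}\t{int(d)}\n")


def plot_coverage(profile: CoverageProfile, path: str | os.PathLike,
                  regions: Optional[Sequence] = None) -> None:
    """Coverage trace along the gene, variable regions shaded and labelled."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    x = np.arange(1, profile.model_length + 1)
    ax.fill_between(x, profile.depth, step="mid", color="steelblue", alpha=0.8)
    if regions:
        top = ax.secondary_xaxis("top")
        ticks, labels = [], []
        for reg in regions:
            ax.axvspan(reg.start, reg.end, color="0.85", zorder=0)
            ticks.append((reg.start + reg.end) / 2)
            labels.append(reg.name)
        top.set_xticks(ticks)
        top.set_xticklabels(labels)
    ax.set_xlabel("position on 16S model (bp)")
    ax.set_ylabel("read depth")
    ax.set_xlim(1, profile.model_length)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_summary(summary: FilterSummary, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        for k, v in summary.as_dict().items():
            fh.write(f"{k}\t{v}\n")
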