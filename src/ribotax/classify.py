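"""Naive Bayesian taxonomic classification with bootstrap confidence.

An in-package implementation of the classical word-based (RDP-style)
classifier: genera are modelled by the distribution of their 8-mers with
pseudo-counted priors, a read's genus is the maximum of summed word
log-likelihoods, and confidence at each rank is the fraction of bootstrap
re-classifications (subsampled word sets) whose lineage passes through the
point call's taxon at that rank.

Training formulas (N sequences total, n(w) containing word w, M(G)
sequences in genus G, m(w,G) of them containing w):

    prior       P(w)   = (n(w) + 0.5) / (N + 1)
    conditional P(w|G) = (m(w,G) + P(w)) / (M(G) + 1)

Both are strictly positive for every word, so unseen words are handled
without special cases. Only genus-rank conditionals are modelled; calls at
higher ranks follow the genus lineage, exactly as fixed-rank output does.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import Lineage, MATES, Mate, RANKS

DEFAULT_WORD_SIZE = 8
DEFAULT_BOOTSTRAP = 100

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ReferenceDB:
    """Training references: sequences plus complete domain-to-genus lineages."""

    sequences: dict[str, str]
    lineages: dict[str, Lineage]
    k: int = DEFAULT_WORD_SIZE

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference database is empty")
        for seq_id in self.sequences:
            lin = self.lineages.get(seq_id)
            if lin is None:
                raise ValueError(f"sequence {seq_id!r} has no lineage")
            if not lin.is_complete():
                raise ValueError(f"sequence {seq_id!r}: lineage incomplete "
                                 f"(must reach genus): {lin.names!r}")


def sequence_words(sequence: str, k: int) -> np.ndarray:
    """Distinct k-words of a sequence as sorted 2-bit codes; words with any
    non-ACGT base (e.g. N) are excluded and can therefore never match."""
    seq = sequence.upper()
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.array([_BASE_CODE.get(c, -1) for c in seq], dtype=np.int64)
    valid = codes >= 0
    words = set()
    for i in range(n):
        window = codes[i:i + k]
        if valid[i:i + k].all():
            code = 0
            for c in window:
                code = (code << 2) | int(c)
            words.add(code)
    return np.array(sorted(words), dtype=np.int64)


@dataclass
class ClassifierModel:
    """Trained word model: per-genus log conditionals plus training counts."""

    k: int
    genera: list[str]                      # sorted; index aligns with rows
    genus_lineages: dict[str, Lineage]
    log_cond: np.ndarray                   # shape (n_genera, 4**k), log P(w|G)
    log_prior: np.ndarray                  # shape (4**k,), log P(w)
    n_sequences: int                       # N
    word_counts: np.ndarray                # n(w)
    genus_sizes: np.ndarray                # M(G), aligned with `genera`

    def genus_index(self, genus: str) -> int:
        return self.genera.index(genus)


@dataclass
class Classification:
    """Per-rank taxon calls with bootstrap confidence in [0, 1].

    Confidence is non-increasing from domain to genus because a bootstrap
    winner agreeing at some rank necessarily agrees at every rank above it.
    """

    read_id: str
    mate: Mate
    lineage: Optional[Lineage]                  # None when unclassifiable
    confidences: tuple[float, ...] = ()         # aligned with lineage.names

    def __post_init__(self) -> None:
        if self.mate not in MATES:
            raise ValueError(f"invalid mate {self.mate!r}")
        if self.lineage is not None:
            if len(self.confidences) != self.lineage.depth:
                raise ValueError("one confidence per named rank required")
            if any(not (0.0 <= c <= 1.0) for c in self.confidences):
                raise ValueError("confidences must lie in [0, 1]")

    @property
    def is_classified(self) -> bool:
        return self.lineage is not None

    @property
    def key(self) -> tuple[str, str]:
        return (self.read_id, self.mate)

    def confidence_at(self, rank: str) -> Optional[float]:
        i = RANKS.index(rank)
        if self.lineage is None or i >= len(self.confidences):
            return None
        return self.confidences[i]

    def taxon_at(self, rank: str) -> Optional[str]:
        return None if self.lineage is None else self.lineage.name_at(rank)


def train(reference: ReferenceDB) -> ClassifierModel:
    """Estimate per-genus word log-likelihoods from the reference set."""
    k = reference.k
    n_words = 4 ** k
    seq_ids = list(reference.sequences)
    genera = sorted({reference.lineages[s].genus for s in seq_ids})
    genus_row = {g: i for i, g in enumerate(genera)}
    genus_lineages: dict[str, Lineage] = {}
    for s in seq_ids:
        lin = reference.lineages[s]
        prev = genus_lineages.setdefault(lin.genus, lin)
        if prev.names != lin.names:
            raise ValueError(f"genus {lin.genus!r} has conflicting lineages")

    word_counts = np.zeros(n_words, dtype=np.int64)          # n(w)
    genus_word = np.zeros((len(genera), n_words), dtype=np.int64)  # m(w,G)
    genus_sizes = np.zeros(len(genera), dtype=np.int64)      # M(G)
    for s in seq_ids:
        words = sequence_words(reference.sequences[s], k)
        row = genus_row[reference.lineages[s].genus]
        word_counts[words] += 1
        genus_word[row, words] += 1
        genus_sizes[row] += 1

    n_seq = len(seq_ids)
    prior = (word_counts + 0.5) / (n_seq + 1)
    cond = (genus_word + prior[None, :]) / (genus_sizes[:, None] + 1)
    return ClassifierModel(
        k=k, genera=genera, genus_lineages=genus_lineages,
        log_cond=np.log(cond), log_prior=np.log(prior),
        n_sequences=n_seq, word_counts=word_counts, genus_sizes=genus_sizes,
    )


def classify_read(
    sequence: str,
    model: ClassifierModel,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    rng: Optional[np.random.Generator] = None,
    read_id: str = "",
    mate: Mate = "single",
) -> Classification:
    """Classify one read: point call by summed log-likelihood over its
    distinct words, confidence by bootstrap over word subsamples.

    Each bootstrap replicate draws ``max(1, |W| // 8)`` words from the read's
    distinct-word set W with replacement and records the winning genus; the
    confidence at a rank is the fraction of replicates whose winner's lineage
    passes through the point call's taxon at that rank. A read with no valid
    word (|W| = 0) is returned as unclassifiable.
    """
    if rng is None:
        rng = np.random.default_rng()
    words = sequence_words(sequence, model.k)
    if len(words) == 0:
        return Classification(read_id=read_id, mate=mate, lineage=None)

    scores = model.log_cond[:, words].sum(axis=1)
    best = _argmax_lexicographic(scores, model.genera)
    lineage = model.genus_lineages[model.genera[best]]

    n_draw = max(1, len(words) // 8)
    agree = np.zeros(lineage.depth, dtype=np.int64)
    sub = model.log_cond[:, words]          # (n_genera, |W|)
    draws = rng.integers(0, len(words), size=(n_bootstrap, n_draw))
    for b in range(n_bootstrap):
        boot_scores = sub[:, draws[b]].sum(axis=1)
        winner = _argmax_lexicographic(boot_scores, model.genera)
        win_lin = model.genus_lineages[model.genera[winner]].names
        for r in range(lineage.depth):
            if win_lin[r] == lineage.names[r]:
                agree[r] += 1
            else:
                break   # lineages are trees: disagreement persists downward
    conf = tuple(float(a) / n_bootstrap for a in agree)
    return Classification(read_id=read_id, mate=mate, lineage=lineage,
                          confidences=conf)


def _argmax_lexicographic(scores: np.ndarray, genera: Sequence[str]) -> int:
    """Argmax with exact-score ties broken by lexicographic genus name."""
    best = np.flatnonzero(scores == scores.max())
    if len(best) == 1:
        return int(best[0])
    return int(min(best, key=lambda i: genera[i]))


def classify_reads(
    reads: Iterable[tuple[str, Mate, str]],
    model: ClassifierModel,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: Optional[int] = None,
) -> list[Classification]:
    """Classify (read_id, mate, sequence) triples reproducibly under a seed."""
    rng = np.random.default_rng(seed)
    return [classify_read(seq, model, n_bootstrap=n_bootstrap, rng=rng,
                          read_id=rid, mate=m)
            for rid, m, seq in reads]


# ---------------------------------------------------------------------------
# Fixed-rank TSV interoperability
#
# Dialect: name, then for each called rank the triple (taxon, rank-label,
# confidence), tab-separated — the fixed-rank format emitted by the standard
# command-line classifier, so external output can be dropped into the
# pipeline in place of the internal classifier.

def write_fixrank(classifications: Iterable[Classification],
                  path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in classifications:
            name = c.read_id if c.mate == "single" else f"{c.read_id}/{c.mate}"
            fields = [name]
            if c.lineage is not None:
                for rank, taxon, conf in zip(RANKS, c.lineage.names, c.confidences):
                    fields += [taxon, rank, format(conf, ".17g")]
            fh.write("\t".join(fields) + "\n")


def parse_fixrank(path: str | os.PathLike) -> list[Classification]:
    """Parse fixed-rank TSV. Confidences must parse into [0, 1]; rows whose
    confidences increase with depth are tolerated but flagged on stderr."""
    import sys

    out = []
    with open(path) as fh:
        for lno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[0]
            rest = fields[1:]
            if len(rest) % 3 != 0:
                raise ValueError(f"{path}:{lno}: rank fields not in triples")
            names, confs = [], []
            try:
                for i in range(0, len(rest), 3):
                    taxon, rank_label, conf = rest[i:i + 3]
                    if rank_label != RANKS[len(names)]:
                        raise ValueError(
                            f"rank {rank_label!r} out of order (expected "
                            f"{RANKS[len(names)]!r})")
                    c = float(conf)
                    if not (0.0 <= c <= 1.0):
                        raise ValueError(f"confidence {c} outside [0,1]")
                    names.append(taxon)
                    confs.append(c)
            except ValueError as exc:
                raise ValueError(f"{path}:{lno}: {exc}") from exc
            if any(b > a for a, b in zip(confs, confs[1:])):
                print(f"{path}:{lno}: warning: confidence not rank-monotone",
                      file=sys.stderr)
            read_id, mate = name, "single"
            if len(name) > 2 and name[-2] == "/" and name[-1] in ("1", "2"):
                read_id, mate = name[:-2], name[-1]
            out.append(Classification(
                read_id=read_id, mate=mate,  # type: ignore[arg-type]
                lineage=Lineage(tuple(names)) if names else None,
                confidences=tuple(confs),
            ))
    return out
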