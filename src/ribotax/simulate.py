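"""Synthetic-data generators with per-read truth labels.

Three generators reproduce the evaluation protocols the pipeline is tested
under:

* :func:`build_reference` — a 16S-like gene family: a conserved random
  backbone with nine hypervariable windows mutated at an elevated rate,
  organised into a genus/species taxonomy with complete lineages;
* :func:`extract_ribo_reads` — pure-ribosomal read sets ("random": one read
  per species; "curated": a fixed number of reads per genus) with known
  source intervals, for recruitment and classification accuracy checks;
* :func:`simulate_metagenome` — paired-end shotgun metagenomes: background
  genomes with one (configurable) embedded 16S-like gene each, normal insert
  sizes, a position-dependent substitution error ramp, and a truth record
  for every read.

Everything is driven by a single integer seed and is bit-reproducible.
A read's ribosomal truth label is defined as ≥ 50% of its bases falling
inside an embedded gene, which makes recruitment sensitivity well-posed for
gene-edge-spanning reads.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from pyhmmer import easel, plan7

from .core import Lineage, RANKS, SequenceRead, write_lineages
from .classify import ReferenceDB
from .profile import RegionSpec, default_regions
from .qc import ReadKey

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_READ_LENGTH = 100
DEFAULT_INSERT_MEAN = 450
DEFAULT_INSERT_SD = 50
DEFAULT_ERROR_START = 0.001   # substitution rate at the 5' end of a read
DEFAULT_ERROR_END = 0.01      # ... rising linearly to this at the 3' end


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


@dataclass
class SyntheticReference:
    """A gapless, model-length 16S-like gene family with full taxonomy."""

    sequences: dict[str, str]            # species_id -> gene string
    lineages: dict[str, Lineage]         # species_id -> complete lineage
    model_length: int
    regions: list[RegionSpec]
    seed: int

    @property
    def species_ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def genera(self) -> list[str]:
        return sorted({lin.genus for lin in self.lineages.values()})

    def species_of_genus(self, genus: str) -> list[str]:
        return [s for s, lin in self.lineages.items() if lin.genus == genus]

    def to_reference_db(self, k: int = 8) -> ReferenceDB:
        return ReferenceDB(sequences=dict(self.sequences),
                           lineages=dict(self.lineages), k=k)


def _genus_lineage(index: int, domain: str) -> Lineage:
    """Deterministic taxonomy tree: 2 genera/family, 2 families/order, ..."""
    return Lineage((
        domain,
        f"{domain[:3]}Phy{index // 16 + 1:02d}",
        f"{domain[:3]}Cls{index // 8 + 1:02d}",
        f"{domain[:3]}Ord{index // 4 + 1:02d}",
        f"{domain[:3]}Fam{index // 2 + 1:02d}",
        f"{domain[:3]}Gen{index + 1:03d}",
    ))


def _mutate(seq: np.ndarray, rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(len(seq)) < rates
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    out[mask] = (out[mask] + shifts) % 4
    return out


def build_reference(
    n_genera: int = 20,
    species_per_genus: int = 5,
    inter_genus_div: float = 0.15,
    intra_genus_div: float = 0.02,
    region_rate_multiplier: float = 3.0,
    model_length: int = 1542,
    regions: Optional[Sequence[RegionSpec]] = None,
    domain: str = "Bacteria",
    seed: int = 0,
) -> SyntheticReference:
    """Simulate a 16S-like gene family.

    Each genus ancestor is mutated from a common backbone at
    ``inter_genus_div`` per site (multiplied by ``region_rate_multiplier``
    inside the hypervariable windows, capped at 0.75); each species is then
    mutated from its genus ancestor at ``intra_genus_div`` per site. All
    sequences are gapless and of identical length, so the family doubles as
    the training alignment for the profile HMM.
    """
    if not (0 < inter_genus_div < 1) or not (0 <= intra_genus_div < 1):
        raise ValueError("divergences must lie in (0, 1)")
    if region_rate_multiplier < 1:
        raise ValueError("region_rate_multiplier must be ≥ 1")
    if regions is None:
        regions = [r for r in default_regions() if r.end <= model_length]
    rng = np.random.default_rng(seed)
    backbone = rng.integers(0, 4, model_length, dtype=np.uint8)

    inter_rates = np.full(model_length, inter_genus_div)
    for reg in regions:
        inter_rates[reg.start - 1:reg.end] = min(
            0.75, inter_genus_div * region_rate_multiplier)

    sequences: dict[str, str] = {}
    lineages: dict[str, Lineage] = {}
    intra_rates = np.full(model_length, intra_genus_div)
    for g in range(n_genera):
        lin = _genus_lineage(g, domain)
        ancestor = _mutate(backbone, inter_rates, rng)
        for s in range(species_per_genus):
            species_id = f"{lin.genus}_sp{s + 1:02d}"
            sequences[species_id] = _decode(_mutate(ancestor, intra_rates, rng))
            lineages[species_id] = lin
    return SyntheticReference(sequences=sequences, lineages=lineages,
                              model_length=model_length, regions=list(regions),
                              seed=seed)


def write_reference(reference: SyntheticReference, fasta_path: str | os.PathLike,
                    lineage_path: str | os.PathLike) -> None:
    with open(fasta_path, "w") as fh:
        for sid, seq in reference.sequences.items():
            fh.write(f">{sid}\n{seq}\n")
    write_lineages(reference.lineages, lineage_path)


def write_alignment(reference: SyntheticReference, path: str | os.PathLike,
                    format: str = "stockholm") -> None:
    """Write the (trivially aligned, gapless) family as an MSA file."""
    msa = _reference_msa(reference)
    with open(path, "wb") as fh:
        msa.write(fh, format=format)


def _reference_msa(reference: SyntheticReference) -> easel.TextMSA:
    return easel.TextMSA(
        name="synthetic_16S",
        sequences=[easel.TextSequence(name=sid, sequence=seq)
                   for sid, seq in reference.sequences.items()],
    )


def build_hmm(reference: SyntheticReference,
              model_id: str = "bacteria_16S") -> plan7.HMM:
    """Build a nucleotide profile HMM from the synthetic family alignment.

    Because the alignment is gapless, every column becomes a match state and
    the model length equals the reference gene length.
    """
    alphabet = easel.Alphabet.dna()
    msa = _reference_msa(reference).digitize(alphabet)
    builder = plan7.Builder(alphabet)
    hmm, _, _ = builder.build_msa(msa, plan7.Background(alphabet))
    hmm.name = model_id
    assert hmm.M == reference.model_length
    return hmm


def write_hmm(hmm: plan7.HMM, path: str | os.PathLike) -> None:
    with open(path, "wb") as fh:
        hmm.write(fh)


# ---------------------------------------------------------------------------
# Truth records

@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read (one mate)."""

    read_id: str
    mate: str
    is_ribosomal: bool
    lineage: Optional[Lineage] = None        # source organism's lineage
    model_from: Optional[int] = None         # gene-coordinate overlap, if ribosomal
    model_to: Optional[int] = None
    source_id: str = ""                      # source species or genome id


SimTruth = dict  # (read_id, mate) -> TruthRecord


def write_truth(truth: SimTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tis_ribosomal\tgenus\tmodel_from\tmodel_to\tsource\n")
        for (rid, mate), t in truth.items():
            genus = t.lineage.genus if t.lineage is not None else ""
            fh.write(f"{rid}\t{mate}\t{int(t.is_ribosomal)}\t{genus}\t"
                     f"{t.model_from or ''}\t{t.model_to or ''}\t{t.source_id}\n")


# ---------------------------------------------------------------------------
# Ribosomal read sets

def extract_ribo_reads(
    reference: SyntheticReference,
    mode: str = "random",
    read_length: int = DEFAULT_READ_LENGTH,
    reads_per_genus: int = 100,
    seed: int = 0,
) -> tuple[list[SequenceRead], SimTruth]:
    """Extract pure 16S reads from the reference genes.

    ``random`` mode emits exactly one read per species (an exhaustive sweep
    of the taxonomy); ``curated`` mode emits ``reads_per_genus`` reads per
    genus from randomly chosen member species (a taxonomically balanced
    set). Every read is an exact substring of its source gene, with the
    source interval recorded in model coordinates.
    """
    if read_length > reference.model_length:
        raise ValueError("read_length exceeds the gene length")
    if mode not in ("random", "curated"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    reads: list[SequenceRead] = []
    truth: SimTruth = {}

    def emit(species_id: str, serial: int) -> None:
        gene = reference.sequences[species_id]
        start = int(rng.integers(1, reference.model_length - read_length + 2))
        rid = f"{species_id}_r{serial}"
        reads.append(SequenceRead(read_id=rid, mate="single",
                                  sequence=gene[start - 1:start + read_length - 1]))
        truth[(rid, "single")] = TruthRecord(
            read_id=rid, mate="single", is_ribosomal=True,
            lineage=reference.lineages[species_id],
            model_from=start, model_to=start + read_length - 1,
            source_id=species_id)

    if mode == "random":
        for species_id in reference.species_ids:
            emit(species_id, 0)
    else:
        for genus in reference.genera:
            members = reference.species_of_genus(genus)
            picks = rng.integers(0, len(members), size=reads_per_genus)
            for serial, p in enumerate(picks):
                emit(members[int(p)], serial)
    return reads, truth


# ---------------------------------------------------------------------------
# Shotgun metagenome simulation

def simulate_metagenome(
    reference: SyntheticReference,
    n_genomes: int = 20,
    genome_length: int = 100_000,
    n_pairs: int = 50_000,
    read_length: int = DEFAULT_READ_LENGTH,
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    error_rate_start: float = DEFAULT_ERROR_START,
    error_rate_end: float = DEFAULT_ERROR_END,
    operons_per_genome: int = 1,
    seed: int = 0,
) -> tuple[list[SequenceRead], list[SequenceRead], SimTruth, dict]:
    """Simulate a paired-end shotgun metagenome with per-read truth labels.

    Each synthetic genome is i.i.d. background sequence with
    ``operons_per_genome`` embedded 16S-like genes drawn from the reference.
    Fragments are placed uniformly; mate 1 is the forward start of the
    insert, mate 2 the reverse complement of its end. Substitution errors
    are applied per base with a rate rising linearly from
    ``error_rate_start`` at the 5' end to ``error_rate_end`` at the 3' end
    (an Illumina-like quality decay). A mate is labelled ribosomal when at
    least half of its bases fall inside an embedded gene.

    Returns (mate-1 reads, mate-2 reads, truth, info); ``info`` includes the
    analytic expectation of the ribosomal read fraction.
    """
    gene_len = reference.model_length
    if genome_length < gene_len * operons_per_genome * 2:
        raise ValueError("genome_length too small for the embedded genes")
    insert_mean = float(insert_mean)
    if insert_mean < read_length:
        raise ValueError("insert size must be at least the read length")
    rng = np.random.default_rng(seed)

    species_ids = reference.species_ids
    picks = rng.integers(0, len(species_ids), size=n_genomes)
    genomes: list[np.ndarray] = []
    gene_spans: list[list[tuple[int, int]]] = []   # 0-based half-open, per genome
    genome_species: list[str] = []
    for gi in range(n_genomes):
        sid = species_ids[int(picks[gi])]
        genome_species.append(sid)
        genome = rng.integers(0, 4, genome_length, dtype=np.uint8)
        gene = np.frombuffer(reference.sequences[sid].encode(), dtype=np.uint8)
        gene_codes = np.zeros(gene_len, dtype=np.uint8)
        for code, base in enumerate(b"ACGT"):
            gene_codes[gene == base] = code
        spans: list[tuple[int, int]] = []
        for _ in range(operons_per_genome):
            for _attempt in range(1000):
                pos = int(rng.integers(0, genome_length - gene_len + 1))
                if all(pos + gene_len <= a or pos >= b for a, b in spans):
                    break
            else:
                raise RuntimeError("could not place non-overlapping operons")
            genome[pos:pos + gene_len] = gene_codes
            spans.append((pos, pos + gene_len))
        genomes.append(genome)
        gene_spans.append(sorted(spans))

    # fragment placement (vectorised)
    genome_idx = rng.integers(0, n_genomes, size=n_pairs)
    inserts = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(np.int64)
    inserts = np.clip(inserts, read_length, genome_length)
    starts = np.floor(rng.random(n_pairs) * (genome_length - inserts + 1)).astype(np.int64)
    r1_start = starts
    r2_start = starts + inserts - read_length

    # per-base error ramp along the read
    if read_length > 1:
        ramp = np.linspace(error_rate_start, error_rate_end, read_length)
    else:
        ramp = np.array([error_rate_start])

    offsets = np.arange(read_length)
    half = (read_length + 1) // 2

    def make_reads(mate_starts: np.ndarray, revcomp: bool) -> np.ndarray:
        mat = np.empty((n_pairs, read_length), dtype=np.uint8)
        for gi in range(n_genomes):
            sel = np.flatnonzero(genome_idx == gi)
            if len(sel):
                mat[sel] = genomes[gi][mate_starts[sel, None] + offsets[None, :]]
        if revcomp:
            mat = (3 - mat)[:, ::-1]
        err = rng.random((n_pairs, read_length)) < ramp[None, :]
        shift = rng.integers(1, 4, size=(n_pairs, read_length), dtype=np.uint8)
        mat = np.where(err, (mat + shift) % 4, mat)
        return mat

    r1_mat = make_reads(r1_start, revcomp=False)
    r2_mat = make_reads(r2_start, revcomp=True)

    reads1: list[SequenceRead] = []
    reads2: list[SequenceRead] = []
    truth: SimTruth = {}
    n_ribo = 0
    for i in range(n_pairs):
        rid = f"sim{i:06d}"
        gi = int(genome_idx[i])
        lin = reference.lineages[genome_species[gi]]
        for mate, mstart, mat in (("1", int(r1_start[i]), r1_mat),
                                  ("2", int(r2_start[i]), r2_mat)):
            seq = _decode(mat[i])
            read = SequenceRead(read_id=rid, mate=mate, sequence=seq)  # type: ignore[arg-type]
            (reads1 if mate == "1" else reads2).append(read)
            m_from = m_to = None
            is_ribo = False
            for a, b in gene_spans[gi]:
                ov_lo = max(mstart, a)
                ov_hi = min(mstart + read_length, b)
                if ov_hi - ov_lo >= half:
                    is_ribo = True
                    m_from = ov_lo - a + 1
                    m_to = ov_hi - a
                    break
            n_ribo += is_ribo
            truth[(rid, mate)] = TruthRecord(
                read_id=rid, mate=mate, is_ribosomal=is_ribo,
                lineage=lin if is_ribo else None,
                model_from=m_from, model_to=m_to,
                source_id=f"genome{gi:02d}:{genome_species[gi]}")

    favourable = gene_len + read_length - 2 * half + 1
    info = {
        "n_reads": 2 * n_pairs,
        "n_ribosomal": n_ribo,
        "observed_ribo_fraction": n_ribo / (2 * n_pairs),
        "expected_ribo_fraction":
            operons_per_genome * favourable / (genome_length - read_length + 1),
    }
    return reads1, reads2, truth, info


# ---------------------------------------------------------------------------
# Recruitment scoring

def score_recruitment(truth: SimTruth, recruited: Iterable[ReadKey]) -> dict:
    """Confusion-matrix scores of recruitment against simulation truth.

    sensitivity = TP / (TP + FN) over truly ribosomal reads;
    specificity = TN / (TN + FP) over truly non-ribosomal reads;
    per_genus_recall = recall restricted to each source genus.
    """
    recruited = set(recruited)
    unknown = recruited - set(truth)
    if unknown:
        raise ValueError(f"unknown read ids in recruited set: {sorted(unknown)[:5]}")
    tp = fn = fp = tn = 0
    genus_tot: dict[str, int] = {}
    genus_hit: dict[str, int] = {}
    for key, t in truth.items():
        hit = key in recruited
        if t.is_ribosomal:
            tp += hit
            fn += not hit
            g = t.lineage.genus if t.lineage is not None else "?"
            genus_tot[g] = genus_tot.get(g, 0) + 1
            genus_hit[g] = genus_hit.get(g, 0) + hit
        else:
            fp += hit
            tn += not hit
    return {
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "per_genus_recall": {g: genus_hit[g] / genus_tot[g] for g in sorted(genus_tot)},
    }
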