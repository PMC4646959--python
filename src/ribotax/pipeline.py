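"""End-to-end pipeline: recruit -> QC/position -> classify -> profile.

`RunConfig` collects every knob with the pipeline's default thresholds
(E-value 1e-5, minimum read length 60 bp, bootstrap confidence 0.8, region
tolerance 0.2) and round-trips losslessly through a flat key=value file;
`run_pipeline` chains the four stages on files, attributing every read lost
at any stage to a reason in the run summary.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

from . import classify as _classify
from . import profile as _profile
from . import qc as _qc
from . import recruit as _recruit
from .core import read_lineages, read_sequences

log = logging.getLogger("ribotax")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    reads1: str = ""
    reads2: str = ""                 # empty -> single-end
    reads_format: str = "fastq"
    hmm_bacteria: str = ""
    hmm_archaea: str = ""            # optional
    ref_fasta: str = ""
    ref_lineages: str = ""
    outdir: str = "ribotax_out"
    evalue: float = 1e-5
    min_length: int = 60
    confidence: float = 0.8
    min_percent: float = 0.0
    region: str = ""                 # e.g. "V3-V5"; empty -> no region filter
    tolerance: float = 0.2
    bootstrap: int = 100
    seed: int = 0
    engine: str = "pyhmmer"          # or "hmmsearch"

    def validate(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if self.min_length < 1:
            raise ValueError("min_length must be ≥ 1")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        if self.min_percent < 0 or self.min_percent > 100:
            raise ValueError("min_percent must lie in [0, 100]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be ≥ 0")
        if self.bootstrap < 1:
            raise ValueError("bootstrap must be ≥ 1")
        if self.reads_format not in ("fasta", "fastq"):
            raise ValueError(f"unknown reads_format {self.reads_format!r}")
        if self.engine not in ("pyhmmer", "hmmsearch"):
            raise ValueError(f"unknown engine {self.engine!r}")

    # flat key=value config file, CLI overrides take precedence over it
    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        kwargs: dict = {}
        casts = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for lno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lno}: expected key=value")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in casts:
                    raise ValueError(f"{path}:{lno}: unknown key {key!r}")
                kwargs[key] = type(getattr(defaults, key))(value.strip())
        kwargs.update(overrides)
        return cls(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all four stages in order; returns the run summary.

    The summary accounts for every read: at each stage,
    reads in = reads kept + sum of per-reason removals. Identical config and
    seed give byte-identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "outputs": {}}
    t_all = time.time()

    def _load_reads():
        reads = list(read_sequences(config.reads1, config.reads_format,
                                    mate="1" if config.reads2 else "single"))
        if config.reads2:
            reads += list(read_sequences(config.reads2, config.reads_format, mate="2"))
        return reads

    try:
        stage = "recruit"
        t0 = time.time()
        reads = _load_reads()
        models = {"bacteria_16S": config.hmm_bacteria}
        if config.hmm_archaea:
            models["archaea_16S"] = config.hmm_archaea
        engine = _recruit.PyhmmerEngine() if config.engine == "pyhmmer" \
            else _recruit.HmmsearchEngine()
        hits = _recruit.search_reads(reads, models, config.evalue, engine=engine)
        hits_path = outdir / "hits.tsv"
        _recruit.write_hit_table(hits, hits_path)
        summary["stages"]["recruit"] = {
            "reads_in": len(reads), "hits": len(hits),
            "reads_with_hits": len({(h.read_id, h.mate) for h in hits}),
            "seconds": round(time.time() - t0, 2)}
        summary["outputs"]["hits"] = str(hits_path)
        log.info("recruit: %d reads -> %d hits", len(reads), len(hits))

        stage = "trap"
        t0 = time.time()
        read_lengths = {r.key: len(r) for r in reads}
        kept, filt = _qc.filter_and_dereplicate(
            hits, min_length=config.min_length, evalue_threshold=config.evalue,
            read_lengths=read_lengths)
        by_key = {r.key: r for r in reads}
        ribo = [_qc.orient_and_annotate(by_key[k], h) for k, h in kept.items()]
        ribo_path = outdir / "ribo.fasta"
        _qc.write_ribo_fasta(ribo, ribo_path)
        cov = _qc.coverage(ribo)
        cov_path = outdir / "coverage.tsv"
        _qc.write_coverage(cov, cov_path)
        summary["stages"]["trap"] = {**filt.as_dict(),
                                     "seconds": round(time.time() - t0, 2)}
        summary["outputs"].update(ribo=str(ribo_path), coverage=str(cov_path))
        log.info("trap: kept %d / %d recruited reads", filt.n_kept, filt.n_reads_in)

        stage = "classify"
        t0 = time.time()
        refdb = _classify.ReferenceDB(
            sequences={r.read_id: r.sequence
                       for r in read_sequences(config.ref_fasta, "fasta")},
            lineages=read_lineages(config.ref_lineages))
        model = _classify.train(refdb)
        cls = _classify.classify_reads(
            [(r.read_id, r.mate, r.oriented_sequence) for r in ribo],
            model, n_bootstrap=config.bootstrap, seed=config.seed)
        cls_path = outdir / "classifications.tsv"
        _classify.write_fixrank(cls, cls_path)
        n_uncls = sum(not c.is_classified for c in cls)
        summary["stages"]["classify"] = {
            "reads_in": len(ribo), "classified": len(cls) - n_uncls,
            "unclassifiable": n_uncls, "seconds": round(time.time() - t0, 2)}
        summary["outputs"]["classifications"] = str(cls_path)
        log.info("classify: %d reads, %d unclassifiable", len(cls), n_uncls)

        stage = "map"
        t0 = time.time()
        selected = ribo
        if config.region:
            region = _profile.parse_region_expr(config.region, config.tolerance)
            selected = _profile.select_by_region(ribo, region)
        weighted = _profile.assign_weights(selected, {c.key: c for c in cls})
        n_rows = {}
        for rank in _classify.RANKS:
            table = _profile.abundance(weighted, rank,
                                       conf_threshold=config.confidence,
                                       min_percent=config.min_percent)
            path = outdir / f"abundance_{rank}.tsv"
            _profile.write_abundance(table, path)
            summary["outputs"][f"abundance_{rank}"] = str(path)
            n_rows[rank] = len(table.rows)
        summary["stages"]["map"] = {
            "reads_in": len(ribo), "selected": len(selected),
            "removed_outside_region": len(ribo) - len(selected),
            "taxa_per_rank": n_rows, "seconds": round(time.time() - t0, 2)}
        log.info("map: %d / %d reads in target region", len(selected), len(ribo))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary["seconds"] = round(time.time() - t_all, 2)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    summary["outputs"]["summary"] = str(outdir / "summary.json")
    return summary
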