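"""Region targeting, paired-end weighting and rank-abundance profiling.

The last pipeline stage: select recruited reads by their position on the
16S model (a read belongs to a region when it contains, or is contained in,
the tolerance-expanded region window), weight them so a fully recruited
pair never counts more than one observation, and accumulate per-rank
abundance tables and confidence profiles.

The nine hypervariable windows V1–V9 ship as an editable data file in
*E. coli* 16S numbering following the standard literature convention; they
are configuration, not ground truth, and users may override them.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import Classification
from .core import DEFAULT_MODEL_LENGTH, Mate, RANKS, check_interval
from .qc import ReadKey, RibosomalRead

DEFAULT_CONFIDENCE = 0.8
DEFAULT_TOLERANCE = 0.2


@dataclass(frozen=True)
class RegionSpec:
    """A named window on the 16S model with a symmetric tolerance.

    ``tolerance`` is a fraction of the region length; the effective window is
    the region expanded on *each* side by ``floor(tolerance * length)`` and
    clipped to the model.
    """

    name: str
    start: int
    end: int
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"invalid region [{self.start},{self.end}]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be ≥ 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def expanded(self, model_length: int = DEFAULT_MODEL_LENGTH) -> tuple[int, int]:
        """Tolerance-expanded window, clipped to [1, model_length]."""
        pad = math.floor(self.tolerance * self.length)
        return (max(1, self.start - pad), min(model_length, self.end + pad))

    def with_tolerance(self, tolerance: float) -> "RegionSpec":
        return RegionSpec(self.name, self.start, self.end, tolerance)


def default_regions(tolerance: float = 0.0) -> list[RegionSpec]:
    """The nine bundled V1–V9 windows, ascending and non-overlapping."""
    text = resources.files("ribotax").joinpath("data/regions_16S.tsv").read_text()
    return _parse_region_rows(text.splitlines(), tolerance, source="<bundled>")


def read_regions(path: str | os.PathLike, tolerance: float = 0.0) -> list[RegionSpec]:
    with open(path) as fh:
        return _parse_region_rows(fh.read().splitlines(), tolerance, source=str(path))


def write_regions(regions: Iterable[RegionSpec], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\n")
        for r in regions:
            fh.write(f"{r.name}\t{r.start}\t{r.end}\n")


def _parse_region_rows(lines: Sequence[str], tolerance: float,
                       source: str) -> list[RegionSpec]:
    if not lines or lines[0].split("\t") != ["name", "start", "end"]:
        raise ValueError(f"{source}: region file needs header name/start/end")
    regions = []
    for lno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            name, start, end = line.split("\t")
            regions.append(RegionSpec(name, int(start), int(end), tolerance))
        except ValueError as exc:
            raise ValueError(f"{source}:{lno}: bad region row: {exc}") from exc
    return regions


def parse_region_expr(expr: str, tolerance: float = 0.0,
                      regions: Optional[Sequence[RegionSpec]] = None) -> RegionSpec:
    """Flexible region syntax: ``V3``, ``V3-V5`` (span), or ``520:680``."""
    if regions is None:
        regions = default_regions()
    by_name = {r.name: r for r in regions}
    expr = expr.strip()
    if ":" in expr:
        start, end = expr.split(":")
        return RegionSpec(expr, int(start), int(end), tolerance)
    if "-" in expr:
        a, b = expr.split("-")
        if a not in by_name or b not in by_name:
            raise ValueError(f"unknown region in span {expr!r}")
        return RegionSpec(expr, min(by_name[a].start, by_name[b].start),
                          max(by_name[a].end, by_name[b].end), tolerance)
    if expr not in by_name:
        raise ValueError(f"unknown region {expr!r}")
    return by_name[expr].with_tolerance(tolerance)


def select_by_region(reads: Iterable[RibosomalRead], region: RegionSpec,
                     model_length: int = DEFAULT_MODEL_LENGTH) -> list[RibosomalRead]:
    """Reads belonging to a region: read interval contains, or is contained
    in, the tolerance-expanded window. Rejection is silent, not an error."""
    lo, hi = region.expanded(model_length)
    check_interval(lo, hi, model_length)
    out = []
    for r in reads:
        contains = r.model_from <= lo and r.model_to >= hi
        contained = r.model_from >= lo and r.model_to <= hi
        if contains or contained:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Paired-end weighting

@dataclass
class WeightedRead:
    """A recruited read carrying its abundance weight and classification.

    Weight 1 for single-end reads and singletons (mate not recruited);
    0.5 for each mate of a fully recruited pair, so a concordant pair sums
    to exactly 1 at every shared rank. Weights are fixed at recruitment and
    never change under later region or confidence filtering.
    """

    read_id: str
    mate: Mate
    weight: float
    model_from: int
    model_to: int
    classification: Optional[Classification] = None

    def __post_init__(self) -> None:
        if self.weight not in (0.5, 1.0):
            raise ValueError(f"weight must be 0.5 or 1, got {self.weight}")

    @property
    def key(self) -> ReadKey:
        return (self.read_id, self.mate)


def assign_weights(
    ribo_reads: Iterable[RibosomalRead],
    classifications: Optional[Mapping[ReadKey, Classification]] = None,
) -> list[WeightedRead]:
    """Attach paired-end weights (and classifications, when given)."""
    reads = list(ribo_reads)
    mates_of: dict[str, set[str]] = {}
    for r in reads:
        mates_of.setdefault(r.read_id, set()).add(r.mate)
    out = []
    for r in reads:
        both = mates_of[r.read_id] >= {"1", "2"}
        cls = classifications.get(r.key) if classifications is not None else None
        out.append(WeightedRead(
            read_id=r.read_id, mate=r.mate, weight=0.5 if both else 1.0,
            model_from=r.model_from, model_to=r.model_to, classification=cls,
        ))
    return out


# ---------------------------------------------------------------------------
# Abundance tables

@dataclass
class AbundanceTable:
    """Per-rank abundance: taxon lineage path -> summed weight, count, percent.

    ``percent`` is relative to the total accepted weight at this rank;
    ``reads_pct_vs_domain`` is the rank's total accepted weight as a
    percentage of the total accepted weight at the domain rank (so the
    domain table shows 100.00 by construction).
    """

    rank: str
    rows: pd.DataFrame          # columns: taxon, lineage, weight, count, percent
    total_weight: float         # accepted weight at this rank
    domain_weight: float        # accepted weight at the domain rank

    @property
    def reads_pct_vs_domain(self) -> float:
        return 100.0 * self.total_weight / self.domain_weight \
            if self.domain_weight > 0 else 0.0


def abundance(weighted: Iterable[WeightedRead], rank: str,
              conf_threshold: float = DEFAULT_CONFIDENCE,
              min_percent: float = 0.0) -> AbundanceTable:
    """Accumulate accepted weight per taxon at one rank.

    A read is accepted at ``rank`` when it is classified there with
    confidence ≥ ``conf_threshold``; it then contributes its (immutable)
    weight to its taxon. ``min_percent`` drops rows *after* percentages are
    computed — remaining percentages are not renormalized, mirroring the
    behaviour of abundance reports with a display cutoff.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if not (0.0 <= conf_threshold <= 1.0):
        raise ValueError("conf_threshold must lie in [0, 1]")
    weighted = list(weighted)
    acc: dict[tuple[str, ...], list[float]] = {}
    total = 0.0
    for w in weighted:
        c = w.classification
        if c is None or not c.is_classified:
            continue
        conf = c.confidence_at(rank)
        if conf is None or conf < conf_threshold:
            continue
        path = c.lineage.path_to(rank)
        entry = acc.setdefault(path, [0.0, 0])
        entry[0] += w.weight
        entry[1] += 1
        total += w.weight
    rows = []
    for path, (wt, n) in sorted(acc.items(), key=lambda kv: (-kv[1][0], kv[0])):
        pct = 100.0 * wt / total if total > 0 else 0.0
        rows.append({"taxon": path[-1], "lineage": ";".join(path),
                     "weight": wt, "count": n, "percent": pct})
    df = pd.DataFrame(rows, columns=["taxon", "lineage", "weight", "count", "percent"])
    if min_percent > 0 and len(df):
        df = df[df["percent"] >= min_percent].reset_index(drop=True)
    domain_total = total if rank == "domain" else \
        _accepted_weight(weighted, "domain", conf_threshold)
    return AbundanceTable(rank=rank, rows=df, total_weight=total,
                          domain_weight=domain_total)


def _accepted_weight(weighted: Sequence[WeightedRead], rank: str,
                     conf_threshold: float) -> float:
    total = 0.0
    for w in weighted:
        c = w.classification
        if c is None or not c.is_classified:
            continue
        conf = c.confidence_at(rank)
        if conf is not None and conf >= conf_threshold:
            total += w.weight
    return total


def write_abundance(table: AbundanceTable, path: str | os.PathLike) -> None:
    df = table.rows.copy()
    df.insert(0, "rank", table.rank)
    df["reads_pct_vs_domain"] = round(table.reads_pct_vs_domain, 2)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_abundance(table: AbundanceTable, path: str | os.PathLike,
                   top_n: int = 15) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.rows.head(top_n)
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.35 * len(df))))
    ax.barh(df["taxon"][::-1], df["percent"][::-1], color="seagreen")
    ax.set_xlabel(f"% of accepted weight at {table.rank} rank")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Confidence profiles

def confidence_profile(
    items: Iterable[tuple[RibosomalRead, Classification]],
    group_by: str,
    rank: str,
    regions: Optional[Sequence[RegionSpec]] = None,
    threshold: float = DEFAULT_CONFIDENCE,
    model_length: int = DEFAULT_MODEL_LENGTH,
) -> pd.DataFrame:
    """Quartile summary (Q1, median, Q3; linear-interpolation quantiles) of
    classification confidence at ``rank``, grouped by read length or by
    variable region, plus the fraction at or above ``threshold``.

    Groups with no confident calls are reported as empty rows, not dropped.
    When grouping by region, membership uses the same contain/contained rule
    (with each region's own tolerance) as read selection.
    """
    if group_by not in ("read_length", "region"):
        raise ValueError(f"unknown group_by {group_by!r}")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    items = list(items)
    groups: dict[str, list[float]] = {}
    if group_by == "read_length":
        for read, cls in items:
            conf = cls.confidence_at(rank)
            groups.setdefault(str(len(read.oriented_sequence)), []).append(
                conf if conf is not None else np.nan)
        keys = sorted(groups, key=int)
    else:
        if regions is None:
            regions = default_regions(tolerance=DEFAULT_TOLERANCE)
        by_key = {(r.read_id, r.mate): c for r, c in items}
        for reg in regions:
            sel = select_by_region([r for r, _ in items], reg, model_length)
            vals = []
            for r in sel:
                conf = by_key[(r.read_id, r.mate)].confidence_at(rank)
                vals.append(conf if conf is not None else np.nan)
            groups[reg.name] = vals
        keys = [reg.name for reg in regions]
    rows = []
    for key in keys:
        vals = np.array([v for v in groups.get(key, []) if not np.isnan(v)])
        if len(vals) == 0:
            rows.append({"group": key, "n": 0, "q1": np.nan, "median": np.nan,
                         "q3": np.nan, "accept_frac": np.nan})
        else:
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # type-7 default
            rows.append({"group": key, "n": len(vals), "q1": q1, "median": med,
                         "q3": q3,
                         "accept_frac": float(np.mean(vals >= threshold))})
    return pd.DataFrame(rows)
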