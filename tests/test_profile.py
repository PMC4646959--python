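"""Region targeting, paired-end weighting and abundance accounting."""

import math

import numpy as np
import pandas as pd
import pytest

import ribotax as rt
from ribotax.core import RANKS


def ribo(read_id, mate, a, b):
    return rt.RibosomalRead(read_id, mate, "A" * (b - a + 1), "bacteria_16S",
                            a, b, 1e-9)


def cls(read_id, mate, genus="G1", conf=1.0, family=None):
    family = family or f"F_{genus}"
    lineage = rt.Lineage(("Bacteria", "P1", "C1", "O1", family, genus))
    return rt.Classification(read_id=read_id, mate=mate, lineage=lineage,
                             confidences=(1.0, 1.0, 1.0, 1.0, conf, conf))


class TestDefaultRegions:
    def test_structure(self):
        regions = rt.default_regions()
        assert [r.name for r in regions] == [f"V{i}" for i in range(1, 10)]
        for r in regions:
            assert 1 <= r.start <= r.end <= 1542
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.start  # ascending, pairwise non-overlapping

    def test_file_override_roundtrip(self, tmp_path):
        custom = [rt.RegionSpec("X1", 10, 50), rt.RegionSpec("X2", 80, 120)]
        path = tmp_path / "regions.tsv"
        rt.write_regions(custom, path)
        assert rt.read_regions(path) == custom

    def test_expression_syntax(self):
        v3 = rt.parse_region_expr("V3")
        assert (v3.start, v3.end) == (433, 497)
        span = rt.parse_region_expr("V3-V5", tolerance=0.1)
        assert (span.start, span.end, span.tolerance) == (433, 879, 0.1)
        custom = rt.parse_region_expr("520:680")
        assert (custom.start, custom.end) == (520, 680)
        with pytest.raises(ValueError):
            rt.parse_region_expr("V12")


class TestSelectByRegion:
    def test_exact_interval_accepted_at_zero_tolerance(self):
        region = rt.RegionSpec("R", 100, 159)
        assert rt.select_by_region([ribo("r", "single", 100, 159)], region)

    def test_disjoint_rejected(self):
        region = rt.RegionSpec("R", 100, 159, tolerance=0.2)
        assert rt.select_by_region([ribo("r", "single", 300, 399)], region) == []

    def test_tolerance_rescues_overhanging_read(self):
        # read starts inside a 60-long region but hangs 10 past its end:
        # neither contained nor containing at tol=0; contained once the
        # window is expanded by floor(0.2 * 60) = 12 ≥ 10
        read = ribo("r", "single", 120, 169)
        assert rt.select_by_region([read], rt.RegionSpec("R", 100, 159)) == []
        assert rt.select_by_region([read], rt.RegionSpec("R", 100, 159, 0.2)) == [read]

    def test_exhaustive_oracle_length_200(self):
        """Selection equals brute-force containment between read and
        tolerance-expanded region for every placement on a length-200 model."""
        L = 200
        regions = [rt.RegionSpec("R", 60, 119, tol) for tol in (0.0, 0.2, 0.5)]
        reads = [ribo(f"{a}-{b}", "single", a, b)
                 for a in range(1, L + 1) for b in range(a, L + 1)]
        for region in regions:
            pad = math.floor(region.tolerance * region.length)
            lo, hi = max(1, region.start - pad), min(L, region.end + pad)
            expected = {(r.model_from, r.model_to) for r in reads
                        if set(range(lo, hi + 1)) <= set(range(r.model_from,
                                                               r.model_to + 1))
                        or set(range(r.model_from, r.model_to + 1))
                        <= set(range(lo, hi + 1))}
            got = {(r.model_from, r.model_to)
                   for r in rt.select_by_region(reads, region, model_length=L)}
            assert got == expected


class TestAssignWeights:
    def test_singleton_weighs_one(self):
        out = rt.assign_weights([ribo("p", "1", 1, 100)])
        assert [(w.mate, w.weight) for w in out] == [("1", 1.0)]

    def test_full_pair_halved(self):
        out = rt.assign_weights([ribo("p", "1", 1, 100), ribo("p", "2", 400, 499)])
        assert sorted((w.mate, w.weight) for w in out) == [("1", 0.5), ("2", 0.5)]

    def test_single_end_all_ones(self):
        reads = [ribo(f"r{i}", "single", 1, 100) for i in range(10)]
        out = rt.assign_weights(reads)
        assert sum(w.weight for w in out) == len(reads)


class TestAbundance:
    def test_plain_relative_frequencies(self):
        reads = [ribo(f"r{i}", "single", 1, 100) for i in range(4)]
        classifications = {("r0", "single"): cls("r0", "single", "A"),
                           ("r1", "single"): cls("r1", "single", "A"),
                           ("r2", "single"): cls("r2", "single", "A"),
                           ("r3", "single"): cls("r3", "single", "B")}
        table = rt.abundance(rt.assign_weights(reads, classifications), "genus")
        pct = dict(zip(table.rows["taxon"], table.rows["percent"]))
        assert pct == {"A": 75.0, "B": 25.0}

    def test_concordant_pair_plus_singleton(self):
        reads = [ribo("p", "1", 1, 100), ribo("p", "2", 200, 299),
                 ribo("s", "1", 1, 100)]
        classifications = {("p", "1"): cls("p", "1", "A"),
                           ("p", "2"): cls("p", "2", "A"),
                           ("s", "1"): cls("s", "1", "B")}
        table = rt.abundance(rt.assign_weights(reads, classifications), "genus")
        pct = dict(zip(table.rows["taxon"], table.rows["percent"]))
        assert pct == {"A": 50.0, "B": 50.0}

    def test_matches_brute_force_accumulator(self):
        rng = np.random.default_rng(31)
        weighted = []
        for i in range(300):
            genus = f"G{rng.integers(0, 6)}"
            conf = float(rng.choice([0.3, 0.7, 0.85, 1.0]))
            weighted.append(rt.WeightedRead(
                read_id=f"r{i}", mate="single",
                weight=float(rng.choice([0.5, 1.0])), model_from=1, model_to=100,
                classification=cls(f"r{i}", "single", genus, conf)))
        for rank, thr in (("genus", 0.8), ("family", 0.5), ("domain", 0.0)):
            table = rt.abundance(weighted, rank, conf_threshold=thr)
            acc = {}
            total = 0.0
            for w in weighted:
                if w.classification.confidence_at(rank) >= thr:
                    taxon = w.classification.taxon_at(rank)
                    acc[taxon] = acc.get(taxon, 0.0) + w.weight
                    total += w.weight
            got = dict(zip(table.rows["taxon"], table.rows["weight"]))
            assert got == acc
            assert math.isclose(table.rows["percent"].sum(), 100.0)
            for taxon, wt in acc.items():
                row = table.rows[table.rows["taxon"] == taxon].iloc[0]
                assert math.isclose(row["percent"], 100.0 * wt / total)

    def test_min_percent_drops_without_renormalizing(self):
        weighted = [rt.WeightedRead(f"r{i}", "single", 1.0, 1, 100,
                                    cls(f"r{i}", "single", g))
                    for i, g in enumerate(["A"] * 97 + ["B"] * 3)]
        table = rt.abundance(weighted, "genus", min_percent=5.0)
        assert list(table.rows["taxon"]) == ["A"]
        assert math.isclose(table.rows["percent"].iloc[0], 97.0)  # not 100

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(37)
        weighted = [rt.WeightedRead(f"r{i}", "single", 1.0, 1, 100,
                                    cls(f"r{i}", "single", f"G{rng.integers(3)}",
                                        float(rng.uniform())))
                    for i in range(200)]
        prev = None
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            table = rt.abundance(weighted, "genus", conf_threshold=thr)
            weights = dict(zip(table.rows["taxon"], table.rows["weight"]))
            if prev is not None:
                for taxon, wt in weights.items():
                    assert wt <= prev.get(taxon, 0.0) + 1e-12
            prev = weights

    def test_reads_pct_vs_domain(self):
        weighted = [
            rt.WeightedRead("r0", "single", 1.0, 1, 100,
                            cls("r0", "single", "A", conf=1.0)),
            rt.WeightedRead("r1", "single", 1.0, 1, 100,
                            cls("r1", "single", "B", conf=0.2)),  # fails at genus
        ]
        domain = rt.abundance(weighted, "domain", conf_threshold=0.8)
        genus = rt.abundance(weighted, "genus", conf_threshold=0.8)
        assert domain.reads_pct_vs_domain == 100.0
        assert genus.reads_pct_vs_domain == 50.0

    def test_unknown_rank(self):
        with pytest.raises(ValueError):
            rt.abundance([], "species")


class TestConfidenceProfile:
    def test_constant_confidence_collapses_quartiles(self):
        items = [(ribo(f"r{i}", "single", 1, 100),
                  cls(f"r{i}", "single", conf=0.9)) for i in range(10)]
        df = rt.confidence_profile(items, "read_length", "genus")
        row = df.iloc[0]
        assert row["q1"] == row["median"] == row["q3"] == 0.9
        assert row["accept_frac"] == 1.0

    def test_decile_median_matches_sorted_computation(self):
        items = [(ribo(f"r{i}", "single", 1, 100),
                  cls(f"r{i}", "single", conf=c))
                 for i, c in enumerate(np.round(np.arange(0.1, 1.01, 0.1), 10))]
        df = rt.confidence_profile(items, "read_length", "genus")
        assert math.isclose(df.iloc[0]["median"], 0.55)
        assert math.isclose(df.iloc[0]["q1"],
                            float(np.quantile(np.arange(0.1, 1.01, 0.1), 0.25)))

    def test_empty_group_reported_not_dropped(self):
        items = [(ribo("r", "single", 440, 490), cls("r", "single", conf=0.9))]
        regions = [rt.RegionSpec("V3", 433, 497), rt.RegionSpec("V6", 986, 1043)]
        df = rt.confidence_profile(items, "region", "genus", regions=regions)
        assert list(df["group"]) == ["V3", "V6"]
        assert df[df["group"] == "V6"].iloc[0]["n"] == 0
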