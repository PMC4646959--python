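"""Hit QC, read orientation/annotation and 16S coverage."""

import itertools

import numpy as np
import pytest

import ribotax as rt
from ribotax.qc import format_header, parse_header
from conftest import random_dna


def make_hit(read_id="r", mate="single", model_id="bacteria_16S", strand="+",
             evalue=1e-8, bit_score=50.0, model_from=100, model_to=199,
             read_from=1, read_to=100, read_length=100):
    return rt.HmmHit(read_id=read_id, mate=mate, model_id=model_id, strand=strand,
                     evalue=evalue, bit_score=bit_score, model_from=model_from,
                     model_to=model_to, read_from=read_from, read_to=read_to,
                     read_length=read_length)


def brute_force_filter(hits, min_length=60, evalue_threshold=1e-5,
                       read_lengths=None):
    """Independent rule-by-rule reference filter (test oracle)."""
    out = {}
    keys = {(h.read_id, h.mate) for h in hits}
    for key in keys:
        mine = [h for h in hits if (h.read_id, h.mate) == key
                and h.evalue <= evalue_threshold]
        if not mine:
            continue
        length = read_lengths[key] if read_lengths else max(h.read_length for h in mine)
        if length < min_length:
            continue
        if any(h.strand == "+" for h in mine) and any(h.strand == "-" for h in mine):
            continue
        best = mine[0]
        for h in mine[1:]:
            if (h.evalue, -h.bit_score, h.model_id != "bacteria_16S", h.model_from) < \
               (best.evalue, -best.bit_score, best.model_id != "bacteria_16S",
                    best.model_from):
                best = h
        out[key] = best
    return out


class TestFilterAndDereplicate:
    def test_lowest_evalue_kept(self):
        hits = [make_hit(evalue=1e-6), make_hit(evalue=1e-8, model_from=300,
                                                model_to=399)]
        kept, _ = rt.filter_and_dereplicate(hits)
        assert kept[("r", "single")].evalue == 1e-8

    def test_incongruent_strands_discarded(self):
        hits = [make_hit(strand="+", evalue=1e-9), make_hit(strand="-", evalue=1e-7)]
        kept, summary = rt.filter_and_dereplicate(hits)
        assert kept == {}
        assert summary.removed_strand == 1

    def test_failing_strand_hit_does_not_disqualify(self):
        """A minus-strand hit above the E-value threshold is not evidence of
        strand incongruence."""
        hits = [make_hit(strand="+", evalue=1e-9), make_hit(strand="-", evalue=1e-3)]
        kept, _ = rt.filter_and_dereplicate(hits)
        assert ("r", "single") in kept

    def test_short_read_removed_via_lengths(self):
        hits = [make_hit(read_to=50, read_length=50)]
        kept, summary = rt.filter_and_dereplicate(
            hits, read_lengths={("r", "single"): 50})
        assert kept == {} and summary.removed_short == 1

    def test_tie_breaking_chain(self):
        # equal E-value: higher bit score wins; then bacteria; then leftmost
        a = make_hit(evalue=1e-8, bit_score=40.0)
        b = make_hit(evalue=1e-8, bit_score=60.0, model_from=500, model_to=599)
        kept, _ = rt.filter_and_dereplicate([a, b])
        assert kept[("r", "single")] is b
        c = make_hit(evalue=1e-8, bit_score=60.0, model_id="archaea_16S")
        kept, _ = rt.filter_and_dereplicate([b, c])
        assert kept[("r", "single")] is b
        d = make_hit(evalue=1e-8, bit_score=60.0, model_from=10, model_to=109)
        kept, _ = rt.filter_and_dereplicate([b, d])
        assert kept[("r", "single")] is d

    def test_matches_brute_force_oracle_and_order_independent(self):
        rng = np.random.default_rng(13)
        hits = []
        for i in range(200):
            mf = int(rng.integers(1, 1400))
            hits.append(make_hit(
                read_id=f"r{rng.integers(0, 40)}",
                mate=str(rng.choice(["single", "1", "2"])),
                model_id=str(rng.choice(["bacteria_16S", "archaea_16S"])),
                strand=str(rng.choice(["+", "-"])),
                evalue=float(10.0 ** -rng.integers(2, 12)),
                bit_score=float(rng.integers(20, 80)),
                model_from=mf, model_to=mf + 99,
                read_length=int(rng.integers(40, 150)),
                read_from=1, read_to=40))
        kept, summary = rt.filter_and_dereplicate(hits)
        assert kept == brute_force_filter(hits)
        assert summary.n_reads_in == summary.n_kept + summary.removed_evalue + \
            summary.removed_short + summary.removed_strand
        # shuffling the input changes nothing
        shuffled = list(hits)
        rng.shuffle(shuffled)
        kept2, _ = rt.filter_and_dereplicate(shuffled)
        assert kept2 == kept


class TestOrientAndAnnotate:
    def test_plus_strand_unchanged(self):
        read = rt.SequenceRead("r", "ACGTACGT")
        hit = make_hit(read_from=1, read_to=8, read_length=8)
        ribo = rt.orient_and_annotate(read, hit)
        assert ribo.oriented_sequence == "ACGTACGT"
        assert (ribo.model_from, ribo.model_to) == (100, 199)

    def test_minus_strand_reversed_and_researchable(self, small_reference, small_hmm):
        """A minus-strand read, once oriented, recruits again on the plus
        strand at the same model interval."""
        sid = small_reference.species_ids[0]
        window = small_reference.sequences[sid][499:599]
        read = rt.SequenceRead("r", rt.reverse_complement(window))
        (hit,) = sorted(rt.search_reads([read], {"bacteria_16S": small_hmm}),
                        key=lambda h: h.evalue)[:1]
        assert hit.strand == "-"
        ribo = rt.orient_and_annotate(read, hit)
        assert ribo.oriented_sequence == window
        rehits = rt.search_reads([rt.SequenceRead("r", ribo.oriented_sequence)],
                                 {"bacteria_16S": small_hmm})
        best = min(rehits, key=lambda h: h.evalue)
        assert best.strand == "+"
        assert (best.model_from, best.model_to) == (hit.model_from, hit.model_to)

    def test_id_mismatch_is_error(self):
        with pytest.raises(ValueError):
            rt.orient_and_annotate(rt.SequenceRead("other", "ACGT"), make_hit())

    def test_header_roundtrip_random(self):
        rng = np.random.default_rng(3)
        for i in range(100):
            mf = int(rng.integers(1, 1440))
            ribo = rt.RibosomalRead(
                read_id=f"read|{i}", mate=str(rng.choice(["single", "1", "2"])),
                oriented_sequence=random_dna(rng, 80),
                model_id="bacteria_16S", model_from=mf,
                model_to=mf + int(rng.integers(0, 100)),
                evalue=float(10.0 ** -rng.integers(6, 30)))
            back = parse_header(format_header(ribo), ribo.oriented_sequence)
            assert back == ribo

    def test_ribo_fasta_roundtrip(self, tmp_path):
        reads = [rt.RibosomalRead("a", "1", "ACGT", "bacteria_16S", 5, 8, 1e-9),
                 rt.RibosomalRead("b", "single", "GGTT", "archaea_16S", 1, 4, 1e-7)]
        path = tmp_path / "ribo.fasta"
        rt.write_ribo_fasta(reads, path)
        assert rt.read_ribo_fasta(path) == reads


class TestCoverage:
    def test_no_reads_all_zero(self):
        prof = rt.coverage([], model_length=100)
        assert prof.depth.sum() == 0 and len(prof.depth) == 100

    def test_two_overlapping_intervals(self):
        reads = [rt.RibosomalRead("a", "single", "A", "bacteria_16S", 1, 100, 1e-9),
                 rt.RibosomalRead("b", "single", "A", "bacteria_16S", 51, 150, 1e-9)]
        depth = rt.coverage(reads, model_length=200).depth
        assert (depth[:50] == 1).all()
        assert (depth[50:100] == 2).all()
        assert (depth[100:150] == 1).all()
        assert (depth[150:] == 0).all()

    def test_conservation_of_mass(self):
        rng = np.random.default_rng(21)
        reads = []
        for i in range(1000):
            a = int(rng.integers(1, 1500))
            b = int(rng.integers(a, 1543))
            reads.append(rt.RibosomalRead(f"r{i}", "single", "A",
                                          "bacteria_16S", a, b, 1e-9))
        prof = rt.coverage(reads)
        assert prof.depth.sum() == sum(r.model_to - r.model_from + 1 for r in reads)

    def test_coverage_tsv(self, tmp_path):
        prof = rt.coverage([rt.RibosomalRead("a", "single", "A", "bacteria_16S",
                                             2, 3, 1e-9)], model_length=4)
        path = tmp_path / "cov.tsv"
        rt.write_coverage(prof, path)
        assert path.read_text() == \
            "position\tdepth\n1\t0\n2\t1\n3\t1\n4\t0\n"


class TestPlots:
    def test_coverage_plot_renders(self, tmp_path):
        reads = [rt.RibosomalRead(f"r{i}", "single", "A", "bacteria_16S",
                                  1 + 10 * i, 120 + 10 * i, 1e-9)
                 for i in range(20)]
        prof = rt.coverage(reads)
        out = tmp_path / "cov.png"
        rt.plot_coverage(prof, out, regions=rt.default_regions())
        assert out.stat().st_size > 0
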