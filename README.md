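# ribotax

**16S-based taxonomic profiling of non-targeted (shotgun) metagenomes.**

Shotgun metagenomic sequencing captures a sample's whole DNA content, so
reads deriving from the 16S rRNA gene — the standard phylogenetic marker for
bacteria and archaea — are buried in the data at a small fraction (on the
order of 0.1–2% depending on genome sizes). `ribotax` finds those reads,
positions them on the 16S gene, classifies them, and turns them into
per-rank abundance profiles, giving amplicon-style community composition
without amplicon sequencing and its primer biases. It is aimed at
microbiome researchers who already have shotgun data and want a 16S view of
it, or who want to pre-screen which hypervariable region to target in a
subsequent amplicon experiment.

## Method

The pipeline has four stages:

1. **Recruit** — every read is searched on both strands against bacterial
   and archaeal 16S profile HMMs (in-process via pyhmmer, or an external
   `hmmsearch`); per-domain matches with E ≤ 10⁻⁵ are kept, along with
   their alignment interval on the gene model (*E. coli* numbering,
   1–1542).
2. **QC / position** — hits are filtered (E-value; reads < 60 bp; reads
   with passing hits on both strands are incongruent and dropped; one best
   hit per read by E-value → bit score → bacteria → leftmost), reads are
   oriented model-forward, their model interval is written into the FASTA
   header, and per-position coverage of the gene is computed.
3. **Classify** — an RDP-style naive Bayesian classifier over 8-mers. With
   N training sequences, n(w) containing word w, M(G) sequences in genus G
   and m(w,G) of them containing w:

       P(w)   = (n(w) + 0.5) / (N + 1)
       P(w|G) = (m(w,G) + P(w)) / (M(G) + 1)

   A read's genus is argmax_G Σ_{w∈W} log P(w|G) over its distinct words W;
   confidence at each rank is the fraction of 100 bootstrap re-
   classifications (⌊|W|/8⌋ words drawn with replacement) agreeing with the
   point call at that rank. Output is fixed-rank TSV, so external
   classifier output can be dropped in instead.
4. **Profile** — reads are selected by gene topology (a read belongs to a
   region, e.g. V3 or V3–V5, if it contains or is contained in the region
   window expanded by a tolerance, default 20% of region length per side);
   paired-end weights avoid double counting (each mate of a fully
   recruited pair weighs 0.5, a singleton or single-end read weighs 1, so
   a concordant pair contributes exactly 1); weights of reads passing a
   confidence threshold (default 0.8) are accumulated into per-rank
   abundance tables.

A fully truth-labelled simulator (synthetic 16S-like gene families with
hypervariable windows, pure-ribosomal read sets, and paired-end shotgun
metagenomes with an Illumina-like error ramp) supports end-to-end
evaluation with known ground truth.

## Worked example

Simulate a small community, recruit, classify and profile it — entirely in
memory:

```python
import ribotax as rt

ref = rt.build_reference(n_genera=8, species_per_genus=4, seed=42)
hmm = rt.build_hmm(ref)
r1, r2, truth, info = rt.simulate_metagenome(
    ref, n_genomes=8, genome_length=50_000, n_pairs=10_000, seed=43)
reads = r1 + r2

hits = rt.search_reads(reads, {"bacteria_16S": hmm})
kept, summary = rt.filter_and_dereplicate(
    hits, read_lengths={r.key: len(r) for r in reads})
by_key = {r.key: r for r in reads}
ribo = [rt.orient_and_annotate(by_key[k], h) for k, h in kept.items()]
print(f"recruited {len(ribo)} / {len(reads)} reads as 16S")

scores = rt.score_recruitment(truth, kept.keys())
print(f"sensitivity {scores['sensitivity']:.3f}, "
      f"specificity {scores['specificity']:.4f}")

model = rt.train(ref.to_reference_db())
cls = rt.classify_reads([(r.read_id, r.mate, r.oriented_sequence)
                         for r in ribo], model, seed=44)
selected = rt.select_by_region(ribo, rt.parse_region_expr("V3-V5",
                                                          tolerance=0.2))
weighted = rt.assign_weights(selected, {c.key: c for c in cls})
table = rt.abundance(weighted, "genus", conf_threshold=0.8)
print(f"{len(selected)} reads in V3-V5; accepted weight {table.total_weight:.1f}")
print(table.rows[["taxon", "weight", "count", "percent"]].head(5).to_string(index=False))
```

This prints:

```
recruited 616 / 20000 reads as 16S
sensitivity 0.987, specificity 0.9998
200 reads in V3-V5; accepted weight 165.0
    taxon  weight  count   percent
BacGen001    36.0     45 21.818182
BacGen005    33.0     40 20.000000
BacGen003    28.0     32 16.969697
BacGen004    25.0     30 15.151515
BacGen007    24.0     30 14.545455
```

616 of 20,000 simulated reads were recruited as ribosomal (98.7% of the
truly ribosomal reads, with 2 in 10,000 non-ribosomal reads falsely
recruited); 200 of them lie in the V3–V5 window, and of those, 165 weight
units passed the 0.8 genus-confidence threshold and were apportioned among
the eight simulated genera — the `percent` column is the community profile.
Note that `count` exceeds `weight` where both mates of a pair were
recruited: each then counts 0.5.

The same flow is available from the shell via the `ribotax` command
(`simulate`, `recruit`, `trap`, `classify`, `map`, `run`, `score`
subcommands); `ribotax run --config run.cfg` chains all four stages and
writes per-stage accounting to `summary.json`.

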