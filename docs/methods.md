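# Methods

This note documents the models, conventions and design choices behind
`ribotax`, in the order the pipeline runs. It describes what the code
computes; every number quoted here is produced by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Coordinates and data model

All gene-model positions are 1-based and inclusive, the convention of
HMMER tabular output; a single helper (`core.check_interval`) enforces it
everywhere. The default model length is 1542 bp — the *E. coli* 16S gene,
the standard positional reference for the nine hypervariable windows — but
it is carried as data on every object that needs it, never assumed.
Lineages span the six ranks domain → genus as a contiguous prefix (a
lineage may stop at, say, family, but cannot skip a rank). `N` bases are
legal everywhere: they reverse-complement to `N` and any classifier word
containing one is simply excluded, so they can never produce a spurious
match.

## Recruitment

Reads are searched as *targets* against the 16S profile HMM queries. The
minus strand is handled explicitly: the reverse complement of each read is
searched as a second target (tagged `_rc`), and hit coordinates are mapped
back onto the original read. Per-domain matches are kept as separate hits;
we threshold on the domain's independent E-value, since a read can overlap
the gene in more than one stretch and the downstream filters operate on
the single best local match. The default threshold is 10⁻⁵.

Two engines implement the same contract and are exercised against each
other in the tests: an in-process engine built on pyhmmer, and an
external-process engine that writes a both-strand target FASTA, runs
`hmmsearch --domtblout`, and parses the table back. E-values depend on the
search-space size; both engines search the identical target set (reads
plus reverse complements), so their reported values agree. Engine defaults
(filter thresholds etc.) are whatever the installed HMMER/pyhmmer version
ships; we do not pin them, and the run log records the engine used.

Real analyses should use curated 16S HMMs (e.g. secondary-structure-aware
bacterial/archaeal models); the package deliberately does not bundle any.
For testing and simulation the HMM is built from the synthetic family
alignment, which is gapless, so every column becomes a match state and
model coordinates coincide with gene coordinates exactly.

## QC and positioning

Four rules, applied per read (the surviving set is order-independent,
which the tests check):

1. drop hits with E-value above threshold;
2. drop reads shorter than 60 bp — the minimum length at which even
   domain-level assignment is dependable for short-read classifiers; the
   rule applies to the *read* length, not the aligned span;
3. drop reads with passing hits on both strands (strand incongruence —
   a genuine 16S fragment matches one orientation only);
4. keep exactly one hit per read: lowest E-value, ties broken by higher
   bit score, then bacteria over archaea, then smaller model start. The
   chain is arbitrary beyond its first element but deterministic, which is
   what matters for reproducibility.

Every removal is attributed to a reason in a `FilterSummary`, so
recruitment-summary tables can be produced for any dataset. Incongruent
reads are dropped rather than strand-voted; they are rare and a vote would
need a rule we have no principled basis for. Surviving reads are oriented
model-forward and serialized with header
`>{read_id}|{mate}|{model_id}|{from}-{to}|{evalue}`; parsing is the exact
inverse. Coverage is computed with a difference array, so total depth
equals summed interval lengths exactly.

## Classification

A word-based naive Bayes classifier in the classical RDP style, trained on
presence/absence of k-mers per sequence (k = 8 by default, configurable).
With N sequences, n(w) containing word w, M(G) sequences in genus G and
m(w,G) of them containing w:

    P(w)   = (n(w) + 0.5) / (N + 1)          (pseudo-counted prior)
    P(w|G) = (m(w,G) + P(w)) / (M(G) + 1)    (genus conditional)

Both are strictly positive, so unseen words need no special case. The
point call maximises Σ log P(w|G) over the read's *distinct* word set W
(words, not positions, are what the model is trained on); exact score ties
break to the lexicographically smallest genus name, purely for
determinism. Each of the 100 bootstrap replicates draws max(1, ⌊|W|/8⌋)
words from W with replacement; confidence at a rank is the fraction of
replicate winners whose lineage passes through the point call's taxon at
that rank. Because lineages form a tree, agreement at a rank implies
agreement at all ranks above it, so confidence is rank-monotone by
construction. Only genus-level conditionals are modelled; higher-rank
calls follow the genus lineage, exactly as fixed-rank output does. A read
with no valid word is returned as an unclassifiable sentinel and counted.

Conditional log-likelihoods are stored as a dense (genera × 4ᵏ) matrix;
at k = 8 that is ~0.5 MB per genus, fine for the reference sizes this
package targets (simulated families, custom references up to a few hundred
genera). Retraining on length-matched fragments is out of scope.

## Region targeting, weighting, abundance

A read belongs to a region when it contains, or is contained in, the
region window expanded symmetrically by ⌊tol × region_length⌋ on each side
(clipped to the model); the default tolerance is 0.2. Containment is
tested against the *expanded* window in both directions — the symmetric
choice; absolute per-side offsets are also supported via custom region
expressions (`520:680`). The bundled V1–V9 coordinates follow the standard
*E. coli* literature convention and live in an editable data file; they
are configuration, and none of the package's quantitative guarantees
depend on their exact values.

Paired-end weighting: a fully recruited pair gets 0.5 per mate, a
singleton or single-end read gets 1, so a pair can never contribute more
than one observation and contributes exactly one when concordant. Weights
are fixed at recruitment time: a 0.5-mate whose partner is later removed
by a region or confidence filter stays at 0.5, because re-promotion would
require a rule the weighting scheme does not define.

Abundance at a rank accumulates the weight of reads classified there with
confidence ≥ the threshold (default 0.8). Percent is relative to total
accepted weight at that rank, so each rank's rows sum to 100; a separate
column reports the rank's accepted weight relative to the domain rank's
(domain = 100 by construction). A `min_percent` display cutoff drops rows
*after* percentages are computed and does not renormalize. Confidence
profiles (per read length or per region) report Q1/median/Q3 using
linear-interpolation (type-7) quantiles — stated because quartile
conventions differ — plus the fraction at or above the threshold; empty
groups are reported, not dropped.

## The simulator

The synthetic reference emulates the statistical shape of a 16S gene
family, not its biology: a uniform-random backbone of model length, genus
ancestors mutated from it at `inter_genus_div` per site (default 0.15,
tripled inside the V windows and capped at 0.75 — variable regions are
what makes genera distinguishable), and species mutated from their genus
ancestor at `intra_genus_div` (default 0.02). Genera are grouped
deterministically two-per-family, two-families-per-order, and so on, to
give a complete six-rank taxonomy. What it does *not* reproduce: real 16S
conservation structure (the backbone is random, not a real consensus),
indels and length variation, secondary-structure covariation, chimeras,
and real taxonomic imbalance. Tests passing on it therefore demonstrate
the pipeline's mechanics and statistical behaviour under controlled
divergence, not performance against curated databases — for that, real
HMMs and a real reference are required, and per-database numbers are not
promised.

Ribosomal read sets come in two protocols: `random` (one read per species
— an exhaustive sweep) and `curated` (a fixed number per genus, default
100 — taxonomically balanced). Every read is an exact gene substring with
its interval recorded.

The metagenome simulator embeds one 16S-like gene (multiplicity is a
parameter) in each of `n_genomes` i.i.d.-uniform background genomes
(default 20 genomes of 100 kb — chosen so a 100,000-read run yields on the
order of 1,500 truth-positive reads, enough to estimate sensitivity
tightly), draws inserts of Normal(450, 50) bp placed uniformly, takes
mate 1 from the forward start and mate 2 as the reverse complement of the
end, and applies per-base substitution errors rising linearly from 0.1% at
the 5′ end to 1% at the 3′ end — a simple stand-in for Illumina quality
decay. A mate is labelled truly ribosomal when ≥ 50% of its bases fall
inside an embedded gene; this makes edge-spanning reads well-posed and
yields a closed-form expectation for the ribosomal fraction,
`(g + r − 2⌈r/2⌉ + 1) / (L − r + 1)` per operon (g gene length, r read
length, L genome length), which the generator reports and the tests check
to within three binomial standard deviations. Everything is driven by one
integer seed, down to byte-identical FASTQ output.

## Numerical and degenerate-input choices

- E-value/score serialization uses 17 significant digits, so tabular
  round-trips are bit-exact.
- Bootstrap draws use numpy's default PRNG; one generator is threaded
  through a batch so a single seed reproduces a whole classification run.
- Empty inputs are empty outputs, never errors (empty FASTA, empty hit
  list, zero-read coverage); malformed inputs are hard errors naming the
  record or line.
- `⌊|W|/8⌋` is floored at 1 so very short (but ≥ k) reads still bootstrap
  rather than divide by zero; such reads are below the QC length cutoff in
  normal operation anyway.

## Known limitations

- Genus is the lowest rank reached; species/strain resolution is not
  attempted (short reads cannot support it).
- Chimera detection and merging of overlapping mate alignments are out of
  scope.
- The simulator's error model is substitution-only; indel-dominated
  platforms are not represented.
- Numeric agreement with results computed against specific curated
  databases is not promised; the synthetic harness bounds behaviour, it
  does not reproduce database-dependent numbers.
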