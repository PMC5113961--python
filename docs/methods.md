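# Methods

## The model

`corecazyome` identifies the *core* carbohydrate-active gene set of a
replicated metagenome study: the set of assembled contigs with a CAZy
database hit that are detected above threshold in **every** replicate
sample. The pipeline has six stages, each communicating only through flat
files so that any stage can be re-run and audited independently.

### Coverage and presence

A contig's abundance in a sample is summarized by its **maximum per-base
depth** (`max_cov`) and its **covered length** (number of distinct
positions with depth ≥ 1). A contig is *present* in a sample when

```
max_cov >= min_cov   AND   covered_len >= min_len
```

with defaults `min_cov = 5` (×) and `min_len = 100` (bp). Maximum depth is
a deliberately liberal abundance proxy: it lets genuinely shared contigs
pass even when most of their length is thinly covered in one replicate.
Covered length is read as *distinct covered positions, not necessarily
contiguous*; the stricter contiguous reading is available via
`contiguous=True` (`--contiguous`), which applies `min_len` to the longest
consecutive covered stretch. Note that coverage summaries reloaded from a
summary TSV do not carry the longest-run column, so contiguous mode is
only meaningful when computing from depth tables directly.

Duplicated (contig, position) rows in a depth table keep the maximum
depth, so covered length is never double-counted. Positions are 1-based
(samtools-depth dialect).

### Core rule and core fraction

`call_core` intersects presence calls over all required samples; it is
antitone in both thresholds and in the sample set. The core fraction is
`100 · |core| / |universe|`, rounded half-up (843 of 226,887 → 0.4%).

### Annotation

Each contig is characterized by its single best-scoring CAZy hit:

1. discard hits with E-value above the cutoff (default ≤ 1e-5, inclusive);
2. keep the hit with the **maximum bitscore** (bitscore, not minimum
   E-value, is the score: E-value ties are far more common and the
   bitscore is the standard alignment score column);
3. resolve exact bitscore ties by a seeded uniform draw over the tied
   candidates, **after sorting them by subject id**, so the resolved
   annotation is reproducible and independent of input row order. The
   `tie_broken` flag records that a draw happened.

CAZy class is derived from the family label prefix (GH13 → GH, GT2 → GT,
CE10 → CE, PL1 → PL, CBM32/CB32 → CB; anything else → unknown). Taxonomy
filtering retains the domains {Bacteria, Archaea, Viruses, Fungi} by
default.

recA counting uses a *strict* E < 1e-5 by default while the CAZy cutoff is
inclusive (E ≤ 1e-5); the asymmetry is intentional and both are
configurable. recA counts are the number of distinct query sequences with
a qualifying hit.

### Normalization and profiles

`copies_per_recA = max_cov / recA_count(sample)` puts contig abundances on
a common per-genome-equivalent scale across samples of different
sequencing depth. Profiles sum copies-per-recA over core contigs within a
group (CAZy class, family, phylum, or family × phylum) per sample, then
average across replicates. Both mean ± SE and a t-based 95% CI
(`mean ± t(0.975, n−1) · sd/√n`; t = 3.1824 at n = 4) are emitted, since
both dispersion conventions are common in figure captions. With one
replicate, SE and CI are NaN, never zero. A contig's entire abundance is
attributed to its single best-hit family and phylum (no fractional
assignment), so group abundances at any level sum exactly to the total
core abundance per sample and prevalences sum to |core|.

### Database-bias randomization test

The observed category distribution of the core (over classes or phyla) is
compared against `n_rep` random draws of `n_draw` items from a reference
pool (the CAZy database or the cumulative metagenome's annotations).
Draws are **without replacement** by default (multivariate hypergeometric:
"select 50,000 proteins" from a finite database means distinct proteins);
multinomial with-replacement sampling is a flag, and the pipeline falls
back to it with a warning when the pool is smaller than `n_draw`.

The default statistic is the chi-square distance of a frequency vector
from the null-mean frequencies; the empirical p-value is
`(1 + #{draws ≥ observed}) / (n_rep + 1)`, never exactly zero. The
`ftest` mode is a max-T style alternative: the statistic is the maximum
per-category standardized deviation, and per-category empirical p-values
are reported with Bonferroni correction. The empirical-null design means
the test is *calibrated when the observed set is a draw of comparable size
from the pool*; comparing a small observed set against large draws
inflates the observed chi-square distance through sampling noise alone, so
choose `n_draw` comparable to the observed count when calibration matters.

### k-mer core fraction

An assembly-free depth-scaling view of the core: per bootstrap,
`subset_size` reads are subsampled without replacement from each sample,
reduced to canonical k-mers (lexicographic minimum of forward and reverse
complement, k = 20 by default, 4 bootstraps by default), and the core
fraction is |intersection across samples| / |union across samples|. The
union is the "total unique k-mers" denominator; a per-sample-mean
denominator is available as an option. Subsampling is *paired*: one
generator per (seed, bootstrap), restarted for each sample over its sorted
reads. This makes the estimate invariant to read order within a sample and
to sample ordering, and gives the exact limiting values — identical read
sets yield fraction 1.0, pairwise-disjoint sets yield 0.0. Reads shorter
than k contribute no k-mers and are counted in `skipped_short_reads`.

### Sharing with other metagenomes

Coverage mode (targets mapped against the same contig reference): a core
contig is shared when present — same presence rule — in at least
`min_samples` (default 1) of the target's replicates. Alignment mode
(targets available only as reads): a core contig is shared when **any** of
its hits passes E ≤ 1e-5, alignment length ≥ 70 columns and identity
≥ 70%; "length" is alignment columns, not a query fraction, and
`best_hit_only=True` restricts the scan to maximal-bitscore hits. Group
summaries report mean, SD and SE explicitly (singleton groups report
missing dispersion), since "±" conventions vary.

## Synthetic communities

The generator emulates a four-replicate whole-soil design with a planted,
exactly recoverable core. Defaults, chosen once as field-realistic:

| parameter | default | why |
|---|---|---|
| n_samples | 4 | replicate block design |
| n_contigs | 2000 | desk-scale contig universe |
| core_fraction | 0.05 | small core, as in real soils |
| contig_length_range | 150–1500 bp | short-read assembly contigs |
| coverage model | lognormal(0.9, 1.1) | heavy-tailed contig abundances |
| presence_min_cov / min_len | 5 / 100 | the analysis defaults |
| dropout_rate | 0.3 | sample-specific contig absence |
| recA_per_sample | ~1000–1400 | deep soil metagenomes |
| tie_fraction | 0.1 | exercises the tie-break rule |

Core contigs receive, in every sample, a mean depth of at least
`min_cov + 1` with ±1 per-base jitter (so the maximum always clears the
threshold) and a length ≥ `min_len`. Every non-core contig is *forced* to
fail in at least one designated sample — by dropout or by capping its depth
at `min_cov − 1` — so the planted truth is unambiguous and downstream
recovery can be asserted by set equality. Per-base depth is the rounded
lognormal mean with ±1 uniform jitter: this reproduces exactly the two
features the analysis consumes (maximum depth, covered length) without
read-level simulation; it does **not** model read errors, GC bias, ragged
contig ends, chimeric assembly, or inter-sample abundance correlation, so
passing tests demonstrate correctness of the analysis logic, not
robustness to real-data artifacts. Fixture hit tables contain the
annotation-consistent best hit, an exact-score duplicate pointing at a
second subject for a `tie_fraction` of contigs (same family/phylum, so tie
resolution never changes the planted annotation), and a below-best decoy
that sometimes fails the E-value cutoff.

Fixtures are byte-identical for identical (config, seed); the fixture
writer uses an RNG stream derived from the config seed but independent of
the community stream, so serialization never perturbs the generated data.

## Numerical choices

- Seeding: one global seed per run, split into per-stage seeds via
  `SeedSequence([seed, crc32(stage_name)])`, all below 2^31.
- Rounding: core fraction uses decimal half-up rounding (banker's rounding
  would print 0.2% for 0.25%).
- Zero-coverage pairs are implicit (absent from the matrix) and read as
  max_cov = covered_len = 0.
- Degenerate inputs: empty hit lists annotate as None; empty cores warn
  and share 0; a zero recA count raises naming the sample; a pool smaller
  than `n_draw` raises (library) or falls back with a warning (pipeline).
- Problem sizes in the shipped tests and acceptance script (2,000-contig
  communities, 5,000-item null draws, 400 calibration replicates,
  200-read k-mer subsets) were chosen as the smallest sizes at which the
  statistical checks are stable.

## Known limitations

- The lognormal coverage model is a stand-in; the real contig-abundance
  distribution of any particular study should be checked before treating
  recovery rates as predictive.
- The bias test's null is the pool's sampling distribution, not a model of
  annotation error; it detects compositional departure only.
- Alignment-mode sharing trusts the hit table: it cannot distinguish a
  truly absent sequence from one missed by the upstream search.
- Contiguous presence calling requires original depth tables (the summary
  TSV does not preserve run lengths).
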