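# corecazyome

Identification and profiling of the **core carbohydrate-active gene set**
shared across replicate soil metagenomes.

Soil microbial communities are so diverse that even deep shotgun sequencing
captures only a sliver of their gene content, and most comparative studies
ask what *differs* between soils. This package asks the opposite question:
which carbohydrate-active (CAZy-annotated) sequences are *consistently
present* in every replicate of a site? Such a core is a candidate set of
minimum carbon-cycling functions for that soil, and a tractable target for
follow-up assays.

## The method

Given per-base depth tables of reads mapped to a shared contig reference,
tabular alignment hits against a CAZy protein reference, and per-sample
recA counts:

1. **Coverage** — each contig × sample is summarized by its maximum
   per-base depth `max_cov` and covered length (positions with depth ≥ 1);
   a contig is *present* when `max_cov ≥ 5` and covered length ≥ 100 bp.
2. **Core rule** — the core is the set of CAZy-annotated contigs present
   in **all** replicates; the core fraction is
   `100·|core|/|all CAZy contigs|` (e.g. 843 / 226,887 = 0.4%).
3. **Annotation** — per contig, the best (maximum-bitscore) hit with
   E ≤ 1e-5 defines family, class and taxonomy; exact score ties are
   broken by a seeded random draw. Taxonomy is filtered to
   bacteria/archaea/viruses/fungi.
4. **Abundance** — contig abundance is normalized to copies per recA
   (`max_cov / recA_count`), summed per category (class, family, phylum)
   per sample, and averaged across replicates with SE and a t-based 95% CI.
5. **Bias test** — the core's category distribution is compared against
   `n_rep` random draws of `n_draw` proteins from a reference pool;
   the empirical p-value is `(1 + #{draws ≥ observed})/(n_rep + 1)`.
6. **k-mer core** — an assembly-free check: the fraction of canonical
   k-mers (k = 20) shared by all samples among bootstrap read subsets.
7. **Sharing** — how many core contigs are detectable in other
   metagenomes, by coverage (≥ 5× in ≥ 1 replicate) or by alignment
   (E ≤ 1e-5, length ≥ 70, identity ≥ 70%).

A synthetic-community generator plants an exactly recoverable core inside
replicated mock metagenomes, so the whole pipeline is testable end-to-end
without any external download. See `docs/methods.md` for the full model.

## Worked example

Simulate a four-replicate community of 2,000 contigs with a planted 5%
core, then run every stage:

```sh
corecazyome simulate --out demo --seed 11
```
```text
{"n_contigs": 2000, "n_core": 100, "out": "demo", "samples": ["S1", "S2", "S3", "S4"]}
```

```python
import json
from corecazyome import RunConfig, run_pipeline

paths = json.load(open("demo/manifest.json"))["paths"]
manifest = run_pipeline(RunConfig(
    out_dir="demo_run", seed=11,
    depth=paths["depth"],
    cazy_hits=sorted(paths["cazy_hits"].values()),
    subject_meta=paths["subject_meta"],
    reca_counts=paths["reca_counts"],
    n_draw=100, n_rep=1000,
))
print(json.dumps(manifest["counts"], indent=2))
```
```text
{
  "coverage_entries": 5332,
  "annotated_contigs": 1960,
  "annotated_contigs_kept_domains": 1810,
  "reca_per_sample": {"S1": 1000, "S2": 1137, "S3": 1274, "S4": 1411},
  "core_size": 100,
  "core_size_filtered": 93,
  "bias_class_p": 0.6013986013986014,
  "bias_phylum_p": 0.2787212787212787
}
```

The pipeline recovers exactly the 100 planted core contigs
(`demo_run/core.txt` equals `demo/truth_core.txt`); 93 survive the
taxonomy filter (7 were planted with plant/unknown origins). The bias
p-values ≈ 0.60 and 0.28 correctly fail to flag the core as compositionally
biased — by construction it is drawn from the same category distribution
as the full community. The class-level profile
(`demo_run/profile_class.tsv`) reports prevalence and mean ± SE / 95% CI
of copies-per-recA per CAZy class:

```text
level  label  prevalence  mean      se        ci_low    ci_high
class  CB      9          0.062437  0.004974  0.046608  0.078266
class  CE     19          0.129150  0.008857  0.100962  0.157337
class  GH     31          0.236114  0.032820  0.131666  0.340563
class  GT     25          0.176219  0.022142  0.105753  0.246686
class  PL      1          0.005903  0.000440  0.004503  0.007303
...
```

Prevalences over all classes sum to the filtered core size (93), and
per-sample class abundances sum to the total core abundance — both are
tested invariants.

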