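"""Synthetic replicated metagenomes with a planted, exactly recoverable core.

The generator emulates the statistical structure of a replicated soil
metagenome study: a shared contig reference, per-sample per-base depth
vectors, CAZy family/class and phylum/domain annotations, and per-sample
recA counts for normalization.  A configurable fraction of contigs is
*planted* as core — guaranteed to pass the presence thresholds (depth and
covered length) in every replicate — while every non-core contig is forced
to fail the rule in at least one replicate (by dropout or by capping its
depth just below the threshold), so the true core is unambiguous and
downstream recovery can be checked by exact set equality.

Per-contig mean depth is drawn from a lognormal distribution (heavy right
tail, as is typical of assembled contig abundances); per-base depth is the
rounded mean with +/-1 uniform jitter.  This reproduces the only two
coverage features the analysis consumes — maximum depth and covered
length — without read-level simulation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import ContigAnnotation, class_from_family
from .errors import ConfigurationError
from .coverage import ContigCoverage

#: Domain of origin for each built-in phylum label.  Streptophyta (land
#: plants) is deliberately outside the bacteria/archaea/viruses/fungi set
#: so taxonomy filtering has something to remove.
PHYLUM_DOMAINS = {
    "Proteobacteria": "Bacteria",
    "Actinobacteria": "Bacteria",
    "Firmicutes": "Bacteria",
    "Acidobacteria": "Bacteria",
    "Bacteroidetes": "Bacteria",
    "Verrucomicrobia": "Bacteria",
    "Planctomycetes": "Bacteria",
    "Euryarchaeota": "Archaea",
    "Ascomycota": "Fungi",
    "Uroviricota": "Viruses",
    "Streptophyta": "Eukaryota",
    "unknown": "unknown",
}

DEFAULT_CLASS_FREQS = {
    "GT": 0.28,
    "GH": 0.30,
    "CE": 0.16,
    "CB": 0.10,
    "PL": 0.04,
    "unknown": 0.12,
}

DEFAULT_FAMILY_FREQS = {
    "GT": {"GT2": 0.45, "GT4": 0.35, "GT51": 0.20},
    "GH": {"GH13": 0.30, "GH3": 0.25, "GH94": 0.20, "GH76": 0.15, "GH5": 0.10},
    "CE": {"CE10": 0.55, "CE1": 0.30, "CE4": 0.15},
    "CB": {"CBM32": 0.55, "CBM50": 0.45},
    "PL": {"PL1": 0.65, "PL9": 0.35},
    "unknown": {"unknown": 1.0},
}

DEFAULT_PHYLUM_FREQS = {
    "Proteobacteria": 0.30,
    "Actinobacteria": 0.16,
    "Firmicutes": 0.10,
    "Acidobacteria": 0.08,
    "Bacteroidetes": 0.07,
    "Verrucomicrobia": 0.06,
    "Planctomycetes": 0.05,
    "Euryarchaeota": 0.04,
    "Ascomycota": 0.06,
    "Uroviricota": 0.02,
    "Streptophyta": 0.04,
    "unknown": 0.02,
}


def _check_probs(name: str, freqs: dict[str, float]) -> None:
    if any(v < 0 for v in freqs.values()):
        raise ConfigurationError(f"{name}: negative probability")
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities must sum to 1")


@dataclasses.dataclass
class CommunityConfig:
    """Parameters of one synthetic replicated community.

    Defaults mirror a four-replicate whole-soil design: presence thresholds
    of 5x depth over >= 100 bp, a lognormal contig-abundance distribution,
    and recA counts in the low thousands per replicate.
    """

    n_samples: int = 4
    n_contigs: int = 2000
    core_fraction: float = 0.05
    contig_length_range: tuple[int, int] = (150, 1500)
    coverage_model: tuple[str, dict] = ("lognormal", {"mean": 0.9, "sigma": 1.1})
    presence_min_cov: int = 5
    presence_min_len: int = 100
    class_freqs: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_CLASS_FREQS))
    family_freqs_per_class: dict = dataclasses.field(
        default_factory=lambda: {c: dict(f) for c, f in DEFAULT_FAMILY_FREQS.items()}
    )
    phylum_freqs: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_PHYLUM_FREQS))
    recA_per_sample: tuple[int, ...] | None = None
    dropout_rate: float = 0.3
    tie_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_contigs < 0:
            raise ConfigurationError("n_samples >= 1 and n_contigs >= 0 required")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ConfigurationError("core_fraction must be in [0, 1]")
        lo, hi = self.contig_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("contig_length_range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1]")
        if not 0.0 <= self.tie_fraction <= 1.0:
            raise ConfigurationError("tie_fraction must be in [0, 1]")
        name, _params = self.coverage_model
        if name != "lognormal":
            raise ConfigurationError(f"unsupported coverage model {name!r}")
        _check_probs("class_freqs", self.class_freqs)
        _check_probs("phylum_freqs", self.phylum_freqs)
        for cls, fams in self.family_freqs_per_class.items():
            _check_probs(f"family_freqs_per_class[{cls}]", fams)
        if self.recA_per_sample is None:
            # deterministic defaults in the low thousands, varied per sample
            self.recA_per_sample = tuple(
                1000 + 137 * (i % 7) for i in range(self.n_samples)
            )
        self.recA_per_sample = tuple(int(r) for r in self.recA_per_sample)
        if len(self.recA_per_sample) != self.n_samples:
            raise ConfigurationError("recA_per_sample must have n_samples entries")
        if any(r < 1 for r in self.recA_per_sample):
            raise ConfigurationError("recA_per_sample entries must be >= 1")

    @property
    def n_core(self) -> int:
        return round(self.core_fraction * self.n_contigs)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_samples))

    @classmethod
    def from_yaml(cls, path) -> "CommunityConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("contig_length_range", "recA_per_sample"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "coverage_model" in raw and isinstance(raw["coverage_model"], (list, tuple)):
            raw["coverage_model"] = (raw["coverage_model"][0], dict(raw["coverage_model"][1]))
        return cls(**raw)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of one generated community."""

    config: CommunityConfig
    core_ids: frozenset[str]
    #: contig -> sample -> per-base depth vector; missing samples mean absent.
    per_sample_depth: dict[str, dict[str, np.ndarray]]
    annotations: dict[str, ContigAnnotation]
    sequences: dict[str, str]
    contig_lengths: dict[str, int]

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.config.sample_ids


def _draw_mean_depth(rng: np.random.Generator, cfg: CommunityConfig) -> float:
    _name, params = cfg.coverage_model
    return float(rng.lognormal(params.get("mean", 0.9), params.get("sigma", 1.1)))


def _depth_vector(
    rng: np.random.Generator, length: int, base: int, cap: int | None = None
) -> np.ndarray:
    jitter = rng.integers(-1, 2, size=length)
    depth = np.clip(base + jitter, 1, None)
    if cap is not None:
        depth = np.minimum(depth, cap)
    return depth.astype(np.int64)


def generate_community(config: CommunityConfig) -> SyntheticTruth:
    """Generate a replicated community; deterministic given ``config.seed``.

    Planted core contigs satisfy the presence thresholds in every sample;
    every non-core contig fails them in at least one sample.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    min_cov, min_len = cfg.presence_min_cov, cfg.presence_min_len
    lo, hi = cfg.contig_length_range

    ids = [f"contig_{i:05d}" for i in range(cfg.n_contigs)]
    core_idx = set(rng.choice(cfg.n_contigs, size=cfg.n_core, replace=False).tolist()) if cfg.n_core else set()

    lengths = rng.integers(lo, hi + 1, size=cfg.n_contigs)
    # core contigs must be long enough to satisfy the covered-length rule
    for i in core_idx:
        lengths[i] = max(int(lengths[i]), min_len)

    classes = list(cfg.class_freqs)
    class_p = np.array([cfg.class_freqs[c] for c in classes])
    phyla = list(cfg.phylum_freqs)
    phylum_p = np.array([cfg.phylum_freqs[p] for p in phyla])

    annotations: dict[str, ContigAnnotation] = {}
    sequences: dict[str, str] = {}
    per_sample_depth: dict[str, dict[str, np.ndarray]] = {}
    bases = np.array(list("ACGT"))

    for i, cid in enumerate(ids):
        cls = classes[int(rng.choice(len(classes), p=class_p))]
        fams = cfg.family_freqs_per_class[cls]
        fam_names = list(fams)
        fam = fam_names[int(rng.choice(len(fam_names), p=np.array([fams[f] for f in fam_names])))]
        phylum = phyla[int(rng.choice(len(phyla), p=phylum_p))]
        annotations[cid] = ContigAnnotation(
            contig_id=cid,
            cazy_family=fam,
            cazy_class=class_from_family(fam),
            phylum=phylum,
            domain=PHYLUM_DOMAINS.get(phylum, "unknown"),
            best_evalue=float(10.0 ** rng.uniform(-40, -6)),
            best_bitscore=float(np.round(rng.uniform(60, 300), 1)),
        )
        sequences[cid] = "".join(rng.choice(bases, size=int(lengths[i])))

        depths: dict[str, np.ndarray] = {}
        length = int(lengths[i])
        if i in core_idx:
            for s in cfg.sample_ids:
                mean = max(_draw_mean_depth(rng, cfg), min_cov + 1)
                depths[s] = _depth_vector(rng, length, int(round(mean)))
        else:
            fail_at = int(rng.integers(cfg.n_samples))
            # when min_cov <= 1 no sub-threshold depth exists: always drop out
            fail_by_dropout = bool(rng.random() < 0.5) or min_cov <= 1
            for j, s in enumerate(cfg.sample_ids):
                if j == fail_at:
                    if fail_by_dropout:
                        continue
                    cap = min_cov - 1
                    mean = min(_draw_mean_depth(rng, cfg), cap)
                    depths[s] = _depth_vector(rng, length, max(int(round(mean)), 1), cap=cap)
                else:
                    if rng.random() < cfg.dropout_rate:
                        continue
                    mean = _draw_mean_depth(rng, cfg)
                    depths[s] = _depth_vector(rng, length, max(int(round(mean)), 1))
        per_sample_depth[cid] = depths

    return SyntheticTruth(
        config=cfg,
        core_ids=frozenset(ids[i] for i in core_idx),
        per_sample_depth=per_sample_depth,
        annotations=annotations,
        sequences=sequences,
        contig_lengths={cid: int(lengths[i]) for i, cid in enumerate(ids)},
    )


def coverage_truth(truth: SyntheticTruth) -> dict[tuple[str, str], ContigCoverage]:
    """Per-(contig, sample) coverage summaries computed directly from the
    emitted depth vectors — the generator-side ground truth."""
    out = {}
    for cid, per_sample in truth.per_sample_depth.items():
        for sid, depth in per_sample.items():
            covered = depth >= 1
            max_cov = int(depth.max()) if depth.size else 0
            out[(cid, sid)] = ContigCoverage(cid, max_cov, int(covered.sum()))
    return out


def _subject_id(ann: ContigAnnotation, variant: int = 0) -> str:
    return f"CAZY|{ann.cazy_family}|{ann.phylum}|{variant:03d}"


def write_fixture(truth: SyntheticTruth, out_dir) -> dict:
    """Write a complete on-disk fixture and return a manifest of paths.

    Emits per-sample depth TSVs (samtools-depth dialect), per-sample CAZy
    hit tables (12-column BLAST tabular, consistent with the planted
    annotations and containing score-tied duplicate rows for a configured
    fraction of contigs), per-sample recA hit tables, a subject metadata
    table, the annotation table, contig FASTA, recA counts, and the true
    core list.  Byte-identical for identical (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    # independent stream so fixture serialization never perturbs community RNG
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    manifest: dict = {"samples": list(truth.sample_ids), "paths": {}}
    paths = manifest["paths"]

    contig_order = sorted(truth.per_sample_depth)

    paths["depth"] = {}
    for sid in truth.sample_ids:
        p = out / f"depth_{sid}.tsv"
        with open(p, "w") as fh:
            for cid in contig_order:
                depth = truth.per_sample_depth[cid].get(sid)
                if depth is None:
                    continue
                for pos, d in enumerate(depth, start=1):
                    if d >= 1:
                        fh.write(f"{cid}\t{pos}\t{int(d)}\n")
        paths["depth"][sid] = str(p)

    ann_path = out / "annotations.tsv"
    with open(ann_path, "w") as fh:
        fh.write("contig_id\tcazy_family\tcazy_class\tphylum\tdomain\n")
        for cid in contig_order:
            a = truth.annotations[cid]
            fh.write(f"{cid}\t{a.cazy_family}\t{a.cazy_class}\t{a.phylum}\t{a.domain}\n")
    paths["annotations"] = str(ann_path)

    # subject metadata: two reference-protein variants per annotation so that
    # score-tied duplicate hits can point at distinct subjects
    meta_path = out / "subject_meta.tsv"
    seen: set[str] = set()
    with open(meta_path, "w") as fh:
        fh.write("subject_id\tcazy_family\tcazy_class\tphylum\tdomain\n")
        for cid in contig_order:
            a = truth.annotations[cid]
            for variant in (0, 1):
                sid_ = _subject_id(a, variant)
                if sid_ not in seen:
                    seen.add(sid_)
                    fh.write(
                        f"{sid_}\t{a.cazy_family}\t{a.cazy_class}\t{a.phylum}\t{a.domain}\n"
                    )
    paths["subject_meta"] = str(meta_path)

    tie_ids = {
        cid for cid in contig_order if rng.random() < cfg.tie_fraction
    }
    paths["cazy_hits"] = {}
    for sid in truth.sample_ids:
        p = out / f"cazy_hits_{sid}.tsv"
        with open(p, "w") as fh:
            for cid in contig_order:
                if sid not in truth.per_sample_depth[cid]:
                    continue
                a = truth.annotations[cid]
                length = max(truth.contig_lengths[cid] // 3, 30)
                pident = float(np.round(rng.uniform(40, 99), 1))

                def row(subject: str, evalue: float, bitscore: float) -> str:
                    return (
                        f"{cid}\t{subject}\t{pident}\t{length}\t"
                        f"{max(1, int(length * 0.1))}\t0\t1\t{length}\t1\t{length}\t"
                        f"{evalue:.2e}\t{bitscore:.1f}\n"
                    )

                fh.write(row(_subject_id(a, 0), a.best_evalue, a.best_bitscore))
                if cid in tie_ids:
                    # exact-score duplicate: same annotation, distinct subject
                    fh.write(row(_subject_id(a, 1), a.best_evalue, a.best_bitscore))
                # decoy below the best score; sometimes above the E-value cutoff
                decoy_e = a.best_evalue * 10 if rng.random() < 0.5 else 1e-3
                fh.write(row(_subject_id(a, 0), decoy_e, a.best_bitscore - 10.0))
        paths["cazy_hits"][sid] = str(p)

    paths["reca_hits"] = {}
    for j, sid in enumerate(truth.sample_ids):
        p = out / f"reca_hits_{sid}.tsv"
        with open(p, "w") as fh:
            for q in range(cfg.recA_per_sample[j]):
                fh.write(
                    f"{sid}_read_{q:06d}\trecA|SS04542\t85.0\t120\t18\t0\t1\t120\t1\t120\t"
                    f"1.00e-20\t180.0\n"
                )
        paths["reca_hits"][sid] = str(p)

    reca_path = out / "reca_counts.tsv"
    with open(reca_path, "w") as fh:
        fh.write("sample_id\treca_count\n")
        for j, sid in enumerate(truth.sample_ids):
            fh.write(f"{sid}\t{cfg.recA_per_sample[j]}\n")
    paths["reca_counts"] = str(reca_path)

    fasta_path = out / "contigs.fasta"
    records = [
        SeqRecord(Seq(truth.sequences[cid]), id=cid, description="")
        for cid in contig_order
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    paths["contigs_fasta"] = str(fasta_path)

    truth_path = out / "truth_core.txt"
    with open(truth_path, "w") as fh:
        for cid in sorted(truth.core_ids):
            fh.write(f"{cid}\n")
    paths["truth_core"] = str(truth_path)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
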