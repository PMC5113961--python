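"""End-to-end pipeline: coverage -> annotate -> core -> profile -> bias -> share.

Stages communicate only through the declared TSV/JSON files, never via
in-memory handoff, so any stage can be re-run independently and the whole
analysis is auditable from its manifest.  Stages whose inputs are absent
are skipped with a warning.  One global seed is split into per-stage seeds
by a fixed derivation so stage-level runs are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, annotate, bias, coreset, coverage, sharing
from .errors import InputError

logger = logging.getLogger(__name__)

STAGES = ("coverage", "annotate", "core", "profile", "bias", "share")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed (< 2**31) from the global seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class RunConfig:
    """Inputs, thresholds and seed of one pipeline run.

    Threshold defaults are the study defaults: presence at >= 5x maximum
    depth over >= 100 covered bp in all replicates, CAZy hits at
    E <= 1e-5, recA hits at E < 1e-5, remote sharing at E <= 1e-5 with
    alignment length >= 70 and identity >= 70%.
    """

    out_dir: str = "corecazyome_out"
    seed: int = 0
    # inputs; sample order of `depth` defines the replicate order
    depth: dict = dataclasses.field(default_factory=dict)  # sample -> depth TSV
    cazy_hits: list = dataclasses.field(default_factory=list)
    subject_meta: str | None = None
    reca_counts: str | None = None
    reca_hits: dict = dataclasses.field(default_factory=dict)  # sample -> hits TSV
    share_targets: list = dataclasses.field(default_factory=list)
    # thresholds
    min_cov: int = 5
    min_len: int = 100
    contiguous: bool = False
    max_evalue: float = 1e-5
    reca_max_evalue: float = 1e-5
    reca_strict: bool = True
    keep_domains: list = dataclasses.field(
        default_factory=lambda: sorted(annotate.DEFAULT_KEEP_DOMAINS)
    )
    n_draw: int = 50_000
    n_rep: int = 1000
    bias_replace: bool = False
    share_min_length: int = 70
    share_min_pident: float = 70.0
    share_min_samples: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _result_to_json(res: bias.BiasTestResult) -> dict:
    return {
        "statistic": res.statistic,
        "observed_statistic": res.observed_statistic,
        "p_empirical": res.p_empirical,
        "n_rep": len(res.null_draws),
        "per_category": {
            cat: {
                "observed_freq": obs,
                "null_mean": mean,
                "null_sd": sd,
                "z": None if np.isnan(z) else z,
            }
            for cat, (obs, mean, sd, z) in res.per_category_enrichment.items()
        },
        "per_category_pvalues": res.per_category_pvalues,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages whose inputs are available; return the manifest."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {}
    for sample, p in cfg.depth.items():
        inputs[f"depth:{sample}"] = p
    for i, p in enumerate(cfg.cazy_hits):
        inputs[f"cazy_hits:{i}"] = p
    if cfg.subject_meta:
        inputs["subject_meta"] = cfg.subject_meta
    if cfg.reca_counts:
        inputs["reca_counts"] = cfg.reca_counts
    for sample, p in cfg.reca_hits.items():
        inputs[f"reca_hits:{sample}"] = p
    missing = [p for p in inputs.values() if not Path(p).exists()]
    if missing:
        raise InputError(f"missing input file(s): {missing}")

    manifest: dict = {
        "parameters": dataclasses.asdict(cfg),
        "input_checksums": {k: _sha256(p) for k, p in sorted(inputs.items())},
        "stages": {},
        "outputs": {},
        "counts": {},
    }

    samples = list(cfg.depth)
    matrix = None
    annotations = None
    annotations_kept = None
    reca = None
    core = None
    core_filtered = None

    # --- coverage ---------------------------------------------------------
    if cfg.depth:
        matrix = coverage.CoverageMatrix.from_depth_files(
            [cfg.depth[s] for s in samples], samples
        )
        p = out / "coverage_summary.tsv"
        matrix.write_summary(p, cfg.min_cov, cfg.min_len, cfg.contiguous)
        manifest["stages"]["coverage"] = "run"
        manifest["outputs"]["coverage_summary"] = str(p)
        manifest["counts"]["coverage_entries"] = len(matrix)
        logger.info("coverage: %d entries over %d samples", len(matrix), len(samples))
    else:
        manifest["stages"]["coverage"] = "skipped"
        logger.warning("coverage stage skipped: no depth tables configured")

    # --- annotate ---------------------------------------------------------
    if cfg.cazy_hits and cfg.subject_meta:
        hits = pd.concat(
            [annotate.read_blast_tab(p) for p in cfg.cazy_hits], ignore_index=True
        )
        meta = annotate.read_subject_meta(cfg.subject_meta)
        annotations = annotate.annotate_table(
            hits, meta, max_evalue=cfg.max_evalue, seed=stage_seed(cfg.seed, "annotate")
        )
        annotations_kept = annotate.filter_taxa(annotations, set(cfg.keep_domains))
        p = out / "annotations.tsv"
        annotate.write_annotations(annotations, p)
        manifest["stages"]["annotate"] = "run"
        manifest["outputs"]["annotations"] = str(p)
        manifest["counts"]["annotated_contigs"] = len(annotations)
        manifest["counts"]["annotated_contigs_kept_domains"] = len(annotations_kept)
    else:
        manifest["stages"]["annotate"] = "skipped"
        logger.warning("annotate stage skipped: hits or subject metadata absent")

    if cfg.reca_counts:
        df = pd.read_csv(cfg.reca_counts, sep="\t", dtype={"sample_id": str})
        reca = dict(zip(df["sample_id"], df["reca_count"].astype(int)))
    elif cfg.reca_hits:
        reca = {
            s: annotate.count_recA(
                annotate.read_blast_tab(p),
                max_evalue=cfg.reca_max_evalue,
                strict=cfg.reca_strict,
            )
            for s, p in cfg.reca_hits.items()
        }
    if reca is not None:
        p = out / "reca_counts.tsv"
        pd.DataFrame(
            {"sample_id": list(reca), "reca_count": list(reca.values())}
        ).to_csv(p, sep="\t", index=False)
        manifest["outputs"]["reca_counts"] = str(p)
        manifest["counts"]["reca_per_sample"] = reca

    # --- core -------------------------------------------------------------
    if matrix is not None:
        restrict = {a.contig_id for a in annotations} if annotations else None
        core = coreset.call_core(
            matrix,
            min_cov=cfg.min_cov,
            min_len=cfg.min_len,
            samples=samples,
            contiguous=cfg.contiguous,
            restrict_to=restrict,
        )
        p = out / "core.txt"
        coreset.write_core_list(core, p)
        manifest["outputs"]["core"] = str(p)
        manifest["counts"]["core_size"] = len(core)
        if annotations_kept is not None:
            kept_ids = {a.contig_id for a in annotations_kept}
            core_filtered = coreset.CoreSet(
                contig_ids=frozenset(core.contig_ids & kept_ids),
                min_cov=core.min_cov,
                min_len=core.min_len,
                required_samples=core.required_samples,
                annotation_filtered=True,
            )
            p2 = out / "core_filtered.txt"
            coreset.write_core_list(core_filtered, p2)
            manifest["outputs"]["core_filtered"] = str(p2)
            manifest["counts"]["core_size_filtered"] = len(core_filtered)
        report = {
            "min_cov": cfg.min_cov,
            "min_len": cfg.min_len,
            "samples": samples,
            "n_contigs": len(matrix.contig_ids),
            "core_size": len(core),
            "core_size_filtered": len(core_filtered) if core_filtered else None,
            "core_fraction_pct": coreset.core_fraction(
                len(core), max(len(matrix.contig_ids), 1)
            ),
        }
        p3 = out / "core_report.json"
        with open(p3, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["stages"]["core"] = "run"
        manifest["outputs"]["core_report"] = str(p3)
    else:
        manifest["stages"]["core"] = "skipped"

    # --- profile ----------------------------------------------------------
    profile_core = core_filtered if core_filtered is not None else core
    if profile_core is not None and annotations is not None and reca is not None:
        norm = abundance.normalize(matrix, reca)
        for level in ("class", "family", "phylum"):
            prof = abundance.profile(
                profile_core, annotations, norm, group_by=level, samples=samples
            )
            p = out / f"profile_{level}.tsv"
            prof.to_csv(p, sep="\t", index=False)
            manifest["outputs"][f"profile_{level}"] = str(p)
        manifest["stages"]["profile"] = "run"
    else:
        manifest["stages"]["profile"] = "skipped"
        logger.warning("profile stage skipped: core, annotations or recA counts absent")

    # --- bias test --------------------------------------------------------
    if profile_core is not None and annotations is not None and len(profile_core):
        ann_map = {a.contig_id: a for a in annotations}
        for field, getter in (
            ("class", lambda a: a.cazy_class),
            ("phylum", lambda a: a.phylum),
        ):
            observed = [getter(ann_map[c]) for c in sorted(profile_core.contig_ids)]
            pool = [getter(a) for a in annotations]
            n_draw, replace = cfg.n_draw, cfg.bias_replace
            if not replace and n_draw > len(pool):
                logger.warning(
                    "bias(%s): pool of %d smaller than n_draw=%d; sampling with replacement",
                    field, len(pool), n_draw,
                )
                replace = True
            res = bias.bias_test(
                observed,
                pool,
                n_draw=n_draw,
                n_rep=cfg.n_rep,
                seed=stage_seed(cfg.seed, f"bias:{field}"),
                replace=replace,
            )
            p = out / f"bias_{field}.json"
            with open(p, "w") as fh:
                json.dump(_result_to_json(res), fh, indent=2, sort_keys=True)
                fh.write("\n")
            manifest["outputs"][f"bias_{field}"] = str(p)
            manifest["counts"][f"bias_{field}_p"] = res.p_empirical
        manifest["stages"]["bias"] = "run"
    else:
        manifest["stages"]["bias"] = "skipped"

    # --- sharing ----------------------------------------------------------
    if profile_core is not None and cfg.share_targets:
        records = []
        for target in cfg.share_targets:
            mode = target.get("mode", "coverage")
            if mode == "coverage":
                t_samples = target["samples"]
                t_matrix = coverage.CoverageMatrix.from_depth_files(
                    [target["depth"][s] for s in t_samples], t_samples
                )
                rec = sharing.shared_by_coverage(
                    profile_core,
                    t_matrix,
                    min_cov=cfg.min_cov,
                    min_len=cfg.min_len,
                    min_samples=cfg.share_min_samples,
                    contiguous=cfg.contiguous,
                    metagenome_id=target["metagenome_id"],
                    group_label=target.get("group_label", ""),
                )
            elif mode == "alignment":
                rec = sharing.shared_by_alignment(
                    profile_core,
                    annotate.read_blast_tab(target["hits"]),
                    max_evalue=cfg.max_evalue,
                    min_length=cfg.share_min_length,
                    min_pident=cfg.share_min_pident,
                    metagenome_id=target["metagenome_id"],
                    group_label=target.get("group_label", ""),
                )
            else:
                raise InputError(f"unknown sharing mode {mode!r}")
            records.append(rec)
        p = out / "sharing.tsv"
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            p, sep="\t", index=False
        )
        p2 = out / "sharing_groups.tsv"
        sharing.summarize_groups(records).to_csv(p2, sep="\t", index=False)
        manifest["stages"]["share"] = "run"
        manifest["outputs"]["sharing"] = str(p)
        manifest["outputs"]["sharing_groups"] = str(p2)
    else:
        manifest["stages"]["share"] = "skipped"

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
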