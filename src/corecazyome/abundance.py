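"""recA-normalized abundance and replicate-averaged category profiles.

To compare contig abundances across samples of very different sequencing
depth, each contig's coverage (its maximum base-pair depth) is divided by
the sample's estimated count of recA genes, a near-universal single-copy
marker; the resulting unit is copies per recA.

Profiles aggregate the normalized abundance of core contigs by CAZy class,
CAZy family, phylum, or family x phylum: within each sample the
copies-per-recA values of the group's contigs are summed, and the
per-sample sums are then averaged across replicates with a standard error
and a t-based 95% confidence interval (n = 4 replicates gives
t(0.975, 3) = 3.1824).  Prevalence is the number of distinct core contigs
in a group, so prevalences over any grouping level sum to the core size.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import ContigAnnotation
from .coreset import CoreSet
from .coverage import CoverageMatrix
from .errors import InputError, NormalizationError

GROUP_LEVELS = ("class", "family", "phylum", "family_phylum")

PROFILE_COLUMNS = ("level", "label", "prevalence", "mean", "se", "ci_low", "ci_high")


@dataclasses.dataclass(frozen=True)
class NormalizedAbundance:
    contig_id: str
    sample_id: str
    copies_per_recA: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.copies_per_recA) or self.copies_per_recA < 0:
            raise InputError("copies_per_recA must be finite and non-negative")


def normalize(
    matrix: CoverageMatrix,
    recA_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Per-(contig, sample) copies-per-recA for entries with nonzero coverage.

    Returns a long DataFrame with columns contig_id, sample_id,
    copies_per_recA.  Raises :class:`NormalizationError` naming the sample
    if any sample's recA count is below 1.
    """
    for s in matrix.samples:
        if recA_counts.get(s, 0) < 1:
            raise NormalizationError(f"sample {s!r} has recA count < 1")
    rows = [
        {
            "contig_id": cid,
            "sample_id": sid,
            "copies_per_recA": cov.max_cov / recA_counts[sid],
        }
        for (cid, sid), cov in sorted(matrix.items())
        if cov.max_cov > 0
    ]
    return pd.DataFrame(rows, columns=["contig_id", "sample_id", "copies_per_recA"])


def _group_label(ann: ContigAnnotation, level: str) -> str:
    if level == "class":
        return ann.cazy_class
    if level == "family":
        return ann.cazy_family
    if level == "phylum":
        return ann.phylum
    if level == "family_phylum":
        return f"{ann.cazy_family}|{ann.phylum}"
    raise InputError(f"unknown grouping level {level!r}; use one of {GROUP_LEVELS}")


def profile(
    core: CoreSet,
    annotations: Iterable[ContigAnnotation],
    abundances: pd.DataFrame,
    group_by: str = "class",
    samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Replicate-averaged abundance profile of the core at one grouping level.

    Every core contig must carry an annotation; contigs whose category is
    unresolved fall into the explicit "unknown" group, so group abundances
    always sum to the total core abundance per sample.  With a single
    replicate, SE and CI are reported as missing (NaN), not zero.
    """
    ann_map = {a.contig_id: a for a in annotations}
    missing = core.contig_ids - ann_map.keys()
    if missing:
        raise InputError(
            f"{len(missing)} core contigs lack annotations, e.g. {sorted(missing)[:3]}"
        )
    if samples is None:
        samples = core.required_samples or tuple(sorted(abundances["sample_id"].unique()))
    samples = list(samples)
    if not samples:
        raise InputError("at least one replicate sample is required")

    labels = {cid: _group_label(ann_map[cid], group_by) for cid in core.contig_ids}
    ab = abundances[abundances["contig_id"].isin(core.contig_ids)].copy()
    ab["label"] = ab["contig_id"].map(labels)

    per_sample = (
        ab.pivot_table(
            index="label",
            columns="sample_id",
            values="copies_per_recA",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=samples, fill_value=0.0)
    )
    # groups present in the core but with zero abundance rows still appear
    all_labels = sorted(set(labels.values()))
    per_sample = per_sample.reindex(index=all_labels, fill_value=0.0)

    prevalence = pd.Series(labels).groupby(pd.Series(labels)).size()
    prevalence = prevalence.reindex(all_labels, fill_value=0)

    n = len(samples)
    values = per_sample.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    if n > 1:
        sd = values.std(axis=1, ddof=1)
        se = sd / np.sqrt(n)
        t_crit = stats.t.ppf(0.975, n - 1)
        ci_low = mean - t_crit * se
        ci_high = mean + t_crit * se
    else:
        se = np.full_like(mean, np.nan)
        ci_low = np.full_like(mean, np.nan)
        ci_high = np.full_like(mean, np.nan)

    out = pd.DataFrame(
        {
            "level": group_by,
            "label": all_labels,
            "prevalence": prevalence.to_numpy(),
            "mean": mean,
            "se": se,
            "ci_low": ci_low,
            "ci_high": ci_high,
        }
    )
    for i, s in enumerate(samples):
        out[f"sum_{s}"] = values[:, i]
    return out
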