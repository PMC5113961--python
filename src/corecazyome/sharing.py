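"""Detection of core contigs in other metagenomes.

Two detection modes mirror how target data are available:

* coverage mode — the target metagenome's reads were mapped onto the same
  contig reference, so a core contig is *shared* when it passes the
  presence rule in at least ``min_samples`` of the target's replicates;
* alignment mode — only similarity search hits of core contigs against the
  target reads exist, so a core contig is shared when at least one of its
  hits passes E-value <= 1e-5, alignment length >= 70 and identity >= 70%
  (defaults; all configurable).

Group summaries report the mean and dispersion of shared counts across the
metagenomes of a habitat group (grassland, agricultural, forest, ...).
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .coreset import CoreSet
from .coverage import CoverageMatrix, is_present

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SharingRecord:
    metagenome_id: str
    group_label: str
    n_shared: int
    mode: str  # "coverage" | "alignment"


def shared_by_coverage(
    core: CoreSet,
    matrix: CoverageMatrix,
    min_cov: int = 5,
    min_len: int = 100,
    min_samples: int = 1,
    contiguous: bool = False,
    metagenome_id: str = "",
    group_label: str = "",
) -> SharingRecord:
    """Count core contigs present in >= min_samples of the target's samples."""
    if not core.contig_ids:
        logger.warning("empty core set: n_shared is trivially 0")
        return SharingRecord(metagenome_id, group_label, 0, "coverage")
    n_shared = sum(
        1
        for cid in core.contig_ids
        if sum(
            is_present(matrix.get(cid, s), min_cov, min_len, contiguous)
            for s in matrix.samples
        )
        >= min_samples
    )
    return SharingRecord(metagenome_id, group_label, n_shared, "coverage")


def shared_by_alignment(
    core: CoreSet,
    hits: pd.DataFrame,
    max_evalue: float = 1e-5,
    min_length: int = 70,
    min_pident: float = 70.0,
    best_hit_only: bool = False,
    metagenome_id: str = "",
    group_label: str = "",
) -> SharingRecord:
    """Count core contigs with at least one qualifying hit against the target.

    ``hits`` is a BLAST-tabular DataFrame (qseqid, pident, length, evalue,
    bitscore, ...) with core contigs as queries; hits from non-core queries
    are ignored with a logged count.  ``best_hit_only`` restricts the scan
    to each query's maximal-bitscore hits before thresholding.
    """
    if hits.empty:
        return SharingRecord(metagenome_id, group_label, 0, "alignment")
    hits = hits.copy()
    hits["qseqid"] = hits["qseqid"].astype(str)
    in_core = hits["qseqid"].isin(core.contig_ids)
    n_foreign = int((~in_core).sum())
    if n_foreign:
        logger.warning("ignored %d hits from non-core queries", n_foreign)
    hits = hits[in_core]
    if hits.empty:
        return SharingRecord(metagenome_id, group_label, 0, "alignment")
    if best_hit_only:
        top = hits.groupby("qseqid")["bitscore"].transform("max")
        hits = hits[hits["bitscore"] == top]
    passing = hits[
        (hits["evalue"] <= max_evalue)
        & (hits["length"] >= min_length)
        & (hits["pident"] >= min_pident)
    ]
    return SharingRecord(
        metagenome_id,
        group_label,
        int(passing["qseqid"].nunique()),
        "alignment",
    )


def summarize_groups(records: Sequence[SharingRecord]) -> pd.DataFrame:
    """Per-group mean and dispersion of shared counts.

    Reports both SD and SE (= sd/sqrt(n)); groups with a single metagenome
    report both as missing.  Rows are sorted by group label.
    """
    df = pd.DataFrame(
        [
            {"group_label": r.group_label, "metagenome_id": r.metagenome_id, "n_shared": r.n_shared}
            for r in records
        ]
    )
    rows = []
    for label, grp in sorted(df.groupby("group_label"), key=lambda kv: kv[0]):
        vals = grp["n_shared"].to_numpy(dtype=float)
        n = len(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
        rows.append(
            {
                "group_label": label,
                "n_metagenomes": n,
                "mean": float(vals.mean()),
                "sd": sd,
                "se": sd / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["group_label", "n_metagenomes", "mean", "sd", "se"])
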