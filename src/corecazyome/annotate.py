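"""Best-hit CAZy annotation, taxonomy filtering and recA counting.

Each contig is characterized by its single best-scoring alignment against a
CAZy protein reference: hits with E-value above the cutoff are discarded,
the surviving hit with the highest bitscore wins, and exact bitscore ties
are broken by a seeded uniform random draw (made order-independent by
sorting the tied candidates by subject identifier first).

The CAZy class of a contig is derived from its family label prefix
(GH13 -> GH, GT2 -> GT, CE10 -> CE, PL1 -> PL, CBM32/CB32 -> CB); anything
else maps to "unknown".

recA, a near-universal single-copy gene, is counted per sample (distinct
query sequences with a qualifying hit) and used downstream to normalize
contig abundances across samples of different sequencing depth.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

CAZY_CLASSES = ("GT", "GH", "CE", "CB", "PL", "unknown")

#: 12-column BLAST tabular (outfmt 6) field names.
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

SUBJECT_META_COLUMNS = ("subject_id", "cazy_family", "cazy_class", "phylum", "domain")
ANNOTATION_COLUMNS = ("contig_id", "cazy_family", "cazy_class", "phylum", "domain")

DEFAULT_KEEP_DOMAINS = frozenset({"Bacteria", "Archaea", "Viruses", "Fungi"})


@dataclasses.dataclass(frozen=True)
class AlignmentHit:
    """One tabular alignment row, optionally joined with subject metadata."""

    query_id: str
    subject_id: str
    pident: float
    length: int
    evalue: float
    bitscore: float
    subject_family: str = "unknown"
    subject_phylum: str = "unknown"
    subject_domain: str = "unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise InputError(f"pident out of [0, 100]: {self.pident}")
        if self.length < 1:
            raise InputError(f"alignment length must be >= 1: {self.length}")
        if self.evalue < 0:
            raise InputError(f"negative E-value: {self.evalue}")

    @property
    def subject_class(self) -> str:
        return class_from_family(self.subject_family)


@dataclasses.dataclass(frozen=True)
class ContigAnnotation:
    contig_id: str
    cazy_family: str
    cazy_class: str
    phylum: str
    domain: str
    best_evalue: float = np.nan
    best_bitscore: float = np.nan
    tie_broken: bool = False


def class_from_family(family: str) -> str:
    """Map a CAZy family label to its class by prefix; unknown otherwise."""
    fam = (family or "").strip()
    for prefix in ("GH", "GT", "CE", "PL"):
        if fam.startswith(prefix) and fam[len(prefix):len(prefix) + 1].isdigit():
            return prefix
    if fam.startswith("CBM") or (fam.startswith("CB") and fam[2:3].isdigit()):
        return "CB"
    return "unknown"


def best_hit(
    hits: Sequence[AlignmentHit],
    max_evalue: float = 1e-5,
    seed: int | np.random.Generator = 0,
) -> ContigAnnotation | None:
    """Resolve one contig's annotation from its alignment hits.

    Returns None when no hit survives the E-value cutoff.  Exact bitscore
    ties are broken uniformly at random with the given seed after sorting
    the tied candidates by subject_id, so the outcome does not depend on
    input order.
    """
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise InputError(f"hits span multiple queries: {sorted(queries)}")
    survivors = [h for h in hits if h.evalue <= max_evalue]
    if not survivors:
        return None
    top = max(h.bitscore for h in survivors)
    tied = sorted((h for h in survivors if h.bitscore == top), key=lambda h: h.subject_id)
    if len(tied) == 1:
        chosen, tie_broken = tied[0], False
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        chosen, tie_broken = tied[rng.integers(len(tied))], True
    return ContigAnnotation(
        contig_id=chosen.query_id,
        cazy_family=chosen.subject_family,
        cazy_class=chosen.subject_class,
        phylum=chosen.subject_phylum,
        domain=chosen.subject_domain,
        best_evalue=min(h.evalue for h in tied),
        best_bitscore=top,
        tie_broken=tie_broken,
    )


def read_blast_tab(path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular file (no header)."""
    return pd.read_csv(
        path,
        sep="\t",
        names=list(BLAST6_COLUMNS),
        header=None,
        dtype={"qseqid": str, "sseqid": str},
    )


def read_subject_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SUBJECT_META_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"subject metadata missing columns: {sorted(missing)}")
    return df


def annotate_table(
    hits: pd.DataFrame,
    subject_meta: pd.DataFrame,
    max_evalue: float = 1e-5,
    seed: int = 0,
) -> list[ContigAnnotation]:
    """Resolve best-hit annotations for every query in a hit table.

    Queries are processed in sorted order with a single seeded generator so
    the full annotation set is reproducible and independent of row order.
    Subjects absent from the metadata table annotate as unknown/unknown.
    """
    meta = subject_meta.set_index("subject_id")
    merged = hits.merge(
        meta[["cazy_family", "phylum", "domain"]],
        left_on="sseqid",
        right_index=True,
        how="left",
    )
    merged[["cazy_family", "phylum", "domain"]] = (
        merged[["cazy_family", "phylum", "domain"]].fillna("unknown")
    )
    rng = np.random.default_rng(seed)
    out: list[ContigAnnotation] = []
    for qid, group in sorted(merged.groupby("qseqid"), key=lambda kv: kv[0]):
        q_hits = [
            AlignmentHit(
                query_id=str(qid),
                subject_id=str(r.sseqid),
                pident=float(r.pident),
                length=int(r.length),
                evalue=float(r.evalue),
                bitscore=float(r.bitscore),
                subject_family=str(r.cazy_family),
                subject_phylum=str(r.phylum),
                subject_domain=str(r.domain),
            )
            for r in group.itertuples(index=False)
        ]
        ann = best_hit(q_hits, max_evalue=max_evalue, seed=rng)
        if ann is not None:
            out.append(ann)
    return out


def filter_taxa(
    annotations: Iterable[ContigAnnotation],
    keep_domains: frozenset[str] | set[str] = DEFAULT_KEEP_DOMAINS,
) -> list[ContigAnnotation]:
    """Retain annotations whose domain is in ``keep_domains``; order preserved."""
    keep = set(keep_domains)
    return [a for a in annotations if a.domain in keep]


def count_recA(
    hits,
    max_evalue: float = 1e-5,
    strict: bool = True,
) -> int:
    """Count distinct query sequences with a qualifying recA hit.

    ``hits`` is a DataFrame with qseqid/evalue columns or an iterable of
    :class:`AlignmentHit`.  ``strict=True`` requires evalue strictly below
    the cutoff; ``strict=False`` allows equality.
    """
    if isinstance(hits, pd.DataFrame):
        pairs = zip(hits["qseqid"].astype(str), hits["evalue"].astype(float))
    else:
        pairs = ((h.query_id, h.evalue) for h in hits)
    qualifying = {
        q for q, e in pairs if (e < max_evalue if strict else e <= max_evalue)
    }
    return len(qualifying)


def annotations_to_frame(annotations: Iterable[ContigAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "contig_id": a.contig_id,
            "cazy_family": a.cazy_family,
            "cazy_class": a.cazy_class,
            "phylum": a.phylum,
            "domain": a.domain,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def read_annotations(path) -> list[ContigAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"annotation table missing columns: {sorted(missing)}")
    return [
        ContigAnnotation(
            contig_id=r.contig_id,
            cazy_family=r.cazy_family,
            cazy_class=r.cazy_class,
            phylum=r.phylum,
            domain=r.domain,
        )
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations: Iterable[ContigAnnotation], path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)
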