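"""k-mer set intersection across samples: a sequencing-depth view of the core.

Contig-level core calling depends on assembly; an assembly-free alternative
asks what fraction of the distinct k-mers in equal-size read subsets is
shared by *all* samples.  k-mers are canonicalized (lexicographic minimum
of a k-mer and its reverse complement) so the measure is strand-agnostic.
The core fraction per bootstrap is |intersection across samples| divided by
|union across samples| (the union being the total unique k-mer count; a
per-sample-mean denominator is available as an option).
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import InputError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int) -> set[str]:
    """All canonical k-mers of a sequence; k-mers with non-ACGT bases are skipped."""
    if k < 1:
        raise InputError("k must be >= 1")
    s = seq.upper()
    out: set[str] = set()
    for i in range(len(s) - k + 1):
        km = s[i : i + k]
        if not _VALID.issuperset(km):
            continue
        rc = reverse_complement(km)
        out.add(km if km <= rc else rc)
    return out


@dataclasses.dataclass(frozen=True)
class KmerCoreEstimate:
    k: int
    subset_size: int
    n_boot: int
    core_fraction_per_boot: tuple[float, ...]
    unique_kmer_counts: dict[str, tuple[int, ...]]
    skipped_short_reads: int = 0

    @property
    def mean_core_fraction(self) -> float:
        return float(np.mean(self.core_fraction_per_boot))


def _load_reads(source) -> list[str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
        return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]
    return [str(s) for s in source]


def kmer_core_fraction(
    read_sets: Mapping[str, Sequence[str]] | Sequence,
    k: int = 20,
    subset_size: int = 1000,
    n_boot: int = 4,
    seed: int = 0,
    denominator: str = "union",
) -> KmerCoreEstimate:
    """Bootstrap estimate of the across-sample core k-mer fraction.

    ``read_sets`` maps sample id to reads (sequences or a FASTA/FASTQ path);
    a plain sequence of paths uses file stems as sample ids.  Per bootstrap,
    ``subset_size`` reads are subsampled without replacement from each
    sample; reads are sorted before subsampling so the result is invariant
    to read order within a sample and to sample ordering.

    Reads shorter than k contribute no k-mers and are counted in
    ``skipped_short_reads``.
    """
    if denominator not in ("union", "mean"):
        raise InputError("denominator must be 'union' or 'mean'")
    if not isinstance(read_sets, Mapping):
        paths = [Path(p) for p in read_sets]
        read_sets = {p.stem: p for p in paths}
    samples = sorted(read_sets)
    if not samples:
        raise InputError("at least one read set is required")
    reads = {s: sorted(_load_reads(read_sets[s])) for s in samples}
    for s, rs in reads.items():
        if len(rs) < subset_size:
            raise InputError(
                f"sample {s!r} has {len(rs)} reads, fewer than subset_size={subset_size}"
            )

    fractions: list[float] = []
    counts: dict[str, list[int]] = {s: [] for s in samples}
    skipped = 0
    for boot in range(n_boot):
        sets: dict[str, set[str]] = {}
        for s in samples:
            # one generator per (boot, sample-independent) stream: samples
            # with identical sorted reads receive identical subsets, so the
            # identical-read-sets limit gives a core fraction of exactly 1
            rng = np.random.default_rng(np.random.SeedSequence([seed, boot]))
            idx = rng.choice(len(reads[s]), size=subset_size, replace=False)
            kmers: set[str] = set()
            for i in idx:
                read = reads[s][i]
                if len(read) < k:
                    skipped += 1
                    continue
                kmers |= canonical_kmers(read, k)
            sets[s] = kmers
            counts[s].append(len(kmers))
        core = set.intersection(*sets.values())
        union = set.union(*sets.values())
        if denominator == "union":
            denom = len(union)
        else:
            denom = float(np.mean([len(v) for v in sets.values()]))
        fractions.append(len(core) / denom if denom else 0.0)
    if skipped:
        logger.warning("skipped %d reads shorter than k=%d", skipped, k)
    return KmerCoreEstimate(
        k=k,
        subset_size=subset_size,
        n_boot=n_boot,
        core_fraction_per_boot=tuple(fractions),
        unique_kmer_counts={s: tuple(c) for s, c in counts.items()},
        skipped_short_reads=skipped,
    )
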