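"""Core-set calling: contigs present above threshold in every replicate.

The core of a replicated metagenome study is the set of contigs whose
coverage passes the presence rule (max depth >= min_cov and covered length
>= min_len) in *all* required samples.  The core fraction expresses the
core size as a percentage of the total contig universe.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from collections.abc import Sequence, Set

from .coverage import CoverageMatrix, is_present
from .errors import InputError


@dataclasses.dataclass(frozen=True)
class CoreSet:
    contig_ids: frozenset[str]
    min_cov: int
    min_len: int
    required_samples: tuple[str, ...]
    annotation_filtered: bool = False

    def __len__(self) -> int:
        return len(self.contig_ids)


def call_core(
    matrix: CoverageMatrix,
    min_cov: int = 5,
    min_len: int = 100,
    samples: Sequence[str] | None = None,
    contiguous: bool = False,
    restrict_to: Set[str] | None = None,
) -> CoreSet:
    """Call core contigs: present in every one of ``samples``.

    ``restrict_to`` optionally limits the candidate universe (e.g. to
    contigs carrying a CAZy annotation, as when only carbohydrate-active
    sequences are of interest).
    """
    if samples is None:
        samples = matrix.samples
    if not samples:
        raise InputError("at least one sample is required")
    unknown = [s for s in samples if s not in matrix.samples]
    if unknown:
        raise InputError(f"unknown sample name(s): {unknown}")
    candidates = matrix.contig_ids
    if restrict_to is not None:
        candidates = [c for c in candidates if c in restrict_to]
    core = frozenset(
        c
        for c in candidates
        if all(
            is_present(matrix.get(c, s), min_cov, min_len, contiguous)
            for s in samples
        )
    )
    return CoreSet(
        contig_ids=core,
        min_cov=min_cov,
        min_len=min_len,
        required_samples=tuple(samples),
        annotation_filtered=restrict_to is not None,
    )


def core_fraction(core_size: int, total_size: int, decimals: int = 1) -> float:
    """Core size as a percentage of the total, rounded half-up.

    Example: 843 core contigs out of 226,887 total gives 0.4 (percent).
    """
    if total_size <= 0:
        raise InputError("total_size must be positive")
    if not 0 <= core_size <= total_size:
        raise InputError("core_size must be in [0, total_size]")
    pct = Decimal(core_size) * 100 / Decimal(total_size)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def write_core_list(core: CoreSet, path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(core.contig_ids):
            fh.write(f"{cid}\n")


def read_core_list(path, min_cov: int = 5, min_len: int = 100, samples: Sequence[str] = ()) -> CoreSet:
    with open(path) as fh:
        ids = frozenset(line.strip() for line in fh if line.strip())
    return CoreSet(ids, min_cov, min_len, tuple(samples))
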