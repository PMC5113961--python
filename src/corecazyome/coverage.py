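"""Per-contig coverage summaries and presence calls from per-base depth tables.

A contig's abundance in a sample is summarized by two numbers derived from
its per-base read depth: the *maximum* depth observed at any position
(``max_cov``) and the number of distinct positions with depth >= 1
(``covered_len``).  A contig is called *present* in a sample when
``max_cov >= min_cov`` AND ``covered_len >= min_len``; the defaults
(5x depth, 100 bp) are deliberately liberal so that genuinely shared contigs
are not lost at low per-sample abundance.

Depth tables use the ``samtools depth`` dialect: three tab-separated columns
(contig_id, 1-based position, depth), no header, rows for uncovered
positions optional.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

DEPTH_COLUMNS = ("contig_id", "position", "depth")

#: Summary TSV column order written by :meth:`CoverageMatrix.to_frame`.
SUMMARY_COLUMNS = ("contig_id", "sample_id", "max_cov", "covered_len", "present")


@dataclasses.dataclass(frozen=True)
class ContigCoverage:
    """Coverage summary of one contig in one sample.

    ``max_run`` is the longest stretch of *consecutive* covered positions;
    it only matters when presence is called in contiguous mode.
    """

    contig_id: str
    max_cov: int
    covered_len: int
    max_run: int = 0

    def __post_init__(self) -> None:
        if self.max_cov < 0 or self.covered_len < 0:
            raise InputError("max_cov and covered_len must be non-negative")
        if self.max_cov > 0 and self.covered_len < 1:
            raise InputError("positive max_cov requires covered_len >= 1")


ZERO_COVERAGE = ContigCoverage("", 0, 0, 0)


def _longest_run(sorted_positions: Sequence[int]) -> int:
    best = run = 0
    prev = None
    for p in sorted_positions:
        run = run + 1 if prev is not None and p == prev + 1 else 1
        best = max(best, run)
        prev = p
    return best


def contig_coverage(
    depth_rows: Iterable[tuple[str, int, int]],
) -> list[ContigCoverage]:
    """Reduce a stream of (contig_id, position, depth) rows to per-contig summaries.

    Rows may arrive in any order.  Duplicate (contig, position) rows keep the
    maximum depth so covered length is never double-counted.  Contigs appear
    in the output in order of first occurrence.

    Raises
    ------
    FormatError
        On a non-positive position or negative depth, naming the offending
        line number (1-based position in the stream).
    """
    acc: dict[str, dict[int, int]] = {}
    for lineno, (cid, pos, depth) in enumerate(depth_rows, start=1):
        pos = int(pos)
        depth = int(depth)
        if pos <= 0:
            raise FormatError(f"line {lineno}: position must be >= 1, got {pos}")
        if depth < 0:
            raise FormatError(f"line {lineno}: depth must be >= 0, got {depth}")
        per_pos = acc.setdefault(str(cid), {})
        if depth > per_pos.get(pos, -1):
            per_pos[pos] = depth
    out = []
    for cid, per_pos in acc.items():
        covered = sorted(p for p, d in per_pos.items() if d >= 1)
        max_cov = max(per_pos.values(), default=0)
        out.append(ContigCoverage(cid, max_cov, len(covered), _longest_run(covered)))
    return out


def coverage_from_depth_file(path) -> list[ContigCoverage]:
    """Vectorized equivalent of :func:`contig_coverage` for a depth TSV on disk."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=list(DEPTH_COLUMNS),
        header=None,
        dtype={"contig_id": str, "position": np.int64, "depth": np.int64},
    )
    if df.empty:
        return []
    bad = df.index[(df["position"] <= 0) | (df["depth"] < 0)]
    if len(bad):
        raise FormatError(f"{path}: line {bad[0] + 1}: negative depth or position")
    # duplicates keep the max depth
    df = (
        df.groupby(["contig_id", "position"], sort=False, as_index=False)["depth"]
        .max()
    )
    first_seen = df.drop_duplicates("contig_id")["contig_id"].tolist()
    max_cov = df.groupby("contig_id", sort=False)["depth"].max()

    cov = df[df["depth"] >= 1].sort_values(["contig_id", "position"])
    covered_len = cov.groupby("contig_id", sort=False)["position"].size()
    if cov.empty:
        runs = pd.Series(dtype=np.int64)
    else:
        new_run = (cov["contig_id"] != cov["contig_id"].shift()) | (
            cov["position"] != cov["position"].shift() + 1
        )
        run_id = new_run.cumsum()
        run_len = cov.groupby(run_id)["position"].size()
        run_contig = cov.groupby(run_id)["contig_id"].first()
        runs = run_len.groupby(run_contig.values).max()

    return [
        ContigCoverage(
            cid,
            int(max_cov.get(cid, 0)),
            int(covered_len.get(cid, 0)),
            int(runs.get(cid, 0)),
        )
        for cid in first_seen
    ]


def is_present(
    cov: ContigCoverage,
    min_cov: int = 5,
    min_len: int = 100,
    contiguous: bool = False,
) -> bool:
    """Presence call: depth and covered-length thresholds combined with AND.

    With ``contiguous=True`` the length condition applies to the longest
    consecutive covered stretch instead of the total covered length.
    """
    if min_cov < 0 or min_len < 0:
        raise InputError("thresholds must be non-negative")
    length = cov.max_run if contiguous else cov.covered_len
    return cov.max_cov >= min_cov and length >= min_len


class CoverageMatrix:
    """Contig x sample coverage summaries; absent pairs mean zero coverage."""

    def __init__(self, samples: Sequence[str]):
        if not samples:
            raise InputError("at least one sample is required")
        self.samples: list[str] = list(samples)
        self._entries: dict[tuple[str, str], ContigCoverage] = {}

    def add(self, sample_id: str, cov: ContigCoverage) -> None:
        if sample_id not in self.samples:
            raise InputError(f"unknown sample {sample_id!r}")
        self._entries[(cov.contig_id, sample_id)] = cov

    def get(self, contig_id: str, sample_id: str) -> ContigCoverage:
        if sample_id not in self.samples:
            raise InputError(f"unknown sample {sample_id!r}")
        return self._entries.get(
            (contig_id, sample_id),
            ContigCoverage(contig_id, 0, 0, 0),
        )

    @property
    def contig_ids(self) -> list[str]:
        return sorted({cid for cid, _ in self._entries})

    def items(self):
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_depth_files(cls, paths: Sequence, samples: Sequence[str]) -> "CoverageMatrix":
        if len(paths) != len(samples):
            raise InputError("one depth file per sample name is required")
        mat = cls(samples)
        for path, sample in zip(paths, samples):
            for cov in coverage_from_depth_file(path):
                mat.add(sample, cov)
        return mat

    def to_frame(self, min_cov: int = 5, min_len: int = 100, contiguous: bool = False) -> pd.DataFrame:
        rows = [
            {
                "contig_id": cid,
                "sample_id": sid,
                "max_cov": cov.max_cov,
                "covered_len": cov.covered_len,
                "present": int(is_present(cov, min_cov, min_len, contiguous)),
            }
            for (cid, sid), cov in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, samples: Sequence[str] | None = None) -> "CoverageMatrix":
        if samples is None:
            samples = sorted(df["sample_id"].unique())
        mat = cls(samples)
        for row in df.itertuples(index=False):
            mat.add(
                row.sample_id,
                ContigCoverage(row.contig_id, int(row.max_cov), int(row.covered_len)),
            )
        return mat

    def write_summary(self, path, min_cov: int = 5, min_len: int = 100, contiguous: bool = False) -> None:
        self.to_frame(min_cov, min_len, contiguous).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_summary(cls, path, samples: Sequence[str] | None = None) -> "CoverageMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"contig_id": str, "sample_id": str}), samples)
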