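"""Randomization test for annotation-database bias in category distributions.

Because core contigs are only those with a CAZy database hit, the observed
distribution of the core over CAZy classes (or phyla) could simply mirror
the composition of the reference database or of the cumulative metagenome.
The test draws many random subsets from such a reference pool, reduces each
draw to a category distribution, and asks whether the core's distribution
is an outlier among them.

The default statistic is the chi-square distance of a frequency vector from
the null-mean frequencies; the empirical p-value uses the standard
+1/(n+1) permutation correction so it is never exactly zero.  An "ftest"
mode runs a max-T style per-category comparison and reports per-category
p-values with Bonferroni correction.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .errors import InputError


@dataclasses.dataclass(frozen=True)
class CategoryDistribution:
    """Counts over an ordered category universe, with derived frequencies."""

    categories: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.counts):
            raise InputError("categories and counts differ in length")
        if any(c < 0 for c in self.counts):
            raise InputError("counts must be non-negative")
        if sum(self.counts) == 0:
            raise InputError("at least one category must have a positive count")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def freqs(self) -> np.ndarray:
        counts = np.asarray(self.counts, dtype=float)
        return counts / counts.sum()

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "CategoryDistribution":
        cats, counts = np.unique(np.asarray(labels, dtype=str), return_counts=True)
        return cls(tuple(cats.tolist()), tuple(int(c) for c in counts))

    def aligned_freqs(self, universe: Sequence[str]) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.categories)}
        freqs = self.freqs
        return np.array([freqs[idx[c]] if c in idx else 0.0 for c in universe])


@dataclasses.dataclass(frozen=True)
class BiasTestResult:
    observed: CategoryDistribution
    null_draws: tuple[CategoryDistribution, ...]
    statistic_per_draw: tuple[float, ...]
    observed_statistic: float
    p_empirical: float
    per_category_enrichment: dict[str, tuple[float, float, float, float]]
    per_category_pvalues: dict[str, float] | None = None
    statistic: str = "chi2"


def draw_null(
    pool: Sequence[str] | CategoryDistribution,
    n_draw: int = 50_000,
    n_rep: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> list[CategoryDistribution]:
    """n_rep seeded random draws of n_draw items from a category pool.

    ``pool`` is either the raw category labels of the reference set or a
    pre-tabulated :class:`CategoryDistribution`.  Without replacement
    (default, sampling distinct proteins from a finite database) the draw
    is multivariate hypergeometric; with replacement it is multinomial.
    """
    if n_rep < 1:
        raise InputError("n_rep must be >= 1")
    if n_draw < 1:
        raise InputError("n_draw must be >= 1")
    dist = pool if isinstance(pool, CategoryDistribution) else CategoryDistribution.from_labels(pool)
    counts = np.asarray(dist.counts, dtype=np.int64)
    if not replace and n_draw > dist.total:
        raise InputError(
            f"pool of {dist.total} is smaller than n_draw={n_draw}; "
            "use replace=True to sample with replacement"
        )
    rng = np.random.default_rng(seed)
    if replace:
        mat = rng.multinomial(n_draw, dist.freqs, size=n_rep)
    else:
        mat = rng.multivariate_hypergeometric(counts, n_draw, size=n_rep)
    return [
        CategoryDistribution(dist.categories, tuple(int(c) for c in row))
        for row in mat
    ]


def _chi2_distance(freqs: np.ndarray, null_mean: np.ndarray) -> float:
    # categories absent from the null pool but observed are infinitely
    # surprising; categories absent from both contribute nothing
    active = null_mean > 0
    if np.any(freqs[~active] > 0):
        return float("inf")
    diff = freqs[active] - null_mean[active]
    return float(np.sum(diff * diff / null_mean[active]))


def compare(
    observed: CategoryDistribution,
    nulls: Sequence[CategoryDistribution],
    statistic: str = "chi2",
) -> BiasTestResult:
    """Compare an observed category distribution against null draws.

    chi2 mode: statistic is the chi-square distance from the null-mean
    frequencies; p_empirical = (1 + #{draws >= observed}) / (n_rep + 1).
    ftest mode: max-T statistic over per-category standardized deviations,
    with Bonferroni-corrected per-category empirical p-values.
    """
    if statistic not in ("chi2", "ftest"):
        raise InputError("statistic must be 'chi2' or 'ftest'")
    if not nulls:
        raise InputError("at least one null draw is required")
    universe = sorted(
        set(observed.categories).union(*(n.categories for n in nulls))
    )
    f_obs = observed.aligned_freqs(universe)
    null_mat = np.vstack([n.aligned_freqs(universe) for n in nulls])
    n_rep, k = null_mat.shape
    null_mean = null_mat.mean(axis=0)
    null_sd = null_mat.std(axis=0, ddof=1) if n_rep > 1 else np.zeros(k)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (f_obs - null_mean) / null_sd, np.nan)

    per_cat_p: dict[str, float] | None = None
    if statistic == "chi2":
        obs_stat = _chi2_distance(f_obs, null_mean)
        active = null_mean > 0
        diffs = null_mat[:, active] - null_mean[active]
        draw_stats = np.sum(diffs * diffs / null_mean[active], axis=1)
    else:
        safe_sd = np.where(null_sd > 0, null_sd, np.inf)
        obs_dev = np.abs(f_obs - null_mean) / safe_sd
        obs_stat = float(np.max(obs_dev))
        draw_dev = np.abs(null_mat - null_mean) / safe_sd
        draw_stats = draw_dev.max(axis=1)
        per_cat_p = {}
        for i, cat in enumerate(universe):
            exceed = int(np.sum(draw_dev[:, i] >= obs_dev[i]))
            per_cat_p[cat] = min(1.0, k * (1 + exceed) / (n_rep + 1))

    p = (1 + int(np.sum(draw_stats >= obs_stat))) / (n_rep + 1)
    enrichment = {
        cat: (float(f_obs[i]), float(null_mean[i]), float(null_sd[i]), float(z[i]))
        for i, cat in enumerate(universe)
    }
    return BiasTestResult(
        observed=observed,
        null_draws=tuple(nulls),
        statistic_per_draw=tuple(float(s) for s in draw_stats),
        observed_statistic=float(obs_stat),
        p_empirical=float(p),
        per_category_enrichment=enrichment,
        per_category_pvalues=per_cat_p,
        statistic=statistic,
    )


def bias_test(
    observed_labels: Sequence[str] | CategoryDistribution,
    pool: Sequence[str] | CategoryDistribution,
    n_draw: int = 50_000,
    n_rep: int = 1000,
    seed: int = 0,
    replace: bool = False,
    statistic: str = "chi2",
) -> BiasTestResult:
    """Convenience wrapper: tabulate, draw nulls, and compare in one call."""
    observed = (
        observed_labels
        if isinstance(observed_labels, CategoryDistribution)
        else CategoryDistribution.from_labels(observed_labels)
    )
    nulls = draw_null(pool, n_draw=n_draw, n_rep=n_rep, seed=seed, replace=replace)
    return compare(observed, nulls, statistic=statistic)
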