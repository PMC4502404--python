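"""Permutation test for differential-expression enrichment in a gene
category.

Given a fixed landscape of per-gene DE calls and a gene category, asks
whether the category contains an excess of DE genes.  The null is built
by drawing random gene sets of the category's testable size uniformly
from the tested universe (label resampling); the one-sided p-value uses
the add-one correction ``(1 + #{null >= observed}) / (reps + 1)`` so it is
never exactly zero, and the 95% band is the 2.5/97.5 percentile interval
of the null fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_REPS = 100_000
#: chunk size bounding the memory of the vectorised subset sampler
_CHUNK_BUDGET = 20_000_000


@dataclass
class CategoryTestResult:
    """Result of a permutation category-enrichment test."""

    category_id: str
    n_testable: int
    n_de: int
    observed_fraction: float
    null_mean: float
    ci_low: float
    ci_high: float
    p: float
    reps: int
    seed: int
    alternative: str = "greater"


def category_de_fraction(
    de_flags: pd.Series, category: set[str]
) -> tuple[int, int, float]:
    """Observed DE fraction of a category within the tested universe.

    Genes absent from the universe are untestable and dropped.  Returns
    ``(n_testable, n_de, fraction)``.
    """
    flags = de_flags.astype(bool)
    testable = [g for g in category if g in flags.index]
    if not testable:
        raise ValidationError("category has no genes in the tested universe")
    n_de = int(flags.loc[testable].sum())
    return len(testable), n_de, n_de / len(testable)


def _null_de_counts(
    flags: np.ndarray, size: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """DE counts of ``reps`` uniformly drawn gene subsets of ``size``.

    Subsets are drawn without replacement by ranking independent random
    keys per gene (random-key trick), chunked to bound memory.
    """
    n = len(flags)
    counts = np.empty(reps, dtype=np.int64)
    chunk = max(1, min(reps, _CHUNK_BUDGET // n))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
        counts[done : done + m] = flags[idx].sum(axis=1)
        done += m
    return counts


def permutation_category_test(
    de_flags: pd.Series,
    category: set[str],
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    category_id: str = "category",
    alternative: str = "greater",
) -> CategoryTestResult:
    """Permutation enrichment test of DE genes in a category.

    The observed DE fraction of the category (over its testable genes) is
    compared with the DE fractions of ``reps`` random gene sets of the
    same size drawn from the universe.  One-sided (excess of DE genes) by
    default; ``alternative='two-sided'`` doubles the smaller tail.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    flags = de_flags.astype(bool)
    n_testable, n_de, observed = category_de_fraction(flags, category)
    if n_testable > len(flags):
        raise ValidationError("category larger than the tested universe")
    rng = np.random.default_rng(seed)
    null_counts = _null_de_counts(flags.to_numpy(), n_testable, reps, rng)
    null_frac = null_counts / n_testable
    p_greater = (1 + int((null_counts >= n_de).sum())) / (reps + 1)
    if alternative == "greater":
        p = p_greater
    elif alternative == "two-sided":
        p_less = (1 + int((null_counts <= n_de).sum())) / (reps + 1)
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    if reps >= 1000:
        ci_low, ci_high = np.percentile(null_frac, [2.5, 97.5])
    else:
        warnings.warn("fewer than 1000 permutations: CI not reported",
                      stacklevel=2)
        ci_low = ci_high = float("nan")
    return CategoryTestResult(
        category_id=category_id,
        n_testable=n_testable,
        n_de=n_de,
        observed_fraction=observed,
        null_mean=float(null_frac.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=float(p),
        reps=reps,
        seed=seed,
        alternative=alternative,
    )
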