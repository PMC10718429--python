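"""Pairwise model comparison via pixel-wise McNemar's test.

Two segmentation models A and B are compared against the same ground truth
on every pixel of the test set. Each pixel is "correct" for a model when the
binarized prediction equals the truth; the discordant counts are

* ``b`` — pixels where A is correct and B is wrong,
* ``c`` — pixels where B is correct and A is wrong,

pooled over all images. The statistic ``(b - c)^2 / (b + c)`` is referred to
the chi-squared distribution with one degree of freedom (no continuity
correction by default; an exact binomial fallback is available for small
``b + c``). Raw p-values from the pairwise family are Bonferroni-adjusted
(multiplied by the number of pairs, capped at 1) and flagged significant at
the family alpha of 0.1 — with four models (six pairs) the per-test cutoff
is 0.1/6, consistent with a printed cutoff of 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class DiscordanceCounts:
    b: int            # A correct, B wrong
    c: int            # B correct, A wrong
    n_images: int
    n_pixels: int

    def __post_init__(self):
        if self.b < 0 or self.c < 0:
            raise ValueError("counts must be non-negative")
        if self.b + self.c > self.n_pixels:
            raise ValueError("discordant pixels exceed the pixel total")


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False
    counts: DiscordanceCounts = None


def _as_binary_stack(masks) -> np.ndarray:
    arr = np.asarray(masks)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("masks must be strictly binary")
    return arr.astype(bool)


def discordant_counts(pred_a, pred_b, truth) -> DiscordanceCounts:
    """Pooled discordant pixel counts of two prediction sets vs. the truth."""
    a = _as_binary_stack(pred_a)
    b_ = _as_binary_stack(pred_b)
    t = _as_binary_stack(truth)
    if a.shape != b_.shape or a.shape != t.shape:
        raise ValueError("prediction and truth collections must be aligned")
    correct_a = a == t
    correct_b = b_ == t
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    n_images = a.shape[0] if a.ndim >= 3 else 1
    return DiscordanceCounts(b=b, c=c, n_images=n_images, n_pixels=int(t.size))


def mcnemar_test(counts: DiscordanceCounts, exact: bool = False) -> McNemarResult:
    """McNemar's test on pooled discordances.

    ``exact=True`` replaces the chi-squared reference by the two-sided exact
    binomial test on (b, b + c) at rate 1/2, useful when ``b + c`` is small.
    Convention: ``b + c == 0`` gives statistic 0 and p = 1.
    """
    b, c = counts.b, counts.c
    if b + c == 0:
        return McNemarResult(statistic=0.0, p_raw=1.0, counts=counts)
    if exact:
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
        return McNemarResult(statistic=float(min(b, c)), p_raw=p, counts=counts)
    statistic = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(statistic=float(statistic), p_raw=p, counts=counts)


def bonferroni_adjust(p_values, m: int = None) -> list:
    """Multiply each p by the number of tests, capped at 1."""
    p_values = list(p_values)
    m = len(p_values) if m is None else m
    if m < len(p_values):
        raise ValueError("m must cover every test performed")
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


def compare_models(predictions: dict, truth, alpha_family: float = 0.1,
                   exact: bool = False) -> dict:
    """All pairwise McNemar tests between named prediction sets.

    Returns a dict keyed by ``(name_a, name_b)`` (lower-triangular order of
    the input's key order) holding :class:`McNemarResult` with
    Bonferroni-adjusted p-values over the ``m = n_pairs`` family and the
    significance flag at ``alpha_family``.
    """
    names = list(predictions)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    pairs = list(combinations(names, 2))
    raws = []
    for a, b in pairs:
        counts = discordant_counts(predictions[a], predictions[b], truth)
        raws.append(mcnemar_test(counts, exact=exact))
    adjusted = bonferroni_adjust([r.p_raw for r in raws], m=len(pairs))
    out = {}
    for (a, b), r, p_adj in zip(pairs, raws, adjusted):
        out[(a, b)] = McNemarResult(statistic=r.statistic, p_raw=r.p_raw,
                                    p_adjusted=p_adj,
                                    significant=p_adj < alpha_family,
                                    counts=r.counts)
    return out


def comparison_table(results: dict) -> "object":
    """Lower-triangular adjusted-p-value table as a pandas DataFrame."""
    import pandas as pd

    names = []
    for a, b in results:
        for n in (a, b):
            if n not in names:
                names.append(n)
    table = pd.DataFrame(index=names, columns=names, dtype=float)
    for (a, b), r in results.items():
        row, col = (b, a) if names.index(a) < names.index(b) else (a, b)
        table.loc[row, col] = r.p_adjusted
    return table
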