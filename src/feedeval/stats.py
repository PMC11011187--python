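"""One-way ANOVA and Duncan's multiple range test with compact letters.

Duncan's test compares the ordered group means span by span: a span of p
consecutive ordered means differs significantly when its observed range
exceeds the least significant range

    LSR_p = q(1 - alpha_p, p, df_error) x sqrt(MSE / n_h)

with q the studentized-range quantile, n_h the harmonic mean group size and
alpha_p = 1 - (1 - alpha)^(p-1) Duncan's span-dependent protection level.
A span contained in a non-significant span is itself declared
non-significant (the classical containment rule), and maximal
non-significant spans become shared letters: groups sharing a letter do not
differ at the chosen alpha, and the group with the largest mean always
carries "a".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .trial import FeedEvalError

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    ms_between: float


@dataclass
class GroupStats:
    label: str
    n: int
    mean: float
    sd: float
    letters: str = ""

    def formatted(self, digits: int = 2) -> str:
        cell = f"{self.mean:.{digits}f} ± {self.sd:.{digits}f}"
        return f"{cell} ^{self.letters}^" if self.letters else cell


@dataclass
class GroupComparison:
    """One variable's treatment comparison: group stats, ANOVA, letters."""

    variable: str
    groups: list[GroupStats]
    anova: AnovaResult
    alpha: float
    protected: bool = False
    letters_by_label: dict[str, str] = field(default_factory=dict)


def _as_arrays(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise FeedEvalError("need at least two groups")
    for i, a in enumerate(arrays):
        if a.ndim != 1 or len(a) < 2:
            raise FeedEvalError(f"group {i} needs at least two observations")
    return arrays


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way decomposition with p from the F distribution.

    When every observation is identical (zero between- and within-group
    variation) F is undefined; the result reports no difference
    (F = 0, p = 1).
    """
    arrays = _as_arrays(groups)
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    mse = ss_within / df_within
    if mse == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_between, df_within, 0.0, 0.0)
        return AnovaResult(np.inf, 0.0, df_between, df_within, 0.0, ms_between)
    f = ms_between / mse
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, df_between, df_within, float(mse),
                       float(ms_between))


@lru_cache(maxsize=4096)
def _duncan_q(span: int, df_within: int, alpha: float) -> float:
    """Studentized-range quantile at Duncan's protection level (cached —
    the quantile is expensive and recurs across instances)."""
    protection = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(sps.studentized_range.ppf(1.0 - protection, span, df_within))


def duncan_lsr(span: int, df_within: int, mse: float, harmonic_n: float,
               alpha: float = 0.05) -> float:
    """Least significant range for a span of ``span`` ordered means."""
    if span < 2:
        raise FeedEvalError("span must cover at least two means")
    return _duncan_q(span, df_within, alpha) * np.sqrt(mse / harmonic_n)


@dataclass
class DuncanResult:
    order: list[int]            # group indices sorted by descending mean
    letters: list[str]          # per input group, e.g. "a", "ab"
    lsr: dict[int, float]       # span width -> least significant range
    alpha: float
    nonsignificant_spans: list[tuple[int, int]]  # in sorted order, maximal


def duncan_mrt(groups: Sequence[Sequence[float]], alpha: float = 0.05,
               anova: AnovaResult | None = None,
               protected: bool = False) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    Unequal group sizes are handled through the harmonic mean size (logged).
    With ``protected=True`` letters are gated on the ANOVA F test: a
    non-significant F yields a single shared letter.  Ties in means keep
    input order, so the partition is stable under relabeling.  A single
    group trivially receives the letter "a".
    """
    if len(groups) == 1:
        return DuncanResult(order=[0], letters=["a"], lsr={}, alpha=alpha,
                            nonsignificant_spans=[(0, 0)])
    arrays = _as_arrays(groups)
    k = len(arrays)
    anova = anova or anova_oneway(arrays)
    means = np.array([a.mean() for a in arrays])
    sizes = np.array([len(a) for a in arrays], dtype=float)
    if len(set(sizes)) > 1:
        logger.info("unequal group sizes %s: using harmonic mean", sizes)
    harmonic_n = k / (1.0 / sizes).sum()

    # sort descending by mean; stable so ties keep input order
    order = list(np.argsort(-means, kind="stable"))
    sorted_means = means[order]

    if protected and anova.p_value >= alpha:
        letters = ["a"] * k
        return DuncanResult(order=order, letters=letters, lsr={},
                            alpha=alpha, nonsignificant_spans=[(0, k - 1)])

    lsr = {span: duncan_lsr(span, anova.df_within, anova.mse, harmonic_n,
                            alpha)
           for span in range(2, k + 1)}

    # Sequential range procedure: widest spans first; a span contained in a
    # non-significant span is non-significant without testing.
    nonsig: set[tuple[int, int]] = set()
    for width in range(k, 1, -1):
        for start in range(0, k - width + 1):
            end = start + width - 1
            if any(ns_start <= start and end <= ns_end
                   for ns_start, ns_end in nonsig):
                nonsig.add((start, end))
                continue
            observed = sorted_means[start] - sorted_means[end]
            if observed <= lsr[width]:
                nonsig.add((start, end))

    letters = assign_letters(k, nonsig)
    per_group = [""] * k
    for rank, group_index in enumerate(order):
        per_group[group_index] = letters[rank]
    maximal = sorted(
        span for span in nonsig
        if not any(other != span and other[0] <= span[0] and
                   span[1] <= other[1] for other in nonsig))
    return DuncanResult(order=order, letters=per_group, lsr=lsr, alpha=alpha,
                        nonsignificant_spans=maximal)


def assign_letters(k: int, nonsignificant: set[tuple[int, int]]) -> list[str]:
    """Compact letter display over ranks 0..k-1 (0 = largest mean).

    Maximal non-significant spans (plus uncovered singletons) each receive
    one letter, assigned left to right so the top group always carries "a";
    a rank's display is the concatenation of the letters of every span
    containing it.
    """
    spans = set(nonsignificant)
    covered = {rank for start, end in spans for rank in range(start, end + 1)}
    spans.update((rank, rank) for rank in range(k) if rank not in covered)
    maximal = [s for s in spans
               if not any(o != s and o[0] <= s[0] and s[1] <= o[1]
                          for o in spans)]
    maximal.sort()
    letters = [""] * k
    for i, (start, end) in enumerate(maximal):
        letter = chr(ord("a") + i)
        for rank in range(start, end + 1):
            letters[rank] += letter
    return letters


def compare_treatments(values: Sequence[Sequence[float]],
                       labels: Sequence[str],
                       variable: str = "value",
                       alpha: float = 0.05,
                       protected: bool = False) -> GroupComparison:
    """Full treatment comparison: descriptives, ANOVA, Duncan letters."""
    if len(values) != len(labels):
        raise FeedEvalError(
            f"{len(values)} groups but {len(labels)} labels")
    arrays = _as_arrays(values)
    anova = anova_oneway(arrays)
    duncan = duncan_mrt(arrays, alpha=alpha, anova=anova, protected=protected)
    groups = [
        GroupStats(label=label, n=len(a), mean=float(a.mean()),
                   sd=float(a.std(ddof=1)), letters=duncan.letters[i])
        for i, (label, a) in enumerate(zip(labels, arrays))
    ]
    return GroupComparison(
        variable=variable, groups=groups, anova=anova, alpha=alpha,
        protected=protected,
        letters_by_label={g.label: g.letters for g in groups})
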