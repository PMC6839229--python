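"""The Lamda3 rule-interestingness measure, wcs, and rule ranking.

Binarizing a continuous omics matrix before mining discards most of the
signal, and the binarization cutoff is arbitrary.  Lamda3 compensates by
scoring each mined rule on the *continuous* matrix: a biologically
coherent rule A => C should show a stronger A–C correlation than A shows
with unrelated genes, both among the samples where the pair is jointly
dysregulated and among the samples where it is jointly normal.

For a single-antecedent, single-consequent rule A => C the samples are
split by the binary matrix into three parts:

* ``both_one``  — A = 1 and C = 1 (jointly dysregulated),
* ``both_zero`` — A = 0 and C = 0 (jointly normal),
* ``inconsistent`` — the rest (computed and reported, unused by the score).

Within ``both_one`` and ``both_zero`` the two-sided correlation-test
p-value of (A, C) is computed on the continuous values, along with the
median p-value of A against every other gene in the matrix.  With
``p2_ac``/``p0_ac`` the pair p-values and ``p2_bg``/``p0_bg`` the median
background p-values::

    Lamda3 = (log10(p2_ac) + log10(p0_ac)) / (log10(p2_bg) + log10(p0_bg))

Values above 1 mean the in-rule association is stronger (smaller
p-values) than the typical background association.  Rules whose
partitions are too small for a meaningful correlation (< 3 samples), or
whose background medians are both exactly 1, get ``None`` instead of a
fabricated score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arm import Rule
from .matrix import check_aligned, validate_binary, validate_matrix

__all__ = [
    "SamplePartition",
    "Lamda3Breakdown",
    "P_FLOOR",
    "MIN_PARTITION",
    "partition_samples",
    "correlation_pvalue",
    "lamda3_score",
    "score_rules",
    "wcs_score",
    "rank_weights",
    "rank_rules",
]

#: p-values are clamped to [P_FLOOR, 1] before taking log10
P_FLOOR = 1e-300
#: a correlation on fewer than this many samples is meaningless
MIN_PARTITION = 3

MEASURES = ("support", "confidence", "lift", "wcs", "lamda3")


@dataclass(frozen=True)
class SamplePartition:
    """Sample IDs split by the joint binary state of a gene pair."""

    both_one: tuple[str, ...]
    inconsistent: tuple[str, ...]
    both_zero: tuple[str, ...]


@dataclass(frozen=True)
class Lamda3Breakdown:
    """Lamda3 with its four constituent p-values.

    ``value`` is ``None`` when the score is undefined (a partition below
    :data:`MIN_PARTITION` samples, no background gene, or a zero
    denominator).  For a multi-gene rule, ``pair`` names the
    (antecedent gene, consequent gene) pair whose breakdown is shown.
    """

    p2_ac: float
    p0_ac: float
    p2_bg: float
    p0_bg: float
    value: float | None
    pair: tuple[str, str] | None = None


def partition_samples(gene_a: str, gene_c: str, B: pd.DataFrame) -> SamplePartition:
    """Split samples into both-1 / inconsistent / both-0 for a gene pair."""
    validate_binary(B)
    for g in (gene_a, gene_c):
        if g not in B.columns:
            raise KeyError(f"gene {g!r} not in binary matrix")
    a = B[gene_a].to_numpy() == 1
    c = B[gene_c].to_numpy() == 1
    ids = np.asarray(B.index, dtype=object)
    return SamplePartition(
        both_one=tuple(ids[a & c]),
        inconsistent=tuple(ids[a ^ c]),
        both_zero=tuple(ids[~a & ~c]),
    )


def correlation_pvalue(x, y, method: str = "pearson") -> float:
    """Two-sided p-value of a correlation test, clamped to [1e-300, 1].

    Returns 1.0 for vectors shorter than 3 or with zero variance, where
    no correlation test is defined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    if x.size < MIN_PARTITION or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0
    test = stats.pearsonr if method == "pearson" else stats.spearmanr
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(test(x, y).pvalue)
    if math.isnan(p):
        return 1.0
    return min(max(p, P_FLOOR), 1.0)


def _pair_lamda3(
    gene_a: str,
    gene_c: str,
    M: pd.DataFrame,
    B: pd.DataFrame,
    method: str,
) -> Lamda3Breakdown:
    """The printed single-pair formula for rule {gene_a} => {gene_c}."""
    part = partition_samples(gene_a, gene_c, B)
    background = [g for g in M.columns if g not in (gene_a, gene_c)]

    p_ac: list[float] = []
    p_bg: list[float] = []
    for subset in (part.both_one, part.both_zero):
        sub = M.loc[list(subset)]
        a = sub[gene_a].to_numpy()
        p_ac.append(correlation_pvalue(a, sub[gene_c].to_numpy(), method))
        if background:
            med = float(
                np.median(
                    [
                        correlation_pvalue(a, sub[g].to_numpy(), method)
                        for g in background
                    ]
                )
            )
        else:
            med = math.nan
        p_bg.append(med)

    p2_ac, p0_ac = p_ac
    p2_bg, p0_bg = p_bg
    value: float | None
    if (
        len(part.both_one) < MIN_PARTITION
        or len(part.both_zero) < MIN_PARTITION
        or not background
    ):
        value = None
    else:
        denom = math.log10(p2_bg) + math.log10(p0_bg)
        if denom == 0.0:
            value = None
        else:
            value = (math.log10(p2_ac) + math.log10(p0_ac)) / denom
    return Lamda3Breakdown(p2_ac, p0_ac, p2_bg, p0_bg, value, (gene_a, gene_c))


def lamda3_score(
    rule: Rule, M: pd.DataFrame, B: pd.DataFrame, method: str = "pearson"
) -> Lamda3Breakdown:
    """Score a rule with Lamda3 on the continuous matrix.

    A single-antecedent, single-consequent rule is scored with the pair
    formula directly.  A multi-gene rule is scored pairwise over every
    (antecedent gene, consequent gene) combination and summarized by the
    lower median of the defined pair values, returning that pair's
    breakdown; if no pair is scorable the result is ``None``.
    """
    validate_matrix(M, allow_missing=False)
    check_aligned(M, B)
    for g in rule.items:
        if g not in M.columns:
            raise KeyError(f"rule gene {g!r} not in matrix")

    pairs = [
        _pair_lamda3(a, c, M, B, method) for a, c in product(rule.lhs, rule.rhs)
    ]
    if len(pairs) == 1:
        return pairs[0]
    scored = sorted(
        (b for b in pairs if b.value is not None), key=lambda b: (b.value, b.pair)
    )
    if not scored:
        return pairs[0]
    return scored[(len(scored) - 1) // 2]  # lower median


def score_rules(
    rules: Sequence[Rule],
    M: pd.DataFrame,
    B: pd.DataFrame,
    method: str = "pearson",
    weights: Mapping[str, float] | None = None,
) -> list[Rule]:
    """Return rules with their ``lamda3`` (and ``wcs``) metrics filled in."""
    out = []
    for r in rules:
        breakdown = lamda3_score(r, M, B, method)
        w = wcs_score(r, B, weights)
        out.append(r.with_metrics(lamda3=breakdown.value, wcs=w))
    return out


def rank_weights(ranking: Sequence[str]) -> dict[str, float]:
    """Rank-derived gene weights: the top-ranked of n genes gets n/n = 1,
    the last gets 1/n."""
    n = len(ranking)
    if n == 0:
        raise ValueError("empty ranking")
    return {g: (n - i) / n for i, g in enumerate(ranking)}


def wcs_score(
    rule: Rule, B: pd.DataFrame, weights: Mapping[str, float] | None = None
) -> float:
    """Weighted condensed support: support(X ∪ Y) times the mean weight of
    the rule's genes.  With unit weights (the default) this is plain support."""
    validate_binary(B)
    items = rule.items
    for g in items:
        if g not in B.columns:
            raise KeyError(f"rule gene {g!r} not in binary matrix")
    if weights is None:
        w = [1.0] * len(items)
    else:
        missing = [g for g in items if g not in weights]
        if missing:
            raise KeyError(f"no weight for genes: {missing}")
        w = [float(weights[g]) for g in items]
    support = float((B[list(items)].to_numpy() == 1).all(axis=1).mean())
    return support * float(np.mean(w))


def _measure(rule: Rule, name: str) -> float | None:
    v = getattr(rule.metrics, name)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def rank_rules(rules: Sequence[Rule], measure: str, top_k: int) -> list[Rule]:
    """Top-k rules by a measure, descending; undefined (NA) values last.

    Ties break by lift (desc), then support (desc), then lexicographic
    LHS and RHS — a fixed, platform-independent order.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")

    def key(r: Rule):
        v = _measure(r, measure)
        return (
            v is None,
            -(v if v is not None else 0.0),
            -r.metrics.lift,
            -r.metrics.support,
            r.lhs,
            r.rhs,
        )

    return sorted(rules, key=key)[:top_k]
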