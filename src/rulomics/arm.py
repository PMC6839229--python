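"""Apriori frequent-itemset mining and association-rule induction.

Transactions are the rows of a binary sample-by-gene matrix: sample *s*
"contains" gene *g* when ``B.loc[s, g] == 1``.  Mining is exact — the
level-wise Apriori search with prefix-join candidate generation and
anti-monotone pruning returns exactly the itemsets whose support meets
the threshold, with exact supports.

Standard rule measures:

* ``support(X=>Y)   = supp(X ∪ Y)``  — fraction of samples with every item,
* ``confidence(X=>Y) = supp(X ∪ Y) / supp(X)``,
* ``lift(X=>Y)      = confidence / supp(Y)``  — 1 means independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import validate_binary

__all__ = [
    "ItemSet",
    "RuleMetrics",
    "Rule",
    "AssociationRuleMiner",
    "apriori_frequent_itemsets",
    "generate_rules",
    "rules_to_frame",
]


@dataclass(frozen=True)
class ItemSet:
    """A frequent itemset: sorted gene IDs plus its exact support."""

    items: tuple[str, ...]
    support: float

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("itemset must be nonempty")
        if list(self.items) != sorted(set(self.items)):
            raise ValueError(f"items must be sorted and duplicate-free: {self.items}")


@dataclass(frozen=True)
class RuleMetrics:
    """Measures attached to a rule; wcs and lamda3 are filled by scoring."""

    support: float
    confidence: float
    lift: float
    wcs: float | None = None
    lamda3: float | None = None


@dataclass(frozen=True)
class Rule:
    """An association rule X => Y over gene items, X ∩ Y = ∅."""

    lhs: tuple[str, ...]
    rhs: tuple[str, ...]
    metrics: RuleMetrics = field(
        default_factory=lambda: RuleMetrics(np.nan, np.nan, np.nan)
    )

    def __post_init__(self) -> None:
        if not self.lhs or not self.rhs:
            raise ValueError("LHS and RHS must be nonempty")
        if set(self.lhs) & set(self.rhs):
            raise ValueError(f"LHS and RHS overlap: {self.lhs} => {self.rhs}")

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.lhs) | set(self.rhs)))

    def with_metrics(self, **kwargs) -> "Rule":
        return replace(self, metrics=replace(self.metrics, **kwargs))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "{%s} => {%s}" % (",".join(self.lhs), ",".join(self.rhs))


class MiningIntegrityError(RuntimeError):
    """The supplied frequent itemsets disagree with the transaction matrix."""


def _columns_as_bool(B: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    validate_binary(B)
    return B.to_numpy(dtype=bool), [str(g) for g in B.columns]


def apriori_frequent_itemsets(
    B: pd.DataFrame, min_support: float
) -> list[ItemSet]:
    """Mine all itemsets with support >= ``min_support``.

    Returns itemsets sorted by (size, lexicographic items), each with its
    exact support.  Raises ``ValueError`` for a threshold outside (0, 1].
    """
    if not 0 < min_support <= 1:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    X, genes = _columns_as_bool(B)
    m = X.shape[0]
    order = np.argsort(genes, kind="stable")

    # per-item boolean sample masks, lexicographically ordered
    masks: dict[tuple[str, ...], np.ndarray] = {}
    level: list[tuple[str, ...]] = []
    out: list[ItemSet] = []
    for j in order:
        mask = X[:, j]
        supp = mask.sum() / m
        if supp >= min_support:
            key = (genes[j],)
            masks[key] = mask
            level.append(key)
            out.append(ItemSet(key, supp))

    # level-wise prefix join: two frequent k-sets sharing their first k-1
    # items yield a (k+1)-candidate; prune candidates with any infrequent
    # k-subset before counting.
    frequent_at_level = set(level)
    while level:
        candidates: list[tuple[str, ...]] = []
        for a, b in combinations(level, 2):
            if a[:-1] != b[:-1]:
                continue
            cand = a + (b[-1],) if a[-1] < b[-1] else b + (a[-1],)
            if all(
                cand[:i] + cand[i + 1 :] in frequent_at_level
                for i in range(len(cand))
            ):
                candidates.append(cand)
        next_level: list[tuple[str, ...]] = []
        for cand in sorted(candidates):
            mask = masks[cand[:-1]] & masks[(cand[-1],)]
            supp = mask.sum() / m
            if supp >= min_support:
                masks[cand] = mask
                next_level.append(cand)
                out.append(ItemSet(cand, supp))
        frequent_at_level = set(next_level)
        level = next_level

    out.sort(key=lambda s: (len(s.items), s.items))
    return out


def generate_rules(
    frequent: Sequence[ItemSet],
    B: pd.DataFrame,
    min_confidence: float,
    max_rhs: int = 1,
) -> list[Rule]:
    """Induce rules X => Y from frequent itemsets.

    Every rule satisfies: X ∪ Y frequent, X ∩ Y = ∅, ``|Y| <= max_rhs``
    and confidence >= ``min_confidence``.  Supports of all sub-itemsets are
    available by anti-monotonicity.  Each itemset's support is recounted
    against ``B``; a mismatch raises :class:`MiningIntegrityError`.
    """
    if not 0 < min_confidence <= 1:
        raise ValueError(f"min_confidence must be in (0, 1], got {min_confidence}")
    if max_rhs < 1:
        raise ValueError(f"max_rhs must be >= 1, got {max_rhs}")
    X, genes = _columns_as_bool(B)
    m = X.shape[0]
    col = {g: j for j, g in enumerate(genes)}

    support: dict[tuple[str, ...], float] = {}
    for s in frequent:
        unknown = [g for g in s.items if g not in col]
        if unknown:
            raise MiningIntegrityError(f"itemset genes not in matrix: {unknown}")
        recount = X[:, [col[g] for g in s.items]].all(axis=1).sum() / m
        if abs(recount - s.support) > 1e-12:
            raise MiningIntegrityError(
                f"itemset {s.items}: stored support {s.support} != recounted {recount}"
            )
        support[s.items] = s.support

    rules: list[Rule] = []
    for items, supp in support.items():
        if len(items) < 2:
            continue
        k = len(items)
        for r in range(1, min(max_rhs, k - 1) + 1):
            for rhs in combinations(items, r):
                lhs = tuple(g for g in items if g not in rhs)
                conf = supp / support[lhs]
                if conf < min_confidence:
                    continue
                lift = conf / support[rhs]
                rules.append(Rule(lhs, rhs, RuleMetrics(supp, conf, lift)))
    rules.sort(
        key=lambda r: (
            -r.metrics.support,
            -r.metrics.confidence,
            r.lhs,
            r.rhs,
        )
    )
    return rules


def rules_to_frame(rules: Iterable[Rule]) -> pd.DataFrame:
    """Tabulate rules with the canonical column order."""
    rows = [
        {
            "lhs": ",".join(sorted(r.lhs)),
            "rhs": ",".join(sorted(r.rhs)),
            "support": r.metrics.support,
            "confidence": r.metrics.confidence,
            "lift": r.metrics.lift,
            "wcs": r.metrics.wcs,
            "lamda3": r.metrics.lamda3,
        }
        for r in rules
    ]
    return pd.DataFrame(
        rows, columns=["lhs", "rhs", "support", "confidence", "lift", "wcs", "lamda3"]
    )


class AssociationRuleMiner(BaseEstimator):
    """Apriori miner with the scikit-learn estimator interface.

    Parameters
    ----------
    min_support : float, default 0.3
        Minimum fraction of samples an itemset must cover.
    min_confidence : float, default 0.8
        Minimum conditional frequency of the consequent given the antecedent.
    max_rhs : int, default 1
        Maximum number of items on the rule's right-hand side.

    Attributes
    ----------
    frequent_itemsets_ : list of ItemSet
    rules_ : list of Rule
    feature_names_in_ : ndarray of gene IDs
    """

    def __init__(
        self, min_support: float = 0.3, min_confidence: float = 0.8, max_rhs: int = 1
    ):
        self.min_support = min_support
        self.min_confidence = min_confidence
        self.max_rhs = max_rhs

    def fit(self, X, y=None) -> "AssociationRuleMiner":
        B = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        if not isinstance(X, pd.DataFrame):
            B.columns = [f"g{j}" for j in range(B.shape[1])]
            B.index = [f"s{i}" for i in range(B.shape[0])]
        self.feature_names_in_ = np.asarray(B.columns, dtype=object)
        self.n_features_in_ = B.shape[1]
        self.frequent_itemsets_ = apriori_frequent_itemsets(B, self.min_support)
        self.rules_ = generate_rules(
            self.frequent_itemsets_, B, self.min_confidence, self.max_rhs
        )
        return self

    def rule_table(self) -> pd.DataFrame:
        """Mined rules as a DataFrame (requires a prior ``fit``)."""
        if not hasattr(self, "rules_"):
            raise AttributeError("miner is not fitted yet; call fit(B) first")
        return rules_to_frame(self.rules_)
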