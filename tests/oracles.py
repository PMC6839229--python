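"""Independent brute-force oracles, deliberately sharing no code with the
package: exhaustive power-set itemset/rule enumeration, and a
straight-line transcription of the Lamda3 formula built on the
closed-form correlation t-test."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def _support_map(B: pd.DataFrame) -> dict[tuple, float]:
    """Exact support of *every* nonempty itemset (full power-set scan)."""
    genes = sorted(map(str, B.columns))
    assert len(genes) <= 14, "power-set oracle limited to small matrices"
    cols = {g: B[g].to_numpy() == 1 for g in genes}
    m = len(B)
    out = {}
    for k in range(1, len(genes) + 1):
        for combo in combinations(genes, k):
            mask = np.ones(m, dtype=bool)
            for g in combo:
                mask &= cols[g]
            out[combo] = mask.sum() / m
    return out


def brute_force_itemsets(B: pd.DataFrame, min_support: float):
    """Every itemset with support >= min_support, by full power-set scan."""
    return {
        items: s for items, s in _support_map(B).items() if s >= min_support
    }


def brute_force_rules(B: pd.DataFrame, min_support: float, min_confidence: float,
                      max_rhs: int):
    """Every rule X=>Y with X∪Y frequent, |Y| <= max_rhs, conf >= cutoff.

    Returns {(lhs, rhs): (support, confidence, lift)}.
    """
    supp_of = _support_map(B)
    rules = {}
    for itemset, supp in supp_of.items():
        if len(itemset) < 2 or supp < min_support:
            continue
        for r in range(1, min(max_rhs, len(itemset) - 1) + 1):
            for rhs in combinations(itemset, r):
                lhs = tuple(g for g in itemset if g not in rhs)
                conf = supp / supp_of[lhs]
                if conf >= min_confidence - 1e-12:
                    rules[(lhs, rhs)] = (supp, conf, conf / supp_of[rhs])
    return rules


def _pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Pearson test p-value via the closed-form t statistic,
    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom."""
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0
    r = np.corrcoef(x, y)[0, 1]
    if abs(r) >= 1.0:
        return 1e-300
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return min(max(p, 1e-300), 1.0)


def lamda3_reference(gene_a: str, gene_c: str, M: pd.DataFrame,
                     B: pd.DataFrame) -> float | None:
    """Straight-line transcription of the single-pair Lamda3 formula."""
    a_bin = B[gene_a].to_numpy()
    c_bin = B[gene_c].to_numpy()
    both_one = (a_bin == 1) & (c_bin == 1)
    both_zero = (a_bin == 0) & (c_bin == 0)
    others = [g for g in M.columns if g not in (gene_a, gene_c)]
    if both_one.sum() < 3 or both_zero.sum() < 3 or not others:
        return None

    V = M.to_numpy()
    ai = list(M.columns).index(gene_a)
    ci = list(M.columns).index(gene_c)

    def block(mask):
        a = V[mask, ai]
        p_ac = _pvalue(a, V[mask, ci])
        p_bg = float(np.median(
            [_pvalue(a, V[mask, list(M.columns).index(g)]) for g in others]
        ))
        return p_ac, p_bg

    p2_ac, p2_bg = block(both_one)
    p0_ac, p0_bg = block(both_zero)
    denom = math.log10(p2_bg) + math.log10(p0_bg)
    if denom == 0.0:
        return None
    return (math.log10(p2_ac) + math.log10(p0_ac)) / denom
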