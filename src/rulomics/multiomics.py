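"""Combine two omics layers measured on the same patients.

Two layers (say RNA-seq expression and DNA methylation) that share
sample IDs are merged column-wise into a single mining input.  To keep
the provenance of each item visible in mined rules, layer-1 gene IDs get
the suffix ``.1`` and layer-2 gene IDs the suffix ``.2`` — so a rule
like ``{TAP1.1, ANXA5.2} => {PSMB9.1}`` reads "TAP1 expression change
plus ANXA5 methylation change implies PSMB9 expression change".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .arm import Rule
from .matrix import MatrixError, check_aligned, validate_binary, validate_matrix

__all__ = ["CombinedLayers", "combine_layers", "filter_cross_omics"]

_SUFFIX_RE = re.compile(r"\.[12]$")


@dataclass(frozen=True)
class CombinedLayers:
    """Two aligned omics layers merged on their shared samples."""

    continuous: pd.DataFrame
    binary: pd.DataFrame
    layer_of: dict[str, int]


def _suffixed(columns, layer: int) -> list[str]:
    out = []
    for g in columns:
        g = str(g)
        if _SUFFIX_RE.search(g):
            warnings.warn(
                f"gene ID {g!r} already ends in a layer suffix; appending anyway",
                UserWarning,
                stacklevel=3,
            )
        out.append(f"{g}.{layer}")
    return out


def combine_layers(
    layer1: tuple[pd.DataFrame, pd.DataFrame],
    layer2: tuple[pd.DataFrame, pd.DataFrame],
) -> CombinedLayers:
    """Merge two (continuous, binary) layer pairs on shared sample IDs.

    Samples are restricted to the intersection of the two layers' sample
    IDs, kept in layer-1 order; columns are layer-1 genes (suffixed
    ``.1``) followed by layer-2 genes (suffixed ``.2``).  Fewer than two
    shared samples is an error.  Sample IDs are compared after stripping
    surrounding whitespace.
    """
    (mc1, mb1), (mc2, mb2) = layer1, layer2
    for mc, mb in ((mc1, mb1), (mc2, mb2)):
        validate_matrix(mc, allow_missing=False)
        validate_binary(mb)
        check_aligned(mc, mb)

    strip1 = {str(s).strip(): s for s in mc1.index}
    strip2 = {str(s).strip(): s for s in mc2.index}
    shared = [s for s in strip1 if s in strip2]  # layer1 order
    if len(shared) < 2:
        raise MatrixError(
            f"layers share only {len(shared)} sample(s); need at least 2"
        )

    idx1 = [strip1[s] for s in shared]
    idx2 = [strip2[s] for s in shared]
    g1 = _suffixed(mc1.columns, 1)
    g2 = _suffixed(mc2.columns, 2)

    def merge(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
        left = a.loc[idx1].copy()
        right = b.loc[idx2].copy()
        left.index = shared
        right.index = shared
        left.columns = g1
        right.columns = g2
        return pd.concat([left, right], axis=1)

    layer_of = {**{g: 1 for g in g1}, **{g: 2 for g in g2}}
    return CombinedLayers(merge(mc1, mc2), merge(mb1, mb2), layer_of)


def filter_cross_omics(
    rules: Sequence[Rule],
    layer_of: Mapping[str, int],
    strict: bool = False,
) -> list[Rule]:
    """Keep rules linking the two omics layers; input order preserved.

    By default a rule is kept when its items (LHS ∪ RHS) span both
    layers — the reading under which a rule with layer-1 genes on both
    sides but a layer-2 gene in the antecedent still counts as
    cross-omics.  With ``strict=True`` the antecedent and consequent may
    share no layer at all.
    """
    out = []
    for r in rules:
        unknown = [g for g in r.items if g not in layer_of]
        if unknown:
            raise KeyError(f"genes missing from layer map: {unknown}")
        lhs_layers = {layer_of[g] for g in r.lhs}
        rhs_layers = {layer_of[g] for g in r.rhs}
        if strict:
            keep = not (lhs_layers & rhs_layers)
        else:
            keep = len(lhs_layers | rhs_layers) == 2
        if keep:
            out.append(r)
    return out
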