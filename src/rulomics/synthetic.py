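"""Seeded generators for matrices with planted gene associations.

These emulate the shape of real tumor-cohort inputs — a continuous
sample-by-gene matrix plus its dysregulation-indicator binarization —
with known ground truth, so the whole pipeline (discretize, mine, score,
combine) can be exercised and judged without any external download.

The planted signal follows a latent-factor design: each planted pair
(A, C) is driven by one shared standard-normal factor plus independent
Gaussian noise scaled so that corr(A, C) approaches a target ``r``
(noise SD ``sqrt((1-r)/r)``).  In a ``dysregulation_fraction`` of the
samples the factor is shifted upward, marking both genes as jointly
dysregulated; the binary matrix records exactly that subset for planted
genes.  All remaining genes are independent noise, binarized by the
default two-sided z-score rule, so they produce a flat correlation
background — the regime the Lamda3 measure is designed to separate.

What this does **not** emulate: realistic expression or methylation
marginals (counts, beta values), batch effects, or correlated background
modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import discretize

__all__ = [
    "SyntheticTruth",
    "generate_single_omics",
    "generate_paired_omics",
    "toy_paired_layers",
]

#: mean shift of the latent factor in dysregulated samples
DYSREGULATION_SHIFT = 3.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset.

    planted_pairs : (geneA, geneC, target correlation) triples
    dysregulation_fraction : fraction of samples where pairs co-dysregulate
    noise_sd : SD of the background noise genes
    seed : RNG seed the matrices were drawn with
    """

    planted_pairs: tuple[tuple[str, str, float], ...] = (("A1", "C1", 0.95),)
    dysregulation_fraction: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dysregulation_fraction < 1:
            raise ValueError("dysregulation_fraction must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for a, c, r in self.planted_pairs:
            if not 0 < r <= 1:
                raise ValueError(f"target correlation must be in (0, 1], got {r}")
            if a == c:
                raise ValueError(f"planted pair uses one gene twice: {a}")


def _planted_pair_values(
    rng: np.random.Generator, m: int, dys: np.ndarray, r: float
) -> tuple[np.ndarray, np.ndarray]:
    factor = rng.standard_normal(m) + DYSREGULATION_SHIFT * dys
    noise_sd = np.sqrt((1 - r) / r) if r < 1 else 0.0
    a = factor + noise_sd * rng.standard_normal(m)
    c = factor + noise_sd * rng.standard_normal(m)
    return a, c


def generate_single_omics(
    m: int = 60,
    n: int = 20,
    truth: SyntheticTruth | None = None,
    sample_prefix: str = "S",
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one omics layer with planted co-dysregulated pairs.

    Returns ``(continuous, binary, truth)``.  Planted genes are named in
    ``truth.planted_pairs``; the remaining ``n - 2 * n_pairs`` genes are
    independent noise named ``N01, N02, ...``.  The binary matrix marks
    the dysregulated sample subset for planted genes and applies the
    default two-sided z-score rule (|z| > 1.96) to noise genes.
    Identical inputs give bit-identical outputs.
    """
    truth = truth if truth is not None else SyntheticTruth()
    if m < 10:
        raise ValueError(f"need at least 10 samples, got {m}")
    planted_genes = [g for pair in truth.planted_pairs for g in pair[:2]]
    if len(set(planted_genes)) != len(planted_genes):
        raise ValueError("planted pairs share genes")
    if n < len(planted_genes) + 2:
        raise ValueError(
            f"need n >= {len(planted_genes) + 2} for {len(planted_genes)} planted genes"
        )

    rng = np.random.default_rng(truth.seed)
    samples = [f"{sample_prefix}{i + 1:03d}" for i in range(m)]
    n_dys = int(round(truth.dysregulation_fraction * m))
    dys_idx = rng.choice(m, size=n_dys, replace=False)
    dys = np.zeros(m)
    dys[dys_idx] = 1.0

    columns: dict[str, np.ndarray] = {}
    for a_name, c_name, r in truth.planted_pairs:
        a, c = _planted_pair_values(rng, m, dys, r)
        columns[a_name] = a
        columns[c_name] = c
    n_noise = n - len(planted_genes)
    for j in range(n_noise):
        columns[f"N{j + 1:02d}"] = truth.noise_sd * rng.standard_normal(m)

    M = pd.DataFrame(columns, index=samples)
    B = discretize(M, method="zscore", threshold=1.96, direction="both")
    for g in planted_genes:
        B[g] = dys.astype(int)
    return M, B, truth


def generate_paired_omics(
    m: int = 60,
    n1: int = 20,
    n2: int = 20,
    truth: SyntheticTruth | None = None,
    overlap: int | None = None,
) -> tuple[
    tuple[pd.DataFrame, pd.DataFrame],
    tuple[pd.DataFrame, pd.DataFrame],
    SyntheticTruth,
]:
    """Generate two omics layers with planted *cross-layer* pairs.

    Each planted pair puts gene A in layer 1 and gene C in layer 2,
    driven by one shared latent factor, so after layer combination the
    cross-omics rule {A.1} => {C.2} (or its converse) is minable.  Layer
    1 has samples ``S001..S<m>``; ``overlap`` (default ``m``) controls
    how many of layer 2's ``m`` samples are shared — the rest get fresh
    IDs, yielding a deliberate partial sample intersection.
    """
    truth = truth if truth is not None else SyntheticTruth()
    overlap = m if overlap is None else overlap
    if not 2 <= overlap <= m:
        raise ValueError(f"overlap must be in [2, {m}], got {overlap}")

    rng = np.random.default_rng(truth.seed)
    samples1 = [f"S{i + 1:03d}" for i in range(m)]
    samples2 = samples1[m - overlap :] + [f"X{i + 1:03d}" for i in range(m - overlap)]
    n_dys = int(round(truth.dysregulation_fraction * m))
    dys_idx = rng.choice(m, size=n_dys, replace=False)
    dys = np.zeros(m)
    dys[dys_idx] = 1.0

    cols1: dict[str, np.ndarray] = {}
    cols2: dict[str, np.ndarray] = {}
    for a_name, c_name, r in truth.planted_pairs:
        a, c = _planted_pair_values(rng, m, dys, r)
        cols1[a_name] = a
        cols2[c_name] = c
    for j in range(n1 - len(cols1)):
        cols1[f"E{j + 1:02d}"] = truth.noise_sd * rng.standard_normal(m)
    for j in range(n2 - len(cols2)):
        cols2[f"M{j + 1:02d}"] = truth.noise_sd * rng.standard_normal(m)

    M1 = pd.DataFrame(cols1, index=samples1)
    M2 = pd.DataFrame(cols2, index=samples2)
    B1 = discretize(M1)
    B2 = discretize(M2)
    for a_name, c_name, _ in truth.planted_pairs:
        B1[a_name] = dys.astype(int)
        B2[c_name] = dys.astype(int)
    return (M1, B1), (M2, B2), truth


def toy_paired_layers() -> tuple[
    tuple[pd.DataFrame, pd.DataFrame], tuple[pd.DataFrame, pd.DataFrame]
]:
    """Deterministic two-layer block fixture for exact-count tests.

    Six shared samples.  Layer 1 genes GA, GB co-dysregulate in samples
    t1–t4 (within-layer pair); layer 2 gene GC co-dysregulates with GA
    across layers on the same block; layer 2 gene GD is altered in a
    disjoint pair of samples.  No noise: the continuous values are the
    indicators themselves, so every count is exact.
    """
    samples = [f"t{i}" for i in range(1, 7)]
    b1 = pd.DataFrame(
        {"GA": [1, 1, 1, 1, 0, 0], "GB": [1, 1, 1, 1, 0, 0]},
        index=samples,
        dtype=float,
    )
    b2 = pd.DataFrame(
        {"GC": [1, 1, 1, 1, 0, 0], "GD": [0, 0, 0, 0, 1, 1]},
        index=samples,
        dtype=float,
    )
    return (b1.copy(), b1.astype(int)), (b2.copy(), b2.astype(int))
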