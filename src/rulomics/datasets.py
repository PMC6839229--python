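"""Small built-in example datasets.

The toy expression matrix is the classic five-sample, five-gene
dysregulation-indicator example used throughout the documentation and
tests: each row is a patient sample, each column a gene, and a 1 marks a
"molecular event" (the gene is dysregulated in that sample).
"""

from __future__ import annotations

import pandas as pd

TOY_GENES = ["NEK2", "TPX2", "CKS1B", "UBE2C", "CDKN3"]

TOY_SAMPLES = [
    "TCGA-2H-A9GF-01",
    "TCGA-2H-A9GG-01",
    "TCGA-2H-A9GH-01",
    "TCGA-2H-A9GI-01",
    "TCGA-2H-A9GJ-01",
]

_TOY_VALUES = [
    [1, 1, 0, 1, 1],
    [0, 0, 0, 0, 0],
    [1, 1, 1, 1, 1],
    [1, 0, 1, 1, 1],
    [0, 1, 0, 0, 0],
]


def toy_expression_matrix() -> pd.DataFrame:
    """Return the 5x5 toy dysregulation matrix (samples x genes).

    The matrix is already binary, so it can serve both as a continuous
    input (``method='fixed', threshold=0.5, direction='up'`` reproduces it)
    and directly as a transaction database.
    """
    return pd.DataFrame(
        _TOY_VALUES, index=list(TOY_SAMPLES), columns=list(TOY_GENES), dtype=float
    )
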