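"""Inter-rater agreement: accuracy, Cohen's kappa, Fleiss' kappa.

Cohen's kappa is unweighted (the three talk-type categories are nominal).
When both raters are constant and identical the chance agreement p_e is 1
and kappa is 0/0; that case is reported as kappa = 1.0 with a ``degenerate``
flag rather than NaN.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .errors import ValidationError


@dataclass(frozen=True)
class AgreementResult:
    accuracy: float
    kappa: float
    n_items: int
    degenerate: bool = False


def agreement(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Accuracy and Cohen's kappa between two raters' label sequences."""
    a = [getattr(x, "value", x) for x in labels_a]
    b = [getattr(x, "value", x) for x in labels_b]
    if len(a) != len(b):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(b)}")
    n = len(a)
    if n < 1:
        raise ValidationError("agreement needs at least one item")
    accuracy = sum(x == y for x, y in zip(a, b)) / n
    ca, cb = Counter(a), Counter(b)
    p_e = sum(ca[c] * cb.get(c, 0) for c in ca) / n**2
    if p_e >= 1.0 - 1e-15:
        # both raters constant on the same category
        return AgreementResult(accuracy, 1.0, n, degenerate=True)
    kappa = float(cohen_kappa_score(a, b))
    return AgreementResult(accuracy, kappa, n)


def fleiss_kappa(counts, n_raters: int) -> float:
    """Fleiss' kappa from an items x categories table of rating counts."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValidationError("counts must be a 2-D items x categories table")
    if n_raters < 2:
        raise ValidationError(f"n_raters must be >= 2, got {n_raters}")
    row_sums = table.sum(axis=1)
    bad = np.nonzero(row_sums != n_raters)[0]
    if bad.size:
        raise ValidationError(
            f"row(s) {bad.tolist()} do not sum to n_raters={n_raters}"
        )
    # perfect agreement on a single category makes chance agreement 1 (0/0)
    p_bar = float(np.mean((np.sum(table**2, axis=1) - n_raters) / (n_raters * (n_raters - 1))))
    p_j = table.sum(axis=0) / table.sum()
    if float(p_j @ p_j) >= 1.0 - 1e-15:
        return 1.0 if p_bar >= 1.0 - 1e-15 else float("nan")
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def agreement_from_csv(path_a, path_b) -> AgreementResult:
    """Agreement between two two-column CSV files (item_id, category).

    Items are aligned on ``item_id``; both files must cover the same items.
    """
    dfs = []
    for p in (path_a, path_b):
        df = pd.read_csv(p, dtype=str)
        for col in ("item_id", "category"):
            if col not in df.columns:
                raise ValidationError(f"{p}: missing required column {col!r}")
        dfs.append(df.set_index("item_id")["category"])
    a, b = dfs
    if set(a.index) != set(b.index):
        raise ValidationError("item_id sets differ between the two files")
    b = b.reindex(a.index)
    return agreement(list(a), list(b))
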