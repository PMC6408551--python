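"""Multiple-testing adjustment over named P-value families.

Five procedures: Bonferroni, Holm (step-down FWER), Hommel (Simes-based
closed testing), Benjamini-Hochberg (step-up FDR) and Benjamini-Yekutieli
(FDR under arbitrary dependence).  Candidate-gene panels test few markers in
strong LD, which is why the dependence-robust FDR variants matter here.
Adjustment itself is delegated to statsmodels; this module owns family
bookkeeping and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

METHODS = ("bonferroni", "holm", "hommel", "bh", "by")
_SM_NAMES = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hommel": "hommel",
    "bh": "fdr_bh",
    "by": "fdr_by",
}


def adjust(pvals, method: str) -> np.ndarray:
    """Adjusted P values, in input order, capped at 1."""
    p = np.asarray(pvals, float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a 1-d family of >= 1 p values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0,1]")
    if method not in _SM_NAMES:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    adj = multipletests(p, alpha=0.05, method=_SM_NAMES[method])[1]
    return np.minimum(np.maximum(adj, p), 1.0)


@dataclass
class PValueFamily:
    """A named, ordered set of raw P values with per-method adjusted vectors."""

    label: str
    test_ids: list[str]
    raw: np.ndarray
    adjusted: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, float)
        if len(self.test_ids) != self.raw.size:
            raise ValueError("test_ids and raw lengths differ")
        if len(set(self.test_ids)) != len(self.test_ids):
            raise ValueError("duplicate test ids in family")

    def adjust_all(self, methods=METHODS) -> "PValueFamily":
        for m in methods:
            self.adjusted[m] = adjust(self.raw, m)
        return self

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"test": self.test_ids, "p_raw": self.raw})
        for m, v in self.adjusted.items():
            df[f"p_{m}"] = v
        df["family"] = self.label
        return df


def make_family(
    results: pd.DataFrame,
    label: str,
    filters: dict | None = None,
    id_cols: tuple[str, ...] = ("variant", "stratum"),
    p_col: str = "p",
) -> PValueFamily:
    """Build a family from an association-results table.

    ``filters`` selects rows by exact column match (e.g. one phenotype, both
    sexes -- the 7 SNP x 2 sex family the per-phenotype FDR columns use).
    Test ids concatenate ``id_cols``; duplicates are an error.
    """
    df = results
    for col, val in (filters or {}).items():
        df = df[df[col] == val]
    if df.empty:
        raise ValueError(f"family {label!r} selects no tests")
    ids = df[list(id_cols)].astype(str).agg(":".join, axis=1).tolist()
    return PValueFamily(label=label, test_ids=ids, raw=df[p_col].to_numpy(float))
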