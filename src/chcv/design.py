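"""Design-matrix construction shared by the logistic and Cox models.

Categorical covariates are expanded to indicator columns against a fixed
reference level (smoking: current; sex: F; four-category CH exposure:
no CH; mutation-count class: 0).  Participants with unknown smoking status
are handled by complete-case deletion wherever smoking enters a model.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

import pandas as pd

CATEGORY_ORDERS = {
    "smoking": ("current", "never", "previous"),
    "sex": ("F", "M"),
    "exposure4": ("no_ch", "both", "chip_only", "mca_only"),
    "mutation_count_class": ("0", "1", "2", "3+"),
}


def expand_terms(df: pd.DataFrame, terms: Iterable[str]
                 ) -> Tuple[pd.DataFrame, List[str]]:
    """Expand model terms into numeric columns; returns (X, column names).

    Rows with unknown smoking (when smoking is a term) or missing values in
    any term are dropped (complete-case analysis).
    """
    terms = list(terms)
    work = df.copy()
    if "smoking" in terms:
        work = work[work["smoking"].isin(CATEGORY_ORDERS["smoking"])]
    cols = {}
    for t in terms:
        s = work[t]
        if t in CATEGORY_ORDERS:
            ref, *others = CATEGORY_ORDERS[t]
            for level in others:
                cols[f"{t}_{level}" if t != "sex" else "sex_M"] = \
                    (s == level).astype(float)
        elif s.dtype == bool or s.dtype == object:
            cols[t] = s.astype(float) if s.dtype == bool else \
                pd.to_numeric(s, errors="raise").astype(float)
        else:
            cols[t] = s.astype(float)
    X = pd.DataFrame(cols, index=work.index).dropna()
    return X, list(X.columns)
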