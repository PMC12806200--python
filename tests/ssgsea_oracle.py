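"""Independent brute-force ssGSEA oracle used by the test suite."""

import pandas as pd
from scipy.stats import rankdata


def brute_force_ssgsea(expr: pd.DataFrame, gene_set, alpha: float) -> pd.Series:
    """Double-loop ECDF-difference implementation, one sample at a time."""
    scores = {}
    for sample in expr.columns:
        ranks = rankdata(expr[sample].to_numpy(), method="average")
        order = sorted(range(len(ranks)), key=lambda i: -ranks[i])
        in_set = [expr.index[i] in gene_set for i in order]
        denom_in = sum(ranks[i] ** alpha for i, flag
                       in zip(order, in_set) if flag)
        n_out = sum(not f for f in in_set)
        total, cum_in, cum_out = 0.0, 0.0, 0.0
        for pos, i in enumerate(order):
            if in_set[pos]:
                cum_in += ranks[i] ** alpha / denom_in
            else:
                cum_out += 1.0 / n_out
            total += cum_in - cum_out
        scores[sample] = total
    return pd.Series(scores)
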