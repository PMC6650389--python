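"""Functional-category enrichment of phenotypic clusters.

For every (cluster, category) pair a 2x2 table is built over the flagged
strains — in-cluster vs out-of-cluster, carrying vs not carrying the
category — and tested with a two-tailed Fisher's exact test (the two-sided
convention that sums the probabilities of all tables, with the observed
margins, no more likely than the observed one).  Categories may be
multi-label per strain.  Following the screening convention, no
multiple-testing correction is applied by default (p < 0.05 flags
significance); Benjamini-Hochberg correction is available as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fisher_enrichment", "two_tailed_fisher"]


def two_tailed_fisher(table) -> float:
    """Two-tailed Fisher exact p for one 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def fisher_enrichment(
    cluster_memberships: dict | pd.Series,
    category_labels: dict | pd.Series,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Enrichment table over all (cluster, category) pairs.

    ``cluster_memberships`` maps strain -> cluster id; ``category_labels``
    maps strain -> iterable of category letters (a string works).  The
    background is the clustered (flagged) strain set.  Categories carried by
    no strain are skipped; a category carried by every strain necessarily
    gives p = 1.
    """
    members = pd.Series(dict(cluster_memberships))
    cats = pd.Series(dict(category_labels)).reindex(members.index).dropna()
    strains = cats.index
    members = members.loc[strains]
    all_cats = sorted({c for v in cats for c in v})
    n_total = len(strains)

    rows = []
    for cl in sorted(pd.unique(members)):
        in_cl = members == cl
        n_in = int(in_cl.sum())
        for cat in all_cats:
            has = cats.apply(lambda v: cat in v)
            a = int((in_cl & has).sum())  # in cluster, has category
            b = n_in - a  # in cluster, lacks it
            c = int(has.sum()) - a  # outside, has it
            d = n_total - n_in - c
            if a + c == 0:
                continue
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
            p = two_tailed_fisher([[a, b], [c, d]])
            rows.append(
                {
                    "cluster": cl,
                    "category": cat,
                    "in_cluster_with": a,
                    "in_cluster_without": b,
                    "out_cluster_with": c,
                    "out_cluster_without": d,
                    "odds_ratio": odds,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "category",
            "in_cluster_with",
            "in_cluster_without",
            "out_cluster_with",
            "out_cluster_without",
            "odds_ratio",
            "p_value",
        ],
    )
    if bh_correct and len(out):
        p = out["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        out["p_adjusted"] = np.clip(adj[np.argsort(order)], 0, 1)
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out
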