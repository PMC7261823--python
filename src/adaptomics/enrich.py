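"""Over-representation analysis (ORA) of gene lists against set collections.

ORA asks whether a query list (e.g. the significantly regulated genes)
overlaps a gene set more than expected by chance given the profiled
universe.  The p-value is the upper tail of the hypergeometric
distribution, P(X >= k) for an overlap of k between a query of size n
and a set of size m inside a universe of size N; FDR control across the
collection uses Benjamini-Hochberg.  Sets are restricted to the
background universe before their sizes enter the test, matching the use
of profiled-gene reference lists as background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dea import bh_adjust

ORA_COLUMNS = ["set_name", "k_overlap", "m_set", "n_query", "N_universe", "p", "fdr", "enriched"]


def ora(
    query: set[str],
    collection: dict[str, set[str]],
    background: set[str],
    fdr_cutoff: float = 0.05,
    min_size: int = 5,
    max_size: int = 2000,
) -> pd.DataFrame:
    """Hypergeometric over-representation test for each set in a collection.

    Parameters
    ----------
    query:
        Genes of interest; must be a subset of ``background``.
    collection:
        Mapping set name -> member genes (restricted to background
        internally; sets outside [min_size, max_size] after restriction
        are not tested).
    background:
        The universe of genes that could have entered the query.
    """
    query = set(query)
    background = set(background)
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query genes missing from background: {offenders[:10]}"
                         + (" ..." if len(offenders) > 10 else ""))
    N = len(background)
    n = len(query)
    rows = []
    for name in sorted(collection):
        members = collection[name] & background
        m = len(members)
        if not (min_size <= m <= max_size):
            continue
        k = len(members & query)
        # upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
        rows.append({"set_name": name, "k_overlap": k, "m_set": m,
                     "n_query": n, "N_universe": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=ORA_COLUMNS[:-2])
    if out.empty:
        out["fdr"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
        return out
    out["fdr"] = bh_adjust(out["p"])
    out["enriched"] = out["fdr"] < fdr_cutoff
    return out


def rank_for_plot(enriched: pd.DataFrame, cap: float = 300.0) -> pd.DataFrame:
    """Order enriched sets by descending -log10(FDR), ties alphabetical.

    Zero FDRs are capped at ``cap`` so the ranking stays finite.
    """
    out = enriched.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_fdr"] = np.minimum(-np.log10(out["fdr"]), cap)
    out = out.sort_values(["neg_log10_fdr", "set_name"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)
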