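"""Enrichment statistics over edited genes.

Two questions, two one-sided exact tests:

* Is a GO term over-represented among edited genes? Upper-tail hypergeometric
  on (k edited-in-term, K term size, n edited total, N universe size).
* Are endosymbiont-derived genes edited more often than the rest of the
  nucleus? One-sided Fisher's exact test on the edited x endosymbiont 2x2.

The universe is exactly the supplied label table: the caller decides whether
it is all genes or annotated genes only. GO p-values are reported raw by
default (an optional BH adjustment is available); terms are called enriched
at raw p < alpha.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .caller import adjust_fdr


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N population, K marked,
    n drawn)."""
    if not (0 <= k <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _universe(labels: pd.DataFrame, edited: set[str] | None) -> pd.DataFrame:
    df = labels.copy()
    if edited is not None:
        df["edited"] = [int(g in edited) for g in df.index]
    if "edited" not in df.columns:
        raise ValueError("supply an 'edited' column or an edited gene set")
    return df


def go_enrichment(
    labels: pd.DataFrame,
    edited: set[str] | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of edited genes.

    ``labels`` is indexed by gene with a ``go_terms`` column (semicolon-joined)
    and optionally an ``edited`` 0/1 column; alternatively pass the edited gene
    ids as a set. One test per term present on at least one gene; returns the
    rows with p < alpha (q < alpha when ``fdr``), sorted by p, with the edited
    and non-edited percentages of each term.
    """
    df = _universe(labels, edited)
    N = len(df)
    n = int(df["edited"].sum())
    term_members: dict[str, list[str]] = {}
    for gene, terms in df["go_terms"].items():
        for term in str(terms).split(";"):
            term = term.strip()
            if term:
                term_members.setdefault(term, []).append(gene)
    edited_set = set(df.index[df["edited"] == 1])
    rows = []
    for term, members in sorted(term_members.items()):
        K = len(members)
        k = sum(1 for g in members if g in edited_set)
        p = hypergeom_tail(k, K, n, N)
        rows.append(
            {
                "term": term,
                "k_edited": k,
                "term_size": K,
                "n_edited_total": n,
                "universe": N,
                "edited_pct": 100.0 * k / K,
                "nonedited_pct": 100.0 * (K - k) / K,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    if fdr:
        table["q_value"] = adjust_fdr(table["p_value"].to_numpy())
        keep = table["q_value"] < alpha
    else:
        keep = table["p_value"] < alpha
    return table[keep].sort_values("p_value", kind="stable").reset_index(drop=True)


def endosymbiont_fisher(
    labels: pd.DataFrame, edited: set[str] | None = None
) -> dict:
    """Editing enrichment among endosymbiont-derived genes.

    Returns the 2x2 table [[edited&endo, nonedited&endo], [edited&other,
    nonedited&other]], the per-stratum edited fractions, the odds ratio and
    the one-sided (greater) exact p.
    """
    df = _universe(labels, edited)
    endo = df["endosymbiont"].astype(bool)
    ed = df["edited"].astype(bool)
    a = int((ed & endo).sum())
    b = int((~ed & endo).sum())
    c = int((ed & ~endo).sum())
    d = int((~ed & ~endo).sum())
    if a + b == 0 or c + d == 0:
        raise ValueError("both strata must be nonempty")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return {
        "table": [[a, b], [c, d]],
        "endo_edited_fraction": a / (a + b),
        "other_edited_fraction": c / (c + d),
        "odds_ratio": float(odds),
        "p_value": float(p),
    }
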