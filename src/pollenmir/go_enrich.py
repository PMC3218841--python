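"""GO-term abundance analysis of miRNA target sets.

One-sided hypergeometric test of each term's representation in a query
gene set against a background universe, with Benjamini-Hochberg control of
the false discovery rate.  Term sets are flat: no propagation up the GO
graph is performed (annotation files are taken at face value).
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def read_go_map(path) -> pd.DataFrame:
    """Read a gene->term TSV with columns gene_id, term_id[, name, branch]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "term_id" not in df.columns:
        raise ValueError("GO map needs gene_id and term_id columns")
    return df


def enrich(query_genes, go_map: pd.DataFrame, universe=None,
           alpha: float = 0.01) -> pd.DataFrame:
    """Hypergeometric term enrichment of ``query_genes``.

    For each term with >= 1 query hit:
        p = P[X >= k],  X ~ Hypergeom(N, K, n)
    with N the universe size, K the term's genes in the universe, n the
    query size and k the term's genes in the query.  P-values are BH
    adjusted across tested terms; significant <=> fdr < ``alpha``.
    """
    if universe is None:
        universe = set(go_map["gene_id"])
    universe = set(universe)
    if not universe:
        raise ValueError("empty background universe")
    query = set(query_genes) & universe
    if set(query_genes) - universe:
        missing = sorted(set(query_genes) - universe)
        raise ValueError(f"query genes outside the universe: {missing[:5]}")
    cols = ["term_id", "name", "branch", "k", "n", "K", "N", "p", "fdr",
            "significant"]
    if not query:
        warnings.warn("empty query gene set: no terms tested")
        return pd.DataFrame(columns=cols)
    gm = go_map[go_map["gene_id"].isin(universe)]
    n, big_n = len(query), len(universe)
    rows = []
    for term, sub in gm.groupby("term_id"):
        genes = set(sub["gene_id"])
        k = len(genes & query)
        if k == 0:
            continue
        big_k = len(genes)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        name = sub["name"].iloc[0] if "name" in sub.columns else ""
        branch = sub["branch"].iloc[0] if "branch" in sub.columns else ""
        rows.append((term, name, branch, k, n, big_k, big_n, p))
    out = pd.DataFrame(rows, columns=cols[:-2]).sort_values("p",
                                                            kind="stable")
    if out.empty:
        out["fdr"] = []
        out["significant"] = []
        return out
    _, fdr, _, _ = multipletests(out["p"], method="fdr_bh")
    out["fdr"] = fdr
    out["significant"] = out["fdr"] < alpha
    return out.reset_index(drop=True)
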