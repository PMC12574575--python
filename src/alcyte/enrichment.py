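"""Hypergeometric over-representation analysis (ORA) of gene lists.

Direction-stratified, cell-type-stratified gene lists are tested against
user-supplied GMT gene-set collections; p-values are upper-tail
hypergeometric probabilities with Benjamini–Hochberg control per collection
(namespace) per stratum. Both k/n and k/K ratios are derivable from the
stored counts; the reported ``gene_ratio`` column is k/n (overlap over query
size), labelled as such.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("alcyte")

ORA_COLUMNS = [
    "set_name", "k", "n", "K", "N", "gene_ratio", "p_raw", "p_adj",
    "significant", "genes",
]


def ora(
    query: list[str],
    universe: list[str],
    sets: dict[str, set[str]],
    alpha: float = 0.05,
    min_set_size: int = 0,
    max_set_size: int = 0,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against gene sets.

    For each set, p = P[overlap ≥ k] drawing n (query size) from N (universe
    size) with K marked (set ∩ universe). Query genes outside the universe are
    dropped with a warning; adjustment is Benjamini–Hochberg across all sets
    in the collection.
    """
    uni = set(universe)
    q = set(query)
    outside = q - uni
    if outside:
        logger.warning("ora: %d query gene(s) outside the universe dropped", len(outside))
        q = q & uni
    if not q:
        logger.warning("ora: empty query; returning empty result")
        return pd.DataFrame(columns=ORA_COLUMNS)
    N, n = len(uni), len(q)
    rows = []
    for name, genes in sets.items():
        marked = set(genes) & uni
        K = len(marked)
        if min_set_size and K < min_set_size:
            continue
        if max_set_size and K > max_set_size:
            continue
        overlap = sorted(q & marked)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "set_name": name, "k": k, "n": n, "K": K, "N": N,
            "gene_ratio": k / n, "p_raw": min(p, 1.0), "genes": ";".join(overlap),
        })
    if not rows:
        return pd.DataFrame(columns=ORA_COLUMNS)
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    df["significant"] = df["p_adj"] < alpha
    df = df[ORA_COLUMNS]
    return df.sort_values("p_adj", kind="stable").reset_index(drop=True)


def stratified_enrichment(
    calls: pd.DataFrame,
    collections: dict[str, dict[str, set[str]]],
    universe: list[str],
    alpha: float = 0.05,
    min_set_size: int = 0,
    max_set_size: int = 0,
) -> pd.DataFrame:
    """One ORA per (cell type × direction) stratum and per collection namespace.

    Inconsistent-direction genes are excluded; empty strata are skipped with a
    log line. ``collections`` maps namespace (e.g. 'BP', 'KEGG') → gene sets;
    BH adjustment is independent per namespace per stratum. Returns a long
    table with stratum/namespace columns prepended.
    """
    definite = calls[calls["direction"].isin(["up", "down"])]
    frames = []
    for (ct, direction), grp in definite.groupby(["cell_type", "direction"], sort=False):
        genes = sorted(grp["gene"].unique())
        if not genes:
            logger.info("stratified_enrichment: stratum %s/%s empty; skipped", ct, direction)
            continue
        for namespace, sets in collections.items():
            res = ora(genes, universe, sets, alpha=alpha,
                      min_set_size=min_set_size, max_set_size=max_set_size)
            if res.empty:
                continue
            res.insert(0, "namespace", namespace)
            res.insert(0, "direction", direction)
            res.insert(0, "cell_type", ct)
            frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["cell_type", "direction", "namespace"] + ORA_COLUMNS)
    return pd.concat(frames, ignore_index=True)
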