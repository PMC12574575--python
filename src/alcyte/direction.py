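"""Direction-of-regulation calling and cross-cell-type summary.

A CpG's methylation state together with the correlation mode it was found in
implies the gene's expression direction in the high-AL group: hypomethylated
in negative mode or hypermethylated in positive mode → upregulated;
hypermethylated in negative mode or hypomethylated in positive mode →
downregulated. Dual CpGs first resolve to the state with the higher
prevalence. A gene is up/down only if *all* of its CpG calls agree, otherwise
it is inconsistent and excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("alcyte")

_RULES = {
    ("hypo", "negative"): "up",
    ("hyper", "positive"): "up",
    ("hyper", "negative"): "down",
    ("hypo", "positive"): "down",
}


def cpg_direction(state: str, mode: str) -> str:
    """Map (methylation state, correlation mode) to up/down regulation."""
    if state == "dual":
        raise ValueError("dual state must be resolved with resolve_dual first")
    try:
        return _RULES[(state, mode)]
    except KeyError:
        raise ValueError(f"no rule for state={state!r}, mode={mode!r}") from None


def resolve_dual(prev_hypo: float, prev_hyper: float) -> str | None:
    """Pick the dominant state of a dual CpG by higher prevalence.

    Equal prevalences have no dominant state; the CpG is excluded from
    direction calling (returns None, logged by the caller).
    """
    if prev_hypo <= 0 and prev_hyper <= 0:
        raise ValueError("both prevalences are zero: not a dual CpG")
    if prev_hypo == prev_hyper:
        return None
    return "hypo" if prev_hypo > prev_hyper else "hyper"


@dataclass
class DirectionCall:
    gene: str
    cell_type: str
    direction: str  # 'up' | 'down' | 'inconsistent'
    cpgs: list[str]
    cpg_directions: list[str]


def gene_direction(gene: str, cell_type: str, cpg_calls: list[tuple[str, str]]) -> DirectionCall:
    """Unanimity rule over a gene's per-CpG up/down calls.

    ``cpg_calls`` is a list of (cpg_id, 'up'|'down'). Mixed calls yield
    'inconsistent'.
    """
    if not cpg_calls:
        raise ValueError(f"gene {gene!r}: empty CpG call list")
    dirs = {d for _, d in cpg_calls}
    direction = dirs.pop() if len(dirs) == 1 else "inconsistent"
    return DirectionCall(
        gene=gene,
        cell_type=cell_type,
        direction=direction,
        cpgs=[c for c, _ in cpg_calls],
        cpg_directions=[d for _, d in cpg_calls],
    )


def call_directions(pairs: pd.DataFrame) -> pd.DataFrame:
    """Direction calls for every (gene, cell type) in a combined pair table.

    Modes are pooled per gene within a cell type before the unanimity check.
    Dual CpGs resolve by prevalence; prevalence ties drop the CpG. Returns a
    frame with gene, cell_type, direction, n_cpgs, cpg_list.
    """
    rows = []
    for (cell_type, gene), grp in pairs.groupby(["cell_type", "gene"], sort=False):
        calls = []
        for _, r in grp.iterrows():
            state = r["state"]
            if state == "dual":
                state = resolve_dual(r["prev_hypo"], r["prev_hyper"])
                if state is None:
                    logger.info(
                        "direction: CpG %s (%s) dual with tied prevalences; excluded",
                        r["cpg"], gene,
                    )
                    continue
            calls.append((r["cpg"], cpg_direction(state, r["mode"])))
        if not calls:
            continue
        dc = gene_direction(gene, cell_type, calls)
        rows.append({
            "gene": gene, "cell_type": cell_type, "direction": dc.direction,
            "n_cpgs": len(dc.cpgs), "cpg_list": ";".join(dc.cpgs),
        })
    return pd.DataFrame(rows, columns=["gene", "cell_type", "direction", "n_cpgs", "cpg_list"])


def summarize(pairs: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Per-cell-type and global counts/proportions of states and directions.

    Percentage fields are rounded to one decimal in the rendered report; the
    returned dict keeps full precision. Shared genes are genes appearing in
    at least two cell types.
    """
    out: dict = {"per_cell_type": {}, "global": {}}
    for ct, grp in pairs.groupby("cell_type", sort=False):
        states = grp["state"].value_counts(normalize=True).to_dict()
        ct_calls = calls[calls["cell_type"] == ct]
        definite = ct_calls[ct_calls["direction"] != "inconsistent"]
        dirs = definite["direction"].value_counts(normalize=True).to_dict()
        out["per_cell_type"][ct] = {
            "n_pairs": int(len(grp)),
            "n_dmgs": int(grp["gene"].nunique()),
            "state_proportions": states,
            "direction_proportions": dirs,
            "n_inconsistent": int((ct_calls["direction"] == "inconsistent").sum()),
        }
    occurrences = calls[["gene", "cell_type"]].drop_duplicates()
    per_gene = occurrences.groupby("gene")["cell_type"].nunique()
    shared = per_gene[per_gene >= 2]
    n_unique = int(pairs["gene"].nunique()) if len(pairs) else 0
    out["global"] = {
        "n_pairs": int(len(pairs)),
        "n_unique_cpgs": int(pairs["cpg"].nunique()) if len(pairs) else 0,
        "n_unique_genes": n_unique,
        "n_occurrences": int(len(occurrences)),
        "n_shared_genes": int(len(shared)),
        "shared_genes": {g: int(k) for g, k in shared.items()},
        "pct_shared": 100.0 * len(shared) / n_unique if n_unique else 0.0,
        "state_proportions": pairs["state"].value_counts(normalize=True).to_dict()
        if len(pairs) else {},
        "direction_proportions": calls.loc[calls["direction"] != "inconsistent", "direction"]
        .value_counts(normalize=True).to_dict() if len(calls) else {},
    }
    return out


def render_report(summary: dict) -> str:
    """Human-readable text report from :func:`summarize` output."""
    lines = ["=== Functional CpG-gene pair summary ==="]
    g = summary["global"]
    lines.append(
        f"Total pairs: {g['n_pairs']}  unique CpGs: {g['n_unique_cpgs']}  "
        f"unique genes (DMGs): {g['n_unique_genes']}"
    )
    lines.append(
        f"Genes shared between ≥2 cell types: {g['n_shared_genes']} "
        f"({g['pct_shared']:.1f}%)"
    )
    for cat, props in (("states", g["state_proportions"]),
                       ("directions", g["direction_proportions"])):
        if props:
            body = ", ".join(f"{k}: {100 * v:.1f}%" for k, v in props.items())
            lines.append(f"Global {cat}: {body}")
    for ct, d in summary["per_cell_type"].items():
        lines.append(
            f"[{ct}] pairs={d['n_pairs']} DMGs={d['n_dmgs']} "
            f"inconsistent={d['n_inconsistent']}"
        )
    return "\n".join(lines) + "\n"
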