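"""Projection of the r.m. gene set onto single-cell analysis summaries.

This module deliberately consumes *summary tables* only — per-cell-type
differential-expression exports (gene, log2 fold change, adjusted p) and
cell-type composition counts — so any upstream single-cell toolchain can
produce the inputs. It overlays the recurrently mutated gene set on DE
rankings, tests gene-set overlap with a hypergeometric upper tail, and
computes cell-type composition differences between conditions in
percentage points.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

DE_COLUMNS = ("gene", "log2fc", "p_adj", "cell_type")


def read_de_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE summary columns {missing}")
    if ((df["p_adj"] < 0) | (df["p_adj"] > 1)).any():
        raise ValueError(f"{path}: adjusted p-values outside [0, 1]")
    return df


def overlay_rm(de_rows: pd.DataFrame, rm_genes, descending: bool = True) -> pd.DataFrame:
    """Rank one cell type's DE genes by log2 fold change and flag r.m. genes.

    Ties in log2fc break alphabetically by gene symbol, so the ranking is
    deterministic.
    """
    if de_rows["gene"].duplicated().any():
        dupes = sorted(de_rows.loc[de_rows["gene"].duplicated(), "gene"].unique())
        raise ValueError(f"duplicate genes within one cell type: {dupes}")
    rm = set(rm_genes)
    out = de_rows.sort_values(["log2fc", "gene"], ascending=[not descending, True],
                              kind="stable").reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    out["is_rm"] = out["gene"].isin(rm)
    return out


def ora_hypergeometric(hit_set, gene_set, universe_size: int) -> tuple[int, float, float, float]:
    """Over-representation of ``gene_set`` among ``hit_set`` within a gene
    universe: upper-tail hypergeometric P(overlap >= observed).

    Returns (overlap, expected overlap, fold enrichment, p).
    """
    hits = set(hit_set)
    target = set(gene_set)
    n_hits, n_target = len(hits), len(target)
    if universe_size < len(hits | target):
        raise ValueError(
            f"universe_size {universe_size} smaller than |hits ∪ set| = {len(hits | target)}"
        )
    overlap = len(hits & target)
    expected = n_hits * n_target / universe_size if universe_size else 0.0
    fold = overlap / expected if expected > 0 else float("nan")
    # P(X >= overlap), X ~ Hypergeom(universe, n_target, n_hits)
    p = float(hypergeom.sf(overlap - 1, universe_size, n_target, n_hits))
    return overlap, expected, fold, min(p, 1.0)


def composition_difference(composition: pd.DataFrame,
                           condition: str, control: str) -> pd.DataFrame:
    """Per-cell-type percentage composition under each condition and the
    difference in percentage points (condition minus control).

    ``composition`` is a cell_type x condition table of cell counts.
    """
    for col in (condition, control):
        if col not in composition.columns:
            raise ValueError(f"condition column {col!r} absent from composition table")
        if (composition[col] < 0).any():
            raise ValueError(f"negative cell counts in {col!r}")
        if composition[col].sum() <= 0:
            raise ValueError(f"condition {col!r} has zero total cells")
    pct_cond = 100.0 * composition[condition] / composition[condition].sum()
    pct_ctrl = 100.0 * composition[control] / composition[control].sum()
    out = pd.DataFrame({
        "cell_type": composition.index,
        "pct_condition": pct_cond.to_numpy(),
        "pct_control": pct_ctrl.to_numpy(),
        "difference": (pct_cond - pct_ctrl).to_numpy(),
    })
    return out.sort_values("difference", ascending=False, kind="stable").reset_index(drop=True)
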