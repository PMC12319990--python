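"""Regional gene-expression validation of the binding components.

Regional GABA_A alpha-subunit gene expression (GABRA1/2/3/5, linear
scale) is converted to fractional units — each gene divided by the
summed expression of the gene set per region — so it is commensurate
with the fractional component contributions.  Component-gene Pearson
correlations are FDR-corrected (Benjamini-Hochberg) and the size of
each positive association is categorized on fixed cutoffs
(0.3 / 0.5 / 0.7 / 0.9).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GENE_SET = ("GABRA1", "GABRA2", "GABRA3", "GABRA5")

#: (upper bound, label); R <= 0 lacks positive correlation entirely.
CATEGORY_CUTOFFS = (
    (0.0, "lack of positive correlation"),
    (0.3, "negligible positive correlation"),
    (0.5, "low positive correlation"),
    (0.7, "moderate positive correlation"),
    (0.9, "high positive correlation"),
    (1.0, "very high positive correlation"),
)


def categorize(r: float) -> str:
    """Category label for a correlation size, exact at the cutoffs."""
    if not np.isfinite(r) or abs(r) > 1 + 1e-12:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    for bound, label in CATEGORY_CUTOFFS:
        if r <= bound:
            return label
    return CATEGORY_CUTOFFS[-1][1]


def fractional_expression(table: pd.DataFrame, gene_set: Sequence[str] = GENE_SET) -> pd.DataFrame:
    """Per-region gene fractions: expression / summed expression of the
    gene set (non-log, linear scale required)."""
    missing = [g for g in gene_set if g not in table.columns]
    if missing:
        raise ValueError(f"expression table is missing genes {missing}")
    sub = table[list(gene_set)].astype(float)
    if (sub <= 0).any().any():
        raise ValueError("gene expression must be strictly positive on a linear scale")
    vals = sub.to_numpy()
    if vals.max() < 20 and vals.min() > 1:
        warnings.warn(
            "expression values look log2-scaled (all in (1, 20)); "
            "fractional conversion expects linear-scale values",
            stacklevel=2,
        )
    return sub.div(sub.sum(axis=1), axis=0)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _predictor_values(expression: pd.DataFrame, predictor) -> tuple[str, pd.Series]:
    if isinstance(predictor, str):
        return predictor, expression[predictor]
    genes = list(predictor)
    return "+".join(genes), expression[genes].sum(axis=1)


def correlate(
    component_table: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: Sequence[tuple[str, object]] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between regional component contributions and
    expression predictors.

    ``component_table``: regions x components (e.g. columns C1..CN);
    ``expression``: regions x genes, typically fractional.  Predictors
    may be single genes or tuples of genes (summed).  Default pairs: all
    component x gene combinations.  Regions are matched by index and
    only regions complete on both sides enter.  Constant vectors give an
    undefined R: the row is flagged and excluded from the FDR family.
    """
    if pairs is None:
        pairs = [(c, g) for c in component_table.columns for g in expression.columns]
    shared = component_table.index.intersection(expression.index)
    comp = component_table.loc[shared].dropna()
    shared = comp.index.intersection(expression.dropna().index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 complete shared regions, got {len(shared)}")
    comp = component_table.loc[shared]
    expr = expression.loc[shared]

    rows = []
    for component, predictor in pairs:
        pname, x = _predictor_values(expr, predictor)
        y = comp[component]
        if np.ptp(x.to_numpy()) == 0 or np.ptp(y.to_numpy()) == 0:
            rows.append(
                {"component": component, "predictor": pname, "r": float("nan"),
                 "p": float("nan"), "n": len(shared), "undefined": True}
            )
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            {"component": component, "predictor": pname, "r": float(r),
             "p": float(p), "n": len(shared), "undefined": False}
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    ok = ~out["undefined"]
    if ok.any():
        out.loc[ok, "p_fdr"] = fdr_adjust(out.loc[ok, "p"].to_numpy())
    out["category"] = [None if u else categorize(r) for r, u in zip(out["r"], out["undefined"])]
    return out


def correlation_matrix(result: pd.DataFrame) -> pd.DataFrame:
    """Pivot a correlation result into a predictor x component R table
    with significance markers (* p_fdr < 0.05, † < 1e-3, ‡ < 1e-10)."""

    def mark(row) -> str:
        if row["undefined"] or not np.isfinite(row["r"]):
            return "n/a"
        p = row["p_fdr"]
        star = "‡" if p < 1e-10 else "†" if p < 1e-3 else "*" if p < 0.05 else ""
        return f"{row['r']:.2f}{star}"

    cells = result.assign(cell=result.apply(mark, axis=1))
    return cells.pivot(index="predictor", columns="component", values="cell")
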