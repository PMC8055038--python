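"""Variable-selection diagnostics: pairwise chi-square tests and MCA.

The selection process is pre-defined but expert-informed: all pairwise
two-way chi-square tests among candidate indicators (alpha = 0.05,
Pearson statistic without continuity correction) plus a multiple
correspondence analysis of the indicator matrix to inspect groupings.
The module emits diagnostics; the final item list is configuration
(default: the nine published items), never an automatic decision.

MCA here is correspondence analysis of the N x 2Q dummy-coded indicator
matrix: relative frequencies, standardized residuals from row/column
masses, SVD; principal inertias are the squared singular values and total
inertia for Q binary variables equals (2Q/Q) - 1 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ItemResponseMatrix
from .synthetic import PAPER9_ITEMS

__all__ = ["Chi2Result", "McaSolution", "pairwise_chi2", "mca", "selection_report"]


@dataclass(frozen=True)
class Chi2Result:
    variable_a: str
    variable_b: str
    statistic: float
    dof: int
    p_value: float
    significant: bool
    degenerate: bool = False
    n: int = 0


@dataclass
class McaSolution:
    category_labels: list[str]
    category_coordinates: np.ndarray  # C x D principal coordinates
    eigenvalues: np.ndarray  # D, non-increasing
    total_inertia: float
    explained_inertia: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.explained_inertia = (
            self.eigenvalues / self.total_inertia
            if self.total_inertia > 0
            else np.zeros_like(self.eigenvalues)
        )

    def coordinates_frame(self) -> pd.DataFrame:
        """Long-format export: category, dimension, coordinate."""
        C, D = self.category_coordinates.shape
        return pd.DataFrame(
            {
                "category": np.repeat(self.category_labels, D),
                "dimension": np.tile(np.arange(1, D + 1), C),
                "coordinate": self.category_coordinates.ravel(),
            }
        )


def chi2_from_table(table: np.ndarray, alpha: float = 0.05) -> tuple[float, int, float, bool]:
    """Pearson chi-square (no continuity correction) for an r x c count table.

    Returns (statistic, dof, p_value, significant); raises on a zero margin.
    """
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero row/column margin")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p), bool(p < alpha)


def pairwise_chi2(X: ItemResponseMatrix, alpha: float = 0.05) -> list[Chi2Result]:
    """Pearson chi-square over every unordered item pair, pairwise-complete rows.

    Tables with a zero row/column margin are flagged degenerate and excluded
    from significance counting (their p-value is NaN).
    """
    items = X.items
    if len(items) < 2:
        raise ValueError("need at least two items")
    out: list[Chi2Result] = []
    vals = X.responses
    for a_idx in range(len(items)):
        for b_idx in range(a_idx + 1, len(items)):
            a, b = items[a_idx], items[b_idx]
            pair = vals[[a, b]].dropna()
            table = pd.crosstab(pair[a], pair[b]).to_numpy()
            degenerate = (
                table.size == 0
                or table.shape[0] < 2
                or table.shape[1] < 2
                or (table.sum(axis=0) == 0).any()
                or (table.sum(axis=1) == 0).any()
            )
            if degenerate:
                out.append(
                    Chi2Result(a, b, float("nan"), 0, float("nan"), False, True, len(pair))
                )
                continue
            stat, dof, p, sig = chi2_from_table(table, alpha)
            out.append(Chi2Result(a, b, stat, dof, p, sig, False, len(pair)))
    return out


def chi2_matrix(results: list[Chi2Result], items: list[str]) -> pd.DataFrame:
    """Symmetric matrix of chi-square statistics for CSV export."""
    m = pd.DataFrame(np.nan, index=items, columns=items)
    for r in results:
        m.loc[r.variable_a, r.variable_b] = r.statistic
        m.loc[r.variable_b, r.variable_a] = r.statistic
    return m


def mca(X: ItemResponseMatrix) -> McaSolution:
    """Indicator-matrix multiple correspondence analysis.

    Requires complete cases and every category observed at least once.
    Category principal coordinates are the standard coordinates scaled by
    the singular values; dimensions retained: min(N-1, C-Q).
    """
    resp = X.responses
    if resp.isna().any().any():
        raise ValueError("MCA requires complete cases")
    Q = resp.shape[1]
    N = resp.shape[0]
    blocks, labels = [], []
    for c in resp.columns:
        col = resp[c].to_numpy(dtype=float)
        if col.min() == col.max():
            raise ValueError(f"variable {c!r} is constant: one category is empty")
        blocks.append(np.column_stack([1.0 - col, col]))
        labels.extend([f"{c}=0", f"{c}=1"])
    Z = np.column_stack(blocks)  # N x C indicator matrix
    C = Z.shape[1]
    P = Z / Z.sum()
    r = P.sum(axis=1)
    c_mass = P.sum(axis=0)
    S = (P - np.outer(r, c_mass)) / np.sqrt(np.outer(r, c_mass))
    _, sv, Vt = np.linalg.svd(S, full_matrices=False)
    D = min(N - 1, C - Q)
    sv = sv[:D]
    # standard coordinates scaled by singular values -> principal coordinates
    std_coords = Vt[:D].T / np.sqrt(c_mass)[:, None]
    principal = std_coords * sv[None, :]
    eigenvalues = sv**2
    total_inertia = float(np.sum(S**2))
    return McaSolution(labels, principal, eigenvalues, total_inertia)


def selection_report(
    chi2: list[Chi2Result],
    mca_solution: McaSolution,
    final_items: list[str] | None = None,
) -> dict:
    """Per-variable diagnostics plus the configured final item list.

    Reports, per variable: how many pairings were significant, the deprived
    category's first-two-dimension MCA coordinates, and the nearest
    neighbouring variable in full MCA space. Selection itself stays an
    expert input (defaults to the nine published items).
    """
    final_items = list(final_items) if final_items is not None else list(PAPER9_ITEMS)
    variables = list(dict.fromkeys(c.split("=")[0] for c in mca_solution.category_labels))
    sig_counts = {v: 0 for v in variables}
    for r in chi2:
        if r.degenerate:
            continue
        if r.significant:
            for v in (r.variable_a, r.variable_b):
                sig_counts.setdefault(v, 0)
                sig_counts[v] += 1
    coords = mca_solution.category_coordinates
    labels = mca_solution.category_labels
    dep_idx = {v: labels.index(f"{v}=1") for v in variables if f"{v}=1" in labels}
    per_variable = {}
    for v in variables:
        entry: dict = {"significant_pairings": int(sig_counts.get(v, 0))}
        if v in dep_idx:
            xy = coords[dep_idx[v], : min(2, coords.shape[1])]
            entry["mca_dim1"] = float(xy[0])
            entry["mca_dim2"] = float(xy[1]) if xy.size > 1 else 0.0
            others = [u for u in dep_idx if u != v]
            if others:
                d = {
                    u: float(np.linalg.norm(coords[dep_idx[v]] - coords[dep_idx[u]]))
                    for u in others
                }
                entry["nearest_variable"] = min(d, key=d.get)
        per_variable[v] = entry
    return {
        "n_candidates": len(variables),
        "candidates": variables,
        "per_variable": per_variable,
        "final_items": final_items,
        "n_final": len(final_items),
        "explained_inertia_dim12": [
            float(x) for x in mca_solution.explained_inertia[:2]
        ],
    }
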