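"""Binary activity, maturity groups, and the marker coactivation scan.

The ternary matrix is collapsed to binary activity (state 2 -> active).
Anchor markers -- OMP for mature and GAP43 for immature olfactory sensory
neurons -- partition cells into mature (OMP active, GAP43 not), immature
(the mirror) and excluded (both or neither).  Every other gene is then tested
for differential activity between the two groups with Fisher's exact test,
Bonferroni-corrected over the genes actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors


@dataclass(frozen=True)
class MaturityGroups:
    mature_cells: tuple[str, ...]
    immature_cells: tuple[str, ...]
    excluded_cells: tuple[str, ...]
    mature_marker: str = "OMP"
    immature_marker: str = "GAP43"


def binarize(ternary: pd.DataFrame, na_policy: str = "zero") -> pd.DataFrame:
    """Collapse ternary states to 0/1 activity: 2 -> 1; 0 and 1 -> 0.

    ``na_policy`` "zero" treats NA as inactive (conservative default);
    "drop" propagates NaN so callers can exclude those entries.
    """
    if na_policy not in {"zero", "drop"}:
        raise ValueError("na_policy must be 'zero' or 'drop'")
    values = ternary.to_numpy(dtype=float)
    out = np.where(values == 2, 1.0, 0.0)
    if na_policy == "drop":
        out[np.isnan(values)] = np.nan
    return pd.DataFrame(out, index=ternary.index, columns=ternary.columns)


def define_maturity_groups(
    binary: pd.DataFrame,
    mature_marker: str = "OMP",
    immature_marker: str = "GAP43",
) -> MaturityGroups:
    """Partition cells by the two anchor markers.

    Mature cells are active for the mature marker and not the immature one;
    immature cells the mirror; cells active for both or neither are excluded.
    """
    for marker in (mature_marker, immature_marker):
        if marker not in binary.index:
            raise ValueError(f"marker gene {marker!r} not in matrix")
    m = binary.loc[mature_marker].to_numpy() == 1
    i = binary.loc[immature_marker].to_numpy() == 1
    cells = np.asarray(binary.columns)
    return MaturityGroups(
        mature_cells=tuple(cells[m & ~i]),
        immature_cells=tuple(cells[i & ~m]),
        excluded_cells=tuple(cells[m == i]),
        mature_marker=mature_marker,
        immature_marker=immature_marker,
    )


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns (odds_ratio, p).  The two-sided p sums hypergeometric
    probabilities of all tables at fixed margins no more probable than the
    observed one.  The odds ratio is ad/bc with the usual zero-cell
    conventions (inf when bc = 0 and ad > 0; NaN when a margin is zero).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    (a, b), (c, d) = t
    if min(a + b, c + d, a + c, b + d) == 0:
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def marker_coactivation_scan(
    binary: pd.DataFrame,
    groups: MaturityGroups,
    alpha: float = 0.01,
    test_universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fisher's-exact scan for genes differentially active between groups.

    For each gene in the test universe (default: all genes except the two
    anchor markers) a 2x2 table of (mature vs immature) x (active vs
    inactive) is tested; p-values are Bonferroni-corrected by the number of
    genes tested and declared significant below ``alpha``.  Direction is
    mature-associated when the active fraction is higher among mature cells.

    Returns a DataFrame indexed by gene with columns
    ``n_active_mature, n_inactive_mature, n_active_immature,
    n_inactive_immature, odds_ratio, p_value, p_bonferroni, direction,
    significant``.
    """
    if not groups.mature_cells or not groups.immature_cells:
        raise ValueError("both maturity groups must be non-empty")
    if test_universe is None:
        universe = [
            g
            for g in binary.index
            if g not in {groups.mature_marker, groups.immature_marker}
        ]
    else:
        universe = [
            g
            for g in test_universe
            if g in binary.index
            and g not in {groups.mature_marker, groups.immature_marker}
        ]
    if not universe:
        raise ValueError("empty test universe")

    mat = binary.loc[universe, list(groups.mature_cells)].to_numpy()
    imm = binary.loc[universe, list(groups.immature_cells)].to_numpy()
    n_mat, n_imm = mat.shape[1], imm.shape[1]
    a = np.nansum(mat == 1, axis=1)
    c = np.nansum(imm == 1, axis=1)
    n_tests = len(universe)

    rows = []
    for gi, gene in enumerate(universe):
        table = [[a[gi], n_mat - a[gi]], [c[gi], n_imm - c[gi]]]
        odds, p = fisher_exact_2x2(table)
        p_bonf = min(1.0, p * n_tests)
        direction = (
            "mature-associated"
            if a[gi] / n_mat >= c[gi] / n_imm
            else "immature-associated"
        )
        rows.append(
            {
                "gene": gene,
                "n_active_mature": int(a[gi]),
                "n_inactive_mature": int(n_mat - a[gi]),
                "n_active_immature": int(c[gi]),
                "n_inactive_immature": int(n_imm - c[gi]),
                "odds_ratio": odds,
                "p_value": p,
                "p_bonferroni": p_bonf,
                "direction": direction,
                "significant": bool(p_bonf < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def knn_loocv_dataset_accuracy(
    features: pd.DataFrame | np.ndarray,
    dataset_labels: Sequence,
    k: int = 5,
) -> float:
    """Leave-one-out k-NN accuracy of predicting each cell's dataset label.

    ``features`` is cells x features (a binary activity or log2CPM matrix
    transposed to cells-as-rows).  Euclidean distance; majority vote among
    the k nearest non-self neighbours, ties broken toward the first label in
    sorted order.  A low accuracy means cells from different datasets are
    well mixed in the feature space.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(dataset_labels)
    n = X.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length must match number of rows")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 label classes")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")

    classes, encoded = np.unique(labels, return_inverse=True)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    correct = 0
    for i in range(n):
        neigh = idx[i][idx[i] != i][:k]
        if neigh.size < k:  # self not returned among ties of duplicates
            neigh = idx[i][:k]
        vote = np.bincount(encoded[neigh], minlength=classes.size).argmax()
        correct += vote == encoded[i]
    return correct / n
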