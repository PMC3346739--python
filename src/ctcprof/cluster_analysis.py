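"""Missing-value-aware hierarchical clustering and cluster composition.

Missing normalized values (undetectable transcripts) are replaced by a
floor of -3 pooled standard deviations before clustering, reflecting
the low expression they represent; for display the observed values are
truncated to +/-3 SD and missing entries are rendered black.  Cells are
then clustered agglomeratively on Euclidean distances (complete linkage
by default, the convention of classic R ``hclust``), and a k-cut labels
the major subgroups, the smaller cluster first.  Cluster composition is
summarized per distinct case (patient): disease stage, receptor status,
triple-negative fraction and cross-cluster case overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ConfigError, DataError
from .normalization import NormalizedMatrix

DEFAULT_K = 2
DEFAULT_K_SD = 3.0
DEFAULT_LINKAGE = "complete"
DEFAULT_METRIC = "euclidean"
_LINKAGES = ("single", "complete", "average", "ward")


def round_half_up(x: float) -> int:
    """Integer percentage rounding used in composition tables (0.5 -> up)."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------
# Imputation / truncation
# ---------------------------------------------------------------------


def impute_and_truncate(
    norm: NormalizedMatrix, k_sd: float = DEFAULT_K_SD, *, clip_clustering: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (clustering matrix, display matrix).

    The clustering matrix replaces missing values with ``-k_sd`` pooled
    standard deviations of the centered expression; observed values are
    left unclipped (set ``clip_clustering`` to truncate them too).  The
    display matrix clips observed values to ``+/- k_sd * SD`` and keeps
    missing entries NaN for black rendering.
    """
    if k_sd <= 0:
        raise ConfigError("k_sd must be positive")
    sd = norm.pooled_sd
    if not np.isfinite(sd) or sd <= 0:
        raise DataError("pooled SD is zero or undefined; matrix is constant")
    floor = -k_sd * sd
    clustering = norm.values.copy()
    if clip_clustering:
        clustering = clustering.clip(floor, k_sd * sd)
    clustering = clustering.fillna(floor)
    display = norm.values.clip(floor, k_sd * sd)
    return clustering, display


# ---------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Agglomerative merge tree over cells.

    ``linkage_matrix`` is the standard (n-1) x 4 merge encoding (child
    ids, merge height, cluster size) with rows in non-decreasing height
    order; ``matrix`` is the imputed matrix actually clustered.
    """

    linkage_matrix: np.ndarray
    cell_ids: tuple[str, ...]
    metric: str
    linkage: str
    matrix: pd.DataFrame

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.cell_ids[i] for i in order]

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hcluster(
    matrix: pd.DataFrame,
    metric: str = DEFAULT_METRIC,
    linkage: str = DEFAULT_LINKAGE,
) -> ClusterResult:
    """Agglomerative hierarchical clustering of matrix rows.

    Deterministic given the input row order; at equal merge distances
    the lowest-index pair merges first.
    """
    if linkage not in _LINKAGES:
        raise ConfigError(f"unknown linkage {linkage!r}; choose from {_LINKAGES}")
    if len(matrix) < 2:
        raise DataError("clustering needs at least 2 cells")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DataError("clustering matrix contains missing/non-finite values")
    dist = pdist(values, metric=metric)
    Z = hierarchy.linkage(dist, method=linkage)
    return ClusterResult(
        linkage_matrix=Z,
        cell_ids=tuple(matrix.index),
        metric=metric,
        linkage=linkage,
        matrix=matrix,
    )


def cut_k(result: ClusterResult, k: int = DEFAULT_K) -> pd.Series:
    """Cut the tree into exactly ``k`` groups; labels 1..k by ascending size.

    Cluster 1 ("Cluster I") is the smallest; ties break by first leaf
    position in the dendrogram order.
    """
    n = len(result.cell_ids)
    if not 1 <= k <= n:
        raise ConfigError(f"k={k} outside [1, {n}]")
    raw = hierarchy.fcluster(result.linkage_matrix, t=k, criterion="maxclust")
    leaf_pos = {cell_idx: pos for pos, cell_idx in
                enumerate(hierarchy.leaves_list(result.linkage_matrix))}
    groups = pd.Series(raw, index=range(n))
    order = sorted(
        groups.unique(),
        key=lambda g: (
            (groups == g).sum(),
            min(leaf_pos[i] for i in groups.index[groups == g]),
        ),
    )
    relabel = {g: i + 1 for i, g in enumerate(order)}
    return pd.Series(
        [relabel[g] for g in raw], index=list(result.cell_ids), name="cluster"
    )


def to_newick(result: ClusterResult) -> str:
    """Serialize the dendrogram as a Newick string with merge heights."""
    tree = hierarchy.to_tree(result.linkage_matrix)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.cell_ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------
# Cluster composition
# ---------------------------------------------------------------------


@dataclass
class CompositionTable:
    """Per-cluster case phenotype summary plus cross-cluster overlap."""

    per_cluster: pd.DataFrame
    n_cases_total: int
    n_cases_in_multiple: int
    pct_cases_in_multiple: int

    def to_dict(self) -> dict:
        return {
            "per_cluster": self.per_cluster.reset_index().to_dict(orient="records"),
            "n_cases_total": self.n_cases_total,
            "n_cases_in_multiple": self.n_cases_in_multiple,
            "pct_cases_in_multiple": self.pct_cases_in_multiple,
        }


def composition_table(labels: pd.Series, meta: pd.DataFrame) -> CompositionTable:
    """Summarize cluster composition by distinct case (patient).

    A case belongs to a cluster iff at least one of its labeled cells
    carries that cluster label.  Percentages use the cluster's case
    count as denominator and round half up to integers; unknown receptor
    statuses never count toward a positive or triple-negative call.
    """
    m = meta.set_index("cell_id")
    missing = [c for c in labels.index if c not in m.index]
    if missing:
        raise DataError(f"labeled cells without metadata: {missing[:5]}")

    rows = {}
    case_sets: dict[int, set[str]] = {}
    for cluster in sorted(labels.unique()):
        cells = labels.index[labels == cluster]
        sub = m.loc[cells]
        cases = sub["subject_id"].drop_duplicates()
        case_sets[cluster] = set(cases)
        per_case = sub.drop_duplicates(subset=["subject_id"]).set_index("subject_id")
        n_cases = len(per_case)

        def count(mask: pd.Series) -> tuple[int, int]:
            n = int(mask.sum())
            return n, round_half_up(100.0 * n / n_cases) if n_cases else 0

        n_primary, pct_primary = count(per_case["stage"] == "primary")
        n_metastatic, pct_metastatic = count(per_case["stage"] == "metastatic")
        n_erpr, pct_erpr = count(
            (per_case["er_status"] == "pos") | (per_case["pr_status"] == "pos")
        )
        n_her2, pct_her2 = count(per_case["her2_status"] == "pos")
        n_tn, pct_tn = count(
            (per_case["er_status"] == "neg")
            & (per_case["pr_status"] == "neg")
            & (per_case["her2_status"] == "neg")
        )
        ages = pd.to_numeric(per_case["age_at_diagnosis"], errors="coerce").dropna()
        rows[cluster] = {
            "n_cases": n_cases,
            "n_ctcs": int(len(cells)),
            "median_age": float(ages.median()) if len(ages) else float("nan"),
            "n_primary": n_primary,
            "pct_primary": pct_primary,
            "n_metastatic": n_metastatic,
            "pct_metastatic": pct_metastatic,
            "n_er_or_pr_pos": n_erpr,
            "pct_er_or_pr_pos": pct_erpr,
            "n_her2_pos": n_her2,
            "pct_her2_pos": pct_her2,
            "n_triple_negative": n_tn,
            "pct_triple_negative": pct_tn,
        }

    all_cases = set().union(*case_sets.values()) if case_sets else set()
    in_multiple = {
        case for case in all_cases if sum(case in s for s in case_sets.values()) > 1
    }
    per_cluster = pd.DataFrame(rows).T
    per_cluster.index.name = "cluster"
    return CompositionTable(
        per_cluster=per_cluster,
        n_cases_total=len(all_cases),
        n_cases_in_multiple=len(in_multiple),
        pct_cases_in_multiple=(
            round_half_up(100.0 * len(in_multiple) / len(all_cases)) if all_cases else 0
        ),
    )


# ---------------------------------------------------------------------
# Heatmap rendering
# ---------------------------------------------------------------------


def _diverging_cmap():
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "blue_gray_yellow", ["#1f4fd8", "#808080", "#ffe600"]
    )
    cmap.set_bad("black")
    return cmap


def render_heatmap(
    display: pd.DataFrame,
    result: ClusterResult,
    annotations: pd.Series | None = None,
    *,
    path: str | None = None,
    manifest_path: str | None = None,
    order_genes: bool = True,
):
    """Render a dendrogram-ordered heatmap of the display matrix.

    Low expression is blue, the per-gene median gray, high expression
    yellow, and undetectable (missing) entries black.  ``annotations``
    maps cells to group names shown as a color sidebar.  Gene (column)
    order comes from clustering the transpose of the imputed matrix.
    Returns (figure, ordered cells, ordered genes); an ordering manifest
    is written as text when ``manifest_path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered_cells = result.leaf_order
    genes = list(display.columns)
    if order_genes and len(genes) > 2:
        gene_result = hcluster(result.matrix.T, result.metric, result.linkage)
        genes = gene_result.leaf_order

    data = display.loc[ordered_cells, genes]
    masked = np.ma.masked_invalid(data.to_numpy(dtype=float))
    vmax = float(np.nanmax(np.abs(data.to_numpy()))) or 1.0

    fig, axes = plt.subplots(
        1,
        2 if annotations is not None else 1,
        figsize=(max(6, len(genes) * 0.18), max(4, len(ordered_cells) * 0.08)),
        gridspec_kw={"width_ratios": [1, 30]} if annotations is not None else None,
        squeeze=False,
    )
    ax = axes[0, -1]
    im = ax.imshow(
        masked, aspect="auto", cmap=_diverging_cmap(), vmin=-vmax, vmax=vmax,
        interpolation="nearest",
    )
    ax.set_xticks(range(len(genes)))
    ax.set_xticklabels(genes, rotation=90, fontsize=4)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.5, label="centered -dCt")

    legend_entries: list[str] = []
    if annotations is not None:
        groups = [str(annotations.get(c, "?")) for c in ordered_cells]
        legend_entries = list(dict.fromkeys(groups))
        palette = plt.get_cmap("tab20")
        color_of = {g: palette(i % 20) for i, g in enumerate(legend_entries)}
        ann_ax = axes[0, 0]
        ann_ax.imshow(
            np.array([[color_of[g]] for g in groups]), aspect="auto",
            interpolation="nearest",
        )
        ann_ax.set_xticks([])
        ann_ax.set_yticks([])
        handles = [plt.Rectangle((0, 0), 1, 1, color=color_of[g]) for g in legend_entries]
        ax.legend(handles, legend_entries, fontsize=4, loc="upper left",
                  bbox_to_anchor=(1.25, 1.0))

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    if manifest_path is not None:
        lines = (
            ["# ordered cells"]
            + [str(c) for c in ordered_cells]
            + ["# ordered genes"]
            + [str(g) for g in genes]
        )
        if legend_entries:
            lines += ["# annotation groups"] + legend_entries
        with open(manifest_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    plt.close(fig)
    return fig, ordered_cells, list(genes)
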