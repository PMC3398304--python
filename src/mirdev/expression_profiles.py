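"""Stage-wise expression normalization, transformation and clustering.

Counts are normalized to relative frequencies per stage library (optionally
scaled to counts per million for reporting), log2-transformed against a
reference stage (hatching by default) and clustered by hierarchical
agglomeration with Euclidean distance and average linkage (UPGMA).  The
module also computes per-stage miRNA diversity and sense/antisense or
guide/star expression-ratio trajectories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io_formats import StageSet, ValidationError


def normalize_counts(matrix: pd.DataFrame, scale: str | None = None) -> pd.DataFrame:
    """Column-normalize a count matrix to per-stage relative frequencies.

    Each stage column is divided by its total so it sums to 1; with
    ``scale='cpm'`` frequencies are multiplied by 1e6 (counts per million).
    A stage with zero total is an error naming the stage.
    """
    if (matrix.values < 0).any():
        raise ValidationError("negative counts")
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(
            f"zero column total in stage(s): {', '.join(map(str, zero.index))}"
        )
    freq = matrix / totals
    if scale == "cpm":
        freq = freq * 1e6
    elif scale is not None:
        raise ValueError(f"unknown scale {scale!r}")
    return freq


def log2_vs_reference(
    norm_matrix: pd.DataFrame,
    reference_stage: str,
    pseudocount: float | pd.Series = 1e-6,
) -> pd.DataFrame:
    """log2 expression relative to a reference stage.

    entry = log2((f + p) / (f_ref + p_ref)); the reference column is
    exactly zero and every entry is finite (the pseudocount absorbs zeros).
    ``pseudocount`` may be a scalar or a per-stage Series (e.g. one read
    equivalent, 1/depth per stage).
    """
    if reference_stage not in norm_matrix.columns:
        raise ValidationError(f"unknown reference stage {reference_stage!r}")
    p = pseudocount
    if np.any(np.asarray(p) <= 0):
        raise ValidationError("pseudocount must be positive")
    shifted = norm_matrix + p
    ref = shifted[reference_stage]
    out = np.log2(shifted.div(ref, axis=0))
    out[reference_stage] = 0.0
    return out


def profile_from_counts(
    counts: pd.DataFrame, reference_stage: str = "HA"
) -> pd.DataFrame:
    """Relative-frequency + log2-vs-reference profile with a one-read
    pseudocount per stage (1 / stage depth)."""
    depth = counts.sum(axis=0)
    return log2_vs_reference(
        normalize_counts(counts), reference_stage, pseudocount=1.0 / depth
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_profiles(
    profile: pd.DataFrame, k: int = 4
) -> tuple[np.ndarray, pd.Series, str]:
    """Average-linkage (UPGMA) hierarchical clustering of expression rows.

    Euclidean distance, deterministic given input order (scipy breaks
    distance ties by the smallest pair indices).  Returns the scipy linkage
    matrix, flat cluster labels from cutting the dendrogram into ``k``
    clusters, and the dendrogram serialized in Newick.
    """
    if len(profile) < 2:
        raise ValidationError("clustering requires at least 2 features")
    Z = hierarchy.linkage(profile.values, method="average", metric="euclidean")
    labels = pd.Series(
        hierarchy.fcluster(Z, t=k, criterion="maxclust"),
        index=profile.index, name="cluster",
    )
    return Z, labels, linkage_to_newick(Z, list(profile.index))


def linkage_to_newick(Z: np.ndarray, names: list) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def render_heatmap(profile: pd.DataFrame, path: str, k: int = 4) -> None:
    """Render the clustered log2 profile as a green-red heatmap (PNG/SVG).

    Rows are features ordered by the dendrogram, columns are stages;
    downregulation shades green, upregulation red, the reference stage
    white.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy as h

    Z, _, _ = cluster_profiles(profile, k=k)
    order = h.leaves_list(Z)
    data = profile.values[order]
    vmax = max(1.0, float(np.abs(data).max()))
    fig, ax = plt.subplots(
        figsize=(4, max(2.0, 0.22 * len(profile) + 1))
    )
    im = ax.imshow(data, aspect="auto", cmap="RdYlGn_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(profile.shape[1]),
                  labels=list(profile.columns), fontsize=7)
    ax.set_yticks(range(len(profile)),
                  labels=[str(profile.index[i]) for i in order], fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 vs reference")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def stage_diversity(matrix: pd.DataFrame, min_count: float = 5) -> pd.Series:
    """Number of distinct features with count >= min_count per stage."""
    return (matrix >= min_count).sum(axis=0)


def strand_ratio(
    matrix: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Per-stage expression ratios for (numerator, denominator) feature pairs.

    Ratios are taken on per-stage normalized frequencies, so they are
    invariant to library depth.  A zero denominator with nonzero numerator
    reports +inf; 0/0 reports NaN (undefined).
    """
    for num, den in pairs:
        for f in (num, den):
            if f not in matrix.index:
                raise ValidationError(f"unknown feature {f!r}")
    freq = normalize_counts(matrix)
    rows = {}
    for num, den in pairs:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = freq.loc[num].values / freq.loc[den].values
        rows[f"{num}/{den}"] = r
    return pd.DataFrame(rows, index=matrix.columns).T
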