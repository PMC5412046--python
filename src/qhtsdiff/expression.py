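"""Microarray-style expression workflow.

Normalization to housekeeping genes, per-probe median centering, collapse of
multi-probe genes by the mean, Ward/Euclidean hierarchical clustering of
samples, and one-vs-rest differential expression (Welch t-test on log2
intensities, Benjamini-Hochberg FDR).  A gene "passes" the headline DE
criterion when |log2 FC| >= 1 (twofold), p < 0.05, and q < 0.1.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .differential import bh_adjust
from .errors import ConfigurationError, DataError
from .screen_sim import ExpressionMatrix

__all__ = [
    "housekeeping_normalize",
    "median_center_probes",
    "collapse_probes",
    "hierarchical_cluster",
    "linkage_to_newick",
    "one_vs_rest_de",
]


def housekeeping_normalize(
    matrix: ExpressionMatrix,
    housekeeping_probes: set[str] | None = None,
    input_is_log2: bool = True,
) -> ExpressionMatrix:
    """Equalize per-sample brightness against a housekeeping probe set.

    Each sample is shifted (on the log2 scale) so that its mean housekeeping
    signal equals the across-sample mean of those signals; linear-scale input
    is log2-transformed first.  Removes array-wide scale factors without
    touching relative expression within a sample.
    """
    hk = housekeeping_probes if housekeeping_probes is not None else (
        matrix.housekeeping_probes
    )
    if not hk:
        raise ConfigurationError("housekeeping probe set is empty")
    missing = set(hk) - set(matrix.values.index)
    if missing:
        raise ConfigurationError(
            f"housekeeping probes absent from matrix: {sorted(missing)[:5]}"
        )
    vals = matrix.values.astype(float)
    if not input_is_log2:
        if (vals.to_numpy() <= 0).any():
            raise DataError("linear-scale input must be positive for log2")
        vals = np.log2(vals)
    hk_mean = vals.loc[sorted(hk)].mean(axis=0)
    offset = hk_mean - hk_mean.mean()
    vals = vals.sub(offset, axis=1)
    return ExpressionMatrix(
        values=vals,
        sample_to_line=dict(matrix.sample_to_line),
        probe_to_gene=dict(matrix.probe_to_gene),
        housekeeping_probes=set(hk),
    )


def median_center_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each probe row's median so every row has median 0."""
    if matrix.values.shape[1] < 1:
        raise DataError("matrix has no samples")
    vals = matrix.values.sub(matrix.values.median(axis=1), axis=0)
    return ExpressionMatrix(
        values=vals,
        sample_to_line=dict(matrix.sample_to_line),
        probe_to_gene=dict(matrix.probe_to_gene),
        housekeeping_probes=set(matrix.housekeeping_probes),
    )


def collapse_probes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene-level matrix: one row per gene = mean of its probe rows.

    Probes without a gene mapping are retained under their probe id with a
    warning, so no measurement silently disappears.
    """
    mapping = matrix.probe_to_gene
    unmapped = [p for p in matrix.values.index if p not in mapping]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} probes have no gene mapping; kept under probe ids",
            stacklevel=2,
        )
    keys = [mapping.get(p, p) for p in matrix.values.index]
    return matrix.values.groupby(pd.Index(keys, name="gene"), sort=True).mean()


def hierarchical_cluster(
    values: pd.DataFrame, axis: str = "samples"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative Ward/Euclidean tree over samples (columns) or probes.

    Returns the scipy linkage matrix and the leaf labels in input order.
    Merge heights are non-decreasing (Ward linkage is reducible).
    """
    if axis == "samples":
        data = values.to_numpy().T
        labels = list(map(str, values.columns))
    elif axis == "probes":
        data = values.to_numpy()
        labels = list(map(str, values.index))
    else:
        raise ValueError("axis must be 'samples' or 'probes'")
    if data.shape[0] < 2:
        raise DataError("need >=2 observations to cluster")
    Z = linkage(data, method="ward", metric="euclidean")
    return Z, labels


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def one_vs_rest_de(
    gene_matrix: pd.DataFrame,
    sample_to_line: dict[str, str],
    line_of_interest: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.1,
    welch: bool = False,
) -> pd.DataFrame:
    """Differential expression of one line's replicates against all others.

    Per gene: log2 FC = mean(line) - mean(rest) on log2 intensities, pooled
    two-sample t-test, BH q-values over all genes.  ``passes`` requires
    |log2 FC| >= log2(fc_threshold), p < p_threshold, q < fdr_threshold.

    The pooled (equal-variance) test is the default: with triplicate arrays
    the per-gene variance estimate from the small group alone is too
    unstable, and Welch's ~2 residual degrees of freedom cost most of the
    power.  Set ``welch=True`` for the unequal-variance test when the
    contrasted groups have genuinely different spreads.
    """
    cols = list(gene_matrix.columns)
    in_line = [c for c in cols if sample_to_line.get(c) == line_of_interest]
    rest = [c for c in cols if sample_to_line.get(c) not in (None, line_of_interest)]
    if len(in_line) < 2:
        raise DataError(
            f"line {line_of_interest!r} has {len(in_line)} replicates (need >=2)"
        )
    if len(rest) < 2:
        raise DataError("rest group needs >=2 samples")

    a = gene_matrix[in_line].to_numpy()
    b = gene_matrix[rest].to_numpy()
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance ties are uninformative
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene": gene_matrix.index.astype(str),
            "log2_fc": log2_fc,
            "p_value": p,
            "q_value": q,
        }
    )
    out["passes"] = (
        (out["log2_fc"].abs() >= np.log2(fc_threshold))
        & (out["p_value"] < p_threshold)
        & (out["q_value"] < fdr_threshold)
    )
    return out
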