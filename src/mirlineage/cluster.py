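"""Hierarchical clustering export for heatmap-style displays.

Agglomerative clustering of samples (and optionally probes) of a z-scored
matrix, exported as Newick trees plus the leaf-ordered matrix, so any
heatmap tool can render the result.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix
from .errors import ValidationError

_LINKAGES = ("average", "complete")
_DISTANCES = ("euclidean", "correlation")


def _tree_newick(linkage_matrix, labels) -> str:
    from skbio import TreeNode    # deferred: slow import, only needed here
    tree = TreeNode.from_linkage_matrix(linkage_matrix, labels)
    return str(tree).strip()


def cluster_export(zmatrix: ExpressionMatrix, linkage: str = "average",
                   distance: str = "euclidean", cluster_probes: bool = False):
    """Cluster samples (columns) and return trees plus the ordered matrix.

    Returns a dict with keys ``sample_tree`` (Newick string),
    ``probe_tree`` (Newick or None), ``ordered`` (ExpressionMatrix with
    leaf-ordered columns/rows) and the raw scipy linkage matrices.
    """
    if linkage not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {_LINKAGES}")
    if distance not in _DISTANCES:
        raise ValidationError(f"distance must be one of {_DISTANCES}")
    if zmatrix.n_samples < 2:
        raise ValidationError("clustering requires >= 2 samples")
    values = zmatrix.values.to_numpy(dtype=float)

    d_samples = pdist(values.T, metric=distance)
    link_samples = hierarchy.linkage(d_samples, method=linkage)
    sample_order = hierarchy.leaves_list(link_samples)
    sample_tree = _tree_newick(link_samples, zmatrix.sample_ids)

    probe_tree = None
    link_probes = None
    probe_order = np.arange(zmatrix.n_probes)
    if cluster_probes:
        if zmatrix.n_probes < 2:
            raise ValidationError("probe clustering requires >= 2 probes")
        d_probes = pdist(values, metric=distance)
        link_probes = hierarchy.linkage(d_probes, method=linkage)
        probe_order = hierarchy.leaves_list(link_probes)
        probe_tree = _tree_newick(link_probes, zmatrix.probe_ids)

    ordered = ExpressionMatrix(
        values=zmatrix.values.iloc[probe_order, sample_order],
        calls=None,
        scale=zmatrix.scale)
    return {"sample_tree": sample_tree, "probe_tree": probe_tree,
            "ordered": ordered, "sample_linkage": link_samples,
            "probe_linkage": link_probes}
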