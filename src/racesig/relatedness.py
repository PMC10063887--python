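"""Distance-based relatedness: allele-sharing distances, NJ trees with
bootstrap support, and principal-coordinates (PCoA) projections.

Tree building and ordination are delegated to scikit-bio behind this
module's interface; the allele-sharing distance and the site-resampling
bootstrap are implemented here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from ._rng import rng_for


def snp_distance(dosages: np.ndarray, sample_ids: list[str]) -> DistanceMatrix:
    """Allele-sharing distance: 1 - IBS = mean(|g_i - g_j| / 2).

    ``dosages`` is (n_samples x n_sites), 0/1/2 with -1 for missing; each
    pair's denominator counts only co-non-missing sites.
    """
    d = np.asarray(dosages, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    miss = d < 0
    n = d.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            if not ok.any():
                raise ValueError(
                    f"samples {sample_ids[i]} and {sample_ids[j]} share no called sites")
            mat[i, j] = mat[j, i] = float(np.mean(np.abs(d[i, ok] - d[j, ok])) / 2)
    return DistanceMatrix(mat, ids=sample_ids)


def snp_distance_from_vcf(vcf_path: str) -> DistanceMatrix:
    from .haplotypes import HaplotypeMatrix

    hap = HaplotypeMatrix.from_vcf(vcf_path)
    return snp_distance(hap.dosages(), hap.sample_ids)


def nj_tree(dm: DistanceMatrix) -> tuple[TreeNode, str]:
    """Neighbor-joining tree (Saitou-Nei) with branch lengths, plus Newick.

    Negative branch lengths are clamped to zero by the builder.  On an
    additive matrix the generating topology and path lengths are recovered
    exactly.
    """
    if dm.shape[0] < 3:
        raise ValueError("NJ needs at least 3 taxa")
    tree = nj(dm)
    return tree, str(tree).strip()


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions, each canonicalized to its smaller side."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        other = taxa - side
        out.add(side if sorted(side) <= sorted(other) else other)
    return out


def bootstrap_support(
    dosages: np.ndarray,
    sample_ids: list[str],
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Site-resampling bootstrap support for the NJ tree's internal edges.

    Sites (columns) are resampled with replacement ``n_reps`` times, the
    tree rebuilt each time, and each original bipartition's recovery rate
    reported as a percentage.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    d = np.asarray(dosages)
    if d.shape[1] < 1:
        raise ValueError("need at least one site")
    base_tree, _ = nj_tree(snp_distance(d, sample_ids))
    taxa = frozenset(sample_ids)
    targets = _bipartitions(base_tree, taxa)
    hits = {bp: 0 for bp in targets}
    rng = rng_for(seed, "bootstrap")
    for _ in range(n_reps):
        cols = rng.integers(0, d.shape[1], size=d.shape[1])
        rep_tree, _ = nj_tree(snp_distance(d[:, cols], sample_ids))
        found = _bipartitions(rep_tree, taxa)
        for bp in targets:
            if bp in found:
                hits[bp] += 1
    support = {bp: 100.0 * h / n_reps for bp, h in hits.items()}
    return base_tree, support


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Principal coordinates via double-centered Gower eigendecomposition.

    Axes are ordered by eigenvalue; negative eigenvalues (non-Euclidean
    input) are reported, never silently dropped.
    """
    import warnings as _w
    from skbio.stats.ordination import pcoa as _pcoa

    n = dm.shape[0]
    if n_axes is not None and not (0 < n_axes < n):
        raise ValueError("n_axes must be in [1, n_samples)")
    with _w.catch_warnings():
        _w.simplefilter("ignore")  # skbio warns when negative eigenvalues exist
        res = _pcoa(dm, method="eigh", number_of_dimensions=0)
    coords = res.samples
    eigvals = res.eigvals
    if n_axes is not None:
        coords = coords.iloc[:, :n_axes]
    coords.index = list(dm.ids)
    return coords, eigvals
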