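"""Robust independent component analysis of an expression compendium.

The centered genes × samples matrix X is decomposed as X ≈ M·A, where M
(genes × K) holds gene weights and A (K × samples) holds condition-
dependent activities. Robustness comes from an ensemble of FastICA runs
with different random seeds: the pooled components are clustered with
DBSCAN under the distance d(x, y) = 1 − |ρ(x, y)| (absolute Pearson
correlation), and each sufficiently recurrent cluster yields one robust
component. Activities are obtained by least-squares projection of X
onto the consensus M, which makes the reconstruction and its explained
variance well defined.

Defaults mirror the published workflow: 100 runs, convergence tolerance
1e-7, DBSCAN epsilon 0.1 with a minimum cluster seed size of 50, and a
dimensionality search over 20..300 in steps of 20.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 1e-7
DEFAULT_N_RUNS = 100
DEFAULT_EPSILON = 0.1
DEFAULT_MIN_CLUSTER_SIZE = 50
DEFAULT_MAX_ITER = 1000
SWEEP_GRID = tuple(range(20, 301, 20))


@dataclass
class IcaRunResult:
    """One FastICA run: unit-normalized gene-weight vectors and mixing."""

    seed: int
    dimension: int
    components: np.ndarray  # genes × dimension, unit-L2 columns
    mixing: np.ndarray  # dimension × samples
    converged: bool = True


@dataclass
class RobustDecomposition:
    """Consensus decomposition X ≈ M·A.

    ``M`` is a genes × K DataFrame (unit-L2 columns), ``A`` a
    K × samples DataFrame sharing M's column ids as its index.
    ``cluster_support`` counts, per component, the number of ICA runs
    that contributed at least one member to its cluster.
    """

    M: pd.DataFrame
    A: pd.DataFrame
    cluster_support: list[int] = field(default_factory=list)
    seeds_used: list[int] = field(default_factory=list)
    n_runs: int = 0

    @property
    def K(self) -> int:
        return self.M.shape[1]

    @property
    def component_ids(self) -> list[str]:
        return list(self.M.columns)


def run_ica_single(
    x: ExpressionMatrix,
    dimension: int,
    seed: int,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> IcaRunResult:
    """One FastICA decomposition at a fixed random seed.

    Genes are treated as observations and samples as features, so the
    estimated sources are gene-weight vectors. Each component is scaled
    to unit L2 norm (the scale moves into the mixing row) and
    sign-oriented so its largest-magnitude weight is positive.
    Deterministic for a fixed seed. A run that fails to converge within
    ``max_iter`` iterations is returned with ``converged=False``.
    """
    if not x.is_centered:
        raise ValueError("ICA requires a centered expression matrix")
    if dimension > min(x.n_genes, x.n_samples):
        raise ValueError(
            f"dimension {dimension} exceeds min(genes, samples) = "
            f"{min(x.n_genes, x.n_samples)}"
        )
    values = x.values
    ica = FastICA(
        n_components=dimension,
        whiten="unit-variance",
        fun="logcosh",
        tol=tolerance,
        max_iter=max_iter,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(values)  # genes × dimension
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    mixing = ica.mixing_.T  # dimension × samples
    norms = np.linalg.norm(sources, axis=0)
    norms[norms == 0] = 1.0
    sources = sources / norms
    mixing = mixing * norms[:, None]
    # orient: largest-|weight| gene positive
    flip = np.sign(sources[np.argmax(np.abs(sources), axis=0), np.arange(dimension)])
    flip[flip == 0] = 1.0
    sources = sources * flip
    mixing = mixing * flip[:, None]
    return IcaRunResult(seed=seed, dimension=dimension, components=sources,
                        mixing=mixing, converged=converged)


def run_ensemble(
    x: ExpressionMatrix,
    dimension: int,
    n_runs: int = DEFAULT_N_RUNS,
    tolerance: float = DEFAULT_TOLERANCE,
    seeds: list[int] | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
) -> list[IcaRunResult]:
    """Run FastICA ``n_runs`` times with distinct seeds; drop
    non-convergent runs (logged, not retried)."""
    if seeds is None:
        seeds = list(range(n_runs))
    runs = []
    for seed in seeds:
        run = run_ica_single(x, dimension, seed, tolerance, max_iter)
        if run.converged:
            runs.append(run)
        else:
            logger.warning("ICA run seed=%d (dim=%d) did not converge; dropped", seed, dimension)
    logger.info("ensemble: %d/%d runs converged at dimension %d", len(runs), len(seeds), dimension)
    return runs


def component_distance(u: np.ndarray, v: np.ndarray) -> float:
    """d(u, v) = 1 − |Pearson ρ(u, v)|: 0 for (anti-)identical vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("zero-variance component vector")
    rho = np.corrcoef(u, v)[0, 1]
    return float(1.0 - abs(rho))


def _pooled_distance_matrix(pool: np.ndarray) -> np.ndarray:
    """1 − |ρ| over all pairs of pooled component columns."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(pool.T)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def cluster_components(
    runs: list[IcaRunResult],
    x: ExpressionMatrix,
    epsilon: float = DEFAULT_EPSILON,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    gene_ids: list[str] | None = None,
) -> RobustDecomposition:
    """Consensus-cluster pooled components into robust components.

    DBSCAN (``eps=epsilon``, ``min_samples=min_cluster_size``) is run on
    the pooled component set under d = 1 − |ρ|. For each cluster the
    member closest to all others (the medoid) fixes the sign convention;
    members are sign-aligned to it, averaged, and re-normalized.
    Activities A are the least-squares projection of centered X onto the
    consensus M. Unclustered (noise) components are discarded; K = 0 is
    a valid outcome. The result is invariant to run order and to sign
    flips of input components, with components reported in a canonical
    order (decreasing support, then position of the top-weight gene).
    """
    if not runs:
        return _empty_decomposition(x, gene_ids)
    pool = np.hstack([r.components for r in runs])  # genes × n_pooled
    run_of = np.concatenate([[i] * r.components.shape[1] for i, r in enumerate(runs)])
    dist = _pooled_distance_matrix(pool)
    labels = DBSCAN(eps=epsilon, min_samples=min_cluster_size, metric="precomputed").fit_predict(dist)

    centroids, supports = [], []
    for lab in sorted(set(labels) - {-1}):
        idx = np.flatnonzero(labels == lab)
        sub = dist[np.ix_(idx, idx)]
        medoid = idx[np.argmin(sub.sum(axis=1))]
        members = pool[:, idx]
        signs = np.sign(members.T @ pool[:, medoid])
        signs[signs == 0] = 1.0
        centroid = (members * signs).mean(axis=1)
        norm = np.linalg.norm(centroid)
        if norm == 0:
            continue
        centroid = centroid / norm
        top = np.argmax(np.abs(centroid))
        if centroid[top] < 0:
            centroid = -centroid
        centroids.append(centroid)
        supports.append(len(set(run_of[idx])))

    if not centroids:
        logger.warning("consensus clustering found zero robust components")
        return _empty_decomposition(x, gene_ids)

    order = sorted(
        range(len(centroids)),
        key=lambda i: (-supports[i], int(np.argmax(np.abs(centroids[i]))), -np.max(np.abs(centroids[i]))),
    )
    M = np.column_stack([centroids[i] for i in order])
    supports = [supports[i] for i in order]

    genes = gene_ids if gene_ids is not None else x.gene_ids
    comp_ids = [f"IM_{i + 1:03d}" for i in range(M.shape[1])]
    A, *_ = np.linalg.lstsq(M, x.values, rcond=None)
    return RobustDecomposition(
        M=pd.DataFrame(M, index=genes, columns=comp_ids),
        A=pd.DataFrame(A, index=comp_ids, columns=x.sample_ids),
        cluster_support=supports,
        seeds_used=[r.seed for r in runs],
        n_runs=len(runs),
    )


def _empty_decomposition(x: ExpressionMatrix, gene_ids=None) -> RobustDecomposition:
    genes = gene_ids if gene_ids is not None else x.gene_ids
    return RobustDecomposition(
        M=pd.DataFrame(index=genes, dtype=float),
        A=pd.DataFrame(columns=x.sample_ids, dtype=float),
        cluster_support=[],
        seeds_used=[],
        n_runs=0,
    )


def explained_variance(
    x: ExpressionMatrix,
    decomp: RobustDecomposition,
    subset: list | None = None,
) -> float:
    """Fraction of ‖X‖²_F captured by the (subset) reconstruction.

    Activities are refit by least squares on the selected component
    subset, so the quantity is monotone non-decreasing as components
    are added. An empty subset returns 0.
    """
    if decomp.M.shape[0] != x.n_genes:
        raise ValueError("gene dimension mismatch between X and decomposition")
    cols = list(decomp.M.columns) if subset is None else list(subset)
    total = float(np.sum(x.values**2))
    if total == 0:
        return 0.0
    if not cols:
        return 0.0
    Ms = decomp.M[cols].to_numpy()
    As, *_ = np.linalg.lstsq(Ms, x.values, rcond=None)
    resid = float(np.sum((x.values - Ms @ As) ** 2))
    return 1.0 - resid / total


def dimension_sweep(
    x: ExpressionMatrix,
    dims: list[int] = SWEEP_GRID,
    n_runs: int = DEFAULT_N_RUNS,
    tolerance: float = DEFAULT_TOLERANCE,
    epsilon: float = DEFAULT_EPSILON,
    min_cluster_size: int | None = None,
    k2_cutoff: float | None = None,
) -> tuple[int, pd.DataFrame]:
    """Search the component-count grid for the optimal dimensionality.

    For each dimension the full ensemble + consensus clustering is run
    and two counts are recorded: the number of robust components K and
    the number of *non-single* robust components (components whose
    outlier thresholding retains more than one member gene). The
    optimal dimension is the largest grid value where the two counts
    are equal; if no dimension satisfies the criterion, the dimension
    maximizing K − |K − non_single| is returned with a warning. The
    per-dimension diagnostics table is always returned.
    """
    from .membership import DEFAULT_K2_CUTOFF, threshold_component

    dims = sorted(dims)
    if min_cluster_size is None:
        min_cluster_size = max(2, n_runs // 2)
    if k2_cutoff is None:
        k2_cutoff = DEFAULT_K2_CUTOFF
    rows = []
    for dim in dims:
        runs = run_ensemble(x, dim, n_runs=n_runs, tolerance=tolerance)
        decomp = cluster_components(runs, x, epsilon=epsilon, min_cluster_size=min_cluster_size)
        n_non_single = 0
        for cid in decomp.component_ids:
            res = threshold_component(decomp.M[cid], k2_cutoff)
            if len(res.members) > 1:
                n_non_single += 1
        rows.append(
            {"dimension": dim, "n_robust": decomp.K, "n_non_single": n_non_single,
             "n_converged_runs": decomp.n_runs}
        )
        logger.info("sweep dim=%d: K=%d non-single=%d", dim, decomp.K, n_non_single)
    diagnostics = pd.DataFrame(rows)
    equal = diagnostics[
        (diagnostics["n_robust"] == diagnostics["n_non_single"]) & (diagnostics["n_robust"] > 0)
    ]
    if len(equal):
        optimal = int(equal["dimension"].max())
    else:
        score = diagnostics["n_robust"] - (diagnostics["n_robust"] - diagnostics["n_non_single"]).abs()
        optimal = int(diagnostics.loc[score.idxmax(), "dimension"])
        logger.warning("no dimension had K == non-single; fallback pick %d", optimal)
    return optimal, diagnostics


def write_decomposition(decomp: RobustDecomposition, out_dir, params: dict | None = None) -> None:
    """Write M.tsv, A.tsv and a run-manifest JSON."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    decomp.M.to_csv(os.path.join(out_dir, "M.tsv"), sep="\t")
    decomp.A.to_csv(os.path.join(out_dir, "A.tsv"), sep="\t")
    manifest = {
        "n_components": decomp.K,
        "cluster_support": decomp.cluster_support,
        "seeds_used": decomp.seeds_used,
        "n_converged_runs": decomp.n_runs,
        "parameters": params or {},
    }
    with open(os.path.join(out_dir, "ica_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_decomposition(out_dir) -> RobustDecomposition:
    import os

    M = pd.read_csv(os.path.join(out_dir, "M.tsv"), sep="\t", index_col=0)
    A = pd.read_csv(os.path.join(out_dir, "A.tsv"), sep="\t", index_col=0)
    with open(os.path.join(out_dir, "ica_manifest.json")) as fh:
        manifest = json.load(fh)
    return RobustDecomposition(
        M=M, A=A,
        cluster_support=manifest.get("cluster_support", []),
        seeds_used=manifest.get("seeds_used", []),
        n_runs=manifest.get("n_converged_runs", 0),
    )
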