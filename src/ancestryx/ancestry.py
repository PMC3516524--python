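"""Ancestry exposure space: LD pruning, genotype PCA, and cluster assignment.

Ancestry groups are defined empirically: markers are thinned to a
near-independent panel (long-range-LD regions removed, then a sliding
window pairwise-r2 pruner), the thinned genotype matrix is normalised
EIGENSTRAT-style and decomposed, and individuals are clustered in the
space of the leading principal components by k-means. The number of
clusters K is selected by BIC over a user grid, scoring each hard
clustering as a spherical shared-variance Gaussian mixture. The cohort
collection label provides a second, algorithm-free clustering of the same
individuals; the switch rate between the two clusterings quantifies how
often collection disagrees with genetic ancestry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.utils.extmath import randomized_svd

from .gwas_io import GenotypeDataset, RegionList

logger = logging.getLogger("ancestryx")


@dataclass
class PcaBasis:
    """A fitted genotype PCA: marker panel, normalisation, and loadings.

    ``loadings`` has shape (n_markers_used, n_components) with orthonormal
    columns; ``eigenvalues`` are the variances of the component scores on
    the fitting data. The stored column means/scales let new samples be
    projected without refitting.
    """

    marker_ids: np.ndarray
    col_means: np.ndarray
    col_scales: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ExposureClustering:
    """A hard assignment of N samples to K clusters in an exposure space E."""

    E: np.ndarray            # (N, d) exposure variables (e.g. top PCs)
    K: int
    Z: np.ndarray            # (N, K) binary indicator matrix, rows sum to 1
    source: str = "custom"   # {ancestry, collection, custom}
    level_names: list[str] = field(default_factory=list)
    bic_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=np.float64)
        if self.E.ndim == 1:
            self.E = self.E[:, None]
        self.Z = np.asarray(self.Z)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.Z.shape != (self.E.shape[0], self.K):
            raise ValueError("Z must be N x K")
        rows = self.Z.sum(axis=1)
        if not np.array_equal(rows, np.ones_like(rows)):
            raise ValueError("each row of Z must sum to exactly 1")
        if (self.Z.sum(axis=0) == 0).any():
            raise ValueError("every cluster must be non-empty")
        if not self.level_names:
            self.level_names = [f"cluster{c + 1}" for c in range(self.K)]

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.Z, axis=1)

    @classmethod
    def from_labels(cls, labels, E=None, source="custom", level_names=None):
        labels = np.asarray(labels)
        levels, codes = np.unique(labels, return_inverse=True)
        K = len(levels)
        Z = np.zeros((len(labels), K), dtype=np.int8)
        Z[np.arange(len(labels)), codes] = 1
        if E is None:
            E = codes.astype(float)[:, None]
        return cls(E=E, K=K, Z=Z, source=source,
                   level_names=list(level_names or map(str, levels)))


# ---------------------------------------------------------------------------
# Step 1a: marker thinning


def prune_markers(
    ds: GenotypeDataset,
    regions: RegionList | None = None,
    r2_threshold: float = 0.2,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Select a near-independent marker panel for PCA.

    Markers inside any exclusion region are removed first; the survivors
    (assumed ordered by chromosome and position) then pass through a
    sliding-window greedy pairwise-r2 pruner: within each window of
    ``window`` markers, while any retained pair has r2 above the
    threshold, one member is removed (the one with the lower minor-allele
    frequency; ties remove the later-positioned marker), after which the
    window slides by ``step`` markers. r2 is the squared Pearson
    correlation of 0/1/2 dosages over pairwise-complete samples.

    Returns the sorted indices of surviving markers.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")

    idx = np.arange(ds.n_markers)
    if regions is not None and len(regions):
        inside = regions.contains(ds.marker_chrom, ds.marker_pos)
        idx = idx[~inside]
    if idx.size == 0:
        return idx

    G = ds.dosages[:, idx]
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(maf, 1 - maf)

    # complete data: standardise once so each window's correlations are a
    # single matrix product; missing data falls back to pairwise-complete
    Zs = None
    if not np.isnan(G).any():
        sd = G.std(axis=0)
        sd[sd == 0] = np.inf  # monomorphic: r2 = 0 against everything
        Zs = (G - G.mean(axis=0)) / (sd * np.sqrt(G.shape[0]))

    kept = np.ones(idx.size, dtype=bool)
    start = 0
    while start < idx.size:
        win = np.arange(start, min(start + window, idx.size))
        win = win[kept[win]]
        if win.size >= 2:
            if Zs is not None:
                Zw = Zs[:, win]
                R2 = (Zw.T @ Zw) ** 2
                np.fill_diagonal(R2, 0.0)
            else:
                R2 = _pairwise_r2(G[:, win])
            iu, ju = np.triu_indices(win.size, k=1)
            active = np.ones(win.size, dtype=bool)
            while True:
                viol = active[iu] & active[ju] & (R2[iu, ju] > r2_threshold)
                if not viol.any():
                    break
                # drop one member of the first violating pair per the
                # MAF rule, then re-scan
                a, b = iu[viol][0], ju[viol][0]
                ma, mb = maf[win[a]], maf[win[b]]
                drop = b if (mb < ma or np.isclose(ma, mb)) else a
                active[drop] = False
            kept[win[~active]] = False
        start += step
    return idx[kept]


def _pairwise_r2(G: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns.

    Uses the fast dense path when no genotypes are missing and masked
    (pairwise-complete) correlations otherwise. Monomorphic columns get
    r2 = 0 against everything.
    """
    if np.isnan(G).any():
        C = np.ma.corrcoef(np.ma.masked_invalid(G), rowvar=False)
        C = np.asarray(C.filled(0.0))
    else:
        sd = G.std(axis=0)
        ok = sd > 0
        C = np.zeros((G.shape[1], G.shape[1]))
        if ok.any():
            C[np.ix_(ok, ok)] = np.corrcoef(G[:, ok], rowvar=False)
    np.fill_diagonal(C, 0.0)
    return C**2


# ---------------------------------------------------------------------------
# Step 1b: PCA


def fit_pca(
    ds: GenotypeDataset,
    markers: np.ndarray | None = None,
    n_components: int = 2,
) -> tuple[PcaBasis, np.ndarray]:
    """Fit a genotype PCA with EIGENSTRAT normalisation.

    Each marker column is centred by its mean dosage and scaled by
    sqrt(p(1-p)) with the shrunk allele-frequency estimate
    p = (1 + sum g) / (2 + 2 n_called); missing entries are replaced by
    the column mean (zero after centring) before decomposition.
    Monomorphic markers are dropped with a warning. Returns the basis and
    the N x n_components score matrix (scores = normalised matrix @
    loadings).
    """
    if markers is None:
        markers = np.arange(ds.n_markers)
    markers = np.asarray(markers)
    G = ds.dosages[:, markers]
    n_called = np.isfinite(G).sum(axis=0)
    g_sum = np.nansum(G, axis=0)
    p_hat = (1.0 + g_sum) / (2.0 + 2.0 * n_called)
    with np.errstate(invalid="ignore"):
        col_mean = g_sum / n_called
    col_var = np.nanvar(G, axis=0)
    poly = (col_var > 0) & (n_called > 0)
    if not poly.all():
        logger.warning("dropping %d monomorphic markers before PCA", (~poly).sum())
    markers = markers[poly]
    if markers.size == 0:
        raise ValueError("no polymorphic markers left for PCA")
    if n_components > min(ds.n_samples, markers.size):
        raise ValueError("n_components exceeds min(N, number of markers)")

    scale = np.sqrt(p_hat[poly] * (1.0 - p_hat[poly]))
    X = _normalise(G[:, poly], col_mean[poly], scale)
    if min(X.shape) <= 4 * n_components or min(X.shape) < 50:
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    else:
        U, S, Vt = randomized_svd(X, n_components=n_components, n_iter=7, random_state=0)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(n_components), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    basis = PcaBasis(
        marker_ids=ds.marker_ids[markers].copy(),
        col_means=col_mean[poly],
        col_scales=scale,
        loadings=Vt.T,
        eigenvalues=S**2 / max(ds.n_samples - 1, 1),
    )
    return basis, U * S


def _normalise(G, means, scales):
    X = (G - means) / scales
    X[~np.isfinite(X)] = 0.0  # mean-imputed missing entries
    return X


def project(ds: GenotypeDataset, basis: PcaBasis) -> np.ndarray:
    """Project samples onto a previously fitted PCA basis (never refits)."""
    order = {m: j for j, m in enumerate(ds.marker_ids)}
    missing = [m for m in basis.marker_ids if m not in order]
    if missing:
        raise ValueError(
            f"{len(missing)} basis markers absent from dataset: {missing[:10]}"
        )
    cols = np.array([order[m] for m in basis.marker_ids])
    X = _normalise(ds.dosages[:, cols], basis.col_means, basis.col_scales)
    return X @ basis.loadings


# ---------------------------------------------------------------------------
# Step 2: clustering


def _kmeans_bic(E: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """BIC of a hard clustering under an axis-aligned shared-variance mixture.

    The classification log-likelihood combines the multinomial cluster
    weights (n_c / N) with Gaussians around each centre sharing one
    diagonal covariance (per-dimension MLE variances pooled over
    clusters). The diagonal model suits principal-component scores,
    whose dimensions are decorrelated by construction but carry very
    different variances: a single spherical variance would reward
    splitting clusters along their widest axis. Parameters: k*d centre
    coordinates plus the d variances.
    """
    n, d = E.shape
    k = centers.shape[0]
    resid2 = (E - centers[labels]) ** 2
    var_d = np.maximum(resid2.mean(axis=0), 1e-300)  # pooled within-cluster, per dim
    counts = np.bincount(labels, minlength=k).astype(float)
    ll = float((counts * np.log(counts / n)).sum()) - 0.5 * n * (
        np.log(2 * np.pi * var_d).sum() + d
    )
    n_params = k * d + d
    return -2.0 * ll + n_params * np.log(n)


def cluster_ancestry(
    scores: np.ndarray,
    k_min: int = 2,
    k_max: int = 6,
    seed: int = 0,
    n_restarts: int = 25,
) -> ExposureClustering:
    """k-means over a K grid with BIC model selection.

    For each k in [k_min, k_max] runs k-means++ with ``n_restarts``
    seeded restarts (best within-cluster SSE kept) and scores the
    resulting hard clustering with the spherical-mixture BIC; the
    clustering with minimal BIC is returned, with the full BIC curve
    attached as ``bic_by_k``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    if n < k_max:
        raise ValueError(f"N={n} smaller than k_max={k_max}")

    bic_by_k: dict[int, float] = {}
    best = None
    for k in range(k_min, k_max + 1):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_restarts,
            random_state=(seed + 7919 * k) % (2**32),
        ).fit(scores)
        bic = _kmeans_bic(scores, km.labels_, km.cluster_centers_)
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, km.labels_)
    _, k_sel, labels = best
    clust = ExposureClustering.from_labels(labels, E=scores, source="ancestry")
    clust.bic_by_k = bic_by_k
    return clust


def collection_clustering(ds: GenotypeDataset) -> ExposureClustering:
    """One-hot clustering defined by the collection factor (no algorithm)."""
    levels = sorted(set(ds.collection))
    clust = ExposureClustering.from_labels(
        ds.collection, source="collection", level_names=levels
    )
    return clust


def switch_rate(a: ExposureClustering, b: ExposureClustering) -> float:
    """Fraction of samples whose labels disagree, minimised over label matchings.

    Comparing two clusterings requires equal K; the optimal one-to-one
    matching of labels is found by the Hungarian algorithm on the
    cross-tabulation, which equals the minimum over all permutations.
    """
    if a.K != b.K:
        raise ValueError(f"switch_rate needs equal K (got {a.K} and {b.K})")
    if a.n_samples != b.n_samples:
        raise ValueError("clusterings cover different numbers of samples")
    confusion = a.Z.T.astype(np.int64) @ b.Z.astype(np.int64)
    rows, cols = linear_sum_assignment(-confusion)
    agree = confusion[rows, cols].sum()
    return 1.0 - agree / a.n_samples
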