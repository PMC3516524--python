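"""Heterogeneous-association models and the BIC-difference statistics T and D.

For a marker with dosage vector x and a hard clustering of the samples
into K groups (indicator matrix Z), two nested GLMs are compared:

* heterogeneous model:  g(E[y_i]) = sum_c z_ic alpha_c + sum_c z_ic beta_c x_i + W_i gamma
* null model:           g(E[y_i]) = sum_c z_ic alpha_c + beta x_i + W_i gamma

The null model keeps cluster-specific intercepts (different background
disease rates per cluster) but forces a single shared genetic effect, so
it nests both "no association" (beta = 0) and "homogeneous association".
The link g is the logit for binary phenotypes and the identity for
quantitative traits. Both models are fitted by maximum likelihood (IRLS
for the logit link) and scored with BIC = -2 logL + p ln n.

The evidence for heterogeneity at the marker is

    T = BIC(null) - BIC(heterogeneous),

positive when cluster-specific effects survive the complexity penalty.
Computing T under two rival clusterings A and B of the same samples and
differencing gives D = T_A - T_B: positive D says exposure A (ancestry)
explains the heterogeneity better, negative D points at exposure B
(a collection artefact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr as _qr
from scipy.special import expit

from .ancestry import ExposureClustering
from .gwas_io import GenotypeDataset

#: cap applied to coefficients when complete separation is detected (log-odds)
SEPARATION_CAP = 15.0
#: IRLS convergence: relative log-likelihood change below this
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


class RankDeficientError(ValueError):
    """Design matrix not of full column rank; names the collinear columns."""


class MarkerSkipped(RuntimeError):
    """Marker cannot be tested (e.g. a cluster with < 2 observed samples)."""


@dataclass
class GlmFit:
    """A fitted GLM with the quantities needed for BIC comparison.

    ``n_params`` counts all mean-model coefficients, plus one residual
    variance parameter for the identity link. ``bic`` always equals
    -2 logL + n_params ln(n_used).
    """

    coef: np.ndarray
    se: np.ndarray
    names: list[str]
    log_likelihood: float
    n_params: int
    n_used: int
    link: str
    converged: bool

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(self.n_used)

    def coef_by_name(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])


@dataclass
class SnpTestResult:
    """Per-marker heterogeneity test under two clusterings."""

    marker_id: str
    t_anc: float
    t_coll: float
    d: float
    beta_anc: np.ndarray        # cluster-specific genetic effects, clustering A
    se_anc: np.ndarray
    beta_coll: np.ndarray       # same for clustering B
    se_coll: np.ndarray
    n_used: int
    converged: bool
    link: str

    @property
    def or_anc(self) -> np.ndarray:
        if self.link != "logit":
            raise ValueError("odds ratios are defined for the logit link only")
        return np.exp(self.beta_anc)

    @property
    def or_coll(self) -> np.ndarray:
        if self.link != "logit":
            raise ValueError("odds ratios are defined for the logit link only")
        return np.exp(self.beta_coll)

    @property
    def directions_anc(self) -> np.ndarray:
        return np.sign(self.beta_anc)


# ---------------------------------------------------------------------------
# GLM fitting


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    XtX = X.T @ X
    ev = np.linalg.eigvalsh(XtX)
    if ev[0] <= ev[-1] * 1e-10:
        _, R, piv = _qr(X, pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int((diag > diag[0] * 1e-10).sum()) if diag.size else 0
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficientError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_glm(y: np.ndarray, X: np.ndarray, link: str = "logit",
            names: list[str] | None = None) -> GlmFit:
    """Maximum-likelihood GLM fit (logit via IRLS, identity via least squares).

    Convergence is declared when the relative log-likelihood change drops
    below 1e-8 (at most 100 iterations); a non-converged fit is still
    returned with ``converged=False``. Complete separation is handled by
    capping |coefficients| at 15 on the log-odds scale and flagging the
    fit rather than raising, so genome scans run to completion. A rank
    deficient design raises :class:`RankDeficientError` naming the
    collinear columns.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if link not in ("logit", "identity"):
        raise ValueError(f"unknown link {link!r}")
    _check_rank(X, names)

    if link == "identity":
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
        sigma2_mle = max(rss / n, 1e-300)
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2_mle) + 1.0)
        dof = max(n - p, 1)
        cov = (rss / dof) * np.linalg.inv(X.T @ X)
        return GlmFit(coef=coef, se=np.sqrt(np.diag(cov)), names=list(names),
                      log_likelihood=ll, n_params=p + 1, n_used=n,
                      link=link, converged=True)

    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logit link requires a 0/1 phenotype")
    beta = np.zeros(p)
    ll_old = _logit_ll(y, np.zeros(n))
    converged = False
    A = np.empty((p, p))
    for _ in range(IRLS_MAX_ITER):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw
        b = Xw.T @ z
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            converged = False
            break
        if np.abs(beta).max() > SEPARATION_CAP:
            beta = np.clip(beta, -SEPARATION_CAP, SEPARATION_CAP)
            converged = False
            break
        ll = _logit_ll(y, X @ beta)
        if abs(ll - ll_old) <= IRLS_TOL * (abs(ll_old) + IRLS_TOL):
            converged = True
            break
        ll_old = ll
    ll = _logit_ll(y, X @ beta)
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(A)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    return GlmFit(coef=beta, se=se, names=list(names), log_likelihood=ll,
                  n_params=p, n_used=n, link=link, converged=converged)


def _logit_ll(y: np.ndarray, eta: np.ndarray) -> float:
    eta = np.clip(eta, -500, 500)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


# ---------------------------------------------------------------------------
# design construction


def build_designs(
    x: np.ndarray,
    clustering: ExposureClustering,
    W: np.ndarray | None = None,
    cov_names: list[str] | None = None,
):
    """Build the heterogeneous and null design matrices for one marker.

    Rows with a missing dosage are dropped from *both* designs so the two
    BICs are computed on the identical sample subset. Returns
    ``(X_het, X_null, names_het, names_null, mask)`` where the
    heterogeneous design holds the K cluster-indicator intercepts, the K
    cluster-specific genotype columns z_ic * x_i and the q covariates,
    and the null design replaces the K genotype columns with a single
    shared one (exactly K - 1 fewer columns).

    Raises :class:`MarkerSkipped` if any cluster retains fewer than two
    observed samples at this marker.
    """
    x = np.asarray(x, dtype=np.float64)
    mask = np.isfinite(x)
    Z = clustering.Z.astype(np.float64)[mask]
    xm = x[mask]
    counts = Z.sum(axis=0)
    if (counts < 2).any():
        small = [clustering.level_names[c] for c in np.flatnonzero(counts < 2)]
        raise MarkerSkipped(
            f"cluster(s) {small} have fewer than 2 observed samples at this marker"
        )
    K = clustering.K
    names_a = [f"alpha_{c + 1}" for c in range(K)]
    names_b = [f"beta_{c + 1}" for c in range(K)]
    cov_names = list(cov_names or [])
    if W is None:
        Wm = np.empty((mask.sum(), 0))
    else:
        Wm = np.asarray(W, dtype=np.float64).reshape(len(x), -1)[mask]
        if not cov_names:
            cov_names = [f"gamma_{j + 1}" for j in range(Wm.shape[1])]
    X_het = np.hstack([Z, Z * xm[:, None], Wm])
    X_null = np.hstack([Z, xm[:, None], Wm])
    return (
        X_het,
        X_null,
        names_a + names_b + cov_names,
        names_a + ["beta"] + cov_names,
        mask,
    )


# ---------------------------------------------------------------------------
# T and D statistics


def t_statistic(
    ds: GenotypeDataset,
    marker: int | str,
    clustering: ExposureClustering,
    W: np.ndarray | None = None,
    link: str | None = None,
) -> tuple[float, GlmFit, GlmFit]:
    """T = BIC(null) - BIC(heterogeneous) for one marker and clustering.

    Positive T favours cluster-specific genetic effects. The link
    defaults to logit for a binary phenotype and identity otherwise.
    """
    j = _marker_index(ds, marker)
    if link is None:
        link = "logit" if ds.is_binary else "identity"
    X_het, X_null, nh, nn, mask = build_designs(
        ds.dosages[:, j], clustering, W, None
    )
    ym = ds.y[mask]
    het = fit_glm(ym, X_het, link=link, names=nh)
    null = fit_glm(ym, X_null, link=link, names=nn)
    return null.bic - het.bic, het, null


def d_statistic(t_a: float, t_b: float) -> float:
    """Difference statistic D = T_A - T_B between two exposure clusterings."""
    return t_a - t_b


def _marker_index(ds: GenotypeDataset, marker: int | str) -> int:
    if isinstance(marker, (int, np.integer)):
        return int(marker)
    hits = np.flatnonzero(ds.marker_ids == marker)
    if hits.size != 1:
        raise KeyError(f"marker {marker!r} not found (or duplicated)")
    return int(hits[0])


def snp_test(
    ds: GenotypeDataset,
    marker: int | str,
    clustering_anc: ExposureClustering,
    clustering_coll: ExposureClustering,
    W: np.ndarray | None = None,
    link: str | None = None,
) -> SnpTestResult:
    """Full per-marker test: T under both clusterings and their difference D."""
    j = _marker_index(ds, marker)
    if link is None:
        link = "logit" if ds.is_binary else "identity"
    x = ds.dosages[:, j]
    t_a, het_a, _ = _t_pair(ds.y, x, clustering_anc, W, link)
    t_b, het_b, _ = _t_pair(ds.y, x, clustering_coll, W, link)
    Ka, Kb = clustering_anc.K, clustering_coll.K
    return SnpTestResult(
        marker_id=str(ds.marker_ids[j]),
        t_anc=t_a,
        t_coll=t_b,
        d=d_statistic(t_a, t_b),
        beta_anc=het_a.coef[Ka: 2 * Ka].copy(),
        se_anc=het_a.se[Ka: 2 * Ka].copy(),
        beta_coll=het_b.coef[Kb: 2 * Kb].copy(),
        se_coll=het_b.se[Kb: 2 * Kb].copy(),
        n_used=het_a.n_used,
        converged=het_a.converged and het_b.converged,
        link=link,
    )


def _t_pair(y, x, clustering, W, link):
    """T statistic plus both fits for a raw (y, x) pair; internal fast path."""
    X_het, X_null, nh, nn, mask = build_designs(x, clustering, W, None)
    ym = y[mask]
    het = fit_glm(ym, X_het, link=link, names=nh)
    null = fit_glm(ym, X_null, link=link, names=nn)
    return null.bic - het.bic, het, null
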