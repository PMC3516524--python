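"""Genome-wide scan orchestration, replication, meta-analysis, and power.

The discovery scan computes T under the ancestry and collection
clusterings and their difference D for every marker, filters on the
calibrated D threshold, and ranks surviving candidates by the ancestry T
statistic. When a second discovery phase exists, candidates must also
show a consistent direction of effect across phases. Targeted
replication in cohorts without genome-wide data uses the collection
label as a noisy proxy for ancestry: a per-group logistic (or linear)
fit with a one-sided p-value in the pre-registered discovery direction.
Because label misclassification attenuates the observable effect, a
switch-rate power analysis quantifies the power loss as the proxy
labels' disagreement with true ancestry grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .ancestry import ExposureClustering
from .gwas_io import GenotypeDataset
from .het_test import (
    GlmFit,
    MarkerSkipped,
    RankDeficientError,
    SnpTestResult,
    fit_glm,
    snp_test,
)
from .null_calibration import ThresholdTable

logger = logging.getLogger("ancestryx")


# ---------------------------------------------------------------------------
# discovery scan


@dataclass
class ScanReport:
    """Per-marker test results plus the D-filtered, T-ranked candidate list."""

    results: list[SnpTestResult]
    skipped: dict[str, str]
    thresholds: ThresholdTable | None
    expected_by_chance: int | None

    @property
    def candidates(self) -> list[SnpTestResult]:
        """Markers with D above the threshold, ordered by T_anc descending."""
        if self.thresholds is None or self.thresholds.d_threshold is None:
            return []
        cands = [r for r in self.results if r.d > self.thresholds.d_threshold]
        return sorted(cands, key=lambda r: -r.t_anc)

    @property
    def candidate_ids(self) -> list[str]:
        return [r.marker_id for r in self.candidates]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        passing = set(self.candidate_ids)
        for r in self.results:
            row = {
                "marker": r.marker_id,
                "T_anc": r.t_anc,
                "T_coll": r.t_coll,
                "D": r.d,
                "n_used": r.n_used,
                "converged": r.converged,
                "pass_d_filter": r.marker_id in passing,
            }
            for c, b in enumerate(r.beta_anc):
                row[f"beta_anc_{c + 1}"] = b
            for c, b in enumerate(r.beta_coll):
                row[f"beta_coll_{c + 1}"] = b
            rows.append(row)
        return pd.DataFrame(rows)


def expected_chance_count(n_markers: int, centile: float = 99.0) -> int:
    """Markers expected past the D filter by chance: floor(M * (1 - centile/100))."""
    return int(np.floor(n_markers * (1.0 - centile / 100.0)))


def scan(
    ds: GenotypeDataset,
    clustering_anc: ExposureClustering,
    clustering_coll: ExposureClustering,
    W: np.ndarray | None = None,
    thresholds: ThresholdTable | None = None,
    link: str | None = None,
) -> ScanReport:
    """Test every marker for heterogeneity under both clusterings.

    Each marker receives T_anc, T_coll and D, or a logged skip reason
    (too-small cluster, collinear design). Deterministic and
    embarrassingly parallel across markers.
    """
    for clust in (clustering_anc, clustering_coll):
        if clust.n_samples != ds.n_samples:
            raise ValueError("clustering covers a different sample set than the data")
    results: list[SnpTestResult] = []
    skipped: dict[str, str] = {}
    for j in range(ds.n_markers):
        mid = str(ds.marker_ids[j])
        try:
            results.append(snp_test(ds, j, clustering_anc, clustering_coll, W, link))
        except (MarkerSkipped, RankDeficientError) as exc:
            skipped[mid] = str(exc)
            logger.info("marker %s skipped: %s", mid, exc)
    n_tested = len(results)
    expected = (
        expected_chance_count(n_tested, thresholds.centile) if thresholds else None
    )
    return ScanReport(
        results=results,
        skipped=skipped,
        thresholds=thresholds,
        expected_by_chance=expected,
    )


def cross_phase_consistency(
    candidates_phase1: ScanReport,
    results_phase2: ScanReport,
    cluster_map: dict[int, int] | None = None,
) -> list[str]:
    """Markers passing the D filter in both phases with consistent direction.

    Direction is checked in the discovery-driving cluster: the cluster
    with the largest |beta| in phase 1, mapped into phase 2 by
    ``cluster_map`` (identity by default since independent clusterings
    carry arbitrary labels; align them first, e.g. by centroid matching).
    """
    c1 = {r.marker_id: r for r in candidates_phase1.candidates}
    c2 = {r.marker_id: r for r in results_phase2.candidates}
    shared = [m for m in c1 if m in c2]
    if not shared:
        logger.warning("no shared candidate markers between phases")
        return []
    out = []
    for m in shared:
        r1, r2 = c1[m], c2[m]
        lead = int(np.argmax(np.abs(r1.beta_anc)))
        lead2 = cluster_map.get(lead, lead) if cluster_map else lead
        if lead2 >= len(r2.beta_anc):
            continue
        s1, s2 = np.sign(r1.beta_anc[lead]), np.sign(r2.beta_anc[lead2])
        if s1 != 0 and s1 == s2:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# replication


@dataclass
class ReplicationResult:
    """Per-group association estimate with Wald CI and directional p-value."""

    group: str
    n: int
    beta: float
    se: float
    direction: str                 # 'protective' or 'risk', carried from discovery
    link: str = "logit"

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        """95% Wald CI on the OR scale (beta scale for the identity link)."""
        lo, hi = self.beta - 1.96 * self.se, self.beta + 1.96 * self.se
        if self.link == "logit":
            return float(np.exp(lo)), float(np.exp(hi))
        return float(lo), float(hi)

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def p_two_sided(self) -> float:
        return float(2 * norm.sf(abs(self.z)))

    @property
    def p_one_sided(self) -> float:
        """Tail probability in the pre-specified discovery direction."""
        z = self.z
        return float(norm.cdf(z) if self.direction == "protective" else norm.sf(z))


def replication_test(
    ds_rep: GenotypeDataset,
    marker: int | str,
    direction: str | dict[str, str],
    proxy_labels: np.ndarray | None = None,
    W: np.ndarray | None = None,
    link: str | None = None,
) -> dict[str, ReplicationResult]:
    """Targeted per-group replication with proxy (e.g. collection) labels.

    Fits phenotype ~ dosage + W separately within each proxy-label group
    and reports the Wald CI plus one-sided p in the pre-registered
    discovery ``direction`` ('protective' or 'risk'; a dict gives a
    per-group direction). Groups with no dosage variation are skipped
    with a logged reason.
    """
    from .het_test import _marker_index

    j = _marker_index(ds_rep, marker)
    if link is None:
        link = "logit" if ds_rep.is_binary else "identity"
    labels = ds_rep.collection if proxy_labels is None else np.asarray(proxy_labels)
    x = ds_rep.dosages[:, j]
    if W is None:
        W = ds_rep.W
    out: dict[str, ReplicationResult] = {}
    for grp in sorted(set(labels)):
        rows = (labels == grp) & np.isfinite(x)
        xg = x[rows]
        if np.nanstd(xg) == 0 or rows.sum() < 3:
            logger.warning("group %s skipped: no dosage variation", grp)
            continue
        Xg = np.column_stack([np.ones(rows.sum()), xg, np.asarray(W)[rows].reshape(rows.sum(), -1)])
        fit = fit_glm(ds_rep.y[rows], Xg, link=link,
                      names=["intercept", "beta"] + [f"gamma_{k}" for k in range(np.asarray(W).reshape(len(x), -1).shape[1])])
        d = direction[grp] if isinstance(direction, dict) else direction
        out[grp] = ReplicationResult(
            group=str(grp), n=int(rows.sum()),
            beta=float(fit.coef[1]), se=float(fit.se[1]),
            direction=d, link=link,
        )
    return out


def pvalue_from_or_ci(or_: float, lo: float, hi: float, sided: int = 2) -> float:
    """Normal-approximation p-value back-computed from an OR and its 95% CI.

    SE = (ln hi - ln lo) / (2 * 1.96), z = ln(OR) / SE; the one-sided
    value takes the tail in the estimate's own direction. Used to check
    consistency of reported results.
    """
    if not 0 < lo < or_ < hi:
        raise ValueError("need 0 < lo < OR < hi")
    if sided not in (1, 2):
        raise ValueError("sided must be 1 or 2")
    se = (np.log(hi) - np.log(lo)) / (2 * 1.959963984540054)
    z = np.log(or_) / se
    tail = float(norm.sf(abs(z)))
    return sided * tail


def pooled_fit(
    datasets: list[GenotypeDataset],
    marker: str,
    W_cols: list[str] | None = None,
    direction: str = "protective",
    link: str | None = None,
) -> ReplicationResult:
    """Fixed-effect pooled fit across datasets with free per-source intercepts.

    Concatenates samples, gives each source dataset its own intercept
    (mirroring the cluster-intercept null model), and estimates one
    shared genetic effect, optionally adjusting for named covariates
    shared by all datasets. Sample IDs must be disjoint across sources
    and phenotype coding must match.
    """
    from .het_test import _marker_index

    ids = np.concatenate([d.sample_ids for d in datasets])
    if len(set(ids)) != len(ids):
        raise ValueError("sample IDs overlap across datasets")
    binary = {d.is_binary for d in datasets}
    if len(binary) != 1:
        raise ValueError("phenotype coding differs across datasets")
    if link is None:
        link = "logit" if binary.pop() else "identity"

    xs, ys, Ws, src = [], [], [], []
    for k, d in enumerate(datasets):
        j = _marker_index(d, marker)
        x = d.dosages[:, j]
        ok = np.isfinite(x)
        xs.append(x[ok])
        ys.append(d.y[ok])
        src.append(np.full(int(ok.sum()), k))
        if W_cols:
            cols = [d.covariate_names.index(c) for c in W_cols]
            Ws.append(d.W[ok][:, cols])
        else:
            Ws.append(np.empty((int(ok.sum()), 0)))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    Wm = np.vstack(Ws)
    src = np.concatenate(src)
    S = np.zeros((len(x), len(datasets)))
    S[np.arange(len(x)), src] = 1.0
    X = np.hstack([S, x[:, None], Wm])
    names = [f"source_{k}" for k in range(len(datasets))] + ["beta"] + [
        f"gamma_{c}" for c in (W_cols or [])
    ]
    fit = fit_glm(y, X, link=link, names=names)
    b = len(datasets)
    return ReplicationResult(
        group="pooled", n=len(x), beta=float(fit.coef[b]), se=float(fit.se[b]),
        direction=direction, link=link,
    )


def inverse_variance_meta(betas, ses) -> tuple[float, float]:
    """Fixed-effect inverse-variance combined estimate (cross-check only)."""
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    beta = float((w * np.asarray(betas, dtype=float)).sum() / w.sum())
    return beta, float(np.sqrt(1.0 / w.sum()))


# ---------------------------------------------------------------------------
# switch-rate power


@dataclass
class PowerResult:
    """Monte-Carlo power along a switch-rate grid."""

    switch_rates: np.ndarray
    power: np.ndarray
    mc_se: np.ndarray
    settings: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"switch_rate": self.switch_rates, "power": self.power, "mc_se": self.mc_se}
        )


def _retro_genotype_probs(maf: float, or_: float, prevalence: float):
    """P(genotype | case) and P(genotype | control) under the logistic model.

    Bayes inversion at HWE genotype frequencies: P(g|Y=y) proportional to
    HWE(g) * P(Y=y|g) with P(Y=1|g) = expit(logit(prevalence) + g ln OR).
    """
    g = np.arange(3)
    hwe = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    risk = expit(logit(prevalence) + g * np.log(or_))
    p_case = hwe * risk
    p_ctrl = hwe * (1 - risk)
    return p_case / p_case.sum(), p_ctrl / p_ctrl.sum()


def wald_power(
    or_: float,
    maf: float,
    n_cases: int,
    n_controls: int,
    alpha: float = 0.05,
    sided: int = 1,
    prevalence: float = 0.05,
) -> float:
    """Closed-form Wald power for a single-group logistic dosage test.

    Under retrospective sampling the prospective logistic slope is
    preserved (the intercept absorbs ascertainment), so the asymptotic
    SE of beta-hat comes from the expected Fisher information of the
    sampled genotype mixture, and power is the normal tail beyond the
    critical value.
    """
    p_case, p_ctrl = _retro_genotype_probs(maf, or_, prevalence)
    n_g = n_cases * p_case + n_controls * p_ctrl        # expected genotype counts
    mu_g = n_cases * p_case / n_g                       # P(case | genotype) in sample
    w = n_g * mu_g * (1 - mu_g)
    g = np.arange(3.0)
    info = np.array([[w.sum(), (w * g).sum()], [(w * g).sum(), (w * g * g).sum()]])
    se = float(np.sqrt(np.linalg.inv(info)[1, 1]))
    beta = abs(np.log(or_))
    z_crit = norm.isf(alpha) if sided == 1 else norm.isf(alpha / 2)
    return float(norm.sf(z_crit - beta / se))


def power_switch(
    or_group1: float,
    or_group2: float,
    maf: float,
    n_cases: int,
    n_controls: int,
    switch_rate_grid=(0.0, 0.1, 0.2, 0.3, 0.5),
    alpha: float = 0.05,
    sided: int = 1,
    sims: int = 1000,
    seed: int = 0,
    prevalence: float = 0.05,
) -> PowerResult:
    """Monte-Carlo power to replicate a group-1 effect under label noise.

    At switch rate s each "group-1-labelled" sample is truly group 1
    with probability 1 - s and group 2 otherwise; genotypes are drawn
    from each true group's retrospective case/control distribution
    implied by its OR, the MAF, and the baseline prevalence. Power is
    the fraction of simulations whose labelled-group logistic fit gives
    a one-sided p below alpha in the direction of group 1's effect
    (two-sided optional). Monotone non-increasing in s up to Monte-Carlo
    error.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    for s in switch_rate_grid:
        if not 0 <= s <= 0.5:
            raise ValueError("switch rates must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    direction = "protective" if or_group1 <= 1.0 else "risk"
    dists = [_retro_genotype_probs(maf, o, prevalence) for o in (or_group1, or_group2)]
    n = n_cases + n_controls
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    X = np.column_stack([np.ones(n), np.zeros(n)])

    rates, power, mc_se = [], [], []
    for s in switch_rate_grid:
        hits = 0
        for _ in range(sims):
            true_grp = (rng.random(n) < s).astype(int)  # 1 = mislabelled (group 2)
            g = np.empty(n)
            for t in (0, 1):
                for status, dist in ((1, dists[t][0]), (0, dists[t][1])):
                    rows = (true_grp == t) & (y == status)
                    if rows.any():
                        g[rows] = rng.choice(3, size=int(rows.sum()), p=dist)
            X[:, 1] = g
            fit = fit_glm(y, X, link="logit", names=["intercept", "beta"])
            rep = ReplicationResult(group="sim", n=n, beta=float(fit.coef[1]),
                                    se=float(fit.se[1]), direction=direction)
            p = rep.p_one_sided if sided == 1 else rep.p_two_sided
            hits += p < alpha
        pw = hits / sims
        rates.append(s)
        power.append(pw)
        mc_se.append(np.sqrt(pw * (1 - pw) / sims))
    return PowerResult(
        switch_rates=np.asarray(rates),
        power=np.asarray(power),
        mc_se=np.asarray(mc_se),
        settings=dict(
            or_group1=or_group1, or_group2=or_group2, maf=maf,
            n_cases=n_cases, n_controls=n_controls, alpha=alpha,
            sided=sided, sims=sims, seed=seed, prevalence=prevalence,
        ),
    )
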