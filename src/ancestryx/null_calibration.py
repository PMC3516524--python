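"""Null distributions and significance thresholds for D (and T) by simulation.

The D statistic has no known theoretical null distribution, so thresholds
are estimated retrospectively: the observed phenotype, adjustment
covariates, and both clusterings stay fixed while marker genotypes are
simulated with no association to anything — i.i.d. Hardy-Weinberg draws
at a given minor-allele frequency. Because case-control data are
ascertained on phenotype, simulating genotype conditional on (fixed)
phenotype is the appropriate null scheme.

Simulations run over a MAF grid (default 0.05 to 0.50 in steps of 0.05,
10,000 replicates each); all D values are pooled across the grid and the
significance threshold is the empirical 99th centile of the pooled
sample, with exceedance defined as strictly greater. The per-MAF strata
are retained so the claimed MAF-invariance of the null D distribution
can be checked. The lower 1% centile is also reported for screens
enriched in collection (exposure-B) heterogeneity, and a T-only mode
covers designs with a single clustering.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ancestry import ExposureClustering
from .het_test import _t_pair

logger = logging.getLogger("ancestryx")

DEFAULT_MAF_GRID = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2))


@dataclass
class ThresholdTable:
    """Pooled null-simulation quantiles of D (and T) with their settings."""

    d_threshold: float | None
    d_lower: float | None
    t_threshold: float
    centile: float
    maf_grid: tuple
    sims_per_maf: int
    seed: int
    #: per-MAF stratum arrays of null D (or T in single-clustering mode)
    strata: dict[float, np.ndarray] = field(default_factory=dict)
    t_strata: dict[float, np.ndarray] = field(default_factory=dict)
    n_failed: int = 0

    @property
    def pooled_d(self) -> np.ndarray:
        return np.concatenate([self.strata[m] for m in sorted(self.strata)])

    @property
    def pooled_t(self) -> np.ndarray:
        return np.concatenate([self.t_strata[m] for m in sorted(self.t_strata)])

    def exceeds(self, d: np.ndarray) -> np.ndarray:
        """Strictly-greater exceedance of the D threshold."""
        if self.d_threshold is None:
            raise ValueError("no D threshold (single-clustering calibration)")
        return np.asarray(d) > self.d_threshold

    def to_json(self, path=None) -> str:
        def summary(vals):
            q = np.quantile(vals, [0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99])
            return {
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "quantiles": {p: float(v) for p, v in zip((1, 5, 25, 50, 75, 95, 99), q)},
            }

        payload = {
            "settings": {
                "maf_grid": [float(m) for m in self.maf_grid],
                "sims_per_maf": self.sims_per_maf,
                "centile": self.centile,
                "seed": self.seed,
            },
            "d_threshold": self.d_threshold,
            "d_lower": self.d_lower,
            "t_threshold": self.t_threshold,
            "n_failed_fits": self.n_failed,
            "strata": {str(m): summary(v) for m, v in sorted(self.strata.items())},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def simulate_null_genotypes(n: int, maf: float, seed=None) -> np.ndarray:
    """i.i.d. Hardy-Weinberg dosages at the given MAF, independent of everything.

    P(0) = (1-p)^2, P(1) = 2p(1-p), P(2) = p^2. ``seed`` may be an int or
    a :class:`numpy.random.Generator`.
    """
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, maf, size=n).astype(np.float64)


def _stratum_rng(seed: int, maf: float, rep: int) -> np.random.Generator:
    # substream keyed by the MAF value itself (not grid position), so
    # thresholds are invariant to grid order and each stratum is
    # independently reproducible
    key = np.random.SeedSequence([int(seed), int(round(maf * 10_000)), int(rep)])
    return np.random.default_rng(key)


def estimate_thresholds(
    y: np.ndarray,
    clustering_a: ExposureClustering,
    clustering_b: ExposureClustering | None = None,
    W: np.ndarray | None = None,
    link: str = "logit",
    maf_grid=DEFAULT_MAF_GRID,
    sims_per_maf: int = 10_000,
    centile: float = 99.0,
    seed: int = 0,
) -> ThresholdTable:
    """Calibrate D (and T) thresholds by retrospective null simulation.

    For each simulated null marker, T is computed under clustering A (and
    B when given) with the real phenotype, covariates and clusterings
    held fixed; D = T_A - T_B values are pooled across the whole MAF grid
    and ``d_threshold`` is their empirical ``centile`` quantile. The
    lower (100 - centile) quantile is reported as ``d_lower``. With a
    single clustering only T is simulated and thresholded.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    if sims_per_maf < 100:
        warnings.warn("sims_per_maf < 100: quantile estimates will be unstable")
    if not 0 < centile <= 100:
        raise ValueError("centile must lie in (0, 100]")

    strata: dict[float, np.ndarray] = {}
    t_strata: dict[float, np.ndarray] = {}
    n_failed = 0
    for maf in maf_grid:
        if not 0 < maf <= 0.5:
            raise ValueError(f"MAF grid entry {maf} outside (0, 0.5]")
        d_vals = np.empty(sims_per_maf)
        t_vals = np.empty(sims_per_maf)
        failed = 0
        for rep in range(sims_per_maf):
            rng = _stratum_rng(seed, maf, rep)
            x = simulate_null_genotypes(n, float(maf), rng)
            t_a, het_a, null_a = _t_pair(y, x, clustering_a, W, link)
            ok = het_a.converged and null_a.converged
            if clustering_b is not None:
                t_b, het_b, null_b = _t_pair(y, x, clustering_b, W, link)
                ok = ok and het_b.converged and null_b.converged
                d_vals[rep] = t_a - t_b
            t_vals[rep] = t_a
            failed += 0 if ok else 1
        if failed > 0.01 * sims_per_maf:
            warnings.warn(
                f"{failed} of {sims_per_maf} null fits failed to converge at MAF {maf}"
            )
        n_failed += failed
        t_strata[float(maf)] = t_vals
        if clustering_b is not None:
            strata[float(maf)] = d_vals

    pooled_t = np.concatenate(list(t_strata.values()))
    t_threshold = float(np.quantile(pooled_t, centile / 100.0))
    if clustering_b is not None:
        pooled_d = np.concatenate(list(strata.values()))
        d_threshold = float(np.quantile(pooled_d, centile / 100.0))
        d_lower = float(np.quantile(pooled_d, 1.0 - centile / 100.0))
    else:
        d_threshold = d_lower = None
    return ThresholdTable(
        d_threshold=d_threshold,
        d_lower=d_lower,
        t_threshold=t_threshold,
        centile=float(centile),
        maf_grid=tuple(float(m) for m in maf_grid),
        sims_per_maf=int(sims_per_maf),
        seed=int(seed),
        strata=strata,
        t_strata=t_strata,
        n_failed=n_failed,
    )
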