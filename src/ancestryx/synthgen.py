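"""Structured case-control GWAS simulator with known truth.

Emulates the study design the heterogeneity test targets: two closely
related populations whose allele frequencies are differentiated under
the Balding-Nichols model (population frequencies drawn from a Beta
around an ancestral frequency, spread governed by F), genotypes in
Hardy-Weinberg proportions within population, disease risk from a
logistic model with population-specific baseline prevalence and,
optionally, population-specific odds ratios at designated causal
markers. Cases and controls are ascertained by rejection sampling to a
configured ratio, and each sample receives a cohort "collection" label
equal to its true population flipped independently with a configured
switch rate — collection disagrees with ancestry for roughly that
fraction of samples, as when two regional cohorts overlap genetically.

For efficiency only the causal genotypes are drawn inside the rejection
loop; non-causal markers are independent of disease status given the
population and are filled in afterwards, which leaves the sampling
distribution exact because markers are simulated without LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .gwas_io import GenotypeDataset


@dataclass(frozen=True)
class CausalMarker:
    """A marker with population-specific odds ratios (or linear effects)."""

    index: int
    or_by_pop: tuple[float, float]
    maf: float | None = None  # fix both population frequencies; None = Balding-Nichols

    @property
    def beta_by_pop(self) -> np.ndarray:
        return np.log(np.asarray(self.or_by_pop, dtype=np.float64))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a two-population case-control simulation.

    Defaults mimic two overlapping within-Britain cohorts: weak
    differentiation (F = 0.005 gives clear but heavily overlapping
    separation on two PCs), baseline disease prevalence 5% in both
    populations, balanced case:control ascertainment, and a collection
    label that disagrees with true ancestry for 20% of samples.
    """

    n_per_population: tuple[int, int] = (1000, 1000)
    n_markers: int = 1000
    fst: float = 0.005
    maf_bounds: tuple[float, float] = (0.05, 0.5)
    causal: tuple[CausalMarker, ...] = ()
    prevalence: tuple[float, float] = (0.05, 0.05)
    label_switch_rate: float = 0.2
    case_control_ratio: float = 1.0
    effect_on: str = "population"   # or "collection": artefact mode
    include_sex_covariate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        if not 0 <= self.label_switch_rate <= 0.5:
            raise ValueError("label_switch_rate must lie in [0, 0.5]")
        if any(c.index >= self.n_markers or c.index < 0 for c in self.causal):
            raise ValueError("causal marker index out of range")
        if self.effect_on not in ("population", "collection"):
            raise ValueError("effect_on must be 'population' or 'collection'")
        lo, hi = self.maf_bounds
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_bounds must satisfy 0 < lo <= hi <= 0.5")
        if self.case_control_ratio <= 0:
            raise ValueError("case_control_ratio must be positive")


@dataclass
class SimTruth:
    """Ground truth aligned 1:1 with the emitted dataset."""

    true_population: np.ndarray          # (N,) 0/1
    pop_freqs: np.ndarray                # (2, M) realized per-population frequencies
    ancestral_freqs: np.ndarray          # (M,)
    causal: tuple[CausalMarker, ...]
    config: SimConfig


def _balding_nichols_freqs(rng: np.random.Generator, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = cfg.maf_bounds
    p0 = rng.uniform(lo, hi, size=cfg.n_markers)
    if cfg.fst == 0:
        freqs = np.vstack([p0, p0])
    else:
        a = p0 * (1 - cfg.fst) / cfg.fst
        b = (1 - p0) * (1 - cfg.fst) / cfg.fst
        freqs = rng.beta(a, b, size=(2, cfg.n_markers))
        freqs = np.clip(freqs, 1e-6, 1 - 1e-6)
    for c in cfg.causal:
        if c.maf is not None:
            p0[c.index] = c.maf
            freqs[:, c.index] = c.maf
    return p0, freqs


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate one ascertained case-control dataset plus its ground truth.

    Per population, quotas of cases and controls implied by
    ``n_per_population`` and ``case_control_ratio`` are filled by
    rejection sampling from the population disease model; the phenotype
    depends on genotype only at the causal markers, whose effect group is
    the true population or (in artefact mode) the flipped collection
    label.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xA17]))
    p0, freqs = _balding_nichols_freqs(rng, cfg)
    return _assemble(cfg, p0, freqs, rng, id_prefix="s")


def _assemble(cfg, p0, freqs, rng, id_prefix) -> tuple[GenotypeDataset, SimTruth]:
    # split out of simulate_dataset so make_two_phase can reuse one
    # frequency draw across phases
    causal_idx = np.array([c.index for c in cfg.causal], dtype=int)
    betas = np.array([c.beta_by_pop for c in cfg.causal], dtype=np.float64)  # (C, 2)
    alphas = logit(np.asarray(cfg.prevalence))

    geno_rows, y_rows, pop_rows, coll_rows = [], [], [], []
    r = cfg.case_control_ratio
    for pop in (0, 1):
        n = cfg.n_per_population[pop]
        n_cases = int(round(n * r / (1 + r)))
        n_controls = n - n_cases
        g_c, y_c, coll_c = _reject_sample(
            rng, cfg, freqs, causal_idx, betas, alphas, pop, n_cases, n_controls
        )
        geno_rows.append(g_c)
        y_rows.append(y_c)
        coll_rows.append(coll_c)
        pop_rows.append(np.full(n, pop))

    causal_geno = np.vstack(geno_rows) if causal_idx.size else np.empty((sum(cfg.n_per_population), 0))
    y = np.concatenate(y_rows)
    pop = np.concatenate(pop_rows)
    coll = np.concatenate(coll_rows)
    N = y.size

    # non-causal genotypes: independent of status given population
    dosages = np.empty((N, cfg.n_markers), dtype=np.float64)
    noncausal = np.setdiff1d(np.arange(cfg.n_markers), causal_idx)
    for p in (0, 1):
        rows = pop == p
        dosages[np.ix_(rows, noncausal)] = rng.binomial(
            2, freqs[p, noncausal], size=(int(rows.sum()), noncausal.size)
        )
    for k, j in enumerate(causal_idx):
        dosages[:, j] = causal_geno[:, k]

    if cfg.include_sex_covariate:
        W = rng.integers(0, 2, size=(N, 1)).astype(np.float64)
        cov_names = ["sex"]
    else:
        W = np.empty((N, 0))
        cov_names = []

    order = rng.permutation(N)  # interleave populations in sample order
    pos = (np.arange(cfg.n_markers, dtype=np.int64) + 1) * 997
    ds = GenotypeDataset(
        dosages=dosages[order],
        sample_ids=np.array([f"{id_prefix}{i:06d}" for i in range(N)]),
        marker_ids=np.array([f"m{j:05d}" for j in range(cfg.n_markers)]),
        marker_chrom=np.full(cfg.n_markers, "1"),
        marker_pos=pos,
        y=y[order],
        collection=np.array(["coll_A", "coll_B"])[coll[order]],
        W=W,  # covariate drawn independently of ordering
        covariate_names=cov_names,
    )
    truth = SimTruth(
        true_population=pop[order],
        pop_freqs=freqs,
        ancestral_freqs=p0,
        causal=cfg.causal,
        config=cfg,
    )
    return ds, truth


def _reject_sample(rng, cfg, freqs, causal_idx, betas, alphas, pop, n_cases, n_controls):
    """Fill case/control quotas for one population; returns causal genotypes,
    phenotype and collection labels for the accepted individuals."""
    need = {1: n_cases, 0: n_controls}
    got_g = {1: [], 0: []}
    got_coll = {1: [], 0: []}
    batch = max(2048, 4 * (n_cases + n_controls))
    max_draws = 500 * (n_cases + n_controls) + 10_000
    drawn = 0
    while (len(got_g[1]) < need[1] or len(got_g[0]) < need[0]) and drawn < max_draws:
        g = rng.binomial(2, freqs[pop, causal_idx], size=(batch, causal_idx.size))
        flip = rng.random(batch) < cfg.label_switch_rate
        coll = np.where(flip, 1 - pop, pop)
        if cfg.effect_on == "population" or not causal_idx.size:
            eff_group = np.full(batch, pop)
        else:
            eff_group = coll
        eta = alphas[pop] + (g * betas[:, eff_group].T).sum(axis=1) if causal_idx.size else np.full(batch, alphas[pop])
        status = (rng.random(batch) < expit(eta)).astype(np.int64)
        for s in (1, 0):
            take = min(need[s] - len(got_g[s]), int((status == s).sum()))
            if take > 0:
                rows = np.flatnonzero(status == s)[:take]
                got_g[s].extend(g[rows])
                got_coll[s].extend(coll[rows])
        drawn += batch
    if len(got_g[1]) < need[1] or len(got_g[0]) < need[0]:
        raise RuntimeError(
            "could not fill case/control quotas by rejection sampling; "
            "increase n, prevalence, or the draw budget"
        )
    g_all = np.array(got_g[1] + got_g[0], dtype=np.float64).reshape(n_cases + n_controls, causal_idx.size)
    y_all = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    coll_all = np.array(got_coll[1] + got_coll[0], dtype=np.int64)
    return g_all, y_all, coll_all


def make_two_phase(
    cfg: SimConfig, cfg2: SimConfig | None = None
) -> tuple[GenotypeDataset, SimTruth, GenotypeDataset, SimTruth]:
    """Two independent sample draws sharing one marker panel and causal truth.

    Population allele frequencies are drawn once from ``cfg``; phase 2
    samples are then drawn from the same frequencies under ``cfg2``
    (defaulting to ``cfg``), whose marker panel must match and whose
    causal structure must be a restriction of phase 1's. Sample IDs are
    disjoint across phases.
    """
    if cfg2 is None:
        cfg2 = cfg
    if cfg2.n_markers != cfg.n_markers:
        raise ValueError("phase 2 marker panel must match phase 1")
    if not set(cfg2.causal) <= set(cfg.causal):
        raise ValueError("phase 2 causal structure must be a subset of phase 1's")

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xA17]))
    p0, freqs = _balding_nichols_freqs(rng, cfg)
    ds1, truth1 = _assemble(cfg, p0, freqs, np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), 1])), id_prefix="ph1_")
    ds2, truth2 = _assemble(cfg2, p0, freqs, np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(cfg2.seed), 2])), id_prefix="ph2_")
    return ds1, truth1, ds2, truth2
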