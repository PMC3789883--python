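"""Enrichment hypothesis testing: hyperparameter grids and Bayes factors.

The two-level prior couples a genome-wide log-odds theta0 (base-10) with a
log-fold enrichment theta for SNPs annotated to the candidate pathway:

    pi_j = sigmoid( log(10) * (theta0 + theta * a_j) ).

Both hyperparameters get uniform priors on discrete grids (default spacing
0.1).  The marginal likelihood at each grid point is approximated by the
variational lower bound; the Bayes factor for enrichment is the ratio of
grid-averaged likelihoods of the enriched model (theta free) and the null
(theta = 0), computed in log space.  For speed, enriched fits by default
update only the factors of annotated SNPs, holding all others at the null
solution for the same theta0 (the fixed-outside-pathway approximation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .annotate import AnnotationVector
from .data import GenotypeData, RunConfig, grid_values
from .engine import SpikeSlabPrior, VariationalState, fit_variational

logger = logging.getLogger(__name__)

__all__ = [
    "HyperGrid",
    "EnrichmentResult",
    "NullScan",
    "EnrichmentScan",
    "prior_inclusion",
    "scan_null",
    "scan_enrichment",
    "grid_marginals",
    "enrichment_bf",
    "hyper_posterior",
    "conditional_enrichment",
    "posterior_odds",
    "two_stage_fit",
    "evaluate_pathway",
]

LN10 = np.log(10.0)


def prior_inclusion(theta0: float, theta: float, a_j) -> float | np.ndarray:
    """Prior probability of inclusion under the two-level prior.

    The prior inclusion odds are 10^theta0 for SNPs outside the enriched
    pathway (a_j = 0) and 10^(theta0 + theta) inside (a_j = 1); e.g. at
    theta0 = -4 and theta = 2 these are 1:10,000 and 1:100.
    """
    a = np.asarray(a_j, dtype=np.float64)
    out = expit(LN10 * (theta0 + theta * a))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HyperGrid:
    """Discrete uniform-prior support for (theta0, theta)."""

    theta0_values: np.ndarray
    theta_values: np.ndarray

    def __post_init__(self) -> None:
        t0 = np.asarray(self.theta0_values, dtype=np.float64)
        t = np.asarray(self.theta_values, dtype=np.float64)
        object.__setattr__(self, "theta0_values", t0)
        object.__setattr__(self, "theta_values", t)
        if t0.size == 0 or t.size == 0:
            raise ValueError("hyperparameter grids must be non-empty")
        if np.any(np.diff(t0) <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("grid values must be strictly ascending")
        if np.any(t < 0):
            raise ValueError("theta grid must be non-negative "
                             "(underrepresentation is not modelled)")
        if t[0] != 0.0:
            raise ValueError("theta grid must include 0 (the null)")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "HyperGrid":
        return cls(grid_values(cfg.theta0_grid), grid_values(cfg.theta_grid))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.theta0_values.size, self.theta_values.size)


@dataclass
class NullScan:
    """Converged null-model fits along the theta0 grid."""

    theta0_values: np.ndarray
    log_marginals: np.ndarray          # (T0,)
    states: list[VariationalState]
    converged: np.ndarray              # (T0,) bool


@dataclass
class EnrichmentScan:
    """Converged enriched-model fits over the (theta0, theta) grid."""

    grid: HyperGrid
    annotation: AnnotationVector
    log_marginals: np.ndarray          # (T0, T)
    states: list[list[VariationalState]]
    converged: np.ndarray              # (T0, T) bool
    null: NullScan
    fixed_outside: bool = True


@dataclass
class EnrichmentResult:
    """Bayes factor and hyperparameter posterior for one enrichment model."""

    label: str
    log10_bf: float
    grid_loglik: np.ndarray
    posterior_weights: np.ndarray
    theta0_summary: dict
    theta_summary: dict
    null_reference: str = "no enrichment"
    n_snps: int = 0
    source_sets: tuple[str, ...] = ()
    all_converged: bool = True
    scan: EnrichmentScan | None = field(default=None, repr=False)


def scan_null(
    data: GenotypeData,
    grid: HyperGrid,
    config: RunConfig | None = None,
    mode: str = "logistic",
) -> NullScan:
    """Fit the no-enrichment model at every theta0, warm-starting each fit
    from the previous (ascending theta0)."""
    cfg = config or RunConfig()
    data.dosages = np.asfortranarray(data.dosages)  # once, for the kernels
    p = data.p
    bounds = np.empty(grid.theta0_values.size)
    states: list[VariationalState] = []
    conv = np.zeros(grid.theta0_values.size, dtype=bool)
    prev: VariationalState | None = None
    for i, t0 in enumerate(grid.theta0_values):
        pi = np.full(p, prior_inclusion(t0, 0.0, 0))
        prior = SpikeSlabPrior(sigma_a=cfg.sigma_a, pi=pi)
        st = fit_variational(
            data, prior, mode=mode, init=prev,
            tol=cfg.convergence_tol, max_iter=cfg.max_outer_iter,
        )
        if not st.converged:
            logger.warning("null fit at theta0=%.2f did not converge", t0)
        bounds[i] = st.lower_bound
        conv[i] = st.converged
        states.append(st)
        prev = st
    return NullScan(grid.theta0_values, bounds, states, conv)


def scan_enrichment(
    data: GenotypeData,
    annotation: AnnotationVector,
    grid: HyperGrid,
    null: NullScan | None = None,
    config: RunConfig | None = None,
    mode: str = "logistic",
    fixed_outside: bool = True,
    update_eta: bool | None = None,
) -> EnrichmentScan:
    """Fit the enriched model at every (theta0, theta) grid point.

    At each theta0, the theta = 0 cell coincides with the null model by
    construction and reuses its state; successive theta cells warm-start
    from the previous one.  When ``fixed_outside`` is set (the default),
    only the factors of annotated SNPs are updated, all others staying at
    the null solution for the same theta0, and — unless ``update_eta``
    overrides it — the logistic bound parameters likewise stay at the
    null solution's values (part of the same efficiency approximation;
    the objective remains a valid lower bound).
    """
    cfg = config or RunConfig()
    data.dosages = np.asfortranarray(data.dosages)
    if null is None:
        null = scan_null(data, grid, cfg, mode=mode)
    a = annotation.a
    if a.shape != (data.p,):
        raise ValueError("annotation length does not match data")
    T0, T = grid.shape
    bounds = np.empty((T0, T))
    conv = np.zeros((T0, T), dtype=bool)
    states: list[list[VariationalState]] = []
    free = a if fixed_outside else None
    if update_eta is None:
        update_eta = not fixed_outside
    upd = update_eta or mode != "logistic"
    for i, t0 in enumerate(grid.theta0_values):
        row: list[VariationalState] = []
        prev = null.states[i]
        for k, t in enumerate(grid.theta_values):
            if t == 0.0:
                st = null.states[i]
            else:
                pi = prior_inclusion(t0, t, a.astype(float))
                prior = SpikeSlabPrior(sigma_a=cfg.sigma_a, pi=pi)
                st = fit_variational(
                    data, prior, mode=mode, init=prev, free_mask=free,
                    tol=cfg.convergence_tol, max_iter=cfg.max_outer_iter,
                    update_eta=upd,
                )
                if not st.converged:
                    logger.warning(
                        "enriched fit (%s) at theta0=%.2f theta=%.2f "
                        "did not converge", annotation.label, t0, t,
                    )
            bounds[i, k] = st.lower_bound
            conv[i, k] = st.converged
            row.append(st)
            prev = st
        states.append(row)
    return EnrichmentScan(grid, annotation, bounds, states, conv, null,
                          fixed_outside)


def grid_marginals(
    data: GenotypeData,
    annotation: AnnotationVector | None,
    grid: HyperGrid,
    config: RunConfig | None = None,
    fixed_outside: bool = True,
    mode: str = "logistic",
    null: NullScan | None = None,
) -> np.ndarray:
    """Matrix of variational log marginal likelihoods over the grid.

    With ``annotation=None`` (the null model, which has no theta) the
    theta0-indexed vector is replicated across the theta axis.
    """
    if annotation is None:
        ns = null or scan_null(data, grid, config, mode=mode)
        return np.tile(ns.log_marginals[:, None], (1, grid.theta_values.size))
    return scan_enrichment(
        data, annotation, grid, null=null, config=config, mode=mode,
        fixed_outside=fixed_outside,
    ).log_marginals


def _log_mean_exp(logv: np.ndarray) -> float:
    logv = np.asarray(logv, dtype=np.float64).ravel()
    ok = ~np.isnan(logv)
    if not ok.any():
        raise ValueError("all grid cells are NaN")
    return float(logsumexp(logv[ok]) - np.log(ok.sum()))


def enrichment_bf(grid_null: np.ndarray, grid_enriched: np.ndarray) -> float:
    """log10 Bayes factor for enrichment.

    Uniform-weight average of exponentiated bounds over the enriched
    (theta0, theta) grid, divided by the average over the null theta0
    grid; evaluated in log space with log-sum-exp.  NaN cells (hard
    non-convergence) are excluded from the averages.
    """
    return (_log_mean_exp(grid_enriched) - _log_mean_exp(grid_null)) / LN10


def _smallest_ci(values: np.ndarray, probs: np.ndarray, mean: float,
                 mass: float = 0.95) -> tuple[float, float]:
    """Smallest contiguous grid interval about the mean holding >= mass."""
    m = values.size
    best = None
    for i in range(m):
        for j in range(i, m):
            if values[i] - 1e-12 <= mean <= values[j] + 1e-12:
                if probs[i:j + 1].sum() >= mass - 1e-12:
                    width = values[j] - values[i]
                    if best is None or width < best[0]:
                        best = (width, values[i], values[j])
                    break
    if best is None:  # numerical fallback: whole grid
        best = (values[-1] - values[0], values[0], values[-1])
    return round(best[1], 1), round(best[2], 1)


def _summary(values: np.ndarray, probs: np.ndarray) -> dict:
    mean = float(values @ probs)
    lo, hi = _smallest_ci(values, probs, mean)
    return {"mean": mean, "ci95_lo": lo, "ci95_hi": hi}


def hyper_posterior(grid_loglik: np.ndarray, grid: HyperGrid
                    ) -> tuple[np.ndarray, dict, dict]:
    """Posterior weights over the grid plus theta0/theta summaries.

    Weights are proportional to exp(lower bound) times the uniform grid
    prior.  Summaries give the posterior mean and the smallest 95%
    credible interval on the grid, endpoints reported to the nearest 0.1.
    """
    L = np.asarray(grid_loglik, dtype=np.float64)
    if L.ndim == 1:
        L = L[:, None]
    finite = ~np.isnan(L)
    logw = np.where(finite, L, -np.inf)
    logw = logw - logsumexp(logw)
    w = np.exp(logw)
    w /= w.sum()
    t0_marg = w.sum(axis=1)
    t_marg = w.sum(axis=0)
    theta0_summary = _summary(grid.theta0_values[: L.shape[0]], t0_marg)
    if L.shape[1] == grid.theta_values.size:
        theta_summary = _summary(grid.theta_values, t_marg)
    else:  # single-theta (e.g. fixed-MAP) column
        theta_summary = {"mean": float("nan"), "ci95_lo": float("nan"),
                         "ci95_hi": float("nan")}
    return w, theta0_summary, theta_summary


def posterior_odds(log10_bf: float, prior_odds: float) -> float:
    """Posterior probability of enrichment given prior odds for it."""
    if prior_odds <= 0:
        raise ValueError("prior odds must be positive")
    log_po = log10_bf * LN10 + np.log(prior_odds)
    return float(expit(log_po))


def evaluate_pathway(
    data: GenotypeData,
    annotation: AnnotationVector,
    grid: HyperGrid,
    null: NullScan | None = None,
    config: RunConfig | None = None,
    mode: str = "logistic",
    fixed_outside: bool = True,
    keep_scan: bool = False,
) -> EnrichmentResult:
    """Score one enrichment hypothesis end to end: scan the grid, form the
    BF against the no-enrichment null, and summarize the hyperposterior."""
    cfg = config or RunConfig()
    if null is None:
        null = scan_null(data, grid, cfg, mode=mode)
    scan = scan_enrichment(data, annotation, grid, null=null, config=cfg,
                           mode=mode, fixed_outside=fixed_outside)
    bf = enrichment_bf(null.log_marginals, scan.log_marginals)
    w, s0, s1 = hyper_posterior(scan.log_marginals, grid)
    return EnrichmentResult(
        label=annotation.label,
        log10_bf=bf,
        grid_loglik=scan.log_marginals,
        posterior_weights=w,
        theta0_summary=s0,
        theta_summary=s1,
        null_reference="no enrichment",
        n_snps=annotation.n_snps_in,
        source_sets=annotation.source_sets,
        all_converged=bool(scan.converged.all() and null.converged.all()),
        scan=scan if keep_scan else None,
    )


def two_stage_fit(
    data: GenotypeData,
    prior: SpikeSlabPrior,
    region_mask: np.ndarray,
    mode: str = "logistic",
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> VariationalState:
    """Two-stage fit for a dominant region (the extended MHC).

    Stage 1 fits the model using only SNPs outside the region (the region's
    factors pinned to exclusion), so large-effect region SNPs cannot mask
    associations elsewhere; stage 2 fits the region's SNPs holding the
    outside factors fixed at their stage-1 values.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    p = data.p
    if region_mask.shape != (p,):
        raise ValueError("region mask length mismatch")
    if region_mask.all() or not region_mask.any():
        raise ValueError("region mask must be a proper, non-empty subset")
    zero = VariationalState(
        alpha=np.where(region_mask, 0.0, prior.pi),
        mu=np.zeros(p),
        s2=np.full(p, prior.sigma_a ** 2),
        intercept=0.0,
        eta=None,
        lower_bound=-np.inf,
    )
    stage1 = fit_variational(
        data, prior, mode=mode, init=zero, free_mask=~region_mask,
        tol=tol, max_iter=max_iter,
    )
    st = stage1.copy()
    st.alpha[region_mask] = prior.pi[region_mask]
    st.mu[region_mask] = 0.0
    stage2 = fit_variational(
        data, prior, mode=mode, init=st, free_mask=region_mask,
        tol=tol, max_iter=max_iter,
    )
    return stage2


def conditional_enrichment(
    data: GenotypeData,
    base_annotation: AnnotationVector,
    candidate_annotation: AnnotationVector,
    grid: HyperGrid,
    config: RunConfig | None = None,
    mode: str = "logistic",
    base_scan: EnrichmentScan | None = None,
) -> EnrichmentResult:
    """Enrichment of a candidate pathway conditional on a base region
    (e.g. the MHC) already being enriched.

    The base enrichment parameter is fixed at its maximum a posteriori
    grid value (ties broken toward smaller theta); the null is the
    base-only model, so the reported BF compares {base at MAP + candidate
    enriched} against {base at MAP}.  Candidate SNPs falling inside the
    base annotation keep the base enrichment level and are excluded from
    the candidate's free set.
    """
    cfg = config or RunConfig()
    if base_scan is None:
        base_scan = scan_enrichment(data, base_annotation, grid, config=cfg,
                                    mode=mode)
    _, _, theta_summary = hyper_posterior(base_scan.log_marginals, grid)
    t_marg = np.exp(
        base_scan.log_marginals - logsumexp(base_scan.log_marginals)
    ).sum(axis=0)
    k_map = int(np.flatnonzero(t_marg == t_marg.max())[0])
    theta_map = float(grid.theta_values[k_map])

    base = base_annotation.a
    cand = candidate_annotation.a & ~base
    overlap = int((candidate_annotation.a & base).sum())
    if overlap:
        logger.info(
            "%d candidate SNP(s) lie inside the base region and keep the "
            "base enrichment level", overlap,
        )
    if not cand.any():
        raise ValueError(
            "candidate annotation is entirely contained in the base region; "
            "no free SNPs to test"
        )

    # base-only reference states/bounds at theta_base = MAP, one per theta0
    base_states = [row[k_map] for row in base_scan.states]
    base_bounds = base_scan.log_marginals[:, k_map]

    T0, T = grid.shape
    bounds = np.empty((T0, T))
    conv = np.zeros((T0, T), dtype=bool)
    states: list[list[VariationalState]] = []
    for i, t0 in enumerate(grid.theta0_values):
        row: list[VariationalState] = []
        prev = base_states[i]
        for k, t in enumerate(grid.theta_values):
            if t == 0.0:
                st = base_states[i]
            else:
                loglevel = t0 + theta_map * base.astype(float) \
                    + t * cand.astype(float)
                pi = expit(LN10 * loglevel)
                prior = SpikeSlabPrior(sigma_a=cfg.sigma_a, pi=pi)
                st = fit_variational(
                    data, prior, mode=mode, init=prev, free_mask=cand,
                    tol=cfg.convergence_tol, max_iter=cfg.max_outer_iter,
                    update_eta=(mode != "logistic"),
                )
            bounds[i, k] = st.lower_bound
            conv[i, k] = st.converged
            row.append(st)
            prev = st
        states.append(row)

    bf = enrichment_bf(base_bounds, bounds)
    w, s0, s1 = hyper_posterior(bounds, grid)
    return EnrichmentResult(
        label=candidate_annotation.label,
        log10_bf=bf,
        grid_loglik=bounds,
        posterior_weights=w,
        theta0_summary=s0,
        theta_summary=s1,
        null_reference=(
            f"{base_annotation.label} enriched at theta={theta_map:g} (MAP)"
        ),
        n_snps=int(cand.sum()),
        source_sets=candidate_annotation.source_sets,
        all_converged=bool(conv.all()),
    )
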