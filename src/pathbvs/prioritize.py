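"""Enrichment-informed association evidence.

Posterior inclusion probabilities (PIPs) are averaged over the
hyperparameter grid with the grid's posterior weights, and optionally
over several enrichment models weighted by their Bayes factors.  Regional
evidence is summarized over overlapping 50-SNP segments (25-SNP overlap)
by the probability that at least n SNPs in the segment are included —
a Poisson-binomial tail that is exact under the factorized variational
posterior.  Effect sizes given inclusion are summarized by the
weight-alpha mixture of per-cell conditional normals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .data import SnpMap
from .engine import VariationalState

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "RegionStats",
    "averaged_pips",
    "model_averaged_pips",
    "make_segments",
    "segment_inclusion_probs",
    "expected_included",
    "effect_summary",
    "segment_scan",
]


@dataclass(frozen=True)
class Segment:
    """A contiguous run of SNP indices on one chromosome (inclusive)."""

    chromosome: str
    start_index: int
    end_index: int

    @property
    def n_snps(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start_index, self.end_index + 1)


@dataclass
class RegionStats:
    segment: Segment
    p_ge1: float
    p_ge2: float
    top_snp_id: str
    top_pip: float
    effect_mean: float | None = None
    effect_ci95: tuple[float, float] | None = None


def _check_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=np.float64).ravel()
    if abs(w.sum() - 1.0) > 1e-8 or np.any(w < 0):
        raise ValueError("grid posterior weights must be non-negative and "
                         "sum to 1")
    return w


def _states_alphas(grid_states) -> np.ndarray:
    """Stack per-cell alpha vectors into a (cells, p) matrix."""
    flat = []
    for item in grid_states:
        if isinstance(item, VariationalState):
            flat.append(item.alpha)
        elif isinstance(item, np.ndarray) and item.ndim == 1:
            flat.append(item)
        else:
            flat.extend(
                s.alpha if isinstance(s, VariationalState) else s
                for s in item
            )
    return np.vstack(flat)


def averaged_pips(grid_states, posterior_weights) -> np.ndarray:
    """PIP_j = sum over grid cells of w_cell * alpha_j(cell)."""
    A = _states_alphas(grid_states)
    w = _check_weights(posterior_weights)
    if w.size != A.shape[0]:
        raise ValueError(
            f"{A.shape[0]} states but {w.size} weights"
        )
    return w @ A


def model_averaged_pips(models: list[dict]) -> np.ndarray:
    """BF-weighted average of PIPs across enrichment models.

    Each model is a mapping with keys ``log10_bf`` and ``pips``; weights
    proportional to the BFs are formed in log space for stability.
    """
    if not models:
        raise ValueError("need at least one model")
    logbf = np.array([m["log10_bf"] for m in models], dtype=np.float64) \
        * np.log(10.0)
    if not np.all(np.isfinite(logbf)):
        raise ValueError("Bayes factors must be finite")
    logw = logbf - logsumexp(logbf)
    w = np.exp(logw)
    P = np.vstack([np.asarray(m["pips"], dtype=np.float64) for m in models])
    return w @ P


def make_segments(snp_map: SnpMap, size: int = 50, overlap: int = 25
                  ) -> list[Segment]:
    """Overlapping fixed-size segments covering every SNP.

    Per chromosome, segments start at offsets 0, size-overlap,
    2(size-overlap), ...; the final segment is anchored at the chromosome
    end (length <= size) so that no SNP is uncovered.  A chromosome with
    fewer than ``size`` SNPs becomes a single whole-chromosome segment.
    """
    if not (0 <= overlap < size):
        raise ValueError("require 0 <= overlap < size")
    step = size - overlap
    segments: list[Segment] = []
    chroms = snp_map.chromosomes
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        lo, hi = int(idx[0]), int(idx[-1])
        m = hi - lo + 1
        if m < size:
            logger.info("chromosome %s has %d < %d SNPs; single segment",
                        chrom, m, size)
            segments.append(Segment(str(chrom), lo, hi))
            continue
        start = lo
        while True:
            end = start + size - 1
            if end >= hi:
                segments.append(Segment(str(chrom), hi - size + 1, hi))
                break
            segments.append(Segment(str(chrom), start, end))
            start += step
    return segments


def _poisson_binomial_tail(probs: np.ndarray, n: int) -> float:
    """P(at least n successes) for independent Bernoulli(probs) by a
    stable dynamic program over P(0), ..., P(n-1) successes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = np.asarray(probs, dtype=np.float64)
    k = min(n - 1, probs.size)
    # state[c] = P(exactly c successes so far), c = 0..k
    state = np.zeros(k + 1)
    state[0] = 1.0
    for q in probs:
        upper = state[:k] * q
        state *= 1.0 - q
        state[1:k + 1] += upper
    if probs.size < n:
        return 0.0
    return float(max(0.0, 1.0 - state.sum()))


def segment_inclusion_probs(pips_or_alphas, segment: Segment | np.ndarray,
                            n: int = 1, weights=None) -> float:
    """P(E >= n): posterior probability that at least n SNPs in the
    segment are included.

    Under the factorized variational posterior the segment's inclusion
    indicators are independent, so the tail is Poisson-binomial in the
    alphas.  When a list of per-cell alpha vectors and matching
    ``weights`` are supplied, the tail is computed per cell and then
    averaged with those weights (the same averaging as the PIPs).
    """
    idx = segment.indices if isinstance(segment, Segment) \
        else np.asarray(segment)
    if weights is not None:
        A = _states_alphas(pips_or_alphas)
        w = _check_weights(weights)
        vals = np.array(
            [_poisson_binomial_tail(A[c, idx], n) for c in range(A.shape[0])]
        )
        return float(w @ vals)
    probs = np.asarray(pips_or_alphas, dtype=np.float64)[idx]
    return _poisson_binomial_tail(probs, n)


def expected_included(annotation, theta0: float, theta: float = 0.0,
                      small_odds: bool = False) -> float:
    """A-priori expected number of included SNPs in a pathway.

    ``annotation`` is an AnnotationVector (its member SNPs are counted)
    or a plain SNP count; each member SNP has prior inclusion probability
    sigmoid(log(10) (theta0 + theta)), or 10^(theta0 + theta) under the
    small-odds approximation — e.g. 440,000 SNPs at theta0 = -2 give
    ~4,400 expected inclusions.
    """
    n_snps = annotation if isinstance(annotation, (int, np.integer)) \
        else annotation.n_snps_in
    if n_snps <= 0:
        raise ValueError("SNP count must be positive")
    if small_odds:
        pi = 10.0 ** (theta0 + theta)
    else:
        from .enrichment import prior_inclusion
        pi = prior_inclusion(theta0, theta, 1.0)
    return float(n_snps * pi)


def _mixture_cdf(x: float, w: np.ndarray, mu: np.ndarray, sd: np.ndarray
                 ) -> float:
    return float(w @ norm.cdf((x - mu) / sd))


def _mixture_quantile(q: float, w, mu, sd, tol: float = 1e-6) -> float:
    lo = float(np.min(mu - 10 * sd))
    hi = float(np.max(mu + 10 * sd))
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _mixture_cdf(mid, w, mu, sd) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def effect_summary(grid_states, weights, snp_index: int,
                   mass: float = 0.95, tol: float = 1e-6) -> dict:
    """Posterior mean and smallest 95% interval of beta_j given inclusion.

    The conditional posterior is approximated by the mixture over grid
    cells of N(mu_j, s2_j) with mixture weights proportional to
    w_cell * alpha_j(cell); the interval is found by bisection on the
    mixture CDF, minimizing width over the lower tail mass.
    """
    w = _check_weights(weights)
    mus, sds, mix = [], [], []
    flat_states: list[VariationalState] = []
    for item in grid_states:
        if isinstance(item, VariationalState):
            flat_states.append(item)
        else:
            flat_states.extend(item)
    if len(flat_states) != w.size:
        raise ValueError("number of states does not match weights")
    for wc, st in zip(w, flat_states):
        mus.append(st.mu[snp_index])
        sds.append(np.sqrt(st.s2[snp_index]))
        mix.append(wc * st.alpha[snp_index])
    mix = np.asarray(mix)
    if mix.sum() <= 0:
        raise ValueError(
            f"SNP {snp_index} has zero posterior inclusion probability; "
            "conditional effect undefined"
        )
    mix = mix / mix.sum()
    mus = np.asarray(mus)
    sds = np.maximum(np.asarray(sds), 1e-12)
    mean = float(mix @ mus)

    # smallest interval: minimize q(t + mass) - q(t) over t in [0, 1-mass];
    # coarse grid, then local refinement around the best tail mass
    def interval(t):
        lo = _mixture_quantile(max(t, 1e-12), mix, mus, sds, tol)
        hi = _mixture_quantile(min(t + mass, 1 - 1e-12), mix, mus, sds, tol)
        return hi - lo, lo, hi

    ts = np.linspace(0.0, 1.0 - mass, 41)
    widths = [interval(t) for t in ts]
    k = int(np.argmin([w[0] for w in widths]))
    best = widths[k]
    lo_t = ts[max(k - 1, 0)]
    hi_t = ts[min(k + 1, len(ts) - 1)]
    for t in np.linspace(lo_t, hi_t, 65):
        cand = interval(t)
        if cand[0] < best[0]:
            best = cand
    return {"mean": mean, "ci95": (best[1], best[2])}


def segment_scan(
    snp_map: SnpMap,
    pips_null: np.ndarray,
    pips_enriched: np.ndarray | None = None,
    states_null=None,
    weights_null=None,
    states_enriched=None,
    weights_enriched=None,
    size: int = 50,
    overlap: int = 25,
) -> pd.DataFrame:
    """Genome scan table: per segment, P(E>=1) and P(E>=2) under the null
    and (optionally) the enriched model, plus the top SNP and its PIP."""
    segments = make_segments(snp_map, size, overlap)
    rows = []
    pos = snp_map.positions
    ids = snp_map.snp_ids
    for seg in segments:
        idx = seg.indices
        pips = pips_enriched if pips_enriched is not None else pips_null
        top = idx[int(np.argmax(pips[idx]))]

        def tail(n, states, weights, fallback):
            if states is not None:
                return segment_inclusion_probs(states, seg, n,
                                               weights=weights)
            return segment_inclusion_probs(fallback, seg, n)

        row = {
            "chromosome": seg.chromosome,
            "start_bp": int(pos[seg.start_index]),
            "end_bp": int(pos[seg.end_index]),
            "n_snps": seg.n_snps,
            "p_ge1_null": tail(1, states_null, weights_null, pips_null),
            "p_ge2_null": tail(2, states_null, weights_null, pips_null),
            "top_snp": ids[top],
            "top_pip": float(pips[top]),
        }
        if pips_enriched is not None:
            row["p_ge1_enriched"] = tail(1, states_enriched,
                                         weights_enriched, pips_enriched)
            row["p_ge2_enriched"] = tail(2, states_enriched,
                                         weights_enriched, pips_enriched)
        rows.append(row)
    return pd.DataFrame(rows)
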