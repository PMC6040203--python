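"""Macro- and micro-inference under a fitted DS prior.

The LP-corrected Bayes objects inherit the pleasant "parametric answer
times a correction factor" structure of the conjugate model:

* marginal:   f_LP(y) = f_G(y) * (1 + sum_j c_j E_G[T_j | y])
* posterior:  pi_LP(theta|y) = pi_G(theta|y) (1 + sum_j c_j T_j(theta)) /
              (1 + sum_j c_j E_G[T_j | y])
* posterior mean of h:  (E_G[h|y] + sum_j c_j E_G[h T_j|y]) /
              (1 + sum_j c_j E_G[T_j|y])

Micro-inference compares three per-study estimates: the isolated MLE,
Stein's parametric empirical Bayes shrinkage (the conjugate posterior
mean, pulling toward the overall prior mean), and the Elastic-Bayes
estimate -- the h = theta specialisation above -- which shrinks
*selectively* toward whichever mode of the corrected prior the study
resembles.  Robbins' prior-free formula (y+1) f(y+1)/f(y) for Poisson
counts is included as the classical nonparametric reference.

Macro-inference summarises all studies at once: the prior mean when the
fitted prior is unimodal, its modes (with smooth-bootstrap standard
errors) when it is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2

from .ds_prior import DSPrior, find_modes
from .estimation import mom2_fit
from .families import (
    ConjugateFamily,
    StudyData,
    marginal_fG,
    posterior_G,
    posterior_basis_moments,
)
from .lp_basis import leg_matrix

__all__ = [
    "PosteriorSummary",
    "MacroSummary",
    "marginal_lp",
    "posterior_lp",
    "posterior_mean_lp",
    "posterior_summary",
    "micro_table",
    "stein_peb",
    "elastic_bayes",
    "robbins",
    "macro_summary",
    "group_studies",
]


def _correction_terms(y, exposure, prior: DSPrior, h: Callable | None = None,
                      nodes: int = 128):
    """(denominator, numerator pieces) shared by the LP-Bayes formulas."""
    if prior.m == 0:
        return 1.0, None, None
    t, _, hvec, h0 = posterior_basis_moments(
        y, exposure, prior.family, prior.m, nodes=nodes, h=h
    )
    denom = 1.0 + float(prior.coef @ t)
    return denom, (hvec, h0), t


def marginal_lp(y, exposure=None, prior: DSPrior = None, nodes: int = 128) -> float:
    """LP-corrected marginal f_LP(y); reduces to f_G when no correction."""
    denom, _, _ = _correction_terms(y, exposure, prior, nodes=nodes)
    if denom < 0:
        warnings.warn(f"negative corrected marginal at y={y}", RuntimeWarning,
                      stacklevel=2)
    return marginal_fG(y, exposure, prior.family) * denom


def posterior_lp(theta, y, exposure=None, prior: DSPrior = None,
                 nodes: int = 128):
    """LP-corrected posterior density pi_LP(theta | y)."""
    denom, _, _ = _correction_terms(y, exposure, prior, nodes=nodes)
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("degenerate prior-data pair: corrected marginal is 0")
    base = posterior_G(y, exposure, prior.family).pdf(theta)
    if prior.m == 0:
        return base
    u = prior.family.cdf(theta)
    bracket = 1.0 + prior.coef @ leg_matrix(prior.m, u)
    out = np.asarray(base * np.asarray(bracket) / denom)
    return float(out.ravel()[0]) if np.ndim(theta) == 0 else out


def posterior_mean_lp(h: Callable | None, y, exposure=None, prior: DSPrior = None,
                      nodes: int = 128) -> float:
    """LP-corrected posterior expectation of h(Theta); h=None means identity."""
    if h is None:
        h = lambda t: t
    denom, pieces, _ = _correction_terms(y, exposure, prior, h=h, nodes=nodes)
    if prior.m == 0:
        from .families import posterior_expect_hT

        return posterior_expect_hT(h, 0, y, exposure, prior.family, nodes=nodes)
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("degenerate prior-data pair: corrected marginal is 0")
    hvec, h0 = pieces
    return (h0 + float(prior.coef @ hvec)) / denom


def stein_peb(y, exposure=None, family: ConjugateFamily = None) -> float:
    """Stein's parametric empirical-Bayes estimate: the conjugate posterior mean.

    Binomial: a weighted average of y/n and the prior mean a/(a+b) with
    weight n/(a+b+n) on the data.  Poisson: (y + a)/(1/b + 1).  Normal:
    lam*mu + (1-lam)*y.  Exponential: (a+1) b/(1+b y).
    """
    return float(posterior_G(y, exposure, family).mean())


def elastic_bayes(y, exposure=None, prior: DSPrior = None, nodes: int = 128) -> float:
    """The Elastic-Bayes estimate: LP-corrected posterior mean of Theta.

    Equals :func:`stein_peb` when the correction vanishes; otherwise the
    LP terms re-aim the shrinkage toward the relevant prior mode.
    """
    if prior.m == 0 or not np.any(prior.coef):
        return stein_peb(y, exposure, prior.family)
    return posterior_mean_lp(None, y, exposure, prior, nodes=nodes)


def robbins(y: int, freq_table: Sequence[int]) -> float | None:
    """Robbins' prior-free Poisson estimate (y+1) N_{y+1} / N_y.

    ``freq_table[i]`` is the number of observations equal to i.  Returns
    ``None`` (undefined) when y+1 falls outside the table or N_y = 0.
    """
    freq = np.asarray(freq_table, dtype=float)
    if np.any(freq < 0):
        raise ValueError("frequencies must be nonnegative")
    if y < 0 or y >= len(freq) - 1:
        return None
    if freq[y] == 0:
        return None
    return float((y + 1) * freq[y + 1] / freq[y])


# ---------------------------------------------------------------------
# micro-inference table
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-study estimates under the three inference routes."""

    study_index: int
    y: float
    exposure: float | None
    mle: float
    peb_mean: float
    ds_mean: float
    ds_median: float
    ds_mode: float


def _posterior_grid(y, exposure, prior: DSPrior, n: int = 2001):
    lo, hi = prior.family.support
    post = posterior_G(y, exposure, prior.family)
    if not np.isfinite(lo):
        lo = post.ppf(1e-6)
    if not np.isfinite(hi):
        hi = post.ppf(1 - 1e-6)
    grid = np.linspace(lo, hi, n)
    dens = posterior_lp(grid, y, exposure, prior)
    return grid, np.asarray(dens)


def posterior_summary(study_index: int, y, exposure, prior: DSPrior) -> PosteriorSummary:
    """All per-study summaries for one observation."""
    fam = prior.family
    if fam.family_id == "binomial":
        mle = y / exposure
    else:
        mle = float(y)
    grid, dens = _posterior_grid(y, exposure, prior)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    median = float(np.interp(0.5, cdf, grid))
    i = int(np.argmax(dens))
    h = grid[1] - grid[0]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda t: -posterior_lp(float(t), y, exposure, prior),
        bounds=(max(grid[0], grid[i] - h), min(grid[-1], grid[i] + h)),
        method="bounded",
    )
    return PosteriorSummary(
        study_index=study_index,
        y=float(y),
        exposure=None if exposure is None else float(exposure),
        mle=float(mle),
        peb_mean=stein_peb(y, exposure, fam),
        ds_mean=elastic_bayes(y, exposure, prior),
        ds_median=median,
        ds_mode=float(res.x),
    )


def micro_table(data: StudyData, prior: DSPrior) -> pd.DataFrame:
    """Per-study estimate table (one row per study) as a DataFrame."""
    rows = []
    cache: dict[tuple, PosteriorSummary] = {}
    for i in range(data.k):
        expo = None if data.exposure is None else data.exposure[i]
        key = (data.y[i], expo)
        if key not in cache:
            cache[key] = posterior_summary(i, data.y[i], expo, prior)
        s = cache[key]
        rows.append(
            {
                "study": i,
                "y": s.y,
                "exposure": s.exposure,
                "mle": s.mle,
                "peb_mean": s.peb_mean,
                "ds_mean": s.ds_mean,
                "ds_median": s.ds_median,
                "ds_mode": s.ds_mode,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# macro-inference
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class MacroSummary:
    """Pooled summary of the study population."""

    prior_mean: float
    pooled_naive: float | None
    modes: list[float]
    mode_se: list[float]
    bootstrap_B: int
    seed: int | None
    boundary_only: bool = False
    n_matched: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "prior_mean": self.prior_mean,
            "pooled_naive": self.pooled_naive,
            "modes": self.modes,
            "mode_se": self.mode_se,
            "bootstrap_B": self.bootstrap_B,
            "seed": self.seed,
            "boundary_only": self.boundary_only,
            "n_matched": self.n_matched,
        }


def macro_summary(
    data: StudyData,
    prior: DSPrior,
    B: int = 200,
    seed: int | None = None,
    m_max: int | None = None,
) -> MacroSummary:
    """Consensus summary with smooth-bootstrap mode standard errors.

    Each bootstrap replicate redraws study effects from the fitted prior,
    regenerates observations with the original exposures, re-runs the
    full coefficient fit, and relocates the modes; replicate modes are
    matched to the original ones by nearest location (within half the
    original inter-mode gap) and the SE of each mode is the standard
    deviation of its matched locations.
    """
    fam = prior.family
    if m_max is None:
        m_max = prior.m if prior.m > 0 else 8
    modes, boundary = find_modes(prior)
    mode_locs = [m[0] for m in modes]
    if fam.family_id == "binomial":
        pooled = float(np.sum(data.y) / np.sum(data.exposure))
    elif fam.family_id == "normal":
        w = 1.0 / data.exposure**2
        pooled = float(np.sum(w * data.y) / np.sum(w))
    else:
        pooled = float(np.mean(data.y))

    mode_se: list[float] = []
    matched_counts: list[int] = []
    if B > 0 and mode_locs:
        if len(mode_locs) > 1:
            half_gap = 0.5 * min(np.diff(mode_locs))
        else:
            half_gap = np.inf
        rng = np.random.default_rng(seed)
        matched = [[] for _ in mode_locs]
        from .datasets import simulate_ds

        for _ in range(B):
            rep_seed = int(rng.integers(2**31))
            rep = simulate_ds(prior, data.k, data.exposure, seed=rep_seed)
            try:
                fit = mom2_fit(rep, fam, m_max=m_max)
            except (RuntimeError, ValueError):
                continue
            rep_modes, _ = find_modes(fit.prior)
            for loc, _dens in rep_modes:
                dists = np.abs(np.asarray(mode_locs) - loc)
                i = int(np.argmin(dists))
                if dists[i] <= half_gap:
                    matched[i].append(loc)
        for locs in matched:
            mode_se.append(float(np.std(locs, ddof=1)) if len(locs) > 1 else float("nan"))
            matched_counts.append(len(locs))
    else:
        mode_se = [float("nan")] * len(mode_locs)
        matched_counts = [0] * len(mode_locs)

    return MacroSummary(
        prior_mean=prior.prior_mean(),
        pooled_naive=pooled,
        modes=mode_locs,
        mode_se=mode_se,
        bootstrap_B=B,
        seed=seed,
        boundary_only=boundary,
        n_matched=matched_counts,
    )


def group_studies(summaries, n_groups: int = 2, seed: int | None = None,
                  n_restarts: int = 10) -> np.ndarray:
    """K-means partition of studies on their posterior-mode estimates.

    ``summaries`` is a DataFrame from :func:`micro_table` or a sequence
    of :class:`PosteriorSummary`.  Labels are relabelled by ascending
    cluster centroid, so group 0 is the lowest-mode cluster.
    """
    if isinstance(summaries, pd.DataFrame):
        values = summaries["ds_mode"].to_numpy(dtype=float)
    else:
        values = np.array([s.ds_mode for s in summaries], dtype=float)
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > len(values):
        raise ValueError("more groups than studies")
    if np.ptp(values) == 0:
        return np.zeros(len(values), dtype=int)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centroids, labels = kmeans2(values[:, None], n_groups, minit="++",
                                    seed=rng.integers(2**31))
        inertia = float(np.sum((values - centroids[labels, 0]) ** 2))
        if best is None or inertia < best[0]:
            best = (inertia, centroids[:, 0], labels)
    _, centroids, labels = best
    order = np.argsort(centroids)
    remap = np.empty_like(order)
    remap[order] = np.arange(n_groups)
    return remap[labels]
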