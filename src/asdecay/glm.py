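"""Binomial logit-linear model of the allelic ratio over time.

The decay model assumes each allele's transcript pool decays exponentially,
N_i(t) = N_i(0) exp(-lambda_i t), and that allele-assignable read counts are
Poisson with a shared capture fraction f(t).  Conditional on the total count
at a timepoint, the allele-1 count is then binomial with

    logit p(t) = log(N1(0)/N2(0)) - (lambda1 - lambda2) * t = alpha + beta*t,

so the slope of a two-parameter logistic regression on time identifies the
decay-rate difference (delta_lambda = lambda1 - lambda2 = -beta).  f(t)
cancels in the conditioning, which is why only the difference is identified.

Because every observation cell shares one of a handful of timepoints, the
binomial log-likelihood depends on the data only through per-timepoint sums
of allele-1 counts and totals.  The solver below exploits that: it takes
aggregated (successes, trials) per timepoint and runs a damped Newton/IRLS
iteration vectorised across many independent fits at once, which is what
makes 5,000-resample bootstraps per gene affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, xlogy

# |linear predictor| cap: beyond this the likelihood is flat to double
# precision and the fit is effectively separated.
_ETA_MAX = 35.0
_COEF_CLIP = 50.0


@dataclass(frozen=True)
class DecayFit:
    """MLE of the logit-linear allelic-ratio model for one gene/replicate.

    ``alpha`` is the intercept (log allelic ratio at t=0), ``beta`` the slope
    per hour, and ``delta_lambda = -beta`` the decay-rate difference
    lambda1 - lambda2 (positive = allele 1 decays faster).
    """

    alpha: float
    beta: float
    converged: bool
    n_iter: int
    n_obs: int

    @property
    def delta_lambda(self) -> float:
        return -self.beta


def _loglik(a, b, t, S, N):
    eta = np.clip(a[:, None] + b[:, None] * t, -_ETA_MAX, _ETA_MAX)
    # S*eta - N*log(1+exp(eta)), stable via logaddexp
    return (S * eta - N * np.logaddexp(0.0, eta)).sum(axis=1)


def fit_binomial_logit_many(
    S: np.ndarray,
    N: np.ndarray,
    t: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
    coef_clip: float = _COEF_CLIP,
):
    """Fit m independent 2-parameter binomial logit models.

    Parameters
    ----------
    S, N : (m, T) arrays
        Per-timepoint allele-1 counts and totals (already summed over SNP
        loci, possibly with resampling weights folded in).
    t : (T,) array of timepoints in hours.

    Returns
    -------
    alpha, beta : (m,) arrays
    converged : (m,) bool array
        False where the deviance did not stabilise within ``max_iter``
        Newton steps or a coefficient hit the separation clip.
    n_iter : int, Newton steps taken.
    """
    S = np.asarray(S, dtype=float)
    N = np.asarray(N, dtype=float)
    t = np.asarray(t, dtype=float)
    if S.ndim == 1:
        S = S[None, :]
        N = N[None, :]
    m = S.shape[0]

    a = np.zeros(m)
    b = np.zeros(m)
    ll = _loglik(a, b, t, S, N)
    converged = np.zeros(m, dtype=bool)
    n_iter = 0
    for it in range(max_iter):
        eta = np.clip(a[:, None] + b[:, None] * t, -_ETA_MAX, _ETA_MAX)
        mu = expit(eta)
        resid = S - N * mu
        ga = resid.sum(axis=1)
        gb = (resid * t).sum(axis=1)
        w = N * mu * (1.0 - mu)
        h00 = w.sum(axis=1)
        h01 = (w * t).sum(axis=1)
        h11 = (w * t * t).sum(axis=1)
        det = h00 * h11 - h01 * h01
        ok = det > np.finfo(float).tiny
        da = np.where(ok, (h11 * ga - h01 * gb) / np.where(ok, det, 1.0), 0.0)
        db = np.where(ok, (h00 * gb - h01 * ga) / np.where(ok, det, 1.0), 0.0)

        # damped step: halve until the likelihood does not decrease
        step = np.ones(m)
        for _ in range(25):
            a_new = np.clip(a + step * da, -coef_clip, coef_clip)
            b_new = np.clip(b + step * db, -coef_clip, coef_clip)
            ll_new = _loglik(a_new, b_new, t, S, N)
            worse = ll_new < ll - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
        n_iter = it + 1
        delta_ll = np.abs(ll_new - ll)
        a, b, ll = a_new, b_new, ll_new
        converged = delta_ll < tol
        if converged.all():
            break

    at_clip = (np.abs(a) >= coef_clip) | (np.abs(b) >= coef_clip)
    converged = converged & ~at_clip
    return a, b, converged, n_iter


def aggregate_timepoints(n1_cells: np.ndarray, ntot_cells: np.ndarray, weights=None):
    """Collapse (snp, timepoint) count cells to per-timepoint sufficient sums.

    ``weights`` (length n_snps, or (m, n_snps) for m resamples) are SNP
    multiplicities, e.g. bootstrap resampling counts.
    """
    n1_cells = np.asarray(n1_cells, dtype=float)
    ntot_cells = np.asarray(ntot_cells, dtype=float)
    if weights is None:
        return n1_cells.sum(axis=0), ntot_cells.sum(axis=0)
    weights = np.asarray(weights, dtype=float)
    return weights @ n1_cells, weights @ ntot_cells


def fit_binomial_logit(n1_cells, ntot_cells, timepoints, weights=None, **kw) -> DecayFit:
    """Single-fit convenience wrapper around :func:`fit_binomial_logit_many`."""
    S, N = aggregate_timepoints(n1_cells, ntot_cells, weights)
    a, b, conv, n_iter = fit_binomial_logit_many(S, N, timepoints, **kw)
    n_obs = int(np.count_nonzero(np.asarray(ntot_cells) > 0))
    return DecayFit(alpha=float(a[0]), beta=float(b[0]), converged=bool(conv[0]),
                    n_iter=n_iter, n_obs=n_obs)
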