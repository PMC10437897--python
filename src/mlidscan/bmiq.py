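"""Beta-mixture quantile (BMIQ) normalization of Infinium type II probes.

Type II probes on Infinium methylation arrays have a compressed dynamic
range relative to type I probes. BMIQ corrects this per sample:

1. fit a 3-component beta mixture — unmethylated (U), hemi-methylated (H),
   methylated (M) states — separately to the type I and type II β values;
2. map type II U-state values onto the type I U component by the quantile
   transform ``β' = F⁻¹_{U,I}(F_{U,II}(β))``, and M-state values onto the
   type I M component analogously;
3. rescale the H-state values by an affine (dilation) transform between
   the mapped U/M state boundaries.

Type I values are returned bit-identical; the transform is monotone within
each state and keeps output in [0, 1].

The mixture is fit by EM with an exact weighted maximum-likelihood M-step:
within each iteration the component shape parameters are re-optimized from
the weighted sufficient statistics (Σw, Σw·ln x, Σw·ln(1−x)) by L-BFGS
warm-started at the current values, so the observed-data log-likelihood is
non-decreasing across iterations. Initialization uses fixed tercile
cut-points of the sorted data, making the fit fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma, logsumexp
from scipy.stats import beta as beta_dist

from .core import DesignType

EPS_CLIP = 1e-6
MIN_PROBES = 30
MIN_WEIGHT = 1e-4


class DegenerateComponentError(ValueError):
    """A mixture component collapsed (vanishing weight or variance)."""


class InsufficientProbesError(ValueError):
    """Too few probes of a design type to fit the mixture."""


@dataclass
class BetaMixtureFit:
    """A fitted 3-state beta mixture, states ordered U < H < M by mean."""

    a: np.ndarray  # shape (k,)
    b: np.ndarray  # shape (k,)
    weights: np.ndarray  # shape (k,), sums to 1
    assignments: np.ndarray  # argmax-posterior state per input value
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)


def _log_densities(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n, k) matrix of component log beta densities."""
    lx = np.log(x)[:, None]
    l1x = np.log1p(-x)[:, None]
    return (a - 1) * lx + (b - 1) * l1x - betaln(a, b)


def _weighted_mle(
    w: np.ndarray, lx: np.ndarray, l1x: np.ndarray, a0: float, b0: float
) -> tuple[float, float]:
    """Weighted beta MLE from sufficient statistics, warm-started.

    Minimizes the negative expected complete-data log-likelihood in (a, b);
    starting at the current parameters guarantees no decrease in the EM
    objective even if the optimizer stops early.
    """
    W = w.sum()
    if W <= 0:
        return a0, b0
    Slx = float(w @ lx)
    Sl1x = float(w @ l1x)

    def neg_ll(theta):
        a, b = theta
        return -((a - 1) * Slx + (b - 1) * Sl1x - W * betaln(a, b))

    def grad(theta):
        a, b = theta
        dab = digamma(a + b)
        return np.array(
            [-(Slx - W * (digamma(a) - dab)), -(Sl1x - W * (digamma(b) - dab))]
        )

    res = minimize(
        neg_ll,
        x0=np.array([a0, b0]),
        jac=grad,
        method="L-BFGS-B",
        bounds=[(1e-2, 1e6)] * 2,
    )
    a, b = res.x
    # keep the better of warm start and optimizer output (monotone EM)
    if neg_ll(res.x) > neg_ll(np.array([a0, b0])):
        return a0, b0
    return float(a), float(b)


def _moment_match(x: np.ndarray) -> tuple[float, float]:
    m, v = float(np.mean(x)), float(np.var(x))
    v = max(v, 1e-8)
    v = min(v, 0.99 * m * (1 - m))
    nu = m * (1 - m) / v - 1.0
    return max(m * nu, 1e-2), max((1 - m) * nu, 1e-2)


def fit_beta_mixture(
    betas: Sequence[float] | np.ndarray,
    k: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> BetaMixtureFit:
    """Fit a k-state beta mixture by deterministic EM.

    Values are clipped to ``[1e-6, 1 − 1e-6]`` before fitting (the beta
    density is undefined at the endpoints). Initialization is by fixed
    quantile cut-points (terciles for k = 3); ``seed`` is accepted for API
    symmetry but unused by the deterministic fit. Non-convergence within
    ``max_iter`` is reported via the ``converged`` flag, not an exception;
    a component whose weight falls below 1e-4, or data with no spread to
    support k components, raises :class:`DegenerateComponentError`.
    """
    x = np.clip(np.asarray(betas, dtype=float), EPS_CLIP, 1 - EPS_CLIP)
    if x.size < MIN_PROBES:
        raise InsufficientProbesError(f"need >= {MIN_PROBES} values, got {x.size}")
    if float(np.std(x)) < 1e-4:
        raise DegenerateComponentError("values have no spread; mixture is degenerate")

    # fixed quantile cut-point initialization
    order = np.argsort(x, kind="stable")
    chunks = np.array_split(order, k)
    a = np.empty(k)
    b = np.empty(k)
    weights = np.array([len(c) / x.size for c in chunks])
    for j, c in enumerate(chunks):
        a[j], b[j] = _moment_match(x[c])

    lx, l1x = np.log(x), np.log1p(-x)
    lls: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_dens = _log_densities(x, a, b) + np.log(weights)
        ll_per_obs = logsumexp(log_dens, axis=1)
        ll = float(ll_per_obs.sum())
        lls.append(ll)
        resp = np.exp(log_dens - ll_per_obs[:, None])

        new_weights = resp.mean(axis=0)
        if np.any(new_weights < MIN_WEIGHT):
            raise DegenerateComponentError(
                f"component weight below {MIN_WEIGHT}: {new_weights}"
            )
        weights = new_weights
        for j in range(k):
            a[j], b[j] = _weighted_mle(resp[:, j], lx, l1x, a[j], b[j])

        if len(lls) >= 2 and abs(lls[-1] - lls[-2]) < tol:
            converged = True
            break

    # relabel states so means increase (U < H < M)
    means = a / (a + b)
    order = np.argsort(means, kind="stable")
    a, b, weights = a[order], b[order], weights[order]

    log_dens = _log_densities(x, a, b) + np.log(weights)
    resp = np.exp(log_dens - logsumexp(log_dens, axis=1)[:, None])
    assignments = resp.argmax(axis=1)
    if k == 3:  # ties broken toward the H state
        top = resp.max(axis=1)
        assignments = np.where(resp[:, 1] >= top, 1, assignments)

    return BetaMixtureFit(
        a=a,
        b=b,
        weights=weights,
        assignments=assignments,
        log_likelihoods=lls,
        converged=converged,
        n_iter=it,
    )


def _quantile_map(x: np.ndarray, a2: float, b2: float, a1: float, b1: float) -> np.ndarray:
    """β' = F⁻¹_{comp I}(F_{comp II}(β)), clipped to the open unit interval."""
    q = beta_dist.cdf(x, a2, b2)
    q = np.clip(q, 1e-12, 1 - 1e-12)
    return np.clip(beta_dist.ppf(q, a1, b1), 0.0, 1.0)


def bmiq_normalize_sample(
    betas: Sequence[float] | np.ndarray,
    design_types: Sequence[str | DesignType],
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> np.ndarray:
    """BMIQ-normalize one sample's β vector.

    Parameters
    ----------
    betas
        β values for every probe of the sample.
    design_types
        Matching vector of Infinium design types ("I" / "II").

    Returns the normalized vector: type I entries bit-identical to the
    input, type II entries quantile-mapped state-wise onto the type I
    mixture. Raises :class:`InsufficientProbesError` when either design
    type has fewer than 30 probes (unless there are no type II probes at
    all, in which case the input is returned unchanged).
    """
    x = np.asarray(betas, dtype=float)
    dt = np.array([DesignType(d).value for d in design_types])
    if x.shape != dt.shape:
        raise ValueError("betas and design_types must align")
    out = x.copy()
    is2 = dt == "II"
    if not is2.any():
        return out
    if is2.sum() < MIN_PROBES or (~is2).sum() < MIN_PROBES:
        raise InsufficientProbesError(
            f"need >= {MIN_PROBES} probes of each design type, got "
            f"{int((~is2).sum())} type I / {int(is2.sum())} type II"
        )

    fit1 = fit_beta_mixture(x[~is2], max_iter=max_iter, tol=tol, seed=seed)
    fit2 = fit_beta_mixture(x[is2], max_iter=max_iter, tol=tol, seed=seed)

    x2 = np.clip(x[is2], EPS_CLIP, 1 - EPS_CLIP)
    state = fit2.assignments
    new2 = x2.copy()

    u_mask, h_mask, m_mask = state == 0, state == 1, state == 2
    if u_mask.any():
        new2[u_mask] = _quantile_map(
            x2[u_mask], fit2.a[0], fit2.b[0], fit1.a[0], fit1.b[0]
        )
    if m_mask.any():
        new2[m_mask] = _quantile_map(
            x2[m_mask], fit2.a[2], fit2.b[2], fit1.a[2], fit1.b[2]
        )

    if h_mask.any():
        # affine dilation between the mapped U/M state boundaries; empty
        # neighbour states anchor to the identity at the H extremes
        h = x2[h_mask]
        if u_mask.any():
            u_right = float(x2[u_mask].max())
            u_right_mapped = float(
                _quantile_map(
                    np.array([u_right]), fit2.a[0], fit2.b[0], fit1.a[0], fit1.b[0]
                )[0]
            )
        else:
            u_right = float(h.min())
            u_right_mapped = u_right
        if m_mask.any():
            m_left = float(x2[m_mask].min())
            m_left_mapped = float(
                _quantile_map(
                    np.array([m_left]), fit2.a[2], fit2.b[2], fit1.a[2], fit1.b[2]
                )[0]
            )
        else:
            m_left = float(h.max())
            m_left_mapped = m_left
        if m_left > u_right and m_left_mapped > u_right_mapped:
            scale = (m_left_mapped - u_right_mapped) / (m_left - u_right)
            new2[h_mask] = np.clip(
                u_right_mapped + (h - u_right) * scale, 0.0, 1.0
            )
        # else: degenerate overlap — leave H values untouched (identity)

    out[is2] = new2
    return out
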