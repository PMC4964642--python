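"""Canonical maximum-entropy ensembles of weighted contact networks.

Two ensembles over nonnegative-integer link weights w in {0, 1, 2, ...}
are fitted to a weighted PCN:

* strength-constrained (``S_s``): only the expected node strengths
  ``<s_i>`` are enforced.  The pairwise weight distribution is geometric,
  ``pi_ij(w) = (1 - x_i x_j) (x_i x_j)^w`` with ``x_i = exp(-alpha_i)``.

* strength-and-degree-constrained (``S_ks``): expected strengths and
  expected degrees ``<k_i>`` are enforced jointly.  The pairwise law is
  ``pi_ij(0) = 1/Z_ij`` and ``pi_ij(w>=1) = y_i y_j (x_i x_j)^w / Z_ij``
  with ``y_i = exp(-beta_i)`` coupling to the link indicator.

The ensemble entropy ``S = -sum_{i<j} sum_w pi_ij(w) ln pi_ij(w)`` (nats)
counts, on a logarithmic scale, how many networks are typical under the
constraints.  The ratio ``S_R = S_s / S_ks >= 1`` measures how much
additional information the degree sequence carries beyond the strengths:
values near 1 mean the strengths alone pin down the ensemble, large
values mean many degree sequences (hence many contact topologies) are
compatible with the observed strengths.

The Lagrange multipliers are found by coordinate-wise exact minimisation
of the convex dual: each node's multiplier is solved to machine
precision with a bracketed root finder while the others are held fixed,
and sweeps repeat until every constraint residual falls below tolerance;
a damped Newton step on the free log-multipliers accelerates the tail.
Each coordinate solve is an exact coordinate minimisation, so the dual
objective is non-increasing across iterations.

Constraint vectors that lie on a facet of the realisable polytope — a
degree sequence saturating an Erdos-Gallai inequality, or strengths that
force a vanishing-probability link to carry finite expected weight
("condensation") — have no finite dual solution: the multipliers
diverge and the coordinate sweeps stall.  Those cases are handled by an
augmented-Lagrangian solve of the equivalent *primal* convex program in
the pairwise link probabilities and expected weights, where polytope
faces are ordinary boundary points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import xlogy

from .errors import (
    DegenerateNetworkError,
    FitError,
    InfeasibleConstraintsError,
    ValidationError,
)
from .structure_io import WeightedContactNetwork

# x_i x_j is capped strictly below 1 (geometric ratio), y at a huge value
# used when a degree constraint saturates (forced link, multiplier -> inf).
_Q_CAP = 1.0 - 1e-13
_Y_CAP = 1e100
_X_CAP = 1e130
# tiny xtol lets roots span hundreds of orders of magnitude (multipliers
# near a constraint boundary); worst-case bisection then needs ~1500 steps
_BRENTQ_KW = dict(xtol=1e-300, rtol=8.9e-16, maxiter=3000)
#: sweep counts at which a Newton polish of the free multipliers is attempted
_POLISH_AT = (40, 200, 600)


@dataclass(frozen=True)
class NodeConstraints:
    """Per-node strength (weighted contact sum) and degree (contact count)."""

    strengths: np.ndarray
    degrees: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.strengths, dtype=float)
        k = np.asarray(self.degrees, dtype=float)
        if s.shape != k.shape or s.ndim != 1:
            raise ValidationError("strengths and degrees must be 1-D and equally long")
        if (s < 0).any() or (k < 0).any():
            raise ValidationError("strengths and degrees must be nonnegative")
        object.__setattr__(self, "strengths", s)
        object.__setattr__(self, "degrees", k)

    @property
    def n_nodes(self) -> int:
        return self.strengths.shape[0]


@dataclass
class EnsembleFit:
    """Result of one constrained maximum-entropy fit.

    ``alpha``/``beta`` are the Lagrange multipliers (``x = exp(-alpha)``,
    ``y = exp(-beta)``); ``entropy`` is in nats; ``residuals`` holds the
    final per-constraint absolute errors; ``dual_path`` records the dual
    objective after each sweep (non-increasing).
    """

    kind: str
    alpha: np.ndarray
    beta: Optional[np.ndarray]
    entropy: float
    residuals: np.ndarray
    converged: bool
    iterations: int
    dual_path: list = field(default_factory=list, repr=False)


def node_constraints(wnet: WeightedContactNetwork) -> NodeConstraints:
    """Strength and degree sequences of a weighted network."""
    w = wnet.weights
    return NodeConstraints(strengths=w.sum(axis=1),
                           degrees=(w > 0).sum(axis=1).astype(float))


# ---------------------------------------------------------------------------
# strength-only ensemble


def _geo_entropy_terms(q: np.ndarray) -> np.ndarray:
    """Entropy of a geometric law on {0,1,...} with ratio q, elementwise."""
    one_minus = 1.0 - q
    return -(xlogy(one_minus, one_minus) + xlogy(q, q)) / one_minus


def fit_strength_ensemble(constraints: NodeConstraints,
                          tolerance: float = 1e-8,
                          max_iter: int = 1000) -> EnsembleFit:
    """Fit the ensemble that enforces expected strengths only.

    Raises :class:`FitError` (carrying the residuals) if the constraint
    system cannot be satisfied within ``max_iter`` sweeps — e.g. for
    strength sequences no network ensemble can realise.
    """
    s = constraints.strengths
    n = constraints.n_nodes
    active = np.flatnonzero(s > 0)
    x = np.zeros(n)
    x[active] = s[active] / (1.0 + s.sum())

    dual_path = []
    res_hist = []
    converged = False
    sweeps = 0
    if active.size <= 1 and active.size and s[active][0] > 0:
        raise InfeasibleConstraintsError(
            "a single node with positive strength has no partner to link to"
        )
    for sweeps in range(1, max_iter + 1):
        for i in active:
            others = active[active != i]
            xo = x[others]

            def f(xi):
                q = np.minimum(xi * xo, _Q_CAP)
                return (q / (1.0 - q)).sum() - s[i]

            hi = min(_Q_CAP / max(xo.max(), 1e-300), _X_CAP)
            x[i] = brentq(f, 0.0, hi, **_BRENTQ_KW) if f(hi) > 0 else hi
        if sweeps in _POLISH_AT:
            x = _polish_strength(x, s, active)
        q = np.minimum(np.outer(x, x), _Q_CAP)
        np.fill_diagonal(q, 0.0)
        expected = (q / (1.0 - q)).sum(axis=1)
        residuals = np.abs(expected - s)
        dual_path.append(_dual_strength(x, s, q))
        res_hist.append(residuals.max())
        if residuals.max() <= tolerance:
            converged = True
            break
        if len(res_hist) >= 120 and res_hist[-1] > 0.5 * res_hist[-100]:
            break  # sub-geometric rate: dual likely divergent (facet case)
    if not converged:
        # dual multipliers may diverge when the strengths sit on a facet of
        # the realisable polytope; solve the primal program instead
        entropy, resid, lam, outers = _al_fit_strength(s, tolerance)
        if resid.max() <= tolerance:
            return EnsembleFit(kind="strength_only", alpha=lam, beta=None,
                               entropy=entropy, residuals=resid,
                               converged=True, iterations=sweeps + outers,
                               dual_path=dual_path)
        raise FitError(
            f"strength ensemble did not converge in {max_iter} sweeps "
            f"(max residual {min(residuals.max(), resid.max()):.3g}); "
            "the strength sequence may be unrealisable",
            residuals=residuals,
        )
    entropy = float(np.triu(_geo_entropy_terms(q), k=1).sum())
    with np.errstate(divide="ignore"):
        alpha = -np.log(x)
    return EnsembleFit(kind="strength_only", alpha=alpha, beta=None,
                       entropy=entropy, residuals=residuals,
                       converged=True, iterations=sweeps,
                       dual_path=dual_path)


def _strength_residual_vec(x, s):
    q = np.minimum(np.outer(x, x), _Q_CAP)
    np.fill_diagonal(q, 0.0)
    return (q / (1.0 - q)).sum(axis=1) - s


def _polish_strength(x, s, active, n_steps=40):
    """Damped Newton on the free log-multipliers (analytic Jacobian).

    Accelerates the linearly-convergent coordinate sweeps near the
    optimum; any step that fails to reduce the residual norm is rejected,
    so the iterate can only improve.
    """
    free = np.array([i for i in active if 0 < x[i] < _X_CAP], dtype=int)
    if free.size == 0:
        return x
    x = x.copy()
    r = _strength_residual_vec(x, s)[free]
    for _ in range(n_steps):
        norm = np.abs(r).max()
        if norm < 1e-14:
            break
        q = np.minimum(np.outer(x, x), _Q_CAP)
        np.fill_diagonal(q, 0.0)
        # d<s_i>/d ln x_j = q_ij / (1 - q_ij)^2 for j != i;
        # d<s_i>/d ln x_i sums that row over every partner (pins included)
        Gfull = q / (1.0 - q) ** 2
        J = Gfull[np.ix_(free, free)] + np.diag(Gfull[free].sum(axis=1))
        try:
            delta = np.linalg.solve(J + 1e-14 * np.eye(free.size), -r)
        except np.linalg.LinAlgError:
            break
        improved = False
        for alpha in 2.0 ** -np.arange(12):
            trial = x.copy()
            trial[free] = x[free] * np.exp(np.clip(alpha * delta, -30, 30))
            r_new = _strength_residual_vec(trial, s)[free]
            if np.abs(r_new).max() < norm:
                x, r, improved = trial, r_new, True
                break
        if not improved:
            break
    return x


def _dual_strength(x, s, q):
    # F = sum_{i<j} ln Z_ij + sum_i alpha_i s_i, Z = 1/(1-q); alpha*s -> 0 when s=0
    lnZ = -np.log1p(-np.triu(q, k=1)).sum()
    pos = s > 0
    return float(lnZ + (-np.log(x[pos]) * s[pos]).sum())


# ---------------------------------------------------------------------------
# strength + degree ensemble


def _pair_p_meanw(T, q):
    """Link probability and expected weight in the (t, x) parametrisation.

    With ``t_i = x_i y_i`` and ``T = t_i t_j``, ``q = x_i x_j``:
    ``p = T / (1 - q + T)`` and ``<w> = p / (1 - q)``.  The point
    ``q = 0, T > 0`` is the binary configuration model (all link weights
    equal to one), so strength sequences equal to the degree sequence —
    a boundary where the original (x, y) multipliers diverge jointly —
    are ordinary interior points here.
    """
    one_minus = 1.0 - q
    p = T / (one_minus + T)
    return p, p / one_minus


def fit_strength_degree_ensemble(constraints: NodeConstraints,
                                 tolerance: float = 1e-8,
                                 max_iter: int = 1000) -> EnsembleFit:
    """Fit the ensemble enforcing expected strengths and degrees jointly.

    Degree constraints that saturate (a node that must link to every
    available partner) drive the corresponding multiplier to infinity;
    these are handled by capping ``t``, which leaves the entropy
    unaffected to O(1/t).
    """
    s = constraints.strengths
    k = constraints.degrees
    n = constraints.n_nodes
    if ((k == 0) & (s > 0)).any():
        raise InfeasibleConstraintsError("positive strength with zero degree")
    if (s < k - 1e-9).any():
        raise InfeasibleConstraintsError(
            "strength below degree is infeasible for link weights >= 1"
        )
    active = np.flatnonzero(k > 0)
    if active.size and (k[active] > active.size - 1 + 1e-9).any():
        raise InfeasibleConstraintsError("degree exceeds available partners")

    t = np.zeros(n)
    x = np.zeros(n)
    t[active] = k[active] / (1.0 + k.sum())
    excess = s - k
    if excess.sum() > 0:
        x[active] = excess[active] / (1.0 + excess.sum())

    dual_path = []
    res_hist = []
    converged = False
    sweeps = 0
    residuals = np.zeros(2 * n)
    for sweeps in range(1, max_iter + 1):
        for i in active:
            others = active[active != i]
            xo, to = x[others], t[others]
            one_minus_q = 1.0 - np.minimum(x[i] * xo, _Q_CAP)

            def fk(ti):
                T = ti * to
                return (T / (one_minus_q + T)).sum() - k[i]

            if k[i] >= (to > 0).sum() * (1.0 - 1e-12):
                t[i] = _Y_CAP
                continue
            hi = max(t[i], 1.0)
            while fk(hi) < 0 and hi < _Y_CAP:
                hi *= 8.0
            t[i] = brentq(fk, 0.0, min(hi, _Y_CAP), **_BRENTQ_KW) \
                if fk(min(hi, _Y_CAP)) > 0 else _Y_CAP
        for i in active:
            others = active[active != i]
            xo, to = x[others], t[others]
            T = t[i] * to

            def fs(xi):
                q = np.minimum(xi * xo, _Q_CAP)
                _, mean_w = _pair_p_meanw(T, q)
                return mean_w.sum() - s[i]

            if fs(0.0) >= 0:
                x[i] = 0.0  # strengths already met by the link indicators
                continue
            hi = min(_Q_CAP / max(xo.max(), 1e-300), _X_CAP)
            x[i] = brentq(fs, 0.0, hi, **_BRENTQ_KW) if fs(hi) > 0 else hi

        if sweeps in _POLISH_AT:
            t, x = _polish_sd(t, x, s, k, active)
        q = np.minimum(np.outer(x, x), _Q_CAP)
        T = np.outer(t, t)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(T, 0.0)
        p, mean_w = _pair_p_meanw(T, q)
        residuals = np.concatenate([np.abs(mean_w.sum(axis=1) - s),
                                    np.abs(p.sum(axis=1) - k)])
        dual_path.append(_dual_strength_degree(t, x, s, k, T, q))
        res_hist.append(residuals.max())
        if residuals.max() <= tolerance:
            converged = True
            break
        if len(res_hist) >= 120 and res_hist[-1] > 0.5 * res_hist[-100]:
            break  # sub-geometric rate: dual likely divergent (facet case)
    if not converged:
        # facet cases (saturated Erdos-Gallai subsets, strength condensation)
        # have no finite dual solution; fall back to the primal program
        entropy, resid, lam, outers = _al_fit_sd(s, k, tolerance)
        if resid.max() <= tolerance:
            return EnsembleFit(kind="strength_and_degree",
                               alpha=lam[n:], beta=lam[:n],
                               entropy=entropy, residuals=resid,
                               converged=True, iterations=sweeps + outers,
                               dual_path=dual_path)
        raise FitError(
            f"strength+degree ensemble did not converge in {max_iter} sweeps "
            f"(max residual {min(residuals.max(), resid.max()):.3g}); "
            "the constraint pair may be unrealisable",
            residuals=residuals,
        )
    entropy = float(np.triu(_pair_entropy_sd(p, q), k=1).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = -np.log(x)
        beta = -(np.log(t) - np.log(x))  # beta_i = -ln y_i, y = t / x
    return EnsembleFit(kind="strength_and_degree", alpha=alpha, beta=beta,
                       entropy=entropy, residuals=residuals,
                       converged=True, iterations=sweeps,
                       dual_path=dual_path)


def _sd_residual_vec(t, x, s, k):
    q = np.minimum(np.outer(x, x), _Q_CAP)
    T = np.outer(t, t)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(T, 0.0)
    p, mean_w = _pair_p_meanw(T, q)
    return p.sum(axis=1) - k, mean_w.sum(axis=1) - s


def _polish_sd(t, x, s, k, active, n_steps=40):
    """Damped Newton on the free log-multipliers (analytic Jacobian).

    Capped t (saturated degrees) and zero x (strength equal to degree)
    stay pinned; only the interior coordinates enter the square system.
    Steps that fail to reduce the residual norm are rejected, so the
    iterate can only improve on the coordinate-sweep state.
    """
    ft = np.array([i for i in active if t[i] < _Y_CAP * 0.999], dtype=int)
    fx = np.array([i for i in active if 0 < x[i] < _X_CAP], dtype=int)
    if ft.size == 0 and fx.size == 0:
        return t, x
    t, x = t.copy(), x.copy()

    def residual(tt, xx):
        rk, rs = _sd_residual_vec(tt, xx, s, k)
        return np.concatenate([rk[ft], rs[fx]])

    r = residual(t, x)
    for _ in range(n_steps):
        norm = np.abs(r).max()
        if norm < 1e-14:
            break
        q = np.minimum(np.outer(x, x), _Q_CAP)
        T = np.outer(t, t)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(T, 0.0)
        D = 1.0 - q
        p = T / (D + T)
        # pairwise sensitivities in log coordinates (u = ln t, v = ln x):
        # dp/du = p(1-p),           dp/dv = p(1-p) q/D,
        # dm/du = p(1-p)/D,         dm/dv = q p (2-p)/D^2
        A = p * (1.0 - p)
        B = A * q / D
        C = A / D
        E = q * p * (2.0 - p) / D ** 2
        def block(M, rows, cols):
            # pair term off the diagonal; same-node entries carry the full
            # row sum (M has a zero diagonal, so no double counting)
            out = M[np.ix_(rows, cols)].copy()
            same = np.equal.outer(rows, cols)
            out[same] = M[rows].sum(axis=1)[same.any(axis=1)]
            return out

        nt, nx = ft.size, fx.size
        J = np.zeros((nt + nx, nt + nx))
        J[:nt, :nt] = block(A, ft, ft)
        J[:nt, nt:] = block(B, ft, fx)
        J[nt:, :nt] = block(C, fx, ft)
        J[nt:, nt:] = block(E, fx, fx)
        try:
            delta = np.linalg.solve(J + 1e-14 * np.eye(nt + nx), -r)
        except np.linalg.LinAlgError:
            break
        improved = False
        for alpha in 2.0 ** -np.arange(12):
            tt, xx = t.copy(), x.copy()
            tt[ft] = np.minimum(t[ft] * np.exp(np.clip(alpha * delta[:nt],
                                                       -30, 30)), _Y_CAP)
            xx[fx] = np.minimum(x[fx] * np.exp(np.clip(alpha * delta[nt:],
                                                       -30, 30)), _X_CAP)
            r_new = residual(tt, xx)
            if np.abs(r_new).max() < norm:
                t, x, r, improved = tt, xx, r_new, True
                break
        if not improved:
            break
    return t, x


def _pair_entropy_sd(p, q):
    """Per-pair entropy, chain-rule form: H(link) + p * H(weight | link).

    Conditional on the link being present the weight is geometric on
    {1, 2, ...} with ratio q; this decomposition avoids the catastrophic
    cancellation of the naive ``ln Z - p ln Y - <w> ln q`` expression
    when a degree constraint saturates.
    """
    h_link = -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p))
    h_weight = -(np.log1p(-q) + xlogy(q / (1.0 - q), q))
    return h_link + p * h_weight


def _dual_strength_degree(t, x, s, k, T, q):
    # F = sum ln Z - sum_i [(s_i - k_i) ln x_i + k_i ln t_i];
    # ln Z = ln(1 - q + T) - ln(1 - q).  Transient x_i = 0 with s_i > k_i
    # makes F infinite; that resolves on the next sweep.
    upper = np.triu_indices_from(q, k=1)
    lnZ = (np.log((1.0 - q + T)[upper]) - np.log1p(-q[upper])).sum()
    out = float(lnZ)
    excess = s - k
    pos_t = k > 0
    out -= float((np.log(t[pos_t]) * k[pos_t]).sum())
    for xi, ex in zip(x, excess):
        if ex > 1e-12:
            out -= math.log(xi) * ex if xi > 0 else -math.inf
    return out


# ---------------------------------------------------------------------------


# ---------------------------------------------------------------------------
# primal fallback (augmented Lagrangian) for constraint sets on polytope faces


def _al_minimize(objective, z0, bounds, residual_rows, targets,
                 tolerance, rho0=10.0, max_outer=80):
    """Method of multipliers for max H(z) s.t. rows(z) = targets, z in box.

    ``objective(z) -> (H_total, dH/dz)``; ``residual_rows(z)`` returns the
    per-constraint totals.  Returns (z, lam, max_violation, n_outer).
    """
    from scipy.optimize import minimize

    lam = np.zeros(len(targets))
    rho = rho0
    z = z0
    prev = np.inf
    for outer in range(1, max_outer + 1):
        def fun(z):
            H, dH, rows, drows = objective(z)
            r = rows - targets
            val = -H + lam @ r + 0.5 * rho * (r @ r)
            grad = -dH + drows.T @ (lam + rho * r)
            return val, grad

        res = minimize(fun, z, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 3000, "ftol": 1e-18,
                                "gtol": 1e-14})
        z = res.x
        r = residual_rows(z) - targets
        viol = np.abs(r).max()
        lam = lam + rho * r
        if viol <= tolerance:
            return z, lam, viol, outer
        if viol > 0.5 * prev:
            rho = min(rho * 4.0, 1e12)
        prev = viol
    return z, lam, viol, max_outer


def _al_fit_strength(s, tolerance):
    """Primal solve of the strength-only ensemble in pair means m >= 0."""
    n = len(s)
    iu, ju = np.triu_indices(n, 1)
    incidence = np.zeros((n, len(iu)))
    incidence[iu, np.arange(len(iu))] = 1.0
    incidence[ju, np.arange(len(iu))] = 1.0

    def objective(m):
        H = (xlogy(m + 1, m + 1) - xlogy(m, m)).sum()
        with np.errstate(divide="ignore"):
            dH = np.log(m + 1) - np.log(m)
        return H, dH, incidence @ m, incidence

    def rows(m):
        return incidence @ m

    m0 = np.full(len(iu), max(s.sum() / max(n * (n - 1), 1), 1e-3))
    bounds = [(1e-300, None)] * len(iu)
    m, lam, viol, outers = _al_minimize(objective, m0, bounds, rows, s,
                                        tolerance)
    entropy = float((xlogy(m + 1, m + 1) - xlogy(m, m)).sum())
    resid = np.abs(rows(m) - s)
    return entropy, resid, lam, outers


def _al_fit_sd(s, k, tolerance):
    """Primal solve of the joint ensemble in (p, e = m - p) per pair.

    Pair entropy in primal variables:
    h(p, e) = -(1-p)ln(1-p) - 2 p ln p + (p+e)ln(p+e) - e ln e,
    concave on 0 <= p <= 1, e >= 0 (chain rule + perspective of the
    shifted-geometric entropy); faces p=0, p=1, e=0 are feasible points.
    """
    n = len(s)
    iu, ju = np.triu_indices(n, 1)
    P = len(iu)
    inc = np.zeros((n, P))
    inc[iu, np.arange(P)] = 1.0
    inc[ju, np.arange(P)] = 1.0
    # constraint rows: degrees (sum p), strengths (sum p + e)
    drows = np.block([[inc, np.zeros_like(inc)], [inc, inc]])

    def h_terms(p, e):
        m = p + e
        return (-xlogy(1 - p, 1 - p) - 2 * xlogy(p, p)
                + xlogy(m, m) - xlogy(e, e))

    def objective(z):
        p, e = z[:P], z[P:]
        m = p + e
        with np.errstate(divide="ignore"):
            dHdp = np.log1p(-p) - 2 * np.log(p) + np.log(m)
            dHde = np.log(m) - np.log(e)
        rows = np.concatenate([inc @ p, inc @ m])
        return h_terms(p, e).sum(), np.concatenate([dHdp, dHde]), rows, drows

    def rows(z):
        p, e = z[:P], z[P:]
        return np.concatenate([inc @ p, inc @ (p + e)])

    z0 = np.concatenate([
        np.full(P, min(0.5, k.sum() / max(n * (n - 1), 1))),
        np.full(P, max((s - k).sum() / max(n * (n - 1), 1), 1e-3)),
    ])
    bounds = [(1e-300, 1 - 1e-16)] * P + [(1e-300, None)] * P
    z, lam, viol, outers = _al_minimize(objective, z0, bounds, rows,
                                        np.concatenate([k, s]), tolerance)
    p, e = z[:P], z[P:]
    entropy = float(h_terms(p, e).sum())
    resid = np.abs(rows(z) - np.concatenate([k, s]))
    return entropy, resid, lam, outers


def entropy_ratio(S_s: float, S_ks: float) -> float:
    """The ensemble-entropy ratio S_R = S_s / S_ks (>= 1 on a common network)."""
    if S_ks <= 0:
        raise DegenerateNetworkError(
            f"S_ks = {S_ks} <= 0: the entropy ratio is undefined for a "
            "network whose constrained ensemble is deterministic"
        )
    return S_s / S_ks


def entropy_features(wnet: WeightedContactNetwork,
                     tolerance: float = 1e-8,
                     max_iter: int = 1000) -> tuple:
    """Convenience: (S_s, S_ks, S_R) for one weighted network."""
    cons = node_constraints(wnet)
    fit_s = fit_strength_ensemble(cons, tolerance=tolerance, max_iter=max_iter)
    fit_ks = fit_strength_degree_ensemble(cons, tolerance=tolerance,
                                          max_iter=max_iter)
    return fit_s.entropy, fit_ks.entropy, entropy_ratio(fit_s.entropy,
                                                        fit_ks.entropy)
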