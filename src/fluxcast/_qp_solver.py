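"""Strictly convex quadratic programming with linear equality/inequality rows.

Solves

    minimize    1/2 x' H x + q' x
    subject to  E x  = d
                A x >= c

for diagonal positive-definite ``H`` by a primal active-set scheme: each
iterate solves the KKT system of the equality rows plus the current working
set exactly (dense linear solve), then drops the working-set row with the
most negative multiplier or adds the most violated inequality.  For the small
dense systems this package produces (tens of variables and rows) every
iterate is exact to linear-solve precision, so the returned point satisfies
the KKT conditions to ~1e-10.  A scipy ``trust-constr`` fallback guards
against the (never observed) possibility of cycling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize


class QPInfeasibleError(ValueError):
    """The constraint set has no solution; carries the offending row labels."""

    def __init__(self, message: str, rows: list[str] | None = None):
        super().__init__(message)
        self.rows = rows or []


@dataclass(frozen=True)
class QPSolution:
    x: np.ndarray
    objective: float
    active_set: tuple[int, ...]  # indices into the inequality rows
    kkt_residual: float
    iterations: int
    method: str


def _kkt_solve(H_diag, q, E, d):
    """Solve the equality-constrained QP; returns (x, multipliers)."""
    n = H_diag.size
    m = E.shape[0]
    if m == 0:
        return -q / H_diag, np.empty(0)
    K = np.zeros((n + m, n + m))
    K[:n, :n] = np.diag(H_diag)
    K[:n, n:] = E.T
    K[n:, :n] = E
    rhs = np.concatenate([-q, d])
    try:
        sol = linalg.solve(K, rhs, assume_a="sym")
    except linalg.LinAlgError:
        sol, *_ = linalg.lstsq(K, rhs)
    if not np.all(np.isfinite(sol)):
        sol, *_ = linalg.lstsq(K, rhs)
    return sol[:n], sol[n:]


def solve_qp(
    H_diag: np.ndarray,
    q: np.ndarray,
    E: np.ndarray,
    d: np.ndarray,
    A: np.ndarray,
    c: np.ndarray,
    *,
    feas_tol: float = 1e-9,
    max_iter: int = 500,
) -> QPSolution:
    """Solve the strictly convex QP; raises :class:`QPInfeasibleError` if empty."""
    H_diag = np.asarray(H_diag, float)
    q = np.asarray(q, float)
    E = np.asarray(E, float).reshape(-1, H_diag.size)
    d = np.asarray(d, float)
    A = np.asarray(A, float).reshape(-1, H_diag.size)
    c = np.asarray(c, float)
    if np.any(H_diag <= 0):
        raise ValueError("quadratic weights must be strictly positive")

    n_eq, n_in = E.shape[0], A.shape[0]
    work: list[int] = []
    mult_tol = 1e-10
    x = None
    for it in range(1, max_iter + 1):
        W = np.array(sorted(work), dtype=int)
        Ew = np.vstack([E, A[W]]) if W.size else E
        dw = np.concatenate([d, c[W]]) if W.size else d
        x, lam = _kkt_solve(H_diag, q, Ew, dw)
        # multipliers of working-set rows; sign: lambda = -nu for a x >= c
        lam_in = -lam[n_eq:] if W.size else np.empty(0)
        if W.size and lam_in.size and lam_in.min() < -mult_tol:
            # drop the lowest-index row with a negative multiplier (Bland)
            bad = W[lam_in < -mult_tol]
            work.remove(int(bad.min()))
            continue
        slack = A @ x - c if n_in else np.empty(0)
        viol = np.where(slack < -feas_tol)[0]
        viol = np.array([i for i in viol if i not in work], dtype=int)
        if viol.size == 0:
            kkt = _kkt_residual(H_diag, q, E, d, A, c, x, work, lam, n_eq)
            if kkt > 1e-6 or np.max(np.abs(E @ x - d), initial=0.0) > 1e-6:
                break  # degenerate solve; fall through to the fallback
            return QPSolution(
                x=x,
                objective=float(0.5 * x @ (H_diag * x) + q @ x),
                active_set=tuple(sorted(work)),
                kkt_residual=kkt,
                iterations=it,
                method="active-set",
            )
        work.append(int(viol[np.argmin(slack[viol])]))

    return _fallback(H_diag, q, E, d, A, c, feas_tol)


def _kkt_residual(H_diag, q, E, d, A, c, x, work, lam, n_eq) -> float:
    grad = H_diag * x + q
    if E.shape[0]:
        grad = grad + E.T @ lam[:n_eq]
    if work:
        W = np.array(sorted(work), dtype=int)
        grad = grad + A[W].T @ lam[n_eq:]
    res = float(np.max(np.abs(grad), initial=0.0))
    if E.shape[0]:
        res = max(res, float(np.max(np.abs(E @ x - d), initial=0.0)))
    return res


def _certify_infeasible(E, d, A, c) -> list[int]:
    """Phase-1 LP; returns indices (eq rows first) that cannot be met."""
    n = E.shape[1] if E.size else A.shape[1]
    res = optimize.linprog(
        c=np.zeros(n),
        A_eq=E if E.shape[0] else None,
        b_eq=d if E.shape[0] else None,
        A_ub=-A if A.shape[0] else None,
        b_ub=-c if A.shape[0] else None,
        bounds=[(None, None)] * n,
        method="highs",
    )
    if res.status == 0:
        return []
    # elastic relaxation: minimize total violation, report stressed rows
    m_eq, m_in = E.shape[0], A.shape[0]
    # variables: x (n), s_eq+ , s_eq- (m_eq each), s_in (m_in)
    n_tot = n + 2 * m_eq + m_in
    cost = np.concatenate([np.zeros(n), np.ones(2 * m_eq + m_in)])
    A_eq = np.hstack([E, np.eye(m_eq), -np.eye(m_eq), np.zeros((m_eq, m_in))]) if m_eq else None
    A_ub = (
        np.hstack([-A, np.zeros((m_in, 2 * m_eq)), -np.eye(m_in)]) if m_in else None
    )
    bounds = [(None, None)] * n + [(0, None)] * (2 * m_eq + m_in)
    res2 = optimize.linprog(
        c=cost,
        A_eq=A_eq,
        b_eq=d if m_eq else None,
        A_ub=A_ub,
        b_ub=-c if m_in else None,
        bounds=bounds,
        method="highs",
    )
    rows: list[int] = []
    if res2.status == 0:
        s = res2.x[n:]
        s_eq = s[: 2 * m_eq].reshape(2, m_eq).sum(axis=0) if m_eq else np.empty(0)
        s_in = s[2 * m_eq :]
        rows = [i for i in range(m_eq) if s_eq[i] > 1e-7]
        rows += [m_eq + i for i in range(m_in) if s_in[i] > 1e-7]
    return rows or list(range(m_eq + m_in))


def _fallback(H_diag, q, E, d, A, c, feas_tol) -> QPSolution:
    bad = _certify_infeasible(E, d, A, c)
    res_f = optimize.linprog(
        c=np.zeros(H_diag.size),
        A_eq=E if E.shape[0] else None,
        b_eq=d if E.shape[0] else None,
        A_ub=-A if A.shape[0] else None,
        b_ub=-c if A.shape[0] else None,
        bounds=[(None, None)] * H_diag.size,
        method="highs",
    )
    if res_f.status != 0:
        raise QPInfeasibleError(
            f"constraint system is infeasible (unsatisfiable row indices: {bad})",
            rows=bad,
        )
    cons = []
    if E.shape[0]:
        cons.append(optimize.LinearConstraint(E, d, d))
    if A.shape[0]:
        cons.append(optimize.LinearConstraint(A, c, np.inf))
    res = optimize.minimize(
        lambda x: 0.5 * x @ (H_diag * x) + q @ x,
        res_f.x,
        jac=lambda x: H_diag * x + q,
        hess=lambda x: np.diag(H_diag),
        method="trust-constr",
        constraints=cons,
        options={"xtol": 1e-12, "gtol": 1e-10, "maxiter": 2000},
    )
    x = res.x
    slack = A @ x - c if A.shape[0] else np.empty(0)
    active = tuple(int(i) for i in np.where(np.abs(slack) < 1e-7)[0])
    return QPSolution(
        x=x,
        objective=float(0.5 * x @ (H_diag * x) + q @ x),
        active_set=active,
        kkt_residual=float(res.optimality),
        iterations=int(res.niter),
        method="trust-constr",
    )
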