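"""Least-squares primitives shared by the association, heterogeneity and
mediation modules.

Two code paths serve the same estimand:

* a QR-based path for single fits, with explicit rank diagnostics;
* a batched normal-equation path (stacked ``solve`` over a 3-d design
  array) used inside bootstrap and permutation loops, where thousands of
  small regressions must be refit per second.

Both compute residual sums of squares exactly; the batched path trades the
QR's extra numerical headroom for vectorisation, which is acceptable at the
condition numbers produced by standardized simulated designs.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

from .errors import CollinearityError, DegenerateDataError

_RANK_TOL = 1e-10


def with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Return an (n, 1+k) design of intercept plus covariate columns."""
    ones = np.ones((n, 1))
    if covariates is None:
        return ones
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError(f"covariate rows ({C.shape[0]}) != observations ({n})")
    if C.shape[1] == 0:
        return ones
    return np.hstack([ones, C])


def check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise :class:`CollinearityError` naming the dependent columns."""
    if X.shape[0] < X.shape[1]:
        raise DegenerateDataError(
            f"{X.shape[0]} observations cannot identify {X.shape[1]} parameters"
        )
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    scale = d[0] if d.size and d[0] > 0 else 1.0
    bad = piv[np.flatnonzero(d <= _RANK_TOL * scale)]
    if d.size < X.shape[1]:
        bad = np.union1d(bad, piv[d.size :])
    if bad.size:
        if names is None:
            names = [f"col{j}" for j in range(X.shape[1])]
        raise CollinearityError([names[j] for j in bad])


def residualize(Q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Residual of ``v`` against the orthonormal column basis ``Q``."""
    return v - Q @ (Q.T @ v)


def partial_r2_qr(
    y: np.ndarray, prs: np.ndarray, C: np.ndarray
) -> tuple[float, float, float, float]:
    """Partial R-squared of ``prs`` in ``y ~ C + prs``.

    ``C`` must already contain the intercept column.  Returns
    ``(partial_r2, beta_prs, rss_reduced, rss_full)`` where
    ``partial_r2 = (RSS_red - RSS_full) / RSS_red``.
    """
    Q, _ = np.linalg.qr(C)
    ry = residualize(Q, y)
    rp = residualize(Q, prs)
    rss_red = float(ry @ ry)
    pp = float(rp @ rp)
    if rss_red <= 0:
        raise DegenerateDataError("outcome has zero residual variance given covariates")
    if pp <= 0:
        raise CollinearityError(["prs (in the span of the covariates)"])
    num = float(ry @ rp)
    rss_full = rss_red - num * num / pp
    r2 = num * num / (rss_red * pp)
    return min(max(r2, 0.0), 1.0), num / pp, rss_red, rss_full


def batched_ols(Xb: np.ndarray, yb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stacked OLS fits: ``Xb`` is (B, n, p), ``yb`` is (B, n).

    Returns ``(beta, rss, ok)``; replicates whose normal equations are
    singular (or numerically non-finite) have ``ok = False`` and undefined
    beta/rss — callers redraw them.
    """
    G = Xb.transpose(0, 2, 1) @ Xb
    c = np.einsum("bnp,bn->bp", Xb, yb)
    B, _, p = Xb.shape
    beta = np.empty((B, p))
    ok = np.ones(B, dtype=bool)
    try:
        beta = np.linalg.solve(G, c[..., None])[..., 0]
    except np.linalg.LinAlgError:
        for i in range(B):
            try:
                beta[i] = np.linalg.solve(G[i], c[i])
            except np.linalg.LinAlgError:
                ok[i] = False
    rss = np.einsum("bn,bn->b", yb, yb) - np.einsum("bp,bp->b", c, beta)
    ok &= np.isfinite(rss) & np.all(np.isfinite(beta), axis=1)
    return beta, rss, ok


def batched_partial_r2(Xb_full: np.ndarray, yb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched partial R-squared of the LAST column of ``Xb_full``.

    The reduced model reuses the leading Gram block, so each replicate costs
    a single design assembly.  Returns ``(partial_r2, ok)``.
    """
    G = Xb_full.transpose(0, 2, 1) @ Xb_full
    c = np.einsum("bnp,bn->bp", Xb_full, yb)
    yy = np.einsum("bn,bn->b", yb, yb)

    def _solve(Gs, cs):
        B, p = cs.shape
        beta = np.empty((B, p))
        ok = np.ones(B, dtype=bool)
        try:
            beta = np.linalg.solve(Gs, cs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for i in range(B):
                try:
                    beta[i] = np.linalg.solve(Gs[i], cs[i])
                except np.linalg.LinAlgError:
                    ok[i] = False
        return beta, ok

    beta_f, ok_f = _solve(G, c)
    beta_r, ok_r = _solve(G[:, :-1, :-1], c[:, :-1])
    rss_full = yy - np.einsum("bp,bp->b", c, beta_f)
    rss_red = yy - np.einsum("bp,bp->b", c[:, :-1], beta_r)
    ok = ok_f & ok_r & np.isfinite(rss_full) & (rss_red > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (rss_red - rss_full) / rss_red
    return np.clip(r2, 0.0, 1.0), ok
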