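"""Constrained-covariance Gaussian mixture engine.

Each component covariance is eigen-decomposed as

    Sigma_k = lambda_k * D_k * A_k * D_k^T

with ``lambda_k`` the volume (scalar), ``A_k`` the shape (diagonal,
determinant 1) and ``D_k`` the orientation (orthogonal).  A three-letter
family code constrains each element to be Equal across components,
Variable, or the Identity: EII is the spherical equal-volume model, VVV
the fully unconstrained one, and the twelve codes in between interpolate.
Constraining geometry this way trades flexibility for parameters, and the
Bayesian Information Criterion

    BIC = 2 * loglik - n_params * ln(n)        (maximised)

arbitrates.  The M-steps follow the standard maximum-likelihood updates
for each family; four families (VEI, VEE, VEV and the shared-orientation
pair EVE/VVE) have no closed form and use short inner fixed-point or
minorise-maximise iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

__all__ = [
    "FAMILIES",
    "GMMFit",
    "DegenerateFitError",
    "count_covariance_params",
    "count_params",
    "fit_gmm",
    "bic_of",
]

FAMILIES = (
    "EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE",
    "EVE", "VEE", "VVE", "EEV", "VEV", "EVV", "VVV",
)

_INNER_TOL = 1e-8
_INNER_MAX = 100


class DegenerateFitError(RuntimeError):
    """The fit collapsed (singular covariance or empty component)."""


def count_covariance_params(family: str, G: int, d: int) -> int:
    """Free covariance parameters of a family with ``G`` components in ``d`` dims."""
    if family not in FAMILIES:
        raise ValueError(f"unknown covariance family {family!r}")
    if G < 1 or d < 1:
        raise ValueError("G and d must be >= 1")
    full = d * (d + 1) // 2
    orient = d * (d - 1) // 2
    table = {
        "EII": 1,
        "VII": G,
        "EEI": d,
        "VEI": G + (d - 1),
        "EVI": 1 + G * (d - 1),
        "VVI": G * d,
        "EEE": full,
        "VEE": G + (d - 1) + orient,
        "EVE": 1 + G * (d - 1) + orient,
        "VVE": G + G * (d - 1) + orient,
        "EEV": 1 + (d - 1) + G * orient,
        "VEV": G + (d - 1) + G * orient,
        "EVV": 1 + G * (d - 1) + G * orient,
        "VVV": G * full,
    }
    return table[family]


def count_params(family: str, G: int, d: int) -> int:
    """Total free parameters: mixing proportions + means + covariance."""
    return (G - 1) + G * d + count_covariance_params(family, G, d)


# ---------------------------------------------------------------------------
# family M-steps: scatter matrices W_k (G,d,d) and weights n_k -> Sigma stack
# ---------------------------------------------------------------------------

def _det1(diag: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalise a positive diagonal to determinant 1; return (shape, scale)."""
    if np.any(diag <= 0):
        raise DegenerateFitError("non-positive diagonal scatter entry")
    scale = float(np.exp(np.mean(np.log(diag))))
    return diag / scale, scale


def _eigh_desc(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(W)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def _mm_orientation(W: np.ndarray, B: np.ndarray, D0: np.ndarray,
                    max_iter: int = _INNER_MAX) -> np.ndarray:
    """Minimise sum_k tr(B_k D^T W_k D) over orthogonal D (minorise-maximise).

    ``B`` holds the positive diagonals ``A_k^{-1}/lambda_k``.  Each sweep
    linearises the concave part tr(B_k D^T (W_k - w_k I) D) at the current D
    and solves the resulting orthogonal Procrustes subproblem by SVD.
    """
    G, d, _ = W.shape
    omega = np.array([np.linalg.eigvalsh(W[k])[-1] for k in range(G)])
    D = D0
    prev = np.inf
    for _ in range(max_iter):
        F = np.zeros((d, d))
        for k in range(G):
            M = W[k] - omega[k] * np.eye(d)
            F += M @ D @ np.diag(B[k])
        U, _s, Vt = np.linalg.svd(F)
        D = -U @ Vt
        obj = sum(np.sum(B[k] * np.diag(D.T @ W[k] @ D)) for k in range(G))
        if abs(prev - obj) <= _INNER_TOL * (1.0 + abs(obj)):
            break
        prev = obj
    return D


def _cov_mstep(family: str, W: np.ndarray, nk: np.ndarray, *,
               inner_max: int = _INNER_MAX, state: dict | None = None) -> np.ndarray:
    """ML covariance stack for a family given per-component scatters.

    ``inner_max`` caps the fixed-point / MM sweeps of the families without
    a closed form; ``state`` (EVE/VVE) carries the shared orientation
    between successive M-steps so a capped update still improves on the
    previous one (generalised EM).
    """
    G, d, _ = W.shape
    n = float(nk.sum())
    eye = np.eye(d)

    if family == "EII":
        lam = np.trace(W.sum(axis=0)) / (n * d)
        return np.repeat((lam * eye)[None], G, axis=0)

    if family == "VII":
        lam = np.einsum("kii->k", W) / (nk * d)
        return lam[:, None, None] * eye

    if family == "EEI":
        diag = np.einsum("kii->i", W) / n
        return np.repeat(np.diag(diag)[None], G, axis=0)

    if family == "VVI":
        diag = np.einsum("kii->ki", W) / nk[:, None]
        return np.stack([np.diag(diag[k]) for k in range(G)])

    if family == "EVI":
        dk = np.einsum("kii->ki", W)                     # (G,d)
        shapes = np.empty_like(dk)
        scales = np.empty(G)
        for k in range(G):
            shapes[k], scales[k] = _det1(dk[k])
        lam = scales.sum() / n
        return np.stack([np.diag(lam * shapes[k]) for k in range(G)])

    if family == "VEI":
        dk = np.einsum("kii->ki", W)
        lam = np.einsum("kii->k", W) / (nk * d)          # spherical start
        for _ in range(_INNER_MAX):
            B, _ = _det1((dk / lam[:, None]).sum(axis=0))
            lam_new = (dk / B).sum(axis=1) / (nk * d)
            if np.max(np.abs(lam_new - lam) / lam_new) < _INNER_TOL:
                lam = lam_new
                break
            lam = lam_new
        B, _ = _det1((dk / lam[:, None]).sum(axis=0))
        return lam[:, None, None] * np.diag(B)[None]

    if family == "EEE":
        return np.repeat((W.sum(axis=0) / n)[None], G, axis=0)

    if family == "VVV":
        return W / nk[:, None, None]

    if family == "EVV":
        shapes = np.empty_like(W)
        scales = np.empty(G)
        for k in range(G):
            sign, logdet = np.linalg.slogdet(W[k])
            if sign <= 0:
                raise DegenerateFitError(f"singular scatter in component {k}")
            scales[k] = np.exp(logdet / d)
            shapes[k] = W[k] / scales[k]
        lam = scales.sum() / n
        return lam * shapes

    if family == "VEE":
        lam = np.einsum("kii->k", W) / (nk * d)
        C = eye
        for _ in range(_INNER_MAX):
            Csum = (W / lam[:, None, None]).sum(axis=0)
            sign, logdet = np.linalg.slogdet(Csum)
            if sign <= 0:
                raise DegenerateFitError("singular pooled scatter (VEE)")
            C = Csum / np.exp(logdet / d)
            Cinv = np.linalg.inv(C)
            lam_new = np.einsum("kij,ji->k", W, Cinv) / (nk * d)
            if np.max(np.abs(lam_new - lam) / lam_new) < _INNER_TOL:
                lam = lam_new
                break
            lam = lam_new
        return lam[:, None, None] * C[None]

    if family in ("EEV", "VEV"):
        vals = np.empty((G, d))
        vecs = np.empty((G, d, d))
        for k in range(G):
            vals[k], vecs[k] = _eigh_desc(W[k])
        if np.any(vals <= 0):
            raise DegenerateFitError("non-positive scatter eigenvalue")
        if family == "EEV":
            lamA = vals.sum(axis=0) / n                  # lambda * A jointly
            return np.stack([vecs[k] @ np.diag(lamA) @ vecs[k].T for k in range(G)])
        lam = np.einsum("kii->k", W) / (nk * d)
        for _ in range(_INNER_MAX):
            A, _ = _det1((vals / lam[:, None]).sum(axis=0))
            lam_new = (vals / A).sum(axis=1) / (nk * d)
            if np.max(np.abs(lam_new - lam) / lam_new) < _INNER_TOL:
                lam = lam_new
                break
            lam = lam_new
        A, _ = _det1((vals / lam[:, None]).sum(axis=0))
        return np.stack([lam[k] * vecs[k] @ np.diag(A) @ vecs[k].T for k in range(G)])

    if family in ("EVE", "VVE"):
        # shared orientation D, per-component shape A_k; flip-flop between
        # (A, lambda) given D and the MM orientation update given (A, lambda)
        if state is not None and "D" in state:
            D = state["D"]
        else:
            _vals, D = _eigh_desc(W.sum(axis=0))
        lam = np.einsum("kii->k", W) / (nk * d)
        A = np.ones((G, d))
        prev = np.inf
        for _ in range(inner_max):
            dk = np.einsum("ji,kjl,li->ki", D, W, D)     # diag(D^T W_k D)
            if np.any(dk <= 0):
                raise DegenerateFitError("non-positive rotated scatter")
            scales = np.empty(G)
            for k in range(G):
                A[k], scales[k] = _det1(dk[k])
            if family == "EVE":
                lam[:] = scales.sum() / n
            else:
                lam = scales / nk
            B = 1.0 / (A * lam[:, None])
            D = _mm_orientation(W, B, D, max_iter=min(inner_max, 20))
            obj = float(np.sum(np.einsum("ji,kjl,li->ki", D, W, D) * B))
            if abs(prev - obj) <= _INNER_TOL * (1.0 + abs(obj)):
                break
            prev = obj
        if state is not None:
            state["D"] = D
        dk = np.einsum("ji,kjl,li->ki", D, W, D)
        scales = np.empty(G)
        for k in range(G):
            A[k], scales[k] = _det1(dk[k])
        lam = np.full(G, scales.sum() / n) if family == "EVE" else scales / nk
        return np.stack([lam[k] * D @ np.diag(A[k]) @ D.T for k in range(G)])

    raise ValueError(f"unknown covariance family {family!r}")


# ---------------------------------------------------------------------------
# densities and EM
# ---------------------------------------------------------------------------

def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("covariance not positive definite") from exc
    z = solve_triangular(L, (X - mean).T, lower=True, check_finite=False)
    maha = np.sum(z * z, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _component_logdens(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    return np.stack([_log_gaussian(X, means[k], covs[k]) for k in range(means.shape[0])], axis=1)


@dataclass
class GMMFit:
    """A fitted constrained-covariance Gaussian mixture."""

    G: int
    family: str
    means: np.ndarray                 # (G, d)
    covariances: np.ndarray           # (G, d, d)
    proportions: np.ndarray           # (G,)
    loglik: float
    n_params: int
    bic: float
    responsibilities: np.ndarray      # (n, G)
    classification: np.ndarray        # (n,) argmax component index
    converged: bool = True
    degenerate: bool = False
    n_iter: int = 0
    loglik_trace: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.responsibilities.shape[0]

    def predict_logdens(self, X: np.ndarray) -> np.ndarray:
        return logsumexp(
            _component_logdens(np.atleast_2d(X), self.means, self.covariances)
            + np.log(self.proportions), axis=1,
        )

    def to_dict(self) -> dict:
        return {
            "G": self.G,
            "family": self.family,
            "n": int(self.n),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_iter": self.n_iter,
            "proportions": self.proportions.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }


def ward_init(X: np.ndarray, G: int) -> np.ndarray:
    """Deterministic hard initial partition: Ward agglomeration on z-scores."""
    n = X.shape[0]
    if G == 1:
        return np.zeros(n, dtype=int)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    labels = fcluster(linkage(Z, method="ward"), t=G, criterion="maxclust") - 1
    return labels


def _z_from_labels(labels: np.ndarray, G: int) -> np.ndarray:
    z = np.zeros((labels.shape[0], G))
    z[np.arange(labels.shape[0]), labels] = 1.0
    return z


def fit_gmm(
    X: np.ndarray,
    G: int,
    family: str = "VVV",
    *,
    init: str | np.ndarray = "ward",
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 3,
) -> GMMFit:
    """Fit a ``G``-component mixture of the given family by EM.

    ``init`` is ``"ward"`` (deterministic agglomerative start), ``"random"``
    (seeded random responsibilities) or an explicit ``(n, G)`` responsibility
    matrix / ``(n,)`` hard-label vector.  EM stops when the relative
    log-likelihood change drops below ``tol``.  A component whose
    responsibility mass collapses triggers a perturbed restart (up to
    ``n_restarts``), after which :class:`DegenerateFitError` is raised.
    Fits whose covariances hit the eigenvalue floor are returned with
    ``degenerate=True`` and should be excluded from model selection.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, d = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if n <= G:
        raise ValueError(f"need n > G (n={n}, G={G})")
    if family not in FAMILIES:
        raise ValueError(f"unknown covariance family {family!r}")

    rng = np.random.default_rng(seed)
    total_cov_diag = np.var(X, axis=0).mean()
    floor = 1e-10 * max(total_cov_diag, np.finfo(float).tiny)

    if isinstance(init, np.ndarray):
        z0 = _z_from_labels(init.astype(int), G) if init.ndim == 1 else init.astype(float).copy()
        if z0.shape != (n, G):
            raise ValueError("init responsibilities have the wrong shape")
    elif init == "ward":
        z0 = _z_from_labels(ward_init(X, G), G)
    elif init == "random":
        z0 = rng.dirichlet(np.ones(G), size=n)
    else:
        raise ValueError(f"unknown init {init!r}")

    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        z = z0 if attempt == 0 else np.clip(z0 + rng.uniform(0, 0.25, size=z0.shape), 1e-6, None)
        z = z / z.sum(axis=1, keepdims=True)
        try:
            return _em(X, G, family, z, tol, max_iter, floor)
        except DegenerateFitError as err:
            last_err = err
    raise DegenerateFitError(
        f"{family} G={G}: EM collapsed after {n_restarts + 1} attempts ({last_err})"
    )


def _em(X, G, family, z, tol, max_iter, floor) -> GMMFit:
    n, d = X.shape
    loglik = -np.inf
    trace: list[float] = []
    degenerate = False
    converged = False
    it = 0
    # warm-started orientation state turns the capped EVE/VVE M-step into a
    # generalised-EM update (never worse than the previous iteration's)
    mstep_state: dict = {}
    for it in range(1, max_iter + 1):
        nk = z.sum(axis=0)
        if np.any(nk < 1e-6 * n):
            raise DegenerateFitError("component responsibility mass collapsed")
        means = (z.T @ X) / nk[:, None]
        dev = X[None] - means[:, None]                      # (G, n, d)
        W = np.einsum("kn,kni,knj->kij", z.T, dev, dev)
        covs = _cov_mstep(family, W, nk, inner_max=10, state=mstep_state)
        covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
        min_eig = min(np.linalg.eigvalsh(covs[k])[0] for k in range(G))
        if min_eig < floor:
            degenerate = True
            covs = covs + (floor - min_eig) * np.eye(d)[None]
        props = nk / n
        logdens = _component_logdens(X, means, covs) + np.log(props)
        norm = logsumexp(logdens, axis=1)
        new_loglik = float(norm.sum())
        if not np.isfinite(new_loglik):
            raise DegenerateFitError("non-finite log-likelihood")
        trace.append(new_loglik)
        z = np.exp(logdens - norm[:, None])
        if degenerate:
            break
        if new_loglik - loglik < tol * (1.0 + abs(new_loglik)) and it > 1:
            converged = True
            loglik = new_loglik
            break
        loglik = new_loglik
    loglik = trace[-1]
    k_params = count_params(family, G, d)
    return GMMFit(
        G=G,
        family=family,
        means=means,
        covariances=covs,
        proportions=props,
        loglik=loglik,
        n_params=k_params,
        bic=2.0 * loglik - k_params * np.log(n),
        responsibilities=z,
        classification=np.argmax(z, axis=1),
        converged=converged and not degenerate,
        degenerate=degenerate,
        n_iter=it,
        loglik_trace=trace,
    )


def bic_of(fit: GMMFit) -> float:
    """BIC on the maximised scale: ``2 loglik - n_params ln(n)``."""
    return 2.0 * fit.loglik - fit.n_params * np.log(fit.n)
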