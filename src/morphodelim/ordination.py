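"""Ordination and permutation tests: PCA, DAPC, PERMANOVA.

PERMANOVA here is the Euclidean-distance partitioning of sums of squares,

    pseudo-F = [SS_between / (K-1)] / [SS_within / (n-K)],
    R^2      = SS_between / SS_total,

with significance from seeded label permutations using the add-one
convention p = (#{F_perm >= F_obs} + 1) / (P + 1), so the smallest
attainable p with P permutations is 1/(P+1).  On Euclidean distances the
partition is identical whether computed from the distance matrix or from
coordinate sums of squares, and running it on all PCA scores equals
running it on the original (corrected) variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PCAResult",
    "DAPCResult",
    "PermanovaResult",
    "pca",
    "dapc",
    "permanova",
    "pairwise_permanova",
]


@dataclass
class PCAResult:
    scores: np.ndarray              # (n, d)
    loadings: np.ndarray            # (d, d), columns are PCs
    explained: np.ndarray           # variance proportions, sum 1
    mean: np.ndarray
    scale: np.ndarray | None        # column SDs when scaled, else None

    def reconstruct(self) -> np.ndarray:
        X = self.scores @ self.loadings.T
        if self.scale is not None:
            X = X * self.scale
        return X + self.mean


@dataclass
class DAPCResult:
    n_pcs: int
    ld_scores: np.ndarray           # (n, n_axes)
    n_axes: int
    accuracy: float                 # training re-assignment accuracy
    groups: list[str]
    predicted: np.ndarray


@dataclass
class PermanovaResult:
    comparison: str
    F: float
    R2: float
    p: float
    p_adjusted: float
    n_permutations: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison, "F": self.F, "R2": self.R2,
            "p": self.p, "p_adjusted": self.p_adjusted,
            "n_permutations": self.n_permutations, "seed": self.seed,
        }


def pca(X: np.ndarray, scale: bool = False) -> PCAResult:
    """Principal components via eigen-decomposition of the covariance
    (or correlation, when ``scale``) matrix.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so results are deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need n >= 2")
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            j = int(np.argmax(sd == 0))
            raise ValueError(f"column {j} is constant; cannot scale to unit variance")
        Xc = Xc / sd
    cov = (Xc.T @ Xc) / (n - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    flip = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    flip[flip == 0] = 1.0
    vecs = vecs * flip
    total = vals.sum()
    explained = vals / total if total > 0 else np.full_like(vals, 1.0 / len(vals))
    return PCAResult(scores=Xc @ vecs, loadings=vecs, explained=explained,
                     mean=mean, scale=sd)


def dapc(X: np.ndarray, labels, n_pcs: int | str = "auto") -> DAPCResult:
    """Discriminant analysis of principal components.

    The data are reduced to ``n_pcs`` leading PCs (``"auto"``: the smallest
    number explaining >= 90% of variance, capped at n/3), then linear
    discriminant axes are computed on the retained scores.  ``n_pcs`` must
    stay below ``n - K`` to avoid a saturated discriminant fit.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    groups = sorted(set(labels))
    K = len(groups)
    n = X.shape[0]
    if K < 2:
        raise ValueError("need at least 2 groups")
    pc = pca(X)
    if n_pcs == "auto":
        cum = np.cumsum(pc.explained)
        n_pcs = int(np.searchsorted(cum, 0.90) + 1)
        n_pcs = max(1, min(n_pcs, n // 3, n - K - 1))
    n_pcs = int(n_pcs)
    if n_pcs >= n - K:
        raise ValueError(f"n_pcs={n_pcs} >= n - K = {n - K}: overfit guard")
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    scores = pc.scores[:, :n_pcs]
    lda = LinearDiscriminantAnalysis(solver="eigen")
    lda.fit(scores, labels)
    ld = lda.transform(scores)
    n_axes = min(K - 1, n_pcs)
    predicted = lda.predict(scores)
    return DAPCResult(
        n_pcs=n_pcs, ld_scores=ld[:, :n_axes], n_axes=n_axes,
        accuracy=float(np.mean(predicted == labels)), groups=groups,
        predicted=predicted,
    )


def _ss_partition(X: np.ndarray, group_idx: np.ndarray, K: int) -> tuple[float, float]:
    """(SS_between, SS_total) from coordinates; Euclidean geometry."""
    grand = X.sum(axis=0)
    n = X.shape[0]
    ss_total = float(np.sum(X * X) - grand @ grand / n)
    ss_b = 0.0
    for k in range(K):
        mask = group_idx == k
        nk = mask.sum()
        s = X[mask].sum(axis=0)
        ss_b += float(s @ s) / nk
    ss_b -= float(grand @ grand) / n
    return ss_b, ss_total


def permanova(
    X: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    ids=None,
    comparison: str | None = None,
) -> PermanovaResult:
    """Euclidean PERMANOVA of group separation.

    ``ids``, when given, canonicalises the permutation stream: specimens
    are sorted by id before permuting, so the p-value does not depend on
    input row order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=object).astype(str)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if ids is not None:
        order = np.argsort(np.asarray(ids, dtype=object).astype(str), kind="stable")
        X, labels = X[order], labels[order]
    groups = sorted(set(labels))
    K = len(groups)
    if K < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has a single specimen")
    n = X.shape[0]
    gidx = np.searchsorted(groups, labels)
    ss_b, ss_t = _ss_partition(X, gidx, K)
    ss_w = ss_t - ss_b
    F_obs = (ss_b / (K - 1)) / (ss_w / (n - K))
    R2 = ss_b / ss_t

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssb_p, _ = _ss_partition(X, gidx[perm], K)
        ssw_p = ss_t - ssb_p
        F_p = (ssb_p / (K - 1)) / (ssw_p / (n - K))
        if F_p >= F_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        comparison=comparison or " vs ".join(groups), F=float(F_obs), R2=float(R2),
        p=float(p), p_adjusted=float(p), n_permutations=n_perm, seed=seed,
    )


def pairwise_permanova(
    X: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    adjust: str = "bonferroni",
    ids=None,
) -> pd.DataFrame:
    """One PERMANOVA per unordered group pair, with p adjusted across pairs."""
    if adjust not in ("bonferroni", "holm", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=object).astype(str)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    results = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            mask = (labels == a) | (labels == b)
            results.append(
                permanova(
                    X[mask], labels[mask], n_perm, seed,
                    ids=None if ids is None else np.asarray(ids, dtype=object)[mask],
                    comparison=f"{a} vs {b}",
                )
            )
    raw = np.array([r.p for r in results])
    method = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}[adjust]
    adj = multipletests(raw, method=method)[1]
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
    return pd.DataFrame([r.to_dict() for r in results])
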