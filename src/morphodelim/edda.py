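"""Supervised delimitation: EDDA fits, greedy merge paths and scheme ranking.

EDDA (eigenvalue-decomposition discriminant analysis) places one Gaussian
on each *known* group, with the across-group covariance structure
constrained by the same fourteen family codes used for mixtures.  Because
the memberships are fixed there is no EM over labels — parameters are the
maximum-likelihood estimates given the grouping — and the classified
log-likelihood

    loglik = sum_i log( pi_{z_i} * phi(x_i | mu_{z_i}, Sigma_{z_i}) )

feeds the same BIC convention (2*loglik - n_params*ln n, maximised).

On top of that sit two ways of comparing taxonomic hypotheses:

* :func:`merge_path` — a greedy agglomeration from the original OTUs down
  to a single group, committing at each level the pairwise merge with the
  highest best-family BIC;
* :func:`compare_schemes` — explicit user-defined schemes, each scored by
  its best-family BIC and ranked via BIC differences, Bayes factors and
  flat-prior posterior model probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmm import FAMILIES, DegenerateFitError, _component_logdens, _cov_mstep, count_covariance_params

__all__ = [
    "EDDAFit",
    "DelimitationScheme",
    "MergeStep",
    "MergePath",
    "fit_edda",
    "best_edda",
    "merge_path",
    "compare_schemes",
    "rank_schemes",
    "format_bayes_factor",
]


@dataclass
class DelimitationScheme:
    """A named taxonomic hypothesis: one group label per specimen."""

    name: str
    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=object)

    @property
    def K(self) -> int:
        return len(set(self.assignment.astype(str)))

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.assignment.astype(str)))

    def coarsens(self, other: "DelimitationScheme") -> bool:
        """True if every group of ``other`` maps into a single group of self."""
        mine = self.assignment.astype(str)
        theirs = other.assignment.astype(str)
        return all(len(set(mine[theirs == g])) == 1 for g in set(theirs))


@dataclass
class EDDAFit:
    """Maximum-likelihood labelled-Gaussian fit under a covariance family."""

    groups: list[str]
    family: str
    means: np.ndarray
    covariances: np.ndarray
    proportions: np.ndarray
    loglik: float
    n_params: int
    bic: float
    n: int

    @property
    def K(self) -> int:
        return len(self.groups)


def _edda_params(K: int, d: int, family: str, *, count_proportions: bool = True) -> int:
    base = (K - 1) if count_proportions else 0
    return base + K * d + count_covariance_params(family, K, d)


def fit_edda(
    X: np.ndarray,
    scheme: DelimitationScheme | np.ndarray,
    family: str = "VVV",
    *,
    count_proportions: bool = True,
) -> EDDAFit:
    """ML fit of one Gaussian per group with family-constrained covariances.

    Every group needs at least 2 specimens.  Mixing proportions are the
    group frequencies and count as K-1 free parameters by default.
    Raises :class:`~morphodelim.gmm.DegenerateFitError` when the family is
    not estimable for this grouping (e.g. a full per-group covariance with
    fewer specimens than dimensions).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if isinstance(scheme, DelimitationScheme):
        labels = scheme.assignment.astype(str)
    else:
        labels = np.asarray(scheme, dtype=object).astype(str)
    if labels.shape[0] != n:
        raise ValueError("scheme length does not match X")
    if family not in FAMILIES:
        raise ValueError(f"unknown covariance family {family!r}")
    groups = sorted(set(labels))
    K = len(groups)
    if n <= K:
        raise ValueError(f"need n > K (n={n}, K={K})")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 specimens; EDDA requires >= 2")

    z = np.zeros((n, K))
    for k, g in enumerate(groups):
        z[labels == g, k] = 1.0
    nk = z.sum(axis=0)
    means = (z.T @ X) / nk[:, None]
    dev = X[None] - means[:, None]
    W = np.einsum("kn,kni,knj->kij", z.T, dev, dev)
    covs = _cov_mstep(family, W, nk)
    covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
    floor = 1e-10 * max(np.var(X, axis=0).mean(), np.finfo(float).tiny)
    if min(np.linalg.eigvalsh(covs[k])[0] for k in range(K)) < floor:
        raise DegenerateFitError(f"{family}: covariance hit the eigenvalue floor")
    props = nk / n
    logdens = _component_logdens(X, means, covs)
    idx = np.argmax(z, axis=1)
    loglik = float(np.sum(logdens[np.arange(n), idx] + np.log(props[idx])))
    k_params = _edda_params(K, d, family, count_proportions=count_proportions)
    return EDDAFit(
        groups=groups,
        family=family,
        means=means,
        covariances=covs,
        proportions=props,
        loglik=loglik,
        n_params=k_params,
        bic=2.0 * loglik - k_params * np.log(n),
        n=n,
    )


def best_edda(
    X: np.ndarray,
    scheme: DelimitationScheme | np.ndarray,
    families: tuple[str, ...] = FAMILIES,
    *,
    count_proportions: bool = True,
) -> EDDAFit:
    """Best-BIC EDDA fit over a family set; non-estimable families are skipped.

    Ties go to the family with fewer parameters, then alphabetical code.
    """
    fits: list[EDDAFit] = []
    for fam in families:
        try:
            fits.append(fit_edda(X, scheme, fam, count_proportions=count_proportions))
        except DegenerateFitError:
            continue
    if not fits:
        raise DegenerateFitError("no covariance family was estimable for this scheme")
    return min(fits, key=lambda f: (-f.bic, f.n_params, f.family))


# ---------------------------------------------------------------------------
# greedy merge path
# ---------------------------------------------------------------------------

@dataclass
class MergeStep:
    scheme: DelimitationScheme
    merged_pair: tuple[str, str] | None   # None for the starting scheme
    fit: EDDAFit


@dataclass
class MergePath:
    """Greedy lumping sequence from the original OTUs down to one group."""

    steps: list[MergeStep] = field(default_factory=list)

    @property
    def schemes(self) -> list[DelimitationScheme]:
        return [s.scheme for s in self.steps]

    def comparison(self) -> pd.DataFrame:
        return _comparison_frame(
            [(s.scheme.name, s.scheme.K, s.fit.family, s.fit.bic) for s in self.steps]
        )

    @property
    def best_step(self) -> MergeStep:
        return max(self.steps, key=lambda s: s.fit.bic)


def _merged_name(a: str, b: str) -> str:
    return "-".join(sorted([a, b]))


def _scheme_name(groups: list[str]) -> str:
    return " | ".join(sorted(groups))


def merge_path(
    X: np.ndarray,
    otu_labels,
    families: tuple[str, ...] = FAMILIES,
    *,
    count_proportions: bool = True,
) -> MergePath:
    """Greedily merge the two most similar groups at each level, by BIC.

    Starting from the OTU labels, every unordered pair of current groups is
    tentatively merged and scored with its best-family EDDA BIC; the merge
    with the highest BIC is committed, until a single group remains.  Equal
    BICs are broken by the lexicographically first pair name.  The path is
    a single greedy trajectory, not an exhaustive partition search.
    """
    labels = np.asarray([str(v) for v in np.asarray(otu_labels).ravel()], dtype=object)
    start = DelimitationScheme(_scheme_name(sorted(set(labels))), labels.copy())
    if start.K < 2:
        raise ValueError("need at least 2 OTUs to build a merge path")
    path = MergePath([MergeStep(start, None, best_edda(X, start, families,
                                                      count_proportions=count_proportions))])
    current = labels.copy()
    while len(set(current)) > 1:
        groups = sorted(set(current))
        best: tuple[float, tuple[str, str]] | None = None
        best_fit = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                trial = current.copy()
                trial[(trial == a) | (trial == b)] = _merged_name(a, b)
                try:
                    fit = best_edda(X, trial, families, count_proportions=count_proportions)
                except DegenerateFitError:
                    continue
                key = (-fit.bic, (a, b))
                if best is None or key < (-best[0], best[1]):
                    best = (fit.bic, (a, b))
                    best_fit = fit
        if best is None:
            raise DegenerateFitError("no pairwise merge was estimable at this level")
        a, b = best[1]
        current[(current == a) | (current == b)] = _merged_name(a, b)
        scheme = DelimitationScheme(_scheme_name(sorted(set(current))), current.copy())
        path.steps.append(MergeStep(scheme, (a, b), best_fit))
    return path


# ---------------------------------------------------------------------------
# explicit hypothesis testing
# ---------------------------------------------------------------------------

def rank_schemes(bics) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BIC differences, Bayes factors and flat-prior posterior probabilities.

    With ``dBIC_i = BIC_best - BIC_i`` (so the best scheme has 0):

    * ``BF_i = exp(dBIC_i / 2)`` — evidence *against* scheme i relative to
      the best one (computed in log space; overflows to ``inf`` only beyond
      float range);
    * ``PP_i = exp(-dBIC_i / 2) / sum_j exp(-dBIC_j / 2)`` — the posterior
      probability of scheme i under equal prior odds.
    """
    bics = np.asarray(bics, dtype=float)
    if bics.size == 0:
        raise ValueError("need at least one BIC value")
    if not np.all(np.isfinite(bics)):
        raise ValueError("BIC values must be finite")
    delta = bics.max() - bics
    with np.errstate(over="ignore"):
        bf = np.exp(delta / 2.0)
    w = np.exp(-delta / 2.0)
    pp = w / w.sum()
    return delta, bf, pp


def format_bayes_factor(bf: float, log_bf: float | None = None) -> str:
    """Table-style BF string: plain to 3 dp, scientific (4 sig. digits) above 1e6."""
    if np.isfinite(bf) and bf <= 1e6:
        return f"{bf:.3f}"
    if not np.isfinite(bf) and log_bf is not None:
        exponent = int(np.floor(log_bf / np.log(10)))
        mantissa = np.exp(log_bf - exponent * np.log(10))
        return f"{mantissa:.3f}E+{exponent}"
    return f"{bf:.3E}"


def _comparison_frame(rows: list[tuple[str, int, str, float]]) -> pd.DataFrame:
    names = [r[0] for r in rows]
    bics = np.array([r[3] for r in rows])
    delta, bf, pp = rank_schemes(bics)
    log_bf = (bics.max() - bics) / 2.0
    df = pd.DataFrame(
        {
            "scheme": names,
            "K": [r[1] for r in rows],
            "family": [r[2] for r in rows],
            "BIC": bics,
            "dBIC": delta,
            "BF": bf,
            "BF_str": [format_bayes_factor(b, lb) for b, lb in zip(bf, log_bf)],
            "PP": pp,
        }
    )
    return df.sort_values("BIC", ascending=False, kind="stable").reset_index(drop=True)


def compare_schemes(
    X: np.ndarray,
    schemes: list[DelimitationScheme],
    families: tuple[str, ...] = FAMILIES,
    *,
    count_proportions: bool = True,
) -> pd.DataFrame:
    """Score explicit delimitation schemes and rank them by BIC / BF / PP.

    Each scheme is scored by its best-family EDDA BIC; the returned table
    is sorted best-first and carries dBIC, Bayes factors and flat-prior
    posterior probabilities.  Scheme names must be unique.
    """
    if len(schemes) < 1:
        raise ValueError("need at least one scheme")
    names = [s.name for s in schemes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate scheme names")
    rows = []
    for s in schemes:
        fit = best_edda(X, s, families, count_proportions=count_proportions)
        rows.append((s.name, s.K, fit.family, fit.bic))
    return _comparison_frame(rows)
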