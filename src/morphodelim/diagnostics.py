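"""Diagnostic-character identification.

Two complementary views of which characters distinguish groups:

* :func:`boruta_select` — an all-relevant feature-selection wrapper around
  a random forest.  Every run appends a shuffled "shadow" copy of each
  surviving character, trains a forest, and scores a *hit* for characters
  whose importance exceeds the best shadow's.  Binomial tests on the hit
  counts (success probability 0.5, Bonferroni-corrected across characters)
  promote characters to Confirmed or demote them to Rejected; undecided
  survivors end Tentative.  Confirmed characters carry real discriminatory
  signal — they classify specimens better than randomised noise does.
* :func:`univariate_tests` — per-character two-group t tests (or one-way
  ANOVA), with multiple-testing adjustment across characters.

The two notions are deliberately different: a character can classify well
without a significant mean shift (e.g. via variance or joint structure),
and vice versa; :func:`diagnostic_report` tabulates the agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BorutaResult",
    "boruta_select",
    "univariate_tests",
    "diagnostic_report",
]


@dataclass
class BorutaResult:
    """Per-character shadow-comparison outcome."""

    decisions: dict[str, str]                 # Confirmed / Tentative / Rejected
    hits: dict[str, int]
    runs: dict[str, int]                      # runs the character participated in
    importance_history: pd.DataFrame          # one row per run: characters + 'shadow_max'
    p_values: dict[str, float]                # final two-sided binomial p (Bonferroni-adj.)

    @property
    def confirmed(self) -> list[str]:
        return sorted(k for k, v in self.decisions.items() if v == "Confirmed")

    @property
    def rejected(self) -> list[str]:
        return sorted(k for k, v in self.decisions.items() if v == "Rejected")

    @property
    def tentative(self) -> list[str]:
        return sorted(k for k, v in self.decisions.items() if v == "Tentative")

    def to_frame(self) -> pd.DataFrame:
        chars = list(self.decisions)
        return pd.DataFrame(
            {
                "character": chars,
                "decision": [self.decisions[c] for c in chars],
                "hits": [self.hits[c] for c in chars],
                "runs": [self.runs[c] for c in chars],
                "p_adjusted": [self.p_values[c] for c in chars],
            }
        )


def _forest_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    rng: np.random.Generator,
    backend: str,
) -> np.ndarray:
    seed = int(rng.integers(0, 2**31 - 1))
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, max_features="sqrt"
    )
    forest.fit(X, y)
    if backend == "gini":
        return forest.feature_importances_
    res = permutation_importance(
        forest, X, y, n_repeats=5, random_state=seed, n_jobs=1, scoring="accuracy"
    )
    return res.importances_mean


def boruta_select(
    X: np.ndarray,
    labels,
    character_names: list[str] | None = None,
    *,
    groups: list[str] | None = None,
    n_trees: int = 500,
    max_runs: int = 100,
    alpha: float = 0.01,
    seed: int | None = None,
    importance: str = "gini",
) -> BorutaResult:
    """Shadow-feature selection of diagnostic characters.

    Parameters
    ----------
    X, labels
        Character matrix and group label per specimen.
    groups
        Optional subset of labels to compare (default: all groups).
    n_trees, max_runs, alpha
        Forest size, run cap, and the significance level of the two-sided
        binomial hit tests (Bonferroni-corrected across characters).
    importance
        ``"gini"`` (impurity decrease; the default, fast and shadow-
        calibrated) or ``"permutation"`` (accuracy drop when a column is
        scrambled; slower but unit-interpretable).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    if character_names is None:
        character_names = [f"char{j + 1}" for j in range(X.shape[1])]
    if groups is not None:
        if len(set(groups)) < 2:
            raise ValueError("need at least 2 groups")
        mask = np.isin(labels, list(groups))
        X, labels = X[mask], labels[mask]
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 groups")
    if X.shape[0] < 5:
        raise ValueError("need at least 5 specimens to train a forest meaningfully")
    for g in set(labels):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 specimens")
    rng = np.random.default_rng(seed)

    chars = list(character_names)
    active = list(range(len(chars)))           # still-undecided or confirmed columns
    decisions = {c: "Tentative" for c in chars}
    hits = {c: 0 for c in chars}
    runs = {c: 0 for c in chars}
    pvals = {c: 1.0 for c in chars}
    history: list[dict[str, float]] = []

    for _run in range(max_runs):
        cols = [j for j in active if decisions[chars[j]] != "Rejected"]
        if not cols:
            break
        Xa = X[:, cols]
        shadows = Xa.copy()
        for jj in range(shadows.shape[1]):
            shadows[:, jj] = rng.permutation(shadows[:, jj])
        imp = _forest_importance(np.hstack([Xa, shadows]), labels, n_trees, rng,
                                 importance)
        real_imp, shadow_imp = imp[: len(cols)], imp[len(cols):]
        shadow_max = float(shadow_imp.max())
        record: dict[str, float] = {"shadow_max": shadow_max}
        for jj, j in enumerate(cols):
            c = chars[j]
            record[c] = float(real_imp[jj])
            runs[c] += 1
            if real_imp[jj] > shadow_max:
                hits[c] += 1
        history.append(record)

        # binomial hit tests with Bonferroni across the full character set
        m = len(chars)
        undecided = [c for c in decisions if decisions[c] == "Tentative"]
        for c in undecided:
            if runs[c] == 0:
                continue
            p = stats.binomtest(hits[c], runs[c], 0.5, alternative="two-sided").pvalue
            p_adj = min(1.0, p * m)
            pvals[c] = p_adj
            if p_adj < alpha:
                decisions[c] = "Confirmed" if hits[c] > runs[c] / 2 else "Rejected"
        if all(v != "Tentative" for v in decisions.values()):
            break

    hist = pd.DataFrame(history)
    return BorutaResult(decisions=decisions, hits=hits, runs=runs,
                        importance_history=hist, p_values=pvals)


def univariate_tests(
    X: np.ndarray,
    labels,
    character_names: list[str] | None = None,
    *,
    groups: tuple[str, str] | None = None,
    test: str = "welch-t",
    adjust: str = "none",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-character mean-difference tests between two groups (or ANOVA).

    Returns one row per character with the statistic, df, raw and adjusted
    p (adjustment across the characters of this comparison) and a
    significance flag at ``alpha`` based on the *adjusted* p ("none" leaves
    p unchanged, matching the common raw-p convention for figures).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    if character_names is None:
        character_names = [f"char{j + 1}" for j in range(X.shape[1])]
    if test not in ("welch-t", "student-t", "anova"):
        raise ValueError(f"unknown test {test!r}")
    if adjust not in ("none", "bonferroni", "holm", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if groups is None:
        gs = sorted(set(labels))
        if test != "anova" and len(gs) != 2:
            raise ValueError("t tests need exactly 2 groups; pass groups=(a, b)")
    else:
        gs = list(groups)
    for g in gs:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 specimens")
    samples = [X[labels == g] for g in gs]

    rows = []
    for j, name in enumerate(character_names):
        vals = [s[:, j] for s in samples]
        if all(np.ptp(v) == 0 for v in vals):
            rows.append({"character": name, "statistic": np.nan, "df": np.nan, "p": np.nan})
            continue
        if test == "anova":
            stat, p = stats.f_oneway(*vals)
            df = (len(gs) - 1, sum(len(v) for v in vals) - len(gs))
            rows.append({"character": name, "statistic": stat, "df": df[1], "p": p})
        else:
            equal_var = test == "student-t"
            res = stats.ttest_ind(vals[0], vals[1], equal_var=equal_var)
            rows.append({"character": name, "statistic": res.statistic,
                         "df": float(res.df), "p": res.pvalue})
    out = pd.DataFrame(rows)
    raw = out["p"].to_numpy()
    ok = np.isfinite(raw)
    adj = raw.copy()
    if adjust != "none" and ok.any():
        method = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}[adjust]
        adj[ok] = multipletests(raw[ok], method=method)[1]
    out["p_adjusted"] = adj
    out["significant"] = np.where(np.isfinite(adj), adj < alpha, False)
    return out


_REPORT_CELLS = {
    ("Confirmed", True): "concordant diagnostic",
    ("Confirmed", False): "discriminatory, not mean-shifted",
    ("Rejected", True): "mean-shifted, weak classifier",
    ("Rejected", False): "concordant non-diagnostic",
    ("Tentative", True): "undecided, mean-shifted",
    ("Tentative", False): "undecided",
}


def diagnostic_report(boruta: BorutaResult, uni: pd.DataFrame) -> pd.DataFrame:
    """Cross Boruta decisions with univariate significance flags.

    Highlights the agreement/disagreement cells — in particular characters
    that classify well without a significant mean difference, and the
    converse.
    """
    uni_chars = list(uni["character"])
    if set(uni_chars) != set(boruta.decisions):
        raise ValueError("Boruta and univariate tables cover different character sets")
    flags = dict(zip(uni["character"], uni["significant"].astype(bool)))
    rows = []
    for c in uni_chars:
        dec = boruta.decisions[c]
        sig = flags[c]
        rows.append({
            "character": c,
            "boruta": dec,
            "significant": sig,
            "interpretation": _REPORT_CELLS[(dec, sig)],
        })
    return pd.DataFrame(rows)
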