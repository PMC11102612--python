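"""Shape statistics: GPA, PCA, permutation MANOVA (RRPP), pairwise tests,
age residualisation, Spearman screening, two-way ANOVA and disparity.

The permutation machinery follows the residual-randomisation family: terms
enter sequentially (group, age, group:age), each term's F statistic is
referenced against permutations of the residuals of the reduced model that
excludes it.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# generalized Procrustes analysis


def centroid_size(config: np.ndarray) -> float:
    c = config - config.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||a R - b|| for centred configs."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d][: a.shape[1]]) @ vt


def generalized_procrustes(configs, tol: float = 1e-10, max_iter: int = 1000
                           ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Iterative GPA: centre, scale to unit centroid size, rotate to the mean.

    Returns (aligned configs (n, k, d), consensus shape, info).  The consensus
    is a fixed point: re-running on the aligned output changes nothing.
    """
    X = np.stack([np.asarray(c, dtype=float) for c in configs])
    if X.ndim != 3 or len(X) < 2:
        raise ValueError("need >= 2 configurations of equal landmark count")
    sizes = np.empty(len(X))
    for i, c in enumerate(X):
        cs = centroid_size(c)
        if cs < 1e-12:
            raise DegenerateDataError(f"configuration {i} has all points coincident")
        sizes[i] = cs
        X[i] = (c - c.mean(axis=0)) / cs
    # initialise the consensus with the normalised average so that already
    # aligned data is a strict fixed point (no collective rotation)
    mean = X.mean(axis=0)
    mean = mean - mean.mean(axis=0)
    norm = np.linalg.norm(mean)
    mean = X[0].copy() if norm < 1e-12 else mean / norm
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean = (new_mean - new_mean.mean(axis=0))
        new_mean /= np.linalg.norm(new_mean)
        delta = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if delta < tol:
            break
    else:
        warnings.warn(f"GPA stopped at max_iter={max_iter} with mean change "
                      f"{delta:.2e} (highly dispersed shapes)", RuntimeWarning,
                      stacklevel=2)
    return X, mean, {"iterations": n_iter, "centroid_sizes": sizes}


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance (translation, scale and rotation removed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = (a - a.mean(axis=0)) / centroid_size(a)
    b = (b - b.mean(axis=0)) / centroid_size(b)
    b = b @ _optimal_rotation(b, a)
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    n_retained: int
    mean: np.ndarray = None

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_retained]


def pca_with_threshold(data: np.ndarray, variance_threshold: float = 0.95,
                       standardize: bool = False) -> PCAResult:
    """Centred PCA retaining the smallest axis count reaching the threshold."""
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2D matrix with >= 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("missing/non-finite values in PCA input")
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance threshold must be in (0, 1]")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).all():
            raise DegenerateDataError("constant matrix")
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if np.allclose(X, X[0]):
        raise DegenerateDataError("constant matrix")
    p = PCA()
    scores = p.fit_transform(X)
    ratios = p.explained_variance_ratio_
    n_ret = int(np.searchsorted(np.cumsum(ratios), variance_threshold - 1e-12) + 1)
    n_ret = min(n_ret, len(ratios))
    return PCAResult(scores=scores, loadings=p.components_,
                     explained_variance_ratio=ratios, n_retained=n_ret,
                     mean=p.mean_)


# ---------------------------------------------------------------------------
# permutation MANOVA (RRPP)


@dataclass
class PermTestResult:
    df: int
    F: float
    R2: float
    p: float
    n_perm: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.R2 <= 1.0 + 1e-9):
            raise ValueError("R2 outside [0, 1]")
        lo = 1.0 / (self.n_perm + 1)
        if not (lo - 1e-12 <= self.p <= 1.0 + 1e-12):
            raise ValueError("permutation p outside attainable range")


def _design_matrices(group, age):
    g = pd.Categorical(group)
    if len(g.categories) < 2:
        raise DegenerateDataError("group factor is constant (confounded design)")
    G = pd.get_dummies(g, drop_first=True).to_numpy(dtype=float)
    n = len(g)
    one = np.ones((n, 1))
    blocks = [one, G]
    if age is not None:
        a = np.asarray(age, dtype=float).reshape(-1, 1)
        a = a - a.mean()
        GA = G * a
        blocks += [a, GA]
    return blocks


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def perm_manova(responses: np.ndarray, group, age=None, n_perm: int = 999,
                seed: int | None = 0) -> dict[str, PermTestResult]:
    """Sequential (type-I) multivariate linear model with RRPP p-values.

    Terms: group, then age and group:age when ``age`` is given.  For each
    term, F = (SS_term/df_term)/(SS_res/df_res) on the summed multivariate
    sums of squares, R2 = SS_term/SS_total, and the p-value counts
    permutations of reduced-model residuals whose F meets or exceeds the
    observed one.
    """
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(Y)
    labels = np.asarray(group)
    counts = pd.Series(labels).value_counts()
    if counts.min() < 3:
        raise ValueError("need n >= 3 per group")
    blocks = _design_matrices(labels, age)
    names = ["group"] if age is None else ["group", "age", "group:age"]
    rng = np.random.default_rng(seed)

    # nested designs X_0 (intercept) .. X_T (full)
    designs = [np.hstack(blocks[: i + 1]) for i in range(len(blocks))]
    hats = [_hat(X) for X in designs]
    ranks = [np.linalg.matrix_rank(X) for X in designs]
    H_full = hats[-1]
    df_res = n - ranks[-1]
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc ** 2).sum())
    if ss_total <= 0:
        raise DegenerateDataError("constant response matrix")
    R_full = Y - H_full @ Y
    ss_res = float((R_full ** 2).sum())

    out: dict[str, PermTestResult] = {}
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    for t, name in enumerate(names, start=1):
        df_t = ranks[t] - ranks[t - 1]
        P_t = hats[t] - hats[t - 1]
        ss_t = float(np.einsum("ij,ij->", P_t @ Y, P_t @ Y))
        F_obs = (ss_t / df_t) / (ss_res / df_res) if df_res > 0 else np.inf
        # RRPP: permute residuals of the reduced model (terms < t)
        fitted_red = hats[t - 1] @ Y
        resid_red = Y - fitted_red
        count = 1
        for perm in perms:
            Yp = fitted_red + resid_red[perm]
            num = float(np.einsum("ij,ij->", P_t @ Yp, P_t @ Yp))
            den = float(((Yp - H_full @ Yp) ** 2).sum())
            Fp = (num / df_t) / (den / df_res) if den > 0 else np.inf
            if Fp >= F_obs - 1e-12:
                count += 1
        out[name] = PermTestResult(df=df_t, F=F_obs, R2=ss_t / ss_total,
                                   p=count / (n_perm + 1), n_perm=n_perm)
    return out


def age_residualize(values: np.ndarray, age: np.ndarray, span: float = 0.75
                    ) -> np.ndarray:
    """Residuals of a local-linear (lowess, tricube) regression on age.

    Columns of a 2D ``values`` matrix are residualised independently.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    age = np.asarray(age, dtype=float)
    if len(age) < 10:
        raise ValueError("need n >= 10 for the non-parametric age regression")
    if np.ptp(age) == 0:
        raise DegenerateDataError("constant age")
    V = np.asarray(values, dtype=float)
    squeeze = V.ndim == 1
    if squeeze:
        V = V[:, None]
    out = np.empty_like(V)
    for j in range(V.shape[1]):
        fit = lowess(V[:, j], age, frac=span, it=0, xvals=age)
        out[:, j] = V[:, j] - fit
    return out[:, 0] if squeeze else out


def pairwise_perm(responses: np.ndarray, group, age=None, n_perm: int = 999,
                  seed: int | None = 0) -> dict[tuple, float]:
    """Permutation tests on group-mean distance for every pair of groups.

    With ``age``, responses are first residualised on age.  The statistic is
    the Euclidean distance between the two group mean vectors; the null
    permutes labels within the pair.  P-values are unadjusted (adjustment is
    the caller's choice).
    """
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    labels = np.asarray(group)
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    for lv in levels:
        if (labels == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has n < 2")
    if age is not None:
        Y = age_residualize(Y, np.asarray(age, dtype=float))
        if Y.ndim == 1:
            Y = Y[:, None]
    rng = np.random.default_rng(seed)
    out = {}
    for a, b in itertools.combinations(levels, 2):
        m = (labels == a) | (labels == b)
        Yp = Y[m]
        la = (labels[m] == a)
        na = int(la.sum())
        stat = np.linalg.norm(Yp[la].mean(axis=0) - Yp[~la].mean(axis=0))
        count = 1
        for _ in range(n_perm):
            perm = rng.permutation(len(Yp))
            pa = perm[:na]
            pb = perm[na:]
            s = np.linalg.norm(Yp[pa].mean(axis=0) - Yp[pb].mean(axis=0))
            if s >= stat - 1e-12:
                count += 1
        out[(a, b)] = count / (n_perm + 1)
    return out


def holm_adjust(pvals: dict) -> dict:
    """Holm step-down adjustment of a dict of p-values."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj = {}
    running = 0.0
    for i, (k, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adj[k] = running
    return adj


def spearman_vs_age(values: np.ndarray, age: np.ndarray) -> tuple[float, float, float]:
    """Spearman rank correlation against age: (S statistic, rho, p).

    S is the rank-difference statistic sum(d_i^2) reported by classical
    implementations, related to rho by rho = 1 - 6S/(n^3 - n) without ties.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    n = len(values)
    if n < 5:
        raise ValueError("need n >= 5")
    if np.ptp(values) == 0 or np.ptp(age) == 0:
        raise DegenerateDataError("ties-only input")
    rho, p = sps.spearmanr(values, age)
    S = (1.0 - rho) * (n ** 3 - n) / 6.0
    return float(S), float(rho), float(p)


def icv_two_way_anova(residual_icv: np.ndarray, sex, group) -> dict[str, dict]:
    """Two-way ANOVA (type II) of residual ICV on sex, group and interaction.

    Returns per-term dicts with df, F, R2 (= SS_term / SS_total) and p.  An
    empty sex-by-group cell drops the interaction with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(residual_icv, dtype=float),
                       "sex": np.asarray(sex), "group": np.asarray(group)})
    for col in ("sex", "group"):
        if df[col].nunique() < 2:
            raise DegenerateDataError(f"factor {col!r} has a single level")
    cells = df.groupby(["sex", "group"]).size()
    full_cells = df["sex"].nunique() * df["group"].nunique()
    formula = "y ~ C(sex) * C(group)"
    if len(cells) < full_cells:
        warnings.warn("empty sex x group cell; dropping the interaction term",
                      RuntimeWarning, stacklevel=2)
        formula = "y ~ C(sex) + C(group)"
    fit = smf.ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    ss_total = float(((df["y"] - df["y"].mean()) ** 2).sum())
    out = {}
    rename = {"C(sex)": "sex", "C(group)": "group",
              "C(sex):C(group)": "sex:group", "Residual": "residual"}
    for term, row in tab.iterrows():
        name = rename.get(term, term)
        out[name] = {"df": float(row["df"]), "F": float(row["F"]),
                     "R2": float(row["sum_sq"] / ss_total), "p": float(row["PR(>F)"])}
    return out


# ---------------------------------------------------------------------------
# disparity


@dataclass
class DisparityResult:
    disparity: dict
    distances: dict
    pairwise_p: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, v in self.disparity.items():
            if v < 0:
                raise ValueError(f"negative disparity for {g!r}")


def disparity_analysis(scores: np.ndarray, group, age=None,
                       age_split: float | None = None) -> DisparityResult:
    """Within-group morphological disparity and pairwise Wilcoxon comparisons.

    Disparity per group is the Procrustes variance in score space (mean
    squared distance of members to the group centroid); the per-subject
    squared distances are compared between groups with Wilcoxon rank-sum
    tests, Bonferroni-adjusted.  With ``age_split`` (days) each group is
    split into young (<= threshold, suffix '-') and old (suffix '+')
    subgroups first.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(group).astype(object)
    if age_split is not None:
        if age is None:
            raise ValueError("age_split requires age values")
        age = np.asarray(age, dtype=float)
        suffix = np.where(age <= age_split, "-", "+")
        labels = np.array([f"{g}{s}" for g, s in zip(labels, suffix)], dtype=object)
    disparity, dists = {}, {}
    for lv in pd.unique(labels):
        m = labels == lv
        if m.sum() < 3:
            warnings.warn(f"group {lv!r} has n < 3; excluded from disparity",
                          RuntimeWarning, stacklevel=2)
            continue
        d2 = ((X[m] - X[m].mean(axis=0)) ** 2).sum(axis=1)
        disparity[lv] = float(d2.mean())
        dists[lv] = d2
    pairs = list(itertools.combinations(dists, 2))
    pw = {}
    for a, b in pairs:
        stat = sps.ranksums(dists[a], dists[b])
        pw[(a, b)] = min(1.0, stat.pvalue * len(pairs))
    return DisparityResult(disparity=disparity, distances=dists, pairwise_p=pw)
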