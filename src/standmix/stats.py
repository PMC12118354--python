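"""Statistical battery for stand/species comparisons.

The suite mirrors a conventional plant-ecology workflow at alpha = 0.05:
Shapiro–Wilk/Levene gating with a natural-log fallback, one-way ANOVA
followed by Tukey's HSD with a compact letter display, pooled-variance
Student's t, two-way factorial ANOVA (classical decomposition when balanced,
Type II sums of squares otherwise), Pearson correlation matrices with
significance stars at 0.05/0.01/0.001, simple linear regression, Z-score
standardisation and random-forest permutation importance expressed as the
percentage increase in out-of-bag MSE (%IncMSE).

Standard machinery is delegated to scipy/statsmodels/scikit-learn; the two
pieces no installed library provides — the insert-and-absorb compact letter
display and the per-tree out-of-bag permutation importance — are implemented
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from string import ascii_lowercase

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor

from .exceptions import DegenerateVarianceError, DomainError, IncompleteDesignError

ALPHA_DEFAULT = 0.05
#: significance-star thresholds used throughout reporting
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for threshold, code in STAR_LEVELS:
        if p < threshold:
            return code
    return ""


@dataclass
class TestResult:
    name: str
    statistic: float
    df: tuple
    pvalue: float
    effect: dict = field(default_factory=dict)
    transform: str = "none"
    alpha: float = ALPHA_DEFAULT


# ---------------------------------------------------------------------------
# assumption gating

@dataclass
class GateReport:
    transform: str  # "none" | "log"
    rounds: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def _gate_round(groups, alpha):
    shapiro_p = []
    for g in groups:
        g = np.asarray(g, float)
        if len(g) < 3 or np.ptp(g) == 0:
            shapiro_p.append(np.nan)  # Shapiro-Wilk undefined; skipped
        else:
            shapiro_p.append(float(sps.shapiro(g).pvalue))
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        levene_p = float(sps.levene(*groups).pvalue)
    else:
        levene_p = np.nan
    failed = any(p < alpha for p in shapiro_p if np.isfinite(p)) or (
        np.isfinite(levene_p) and levene_p < alpha
    )
    return {"shapiro_p": shapiro_p, "levene_p": levene_p, "failed": failed}


def gate_and_transform(groups, alpha: float = ALPHA_DEFAULT):
    """Normality/homogeneity gate with a natural-log fallback.

    Each group is Shapiro–Wilk tested and the set Levene tested; if either
    fails at ``alpha``, all groups are natural-log transformed and re-tested.
    If the transformed data still fail, the analysis proceeds anyway and the
    report carries a warning. Returns ``(groups_out, GateReport)``.
    """
    groups = [np.asarray(g, float) for g in groups]
    report = GateReport(transform="none")
    first = _gate_round(groups, alpha)
    report.rounds.append(first)
    if not first["failed"]:
        return groups, report
    if any(np.any(g <= 0) for g in groups):
        raise DomainError(
            "log transform required but data contain non-positive values; "
            "shift the data or use a different transform"
        )
    logged = [np.log(g) for g in groups]
    report.transform = "log"
    second = _gate_round(logged, alpha)
    report.rounds.append(second)
    if second["failed"]:
        report.warnings.append(
            "assumption checks still fail after log transform; proceeding"
        )
    return logged, report


# ---------------------------------------------------------------------------
# location tests

def one_way_anova(groups, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Classical one-way ANOVA: F = MS_between / MS_within, df (k-1, N-k)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DomainError("one-way ANOVA needs >= 2 groups with n >= 2 each")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        raise DegenerateVarianceError("zero within-group variance in every group")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(
        name="one_way_anova",
        statistic=float(f),
        df=(df_b, df_w),
        pvalue=p,
        effect={
            "ss_between": float(ss_between),
            "ss_within": float(ss_within),
            "group_means": [float(g.mean()) for g in groups],
        },
        alpha=alpha,
    )


def student_t(a, b, equal_var: bool = True, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Two-sided Student's t (pooled variance by default; Welch optional)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("Student's t needs n >= 2 in both samples")
    if equal_var and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("student_t", 0.0, (len(a) + len(b) - 2,), 1.0, alpha=alpha)
        raise DegenerateVarianceError(
            "zero pooled variance with unequal means: t undefined"
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return TestResult(
        name="student_t" if equal_var else "welch_t",
        statistic=float(res.statistic),
        df=(df,),
        pvalue=float(res.pvalue),
        effect={"mean_a": float(a.mean()), "mean_b": float(b.mean())},
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display

def compact_letters(labels, means, sig_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    ``sig_pairs`` is an iterable of label pairs that differ significantly.
    Two groups share a letter iff no significant difference separates them
    (within the limits of the algorithm: significant pairs never share;
    non-significant pairs always share at least one letter). Letters are
    ordered so 'a' contains the highest mean.
    """
    labels = list(labels)
    means = dict(zip(labels, means))
    sets: list[set] = [set(labels)]
    for i, j in sig_pairs:
        new_sets: list[set] = []
        for s in sets:
            if i in s and j in s:
                new_sets.append(s - {i})
                new_sets.append(s - {j})
            else:
                new_sets.append(s)
        # absorb: drop any set contained in another (keep one of duplicates)
        sets = []
        for s in new_sets:
            if any(s < t for t in new_sets):
                continue
            if any(s == t for t in sets):
                continue
            sets.append(s)
    sets.sort(key=lambda s: -max(means[g] for g in s) if s else np.inf)
    letters = {g: "" for g in labels}
    for letter, s in zip(ascii_lowercase, sets):
        for g in sorted(s, key=lambda g: -means[g]):
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in labels}


def tukey_hsd(groups, labels=None, alpha: float = ALPHA_DEFAULT):
    """Tukey's HSD (Tukey–Kramer for unequal n) with compact letters.

    Pairwise p-values come from the studentized-range distribution with the
    pooled within-group mean square. Returns ``(pairwise, letters)`` where
    ``pairwise`` is a DataFrame (group_a, group_b, diff, p) and ``letters``
    maps group label -> compact letters (lowest letter = highest mean).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise DomainError("Tukey's test needs >= 2 groups")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    res = sps.tukey_hsd(*groups)
    rows = []
    sig = []
    for i, j in combinations(range(len(groups)), 2):
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "diff": float(groups[i].mean() - groups[j].mean()),
                "p": p,
            }
        )
        if p < alpha:
            sig.append((labels[i], labels[j]))
    letters = compact_letters(labels, [g.mean() for g in groups], sig)
    return pd.DataFrame(rows), letters


# ---------------------------------------------------------------------------
# two-way factorial ANOVA

def _is_balanced(counts: np.ndarray) -> bool:
    return counts.min() == counts.max()


def two_way_anova(
    response,
    factor_a,
    factor_b,
    a_name: str = "A",
    b_name: str = "B",
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Two-way ANOVA with interaction.

    Balanced layouts use the classical orthogonal decomposition
    SS_total = SS_A + SS_B + SS_AB + SS_E; unbalanced layouts fall back to
    Type II sums of squares via statsmodels. Every crossed cell must be
    non-empty — an incomplete layout raises, naming the first empty cell
    (callers subset incomplete field designs to complete species-pair
    layouts first).

    Returns a DataFrame with rows [A, B, A:B, Residual] and columns
    term/df/sum_sq/F/p.
    """
    y = np.asarray(response, float)
    fa = pd.Categorical(factor_a)
    fb = pd.Categorical(factor_b)
    if len(fa.categories) < 2 or len(fb.categories) < 2:
        raise DomainError("two-way ANOVA needs >= 2 levels per factor")
    counts = np.zeros((len(fa.categories), len(fb.categories)), dtype=int)
    np.add.at(counts, (fa.codes, fb.codes), 1)
    if (counts == 0).any():
        i, j = np.argwhere(counts == 0)[0]
        raise IncompleteDesignError(
            f"empty design cell ({fa.categories[i]!r}, {fb.categories[j]!r}); "
            "subset to a complete layout first"
        )
    a, b = counts.shape
    n = len(y)
    df_e = n - a * b
    if df_e < 1:
        raise DomainError("no residual degrees of freedom for the interaction")

    if _is_balanced(counts):
        grand = y.mean()
        sums = np.zeros((a, b))
        np.add.at(sums, (fa.codes, fb.codes), y)
        cell_means = sums / counts
        a_means = (cell_means * counts).sum(axis=1) / counts.sum(axis=1)
        b_means = (cell_means * counts).sum(axis=0) / counts.sum(axis=0)
        ss_a = float((counts.sum(axis=1) * (a_means - grand) ** 2).sum())
        ss_b = float((counts.sum(axis=0) * (b_means - grand) ** 2).sum())
        ss_cells = float((counts * (cell_means - grand) ** 2).sum())
        ss_ab = ss_cells - ss_a - ss_b
        ss_t = float(((y - grand) ** 2).sum())
        ss_e = ss_t - ss_cells
        ss = [ss_a, ss_b, ss_ab]
    else:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        frame = pd.DataFrame({"y": y, "fa": fa, "fb": fb})
        model = smf.ols("y ~ C(fa) * C(fb)", data=frame).fit()
        table = sm.stats.anova_lm(model, typ=2)
        ss = [
            float(table.loc["C(fa)", "sum_sq"]),
            float(table.loc["C(fb)", "sum_sq"]),
            float(table.loc["C(fa):C(fb)", "sum_sq"]),
        ]
        ss_e = float(table.loc["Residual", "sum_sq"])

    dfs = [a - 1, b - 1, (a - 1) * (b - 1)]
    mse = ss_e / df_e
    if mse == 0:
        raise DegenerateVarianceError("zero residual variance: F undefined")
    rows = []
    for term, s, d in zip([a_name, b_name, f"{a_name}:{b_name}"], ss, dfs):
        f = (s / d) / mse
        rows.append(
            {"term": term, "df": d, "sum_sq": s, "F": f, "p": float(sps.f.sf(f, d, df_e))}
        )
    rows.append({"term": "Residual", "df": df_e, "sum_sq": ss_e, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation / regression / standardisation

@dataclass
class CorrelationMatrix:
    variables: list
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for v1, v2 in combinations(self.variables, 2):
            rows.append(
                {
                    "var1": v1,
                    "var2": v2,
                    "r": self.r.loc[v1, v2],
                    "p": self.p.loc[v1, v2],
                    "stars": self.stars.loc[v1, v2],
                    "n": self.n.loc[v1, v2],
                }
            )
        return pd.DataFrame(rows)


def pearson_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation matrix with significance stars.

    Two-sided p-values via t = r sqrt((n-2)/(1-r^2)); stars at
    0.05/0.01/0.001. Pairs with fewer than 3 complete rows or a
    zero-variance variable are reported missing with a warning.
    """
    variables = list(table.columns)
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(table))
    for i, j in combinations(range(k), 2):
        pair = table.iloc[:, [i, j]].dropna()
        n[i, j] = n[j, i] = len(pair)
        if len(pair) < 3:
            warnings.warn(
                f"fewer than 3 complete rows for ({variables[i]}, {variables[j]})"
            )
            r[i, j] = r[j, i] = p[i, j] = p[j, i] = np.nan
            continue
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"zero variance in pair ({variables[i]}, {variables[j]}); r undefined"
            )
            r[i, j] = r[j, i] = p[i, j] = p[j, i] = np.nan
            continue
        res = sps.pearsonr(x, y)
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    star = np.vectorize(lambda q: "" if not np.isfinite(q) else stars(q))(p)
    np.fill_diagonal(star, "")
    idx = pd.Index(variables)
    return CorrelationMatrix(
        variables=variables,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        stars=pd.DataFrame(star, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


def linear_fit(x, y, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Ordinary least squares y ~ x; p for the slope; R^2 = squared Pearson r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3:
        raise DomainError("linear regression needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateVarianceError("constant x: slope undefined")
    if np.ptp(y) == 0:
        return TestResult(
            "linear_regression",
            0.0,
            (len(x) - 2,),
            1.0,
            effect={"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0},
            alpha=alpha,
        )
    res = sps.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return TestResult(
        "linear_regression",
        float(t),
        (len(x) - 2,),
        float(res.pvalue),
        effect={
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
        },
        alpha=alpha,
    )


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise Z-score (sample SD, ddof=1). Constant columns raise."""
    out = table.copy().astype(float)
    for col in out.columns:
        sd = out[col].std(ddof=1)
        if not sd > 0:
            raise DomainError(f"constant column {col!r}: Z-score undefined")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# random-forest permutation importance (%IncMSE)

def _bootstrap_indices(tree_seed: int, n_samples: int) -> np.ndarray:
    # replicates sklearn's per-tree bootstrap (max_samples=None)
    return np.random.RandomState(tree_seed).randint(0, n_samples, n_samples)


def rf_importance(
    predictors: pd.DataFrame,
    response,
    n_trees: int = 500,
    mtry: int | None = None,
    min_samples_leaf: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-bag permutation importance of a regression forest, as %IncMSE.

    For each tree, each predictor is permuted on that tree's out-of-bag
    samples and the increase in the tree's OOB MSE recorded; the importance
    of a predictor is the mean increase across trees expressed as a
    percentage of the mean OOB MSE. Negative importances are reported as-is.
    Deterministic under a fixed seed. ``mtry`` defaults to max(1, p//3),
    the regression-forest convention.

    Returns a DataFrame (predictor, pct_inc_mse, rank), rank 1 = largest.
    """
    X = predictors.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n < 10:
        raise DomainError("random forest importance needs >= 10 rows")
    if p < 2:
        raise DomainError("random forest importance needs >= 2 predictors")
    if p > n:
        warnings.warn("more predictors than rows; forest fitted anyway")
    if mtry is None:
        mtry = max(1, p // 3)

    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_samples_leaf,
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)

    # per-tree OOB masks, replicating sklearn's unweighted per-tree bootstrap
    # (unit sample weights, max_samples=None -> n draws with replacement
    # seeded by the tree's random_state)
    def oob_indices(tree):
        mask = np.ones(n, dtype=bool)
        mask[_bootstrap_indices(tree.random_state, n)] = False
        return np.where(mask)[0]

    X32 = X.astype(np.float32)  # tree_.predict via check_input=False wants float32
    increases = np.zeros(p)
    base_total = 0.0
    used_trees = 0
    perm_rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 1]))
    for tree in forest.estimators_:
        oob = oob_indices(tree)
        if len(oob) < 2:
            continue
        Xo, yo = X32[oob], y[oob]
        base_mse = float(np.mean((tree.predict(Xo, check_input=False) - yo) ** 2))
        for j in range(p):
            perm = perm_rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            perm_mse = float(np.mean((tree.predict(Xp, check_input=False) - yo) ** 2))
            increases[j] += perm_mse - base_mse
        base_total += base_mse
        used_trees += 1
    if used_trees == 0:
        raise DegenerateVarianceError("no tree had enough out-of-bag samples")
    pct = 100.0 * (increases / used_trees) / (base_total / used_trees)
    table = pd.DataFrame(
        {"predictor": list(predictors.columns), "pct_inc_mse": pct}
    ).sort_values("pct_inc_mse", ascending=False, ignore_index=True)
    table["rank"] = np.arange(1, p + 1)
    return table
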