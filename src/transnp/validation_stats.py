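"""Genotype QC and the validation statistical battery.

Implements the statistics used to compare two discovery platforms and to
model assay outcomes: Yates continuity-corrected chi-square for 2x2
tables, Mann-Whitney U with Monte-Carlo permutation confidence
intervals, the paired Wilcoxon signed-rank test, binomial logistic
regression with enter/backward-Wald variable selection, and ROC analysis
with DeLong (or Hanley-McNeil) AUC standard errors and a Youden-optimal
cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_core import DataError, GenotypeMatrix, get_logger

__all__ = [
    "TwoByTwoTable",
    "LogisticModel",
    "RocResult",
    "MannWhitneyResult",
    "apply_qc",
    "yates_chi2",
    "chi2_yates",
    "mann_whitney_mc",
    "wilcoxon_signed_rank",
    "logistic_fit",
    "roc_analysis",
    "compare_platforms",
    "DEFAULT_VARIABLE_TESTS",
]

log = get_logger(__name__)


@dataclass
class TwoByTwoTable:
    """2x2 contingency table; rows = groups, columns = outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise DataError("empty table")


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------

def apply_qc(matrix: GenotypeMatrix, min_call_rate: float = 0.8) -> GenotypeMatrix:
    """Drop samples below the call-rate threshold; flag unclustered loci.

    Sample call rates are recomputed after removal; loci with
    ``cluster_ok = False`` stay in the matrix but will be reported as
    conversion failures downstream. All samples removed is an error.
    """
    rates = matrix.call_rates()
    keep = rates[rates >= min_call_rate].index
    if len(keep) == 0:
        raise DataError("QC removed every sample")
    dropped = len(matrix.samples) - len(keep)
    if dropped:
        log.info("QC: removed %d samples below call rate %.2f", dropped, min_call_rate)
    return GenotypeMatrix(matrix.calls[keep].copy(), matrix.cluster_ok.copy())


# ---------------------------------------------------------------------------
# Chi-square with continuity correction
# ---------------------------------------------------------------------------

def yates_chi2(a, b, c, d, correction: bool = True):
    """Vectorized Pearson chi-square for 2x2 tables with Yates correction.

    The correction is floored: when |ad - bc| <= N/2 the statistic is 0
    (and p = 1). Tables with a zero marginal give statistic 0, p 1.
    Accepts scalars or arrays; returns (statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    cross = np.abs(a * d - b * c)
    if correction:
        cross = np.maximum(cross - n / 2.0, 0.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * cross**2 / np.where(denom > 0, denom, 1.0), 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(stat == 0.0, 1.0, p)
    return stat, p


def chi2_yates(
    table: TwoByTwoTable | Sequence[int], correction: bool = True
) -> tuple[float, float]:
    """Continuity-corrected chi-square test of one 2x2 table."""
    if not isinstance(table, TwoByTwoTable):
        table = TwoByTwoTable(*table)
    t = table
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        log.warning("chi2_yates: zero marginal; statistic 0, p 1")
        return 0.0, 1.0
    stat, p = yates_chi2(t.a, t.b, t.c, t.d, correction=correction)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

@dataclass
class MannWhitneyResult:
    u: float
    p: float
    p_ci: tuple[float, float]
    n_perm: int


def mann_whitney_mc(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 1_000_000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> MannWhitneyResult:
    """Mann-Whitney U with a Monte-Carlo permutation p-value.

    U is the tie-corrected statistic for the first sample. The p-value
    is estimated by label permutation (add-one estimator) together with
    a 99% Clopper-Pearson confidence interval for the estimate itself.
    Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mu = nx * ny / 2.0
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    chunk = max(1, min(20_000, n_perm))
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((m, nx + ny)), axis=1)[:, :nx]
        u_perm = ranks[perm].sum(axis=1) - nx * (nx + 1) / 2.0
        if alternative == "two-sided":
            exceed += int(np.sum(np.abs(u_perm - mu) >= abs(u_obs - mu) - 1e-12))
        elif alternative == "greater":
            exceed += int(np.sum(u_perm >= u_obs - 1e-12))
        elif alternative == "less":
            exceed += int(np.sum(u_perm <= u_obs + 1e-12))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        done += m
    p = (exceed + 1) / (n_perm + 1)
    ci = stats.binomtest(exceed, n_perm).proportion_ci(confidence_level=0.99)
    return MannWhitneyResult(u_obs, float(p), (float(ci.low), float(ci.high)), n_perm)


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (V, p).

    V is the sum of ranks of positive differences after dropping zero
    differences. Small samples without ties use the exact null; larger
    samples the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataError("paired samples must have equal length")
    diff = x - y
    diff = diff[diff != 0]
    if len(diff) == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(diff))
    v = float(ranks[diff > 0].sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(diff, zero_method="wilcox", correction=False)
    return v, float(res.pvalue)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Binomial logistic fit summary.

    ``terms`` has one row per retained model column (plus the
    intercept): B, se, wald, df, p. ``model_chi2`` is the likelihood
    ratio of the fitted model against the intercept-only model.
    """

    terms: pd.DataFrame
    llf: float
    llnull: float
    model_chi2: float
    model_df: int
    model_p: float
    classification_rate: float
    removed: list[str] = field(default_factory=list)
    separation_flag: bool = False

    @property
    def intercept(self) -> float:
        return float(self.terms.loc["const", "B"])


def _expand_predictors(
    predictors: pd.DataFrame, categorical: Sequence[str] | None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand categoricals to indicator contrasts (reference = last level)."""
    if categorical is None:
        categorical = [
            c
            for c in predictors.columns
            if predictors[c].dtype == object or str(predictors[c].dtype) == "category"
        ]
    groups: dict[str, list[str]] = {}
    cols = []
    for name in predictors.columns:
        col = predictors[name]
        if name in categorical:
            levels = list(pd.unique(col.astype(str)))
            dummy_levels = levels[:-1]  # last level is the reference
            members = []
            for i, level in enumerate(dummy_levels, start=1):
                dname = f"{name}({i})"
                cols.append(pd.Series((col.astype(str) == level).astype(float), name=dname))
                members.append(dname)
            groups[name] = members
        else:
            cols.append(pd.Series(col.astype(float), name=name))
            groups[name] = [name]
    X = pd.concat(cols, axis=1)
    return X, groups


def _drop_degenerate(X: pd.DataFrame, groups: dict[str, list[str]]) -> list[str]:
    """Remove constant or collinear columns (with a warning); return removals."""
    removed = []
    for col in list(X.columns):
        if X[col].nunique() <= 1:
            log.warning("logistic_fit: dropping constant predictor %s", col)
            X.drop(columns=col, inplace=True)
            removed.append(col)
    # collinearity: drop columns that do not increase matrix rank
    keep: list[str] = []
    for col in list(X.columns):
        trial = X[keep + [col]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(col)
        else:
            log.warning("logistic_fit: dropping collinear predictor %s", col)
            removed.append(col)
    drop = [c for c in X.columns if c not in keep]
    if drop:
        X.drop(columns=drop, inplace=True)
    for name in list(groups):
        groups[name] = [c for c in groups[name] if c in X.columns]
        if not groups[name]:
            del groups[name]
    return removed


def _fit_once(X: pd.DataFrame, y: np.ndarray):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(disp=0, maxiter=200)


def _group_wald(result, members: list[str]) -> tuple[float, int, float]:
    """Wald chi-square for a (possibly multi-column) predictor group."""
    params = result.params[members].to_numpy()
    cov = result.cov_params().loc[members, members].to_numpy()
    try:
        w = float(params @ np.linalg.solve(cov, params))
    except np.linalg.LinAlgError:
        w = 0.0
    df = len(members)
    return w, df, float(stats.chi2.sf(w, df))


def logistic_fit(
    predictors: pd.DataFrame,
    outcome: Sequence[int],
    mode: str = "enter",
    removal_p: float = 0.10,
    categorical: Sequence[str] | None = None,
) -> LogisticModel:
    """Maximum-likelihood binomial logistic regression.

    ``mode="enter"`` fits all predictors; ``mode="backward_wald"``
    repeatedly removes the predictor with the largest Wald p-value while
    it exceeds ``removal_p``, refitting each round (multi-level
    categorical predictors are removed as a block on their joint Wald
    test). Reports per-term B, Wald chi-square, df, p; the model
    likelihood-ratio chi-square against the intercept-only model; and
    the correct-classification rate at the 0.5 probability cutoff.
    """
    if mode not in ("enter", "backward_wald"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DataError("outcome must be dichotomous 0/1")
    X, groups = _expand_predictors(predictors.reset_index(drop=True), categorical)
    removed = _drop_degenerate(X, groups)

    separation = False
    while True:
        result = _fit_once(X, y)
        if not np.all(np.isfinite(result.bse)) or np.any(result.bse > 1e3):
            separation = True
        if mode == "enter" or len(groups) == 0:
            break
        worst_name, worst_p = None, -1.0
        for name, members in groups.items():
            _, _, p = _group_wald(result, members)
            if p > worst_p:
                worst_name, worst_p = name, p
        if worst_p <= removal_p:
            break
        log.info("backward: removing %s (Wald p = %.3f)", worst_name, worst_p)
        X = X.drop(columns=groups.pop(worst_name))
        removed.append(worst_name)
        if X.shape[1] == 0:
            result = _fit_once(X, y)
            break

    rows = []
    for name, members in groups.items():
        if len(members) > 1:
            w, df, p = _group_wald(result, members)
            rows.append((name, np.nan, np.nan, w, df, p))
        for col in members:
            b = float(result.params[col])
            se = float(result.bse[col])
            w = (b / se) ** 2 if se > 0 else np.inf
            rows.append((col, b, se, w, 1, float(stats.chi2.sf(w, 1))))
    b0 = float(result.params["const"])
    se0 = float(result.bse["const"])
    w0 = (b0 / se0) ** 2 if se0 > 0 else np.inf
    rows.append(("const", b0, se0, w0, 1, float(stats.chi2.sf(w0, 1))))
    terms = pd.DataFrame(
        rows, columns=["term", "B", "se", "wald", "df", "p"]
    ).set_index("term")

    pred = (result.predict(sm.add_constant(X, has_constant="add")) >= 0.5).astype(float)
    rate = float(np.mean(pred == y))
    model_df = X.shape[1]
    model_chi2 = 2.0 * (result.llf - result.llnull)
    model_p = float(stats.chi2.sf(model_chi2, model_df)) if model_df else 1.0
    if separation:
        log.warning("logistic_fit: possible separation; coefficients unstable")
    return LogisticModel(
        terms=terms,
        llf=float(result.llf),
        llnull=float(result.llnull),
        model_chi2=float(model_chi2),
        model_df=model_df,
        model_p=model_p,
        classification_rate=rate,
        removed=removed,
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    se_auc: float
    z: float
    p: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    method: str = "delong"


def _delong_se(scores: np.ndarray, labels: np.ndarray, auc: float) -> float:
    """DeLong standard error of the AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array(
        [(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos]
    )
    v01 = np.array(
        [(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg]
    )
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def _hanley_se(auc: float, m: int, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    num = auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)
    return float(np.sqrt(num / (m * n)))


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    se_method: str = "delong",
) -> RocResult:
    """ROC curve analysis of a continuous score against a binary label.

    AUC equals the Mann-Whitney concordance (ties counted half); its
    standard error comes from the DeLong estimator (or Hanley-McNeil
    when requested); z tests AUC against 0.5. The optimal cutoff
    maximizes Youden J = sensitivity + specificity - 1 with predicted
    positives defined as score > cutoff; ties prefer the smaller cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("roc_analysis needs both classes present")
    m, n = len(pos), len(neg)
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - m * (m + 1) / 2.0
    auc = float(u / (m * n))
    if se_method == "delong":
        se = _delong_se(scores, labels, auc)
    elif se_method == "hanley":
        se = _hanley_se(auc, m, n)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    z = (auc - 0.5) / se if se > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(z)))
    best = None  # (J, cutoff, sens, spec)
    for cutoff in np.unique(scores):
        sens = float(np.mean(pos > cutoff))
        spec = float(np.mean(neg <= cutoff))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(cutoff), sens, spec)
    return RocResult(
        auc=auc,
        se_auc=se,
        z=float(z),
        p=p,
        optimal_cutoff=best[1],
        sensitivity=best[2],
        specificity=best[3],
        method=se_method,
    )


# ---------------------------------------------------------------------------
# Platform comparison report
# ---------------------------------------------------------------------------

#: Declared test per descriptor variable.
DEFAULT_VARIABLE_TESTS: dict[str, str] = {
    "contig_length": "t",
    "depth": "t",
    "snp_assay_conversion": "chi2",
    "snp_genotype": "chi2",
    "ie_code": "chi2",
    "ie_species_match": "mannwhitney",
    "geosites": "mannwhitney",
    "snp_score": "mannwhitney",
    "msaf": "mannwhitney",
}


def compare_platforms(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    variable_tests: Mapping[str, str] | None = None,
    paired: Mapping[str, tuple[Sequence[float], Sequence[float]]] | None = None,
) -> pd.DataFrame:
    """Compare descriptor tables from two discovery datasets.

    One row per declared variable: quantitative normal variables get a
    two-sample t-test, categorical variables a chi-square (Yates for
    2x2), ordinal/non-normal variables a Mann-Whitney U. ``paired``
    optionally adds Wilcoxon signed-rank rows (e.g. discovery MSAF vs
    validated MAF) as ``(x, y)`` pairs. Variables missing from either
    table are skipped with a warning.
    """
    tests = dict(variable_tests or DEFAULT_VARIABLE_TESTS)
    rows = []
    for var, test in tests.items():
        if var not in table_a.columns or var not in table_b.columns:
            log.warning("compare_platforms: variable %s missing; skipped", var)
            continue
        a = table_a[var].dropna()
        b = table_b[var].dropna()
        if test == "t":
            res = stats.ttest_ind(a.astype(float), b.astype(float), equal_var=True)
            stat, p = float(res.statistic), float(res.pvalue)
        elif test == "chi2":
            ct = pd.crosstab(
                np.repeat(["a", "b"], [len(a), len(b)]),
                pd.concat([a, b]).astype(str).to_numpy(),
            )
            if ct.shape == (2, 2):
                stat, p = chi2_yates(
                    TwoByTwoTable(*ct.to_numpy().ravel().astype(int))
                )
            else:
                stat, p, _, _ = stats.chi2_contingency(ct, correction=False)[:4]
                stat, p = float(stat), float(p)
        elif test == "mannwhitney":
            res = stats.mannwhitneyu(
                a.astype(float), b.astype(float), alternative="two-sided"
            )
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown test {test!r} for {var}")
        rows.append((var, test, stat, p))
    if paired:
        for name, (x, y) in paired.items():
            v, p = wilcoxon_signed_rank(x, y)
            rows.append((name, "wilcoxon", v, p))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])
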