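"""Growth and fitness statistics, effect-size screening, and the 2x2
factorial linear model for treatment marginal means.

The statistics here are deliberately small and explicit: Malthusian growth
rates, relative fitness as a ratio of rates, selection rate as a difference,
Cohen's d with pooled SD, Spearman rank correlation with midrank ties, and
an ordinary-least-squares 2x2 factorial with sequential F-tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthAssay",
    "CompetitionAssay",
    "EffectSizeRecord",
    "SpearmanResult",
    "malthusian",
    "relative_fitness",
    "selection_rate",
    "cohens_d",
    "spearman_rho",
    "factorial_lm",
    "FactorialLMResult",
    "genus_effect_sizes",
]


# ---------------------------------------------------------------------------
# assay records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthAssay:
    """A monoculture growth assay: start/final density over a duration."""

    strain: str
    copper: bool
    density_t0: float
    density_t1: float
    duration: float  # hours

    def __post_init__(self) -> None:
        if self.density_t0 <= 0 or self.density_t1 <= 0:
            raise ValueError("densities must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def m(self) -> float:
        """Malthusian growth parameter (per hour)."""
        return malthusian(self.density_t0, self.density_t1, self.duration)


@dataclass(frozen=True)
class CompetitionAssay:
    """A pairwise competition assay with per-strain densities at both ends."""

    strain_a: str
    strain_b: str
    density_t0_a: float
    density_t1_a: float
    density_t0_b: float
    density_t1_b: float
    duration: float  # hours
    initial_frequency_a: float = 0.5

    def __post_init__(self) -> None:
        for name in ("density_t0_a", "density_t1_a", "density_t0_b", "density_t1_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.initial_frequency_a < 1:
            raise ValueError("initial_frequency_a must lie strictly in (0, 1)")

    @property
    def m_a(self) -> float:
        return malthusian(self.density_t0_a, self.density_t1_a, self.duration)

    @property
    def m_b(self) -> float:
        return malthusian(self.density_t0_b, self.density_t1_b, self.duration)

    @property
    def r(self) -> float:
        """Relative fitness of strain a (ratio of Malthusian parameters)."""
        return relative_fitness(self.m_a, self.m_b)

    @property
    def s(self) -> float:
        """Selection rate of strain a (difference of Malthusian parameters)."""
        return selection_rate(self.m_a, self.m_b)


@dataclass(frozen=True)
class EffectSizeRecord:
    """Per-taxon copper effect size against its no-copper baseline."""

    genus: str
    baseline_mean: float
    cohens_d: float
    n_control: int
    n_copper: int
    high_baseline: bool = False

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_copper < 2:
            raise ValueError("effect sizes need >= 2 observations per treatment")
        if not math.isfinite(self.cohens_d):
            raise ValueError("cohens_d must be finite")


# ---------------------------------------------------------------------------
# elementary fitness statistics
# ---------------------------------------------------------------------------

def malthusian(density_t0: float, density_t1: float, duration: float) -> float:
    """Malthusian growth parameter m = ln(final/start) / duration (per hour)."""
    if np.any(np.asarray(density_t0) <= 0) or np.any(np.asarray(density_t1) <= 0):
        raise ValueError("densities must be positive")
    if np.any(np.asarray(duration) <= 0):
        raise ValueError("duration must be positive")
    return np.log(np.asarray(density_t1) / np.asarray(density_t0)) / duration


def relative_fitness(m_producer: float, m_nonproducer: float) -> float:
    """Relative fitness r = m_producer / m_nonproducer."""
    if m_nonproducer == 0:
        raise ZeroDivisionError(
            "relative fitness is undefined for m_nonproducer == 0; "
            "use selection_rate for rates that can be zero or negative"
        )
    return m_producer / m_nonproducer


def selection_rate(m_mutant: float, m_wildtype: float) -> float:
    """Selection rate s = m_mutant - m_wildtype (well-defined for negative m)."""
    if not (math.isfinite(m_mutant) and math.isfinite(m_wildtype)):
        raise ValueError("Malthusian parameters must be finite")
    return m_mutant - m_wildtype


def cohens_d(group_copper, group_control) -> float:
    """Cohen's d = (mean_copper - mean_control) / pooled SD.

    Pooling uses the classic (n-1)-weighted variance estimate.  Negative
    values indicate lower values under copper.
    """
    a = np.asarray(group_copper, dtype=float)
    b = np.asarray(group_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if pooled <= 0:
        raise ValueError("pooled variance is zero; Cohen's d is undefined")
    return float((a.mean() - b.mean()) / math.sqrt(pooled))


# ---------------------------------------------------------------------------
# Spearman rank correlation with midrank ties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanResult:
    S: float      #: sum of squared rank differences (midranks for ties)
    rho: float    #: Pearson correlation of the rank vectors
    pvalue: float  #: two-sided p (exact permutation for n <= 9, else t-approx)
    n: int
    method: str


def _spearman_core(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    S = float(np.sum((rx - ry) ** 2))
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return S, float("nan")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return S, rho


def spearman_rho(x, y, exact_max_n: int = 9) -> SpearmanResult:
    """Spearman rank correlation with midrank tie handling.

    Returns the S statistic (sum of squared rank differences), rho and a
    two-sided p-value.  For ``n <= exact_max_n`` the p-value is an exact
    permutation p (all n! orderings of y); beyond that the usual t
    approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    S, rho = _spearman_core(x, y)
    if math.isnan(rho):
        return SpearmanResult(S, float("nan"), float("nan"), n, "degenerate")
    if n <= exact_max_n:
        ry = stats.rankdata(y, method="average")
        rx = stats.rankdata(x, method="average")
        rxc = rx - rx.mean()
        count = 0
        total = 0
        obs = abs(rho)
        sx = rx.std()
        sy = ry.std()
        for perm in itertools.permutations(ry):
            ryp = np.asarray(perm)
            r = np.mean(rxc * (ryp - ry.mean())) / (sx * sy)
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact-permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        method = "t-approximation"
    return SpearmanResult(S, rho, float(p), n, method)


# ---------------------------------------------------------------------------
# 2x2 factorial OLS with sequential F-tests and marginal means
# ---------------------------------------------------------------------------

@dataclass
class FactorialLMResult:
    """Fit of an OLS 2x2 factorial (with interaction) on per-unit means."""

    coefficients: dict[str, float]
    anova: pd.DataFrame                 # sequential (type-I) F-tests
    marginal_means: pd.DataFrame        # per factor level, pooled over the other
    residual_df: int
    sigma2: float
    reduced_terms: list[str] = field(default_factory=list)

    def coef_vector(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))


def _design_matrix(a: np.ndarray, b: np.ndarray, terms: list[str]) -> np.ndarray:
    cols = [np.ones_like(a, dtype=float)]
    for t in terms:
        if t == "a":
            cols.append(a.astype(float))
        elif t == "b":
            cols.append(b.astype(float))
        elif t == "a:b":
            cols.append((a * b).astype(float))
    return np.column_stack(cols)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    resid = y - X @ coef
    return coef, float(resid @ resid)


def factorial_lm(
    table: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    alpha: float = 0.05,
    reduce: bool = True,
) -> FactorialLMResult:
    """Fit ``response ~ factor_a * factor_b`` by ordinary least squares.

    Both factors must be binary (coded to 0/1 internally).  Sequential
    (type-I) F-tests are reported for the interaction and main effects;
    if ``reduce`` is set, the interaction (then non-significant main
    effects, tested at level ``alpha``) is dropped before marginal means
    are computed.  Marginal means pool over the non-focal factor with
    t-based 95% confidence intervals on the residual df of the reduced
    model.
    """
    for col in (response, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
    y = table[response].to_numpy(float)
    a_lv = np.unique(table[factor_a].to_numpy())
    b_lv = np.unique(table[factor_b].to_numpy())
    if len(a_lv) != 2 or len(b_lv) != 2:
        raise ValueError("factorial_lm expects exactly two levels per factor")
    a = (table[factor_a].to_numpy() == a_lv[1]).astype(float)
    b = (table[factor_b].to_numpy() == b_lv[1]).astype(float)
    counts = pd.crosstab(a, b)
    if counts.shape != (2, 2) or (counts.to_numpy() < 2).any():
        raise ValueError("each of the four cells needs at least two units")
    n = y.size

    # sequential model sequence: 1, +a, +b, +a:b
    seqs = [[], ["a"], ["a", "b"], ["a", "b", "a:b"]]
    rss = []
    for terms in seqs:
        _, r = _ols_rss(_design_matrix(a, b, terms), y)
        rss.append(r)
    full_terms = ["a", "b", "a:b"]
    full_df = n - 4
    if full_df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    mse_full = rss[3] / full_df
    # a residual scale this small relative to the response is numerical noise
    # (constant response); report null F-statistics rather than 0/0 artifacts
    tiny = 1e-12 * (np.mean(np.abs(y)) ** 2 + 1.0)
    rows = []
    for i, term in enumerate(full_terms):
        num = max(rss[i] - rss[i + 1], 0.0)
        F = num / mse_full if mse_full > tiny else 0.0
        p = float(stats.f.sf(F, 1, full_df)) if mse_full > tiny else 1.0
        label = {
            "a": factor_a,
            "b": factor_b,
            "a:b": f"{factor_a}:{factor_b}",
        }[term]
        rows.append({"term": label, "df": 1, "ss": num, "F": F, "p": p})
    anova = pd.DataFrame(rows).set_index("term")

    # model reduction: drop interaction first, then main effects, each by an
    # F-test of the deletion against the model containing it
    terms = list(full_terms)
    if reduce:
        for term in ("a:b", "b", "a"):
            if term not in terms:
                continue
            if term == "a:b":
                candidates = [t for t in terms if t != term]
            else:
                if "a:b" in terms:
                    continue  # keep main effects under an interaction
                candidates = [t for t in terms if t != term]
            _, rss_with = _ols_rss(_design_matrix(a, b, terms), y)
            _, rss_without = _ols_rss(_design_matrix(a, b, candidates), y)
            df_resid = n - (len(terms) + 1)
            mse = rss_with / df_resid
            F = (rss_without - rss_with) / mse if mse > 0 else 0.0
            p = float(stats.f.sf(F, 1, df_resid)) if mse > 0 else 1.0
            if p > alpha:
                terms = candidates

    X = _design_matrix(a, b, terms)
    coef, rss_red = _ols_rss(X, y)
    df_resid = n - X.shape[1]
    sigma2 = rss_red / df_resid
    names = ["intercept"] + [
        {"a": factor_a, "b": factor_b, "a:b": f"{factor_a}:{factor_b}"}[t]
        for t in terms
    ]
    coefficients = dict(zip(names, coef.tolist()))

    # marginal means: average the four predicted cell means over the
    # non-focal factor; CI from the coefficient covariance
    XtX_inv = np.linalg.inv(X.T @ X)
    tcrit = stats.t.ppf(0.975, df_resid)
    mm_rows = []
    cells = {(ai, bi): _design_matrix(np.array([ai]), np.array([bi]), terms)[0]
             for ai in (0.0, 1.0) for bi in (0.0, 1.0)}
    for factor, levels, is_a in ((factor_a, a_lv, True), (factor_b, b_lv, False)):
        for code, level in zip((0.0, 1.0), levels):
            if is_a:
                w = (cells[(code, 0.0)] + cells[(code, 1.0)]) / 2.0
            else:
                w = (cells[(0.0, code)] + cells[(1.0, code)]) / 2.0
            est = float(w @ coef)
            se = float(np.sqrt(sigma2 * (w @ XtX_inv @ w)))
            mm_rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "mean": est,
                    "se": se,
                    "ci_low": est - tcrit * se,
                    "ci_high": est + tcrit * se,
                }
            )
    marginal = pd.DataFrame(mm_rows)
    return FactorialLMResult(
        coefficients=coefficients,
        anova=anova,
        marginal_means=marginal,
        residual_df=df_resid,
        sigma2=float(sigma2),
        reduced_terms=names[1:],
    )


# ---------------------------------------------------------------------------
# per-genus effect-size screen
# ---------------------------------------------------------------------------

def genus_effect_sizes(
    records: pd.DataFrame,
    min_n: int = 3,
    baseline_threshold: float = 0.55,
    value_col: str = "siderophore",
    genus_col: str = "genus",
    copper_col: str = "copper",
) -> tuple[list[EffectSizeRecord], SpearmanResult]:
    """Per-genus copper effect sizes and their rank correlation with baseline.

    For every genus with at least ``min_n`` isolates in both copper
    treatments: the control (no-copper) mean, Cohen's d of copper versus
    control, and a high-baseline flag at ``baseline_threshold``.  The
    Spearman correlation of d against baseline mean across genera
    summarizes whether copper selects against trait extremes.
    """
    for col in (value_col, genus_col, copper_col):
        if col not in records.columns:
            raise ValueError(f"column {col!r} not in records")
    out: list[EffectSizeRecord] = []
    for genus, sub in records.groupby(genus_col, sort=True):
        cu = sub.loc[sub[copper_col].astype(bool), value_col].to_numpy(float)
        ctrl = sub.loc[~sub[copper_col].astype(bool), value_col].to_numpy(float)
        if cu.size < min_n or ctrl.size < min_n:
            continue
        baseline = float(ctrl.mean())
        d = cohens_d(cu, ctrl)
        out.append(
            EffectSizeRecord(
                genus=str(genus),
                baseline_mean=baseline,
                cohens_d=d,
                n_control=int(ctrl.size),
                n_copper=int(cu.size),
                high_baseline=baseline > baseline_threshold,
            )
        )
    if len(out) < 3:
        raise ValueError(
            f"only {len(out)} genera qualify (min_n={min_n}); the Spearman "
            "correlation needs at least 3"
        )
    baselines = [r.baseline_mean for r in out]
    ds = [r.cohens_d for r in out]
    summary = spearman_rho(ds, baselines)
    return out, summary
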