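"""Aligned-rank-transform (ART) factorial ANOVA and companion tests.

The ART procedure makes a factorial ANOVA nonparametric: for each
effect (main or interaction) the data are *aligned* — every other
effect's least-squares estimate is subtracted, leaving residual plus
the effect of interest — then ranked (midranks), and an ordinary
full-factorial ANOVA is run on the ranks; only the target effect's row
is reported. The defining correctness property is that on the aligned
(pre-rank) data all non-target effects show F ~ 0 ("stripped effects").

Alignment here is regression-based: the full factorial linear model is
fitted with sum-to-zero contrasts and the aligned response is
``residual + X_effect @ beta_effect``. This makes the stripped-effect
property exact (to machine precision) even for unbalanced designs such
as 26 PD vs 13 HC. Effect F tests use Type-III sums of squares via
full/reduced model comparison; for a complete balanced design these
coincide with the classical sequential decomposition.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDesignError

DEFAULT_FACTORS = ("band", "group", "condition")


# ---------------------------------------------------------------------------
# design matrix machinery


class _Design:
    """Sum-to-zero coded full-factorial design built from a data frame."""

    def __init__(self, data: pd.DataFrame, factors: tuple[str, ...]):
        self.factors = tuple(factors)
        self.n = len(data)
        self.levels: dict[str, np.ndarray] = {}
        self.codes: dict[str, np.ndarray] = {}
        self.blocks: dict[str, np.ndarray] = {}
        for f in self.factors:
            codes, levels = pd.factorize(data[f], sort=True)
            if (codes < 0).any():
                raise ValueError(f"factor {f!r} contains missing values")
            if len(levels) < 2:
                raise ValueError(f"factor {f!r} needs at least 2 levels")
            self.levels[f] = np.asarray(levels)
            self.codes[f] = codes
            # sum coding: indicator(level j) - indicator(last level), j < L-1
            L = len(levels)
            contrast = np.zeros((L, L - 1))
            contrast[:-1, :] = np.eye(L - 1)
            contrast[-1, :] = -1.0
            self.blocks[f] = contrast[codes]
        self.terms: list[tuple[str, ...]] = []
        for size in range(1, len(self.factors) + 1):
            self.terms.extend(itertools.combinations(self.factors, size))
        self.term_columns: dict[tuple[str, ...], np.ndarray] = {}
        for term in self.terms:
            cols = self.blocks[term[0]]
            for f in term[1:]:
                cols = np.einsum("ij,ik->ijk", cols, self.blocks[f]).reshape(
                    self.n, -1
                )
            self.term_columns[term] = cols
        self.X = np.column_stack(
            [np.ones(self.n)] + [self.term_columns[t] for t in self.terms]
        )
        # column slices per term inside X
        self.slices: dict[tuple[str, ...], slice] = {}
        start = 1
        for term in self.terms:
            width = self.term_columns[term].shape[1]
            self.slices[term] = slice(start, start + width)
            start += width
        self.n_params = start

    def term_label(self, term: tuple[str, ...]) -> str:
        return ":".join(term)

    def resolve(self, effect: str) -> tuple[str, ...]:
        parts = tuple(effect.split(":"))
        for term in self.terms:
            if tuple(sorted(term)) == tuple(sorted(parts)):
                return term
        known = [self.term_label(t) for t in self.terms]
        raise ValueError(f"unknown effect {effect!r}; known effects: {known}")

    def is_complete(self) -> bool:
        """True when every factor-level combination has >= 1 observation."""
        cells = {tuple(self.codes[f][i] for f in self.factors) for i in range(self.n)}
        n_cells = int(np.prod([len(self.levels[f]) for f in self.factors]))
        return len(cells) == n_cells


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def factorial_anova_f(
    response: np.ndarray,
    data: pd.DataFrame,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
) -> pd.DataFrame:
    """Fixed-effects full-factorial ANOVA table (Type-III SS).

    Returns a data frame indexed by effect label with columns
    ``ss, F, df_num, df_den, p``; the residual sum of squares and df are
    attached as ``attrs["sse"]`` / ``attrs["df_den"]``. The denominator
    df for a complete design with N observations and C cells is N - C.
    """
    y = np.asarray(response, dtype=float)
    if y.ndim != 1 or len(y) != len(data):
        raise ValueError("response must be 1-D and match the data frame length")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    design = _Design(data, factors)
    df_den = design.n - design.n_params
    if df_den < 1:
        raise DegenerateDesignError(
            f"no residual degrees of freedom (n={design.n}, "
            f"parameters={design.n_params})"
        )
    sse_full = _sse(design.X, y)
    ms_den = sse_full / df_den
    # numerical-degeneracy scale: data magnitude, not the (possibly
    # rounding-noise) centred sum of squares
    scale = max(float(np.sum(np.square(y))), float(len(y)), 1e-300)
    degenerate = sse_full <= 1e-12 * scale
    rows = []
    for term in design.terms:
        keep = np.ones(design.X.shape[1], dtype=bool)
        keep[design.slices[term]] = False
        ss = max(_sse(design.X[:, keep], y) - sse_full, 0.0)
        df_num = design.slices[term].stop - design.slices[term].start
        if not degenerate:
            f_stat = (ss / df_num) / ms_den
        else:
            # zero residual variance (e.g. constant response): an effect
            # is either exactly absent (F = 0) or infinitely resolved
            f_stat = 0.0 if ss <= 1e-12 * scale else np.inf
        p = float(stats.f.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else 0.0
        rows.append(
            {
                "effect": design.term_label(term),
                "ss": ss,
                "F": f_stat,
                "df_num": df_num,
                "df_den": df_den,
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("effect")
    table.attrs["sse"] = sse_full
    table.attrs["df_den"] = df_den
    return table


def align(
    data: pd.DataFrame,
    effect: str,
    response: str = "global_plv",
    factors: tuple[str, ...] = DEFAULT_FACTORS,
) -> np.ndarray:
    """Aligned response for one effect: model residual + that effect's
    least-squares estimate. All other effects are stripped exactly."""
    design = _Design(data, factors)
    if not design.is_complete():
        raise ValueError("alignment requires a complete design (no empty cells)")
    term = design.resolve(effect)
    y = np.asarray(data[response], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    beta, *_ = np.linalg.lstsq(design.X, y, rcond=None)
    fitted = design.X @ beta
    sl = design.slices[term]
    effect_fit = design.X[:, sl] @ beta[sl]
    return (y - fitted) + effect_fit


def rank_midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their midrank."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot rank an empty list")
    if np.isnan(v).any():
        raise ValueError("values contain NaN")
    return stats.rankdata(v, method="average")


@dataclass
class ARTResult:
    """Per-effect ART ANOVA rows plus alignment diagnostics.

    ``anova`` is indexed by effect with columns F, df_num, df_den, p —
    each row taken from the factorial ANOVA on the ranks of the data
    aligned for that effect. ``stripped_max_f`` maps each effect to the
    largest non-target F on its aligned (pre-rank) data; values near 0
    certify the alignment.
    """

    anova: pd.DataFrame
    stripped_max_f: dict[str, float]


def art_anova(
    data: pd.DataFrame,
    response: str = "global_plv",
    factors: tuple[str, ...] = DEFAULT_FACTORS,
) -> ARTResult:
    """Aligned-rank-transform factorial ANOVA over all effects."""
    design = _Design(data, factors)
    if not design.is_complete():
        raise ValueError("ART requires a complete design (no empty cells)")
    rows = []
    stripped: dict[str, float] = {}
    for term in design.terms:
        label = design.term_label(term)
        aligned = align(data, label, response=response, factors=factors)
        diag = factorial_anova_f(aligned, data, factors)
        stripped[label] = float(diag["F"].drop(label).max())
        ranked = rank_midranks(aligned)
        table = factorial_anova_f(ranked, data, factors)
        rows.append(table.loc[[label]])
    return ARTResult(anova=pd.concat(rows), stripped_max_f=stripped)


# ---------------------------------------------------------------------------
# post-hoc and auxiliary tests


@dataclass
class PosthocResult:
    """One Bonferroni-corrected two-sample contrast on a table slice."""

    description: str
    level_a: str
    level_b: str
    n_a: int
    n_b: int
    statistic: float
    p_raw: float
    p_adjusted: float
    family: int


def posthoc_pairwise(
    table: pd.DataFrame,
    between: str,
    where: dict[str, str] | None = None,
    family: int = 1,
    response: str = "global_plv",
) -> PosthocResult:
    """Two-sided Wilcoxon rank-sum contrast on a slice of the table.

    ``between`` names a two-level column (e.g. ``group``); ``where``
    filters the slice (e.g. ``{"band": "delta", "condition": "motor"}``).
    The p-value is exact (full enumeration) whenever there are no ties
    and the combined sample size permits it (n <= 60, which covers the
    13-vs-26 cohort contrast); otherwise the normal approximation with
    continuity correction is used. Bonferroni adjustment multiplies by
    ``family`` and caps at 1.
    """
    if family < 1:
        raise ValueError("family size must be >= 1")
    sliced = table
    where = where or {}
    for col, val in where.items():
        sliced = sliced[sliced[col] == val]
    if len(sliced) == 0:
        raise ValueError(f"empty slice for {where}")
    levels = sorted(sliced[between].unique())
    if len(levels) != 2:
        raise ValueError(
            f"contrast column {between!r} must have exactly 2 levels in the "
            f"slice, found {levels}"
        )
    a = np.asarray(sliced.loc[sliced[between] == levels[0], response], dtype=float)
    b = np.asarray(sliced.loc[sliced[between] == levels[1], response], dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"one side of the contrast {levels} is empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 60 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    desc = ", ".join(f"{k}={v}" for k, v in where.items()) or "all rows"
    return PosthocResult(
        description=f"{between}: {levels[0]} vs {levels[1]} ({desc})",
        level_a=str(levels[0]),
        level_b=str(levels[1]),
        n_a=len(a),
        n_b=len(b),
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=min(1.0, float(res.pvalue) * family),
        family=family,
    )


def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a normal with the
    sample's own mean and standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("KS normality test needs at least 3 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("KS normality test undefined for zero-variance input")
    res = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def spearman_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
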