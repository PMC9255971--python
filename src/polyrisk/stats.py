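"""Bivariate association statistics for cross-sectional medication data.

The workhorse is the prevalence odds ratio (POR) from a 2x2 contingency
table with a Woolf (log-odds) confidence interval:

    POR = ad / bc,
    CI  = exp( ln POR +/- z * sqrt(1/a + 1/b + 1/c + 1/d) ).

Supporting tests: Fisher's exact (two-sided, probability-mass convention),
Pearson's chi-square without continuity correction, the independent-samples
t-test (Welch by default), and a univariate logistic model giving the odds
ratio per additional medication.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._util import round_half_up

logger = logging.getLogger(__name__)

#: two-sided 95% normal quantile
Z95 = 1.959964

ALPHA = 0.05  # two-sided significance threshold


class SeparationError(RuntimeError):
    """Logistic fit is degenerate (complete separation / non-convergence)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = exposed-outcome, b = exposed-no-outcome,
    c = referent-outcome, d = referent-no-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")

    @property
    def counts(self) -> tuple:
        return (self.a, self.b, self.c, self.d)

    def transpose_exposure(self) -> "ContingencyTable2x2":
        """Swap exposed and referent rows."""
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class AssociationResult:
    por: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not self.ci_low <= self.por <= self.ci_high:
            raise ValueError("odds ratio outside its confidence interval")

    def rounded(self, ndigits: int = 2) -> tuple:
        """Report-layer (POR, low, high), half-up rounded."""
        return (
            round_half_up(self.por, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )


def prevalence_odds_ratio(t: ContingencyTable2x2, z: float = Z95) -> AssociationResult:
    """Cross-product POR with a Woolf confidence interval.

    A zero cell triggers the Haldane-Anscombe correction (add 0.5 to every
    cell) and tags the method string; a fully empty margin is undefined.
    """
    a, b, c, d = t.counts
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("POR undefined: a table margin is empty")
    method = "POR/Woolf"
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in t.counts)
        method += "+haldane"
    por = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_por = math.log(por)
    return AssociationResult(
        por=por,
        ci_low=math.exp(log_por - z * se),
        ci_high=math.exp(log_por + z * se),
        p_value=fisher_exact(t),
        method=method,
    )


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (probability-mass convention).

    Sums hypergeometric probabilities, at the observed fixed margins, of all
    tables at most as probable as the observed one.
    """
    table = np.array([[t.a, t.b], [t.c, t.d]])
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def chi_square(table) -> tuple:
    """Pearson chi-square on an r x c count table -> (statistic, p_value, df).

    No continuity correction; df = (r-1)(c-1). A zero row or column margin
    makes expected counts degenerate and raises.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chi-square needs a 2-D count table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p), int(df)


def t_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> float:
    """Two-sided independent-samples t-test p-value (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test needs at least 2 observations per sample")
    if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
        logger.warning("t-test on two identical constant samples: p = 1")
        return 1.0
    return float(sps.ttest_ind(x, y, equal_var=equal_var).pvalue)


def logistic_or_per_unit(
    x: Sequence[float], y: Sequence[int], z: float = Z95
) -> AssociationResult:
    """Univariate logistic regression: odds ratio per one-unit increase in x.

    Fit by Newton-Raphson (iteratively reweighted least squares) to a relative
    log-likelihood tolerance of 1e-10 within 100 iterations; the Wald interval
    is exp(slope +/- z * SE). Complete separation or non-convergence raises
    rather than returning a silent estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(x)) < 2:
        raise ValueError("logistic fit needs >= 2 distinct predictor values")
    if len(np.unique(y)) < 2:
        raise ValueError("logistic fit needs both outcome classes present")
    design = sm.add_constant(x)
    try:
        with np.errstate(over="ignore", divide="ignore"):  # separation path
            fit = sm.Logit(y, design).fit(
                method="newton", maxiter=100, tol=1e-10, disp=0, warn_convergence=False
            )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit degenerate: {exc}") from exc
    if not fit.mle_retvals.get("converged", False) or abs(fit.params[1]) > 30:
        raise SeparationError("logistic fit did not converge (separation?)")
    slope, se = fit.params[1], fit.bse[1]
    return AssociationResult(
        por=math.exp(slope),
        ci_low=math.exp(slope - z * se),
        ci_high=math.exp(slope + z * se),
        p_value=float(fit.pvalues[1]),
        method="logistic/Wald",
    )


# ---------------------------------------------------------------------------
# Association-report layer (mirrors the layout of published bivariate tables)

def association_table(
    df: pd.DataFrame,
    outcome: str,
    variables: Sequence[str],
    reference: dict | None = None,
) -> pd.DataFrame:
    """Per-category POR table for a binary outcome column.

    For each variable, the reference category (configurable; defaults to the
    most frequent) anchors the odds; every other category gets a 2x2 table
    (category vs reference) crossed with the outcome and a POR/Woolf row.
    Output columns mirror a standard bivariate association table: variable,
    category, n_outcome, n_no_outcome, por, ci_low, ci_high, p_value.
    """
    reference = reference or {}
    out_rows = []
    y = df[outcome].astype(bool)
    for var in variables:
        cats = df[var].astype(str)
        ref = str(reference.get(var, cats.value_counts().idxmax()))
        c = int((y & (cats == ref)).sum())
        d = int((~y & (cats == ref)).sum())
        out_rows.append(
            {
                "variable": var, "category": ref,
                "n_outcome": c, "n_no_outcome": d,
                "por": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p_value": np.nan, "is_reference": True,
            }
        )
        for cat in sorted(set(cats) - {ref}):
            a = int((y & (cats == cat)).sum())
            b = int((~y & (cats == cat)).sum())
            row = {
                "variable": var, "category": cat,
                "n_outcome": a, "n_no_outcome": b,
                "por": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p_value": np.nan, "is_reference": False,
            }
            try:
                res = prevalence_odds_ratio(ContingencyTable2x2(a, b, c, d))
                row.update(
                    por=res.por, ci_low=res.ci_low, ci_high=res.ci_high,
                    p_value=res.p_value,
                )
            except ValueError:
                logger.warning(
                    "POR undefined for %s=%s vs %s; row reported without estimate",
                    var, cat, ref,
                )
            out_rows.append(row)
    return pd.DataFrame(out_rows)
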