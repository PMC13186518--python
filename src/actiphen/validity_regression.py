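"""Discriminant-validity regressions on person-level model predictions.

Two complementary analyses per outcome definition:

* OLS of each participant's averaged predicted probability on the PTSD
  outcome flag, a non-PTSD current-diagnosis flag (1=present, 0=absent), and
  age in years.  A positive, significant outcome coefficient alongside a null
  non-PTSD coefficient indicates the model tracks PTSD specifically rather
  than mental-health burden in general.  p-values use the t distribution
  with n - k - 1 degrees of freedom.
* Logistic regression of the outcome flag on the within-person averaged
  selected features, summarized by the Nagelkerke pseudo-R^2

      R^2_N = (1 - exp(2 (L0 - L1) / n)) / (1 - exp(2 L0 / n)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["OlsResult", "LogisticResult", "fit_discriminant_ols", "fit_logistic",
           "nagelkerke_r2"]


@dataclass
class OlsResult:
    """OLS coefficient table plus adjusted R^2."""

    coefficients: dict[str, tuple[float, float, float, float]]  # term -> (B, SE, t, p)
    adjusted_r_squared: float
    n: int

    def format_table(self, title: str = "Discriminant validity (OLS)") -> str:
        lines = [title, f"  n = {self.n}, adjusted R2 = {self.adjusted_r_squared:.2f}",
                 f"  {'term':<28}{'B':>9}{'SE':>9}{'t':>9}{'p':>9}"]
        for term, (b, se, t, p) in self.coefficients.items():
            lines.append(f"  {term:<28}{b:>9.3f}{se:>9.3f}{t:>9.2f}{p:>9.3f}")
        return "\n".join(lines)


@dataclass
class LogisticResult:
    """Maximum-likelihood logistic fit with Nagelkerke pseudo-R^2."""

    coefficients: dict[str, tuple[float, float, float, float]]
    log_likelihood: float
    null_log_likelihood: float
    nagelkerke_r2: float
    separation_flagged: bool = False


def fit_discriminant_ols(
    person_scores: np.ndarray,
    outcome: np.ndarray,
    nonptsd: np.ndarray,
    age: np.ndarray,
    term_names: tuple[str, str, str] = ("outcome", "nonptsd_dx", "age"),
) -> OlsResult:
    """OLS of predicted scores on outcome + non-PTSD diagnosis + age.

    Raises on a rank-deficient design, naming the collinear terms.
    """
    y = np.asarray(person_scores, dtype=float)
    X = np.column_stack([
        np.asarray(outcome, dtype=float),
        np.asarray(nonptsd, dtype=float),
        np.asarray(age, dtype=float),
    ])
    names = ["intercept", *term_names]
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        degenerate = [
            names[j] for j in range(1, design.shape[1])
            if np.ptp(design[:, j]) == 0
        ]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"constant/collinear terms: {degenerate or 'linear dependence'}"
        )
    if len(y) <= design.shape[1]:
        raise ValueError("need n > number of parameters")
    fit = sm.OLS(y, design).fit()
    coefs = {
        name: (float(fit.params[j]), float(fit.bse[j]), float(fit.tvalues[j]),
               float(fit.pvalues[j]))
        for j, name in enumerate(names)
    }
    return OlsResult(coefs, float(fit.rsquared_adj), int(len(y)))


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from model and null log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def fit_logistic(
    outcome: np.ndarray,
    features: pd.DataFrame,
) -> LogisticResult:
    """Logistic regression of a binary outcome on averaged selected features.

    Perfect separation is detected (non-convergence / unbounded likelihood)
    and flagged; the Nagelkerke R^2 is then 1 by its limit.
    """
    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("logistic fit needs both classes present")
    X = sm.add_constant(np.asarray(features, dtype=float), has_constant="add")
    names = ["intercept", *list(features.columns)]
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            separated = True
            fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-8, maxiter=500)
        for w in caught:
            if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
                separated = True
    ll = float(fit.llf)
    ll0 = float(sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf)
    if features.shape[1] == 0:
        ll = ll0
    r2 = 1.0 if separated else nagelkerke_r2(ll, ll0, len(y))
    params = np.atleast_1d(np.asarray(fit.params, dtype=float))
    try:
        bse = np.atleast_1d(np.asarray(fit.bse, dtype=float))
        tvals = np.atleast_1d(np.asarray(fit.tvalues, dtype=float))
        pvals = np.atleast_1d(np.asarray(fit.pvalues, dtype=float))
    except Exception:
        bse = tvals = pvals = np.full_like(params, np.nan)
    coefs = {
        name: (float(params[j]), float(bse[j]), float(tvals[j]), float(pvals[j]))
        for j, name in enumerate(names)
    }
    if separated:
        warnings.warn(
            "perfect separation detected: coefficients are unstable and "
            "Nagelkerke R2 is reported at its limit of 1",
            stacklevel=2,
        )
    return LogisticResult(coefs, ll, ll0, r2, separation_flagged=separated)
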