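"""Variable screening and stratified multiple logistic regression.

The modelling chain mirrors a standard cross-sectional risk-factor analysis:

1. bivariate pre-selection — each candidate is fit alone against the outcome
   and kept when its Wald p-value is below ``screen_p`` (default 0.1);
2. multicollinearity screen — variance inflation factors over the kept
   candidates; variables with VIF above ``vif_max`` (default 5) are excluded,
   iteratively dropping the worst offender per pass;
3. one joint logistic fit per stratum (general population / under-fives),
   reporting adjusted odds ratios exp(beta) with 95% Wald confidence
   intervals on the log-odds scale.

A variable counts as significantly associated only when its CI excludes 1
AND the model-level likelihood-ratio test against the intercept-only model
has p < ``llr_alpha`` — a conjunctive criterion.

Fits are maximum-likelihood logistic regressions (statsmodels ``Logit``,
Newton); degenerate inputs (constant outcome, perfect separation, rank
deficiency) are surfaced explicitly, never silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm
from statsmodels.tools.sm_exceptions import (ConvergenceWarning, PerfectSeparationError,
                                             PerfectSeparationWarning)

from .errors import DomainError, SeparationError
from .schema import MODEL_COVARIATES, OUTCOME

Z95 = 1.96  # symmetric 95% Wald multiplier on the log-odds scale


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one stratified model."""

    outcome: str = OUTCOME
    candidates: tuple = tuple(MODEL_COVARIATES)
    stratum: str = "general"  # "general" | "under5"
    screen_p: float = 0.1
    vif_max: float = 5.0
    llr_alpha: float = 0.05
    degenerate_min_frac: float = 0.02
    iterative_vif: bool = True

    def __post_init__(self) -> None:
        if self.outcome in self.candidates:
            raise DomainError("outcome cannot be a candidate covariate")
        if not 0 < self.screen_p <= 1:
            raise DomainError("screen_p must be in (0,1]")
        if self.vif_max <= 1:
            raise DomainError("vif_max must exceed 1")
        if self.stratum not in ("general", "under5"):
            raise DomainError(f"unknown stratum {self.stratum!r}")


@dataclass
class LogitFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    note: str = ""


@dataclass
class FitResult:
    """Joint model fit for one stratum: aOR table plus model-level LLR test."""

    stratum: str
    n_rows: int
    estimates: pd.DataFrame  # variable, beta, se, aOR, ci_low, ci_high, wald_p, stars, significant
    loglik: float
    null_loglik: float
    llr_stat: float
    llr_p: float
    converged: bool
    screening: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# core fit

def fit_logit(y, X, maxiter: int = 100, tol: float = 1e-8) -> LogitFit:
    """ML logistic fit of binary ``y`` on design matrix ``X`` (with intercept).

    Raises :class:`SeparationError` for a constant outcome or detected perfect
    separation; rank deficiency and non-convergence are returned as
    ``converged=False`` with a diagnostic note.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.isin(y, [0, 1]).all():
        raise DomainError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError("outcome is constant; the logit MLE does not exist")
    if X.ndim != 2 or len(y) != len(X):
        raise DomainError("X must be 2-D with one row per outcome")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return LogitFit(
            beta=np.full(X.shape[1], np.nan), se=np.full(X.shape[1], np.nan),
            loglik=np.nan, converged=False,
            note=f"design matrix rank deficient (rank {rank} < {X.shape[1]} columns)",
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            # non-convergence is reported via mle_retvals and the note field
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = sm.Logit(y, X).fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"perfect separation detected: {exc}") from None
    except np.linalg.LinAlgError as exc:
        return LogitFit(
            beta=np.full(X.shape[1], np.nan), se=np.full(X.shape[1], np.nan),
            loglik=np.nan, converged=False, note=f"singular information matrix: {exc}",
        )
    note = ""
    converged = bool(res.mle_retvals.get("converged", True))
    se = np.asarray(res.bse, dtype=float)
    if not np.isfinite(se).all() or np.abs(res.params).max() > 30:
        converged = False
        note = "unstable estimates (possible quasi-separation)"
    return LogitFit(beta=np.asarray(res.params, float), se=se,
                    loglik=float(res.llf), converged=converged, note=note)


def _design(data: pd.DataFrame, variables) -> np.ndarray:
    X = data[list(variables)].astype(float).to_numpy()
    return np.column_stack([np.ones(len(X)), X])


# ---------------------------------------------------------------------------
# screening

def bivariate_screen(data: pd.DataFrame, candidates=None, screen_p: float = 0.1,
                     outcome: str = OUTCOME,
                     degenerate_min_frac: float = 0.02) -> pd.DataFrame:
    """One-predictor logit per candidate; keep those with Wald p < screen_p.

    Degenerate candidates (constant, or minority class below
    ``degenerate_min_frac``) are dropped with an explanatory note rather than
    raising — this also guards near-universal exposures that a pure VIF pass
    need not catch.
    """
    candidates = list(candidates if candidates is not None else MODEL_COVARIATES)
    y = data[outcome].astype(float).to_numpy()
    rows = []
    for var in candidates:
        x = data[var].astype(float).to_numpy()
        minority = min(x.mean(), 1 - x.mean()) if np.isin(x, [0, 1]).all() else None
        if np.all(x == x[0]):
            rows.append((var, np.nan, np.nan, "dropped_screen", "degenerate: constant"))
            continue
        if minority is not None and minority < degenerate_min_frac:
            rows.append((var, np.nan, np.nan, "dropped_screen",
                         f"degenerate: minority class {minority:.1%} < {degenerate_min_frac:.0%}"))
            continue
        try:
            fit = fit_logit(y, np.column_stack([np.ones(len(x)), x]))
        except SeparationError as exc:
            rows.append((var, np.nan, np.nan, "dropped_screen", f"degenerate: {exc}"))
            continue
        if not fit.converged:
            rows.append((var, np.nan, np.nan, "dropped_screen", fit.note))
            continue
        beta, se = fit.beta[1], fit.se[1]
        p = 2 * norm.sf(abs(beta / se))
        status = "kept" if p < screen_p else "dropped_screen"
        rows.append((var, beta, p, status, ""))
    return pd.DataFrame(rows, columns=["variable", "bivariate_beta", "bivariate_p",
                                       "status", "note"]).assign(vif=np.nan)


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1-R²_j), R²_j from OLS of column j on the others + intercept.

    Exact collinearity reports +inf.
    """
    if X.shape[1] < 2:
        raise DomainError("VIF needs at least two columns")
    out = {}
    arr = X.astype(float)
    for col in arr.columns:
        others = sm.add_constant(arr.drop(columns=col).to_numpy())
        target = arr[col].to_numpy()
        res = sm.OLS(target, others).fit()
        r2 = min(res.rsquared, 1.0)
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_exclude(screening: pd.DataFrame, data: pd.DataFrame, vif_max: float = 5.0,
                iterative: bool = True) -> pd.DataFrame:
    """Drop kept variables whose VIF exceeds ``vif_max``.

    Iterative mode removes the single worst variable and recomputes until all
    remaining VIFs pass; single-pass mode drops every offender at once.
    """
    screening = screening.copy()
    kept = list(screening.loc[screening["status"] == "kept", "variable"])
    while len(kept) >= 2:
        vifs = compute_vif(data[kept])
        screening.loc[screening["variable"].isin(kept), "vif"] = (
            screening.loc[screening["variable"].isin(kept), "variable"].map(vifs)
        )
        offenders = vifs[vifs > vif_max]
        if offenders.empty:
            break
        if iterative:
            worst = offenders.idxmax()
            drop = [worst]
        else:
            drop = list(offenders.index)
        for var in drop:
            screening.loc[screening["variable"] == var,
                          ["status", "note"]] = ["dropped_vif", f"VIF {vifs[var]:.3g} > {vif_max}"]
            kept.remove(var)
        if not iterative:
            vifs = compute_vif(data[kept]) if len(kept) >= 2 else None
            break
    return screening


# ---------------------------------------------------------------------------
# joint model

def _stars(p: float) -> str:
    if p < 0.001:
        return "****"
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def fit_mlr(data: pd.DataFrame, variables, stratum: str = "general",
            outcome: str = OUTCOME, llr_alpha: float = 0.05,
            screening: pd.DataFrame | None = None) -> FitResult:
    """Joint logistic fit on the kept variables for one stratum.

    ``data`` must already be complete-case and stratum-filtered.  A variable
    is flagged significant only when its 95% CI excludes 1 and the model's
    LLR p-value is below ``llr_alpha``.
    """
    variables = list(variables)
    if not variables:
        raise DomainError("no variables survived screening; nothing to fit")
    y = data[outcome].astype(float).to_numpy()
    fit = fit_logit(y, _design(data, variables))
    # intercept-only log-likelihood in closed form
    pbar = y.mean()
    null_ll = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log1p(-pbar)))
    llr_stat = max(0.0, 2 * (fit.loglik - null_ll)) if np.isfinite(fit.loglik) else np.nan
    llr_p = float(chi2.sf(llr_stat, df=len(variables))) if np.isfinite(llr_stat) else np.nan
    model_ok = np.isfinite(llr_p) and llr_p < llr_alpha
    rows = []
    for j, var in enumerate(variables, start=1):
        beta, se = fit.beta[j], fit.se[j]
        aor = float(np.exp(beta))
        lo, hi = float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))
        p = float(2 * norm.sf(abs(beta / se))) if se > 0 else np.nan
        excludes_one = (lo > 1) or (hi < 1)
        rows.append({
            "variable": var, "beta": float(beta), "se": float(se), "aOR": aor,
            "ci_low": lo, "ci_high": hi, "wald_p": p, "stars": _stars(p),
            "significant": bool(excludes_one and model_ok and fit.converged),
        })
    return FitResult(
        stratum=stratum, n_rows=len(data), estimates=pd.DataFrame(rows),
        loglik=fit.loglik, null_loglik=null_ll, llr_stat=llr_stat, llr_p=llr_p,
        converged=fit.converged, screening=screening,
    )


def run_model(data: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Full chain for one stratum: filter, screen, VIF-exclude, joint fit."""
    spec = spec or ModelSpec()
    rows = data
    if spec.stratum == "under5":
        rows = rows.loc[rows["under5"].astype(bool)]
    if rows.empty:
        raise DomainError(f"no rows in stratum {spec.stratum!r}")
    screening = bivariate_screen(rows, spec.candidates, spec.screen_p,
                                 spec.outcome, spec.degenerate_min_frac)
    screening = vif_exclude(screening, rows, spec.vif_max, spec.iterative_vif)
    kept = list(screening.loc[screening["status"] == "kept", "variable"])
    return fit_mlr(rows, kept, spec.stratum, spec.outcome, spec.llr_alpha, screening)


# ---------------------------------------------------------------------------
# descriptive

def prevalence(individuals: pd.DataFrame, site: str | None = None,
               under5: bool | None = None, outcome: str = OUTCOME) -> float:
    """Percent of persons with the outcome in the selected slice."""
    rows = individuals
    if site is not None:
        rows = rows.loc[rows["site_id"] == site]
    if under5 is not None:
        rows = rows.loc[rows["under5"].astype(bool) == under5]
    rows = rows.loc[rows[outcome].notna()]
    if rows.empty:
        raise DomainError("prevalence of an empty selection is undefined")
    return float(100.0 * rows[outcome].astype(float).mean())
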