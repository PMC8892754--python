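"""Multimodel mixed-effects inference.

Pipeline: standardize predictors (1 SD, centered) -> collinearity screen
(drop while tolerance < 0.20, i.e. VIF > 5) -> Box-Cox power transform of
the response -> choose the random-effect structure by AICc among
non-singular fits -> fit all fixed-effect subsets by ML -> information-
criterion (AICc or BIC) Akaike weights -> average coefficients over the
95% cumulative-weight confidence set by the zero method, with unconditional
standard errors and normal 95% CIs.

Numerics are delegated to statsmodels MixedLM; extra random factors beyond
the grouping individual (colony, year, segment nested in individual) are
expressed as variance components under a single constant group, which is an
equivalent parameterization of crossed/nested intercepts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

TOLERANCE_THRESHOLD = 0.20       # drop predictors while tolerance < 0.20 (VIF > 5)
SINGULARITY_RATIO = 1e-6         # variance component / residual variance
CONFIDENCE_WEIGHT = 0.95
MAX_SUBSET_PREDICTORS = 20

#: predictors not available or collinear in spring models (winter staging
#: durations are unobservable; precipitation tracks temperature too closely)
SPRING_EXCLUDED = ("days_at_previous_stopover", "precipitation", "age")


# ---------------------------------------------------------------------------
# Predictor conditioning
# ---------------------------------------------------------------------------

def standardize(df: pd.DataFrame, columns=None):
    """Center numeric predictors and scale to one (sample) SD.

    Returns (standardized frame, record) where record maps column ->
    (mean, sd) for inversion. Non-numeric columns pass through untouched;
    constant columns raise, naming the column.
    """
    out = df.copy()
    record = {}
    cols = columns if columns is not None else \
        [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    for c in cols:
        x = df[c].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize zero-variance column {c!r}")
        record[c] = (float(x.mean()), float(sd))
        out[c] = (x - x.mean()) / sd
    return out, record


def unstandardize_coef(coef: float, response_record=None, predictor_record=None):
    """Map a coefficient fit on standardized variables back to raw scale."""
    out = coef
    if predictor_record is not None:
        out = out / predictor_record[1]
    if response_record is not None:
        out = out * response_record[1]
    return out


def vif_screen(df: pd.DataFrame, predictors, tolerance_threshold: float = TOLERANCE_THRESHOLD,
               keep: tuple = ()):
    """Iteratively drop the worst-VIF predictor until all tolerances pass.

    tolerance_j = 1 - R^2 of predictor j regressed on the others; predictors
    listed in ``keep`` are never dropped (the domain override for which of a
    correlated pair to retain). Returns (retained list, report DataFrame).
    """
    retained = list(predictors)
    report = []
    while len(retained) >= 2:
        vifs = {}
        for j in retained:
            X = sm.add_constant(df[[c for c in retained if c != j]].astype(float))
            r2 = sm.OLS(df[j].astype(float), X).fit().rsquared
            vifs[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        worst = max((c for c in vifs if c not in keep),
                    key=lambda c: vifs[c], default=None)
        report.append({c: vifs[c] for c in retained})
        if worst is None or 1.0 / vifs[worst] >= tolerance_threshold:
            break
        retained.remove(worst)
    rep = pd.DataFrame(report)
    return retained, rep


def power_transform(y, lambda_grid=None):
    """Box-Cox transform with ML lambda over a grid; shifts non-positive data.

    Returns (transformed array, lambda, shift). The shift (0 for already-
    positive data) must be re-applied before back-transforming.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("constant response; identity transform")
        return y.copy(), 1.0, 0.0
    shift = 0.0
    if y.min() <= 0:
        shift = -y.min() + 0.01 * max(np.ptp(y), 1.0)
    ys = y + shift
    if lambda_grid is None:
        lambda_grid = np.arange(-2.0, 2.0001, 0.01)
    llf = [stats.boxcox_llf(l, ys) for l in lambda_grid]
    lam = float(lambda_grid[int(np.argmax(llf))])
    return stats.boxcox(ys, lmbda=lam), lam, shift


# ---------------------------------------------------------------------------
# Mixed-model fitting contract
# ---------------------------------------------------------------------------

@dataclass
class FittedLMM:
    """Slim view of a fitted linear mixed model for the averaging machinery."""
    predictors: tuple
    params: pd.Series               # fixed-effect coefficients (incl. intercept)
    bse: pd.Series
    llf: float
    k: int                          # estimated parameters (fixed + variances)
    nobs: int
    vcomp: dict                     # random-effect variances
    sigma2: float                   # residual variance
    singular: bool
    converged: bool
    random: tuple = ("individual",)

    @property
    def aic(self):
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def aicc(self):
        n, k = self.nobs, self.k
        if n - k - 1 <= 0:
            return np.nan
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def bic(self):
        return -2.0 * self.llf + self.k * np.log(self.nobs)


def fit_lmm(data: pd.DataFrame, response: str, predictors=(),
            random=("individual",), reml: bool = False) -> FittedLMM:
    """Fit a linear mixed model with the given fixed and random structure.

    ``random`` is a tuple of grouping column names; ``individual`` alone is
    fit as a classic random intercept, richer structures (colony, year,
    segment-in-individual) as variance components. ML (reml=False) is the
    default so that fits are comparable across fixed-effect subsets by
    information criteria and likelihood-ratio tests.
    """
    predictors = tuple(predictors)
    rhs = " + ".join(predictors) if predictors else "1"
    formula = f"{response} ~ {rhs}"
    data = data.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if tuple(random) == ("individual",):
            model = smf.mixedlm(formula, data, groups=data["individual"])
            n_var = 1
        else:
            data["_one"] = 1
            vcf = {g: f"0 + C({g if g != 'segment' else 'segment'})"
                   for g in random}
            model = smf.mixedlm(formula, data, groups=data["_one"],
                                re_formula="0", vc_formula=vcf)
            n_var = len(random)
        res = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=reml, method=method)
            except Exception:
                continue
            # lbfgs can report convergence with a non-finite profiled
            # likelihood at the variance boundary; fall through if so
            if np.isfinite(cand.llf):
                res = cand
                break
        if res is None:
            res = model.fit(reml=reml, method="nm", maxiter=2000)
        converged = bool(res.converged) and np.isfinite(res.llf)

    fe = res.fe_params
    sigma2 = float(res.scale)
    if tuple(random) == ("individual",):
        vcomp = {"individual": float(np.asarray(res.cov_re)[0, 0])}
    else:
        vcomp = {g: float(v) for g, v in zip(random, np.atleast_1d(res.vcomp))}
    singular = any(v < SINGULARITY_RATIO * sigma2 for v in vcomp.values())
    k = len(fe) + n_var + 1
    return FittedLMM(predictors=predictors, params=fe, bse=res.bse_fe,
                     llf=float(res.llf), k=k, nobs=int(res.nobs),
                     vcomp=vcomp, sigma2=sigma2, singular=singular,
                     converged=converged, random=tuple(random))


def select_random_effects(data: pd.DataFrame, response: str, predictors,
                          candidates=(("individual",),
                                      ("individual", "colony"),
                                      ("individual", "year"),
                                      ("individual", "colony", "year"))):
    """Random structure of the lowest-AICc non-singular REML fit.

    Falls back to individual-only when every candidate is singular.
    Returns (structure, table of candidate AICc/singularity).
    """
    rows = []
    for cand in candidates:
        usable = all(g == "individual" or g in data.columns for g in cand)
        if not usable:
            continue
        try:
            fit = fit_lmm(data, response, predictors, random=cand, reml=True)
        except Exception:
            continue
        rows.append({"random": cand, "aicc": fit.aicc, "singular": fit.singular,
                     "converged": fit.converged})
    tab = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    ok = tab[~tab["singular"] & tab["converged"]]
    if ok.empty:
        warnings.warn("all candidate random structures singular; "
                      "falling back to individual-only")
        return ("individual",), tab
    return tuple(ok.iloc[0]["random"]), tab


# ---------------------------------------------------------------------------
# Candidate sets, weights, averaging
# ---------------------------------------------------------------------------

def candidate_set(predictors):
    """All 2^p fixed-effect subsets (intercept-only included)."""
    predictors = list(predictors)
    if len(predictors) > MAX_SUBSET_PREDICTORS:
        raise ValueError(f"{len(predictors)} predictors: all-subsets set too large")
    subsets = []
    for r in range(len(predictors) + 1):
        subsets.extend(itertools.combinations(predictors, r))
    return subsets


def fit_candidates(data: pd.DataFrame, response: str, predictors,
                   random=("individual",)) -> list[FittedLMM]:
    """ML fits of every fixed-effect subset under one random structure."""
    fits = []
    for subset in candidate_set(predictors):
        try:
            fit = fit_lmm(data, response, subset, random=random, reml=False)
        except Exception as e:
            warnings.warn(f"candidate {subset} failed to fit: {e}")
            continue
        if not fit.converged:
            warnings.warn(f"candidate {subset} did not converge; excluded")
            continue
        fits.append(fit)
    if not fits:
        raise RuntimeError("no candidate model converged")
    return fits


def ic_weights(fits: list[FittedLMM], criterion: str = "BIC") -> pd.DataFrame:
    """Candidate table with criterion values and Akaike weights.

    w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2), Delta against the
    criterion minimum. Models whose AICc is undefined (n <= k + 1) are
    excluded with a warning.
    """
    crit = criterion.lower()
    if crit not in ("aicc", "bic"):
        raise ValueError("criterion must be 'AICc' or 'BIC'")
    rows = []
    for f in fits:
        val = f.aicc if crit == "aicc" else f.bic
        if not np.isfinite(val):
            warnings.warn(f"{criterion} undefined for {f.predictors} "
                          f"(n={f.nobs}, k={f.k}); excluded")
            continue
        rows.append({"predictors": f.predictors, "k": f.k, "llf": f.llf,
                     "criterion": val, "fit": f})
    tab = pd.DataFrame(rows)
    delta = tab["criterion"] - tab["criterion"].min()
    w = np.exp(-delta / 2.0)
    tab["delta"] = delta
    tab["weight"] = w / w.sum()
    tab = tab.sort_values("weight", ascending=False).reset_index(drop=True)
    tab["cum_weight"] = tab["weight"].cumsum()
    return tab


@dataclass
class AveragedEstimates:
    table: pd.DataFrame            # per-predictor estimate, SE, CI, flag
    n_models: int
    criterion: str

    def __getitem__(self, predictor):
        return self.table.loc[predictor]


def model_average(candidate_table: pd.DataFrame,
                  cumulative_weight: float = CONFIDENCE_WEIGHT,
                  z: float = 1.96, criterion: str = "BIC") -> AveragedEstimates:
    """Zero-method averages over the smallest 95%-cumulative-weight set.

    A predictor's coefficient is taken as 0 in models that exclude it; the
    unconditional SE combines within-model variance and between-model
    spread: sqrt(sum_i w_i (se_i^2 + (b_i - b_bar)^2)). The
    distinguishable-from-zero flag is set when the +-z SE interval excludes 0.
    """
    if candidate_table.empty:
        raise ValueError("empty candidate set")
    ncut = int(np.searchsorted(candidate_table["cum_weight"].to_numpy(),
                               cumulative_weight) + 1)
    top = candidate_table.iloc[:ncut].copy()
    top["weight"] = top["weight"] / top["weight"].sum()

    all_preds: list = []
    for f in top["fit"]:
        for p in f.params.index:
            if p not in all_preds:
                all_preds.append(p)
    rows = []
    for pname in all_preds:
        b = np.zeros(len(top))
        se = np.zeros(len(top))
        for i, f in enumerate(top["fit"]):
            if pname in f.params.index:
                b[i] = f.params[pname]
                se[i] = f.bse[pname]
        w = top["weight"].to_numpy()
        bbar = float(np.sum(w * b))
        use = float(np.sqrt(np.sum(w * (se ** 2 + (b - bbar) ** 2))))
        rows.append({"predictor": pname, "estimate": bbar, "se": use,
                     "ci_low": bbar - z * use, "ci_high": bbar + z * use,
                     "distinguishable": (bbar - z * use > 0) or (bbar + z * use < 0)})
    tab = pd.DataFrame(rows).set_index("predictor")
    return AveragedEstimates(table=tab, n_models=ncut, criterion=criterion)


def conditional_average(candidate_table: pd.DataFrame,
                        cumulative_weight: float = CONFIDENCE_WEIGHT) -> pd.Series:
    """Natural-method average (weights renormalized over containing models only).

    Used as the comparison point for the zero-method shrinkage property.
    """
    ncut = int(np.searchsorted(candidate_table["cum_weight"].to_numpy(),
                               cumulative_weight) + 1)
    top = candidate_table.iloc[:ncut]
    sums: dict = {}
    wsums: dict = {}
    for w, f in zip(top["weight"], top["fit"]):
        for p, val in f.params.items():
            sums[p] = sums.get(p, 0.0) + w * val
            wsums[p] = wsums.get(p, 0.0) + w
    return pd.Series({p: sums[p] / wsums[p] for p in sums})


def likelihood_ratio_test(nested: FittedLMM, full: FittedLMM):
    """chi^2 = 2 (llf_full - llf_nested), df = k difference, p from chi^2.

    Both fits must be ML fits of nested fixed-effect sets on the same data.
    """
    if nested.nobs != full.nobs:
        raise ValueError("fits are not on the same data")
    if not set(nested.predictors) <= set(full.predictors):
        raise ValueError("models are not nested")
    df = full.k - nested.k
    if df <= 0:
        raise ValueError("full model has no extra parameters")
    chi2 = max(2.0 * (full.llf - nested.llf), 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# High-level driver
# ---------------------------------------------------------------------------

def average_models(data: pd.DataFrame, response: str, predictors,
                   season: str = "autumn", criterion: str = "BIC",
                   standardize_predictors: bool = True,
                   transform_response: bool = True,
                   keep_on_collinearity: tuple = ("air_temperature",),
                   random_candidates=None):
    """Full inference chain for one traveling-behavior response.

    Applies the seasonal predictor exclusions, conditioning, screening,
    random-structure selection, all-subsets ML fitting and zero-method
    averaging. Returns a dict with the averaged estimates, candidate table,
    chosen random structure, screening report and transform parameters.
    """
    predictors = [p for p in predictors
                  if not (season == "spring" and p in SPRING_EXCLUDED)]
    work = data.copy()
    record = None
    if standardize_predictors:
        numeric = [p for p in predictors if pd.api.types.is_numeric_dtype(work[p])]
        work, record = standardize(work, columns=numeric)
    retained, vif_report = (vif_screen(work, predictors, keep=keep_on_collinearity)
                            if len(predictors) >= 2 else (predictors, pd.DataFrame()))
    lam = shift = None
    if transform_response:
        work[response], lam, shift = power_transform(work[response].to_numpy())
    if random_candidates is None:
        random_candidates = [("individual",)]
        for extra in ("colony", "year"):
            if extra in work.columns:
                random_candidates.append(("individual", extra))
        if "colony" in work.columns and "year" in work.columns:
            random_candidates.append(("individual", "colony", "year"))
    random, random_table = select_random_effects(work, response, retained,
                                                 candidates=random_candidates)
    fits = fit_candidates(work, response, retained, random=random)
    table = ic_weights(fits, criterion=criterion)
    averaged = model_average(table, criterion=criterion)
    return {"averaged": averaged, "candidates": table, "random": random,
            "random_table": random_table, "vif_report": vif_report,
            "retained_predictors": retained, "scaling": record,
            "boxcox_lambda": lam, "boxcox_shift": shift}
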