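"""Mixed-effects inference: factorial models with a participant random
intercept, normality-driven log transforms, and Tukey-corrected post hoc
contrasts (including the rise-onset contrast of each timepoint against the
cue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .mep import CUE_BIN_LABELS


@dataclass(frozen=True)
class ModelSpec:
    """Model description: response column, fully crossed fixed factors,
    grouping column for the random intercept, and the transform policy
    ("none", "log", or "auto" = log iff residual skewness exceeds the
    threshold and the response is strictly positive)."""

    response: str
    fixed_factors: tuple[str, ...]
    random_intercept: str = "participant"
    transform: str = "auto"
    skew_threshold: float = 1.0

    def fixed_formula_rhs(self) -> str:
        # sum-to-zero contrasts so each term's Wald test is marginal (the
        # type-III convention of the R mixed-model ecosystem) rather than a
        # contrast at the reference levels of the other factors
        return " * ".join(f"C({f}, Sum)" for f in self.fixed_factors)

    def formula(self, response: str | None = None) -> str:
        return f"{response or self.response} ~ {self.fixed_formula_rhs()}"


@dataclass
class ModelResult:
    """Per-term Wald tests, fixed-effect estimates and fit diagnostics."""

    terms: pd.DataFrame  # index: term; columns: statistic, df, pvalue
    params: pd.Series
    converged: bool
    transform_applied: str
    residual_skewness: float
    group_var: float
    n_obs: int
    notes: list[str] = field(default_factory=list)

    def pvalue(self, term: str) -> float:
        """P-value for a fixed term; bare factor names match their main effect."""
        exact = f"C({term}, Sum)"
        if exact in self.terms.index:
            return float(self.terms.loc[exact, "pvalue"])
        for idx in self.terms.index:
            if term in idx:
                return float(self.terms.loc[idx, "pvalue"])
        raise KeyError(term)


def _validate(table: pd.DataFrame, spec: ModelSpec) -> None:
    cols = [spec.response, spec.random_intercept, *spec.fixed_factors]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"columns missing from table: {missing}")
    if table[spec.random_intercept].nunique() < 2:
        raise ValueError("random intercept needs >= 2 grouping levels (single-participant table)")


def check_and_transform(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, dict]:
    """Automated surrogate for QQ inspection of residual normality.

    Fits the fixed-effects structure by OLS and measures residual skewness;
    under ``transform="auto"`` a log transform is applied iff |skewness|
    exceeds the threshold and the response is strictly positive. A forced
    log on a non-positive response is an error. Returns the (possibly
    transformed) table and a decision record.
    """
    _validate(table, spec)
    y = table[spec.response]
    ols = smf.ols(spec.formula(), data=table).fit()
    skew = float(stats.skew(ols.resid))
    positive = bool((y > 0).all())
    if spec.transform == "log":
        apply_log = True
    elif spec.transform == "none":
        apply_log = False
    elif spec.transform == "auto":
        apply_log = abs(skew) > spec.skew_threshold and positive
    else:
        raise ValueError(f"unknown transform {spec.transform!r}")
    if apply_log and not positive:
        raise ValueError("log transform requested but response has non-positive values")
    out = table
    decision = {"applied": "log" if apply_log else "none", "residual_skewness": skew}
    if apply_log:
        out = table.copy()
        out[spec.response] = np.log(y)
        resid = smf.ols(spec.formula(), data=out).fit().resid
        decision["post_transform_skewness"] = float(stats.skew(resid))
    return out, decision


def _manual_wald_terms(res) -> pd.DataFrame:
    """Per-term Wald chi-square from fe_params and their covariance."""
    design_info = res.model.data.design_info
    params = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(params), : len(params)]
    rows = {}
    for term, sl in design_info.term_name_slices.items():
        b = params[sl]
        v = cov[sl, sl]
        try:
            stat = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            stat = np.nan
        df = int(len(b))
        rows[term] = dict(
            statistic=stat, pvalue=float(stats.chi2.sf(stat, df)), df_constraint=df
        )
    return pd.DataFrame(rows).T


def fit_mixed(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit the factorial linear mixed model with a participant random intercept.

    Term tests are Wald chi-square tests on the REML fit (reported with their
    constraint df). Non-convergence is retried across optimizers and, failing
    that, flagged on the result with the fixed-effects fit retained.
    """
    _validate(table, spec)
    work, decision = check_and_transform(table, spec)
    notes = [f"transform={decision['applied']} (residual skewness {decision['residual_skewness']:.2f})"]
    model = smf.mixedlm(
        spec.formula(),
        data=work,
        groups=work[spec.random_intercept],
    )
    res = None
    converged = False
    for method in (["lbfgs"], ["powell"], ["cg"]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cand = model.fit(reml=True, method=method)
            except Exception as exc:  # singular fits on degenerate inputs
                notes.append(f"optimizer {method[0]} failed: {exc}")
                continue
        res = cand
        if cand.converged:
            converged = True
            break
    if res is None:
        raise RuntimeError("mixed model could not be fit: " + "; ".join(notes))
    if not converged:
        notes.append("non-convergence: result flagged; simplified-covariance fallback retained")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            wt = res.wald_test_terms(scalar=True).table
        except (ValueError, np.linalg.LinAlgError):
            # degenerate covariance (tiny or boundary fits): build the Wald
            # statistics per term directly from the fixed-effect estimates
            wt = _manual_wald_terms(res)
            notes.append("wald_test_terms failed; manual per-term Wald statistics used")
    wt = wt.rename(columns={"df_constraint": "df"})
    wt = wt[~wt.index.str.contains("Intercept")]
    try:
        resid = np.asarray(res.resid)
    except (ValueError, np.linalg.LinAlgError):
        # boundary fit (zero group variance): residuals from the fixed part
        resid = np.asarray(model.endog) - model.exog @ np.asarray(res.fe_params)
    resid_skew = float(stats.skew(resid))
    return ModelResult(
        terms=wt[["statistic", "df", "pvalue"]],
        params=res.fe_params,
        converged=converged,
        transform_applied=decision["applied"],
        residual_skewness=resid_skew,
        group_var=float(np.asarray(res.cov_re).ravel()[0]),
        n_obs=len(work),
        notes=notes,
    )


def tukey_paired_vs_reference(
    wide: pd.DataFrame,
    reference: str,
    family_size: int | None = None,
    correction: str = "tukey",
) -> pd.DataFrame:
    """Paired contrasts of each column against a reference column.

    ``wide`` has one row per participant and one column per condition. Each
    contrast is a paired t test; p-values carry a Tukey-style family
    correction via the studentized-range distribution (q = |t|*sqrt(2) with
    k = family size groups), or Bonferroni with ``correction="bonferroni"``.
    """
    if reference not in wide.columns:
        raise ValueError(f"reference level {reference!r} not in table")
    others = [c for c in wide.columns if c != reference]
    k = family_size or len(wide.columns)
    n = len(wide)
    if n < 2:
        raise ValueError("paired contrasts need >= 2 participants")
    rows = []
    for col in others:
        d = (wide[col] - wide[reference]).dropna()
        m = float(d.mean())
        se = float(d.std(ddof=1) / np.sqrt(len(d)))
        t = m / se if se > 0 else np.inf * np.sign(m) if m != 0 else 0.0
        df = len(d) - 1
        p_raw = 2 * stats.t.sf(abs(t), df)
        if correction == "tukey":
            p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        elif correction == "bonferroni":
            p_adj = min(1.0, p_raw * len(others))
        else:
            raise ValueError("correction must be 'tukey' or 'bonferroni'")
        rows.append(
            dict(contrast=f"{col} - {reference}", estimate=m, t=t, df=df, p_raw=p_raw, p_adj=p_adj)
        )
    return pd.DataFrame(rows)


def posthoc_rise_onset(
    binned_cue: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "tukey",
) -> dict:
    """Earliest timepoint at which excitability significantly exceeds the cue.

    For each task, participant bin means (averaged over coils) are contrasted
    against the Cue bin with paired t tests under a Tukey family correction;
    the rise onset is the earliest timepoint with adjusted p < alpha and a
    positive excitability difference, or None if the profile is flat.
    """
    out = {}
    for task, grp in binned_cue.groupby("task", observed=True):
        per = (
            grp.groupby(["participant_id", "bin_label"], observed=True)["mean_normalized_mep"]
            .mean()
            .reset_index()
        )
        wide = per.pivot(index="participant_id", columns="bin_label", values="mean_normalized_mep")
        wide = wide.reindex(columns=[b for b in CUE_BIN_LABELS if b in wide.columns])
        if len(wide) < 2:
            raise ValueError("rise-onset contrasts need >= 2 participants")
        if "Cue" not in wide.columns:
            raise ValueError("cue-locked table lacks the Cue bin")
        contrasts = tukey_paired_vs_reference(wide, "Cue", correction=correction)
        onset = None
        for b in CUE_BIN_LABELS[1:]:
            row = contrasts[contrasts["contrast"] == f"{b} - Cue"]
            if len(row) and row["p_adj"].iloc[0] < alpha and row["estimate"].iloc[0] > 0:
                onset = b
                break
        out[task] = {"onset": onset, "contrasts": contrasts}
    return out
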