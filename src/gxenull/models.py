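"""Linear models for GRS-exposure interaction analysis.

All fits are ordinary least squares (via statsmodels).  The central model is

    outcome ~ G + E + G:E + covariates

where G is the allele-count GRS (or a single-variant dosage) and E a binary
exposure; ``beta_int`` is the G:E coefficient.  The Keller-style sensitivity
fit additionally includes every covariate-by-E and covariate-by-G product,
guarding against confounder-driven interactions.  Stratified per-allele
associations (outcome ~ G + covariates within E = 0 and E = 1) accompany each
interaction fit, as do covariate-adjusted exposure contrasts of *raw* BMI
within the bottom and top GRS deciles.

Two-sided P-values use the normal approximation to the t statistic except
when the residual degrees of freedom fall below 200, where the exact t
distribution is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    EmptyCellError,
    EmptyGroupError,
    InsufficientDataError,
    InvalidInputError,
    InvalidSpecError,
)

__all__ = [
    "ModelSpec",
    "StratumFit",
    "InteractionResult",
    "build_design",
    "fit_stratified_association",
    "fit_interaction_model",
    "decile_contrast",
    "per_snp_interaction_scan",
    "beta_to_weight_change",
    "bonferroni_threshold",
]

_T_DF_CUTOFF = 200


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, genetic term, exposure, covariates, options.

    ``stratum`` restricts the analysis sample before fitting (e.g.
    ``{"sex": 1}`` or ``{"case": 1}`` for within-case models).
    ``extra_interactions`` adds further genetic-by-column products, e.g. a
    G x severity term to test whether a treatment interaction is explained
    by severity.
    """

    outcome: str = "bmi_int"
    genetic: str = "grs"
    exposure: str = "case"
    covariates: tuple[str, ...] = ()
    keller: bool = False
    stratum: dict | None = None
    extra_interactions: tuple[str, ...] = ()

    def __post_init__(self):
        forbidden = {self.outcome, self.genetic} & set(self.covariates)
        if forbidden:
            raise InvalidSpecError(
                f"covariates must exclude outcome/genetic term: {sorted(forbidden)}"
            )
        if self.exposure in self.covariates:
            raise InvalidSpecError("exposure must not also be a covariate")


@dataclass
class StratumFit:
    beta: float
    se: float
    p: float
    n: int


@dataclass
class InteractionResult:
    beta_int: float
    se_int: float
    p_int: float
    strata: dict = field(default_factory=dict)  # exposure level -> StratumFit
    n_total: int = 0
    decile_contrasts: dict | None = None  # {"bottom": (beta, se), "top": (beta, se)}
    params: pd.Series | None = None
    bse: pd.Series | None = None
    pvalues: pd.Series | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# design construction


def build_design(data: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariate design.

    Categorical columns (non-numeric dtype) expand to indicator sets with
    the most frequent level as the reference; numeric columns pass through
    as float.
    """
    pieces = []
    for col in covariates:
        if col not in data.columns:
            raise InvalidSpecError(f"covariate {col!r} not in data")
        s = data[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            pieces.append(s.astype(float).rename(col))
        else:
            ref = s.value_counts().idxmax()
            levels = [lv for lv in s.value_counts().index if lv != ref]
            for lv in levels:
                pieces.append((s == lv).astype(float).rename(f"{col}[{lv}]"))
    if not pieces:
        return pd.DataFrame(index=data.index)
    return pd.concat(pieces, axis=1)


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offending = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
            else:
                offending.append(names[j])
        raise CollinearityError(offending)


def _pvalues(tvals: np.ndarray, df_resid: float) -> np.ndarray:
    if df_resid < _T_DF_CUTOFF:
        return 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return 2.0 * stats.norm.sf(np.abs(tvals))


def _ols(y: np.ndarray, X: np.ndarray, names, check_rank: bool = True):
    if len(y) <= X.shape[1]:
        raise InsufficientDataError(
            f"n = {len(y)} observations for {X.shape[1]} model terms"
        )
    if check_rank:
        _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    p = _pvalues(res.tvalues, res.df_resid)
    return (
        pd.Series(res.params, index=names),
        pd.Series(res.bse, index=names),
        pd.Series(p, index=names),
        res,
    )


def _apply_stratum(data: pd.DataFrame, stratum: dict | None) -> pd.DataFrame:
    if not stratum:
        return data
    mask = pd.Series(True, index=data.index)
    for col, val in stratum.items():
        mask &= data[col] == val
    return data.loc[mask]


def _analysis_frame(data: pd.DataFrame, spec: ModelSpec, grs: pd.Series | None):
    df = data
    if grs is not None:
        df = df.copy()
        df[spec.genetic] = grs.reindex(df.index)
    df = _apply_stratum(df, spec.stratum)
    needed = [spec.outcome, spec.genetic, spec.exposure, *spec.covariates,
              *spec.extra_interactions]
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if df.empty:
        raise EmptyGroupError("analysis sample is empty after filtering")
    return df


# ---------------------------------------------------------------------------
# fits


def fit_stratified_association(
    data: pd.DataFrame, spec: ModelSpec, grs: pd.Series | None = None
) -> dict:
    """OLS of outcome on the genetic term + covariates within each exposure level.

    Returns ``{0: StratumFit, 1: StratumFit}`` (the "per-allele beta" rows of
    a stratified association table).
    """
    df = _analysis_frame(data, spec, grs)
    out = {}
    for level in (0, 1):
        sub = df.loc[df[spec.exposure] == level]
        if sub.empty:
            raise EmptyGroupError(f"no observations with {spec.exposure} == {level}")
        C = build_design(sub, spec.covariates)
        names = ["const", spec.genetic, *C.columns]
        X = np.column_stack(
            [np.ones(len(sub)), sub[spec.genetic].to_numpy(float), C.to_numpy(float)]
        ) if len(C.columns) else np.column_stack(
            [np.ones(len(sub)), sub[spec.genetic].to_numpy(float)]
        )
        params, bse, pvals, _ = _ols(sub[spec.outcome].to_numpy(float), X, names)
        out[level] = StratumFit(
            beta=float(params[spec.genetic]),
            se=float(bse[spec.genetic]),
            p=float(pvals[spec.genetic]),
            n=len(sub),
        )
    return out


def _interaction_design(
    g: np.ndarray, e: np.ndarray, C: np.ndarray, cnames, keller: bool,
    extras: dict | None = None,
):
    cols = [np.ones(len(g)), g, e, g * e]
    names = ["const", "G", "E", "G:E"]
    for j, nm in enumerate(cnames):
        cols.append(C[:, j])
        names.append(nm)
    if extras:
        for nm, x in extras.items():
            cols.append(g * x)
            names.append(f"G:{nm}")
    if keller:
        for j, nm in enumerate(cnames):
            cols.append(C[:, j] * e)
            names.append(f"{nm}:E")
        for j, nm in enumerate(cnames):
            cols.append(C[:, j] * g)
            names.append(f"{nm}:G")
    return np.column_stack(cols), names


def fit_interaction_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    grs: pd.Series | None = None,
    with_strata: bool = True,
) -> InteractionResult:
    """Pooled interaction fit: outcome ~ G + E + G:E + covariates.

    With ``spec.keller`` every covariate-by-E and covariate-by-G product is
    added.  ``spec.extra_interactions`` columns contribute further G-by-x
    terms.  The result embeds the per-stratum associations.
    """
    df = _analysis_frame(data, spec, grs)
    e = df[spec.exposure].to_numpy(float)
    levels = np.unique(e)
    if len(levels) < 2:
        raise InvalidSpecError(f"exposure {spec.exposure!r} is constant")
    if not set(levels) <= {0.0, 1.0}:
        raise InvalidSpecError(f"exposure {spec.exposure!r} must be binary 0/1")
    g = df[spec.genetic].to_numpy(float)
    y = df[spec.outcome].to_numpy(float)
    C = build_design(df, spec.covariates)
    extras = {nm: df[nm].to_numpy(float) for nm in spec.extra_interactions}
    X, names = _interaction_design(
        g, e, C.to_numpy(float), list(C.columns), spec.keller, extras
    )
    params, bse, pvals, _ = _ols(y, X, names)
    result = InteractionResult(
        beta_int=float(params["G:E"]),
        se_int=float(bse["G:E"]),
        p_int=float(pvals["G:E"]),
        n_total=len(df),
        params=params,
        bse=bse,
        pvalues=pvals,
        meta={
            "outcome": spec.outcome,
            "genetic": spec.genetic,
            "exposure": spec.exposure,
            "keller": spec.keller,
            "scale": "inverse-normal" if spec.outcome == "bmi_int" else "raw",
        },
    )
    if with_strata:
        result.strata = fit_stratified_association(data, spec, grs)
    return result


def _fit_interaction_arrays(
    y: np.ndarray, g: np.ndarray, e: np.ndarray, C: np.ndarray, cnames,
    keller: bool = False,
):
    """Hot-loop interaction fit on pre-built arrays (no rank check)."""
    X, names = _interaction_design(g, e, C, cnames, keller)
    res = sm.OLS(y, X).fit()
    j = names.index("G:E")
    p = _pvalues(np.array([res.tvalues[j]]), res.df_resid)[0]
    return float(res.params[j]), float(res.bse[j]), float(p)


def decile_contrast(
    data: pd.DataFrame,
    deciles: pd.Series,
    spec: ModelSpec,
    adjust: bool = True,
    outcome: str = "bmi_raw",
) -> dict:
    """Exposure effect on raw BMI within the bottom and top GRS deciles.

    Fits outcome ~ exposure (+ covariates when ``adjust``) separately in
    decile 1 and decile 10; returns ``{"bottom": (beta, se), "top": ...}``
    in the outcome's units (kg/m^2 for raw BMI).
    """
    df = _apply_stratum(data, spec.stratum).copy()
    df["_decile"] = deciles.reindex(df.index)
    df = df.dropna(subset=[outcome, spec.exposure, "_decile"])
    out = {}
    for label, d in (("bottom", 1), ("top", 10)):
        sub = df.loc[df["_decile"] == d]
        counts = sub[spec.exposure].value_counts()
        if len(sub) == 0 or counts.get(0, 0) == 0 or counts.get(1, 0) == 0:
            raise EmptyCellError(
                f"decile {d} lacks both exposure levels "
                f"({dict(counts)} for {spec.exposure!r})"
            )
        covs = spec.covariates if adjust else ()
        C = build_design(sub, covs)
        names = ["const", spec.exposure, *C.columns]
        X = np.column_stack(
            [np.ones(len(sub)), sub[spec.exposure].to_numpy(float)]
            + ([C.to_numpy(float)] if len(C.columns) else [])
        )
        params, bse, _, _ = _ols(sub[outcome].to_numpy(float), X, names)
        out[label] = (float(params[spec.exposure]), float(bse[spec.exposure]))
    return out


def per_snp_interaction_scan(
    dosages: pd.DataFrame,
    data: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One interaction model per variant, dosage replacing the score.

    Monomorphic variants are skipped (recorded with ``skipped=True``).  The
    Bonferroni threshold is alpha / (number of variants actually tested);
    ``bonferroni_sig`` flags interaction P below it.
    """
    rows = []
    for vid in dosages.columns:
        dose = dosages[vid]
        if dose.dropna().nunique() <= 1:
            rows.append({"variant_id": vid, "skipped": True})
            continue
        vspec = ModelSpec(
            outcome=spec.outcome,
            genetic="_snp",
            exposure=spec.exposure,
            covariates=spec.covariates,
            keller=spec.keller,
            stratum=spec.stratum,
        )
        res = fit_interaction_model(data, vspec, grs=dose.rename("_snp"))
        rows.append(
            {
                "variant_id": vid,
                "skipped": False,
                "beta_control": res.strata[0].beta,
                "se_control": res.strata[0].se,
                "p_control": res.strata[0].p,
                "beta_case": res.strata[1].beta,
                "se_case": res.strata[1].se,
                "p_case": res.strata[1].p,
                "beta_int": res.beta_int,
                "se_int": res.se_int,
                "p_int": res.p_int,
            }
        )
    table = pd.DataFrame(rows)
    n_tested = int((~table["skipped"]).sum())
    if n_tested == 0:
        raise InvalidSpecError("every variant was monomorphic; nothing tested")
    threshold = bonferroni_threshold(n_tested, alpha)
    table["bonferroni_threshold"] = threshold
    table["bonferroni_sig"] = (~table["skipped"]) & (table["p_int"] < threshold)
    return table


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise InvalidInputError("n_tests must be >= 1")
    return alpha / n_tests


def beta_to_weight_change(
    per_allele_beta: float,
    n_alleles: float,
    height_m: float,
    bmi_sd_raw: float,
) -> float:
    """Convert an inverse-normal-scale per-allele beta to kilograms.

    delta-BMI = beta * n_alleles * bmi_sd_raw (back-transform by the raw
    BMI SD), then kg = delta-BMI * height^2.  E.g. 10 extra risk alleles at
    beta = 0.0255 SD/allele, raw SD 4.6 kg/m^2, height 1.73 m -> ~3.5 kg.
    """
    if height_m <= 0:
        raise InvalidInputError("height must be positive")
    if bmi_sd_raw <= 0:
        raise InvalidInputError("bmi_sd_raw must be positive")
    return per_allele_beta * n_alleles * bmi_sd_raw * height_m**2
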