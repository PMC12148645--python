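"""Developmental statistics for bundle-wise microstructural features.

The core model regresses each bundle-wise feature on age, sex, their
interaction, and total intracranial volume:

    feature = b0 + b1*Age + b2*Sex + b3*Age*Sex + b4*zTICV

with sex coded 0 = female, 1 = male, so b1 is the female age slope and
b1 + b3 the male age slope.  Features (and TICV) are z-transformed before
fitting so coefficients read as standard-deviation change; age stays in raw
years so slopes read as SD/year.  Fits use bisquare robust regression;
multiple comparisons across the pathway x feature grid are controlled with
Benjamini-Hochberg FDR at alpha = 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .robust import BisquareRegressor, compare_effect_sizes

FEATURES = ("FA", "MD", "AD", "RD", "ICVF", "ISOVF", "ODI")
TIERS = ("SAF", "LR")
TERMS = {"intercept": 0, "age": 1, "sex": 2, "interaction": 3, "ticv": 4}
ALPHA = 0.05


def z_transform(values: np.ndarray | pd.Series, name: str = "column") -> np.ndarray:
    """Z-scores with the sample SD (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"z_transform needs >=2 values in '{name}'")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero variance in '{name}'; cannot z-transform")
    return (x - x.mean()) / sd


def build_design(cohort: pd.DataFrame) -> np.ndarray:
    """Design matrix [1, Age, Sex, Age*Sex, zTICV] from a cohort table.

    Age in raw years; Sex must be coded 0 (female) / 1 (male); TICV is
    z-transformed across the sample.
    """
    required = ["Age", "Sex", "TICV"]
    missing_cols = [c for c in required if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {missing_cols}")
    bad = cohort.index[cohort[required].isna().any(axis=1)]
    if len(bad):
        ids = (
            cohort.loc[bad, "participant_id"].tolist()
            if "participant_id" in cohort.columns
            else bad.tolist()
        )
        raise ValueError(f"missing covariates for participants: {ids}")
    sex = cohort["Sex"].to_numpy(dtype=float)
    if not np.isin(sex, [0.0, 1.0]).all():
        raise ValueError("Sex must be coded 0 (female) / 1 (male)")
    age = cohort["Age"].to_numpy(dtype=float)
    zticv = z_transform(cohort["TICV"].to_numpy(), name="TICV")
    return np.column_stack([np.ones_like(age), age, sex, age * sex, zticv])


def bh_fdr(pvalues: np.ndarray, alpha: float = ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def relative_percent_change(beta1_raw: float, mean_feature: float) -> float:
    """Cross-sectional percent change per year: 100 * slope / population mean.

    The slope is the raw-data age coefficient (female model, sex coded 0/1).
    """
    if mean_feature == 0:
        raise ValueError("mean feature value is zero; percent change undefined")
    return 100.0 * beta1_raw / mean_feature


def sex_specific_slopes(beta_age: float, beta_interaction: float) -> tuple[float, float]:
    """(female, male) age slopes under the 0=F / 1=M coding.

    The female slope is the age coefficient itself; the male slope adds the
    age-by-sex interaction coefficient.
    """
    return float(beta_age), float(beta_age + beta_interaction)


def fit_ticv_model(cohort: pd.DataFrame, **fit_kwargs) -> pd.Series:
    """Regress z-transformed TICV on age, sex and age*sex.

    A worked example of the coding contract: with coefficients
    (beta_age, beta_sex, beta_agexsex) the female TICV trajectory has slope
    beta_age SD/year and the male trajectory beta_age + beta_agexsex.
    """
    age = cohort["Age"].to_numpy(dtype=float)
    sex = cohort["Sex"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(age), age, sex, age * sex])
    y = z_transform(cohort["TICV"].to_numpy(), name="TICV")
    reg = BisquareRegressor(**fit_kwargs).fit(X, y)
    return pd.Series(
        {
            "beta0": reg.coef_[0],
            "beta_age": reg.coef_[1],
            "beta_sex": reg.coef_[2],
            "beta_agexsex": reg.coef_[3],
            "p_age": reg.pvalues_[1],
            "p_sex": reg.pvalues_[2],
            "p_agexsex": reg.pvalues_[3],
            "female_age_slope": sex_specific_slopes(reg.coef_[1], reg.coef_[3])[0],
            "male_age_slope": sex_specific_slopes(reg.coef_[1], reg.coef_[3])[1],
        }
    )


def _pivot_features(features: pd.DataFrame) -> pd.DataFrame:
    """Long feature table -> participants x (pathway, tier, feature) wide."""
    required = {"participant_id", "pathway", "tier", "feature", "value"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    wide = features.pivot_table(
        index="participant_id",
        columns=["pathway", "tier", "feature"],
        values="value",
        aggfunc="first",
    )
    return wide


def fit_all_bundles(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    standardize: bool = True,
    alpha: float = ALPHA,
    screen_ticv_interactions: bool = False,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit the age/sex/interaction/TICV model per (pathway, tier, feature).

    Returns a long table with one row per cell and term, carrying beta, SE,
    p, BH-FDR q and a significance flag.  The FDR family is all pathway x
    feature cells within one coefficient panel (term x tier), mirroring how
    effect matrices are displayed per tier.

    ``standardize=False`` fits the raw feature values (used for percent-
    change-per-year slopes and for exact recovery checks on noise-free
    simulations).  A failed cell is recorded with NaNs rather than aborting
    the batch.

    With ``screen_ticv_interactions=True`` the design is extended with
    TICV*age, TICV*sex and TICV*age*sex columns per cell; each extended
    column is retained only when significant at ``alpha`` (a model-selection
    screen — in the default model the TICV main effect is purely additive).
    """
    X = build_design(cohort)
    wide = _pivot_features(features)
    wide = wide.loc[cohort["participant_id"].to_numpy()]
    rows = []
    for pathway, tier, feature in wide.columns:
        y = wide[(pathway, tier, feature)].to_numpy(dtype=float)
        cell = {"pathway": pathway, "tier": tier, "feature": feature}
        try:
            if np.isnan(y).any():
                raise ValueError("missing feature values")
            y_fit = z_transform(y, name=f"{pathway}/{tier}/{feature}") if standardize else y
            X_cell = X
            if screen_ticv_interactions:
                X_cell = _screen_ticv_interactions(X, y_fit, alpha, fit_kwargs)
            reg = BisquareRegressor(**fit_kwargs).fit(X_cell, y_fit)
            for term, idx in TERMS.items():
                rows.append(
                    cell
                    | {
                        "term": term,
                        "beta": reg.coef_[idx],
                        "se": reg.se_[idx],
                        "p": reg.pvalues_[idx],
                        "converged": reg.converged_,
                        "failed": False,
                        "mean_raw": float(np.mean(y)),
                    }
                )
        except ValueError:
            for term in TERMS:
                rows.append(
                    cell
                    | {
                        "term": term,
                        "beta": np.nan,
                        "se": np.nan,
                        "p": np.nan,
                        "converged": False,
                        "failed": True,
                        "mean_raw": float(np.nanmean(y)) if np.isfinite(y).any() else np.nan,
                    }
                )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    out["significant"] = False
    for (term, tier), idx in out.groupby(["term", "tier"]).groups.items():
        sub = out.loc[idx]
        ok = sub["p"].notna()
        if ok.any():
            q, rej = bh_fdr(sub.loc[ok, "p"].to_numpy(), alpha=alpha)
            out.loc[sub.index[ok], "q"] = q
            out.loc[sub.index[ok], "significant"] = rej
    return out


def _screen_ticv_interactions(X, y, alpha, fit_kwargs) -> np.ndarray:
    """Extend the design with TICV interactions, keeping only significant ones."""
    age, sex, zticv = X[:, 1], X[:, 2], X[:, 4]
    candidates = {
        "ticv_x_age": zticv * age,
        "ticv_x_sex": zticv * sex,
        "ticv_x_age_x_sex": zticv * age * sex,
    }
    X_ext = np.column_stack([X] + list(candidates.values()))
    if np.linalg.matrix_rank(X_ext) < X_ext.shape[1]:
        return X
    reg = BisquareRegressor(**fit_kwargs).fit(X_ext, y)
    keep = [j for j in range(X.shape[1], X_ext.shape[1]) if reg.pvalues_[j] <= alpha]
    if not keep:
        return X
    return np.column_stack([X, X_ext[:, keep]])


def effect_matrix(
    results: pd.DataFrame, term: str, tier: str
) -> pd.DataFrame:
    """Pivot one term/tier panel to a pathway x feature matrix of betas."""
    sub = results[(results["term"] == term) & (results["tier"] == tier)]
    return sub.pivot(index="pathway", columns="feature", values="beta").reindex(
        columns=[f for f in FEATURES if f in sub["feature"].unique()]
    )


def percent_change_table(
    features: pd.DataFrame, cohort: pd.DataFrame, **fit_kwargs
) -> pd.DataFrame:
    """Relative percent change per year per cell, from raw-data fits."""
    raw = fit_all_bundles(features, cohort, standardize=False, **fit_kwargs)
    age_rows = raw[raw["term"] == "age"].copy()
    age_rows["pct_change_per_year"] = [
        relative_percent_change(b, m) if np.isfinite(b) and m != 0 else np.nan
        for b, m in zip(age_rows["beta"], age_rows["mean_raw"])
    ]
    return age_rows[["pathway", "tier", "feature", "beta", "mean_raw", "pct_change_per_year"]]


def compare_saf_lr(
    results: pd.DataFrame, term: str = "age", alpha: float = ALPHA
) -> pd.DataFrame:
    """SAF-vs-LR effect-size comparison per pathway x feature for one term.

    Two-tailed z-test on the difference of the two robust-fit coefficients,
    BH FDR across all pathway x feature cells of the panel.
    """
    sub = results[results["term"] == term]
    saf = sub[sub["tier"] == "SAF"].set_index(["pathway", "feature"])
    lr = sub[sub["tier"] == "LR"].set_index(["pathway", "feature"])
    common = saf.index.intersection(lr.index)
    rows = []
    for key in common:
        ba, sa = saf.loc[key, "beta"], saf.loc[key, "se"]
        bb, sb = lr.loc[key, "beta"], lr.loc[key, "se"]
        if not (np.isfinite(ba) and np.isfinite(bb) and sa > 0 and sb > 0):
            continue
        t, p = compare_effect_sizes(ba, sa, bb, sb)
        rows.append(
            {
                "pathway": key[0],
                "feature": key[1],
                "beta_saf": ba,
                "beta_lr": bb,
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"], out["significant"] = bh_fdr(out["p"].to_numpy(), alpha=alpha)
    return out
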