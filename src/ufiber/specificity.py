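"""Partial correlations and SAF-LR coupling specificity tests.

Two questions about microstructural coupling are addressed here:

1. How do the seven features co-vary within and across bundle tiers?
   Answered with partial Pearson correlations across participants,
   controlling for age, sex and z-scored TICV (the developmental
   covariates), so the correlations reflect residual individual
   differences rather than shared age trends.

2. Is the coupling between a long-range (LR) pathway and its structurally
   associated SAF *specific*?  For each LR pathway and feature the
   Fisher-z-transformed associated correlation is compared to the mean of
   the z-transformed correlations with all other SAFs (hypothesis
   "saf": specificity relative to other SAF systems) or with all other LR
   pathways (hypothesis "lr").  The difference is scaled by the standard
   error of a single z-transformed partial correlation,
   SE = 1/sqrt(N - k - 3) with k = 3 covariates, giving a one-tailed
   Z-test (associated > comparison mean).  Dependence among correlations
   sharing the LR pathway is deliberately ignored — the test is an
   approximation that quantifies specificity, not an exact comparison.

BH FDR is applied across pathways within each feature x hypothesis family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import ALPHA, FEATURES, _pivot_features, bh_fdr, z_transform

N_COVARIATES = 3  # age, sex, zTICV


@dataclass
class PartialCorrResult:
    r: float
    p: float
    n: int
    k: int


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by least squares;
    r is the Pearson correlation of the residuals, with the p-value from
    ``t = r sqrt((n - 2 - k) / (1 - r^2))`` on n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != x.size:
        C = C.T
    if C.shape[0] != x.size or y.size != x.size:
        raise ValueError("x, y and covariates must have matching length")
    n = x.size
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 = {k + 2} observations, have {n}")
    Z = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        # constant covariate columns collapse into the intercept
        Z = _drop_dependent_columns(Z)
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx = np.linalg.norm(rx)
    sy = np.linalg.norm(ry)
    # scale-aware zero test: residuals at numerical-noise level count as zero
    if sx <= 1e-10 * max(np.linalg.norm(x), 1.0) or sy <= 1e-10 * max(
        np.linalg.norm(y), 1.0
    ):
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p=p, n=n, k=k)


def _drop_dependent_columns(Z: np.ndarray) -> np.ndarray:
    keep = [0]
    for j in range(1, Z.shape[1]):
        cand = Z[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    return Z[:, keep]


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform, z = atanh(r).

    |r| = 1 is clipped to 1 - 1e-15 so the transform stays finite.
    """
    if abs(r) > 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    clipped = np.clip(r, -(1.0 - 1e-15), 1.0 - 1e-15)
    return float(np.arctanh(clipped))


def specificity_ztest(
    z_assoc: float, z_others: list[float] | np.ndarray, N: int, k: int = N_COVARIATES
) -> tuple[float, float]:
    """One-tailed Z-test: is the associated z-correlation larger than the mean?

    Z = (z_assoc - mean(z_others)) * sqrt(N - k - 3); p = 1 - Phi(Z).
    """
    z_others = np.asarray(z_others, dtype=float)
    if z_others.size == 0:
        raise ValueError("comparison set is empty")
    if N <= k + 3:
        raise ValueError(f"need N > k + 3 = {k + 3} subjects, have {N}")
    Z = (z_assoc - z_others.mean()) * np.sqrt(N - k - 3)
    p = float(stats.norm.sf(Z))
    return float(Z), p


def _covariate_matrix(cohort: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [
            cohort["Age"].to_numpy(dtype=float),
            cohort["Sex"].to_numpy(dtype=float),
            z_transform(cohort["TICV"].to_numpy(), name="TICV"),
        ]
    )


@dataclass
class InterFeatureMatrices:
    """7x7 inter-feature partial-correlation matrices for one pathway."""

    saf_saf: pd.DataFrame
    lr_lr: pd.DataFrame
    saf_lr: pd.DataFrame  # rows: SAF feature, cols: LR feature (asymmetric)
    p_saf_saf: pd.DataFrame
    p_lr_lr: pd.DataFrame
    p_saf_lr: pd.DataFrame
    sig_saf_saf: pd.DataFrame
    sig_lr_lr: pd.DataFrame
    sig_saf_lr: pd.DataFrame


def inter_feature_matrices(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    pathway: str,
    alpha: float = ALPHA,
) -> InterFeatureMatrices:
    """SAF-SAF, LR-LR and SAF-LR inter-feature partial correlations.

    The symmetric within-tier matrices have unit diagonal; FDR is applied
    within each matrix (upper-triangle family for the symmetric ones, all
    49 cells for the cross-tier matrix).
    """
    wide = _pivot_features(features).loc[cohort["participant_id"].to_numpy()]
    C = _covariate_matrix(cohort)
    cols = {}
    for tier in ("SAF", "LR"):
        for f in FEATURES:
            key = (pathway, tier, f)
            if key not in wide.columns:
                raise ValueError(f"feature table missing column {key}")
            cols[(tier, f)] = wide[key].to_numpy(dtype=float)

    def corr(tier_a: str, fa: str, tier_b: str, fb: str) -> PartialCorrResult:
        return partial_correlation(cols[(tier_a, fa)], cols[(tier_b, fb)], C)

    nf = len(FEATURES)
    out = {}
    for name, (ta, tb) in {"saf_saf": ("SAF", "SAF"), "lr_lr": ("LR", "LR"), "saf_lr": ("SAF", "LR")}.items():
        r = np.eye(nf)
        p = np.zeros((nf, nf))
        symmetric = ta == tb
        for i, fa in enumerate(FEATURES):
            for j, fb in enumerate(FEATURES):
                if symmetric and j <= i:
                    continue
                res = corr(ta, fa, tb, fb)
                r[i, j], p[i, j] = res.r, res.p
                if symmetric:
                    r[j, i], p[j, i] = res.r, res.p
        if not symmetric:
            for i, fa in enumerate(FEATURES):
                res = corr(ta, fa, tb, fa)
                r[i, i], p[i, i] = res.r, res.p
        # FDR within the matrix family
        if symmetric:
            iu = np.triu_indices(nf, k=1)
            q, rej = bh_fdr(p[iu], alpha=alpha)
            sig = np.zeros((nf, nf), dtype=bool)
            sig[iu] = rej
            sig |= sig.T
        else:
            q, rej = bh_fdr(p.ravel(), alpha=alpha)
            sig = rej.reshape(nf, nf)
        idx = list(FEATURES)
        out[name] = pd.DataFrame(r, index=idx, columns=idx)
        out[f"p_{name}"] = pd.DataFrame(p, index=idx, columns=idx)
        out[f"sig_{name}"] = pd.DataFrame(sig, index=idx, columns=idx)
    return InterFeatureMatrices(**out)


def pathway_feature_correlations(
    features: pd.DataFrame, cohort: pd.DataFrame, feature: str
) -> tuple[pd.DataFrame, int]:
    """Partial-correlation matrix between all bundles for one feature.

    Rows/columns are (tier, pathway) bundle columns; returns the matrix and
    the participant count.
    """
    wide = _pivot_features(features).loc[cohort["participant_id"].to_numpy()]
    C = _covariate_matrix(cohort)
    bundles = [
        (tier, pathway)
        for (pathway, tier, f) in wide.columns
        if f == feature
    ]
    bundles = sorted(set(bundles))
    n = len(bundles)
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ti, pi = bundles[i]
            tj, pj = bundles[j]
            res = partial_correlation(
                wide[(pi, ti, feature)].to_numpy(dtype=float),
                wide[(pj, tj, feature)].to_numpy(dtype=float),
                C,
            )
            r[i, j] = r[j, i] = res.r
    labels = [f"{tier}:{pathway}" for tier, pathway in bundles]
    return pd.DataFrame(r, index=labels, columns=labels), len(cohort)


def run_specificity(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    pairing: dict[str, str] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Specificity of associated SAF-LR coupling, per pathway x feature.

    ``pairing`` maps each LR pathway label to its associated SAF pathway
    label; by default each pathway is paired with its own SAF bundle (the
    proximity-based classification names SAF bundles after the LR bundle
    they pass through).

    For each LR pathway i and feature, hypothesis "saf" compares the
    associated correlation r(LR_i, SAF_i) against the mean over j != i of
    r(LR_i, SAF_j); hypothesis "lr" against the mean over k != i of
    r(LR_i, LR_k).  All correlations are partial (age, sex, zTICV) and
    Fisher-z-transformed; FDR runs across pathways within each
    feature x hypothesis family.
    """
    wide = _pivot_features(features).loc[cohort["participant_id"].to_numpy()]
    C = _covariate_matrix(cohort)
    N = len(cohort)
    pathways = sorted({p for (p, t, f) in wide.columns})
    if len(pathways) < 3:
        raise ValueError("specificity testing needs at least 3 pathways")
    if pairing is None:
        pairing = {p: p for p in pathways}

    feature_list = sorted({f for (p, t, f) in wide.columns})
    rows = []
    for feature in feature_list:
        # z-transformed partial correlations of LR_i with every other bundle
        z_cache: dict[tuple[str, str, str], float] = {}

        def zcorr(pa: str, ta: str, pb: str, tb: str) -> float:
            key = (f"{pa}|{ta}", f"{pb}|{tb}", feature)
            rkey = (key[1], key[0], key[2])
            if key in z_cache:
                return z_cache[key]
            if rkey in z_cache:
                return z_cache[rkey]
            res = partial_correlation(
                wide[(pa, ta, feature)].to_numpy(dtype=float),
                wide[(pb, tb, feature)].to_numpy(dtype=float),
                C,
            )
            z = fisher_z(res.r)
            z_cache[key] = z
            return z

        for lr_i in pathways:
            saf_i = pairing.get(lr_i)
            cell = {"pathway": lr_i, "feature": feature}
            if saf_i is None or (saf_i, "SAF", feature) not in wide.columns:
                for hyp in ("saf", "lr"):
                    rows.append(cell | {"hypothesis": hyp, "missing": True})
                continue
            z_assoc = zcorr(lr_i, "LR", saf_i, "SAF")
            others_saf = [
                zcorr(lr_i, "LR", pairing[p], "SAF")
                for p in pathways
                if p != lr_i and pairing.get(p) in pathways
            ]
            others_lr = [zcorr(lr_i, "LR", p, "LR") for p in pathways if p != lr_i]
            for hyp, others in (("saf", others_saf), ("lr", others_lr)):
                Z, p_one = specificity_ztest(z_assoc, others, N)
                rows.append(
                    cell
                    | {
                        "hypothesis": hyp,
                        "missing": False,
                        "z_assoc": z_assoc,
                        "mean_z_other": float(np.mean(others)),
                        "se": 1.0 / np.sqrt(N - N_COVARIATES - 3),
                        "Z": Z,
                        "p_one_tailed": p_one,
                    }
                )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    out["significant"] = False
    for (feature, hyp), idx in out.groupby(["feature", "hypothesis"]).groups.items():
        sub = out.loc[idx]
        ok = sub["missing"] == False  # noqa: E712
        if ok.any():
            q, rej = bh_fdr(sub.loc[ok, "p_one_tailed"].to_numpy(), alpha=alpha)
            out.loc[sub.index[ok], "q"] = q
            out.loc[sub.index[ok], "significant"] = rej
    return out
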