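"""Differentially methylated position (DMP) discovery and clock-site profiles.

Per probe a linear model of the beta value on covariates is fitted by least
squares (all probes share one design matrix, so the fits are vectorised):

    aging contrast:    beta_i ~ Age + Sex + cells + PCs
    disease contrast:  beta_i ~ Disease_status + Age + Sex + cells + PCs

The target covariate's coefficient and two-sided t-test p are extracted,
Bonferroni-corrected over the probes actually tested; direction is the sign
of the coefficient (Disease_status coded case=1, control=0, so a hypomethyl-
ated case signature has a negative coefficient).

Clock-site profile models add a quadratic age term to capture the non-linear
beta trajectories of clock CpGs:

    beta_i ~ Age + Age^2 + Sex + cells + PCs

fitted on controls; a case's deviation is observed minus predicted beta.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bonferroni, build_design, check_full_rank
from .core_io import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger("agescreen")


# ---------------------------------------------------------------------------
# Vectorised multi-response OLS (shared design matrix)
# ---------------------------------------------------------------------------


@dataclass
class ProbeLinearModelResults:
    """Per-probe OLS over a shared design: coefficients, SEs and t-test p."""

    params: pd.DataFrame        # probes x design columns
    bse: pd.DataFrame
    pvalues: pd.DataFrame
    design_columns: list[str]
    df_resid: int
    resid_sd: pd.Series | None = None  # per-probe residual scale

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Fitted values for a new design matrix: probes x samples."""
        B = self.params[self.design_columns].to_numpy()
        return pd.DataFrame(B @ X[self.design_columns].to_numpy().T,
                            index=self.params.index, columns=X.index)


def fit_probe_linear_models(Y: pd.DataFrame, X: pd.DataFrame,
                            ) -> ProbeLinearModelResults:
    """Fit beta_i ~ X for every probe i (rows of Y) by least squares.

    Y : probes x samples (no NaN), X : samples x covariates (incl. const).
    """
    check_full_rank(X)
    Xa = X.to_numpy(dtype=float)
    Ya = Y.to_numpy(dtype=float).T  # samples x probes
    if np.isnan(Ya).any():
        raise ValidationError("NaN betas are not supported in per-probe models; "
                              "impute or drop probes first")
    n, k = Xa.shape
    if n <= k:
        raise ValidationError("more covariates than samples in per-probe models")
    XtX_inv = np.linalg.inv(Xa.T @ Xa)
    B = XtX_inv @ Xa.T @ Ya              # k x probes
    resid = Ya - Xa @ B
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # k x probes
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, B / se, np.inf * np.sign(B))
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    pvals = np.where(se > 0, pvals, np.where(B == 0, 1.0, 0.0))
    cols = list(X.columns)
    return ProbeLinearModelResults(
        params=pd.DataFrame(B.T, index=Y.index, columns=cols),
        bse=pd.DataFrame(se.T, index=Y.index, columns=cols),
        pvalues=pd.DataFrame(pvals.T, index=Y.index, columns=cols),
        design_columns=cols, df_resid=dof,
        resid_sd=pd.Series(np.sqrt(sigma2), index=Y.index, name="resid_sd"))


# ---------------------------------------------------------------------------
# DMP discovery
# ---------------------------------------------------------------------------


@dataclass
class DMPTable:
    """Per-probe coefficient, p, Bonferroni-adjusted p, direction and flag."""

    table: pd.DataFrame  # index probe_id; columns coefficient, p_raw, p_adjusted,
    #                      direction, significant
    contrast: str = "age"
    alpha: float = 0.01
    n_tested: int = 0

    def significant_probes(self, direction: str | None = None) -> pd.Index:
        t = self.table[self.table["significant"]]
        if direction is not None:
            t = t[t["direction"] == direction]
        return t.index


def find_dmps(betas: BetaMatrix, sheet: SampleSheet,
              pcs: pd.DataFrame | None = None,
              composition: pd.DataFrame | None = None,
              contrast: Literal["age", "disease"] = "age",
              case_label: str | None = None,
              alpha: float = 0.01) -> DMPTable:
    """Discover DMPs for the age or disease contrast.

    The age contrast is fitted on control samples only; the disease contrast
    uses the named case group against controls with Disease_status as the
    target covariate.  Zero-variance probes are excluded (logged) and the
    Bonferroni divisor is the number of probes actually tested.
    """
    if contrast == "age":
        ids = sheet.control_ids()
        target = "Age"
        ssheet = sheet.subset(ids)
        extra = None
    elif contrast == "disease":
        if case_label is None:
            raise ValidationError("disease contrast requires case_label")
        case_ids = sheet.case_ids(case_label)
        if len(case_ids) == 0:
            raise ValidationError(f"no samples for case label {case_label!r}")
        ids = sheet.control_ids().append(case_ids)
        ssheet = sheet.subset(ids)
        status = pd.Series(0.0, index=ids, name="Disease_status")
        status.loc[case_ids] = 1.0
        extra = status.to_frame()
        target = "Disease_status"
    else:
        raise ValidationError(f"unknown contrast {contrast!r}")

    X = build_design(ssheet, pcs=pcs, composition=composition, extra=extra)
    Y = betas.values[list(ids)]
    variances = Y.var(axis=1, ddof=0)
    keep = variances > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("find_dmps: excluded %d zero-variance probes", n_dropped)
    Y = Y.loc[keep]
    if Y.shape[0] == 0:
        raise ValidationError("no probes with variance to test")
    res = fit_probe_linear_models(Y, X)
    coef = res.params[target]
    p_raw = res.pvalues[target]
    n_tested = len(coef)
    p_adj = pd.Series(bonferroni(p_raw, n_tested), index=coef.index)
    table = pd.DataFrame({
        "coefficient": coef,
        "p_raw": p_raw,
        "p_adjusted": p_adj,
        "direction": np.where(coef >= 0, "hyper", "hypo"),
        "significant": p_adj < alpha,
    })
    # excluded probes re-enter as untested (p=1, not significant) for bookkeeping
    dropped = variances.index[~keep]
    if len(dropped):
        filler = pd.DataFrame({
            "coefficient": 0.0, "p_raw": 1.0, "p_adjusted": 1.0,
            "direction": "hyper", "significant": False}, index=dropped)
        table = pd.concat([table, filler]).loc[betas.probe_ids]
    return DMPTable(table=table, contrast=contrast, alpha=alpha, n_tested=n_tested)


# ---------------------------------------------------------------------------
# Intersections
# ---------------------------------------------------------------------------


@dataclass
class DMPIntersection:
    """Direction-stratified partition of the probe universe."""

    subsets: dict[str, set[str]]
    counts: pd.Series

    def __getitem__(self, key: str) -> set[str]:
        return self.subsets[key]


def intersect_dmps(aging: DMPTable, disease: DMPTable) -> DMPIntersection:
    """Partition probes by (aging direction x disease direction).

    Named subsets: hyper-hyper, hyper-hypo, hypo-hyper, hypo-hypo (the
    aging direction first), aging-only, disease-only, neither.
    """
    universe_a = set(aging.table.index)
    universe_d = set(disease.table.index)
    if universe_a != universe_d:
        asym = sorted(universe_a ^ universe_d)
        raise ValidationError(f"probe universes differ; asymmetric: {asym[:10]}")
    a_hyper = set(aging.significant_probes("hyper"))
    a_hypo = set(aging.significant_probes("hypo"))
    d_hyper = set(disease.significant_probes("hyper"))
    d_hypo = set(disease.significant_probes("hypo"))
    a_all = a_hyper | a_hypo
    d_all = d_hyper | d_hypo
    subsets = {
        "hyper-hyper": a_hyper & d_hyper,
        "hyper-hypo": a_hyper & d_hypo,
        "hypo-hyper": a_hypo & d_hyper,
        "hypo-hypo": a_hypo & d_hypo,
        "aging-only": a_all - d_all,
        "disease-only": d_all - a_all,
        "neither": universe_a - a_all - d_all,
    }
    counts = pd.Series({k: len(v) for k, v in subsets.items()})
    return DMPIntersection(subsets=subsets, counts=counts)


# ---------------------------------------------------------------------------
# Clock-site profile models (quadratic in age)
# ---------------------------------------------------------------------------


@dataclass
class ClockSiteProfile:
    """Quadratic beta-trajectory models per clock probe, fitted on controls."""

    results: ProbeLinearModelResults
    sheet: SampleSheet
    pcs: pd.DataFrame | None
    composition: pd.DataFrame | None

    @property
    def params(self) -> pd.DataFrame:
        return self.results.params

    def predict(self, sheet: SampleSheet) -> pd.DataFrame:
        X = build_design(sheet, pcs=self.pcs, composition=self.composition,
                         quadratic_age=True)
        return self.results.predict(X)


def fit_clock_site_profiles(betas: BetaMatrix, sheet: SampleSheet,
                            pcs: pd.DataFrame | None = None,
                            composition: pd.DataFrame | None = None,
                            ) -> ClockSiteProfile:
    """One beta ~ Age + Age^2 + covariates model per clock probe (controls)."""
    controls = sheet.control_ids()
    if len(controls) < 10:
        warnings.warn("fewer than 10 controls: clock-site profiles will have "
                      "wide variance", stacklevel=2)
    csheet = sheet.subset(controls)
    if csheet.ages.nunique() < 3:
        raise ValidationError("controls must span an age range")
    X = build_design(csheet, pcs=pcs, composition=composition, quadratic_age=True)
    Y = betas.values[list(controls)]
    res = fit_probe_linear_models(Y, X)
    return ClockSiteProfile(results=res, sheet=sheet, pcs=pcs,
                            composition=composition)


def case_deviations(profiles: ClockSiteProfile, betas: BetaMatrix,
                    sample_ids: Iterable[str],
                    standardize: bool = False) -> pd.DataFrame:
    """Observed minus predicted beta per clock probe for the given samples
    (probes x samples, heatmap-ready).  ``standardize`` divides each probe's
    deviations by the model's residual-scale estimate."""
    ids = list(sample_ids)
    sub = profiles.sheet.subset(ids)
    pred = profiles.predict(sub)
    obs = betas.values.loc[pred.index, ids]
    dev = obs - pred
    if standardize:
        sd = profiles.results.resid_sd.replace(0.0, np.nan)
        dev = dev.div(sd, axis=0)
    return dev
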