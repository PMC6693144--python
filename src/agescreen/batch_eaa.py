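"""Technical-variance correction and epigenetic age acceleration (EAA).

The workflow mirrors how EAA screens on 450K blood cohorts are run:

1. PCA (centred, unscaled) on raw control-probe intensities gives technical
   PCs that capture batch structure; a scree elbow picks how many to keep.
2. A *control model* is fitted on healthy samples only:

       DNAmAge ~ Age + Sex [+ 6 cell proportions] + PC1 + ... + PCK

   Its residuals are the controls' EAA; a case's EAA is its observed DNAmAge
   minus the control model's prediction.  The calibration metric is
   MAE = median(|EAA_i|) over controls.
3. Each eligible disorder's EAA distribution is compared against the controls
   with a two-sided Wilcoxon rank-sum test, Bonferroni-corrected across the
   disorders screened (alpha = 0.01 by default).

The model objects follow the statsmodels convention: ``ControlAgeModel``
holds data and design, ``fit()`` returns a ``ControlAgeResults`` carrying
coefficients, residuals, the MAE and prediction machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._stats import bonferroni, build_design, check_full_rank, rank_sum_test
from .core_io import CONTROL_GROUP, ControlProbeMatrix, SampleSheet, ValidationError

logger = logging.getLogger("agescreen")

PAPER_DEFAULT_N_PCS = 17  # optimal PC count reported for the real 450K screen


# ---------------------------------------------------------------------------
# Control-probe PCA
# ---------------------------------------------------------------------------


@dataclass
class TechnicalPCs:
    """Per-sample technical PC scores from control-probe intensities."""

    scores: pd.DataFrame           # samples x PCs ("PC1", ...)
    variance_fractions: np.ndarray
    fitting_samples: list[str] = field(default_factory=list)

    def top(self, k: int) -> pd.DataFrame:
        if k > self.scores.shape[1]:
            raise ValidationError(
                f"requested {k} PCs but only {self.scores.shape[1]} available")
        return self.scores.iloc[:, :k]


def fit_control_pca(control_probes: ControlProbeMatrix) -> TechnicalPCs:
    """PCA with centering but no scaling on raw control-probe intensities.

    Scores are the centred data projected on the right singular vectors; the
    sign of each component is fixed so its largest-magnitude loading is
    positive.  The input should contain every sample whose scores will be
    used downstream (controls and cases jointly).
    """
    X = control_probes.intensities.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("control-probe PCA needs >= 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValidationError("no variance in control-probe matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix sign: largest-|.| entry of each loading vector positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = Xc @ Vt.T
    var = s ** 2
    frac = var / var.sum()
    k = scores.shape[1]
    cols = [f"PC{i + 1}" for i in range(k)]
    return TechnicalPCs(
        scores=pd.DataFrame(scores, index=control_probes.sample_ids, columns=cols),
        variance_fractions=frac,
        fitting_samples=list(control_probes.sample_ids),
    )


def choose_n_pcs(variance_fractions: Sequence[float]) -> int:
    """Scree elbow: the point with maximum perpendicular distance to the line
    joining the first and last scree points; ties break toward smaller K."""
    v = np.asarray(variance_fractions, dtype=float)
    if len(v) < 3:
        raise ValidationError("choose_n_pcs needs >= 3 scree points")
    x = np.arange(1, len(v) + 1, dtype=float)
    p1 = np.array([x[0], v[0]])
    p2 = np.array([x[-1], v[-1]])
    d = p2 - p1
    norm = np.hypot(*d)
    if norm == 0:
        return 1
    # perpendicular distance of each point to the first-to-last chord
    dist = np.abs(d[1] * (x - p1[0]) - d[0] * (v - p1[1])) / norm
    return int(np.argmax(dist)) + 1  # argmax takes the first (smallest K) maximum


# ---------------------------------------------------------------------------
# Control model (statsmodels-style Model / Results)
# ---------------------------------------------------------------------------


class ControlAgeModel:
    """Linear control model for epigenetic age: DNAmAge ~ Age + Sex [+ cells] + PCs.

    Parameters
    ----------
    sheet : SampleSheet restricted to the samples available.
    dnam_age : per-sample epigenetic age in years.
    pcs : technical PC scores to include (samples x K), or None.
    composition : cell proportions (samples x types) when correcting for cell
        composition (CCC), or None.
    response_name : label of the modelled response (default "DNAmAge"); the
        same machinery backs entropy and mitotic-score acceleration models.

    Only control samples (group == "control") enter the fit; ``fit`` returns
    a :class:`ControlAgeResults`.
    """

    def __init__(self, sheet: SampleSheet, dnam_age: pd.Series,
                 pcs: pd.DataFrame | None = None,
                 composition: pd.DataFrame | None = None,
                 response_name: str = "DNAmAge") -> None:
        self.sheet = sheet
        self.response = dnam_age.astype(float)
        self.pcs = pcs
        self.composition = composition
        self.response_name = response_name
        self.with_ccc = composition is not None

    def _design(self, sheet: SampleSheet) -> pd.DataFrame:
        return build_design(sheet, pcs=self.pcs, composition=self.composition)

    def fit(self) -> "ControlAgeResults":
        controls = self.sheet.control_ids()
        if len(controls) < 3:
            raise ValidationError("control model needs >= 3 control samples")
        csheet = self.sheet.subset(controls)
        if csheet.ages.nunique() < 2:
            raise ValidationError("control ages must span a range")
        X = self._design(csheet)
        check_full_rank(X)
        y = self.response.loc[controls]
        if y.isna().any():
            bad = y.index[y.isna()].tolist()
            raise ValidationError(f"missing response for samples {bad[:5]}")
        ols = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        params = pd.Series(ols.params, index=X.columns)
        resid = pd.Series(ols.resid, index=controls)
        return ControlAgeResults(model=self, params=params,
                                 control_residuals=resid,
                                 design_columns=list(X.columns),
                                 sm_results=ols)


@dataclass
class ControlAgeResults:
    """Fitted control model: coefficients, control residuals (= control EAA),
    MAE, and prediction for new samples."""

    model: ControlAgeModel
    params: pd.Series
    control_residuals: pd.Series
    design_columns: list[str]
    sm_results: object = None

    @property
    def mae(self) -> float:
        """median(|EAA_i|) over the control samples used in the fit."""
        return float(np.median(np.abs(self.control_residuals.to_numpy())))

    def predict(self, sheet: SampleSheet) -> pd.Series:
        X = self.model._design(sheet)
        X = X[self.design_columns]
        return pd.Series(X.to_numpy() @ self.params.to_numpy(),
                         index=sheet.sample_ids, name="predicted")

    def compute_eaa(self, sheet: SampleSheet | None = None,
                    response: pd.Series | None = None) -> "EAAResult":
        """EAA for all samples: control residuals; cases observed - predicted."""
        sheet = sheet if sheet is not None else self.model.sheet
        response = response if response is not None else self.model.response
        controls = set(self.control_residuals.index)
        pred = self.predict(sheet)
        eaa = response.loc[sheet.sample_ids] - pred
        # controls from the fitting set carry their exact fit residuals
        fit_controls = [s for s in sheet.sample_ids if s in controls]
        eaa.loc[fit_controls] = self.control_residuals.loc[fit_controls]
        role = pd.Series(
            ["control-residual" if s in controls else "case-prediction-difference"
             for s in sheet.sample_ids], index=sheet.sample_ids)
        return EAAResult(eaa=eaa.rename("eaa"), role=role, mae=self.mae,
                         with_ccc=self.model.with_ccc,
                         response_name=self.model.response_name)

    def summary(self) -> str:
        lines = [
            f"Control model: {self.model.response_name} ~ "
            + " + ".join(c for c in self.design_columns if c != "const"),
            f"  n controls: {len(self.control_residuals)}",
            f"  with CCC:   {self.model.with_ccc}",
            f"  MAE:        {self.mae:.4f}",
            "  coefficients:",
        ]
        lines += [f"    {name:>12s}  {val: .6g}" for name, val in self.params.items()]
        return "\n".join(lines)


def fit_control_model(sheet: SampleSheet, dnam_age: pd.Series,
                      pcs: pd.DataFrame | None = None,
                      composition: pd.DataFrame | None = None,
                      with_ccc: bool = False) -> ControlAgeResults:
    """Functional wrapper over :class:`ControlAgeModel`."""
    if with_ccc and composition is None:
        raise ValidationError("with_ccc=True requires a cell composition")
    comp = composition if with_ccc else None
    return ControlAgeModel(sheet, dnam_age, pcs=pcs, composition=comp).fit()


@dataclass
class EAAResult:
    """Per-sample epigenetic age acceleration in years."""

    eaa: pd.Series
    role: pd.Series
    mae: float
    with_ccc: bool = False
    response_name: str = "DNAmAge"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"eaa": self.eaa, "role": self.role})


def compute_eaa(results: ControlAgeResults, sheet: SampleSheet,
                response: pd.Series) -> EAAResult:
    return results.compute_eaa(sheet, response)


# ---------------------------------------------------------------------------
# Screen
# ---------------------------------------------------------------------------


def filter_disorders(sheet: SampleSheet, min_n: int = 5, min_adults: int = 2,
                     adult_age: float = 20.0) -> list[str]:
    """Disorders eligible for the screen: >= min_n samples, >= min_adults of
    them with age >= adult_age."""
    eligible = []
    for group, sub in sheet.table.groupby("group", sort=True):
        if group == CONTROL_GROUP:
            continue
        n = len(sub)
        n_adults = int((sub["age"].astype(float) >= adult_age).sum())
        if n >= min_n and n_adults >= min_adults:
            eligible.append(str(group))
        else:
            logger.info("screen: excluded %r (n=%d, adults=%d)", group, n, n_adults)
    return eligible


@dataclass
class ScreenResult:
    """Per-disorder screen table: n, median EAA, raw and Bonferroni p."""

    table: pd.DataFrame  # index = disorder
    alpha: float = 0.01

    def significant(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def screen_disorders(eaa: EAAResult, sheet: SampleSheet,
                     disorders: Iterable[str] | None = None,
                     alpha: float = 0.01) -> ScreenResult:
    """Two-sided rank-sum test of each disorder's EAA vs control EAA,
    Bonferroni-corrected across the disorders tested in this run."""
    if disorders is None:
        disorders = filter_disorders(sheet)
    disorders = list(disorders)
    if not disorders:
        raise ValidationError("no eligible disorders to screen")
    control_eaa = eaa.eaa.loc[sheet.control_ids()].to_numpy()
    rows = []
    for d in disorders:
        ids = sheet.case_ids(d)
        if len(ids) == 0:
            raise ValidationError(f"disorder {d!r} has no samples after joining")
        case_eaa = eaa.eaa.loc[ids].to_numpy()
        p = rank_sum_test(case_eaa, control_eaa)
        rows.append({"disorder": d, "n": len(ids),
                     "median_eaa": float(np.median(case_eaa)), "p_raw": p})
    table = pd.DataFrame(rows).set_index("disorder")
    table["p_adjusted"] = bonferroni(table["p_raw"], len(disorders))
    table["significant"] = table["p_adjusted"] < alpha
    return ScreenResult(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# EAA ~ Age slope
# ---------------------------------------------------------------------------


@dataclass
class SlopeResult:
    slope: float
    p_value: float
    n: int
    intercept: float


def eaa_age_slope(eaa: EAAResult, sheet: SampleSheet, group: str,
                  exclude: Iterable[str] | None = None) -> SlopeResult:
    """OLS slope of EAA on chronological age within one group, with its
    two-sided t-test p; ``exclude`` supports leave-one-out sensitivity."""
    ids = sheet.case_ids(group) if group != CONTROL_GROUP else sheet.control_ids()
    if exclude:
        excl = set(exclude)
        ids = pd.Index([s for s in ids if s not in excl])
    if len(ids) < 3:
        raise ValidationError("eaa_age_slope needs >= 3 samples")
    ages = sheet.ages.loc[ids].to_numpy()
    if np.ptp(ages) == 0:
        raise ValidationError("constant age in group")
    y = eaa.eaa.loc[ids].to_numpy()
    X = sm.add_constant(ages)
    res = sm.OLS(y, X).fit()
    return SlopeResult(slope=float(res.params[1]), p_value=float(res.pvalues[1]),
                       n=len(ids), intercept=float(res.params[0]))
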