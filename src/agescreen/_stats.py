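"""Shared statistical primitives: rank-sum test policy and design matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SampleSheet, ValidationError

EXACT_RANKSUM_MAX_N = 10


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when min(n1, n2) <= 10 and there are no
    ties across the pooled sample, and the normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def bonferroni(p, n_tests: int) -> np.ndarray:
    return np.minimum(1.0, np.asarray(p, dtype=float) * n_tests)


def build_design(sheet: SampleSheet,
                 pcs: pd.DataFrame | None = None,
                 composition: pd.DataFrame | None = None,
                 extra: pd.DataFrame | None = None,
                 quadratic_age: bool = False,
                 drop_collinear_celltype: bool = True) -> pd.DataFrame:
    """Assemble the covariate design matrix (with intercept) for a sample set.

    Columns: const, Age [, Age2], Sex (female=0, male=1), cell proportions,
    technical PCs, then any extra columns.  Under sum-to-one compositions one
    cell-type column is dropped to keep the design full rank.
    """
    samples = sheet.sample_ids
    cols = {"const": pd.Series(1.0, index=samples),
            "Age": sheet.ages}
    if quadratic_age:
        cols["Age2"] = sheet.ages ** 2
    cols["Sex"] = sheet.sex_indicator()
    X = pd.DataFrame(cols)
    if extra is not None:
        X = pd.concat([X, extra.loc[samples]], axis=1)
    if composition is not None:
        comp = composition.loc[samples]
        sums = comp.sum(axis=1).to_numpy()
        if drop_collinear_celltype and np.allclose(sums, 1.0, atol=1e-8):
            dropped = comp.columns[-1]
            comp = comp.drop(columns=dropped)
            import logging
            logging.getLogger("agescreen").info(
                "design: dropped cell-type column %r (sum-to-one composition)",
                dropped)
        X = pd.concat([X, comp], axis=1)
    if pcs is not None:
        X = pd.concat([X, pcs.loc[samples]], axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        rows = X.index[X.isna().any(axis=1)].tolist()
        raise ValidationError(
            f"missing covariates {bad} for samples {rows[:5]}")
    return X


def check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns involved in collinearity via QR pivoting
        from numpy.linalg import qr
        _, r = qr(arr)
        diag = np.abs(np.diag(r))
        suspects = [X.columns[i] for i in range(len(diag))
                    if diag[i] < 1e-8 * diag.max()]
        raise ValidationError(f"rank-deficient design; collinear columns: {suspects}")
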