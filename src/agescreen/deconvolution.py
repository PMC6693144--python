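"""Reference-based cell-composition estimation (Houseman-style constrained
projection) and the benchmark metrics used to rank deconvolution strategies.

Per sample the estimate solves

    min_p || beta - R p ||^2   s.t.  p >= 0  and  sum(p) <= 1  (or = 1)

where R holds the reference methylomes (probes x cell types).  The solver is
deterministic: non-negative least squares (Lawson-Hanson) for the inequality
mode, escalating to an exact active-set equality-constrained solve when the
unconstrained-sum optimum leaves the simplex.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_io import BetaMatrix, ValidationError

logger = logging.getLogger("agescreen")

DEFAULT_CELL_TYPES = ("Gran", "CD4T", "CD8T", "B", "Mono", "NK")


@dataclass
class CellTypeReference:
    """Mean beta per probe per cell type (probes x cell types)."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.profiles
        if df.shape[1] < 2:
            raise ValidationError("reference needs >= 2 cell types")
        if df.index.duplicated().any():
            raise ValidationError("duplicate probe ids in reference")
        arr = df.to_numpy(dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            raise ValidationError("reference betas must be in [0,1]")

    @property
    def cell_types(self) -> pd.Index:
        return self.profiles.columns

    @property
    def probe_ids(self) -> pd.Index:
        return self.profiles.index

    def is_collinear(self, tol: float = 1e-10) -> bool:
        arr = self.profiles.to_numpy(dtype=float)
        return np.linalg.matrix_rank(arr, tol=tol) < arr.shape[1]


def read_cell_reference(path, delimiter: str = "\t") -> CellTypeReference:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    return CellTypeReference(df.astype(float))


def write_cell_reference(ref: CellTypeReference, path, delimiter: str = "\t") -> None:
    ref.profiles.to_csv(path, sep=delimiter, index_label="probe_id",
                        float_format="%.12g")


@dataclass
class CellComposition:
    """Per-sample cell-type proportions under a declared sum constraint."""

    proportions: pd.DataFrame  # samples x cell types
    constraint: Literal["sum-to-one", "sum-leq-one"] = "sum-leq-one"

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if (arr < -1e-9).any():
            raise ValidationError("negative cell proportions")
        sums = arr.sum(axis=1)
        if self.constraint == "sum-to-one":
            if np.abs(sums - 1.0).max() > 1e-6:
                raise ValidationError("proportions must sum to one")
        elif (sums > 1 + 1e-8).any():
            raise ValidationError("proportions must sum to <= 1")

    @property
    def cell_types(self) -> pd.Index:
        return self.proportions.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.proportions.index


def _simplex_ls(R: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact active-set least squares on the probability simplex.

    Solves min ||R p - y||^2 with p >= 0 and sum(p) = 1 via KKT solves on the
    free set, fixing the most negative coordinate to zero until feasible.
    """
    k = R.shape[1]
    free = np.ones(k, dtype=bool)
    for _ in range(k + 1):
        idx = np.flatnonzero(free)
        Rf = R[:, idx]
        # KKT system for equality-constrained LS: [RtR 1; 1t 0][p; l] = [Rty; 1]
        RtR = Rf.T @ Rf
        ones = np.ones((len(idx), 1))
        kkt = np.block([[RtR, ones], [ones.T, np.zeros((1, 1))]])
        rhs = np.concatenate([Rf.T @ y, [1.0]])
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        p_free = sol[:-1]
        if (p_free >= -1e-12).all():
            p = np.zeros(k)
            p[idx] = np.clip(p_free, 0.0, None)
            s = p.sum()
            return p / s if s > 0 else p
        free[idx[np.argmin(p_free)]] = False
        if not free.any():
            break
    p = np.zeros(k)
    p[np.argmin(((R - y[:, None]) ** 2).sum(axis=0))] = 1.0
    return p


def estimate_cell_composition(
    betas: BetaMatrix,
    reference: CellTypeReference,
    constraint: Literal["sum-to-one", "sum-leq-one"] = "sum-leq-one",
) -> CellComposition:
    """Estimate per-sample cell-type proportions by constrained projection.

    Probes are matched by id between the beta matrix and the reference;
    per-sample missing betas are dropped pairwise.  The solution does not
    depend on probe order.
    """
    shared = reference.probe_ids[reference.probe_ids.isin(betas.probe_ids)]
    k = len(reference.cell_types)
    if len(shared) < k:
        raise ValidationError(
            f"only {len(shared)} shared probes for {k} cell types")
    shared = shared.sort_values()  # order-invariance by canonical ordering
    R_full = reference.profiles.loc[shared].to_numpy(dtype=float)
    if reference.is_collinear():
        warnings.warn("rank-deficient cell-type reference; "
                      "minimum-norm solutions returned", stacklevel=2)
        logger.warning("estimate_cell_composition: reference is rank-deficient")
    Y = betas.values.loc[shared].to_numpy(dtype=float)

    out = np.zeros((Y.shape[1], k))
    for j in range(Y.shape[1]):
        y = Y[:, j]
        ok = ~np.isnan(y)
        if ok.sum() < k:
            raise ValidationError(
                f"sample {betas.sample_ids[j]!r}: fewer usable probes than cell types")
        R = R_full[ok]
        yy = y[ok]
        if constraint == "sum-to-one":
            out[j] = _simplex_ls(R, yy)
        else:
            p, _ = nnls(R, yy)
            if p.sum() > 1.0 + 1e-10:
                # optimum lies on the simplex boundary of the convex feasible set
                out[j] = _simplex_ls(R, yy)
            else:
                out[j] = p
    props = pd.DataFrame(out, index=betas.sample_ids, columns=reference.cell_types)
    return CellComposition(proportions=props, constraint=constraint)


@dataclass
class DeconvolutionBenchmark:
    """Deviation summary between estimated and true compositions."""

    per_cell_type: pd.DataFrame  # columns: mad, rmse
    overall_mad: float
    overall_rmse: float


def benchmark_deconvolution(estimates: CellComposition,
                            truth: CellComposition) -> DeconvolutionBenchmark:
    """MAD and RMSE per cell type and pooled; RMSE orders competing strategies."""
    if list(estimates.cell_types) != list(truth.cell_types):
        raise ValidationError("cell-type labels differ between estimates and truth")
    if not estimates.sample_ids.equals(truth.sample_ids):
        raise ValidationError("sample ids differ between estimates and truth")
    diff = estimates.proportions.to_numpy() - truth.proportions.to_numpy()
    per = pd.DataFrame({
        "mad": np.abs(diff).mean(axis=0),
        "rmse": np.sqrt((diff ** 2).mean(axis=0)),
    }, index=estimates.cell_types)
    return DeconvolutionBenchmark(
        per_cell_type=per,
        overall_mad=float(np.abs(diff).mean()),
        overall_rmse=float(np.sqrt((diff ** 2).mean())),
    )
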