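"""Linear epigenetic clocks and the mitotic (pcgtAge) score.

A clock is an intercept plus probe weights applied to beta values, optionally
composed with the Horvath age transform that is anchored at reproductive age
(``adult_age``, 20 years in humans):

    F(age) = log((age + 1) / (adult_age + 1))      for age <= adult_age
    F(age) = (age - adult_age) / (adult_age + 1)   for age  > adult_age

F is continuous with a continuous first derivative at ``adult_age`` and maps
age > -1 onto the real line.  Published coefficient sets are pluggable input
files; the package ships none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, ValidationError

logger = logging.getLogger("agescreen")

DEFAULT_ADULT_AGE = 20.0


# ---------------------------------------------------------------------------
# Age transform
# ---------------------------------------------------------------------------


def transform_age(age, adult_age: float = DEFAULT_ADULT_AGE):
    """Horvath age transform F(age); vectorised, defined for age > -1."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise ValidationError("transform_age requires age > -1")
    out = np.where(
        age <= adult_age,
        np.log((age + 1.0) / (adult_age + 1.0)),
        (age - adult_age) / (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


def inverse_transform_age(t, adult_age: float = DEFAULT_ADULT_AGE):
    """Inverse of :func:`transform_age`: years from the transformed scale."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t <= 0,
        (adult_age + 1.0) * np.exp(t) - 1.0,
        adult_age + t * (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Clock definition and evaluation
# ---------------------------------------------------------------------------


@dataclass
class ClockDefinition:
    """A linear clock: intercept + sum(w_j * beta_j), then an age transform."""

    name: str
    intercept: float
    coefficients: pd.Series  # index = probe ids, values = weights
    transform: Literal["log-linear", "identity"] = "log-linear"
    adult_age: float = DEFAULT_ADULT_AGE

    def __post_init__(self) -> None:
        if self.coefficients.index.duplicated().any():
            raise ValidationError("duplicate probe ids in clock coefficients")
        if self.transform == "log-linear" and self.adult_age <= 0:
            raise ValidationError("adult_age must be > 0 for a log-linear clock")
        if self.transform not in ("log-linear", "identity"):
            raise ValidationError(f"unknown transform {self.transform!r}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.coefficients.index

    def to_years(self, raw):
        if self.transform == "log-linear":
            return inverse_transform_age(raw, self.adult_age)
        return raw

    def from_years(self, age):
        if self.transform == "log-linear":
            return transform_age(age, self.adult_age)
        return np.asarray(age, dtype=float)


def read_clock_definition(path) -> ClockDefinition:
    """Read a clock CSV: '# key=value' metadata header then probe_id,coefficient."""
    meta: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition("=")
                meta[key.strip()] = val.strip()
                continue
            probe, _, coef = line.partition(",")
            if probe == "probe_id":
                continue
            rows.append((probe, float(coef)))
    coefs = pd.Series(dict(rows), dtype=float)
    coefs.index.name = "probe_id"
    return ClockDefinition(
        name=meta.get("name", "clock"),
        intercept=float(meta.get("intercept", 0.0)),
        coefficients=coefs,
        transform=meta.get("transform", "log-linear"),
        adult_age=float(meta.get("adult_age", DEFAULT_ADULT_AGE)),
    )


def write_clock_definition(clock: ClockDefinition, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name={clock.name}\n")
        fh.write(f"# intercept={clock.intercept!r}\n")
        fh.write(f"# transform={clock.transform}\n")
        fh.write(f"# adult_age={clock.adult_age!r}\n")
        fh.write("probe_id,coefficient\n")
        for probe, coef in clock.coefficients.items():
            fh.write(f"{probe},{coef!r}\n")


@dataclass
class ClockResult:
    """Per-sample epigenetic age (years) and clock-probe coverage."""

    dnam_age: pd.Series       # years
    coverage: pd.Series       # fraction of clock probes available
    clock_name: str = "clock"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dnam_age": self.dnam_age, "coverage": self.coverage})


def evaluate_clock(betas: BetaMatrix, clock: ClockDefinition,
                   missing_policy: Literal["available-only", "fail"] = "available-only",
                   ) -> ClockResult:
    """Evaluate a linear clock on a beta matrix.

    Raw score = intercept + sum over *available* clock probes of w_j*beta_j;
    DNAmAge is its inverse transform.  Missing probes (absent from the matrix
    or NaN per sample) reduce the reported coverage; under the "fail" policy
    any missing probe raises instead.  When coverage < 1 the prediction may
    carry an offset, which is logged.
    """
    probes = clock.probe_ids
    present = probes[probes.isin(betas.probe_ids)]
    absent = probes.difference(present)
    if missing_policy == "fail" and len(absent):
        raise ValidationError(f"clock probes missing from matrix: {list(absent)[:10]}")

    sub = betas.values.reindex(probes)  # probes x samples, NaN where absent
    w = clock.coefficients.to_numpy(dtype=float)[:, None]
    vals = sub.to_numpy(dtype=float)
    available = ~np.isnan(vals)
    if missing_policy == "fail" and not available.all():
        bad = sub.index[np.isnan(vals).any(axis=1)]
        raise ValidationError(f"NaN clock-probe betas for probes: {list(bad)[:10]}")
    coverage = available.sum(axis=0) / len(probes)
    if (coverage == 0).any():
        raise ValidationError("sample with no available clock probes")
    raw = clock.intercept + np.nansum(np.where(available, w * vals, 0.0), axis=0)
    if (coverage < 1).any():
        logger.warning(
            "clock %s: %d/%d samples have incomplete probe coverage (min %.3f); "
            "predictions may be offset", clock.name,
            int((coverage < 1).sum()), vals.shape[1], float(coverage.min()))
    dnam_age = clock.to_years(raw)
    samples = betas.sample_ids
    return ClockResult(
        dnam_age=pd.Series(np.asarray(dnam_age, dtype=float), index=samples,
                           name="dnam_age"),
        coverage=pd.Series(coverage, index=samples, name="coverage"),
        clock_name=clock.name,
    )


# ---------------------------------------------------------------------------
# Mitotic clock
# ---------------------------------------------------------------------------


@dataclass
class MitoticScore:
    """pcgtAge: mean beta over Polycomb-target promoter probes, in [0, 1]."""

    score: pd.Series
    coverage: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pcgt_age": self.score, "coverage": self.coverage})


def pcgt_age(betas: BetaMatrix, probe_set: Iterable[str]) -> MitoticScore:
    """Unweighted per-sample mean beta over the available mitotic-clock probes."""
    probe_set = pd.Index(pd.unique(pd.Series(list(probe_set))))
    if len(probe_set) == 0:
        raise ValidationError("empty mitotic-clock probe set")
    present = probe_set[probe_set.isin(betas.probe_ids)]
    if len(present) == 0:
        raise ValidationError("no overlap between probe set and beta matrix")
    sub = betas.values.loc[present]
    score = sub.mean(axis=0, skipna=True)
    coverage = sub.notna().sum(axis=0) / len(probe_set)
    if len(present) < len(probe_set):
        logger.warning("pcgt_age: %d/%d probes available",
                       len(present), len(probe_set))
    return MitoticScore(score=score.rename("pcgt_age"),
                        coverage=coverage.astype(float).rename("coverage"))
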