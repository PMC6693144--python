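"""Domain containers and text-format readers/writers shared by every pipeline stage.

All genomic coordinates are 0-based half-open (BED convention) internally.
Beta matrices are probes x samples tab-delimited text with a probe-id first
column; sample sheets are TSV with at least ``sample_id, age, sex, batch,
group`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("agescreen")

REQUIRED_SHEET_COLUMNS = ("sample_id", "age", "sex", "batch", "group")
VALID_SEXES = frozenset({"male", "female"})
CONTROL_GROUP = "control"


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    Missing entries are stored as NaN and excluded pairwise by downstream
    computations.
    """

    values: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dup[:5]}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        arr = df.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        bad &= ~np.isnan(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0,1] at probe {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        probes = [p for p in probes if p in self.values.index]
        return BetaMatrix(self.values.loc[probes])


def read_beta_matrix(path, delimiter: str = "\t") -> BetaMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df.astype(float))


def write_beta_matrix(betas: BetaMatrix, path, delimiter: str = "\t") -> None:
    betas.values.to_csv(path, sep=delimiter, index_label="probe_id",
                        float_format="%.12g")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Per-sample metadata: age (years), sex, batch label and disorder group."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ("age", "sex", "batch", "group") if c not in t.columns]
        if missing:
            raise ValidationError(f"sample sheet missing required columns: {missing}")
        if t.index.duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        ages = t["age"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or (ages < 0).any():
            raise ValidationError("ages must be finite and >= 0")
        bad_sex = set(t["sex"]) - VALID_SEXES
        if bad_sex:
            raise ValidationError(f"unrecognised sex labels: {sorted(bad_sex)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def ages(self) -> pd.Series:
        return self.table["age"].astype(float)

    def sex_indicator(self) -> pd.Series:
        """Sex as 0/1 (female=0, male=1) for design matrices."""
        return (self.table["sex"] == "male").astype(float)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def control_ids(self) -> pd.Index:
        return self.table.index[self.table["group"] == CONTROL_GROUP]

    def case_ids(self, group: str | None = None) -> pd.Index:
        mask = self.table["group"] != CONTROL_GROUP
        if group is not None:
            mask = self.table["group"] == group
        return self.table.index[mask]

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)])


def read_sample_sheet(path, delimiter: str = "\t") -> SampleSheet:
    df = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str})
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet missing required columns: {missing}")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path, delimiter: str = "\t") -> None:
    sheet.table.to_csv(path, sep=delimiter, index_label="sample_id")


# ---------------------------------------------------------------------------
# Intensities / control probes
# ---------------------------------------------------------------------------


@dataclass
class IntensityPair:
    """Methylated/unmethylated probe fluorescence intensities (probes x samples)."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def __post_init__(self) -> None:
        if self.methylated.shape != self.unmethylated.shape:
            raise ValidationError("methylated/unmethylated shapes differ")
        for name, df in (("methylated", self.methylated),
                         ("unmethylated", self.unmethylated)):
            if (df.to_numpy(dtype=float) < 0).any():
                raise ValidationError(f"negative {name} intensities")

    @property
    def sample_ids(self) -> pd.Index:
        return self.methylated.columns


@dataclass
class ControlProbeMatrix:
    """Raw control-probe intensities, samples x features.

    On the real 450K platform the expected width is 847 probes x 2 channels =
    1694 intensity values; synthetic widths are free.
    """

    intensities: pd.DataFrame  # index = sample ids, columns = feature ids

    def __post_init__(self) -> None:
        arr = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("control probe intensities must be finite")

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns


def read_control_probes(path, delimiter: str = "\t") -> ControlProbeMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    return ControlProbeMatrix(df.astype(float))


def write_control_probes(cp: ControlProbeMatrix, path, delimiter: str = "\t") -> None:
    cp.intensities.to_csv(path, sep=delimiter, index_label="sample_id",
                          float_format="%.12g")


def qc_intensity_filter(intensities: IntensityPair, threshold: float = 10.5,
                        floor: float = 1.0) -> pd.DataFrame:
    """Per-sample intensity QC.

    A sample passes iff ``(median(log2 M) + median(log2 U)) / 2 >= threshold``
    with medians taken over all probes of that sample.  Zero intensities are
    replaced by ``floor`` before the log (the statistic is undefined at zero
    fluorescence); all-zero samples fail with reason "degenerate intensities".
    """
    m = intensities.methylated.to_numpy(dtype=float)
    u = intensities.unmethylated.to_numpy(dtype=float)
    degenerate = (m.sum(axis=0) == 0) & (u.sum(axis=0) == 0)
    m = np.where(m <= 0, floor, m)
    u = np.where(u <= 0, floor, u)
    stat = (np.median(np.log2(m), axis=0) + np.median(np.log2(u), axis=0)) / 2.0
    passed = (stat >= threshold) & ~degenerate
    reasons = np.where(degenerate, "degenerate intensities",
                       np.where(passed, "", "below intensity threshold"))
    out = pd.DataFrame({
        "statistic": stat,
        "passed": passed,
        "reason": reasons,
    }, index=intensities.sample_ids)
    n_fail = int((~passed).sum())
    if n_fail:
        logger.info("qc_intensity_filter: %d/%d samples failed", n_fail, len(out))
    return out


# ---------------------------------------------------------------------------
# Intervals / signal tracks / probe coordinates
# ---------------------------------------------------------------------------


@dataclass
class IntervalSet:
    """Genomic intervals, 0-based half-open, sorted by (chrom, start)."""

    records: pd.DataFrame  # columns: chrom, start, end [, name]

    def __post_init__(self) -> None:
        df = self.records
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"interval set missing column {col!r}")
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        if np.isnan(starts.astype(float)).any() or np.isnan(ends.astype(float)).any():
            raise ValidationError("NaN interval coordinates")
        if (starts < 0).any():
            raise ValidationError("negative interval coordinates")
        if (starts >= ends).any():
            raise ValidationError("intervals require start < end")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "records", df)

    def __len__(self) -> int:
        return len(self.records)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for chrom, sub in self.records.groupby("chrom", sort=False):
            out[str(chrom)] = (sub["start"].to_numpy(dtype=np.int64),
                               sub["end"].to_numpy(dtype=np.int64))
        return out


def read_intervals(path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValidationError("BED file needs at least 3 columns")
    cols = ["chrom", "start", "end"] + (["name"] if df.shape[1] >= 4 else [])
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return IntervalSet(df)


def write_intervals(ivs: IntervalSet, path) -> None:
    ivs.records.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SignalTrack:
    """bedGraph-style continuous signal; intervals non-overlapping per chromosome."""

    records: pd.DataFrame  # columns: chrom, start, end, value
    statistic_label: str = "generic"

    def __post_init__(self) -> None:
        df = self.records
        for col in ("chrom", "start", "end", "value"):
            if col not in df.columns:
                raise ValidationError(f"signal track missing column {col!r}")
        if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
            raise ValidationError("signal values must be finite")
        if (df["start"].to_numpy() < 0).any():
            raise ValidationError("negative track coordinates")
        if (df["start"].to_numpy() >= df["end"].to_numpy()).any():
            raise ValidationError("track intervals require start < end")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        # overlap check within chromosomes
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValidationError(f"overlapping track intervals on {chrom}")
        object.__setattr__(self, "records", df)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        out = {}
        for chrom, sub in self.records.groupby("chrom", sort=False):
            out[str(chrom)] = (sub["start"].to_numpy(dtype=np.int64),
                               sub["end"].to_numpy(dtype=np.int64),
                               sub["value"].to_numpy(dtype=float))
        return out


def read_signal_track(path, statistic_label: str = "generic") -> SignalTrack:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return SignalTrack(df, statistic_label=statistic_label)


def write_signal_track(track: SignalTrack, path) -> None:
    track.records.to_csv(path, sep="\t", header=False, index=False,
                         float_format="%.12g")


@dataclass
class ProbeCoordinates:
    """probe_id -> (chromosome, 0-based CpG position)."""

    table: pd.DataFrame  # index = probe_id, columns chrom, pos

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "pos"):
            if col not in t.columns:
                raise ValidationError(f"probe coordinates missing column {col!r}")
        if t.index.duplicated().any():
            raise ValidationError("duplicate probe ids in coordinates")
        if (t["pos"].to_numpy() < 0).any():
            raise ValidationError("negative probe positions")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


def read_probe_coordinates(path, delimiter: str = "\t",
                           one_based: bool = False) -> ProbeCoordinates:
    """Read probe coordinates (probe_id, chrom, pos).

    ``one_based=True`` converts 1-based manifest positions to the internal
    0-based convention at load time.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"probe_id": str})
    df = df.set_index("probe_id")
    df["pos"] = df["pos"].astype(np.int64)
    if one_based:
        df["pos"] -= 1
    return ProbeCoordinates(df[["chrom", "pos"]])


def write_probe_coordinates(coords: ProbeCoordinates, path,
                            delimiter: str = "\t") -> None:
    coords.table.to_csv(path, sep=delimiter, index_label="probe_id")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


DEFAULT_CONFIG: dict[str, float] = {
    "qc_threshold": 10.5,        # log2-intensity QC rule
    "alpha": 0.01,               # Bonferroni-corrected significance level
    "n_pcs": -1,                 # -1 = auto (scree elbow); 17 = 450K paper default
    "window_half_width": 200,    # bp around each CpG for continuous features
    "min_n": 5,                  # screen eligibility: samples per disorder
    "min_adults": 2,             # screen eligibility: samples with age >= adult_age
    "adult_age": 20.0,
}


def read_config(path) -> dict[str, float]:
    """Read a key=value config file; unknown keys pass through as floats/strings."""
    cfg = dict(DEFAULT_CONFIG)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"bad config line: {line!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            try:
                cfg[key] = float(val)
            except ValueError:
                cfg[key] = val
    return cfg
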