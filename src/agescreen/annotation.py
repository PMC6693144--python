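"""Genomic-context characterisation of probe subsets.

Continuous tracks (bedGraph) are summarised per probe as the per-base mean in
a +/- 200 bp window around the CpG coordinate (uncovered bases count as 0),
then Z-scored across probes; biological replicates are aggregated as the mean
of the Z-scores (NFC).  Strand-summed RNA signal is log2(1 + sur+ + sur-)
before Z-scoring (NRE).  Categorical features are half-open point-in-interval
overlaps; CpG-island context uses the shore (0-2 kb) / shelf (2-4 kb) distance
rule.  Enrichment of a probe subset against the rest of its universe is a
two-sided Fisher exact test on the 2x2 overlap table, Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bonferroni, rank_sum_test
from .core_io import IntervalSet, ProbeCoordinates, SignalTrack, ValidationError

logger = logging.getLogger("agescreen")

DEFAULT_HALF_WIDTH = 200  # bp; neighbouring-CpG methylation correlation scale


# ---------------------------------------------------------------------------
# Windowed continuous signals
# ---------------------------------------------------------------------------


def window_mean_signal(track: SignalTrack, coords: ProbeCoordinates,
                       half_width: int = DEFAULT_HALF_WIDTH,
                       chrom_sizes: dict[str, int] | None = None) -> pd.Series:
    """Per-base mean track value over [pos - half_width, pos + half_width].

    The window spans ``2*half_width + 1`` bases (inclusive of both ends),
    truncated at position 0 and at the chromosome size when provided.  Bases
    not covered by any track interval contribute 0.  Probes on chromosomes
    absent from the track get NaN (logged).
    """
    if half_width <= 0:
        raise ValidationError("half_width must be positive")
    per_chrom = track.by_chrom()
    out = np.full(len(coords.table), np.nan)
    missing_chroms: set[str] = set()
    chroms = coords.table["chrom"].to_numpy()
    positions = coords.table["pos"].to_numpy(dtype=np.int64)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        pos = positions[mask]
        if chrom not in per_chrom:
            missing_chroms.add(str(chrom))
            continue
        starts, ends, values = per_chrom[chrom]
        # cumulative integral of the piecewise-constant track
        lo = np.maximum(pos - half_width, 0)
        hi = pos + half_width + 1  # half-open upper bound
        if chrom_sizes and chrom in chrom_sizes:
            hi = np.minimum(hi, chrom_sizes[chrom])
        seg = values * (ends - starts)
        cum = np.concatenate([[0.0], np.cumsum(seg)])

        def integral(points: np.ndarray) -> np.ndarray:
            """Integral of the piecewise-constant track from 0 to each point."""
            idx = np.searchsorted(starts, points, side="right") - 1
            safe = np.maximum(idx, 0)
            inside = np.clip(points - starts[safe], 0, ends[safe] - starts[safe])
            return np.where(idx < 0, 0.0, cum[safe] + values[safe] * inside)

        total = integral(hi) - integral(lo)
        width = (hi - lo).astype(float)
        out[mask] = np.where(width > 0, total / width, np.nan)
    if missing_chroms:
        logger.info("window_mean_signal: chromosomes absent from track: %s",
                    sorted(missing_chroms))
    return pd.Series(out, index=coords.probe_ids, name=track.statistic_label)


def zscore(values) -> np.ndarray:
    """(x - mean) / sd with sample sd (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValidationError("zscore needs >= 2 values")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValidationError("zero standard deviation in zscore")
    return (x - x.mean()) / sd


def aggregate_replicates(z_matrices: Sequence[pd.Series]) -> pd.Series:
    """NFC: unweighted elementwise mean of per-replicate Z-scored signals."""
    if not z_matrices:
        raise ValidationError("no replicates to aggregate")
    df = pd.concat(list(z_matrices), axis=1)
    if df.isna().all(axis=1).any():
        logger.info("aggregate_replicates: %d probes missing in all replicates",
                    int(df.isna().all(axis=1).sum()))
    return df.mean(axis=1).rename("NFC")


def rna_signal(sur_plus: SignalTrack, sur_minus: SignalTrack,
               coords: ProbeCoordinates,
               half_width: int = DEFAULT_HALF_WIDTH) -> pd.Series:
    """NRE: Z-scored log2(1 + sur+ + sur-) of windowed strand signals."""
    for name, trk in (("sur+", sur_plus), ("sur-", sur_minus)):
        if (trk.records["value"].to_numpy() < 0).any():
            raise ValidationError(f"negative signal values in {name} track")
    plus = window_mean_signal(sur_plus, coords, half_width)
    minus = window_mean_signal(sur_minus, coords, half_width)
    rna = np.log2(1.0 + plus + minus)
    ok = rna.notna()
    out = pd.Series(np.nan, index=rna.index, name="NRE")
    out[ok] = zscore(rna[ok].to_numpy())
    return out


def rna_pre_scaling(sur_plus_mean: float, sur_minus_mean: float) -> float:
    """The unscaled RNA statistic log2(1 + sur+ + sur-) for one probe."""
    return float(np.log2(1.0 + sur_plus_mean + sur_minus_mean))


# ---------------------------------------------------------------------------
# Categorical context
# ---------------------------------------------------------------------------


def _merge_intervals(starts: np.ndarray, ends: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def overlap_categorical(coords: ProbeCoordinates,
                        intervals: IntervalSet) -> pd.Series:
    """True iff the probe position lies inside any interval ([start, end))."""
    per_chrom = {c: _merge_intervals(s, e)
                 for c, (s, e) in intervals.by_chrom().items()}
    chroms = coords.table["chrom"].to_numpy()
    positions = coords.table["pos"].to_numpy(dtype=np.int64)
    out = np.zeros(len(positions), dtype=bool)
    for chrom in pd.unique(chroms):
        if chrom not in per_chrom:
            continue
        mask = chroms == chrom
        starts, ends = per_chrom[chrom]
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        hit = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
        out[mask] = hit
    return pd.Series(out, index=coords.probe_ids, name="overlap")


SHORE_MAX = 2000
SHELF_MAX = 4000


def classify_cgi_context(coords: ProbeCoordinates, cgis: IntervalSet) -> pd.Series:
    """Island / shore (0-2 kb) / shelf (2-4 kb) / open-sea labels per probe.

    The distance d is to the nearest base contained in a CGI; a probe at
    exactly d = 2000 is a shore and d = 4000 a shelf (inclusive upper bounds).
    """
    per_chrom = {c: _merge_intervals(s, e) for c, (s, e) in cgis.by_chrom().items()}
    chroms = coords.table["chrom"].to_numpy()
    positions = coords.table["pos"].to_numpy(dtype=np.int64)
    labels = np.full(len(positions), "open-sea", dtype=object)
    for chrom in pd.unique(chroms):
        if chrom not in per_chrom:
            continue
        mask = chroms == chrom
        starts, ends = per_chrom[chrom]
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
        # distance to nearest CGI base: previous interval's last base or next start
        prev_end = np.where(idx >= 0, ends[np.maximum(idx, 0)], -10**15)
        d_prev = pos - (prev_end - 1)
        nxt = np.minimum(idx + 1, len(starts) - 1)
        d_next = np.where(idx + 1 < len(starts), starts[nxt] - pos, 10**15)
        d = np.minimum(np.where(d_prev > 0, d_prev, 10**15), d_next)
        lab = np.full(len(pos), "open-sea", dtype=object)
        lab[d <= SHELF_MAX] = "shelf"
        lab[d <= SHORE_MAX] = "shore"
        lab[inside] = "island"
        labels[mask] = lab
    return pd.Series(labels, index=coords.probe_ids, name="cgi_context")


# ---------------------------------------------------------------------------
# Enrichment and continuous comparisons
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """2x2 Fisher enrichment of a feature in a probe subset vs the rest."""

    feature: str
    subset_with: int
    subset_without: int
    control_with: int
    control_without: int
    odds_ratio: float
    p_raw: float
    p_adjusted: float
    significant: bool
    haldane: bool = False  # 0.5 added to all cells for the OR


def enrichment_test(subset: Iterable[str], universe: Iterable[str],
                    feature: pd.Series, alpha: float = 0.01,
                    n_tests: int = 1,
                    feature_name: str = "feature") -> EnrichmentResult:
    """Fisher exact enrichment of a boolean feature in subset vs universe-subset.

    The control set is the universe minus the subset (no double counting).
    OR is the sample odds ratio (a*d)/(b*c) with Haldane 0.5 added to every
    cell iff any cell is zero; the two-sided p sums hypergeometric point
    probabilities <= that of the observed table.
    """
    subset = set(subset)
    universe = set(universe)
    if not subset:
        raise ValidationError("empty probe subset")
    if not subset <= universe:
        raise ValidationError("subset must be contained in the universe")
    control = universe - subset
    if not control:
        raise ValidationError("empty control set (subset == universe)")
    feat = feature.astype(bool)
    a = int(feat.loc[list(subset)].sum())
    b = len(subset) - a
    c = int(feat.loc[list(control)].sum())
    d = len(control) - c
    haldane = 0 in (a, b, c, d)
    if haldane:
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    p_adj = float(min(1.0, p * n_tests))
    return EnrichmentResult(
        feature=feature_name, subset_with=a, subset_without=b,
        control_with=c, control_without=d, odds_ratio=float(oddsr),
        p_raw=float(p), p_adjusted=p_adj, significant=p_adj < alpha,
        haldane=haldane)


@dataclass
class ContinuousComparison:
    p_value: float
    median_subset: float
    median_control: float
    n_subset: int
    n_control: int
    all_tied: bool = False


def compare_continuous(subset_values, control_values) -> ContinuousComparison:
    """Two-sided rank-sum comparison of a continuous feature between a probe
    subset and its control set, with medians and group sizes."""
    x = np.asarray(subset_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return ContinuousComparison(p_value=1.0, median_subset=float(np.median(x)),
                                    median_control=float(np.median(y)),
                                    n_subset=len(x), n_control=len(y), all_tied=True)
    p = rank_sum_test(x, y)
    return ContinuousComparison(p_value=p, median_subset=float(np.median(x)),
                                median_control=float(np.median(y)),
                                n_subset=len(x), n_control=len(y))
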