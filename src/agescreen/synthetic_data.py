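"""Synthetic 450K-style blood methylation cohorts with known ground truth.

The generator emulates the statistical structure the EAA screen assumes:

* clock probes whose betas follow saturating linear trajectories of the
  transformed age, built so the bundled clock definition inverts them exactly
  back to age (plus the injected acceleration and residual noise);
* per-batch technical offsets, visible both in the clock-probe betas (as a
  coherent per-batch epigenetic-age shift) and in the control-probe
  intensities (as per-batch mean vectors), so batch is recoverable from the
  top control-probe PCs;
* cell-composition-sensitive probes that are convex mixtures of a bundled
  reference, with age-drifting Dirichlet proportions;
* age DMPs drifting linearly in age (hyper and hypo), disease DMPs shifted in
  cases of one disorder only, and null probes;
* a toy genome (one synthetic chromosome) with enhancer / gene-body / CGI
  interval annotations and bedGraph signal tracks designed so hypomethylated
  disease DMPs are enriched in enhancers and depleted of signal.

Acceleration is injected on the transformed-age scale (delta /
(adult_age + 1)), which equals a shift of exactly ``delta`` years for samples
older than ``adult_age``; the default case age range is adult-only so
"median EAA = delta" holds exactly in expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clocks import ClockDefinition, transform_age, write_clock_definition
from .core_io import (
    BetaMatrix,
    ControlProbeMatrix,
    IntensityPair,
    IntervalSet,
    ProbeCoordinates,
    SampleSheet,
    SignalTrack,
    ValidationError,
    write_beta_matrix,
    write_control_probes,
    write_intervals,
    write_probe_coordinates,
    write_sample_sheet,
    write_signal_track,
)
from .deconvolution import CellComposition, CellTypeReference, write_cell_reference

logger = logging.getLogger("agescreen")

DEFAULT_CELL_TYPES = ("Gran", "CD4T", "CD8T", "B", "Mono", "NK")
DEFAULT_CELL_BASE = (0.55, 0.15, 0.10, 0.08, 0.07, 0.05)
# per-year linear drift of blood cell proportions (sums to zero)
DEFAULT_CELL_DRIFT = (0.002, -0.0008, -0.0005, -0.0003, -0.0002, -0.0002)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror a desk-scale version of a blood 450K meta-cohort: ages
    0-55 years, several batches with visible technical structure, one
    accelerated disorder and one neutral disorder of 20 cases each, clock
    residual sd of 2 years on the adult scale.
    """

    n_controls: int = 300
    cases: Mapping[str, int] = field(
        default_factory=lambda: {"accelerated": 20, "neutral": 20})
    accelerations: Mapping[str, float] = field(
        default_factory=lambda: {"accelerated": 7.5, "neutral": 0.0})
    age_range: tuple[float, float] = (0.0, 55.0)
    case_age_range: tuple[float, float] = (20.0, 55.0)

    n_batches: int = 4
    batch_effect_years: float = 4.0     # sd of per-batch DNAmAge shift (adult scale)
    batch_offset_beta: float = 0.01     # sd of per-(batch, probe) beta offsets
    batch_intensity_scale: float = 300.0
    intensity_noise: float = 50.0
    n_control_features: int = 200

    n_probes: int = 2000                # total probes; null probes fill the rest
    n_clock_probes: int = 30
    adult_age: float = 20.0
    residual_sd: float = 2.0            # years, on the adult scale

    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    cell_base: Sequence[float] = DEFAULT_CELL_BASE
    cell_drift: Sequence[float] = DEFAULT_CELL_DRIFT
    dirichlet_concentration: float = 400.0
    n_cell_probes: int = 60
    cell_noise_sd: float = 0.01

    n_admp_hyper: int = 150
    n_admp_hypo: int = 150
    admp_slope: float = 0.003           # beta units per year

    n_disease_hypo: int = 100
    n_disease_hyper: int = 20
    disease_effect: float = 0.1         # beta units
    disease_label: str = "accelerated"

    beta_noise_sd: float = 0.02

    enhancer_odds: float = 6.0          # designed OR of hypo disease DMPs in enhancers
    enhancer_base_rate: float = 0.1
    gene_body_rate: float = 0.25
    cgi_rate: float = 0.15
    probe_spacing: int = 1000
    chrom: str = "chrS"

    intensity_log2_mean: float = 11.5   # QC statistic ~ 11.5 >= 10.5 by default
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_controls, self.n_batches, self.n_probes,
                  self.n_clock_probes, self.n_cell_probes, self.n_admp_hyper,
                  self.n_admp_hypo, self.n_disease_hypo, self.n_disease_hyper,
                  *self.cases.values()]
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be >= 0")
        if self.n_null_probes < 0:
            raise ValidationError(
                "infeasible config: designed probes exceed n_probes "
                f"({self.n_probes - self.n_null_probes} > {self.n_probes})")
        if self.age_range[0] >= self.age_range[1]:
            raise ValidationError("age range must be increasing")
        if len(self.cell_types) < 2:
            raise ValidationError("need >= 2 cell types")
        for d in self.cases:
            if d == "control":
                raise ValidationError("'control' is reserved for healthy samples")

    @property
    def n_null_probes(self) -> int:
        designed = (self.n_clock_probes + self.n_cell_probes + self.n_admp_hyper
                    + self.n_admp_hypo + self.n_disease_hypo + self.n_disease_hyper)
        return self.n_probes - designed


@dataclass
class GroundTruth:
    """Generating parameters recorded for recovery tests."""

    probe_roles: pd.DataFrame          # role, true_slope, true_effect, in_enhancer
    cell_proportions: pd.DataFrame     # samples x cell types (true mixtures)
    accelerations: dict[str, float]    # disorder -> injected years
    batch_shift_years: pd.Series       # batch label -> DNAmAge shift (adult scale)
    batch_assignment: pd.Series        # sample -> batch label
    clock: ClockDefinition = None


@dataclass
class SimulatedCohort:
    """Full bundle produced by :func:`generate_cohort`."""

    betas: BetaMatrix
    sheet: SampleSheet
    control_probes: ControlProbeMatrix
    intensities: IntensityPair
    coordinates: ProbeCoordinates
    intervals: dict[str, IntervalSet]
    tracks: dict[str, SignalTrack]
    cell_reference: CellTypeReference
    clock: ClockDefinition
    truth: GroundTruth


def _squash(x: np.ndarray, lo: float = 0.001, hi: float = 0.999) -> np.ndarray:
    """Saturating squash into (0,1): identity inside [lo, hi], clipped outside."""
    return np.clip(x, lo, hi)


def generate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate a deterministic synthetic cohort from the study conditions."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    adult1 = cfg.adult_age + 1.0

    # ----- samples ---------------------------------------------------------
    groups = ["control"] * cfg.n_controls
    for disorder, n in sorted(cfg.cases.items()):
        groups += [disorder] * n
    n_samples = len(groups)
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    is_control = np.array([g == "control" for g in groups])
    ages = np.where(
        is_control,
        rng.uniform(*cfg.age_range, size=n_samples),
        rng.uniform(*cfg.case_age_range, size=n_samples),
    )
    sexes = rng.choice(["female", "male"], size=n_samples)
    batch_idx = rng.integers(0, cfg.n_batches, size=n_samples)
    batch_labels = np.array([f"batch_{b + 1}" for b in batch_idx])
    sheet = SampleSheet(pd.DataFrame({
        "age": ages, "sex": sexes, "batch": batch_labels, "group": groups,
    }, index=pd.Index(sample_ids, name="sample_id")))

    # ----- cell proportions ------------------------------------------------
    k = len(cfg.cell_types)
    base = np.asarray(cfg.cell_base, dtype=float)[:k]
    drift = np.asarray(cfg.cell_drift, dtype=float)[:k]
    target = base[None, :] + drift[None, :] * (ages[:, None] - 30.0)
    target = np.clip(target, 0.01, None)
    target /= target.sum(axis=1, keepdims=True)
    proportions = np.vstack([
        rng.dirichlet(cfg.dirichlet_concentration * t) for t in target])
    props = pd.DataFrame(proportions, index=sample_ids, columns=list(cfg.cell_types))

    # ----- probe layout ----------------------------------------------------
    roles: list[str] = (
        ["clock"] * cfg.n_clock_probes
        + ["cell"] * cfg.n_cell_probes
        + ["aDMP-hyper"] * cfg.n_admp_hyper
        + ["aDMP-hypo"] * cfg.n_admp_hypo
        + ["disease-hypo"] * cfg.n_disease_hypo
        + ["disease-hyper"] * cfg.n_disease_hyper
        + ["null"] * cfg.n_null_probes
    )
    n_probes = len(roles)
    probe_ids = [f"cg{i:06d}" for i in range(n_probes)]
    role_arr = np.array(roles)

    # ----- batch effects ---------------------------------------------------
    # standard variates are drawn unconditionally and then scaled, so cohorts
    # that differ only in effect sizes share every other random realisation
    # (paired counterfactuals for before/after comparisons)
    batch_names = [f"batch_{b + 1}" for b in range(cfg.n_batches)]
    shifts = rng.standard_normal(cfg.n_batches)
    if cfg.n_batches > 1 and cfg.batch_effect_years > 0:
        # centre and standardise the realised shifts so the injected between-
        # batch spread equals the configured scale exactly in every cohort
        shifts -= shifts.mean()
        shifts *= cfg.batch_effect_years / shifts.std()
    else:
        shifts = np.zeros(cfg.n_batches)
    batch_shift_years = pd.Series(shifts, index=batch_names)
    sample_batch_shift = shifts[batch_idx]
    # incoherent per-(batch, probe) beta offsets for non-clock probes
    probe_batch_offsets = (rng.standard_normal((cfg.n_batches, n_probes))
                           * cfg.batch_offset_beta)
    if cfg.n_batches <= 1:
        probe_batch_offsets[:] = 0.0

    betas = np.empty((n_probes, n_samples))

    # ----- clock probes ----------------------------------------------------
    delta = np.array([cfg.accelerations.get(g, 0.0) for g in groups])
    eps_years = rng.standard_normal(n_samples) * cfg.residual_sd
    T = (transform_age(ages, cfg.adult_age)
         + (delta + eps_years + sample_batch_shift) / adult1)
    t_lo = transform_age(cfg.age_range[0], cfg.adult_age)
    t_hi = transform_age(cfg.age_range[1], cfg.adult_age)
    t_mid = 0.5 * (t_lo + t_hi)
    n_clock = cfg.n_clock_probes
    clock_sign = np.where(rng.random(n_clock) < 0.5, -1.0, 1.0)
    clock_slope = clock_sign * rng.uniform(0.05, 0.09, size=n_clock)
    clock_anchor = rng.uniform(0.45, 0.55, size=n_clock) - clock_slope * t_mid
    clock_rows = np.flatnonzero(role_arr == "clock")
    betas[clock_rows] = _squash(clock_anchor[:, None] + clock_slope[:, None] * T)
    weights = 1.0 / (n_clock * clock_slope)
    intercept = float(-(weights * clock_anchor).sum())
    clock = ClockDefinition(
        name="synthetic-clock", intercept=intercept,
        coefficients=pd.Series(weights, index=[probe_ids[i] for i in clock_rows]),
        transform="log-linear", adult_age=cfg.adult_age)

    # ----- cell-sensitive probes -------------------------------------------
    cell_rows = np.flatnonzero(role_arr == "cell")
    ref = np.empty((cfg.n_cell_probes, k))
    for j, row in enumerate(cell_rows):
        marked = j % k  # each probe marks one cell type
        ref[j] = rng.uniform(0.05, 0.30, size=k)
        ref[j, marked] = rng.uniform(0.70, 0.95)
    bulk = ref @ proportions.T
    noise = rng.normal(0.0, cfg.cell_noise_sd, size=bulk.shape)
    betas[cell_rows] = np.clip(bulk + noise, 0.0, 1.0)
    reference = CellTypeReference(pd.DataFrame(
        ref, index=[probe_ids[i] for i in cell_rows], columns=list(cfg.cell_types)))

    # ----- aDMP / disease / null probes ------------------------------------
    is_case_disease = np.array([g == cfg.disease_label for g in groups], dtype=float)

    def fill(rows: np.ndarray, base_lo: float, base_hi: float,
             slope: float = 0.0, effect: float = 0.0) -> np.ndarray:
        b0 = rng.uniform(base_lo, base_hi, size=len(rows))
        sig = (b0[:, None] + slope * ages[None, :]
               + effect * is_case_disease[None, :]
               + probe_batch_offsets[batch_idx, :][:, rows].T
               + rng.normal(0.0, cfg.beta_noise_sd, size=(len(rows), n_samples)))
        betas[rows] = np.clip(sig, 0.0, 1.0)
        return b0

    fill(np.flatnonzero(role_arr == "aDMP-hyper"), 0.15, 0.50, slope=cfg.admp_slope)
    fill(np.flatnonzero(role_arr == "aDMP-hypo"), 0.50, 0.85, slope=-cfg.admp_slope)
    fill(np.flatnonzero(role_arr == "disease-hypo"), 0.40, 0.80,
         effect=-cfg.disease_effect)
    fill(np.flatnonzero(role_arr == "disease-hyper"), 0.20, 0.60,
         effect=cfg.disease_effect)
    fill(np.flatnonzero(role_arr == "null"), 0.05, 0.95)

    beta_matrix = BetaMatrix(pd.DataFrame(
        betas, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids))

    # ----- control-probe intensities ---------------------------------------
    feat_mean = rng.normal(3000.0, 200.0, size=cfg.n_control_features)
    feat_batch = (rng.standard_normal((cfg.n_batches, cfg.n_control_features))
                  * cfg.batch_intensity_scale)
    if cfg.n_batches <= 1:
        feat_batch[:] = 0.0
    cp = (feat_mean[None, :] + feat_batch[batch_idx, :]
          + rng.normal(0.0, cfg.intensity_noise,
                       size=(n_samples, cfg.n_control_features)))
    control_probes = ControlProbeMatrix(pd.DataFrame(
        cp, index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"ctrl_{i:04d}" for i in range(cfg.n_control_features)]))

    # ----- raw M/U intensities for the QC filter ---------------------------
    log2m = rng.normal(cfg.intensity_log2_mean, 0.4, size=(n_probes, n_samples))
    log2u = rng.normal(cfg.intensity_log2_mean, 0.4, size=(n_probes, n_samples))
    intensities = IntensityPair(
        methylated=pd.DataFrame(2.0 ** log2m, index=probe_ids, columns=sample_ids),
        unmethylated=pd.DataFrame(2.0 ** log2u, index=probe_ids, columns=sample_ids))

    # ----- toy genome: coordinates, intervals, tracks ----------------------
    positions = 500 + np.arange(n_probes, dtype=np.int64) * cfg.probe_spacing
    coords = ProbeCoordinates(pd.DataFrame(
        {"chrom": cfg.chrom, "pos": positions},
        index=pd.Index(probe_ids, name="probe_id")))

    # enhancer membership with designed odds for hypomethylated disease DMPs
    b = cfg.enhancer_base_rate
    odds_in = cfg.enhancer_odds * b / (1.0 - b)
    rate_in = odds_in / (1.0 + odds_in)
    p_enh = np.where(role_arr == "disease-hypo", rate_in, b)
    in_enhancer = rng.random(n_probes) < p_enh
    half_block = min(100, cfg.probe_spacing // 2 - 1)

    def blocks(mask: np.ndarray, half: int, name: str) -> IntervalSet:
        pos = positions[mask]
        return IntervalSet(pd.DataFrame({
            "chrom": cfg.chrom,
            "start": np.maximum(pos - half, 0),
            "end": pos + half + 1,
            "name": name,
        }))

    in_gene_body = rng.random(n_probes) < cfg.gene_body_rate
    in_cgi = rng.random(n_probes) < cfg.cgi_rate
    intervals = {
        "enhancer": blocks(in_enhancer, half_block, "enhancer"),
        "gene_body": blocks(in_gene_body, half_block, "gene_body"),
        "cgi": blocks(in_cgi, half_block, "CGI"),
    }

    # signal tracks: tile per probe window; designed depletion around hypo DMPs
    tile_half = min(cfg.probe_spacing // 2 - 1, 400)
    hypo_like = np.isin(role_arr, ["disease-hypo", "aDMP-hypo"])
    base_fc = rng.uniform(1.0, 3.0, size=n_probes)
    base_fc[hypo_like] = rng.uniform(0.1, 0.8, size=int(hypo_like.sum()))

    def tiled_track(values: np.ndarray, label: str) -> SignalTrack:
        return SignalTrack(pd.DataFrame({
            "chrom": cfg.chrom,
            "start": np.maximum(positions - tile_half, 0),
            "end": positions + tile_half + 1,
            "value": values,
        }), statistic_label=label)

    rna_base = rng.gamma(2.0, 2.0, size=n_probes)
    rna_base[hypo_like] *= 0.25
    tracks = {
        "h3k36me3_rep1": tiled_track(
            np.clip(base_fc + rng.normal(0, 0.1, n_probes), 0, None), "fold-change"),
        "h3k36me3_rep2": tiled_track(
            np.clip(base_fc + rng.normal(0, 0.1, n_probes), 0, None), "fold-change"),
        "rna_sur_plus": tiled_track(
            rna_base * rng.uniform(0.4, 0.6, n_probes), "sur+"),
        "rna_sur_minus": tiled_track(
            rna_base * rng.uniform(0.4, 0.6, n_probes), "sur-"),
    }

    # ----- ground truth -----------------------------------------------------
    true_slope = np.zeros(n_probes)
    true_slope[role_arr == "aDMP-hyper"] = cfg.admp_slope
    true_slope[role_arr == "aDMP-hypo"] = -cfg.admp_slope
    true_effect = np.zeros(n_probes)
    true_effect[role_arr == "disease-hypo"] = -cfg.disease_effect
    true_effect[role_arr == "disease-hyper"] = cfg.disease_effect
    truth = GroundTruth(
        probe_roles=pd.DataFrame({
            "role": role_arr, "true_slope": true_slope,
            "true_effect": true_effect, "in_enhancer": in_enhancer,
        }, index=pd.Index(probe_ids, name="probe_id")),
        cell_proportions=props,
        accelerations=dict(cfg.accelerations),
        batch_shift_years=batch_shift_years,
        batch_assignment=pd.Series(batch_labels, index=sample_ids, name="batch"),
        clock=clock,
    )

    return SimulatedCohort(
        betas=beta_matrix, sheet=sheet, control_probes=control_probes,
        intensities=intensities, coordinates=coords, intervals=intervals,
        tracks=tracks, cell_reference=reference, clock=clock, truth=truth)


def generate_deconvolution_benchmark(
        n_samples: int = 50,
        n_cell_types: int = 6,
        n_probes: int = 60,
        noise_sd: float = 0.0,
        seed: int = 0,
        cell_types: Sequence[str] | None = None,
        weights: np.ndarray | None = None,
) -> tuple[BetaMatrix, CellTypeReference, CellComposition]:
    """Mixtures of known composition for benchmarking deconvolution.

    Mixtures are exact (noise_sd=0) or noisy convex combinations of reference
    profiles; the true Dirichlet weights are returned as a CellComposition.
    """
    if n_cell_types < 2:
        raise ValidationError("need >= 2 cell types")
    rng = np.random.default_rng(seed)
    names = list(cell_types) if cell_types else \
        list(DEFAULT_CELL_TYPES[:n_cell_types]) + \
        [f"ct{i}" for i in range(len(DEFAULT_CELL_TYPES), n_cell_types)]
    ref = np.empty((n_probes, n_cell_types))
    for j in range(n_probes):
        marked = j % n_cell_types
        ref[j] = rng.uniform(0.05, 0.30, size=n_cell_types)
        ref[j, marked] = rng.uniform(0.70, 0.95)
    probe_ids = [f"cg{i:06d}" for i in range(n_probes)]
    reference = CellTypeReference(pd.DataFrame(ref, index=probe_ids, columns=names))
    if reference.is_collinear():
        logger.warning("deconvolution benchmark: collinear reference profiles")
    if weights is None:
        weights = rng.dirichlet(np.full(n_cell_types, 5.0), size=n_samples)
    else:
        weights = np.atleast_2d(np.asarray(weights, dtype=float))
        n_samples = weights.shape[0]
    sample_ids = [f"MIX{i:04d}" for i in range(n_samples)]
    mix = ref @ weights.T
    if noise_sd > 0:
        mix = np.clip(mix + rng.normal(0.0, noise_sd, size=mix.shape), 0.0, 1.0)
    betas = BetaMatrix(pd.DataFrame(mix, index=probe_ids, columns=sample_ids))
    truth = CellComposition(
        proportions=pd.DataFrame(weights, index=sample_ids, columns=names),
        constraint="sum-to-one")
    return betas, reference, truth


def write_bundle(cohort: SimulatedCohort, out_dir) -> None:
    """Write the full simulated bundle in the pipeline's text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(cohort.betas, out / "betas.tsv")
    write_sample_sheet(cohort.sheet, out / "sample_sheet.tsv")
    write_control_probes(cohort.control_probes, out / "control_probes.tsv")
    cohort.intensities.methylated.to_csv(out / "intensity_methylated.tsv",
                                         sep="\t", index_label="probe_id")
    cohort.intensities.unmethylated.to_csv(out / "intensity_unmethylated.tsv",
                                           sep="\t", index_label="probe_id")
    write_probe_coordinates(cohort.coordinates, out / "probe_coordinates.tsv")
    for name, ivs in cohort.intervals.items():
        write_intervals(ivs, out / f"{name}.bed")
    for name, track in cohort.tracks.items():
        write_signal_track(track, out / f"{name}.bedgraph")
    write_cell_reference(cohort.cell_reference, out / "cell_reference.tsv")
    write_clock_definition(cohort.clock, out / "clock.csv")
    truth = cohort.truth
    truth.probe_roles.to_csv(out / "ground_truth_probes.tsv", sep="\t")
    truth.cell_proportions.to_csv(out / "ground_truth_proportions.tsv", sep="\t",
                                  index_label="sample_id")
    pd.DataFrame({"batch": truth.batch_shift_years.index,
                  "shift_years": truth.batch_shift_years.to_numpy()}
                 ).to_csv(out / "ground_truth_batches.tsv", sep="\t", index=False)
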