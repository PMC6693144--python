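"""Shannon methylation entropy and its acceleration models.

Per sample over N usable probes:

    Entropy = 1 / (N * log2(1/2)) * sum_i [ b_i*log2(b_i) + (1-b_i)*log2(1-b_i) ]

which is 1 when every beta is 0.5 and 0 when every beta sits at 0 or 1 (the
0*log0 = 0 convention is applied exactly).  Entropy/mitotic-score
acceleration reuses the control-model machinery with the response swapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .batch_eaa import ControlAgeModel, EAAResult
from .core_io import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger("agescreen")


@dataclass
class EntropyResult:
    """Per-sample methylation entropy in [0, 1] and the probe count used."""

    entropy: pd.Series
    n_probes: pd.Series          # usable (non-missing) probes per sample
    probe_set: str = "genome-wide"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"entropy": self.entropy, "n_probes": self.n_probes})


def _binary_entropy_terms(b: np.ndarray) -> np.ndarray:
    """b*log2(b) + (1-b)*log2(1-b) with exact 0 at b in {0,1}."""
    out = np.zeros_like(b)
    interior = (b > 0) & (b < 1)
    bi = b[interior]
    out[interior] = bi * np.log2(bi) + (1 - bi) * np.log2(1 - bi)
    return out


def shannon_entropy(betas: BetaMatrix, probe_subset: Iterable[str] | None = None,
                    probe_set_label: str | None = None,
                    clip: float | None = None) -> EntropyResult:
    """Normalised Shannon entropy per sample.

    ``probe_subset`` restricts to e.g. the clock CpGs; missing betas are
    excluded pairwise and N reduced accordingly.  ``clip`` optionally clips
    betas into [clip, 1-clip] before the computation for noisy inputs
    (default: exact convention, no clipping).
    """
    if probe_subset is not None:
        subset = [p for p in probe_subset if p in betas.probe_ids]
        if not subset:
            raise ValidationError("empty probe subset for entropy")
        values = betas.values.loc[subset]
        label = probe_set_label or "custom"
    else:
        values = betas.values
        label = probe_set_label or "genome-wide"
    arr = values.to_numpy(dtype=float)
    if arr.shape[0] == 0:
        raise ValidationError("no probes available for entropy")
    if clip is not None:
        arr = np.clip(arr, clip, 1 - clip)
    usable = ~np.isnan(arr)
    n = usable.sum(axis=0)
    if (n == 0).any():
        raise ValidationError("sample with no usable probes for entropy")
    terms = np.where(usable, _binary_entropy_terms(np.nan_to_num(arr, nan=0.5)), 0.0)
    # log2(1/2) = -1, so the normaliser is -N
    ent = terms.sum(axis=0) / (n * np.log2(0.5))
    n_missing = int((~usable).sum())
    if n_missing:
        logger.info("shannon_entropy: %d missing betas excluded", n_missing)
    samples = betas.sample_ids
    return EntropyResult(entropy=pd.Series(ent, index=samples, name="entropy"),
                         n_probes=pd.Series(n, index=samples, name="n_probes"),
                         probe_set=label)


def fit_acceleration(response: pd.Series, sheet: SampleSheet,
                     pcs: pd.DataFrame | None = None,
                     composition: pd.DataFrame | None = None,
                     response_name: str = "Entropy") -> EAAResult:
    """Acceleration model: response ~ Age + Sex + cell proportions + PCs,
    fitted on controls; cases get observed - predicted.

    The batch composition of the inputs is logged because entropy is highly
    sensitive to batch effects.
    """
    batches = sheet.table["batch"].value_counts().to_dict()
    logger.info("fit_acceleration(%s): batch distribution %s", response_name, batches)
    model = ControlAgeModel(sheet, response, pcs=pcs, composition=composition,
                            response_name=response_name)
    return model.fit().compute_eaa()


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


def entropy_age_correlation(entropy: EntropyResult, sheet: SampleSheet,
                            sample_ids: Iterable[str] | None = None,
                            ) -> CorrelationResult:
    """Spearman correlation (average-rank ties) of entropy with age."""
    ids = pd.Index(list(sample_ids)) if sample_ids is not None else sheet.sample_ids
    ids = ids[ids.isin(entropy.entropy.index)]
    if len(ids) < 3:
        raise ValidationError("entropy_age_correlation needs >= 3 samples")
    e = entropy.entropy.loc[ids].to_numpy()
    a = sheet.ages.loc[ids].to_numpy()
    if np.ptp(e) == 0 or np.ptp(a) == 0:
        return CorrelationResult(rho=float("nan"), p_value=float("nan"),
                                 n=len(ids), degenerate=True)
    rho, p = stats.spearmanr(a, e)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(ids))
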