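"""End-to-end convenience wrapper: cohort in, screen out.

Chains clock evaluation, control-probe PCA, optional cell deconvolution, the
control model, EAA and the disorder screen.  The CLI and higher-level scripts
call this; every step is also available individually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .batch_eaa import (
    ControlAgeResults,
    EAAResult,
    ScreenResult,
    TechnicalPCs,
    choose_n_pcs,
    filter_disorders,
    fit_control_model,
    fit_control_pca,
    screen_disorders,
)
from .clocks import ClockDefinition, ClockResult, evaluate_clock
from .core_io import BetaMatrix, ControlProbeMatrix, SampleSheet
from .deconvolution import CellTypeReference, estimate_cell_composition

logger = logging.getLogger("agescreen")


@dataclass
class EAAPipelineResult:
    clock_result: ClockResult
    pcs: TechnicalPCs
    n_pcs: int
    control_model: ControlAgeResults
    eaa: EAAResult
    screen: ScreenResult | None = None


def run_eaa_pipeline(betas: BetaMatrix, sheet: SampleSheet,
                     clock: ClockDefinition,
                     control_probes: ControlProbeMatrix | None = None,
                     reference: CellTypeReference | None = None,
                     with_ccc: bool = False,
                     n_pcs: int | str = "auto",
                     alpha: float = 0.01,
                     min_n: int = 5, min_adults: int = 2,
                     adult_age: float = 20.0,
                     run_screen: bool = True) -> EAAPipelineResult:
    """Evaluate the clock, correct for batch and cell composition, compute EAA
    and (optionally) screen every eligible disorder against the controls.

    ``n_pcs`` is "auto" (scree elbow), "paper-default" (17, the published 450K
    optimum) or an explicit integer; 0 disables technical PCs.
    """
    clock_result = evaluate_clock(betas, clock)

    pcs_obj = None
    pc_scores = None
    k = 0
    if control_probes is not None:
        pcs_obj = fit_control_pca(control_probes)
        if n_pcs == "auto":
            k = choose_n_pcs(pcs_obj.variance_fractions)
        elif n_pcs == "paper-default":
            from .batch_eaa import PAPER_DEFAULT_N_PCS
            k = PAPER_DEFAULT_N_PCS
        else:
            k = int(n_pcs)
        if k > 0:
            pc_scores = pcs_obj.top(k)
        logger.info("pipeline: using %d technical PCs", k)

    composition = None
    if with_ccc:
        if reference is None:
            raise ValueError("with_ccc=True requires a cell-type reference")
        composition = estimate_cell_composition(betas, reference).proportions

    model = fit_control_model(sheet, clock_result.dnam_age, pcs=pc_scores,
                              composition=composition, with_ccc=with_ccc)
    eaa = model.compute_eaa(sheet, clock_result.dnam_age)

    screen = None
    if run_screen:
        eligible = filter_disorders(sheet, min_n=min_n, min_adults=min_adults,
                                    adult_age=adult_age)
        if eligible:
            screen = screen_disorders(eaa, sheet, disorders=eligible, alpha=alpha)
    return EAAPipelineResult(clock_result=clock_result, pcs=pcs_obj, n_pcs=k,
                             control_model=model, eaa=eaa, screen=screen)
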