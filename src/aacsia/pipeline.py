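"""End-to-end orchestration: raw sequence runs → corrected samples → inference.

These helpers chain the per-module operations in the order the acquisition
protocol implies, so callers (CLI, simulation studies, tests) don't repeat
the plumbing.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .corrections import (
    CalibrationModel,
    DerivatizationModel,
    aggregate_replicates,
    apply_nitrogen_calibration,
    average_standard_brackets,
    calibrate_derivatization,
    correct_carbon,
    fit_nitrogen_calibration,
)
from .errors import IntegrityError
from .registry import AminoAcid, aa_registry, registry_index
from .trophic import TrophicParams, TrophicPositionResult, compute_tp, tp_group_summary
from .types import CorrectedSample, Injection, SampleMeta, SequenceRun


def _group_by_sample(run: SequenceRun, injections: list[Injection]):
    order: list[str] = []
    groups: dict[str, list[Injection]] = {}
    for inj in injections:
        if inj.role != "sample":
            continue
        groups.setdefault(inj.sample_id, []).append(inj)
        if inj.sample_id not in order:
            order.append(inj.sample_id)
    for sample_id in order:
        meta = run.sample_meta.get(sample_id)
        if meta is None:
            raise IntegrityError(f"no metadata for sample {sample_id}")
        yield meta, groups[sample_id]


def correct_nitrogen_run(
    run: SequenceRun, *, per_aa: bool = False
) -> tuple[list[CorrectedSample], CalibrationModel | dict[str, CalibrationModel]]:
    """Bracket-average, fit the δ15N calibration, apply it, aggregate replicates."""
    bracket = average_standard_brackets(run)
    model = fit_nitrogen_calibration(bracket, run.standard_ref, per_aa=per_aa)
    corrected_inj = apply_nitrogen_calibration(run, model)
    samples = [
        aggregate_replicates(group, meta)
        for meta, group in _group_by_sample(run, corrected_inj)
    ]
    return samples, model


def correct_carbon_run(
    run: SequenceRun, registry: Iterable[AminoAcid] | None = None
) -> tuple[list[CorrectedSample], DerivatizationModel]:
    """Calibrate the reagent-carbon signature, invert the mole balance, aggregate."""
    registry = list(registry) if registry is not None else aa_registry()
    index = registry_index(registry)
    bracket = average_standard_brackets(run)
    model = calibrate_derivatization(bracket, run.standard_ref, registry)
    corrected_inj = []
    for inj in run.injections:
        values = {
            code: correct_carbon(value, index[code], model)
            for code, value in inj.measured.items()
        }
        corrected_inj.append(
            Injection(
                sequence_index=inj.sequence_index,
                role=inj.role,
                sample_id=inj.sample_id,
                element=inj.element,
                replicate_index=inj.replicate_index,
                measured=values,
            )
        )
    samples = [
        aggregate_replicates(group, meta)
        for meta, group in _group_by_sample(run, corrected_inj)
    ]
    return samples, model


def correct_study(
    run_n: SequenceRun,
    run_c: SequenceRun,
    registry: Iterable[AminoAcid] | None = None,
) -> tuple[list[CorrectedSample], list[CorrectedSample]]:
    """Correct both elements of a study; returns (nitrogen, carbon) samples."""
    samples_n, _ = correct_nitrogen_run(run_n)
    samples_c, _ = correct_carbon_run(run_c, registry)
    return samples_n, samples_c


def tp_results(
    corrected_n: list[CorrectedSample], params: TrophicParams | None = None
) -> list[TrophicPositionResult]:
    return [compute_tp(sample, params) for sample in corrected_n]


def group_tp_table(
    corrected_n: list[CorrectedSample], params: TrophicParams | None = None
) -> pd.DataFrame:
    """Per-(group, fraction) TP summary: per-colony TP first, then averaged."""
    return tp_group_summary(tp_results(corrected_n, params))
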