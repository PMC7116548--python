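"""Drift calibration, derivatization carbon correction, replicate aggregation.

The correction chain for one instrument sequence:

1. ``average_standard_brackets`` — average the standard-mixture injections of
   the opening and closing brackets. Amino acids combust with different
   efficiencies, so drift is summarized per amino acid by this bracket mean
   rather than interpolated over injection index.
2. Nitrogen: ``fit_nitrogen_calibration`` regresses certified δ15N on the
   bracket-mean measured δ15N, pooled over the seven standard amino acids, and
   ``apply_nitrogen_calibration`` maps every injection through the fitted
   affine model. No derivatization correction is needed for nitrogen — the
   reagents add carbon only.
3. Carbon: ``calibrate_derivatization`` solves the carbon mole balance

       ncd · δ13C_cd = nc · δ13C_c + nd · δ13C_dcorr

   for the reagent-carbon signature δ13C_dcorr per amino acid (certified
   δ13C_c, bracket-mean measured δ13C_cd), and ``correct_carbon`` inverts the
   same balance for sample peaks. Because δ13C_dcorr is re-derived from the
   standards of each sequence, any additive per-amino-acid drift cancels
   exactly in the corrected value.
4. ``aggregate_replicates`` reduces replicate injections (duplicate carbon,
   triplicate nitrogen) to a per-sample mean and n−1 standard deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .errors import (
    CalibrationError,
    ConfigurationError,
    CorrectionError,
    IntegrityError,
    ValidationError,
)
from .registry import AminoAcid, registry_index
from .types import (
    ROLE_STANDARD,
    CorrectedSample,
    Injection,
    SampleMeta,
    SequenceRun,
    StandardReference,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationModel:
    """Affine δ15N calibration: corrected = slope · measured + intercept."""

    element: str
    scope: str  # "pooled" or an amino-acid code
    slope: float
    intercept: float
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_points < 2 and self.scope == "pooled":
            raise ValidationError("pooled calibration needs >= 2 points")
        if not math.isfinite(self.slope) or self.slope == 0:
            raise ValidationError("calibration slope must be finite and non-zero")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValidationError("r_squared must lie in [0, 1]")

    def apply(self, measured: float) -> float:
        return self.slope * measured + self.intercept


@dataclass(frozen=True)
class DerivatizationModel:
    """Per-amino-acid reagent-carbon signature δ13C_dcorr and the counts used."""

    element: str
    cdcorr: Mapping[str, float]
    counts_used: Mapping[str, tuple[int, int, int]]  # code -> (nc, ncd, nd)

    def __post_init__(self) -> None:
        for code, value in self.cdcorr.items():
            if not math.isfinite(value):
                raise ValidationError(f"non-finite cdcorr for {code}")
            nc, ncd, nd = self.counts_used[code]
            if nd < 1:
                raise ValidationError(
                    f"{code}: amino acids without added carbon are pass-through "
                    "and do not belong in the model"
                )


@dataclass(frozen=True)
class BracketSummary:
    """Per-amino-acid mean of the first- and last-bracket standard injections."""

    element: str
    mean_measured: Mapping[str, float]
    n_start: int
    n_end: int

    def __post_init__(self) -> None:
        if self.n_start < 1 or self.n_end < 1:
            raise ValidationError("each terminal bracket needs >= 1 standard")


def _terminal_brackets(run: SequenceRun) -> tuple[list[Injection], list[Injection]]:
    injections = run.injections
    start: list[Injection] = []
    for inj in injections:
        if inj.role != ROLE_STANDARD:
            break
        start.append(inj)
    end: list[Injection] = []
    for inj in reversed(injections):
        if inj.role != ROLE_STANDARD:
            break
        end.append(inj)
    end.reverse()
    return start, end


def average_standard_brackets(run: SequenceRun) -> BracketSummary:
    """Average the standards of the opening and closing brackets of a run.

    Amino acids absent from any contributing standard injection are dropped
    with a warning. A run whose standards all sit in one terminal bracket
    (start = end) is averaged once, not twice.
    """
    start, end = _terminal_brackets(run)
    if not start or not end:
        raise CalibrationError("run has no standard injections in a terminal bracket")
    pool = list(start)
    start_indices = {inj.sequence_index for inj in start}
    pool += [inj for inj in end if inj.sequence_index not in start_indices]

    shared = set(pool[0].measured)
    for inj in pool[1:]:
        shared &= set(inj.measured)
    dropped = set().union(*(inj.measured.keys() for inj in pool)) - shared
    if dropped:
        logger.warning(
            "amino acids missing from some standard injections dropped from "
            "bracket mean: %s",
            sorted(dropped),
        )
    mean_measured = {
        code: float(np.mean([inj.measured[code] for inj in pool]))
        for code in sorted(shared)
    }
    return BracketSummary(
        element=run.element,
        mean_measured=mean_measured,
        n_start=len(start),
        n_end=len(end),
    )


def fit_nitrogen_calibration(
    bracket: BracketSummary,
    ref: StandardReference,
    *,
    per_aa: bool = False,
) -> CalibrationModel | dict[str, CalibrationModel]:
    """Fit the sequence's δ15N calibration from bracket means and certified values.

    The default (pooled) model is an ordinary least-squares regression of
    certified δ15N on bracket-mean measured δ15N over all shared amino acids —
    one affine map per sequence. With ``per_aa=True`` each amino acid instead
    gets an offset-only model (slope 1, intercept = certified − measured):
    with a single certified value per amino acid there is no within-amino-acid
    spread to regress on.
    """
    shared = sorted(set(bracket.mean_measured) & set(ref.certified))
    if len(shared) < 2:
        raise CalibrationError(
            f"need >= 2 amino acids shared between bracket and reference, "
            f"got {len(shared)}"
        )
    if per_aa:
        n_points = bracket.n_start + bracket.n_end
        return {
            code: CalibrationModel(
                element="N",
                scope=code,
                slope=1.0,
                intercept=ref.certified[code] - bracket.mean_measured[code],
                n_points=n_points,
                r_squared=1.0,
            )
            for code in shared
        }
    measured = np.array([bracket.mean_measured[code] for code in shared])
    certified = np.array([ref.certified[code] for code in shared])
    if np.ptp(measured) == 0:
        raise CalibrationError("measured standard values have zero variance")
    fit = stats.linregress(measured, certified)
    return CalibrationModel(
        element="N",
        scope="pooled",
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=len(shared),
        r_squared=float(min(fit.rvalue**2, 1.0)),
    )


def apply_nitrogen_calibration(
    run: SequenceRun,
    model: CalibrationModel | Mapping[str, CalibrationModel],
) -> list[Injection]:
    """Map every injection of the run through the fitted calibration.

    Standards pass through the same map; their residuals against the certified
    values are the sequence's QC diagnostics. With a per-amino-acid model,
    amino acids without a model pass through unchanged and are flagged
    ``"uncalibrated"``.
    """
    per_aa = isinstance(model, Mapping)
    corrected = []
    for inj in run.injections:
        values: dict[str, float] = {}
        flags: dict[str, str] = {}
        for code, measured in inj.measured.items():
            if per_aa:
                sub = model.get(code)
                if sub is None:
                    logger.warning(
                        "no calibration for %s in injection %d; passed through",
                        code,
                        inj.sequence_index,
                    )
                    values[code] = measured
                    flags[code] = "uncalibrated"
                    continue
                values[code] = sub.apply(measured)
            else:
                values[code] = model.apply(measured)
        corrected.append(replace(inj, measured=values, qc_flags=flags))
    return corrected


def calibrate_derivatization(
    bracket_c: BracketSummary,
    ref_c: StandardReference,
    registry: Iterable[AminoAcid] | None = None,
) -> DerivatizationModel:
    """Solve the mole balance for δ13C_dcorr per amino acid.

    δ13C_dcorr = (ncd · δ13C_cd − nc · δ13C_c) / nd with certified δ13C_c and
    bracket-mean measured δ13C_cd. Amino acids that gain no carbon during
    derivatization (nd = 0) are excluded: they need no correction.
    """
    index = registry_index(registry)
    shared = sorted(set(bracket_c.mean_measured) & set(ref_c.certified))
    if not shared:
        raise CalibrationError("no amino acids shared between carbon bracket and reference")
    cdcorr: dict[str, float] = {}
    counts: dict[str, tuple[int, int, int]] = {}
    for code in shared:
        aa = index.get(code)
        if aa is None:
            raise ConfigurationError(f"no carbon counts configured for {code}")
        nd = aa.n_carbon_added
        if nd == 0:
            logger.info("%s gains no derivatization carbon; pass-through", code)
            continue
        nc, ncd = aa.n_carbon_free, aa.n_carbon_derivatized
        cdcorr[code] = (ncd * bracket_c.mean_measured[code] - nc * ref_c.certified[code]) / nd
        counts[code] = (nc, ncd, nd)
    return DerivatizationModel(element="C", cdcorr=cdcorr, counts_used=counts)


def correct_carbon(
    measured_cd: float, aa: AminoAcid, model: DerivatizationModel
) -> float:
    """Invert the mole balance: δ13C_c = (ncd · δ13C_cd − nd · δ13C_dcorr) / nc."""
    if aa.n_carbon_added == 0:
        return measured_cd
    if aa.code not in model.cdcorr:
        raise CorrectionError(
            f"{aa.code} gains derivatization carbon but has no calibrated cdcorr"
        )
    nc, ncd, nd = model.counts_used[aa.code]
    return (ncd * measured_cd - nd * model.cdcorr[aa.code]) / nc


def aggregate_replicates(
    injections: list[Injection], meta: SampleMeta
) -> CorrectedSample:
    """Collapse one sample's replicate injections to mean ± SD per amino acid.

    Uses the n−1 (sample) standard deviation. A single replicate yields
    dispersion 0 with a warning — the duplicate/triplicate scheme expects
    more.
    """
    if not injections:
        raise IntegrityError(f"no replicate injections for sample {meta.sample_id}")
    elements = {inj.element for inj in injections}
    if len(elements) != 1:
        raise IntegrityError(
            f"sample {meta.sample_id} mixes elements {sorted(elements)}"
        )
    ids = {inj.sample_id for inj in injections}
    if ids != {meta.sample_id}:
        raise IntegrityError(
            f"injections for {sorted(ids)} grouped under sample {meta.sample_id}"
        )
    if len(injections) == 1:
        logger.warning(
            "sample %s has a single replicate; dispersion set to 0", meta.sample_id
        )
    codes = sorted(set().union(*(inj.measured.keys() for inj in injections)))
    delta: dict[str, float] = {}
    dispersion: dict[str, float] = {}
    for code in codes:
        values = np.array([inj.measured[code] for inj in injections if code in inj.measured])
        delta[code] = float(values.mean())
        dispersion[code] = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return CorrectedSample(
        meta=meta,
        element=injections[0].element,
        delta=delta,
        dispersion=dispersion,
        n_replicates=len(injections),
    )
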