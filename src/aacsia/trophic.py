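"""Trophic position from Glu/Phe δ15N and the two-endmember heterotrophy balance.

Glutamic acid ("trophic" amino acid) is enriched in 15N by a roughly constant
trophic discrimination factor (TDF) at each transfer, while phenylalanine
("source" amino acid) retains the primary-producer baseline. With the producer
offset β = δ15N_Glu − δ15N_Phe at trophic position 1, the consumer's position
is

    TP = (δ15N_Glu − δ15N_Phe − β) / TDF + 1

Defaults β = −0.36‰ and TDF = 4.54‰ are the values commonly used for the
Glu/Phe pair in marine food webs.

The heterotrophy fraction treats the measured TP as a linear mixture of two
endmembers: pure autotrophy (TP 1, photosynthate) and pure predation (TP 2.86,
the value derived for a fully heterotrophic coral by the same method), so

    f_het = (TP − TP_auto) / (TP_het − TP_auto)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MixingError, TrophicError, ValidationError
from .types import CorrectedSample, SampleMeta


@dataclass(frozen=True)
class TrophicParams:
    """β (producer Glu−Phe offset, ‰) and TDF (‰ per trophic step)."""

    beta: float = -0.36
    tdf: float = 4.54

    def __post_init__(self) -> None:
        if self.tdf <= 0:
            raise ValidationError("tdf must be > 0")


@dataclass(frozen=True)
class MixingEndmembers:
    """Trophic positions of the pure-predation and pure-photosynthesis endmembers."""

    tp_heterotrophy: float = 2.86
    tp_autotrophy: float = 1.0

    def __post_init__(self) -> None:
        if not self.tp_heterotrophy > self.tp_autotrophy:
            raise MixingError(
                "heterotrophic endmember TP must exceed the autotrophic one"
            )


@dataclass(frozen=True)
class MixingResult:
    f_het: float
    clamped: bool
    endmembers: MixingEndmembers

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_het <= 1.0:
            raise ValidationError("f_het must lie in [0, 1]")


@dataclass(frozen=True)
class TrophicPositionResult:
    meta: SampleMeta
    tp: float
    se: float
    params: TrophicParams
    d15n_glu: float
    d15n_phe: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("se must be >= 0")
        if not math.isfinite(self.tp):
            raise ValidationError("tp must be finite")


def trophic_position(d15n_glu: float, d15n_phe: float, params: TrophicParams) -> float:
    """The Glu/Phe trophic-position formula on raw δ values."""
    return (d15n_glu - d15n_phe - params.beta) / params.tdf + 1.0


def propagate_tp_se(
    sd_glu: float,
    sd_phe: float,
    n_glu: int,
    n_phe: int,
    params: TrophicParams,
    sd_beta: float = 0.0,
    sd_tdf: float = 0.0,
    tp: float | None = None,
) -> float:
    """First-order (quadrature) standard error of TP.

    Combines the standard errors of the replicate means of Glu and Phe with
    optional parameter uncertainty. The TDF sensitivity is −(TP − 1)/TDF, so
    ``tp`` must be supplied when ``sd_tdf > 0``.
    """
    if min(sd_glu, sd_phe, sd_beta, sd_tdf) < 0:
        raise ValidationError("standard deviations must be >= 0")
    if min(n_glu, n_phe) < 1:
        raise ValidationError("replicate counts must be >= 1")
    var = (sd_glu**2 / n_glu + sd_phe**2 / n_phe + sd_beta**2) / params.tdf**2
    if sd_tdf > 0:
        if tp is None:
            raise ValidationError("tp is required to propagate TDF uncertainty")
        var += ((tp - 1.0) / params.tdf) ** 2 * sd_tdf**2
    return math.sqrt(var)


def compute_tp(
    sample: CorrectedSample, params: TrophicParams | None = None
) -> TrophicPositionResult:
    """Trophic position of one corrected nitrogen sample.

    The standard error propagates the sample's replicate dispersion of Glu and
    Phe through the TP formula.
    """
    if params is None:
        params = TrophicParams()
    if sample.element != "N":
        raise TrophicError("trophic position needs a nitrogen sample")
    for code in ("Glu", "Phe"):
        if code not in sample.delta:
            raise TrophicError(f"sample {sample.meta.sample_id} is missing {code}")
    glu, phe = sample.delta["Glu"], sample.delta["Phe"]
    tp = trophic_position(glu, phe, params)
    se = propagate_tp_se(
        sample.dispersion.get("Glu", 0.0),
        sample.dispersion.get("Phe", 0.0),
        sample.n_replicates,
        sample.n_replicates,
        params,
    )
    return TrophicPositionResult(
        meta=sample.meta, tp=tp, se=se, params=params, d15n_glu=glu, d15n_phe=phe
    )


def heterotrophy_fraction(
    tp: float, ends: MixingEndmembers | None = None
) -> MixingResult:
    """Two-endmember mass balance for the heterotrophic share of the diet.

    The raw fraction is clamped to [0, 1] with ``clamped`` set: replicate
    noise can push an essentially autotrophic sample's TP below the
    autotrophy endmember.
    """
    if ends is None:
        ends = MixingEndmembers()
    raw = (tp - ends.tp_autotrophy) / (ends.tp_heterotrophy - ends.tp_autotrophy)
    clamped = not 0.0 <= raw <= 1.0
    return MixingResult(
        f_het=float(min(max(raw, 0.0), 1.0)), clamped=clamped, endmembers=ends
    )


def tp_group_summary(
    results: list[TrophicPositionResult],
    group_by: tuple[str, ...] = ("group", "fraction"),
) -> pd.DataFrame:
    """Mean ± SD of TP per metadata cell (default: habitat group × fraction).

    Returns machine-precision ``tp_mean``/``tp_sd`` plus display columns
    rounded to one decimal, matching how such tables are reported.
    """
    if not results:
        raise TrophicError("no trophic-position results to summarize")
    frame = pd.DataFrame(
        {
            "group": [r.meta.group for r in results],
            "fraction": [r.meta.fraction for r in results],
            "colony_id": [r.meta.colony_id for r in results],
            "tp": [r.tp for r in results],
        }
    )
    grouped = (
        frame.groupby(list(group_by))["tp"]
        .agg(tp_mean="mean", tp_sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="size")
        .reset_index()
    )
    grouped["tp_mean_display"] = grouped["tp_mean"].round(1)
    grouped["tp_sd_display"] = grouped["tp_sd"].round(1)
    return grouped
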