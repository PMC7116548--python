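"""Forward simulator of the study design and measurement chain.

The simulator emulates a depth-transplantation experiment on a reef coral:
three habitat groups (shallow, mesophotic, fragments transplanted from
mesophotic to shallow) × two tissue fractions (host, algal symbiont) × three
colonies, each sample injected in triplicate for nitrogen and duplicate for
carbon, with 7-amino-acid standard brackets (three injections each) opening
and closing the sequence and inserted after at most 18 sample injections.

Generation runs the measurement chain forward from known truth:

1. draw a per-colony phenylalanine δ15N baseline;
2. set δ15N_Glu = δ15N_Phe + β + TDF·(TP_true − 1) from the per-sample true
   trophic position;
3. draw essential-amino-acid δ13C around group means;
4. mix in derivatization reagent carbon, δ13C_cd = (nc·δ13C_c + nd·δ13C_dcorr)/ncd;
5. distort by the sequence's drift — measured = (true − offset)/slope — the
   exact inverse of the affine calibration, so the correction chain can
   recover truth;
6. add per-injection Gaussian noise;
7. interleave standard brackets.

Nitrogen drift is affine; carbon drift is additive only (slope 1): the
acquisition protocol calibrates carbon solely through the per-amino-acid
reagent signature, which cancels additive offsets exactly but cannot identify
a multiplicative term.

The accompanying :class:`TruthTable` records the realized per-sample truth so
every downstream stage is testable by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .io import default_standard_reference
from .registry import ESSENTIAL_AAS, STANDARD_AAS, aa_registry, registry_index
from .trophic import TrophicParams, heterotrophy_fraction, trophic_position
from .types import (
    GROUPS,
    ROLE_SAMPLE,
    ROLE_STANDARD,
    Injection,
    SampleMeta,
    SequenceRun,
)

# True reagent-carbon signatures (‰ vs VPDB) per amino acid: petroleum-derived
# propanol/chloroformate carbon sits near −30‰; small per-AA spread.
DEFAULT_DCORR_TRUTH: dict[str, float] = {
    "Ala": -29.3,
    "Val": -29.8,
    "Leu": -30.1,
    "Ile": -29.5,
    "Met": -30.4,
    "Glu": -28.9,
    "Phe": -29.9,
}

# δ15N offsets (‰) of the carried-but-uninformative amino acids relative to
# the colony's Phe baseline.
DEFAULT_D15N_OFFSETS: dict[str, float] = {
    "Ala": 2.0,
    "Val": 1.0,
    "Leu": 0.5,
    "Ile": 0.8,
    "Met": -0.5,
}

# δ13C offsets (‰) of the non-essential amino acids relative to the group's
# Phe δ13C mean.
DEFAULT_D13C_OFFSETS: dict[str, float] = {"Glu": 7.0, "Ala": 5.0}

# Group-mean essential-amino-acid δ13C (‰ vs VPDB). Shallow and transplanted
# fragments share a carbon source; mesophotic colonies are isotopically
# lighter, most strongly on Leu and Phe, barely on Met.
_SHALLOW_D13C = {"Val": -24.0, "Leu": -26.0, "Ile": -22.5, "Met": -23.5, "Phe": -25.5}
_MESO_SHIFT = {"Val": -1.0, "Leu": -2.5, "Ile": -1.5, "Met": -0.2, "Phe": -2.5}


@dataclass
class SimulationConfig:
    """All knobs of the forward model; defaults reproduce the study design."""

    seed: int = 0
    #: (group, fraction) -> true trophic position
    group_tp: dict[tuple[str, str], float] = field(default_factory=dict)
    #: group -> essential-amino-acid δ13C means (‰)
    group_d13c: dict[str, dict[str, float]] = field(default_factory=dict)
    n_colonies: int = 3
    phe_baseline: float = 4.0  # ‰ vs Air, producer Phe δ15N
    phe_colony_sd: float = 0.5  # between-colony SD of the Phe baseline, ‰
    tp_colony_sd: float = 0.2  # between-colony SD of true TP
    d13c_colony_sd: float = 0.5  # between-colony SD of essential δ13C, ‰
    trophic_params: TrophicParams = field(default_factory=TrophicParams)
    d15n_offsets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_D15N_OFFSETS)
    )
    d13c_offsets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_D13C_OFFSETS)
    )
    noise_sd_n: float = 0.3  # per-injection δ15N noise, ‰
    noise_sd_c: float = 0.5  # per-injection δ13C noise, ‰
    drift_n: tuple[float, float] = (1.03, 0.8)  # (slope, offset) for nitrogen
    drift_c: tuple[float, float] = (1.0, -0.7)  # slope fixed at 1 for carbon
    derivatization_truth: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DCORR_TRUTH)
    )
    replicates_n: int = 3
    replicates_c: int = 2
    bracket_spacing: int = 18
    standards_per_bracket: int = 3

    def __post_init__(self) -> None:
        for name in ("phe_colony_sd", "tp_colony_sd", "d13c_colony_sd",
                     "noise_sd_n", "noise_sd_c"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 1 <= self.bracket_spacing <= 18:
            raise ConfigurationError("bracket_spacing must lie in [1, 18]")
        if self.replicates_n < 1 or self.replicates_c < 1:
            raise ConfigurationError("replicate counts must be >= 1")


def paper_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The canonical study configuration.

    True trophic positions are (host, symbiont) = (1.7, 1.3) for shallow and
    mesophotic colonies and (1.2, 0.9) for the transplanted fragments; the
    mesophotic essential-amino-acid δ13C means are shifted lighter than the
    shared shallow/transplant source, most strongly on Leu and Phe.
    """
    group_tp = {
        ("shallow", "host"): 1.7,
        ("shallow", "symbiont"): 1.3,
        ("mesophotic", "host"): 1.7,
        ("mesophotic", "symbiont"): 1.3,
        ("transplant", "host"): 1.2,
        ("transplant", "symbiont"): 0.9,
    }
    meso = {code: _SHALLOW_D13C[code] + _MESO_SHIFT[code] for code in ESSENTIAL_AAS}
    group_d13c = {
        "shallow": dict(_SHALLOW_D13C),
        "mesophotic": meso,
        "transplant": dict(_SHALLOW_D13C),
    }
    return SimulationConfig(
        seed=seed, group_tp=group_tp, group_d13c=group_d13c, **overrides
    )


@dataclass
class TruthRow:
    meta: SampleMeta
    d15n_glu: float
    d15n_phe: float
    d13c: dict[str, float]  # essential amino acids
    tp: float
    f_het: float


@dataclass
class TruthTable:
    """Realized per-sample ground truth of one simulated study."""

    rows: list[TruthRow]
    params: TrophicParams

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {
                "sample_id": row.meta.sample_id,
                "group": row.meta.group,
                "fraction": row.meta.fraction,
                "colony_id": row.meta.colony_id,
                "d15n_glu": row.d15n_glu,
                "d15n_phe": row.d15n_phe,
                "tp": row.tp,
                "f_het": row.f_het,
            }
            for code in ESSENTIAL_AAS:
                rec[f"d13c_{code.lower()}"] = row.d13c[code]
            records.append(rec)
        return pd.DataFrame.from_records(records)


def write_truth(truth: TruthTable, sink: str | IO[str]) -> None:
    truth.to_dataframe().to_csv(sink, index=False)


def read_truth(source: str | IO[str]) -> TruthTable:
    frame = pd.read_csv(
        source,
        dtype={"sample_id": str, "colony_id": str},
        float_precision="round_trip",
    )
    if frame.empty:
        raise SchemaError("truth table has no rows")
    rows = []
    for _, rec in frame.iterrows():
        rows.append(
            TruthRow(
                meta=SampleMeta(
                    sample_id=str(rec["sample_id"]),
                    group=str(rec["group"]),
                    fraction=str(rec["fraction"]),
                    colony_id=str(rec["colony_id"]),
                ),
                d15n_glu=float(rec["d15n_glu"]),
                d15n_phe=float(rec["d15n_phe"]),
                d13c={
                    code: float(rec[f"d13c_{code.lower()}"]) for code in ESSENTIAL_AAS
                },
                tp=float(rec["tp"]),
                f_het=float(rec["f_het"]),
            )
        )
    return TruthTable(rows=rows, params=TrophicParams())


def _draw_truth(config: SimulationConfig, rng: np.random.Generator) -> TruthTable:
    params = config.trophic_params
    rows: list[TruthRow] = []
    groups = sorted({g for g, _ in config.group_tp}, key=GROUPS.index)
    for group in groups:
        for colony in range(1, config.n_colonies + 1):
            colony_id = f"{group[:2]}{colony}"
            phe_base = config.phe_baseline + rng.normal(0.0, config.phe_colony_sd)
            for fraction in ("host", "symbiont"):
                if (group, fraction) not in config.group_tp:
                    continue
                tp_true = config.group_tp[(group, fraction)] + rng.normal(
                    0.0, config.tp_colony_sd
                )
                d15n_phe = phe_base
                d15n_glu = d15n_phe + params.beta + params.tdf * (tp_true - 1.0)
                means = config.group_d13c[group]
                d13c = {
                    code: means[code] + rng.normal(0.0, config.d13c_colony_sd)
                    for code in ESSENTIAL_AAS
                }
                meta = SampleMeta(
                    sample_id=f"{group[:2]}-{colony}-{fraction[:3]}",
                    group=group,
                    fraction=fraction,
                    colony_id=colony_id,
                )
                rows.append(
                    TruthRow(
                        meta=meta,
                        d15n_glu=d15n_glu,
                        d15n_phe=d15n_phe,
                        d13c=d13c,
                        tp=trophic_position(d15n_glu, d15n_phe, params),
                        f_het=heterotrophy_fraction(
                            trophic_position(d15n_glu, d15n_phe, params)
                        ).f_het,
                    )
                )
    return TruthTable(rows=rows, params=params)


def _assemble_run(
    element: str,
    sample_true: list[tuple[SampleMeta, dict[str, float]]],
    standard_true: dict[str, float],
    n_replicates: int,
    drift: tuple[float, float],
    noise_sd: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SequenceRun:
    slope, offset = drift

    def measure(true: Mapping[str, float]) -> dict[str, float]:
        return {
            code: (value - offset) / slope + rng.normal(0.0, noise_sd)
            for code, value in true.items()
        }

    injections: list[Injection] = []
    seq = 0

    def add_bracket() -> None:
        nonlocal seq
        for rep in range(1, config.standards_per_bracket + 1):
            seq += 1
            injections.append(
                Injection(
                    sequence_index=seq,
                    role=ROLE_STANDARD,
                    sample_id="",
                    element=element,
                    replicate_index=rep,
                    measured=measure(standard_true),
                )
            )

    add_bracket()
    since_bracket = 0
    for meta, true in sample_true:
        for rep in range(1, n_replicates + 1):
            if since_bracket == config.bracket_spacing:
                add_bracket()
                since_bracket = 0
            seq += 1
            injections.append(
                Injection(
                    sequence_index=seq,
                    role=ROLE_SAMPLE,
                    sample_id=meta.sample_id,
                    element=element,
                    replicate_index=rep,
                    measured=measure(true),
                )
            )
            since_bracket += 1
    add_bracket()
    return SequenceRun(
        element=element,
        injections=injections,
        standard_ref=default_standard_reference(element),
        bracket_limit=18,
        sample_meta={meta.sample_id: meta for meta, _ in sample_true},
    )


def simulate_study(
    config: SimulationConfig,
) -> tuple[SequenceRun, SequenceRun, TruthTable]:
    """Run the forward model: returns (nitrogen run, carbon run, truth table).

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    index = registry_index(aa_registry())
    for code in config.derivatization_truth:
        if code not in index:
            raise ConfigurationError(f"derivatization truth for unknown amino acid {code}")
    truth = _draw_truth(config, rng)

    # --- nitrogen -----------------------------------------------------------
    ref_n = default_standard_reference("N").certified
    n_samples: list[tuple[SampleMeta, dict[str, float]]] = []
    for row in truth.rows:
        true_n = {"Glu": row.d15n_glu, "Phe": row.d15n_phe}
        for code, off in config.d15n_offsets.items():
            true_n[code] = row.d15n_phe + off
        n_samples.append((row.meta, true_n))
    run_n = _assemble_run(
        "N", n_samples, dict(ref_n), config.replicates_n, config.drift_n,
        config.noise_sd_n, config, rng,
    )

    # --- carbon -------------------------------------------------------------
    def derivatize(true_c: Mapping[str, float]) -> dict[str, float]:
        out = {}
        for code, delta_c in true_c.items():
            aa = index[code]
            nd = aa.n_carbon_added
            if nd == 0:
                out[code] = delta_c
                continue
            dcorr = config.derivatization_truth[code]
            out[code] = (
                aa.n_carbon_free * delta_c + nd * dcorr
            ) / aa.n_carbon_derivatized
        return out

    ref_c = default_standard_reference("C").certified
    c_samples: list[tuple[SampleMeta, dict[str, float]]] = []
    for row in truth.rows:
        true_c = dict(row.d13c)
        phe_mean = config.group_d13c[row.meta.group]["Phe"]
        for code, off in config.d13c_offsets.items():
            true_c[code] = phe_mean + off
        c_samples.append((row.meta, derivatize(true_c)))
    run_c = _assemble_run(
        "C", c_samples, derivatize(ref_c), config.replicates_c, config.drift_c,
        config.noise_sd_c, config, rng,
    )
    return run_n, run_c, truth


def randomized_drift(
    rng: np.random.Generator,
    slope_range: tuple[float, float] = (0.9, 1.1),
    offset_range: tuple[float, float] = (-2.0, 2.0),
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Draw per-sequence drift: affine for nitrogen, additive for carbon."""
    drift_n = (rng.uniform(*slope_range), rng.uniform(*offset_range))
    drift_c = (1.0, rng.uniform(*offset_range))
    return drift_n, drift_c
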