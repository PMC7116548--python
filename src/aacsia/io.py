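"""Readers and writers for the delimited-table schemas.

All tables are comma-separated UTF-8 text with '.' decimal separators and a
header row. Three schemas exist:

* injection table — one row per injection × amino acid:
  ``sequence_index, role, sample_id, group, fraction, colony_id, element,
  replicate_index, amino_acid, delta_measured``
* standards table — ``element, amino_acid, delta_certified``
* carbon-count table — ``amino_acid, n_carbon_free, n_carbon_derivatized``

Corrected samples round-trip through ``write_corrected_table`` /
``read_corrected_table``. Floats are written at full precision so round-trips
are lossless.
"""

from __future__ import annotations

import logging
from typing import IO, Iterable, Mapping

import pandas as pd

from .errors import IntegrityError, RegistryError, SchemaError
from .registry import AminoAcid, aa_registry, canonical_code, registry_index
from .types import (
    ROLE_SAMPLE,
    ROLE_STANDARD,
    CorrectedSample,
    Injection,
    SampleMeta,
    SequenceRun,
    StandardReference,
)

logger = logging.getLogger(__name__)

INJECTION_COLUMNS = [
    "sequence_index",
    "role",
    "sample_id",
    "group",
    "fraction",
    "colony_id",
    "element",
    "replicate_index",
    "amino_acid",
    "delta_measured",
]

CORRECTED_COLUMNS = [
    "sample_id",
    "group",
    "fraction",
    "colony_id",
    "element",
    "amino_acid",
    "delta",
    "dispersion",
    "n_replicates",
]


def _read_csv(source: str | IO[str], required: list[str], what: str) -> pd.DataFrame:
    frame = pd.read_csv(
        source,
        dtype={"sample_id": str, "colony_id": str},
        float_precision="round_trip",
    )
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")
    return frame


def read_injection_table(
    source: str | IO[str],
    *,
    standard_ref: StandardReference | None = None,
    registry: Iterable[AminoAcid] | None = None,
    bracket_limit: int = 18,
) -> SequenceRun:
    """Parse an injection table into a validated :class:`SequenceRun`.

    The file must contain exactly one element; the certified standard values
    come from ``standard_ref`` or, if omitted, from the packaged defaults for
    that element.

    Raises
    ------
    SchemaError
        Missing required column, or no injections at all.
    IntegrityError
        Duplicate (sequence_index, amino_acid) rows, mixed elements, or a
        bracket-spacing violation.
    RegistryError
        Amino-acid code absent from the registry.
    """
    frame = _read_csv(source, INJECTION_COLUMNS, "injection table")
    if frame.empty:
        raise SchemaError("no injections")
    index = registry_index(registry)

    element = frame["element"].astype(str).str.strip().unique()
    if len(element) != 1:
        raise IntegrityError(f"injection table mixes elements: {sorted(element)}")
    element = element[0]

    frame = frame.copy()
    frame["amino_acid"] = [
        _known_code(code, index) for code in frame["amino_acid"].astype(str)
    ]
    dup = frame.duplicated(subset=["sequence_index", "amino_acid"])
    if dup.any():
        pair = frame.loc[dup, ["sequence_index", "amino_acid"]].iloc[0]
        raise IntegrityError(
            f"duplicate measurement for injection {pair['sequence_index']} "
            f"amino acid {pair['amino_acid']}"
        )

    injections: list[Injection] = []
    sample_meta: dict[str, SampleMeta] = {}
    for seq_idx, rows in frame.groupby("sequence_index", sort=True):
        role = rows["role"].iloc[0]
        sample_id = str(rows["sample_id"].iloc[0] or "") if role == ROLE_SAMPLE else ""
        replicate = int(rows["replicate_index"].iloc[0])
        measured = dict(zip(rows["amino_acid"], rows["delta_measured"].astype(float)))
        injections.append(
            Injection(
                sequence_index=int(seq_idx),
                role=str(role),
                sample_id=sample_id,
                element=element,
                replicate_index=replicate,
                measured=measured,
            )
        )
        if role == ROLE_SAMPLE and sample_id not in sample_meta:
            sample_meta[sample_id] = SampleMeta(
                sample_id=sample_id,
                group=str(rows["group"].iloc[0]),
                fraction=str(rows["fraction"].iloc[0]),
                colony_id=str(rows["colony_id"].iloc[0]),
            )

    if standard_ref is None:
        standard_ref = default_standard_reference(element)
    return SequenceRun(
        element=element,
        injections=injections,
        standard_ref=standard_ref,
        bracket_limit=bracket_limit,
        sample_meta=sample_meta,
    )


def _known_code(code: str, index: Mapping[str, AminoAcid]) -> str:
    canonical = canonical_code(code)
    if canonical not in index:
        raise RegistryError(f"amino acid {code!r} not in registry")
    return canonical


def default_standard_reference(element: str) -> StandardReference:
    """Packaged default certified values for the 7-amino-acid standard."""
    from .registry import DEFAULT_CERTIFIED_D13C, DEFAULT_CERTIFIED_D15N

    table = DEFAULT_CERTIFIED_D15N if element == "N" else DEFAULT_CERTIFIED_D13C
    return StandardReference(element=element, certified=dict(table))


def write_injection_table(run: SequenceRun, sink: str | IO[str]) -> None:
    """Emit a :class:`SequenceRun` in the injection-table schema."""
    records = []
    for inj in run.injections:
        meta = run.sample_meta.get(inj.sample_id)
        for code, value in inj.measured.items():
            records.append(
                {
                    "sequence_index": inj.sequence_index,
                    "role": inj.role,
                    "sample_id": inj.sample_id,
                    "group": meta.group if meta else "",
                    "fraction": meta.fraction if meta else "",
                    "colony_id": meta.colony_id if meta else "",
                    "element": inj.element,
                    "replicate_index": inj.replicate_index,
                    "amino_acid": code,
                    "delta_measured": value,
                }
            )
    pd.DataFrame.from_records(records, columns=INJECTION_COLUMNS).to_csv(
        sink, index=False
    )


def write_corrected_table(samples: list[CorrectedSample], sink: str | IO[str]) -> None:
    """Write corrected samples, one row per sample × amino acid."""
    if not samples:
        raise SchemaError("no corrected samples to write")
    records = []
    for sample in samples:
        for code in sorted(sample.delta):
            records.append(
                {
                    "sample_id": sample.meta.sample_id,
                    "group": sample.meta.group,
                    "fraction": sample.meta.fraction,
                    "colony_id": sample.meta.colony_id,
                    "element": sample.element,
                    "amino_acid": code,
                    "delta": sample.delta[code],
                    "dispersion": sample.dispersion.get(code, 0.0),
                    "n_replicates": sample.n_replicates,
                }
            )
    pd.DataFrame.from_records(records, columns=CORRECTED_COLUMNS).to_csv(
        sink, index=False
    )


def read_corrected_table(source: str | IO[str]) -> list[CorrectedSample]:
    """Inverse of :func:`write_corrected_table` (sample order = file order)."""
    frame = _read_csv(source, CORRECTED_COLUMNS, "corrected table")
    if frame.empty:
        raise SchemaError("corrected table has no rows")
    samples = []
    for sample_id, rows in frame.groupby("sample_id", sort=False):
        first = rows.iloc[0]
        samples.append(
            CorrectedSample(
                meta=SampleMeta(
                    sample_id=str(sample_id),
                    group=str(first["group"]),
                    fraction=str(first["fraction"]),
                    colony_id=str(first["colony_id"]),
                ),
                element=str(first["element"]),
                delta={
                    canonical_code(code): float(value)
                    for code, value in zip(rows["amino_acid"], rows["delta"])
                },
                dispersion={
                    canonical_code(code): float(value)
                    for code, value in zip(rows["amino_acid"], rows["dispersion"])
                },
                n_replicates=int(first["n_replicates"]),
            )
        )
    return samples


def read_standard_table(source: str | IO[str]) -> dict[str, StandardReference]:
    """Read certified standard values, one :class:`StandardReference` per element."""
    frame = _read_csv(
        source, ["element", "amino_acid", "delta_certified"], "standards table"
    )
    refs = {}
    for element, rows in frame.groupby("element"):
        refs[str(element)] = StandardReference(
            element=str(element),
            certified={
                canonical_code(code): float(value)
                for code, value in zip(rows["amino_acid"], rows["delta_certified"])
            },
        )
    return refs


def write_standard_table(
    refs: Mapping[str, StandardReference], sink: str | IO[str]
) -> None:
    records = [
        {"element": element, "amino_acid": code, "delta_certified": value}
        for element, ref in refs.items()
        for code, value in sorted(ref.certified.items())
    ]
    pd.DataFrame.from_records(
        records, columns=["element", "amino_acid", "delta_certified"]
    ).to_csv(sink, index=False)


def read_carbon_counts(source: str | IO[str]) -> dict[str, tuple[int, int]]:
    """Read a carbon-count override table for :func:`aacsia.registry.aa_registry`."""
    frame = _read_csv(
        source,
        ["amino_acid", "n_carbon_free", "n_carbon_derivatized"],
        "carbon-count table",
    )
    return {
        canonical_code(code): (int(nc), int(ncd))
        for code, nc, ncd in zip(
            frame["amino_acid"], frame["n_carbon_free"], frame["n_carbon_derivatized"]
        )
    }


def write_carbon_counts(
    registry: Iterable[AminoAcid] | None, sink: str | IO[str]
) -> None:
    if registry is None:
        registry = aa_registry()
    records = [
        {
            "amino_acid": aa.code,
            "n_carbon_free": aa.n_carbon_free,
            "n_carbon_derivatized": aa.n_carbon_derivatized,
        }
        for aa in registry
    ]
    pd.DataFrame.from_records(
        records, columns=["amino_acid", "n_carbon_free", "n_carbon_derivatized"]
    ).to_csv(sink, index=False)
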