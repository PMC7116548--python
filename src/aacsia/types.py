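"""Core domain types: δ values, injections, instrument sequences, sample metadata.

Measured and corrected isotope ratios are carried as plain floats in per mil
(‰); :class:`DeltaValue` makes the reference-scale convention explicit where a
value leaves the package (δ13C vs VPDB, δ15N vs Air).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import CalibrationError, IntegrityError, ValidationError

ELEMENTS = ("C", "N")
GROUPS = ("shallow", "mesophotic", "transplant")
FRACTIONS = ("host", "symbiont")

ROLE_STANDARD = "standard"
ROLE_SAMPLE = "sample"

#: Reference scale per element: carbon vs Vienna PeeDee Belemnite, nitrogen
#: vs atmospheric N2.
REFERENCE_BY_ELEMENT = {"C": "VPDB", "N": "Air"}


def _check_element(element: str) -> None:
    if element not in ELEMENTS:
        raise ValidationError(f"element must be one of {ELEMENTS}, got {element!r}")


@dataclass(frozen=True)
class DeltaValue:
    """An isotope ratio in δ notation (‰) against the element's reference scale."""

    value: float
    element: str
    reference: str

    def __post_init__(self) -> None:
        _check_element(self.element)
        if not math.isfinite(self.value):
            raise ValidationError("delta value must be finite")
        expected = REFERENCE_BY_ELEMENT[self.element]
        if self.reference != expected:
            raise ValidationError(
                f"element {self.element} must be reported vs {expected}, "
                f"got {self.reference!r}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one analysed sample: habitat group, tissue fraction, colony."""

    sample_id: str
    group: str
    fraction: str
    colony_id: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"fraction must be one of {FRACTIONS}, got {self.fraction!r}"
            )


@dataclass
class Injection:
    """One chromatographic injection: a standard mixture or a sample replicate.

    ``measured`` maps amino-acid code to the measured δ value (‰) of that
    injection. ``qc_flags`` carries per-amino-acid quality annotations added
    downstream (e.g. ``"uncalibrated"``).
    """

    sequence_index: int
    role: str
    sample_id: str
    element: str
    replicate_index: int
    measured: dict[str, float]
    qc_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_element(self.element)
        if self.sequence_index < 1:
            raise ValidationError("sequence_index must be >= 1")
        if self.role not in (ROLE_STANDARD, ROLE_SAMPLE):
            raise ValidationError(f"unknown injection role {self.role!r}")
        if self.role == ROLE_STANDARD and self.sample_id:
            raise ValidationError("standard injections carry no sample_id")
        if self.role == ROLE_SAMPLE and not self.sample_id:
            raise ValidationError("sample injections need a sample_id")
        if self.replicate_index < 1:
            raise ValidationError("replicate_index must be >= 1")
        if not self.measured:
            raise ValidationError("injection has no measured values")


@dataclass(frozen=True)
class StandardReference:
    """Certified δ values of the calibration standard mixture for one element."""

    element: str
    certified: Mapping[str, float]

    def __post_init__(self) -> None:
        _check_element(self.element)
        if not self.certified:
            raise ValidationError("certified table is empty")


def max_samples_between_standards(roles: Sequence[str]) -> int:
    """Longest run of consecutive sample injections not interrupted by a standard."""
    longest = current = 0
    for role in roles:
        if role == ROLE_SAMPLE:
            current += 1
            longest = max(longest, current)
        else:
            current = 0
    return longest


@dataclass
class SequenceRun:
    """An ordered instrument sequence for one element.

    Validity requires the run to open and close with at least one standard
    injection and never to exceed ``bracket_limit`` consecutive sample
    injections between standard brackets — the drift-calibration contract of
    the acquisition protocol. For nitrogen runs every injection must report
    glutamic acid and phenylalanine, the pair the trophic-position model needs.
    """

    element: str
    injections: list[Injection]
    standard_ref: StandardReference
    bracket_limit: int = 18
    sample_meta: dict[str, SampleMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_element(self.element)
        if not self.injections:
            raise IntegrityError("no injections")
        if self.bracket_limit < 1:
            raise ValidationError("bracket_limit must be >= 1")
        if self.standard_ref.element != self.element:
            raise IntegrityError("standard reference element does not match run")
        self.injections.sort(key=lambda inj: inj.sequence_index)
        indices = [inj.sequence_index for inj in self.injections]
        if len(set(indices)) != len(indices):
            raise IntegrityError("duplicate sequence_index in run")
        for inj in self.injections:
            if inj.element != self.element:
                raise IntegrityError(
                    f"injection {inj.sequence_index} element {inj.element} "
                    f"in a {self.element} run"
                )
            if self.element == "N" and not {"Glu", "Phe"} <= inj.measured.keys():
                raise IntegrityError(
                    f"nitrogen injection {inj.sequence_index} lacks Glu or Phe"
                )
        roles = [inj.role for inj in self.injections]
        if ROLE_STANDARD not in roles:
            raise CalibrationError("run contains no standard injections")
        if roles[0] != ROLE_STANDARD or roles[-1] != ROLE_STANDARD:
            raise IntegrityError("run must start and end with a standard bracket")
        worst = max_samples_between_standards(roles)
        if worst > self.bracket_limit:
            raise IntegrityError(
                f"{worst} consecutive sample injections exceed the bracket "
                f"limit of {self.bracket_limit}"
            )

    def standards(self) -> list[Injection]:
        return [inj for inj in self.injections if inj.role == ROLE_STANDARD]

    def samples(self) -> list[Injection]:
        return [inj for inj in self.injections if inj.role == ROLE_SAMPLE]


@dataclass
class CorrectedSample:
    """Per-sample, per-amino-acid corrected δ values with replicate dispersion.

    ``delta`` holds the replicate-mean corrected δ (‰); ``dispersion`` the
    sample (n−1) standard deviation across replicate injections.
    """

    meta: SampleMeta
    element: str
    delta: dict[str, float]
    dispersion: dict[str, float]
    n_replicates: int

    def __post_init__(self) -> None:
        _check_element(self.element)
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        extra = set(self.dispersion) - set(self.delta)
        if extra:
            raise ValidationError(
                f"dispersion reported for amino acids without a delta: {sorted(extra)}"
            )
        for code, sd in self.dispersion.items():
            if sd < 0:
                raise ValidationError(f"negative dispersion for {code}")
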