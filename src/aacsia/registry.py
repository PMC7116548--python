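"""Amino-acid registry: trophic roles, essentiality, and derivatization carbon counts.

The registry is the single place where the package knows which amino acid is
the trophic tracer (glutamic acid), which is the source tracer (phenylalanine),
which five are the essential carbon-source fingerprint set, and how many carbon
atoms each molecule carries before and after derivatization.

Carbon counts follow propyl-chloroformate (EZfaast-style) chemistry: each
carboxyl group gains a propyl ester (+3 C) and each amine a propoxycarbonyl
carbamate (+4 C). Reagent lots and chemistry variants differ, so the counts are
defaults that can be overridden from a carbon-count table; the empirical
reagent-carbon calibration absorbs residual error as long as the same counts
are used for calibration and correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import RegistryError, ValidationError

ROLE_TROPHIC = "trophic"
ROLE_SOURCE = "source"
ROLE_NEITHER = "neither"
_ROLES = (ROLE_TROPHIC, ROLE_SOURCE, ROLE_NEITHER)

#: The seven amino acids of the calibration standard mixture.
STANDARD_AAS: tuple[str, ...] = ("Ala", "Val", "Leu", "Ile", "Met", "Glu", "Phe")

#: The essential amino acids used for carbon-source fingerprinting.
ESSENTIAL_AAS: tuple[str, ...] = ("Val", "Leu", "Ile", "Met", "Phe")

# (n_carbon_free, n_carbon_derivatized) per amino acid for the
# N(O)-propoxycarbonyl propyl-ester derivatives.
DEFAULT_CARBON_COUNTS: dict[str, tuple[int, int]] = {
    "Ala": (3, 10),
    "Val": (5, 12),
    "Leu": (6, 13),
    "Ile": (6, 13),
    "Met": (5, 12),
    "Glu": (5, 15),  # two carboxyls -> two propyl esters
    "Phe": (9, 16),
}

# Certified δ15N (‰ vs Air) of the standard mixture. Ala (+43.25‰) and
# Val (+30.19‰) are certified reference materials (Biogeochemical
# Laboratories, Indiana University) added to extend the calibration range;
# the remaining five are synthetic defaults chosen to span the mixture's
# working range down to −6.69‰. Override from a standards table for a real
# standard lot.
DEFAULT_CERTIFIED_D15N: dict[str, float] = {
    "Ala": 43.25,
    "Val": 30.19,
    "Leu": -6.69,
    "Ile": 11.20,
    "Met": 0.80,
    "Glu": 22.50,
    "Phe": 5.30,
}

# Certified δ13C (‰ vs VPDB) of the standard mixture: synthetic defaults in a
# realistic range for commercial amino acids; override for a real lot.
DEFAULT_CERTIFIED_D13C: dict[str, float] = {
    "Ala": -23.10,
    "Val": -26.60,
    "Leu": -28.30,
    "Ile": -12.20,
    "Met": -24.40,
    "Glu": -16.70,
    "Phe": -22.90,
}


@dataclass(frozen=True)
class AminoAcid:
    """One registry entry.

    Parameters
    ----------
    code:
        Canonical 3-letter abbreviation (e.g. ``"Glu"``).
    role:
        ``"trophic"`` (δ15N enriched each trophic step), ``"source"``
        (tracks the producer baseline), or ``"neither"``.
    essential:
        Whether the amino acid belongs to the carbon-source fingerprint set.
    n_carbon_free:
        Carbon atoms in the underivatized molecule.
    n_carbon_derivatized:
        Carbon atoms in the derivatized analyte.
    """

    code: str
    role: str
    essential: bool
    n_carbon_free: int
    n_carbon_derivatized: int

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValidationError(f"unknown role {self.role!r} for {self.code}")
        if self.n_carbon_free < 1:
            raise ValidationError(f"{self.code}: n_carbon_free must be >= 1")
        if self.n_carbon_derivatized < self.n_carbon_free:
            raise ValidationError(
                f"{self.code}: n_carbon_derivatized ({self.n_carbon_derivatized}) "
                f"< n_carbon_free ({self.n_carbon_free})"
            )

    @property
    def n_carbon_added(self) -> int:
        """Carbon atoms contributed by the derivatization reagents."""
        return self.n_carbon_derivatized - self.n_carbon_free


def canonical_code(code: str) -> str:
    """Canonicalize an amino-acid code: case-insensitive, 3 letters, title case."""
    code = code.strip()
    if len(code) != 3 or not code.isalpha():
        raise RegistryError(f"not a 3-letter amino-acid code: {code!r}")
    return code.capitalize()


_ROLE_BY_CODE = {"Glu": ROLE_TROPHIC, "Phe": ROLE_SOURCE}


def aa_registry(
    counts: Mapping[str, tuple[int, int]] | None = None,
) -> list[AminoAcid]:
    """Build the default amino-acid registry.

    Parameters
    ----------
    counts:
        Optional override mapping ``code -> (n_carbon_free,
        n_carbon_derivatized)``; entries replace or extend the packaged
        defaults.

    Returns
    -------
    list of :class:`AminoAcid` covering the seven standard amino acids (which
    include the five essential fingerprint ones).
    """
    table = dict(DEFAULT_CARBON_COUNTS)
    if counts is not None:
        for code, pair in counts.items():
            table[canonical_code(code)] = (int(pair[0]), int(pair[1]))
    entries = []
    for code, (nc, ncd) in table.items():
        entries.append(
            AminoAcid(
                code=code,
                role=_ROLE_BY_CODE.get(code, ROLE_NEITHER),
                essential=code in ESSENTIAL_AAS,
                n_carbon_free=nc,
                n_carbon_derivatized=ncd,
            )
        )
    return entries


def registry_index(registry: Iterable[AminoAcid] | None = None) -> dict[str, AminoAcid]:
    """Index a registry by canonical code (default registry if none given)."""
    if registry is None:
        registry = aa_registry()
    return {aa.code: aa for aa in registry}
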