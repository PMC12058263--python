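"""Elemental-composition arithmetic for acyl-adenosine species.

RNase A cleavage of an acylated tRNA releases its 3'-terminal adenosine
still carrying 0, 1, or 2 acyl groups.  Every species this package
quantifies is therefore adenosine (C10H13N5O4) plus ``n`` monomers minus
``n`` waters — a condensation loses one H2O per acyl bond, whether the
linkage is an amide (alpha-amino acid) or an ester (hydroxy acid or
malonate).  This module provides the composition algebra, monoisotopic
[M+H]+ masses, aggregated isotope envelopes, and the expected number of
isobaric chromatographic peaks for each species class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "PROTON_MASS",
    "ElementComposition",
    "Linkage",
    "ChiralityClass",
    "Monomer",
    "AcylAdenosineSpecies",
    "MassSpecies",
    "IsotopeEnvelope",
    "ADENOSINE",
    "WATER",
    "LEU_ENK",
    "compose_species",
    "protonated_mz",
    "isotope_envelope",
    "expected_isomer_count",
    "load_monomer_registry",
    "default_registry",
]

#: Mass of a proton, Da.  Added to the neutral monoisotopic mass for [M+H]+.
PROTON_MASS = 1.007276

# Monoisotopic mass of the principal (lightest, most abundant) isotope and
# the full isotopic distribution as (nominal mass offset, abundance) pairs.
# Values are the NIST/IUPAC recommended atomic masses and abundances.
_ISOTOPES: dict[str, tuple[float, tuple[tuple[int, float], ...]]] = {
    "H": (1.00782503207, ((0, 0.999885), (1, 0.000115))),
    "C": (12.0, ((0, 0.9893), (1, 0.0107))),
    "N": (14.0030740048, ((0, 0.99636), (1, 0.00364))),
    "O": (15.9949146196, ((0, 0.99757), (1, 0.00038), (2, 0.00205))),
    "P": (30.97376163, ((0, 1.0),)),
    "S": (31.97207100, ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001))),
    "F": (18.99840322, ((0, 1.0),)),
    "Cl": (34.96885268, ((0, 0.7576), (2, 0.2424))),
    "Br": (78.9183371, ((0, 0.5069), (2, 0.4931))),
    "I": (126.904473, ((0, 1.0),)),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Linkage(str, Enum):
    """Chemistry of the bond the monomer's carboxylate forms with ribose."""

    AMIDE = "amide"
    ESTER_HYDROXY = "ester_hydroxy"
    ESTER_MALONATE = "ester_malonate"


class ChiralityClass(str, Enum):
    CHIRAL = "chiral"
    PROCHIRAL = "prochiral"
    ACHIRAL = "achiral"


@dataclass(frozen=True)
class ElementComposition:
    """Integer element counts; the substrate for all mass computation.

    Immutable.  Supports ``+``, ``-`` and scalar ``*``; subtraction that
    would drive any count negative raises ``ValueError`` (a malformed
    condensation).
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in _ISOTOPES:
                raise ValueError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementComposition":
        """Parse a Hill-notation molecular formula, e.g. ``C10H13N5O4``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementComposition(counts)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count "
                    f"({self.formula} - {other.formula})"
                )
            counts[el] = new
        return ElementComposition(counts)

    def __mul__(self, k: int) -> "ElementComposition":
        if not isinstance(k, int) or k < 0:
            raise ValueError("multiplier must be a non-negative integer")
        return ElementComposition({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    @property
    def formula(self) -> str:
        """Hill-notation formula (C first, H second, then alphabetical)."""
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in
                       ((el, self.counts[el]) for el in order))

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return sum(_ISOTOPES[el][0] * n for el, n in self.counts.items())


ADENOSINE = ElementComposition.from_formula("C10H13N5O4")
WATER = ElementComposition.from_formula("H2O")


@dataclass(frozen=True)
class Monomer:
    """A candidate aaRS substrate: anything with a carboxylate that can
    acylate the tRNA terminal ribose."""

    name: str
    composition: ElementComposition
    linkage: Linkage
    chirality_class: ChiralityClass
    n_alkylated: bool = False

    def __post_init__(self) -> None:
        if self.composition["C"] < 1 or self.composition["O"] < 2:
            raise ValueError(
                f"monomer {self.name!r} lacks a carboxylate "
                f"(needs >=1 C and >=2 O; got {self.composition.formula})"
            )


@dataclass(frozen=True)
class MassSpecies:
    """A generic quantification target (e.g. the Leu-Enk internal standard)."""

    name: str
    composition: ElementComposition

    @property
    def monoisotopic_mass(self) -> float:
        return self.composition.monoisotopic_mass

    @property
    def protonated_mz(self) -> float:
        return self.monoisotopic_mass + PROTON_MASS


#: Leucine-enkephalin (YGGFL), the spiked internal standard.
LEU_ENK = MassSpecies("Leu-Enk", ElementComposition.from_formula("C28H37N5O7"))


@dataclass(frozen=True)
class AcylAdenosineSpecies:
    """Adenosine carrying 0, 1 or 2 copies of one monomer.

    Diacyl species are homo-diacylated only (the same monomer on both the
    2'- and 3'-hydroxyl); mixed diacylation is not modelled.
    """

    monomer: Monomer | None
    acyl_count: int
    composition: ElementComposition

    @property
    def name(self) -> str:
        if self.acyl_count == 0:
            return "Ade"
        prefix = "di-" if self.acyl_count == 2 else ""
        return f"{prefix}{self.monomer.name}-Ade"

    @property
    def monoisotopic_mass(self) -> float:
        return self.composition.monoisotopic_mass

    @property
    def protonated_mz(self) -> float:
        return self.monoisotopic_mass + PROTON_MASS


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Aggregated isotopic distribution: relative abundance per nominal
    mass offset (M, M+1, ...), renormalized to sum to 1."""

    offsets: tuple[int, ...]
    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        if 0 not in self.offsets:
            raise ValueError("envelope must contain the offset-0 (monoisotopic) line")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("envelope abundances must sum to 1")

    def abundance_at(self, offset: int) -> float:
        try:
            return self.abundances[self.offsets.index(offset)]
        except ValueError:
            return 0.0

    @property
    def m1_over_m0(self) -> float:
        """The M+1/M intensity ratio used by the envelope check."""
        return self.abundance_at(1) / self.abundance_at(0)


def compose_species(monomer: Monomer | None, acyl_count: int) -> AcylAdenosineSpecies:
    """Build the RNase A cleavage product with ``acyl_count`` acyl groups.

    composition = adenosine + acyl_count * monomer - acyl_count * H2O.
    """
    if acyl_count not in (0, 1, 2):
        raise ValueError(f"acyl_count must be 0, 1 or 2; got {acyl_count}")
    if acyl_count > 0 and monomer is None:
        raise ValueError("monomer is required when acyl_count > 0")
    comp = ADENOSINE
    if acyl_count:
        comp = comp + acyl_count * monomer.composition - acyl_count * WATER
    return AcylAdenosineSpecies(monomer=monomer if acyl_count else None,
                                acyl_count=acyl_count, composition=comp)


def protonated_mz(species: AcylAdenosineSpecies | MassSpecies) -> float:
    """Monoisotopic [M+H]+ (z = 1) in Da."""
    return species.protonated_mz


def isotope_envelope(composition: ElementComposition, n_peaks: int = 4) -> IsotopeEnvelope:
    """Aggregated isotope envelope by convolution of per-element distributions.

    The distribution of each element raised to its count is obtained by
    repeated polynomial convolution; the product over elements gives the
    isotopologue abundance per nominal mass offset.  The result is
    truncated to the first ``n_peaks`` offsets and renormalized.
    """
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2")
    dist = np.array([1.0])
    for el, n in composition:
        base = np.zeros(max(off for off, _ in _ISOTOPES[el][1]) + 1)
        for off, ab in _ISOTOPES[el][1]:
            base[off] = ab
        # exponentiation by squaring keeps this fast for large H counts
        power = np.array([1.0])
        k = n
        while k:
            if k & 1:
                power = np.convolve(power, base)
            base = np.convolve(base, base)
            k >>= 1
        dist = np.convolve(dist, power)
    dist = dist[:n_peaks]
    dist = dist / dist.sum()
    return IsotopeEnvelope(offsets=tuple(range(len(dist))),
                           abundances=tuple(float(a) for a in dist))


def expected_isomer_count(species: AcylAdenosineSpecies | MassSpecies) -> tuple[int, int]:
    """(min, max) number of isobaric EIC peaks expected for a species.

    Free adenosine and diacyl species elute as a single peak.  Monoacyl
    species interconvert between the 2'- and 3'-regioisomers, giving up to
    two peaks; a prochiral monomer (a 2-benzylmalonate) additionally gains
    a stereocenter on acylation, so each regioisomer is a pair of
    diastereomers — up to four peaks.
    """
    if isinstance(species, MassSpecies):
        return (1, 1)
    if species.acyl_count == 0 or species.acyl_count == 2:
        return (1, 1)
    if species.monomer.chirality_class is ChiralityClass.PROCHIRAL:
        return (1, 4)
    return (1, 2)


def load_monomer_registry(
    path: str | Path | None = None,
) -> tuple[dict[str, Monomer], dict[str, MassSpecies]]:
    """Load the monomer registry TSV.

    Columns: name, formula, linkage, chirality_class, n_alkylated.  Rows
    with linkage ``internal_standard`` are returned separately as generic
    mass species.  With no ``path``, the packaged registry is used.
    """
    if path is None:
        text = resources.files("parti.data").joinpath("monomers.tsv").read_text()
    else:
        text = Path(path).read_text()
    monomers: dict[str, Monomer] = {}
    standards: dict[str, MassSpecies] = {}
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        comp = ElementComposition.from_formula(row["formula"])
        if row["linkage"] == "internal_standard":
            standards[row["name"]] = MassSpecies(row["name"], comp)
            continue
        monomers[row["name"]] = Monomer(
            name=row["name"],
            composition=comp,
            linkage=Linkage(row["linkage"]),
            chirality_class=ChiralityClass(row["chirality_class"]),
            n_alkylated=row.get("n_alkylated", "false").lower() == "true",
        )
    return monomers, standards


def default_registry() -> tuple[dict[str, Monomer], dict[str, MassSpecies]]:
    """The packaged registry: the assay's monomers plus Leu-Enk."""
    return load_monomer_registry(None)
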