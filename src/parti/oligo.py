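"""Design of biotinylated DNA capture oligonucleotides for a target tRNA.

A capture oligo is the DNA reverse complement of a contiguous span of the
tRNA (5'->3', 1-based inclusive coordinates on the tRNA).  Candidate
spans must avoid annotated modified-base positions — modifications such
as 4-thiouridine or 1-methylpseudouridine perturb hybridization — and
are ranked by closeness of their predicted melting temperature to an
established reference oligo.

Tm prediction uses the unified nearest-neighbor DNA/DNA parameter set
(SantaLucia 2004, Biopython's ``DNA_NN4`` table) with a monovalent-salt
correction.  DNA/DNA parameters are the standard proxy for the DNA:RNA
hybrid formed during capture; absolute temperatures therefore carry a
systematic offset, which is why ranking is relative to a reference oligo
scored with the same model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = ["TargetTRNA", "CaptureOligo", "reverse_complement_dna",
           "predict_tm", "design_capture_oligo"]

_RNA_TO_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "U": "A"}

#: Defaults for Tm evaluation: 50 mM monovalent salt, 250 nM oligo.
DEFAULT_SALT_M = 0.05
DEFAULT_OLIGO_CONC_M = 250e-9


@dataclass(frozen=True)
class TargetTRNA:
    """A tRNA sequence (RNA alphabet, 5'->3') with 1-based modified positions."""

    name: str
    sequence: str
    modified_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if not seq or set(seq) - set("ACGU"):
            raise ValueError("sequence must be nonempty RNA (ACGU)")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "modified_positions",
                           frozenset(self.modified_positions))
        if any(p < 1 or p > len(seq) for p in self.modified_positions):
            raise ValueError("modified positions must lie within the sequence")


@dataclass(frozen=True)
class CaptureOligo:
    """A biotinylated DNA oligo complementary to tRNA span [start, end]."""

    sequence: str
    target_span: tuple[int, int]     # 1-based inclusive on the tRNA
    biotin_end: str = "5prime"
    predicted_tm: float | None = None

    def __post_init__(self) -> None:
        if set(self.sequence.upper()) - set("ACGT"):
            raise ValueError("oligo must be DNA (ACGT)")
        start, end = self.target_span
        if end - start + 1 != len(self.sequence):
            raise ValueError("oligo length must equal span length")
        if self.biotin_end not in ("5prime", "3prime"):
            raise ValueError("biotin_end must be '5prime' or '3prime'")


def reverse_complement_dna(rna_span: str) -> str:
    """DNA reverse complement of an RNA segment, 5'->3' (A<->T via U->A)."""
    seq = rna_span.upper()
    try:
        return "".join(_RNA_TO_DNA_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGU character in RNA span: {exc.args[0]!r}") from exc


def predict_tm(
    dna_sequence: str,
    salt: float = DEFAULT_SALT_M,
    oligo_conc: float = DEFAULT_OLIGO_CONC_M,
) -> float:
    """Nearest-neighbor Tm (degC) of a DNA duplex.

    ``salt`` is the molar Na+-equivalent concentration; ``oligo_conc`` the
    molar single-strand concentration (non-self-complementary duplex).
    """
    seq = dna_sequence.upper()
    if len(seq) < 8:
        raise ValueError("sequence too short for nearest-neighbor Tm (need >= 8 nt)")
    if set(seq) - set("ACGT"):
        raise ValueError("non-ACGT character in DNA sequence")
    return float(_mt.Tm_NN(seq, nn_table=_mt.DNA_NN4, Na=salt * 1000.0,
                           dnac1=oligo_conc * 1e9, dnac2=0, saltcorr=5))


def design_capture_oligo(
    target: TargetTRNA,
    reference: CaptureOligo,
    length_range: tuple[int, int],
    tm_tolerance: float = 3.0,
    salt: float = DEFAULT_SALT_M,
    oligo_conc: float = DEFAULT_OLIGO_CONC_M,
) -> list[CaptureOligo]:
    """Enumerate all feasible spans and rank by |Tm - reference Tm|.

    A span is feasible when it lies within the tRNA, has a length in
    ``length_range`` (inclusive), and contains no modified position.
    Candidates within ``tm_tolerance`` degC of the reference Tm are
    returned ranked by Tm distance, ties broken by leftmost span; the
    ranking is a deterministic total order.  Raises when no span is
    feasible.
    """
    ref_tm = (reference.predicted_tm if reference.predicted_tm is not None
              else predict_tm(reference.sequence, salt, oligo_conc))
    n = len(target.sequence)
    lo_len, hi_len = length_range
    if lo_len < 8 or hi_len < lo_len:
        raise ValueError("invalid length_range (minimum usable length is 8)")
    candidates: list[tuple[float, int, CaptureOligo]] = []
    feasible = 0
    for length in range(lo_len, hi_len + 1):
        for start in range(1, n - length + 2):
            end = start + length - 1
            if any(start <= p <= end for p in target.modified_positions):
                continue
            feasible += 1
            span_rna = target.sequence[start - 1:end]
            seq = reverse_complement_dna(span_rna)
            tm = predict_tm(seq, salt, oligo_conc)
            if abs(tm - ref_tm) <= tm_tolerance:
                oligo = CaptureOligo(seq, (start, end), biotin_end="5prime",
                                     predicted_tm=tm)
                candidates.append((abs(tm - ref_tm), start, oligo))
    if feasible == 0:
        raise ValueError(
            "no feasible span: every window intersects a modified position"
        )
    candidates.sort(key=lambda c: (c[0], c[1], len(c[2].sequence)))
    return [c[2] for c in candidates]
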