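"""Exact [M+H]+ masses and isotope envelopes of acyl-adenosine species.

Builds each RNase A cleavage product from the monomer registry by the
condensation rule (adenosine + n x monomer - n x H2O) and prints the
monoisotopic [M+H]+ alongside the predicted M+1/M isotope ratio and the
expected number of isobaric chromatographic peaks.
"""

from parti import (
    compose_species,
    default_registry,
    expected_isomer_count,
    isotope_envelope,
)

monomers, standards = default_registry()

print(f"{'species':<22}{'[M+H]+ (Da)':>12}{'M+1/M':>8}{'peaks':>8}")
ade = compose_species(None, 0)
rows = [ade] + [compose_species(m, 1) for m in monomers.values()]
rows += [compose_species(monomers["R-b2-OH-BocK"], 2)]
for sp in rows:
    env = isotope_envelope(sp.composition)
    lo, hi = expected_isomer_count(sp)
    print(f"{sp.name:<22}{sp.protonated_mz:>12.4f}{env.m1_over_m0:>8.3f}"
          f"{f'{lo}-{hi}':>8}")
std = standards["Leu-Enk"]
print(f"{std.name + ' (standard)':<22}{std.protonated_mz:>12.4f}")

# The [M+H]+ column is what one extracts an EIC for; the M+1/M ratio is the
# envelope check a peak must pass; the peaks column is how many isobaric
# EIC peaks (2'/3' isomers, diastereomers) may legitimately appear.
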