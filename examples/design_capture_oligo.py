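"""Design a biotinylated DNA capture oligo for a toy tRNA target.

The target carries modified bases at positions 8 and 50 (the classic
4-thiouridine / 1-methylpseudouridine sites), which capture oligos must
avoid; candidates are ranked by closeness of their nearest-neighbor Tm
to an established reference oligo.
"""

from parti import CaptureOligo, TargetTRNA, design_capture_oligo, predict_tm

# a deterministic 72-nt pseudo-tRNA sequence
seq = "".join("ACGU"[(i * 7 + i // 3) % 4] for i in range(72))
target = TargetTRNA("toy-tRNA", seq, modified_positions=frozenset({8, 50}))

ref_seq = "AGCGTACCGTTAGCAACGTGGAT"
reference = CaptureOligo(ref_seq, (1, len(ref_seq)),
                         predicted_tm=predict_tm(ref_seq))
print(f"reference oligo Tm: {reference.predicted_tm:.1f} C")

oligos = design_capture_oligo(target, reference, length_range=(20, 26),
                              tm_tolerance=5.0)
print(f"{len(oligos)} candidates within 5 C of the reference; top 3:")
for o in oligos[:3]:
    print(f"  span {o.target_span}  Tm {o.predicted_tm:5.1f} C  "
          f"5'-biotin-{o.sequence}-3'")
# Each candidate is the exact DNA reverse complement of its tRNA span and
# skips both modified positions; smaller |dTm to reference| ranks first.
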