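"""Full workflow on a synthetic digest: simulate, confirm peaks, quantify.

Generates a ground-truthed run in which 40 % of the tRNA is acylated with
BocK and 10 % of the acyl signal fragments in-source to free adenosine,
then runs peak confirmation and reports A_norm values and the acylation
yield with and without fragmentation-artifact exclusion.
"""

from parti import (
    PipelineConfig,
    SampleMeta,
    compose_species,
    default_registry,
    process_sample,
    yield_ratio,
)
from parti.simulate import make_parti_fixture, simulate_run

monomers, standards = default_registry()
spec = make_parti_fixture("fragmentation", seed=7)[0]
run, truth = simulate_run(spec)
print(f"simulated {len(run.spectra)} scans; injected areas: "
      f"{ {k: round(truth.total(k)) for k in truth.isomer_areas} }")

ade = compose_species(None, 0)
bock_ade = compose_species(monomers["BocK"], 1)
res = process_sample(run, SampleMeta("demo", "1 mM BocK"),
                     [ade, bock_ade], standards["Leu-Enk"], PipelineConfig())

for name, peaks in res.peaks.items():
    for p in peaks:
        tag = " (fragmentation artifact)" if p.fragmentation_artifact else ""
        print(f"  {name:<10} apex {p.apex_rt:5.2f} min  area {p.area:9.1f}  "
              f"{p.mass_error_ppm:+5.2f} ppm  validated={p.validated}{tag}")

print("A_norm:", {k: round(v.a_norm, 4) for k, v in res.anorm.items()})

acyl = sum(p.area for p in res.peaks["BocK-Ade"] if p.validated)
ade_clean = sum(p.area for p in res.peaks["Ade"]
                if p.validated and not p.fragmentation_artifact)
ade_raw = sum(p.area for p in res.peaks["Ade"] if p.validated)
print(f"acylation yield, artifacts excluded: "
      f"{yield_ratio(acyl, ade_clean).percent_acylation:.1f} % (truth 40 %)")
print(f"acylation yield, artifacts included: "
      f"{yield_ratio(acyl, ade_raw).percent_acylation:.1f} % (biased low)")
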