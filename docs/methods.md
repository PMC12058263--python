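# Methods

This note documents the models, constants and design choices behind the
package, in the order data flows through it.

## Species chemistry

Every quantified species is built by composition algebra from three
inputs: adenosine C₁₀H₁₃N₅O₄, a monomer formula from the registry, and
the condensation rule

    composition(n-acyl adenosine) = adenosine + n·monomer − n·H₂O,  n ∈ {0, 1, 2}.

One water is lost per acyl bond regardless of linkage chemistry (amide
for α-amino acids, ester for hydroxy acids and malonates); the linkage
field affects isomer semantics and reporting only, never mass. Diacyl
species are homo-diacylated (the same monomer on the 2′- and 3′-OH) —
the only diacyl products the assay characterizes; mixed diacylation is
rejected rather than silently mis-modeled.

Monoisotopic masses are summed from hard-coded NIST/IUPAC principal-
isotope masses (≥6 decimal places; e.g. ¹H 1.00782503207, ¹²C 12 exactly,
⁷⁹Br 78.9183371) and [M+H]⁺ adds the proton mass 1.007276 Da. Only the
singly protonated adduct is modeled. Isotope envelopes are aggregated
distributions over nominal mass offsets, computed by per-element
polynomial convolution (exponentiation by squaring over atom counts),
truncated to 4 offsets (M…M+3) and renormalized — ample for species
under 800 Da, where M+4 and beyond is at noise level.

Expected isobaric peak multiplicities encode the assay's chromatographic
phenomenology: free adenosine and diacyl species elute as one peak;
monoacyl species transacylate between the 2′ and 3′ hydroxyls and give up
to two peaks; prochiral 2-benzylmalonates also gain a stereocenter on
acylation, so each regioisomer is a diastereomer pair — up to four peaks.
The bounds are (1, max): fewer peaks than the maximum is legitimate
(isomers can co-elute or sit below the noise floor), more is not.

## mzML I/O

Runs are centroided MS1 spectra with retention times in minutes. The
mzML 1.1 serializer/parser is self-contained (stdlib XML, uncompressed
little-endian 64-bit float arrays, standard PSI-MS CV terms); a test
cross-checks round-trips against Bioconductor's mzR to guard against
dialect drift. Profile-mode spectra are rejected with an explicit error:
centroiding is an instrument/vendor step, and quietly integrating profile
points as centroids would corrupt every downstream area.

## Peak confirmation workflow

1. **Discovery EIC**: per spectrum, sum centroid intensities within a
   symmetric 100 ppm window around the expected exact [M+H]⁺.
2. **Detection**: local maxima above a noise floor of 3× the median
   nonzero trace intensity (deterministic and scale-free). Peak bounds
   walk outward to the nearest flanking valley or the first point ≤1 % of
   apex; apexes closer than 2× the median scan interval merge (the more
   intense wins, ties to the earlier RT); areas are trapezoidal.
3. **Confirmation**: the observed apex m/z is the intensity-weighted mean
   centroid in the discovery window at the apex spectrum; a peak is
   validated when |mass error| < 5 ppm *and* the envelope score passes.
   The envelope check uses only M+1/M (higher offsets are near noise for
   these species): score 1 at exact agreement with the predicted ratio,
   0 at a ≥2-fold deviation, linear in fold-deviation between, threshold
   0.5. The apex-m/z estimator and the envelope tolerance are design
   choices of this package and are recorded in output metadata.
4. **Re-quantification**: validated peaks are re-integrated over a narrow
   ±25 ppm EIC centred on the observed monoisotopic centroid — wide
   enough for centroid jitter on an Orbitrap-class instrument, narrow
   enough to shed 100 ppm-window interferences. An empty narrow trace
   falls back to the discovery-window area with a warning.
5. **Fragmentation artifacts**: acyl-adenosines partially fragment to
   adenosine in the source, so free-Ade peaks whose RT bounds overlap a
   validated acyl peak are flagged and excluded from free-Ade
   quantification. Without the exclusion, percent-acylation estimates
   are biased low (the artifact inflates the "unacylated" signal); a
   regression test pins both behaviors.

## Quantification

    A_norm = (analyte area / standard area) × (V_a + V_s)/V_a × (V_a + V_leftover)/V_a

with the aliquot volume V_a = 20 µl and standard spike V_s = 2 µl kept
symbolic in a configuration record (defaults give the canonical 22/20
factor). The analyte area is the **sum** of all validated, non-artifact
isomer peaks of the species, never the maximum; an undetected species
reports A_norm exactly 0 (not missing); a missing internal standard
fails that sample hard while the rest of the batch continues.

Percent acylation has two estimators that agree when ionization is equal
and fragmentation is handled: the within-sample ratio
100·acyl/(acyl + Ade), and free-Ade depletion against a no-substrate
control, 100 − 100·(sample/control), clamped to [0, 100] with a warning.
Response factors (A_norm per % independently measured acylation) divide
out species-specific ionization efficiency so abundances of different
monomers can be compared. Intact-tRNA yields use the same ratio form on
deconvoluted major-ion areas; the deconvolution itself is out of scope.

Condition comparisons use Welch's *t*-test for two groups (group sizes
here are typically 2–5 with day-to-day variance differences, making the
unequal-variance form the safer default) and one-way ANOVA for more,
with ns / * / ** / *** at 0.05 / 0.01 / 0.001. Pairwise contrasts are
reported unadjusted and labeled as such.

## Synthetic runs

The generator emulates the structure of real digests: Gaussian
chromatographic profiles per isomer peak (default σ = 0.02 min), the
2′/3′ area split defaulting to 55:45 (configurable), isotope lines at
offsets M…M+3 spaced 1.0033548 Da, centroid m/z jitter (default 1 ppm,
clipped at 2 ppm), multiplicative log-normal intensity jitter (default
σ = 0.02, chosen so isolated-peak area recovery stays within the ±2 %
contract), three uniform noise centroids per scan below a 30-count
baseline, and in-source fragmentation that re-emits a set fraction of
every acyl peak as adenosine at the same RT. The acquisition defaults
mirror the assay: RT window 1.4–7.0 min, 0.01-min scan interval, m/z
100–3000.

Abundances are expressed on the **monoisotopic-ion scale**: the M line
of a peak integrates to `abundance × response_factor × isomer_fraction`,
and M+1…M+3 are added in envelope proportion on top. This makes the
ground truth directly comparable to what a monoisotopic EIC recovers,
so recovery, linearity and yield checks have exact targets. The
corresponding simplification is that "equal response factors" means
equal monoisotopic-ion yield; the small envelope-fraction differences
between species that exist in reality are absorbed into the response
factor rather than modeled separately.

Fixture scenarios (`no_substrate`, `phe_in_vitro` with a 74 % acylated
fraction, `enantiomer_panel` at 2.76 : 2.18 : 0.20 relative abundance,
`diacyl`, `metabolism` with a 1.5× ionization imbalance, `fragmentation`
at fraction 0.1, `dilution_series` over 100×) mirror the assay's
characteristic sample types. What passing tests on these runs shows is
that the *computational* workflow is unbiased and linear under its own
assumptions; they do not exercise real-data pathologies such as RT
drift, detector saturation, co-eluting isobars or ion-statistics noise,
all of which are explicit non-goals.

## Oligo design

Capture oligos are exact DNA reverse complements of tRNA spans (1-based
inclusive coordinates, 5′→3′ on the tRNA), 5′-biotinylated. Spans that
touch annotated modified-base positions are discarded; the rest are
ranked by |Tm − reference Tm|, ties to the leftmost span, a total order.
Tm uses the unified nearest-neighbor DNA/DNA parameter set
(SantaLucia & Hicks 2004; Biopython's `DNA_NN4`) with the entropic
monovalent-salt correction ΔS += 0.368·(N−1)·ln[Na⁺], at 50 mM Na⁺ and
250 nM oligo by default. DNA/DNA parameters stand proxy for the actual
DNA:RNA hybrid, as in standard design tools; absolute temperatures
therefore carry a systematic offset, which cancels in the ranking
because the reference is scored with the same model — output metadata
flags the proxy. Secondary-structure accessibility and transcriptome
cross-hybridization are out of scope.

## Determinism and numerics

All randomness flows from one integer seed per simulated run; identical
seeds give byte-identical mzML files. Pipeline outputs are TSV with a
config hash and package version on every row. Degenerate inputs have
defined behavior throughout: empty traces detect no peaks, all-zero
group comparisons report ns, subtraction below zero element counts and
negative volumes raise immediately. Test problem sizes are kept small —
simulated runs of a few hundred scans — which is ample to separate the
estimators' bias from their (percent-level) noise.
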