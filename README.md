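# triplexkit

Tools for identifying and validating **DNA:DNA:RNA triplex-forming long
non-coding RNAs**. A lncRNA can lie in the major groove of duplex DNA and
read the purine-rich strand through Hoogsteen or reverse-Hoogsteen hydrogen
bonds; such triplexes let a lncRNA act as a sequence-addressable adapter
that tethers chromatin regulators to specific loci. `triplexkit`
re-implements, as a tested and reusable pipeline, the computational side of
that kind of study: prioritizing triplex-associated lncRNAs from
Triplex-Seq peak statistics, predicting triplex-forming regions (TFRs) of
an RNA and their DNA target sites (TTSs) with a randomization null, the
qPCR statistics used for wet-lab validation (ΔΔCt, percent input, the
RNase-H resistance ratio), and biphasic melting-curve analysis as the
biophysical triplex signature — all exercisable on synthetic inputs with
known ground truth.

## What is inside

| module | role |
| --- | --- |
| `triplexkit.triplex` | Hoogsteen pairing codes (purine G·G:C / A·A:T / T·A:T, pyrimidine C·G:C / T·A:T, mixed), purine-tract discovery, and `find_tts`: all maximal gapless mismatch-bounded TFO↔duplex matches over both strands and orientations |
| `triplexkit.tfr` | chromosome-preserving region shuffling and `discover_tfrs`: empirical enrichment p-values `(r+1)/(n+1)` of RNA windows against re-scored shuffled region sets; cross-TFR TTS overlap |
| `triplexkit.screen` | Poisson peak enrichment (`p = P(X ≥ observed | λ = expected)`), two-cell-line intersection, and the stringency cascade (fold > 10, −log10 p > 20, nuclear/tissue expression, non-coding probability, overlapping-gene conflicts) |
| `triplexkit.qpcr` | ΔΔCt fold change `2^−ΔΔCt`, dilution-adjusted percent input, ±RNase-H recovery ratio |
| `triplexkit.melting` | the double-sigmoid melting model `f(x) = a/(1+e^{−(x−x0)/b}) + c/(1+e^{−(x−x2)/d})`, grid-initialized least-squares fitting, Tm extraction, and AICc-based mono/biphasic classification |
| `triplexkit.synthetic` | seeded generators for every input (genomes with planted TTSs, lncRNAs with planted TFRs, Poisson peak tables, Ct tables, model melting curves) plus the ground-truth manifest |
| `triplexkit.sequences` | the oligonucleotide constructs used in EMSA/CD/NMR characterization of the HIF1α-AS1 TFR2 triplexes (TFO2-23, the EPHA2/ADM target duplexes and hairpins) and their published melting transitions |
| `triplexkit.io`, `triplexkit.pipeline`, `triplexkit.cli` | FASTA/BED/TSV/CSV I/O (0-based half-open), the seeded end-to-end run with a checksummed manifest, and the `triplexkit` command line |

## Worked example

The 23-nt TFR2 third strand of the lncRNA *HIF1α-AS1* against its EPHA2
intron-1 target duplex, followed by classification of a simulated melting
curve at the published triplex transitions (49.52 °C Hoogsteen release,
~70 °C broad duplex melt, noise σ = 0.02):

```python
import triplexkit as tk
from triplexkit import sequences as sq

for h in tk.find_tts(sq.TFO2_23, sq.EPHA2_GA):
    print(f"{h.motif:>20s}  RNA {h.tfo_start}-{h.tfo_end}  "
          f"DNA {h.chrom}:{h.start}-{h.end}({h.strand})  "
          f"len {h.length}  mismatches {h.mismatches}  score {h.score}")

curve = tk.make_melting_curve(x0=49.52, x2=70.0, noise_sd=0.02, seed=0,
                              curve_id="EPHA2:TFR2_triplex")
call = tk.classify_transition(curve)
fit = call.best
print(f"{call.curve_id}: {call.model}, Tm1 = {fit.tm1:.2f} C, "
      f"Tm2 = {fit.tm2:.2f} C (delta-AICc = {call.delta_aicc:.0f})")
```

prints

```
 antiparallel_purine  RNA 6-21  DNA EPHA2_GA:5-20(+)  len 15  mismatches 3  score 12
EPHA2:TFR2_triplex: biphasic, Tm1 = 49.53 C, Tm2 = 69.99 C (delta-AICc = 278)
```

The search finds a 15-nt reverse-Hoogsteen (antiparallel purine-motif)
core match — TFO positions 6–21 against the GA-rich strand, 12 of 15
positions paired — rather than the full 23-mer, because the TFO's two
cytosines cannot pair in the purine motif. The melting fit recovers both
generating midpoints to 0.01–0.02 °C and the AICc margin calls the curve
biphasic, the diagnostic signature of a triplex (Hoogsteen strands release
below the Watson-Crick melt).

A full synthetic run — simulate → screen → scan → enrich → qpcr →
melt-fit, with a manifest of SHA-256 checksums — is:

```sh
triplexkit -v run-all --seed 11 --out-dir demo_run
```

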