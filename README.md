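# dnamod

Desk-scale analysis of N4-methylcytosine (4mC) and N6-methyladenine (6mA)
DNA methylomes: single-base modification calling from single-molecule
sequencing kinetics, antibody-enrichment (DIP/ChIP) peak calling, and the
feature-association and sequence-context statistics that connect the marks
to transposable elements (TEs), chromatin state and gene expression. A
built-in simulator generates an annotated genome with a planted methylome
and matching kinetic/read observations, so every stage is testable against
a known truth without downloading data.

The package is written for researchers studying feature-targeted DNA
methylation — in particular the bdelloid-rotifer-like situation where 4mC,
deposited by a bacterial-origin N4-cytosine methyltransferase, marks
intact TE copies and tandem repeats on one strand at CpG/CpA contexts,
while 6mA sits at GA-context adenines with a broader methylation-level
distribution.

## The statistics at the core

* **Kinetic calling.** At each site the IPD ratio is
  `mean(native IPD) / mean(control IPD)`; the modification score is
  Phred-scaled one-sided evidence that native log-IPDs exceed the control,
  `mQv = −10·log₁₀ p` (exact t-test under the log-normal kinetic model).
  Calls require coverage ≥ 10×, mQv ≥ 22 and IPD ratio > 1; primary calls
  require 20×. The per-site methylation fraction is the share of passes
  classified to the modified kinetic component, binned into low
  [0.1, 0.5), moderate [0.5, 0.8) and high [0.8, 1] classes.
* **Peak calling.** A global-Poisson caller ("no model, no local lambda"):
  per-bin counts of overlapping extended reads vs the genome-wide rate,
  p < 1e−5, merged across ≤ 300-bp gaps, summit at the maximal bin.
  Tracks support RPGC (1× genome coverage) normalization and IP/input
  log2 ratios.
* **Association.** Occupancy profiles and 0–100 % body metaprofiles,
  normalized density `(sites/annotations)/genome-fraction`, ±window
  peak–feature intersection, bp-Jaccard and nearest-distance spatial
  correlation with relocation permutation nulls, TE-integrity
  stratification (full/medium/short), DIP×ChIP co-localization, strand
  symmetry, observed/expected CpG, RPKM with Student's t / ANOVA+Tukey
  group tests.
* **Sequence context.** Strand-aware ±5/10/20-bp windows, doublet/triplet
  composition, exhaustive k-mer enrichment by one-sided Fisher's exact
  test with Benjamini–Hochberg correction against a matched genomic
  background.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

Run the full pipeline (simulate → call → peaks → associate → motifs) on
the default 200-kb synthetic genome:

```python
from dnamod import SimConfig, RunConfig, run_pipeline

report = run_pipeline(RunConfig(sim=SimConfig(seed=11), outdir="run"))
print(report["summary"]["calls_per_mark"])
print(report["summary"]["peak_counts"])
```

which prints

```
{'4mC': 1822, '6mA': 1175}
{'dip4mC': 20, 'dip6mA': 28, 'H3K4me3': 19, 'H3K9me3': 56, 'H3K27me3': 54}
```

— 1,822 4mC and 1,175 6mA sites called from the simulated kinetics, and
the enrichment peaks found per assay. The run directory holds the genome
(FASTA), annotations (GFF3), truth methylome, kinetics, read sets (BED6),
calls (TSV + GFF3), peaks (narrowPeak), log2-ratio tracks (bedGraph), the
association tables and `report.json` with parameter echo and per-artifact
checksums. Highlights from this run's tables:

```
normalized 4mC density   genes 14.9   TE 137.4   TR 6181.9
4mC fractions            mean 0.85, high:low ratio 40.5
6mA fractions            mean 0.69, high:low ratio 2.9
top 4mC doublets         CG 0.44, CA 0.38
strand symmetry          4mC 0.086, 6mA 0.099
```

i.e. 4mC density is ~9× higher over TEs than genes and extreme in tandem
repeats, 4mC is dominated by high-fraction sites at CpG/CpA doublets, and
~90 % of modified positions are methylated on one strand only — the
structure the simulator plants and the analyses are designed to detect.

The same stages are available from the shell:

```sh
dnamod write-config config.yaml --seed 11
dnamod run -c config.yaml -o run
dnamod validate --fasta run/genome.fasta --gff3 run/annotations.gff3
```

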