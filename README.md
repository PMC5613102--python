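# vlcfa

Quantitative analysis of very long-chain fatty-acid (VLC-FA) elongation
experiments, built for functional characterization of Elovl-family
elongases (Elovl4 in particular) in heterologous yeast expression, with
companion tools for tissue-expression qPCR and sequence diagnostics.

When an elongase ORF is expressed in *Saccharomyces cerevisiae* and the
culture is supplemented with a PUFA substrate, the enzyme drives an
elongation cascade — repeated +2C condensations producing, say,
22:5n-3 → 24:5n-3 → … → 36:5n-3 — quantified by GC as FAME peak areas.
The package computes the field's step-wise conversion statistic for
each cascade step k (substrate redefined at every step):

```
conversion_k = 100 · Σ_{i≥k} area_i / (area_{k−1} + Σ_{i≥k} area_i)
```

together with: VLC-SFA profile comparison (area % of saturates ≥ C24,
one-way ANOVA + Tukey HSD + compact letter display), absolute qPCR
quantification (plasmid copy numbers via 660 g·mol⁻¹·bp⁻¹, standard
curves of Cq on log10 copies, reference-gene normalization, per-tissue
mean ± SE with letters), Elovl motif scanning (histidine box HXXHH,
C-terminal ER retrieval signal RXKXX, conserved blocks) on deduced
proteins, and synthetic-data generators with known ground truth for
every stage.

Intended users: lipid biochemists and fish-nutrition labs analysing
elongase assays, and anyone needing a tested reference implementation
of the conversion statistic.

## Worked example

```python
from vlcfa import parse_fa, build_cascade, stepwise_conversions, PeakTable

cascade = build_cascade(parse_fa("18:4n-3"), max_carbons=22)
areas = dict(zip(cascade.members, [60.0, 30.0, 10.0]))
for step in stepwise_conversions(PeakTable("yeast1", "elovl4a", areas), cascade):
    print(step.label, "ND" if step.not_detected else round(step.conversion, 1))
```

prints

```
C18 → 20 40.0
C20 → 22 25.0
```

— of the 100 area units in the C18 pool, 40 units (the 30 + 10 at C20
and beyond) were elongated at least once, hence 40.0% at step 1; of the
40 units reaching C20, the 10 at C22 moved on, hence 25.0% at step 2.

The same stage from the shell, on a peak-table CSV
(`sample_id,treatment,fatty_acid,area`):

```
vlcfa convert --peaks peaks.csv --substrate 18:4n-3 --max-c 36
vlcfa sfa-compare --peaks sfa_peaks.csv
vlcfa qpcr --measurements meas.csv --dilutions dil.csv --target elovl4a
vlcfa motifs --fasta proteins.fa
vlcfa simulate cascade --substrate 18:4n-3 --fractions 0.5,0.25 --seed 7
```

## Analysis pipeline

The `analysis/` drivers re-create the full study on synthetic data
generated from the published summary tables (under `analysis/inputs/`)
and write their tables to `results/`:

```
python analysis/01_simulate_data.py --seed 1   # cascades, SFA replicates, qPCR panel
python analysis/02_stepwise_conversions.py     # conversion tables per substrate
python analysis/03_vlc_sfa_comparison.py       # control vs transgenic saturates
python analysis/04_qpcr_expression.py          # tissue expression, mean ± SE + letters
python analysis/05_motif_scan.py --seed 1      # synthetic ORFs, motif hits
```

With seed 1, step 02 reports a mean recovery error of 0.82 percentage
points across 77 interior cascade steps, step 03 flags 26:0–32:0 as
significantly different between control and *elovl4a* yeast, and step
04 recovers the pituitary-high / liver-low expression ranking with
per-tissue means within a few percent of the simulated truth.

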