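# Methods

## Scope and model of the data

`vlcfa` implements the quantitative layer of an elongase (Elovl4)
functional-characterization workflow. The pipeline starts from
*integrated* GC peak areas of fatty acid methyl esters (FAME) — peak
detection, identification and integration are upstream and out of
scope — and from qPCR Cq tables plus plasmid dilution series. Sequences
enter as FASTA.

## Fatty-acid model

Fatty acids are held as (carbons, double bonds, n-series) triples in the
standard shorthand (`22:5n-3`, `24:0`). The accepted input dialects are
`22:5n-3`, `22:5 n-3` and `22:5(n-3)`; canonical output is `22:5n-3`.
The valid grid is even carbon counts 12–40 with 0–6 double bonds; the
assays analysed here span C18–C36, and the extra headroom simply avoids
hard-coding one study. n-9 is admitted for generality although no
cascade here uses it. Double-bond positions beyond the series, geometric
isomers and odd/branched chains are out of scope.

An elongation cascade is the +2C chain substrate → +2 → +4 → … with
double bonds and series constant. The default ceiling is C36 (the
longest product class observed with the C18–C22 PUFA substrates); the
22:6n-3 assay is reported only to C32, so the ceiling is configurable
per substrate and treated as observed-data-driven rather than
mechanistic.

## The step-wise conversion statistic

For cascade members with areas a_0 … a_K (a_0 the supplemented
substrate), step k has substrate a_{k−1} and

conversion_k = 100 · Σ_{i≥k} a_i / (a_{k−1} + Σ_{i≥k} a_i),

i.e. the fraction of the step's substrate pool elongated to the
immediate product *or beyond*, with the substrate redefined at each
step. The statistic is dimensionless and invariant to uniform rescaling
of areas. Edge semantics: if the substrate and the entire downstream
tail are undetected the step is *not detected* (N.D.); if the substrate
alone is undetected but product exists downstream, conversion is 100.
This is how 100-rows and N.D.-rows coexist in one cascade. A detection
limit (LOD, default 0) zeroes areas below threshold before the
statistic; integration thresholds are instrument-specific, hence
configurable. No control subtraction is applied — conversions are
computed on raw areas, and detecting a cascade product in a control
sample is a warning, not a correction. Whether replicate cultures are
averaged before or after the statistic is not determined by a printed
single-value table; the package computes per sample and reports means
across samples when replicates exist.

Floating-point note: the ratio is computed before scaling by 100 and
clamped at 100 to absorb one-ulp overshoot when the substrate area is
exactly zero.

## VLC-SFA profiles and group statistics

Saturates at or above a carbon threshold (default C24) are expressed as
percentages of the qualifying pool, so every profile sums to 100; this
makes profiles comparable across cultures with different total lipid
yield. (Published summary tables sometimes normalize to *all* saturates
instead, so absolute percentages are not directly comparable — the
ranking and the control-vs-transgenic contrasts are.) Group comparison
runs per fatty acid on the percentages (no transformation): one-way
ANOVA (`scipy.stats.f_oneway`), Tukey HSD
(`statsmodels pairwise_tukeyhsd`), and a compact letter display via the
insert-and-absorb algorithm (start with one letter column holding all
groups; for each significant pair, split every column containing both;
absorb columns that became subsets). Letters are ordered by descending
group mean — purely presentational. The display satisfies, by
construction: two groups share a letter iff their Tukey p > α. With
zero within-group variance everywhere the comparison degenerates; all
pairs are declared equal.

## Absolute qPCR quantification

Plasmid standards: copies = mass / (660 g · mol⁻¹ · bp⁻¹ × length) ×
N_A, with N_A fixed at 6.02214076 × 10²³. The standard curve is an
ordinary least-squares fit of Cq on log10(copies), at least three
distinct dilution points, fit per gene (cross-gene curves are
rejected); amplification efficiency is 10^(−1/slope) − 1 and a valid
assay has slope < 0. Unknowns invert the line: copies =
10^((Cq − intercept)/slope). Duplicate reactions are averaged on the Cq
scale by default (the geometric mean on the copy scale); averaging on
the copy scale is available, as neither convention is universal.
Expression is normalized as absolute target copies over absolute
reference copies (28S rRNA) in the same sample, so constant factors
such as the 1/20 cDNA dilution cancel; copies are per reaction, not per
µg RNA. No-template controls are never quantified. Tissue summaries
report mean ± SE (SE = sd/√n) over fish with the same ANOVA/Tukey/
letters machinery; tissue-only pooling is the default grouping, with
sex kept as metadata.

## Sequence motifs

ORFs are validated strictly (ATG start, terminal stop, no internal
stops, triplet length — each its own error class) and translated with
the standard code, excluding the stop: a 945 bp ORF gives 314 residues,
915 bp gives 304. Codons containing N translate to X with a warning so
ambiguity never silently changes coordinates. A convenience
longest-ATG-to-stop search extracts the ORF from full-length cDNA. Motif
patterns use the 20 amino-acid letters plus the wildcard X only (no
bracket classes — the diagnostic Elovl motifs need none): the histidine
box HXXHH, conserved blocks KXXEXXDT, QXXFLHXXHH, NXXXHXXMYXYY,
TXXQXXQ, and the C-terminal di-basic ER retrieval signal RXKXX
(R at −5, K at −3). Scanning reports all, possibly overlapping, matches
at 1-based inclusive coordinates. Hits are reported without
classification — the motif set is diagnostic, not a definition of
family membership.

## Synthetic data: what it emulates and what it does not

The cascade generator uses a sequential irreversible partition: a
fraction e_k ∈ [0, 1) of the material reaching node k−1 moves on, so
terminal amounts are A0 · Π_{j≤k} e_j · (1 − e_{k+1}) and sum to A0.
End-point areas after a fixed culture period identify only this
terminal partitioning, not kinetics, so no ODE model is attempted; the
conversion statistic recovers 100·e_k exactly in the noiseless case
(the recovery theorem, tested over randomized fraction vectors at
cascade lengths 2–10). Areas get multiplicative lognormal noise
(positive, constant-CV, as chromatographic areas behave) and LOD
censoring. Censoring can only push a step to N.D., to 100 (substrate
censored away) or monotonically downward — it cannot inflate a
conversion. The qPCR generator produces exact dilution points and
Gaussian-noise sample Cq values in duplicate. The generators do *not*
emulate desaturation, β-oxidation/chain shortening, substrate
competition between cascades, chain-length-dependent FAME response
factors, or yeast growth dynamics — so green tests certify the
statistics pipeline, not those biological complications.

## Validation studies and problem sizes

`vlcfa.studies` packages the correctness experiments the test suite and
the reproduction script run: 500 random fraction vectors for the exact
recovery theorem (tolerance 1e-10 pp); 200 noisy tables at σ = 0.05 on
an 8-step cascade with per-step mean |error| < 2 pp; the noiseless qPCR
round trip (relative error ≤ 1e-6); 500 noisy qPCR replicates
(Cq sd 0.2, 4 fish per tissue) requiring recovered tissue means within
3 SE of truth ≥ 95% of the time, where SE is the *true* sampling
standard error of the mean under the generative model (with n = 4 the
sample-SE version is a t₃ statistic whose 3-SE coverage is ~94%, which
would measure small-sample SE behaviour rather than pipeline bias);
100 random datasets for letter/Tukey agreement; 1000 random proteins
against a regex-lookahead scanning oracle. These sizes keep the full
suite around half a minute on one CPU while leaving Monte-Carlo margins
far from the asserted bounds.

## Analysis drivers

`analysis/01–05` re-create the study conditions from the published
summary tables used as inputs: reported step conversions become true
step fractions (printed 100s as 0.98 — a step fraction must stay below
1 — and N.D. as 0), reported saturate means become generator baselines
and boost factors, and the tissue panel echoes the reported expression
ranking (pituitary/brain highest for one paralog, female gonad/
pituitary for the other, liver lowest). Each driver prints what it
found and writes TSV/JSON under `results/`, embedding a configuration
hash and seed so identical configurations reproduce byte-identical
outputs.
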