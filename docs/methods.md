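# Methods

## Subtraction statistic

The unit of evidence is the 25-mer (configurable `k`), encoded 2 bits per
base with A=0, C=1, G=2, T=3 so numeric order equals lexicographic order.
U is read as T, so RNA- and DNA-alphabet inputs unify. Windows containing
any other symbol are skipped whole rather than expanded — the behavior of
standard k-mer counters, and it avoids inflating counts from ambiguity
codes. Counting is stranded by default: candidates are later matched to
stranded transcript sequences, and collapsing a word with its reverse
complement would create false transcript joins. A `canonical` option exists
for interoperability with canonically-counted dumps.

Per sample, words seen fewer than `min_count = 10` times are discarded
("less than" is strict: a count of exactly 10 survives). Sequencing effort
`total_bp` is the sum of read lengths — the only computable interpretation
when reads are the input — unless a sample sheet supplies an override.
Abundance is count × 10⁹ / total_bp (counts per billion bp).

Imputation happens at the raw-count level, before normalization: a k-mer
missing from a tumor catalog enters as 0, missing from a normal catalog as
the 10-count floor, and only then is each column normalized by its own
total_bp. The normal-side floor therefore equals 10 × 10⁹ / total_bp for
that sample. K-mers absent from every catalog are never materialized. This
ordering follows from the floor being defined on counts; it also guarantees
every per-tissue denominator is positive, so all ratios are finite.

The per-tissue ratio is min-over-tumor / max-over-that-tissue's-normals of
abundance — a worst-case statistic on both sides. Over-abundance is a
strict `ratio > 500` per tissue; target calls downstream use a strict
`ratio > 10,000`. Files keep full precision; a display helper truncates
toward zero at two decimals to match conventional reporting (0.16896 →
0.16).

Candidate retention requires over-abundance in at least one tissue; breadth
(the number of flagged tissues) is rewarded at ranking time rather than
gating retention. Candidates sort by flagged-tissue count descending, then
k-mer code ascending, making output independent of sample order.

## Transcript scoring and targets

The transcriptome index records every valid k-window of every transcript
with its 0-based offset (1-based appears only in human-facing reports). A
k-mer occurring in several transcripts credits each of them; splice
variants are deliberately not collapsed. Per transcript, the selected k-mer
maximizes (1) flagged-tissue count, (2) the minimum per-tissue ratio, (3)
— for exact ties — the smaller k-mer code. The tie-break favors uniformly
extreme k-mers and makes the ranking a total, deterministic order; ranking
sorts by breadth, then minimum selected-k-mer ratio, then transcript id,
truncated to `top_n = 400`. The heat-map export is the selected-k-mer ratio
per (ranked transcript × tissue), with an optional log10(1 + ratio)
rendering. Antisense design is the reverse complement of the chosen window
(an involution); oligo lengths outside 15–30 nt warn but are permitted.

## Dose-response models

Fraction affected: FA = (control − treated)/control against the mean
untreated-control signal of the same plate; negative values are meaningful
(growth stimulation) and preserved. Scramble adjustment is subtractive
(FA_treatment − mean FA_scramble), which is why adjusted values can go
negative.

Linear sensitivity regresses FA × 100 (%) on dose in nM — linear dose, not
log dose, because the sensitivity unit is "% dead cells per nM" and the
implied EC₅₀ = 50/|slope| nM is then exact by construction. The
slope-implied EC₅₀ ignores the intercept and uses |slope|; non-positive
slopes are flagged non-cytotoxic rather than erroring, since screening
tables routinely carry such rows. Saturated points (FA ≥ 1) are off the
linear regime and should be excluded by the caller; the acceptance script
does so.

The median-effect fit is OLS of log10(fa/(1−fa)) on log10(D); m is the
slope and Dm = 10^(−intercept/m). Points with FA outside the open unit
interval have no logit and are excluded with a reported count; at least two
usable points are required. Noise-free data generated from any (m, Dm) are
recovered to machine precision because the transform linearizes exactly.
The iso-effective dose is Dx = Dm·(fa/(1−fa))^(1/m), strictly increasing in
fa with Dx(0.5) = Dm.

The combination index for an n-component fixed-ratio mixture (fractions
summing to 1 within 10⁻⁶) at effect level fa is Σ fᵢ·D_combo(fa)/Dᵢ(fa),
where the mixture is dosed by total concentration. A sham self-combination
gives CI = 1 identically — the internal consistency anchor. Pairwise tables
evaluate CI at fa = 0.5 (ED₅₀) by default. Classification uses an additive
band of [0.9, 1.1]: an exact-equality "additive" call would be vacuous in
floating point, and published practice labels CI values like 1.10 additive.
Consensus across cell lines is the shared label when all lines agree,
"discordant" otherwise. CI is positive by definition; "synergy" means CI
well below one, not below zero.

## Synthetic data

The cohort simulator emulates a multi-tissue normal reference (default 26
tissues, 6–26 samples each) against a small tumor cell-line set (default
3), with 100 bp single-end reads. Shared transcripts draw independent
lognormal(0, 1) expression weights per sample — a standard heavy-tailed
stand-in; the generator makes no claim about covariance structure across
samples. Planted transcripts have weight exactly 0 in every normal sample
and weight `tumor_fold_excess` (default 1000, relative to the unit median
shared weight) in tumor samples. Reads are drawn from transcripts
proportionally to weight with uniform starts and i.i.d. substitution
errors (default 0.1%; no indels — substitutions suffice to exercise the
min-count threshold's noise suppression). All outputs are deterministic
functions of the seed.

Depth defaults are desk-scale, chosen from the arithmetic of the
imputation floor: for a k-mer absent from all normals, the ratio is
(tumor count / 10) × (normal bp / tumor bp), which grows with
normal-sample depth and is independent of tumor depth. The default
60,000-read normal samples put planted-k-mer ratios at O(10²–10³) —
comfortably past the 500:1 filter — while 10,000-read tumor samples keep
planted counts far above the 10-count threshold. Reaching 10,000:1 ratios
would require ~100× deeper normals, so desk-scale target selection is
demonstrated at the 500:1 threshold via configuration. Two presets exist:
`toy_config()` (24 transcripts, 10 tissues, 2 samples per tissue) sized for
the test suite, and the full 26-tissue default structure.

What passing tests on this generator do **not** show: robustness to
alignment-free confounders in real data — shared k-mers between paralogs,
expression covariance across tissues, coverage bias, indels and quality
artifacts, or catalog scales of 10⁹ k-mers (the in-memory design targets
~10⁶–10⁷ distinct k-mers).

The plate simulator draws fluorescence as control × (1 − FA_true) ×
(1 + N(0, noise_sd)) from the median-effect model, with untreated wells
and scramble wells at a small true FA (default 0.02). Its round trip
through `summarize_plate` → `median_effect_fit` is exact at zero noise and
recovers Dm within 5% in the median at 5% noise with 6 replicates.

## Numerical and design notes

- All thresholds are strict inequalities (counts "< 10" dropped, ratios
  "> 500" and "> 10,000" flagged).
- k-mer codes use int64; k ≤ 31 fits without overflow.
- Window extraction is a vectorized shift-or scan; counting uses a single
  sort-based unique per sample.
- The Jellyfish-dump reader accepts both the column (`KMER COUNT`) and
  FASTA (`>COUNT`) dialects, never mixed, with line-numbered errors.
- Catalog TSVs serialize k-mers in lexicographic order, so round trips are
  byte-identical.
- The CLI's run configuration is a flat `key=value` file with flag
  overrides; every run embeds the resolved configuration in its summary
  JSON, and the funnel log reports k-mer counts at each stage so successive
  stages are provably non-increasing.

## Limitations

- No disk-backed counting: the full-scale catalogs of real studies exceed
  the in-memory design.
- Transcript assignment is exact substring matching; no alignment, fusion
  breakpoints, or GTF-aware gene models (an optional id→gene TSV covers
  gene labels).
- Dose-response fitting is intentionally minimal (no four-parameter
  logistic, no Bliss independence); non-constant-ratio combinations are
  out of scope — the fixed-ratio formulation is the implemented one.
- ANOVA/t-test layers of assay analysis are routine statistics left to
  general-purpose tools.
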