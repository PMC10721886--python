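# Methods

## Data model

A `ProteinTable` holds one row per protein group with per-sample
linear-scale LFQ and iBAQ intensities; zero encodes "not quantified". A
`SampleDesign` maps samples to groups and assigns the two control roles of
an enrichment experiment: *background* (untagged ubiquitin — anything
recovered binds the resin nonspecifically) and *blocked* (E1 enzyme
inhibited — no de novo conjugation, so recovery reflects pre-existing or
nonspecific signal). A `LogMatrix` carries log2 values plus a per-cell
provenance mask (`observed` / `missing` / `imputed`), so imputation status
survives writing and re-reading.

Decoy ("Reverse"), contaminant, and "only identified by site" rows are
flagged at parse time and removed by default before quantification; each
flag class can be retained via `remove_flagged` arguments. Site-only
removal is a convention choice, not derivable from the input format; we
remove them because their quantification rests on modified peptides only.

## Preprocessing

Intensities are log2-transformed (zeros become missing). The presence
filter keeps a protein if it is observed in at least
`ceil(min_valid_fraction · n_g)` replicates of some group; the default
fraction of 1.0 demands complete observation in at least one group, and
only *observed* (never imputed) cells satisfy presence. Remaining missing
cells are replaced by independent draws from
`Normal(μ − downshift·σ, (width·σ)²)` with μ, σ the mean and SD of **all**
observed log2 values (a global detection limit; defaults downshift 1.8,
width 0.3). A per-column variant is available behind
`AnalysisConfig(impute_mode="per_column")` for sensitivity analysis.
Imputation happens once on the full filtered matrix; every downstream
contrast reuses the same imputed values, so contrasts are consistent with
each other. Observed cells are returned bit-identically. σ = 0 (a
degenerate matrix) is a hard error.

## Moderated statistic and permutation FDR

The two-sample statistic is the SAM-style construction
`d = (mean(A) − mean(B)) / (s + s0)` with the pooled standard error
`s = sqrt((1/nA + 1/nB)·SS_pooled/(nA + nB − 2))` and `s0 ≥ 0` (default
0.1). At `s0 = 0`, `d` is the equal-variance Student t statistic; at zero
within-group variance it degrades gracefully to `diff / s0`.

The null is built from relabellings of the samples that respect group
sizes. When the number of distinct relabellings is at most `n_perm`
(default 2500) all are enumerated exactly once, identity included — a 4 vs 4
design therefore uses all 70, and results are invariant to the requested
count. Otherwise `n_perm` distinct non-identity relabellings are sampled
uniformly without replacement. For a threshold `t` over the ranking
statistic (|d| two-tailed, signed d one-tailed), the estimated FDR is

```
FDR(t) = min(1, mean over relabellings of #{permuted stats ≥ t} / #{observed stats ≥ t})
```

with the mean (not median) permuted exceedance count, ties in the statistic
sharing one threshold, and no null-proportion (π₀) rescaling — deliberately
conservative and exactly reproducible. A protein's q-value is the smallest
`FDR(t)` over the thresholds at which it would be called (`t ≤` its own
statistic), enforced as a running minimum from the least extreme threshold;
q is therefore monotone non-decreasing as |d| decreases, and `significant`
means `q ≤ fdr` (default 0.05). Per-protein `p_perm` is the fraction of the
protein's own permuted statistics at or beyond its observed one.

A consequence of enumerating the identity (and, two-tailed, its
complement) is a quantised q floor of 2/70 ≈ 0.029 for a lone extreme
protein in a 4 vs 4 design; individual moderate effects can land at
3–4/70 > 0.05 even when they rank first. This is the honest behaviour of
the estimator, not a defect, and the FDR-control simulations confirm the
declared level is met on average.

### Double-control gate and contrasts

For each target group, one-tailed (`greater`) tests against the background
and blocked controls are combined: a protein is *gated* when `q ≤ fdr` with
a positive difference against **both** controls. A protein gated in at
least one target group counts as a ubiquitylation target overall
(`gate_scope="any"`, the default; `"all"` requires every target group —
the stricter reading of an ambiguous convention). Condition contrasts are
two-tailed tests between two target groups, returning volcano coordinates
(`diff`, `−log10 p_perm` clipped at one pooled-count unit) and
enriched/depleted labels.

## QC and clustering

Pairwise Pearson correlations use jointly observed cells only (≥ 3 rows
required, else undefined), so they reflect measured, not imputed, signal.
CVs are computed per protein and group on linear-scale intensities — CV% of
log values is not meaningful — and summarized as group medians. PCA scores
come from an SVD of the protein-centred samples × proteins matrix restricted
to complete rows. Enrichment efficiency is the percent of summed peptide
intensity carried by peptides whose protein assignment intersects the
ubiquitin accession set; the set is configuration (by default derived from
ubiquitin precursor gene names ubb/ubc/uba52/rps27a), since accessions are
database-specific. iBAQ summaries report the median log10 of per-protein
mean positive iBAQ and the max/min dynamic range.

A protein is **robustly changing** across selected groups when, relative to
its median over all selected samples, every replicate of some group lies
strictly above and every replicate of another strictly below; ties count as
neither. The rule depends only on ranks, so it is invariant to strictly
increasing transforms of a row. The robust set is row-Z-scored and
clustered agglomeratively (Euclidean distance, average linkage — the
defaults of mainstream analysis tools, configurable); rows are pre-sorted
lexicographically by identifier so leaf order is deterministic under
distance ties, and zero-variance rows are excluded with a warning.

## Degron scanning

Patterns use a PROSITE-like syntax; two ship as built-ins: the canonical
β-TrCP degron `[DES]-[SDE]-G-x-x-[SED]` and the DDR-responsive variant
`[DEST]-[DES]-G-x(2)-[ST]-Q`. Every window is tested, so overlapping
matches are all reported; coordinates are 1-based inclusive (UniProt
residue numbering). Ambiguous residues (X, U, B, Z) satisfy only wildcard
positions. For S/T-Q-anchored motifs the phosphoacceptor position
(`end − 1`) is recorded and joined exactly against phosphosite annotation
tables (`accession`, `position`, optional `kinase`).

## Synthetic data

The generator emulates the study design the statistics were built for:
five groups × four replicates (three DNA-stimulus target groups, the two
controls) by default, with a 6 × 3 preset and a minimal two-group spike-in
preset. Per protein, a true log2 abundance is drawn from
`Normal(base_mean=30, base_sd=2)`; replicates add `Normal(0, rep_sd²)`
noise. `rep_sd = 0.3` is chosen so simulated between-replicate Pearson
correlations (≈ base_sd²/(base_sd² + rep_sd²) ≈ 0.98) fall in the
0.94–0.99 range typical of replicate pulldowns. Regulated proteins (uniform
log2 effects, default 1–4) receive their effect in designated target groups
and are attenuated by 3 log2 units in both control groups, mimicking the
loss of specific enrichment without conjugatable tagged ubiquitin. Dropout
is missing-not-at-random: each cell is censored with probability logistic
in its true log2 intensity (slope 1.5 per log2 unit; midpoint
auto-calibrated so the realized overall rate matches `missing_rate`) —
the assumption that justifies downshifted imputation, made testable.
Ubiquitin is simulated at the peptide level only, at role-specific target
fractions of summed peptide intensity (target 0.40, blocked 0.20,
background 0.04, so the specific fraction of ubiquitin signal is 90% and
the blocked control sits at half the target level); the protein-level
ubiquitin row is derived by summation and sits outside the simulated truth
set.

What the generator does **not** emulate: peptide identification error,
shared/razor peptides, intensity-dependent variance beyond censoring,
batch effects, or between-protein correlation. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not performance guarantees on any particular real
dataset.

## Problem sizes and numerical choices

The FDR-control and bias simulations use ten datasets of 1000 null + 100
regulated proteins at 4 vs 4 — large enough for stable false-discovery
proportions while keeping the whole suite fast, since a 4 vs 4 design
enumerates its 70 relabellings exactly. Permutation sampling, imputation,
and simulation each consume independent child seeds spawned from one master
seed, so changing one stage's parameters never perturbs another's draws.
Degenerate inputs fail loudly rather than silently: empty FASTA records,
duplicate identifiers, negative intensities, zero-variance matrices, and
designs with fewer than two distinct relabellings are all hard errors.
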