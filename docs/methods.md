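# Methods

## Leader models and coordinates

A gene's 5′ leader (5′UTR) is modelled as an oriented sequence: leader index
0 is the cap-proximal base, index L−1 abuts the start codon. All genomic
intervals are handled internally as 0-based half-open (BED convention);
GFF3's 1-based closed coordinates are converted on read. On the minus strand
the leader is the reverse complement of the annotated blocks read in
descending genomic order, so index 0 maps to the highest genomic coordinate.
Soft-masked bases are uppercased and any character outside {A,C,G,T} becomes
N, so repeat masking cannot change scoring.

When a gene has several annotated 5′UTR isoforms (GFF3 input), the longest
isoform's UTR is kept; this is a package choice — the collapse rule is
genuinely open — and can be overridden with an explicit transcript→gene map.
BED input treats the name column as the gene id and merges all lines for a
gene into one block set.

## TSS profiles and the site filter

TSS-Seq/PEAT pileups are read from single-base BED6 (count in the score
column) or a strand-split bedGraph pair; duplicate positions aggregate.
Only reads whose 5′ end lies on the model's strand inside an annotated
leader block contribute to a profile — upstream 5′ ends and CDS reads are
excluded rather than extending the leader. Sites supported by fewer than
`min_site_reads` reads (default 10) are then removed from **both** the site
list and the retained-read total R, i.e. excluded from further analysis
entirely rather than only from the numerator. A gene is emitted as scored
only when its retained R is at least `min_total_reads` (default 10, the
same scale as the site filter); below that it is reported as unscored,
which is distinct from scoring 0.

## TOPscore

Each retained site at leader index *i* is weighted by the pyrimidine-run
length ℓ(*i*): the maximal number of consecutive C/T bases starting at *i*,
truncated at the leader's 3′ end and terminated by any purine or N (N also
scores 0 at its own position — a conservative, deterministic choice for
ambiguous bases). The gene score is Σ cᵢ·ℓ(i)/R, computed with an integer
numerator so it equals the mean of per-read scores exactly. Truncation at
the annotated 3′ end means a run abutting the start codon never extends into
the CDS; this is a documented choice where behaviour is not otherwise
pinned down.

Percentile ranks use the weak inequality: percentile(g) = #{scored genes
with score ≤ score(g)} / #scored. Ties share a percentile and the maximum is
exactly 1.0, which makes the "top fifth" criterion inclusive and tie-stable.

## Translation efficiency

FPKM(g, s) = count/(length_kb · library_total/10⁶); RPKM and FPKM are
treated as the same gene-level quantity. Replicates are averaged at the FPKM
level within each (genotype, treatment) cell before the TE ratio
TE = mean ribo FPKM / mean rna FPKM — one TE per design cell per gene. No
pseudocount is added by default; genes with a zero rna mean get an undefined
TE and drop out of fold-change comparisons (a configurable pseudocount
exists for robustness experiments). Fold-change boundaries are inclusive:
"twofold or greater" means fold ≤ 0.5 or ≥ 2.0. The expression floor keeps
genes whose mean Ribo-Seq FPKM across all ribo samples is ≥ `min_rpkm`
(default 10, inclusive).

Because FPKM renormalizes each library, a repression applied uniformly to
every gene is invisible to TE; signals are only detectable as *relative*
shifts. This is inherent to ratio-of-relative-abundance measures, not an
implementation artifact.

## The three-criterion 5′TOP classifier

Criterion (i) — TOPscore percentile ≥ `topscore_percentile_min`
(default 0.80) — has a canonical threshold. Criteria (ii) and (iii)
("decreased TE under TOR inhibition in WT", "little or no effect in
*larp1*") do not; the defaults are reverse-engineered from the exemplar
pattern of a gene called at a 1.7-fold WT decrease and a 1.2-fold *larp1*
increase:

| parameter | default | meaning |
| --- | --- | --- |
| `wt_repression_fold_min` | 1.5 | WT fold change ≤ 1/1.5 satisfies (ii) |
| `larp1_repression_fold_max` | 1.2 | *larp1* fold change ≥ 1/1.2 satisfies (iii); increases always qualify |

Note (ii)'s default is deliberately weaker than the 2-fold cutoff used for
aggregate "TE-changed" gene sets: a 2-fold classifier cutoff would
contradict the 1.7-fold exemplar. Both are exposed in configuration. Genes
without a TOPscore, without both fold changes defined, or below the
expression floor receive no call and can never be high-confidence.

## Category and overlap statistics

Mann–Whitney U tests are two-sided throughout (direction is reported
separately from the medians): exact p by full null enumeration when the
pooled sample has ≤ 20 tieless observations, otherwise a normal
approximation with midrank tie-corrected variance and a 0.5 continuity
correction. The scipy implementation provides both paths; the test suite
checks it against an independent full-enumeration oracle. The
Benjamini–Yekutieli correction (statsmodels, `fdr_by`) is applied across
all categories tested in one screen — the screen is the family. Categories
with fewer than `min_size` (default 5) scored members are skipped.

Overlap enrichment always takes the universe as an explicit argument (the
natural choice is everything detected in both compared experiments), reports
the expected overlap n·K/N, the exact hypergeometric upper tail P(X ≥ k)
(scipy), and whether the observed overlap exceeds twice the expectation.
With a universe of 657 quantified phosphoproteins and sets of 85 and 96, the
expectation is 12.4, the tail at the observed overlap of 36 is ≈ 10⁻¹¹, and
the smallest overlap with tail > 0.05 is 17 — so the "at most 17 expected"
phrasing corresponds exactly to this universe choice, which is why the
universe is never hard-coded.

## Synthetic studies

The generator plants the structure the pipeline is meant to detect, at the
standard scenario used throughout the tests: 600 genes, 15% TOP,
leaders 30–300 nt, planted runs of 5–15 pyrimidines (TOP genes start with C,
then run−1 pyrimidines, then a purine; non-TOP genes start with a purine;
remaining bases i.i.d. with pyrimidine probability 0.5). TSS reads per gene
are negative binomial (mean 300, size 5) with 80% of reads at leader index 0
and the rest uniform over indices 1–10 — entirely inside the leader, since
upstream exclusion is exercised by unit fixtures. Leaders are embedded on
random strands of per-gene contigs with 20 bp flanks so the strand-aware
extraction path is exercised end to end.

Counts follow the standard bulk RNA-Seq noise model: gene means are
log-normal (median 300, log-sd 1), counts negative binomial with size 50
(dispersion α = 0.02, typical of pooled-material biological replicates),
baseline TE log-normal (log-sd 0.25), gene lengths uniform 0.5–3 kb, and
3 replicates per design cell. The only planted effect is a 2.5-fold ribo-mean
reduction in (TOP gene, WT, torin2); `larp1_effect_fold` defaults to 1.0,
encoding fully LARP1-dependent repression, and can be raised to probe
partial dependence.

What the simulation does **not** emulate: alternative/condition-dependent
TSSs, reads upstream of the annotated leader, batch effects, length biases,
ORF-level footprint structure, or mapping artifacts. Passing recovery tests
therefore demonstrates the pipeline's correctness and statistical behaviour
under its stated model, not robustness to annotation error or protocol
artifacts in real data.

At the standard scenario the full pipeline recovers planted TOP genes with
mean precision ≈ 1.0 and mean recall ≈ 0.83 over seeds 1–5 (recall is
bounded by criteria (ii)/(iii): with 3 replicates at α = 0.02, the sampling
noise of a TE fold estimate leaves a minority of true TOP genes on the wrong
side of a threshold). Under the global null (repression fold 1.0) the
false-positive call rate among non-TOP genes and the BY discovery rate over
200 random categories both stay at or below 5%.

## Numerical and I/O choices

- TOPscore numerators are integer sums; scores are exact ratios.
- All output tables are TSV with one header line, stable column order, and
  floats at 6 significant digits, so identical inputs give byte-identical
  outputs (used for golden-file testing and the `report.json` run report).
- Randomness everywhere flows through one `numpy` Generator seeded from the
  config; repeated runs with one seed are byte-identical.
- Problem sizes in the test suite (600-gene studies, 5 seeds, enumeration
  oracles up to N = 20 and group size 8) are chosen so the whole suite runs
  in seconds while the enumerations remain exhaustive.

## Known limitations

- One leader per gene: alternative TSS isoforms are collapsed (longest UTR),
  so genes whose TOP character is isoform-specific are averaged or missed.
- TE uses gene-level counts; ORF-restricted footprint counting may differ.
- The classifier's (ii)/(iii) thresholds are heuristics over noisy fold
  changes, not calibrated tests; with few replicates the recall of true TOP
  genes is threshold-limited (see above).
- The Mann–Whitney exact path is capped at 20 pooled observations; beyond
  that the normal approximation is used (accurate to < 0.02 by then).
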