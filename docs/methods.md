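# Methods

This note documents the statistical models, the geometry conventions, the
synthetic-data generator, and the design decisions behind `smnsplice`,
including what the passing tests do and do not establish about real data.

## Coordinates and event strings

Internal coordinates are 0-based half-open. The two external conventions
each cross that boundary in exactly one place: MISO-style event strings and
GTF are read/written 1-based inclusive, BED 0-based half-open. Each
boundary is covered by a round-trip test, and the packaged 144-event corpus
(curated SE/RI calls from an SMN-depletion screen in NSC-34 cells, mm9
coordinates) round-trips byte-exactly through the parser.

"Upstream/downstream" always means transcript orientation. Minus-strand
event strings print their exon blocks genomically descending, so the first
printed block is the transcript-upstream exon on either strand; the parser
keeps that order and derives introns between consecutive exons. Sequences
are uppercased on read; characters outside {A, C, G, T, N} are rejected.
Intervals containing N are retained, but N-containing pentamer windows are
excluded from both the numerator and the denominator of every motif count,
and N breaks adjacent-pair runs during Markov training.

## PSI posterior and Bayes factor

Replicates are pooled by summation before inference — the analysis reports
one Ψ per condition, and a per-replicate hierarchical extension is
deliberately not attempted. With k of n informative reads supporting
inclusion and a uniform prior, θ | data ~ Beta(k+1, n−k+1). Ψ is the
monotone transform (θ/ℓ_inc)/(θ/ℓ_inc + (1−θ)/ℓ_exc); with the default
equal effective lengths Ψ = θ and the posterior mean is (k+1)/(n+2).
For unequal lengths the mean is computed by adaptive quadrature of the
transform against the Beta density, and the 95% interval maps the
equal-tailed Beta quantiles through the transform. Equal-tailed quantiles
were chosen to match how splicing posteriors are conventionally summarised
(posterior mean with central 95% interval).

The Bayes factor compares M1 (independent Uniform(0,1) θ per condition)
with M0 (shared θ): both marginals are Beta functions and the binomial
coefficients cancel, giving

    BF = B(k_c+1, n_c−k_c+1) B(k_d+1, n_d−k_d+1) / B(k_c+k_d+1, n_c+n_d−k_c−k_d+1)

computed with `scipy.special.betaln`. The model is an intentionally simple,
fully documented two-isoform counterpart of MISO-style inference;
correctness is established against independent oracles (exact
Gauss–Legendre quadrature of the marginals, which is polynomial-exact at
the tested grid sizes, and Monte-Carlo sampling), not against any external
tool's output. The BF is computed in θ-space; with unequal lengths the
monotone transform preserves the "changed vs unchanged" hypothesis, so the
approximation affects only the Ψ scale, not the test.

Events with fewer than 20 pooled informative reads (configurable) are
flagged `low_coverage` but never silently dropped. Events with counts in
only one condition are skipped with a logged warning.

## Classification thresholds

Discovery keeps BF ≥ 5, boundary inclusive ("a cutoff of 5" includes 5).
Validation is strict (>): SE events need |ΔΨ| > 0.5 and BF > 10, RI events
BF > 5. ΔΨ = Ψ(depleted) − Ψ(control). Ψ is oriented as exon inclusion for
SE and as the spliced (intron-removed) fraction for RI — the only
orientation under which "intron retained upon depletion" yields ΔΨ < 0 and
the four groups partition cleanly by (event type, sign): SE/ΔΨ<0 → G1,
SE/ΔΨ>0 → G2, RI/ΔΨ<0 → G3, RI/ΔΨ>0 → G4; ΔΨ = 0 is emitted as
"unchanged". U12 flagging is exact interval membership of an event intron
in the supplied BED list on (chrom, start, end, strand) — no fuzzy
matching. An optional q-value predicate can be added to validation for
workflows that carry an FDR column; it is off by default because the
upstream calls carry none.

## Motif enrichment

Each SE event is split into 7 transcript-oriented regions: the last 150 bp
of the upstream exon, the first and last 300 bp of the upstream intron, the
whole cassette exon, the first and last 300 bp of the downstream intron,
and the first 150 bp of the downstream exon. This is the unique reading of
"150 bp exon flanks + 300 bp intron flanks + whole cassette" that yields
exactly 7 regions without crossing a splice site. RI events get the
analogous 4-region partition (a documented extension). Windows truncate to
the available length; an intron shorter than 600 bp contributes its
disjoint first and second halves (5' half gets ⌊len/2⌋), so no base is
double-counted.

Per (region label, ΔΨ direction) stratum — up- and down-regulated events
are analyzed separately, with foreground defined by BF ≥ 10 — sequences
are cut into 5 equal-occupancy GC quantile bins (value-based; identical GC
collapses to one bin, fewer sequences than bins collapse to the achievable
number, both logged). A first-order Markov chain is fitted per bin from
adjacent-pair counts with add-1 smoothing; initial probabilities come from
smoothed mononucleotide frequencies, so every pentamer probability is
strictly positive and Σ_w P(w) = 1 exactly (verified to 1e-9 after
position-weighted pooling). The expected probability per pentamer is the
positions-weighted mean over bins — a single binomial approximation to the
exact Poisson-binomial across bins; at these scales the error is
negligible and it keeps one exact test per pentamer per stratum.

The test is the one-sided upper tail P(X ≥ observed) with
X ~ Binomial(scanned positions, p̂(w)) — enrichment only, since depleted
motifs are not the question asked. BH correction runs within one stratum
(1024 pentamers); the family choice is a documented convention. The Markov
background is trained on the stratum's own sequences by default
(self-background), so the test detects enrichment beyond local
composition; an external control sequence set can be supplied instead.
Self-background makes the test slightly conservative for a heavily planted
motif (the plant inflates its own expectation), which the recovery tests
absorb.

The packaged RBP → pentamer table is explicitly illustrative: the RBP
names are real splicing regulators, but the pentamer assignments are
simplified stand-ins for demonstration and testing. Real analyses must
supply a curated table.

## Consequence annotation

A retained intron is spliced back into the longest CDS-bearing transcript
whose annotated introns contain it exactly (logged choice; the analysis
does not attempt isoform-level assignment). Translation proceeds from the
(possibly shifted) CDS start; the first stop codon strictly before the
reference stop is the PTC, the truncated protein length is the codon count
before it, and `lost_cterm_length` is the difference to the reference
protein. An intron whose transcript position lies at or after the
reference stop codon is reported as UTR retention with `ptc_present =
False`. Frame preservation requires intron length divisible by 3 and no
in-frame stop. The NMD candidate flag applies the canonical 50-nt rule —
the end of the stop codon more than 50 nt upstream of the last exon–exon
junction of the *edited* transcript (the retained intron removes its own
junction) — and is a prediction reported alongside the call, never a
filter: intron-retained transcripts in neurons are frequently stable, and
stability is an experimental question.

## Synthetic-data generator

The generator is first-class, tested code. Its defaults mirror the
emulated study design: two conditions × three biological replicates,
~100 informative reads per event per replicate, 45% GC background. True Ψ
defaults populate all four groups (SE events alternate 0.75→0.25 and
0.25→0.75; RI events are mostly 0.90→0.40 spliced fraction with a G4
minority), giving |ΔΨ| = 0.5 — the scale of the validation threshold.

SE genes carry 200 bp flanking exons, a 150 bp cassette and 900 bp introns
so the full 150/300 windows always exist unless a config asks for short
introns. RI genes have three exons so that retaining intron 1 leaves a
downstream junction for the NMD rule; their CDS is built from stop-free
codons with either a planted in-frame TAA at a known codon offset inside
the intron (the generator records the exact PTC codon index and truncated
length) or a frame-preserving stop-free intron of length divisible by 3.
Roughly 70% of RI genes carry a PTC intron by default.

Counts are simulated at the event level — Binomial(coverage, θ(Ψ)) per
replicate — not as positional reads; the inference consumes only
inclusion/exclusion counts, so positional simulation would add no test
power. Motif planting overwrites (fold−1)·positions·P_bg(w) pentamer
copies at uniform random non-overlapping offsets, leaving lengths and
coordinates unchanged; genome-level planting maps offsets back through the
strand so re-extraction recovers the motif. Ct tables follow
Ct = baseline − log₂(expression) + N(0, sd) with the reference gene's fold
fixed at 1, so a noiseless table inverts exactly under ΔΔCt.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, one child stream per stage, so
stages re-run independently and identical configs produce byte-identical
FASTA/GTF/TSV/JSON outputs (manifests store parameters and sha256
checksums but no timings, precisely so they reproduce).

What the simulation does *not* model: read mapping and mapping bias,
sequencing error, positional read structure, expression-level confounding,
overdispersion across replicates beyond binomial sampling, and correlated
evolution of motif content with GC. Passing tests therefore establish the
correctness of the arithmetic and the calibration of the statistics under
the stated generative model — not robustness to alignment artifacts or
biological overdispersion in real libraries.

## Quantification utilities

ΔΔCt averages replicates arithmetically on the Ct scale before
subtraction (the averaging order is a documented convention), computes
ΔCt = Ct(target) − Ct(reference) per condition, ΔΔCt against the control
condition, and fold = 2^(−ΔΔCt); the control fold is 1 identically and the
result is invariant to any constant machine offset. Gel densitometry
reports alt/(alt+canonical). Significance testing of these values is out
of scope; the module emits values and replicate tables.

## Problem sizes and numerical choices

The oracle grid for the Bayes factor runs over all k_c, k_d ≤ n ≤ 50
(45,526 points) with 120-node Gauss–Legendre quadrature, exact for the
polynomial integrands up to degree 239. Calibration uses 2000 events per
arm at coverage 100×3; motif recovery uses 100 regions × 300 bp × 20
seeded runs at fold 5, with 5 unplanted runs for the false-positive check;
consequence recovery uses 100 RI genes; the determinism check runs the
full pipeline twice at 8 SE + 6 RI events. These sizes make the whole
suite and the acceptance script complete in well under a minute while
keeping every stochastic bound comfortably away from its threshold.

Ties in GC binning are value-based (equal GC, same bin). The binomial
tail uses `scipy.stats.binom.sf(observed−1, ...)`; BH is
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`. Degenerate
inputs fail loudly: zero-length intervals, mixed strands, negative or
duplicate counts, non-positive folds, empty Markov training sets and
out-of-bounds fetches all raise typed errors naming the offending input.

## Known limitations

* The two-isoform model ignores isoform-level deconvolution, paired-end
  insert-size information, and replicate overdispersion.
* The RI Ψ orientation (spliced fraction) is a package convention; tools
  whose native RI Ψ is the retained fraction need a sign flip on import.
* The 4-region RI partition and the BH family (per stratum) are
  conventions where the emulated analysis left the choice open.
* Consequence annotation models single-intron retention only, against one
  selected transcript; combinatorial retention and protein-domain mapping
  are out of scope.
* The NMD flag is a sequence-based prediction; it does not assert decay.
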