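# Methods

## Coordinate conventions and the genome model

All coordinates are 0-based half-open (BED convention) internally; 1-based
closed coordinates appear only in rendered text. The genome model enforces
point-centromere geometry: exactly one CEN core per chromosome, core width
inside a configurable validation band (default 113–121 bp around the
canonical 117 ± 2 bp), and a pericentromeric window of `window_bp` on each
side, clipped at chromosome ends. The window width defaults to 500 bp but
is a genuine parameter because sub-window analyses (e.g. the 200 bp or
100 bp bands nearest the core) are common; profiles refuse to run with a
window differing from the classification geometry so that the two can never
silently disagree.

The CDE partition of the core defaults to 8 bp (CDEI) / remainder (CDEII) /
25 bp (CDEIII), measured left-to-right on the reference strand. Element
sizes are not universal constants, so a per-chromosome `cde_bed` overrides
the derived layout; the partition must tile the core exactly either way.

## Fragments

A fragment is the full genomic span of a read pair (leftmost to rightmost
aligned base); its width is the fragment "length". In effectively
intronless (peri)centromeric regions this span approximates the transcript
extent, which is what makes multi-kilobase "read-pair lengths" meaningful.
Strand follows the dUTP convention (`fr-firststrand`: read 2 carries the
transcript sense) and is configurable; duplicates are *not* collapsed,
because counting statistics downstream are defined on raw read pairs and no
UMI processing is modelled. SAM input requires paired, primary, mapped
mates on one chromosome; failing pairs are counted per reason and skipped,
and the fragment multiset is independent of record order.

## Classification rules

Subtraction semantics: ≥1 bp overlap with the core makes a fragment CEN
regardless of window or ORF overlap; otherwise ≥1 bp window overlap makes
it pericentromeric, split coding/noncoding by ≥1 bp overlap with an ORF
that itself intersects a pericen window (strand-agnostic by default, with a
strand-matched switch). The ≥1 bp threshold is deliberate: partial core
coverage counts as centromeric.

Termination classes: FULL_CEN iff the fragment covers the whole core.
Otherwise the classifying position is the fragment boundary lying strictly
inside the core — the start boundary is the first covered base, the end
boundary the *last* covered base (`end − 1`), since "terminates in an
element" can only refer to the element containing the last transcribed
base. When both boundaries fall inside the core, the 3′ boundary with
respect to fragment strand decides; a fragment wholly inside the core
counts once. Length classes: SHORT iff span < 1000; exactly 1000 is LONG
(the published "<1000 / >1000" wording leaves the boundary open; a closed
rule is required and this one is fixed here). The initiation flag is true
iff the strand-aware 5′ end (leftmost base on `+`, rightmost on `−`) lies
outside the core. Initiation statistics are reported twice — 5′ anywhere
outside the core, and 5′ strictly upstream — because the two definitions
circulate side by side and differ.

A scalar and a vectorised implementation share these rules; the test suite
holds them to each other on random fixtures and holds both to a set-based
brute-force oracle exhaustively (every start/end pair, both strands) on a
200 bp toy chromosome.

## Profiles

Profiles are CEN-anchored: offset 0 is the first core base, so chromosomes
superpose. Coverage mode adds 1 at every covered position inside
[−W, core width + W); start-site mode adds 1 only at the 5′ end. Raw
counts are kept per sample; CPM scales each sample by 10⁶ / total mapped
fragments — the library depth from the sample sheet, *not* the (peri)cen
fragment count — before aggregating replicates per condition (sum by
default, mean available for figure-style rendering). Both conservation laws
(coverage mass = summed window overlaps; start-site mass = in-window 5′
count) are asserted across 100 seeded fixtures.

## Quantification

Ratios and folds are computed at full precision and displayed at two
significant figures, the rounding that reconciles the published display
values (389.7 → 390, 309.7 → 310, 2.33 → 2.3, 1.85 → 1.9). Absolute
abundance calibrates the target's length-normalised count against reference
genes of known mRNA copies per cell: kᵢ = (countᵢ/lengthᵢ)/copiesᵢ,
estimate = (target count / target length) / mean(kᵢ), with the SEM of the
kᵢ propagated to the estimate. Length-density normalisation defaults on
(`normalise_by_length`): a ~117 bp centromeric feature and kilobase-scale
mRNAs differ too grossly for unnormalised counts to be comparable. ΔΔCq
follows the comparative-Cq method (fold = 2^−ΔΔCq), with Cq values
validated into a configurable 10–40 cycle band.

## Synthetic data generator

The generator emulates the mock vs auxin (Rio1-depletion) experiment's
*classified-fragment structure*, not sequence: no bases, no sequencing
errors, no splicing.

Study-condition defaults: 16 chromosomes of 100 kb; core widths drawn
uniformly in 115–119 bp; 22 ORFs intersecting pericen windows, none within
200 bp of a core, all of a chromosome's ORFs on one side so noncoding
fragments always have ORF-free room; per-condition mock totals of 42 × scale
cen fragments (1:1 short:long) and 16,369 × scale noncoding pericen
fragments, coding pericen at 10× the mock noncoding count; a plus-strand
bias (P(+) = 0.7) on 10 of 16 chromosomes; pericen-initiation probability
0.79; 3 replicates per condition, with condition totals split multinomially
over replicates; 10⁶ background fragments per library standing in for
genome-wide depth so CPM denominators are meaningful. The count scale
defaults to 10, keeping Monte-Carlo error small at desk scale.

Lengths are log-normal parameterised by (median, σ_log), so the published
medians map exactly to the log-mean: SHORT cen (231, 0.45), LONG cen
(4458, 0.35), noncoding pericen (225, 0.45), with draws resampled (not
clipped) across the 1000 nt class boundary. σ_log values are choices — only
medians and extremes are published — picked so SHORT mass stays below
1000 nt and the LONG upper tail plausibly reaches ~9.4 kb. Coding pericen
(median 500, σ 0.5) and background (300, 0.5) lengths are likewise
package choices.

Termination composition: mock FULL_CEN is exactly 0.48, with the remainder
split CDEI:CDEII:CDEIII ∝ 12:24:17; auxin FULL_CEN is exactly 0.32 and the
whole deficit moves to CDEI (the depletion phenotype concentrates new
terminations there). Auxin count multipliers are the published count
ratios — 98/42 (≈2.33, display 2.3) net over total cen with the long class
held at 1.0, and 30346/16369 (≈1.85, display 1.9) for noncoding pericen —
so folds *and* per-condition ratios (390 mock, 310 auxin) are mutually
consistent; coding pericen is unchanged by depletion.

Placement is constructive: cen fragments anchor the boundary that carries
the intended termination class inside the target CDE element, then place
the other end by the drawn length; FULL_CEN lengths are resampled to ≥ core
width (the only length conditioning, biasing the realised SHORT median up
by ~1–2%). The drawn pericen-initiation wish is honoured whenever geometry
permits; for the small set of infeasible (class, length, origin) triples
the termination class and length win and the origin flag follows geometry,
so the realised initiation fraction tracks 0.79 to within a few percent.
Noncoding pericen fragments end at the core border (up side) or begin at it
(down side) and are rejection-resampled off ORFs, flipping window side when
stuck; coding fragments are sub-intervals of an ORF constrained to overlap
its window; background fragments avoid the core ± window span entirely.
Every emitted fragment re-classifies to its intended class (asserted in
tests).

Determinism: all randomness derives from `numpy` child seeds of
(seed, stream-id, condition, replicate); identical configs give
byte-identical outputs, replicates differ, and the replicate split is drawn
once per condition so any replicate can be generated independently.

What passing tests do **not** show about real data: the generator has
uniform per-chromosome abundance by default (optional weights exist, but no
published per-chromosome parameterisation is usable), no chromatin-context
correlation between neighbouring fragments, idealised log-normal lengths,
and background fragments that never touch the windows. Recovery of the
configured medians and compositions validates the estimator machinery, not
the biological values themselves.

## Pipeline and problem sizes

`run-all` chains simulate → classify → profile → quantify, writing tallies,
termination distributions, profiles (raw + CPM), the ratio report,
initiation and start-site statistics, molecules-per-cell estimates and a
manifest; outputs are pure functions of the manifest-recorded inputs, and
reruns at a fixed seed are byte-identical. By default only
CEN/PERICEN_* fragments are written to `classified.tsv` (mirroring the
extraction step of the original analysis); background fragments appear in
tallies and counts, and `--write-classified all` overrides. Reference-gene
counts for the calibration stage are drawn Poisson around
density × copies × length, so the molecules-per-cell machinery is exercised
end to end; its synthetic absolute values reflect the synthetic depth, not
the biology.

Test and acceptance cohorts use 5,000–20,000 fragments per class — the
sizes at which binomial confidence intervals on a 48% composition are
~±1.4 pp and median estimates are stable to well under 5% — and the
end-to-end determinism check runs the full default-scale experiment
(~10⁷ fragments) twice.
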