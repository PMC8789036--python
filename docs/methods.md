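# Methods

This note documents the models, numerical choices and limitations of
`pentamsea`. It is the package's own account of what it computes; every
number quoted here is produced by the test suite or the example commands,
not asserted from elsewhere.

## Library model and coordinates

The library is the complete set of 4⁵ = 1024 RNA pentamers substituted at
one fixed intronic window. The default `LibraryContext` describes the
*SMN2* intron-7 screen: wild-type pentamer `CAGCA` at intron positions
+11..+15, upstream flank ending `...UGC`, downstream flank beginning
`UUAU`. (Published descriptions of this screen disagree in one place on
whether the wild-type window reads CAGCA or GCACC; the library definition
used throughout the primary analysis is CAGCA, and that is what this
package uses. GCACC appears in the library as the strongest silencer
mutant, which makes the two easy to conflate.)

Pentamer positions are 1..5. Flank coordinates count outward without a
position 0: the base immediately 5′ of the pentamer is −1 (so the upstream
`UGC` occupies −3..−1) and the first downstream base is 6. A flank-aware
motif match must overlap the pentamer by at least one base — flank-only
matches describe the invariant backbone, not the variable site — and
match offsets are reported in these coordinates (the RBFOX site `UGCAUG`
completed by the upstream flank starts at −3). Degenerate IUPAC codes
(N, Y, R, W, S, K, M, B, D, H, V) expand letter-by-letter; DNA input is
normalized T→U everywhere.

Lexicographic order A < C < G < U is the canonical library order and the
tie-break for equal ΔPSI values, making every downstream ranking
deterministic.

## ΔPSI and the ranking

The PSI matrix is 4 × 1024 (GCT v1.2): rows `MUT_PSI_R1`, `WT_PSI_R1`,
`MUT_PSI_R2`, `WT_PSI_R2`, one column per pentamer. Each replicate batch
carries its own wild-type control measurement, broadcast across the WT
row, and ΔPSI subtracts the *matched-batch* control before averaging:
ΔPSI(p) = mean_r (MUT_r(p) − WT_r). A pooled-WT alternative would differ
only when batch controls differ, and then only in late decimals; per-batch
subtraction is the design that cancels batch offsets exactly (ΔPSI is
invariant to adding a constant to both rows of one batch, a property the
suite tests). The wild-type pentamer is its own control and is fixed at
ΔPSI = 0 but retained in the ranking so the list always has 1024 entries.

Sign summaries (stimulatory / inhibitory / neutral counts) classify ΔPSI
after rounding to 2 decimals — the precision at which such screens report
PSI — because "zero ΔPSI" is only meaningful at reporting precision.
Threshold counts (> +10, < −10 percentage points) use strict inequalities.

## Motif-set construction

Six layers describe a pentamer, generated over the pentamer word itself
(flank-completed motifs are the classifier's business, not the set
builder's):

| layer | sets | membership |
|---|---|---|
| non_positional | 64 + 256 | contains the 3-mer / 4-mer anywhere |
| pos1 / pos2 / pos3 | 64 each | 3-mer anchored at positions 1–3 / 2–4 / 3–5 |
| repeat | 16 + 16 | base repeated ≥ c times (c = 2..5); dinucleotide ≥ 2 non-overlapping (greedy scan) |
| interaction | 160 | ordered base pair at an ordered position pair |

This yields 704 sets; the size filter [7, 200] removes the four
single-base "≥2" sets (376 members each, too unspecific) and the four
"≥5" sets (1 member each), leaving 696. Repeat membership uses "at
least c" semantics, so `AUUUU` belongs to `U:U`, `U:U:U`, `U:U:U:U` and
`UU:UU`; greedy left-to-right dinucleotide counting equals maximal
disjoint packing for a fixed 2-mer (property-tested). The original screen
reported a different, larger set inventory whose construction is not
reconstructible from its description; all statistics here are defined per
set, so the pipeline is unaffected, but per-layer enriched-motif tallies
are not comparable across inventories and are not targets of this
package.

## Enrichment statistics

Scoring follows the preranked weighted-KS scheme standard in set
enrichment tools. For a set S of size m against a ranking of length N
with metric r_i and weight exponent p (default 1):

* hits add |r_i|^p / Σ_{j∈S}|r_j|^p, misses subtract 1/(N−m);
* ES is the running-sum value of maximal |deviation|; exact ties between
  the positive and negative extreme (a measure-zero event for continuous
  metrics) resolve to the positive one, with a 10⁻¹² tolerance so the
  resolution is stable under floating-point noise;
* if every member's metric is zero the set falls back to p = 0
  (classical KS), keeping the score defined;
* the running sum provably starts and ends at 0; ES ∈ [−1, 1]; with
  p = 0 the score equals the signed ECDF difference, and both facts are
  verified against an independent brute-force walk over all subsets of a
  toy list.

The null distribution per set **size** is the ES of `n_perm` (default
1000) uniformly random member subsets, the only permutation scheme
available to a preranked list. Null draws are seeded per size from a
spawned `SeedSequence`, so results are byte-identical under a fixed
`random_state` (default 17) regardless of execution order.
NES = ES / mean(|null ES| of the same sign); the nominal p is the
same-sign null tail fraction with a +1/(n+1) continuity correction
(uniform under the null, which the suite checks by KS test). The FDR q
follows the sign-stratified pooled scheme: for positive NES*,
q = [fraction of pooled normalized null NES ≥ NES*] / [fraction of
observed NES ≥ NES*], clipped to [0, 1], mirrored for negative.
Benjamini–Hochberg is deliberately **not** used — q-values here estimate
the FDR from the permutation null itself, matching preranked-GSEA
conventions. Sets with no same-sign null draws get an undefined NES and
are excluded from significance.

Leading edge: for positive ES, `tags` = fraction of members at rank ≤
peak, `list` = peak/N; mirrored for negative ES (the peak of a negative
set is the running-sum minimum, attained just before a member);
`signal` = tags·(1−list)·N/(N−m), clipped to [0, 1]. Significance =
(q < 0.05) ∧ (list < 0.5), both strict.

The enrichment score implementation is cross-checked in the test suite
against `gseapy`'s preranked ES on random inputs; `gseapy` is never used
to produce results.

## Feature-space PCA

Pentamers are embedded as binary membership vectors over the filtered
sets (column order: layer, then set id). PCA is column-centered,
unscaled, full SVD, with each component's sign fixed so its
largest-magnitude loading is positive. The choice of binary membership
(rather than NES-weighted features) is a design decision: it encodes the
six-layer space directly and is data-independent; users can substitute
weighted features.

One structural consequence worth knowing: the set system is invariant
under permutations of the four-letter alphabet, so the membership
covariance has degenerate eigenvalue multiplets and the leading
eigenspace is a three-dimensional space of base-composition contrasts.
Directions *within* a multiplet are arbitrary; scores are reproducible
(deterministic solver + sign convention) but individually
uninterpretable, and variance-explained percentages depend on the chosen
feature encoding. For that reason cluster separation is quantified not by
eyeballing components but by the mean silhouette of the sign(ΔPSI)
groups in the leading-component space, compared against label shuffles.
Pentamers with ΔPSI = 0 are excluded from the silhouette.

## SRE classification rules

Stimulatory rules fire in order CG-core (contains CG) → C-rich (≥ 2 C and
more C than U) → U-rich (≥ 2 U) → RBFOX-related (motif completes UGCAUG
with the upstream flank at an anchor that touches it). The precedence
puts CG-containing motifs in CG-core even when U-rich also applies, and
C-rich before U-rich, reproducing the family partition observed in this
screen. A/U-only motifs with a single U (e.g. AAU) are classed U-rich
with flank evidence: they extend the downstream `UUAU` into a UA-rich
enhancer.

Inhibitory rules are multi-label (all matches reported, primary first;
precedence GCWCC-type > GAC-core > AG-core > UG-type, so AGAC is
primarily GAC-core while also AG-core, and AGGN motifs stay AG-core
despite containing GGU): AG-core (contains AG); UG-type (UGG or GGU);
GAC-core (contains GAC whose immediately preceding base — the flank C
when anchored at position 1; a known base inside the motif; an unknown
pentamer base otherwise — is not C, since a preceding C neutralizes the
silencer); GCWCC-type (the motif is a 3′-anchored piece of GCACC or
GCUCC completed by the upstream `...GC` or within the pentamer — so ACC,
UCC, CUCC, CACC qualify but a prefix like GCA, which leaves the CC tail
unspecified, does not).

Pentamer annotation scans every 2–6-nt window overlapping the pentamer in
its flanked context; since window neighborhoods are fully known there,
flank rules reduce to substring checks, with one extra provision: a
window containing the complete UGCAUG is RBFOX-related regardless of what
else it contains. Nucleotide-interaction set ids (`A.U..`) do not decode
to a contiguous motif and are flagged rather than classified. Rules are
pure functions; thresholds and patterns live in a `ClassRuleSet`
serializable to editable YAML.

## Synthetic screens

The generator draws one screen from: true PSI(p) = 100 ·
expit(logit(baseline/100) + Σ effects of planted motifs matching p), with
baseline 41% (the basal inclusion level of the assayed exon), replicate
observations = truth + N(0, sd²) truncated to [0, 100] (sd default 3
percentage points, consistent with the replicate differences such screens
report; truncation events are counted in the ground truth), and WT rows =
one noisy baseline draw per batch. Logit additivity is a modeling choice,
not a measured fact: PSI is a bounded proportion, so effects should
compose on the log-odds scale and saturate near the boundaries, and the
closed form is unit-tested by hand arithmetic.

The default planted panel — UAG −1.5 and AGG −1.2 logits, UUU +1.5, CG
+0.8, and the flank-aware GCACC −2.5 (covering ACC-at-position-1
pentamers plus GCACC itself) — mirrors the screen's headline regulators
and exercises every classifier family. Recovery evaluation maps each
planted motif to the scored set with maximal Jaccard overlap to its
member list and asks for significance with the planted sign; the
false-positive rate is measured over scored sets sharing no member with
any planted motif.

What the simulation does *not* emulate: transfection batch effects beyond
per-batch WT controls, measurement-mechanics artifacts (PCR, gel
quantitation), RNA secondary structure, or correlated noise between
sequence-similar pentamers. Passing recovery tests therefore demonstrates
the statistics and plumbing are sound under a known generative model, not
that real screens behave this way.

## Problem sizes and defaults

Default analyses score 696 sets over 1024 pentamers with 1000
permutations per distinct set size (~20 sizes), which completes in a few
seconds on one core; calibration tests use an i.i.d. ranking of length
400 with 60 disjoint sets and 2000 permutations. Enrichment on a measured
table intended for publication-grade q-values should raise `n_perm`
(10 000 gives q resolution of ~10⁻⁴ and runs in well under a minute).

## Known limitations

* The permutation null is member-subset sampling; no phenotype
  permutation is possible (or offered) for a preranked list.
* FDR q-values are ratio estimates and can be 0 when no pooled null
  value exceeds the observed NES; they are clipped, not smoothed.
* The motif-set inventory is the documented construction above; analyses
  published with other inventories will differ in per-layer tallies.
* PCA variance percentages are encoding-dependent (see above) and should
  not be compared across feature definitions.
* The classifier encodes this screen's flanks; other insertion contexts
  need their own `LibraryContext` and possibly extended rules.
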