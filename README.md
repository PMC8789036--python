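# pentamsea

Motif set enrichment analysis (MSEA) of a complete intronic
pentamer-mutagenesis library.

## The problem

Short splicing-regulatory elements (SREs) — intronic splicing enhancers and
silencers a few nucleotides long — steer splice-site choice, and their
disruption is a recurrent disease mechanism. One way to map them
exhaustively is a saturation screen: replace a single 5-nt intronic window
(here, positions +11..+15 of *SMN2* intron 7, wild type `CAGCA`, flanked by
`...UGC` upstream and `UUAU...` downstream) with **every** RNA pentamer
(4⁵ = 1024 words) and measure percent spliced-in (PSI) of the regulated
exon for each mutant minigene in replicate transfections.

The analysis problem this package solves: given the replicate PSI table,
find which *sequence features* — not which individual pentamers — drive
exon inclusion or skipping. `pentamsea` is written for computational
biologists who have such a screen (or want to prototype one in
simulation) and want a tested, reproducible pipeline from raw PSI to
classified SRE motifs.

## The method

1. **ΔPSI ranking** — for every pentamer *p*,
   ΔPSI(*p*) = mean over replicates *r* of (PSI_mut,r(*p*) − PSI_wt,r);
   all 1024 pentamers are ranked by ΔPSI descending (`.rnk`).
2. **Six motif-set layers** — each set groups pentamers sharing one
   feature: a 3/4-mer anywhere (non-positional), a 3-mer anchored at
   positions 1–3/2–4/3–5, a repeated mono- or dinucleotide (`U:U`,
   `AG:AG`), or a two-position base pair (`A.U..`). 704 sets are
   generated; sets with < 7 or > 200 members are removed (696 remain).
3. **Preranked enrichment** — each set *S* (size *m*, list length *N*) is
   scored with the weighted Kolmogorov–Smirnov running sum: walking down
   the ranking, hits add |ΔPSI|^p / Σ_{i∈S}|ΔPSI_i|^p (*p* = 1), misses
   subtract 1/(N−m); the enrichment score ES is the extreme deviation.
   A size-matched permutation null (random member subsets) yields
   NES = ES / mean|null ES of the same sign|, a nominal *p*, and a
   sign-stratified FDR *q*. Leading-edge statistics `tags`, `list`,
   `signal` describe the members driving the peak. A set is significant
   when *q* < 0.05 and `list` < 50%. Positive NES = stimulatory feature
   (enhancer), negative = inhibitory (silencer).
4. **Feature-space PCA** — pentamers are embedded as binary membership
   vectors over the filtered sets; PCA scores and a silhouette statistic
   quantify how well the feature space separates stimulatory from
   inhibitory pentamers.
5. **SRE classification** — enriched motifs are assigned to families by
   flank-aware rules: stimulatory CG-core, C-rich, U-rich, RBFOX-related
   (…UGC + AUG → UGCAUG); inhibitory AG-core, UG-type (UGG/GGU), GAC-core
   (GAC not preceded by C) and GCWCC-type (GCACC/GCUCC).

A synthetic-screen generator (logit-additive planted motif effects around
a 41% baseline, truncated Gaussian replicate noise) makes the whole
pipeline testable without measured data and supports power/false-positive
evaluation against known ground truth.

## Worked example

Run the full pipeline on a simulated screen (planted effects: UAG −1.5 and
AGG −1.2 logits, UUU +1.5, CG +0.8, flank-completed GCACC −2.5):

```bash
pentamsea all --nperm 1000 --seed 7 --out-dir out/
```

The summary it prints (abridged):

```
"library_summary": { "n_positive": 654, "n_negative": 366, "n_zero": 3,
                     "min_pentamer": "UAGGG", "max_pentamer": "UUUCG", ... }
"n_motif_sets_scored": 696,
"n_significant": 132,
"replicate_concordance": { "pearson_r": 0.9593, ... }
```

654 mutants increase inclusion and 366 decrease it; the most inhibitory
pentamer is `UAGGG` (every base hits a planted silencer) and the most
stimulatory is `UUUCG` (U-run plus CG). The top of `out/msea_results.tsv`:

```
set_id  layer           size  es        nes      p_nominal   fdr_q
UUU     non_positional  40    0.99976   2.40198  0.00127226  0
U:U:U   repeat          106   0.863863  2.34102  0.00111982  0
...
AGG     non_positional  48   -0.940574 -2.80377  0.00456621  0
UAG     non_positional  48   -0.943399 -2.81219  0.00456621  0
```

The planted silencers UAG/AGG carry the most negative NES and the planted
U-run the most positive, each with FDR q ≈ 0; `out/classifications.tsv`
labels them AG-core and U-rich respectively. Every stage is also available
as a subcommand (`simulate`, `delta-psi`, `make-sets`, `run-msea`, `pca`,
`classify`) or as library calls (`pentamsea.run_msea`, the sklearn-style
`pentamsea.MSEA` estimator, …).

To analyse a measured screen instead, pass `--gct your_table.gct`
(GCT v1.2, rows `MUT_PSI_R1`, `WT_PSI_R1`, `MUT_PSI_R2`, `WT_PSI_R2` by
1024 pentamer columns).

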