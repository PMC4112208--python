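# Methods

This note documents the models, declared parameters and numerical choices
behind each stage, what the synthetic data does and does not emulate, and
the known limitations.

## Coordinates, alphabets and formats

Intervals are 0-based half-open internally; GFF3 I/O (miRBase dialect:
`miRNA_primary_transcript` parents, `miRNA` children linked by
`Derives_from`) converts at the boundary. Sequences are stored as DNA
(U→T on input); reports that print mature miRNAs emit RNA. Collapsed FASTA
headers use the common `_x<count>` suffix. Reads shorter than 15 nt or
longer than 35 nt are rejected; reads outside 17–30 nt are kept but
flagged. SAM input honours NM (mismatches) and NH (hit count); multi-map
weight is 1/NH, and SAM files lacking NH are refused when weighting is
requested rather than silently treated as unique.

## Read mapping

The built-in mapper is exact for its contract: every alignment with at most
`max_mismatch` (default 2) substitutions on either strand is reported. Each
read is split into `max_mismatch + 1` chunks (length capped at `seed_k`,
default 12); by pigeonhole at least one chunk is exact in any in-budget
alignment, so looking up each chunk in an exact k-mer index and verifying by
Hamming distance enumerates all hits. This is O(genome) per lookup table
and is intended for the small genomes used here (≤ a few hundred kb);
equality with a brute-force scan is asserted in tests. Indels are not
modelled.

## Shifted-window arm quantification

A read counts toward an arm when its 5' end lies within ±`shift` (default
2) nt of the annotated mature 5' start and the read is contained in the
precursor extended by `shift`. Counts are weighted sums; the count is
monotone in `shift` by construction.

## Hairpin folding

The default backend is a reduced nearest-neighbour model: Watson-Crick and
G·U pairs; stack energy −(s₁·s₂)·0.33 − 0.4 kcal/mol with pair strengths
GC=3, AU=2, GU=1 (calibrated so GC/GC ≈ −3.4 and AU/AU ≈ −1.7); a tabulated
hairpin-loop penalty with logarithmic extrapolation; affine bulge/interior
penalties with per-side size cap 10; external-loop decomposition but no
multiloops. It returns a dot-bracket structure, an MFE estimate, the number
of stem-loops (innermost loops) and the first loop length. ViennaRNA is a
pluggable backend (`backend="vienna"`) and serves as the independent
cross-check in tests: on designed stems the two agree on structure and
within ~20% on energy. The −15 kcal/mol acceptance rule is applied to
whichever backend is configured; energies are not claimed bit-compatible
between backends.

Duplex 3' overhangs are read off the fold's pair table: the 3' end of each
arm's predominant read is compared with the pairing partner of the other
arm's 5' start (scanning inward over unpaired positions and extrapolating
along the helix). Both overhangs in {1,2} → canonical; otherwise atypical,
with overhangs beyond [−2, 4] flagging the candidate low-confidence. A
missing star arm leaves overhangs undefined without penalizing the
candidate.

## Candidate filtering

Acceptance requires, conjunctively: ≥`min_reads` (10) weighted reads in
each of ≥2 libraries spanning ≥2 biological experiments; fold energy
< −15 kcal/mol with a single stem-loop; 5'-start consistency — the weighted
modal 5' fraction of the predominant arm ≥ 0.66, with a two-mode exception
(top two positions jointly ≥ 0.9) for alternatively processed loci; a
placed chromosome; and support not restricted to multi-mapping or
mismatched reads. The 0.66/0.9 thresholds are declared choices (no
published number exists for this criterion); every rejection carries all
reasons that applied, making the filter idempotent and order-independent.

## Homology classes

Full homolog: identical seed (nt 2–8) and global identity > 0.70, where
identity = 1 − edit distance / max length (edlib, global alignment).
Seed-only: identical seed and first 10 nt agreeing up to one substitution
outside the seed — a declared sharpening of "first 10 nt alignment". Ties
resolve to highest identity, then lexicographically smallest id. The
packaged novel-miRNA table maps free-text conservation notes to the same
three classes: notes naming a known foreign miRNA → full homolog; notes
containing "seed" → seed-only; notes claiming conservation only of the
candidate's own newly named miR → seed-only; "No…" → none. Five
typographically merged rows of the source table carry
`fields_ambiguous=1`: their mature sequence and seed are uniquely
recoverable (the seed must equal mature[2..8]), their per-arm raw counts
are a best-effort split consistent with the printed predominant arm, and
they are excluded from strict seed validation.

## Iso-miR model

Reference isoform: the highest-count perfectly matching read; ties break by
length, then 5'-most start, then sequence — declared, since abundance alone
can tie. Offsets: δ5 = read 5' − reference 5' and δ3 = read 3' − reference
3' in transcript orientation (negative δ5 = upstream/extended 5'; positive
δ3 = extended 3'). The stack window is |δ5| ≤ 3 and |δ3| ≤ 3; beyond-window
reads are tallied as degradation/other. Reads with internal mismatches
(any position except the 3'-terminal base, which may be a tail) are
excluded from the histograms and routed to the editing scan — this
separation prevents a tail from being double-counted as an edit.

3'-extension classification: all added bases matching the next genomic
bases → template(k), k ≤ 3; a single mismatching addition →
non-template(nt); a single matching A/U → template flagged ambiguous
(tailing and imprecise processing cannot be distinguished, so the
non-template totals are lower bounds and the ambiguous tally is reported
alongside); multi-nucleotide additions that do not all match → complex
tail, not attributed to a nucleotide. The profile partition
(untailed+trimmed, template, ambiguous, non-template by nt, complex) sums
to 1 over the stack.

Editing scan: weighted 12-cell substitution matrix over internal
mismatches; enrichment = observed (A→G)+(C→U) fraction over the uniform
expectation 2/12, with a two-sided binomial test on rounded weighted
counts. The mismatch rate is reported raw: sequencing error and
strain-vs-reference variation are not deconvolved from editing.

## Arm usage and switching

proportion₅ₚ is computed on raw weighted counts; the ratio uses a +0.5
pseudocount on both arms only when one arm is empty (flagged). The
balanced band is ratio ∈ [0.8, 1.25] — the widest band consistent with
every row of the packaged arm-shift table (1.33 must call 5p; 0.93 and
1.02 must call balanced); the underlying study states no numeric rule, so
the band is declared, not derived. A shift against annotation is a switch
only when the observed call is the opposite arm; balanced observations are
reported "5p~3p". Between paired records the fold difference is
max(r_a/r_b, r_b/r_a) with a 10-fold switching threshold; the comparison is
symmetric. The global arm bias is the unweighted mean of per-locus
proportions (so highly expressed loci do not dominate); the pooled-read
variant is also emitted because the underlying phrasing is ambiguous.

## Clusters

Distance = gap between precursor intervals (0 when overlapping), boundary
inclusive; single-linkage chaining per chromosome with a running maximum
end, which equals connected components of the pairwise-gap graph (asserted
against that oracle). Same-arm concordance counts each clustered miRNA
against its cluster's majority arm; the non-clustered baseline is the
probability that two random singletons share their dominant arm (the
pairwise variant; a pooled variant is also computable since the intended
statistic is ambiguous). Cluster conservation: conserved when all
orthologous families co-cluster in the other species, fragmented for a
proper non-empty subset, species-specific otherwise; ortholog identity
comes from family labels, not re-alignment. Paralogs: identical mature
sequence or ≥0.70 precursor identity, grouped single-linkage. Member
co-expression: mean pairwise squared Pearson correlation of log2(normalized
count + 1) across ≥3 libraries.

## Expression and differential calls

Counts per locus sum both arms' stacks plus internally mismatched mature
reads (non-template-tailed reads included); beyond-window degradation and
loop reads are excluded. Normalization modes: median-of-ratios (geometric
mean reference over all-positive rows), reference gene (factors
proportional to the reference counts, relative to the first library;
errors on any zero), or total mapped. On libraries differing by a global
scalar all three agree up to scale.

The decision rule is |log₂FC| > 1.5 and p < 0.05. Fold changes are
log₂((mean_a + 0.5)/(mean_b + 0.5)) on normalized per-condition means. The
p-value comes from a label permutation test on the same statistic. With 2
replicates per condition only C(4,2) = 6 distinct relabelings exist and
p < 0.05 is unreachable within a locus, so when fewer than 40 distinct
relabelings exist the permutation statistics are pooled across loci
(SAM-style shared null); p = (1 + #{null ≥ observed})/(1 + #null). With
fewer than 2 replicates per side p is NA and nothing is called. Under null
simulations the pooled p-values are uniform and the call rate is ≤5%;
planted 4-fold changes at 2×2 replicates are recovered with >90% power.
No negative-binomial dispersion model and no multiple-testing correction
are applied: the thresholds above are the declared decision rule.

Host/vector partitioning is by exact sequence match against declared
per-species isoform sets; identical sequences in both sets are a
configuration error, and non-matching reads are reported unmatched.

## Synthetic data

The generator emulates a replicated multi-condition small RNA-seq design:
3 placed chromosomes (30 kb each) plus an unplaced decoy contig; designed
52-nt precursors (22-nt arms, 6-nt loop, 2-nt 3' duplex overhangs) whose
stems are perfect WC duplexes with five evenly spaced G·U wobbles — the
wobbles keep the hairpin folding far below −15 kcal/mol while making the
two arms non-complementary enough (5 positions) that arm reads do not
shadow-map to the opposite arm; real precursors achieve the same through
bulges and wobbles. Three bases of fixed C downstream of each arm make
planted A/U/G tails unambiguously non-template. Non-miRNA small RNAs
(tRNA/rRNA/snoRNA class and an invariant U2 reference) are plain expressed
windows; decoys use an A/C-only alphabet so they cannot base-pair at all.

Reads are drawn multinomially per locus × library from declared category
probabilities (defaults per arm: 5' offsets ±1 at 0.04 each; 3' trims
−1/−2 at 0.08/0.05; template extensions +1/+2 at 0.08/0.02; non-template
tails A/U at 0.04/0.05; editing 0.01 — magnitudes of the order reported
for insect libraries, with 3' variation exceeding 5' variation), scaled by
per-condition fold maps and per-class scalings. Sequencing errors are
substitutions at 0.1% per base, never at the terminal base of a planted
tail (so tail truth is conserved; the residual ambiguity is exercised by
the error-bearing reads elsewhere). The truth table records pre-error
category counts per locus × library × arm and sums exactly to each
library's read count. Identical config and seed give byte-identical
output.

Presets: *feeding* (sugar/blood × 2 replicates, 26% host contamination in
blood, planted 5× and 4× responders, a shared miR-92a-like family with
host isoforms diverged at 3 positions per arm and weights placing 90% of
the family's blood reads on the host copy); *infection* (6 planted
responders at 3–5×); *ago_knockdown* (miRNA ×0.35 and tRNA/rRNA/snoRNA
×0.91 in the Ago1 library — medians −1.51 and −0.14 — and ×2^0.54 / ×2^0.16
in the Ago2 library); *arm_switch* (two >10-fold switchers, one balanced
locus); *cluster_conservation* and its species-B counterpart (conserved,
fragmented and species-specific clusters, an identical-mature paralog
pair, co-expression groups). The default panel of 12 background loci has
arm proportions averaging 0.40 (3'-biased). Default depth is 50,000 reads
per library — large enough for ±0.02 binomial recovery of the planted
fractions, small enough that a full preset runs in seconds; tests use
reduced depths of 3,000–20,000 where the statistic allows it.

What the simulation does not emulate: PCR duplication, ligation bias,
quality-score structure, indel errors, repeat-derived multimapping beyond
planted paralogs, genuine biological replicate dispersion beyond the
planted per-library expression-group noise, and strain-level genome
variation. Passing recovery tests therefore demonstrates correctness of
the bookkeeping and estimators under the declared generative model, not
robustness to those real-data effects.

## Known limitations

* The mapper is substitution-only and intended for small genomes.
* Built-in fold energies are approximate; borderline candidates near the
  −15 kcal/mol rule should be re-evaluated with ViennaRNA.
* The pooled permutation null assumes loci are largely exchangeable under
  the null; many strong true effects shift the pooled null conservative.
* Conservation classification of table notes is rule-based; two summary
  class counts printed in the source study (19 full homologs, 17
  seed-only) are not reproducible from the table text as transcribed,
  which yields 17/20/21 — the discrepancy is surfaced rather than patched.
* Species partitioning is exact-match only; isoform variants of shared
  families fall into the unmatched bucket.
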