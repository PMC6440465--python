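# Methods

This note documents the models and procedures famscan implements, the
defaults that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Family identification

The family is defined structurally: a complete ID domain of four zinc
fingers in the order C2H2, C2H2, C2HC, C2HC, each matching

    (F/Y) X C X{2,5} C X{3} (F/Y) X{5} ψ X{2} H X{3,5} H     (C2H2)
    (F/Y) X C X{2,5} C X{3} (F/Y) X{5} ψ X{2} H X{3,5} C     (C2HC)

The hydrophobic class ψ is instantiated as `[AVLIMFWC]`; the consensus
literature does not enumerate it, so the set is configurable in
`identify.HYDROPHOBIC`. Finger matches are resolved non-overlapping,
leftmost-first (earliest start wins, C2H2 preferred on an exact-start
tie; scanning resumes after each accepted match). Domain assembly takes
the first window of four fingers in the canonical kind-order whose total
span is at most `max_domain_span` = 220 aa — the literature gives no
inter-finger spacing, so the bound is an explicit, exposed parameter
chosen to accommodate a compact domain with generous linkers.

`identify_family` runs three stages: (1) a similarity prefilter keeping
proteins whose best global-alignment identity to any query is ≥ 0.25 — a
deliberately loose stand-in for a translated database search, since
inputs here are annotated proteomes and the domain test is the real
filter; (2) domain assembly; (3) locus de-duplication keeping the
longest isoform (a trailing `.N` suffix is read as the isoform id). The
source protocol discarded "redundant sequences" without stating the
criterion; longest-isoform-per-locus is this package's convention.

The NLS is the leftmost KKKR or KRKR lying entirely N-terminal of the
domain; its absence is legal (several real members lack it). C-terminal
motifs MSATALLQKAA and TRDFLG are searched only C-terminal of the
domain as best ungapped occurrences within mismatch budgets of 2 and 1
respectively; members of one subgroup characteristically lack both.

## Alignment

Global Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner`: BLOSUM62 with gap open 10 / extend 0.5 for proteins;
match +2 / mismatch −3, open 5 / extend 2 for DNA. The upstream tools
this replaces ran with unstated defaults, so the parameters live in one
place (`align._aligner`) and the tests verify optimality against
brute-force enumeration on short strings rather than any particular
traceback path. Tie-breaking among co-optimal alignments is the
aligner's deterministic first-path order.

Identity is identical columns over a denominator that by default
excludes terminal gap overhangs (the duplicate-pair rule compares coding
sequences of unequal length; overhangs would dilute the statistic) and
counts internal gaps as mismatches; `all_columns` is available as a
convention switch. Codon alignments are protein-guided: each protein
residue maps to its codon, each protein gap to `---`, with exact
translation checks on both sides.

## NG86 Ka/Ks and sliding windows

Site counts: for each codon position, the synonymous fraction among the
non-stop single-nucleotide mutants at that position; the three positions
sum to exactly 3 sites per codon, and S/N are averaged between the two
sequences. Differences: for each differing codon pair, all orderings of
the differing positions are enumerated; pathways passing through a stop
codon are excluded from the equal-weight average (standard NG86
practice; if every pathway is blocked, all are used with stop steps
counted as nonsynonymous — a degenerate case that cannot occur for
sense-codon pairs differing at ≤ 3 positions but is handled
deterministically). Columns containing a gap or stop in either row are
skipped. Proportions pS = Sd/S and pN = Nd/N are corrected with
d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is reported as saturated (rate
undefined) rather than infinite, and Ka/Ks is undefined whenever Ks is
zero or undefined, so tables never carry non-finite sentinels. The
selection label reads purifying / neutral / positive at the Ka/Ks = 1
cut-off.

Sliding windows use a 150 bp window and 9 bp step (both must be
multiples of 3), windows fully inside the alignment:
count = ⌊(L−150)/9⌋ + 1.

Duplicate pairs are all unordered pairs with coding-sequence identity
> 0.80. Location rules follow the source text as printed: different
chromosomes → segmental; same chromosome and separated by ≥ 200 kb →
tandem; same chromosome closer than 200 kb → unclassified. The printed
tandem rule inverts the field's usual distance reading; because the
authors' intent cannot be established from the text, the printed form is
the default and `tandem_rule="conventional"` swaps the distance test.
Separation is measured between the nearest gene ends.

## Microsynteny

Anchors are, for each gene in genome A, up to `top_hits` = 5 partners in
B with global protein score ≥ `min_score` = 100; ranks are gene order by
start coordinate per chromosome. Chaining is per chromosome pair and
orientation: a longest-chain dynamic program over anchors requiring
strictly increasing ranks (decreasing in B for inverted blocks) with
rank gaps ≤ `max_gap` = 25 on both genomes, extracting disjoint chains
greedily in decreasing size. `min_block` = 5, `top_hits` and `max_gap`
follow the documented defaults of the standard collinearity scanner
this module re-implements in simplified form.

Gap-constrained chaining alone reports chance chains on unrelated gene
orders (a random permutation of 200 ranks almost always contains
gap-25-bounded increasing runs of five). The standard tool suppresses
these with a block e-value; famscan uses a simpler surrogate with the
same effect: a minimum block density, anchors per spanned rank ≥ 0.5 on
both genomes. True collinear runs are dense; chance chains are sparse.
With the filter, shuffled gene orders yield zero blocks in 100/100
trials at n = 200, while planted consecutive-rank blocks are unaffected.
The trade-off: a real block diluted below the density threshold by
extensive interleaved gene loss would be discarded; lower `min_density`
for such data. Block score is anchor count (no e-value model).

## ProtParam

Average residue masses, the Bjellqvist pK set (side chains D 4.05,
E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; termini 3.55/7.5 with
residue-specific exceptions) and the Kyte–Doolittle scale follow the
ExPASy ProtParam convention, because published per-protein tables in
this literature come from that site; all three tables are module data
and can be substituted. pI is the bisection root of the net charge on
pH [0, 14] to |charge| < 1e−4 in ≤ 100 iterations (the charge is
strictly decreasing in pH, so the root is unique). X residues weigh the
mean residue mass, carry no charge, and are excluded from the GRAVY
denominator. The test suite cross-checks every value against
Biopython's independent implementation of the same convention.

## Phylogeny and grouping

Distances are pairwise p-distances (mismatch fraction over gap-free
columns of the global protein alignment). Trees are Saitou–Nei neighbor
joining with a deterministic tie-break (first minimal Q pair in index
order); on additive matrices NJ provably recovers the generating tree,
and the tests verify exact recovery (topology; patristic distances
within 1e−9) on random 8-leaf trees. Negative branch-length estimates
are clamped to zero and counted in the `clamped_branches` annotation.
Maximum-likelihood inference and bootstrap support are deliberately out
of scope: group identity is anchored by reference leaves (each unlabeled
leaf takes the group of its patristically nearest reference; ties go to
the lexicographically smallest group name), not by tree-shape fidelity
to any published figure.

## Promoters and cis-elements

Promoters are the 1,500 bp immediately 5′ of the translation start on
the coding strand, excluding the start codon itself ("upstream of" read
strictly; `include_start` appends it), reverse-complemented for
minus-strand genes and truncated with a warning at chromosome edges.
Scanning reports every overlapping occurrence of every catalog pattern
on both strands separately — a CGTCA site is simultaneously a plus-strand
CGTCA-motif hit and a minus-strand TGACG-motif hit and both are
reported; N in the sequence never matches. The shipped catalog carries
one consensus string per element (G-Box CACGTG, ABRE TACGTGTC, CGTCA-
and TGACG-motifs, P-box, GARE-motif, TGA-element, TCA-element, HSE, MBS,
TC-rich repeats, CAT-box, CCGTCC-box) across light, hormone, stress and
meristem classes. Consensus strings for several of these elements vary
between database versions; the catalog is data, not code, and per-gene
counts from it are not comparable to any particular database's output.

## Expression

ΔCt = mean Ct(target) − mean Ct(reference) per sample,
ΔΔCt = ΔCt(sample) − ΔCt(calibrator), fold = 2^−ΔΔCt, with the spread
propagated as 2^−(ΔΔCt ± sd) from the replicate SD of ΔCt.
Significance is a two-sided Welch t-test on per-replicate ΔCt values,
sample versus calibrator, starred at 0.05/0.01 with no multiple-testing
correction — the raw-threshold convention of qPCR bar plots; the
source protocol names no test, and Welch on ΔCt is the standard choice
for 2^−ΔΔCt designs. Identical replicate sets report P = 1. Undetected
genes are absent rows, not zeros.

## Synthetic data: what it emulates and what it does not

The generator is the package's test surface; its defaults are the study
conditions for every quantitative guarantee.

Family proteins derive from a shared scaffold (families descend from a
common ancestor): a base scaffold → four group scaffolds (background
substitution rate 0.22) → members (rate 0.08), with query proteins at
rate 0.30 emulating homologs from another species. Only background
positions mutate — consensus-critical residues never do — and background
alphabets are chosen so ground truth is unambiguous: member linkers are
hydrophilic and free of C/H/F/Y/W/R (no accidental fingers, no
accidental KKKR/KRKR), decoy backgrounds are broad but cysteine-free
(every finger pattern needs two cysteines, and compositionally narrow
sequences would cross-score under BLOSUM62). Decoys carry at most two
fingers or a four-finger domain broken at a coordinating Cys→Ser.
Groups 1–3 carry both C-terminal motifs; group 4 carries neither. The
NLS is planted per member with probability 0.8.

Coding sequences are uniform-synonymous back-translations (no codon
bias; no claim here depends on it) split into 2–4 exons with random
introns, placed on random-sequence chromosomes (default five of
600 kb) on random strands with promoter headroom. Planted duplicate
pairs (default two tandem at ≥ 200 kb separation, mirroring the printed
rule, and two segmental on different chromosomes) are evolved copies of
distinct base members: the evolver plants round(S·pS) synonymous and
round(N·pN) nonsynonymous substitutions at distinct nucleotide
positions, where pS and pN invert the Jukes–Cantor map at the target Ks
and Ka and S, N are the NG86 site counts of the input — so the NG86
estimator is expected to recover the targets (defaults Ka 0.05,
Ks 0.25, the purifying-selection regime reported for real pear
duplicates, ratio ≈ 0.2). Substitutions never create stops, and
nonsynonymous ones avoid the domain, NLS and motif spans so a duplicate
remains a detectable member.

Member promoters are rewritten in-genome: a background scrubbed of every
catalog pattern on both strands, plus planted element copies at disjoint
positions (default 3 CGTCA + 2 G-Box per member). The construction is
verified: plus-strand per-element counts equal the plan exactly and
every hit on either strand lies inside a planted site. Truth counts use
the plus-strand convention, since a planted site also produces the
minus-strand hits its reverse complement implies (G-Box is palindromic;
CGTCA mirrors TGACG).

The two-genome bundle plants one collinear block per chromosome pair
(default an 8-anchor same-orientation and a 6-anchor inverted block),
each a run of genes — one family member, the rest generic neighbors —
whose orthologous copies (Ka 0.02 / Ks 0.05) appear in preserved or
reversed order in genome B.

Ct tables put the reference gene at expected Ct 20 across samples and
targets at ref + 3 − log2(fold change), Gaussian noise sd 0.2 cycles
(within the typical technical-replicate range), three replicates.

Not emulated: realistic intergenic composition, codon bias, indels and
alignment ambiguity, gene losses inside collinear blocks, splice-variant
complexity, amplification-efficiency variation. Passing tests therefore
demonstrate correctness of the algorithms under clean, planted
conditions — not robustness to every artifact of real genome data.

## Problem sizes

Test and reproduction runs are sized for a laptop: 20 members + 20
decoys for identification (the pear-style duplication analysis uses 16
members with 4 segmental pairs), 900-codon sequences × 20 seeds for
divergence-target recovery, 250-codon alignments × 20 seeds for window
ranking, two planted blocks plus a 100-seed × 200-gene shuffled null
for synteny, 8-leaf trees × 50 seeds for NJ, and 1,000 null runs for
the Welch type-I error. The whole suite runs in well under a minute of
compute for the acceptance script and about half a minute for the test
suite.

## Known limitations

- The identification rule codifies a "manual domain check"; borderline
  real proteins with unusual finger spacing (> 220 aa span) would be
  rejected unless `max_domain_span` is raised.
- NG86 is a counting method; for highly diverged pairs (Ks ≳ 1) a
  maximum-likelihood codon model would be preferable and is out of
  scope.
- The DnaSP-style exact correction details may differ from this NG86
  implementation at the third decimal; comparisons to published tables
  should allow for implementation variance.
- The block-density filter substitutes for a proper collinearity
  e-value; data with heavy post-duplication gene loss may need a lower
  `min_density`.
- PlantCARE-style element consensi are version-dependent; shipped
  catalog counts are not comparable to web-server outputs.
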