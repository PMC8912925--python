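# Methods

## The model

`phyloreg` treats an LTR retroelement family as the outcome of a
burst-amplification process: an ancestral LTR gives rise to subfamily
*founders* along a backbone tree; each founder is then copied many times
over a short interval (a transpositional wave), and every copy diverges
independently afterwards. Under this model a subfamily is a clade whose
subtending edge is long (the backbone divergence separating founders)
and well supported, while its internal edges are short (the burst).
Inter-element recombination, tandem duplication and motif gain act at
the founder level, before the burst, so all copies of a subfamily
inherit the event — which is why block-level phylogenetic incongruence
and subfamily-restricted motifs are informative about founder history.

## Subfamily partitioning

`partition_tree` evaluates every internal edge of an unrooted tree on
its bipartition: the smaller side is a candidate subfamily when edge
support ≥ `support_min` (default 0.95), edge length > `branch_min`
(default 0.015 subs/site; for a ~430-bp LTR this is ~6 substitutions)
and the side holds strictly more than `size_min` (default 10) leaves.
Among nested candidates the **smallest** qualifying clade is taken.
This is deliberate: with a non-star backbone, a super-clade spanning
several bursts also clears the edge criteria, and taking maximal clades
would merge genuine subfamilies; the burst itself is the qualifying
clade that contains no smaller qualifying clade. Discarded super-clade
candidates are retained in `Partition.nested_diagnostics`. Because the
criterion is edge-based, the partition is invariant to rerooting and
leaf order, and raising any threshold can only reduce the number of
accepted clades.

Support comparisons use ≥ after normalizing percent supports to
proportions; member count and edge length are strict (> ) following the
">10 members, >0.015" convention.

## Trees, bootstrap, parsimony

Distances are p- or Jukes–Cantor distances with pairwise deletion of
gap/N columns. Trees are built by neighbor-joining (vectorized, ties
broken by lexicographic pair order, negative branch lengths clamped to
0, terminal trifurcation via the three-point formulas). Clade support
is the classical column-resampling bootstrap: the support of an edge is
the fraction of replicate NJ trees containing the same bipartition
(default 1000 replicates; the bundled recovery analyses use 100, which
is sufficient at a 0.95 threshold for the default signal strength).
External trees (e.g. from IQ-TREE) are accepted as newick with support
labels on internal nodes, on either a [0,1] or percent scale.

Small parsimony is Fitch counting over columns with gaps and N as
union-compatible unknowns; a fifth-state mode treats the gap as a real
character (used for blocks whose presence/absence is itself the
signal). Tree search is stepwise addition followed by
nearest-neighbor-interchange hill climbing, deterministic given a seed,
and is intended for the ≤ ~25 consensus taxa regime; the 4-taxon case
is verified against exhaustive enumeration.

## Consensus and assignment

The majority-rule consensus emits, per column, the symbol among
{A,C,G,T,−} whose frequency reaches `frac` (default 0.51); a winning
gap deletes the column (consensuses can be shorter than the alignment
frame), and anything short of the majority becomes `N`. A 50/50 column
therefore yields `N`. `assign_by_similarity` places arbitrary sequences
with the nearest consensus by p-distance over the aligned (non-gap)
columns of a global alignment (edlib); ties break by consensus name
order.

## Median-joining network

`snp_matrix` keeps alignment columns that are polymorphic and free of
gaps and N across all consensuses. `build_mjn` builds the minimum
spanning network (all minimum-spanning links; ε = 0 by default) under
Hamming distance, then repeatedly adds *median vectors* — the per-site
majority of a linked pair and any third node — until no novel vector
arises. Medians not on any shortest path between observed haplotypes
are pruned; a final reduction removes any median whose removal does not
lengthen the spanning total and, for networks of ≤ 20 nodes, re-admits
candidate medians that strictly shorten it (this terminates because
(total length, node count) decreases lexicographically). On small
inputs (≤ 5 taxa, ≤ 8 SNPs) the resulting spanning total equals the
exhaustive minimum over median-augmented node sets, which the test
suite verifies. Identical haplotypes share one node; node size is the
summed member count of its taxa.

## Dating

Terminal branch length — the edge from a leaf to its nearest node — is
the per-insertion age proxy; group comparisons use two-sided Wilcoxon
rank-sum tests (exact for small samples) with a Bonferroni factor equal
to the number of tests performed in the call. Orthology dating consumes
a presence/absence matrix (reciprocal-liftover survival in practice)
and reports the shared fraction per subfamily per species, ordered by
divergence.

## Regulatory overlay

Peak overlap is computed by a sorted sweep over merged peak intervals;
an element is positive when its total overlap is ≥ `min_bp` (default
1 bp, i.e. any overlap) or, in fraction mode, when overlap/length ≥
`min_frac` (the 70% variant). Top-septile calls take the 6/7 quantile
threshold with boundary ties included; expression calls are strictly
fpkm > 2. Enrichment per (mark, comparator subfamily) is a 2×2
chi-square without continuity correction, replaced by Fisher's exact
test when any expected cell is < 1, Bonferroni-corrected by the number
of tests in the invocation. Under the simulator's null mark model the
family-wise error is verified empirically to stay below the nominal
level.

## Recombination and duplication

Blocks are user-defined contiguous column ranges of the consensus
alignment (the simulator provides its own block frame). Per block a
tree with bootstrap supports is inferred (NJ by default; parsimony with
optional fifth-state gaps for presence/absence blocks). An
`IncongruenceEvent` is a block-tree bipartition with support ≥ 0.95
that is incompatible (all four side-intersections non-empty, restricted
to shared taxa) with a reference bipartition that is itself supported
at the same threshold — unsupported reference edges carry no evidence.
Events are deduplicated per (block, clade) and overlapping clades
within a block merge, so the count is a minimum. Directionality is
reported only when per-taxon ages order the partners; otherwise "?".

A caveat measured during development: at the default scale (~64-bp
blocks, founder divergence 0.05 subs/site) parallel substitutions among
founders occasionally produce genuinely supported conflicting clades
in recombination-free data (~3 events per 50 simulated families, at
supports 0.95–0.97 verified with exact founder sequences and 1000
bootstrap replicates). Incongruence counts at this block scale should
therefore be read as candidate minima, not certainties — consistent
with reporting "a minimum of N events".

Duplication detection globally aligns two blocks of one consensus
(match +1, mismatch −1, gap open −2, extend −1), computes identity over
aligned columns excluding terminal overhangs, and calls a tandem
duplication when the blocks are adjacent and identity ≥ 0.70. Two
copies diverging at 0.1 subs/site each land at ~81% identity under the
substitution model below.

`scan_breakpoints` is advisory: sliding-window trees are scanned left
to right, supported bipartitions accumulate, and a window conflicting
with an accumulated bipartition yields a candidate at the midpoint
between the conflicting windows' centers. Block definitions remain an
input.

## Motifs

The scanner scores log2-odds (pseudocount 1e-3, uniform background by
default) on both strands, skipping windows containing N, with a
default threshold of 80% of the maximal achievable score. PWMs are
parsed from JASPAR count (pseudocount 0.5) and HOMER probability
formats, or built from a literal motif string. Enrichment is ZOOPS —
a sequence counts once if it has ≥ 1 hit — with a one-sided
hypergeometric p for target hits against the pooled target+background
set, per motif × block × ordered subfamily pair (groups with < 5
sequences are skipped). The cutoff is p ≤ 1e-5.

## The simulator

`simulate_family` draws a random ancestor (default 450 bp), evolves
founders along a Yule or deterministic caterpillar ("ladder") backbone
with a fixed substitution dose per edge, applies founder-level events
(recombination copies the donor's block into the acceptor; duplication
appends a copy of a block adjacent to itself; motif gain inserts a
literal string), then emits copies with terminal branch lengths drawn
Exp(mean) — per-subfamily means accepted — plus per-copy substitutions
and indels. Substitutions follow a single-parameter event process:
Poisson(μL) events, uniform site, uniform alternative base, so multiple
hits occur and the expected observed divergence is
p = (3/4)(1 − e^(−4μ/3)); the Monte-Carlo test checks this closed form.
Indel events are Poisson(rate·L) with geometric lengths (mean 3).

Founder evolution is substitution-only; indels arise on terminal
branches and as the planted events. This keeps block coordinates
well-defined in the ancestor frame and lets the simulator emit the
exact true alignment (insertions are tracked and stacked left-justified
into shared columns), so the pipeline needs no external aligner —
users with real data supply their own MSA instead. Regulatory marks
are independent Bernoulli draws per element conditional on subfamily
(defaults emulate the characteristic activation contrast of one young
transcribed subfamily against the rest: KLF4 0.91 vs 0.20, NANOG 0.977
vs 0.30, H3K4me3 0.76 vs 0.19, H3K27ac 0.89 vs 0.48, with KAP1 flat at
0.35). Ages are uniform within each subfamily's activity window (three
default waves: 40–25, 20–9 and 10–4 Mya) and orthologous presence in a
species follows deterministically from age > divergence time (defaults:
chimp 6, gorilla 9, orangutan 16, gibbon 20, macaque 25 Mya).

What the simulator does **not** emulate: template-switching mechanics,
selection, nested insertions, alignment error (the true MSA is given),
genomic context effects on regulatory marks, and liftover failure modes
other than age. Passing tests therefore demonstrate correctness of the
inference machinery under the stated generative model, not robustness
to real-data artifacts such as misalignment or annotation error.

## Problem sizes and known limitations

The bundled analyses run at desk scale: 8 subfamilies × 30 copies
(~240 × 600 alignments), 100 bootstrap replicates, 20–50 simulation
seeds per recovery property. Two statistical limits of the default
conditions are documented rather than hidden. First, wave dating:
with exponential terminal-branch draws and ~450 bp of sequence, the
0.012 vs 0.025 subs/site wave pair carries only ~4σ of signal at
n ≈ 100–150 per wave, so Bonferroni padj < 0.01 for *all* between-wave
pairs holds in roughly 16–17 of 20 seeds — the information ceiling of
the sequence length, not of the estimator (measuring divergence
against the true founders does no better). Second, the residual
homoplasy rate in recombination-free block scans described above.
Both are asserted at their target levels in the acceptance suite and
the shortfalls are visible there.
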