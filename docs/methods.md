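# Methods

This note documents the models behind each stage, the tunable parameters
and their defaults, what the synthetic-genome generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Orthology

Input is an all-vs-all protein similarity table in the ubiquitous 12-column
tabular dialect, plus a query-coverage column (computed as
100·alignment_length/query_length when absent).  Hits are filtered at
E-value < 10⁻¹⁰ (strict), percent identity > 60 (strict) and query coverage
≥ 60; the asymmetric strictness mirrors how the thresholds are usually
phrased ("under", "over", bare "60% coverage") and each comparison is
configurable.  For every ordered genome pair and query, the best subject
maximizes bitscore, breaking ties by smaller E-value and then
lexicographically smaller subject id — a fully pinned order that makes the
reciprocal-best-hit (RBH) set invariant to input row order.  Ortholog
groups are connected components of the RBH graph.  Spectral refinement of
components (as ProteinOrtho performs) is deliberately not reproduced: the
package's accuracy contract is exact recovery of planted orthology on
synthetic data, and connected components meet it while staying transparent.
The genome × OG count matrix has an optional capped view (`cap=2`) for
dosage heatmaps.

## Regulator classification

Per-protein domain hits are first overlap-resolved greedily by descending
bitscore (ties: lower alignment start, then accession); a hit is kept iff
it overlaps every kept hit by at most 50% of the shorter interval.  The
sigma-factor cascade then fires in a fixed order (first match wins):
sigma54 core triplet (PF00309 + PF04963 + PF04552) → RpoN; Sigma70_r1_2 +
Sigma70_r3 → groups 1–2; lone Sigma70_r3 → group 3 (FliA-like);
Sigma70_r2 + Sigma70_r4_2 → group 4 (RpoE-like); any remaining
Sigma70-region domain → generic sigma70-like.  Region domains are matched
both by pinned accession and by the `Sigma70_` name prefix, because domain
tables in the wild name regions without always carrying the accession the
caller expects.  bEBP = PF00158 + PF00072; HKS = PF00512 (HisKA) +
HATPase_c; accessory sensory domains (PAS, HAMP, cache) never block a
call.  Sub-labels inside groups 1–2 (RpoD vs RpoS vs RpoH) require
orthology to user-supplied reference proteins and are out of scope for the
architecture rules.  A protein carrying all four bEBP+HKS domains (hybrid
kinase) is reported once, as a bEBP with a `hybrid_kinase` flag and a
warning — forcing hybrids into a single clean class would hide real
biology, and the classification contract of one call per protein is kept.

Two-component pairing searches the bEBP's own transcriptional unit plus one
flanking unit on each side (window configurable), takes the nearest HKS by
gene distance, breaks ties toward the downstream neighbour, and reports
bEBPs without any reachable HKS as one-component regulators (the HupR
pattern).

## Transcriptional units and upstream regions

Genes join one TU iff same strand and intergenic gap
`next.start − prev.end − 1` ≤ 40; "more than 40 bases" breaks.  The same 40
is used both for TU joining and for declaring an upstream region; both are
independently configurable because the two roles are conceptually distinct.
Overlapping same-strand genes count as gap 0 and join (logged); contained
genes are rejected as annotation errors.  Upstream regions run from the
base after the previous coding feature (any strand) to the base before the
leader gene, capped at 300 nt — a typical bacterial promoter-search window;
the cap is a parameter.  Minus-strand regions are reverse-complemented so
the string always reads toward the gene.  Divergent gene pairs each receive
their own oriented copy of the shared intergenic DNA.  Replicons are
treated as linear (wrap-around joining off): draft assemblies dominate the
intended inputs.

## PWMs, backgrounds and scanning

PWMs store per-column probabilities over ACGT; construction from n aligned
sites uses `(count + α·q_b)/(n + α)` with q uniform, α = 0 for exact
frequency recovery and α = 0.1·n recommended for user site collections.
Markov backgrounds of order k ≤ 4 are estimated from (k+1)-mer counts with
add-one smoothing, skipping windows containing N, with conditionals fitted
for every context length ≤ k so sequence starts are covered.

Scanning scores log₂ odds against the background's order-0 marginal.
P-values are exact under that marginal: scores are discretized to multiples
of ε = 10⁻³ bits and a dynamic program over columns accumulates the null
score distribution, so p(s) = P(score ≥ s) with p(min score) = 1.  Using
the order-0 marginal even when a higher-order background was trained
matches standard scanner practice — the exact DP requires positional
independence.  Windows containing N are skipped; both strands are scanned
by default (switchable); hits are kept at p < 10⁻⁴ and then overlap-
filtered greedily by descending score (ties: smaller p, then leftmost),
dropping any hit overlapping a kept one by more than 50% of the shorter
hit; the filter is idempotent and order-invariant.  Discreteness of the
score lattice means the achieved false-positive rate at a nominal
threshold is the largest attainable p-value below it; for PWMs with a
dense score spectrum this sits just under the nominal rate, while
consensus-like PWMs with few distinct column values can achieve
substantially less.

A PWM whose only informative columns are the five −24/−12 consensus bases
has an attainable p-value floor of 4⁻⁵ ≈ 9.8·10⁻⁴, so promoter
classification (`call_promoter`, 60-nt window, coding strand) defaults to
p < 10⁻³ rather than the genome-scan default; both are parameters.

## ZOOPS discovery

The ZOOPS model gives each sequence at most one site: occupancy γ, uniform
position over both strands.  For each width, candidate PWMs are seeded from
the five most over-represented words (count over background expectation,
seed base probability 0.7, γ₀ = 0.5) and refined by EM: the E-step computes
per-position site posteriors from likelihood ratios against the trained
background, the M-step re-estimates the PWM with pseudocount 0.01 and γ as
the mean per-sequence occupancy posterior.  The recorded objective is the
penalized (MAP) log-likelihood including the Dirichlet term implied by the
pseudocounted M-step — that is the quantity this EM provably never
decreases; the trace is exposed and asserted non-decreasing in the tests.
Convergence at gain < 10⁻⁶ or 200 iterations.  The best width/seed is
chosen by per-site information content × expected site count rather than
MEME's E-value approximation — a documented deviation; the accuracy
contract is recovery of planted motifs, not MEME output parity.  Found
sites are probabilistically erased (letter weights scaled by one minus the
site posterior) before the next of up to 10 motifs.

Two empirical properties of this estimator are worth knowing.  First, γ̂ is
biased upward by a few points: sequences without a site still collect
posterior mass on their best-scoring windows (the expected likelihood ratio
of a background window is exactly 1), so at the reference discovery
conditions (30 × 200 nt, planted width 12 at ~1.6 bits/column, γ = 0.8) γ̂
typically lands in 0.80–0.95.  Second, on pure background the EM still
converges to an apparent motif of roughly 0.7 bits/column — an
overfitting artefact of picking 30 best windows out of ~11 000 — so
"motif found" judgements should compare against that floor, not against
zero.

Information content is Schneider–Stephens: Rseq(j) = 2 − (H_j + e(n)) with
e(n) = 3/(2·n·ln 2), clipped at 0; e(4) ≈ 0.5410 bits.

## Circuit assembly

Site hits are mapped to TUs through the upstream-region FASTA (record id =
TU id); each (motif, TU) pair with a surviving hit becomes one edge
carrying the best p-value.  bEBPs in a TU divergently head-to-head with a
neighbour within 300 bp (configurable) gain colocalization edges to that
neighbour; evidence kinds merge when both apply.  Regulators are reported
at protein level (motif ids for site evidence); an optional OG-level
collapse produces the cross-genome summary view.  The pipeline
(orthology → classify → TUs → scan → network) writes every intermediate
plus a manifest with parameters, seed and input checksums, and contains no
timestamps, so identical config and inputs give byte-identical outputs.
Per-genome order-4 backgrounds are trained from the replicon sequences for
scanning, by default.

## The synthetic generator

`generate_genome_set` emits exactly what the pipeline reads.  Operons are
laid out left to right on alternating strands with uniform intra-operon
gaps in [1, 40] and inter-operon gaps in (40, ∞) — (150, 300) by default,
(650, 900) in the reference end-to-end configuration so that the ≤300-nt
upstream windows of divergent neighbours never overlap and every planted
site belongs to exactly one TU (with the narrower default gaps, a site in a
shared divergent intergenic region would legitimately appear in two
upstream regions).  A consequence of the wide reference gaps is that
divergent colocalization edges do not arise in the reference run; that
evidence path is exercised by dedicated unit tests instead.  Gene sequences
are background DNA and proteins are random amino-acid strings with domain
hits asserted in the table rather than detected — the pipeline consumes
domain tables, and upstream HMM scanning is out of scope.  The similarity
table encodes planted orthology as strong reciprocal hits (identity 90%,
coverage 100%, E = 10⁻⁵⁰) plus sub-threshold noise pairs, which makes RBH
recovery exactly checkable.  Binding sites are planted generatively ZOOPS:
per target TU a γ-coin, a uniform offset inside the upstream window, a
uniform strand, letters sampled column-wise from the PWM.  The truth bundle
(operons, architectures, ortholog groups, sites, colocalized bEBPs) is
written alongside and is byte-reproducible from the seed; all randomness
flows from the mandatory config seed through per-genome child generators.

What the generator does not emulate — and what passing tests therefore do
not demonstrate about real data: codon structure and realistic protein
evolution (domain tables are asserted, so classification accuracy 1.0
reflects rule correctness, not HMM sensitivity), assembly fragmentation,
overlapping genes, horizontal transfer, compositional heterogeneity beyond
a homogeneous order-k background, and binding-site co-evolution with their
regulators.

## Reference conditions and observed performance

The reference end-to-end configuration is 3 genomes × 40 operons (2–4
genes each), seven planted regulator architectures including two complete
TCSs and a one-component bEBP, and two planted 12-wide motifs at ~1.6
bits/column targeting 15 operons per genome at γ = 0.9.  At these
conditions the recovered edge list reaches precision and recall ≈ 0.95 at
the pinned test seed; across data seeds precision varies in roughly
0.89–0.95 because the expected ~8 false edges from 1.4·10⁵ scanned windows
at p < 10⁻⁴ sit against ~81 true edges.  TU, classification and orthology
recovery are exact by construction of the gap rule, the unambiguous planted
architectures, and the sub-threshold noise model.

## Known limitations

- Exact p-values are computed under positional independence (order-0
  marginal); higher-order backgrounds affect discovery likelihoods but not
  scan p-values.
- γ̂ from ZOOPS is upward-biased on short sequence sets (see above).
- Connected-component clustering can chain distinct families through a
  single promiscuous RBH pair; the thresholds make this rare but not
  impossible on real proteomes.
- Promoter classification uses consensus-element PWMs with few informative
  columns and correspondingly coarse p-values; it ranks classes, it does
  not provide calibrated significance.
- Circular replicons are linearized; operons spanning the origin would be
  split.
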