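# Methods

This note documents the models, parameter choices and numerical decisions
behind `pletype`, and what its synthetic fixtures do and do not demonstrate
about real data.

## The marker-gene model

Each *Pseudomonas* lipopeptide (LP) biosynthetic gene cluster carries a
dedicated tripartite efflux system (periplasmic adaptor / MacB-like ABC
transporter / outer-membrane protein, generically PleA/PleB/PleC). Because
the transporter binds the LP it exports, its sequence tracks the chemistry
of the product, and a fragment of *pleB* works as an MLST-style marker for
the LP family. The package operationalizes this as:

1. amplify *pleB* in silico with one of two degenerate primer sets,
2. trim the amplicon to the 878-nt diagnostic core the two assays share
   (reference-gene positions 590–1467; the transporter's periplasmic core
   domain),
3. assign the family of the nearest reference by percent identity, and
4. optionally corroborate with a neighbor-joining tree and with the
   correlation between *pleB* and concatenated-NRPS identities.

Known caveats built into the interface: a negative amplification is a
reportable outcome, never an error (primer specificity, not absence of a
cluster, may be the cause); the Xantholysin and Entolysin transporters form
one intertwined clade, so when the top two references straddle those
families within 2 identity points the merged clade label is reported; and
transporter typing can disagree with the product (one Antarctic isolate
clusters with Viscosin on *pleB* yet makes a Bananamide-family LP), which
is why `flag_discordance` exists. A single transporter can also serve two
clusters in rare strains; typing reports one family per *pleB* and cannot
represent dual products.

## In-silico PCR

A primer position is compatible with a template position when their IUPAC
base sets intersect; template ambiguity codes are therefore matched
permissively. Inosine (`I`, present in one published reverse primer) pairs
with any base but is a single synthesized molecule, so it matches like `N`
while contributing ×1 to degeneracy. Degeneracy is the product of
per-position base-set sizes (BanAmpGac F = 6, PutXanTol F = 48).

A site qualifies when it has at most `max_mismatch` incompatible positions
(default 2) and none within the 3′-terminal `clamp_len` bases (default 3,
the polymerase-extension clamp). Products pair a forward site with a
downstream reverse-complement site on the opposite strand, in both
orientations, within a size window (defaults 400–2500 bp). These defaults
were chosen once so that both published assays amplify their target
families while suppressing spurious short products; the wet protocol's
thermodynamics (annealing temperature, cycling) are deliberately out of
scope, and no melting-temperature or dimer model is attempted. The
published mismatch tolerance is not stated anywhere, so the default of 2 is
a calibration choice exposed in the API and CLI.

Coordinates are 1-based inclusive on the + strand; amplicon FASTA headers
record `template:start-end(strand)`.

Implementation: templates and primers are encoded as 4-bit base masks and
scanned with a sliding-window AND; the test suite checks the site lists
against a position-by-position pure-Python scan over all offsets and both
strands.

## Alignment and identity

Pairwise only — typing needs no multiple alignment, and keeping MSA out of
scope avoids re-implementing aligner heuristics. Scores: nucleotide +5/−4,
gap open 10, gap extend 0.5 (first gap position costs the open penalty);
protein BLOSUM62. Dynamic programming is delegated to Biopython's
`PairwiseAligner`; `semiglobal` mode frees terminal gaps for locating a
fragment inside a longer sequence.

Percent identity = 100 × matches / counted columns, excluding columns
inside leading/trailing gap runs of either row by default so partial
amplicons compare fairly against full genes. Identity is symmetric,
bounded in [0, 100], and 100 exactly iff the sequences are identical under
terminal-gap exclusion.

**Core trimming** aligns the 878-nt core semiglobally against the query and
returns the query subsequence spanning the aligned core columns, with the
core coverage fraction (< 0.9 flags the fragment partial). Rejection is
two-fold: aligned-region identity < 40% or core coverage < 30% raises a
no-core-found error. The coverage floor matters because gapped alignment of
*unrelated* sequences does not drop to the naive 25% background: random DNA
reaches ~43% identity at ~0.7 coverage (it then passes as heavily partial
and is discarded at typing, below the family floor), while low-complexity
input can pathologically reach 100% identity at a few percent coverage —
the coverage floor catches it. The exact core length is 878 nt; the
package reports the exact value and leaves "≈880 bp" phrasing to prose.

The packaged core sequence is a **synthetic stand-in** generated from a
fixed seed with *Pseudomonas*-like GC (0.60): it reproduces the real
reference gene's geometry, not its sequence. Users with the real reference
region supply it via `CoreRegion(core_seq=..., reference_id=...)`; nothing
in the package fetches accessions at import or test time.

## Typing

1-nearest-neighbour on percent identity is the primary classifier; tree
placement is advisory output. Tiers: identity ≥ 95% → `known_LP_match`,
≥ 75% → `novel_within_family`, else `unassigned`. The published identity
anchors are protein-level (most divergent transporters ~70%, intra-family
typically > 90%); fragment-level nucleotide cutoffs are not published, so
95/75 are calibration defaults exposed in `TypingThresholds`, and
`calibrate` re-derives a family floor from any panel as the midpoint
between the lowest intra-family and highest inter-family identity. Ties
break on higher identity then lexicographic strain id; results carry the
top-3 references. Typing against families the primers were not designed
for (Factin, Viscosin, Orfamide, Poaeamide, Peptin) requires an explicit
flag — the published assays do amplify many of those producers, but were
not validated for them.

## Neighbor joining and bootstrap

Standard NJ agglomeration on identity distances (d = 1 − identity/100),
with deterministic tie-breaking (lowest row/column pair) and negative
branch lengths clamped to zero with the deficit moved to the sibling so
path lengths through the join are preserved. An all-zero matrix returns a
star tree. On exactly additive matrices NJ provably recovers the true
topology and all path lengths; the suite verifies this on 200 random
6-taxon trees and checks the 3-taxon closed form to 1e-9, with
scikit-bio's independent `nj()` as a cross-check oracle.

Maximum-likelihood inference (the published trees used GTR+G+I / JTT+F+I+G
models) is intentionally not re-implemented: the typing claims rest on
cluster membership, not branch-length estimates, and the distance matrix
can be exported (PHYLIP/TSV) for external ML tools. Bootstrap support
resamples alignment columns of equal-length fragments (p-distance per
replicate, gap-pair columns ignored per pair) and reports the percentage
of replicates containing each internal bipartition. Trees serialize to
Newick with single-quoted labels when needed; midpoint rooting is for
display only.

## pleB–NRPS correlation

Pearson *r* is computed over strain pairs exactly as the published analysis
does (x = *pleB* nucleotide identity, y = concatenated-NRPS amino-acid
identity, concatenation in gene order). Because the C(n,2) pairs share
strains they are not independent, so significance uses a Mantel
permutation: strain labels of the y identity matrix are permuted,
*r* recomputed, and p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm). The naive
parametric p-value is reported alongside for comparability only.

Identity method: when both input sets are length-uniform (trimmed cores of
indel-free sequences) identities default to the ungapped p-distance, which
is exact for equal-length gap-free homologs; otherwise every pair is
globally aligned. The distinction matters at the margins: at ~25%
divergence an optimal-score affine-gap alignment occasionally buys two
compensating 1-nt gaps to convert three or more mismatches into matches,
over-estimating identity by ~0.1 points — harmless for typing, but enough
to blur an exactness property the synthetic generator guarantees.

## Synthetic data

The generator is the package's study-conditions fixture, a pure function of
its spec and seed (byte-identical output across runs).

**Genes.** 1,950 nt with the diagnostic core at positions 590–1467 and
exact-match expansions of *both* primer sets embedded in the flanks, so the
BanAmpGac assay yields a 1,300-bp product (300–1599) and PutXanTol a
1,000-bp product (520–1519), both spanning the core — the real genes'
layout. Backbone GC is fixed at 0.60 (cosmetic, *Pseudomonas*-like).

**Panels.** Star topology: each family's centroid core substitutes a
fraction of reference positions, each member/query a further fraction at
positions disjoint from its centroid's. Requested intra-/inter-family
divergences are *pairwise* p-distance targets; the planted per-lineage
fraction solves t = 2p − (4/3)p² to correct for coincident substitutions.
Defaults (5 families × 4 references, intra 5%, inter 35%) give clean
family structure; setting intra = inter collapses the centroids and typing
falls to chance — the negative control. Mutations are substitutions only
by default so identity arithmetic stays exact; an indel mode exists for
trimming stress tests. Primer sites are never mutated, so synthetic panels
do not exercise amplification *failure* from primer-site divergence (the
behaviour real screens show for some producers); failure handling is
tested with site-free templates instead.

**Coupled sets.** Each strain mutates a disjoint block of positions in
both its *pleB* (nucleotide) and NRPS (protein) sequence, with per-strain
counts proportional to a common integer unit; NRPS counts are slope-scaled
with optional per-strain Gaussian noise (in divergence-fraction units).
Positions sit on a stride-3 grid so every mismatch is isolated and the
optimal pairwise alignment is provably gapless; at zero noise the pair
identities are then exactly affine and *r* = 1 to machine precision.
Because noise enters per strain, it is correlated across pairs sharing a
strain — exactly the non-independence the Mantel test addresses.
`calibrate_noise_sd` bisects the noise level to hit a target mean *r*
(e.g. 0.9) using a fast Hamming-based probe.

**What passing these tests shows.** That the pipeline's logic — site
matching, trimming, identity tiers, tree clustering, correlation — behaves
as specified under controlled divergence. Star-topology substitution-only
evolution has no rate heterogeneity, no tree structure within families, no
recombination and no compositional drift, so synthetic accuracy figures
(e.g. 100/100 typing recovery) bound what the method can do under its own
assumptions, not its field accuracy on environmental isolates. The
published screen-scale numbers (92/126 amplicon-positive strains, 77
family assignments, per-family *r* between 0.79 and 0.96) depend on
sequence accessions that are deliberately not fetched here; reproducing
them is an optional workflow with user-supplied data, not a test.

## Reference tables

Transcribed family/producer/peptide tables ship as UTF-8 TSVs. Decisions
taken in transcription: the known-producer census counts 23 strains over
the seven targeted families (Bananamide 3, Amphisin 6, Gacamide 2,
Putisolvin 5, Xantholysin 3, Entolysin 1, Tolaasin 3); the Amphisin family
lists seven strain rows because lokisin has two producer strains, so the
second one is flagged `additional_strain` and excluded from the census.
One source tally elsewhere gives 53 vs 54 known producers in different
places; the packaged panel follows the table rows. Lokisin itself has no
printed residue sequence and is omitted from the peptide table. The Peptin
family spans lengths 19–25 with macrocycles 5–8 or linear; its single
profile row follows syringopeptin SP22 (22, 8) with the spread recorded in
the note column, and Peptin is non-targeted so nothing downstream depends
on it. Cells the printed peptide table left blank (congener rows
inheriting strain or residues) are filled explicitly and flagged in the
`inherited` column for audit. Strain ids drop type-strain superscript
markers; macrocycle membership is stored explicitly per peptide (always a
contiguous C-terminal block) rather than inferred from Ser/Thr chemistry,
and fatty acids are opaque descriptors (no mass computation).

## Primer design

Column consensus is the smallest IUPAC code covering every base with
frequency ≥ `min_freq` (default 0.05 — rare variants may be sacrificed as
tolerated mismatches; the published consensus rule is unstated).
Gap-majority columns disqualify their windows. Candidates are ranked by
degeneracy, then worst-column coverage, then length. The 3′-clamp default
requires only the terminal base to be non-degenerate, matching the
published primers, which carry ambiguity codes two bases from the 3′ end.
Input alignments are user-supplied; the tool validates equal lengths
rather than aligning. Inosine is accepted in input primers but never
emitted. No thermodynamic filtering and no automatic two-set partitioning:
the split into two published sets was a manual design decision, and when
no window passes the degeneracy cap the empty result (with an advisory
log) is the faithful outcome.

## Problem sizes and determinism

Everything is single-threaded and seed-deterministic. The suite's chosen
scales: in-silico PCR oracle equivalence on ~155 random 0.3–1.2 kb
templates (vectorized scan vs pure-Python loop), typing recovery on 100
held-out queries against a 20-reference panel plus a 60-query chance-level
control, NJ recovery on 200 random additive 6-taxon matrices, correlation
recovery over 50 replicates of 10-strain coupled sets, and Mantel null
calibration over 60 decoupled sets at 99 permutations. The acceptance
script (`scripts/acceptance.py`) recomputes all headline quantities from a
single seed in a few minutes.

## Known limitations

- Sequence-only PCR model: no annealing thermodynamics, so a site with two
  tolerated mismatches may amplify in silico and fail at the bench.
- Nucleotide thresholds (95/75) are calibration defaults, not published
  values; re-derive them per panel with `calibrate` for real screens.
- NJ on p-distance-style identities underestimates deep divergences
  relative to model-based distances; use the exported matrix with ML tools
  when branch lengths matter.
- One family label per query: dual-product strains and chimeric amplicons
  are out of scope.
- The packaged diagnostic core is synthetic; typing real amplicons against
  public reference genes requires user-supplied sequences.
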