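# pletype

Transporter-gene (*pleB*) mediated typing of lipopeptide-producing
*Pseudomonas*.

## The problem

*Pseudomonas* lipopeptides (LPs) — cyclic or linear oligopeptides of 8–25
residues with an N-terminal fatty acid, assembled by giant nonribosomal
peptide synthetases (NRPS) — are classified into families by peptide length
and macrocycle size (4–9 residues, or linear). Every LP biosynthetic gene
cluster carries a dedicated tripartite efflux pump whose MacB-like
inner-membrane ABC transporter, generically named **PleB**, captures the LP
in the periplasm and therefore coevolves with the NRPS assembling it. The
phylogeny of *pleB* consequently tracks LP chemical diversity: a single
~880-bp fragment of the transporter gene is enough to assign a strain's
(putative) product to an LP family.

`pletype` implements this typing scheme end to end for microbiologists and
genome miners screening *Pseudomonas* isolates:

- **In-silico PCR** with the two published degenerate primer sets —
  `BanAmpGac F/R` (Bananamide, Amphisin, Gacamide; ~1,300-bp product) and
  `PutXanTol F/R` (Putisolvin, Xantholysin, Entolysin, Tolaasin; ~1,000-bp
  product) — under IUPAC base-set matching with a 3′-clamp rule.
- **Diagnostic-core trimming** to the 878-nt region both amplicons share
  (reference-gene positions 590–1467), covering the transporter's
  periplasmic core domain.
- **Family typing**: nearest-reference percent identity with tiered
  confidence (`known_LP_match` ≥ 95%, `novel_within_family` ≥ 75%, else
  `unassigned`), predicted peptide length and macrocycle size from the
  packaged family table, and a discordance flag when independent BGC/NRPS
  evidence disagrees with the *pleB* call.
- **Neighbor-joining trees** over identity distances, with column-resampling
  bootstrap support, for the clustering view of the same assignment.
- **pleB–NRPS correlation**: pair-level Pearson *r* between *pleB*
  nucleotide identity and concatenated-NRPS amino-acid identity, with a
  Mantel permutation test (pairwise identities are not independent).
- **Degenerate-primer design**: IUPAC consensus windows over a user-supplied
  alignment, ranked by degeneracy and coverage.
- **Reference data**: packaged TSV transcriptions of the characterized
  producer panel (12 families, 23 known producers across the seven targeted
  families) and the LP peptide sequences (e.g. prosekin, which differs from
  the Bananamide namesake only by Ile at position 7).
- **Synthetic data**: a deterministic generator of *pleB*-like genes
  (~2 kb, both primer sites flanking the core), reference panels with known
  truth, and coupled pleB/NRPS sets — so the entire toolkit is testable
  without downloading a single accession.

## Worked example

Simulate a 5-family reference panel with three held-out queries, amplify
with the BanAmpGac set, trim to the diagnostic core, and classify:

```bash
pletype simulate --seed 7 --queries 3 --out sim
# wrote 20 references and 3 queries to sim
pletype amplify --in sim/queries.fasta --primer-set BanAmpGac --out-prefix amp
# 3 amplicon(s); 0 record(s) without product
pletype trim --in amp.fasta --out cores.fasta
# trimmed 3 sequence(s) to cores.fasta
pletype classify --in cores.fasta --refs sim/references.fasta --out typing.json
# classified 3 query(ies) -> typing.json
```

The site report shows each query amplifying a single 1,300-bp product
(coordinates 300–1599, plus strand, zero primer mismatches):

```
template  primer_set  start  end   strand  mismatches  length
query1    BanAmpGac   300    1599  +       0           1300
```

and `typing.json` records, per query, the assigned family, the confidence
tier, and the top references, e.g.

```json
{
  "query_id": "query1:300-1599(+)",
  "family": "fam4",
  "tier": "known_LP_match",
  "identity": 95.1025,
  "nearest_reference": "fam4_ref1"
}
```

Identity 95.1% to the nearest reference is exactly what a panel simulated
at 5% intra-family divergence should produce, and it clears the 95%
known-match threshold; all three queries recover their true family. With a
real isolate the same JSON would also carry the family's predicted peptide
length and macrocycle size (e.g. Bananamide → 8 residues, 6-membered ring).

The library surface mirrors the CLI — `pletype.amplify`,
`pletype.trim_to_core`, `pletype.assign_family`, `pletype.nj_tree`,
`pletype.build_pairs` / `pearson_r` / `mantel_p`, and
`pletype.synthetic.make_panel` — see the module docstrings and
`docs/methods.md`.

## Reference tables

`src/pletype/data/` ships three UTF-8 TSVs documented in
`pletype.refdata`: `families.tsv` (family → peptide length, macrocycle size
or `Linear`, targeted flag, clade), `producers.tsv` (one row per
characterized producer strain per family), and `peptides.tsv` (residues as
dash-joined 3-letter codes, macrocycle positions as a 1-based range,
inherited-cell audit flags). Reference *pleB* sequences are user-supplied
as multi-FASTA keyed by strain id; the packaged diagnostic core is a
synthetic stand-in with the real gene's geometry, and a user-fetched
reference sequence can be swapped in via `pletype.CoreRegion`.

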