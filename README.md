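# epiconserve

Epitope-conservancy analysis for predicting IgE cross-reactivity between
shellfish and other invertebrate allergens.

Shellfish allergy is driven by a handful of pan-allergens — above all
tropomyosin (TM) and arginine kinase (AK) — whose sequences are highly
conserved across crustaceans, molluscs, mites and cockroaches. Whether a
shrimp-allergic patient will react to, say, squid or house dust mite
depends less on whole-protein identity than on whether the short linear
peptides their IgE actually binds (epitopes) are conserved in the other
species' homolog. `epiconserve` turns that idea into a reusable pipeline
for allergy researchers working on component-resolved diagnostics:

- **Mismatch-tolerant epitope scan** — for an epitope peptide of length
  *L* and a homolog sequence, the minimum Hamming distance over all
  ungapped length-*L* windows; the epitope is *conserved* in the homolog
  when that minimum is ≤ *m* substitutions (default *m* = 2). Identity is
  reported as (L − mismatches)/L.
- **Group presentation** — per epitope and taxonomic group (crustacean,
  cockroach, mite, mollusc; molluscs subdivided into bivalves,
  cephalopods, gastropods), the percentage of the group's species whose
  homolog carries a conserved variant; isoforms of one species collapse
  by their minimum mismatch.
- **Pan-epitopes and Venn partition** — epitopes conserved in every
  group, plus the full overlap partition; one-way ANOVA of per-species
  conserved fractions between groups; Manhattan-distance / average-linkage
  clustering of the mismatch heatmap.
- **Cross-reactive regions** — overlapping epitope spans merged into
  maximal regions on the source allergen, each classified by its
  mollusc-class conservation pattern (all molluscs /
  cephalopod+gastropod / bivalve+cephalopod / crustacean-only).
- **Diagnostic decision tree** — maps a patient's serology (extract, TM
  and AK sIgE) plus epitope-region reactivity to one of five
  cross-reactivity classes (plus a no-sensitization outcome).
- **Synthetic homolog families** — a seeded simulator (ancestral
  sequence, planted conserved blocks, per-group substitution rates,
  tiled epitopes) with an independent brute-force truth oracle, so the
  whole pipeline is testable without any database downloads.

The package ships the published conservation tables for the 22 TM and
5 AK pan-epitopes as fixtures (`load_fixture("table1_tm")`,
`load_fixture("table2_ak")`), transcribed verbatim — including one
internally inconsistent printed span that the consistency checker
surfaces rather than corrects.

## Worked example

```python
import epiconserve as ec

# pan-epitopes from the packaged TM table
table = ec.load_fixture("table1_tm")
part = ec.venn_partition(table.presentation)
print(len(part.pan_epitopes))            # 22

# merge the printed epitope spans into cross-reactive regions
regions = ec.merge_epitope_regions(list(table.records))
print([(r.start, r.end) for r in regions])
# [(1, 18), (85, 105), (115, 129), (144, 151), (154, 171), (187, 207), (241, 267)]
print(sum(len(r) for r in regions))      # 128 residues covered

# scan one epitope against a homolog
r = ec.min_mismatch_scan("RIQLLEEDLER", "NRRIQLLEEDLERSEER")
print(r.min_mismatches, r.best_offset)   # 0 3   (exact match at position 3)

# decision tree: TM-positive patient reactive to an all-mollusc region
from epiconserve.decision_engine import default_config, decide, PatientProfile
call = decide(
    PatientProfile(extract_sige=1.0, tm_sige=1.0, ak_sige=0.0,
                   region_reactivity={"TM-R1": True}),
    default_config(),
)
print(call.call)                         # crustacean_mollusc
```

The same stages are available from the shell via the `epiconserve`
console script (`simulate`, `scan`, `groups`, `venn`, `regions`,
`grades`, `tree`, `decide`, `report`); every artifact is a plain TSV,
Newick or JSON file plus a provenance record, and reruns with the same
seed are byte-identical:

```bash
epiconserve simulate --seed 3 --out-dir run
epiconserve scan  --fasta run/family.fasta --epitopes run/epitopes.tsv --out run/matrix.tsv
epiconserve groups --matrix run/matrix.tsv --config run/groups.yaml --out run/presentation.tsv
epiconserve venn --fixture table1_tm --out run/partition.tsv
# venn: 22 pan-epitopes of 22 -> run/partition.tsv
```

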