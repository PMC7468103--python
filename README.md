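# isonet

Isoform-specific protein–protein interaction networks and
cancer-specific dominant-transcript switch calling.

## The problem

In most normal tissues each gene locus expresses one predominant
("most dominant") transcript isoform. In tumors, splicing regulation is
frequently disturbed and an alternative isoform can take over as the
dominant transcript. When the replacement isoform has lost the protein
domains through which the canonical protein binds its partners, the
switch silently deletes edges from the cell's protein-interaction
network — a plausible pathogenic mechanism that sequence-level variant
calling never sees.

`isonet` implements the full analysis chain for this question, for
anyone with transcript-level TPM matrices from a tumor cohort and a
matched normal cohort:

1. **Isoform-specific interaction network.** Functional protein–protein
   edges (STRING-style combined scores, kept at ≥ 0.9) are flagged as
   *physical* when the two endpoints carry domain instances whose
   families physically interact in solved structures (3did-style
   domain–domain pairs). For every alternative isoform, each physical
   edge of its gene's canonical protein *persists* if the canonical
   interacting-domain sequence is still present verbatim in the isoform,
   otherwise it is *lost*.
2. **MDT calling.** Per sample and gene, the transcript with the highest
   TPM is the most dominant transcript (MDT) if it is ≥ 2× the
   runner-up and above a noise floor (tumor 2.0 TPM, normal 0.2 TPM).
3. **cMDT calling.** A tumor MDT is cancer-specific (cMDT) when it is
   never an MDT in the normal compendium, its gene has an MDT in ≥ 50 %
   of matched normals, its relative expression
   (TPM / gene-total TPM) is significantly shifted against the normal
   cohort — sign test into an exact two-sided binomial, BH-corrected per
   cancer type, q < 0.01 — and exceeds the normal median.
4. **Impact scoring.** Disrupted interactions per sample; the network
   density score NDS(a) = int(a) + Σ_{s=1..3} Σ_b 2⁻ˢ · int(b) ·
   score(b, parent(b)) over a breadth-first neighbourhood, ranked to
   [0, 1]; BFS hop distance to the nearest cancer-census gene with an
   expression-matched random control; hypergeometric gene-set enrichment
   of each sample's disrupted subnetworks.
5. **Mutation association.** Per cancer type, Wilcoxon rank-sum tests of
   transcript expression between samples with and without cis mutations
   (promoter, UTRs, CDS, splice sites; ≥ 5 mutated samples required),
   BH-corrected, plus the Spearman correlation of per-sample cMDT load
   with variant load.

A seeded synthetic-data module generates complete toy studies (proteome,
domains, network, cohorts, mutations) with planted switches and exact
ground truth for every downstream step.

## Worked example

```sh
isonet simulate --out world --seed 1
isonet run-all --config world/config.yaml --out report
```

The second command prints the run summary (also written to
`report/summary.json`):

```
cancer_type                     SynthCancer
cmdt_variant_load_spearman      0.49690399499995325
mean_disrupted_ppi_per_sample   60.2
median_cmdt_per_sample          10.0
n_associations_significant      9
n_cmdt_calls                    99
n_normal_samples                20
n_tumor_mdt                     475
n_tumor_samples                 10
n_unique_cmdt                   10
proximity_control_p             0.47885500259598923
total_disrupted_ppi             602.0
```

Reading: the toy cohort plants 10 switch genes in 10 tumor samples
(100 planted switches); 99 are recovered as cMDT calls with no false
calls, a median of 10 cMDT per sample. Those switches disrupt 602
physical interactions, 60.2 per sample on average. All 9 transcripts of
the three genes with planted cis mutations come out significant in the
association screen. Per-stage tables (`network.tsv`, `cmdt.tsv`,
`disruptions.tsv`, `nds.tsv`, `proximity.tsv`, `enrichment.tsv`,
`associations.tsv`) land in the report directory. Each stage is also
available as its own subcommand (`build-network`, `call-mdt`,
`call-cmdt`, `nds`, `proximity`, `mut-assoc`) and as plain library
functions.

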