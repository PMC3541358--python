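# cnediv

Cross-species comparison of enhancer activity for conserved non-coding
elements (CNEs).

## The problem

Identical enhancer sequences can drive different expression when tested in
different species, because the *trans* environment — the set of expressed
transcription factors reading the sequence — has itself evolved.  A standard
experimental design tests the same human CNEs as transgenic reporters in
mouse embryos (11.5 dpc) and in stable zebrafish lines (24–48 hpf), scores
reporter expression as presence/absence over a shared vocabulary of major
anatomical domains, and asks three questions:

1. **How divergent is enhancer activity between species?**  For each CNE
   with mouse transgenic domain set *M* and zebrafish set *Z* (restricted to
   anatomy homologous in both species), the divergence fraction is

   f = (|M \ Z| + |Z \ M|) / |M ∪ Z|

   A CNE is *identical* at f = 0, shows a *global* pattern change at
   f ≥ 0.75, and is *partial* in between.

2. **Does sequence (cis) divergence matter?**  Ancestral CNEs — those with a
   homology hit in the elephant shark genome at e-value < 10⁻⁵ — are split
   into zebrafish-**conserved** and zebrafish-**lost** groups.  Per-element
   mean phyloP/phastCons scores are compared by one-way ANOVA (the element,
   not the base, is the unit of observation), and the pooled ratio of
   accelerated (phyloP < −1) to constrained (phyloP > +1) positions by a
   chi-square test on the 2×2 count table.  Alignment percent identity is
   averaged over sequence pairs, skipping columns where either member is
   gapped.

3. **Do activity changes track gene-expression changes?**  For CNEs with a
   confidently associated target gene, each domain gets four presence calls:
   mouse transgenic (Mt), zebrafish transgenic (Zt), mouse gene (Mg),
   zebrafish gene (Zg).  A domain is **trans_and_gene** when reporter and
   gene diverged together (Mt ≠ Zt, Mg ≠ Zg, Mt = Mg, Zt = Zg) —
   the signature of a trans change propagating to the gene — and
   **notrans_and_gene** when the gene diverged but the concordant reporters
   match the mouse gene.

Replicate transgenic lines are aggregated with an inclusive majority rule:
a domain is present when the reporter was seen in at least half of the
lines (2 × positive ≥ total).

The package implements all of this plus a synthetic-data generator that
emulates the screen (Bernoulli domain activity, per-domain trans flips,
endogenous genes mirroring the reporter with configurable fidelity,
replicate-line detection noise, group-specific Gaussian phyloP tracks) with
fully recorded ground truth, so every stage can be validated end to end.

## Worked example

The packaged table `cnediv/data/fourway_divergent_genes.tsv` holds the
Mt/Zt/Mg/Zg calls for 11 CNEs whose target genes changed expression between
mouse and zebrafish (39 domain rows):

```python
from cnediv import classify_records, load_divergent_gene_table, summarize_gene_set

records = classify_records(load_divergent_gene_table())
summary = summarize_gene_set(records)
print(summary.label_counts, summary.n_trans_consistent, summary.n_cnes)
```

prints

```
{'trans_and_gene': 8, 'unclassified': 29, 'notrans_and_gene': 2} 8 11
```

— 8 of the 39 rows are trans-and-gene consistent, 2 are gene-only changes,
and 8/11 (73%) of the CNEs have at least one domain where the reporter
change mirrors the gene change.  `examples/` contains narrative scripts for
each capability (divergence metrics, four-way classification, conservation
group comparisons, simulation + parameter recovery), e.g.:

```
$ python examples/04_simulate_and_recover.py
divergent-domain fraction: observed 0.263 vs analytic 0.250 (over 2400 element-domain slots)
trans_and_gene fraction among divergent slots: 0.819 (gene mirrors reporter with prob 0.9)
```

The observed fraction estimates the generator's trans-change rate; the
trans_and_gene fraction tracks the gene-mirroring fidelity.

## Command line

A thin CLI wraps the pipeline:

```
cnediv compare  --annotations calls.tsv --vocab vocab.yaml --out outdir
cnediv fourway  --table fourway.tsv --rule asymmetric --out outdir
cnediv conservation --bed cnes.bed --scores phylop.bedGraph --groups groups.tsv --out outdir
cnediv simulate --seed 1 --recover --out outdir
```

Inputs are plain-text TSV/BED/bedGraph/wiggle/FASTA; reports are TSV plus
JSON with provenance.

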