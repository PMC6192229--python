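# wrkyevol

Comparative-genomics toolkit for the WRKY transcription-factor family in
plants: identify family members by their defining motifs, classify them
into the classical groups, pair orthologs and paralogs, estimate selective
pressure (Ka/Ks), and relate evolutionary rates to codon-usage features
and tissue expression — the full analysis chain a study of gene-family
evolution in a set of plant genomes needs, runnable end to end on a
bundled, fully labeled synthetic-cohort generator.

## Who it is for

Researchers analysing a transcription-factor family across one or more
plant genomes who want a scriptable, tested implementation of the standard
workflow instead of a chain of one-off scripts around HMMER/BLAST/PAML
output files. Every stage is a library function with a thin CLI wrapper;
every stage also accepts the corresponding external file (e.g. a BLAST
tabular hit file) where you already have one.

## The science in brief

**Domain model.** A WRKY domain is the heptapeptide `WRKYGQK` (the W is
invariant; `WRKYGKK` is the common variant) followed by a zinc finger,
either C-X(4,5)-C-X(22,23)-H-X-H (C2H2) or C-X(7)-C-X(23)-H-X-C (C2HC).
Proteins with two valid domains form group I; a single C2H2 domain, group
II (subgroups IIa–IIe assigned by nearest labeled reference domain); a
single C2HC domain, group III. Sequences that lost either motif are
excluded from the family; rare proteins with three or more domains are
reported as a separate multi-domain class.

**Homology.** Gene pairs count as homologous when a pairwise alignment
covers > 80% of each sequence at > 80% identity (and E ≤ 1e-10 when a hit
table supplies one); within-species pairs are paralogs, between-species
pairs orthologs.

**Selective pressure.** Ka and Ks are estimated with the Nei–Gojobori
(1986) counting method on a codon alignment back-translated from the
protein alignment: per-codon synonymous site fractions from the standard
code, multi-position codon differences averaged over all minimal
mutational pathways (stop-passing pathways discarded), Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3). Pairs with Ks < 0.01 (unstable) or
Ks > 3 (saturated) are filtered; Ka/Ks < 1, = 1, > 1 indicate purifying,
neutral and positive selection.

**Features and expression.** Per gene: Fop (frequency of optimal codons,
codonW denominator convention), GC1/GC2/GC3 and polypeptide length; per
duplicate pair: per-tissue |Δ log2(RPKM + 1)| with divergence called at a
two-fold difference, plus Pearson correlation grids of rates × features ×
tissue expression with the conventional star annotation.

## Worked example

```python
from wrkyevol.synthetic_data import SimConfig, gen_cohort
from wrkyevol.domain_model import annotate_proteins, table1_report, census_variants
from wrkyevol.evol_rates import (
    kaks_for_cds_pair, apply_rate_filters, rates_table, summarize_rates,
)

cohort = gen_cohort(SimConfig(seed=1))          # 3 species, labeled truth
anns = annotate_proteins(cohort.proteins, cohort.references)
print(table1_report(anns))

counts, tally = census_variants(d for a in anns for d in a.domains)
print("top variants:", tally.most_common(3))

cds = {c.id: c.seq for c in cohort.cds}
ests = [kaks_for_cds_pair(cds[r.a], cds[r.b], r.a, r.b)
        for r in cohort.pairs.itertuples()]
retained, _ = apply_rate_filters(ests)
table = rates_table(retained).merge(
    cohort.pairs[["a", "b", "relation"]], on=["a", "b"])
print(summarize_rates(table).round(3).to_string(index=False))
```

Output:

```
          I  II  III  multi_domain  total
species
sp1      12  47   10             1     70
sp2      14  43   13             1     71
sp3      11  49   10             1     71
top variants: [('WRKYGKK', 9), ('WRVYGQK', 5), ('WPKYGQK', 3)]
relation  n  mean_ka  mean_ks  mean_ratio  p_ka  p_ks  p_ratio
ortholog 30    0.057    0.357       0.165 0.025   0.0    0.739
 paralog 48    0.031    0.195       0.166 0.025   0.0    0.739
```

The count table is the per-species group census (the planted composition
is recovered exactly; decoys are excluded). `WRKYGKK` dominating the
variant tally reflects the planted Q→K bias at heptapeptide position 6.
The rate summary shows orthologs evolving faster than paralogs (higher
mean Ka and Ks — here the planted condition, Ks 0.34 vs 0.19) with the
Mann–Whitney p-values for each metric.

The same pipeline is available from the shell:

```bash
wrkyevol simulate --seed 1 --out cohort/
wrkyevol classify cohort/proteins.fasta --refs cohort/references.fasta --out-prefix run
wrkyevol homologs cohort/cds.fasta --out pairs.tsv
wrkyevol kaks cohort/cds.fasta --pairs pairs.tsv --out-prefix rates
wrkyevol features cohort/cds.fasta --out-prefix feat
wrkyevol express --pairs pairs.tsv --expr cohort/expression.tsv --out divergence.tsv
```

Every report is a TSV with a `.params.json` sidecar recording the run
parameters.

## Layout

```
src/wrkyevol/
  io_formats.py         FASTA / hit-table / expression readers, report writers
  domain_model.py       motif scanner, variant census, group classification
  homology.py           pairwise alignment + ortholog/paralog thresholds
  evol_rates.py         back-translation, NG86 Ka/Ks, filters, summaries
  gene_features.py      Fop, GC1/GC2/GC3, duplicate-vs-singleton comparison
  comparative_stats.py  correlation grids, expression divergence
  synthetic_data.py     labeled cohort generator and sequence evolver
  cli.py                click CLI over the above
docs/methods.md         model, defaults and design notes
```
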