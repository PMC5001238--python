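# phenodrug

Phenotype-profile drug repositioning: rank approved drugs as candidate
therapies for a disease by comparing mouse phenotype profiles.

## The problem

For many diseases the genetics are far better charted than the
therapeutics. When a disease's associated genes are known, the phenotypes
those genes produce in mouse models form a phenotype signature of the
disease; the same is true of a drug through its target genes. `phenodrug`
builds both signatures and asks, for every candidate drug: *how similar are
the phenotypes of your targets to the phenotypes of the disease genes?*
Drugs whose target-gene phenotypes mirror the disease signature are
promising repositioning candidates. The package is aimed at computational
drug-discovery and translational-bioinformatics groups working with
MGI-style gene–phenotype annotations and STITCH-style drug–target tables.

## The method

1. **Disease profile** — each phenotype term linked to ≥ 1 disease gene is
   weighted by the number of disease genes carrying it; terms with weight
   strictly below the median weight are removed.
2. **Drug profiles** — each term linked to ≥ 1 target gene is weighted by
   the sum of the drug–target confidence scores.
3. **Information content** — with the true-path rule (a gene annotated
   with a term is also annotated with its ancestors),
   IC(t) = −log p(t), p(t) the fraction of annotated genes carrying *t*.
4. **Similarity** — Resnik term similarity
   sim(t₁,t₂) = max over common ancestors *a* of IC(*a*), combined into a
   symmetric best-match average between profiles:
   sim(p₁,p₂) = ½·avg over t₁∈p₁ of max over t₂∈p₂ of sim(t₁,t₂) + ½·(the reverse direction).
5. **Ranking & evaluation** — drugs sorted by similarity with average-rank
   ties and percentile = rank/n×100; rankings scored against labeled drug
   sets by median percentile, paired t-tests between methods,
   precision–recall and average precision.

See `docs/methods.md` for assumptions, parameter defaults, and the design
of the synthetic benchmark.

## Worked example

Generate a seeded synthetic benchmark (a 200-term ontology, 500 annotated
genes, 100 drugs of which 10 are planted positives whose targets overlap
the disease genes) and run the full screen:

```bash
phenodrug simulate --out fixtures --seed 42
phenodrug run-all \
    --ontology fixtures/ontology.obo \
    --annotations fixtures/gene_phenotypes.tsv \
    --targets fixtures/drug_targets.tsv \
    --genes fixtures/disease_genes.txt \
    --eval-sets fixtures/evaluation_sets.tsv \
    --out results
# ranked 100 drugs; outputs in results
head -4 results/ranked_drugs.tsv
```

```
rank    drug_id     score               percentile
1.0     drug0035    2.769750027613095   1.0
2.0     drug0088    2.5890456497420278  2.0
3.0     drug0056    2.508515371676583   3.0
```

`drug0035` — the top-ranked candidate — is one of the planted positives
(see `fixtures/truth.json`): its targets were drawn from the disease gene
set, and the phenotype similarity recovers that. The evaluation report
summarizes recovery of all ten positives:

```
$ python -c "import json; r=json.load(open('results/evaluation_report.json')); \
             print(r['per_set_median']['potential'], r['average_precision'])"
5.5 0.9909090909090909
```

A median percentile of 5.5 means half the positive drugs rank in the top
5.5 % of the 100-drug screen, and an average precision of 0.99 (against a
chance level of 0.10) means the positives are almost perfectly concentrated
at the head of the list. `results/category_scores.tsv` additionally ranks
the top-level phenotype categories of the disease profile by summed weight,
and `results/pr_curve.tsv` holds the precision–recall curve.

Real data go through the same flags: `--score-scale 1000` for STITCH-style
integer confidence scores, `--min-confidence` to drop weak target links,
`--comparator other_ranking.tsv` to add paired t-tests against another
method's ranked list.

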