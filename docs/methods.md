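# Methods

## The model

`phenodrug` ranks candidate drugs for a disease by comparing *mouse
phenotype profiles*. The premise is that a disease's associated genes and a
drug's target genes each induce a characteristic set of phenotypes in mouse
knockout/mutant models, and that a drug whose target-gene phenotypes
resemble the disease-gene phenotypes is a plausible therapeutic candidate.

**Disease profile.** Every phenotype term directly annotated to at least
one disease gene enters the profile with weight equal to the number of
distinct disease genes carrying that annotation. The profile is then
pruned: terms whose weight falls *strictly below* the median of all profile
weights are removed (ties at the median survive, so at most ⌊n/2⌋ terms are
ever dropped). The median is computed once, on the unfiltered weights, with
the conventional midpoint-mean for even counts. The filter keeps the
recurrently implicated half of the phenotype signature and discards terms
supported by single genes.

**Drug profiles.** For each drug, every phenotype term directly annotated
to at least one of its target genes enters with weight equal to the sum of
the drug–target confidence scores of the targets carrying that annotation.
Drug profiles are not pruned.

Profiles use **direct** annotations only. The ancestor closure (true-path
rule: a gene annotated with a term is implicitly annotated with all its
ancestors) is applied when computing information content, not when forming
profiles — propagating profiles would flood them with uninformative
ancestor terms.

**Information content.** For a term *t*,

    IC(t) = −log p(t),   p(t) = (genes whose closed annotation set contains t) / (all annotated genes)

Natural log by default; any base rescales every score by a constant and
leaves all rankings unchanged (asserted as a test). Closure guarantees
IC(root) = 0 and IC never decreases down an is-a edge. Terms never
annotated in the corpus have no IC entry; profile terms without entries are
skipped (not treated as IC = 0) with a reported count.

**Similarity.** Term–term similarity is Resnik's measure, the IC of the
most informative common ancestor:

    sim(t1, t2) = max{ IC(a) : a ∈ A(t1, t2) }

where A is the set of common ancestors under *reflexive* ancestor sets, so
sim(t, t) = IC(t). Profile similarity is the symmetric best-match average
(BMA): each term of one profile is matched to its most similar term in the
other and averaged,

    sim(p1 → p2) = mean over t1∈p1 of max over t2∈p2 of sim(t1, t2)
    sim(p1, p2)  = ½ sim(p1→p2) + ½ sim(p2→p1)

The directed mean is unweighted over profile terms; profile weights enter
the pipeline only through the median filter and the category scores. An
optional weighted mode (weights normalized within each profile) exists
behind a flag, default off. Pairwise term similarities are memoized across
a screen; the cache is purely a performance device and results are
identical with or without it.

**Ranking.** Drugs are sorted by descending similarity; tied scores share
the average of their positional ranks; percentile = rank / n × 100 (the
"top X %" convention). A drug whose profile is empty after IC filtering
has *undefined* similarity — it is listed as excluded, never scored zero,
because evaluation medians depend on the denominator.

**Categories.** Top-level phenotype categories are the direct children of
the ontology root. A profile term contributes its full weight to every
category it reaches by tracing is-a edges (multi-inheritance counts toward
each); categories are ranked by summed weight, ties broken lexicographically.
The module reports however many root children the loaded ontology has
rather than assuming a fixed count, which depends on the ontology release.

## Evaluation

- **Median percentile** per labeled drug set and per drug type, plus a
  combined median. The median, not the mean, because a single very poor
  rank should not dominate a set-level summary. Drugs absent from a list
  are excluded from that list's metrics (with a reported count), never
  imputed a worst rank.
- **Paired Student's t-test** (two-sided) on percentile differences over
  the drugs *both* lists rank. Percentiles rather than raw ranks so lists
  of different lengths are comparable; the choice is recorded in the report
  (`rank_scale`). Degenerate cases: identical vectors → t = 0, p = 1; a
  nonzero constant shift → p = 0.
- **Precision–recall / average precision**: the raw step curve recorded at
  each positive hit, no interpolation; AP is the mean precision at hits
  (single query, so MAP = AP). The denominator is the number of positives
  present in the list, consistent with the exclusion policy above.

Undefined metrics (no evaluation drug found, overlap < 2) are rendered as
NA/None in reports, never as zero.

## The synthetic benchmark

The generator emulates the five real inputs (OBO ontology, gene–phenotype
TSV, drug–target TSV, disease gene list, evaluation sets) at desk scale,
fully determined by one integer seed.

- **Ontology** (default 200 terms, 6 levels): a single-root layered DAG
  whose layers widen geometrically with depth (growth factor 3, top level
  floored at 6 terms), mirroring the branching of real phenotype
  ontologies. Each non-root term draws 1–2 parents from the layer above.
- **Annotations** (default 500 genes, mean 4 direct annotations each,
  Poisson floored at 1): terms are sampled with per-term probability
  decaying 0.8× per level of depth. Combined with depth-widening layers,
  each individual deep term is rare (high IC) while most annotation mass
  still lands on specific terms — the property of real curated corpora that
  Resnik similarity needs to carry signal. With uniform layers and dense
  annotation the disease profile blankets most of the ontology and all
  drugs look alike; the defaults were chosen so the disease profile covers
  a small minority of terms, as real disease profiles do.
- **Disease and drugs** (default 10 disease genes, 100 drugs, 5 targets
  each, 10 planted positives): positive drugs draw 80 % of their targets
  from the disease gene set, negatives from the background; confidences are
  uniform in [0.4, 1.0]. The truth labels are written alongside the
  fixtures, rendered as the "potential" evaluation set.

Everything the generator writes is read back by the package's own loaders
(exact round-trip, asserted byte-for-byte for the similarity-relevant
content), so loader tests and the end-to-end pipeline share one fixture
path.

What the benchmark does **not** emulate: real identifier schemes,
annotation bias toward well-studied genes, correlated target sets among
drugs of one class, multi-evidence confidence structure, or part-of
relations. Passing the planted-positive test shows the pipeline recovers a
genuine target-overlap signal through the phenotype layer; it does not
certify performance on real MGI/STITCH snapshots.

## Numerical and design choices

- Natural log for IC; log-base invariance of the ranking is tested.
- Reflexive ancestor sets, so self-similarity equals own IC.
- Only `is_a` edges are traversed; other OBO relations are ignored.
- Multi-root OBO files are rejected by default; an opt-in virtual root
  (receiving p = 1, hence IC 0) supports multi-rooted inputs.
- Duplicate drug–gene links collapse by maximum confidence, avoiding
  double-counting one interaction reported through several channels.
- Drug–target score scale is a reader parameter (1000 for STITCH-style
  integer scores, 1 for unit reals); the default minimum-confidence
  threshold is 0 (keep all links).
- Tie-breaks are deterministic everywhere (lexicographic on ids), so runs
  are byte-reproducible; ranking is seed-free by construction and only the
  generator consumes the seed.
- Problem sizes in the test suite (50-term DAGs / 20 genes for oracle
  equivalence, the 200-term default benchmark, 10–50 seeds for stochastic
  checks) are chosen so exhaustive reference implementations stay exact and
  the whole suite runs in seconds.

## Known limitations

- Scores are comparable only within one run (one corpus, one IC table);
  cross-corpus score comparison is meaningless, though ranks are stable
  under global IC rescaling.
- The unweighted BMA discards profile weights after the median filter;
  whether weighting helps is an open experimental question (the weighted
  flag exists for exactly that experiment).
- No identifier mapping: gene symbols must agree across input files.
- Single disease per run; no batch screening.
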