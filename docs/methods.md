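# Methods

## Problem setting

Given a compendium of treatment-instance expression profiles (one profile
per compound x concentration x cell line x platform combination) and a
sparse table of compound-target bioactivities, the package asks how few
probesets suffice to predict a compound's protein targets by
guilt-by-association: correlate a query instance against all other
instances on a chosen probeset subset (the *gene signature*), take the
most similar instances of *other* compounds, and transfer their targets.

## Prediction model and metrics

Similarity is the Pearson product-moment correlation computed on the
signature's probesets only. For a query instance, every instance of the
query's own compound is excluded from the candidate pool (a self-match
carries no information about an unknown molecule), and by default
candidates are further restricted to instances of annotated compounds —
unannotated neighbours would contribute empty predictions and conflate
annotation coverage with signal. The k nearest neighbours (k in {1,2,3},
ties at equal correlation broken by instance id) contribute the union of
their target sets as the prediction.

A prediction is *successful* when the predicted and true target sets
intersect; **accuracy** is the fraction of successful queries, and
**precision** is the mean over queries of |predicted ∩ true| /
|predicted|. The intersection rule is deliberately permissive: the
annotation matrix is well under 1% populated at full scale, so absent
pairs cannot be read as true negatives, and stricter per-target metrics
would be dominated by spurious false positives. Accuracy is aggregated
per treatment instance; per-compound aggregation is available as an
option. Queries whose profile is constant on the signature (Pearson
undefined) are skipped and counted separately, never silently scored.

The chance baseline re-scores the same signature against annotation
tables whose target *sets* have been permuted across compound ids. Set
permutation (rather than permuting individual pairs) preserves each
compound's target count exactly, which keeps the null comparable under a
set-intersection success metric; pair-level shuffling is available behind
a flag but collapses colliding duplicates and therefore shrinks some
sets.

## Inputs and normalisation

Activities are filtered to IC50/Ki records at <= 5 µM (inclusive); other
activity types are dropped with a logged count. Expression matrices are
batch mean-centred per probeset: within each batch of more than
`min_batch_size` (default 5) instances, the batch mean of each probeset
is subtracted, making every value an expression change relative to the
batch average without requiring vehicle controls. Batches at or below the
threshold are *dropped* rather than passed through un-centred — an
un-centred instance would retain its batch offset, which dominates
correlation against centred instances; the drop is logged and the
threshold configurable. Loaders reject missing values by default
(probeset-median imputation behind a flag) and auto-detect TSV
orientation against the metadata, erroring when both orientations match.

## Signature design

Seven unsupervised expression-statistic criteria rank probesets across
all instances: highest/lowest mean, highest/lowest standard deviation
(sample sd, ddof=1 — ranking is unaffected by the denominator), highest/
lowest mean absolute value, and Shannon entropy of values binned into 200
equal-width bins on [-5, 8]. Entropy is reported in bits; the base is a
monotone rescaling and cannot change any ranking. Out-of-range values are
clamped into the boundary bins so every observation contributes; dropping
them would silently reweight probesets. Empty bins contribute nothing
(0·log 0 := 0). All rankings break ties by lexicographic probeset id so
the cut at size k is deterministic.

Six network criteria score genes of a directed, mode-labelled interaction
network: betweenness, closeness, total/in/out-degree, and the mean
shortest-path distance from upstream transcriptional regulators.
Interpretation choices, since several conventions are defensible:

- Graphs are treated as **directed and unweighted** (the in/out-degree
  criteria only exist directed); an undirected option is provided.
- Betweenness is **unnormalised** with fractional counting of tied
  shortest paths; only the ranking is consumed and the normalising
  constant cannot alter it.
- Closeness of v is (number of nodes reachable *from* v) / (sum of
  distances to them), 0 for sinks.
- Regulators are nodes with >= 1 outgoing edge of mode `expression`.
  Every non-regulator node reachable from at least one regulator is
  scored with its mean hop distance over exactly the regulators that
  reach it, counting hops over edges of any mode; ranking is
  **descending** (genes far downstream of the regulatory layer), which is
  one reading of "maximum average distance" — the alternative ascending
  reading is a one-line change.
- Degree counts distinct (source, target, mode) records, so a pair
  connected by two modes contributes two.

Gene scores become probeset signatures by walking genes in descending
score (ties by gene id), appending each gene's probesets in id order, and
keeping a probeset shared by several genes once, at first occurrence.

Random signatures are uniform draws without replacement; the size ladder
runs 16..4096 in half-logarithmic base-2 steps, and random accuracies are
reported as mean ± sd over repeated draws (50 by default).

## Genetic algorithm

Individuals are fixed-size probeset sets; fitness is 1-NN prediction
accuracy (k configurable). Each generation keeps the top
⌈elite_fraction·population⌉ individuals unchanged — so the best fitness
is non-decreasing by construction — and refills the remainder with
offspring of uniformly chosen elites: with probability `crossover_rate` a
uniform size-|parent| sample from the union of two distinct elites,
otherwise a single-element replacement mutation (one member swapped for a
uniform outsider). Both operators preserve size and uniqueness by
construction, which is why they were chosen over classical bit-string
operators for this fixed-size set encoding. The mutation rate applies
per offspring, not per gene. Parent selection is uniform over the elite
pool (no fitness-proportional roulette). Fitness evaluations are cached
on the sorted probeset tuple. Defaults mirror the full-scale study
(population 200, 150 generations, 20% elitism, 70/30 crossover/mutation);
the bundled analysis uses population 50 and 30 generations at signature
size 32, which converges in seconds at the synthetic compendium's scale.

## Pathway enrichment

Signature probesets are translated to genes (deduplicated) and each gene
set is tested with the hypergeometric upper tail
p = Σ_{i>=x} C(K,i)·C(N-K,n-i)/C(N,n) — identical to a one-sided Fisher
exact test. The universe N is the intersection of the collection's
declared universe with the genes mapped on the chip; this choice is
configurable and must be held fixed across signatures being compared,
since absolute p-values scale strongly with N. Raw p-values are the
comparison surface; Benjamini-Hochberg adjusted values are reported
alongside as a convenience.

## Synthetic compendium

The generator emulates the statistical structure the analysis needs,
at desk scale, with known ground truth:

- Each of 40 targets owns an effect vector supported on 8 of 32
  *informative* probesets (out of 1,000), entries N(0,1) scaled by
  `effect_size` (default 2.0, in units of the noise sd).
- Each of 100 compounds draws 1 + a truncated heavy-tailed (Zipf)
  number of targets, capped at 10 — echoing the promiscuous tail of real
  chemogenomics repositories — giving a compound-target matrix a few
  percent dense.
- An instance's profile is the sum of its compound's target effects, a
  per-batch per-probeset Gaussian offset (sd 0.5), and i.i.d. Gaussian
  noise (sd 1.0); 3 replicate instances per compound across 10 batches.
- Activities: true pairs get IC50/Ki values <= 5 µM; decoy records sit
  above the cutoff, plus a handful of out-of-scope activity types to
  exercise the filter.
- The network wires each target's support genes into chains, adds
  ~3 background edges per gene (supercritical, so most genes are
  reachable from the regulatory layer, as in STRING), and gives two
  regulator genes outgoing `expression` edges.
- The gene-set collection contains the informative genes as one planted
  pathway among 30 random decoy sets.

The additive signal model is the simplest generative story consistent
with the premise that shared targets induce correlated profiles; it is a
modelling choice of this package. The generator does **not** emulate
probe-level intensity distributions, cell-line-specific biology,
concentration-response structure, or correlated noise beyond the batch
offset — so passing tests demonstrate the pipeline's statistical
machinery, not performance on real compendia.

Seeding: every seeded component (generator, GA, random signatures,
annotation shuffles) derives its random stream from the user seed plus a
component-specific constant. This domain separation matters: with a bare
shared seed, the optimiser's first "random" individual would replay the
exact draw that planted the informative set, silently leaking the ground
truth into the search.

## Problem sizes in the bundled analysis

The analysis drivers and acceptance script run the synthetic compendium
at its defaults (300 instances x 1,000 probesets), scan sizes 16-256 with
50 random draws per size, and evolve size-32 signatures with population
50 for 30 generations — sizes chosen so the full analysis completes in
well under a minute per step on a single CPU while leaving all
qualitative contrasts (designed vs random vs shuffled, convergence,
enrichment) clearly resolved.

## Known limitations

- Fitness is measured on the same compendium the search runs on, so the
  GA partially overfits: evolved signatures include noise probesets that
  help only on the training instances. Related, accuracy does not force
  recovery of the *whole* planted set — with 40 targets sharing 32
  informative probesets, a small "hub" subset already separates most
  compound pairs, and measured planted-set recovery plateaus near a third
  even at much larger search budgets while fitness keeps improving.
  Recovery is therefore reported alongside fitness, not inferred from it.
- The success metric saturates as k grows or as target sets overlap;
  comparisons are only meaningful at fixed k and fixed annotation table.
- Absolute enrichment p-values depend on the universe choice; only
  rankings within one universe are comparable.
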