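# Methods

## Model and rationale

`hubscore` treats a gene's cancer relevance as a property of its protein's
interaction neighbourhood rather than of the gene alone. The premise: a
protein whose partners are recurrently mutated participates in a perturbed
module even if the gene itself is rarely hit. The network score of gene *g*
is

    S(g) = T(g) x (M(g) / T(g)) = M(g)

where *T* is the degree of *g* in the full protein–protein interaction
network and *M* the number of neighbours encoded by cancer-mutated genes.
The product algebraically collapses to *M*; it is evaluated as `(T*M)/T`
(mathematically identical, exact in IEEE arithmetic because the quotient is
the integer *M*) and both *T* and *M* are written to every output row so a
user can form variants such as M²/T without rescoring. The denominator *T*
is the *full* interactome degree, not the degree within a cancer-restricted
subgraph.

Because *M* grows with a cohort's mutation rate, raw scores are comparable
only within one cancer. Cross-cancer comparisons use per-cancer min-max
normalization of the gene × cancer score matrix (columns mapped to [0, 1];
an all-constant column maps to 0).

## Inputs and harmonization

* **Mutation table** (TSV, MAF-like; default columns `Hugo_Symbol`,
  `Variant_Classification`). One row = one mutation event; counts are raw
  event counts, since the format carries no sample identifiers. Variant
  labels map to ORF/NON_ORF through a configurable, case-insensitive map.
  Synonymous/silent changes count as ORF: synonymous mutations can still
  perturb transcript stability. Unknown labels fail loudly by default
  (`error`), with `skip` and `non_orf` policies for permissive runs.
* **Meta-Z table** (TSV, `Gene` column plus one column per cancer). The
  Meta-Z quantifies the association between a gene's expression and overall
  survival; |Z| ≥ 1.96 ≈ 95% confidence, |Z| ≥ 2.58 ≈ 99%. Duplicate gene
  rows keep the entry with the largest |Z|, preserving a significance call
  in either direction.
* **Interaction file** (BioGRID TAB3 dialect, official-symbol columns).
  Loaded as an undirected graph; self-loops dropped; duplicate and reversed
  pairs collapsed. No evidence-type filter is applied by default; genetic
  and physical interactions are both consumed.
* Gene symbols are uppercased and whitespace-stripped everywhere; no
  alias/identifier mapping is attempted (symbol synonymy is out of scope).

## Filtering parameters

| parameter | default | meaning |
|---|---|---|
| `z_sig` | 1.96 | Meta-Z magnitude defining a survival effect (unitless) |
| `z_strong` | 2.58 | rescue threshold for unmutated genes |
| `md`, `min` | per cancer | median / minimum per-gene mutation count, computed over genes with ≥1 mutation |
| `non_orf_no_effect_mult` | 3 | multiplier in the NON_ORF-without-effect rule |
| `both_no_effect_mult` | 3 | multiplier in the BOTH-without-effect rule |

Numerical conventions: the median of an even-length sample is the mean of
the two middle order statistics, so `md` may be non-integer and all
inequalities are evaluated in real arithmetic. The ≥ vs > distinctions of
the five rules are implemented exactly as specified and each is covered by
an equality-point test. Genes absent from the mutation table cannot
contribute a zero minimum (that would make every threshold degenerate), so
md/min are computed over the mutated subset only. The ORF rule ignores the
survival label entirely; if `md − min` falls at or below the smallest
observed count, all ORF genes pass — no floor is imposed. The BOTH-no-effect
rule intentionally uses `3·md` without `+ min`; the multiplier is
configurable for users who prefer the symmetric form.

"Survival effect" inside the filter rules means |Z| ≥ `z_sig`; the stronger
`z_strong` level is reserved for rescuing unmutated genes.

## The mutated reference set

The score counts neighbours in a *mutated set*. Two defensible readings
exist: all genes mutated in the cohort (`raw`), or only the genes that
survive filtering and have ≥1 mutation (`filtered`). The default is
`filtered` — neighbours must themselves be cancer-relevant — and the choice
is a config switch (`mutated_reference`) recorded in run metadata, so the
two readings can be compared on any dataset.

## Ranking and outputs

Retained genes are clustered MUT (mutated only), PRECOG (unmutated,
significant Z) or MUT+PRECOG; PRECOG and MUT+PRECOG genes are *seeds*,
MUT genes *interactors*. Each list is sorted by (score desc, M desc,
symbol asc) — the tie-break is a package choice, made deterministic and
documented. Genes absent from the interactome stay in the output with score
0 rather than being dropped. TSVs use '.' decimals, UTF-8 and LF endings so
repeated runs are byte-identical.

## Cross-cancer analytics

* `shared_hubs`: genes in the top-N (default 50) list of ≥ k (default 3)
  cancers, by exact set intersection.
* `detect_outliers`: score > mean + k·SD (sample SD, k = 1.96 by default)
  of the selected list; this instantiates "significantly above the mean"
  under a normal approximation and is deliberately a config knob, since the
  score distribution is heavy-tailed.
* `external_overlap`: |hubs ∩ external| / |external| × 100, i.e. the share
  of an external cancer-gene list recovered.
* `score_correlations`: Pearson (default; Spearman available because the
  scores are heavy-tailed) correlations between mutation count, Meta-Z and
  score, pairwise-complete; a zero-variance variable yields NaN, not 0.
  Low off-diagonals indicate the three inputs carry non-redundant
  information.
* Hierarchical clustering of the normalized matrix is left to downstream
  tooling; the package emits the matrix only.

## Synthetic cohorts and what they show

The generator emulates the structure of the real inputs, not their biology:

* per-gene mutation counts are geometric (p = 0.3 by default, minimum 1
  over a mutated subset of 300 of 500 genes) — right-skewed like real
  per-gene burdens;
* each event is ORF with probability 0.8, using real MAF variant labels;
* 40 genes receive |Z| ≥ 1.96 (half ≥ 2.58), signs random, on a standard
  normal background — a sparse survival signal;
* the interactome is Erdős–Rényi with mean degree 3, plus `n_hubs = 3`
  planted genes each wired to `hub_degree = 25` distinct mutated genes and
  given |Z| ≥ 2.7 so they survive filtering as seeds.

Hubs are wired to mutated genes specifically because the score counts
mutated neighbours; the expected ranking is then analytically transparent
(planted M ≈ 25 × retention fraction ≈ 8–15 against a background of ~1–3).
One seed drives per-file sub-streams, so identical seeds give byte-identical
files. Symbols are synthetic (`G000001`…) to avoid collisions with real
gene lists in overlap tests.

Not emulated: mutational signatures, per-sample genotypes, degree
distributions of real interactomes (scale-free tails), correlated survival
and mutation signals. Passing tests therefore demonstrate correctness of
the algorithmic pipeline and recoverability of planted structure — not that
the score finds true cancer genes in real cohorts, which depends on the
specific dataset releases used.

Problem sizes used by the test suite and the acceptance script — 100
replicate 500-gene cohorts for hub recovery, one 10,000-gene cohort for the
null-correlation diagnostic, 500 toy cohorts for the rule-table check —
keep full runs in the seconds-to-minutes range while leaving the statistics
stable across seeds.

## Known limitations

* Event counts, not patient fractions: a "mutation frequency" defined as
  fraction of samples would need sample identifiers the input format does
  not carry.
* No multiple-testing correction is applied to Meta-Z values; they are
  consumed as published.
* Score significance is distributional (outlier rule), not inferential; no
  per-gene p-value is produced.
* Symbol-level matching means identifier drift between the three inputs
  silently reduces overlap; run metadata records per-stage gene counts so
  such attrition is visible.
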