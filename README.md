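# hubscore

`hubscore` ranks genes by how embedded their proteins are in cancer-mutated
interaction neighbourhoods. It is aimed at cancer-genomics researchers who
have, for each tumour type, (1) a MAF-like mutation table, (2) Precog Meta-Z
survival scores, and (3) a BioGRID TAB3 protein–protein interaction file, and
who want ranked candidate lists of *hub* genes whose protein partners are
recurrently mutated — including genes that are themselves rarely or never
mutated.

## The method

For one cancer, per gene *g*:

1. **Classify.** Each mutation event is labelled ORF (coding sequence,
   including synonymous changes) or NON_ORF; gene *g* gets a location class
   in {ORF, NON_ORF, BOTH, NONE} and a total event count *f(g)*.
2. **Label by survival.** With Meta-Z score *Z(g)*: *Z* ≥ 1.96 ⇒ oncogene-like,
   *Z* ≤ −1.96 ⇒ tumour-suppressor-like, otherwise none. Unmutated genes with
   no survival label are discarded.
3. **Filter by mutation burden.** With *md* and *min* the median and minimum
   of per-gene mutation counts in this cancer, a gene is retained when

   | class   | survival effect | keep when        |
   |---------|-----------------|------------------|
   | NON_ORF | yes             | f ≥ md + min     |
   | NON_ORF | no              | f > 3·md + min   |
   | ORF     | any             | f ≥ md − min     |
   | BOTH    | yes             | f ≥ md − min     |
   | BOTH    | no              | f > 3·md         |
   | NONE    | —               | \|Z\| ≥ 2.58     |

4. **Score.** With *T(g)* the gene's interactome degree and *M(g)* its number
   of neighbours encoded by mutated genes, the network score is
   *S(g) = T · (M/T) = M*, the count of mutated interactors.
5. **Rank.** Retained genes split into **seeds** (survival-significant:
   PRECOG and MUT+PRECOG clusters) and **interactors** (mutated only: MUT
   cluster), each list ranked by *S* descending.

Cross-cancer analytics intersect top-N lists, min-max normalize the
gene × cancer score matrix, flag outlier genes (score > mean + 1.96·SD), and
measure overlap with external cancer-gene lists.

## Worked example

Generate a synthetic cohort with 3 planted hub genes, run the pipeline, and
check the planted hubs top the seed list:

```python
import hubscore as hs

paths, truth = hs.generate_cohort(hs.SimConfig(seed=7), "demo")
cfg = hs.RunConfig(
    mutation_tables={"SIM": paths.mutations},
    precog_table=paths.precog,
    interactome=paths.interactome,
    out_dir="demo/out",
)
res = hs.run_pipeline(cfg)["SIM"]
print(len(res.seeds), len(res.interactors))   # 40 90
print(sorted(truth.hub_genes))                # ['G000272', 'G000371', 'G000479']
for sg in res.seeds[:3]:
    print(sg.rank, sg.gene, sg.total_interactors,
          sg.mutated_interactors, sg.network_score)
# 1 G000371 28 15 15.0
# 2 G000479 25 12 12.0
# 3 G000272 28 8 8.0
```

All three planted hubs rank 1–3: each was wired to 25 mutated genes, of
which 8–15 survive the md/min filter, while background genes average ~1–3
mutated neighbours. The same run from the shell:

```bash
hubscore simulate --out-dir demo --seed 7
hubscore run --config demo/config.yaml --out-dir demo/out
hubscore compare demo/out/SIM other/out/BC --out-dir demo/cmp -n 50 -k 2
```

Outputs are ranked TSV/JSON lists per cancer (gene, cluster, Meta-Z,
mutation count, T, M, score, rank) plus a `run_metadata.json` recording
thresholds, md/min, stage gene counts and input checksums.

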