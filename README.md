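# slimcons

Co-conservation analysis of kinase docking motifs and phosphorylation
consensus sites across ortholog alignments.

## The problem

NDR/LATS-family kinases such as budding-yeast Cbk1 recognize substrates
through two short linear motifs (SLiMs): a phosphorylation consensus
around the acceptor residue (`Hx[RK]xx[ST]`) and a separate docking motif
(`[YF]xFP`) that binds a surface on the kinase's catalytic lobe and makes
regulation robust. Both motifs are short and degenerate, so chance matches
are everywhere in a proteome; the signal that distinguishes functional
instances is **conservation across orthologs beyond neutral expectation**,
and — for substrates of the same kinase — **co-occurrence and
co-conservation of the two motif classes in the same proteins**. Because
docking motifs arise in rapidly evolving disordered sequence, one can
further ask in which order the two motif classes were acquired on the
species tree.

`slimcons` implements that full analysis as a tested, reusable pipeline:

1. **motif scanning** (`slimcons.motifs`) — degenerate fixed-width
   patterns over the 20 amino acids, proteome scans, per-1,000-aa match
   densities, optional region masks (e.g. disordered segments);
2. **ortholog data** (`slimcons.orthologs`) — aligned FASTA ortholog
   groups with gap-aware coordinate maps, Newick species trees, local
   reference-vs-species identity;
3. **conservation scoring** (`slimcons.scoring`) — for each motif
   instance, per-species retention evidence against a neutral null in
   which retention is as probable as the local background conservation
   makes it (`r_s = I_s^k`, floored at the composition-based chance of a
   de-novo match), combined into a score `S = Σ −ln p_s` with a
   calibrated tail probability under a joint retention null on the
   species tree;
4. **co-conservation statistics** (`slimcons.cooccur`) — top-k /
   threshold conservation classes, 2×2 contingency tables, Fisher's exact
   test, per-1,000-aa density comparisons, phospho-annotation overlap,
   and the per-protein dual-score scatter;
5. **acquisition order** (`slimcons.ancestry`) — per-species presence on
   the tree, single-gain (Dollo) placement of each motif class, and the
   ordering call (phospho-first / simultaneous / dock-first /
   undetermined);
6. **synthetic data** (`slimcons.simulate`) — ortholog families evolved
   down a species tree with planted motifs maintained by selection of
   tunable strength σ, plus proteome-scale generators with ground truth,
   so every stage is verifiable offline.

## Worked example

Simulate a 200-protein proteome in which 10 proteins carry a
selection-maintained docking motif (6 of them also a consensus site), then
run the whole pipeline:

```bash
slimcons simulate --out demo/data --seed 11 \
    --n-proteins 200 --n-docking-planted 10 --co-occurrence-fraction 0.6
slimcons all --data demo/data --out demo/run --top-k 10
```

`demo/run/scores.docking.tsv` holds one row per protein with at least one
docking match (best-scoring instance; 1-based coordinates):

```
protein_id  pattern_label  start_1based  end_1based  matched_seq  n_species_retained  score      combined_p    combined_p_chisq
P0000       docking        31            34          FVFP         5                   8.574538   9.442688e-05  0.071130
P0001       docking        328           331         YRFP         5                   7.097108   4.137472e-04  0.164316
P0002       docking        44            47          FCFP         5                   8.106525   1.507825e-04  0.093694
```

Here `score` is `S = Σ −ln p_s`: P0000's docking motif is retained in all
5 non-reference species across substantially diverged backgrounds, so its
retention is very unlikely under neutrality (`combined_p ≈ 9.4e-05`).
`demo/run/scatter.tsv` plots every protein on the two score axes and
flags those conserved on both; with `--top-k 10` the run flags 5 proteins,
all of them planted dual-motif proteins. `demo/run/enrichment.json`
records the annotation-overlap test — consensus acceptors in
conserved-docking proteins versus the rest:

```
"annotation_overlap": {"table": {"a": 5, "b": 3, "c": 0, "d": 33},
                       "odds_ratio": 105.3, "p_two_sided": 7.47e-05}
```

i.e. 5 of 8 consensus matches in conserved-docking proteins carry a
phospho annotation versus 0 of 33 elsewhere. `demo/run/ordering.tsv` and
`cohort.json` report each family's inferred gain nodes and the ordering
tally.

The same machinery is available as a library:

```python
import slimcons as sc

pattern = sc.PATTERNS["docking"]              # [YF]xFP
matches = sc.scan_sequence(pattern, "TTEQSDFKFP")
# -> one match: [6, 10) "FKFP"

table = sc.ContingencyTable.from_nested_counts(14, 27, 50, 887)
sc.fisher_exact(table).p_two_sided            # -> 5.8e-12
```

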