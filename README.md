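# gmpsig

Gene module pair (GMP) extraction and target scoring for perturbation
signature compendia.

Given a differential-expression signature matrix (genes x signatures,
L1000-style moderated z-scores), perturbagen-to-target annotations and
optional gene networks, `gmpsig`:

1. computes pairwise signature distances with the inverse total
   enrichment score (ITES) built on the classic running-sum enrichment
   statistic;
2. removes per-target outlier signatures by cutting an average-linkage
   dendrogram at a fixed height (default 0.8) and keeps targets with at
   least 3 retained signatures;
3. detects co-expressed gene modules per target (soft-thresholded
   correlation network + topological overlap), dropping genes in no
   module;
4. Borda-merges the retained signatures into a consensus gene ranking
   and cuts the top/bottom 250 genes into the target's gene module pair
   (t_up, t_down), with specificity filtering and effect labeling
   (inhibited / stimulated / undetermined);
5. characterizes module coherence in external gene networks (PPI ratio
   against random same-size gene sets);
6. builds a GMP-overlap target network (hypergeometric + module-level
   permutation significance) and finds communities with affinity
   propagation;
7. scores query expression profiles against all GMPs (TCS/NCS with a
   permutation p-value) to predict compound-target interactions.

A synthetic-data module generates L1000-like compendia with planted
up/down modules, replicate structure, outlier signatures and
multi-target perturbagens, so the whole pipeline is testable offline.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact
combinatorial identities, the TCS bound, the GMP size contract,
brute-force oracle equivalence, parameter recovery on the default
synthetic compendium, and null calibration).

## CLI

```sh
# simulate a compendium with planted ground truth
gmpsig simulate --targets 20 --delta 2 --outlier-frac 0.1 --seed 7 --out sim/

# extract the GMP target space
gmpsig extract-gmp --matrix sim/matrix.tsv --meta sim/metadata.tsv \
    --annotations sim/annotations.tsv --module-size 50 --n-extreme 50 \
    --soft-power 2 --seed 7 --out gmp/

# score a query profile (two-column TSV: gene, score)
gmpsig score --gmt gmp/space.gmt --query profile.tsv --reps 1000 --out scores.tsv

# target network + communities
gmpsig network --gmt gmp/space.gmt --alpha 0.05 --out net.tsv
gmpsig cluster --network net.tsv --out communities.tsv

# module enrichment in a gene network (edge-list TSV)
gmpsig enrich --gmt gmp/space.gmt --network string_edges.tsv --mode pair --out enrich.tsv

# self-recovery evaluation of a target space
gmpsig evaluate --gmt gmp/space.gmt --matrix sim/matrix.tsv \
    --meta sim/metadata.tsv --annotations sim/annotations.tsv --out selfrec.tsv
```

Common flags: `--config cfg.yaml` (flags override config values),
`--seed`, `--log-level`. Every run writes a JSON manifest next to its
outputs; identical config + seed reproduces identical artifacts.

Formats: GCT 1.2 or headered TSV matrices, TSV metadata/annotations,
GMT module pairs (`<target>_up` / `<target>_down` records), TSV edge
lists, GraphML export for network viewers.

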