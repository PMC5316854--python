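# hapnet

Dose-sensitivity-weighted protein–protein-interaction (PPI) network scoring
of somatic copy-number cohorts.

Given pathway gene sets (GMT), an interactome (two-column TSV), per-gene
dose-sensitivity evidence (yeast/mouse orthologue lists), and a gene × sample
copy-number call matrix (discrete GISTIC-style calls in {−2,−1,0,1,2}, or
continuous log₂ values to be thresholded), `hapnet`:

1. builds one undirected network per pathway (intrinsic, cross-pathway, or
   1°/2°-interactor-expanded edge retention);
2. scores every edge from its endpoints' calls and dose-sensitivity weights
   (1 = no evidence, 2 = yeast, 3 = mouse) — deletions score negatively,
   gains positively, with haploinsufficient genes weighted up;
3. sums edge scores per tumour into module scores, normalized so that a
   cohort in which every module gene carries a monoallelic loss scores −1;
4. assigns significance with a tumour-paired permutation null (per-sample
   call shuffling, 1,000 replicates by default), aggregating replicate
   t-test p-values as 10^mean(log₁₀ p) with Bonferroni correction;
5. ranks genes by their summed edge-score impact across the cohort and
   benchmarks top-k tables against reference driver-gene sets (QC
   efficiency);
6. exports annotated cohort-summary networks (GraphML / Cytoscape JSON) with
   loss/gain/antagonistic/mutation edge styling and dose-sensitivity node
   outlines.

A fully seeded synthetic-cohort generator (`hapnet.synth`) provides inputs
with known ground truth, so the entire pipeline is testable offline.

## CLI

```sh
# generate a synthetic demo cohort
hapnet simulate --config sim.yaml --out demo/

# full analysis: pathway significance + module scores + gene impact
hapnet run --gene-sets demo/pathways.gmt --interactions demo/interactions.tsv \
    --yeast demo/gds_yeast.tsv --mouse demo/gds_mouse.tsv \
    --copy-number demo/copy_number.tsv --n-reps 1000 --seed 1 --out results/

# gene-impact tables, QC efficiency, Cytoscape export
hapnet impact ... --out results/
hapnet qc ... --reference drivers.tsv --out results/
hapnet viz ... --pathway NAME --format graphml --out results/
```

Every command takes `--seed`, writes a `manifest.json` (config, version,
input checksums), and is bit-for-bit reproducible from the manifest.
Continuous log₂ matrices are supported via `--continuous`
(`--cuts -1.3 -0.3 0.3 1.3` by default; boundary values are called altered).

Example simulation config (YAML):

```yaml
n_samples: 200
n_background_genes: 1000
background_rate: 0.1
planted:
  - name: PLANTED
    n_genes: 20
    edge_density: 0.3
    penetrance: 0.6
    direction: deletion
    hub: {degree: 6, penetrance: 0.7, gds: 3}
seed: 1
```

## Layout

- `src/hapnet/io.py` — format readers/writers (GMT, TSV dialects), domain types
- `src/hapnet/network.py` — network construction, edge/module scoring
- `src/hapnet/stats.py` — permutation null, p aggregation, Bonferroni
- `src/hapnet/impact.py` — gene-impact ranking, QC efficiency
- `src/hapnet/viz.py` — cohort-summary graph styling and export
- `src/hapnet/synth.py` — seeded synthetic cohorts with ground truth
- `src/hapnet/cli.py` — `hapnet run|simulate|impact|qc|viz`
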