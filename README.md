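# demesweep

Demographic inference and selection-scan toolkit for SNP-array panels, with
a synthetic-data generator that produces every input with known truth.

The pipeline covers:

- **Genotype core** (`demesweep.panel`, `demesweep.io`) — VCF / PLINK-text
  panels with a population map; MAF / call-rate filters, windowed LD
  pruning, composite (dosage) r², Weir–Cockerham FST components, Reynolds
  distances (PHYLIP export) and classical MDS on Hamming distances.
- **Synthetic data** (`demesweep.simulate`) — coalescent simulation of
  eight configurable colonization scenarios (founder bottleneck, expansion
  phases, restocking migration) over unlinked array-like loci;
  recombining multi-chromosome panels; admixed genomes with recorded
  ancestry tracks; planted hard sweeps; SNP ascertainment.
- **ABC** (`demesweep.abc`) — 17 summary statistics over four analysis
  groups, Spearman correlation pruning, rejection sampling, linear
  regression adjustment, KDE marginal densities, posterior P-values, Bayes
  factors, scenario ranking and posterior summaries (mode, 50%/90%
  intervals).
- **LD-based Ne** (`demesweep.ldne`) — distance-binned adjusted r², the
  `Ne = (1/4c)(1/r² − α)` inversion, trajectories over 13–50 generations,
  and the median-normalized slope statistic
  `NeS_n = (S_n − med{S_n,S_{n+1},S_{n+2}}) / (1 + med{...})`.
- **Sweep scans** (`demesweep.sweeps`) — XP-EHH (per-pair first-mismatch
  algorithm, exactly matching the brute-force EHH definition), top-tail
  significance, multi-reference validation, one-gap region merging with
  half-distance extension and singleton discard; windowed FST outlier scan
  on a 500-kb grid; Table-style region lengths (kbp, half-up rounding).
- **Local ancestry** (`demesweep.ancestry`) — ancestry HMM
  (forward–backward, switch rate `1 − exp(−g·r·d)`), genome-wide
  proportion tables, and region-level ancestry excess/deficiency scoring
  with 2-SD flags.

## CLI

```sh
demesweep simulate --scenario sc2 --out-prefix out/sim --samples 20 --n-loci 1000 --seed 1
demesweep abc-simulate --scenario sc2 --out out/sc2.tsv --n-sims 2000 --seed 1
demesweep abc-compare --tables out/sc1.tsv --tables out/sc2.tsv \
    --observed-vcf obs.vcf --popmap obs.pop.tsv --out out/comparison.tsv
demesweep ne --vcf panel.vcf --popmap pop.tsv --population pop0 --out ne.tsv
demesweep nes --trajectory ne.tsv --out nes.tsv
demesweep xpehh --vcf panel.vcf --popmap pop.tsv --focal colony_a --reference source --out scores.tsv
demesweep call-regions --scores s1.tsv --scores s2.tsv --scores s3.tsv --out regions.tsv --bed regions.bed
demesweep fst-windows --vcf panel.vcf --popmap pop.tsv --focal colony_a \
    --references r1 --references r2 --references r3 --out windows.tsv
demesweep ancestry --vcf admixed.vcf --popmap pop.tsv \
    --ancestral-vcf a.vcf --ancestral-vcf b.vcf --labels A --labels B \
    --alpha 0.7 --alpha 0.3 --out dosages.tsv
```

Population maps are TSVs with columns `sample_id`, `population`, `role`
(`focal` / `reference` / `ancestral` / `outgroup`). Scenario configurations
are JSON (see `src/demesweep/scenarios/`) and can be edited freely; times
may reference the sampled parameters (`t1`, `t2`, `t3`) and sizes the
parameter names (`ne_founder`, ...).

The shipped 17-statistic ABC summary set is a documented stand-in (the
original tool's exact list is unpublished); it is configurable by name
list in `demesweep.abc.model_choice`.

## Notes

- Coordinates are 1-based inclusive internally; BED exports are 0-based
  half-open.
- Unphased dosage r² uses a 1/n sample-size correction, phased haplotype
  r² 1/(2n).
- All stochastic operations are pure functions of (inputs, seed).
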