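# lampsim

Simulation and analysis toolkit for transcription-driven chromatin
organization in hypertranscribing (meiotic, lampbrush-stage) nuclei:

- **annotations** — transcription-unit models (GTF/BED12 + activity tables),
  FPKM metrics, co-directional tandems with length/activity classes, and
  orientation classification of adjacent pairs (FF/RR/FR/RF).
- **sim1d** — stochastic lattice simulation of RNA polymerases, two-sided
  loop-extruding factors (LEFs) and non-extruding cohesive cohesins on a
  heterogeneous bead array (45-bp unit beads / 225-bp nucleosomal beads),
  with polymerase pushing of SMC runs, probabilistic bypass, and
  lifetime-calibrated LEF turnover.
- **sim3d** — coarse-grained Brownian-dynamics relaxation of 1D snapshots
  (clusters of 10 beads, LEF bridge springs, sister-chromatid bonds at
  cohesive sites, nascent-RNA-inflated excluded volume, optional slab
  flattening).
- **simhic** — simulated contact maps from 3D conformations with a per-site
  contact cap (8 per site, the single-nucleus bound), cooler-schema HDF5
  output, and P(s) scaling curves.
- **hicstats** — cross-pattern score (CPS), diamond insulation,
  random-shift and rescaled pileups, quadrant insulation, saddle
  compartment strength, contact-composition fractions.
- **domains** — exact dynamic-programming segmentation with a gamma scan,
  LUD/SSD labeling by N50, boundary F1 with a permutation baseline, and
  interval-feature aggregation against shuffled intervals.
- **synthetic** — seeded generators for unit landscapes (orientation
  grammars, log-normal lengths/activities) and toy contact maps with
  planted domains, cross loci and compartment plaids.
- **experiments** — end-to-end drivers for the bypass-probability regime
  comparison (D/E/F/G) and the hypertranscribing -> damped stage
  transition on synthetic convergent tandem pairs.

## CLI

Everything is reachable through one executable:

```sh
lampsim synth --region-bp 2000000 --grammar "F F R gap R F" \
    --out-gtf tus.gtf --out-fpkm act.tsv
lampsim sim1d --tus tus.gtf --fpkm act.tsv --duration 1000 --out snaps.h5
lampsim sim3d --snapshots snaps.h5 --out traj.h5
lampsim simhic --snapshots snaps.h5 --traj traj.h5 --resolution 16000 \
    --out sim.cool
lampsim cps --cool sim.cool --out cps.bedgraph
lampsim insulation --cool sim.cool --out ins.bedgraph
lampsim domains --cool sim.cool --target-size 1000000 --out domains.bed
lampsim pileup --cool sim.cool --anchors anchors.txt --out pileup.tsv
lampsim saddle --cool sim.cool --eigenvector ev.bedgraph --out saddle.tsv
lampsim fractions --pairs pairs.tsv
lampsim experiment --regimes D,G --stages post --replicates 3 --seed 0 \
    --out scores.json
```

Contact maps use the cooler single-resolution HDF5 schema (unbalanced;
weights are 1 for covered bins and NaN for empty bins), so they
interoperate with external cooler tooling.

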