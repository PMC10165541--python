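# fishscreen

Quantitative analysis pipeline for genome-scale smFISH / fluorescent
protein-trap screens of the nervous system:

* **`fishscreen.synthetic`** — seeded generators for multichannel 3D image
  stacks (probe A, probe B, compartment marker, nuclear stain) and
  multi-annotator scoring tables, with complete ground truth.
* **`fishscreen.spots`** — rolling-ball background subtraction (grey tophat,
  5 px for smFISH / 20 px for markers), Laplacian-of-Gaussian 3D spot
  detection with subpixel Gaussian refinement, single-molecule unit-intensity
  estimation, single/focus/rejected classification, and two-channel
  codetection by one-to-one optimal assignment.
* **`fishscreen.compartments`** — 3D marker segmentation into labeled
  compartments, spot-to-compartment assignment and counting, ghost/mature
  bouton classification, and condition comparison with an assumption-driven
  test-selection tree (Shapiro–Wilk; F test / Levene; Student's t / ANOVA +
  Tukey; Wilcoxon rank sum / Kruskal–Wallis + Dunn).
* **`fishscreen.scoring`** — majority-vote aggregation of ≥3 annotators with
  escalation of ties, intercellular/intracellular mRNA–protein discordance
  classification over a compartment taxonomy, screen tabulations (four-category
  splits, UpSet counts, headline percentages), neuroblast expression-pattern
  classification, and genome-scale extrapolation with Wilson bounds.
* **`fishscreen.cli`** — `fishscreen` command with subcommands
  `simulate, detect, codetect, segment, count, compare, score, tabulate,
  report`; deterministic outputs and checksummed run manifests.

## CLI quick start

```bash
cat > demo.yaml <<'YAML'
seed: 7
simulate:
  image:
    image_shape: [16, 96, 96]
    n_single_spots: 40
    codetection_fraction: 0.85
    min_separation_um: 0.6
  annotation:
    n_genes: 20
YAML

fishscreen --config demo.yaml --out run/sim simulate
fishscreen --config demo.yaml --out run/det detect run/sim/stack.ome.tif
fishscreen --out run/report report run/sim/annotations.csv
```

Every stage writes a `manifest.json` with the config hash and SHA-256
checksums of inputs and outputs; fixed seed + config give bit-identical
files. Exit codes: 0 ok, 2 config error, 3 input error, 4 internal error.

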