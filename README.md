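# rosquant

Area-based quantification of a ROS (reactive oxygen species) stain in
multi-channel confocal z-stacks of translucent juvenile bivalves, plus the
statistical chain used to compare treatment groups and a synthetic phantom
generator so the whole pipeline can be exercised end-to-end without any
microscope data.

## What it computes

Per individual, from a 3-channel z-stack (CH1 shell autofluorescence, CH2
ROS stain, CH3 optional gut autofluorescence):

1. per-channel maximum-intensity projection;
2. shell footprint segmentation from CH1 (threshold, morphological closing,
   hole filling, largest connected component);
3. removal of non-specific CH2 signal by clipped channel subtraction
   `max(0, CH2 − gain·CH1)`, with the gain either fixed (default 1, the
   gain-balanced acquisition design) or estimated from shell-ring pixels;
4. ROS-positive segmentation of the subtracted image *inside* the shell
   footprint (Otsu by default, fixed threshold override, plus a
   scale-invariant floor referenced to the shell autofluorescence level);
5. the readout `ros_percent = 100 · ros_area / shell_area`.

On a tidy table of individuals × {treatment, container, ros_percent} it then
runs: arcsine square-root transform, Shapiro–Wilk and Brown–Forsythe
assumption checks, a nested one-way ANOVA with container as a random factor
nested in treatment (treatment tested over the among-container mean square),
and a Tukey HSD post-hoc on the same error term.

The `synth` module renders elliptical "mussel" phantoms with known
ground-truth shell and ROS masks, and simulates a containers-within-
treatment experiment with a two-level Gaussian hierarchy of true ROS
fractions.

## CLI

```sh
# render a simulated experiment to OME-TIFF stacks + labels/truth tables
rosquant simulate --design design.yaml --phantom phantom.yaml --out stacks/

# quantify every stack in a directory into a tidy CSV
rosquant quantify --input stacks/ --labels stacks/labels.csv --out results.csv

# transform + nested ANOVA + Tukey on the results table
rosquant analyze --table results.csv --out anova.json

# all three stages, in memory, with a manifest and run log
rosquant run-all --config run.yaml [--seed 7]
```

`run-all` emits `results.csv`, `anova.json`, `posthoc.csv`,
`group_means.csv`, `truth_table.csv`, `run.log` and `manifest.json` (every
default materialised, config hash, seed) into the configured output
directory; identical config + seed reproduce `results.csv` byte for byte.

Example `run.yaml`:

```yaml
seed: 7
out_dir: run-bundle
design:
  treatments:
    - {label: control,  mean_fraction: 0.05, between_container_sd: 0.03, within_container_sd: 0.06}
    - {label: stressed, mean_fraction: 0.30, between_container_sd: 0.03, within_container_sd: 0.06}
  containers_per_treatment: 3
  individuals_per_container: 10
phantom: {image_shape: [256, 256], noise_sd: 6.0}
segmentation: {shell_threshold: otsu, ros_threshold: otsu, closing_radius: 2}
stats: {transform: arcsine-sqrt, alpha: 0.05, posthoc: tukey}
```

Unknown configuration keys are rejected at load time.

## Package layout

- `rosquant.image_io` — z-stack/mask I/O, OME-TIFF and plain TIFF dialects,
  CH1/CH2/CH3 channel-role convention.
- `rosquant.pipeline` — projection, gain estimation, subtraction,
  segmentation, per-individual and batch quantification.
- `rosquant.stats` — transform, assumption checks, nested ANOVA, Tukey,
  pooled t-test.
- `rosquant.synth` — phantom renderer and experiment simulator.
- `rosquant.config` / `rosquant.cli` — strict YAML configs and the
  `rosquant` command.
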