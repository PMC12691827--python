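# mvnperm

Quantification of tracer transport across 3D microvascular networks (MVNs)
imaged as two-channel confocal z-stacks — the readout used to test whether a
surface ligand (e.g. transferrin, "TF") on a nanocarrier improves delivery of
its cargo across a blood–brain-barrier-like endothelium grown in a
microfluidic chip.

The package is aimed at groups running organ-on-chip permeability assays:
one channel carries the vessel marker (GFP-labelled endothelium), the other
the cargo tracer (e.g. Cy3-labelled antisense oligonucleotide). It answers
two questions:

1. **How much tracer got out of the vessels?** The vessel channel is
   segmented into a binary lumen mask (Otsu by default); mean tracer
   intensity is computed inside (intraluminal) and outside (extravascular)
   the mask per z-slice and averaged across the stack. Condition effects are
   expressed as day-normalized differences

   Δ = I(TF device) − mean(I of control devices), per measurement day,

   which cancels day-to-day drift in microscope intensity.

2. **How far did it get?** Line scans are drawn perpendicular to vessels on
   z-projections; lumen borders are located by level crossing (half-maximum
   above baseline, i.e. FWHM) on the vessel profile; the tracer profile is
   background-corrected, expressed as a percentage of the mean intraluminal
   intensity, and followed 100 µm outward. Fifty-plus scans are binned and
   averaged, an ordinary least-squares line value = intercept + slope·d is
   fitted, and conditions are compared by their mean "permeability"
   (mean % over 0–100 µm) and the ratio of slope magnitudes. The same border
   detection yields vessel diameters for morphometry.

Because such experiments rarely ship with ground truth, the package includes
a synthetic phantom generator (tubes + linear tracer decay + Gaussian PSF +
Poisson/Gaussian noise) so that every stage is tested against known
geometry and decay parameters, plus the standard liposome formulation
formulas (encapsulation efficiency EE% = 100·C_A/C_At, and calibration-curve
ligand grafting yield).

## Worked example

Run the full synthetic experiment — 2 conditions × 2 timepoints × 3 devices,
segmented, partitioned and profiled end to end:

```python
from mvnperm.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=1, output_dir="out"))
for cell, vals in summary["cells"].items():
    print(f"{cell:16s} mean permeability {vals['mean_permeability_pct']:5.1f} %"
          f"   slope {vals['slope_pct_per_um']:+.3f} %/µm   (n={vals['n_scans']} scans)")
print("24 h slope fold change (control/TF):",
      round(summary["slope_fold_change_control_over_tf"]["24 h"], 2))
```

prints

```
TF|24 h          mean permeability  83.7 %   slope -0.102 %/µm   (n=51 scans)
TF|30 min        mean permeability  89.8 %   slope -0.060 %/µm   (n=51 scans)
control|24 h     mean permeability  70.5 %   slope -0.360 %/µm   (n=51 scans)
control|30 min   mean permeability  88.0 %   slope -0.060 %/µm   (n=51 scans)
24 h slope fold change (control/TF): 3.54
```

Read: shortly after perfusion the two liposome formulations are
indistinguishable (≈90 % vs ≈88 % of luminal signal within 100 µm of the
vessel wall). After 24 h the control tracer has fallen off ~3.5× more
steeply with distance, so the TF-functionalized carrier sustains much
higher extravascular delivery (83.7 % vs 70.5 %). The `out/` directory
contains the tidy per-device partition table, the day-normalized Δ table,
per-scan diameters, binned profiles, and a JSON summary, all stamped with
the config hash.

The same pipeline is scriptable from the shell:

```sh
mvnperm run --config config.json --seed 1 --out out/
mvnperm quantify --stack device.ome.tif --out quant.csv
mvnperm profiles --stack device.ome.tif --n-scans 50 --seed 17 --out dev
mvnperm assay --standards standards.csv --samples samples.csv --out yields.csv
```

## Layout

| module | role |
| --- | --- |
| `mvnperm.io` | TIFF/OME-TIFF stack reading/writing, z-projections |
| `mvnperm.lumen` | vessel segmentation, in/out intensity partitioning, Δ signal |
| `mvnperm.profiles` | line scans, level-crossing borders, permeability profiles, fits, morphometry |
| `mvnperm.synth` | phantom generator, experiment designs, assay fixtures |
| `mvnperm.assays` | encapsulation efficiency, calibration curves, grafting yield |
| `mvnperm.pipeline` / `mvnperm.cli` | config-driven orchestration and the `mvnperm` CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
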