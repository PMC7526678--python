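# meniscus-strain

Image-to-strain analysis of human menisci under compressive load.

Degenerative changes in the knee's menisci alter how load is transmitted
to the articular cartilage. One way to probe this in situ is to image a
loaded knee at several fractions of body weight (BW), register the
loaded MRI volumes to the unloaded reference, and read tissue strain
directly off the recovered displacement field. This package implements
that pipeline end to end, for researchers in orthopaedic biomechanics
and quantitative MRI:

1. **Registration.** A loaded volume is rigidly aligned (6-parameter,
   tibia-mask driven), cropped to an ROI, and non-rigidly registered to
   the unloaded volume with a demons-style diffeomorphic scheme driven
   by a windowed normalized cross-correlation metric (window radius 2,
   gradient step 0.25, Gaussian update regularization σ = 3 voxels,
   four resolution levels with iteration caps 1000/500/250/100, energy
   tolerance 1e-6). The result is the displacement field u(x) mapping
   unloaded voxel positions to their loaded positions.
2. **Meshing.** The segmented meniscus (plus root attachments) becomes
   a hexahedral finite-element mesh with one 8-node brick per voxel
   (element size = image resolution, e.g. 0.4 × 0.4 × 0.6 mm³), and
   u is interpolated to the mesh nodes.
3. **Strain.** Per element, the displacement gradient ∇u of the
   trilinear interpolant is evaluated at the centroid and converted to
   the infinitesimal strain ε = ½(∇u + ∇uᵀ) (Green–Lagrange
   E = ½(FᵀF − I) available). ε is projected onto a per-meniscus
   cylindrical frame — origin from a circle fit (Kåsa) to outer-rim
   points, axis along the load direction — giving radial (ε_rr),
   circumferential/hoop (ε_θθ) and axial (ε_zz) normal strains.
4. **Regions.** Elements are partitioned into the five anatomical
   regions (ARA, AH, PI, PH, PRA) by two user-specified separation
   lines and equal trisection of the remaining body arc, and into
   inner/outer zones at two-thirds of the local radial width. The
   per-region **median** strain is the characteristic value.
5. **Statistics.** Characteristic strains feed a nonparametric battery:
   Mann-Whitney U (mild vs severe degeneration), Friedman + post hoc
   paired Wilcoxon with Holm correction (locations), paired Wilcoxon
   (ARA vs PRA), Kruskal-Wallis (load levels), Shapiro-Wilk screen.
6. **Agreement.** Repeat segmentations are compared with the Dice
   similarity coefficient, DSC = 2|A∩B|/(|A|+|B|) (> 0.7 = excellent).

Because cadaver MRI data are not distributable, the package ships a
first-class **phantom generator**: C-shaped wedge meniscus geometry,
MRI-like textured volumes with Rician noise, analytic ground-truth
deformation fields per load level, and a two-group synthetic cohort of
characteristic strains whose group means follow the published pattern
(axial −3.1 % mild vs −7.3 % severe at 100 % BW; circumferential
+0.35/+0.45 %; radial +0.37/+0.41 %). Every stage is validated against
these analytic ground truths.

## Worked example

Run the cohort analysis on generator defaults (12 + 12 specimens,
3 load levels):

```sh
python analysis/03_cohort_statistics.py --seed 0
```

prints

```
group means at 100% BW (%):
group   direction
mild    axial             -3.32
        circumferential    0.31
        radial             0.40
severe  axial             -7.51
        circumferential    0.44
        radial             0.44

fraction of significant mild-vs-severe contrasts at 100% BW:
direction
axial              1.0
circumferential    0.1
radial             0.0
```

Axial compression roughly doubles with severe degeneration and every
regional axial contrast is significant, while the small tensile
(circumferential/radial) differences stay at chance level — compressive
integrity degrades, tensile behavior is maintained. The registration
validation driver (`analysis/02_registration_validation.py`) reports
median endpoint errors of ~0.02–0.10 voxel and regional median strain
recovery within 0.5 percentage points for confined compression up to
7.3 %.

A CLI mirrors the stages for shell use:

```sh
meniscus-strain phantom --out-dir scratch/demo --seed 1
meniscus-strain register scratch/demo/unloaded.nii.gz scratch/demo/loaded_100bw.nii.gz --out scratch/demo/field.nii.gz
meniscus-strain run-all study.yaml --out-dir results/
```

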