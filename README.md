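# scarvt

Computational models of infarcted ventricles built from imaging and ECG data
are used to predict paced activation and the inducibility of scar-related
ventricular tachycardia (VT). Their predictions hinge on modelling choices
that are rarely quantified: how finely the scar is imaged (thin conducting
isthmuses are lost between thick clinical slices), whether the right
ventricle is included, and whether tissue electrophysiology is personalised
from the 12-lead ECG or taken from the literature.

`scarvt` implements that whole pipeline at desk scale, with a synthetic
anatomy generator standing in for animal MRI so every stage is testable:

- **synthetic anatomy** — labelled two-ventricle voxel phantoms with a
  parameterized anteroseptal scar, border-zone rim and configurable
  conducting isthmus; synthetic late-enhancement intensities and
  fraction-of-maximum threshold segmentation; clinical z-direction
  down-sampling (1 → 4/10 mm slices);
- **scar reconstruction** — logOdds shape interpolation (Gaussian-blurred
  occupancy → logit → cubic inter-slice interpolation → logistic
  re-threshold) and a quantitative isthmus-patency check
  (widest-path clearance between anchors flanking the channel);
- **meshing** — voxel-derived hex/tet meshes with region tags, universal
  ventricular coordinates from Laplace solves, rule-based fibres
  (helix angle linear in transmural depth), a fast endocardial conduction
  (FEC) layer at 5% transmural depth, LV-only sub-meshes, and AHA-style
  pacing-site selection;
- **membrane model** — the 2006 epicardial human ventricular cell
  (ten Tusscher–Panfilov formulation) with porcine modification
  (gKs, gKr × 2.3 → APD ≈ 205 ms at a 500 ms cycle length), border-zone
  remodelling (INa −62%, ICaL −69%, IKr −70%, IKs −80%) and QT-based APD
  fitting;
- **propagation** — anisotropic eikonal activation ‖∇T‖_M = 1 (per-region
  conduction velocities, scar non-conducting), reaction-eikonal voltage
  synthesis, and a mass-lumped P1 monodomain solver
  ∂V/∂t = ∇·(σ∇V)/(βC_m) − I_ion/C_m with Rush–Larsen membrane updates;
- **ECG** — dipole-source extracellular potentials via a precomputed
  lead-field matrix, standard 12-lead assembly, VCG spatial-velocity QRS
  bounds, tangent-method QT with outlier-lead rejection, unipolar
  electrograms with Wyatt-method repolarization times;
- **personalisation** — TACT-fit (total activation time at the base as a
  QRSd surrogate; CV swept 0.36–0.96 m/s) and QRSd-fit (full forward-ECG
  match) conduction velocities, plus automated conductivity tuning on a
  325 µm strand;
- **VT protocol** — S1–S2 programmed stimulation over the pacing sites with
  a 2 s observation window, ECG-based sustained-VT classification, ring
  wavelength-law experiments and a canonical 2-D isthmus phantom;
- **comparison** — ICP registration of mapping-catheter point clouds and
  nearest-neighbour activation-time error.

## Worked example

The package's central qualitative result — a 3 mm conducting isthmus
survives 1 mm imaging but is closed by reconstruction from 10 mm slices:

```python
from scarvt.anatomy import generate_biv_labels, paint_scar, downsample_z
from scarvt.volumes import ScarSpec
from scarvt.reconstruct import reconstruct_scar, isthmus_patency, channel_anchors
from scarvt.ionic import make_porcine_baseline, paced_apd

vol = generate_biv_labels()                      # 1 mm two-ventricle phantom
scarred = paint_scar(vol, ScarSpec(isthmus_width=3.0))
a, b = channel_anchors(scarred)

print("native 1 mm:", isthmus_patency(scarred, a, b))
low = downsample_z(scarred, 10.0)                # clinical 10 mm slices
rec = reconstruct_scar(low, dz_out=1.0)          # logOdds reconstruction
print("10 mm recon:", isthmus_patency(rec, a, b))

apd = paced_apd(make_porcine_baseline(), bcl=500.0)
print(f"porcine-modified APD90 at BCL 500 ms: {apd:.1f} ms")
```

prints

```
native 1 mm: {'patent': True, 'min_width': 4.0}
10 mm recon: {'patent': False, 'min_width': 0.0}
porcine-modified APD90 at BCL 500 ms: 207.1 ms
```

The patency flag is the anatomical substrate for re-entry: with the channel
open, S1–S2 stimulation of the 2-D isthmus phantom
(`scarvt.pes.isthmus_sheet_phantom`) induces sustained VT, and with the
10 mm-reconstructed (closed) scar it does not — see
`tests/test_acceptance.py`.

A command-line interface mirrors the file-based stages:

```sh
scarvt generate --isthmus-width 3 --dz 10 --out low.nii
scarvt reconstruct-scar --in low.nii --dz-out 1 --out rec.nii
scarvt mesh --in rec.nii --fibres 60,-60 --out model.vtk
```

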