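# lesioncorr

Surface-based cortical **lesion correction** for volumetric MRI analysis.

Patients with chronic focal brain lesions (e.g. post-traumatic
encephalomalacia) are routinely excluded from cortical volumetric studies
because the reconstructed cortical surfaces are unreliable at lesion sites.
`lesioncorr` implements the alternative: instead of editing the surfaces, a
rater *labels* the inaccurate vertices, and the labelled patch is removed
from all downstream regional statistics. The package provides

* readers/writers for the FreeSurfer file formats involved (binary triangle
  surface, per-vertex "curv" scalars, ASCII labels, binary annotations with
  colortables), plus TSV stats tables;
* a mesh geometry kernel (triangle/vertex areas, graph geodesics);
* a non-interactive reimplementation of the "Custom Fill" labeling
  workflow: close an anchor outline with shortest paths, flood-fill the
  enclosed patch, save protocol-named labels (`lh.lesion-01.label`, ...),
  and combine them into per-hemisphere `all-lesions` overlays;
* the statistics engine: per-region surface area `A`, area-weighted mean
  thickness `t̄`, and volume `V = A·t̄/1000` (ml), before and after lesion
  exclusion; percent network surface area affected, percent volume change,
  lesion counts per network, and group lesion-frequency maps;
* quality control: SNR (`μ/σ` within the WM segmentation), CNR (mean of the
  WM–GM and GM–CSF pooled-SD contrasts `|μa−μb|/√((σa²+σb²)/2)`), ABC/2
  lesion volumetry (`A·B·C/2`), and the two-way intraclass correlation
  ICC(2,1)/ICC(3,1) with F-based confidence intervals;
* a synthetic-subject generator (spherical "hemispheres", 7-network
  parcellation, smooth thickness with planted thinned lesions of known area
  fraction, voxel phantoms, rater matrices) so everything is testable
  without patient data.

## Worked example

```python
import lesioncorr as lc

# synthetic subject: 10% of the limbic network's surface area is lesioned
subject = lc.make_subject(seed=7, subdivisions=4, lesion_specs=[("Limbic", 0.10)])
mesh, th, parc = subject.meshes["lh"], subject.thickness["lh"], subject.parcellations["lh"]

overlay = lc.combine_labels(subject.lesions["lh"], "lh")
pre, post = lc.corrected_stats(mesh, th, parc, overlay, "lh")
pct = lc.pct_surface_area_affected(mesh, parc, subject.lesions["lh"])
for a, b in zip(pre, post):
    dv = lc.pct_volume_change(a.volume_ml, b.volume_ml, "post")
    print(f"{a.region_name:16s} pre={a.volume_ml:6.2f} ml  post={b.volume_ml:6.2f} ml  "
          f"area affected={pct[a.region_name]:5.2f}%  volume change={dv:+6.2f}%")
```

prints

```
Visual           pre= 17.45 ml  post= 17.45 ml  area affected= 0.00%  volume change= +0.00%
Somatomotor      pre= 14.05 ml  post= 14.05 ml  area affected= 0.00%  volume change= +0.00%
DorsalAttention  pre=  6.58 ml  post=  6.58 ml  area affected= 0.00%  volume change= +0.00%
Salience         pre=  3.10 ml  post=  3.10 ml  area affected= 0.00%  volume change= +0.00%
Limbic           pre=  3.67 ml  post=  3.58 ml  area affected=10.43%  volume change= -2.32%
ExecutiveControl pre= 18.22 ml  post= 18.22 ml  area affected= 0.00%  volume change= +0.00%
DefaultMode      pre= 11.35 ml  post= 11.35 ml  area affected= 0.00%  volume change= +0.00%
```

The planted lesion covers 10.43% of the limbic network's surface area (the
target was 10%; the excess is vertex quantization — lesions grow vertex by
vertex). Because the lesioned patch was also thinned, removing it changes
the limbic volume by −2.32% and leaves every other network untouched.

The same pipeline is available from the shell:

```sh
lesioncorr simulate --seed 7 --out subj --lesion Limbic:0.10:lh
lesioncorr label --subject-dir subj --hemi lh --anchors anchors.txt --seed-vertex 1200
lesioncorr correct --subject-dir subj --out stats      # overlays + pre/post TSVs + overlap report
lesioncorr qc --volume t1.nii --wm wm.nii --gm gm.nii --csf csf.nii --out qc.tsv
lesioncorr groupmap --template lh.template --out freq.curv subj*/lh.all-lesions.label
```

`correct` writes, per hemisphere, the `all-lesions` overlay (as a label and
as a curv-format indicator field), `stats.pre.tsv` / `stats.post.tsv`
region tables, and a combined `overlap_report.tsv` with per-network lesion
counts, % surface area affected, and pre/post volumes.

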