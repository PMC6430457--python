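# femoromorph

Automated 3-D morphometry of the proximal human femur from triangulated
surface meshes, with cohort statistics and a parametric synthetic-femur
generator for validation.

## The problem

Orthopaedic planning (total hip replacement, hip resurfacing, osteotomy) and
implant design need quantitative descriptions of proximal-femur anatomy:
how long the bone is, how large and where the head is, how the neck is
angled, and how these quantities co-vary across a population.  Such
parameters are routinely extracted from CT-derived surface models, but the
extraction is usually manual.  `femoromorph` turns an STL/PLY femur surface
(one bone per file, millimetres, either side) into the twelve standard
parameters automatically, and reproduces the statistical analysis a
morphometric study applies to a cohort of such measurements.

## The twelve parameters

With FHC the femoral head centre, FSA the femoral shaft axis, FNA the
femoral neck axis, and the frontal/sagittal/transversal planes anchored on
the shaft axis and the posterior condylar line:

| symbol | definition | unit |
|---|---|---|
| FHD | diameter of the best-fit sphere of the femoral head | mm |
| TFL | total femur length along the superior axis | mm |
| NSA | neck-shaft angle between FNA and FSA (obtuse, 3-D) | deg |
| ATA | anteversion: transversal-plane angle of the FNA against the knee medio-lateral line, anterior positive | deg |
| OSA | absolute offset: distance FHC→FSA | mm |
| OSH | horizontal offset: the same distance projected into the frontal plane | mm |
| OSV | vertical offset: FHC height above the lesser-trochanter plane | mm |
| GTH | FHC height above the greater-trochanter apex plane (signed) | mm |
| NCDF, NCDS | FHC→FNA distance projected into the frontal / sagittal plane (≥ 0) | mm |
| NCVD, NCHD | cranial(+)/caudal(−) and anterior(+)/posterior(−) components of the FHC eccentricity off the FNA | mm |

The geometric estimators are: iterated total-least-squares line through
diaphyseal cross-section area centroids in the 50–80 % band of bone length
(FSA); robust RANSAC-refined least-squares sphere on the proximal-medial
surface (FHC/FHD); total-least-squares line through neck cross-section
centroids between the head surface and the trochanteric junction (FNA).
Left and right femurs are measured in their own anatomical frame
(medial +, anterior +, superior +), so all parameters are side-independent;
the side itself is recovered from the handedness of the frame.

Cohort statistics follow the standard recipe: per-parameter
min/max/mean/SD/median, the 12×12 Pearson inter-correlation matrix with
two-sided t-tests (`t = r√((n−2)/(1−r²))`, df = n−2) at α = 0.05, and a
Shapiro–Wilk normality assessment with Freedman–Diaconis histogram binning.

Because real CT cohorts are rarely shareable, the package includes a
synthetic generator: cohorts are drawn from a Gaussian-copula model
calibrated to a published reference cohort of 169 adult femurs (means, SDs,
full correlation matrix; the two non-negative neck distances get folded-
normal marginals), and any parameter vector can be realised as a watertight
parametric femur mesh with exactly known ground truth — which is how the
pipeline is validated end to end.

## Worked example

```python
from femoromorph import synthetic_femur as sf
from femoromorph.model import FemurModel, CohortModel

# a synthetic femur built from the reference-cohort mean parameters
mesh, truth = sf.generate_femur_mesh(sf.mean_parameters(specimen_id="demo"))
res = FemurModel(mesh, specimen_id="demo").fit(repeats=6, seed=42)
print(res.summary())
```

```
Proximal femur morphometry
==============================================
specimen: demo    side: right    repeats: 6
----------------------------------------------
parameter     estimate   repeat SD  unit
FHD             46.308      0.0009  mm
OSA             42.365      0.0010  mm
OSV             54.353      0.0005  mm
OSH             40.419      0.0010  mm
ATA             17.394      0.0002  deg
NSA            126.410      0.0002  deg
GTH              7.424      0.0005  mm
TFL            439.207      0.0000  mm
...
head sphere inlier fraction: 0.73
```

The estimates sit within 0.15 mm / 0.07° of the generator's analytic ground
truth (FHD 46.29, OSA 42.39, NSA 126.35, ATA 17.46, TFL 439.22; OSH and the
neck eccentricities are derived from the realised geometry).  The repeat SD
column is the spread over the six repeated measurements.

```python
cohort = sf.sample_cohort(sf.GeneratorSpec(n=169, seed=42))
print(CohortModel(cohort).fit().summary())
```

prints the descriptive table and the headline correlations, e.g.
`r(OSA,OSH)=+0.92, r(OSV,TFL)=+0.75, r(TFL,FHD)=+0.68`, with the two folded
neck-distance parameters classified non-normal and 36 of the 66 parameter
pairs significant at α = 0.05.

From a shell, the same pipelines are available as

```bash
femoromorph measure femur.stl --repeats 6 --out params.csv
femoromorph cohort params/*.csv --out report/
femoromorph simulate --n 169 --seed 42 --out cohort/
```

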