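# fpdremodel

Automated connector detection and parametric cross-section remodelling for
n-unit fixed partial denture (FPD) surface meshes.

An FPD — a multi-unit dental bridge — fails mechanically at its *connectors*,
the narrow necks of material joining adjacent crown or pontic units. Studying
how connector design affects stress requires many variants of the same
prosthesis that differ only in one connector's cross-sectional area, reduced
from a chosen anatomical side. Producing such variants by hand in a CAD tool
is slow and irreproducible. `fpdremodel` automates the whole loop on a plain
STL surface mesh:

1. **Detect** the connectors. The bridge is framed in its smallest oriented
   bounding box B₀ (faces labeled occlusal/gingival, mesial/distal,
   lingual/buccal from orientation hints), the mesio-distal mid-axis L₁ is
   sliced with 300 equally spaced perpendicular planes Eᵢ, each intersection
   curve Cᵢ is bounded by a rectangle Rᵢ split at mid-height (E_mid) into an
   occlusal and a gingival part, and the local minima of the two area series
   (A_i-occlusal → α_j, A_i-gingival → β_j) mark the connector necks — found
   separately per side, so oblique connectors are handled.
2. **Adjust** a connector to a target area A_input. In a local frame on the
   connector mid-plane E_midCon (x̂ occlusal, ŷ buccal), every mesh vertex
   with distance dᵢ < w to the plane (w = 1 mm by default) is displaced by

       x_new = x − k · d_yz · B(d_xy) · x,
       B(t)  = (w−t)³·w + 3t(w−t)²·0.9w + 3t²(w−t)·0.1w,

   a cubic-Bézier-weighted shrink toward the mid-plane that fades smoothly to
   zero at distance w. The gingival, lingual and buccal laws are the
   sign/axis mirrors; `iso` applies all four with one shared k. The parameter
   k is solved by bracketed bisection on the monotone map k ↦ area(k) until
   |A₂ − A_input| ≤ 0.001 mm².
3. **QC** the result: symmetric sampled Hausdorff distance between meshes,
   plus uniform remeshing when a different element density is needed.

Because scanned prostheses are rarely redistributable, the package ships a
**synthetic generator** (`fpdremodel.synthetic_fpd`) producing watertight
n-unit bridges with known connector ground truth — by default a 4-unit bridge
of 32.5 × 11.7 × 9.0 mm with three oval connector necks of 33.1 / 28.5 /
33.2 mm². All geometry is interpreted in millimetres.

## Worked example

```sh
fpdremodel synth --preset fpd --pitch 0.3 --out fpd.stl
fpdremodel detect --in fpd.stl --out-csv detection.csv
fpdremodel adjust --in fpd.stl --out-dir runs --site 1 --direction gingival --reduce 0.1
```

`detection.csv` (one row per connector, distal→mesial):

```
j,alpha,beta,station_mm,a0_mm2,obliquity_deg,height_mm,length_mm
0,71,71,7.74583333,33.1382547,0,5.70795512,6.80985932
1,149,149,16.1958333,28.8811019,0,5.73916755,6.05111077
2,228,228,24.7541667,33.2301654,0,5.80668002,6.80911995
```

Each connector is reported with the slice indices of its occlusal/gingival
area minima (α, β), its station along the mid-axis from the distal face, the
initial cross-sectional area A₀ at the connector mid-plane, and the section's
occluso-gingival height and bucco-lingual length. The three areas sit within
~1.5% of the generator's construction targets (33.1 / 28.5 / 33.2 mm²).

`runs/results.csv` after the 10% gingival reduction of the middle connector:

```
site,direction,a0_mm2,a_input_mm2,a_final_mm2,k,iterations,achieved_mm2,status,stl
1,gingival,28.8811019,25.9929917,25.9928072,0.0860461214,12,0.000184562554,ok,adjusted_site1_gingival_r10.stl
```

The solver reached the requested area (0.9 × 28.881 = 25.993 mm²) to within
0.0002 mm² — inside the ±0.001 mm² stopping tolerance — after 12 bisection
iterations, and wrote the adjusted STL (same face connectivity, vertices
moved only within 1 mm of the connector plane).

The full study sweep (every connector × {iso, gingival, occlusal, lingual,
buccal} × {10%, 20%}) is one flag: `fpdremodel adjust --in fpd.stl
--out-dir sweep --sweep` → 30 adjusted STLs plus a results table.

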