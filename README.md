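# radioplan

Virtual osteotomy planning, ICP-based transformation measurement and
3D-print quality control for distal-radius corrective surgery — exercised
end-to-end on synthetic, ground-truthed radius meshes.

The package implements the computational core of a patient-specific-guide
workflow:

- **geometry** — triangle meshes (binary/ASCII STL I/O with exact vertex
  welding), rigid/improper transforms, plane cutting, mirroring;
- **registration** — closed-form Kabsch alignment (the oracle) and ICP with
  point-to-triangle correspondences, an automatic mean + 2 SD distance
  threshold for trimming, and an optional point-to-plane minimiser;
- **frame** — the landmark-defined distal-radius coordinate system: CRP
  origin, automatic central-axis fit 30–50 mm proximal of the CRP, x toward
  the styloid projection, y volar-positive (mirrored anatomy gives a
  mirrored, left-handed frame);
- **planning** — cut the malunited radius at the osteotomy plane, align the
  distal fragment onto the mirrored healthy reference, back-transform drill
  trajectories into the malunited pose;
- **measurement** — register result-to-plan proximally, world-align via the
  anatomical frame, register distally, and decompose the residual transform
  into six clinical parameters (volar tilt / radial inclination / axial
  rotation errors in degrees; translations in mm, ulnar-variance error on
  z). Cardan sequence `R = Rz·Ry·Rx`, volar and lengthening positive;
- **qa** — average distance error (ADE) of scanned guides against design
  files and pre/post-sterilisation comparisons, with surface masks;
- **stats** — paired absolute-error noninferiority (t-interval vs. margins,
  default 5° volar tilt / 2 mm ulnar variance), exact and
  normal-approximation Mann-Whitney U, Shapiro-Wilk, approximate post-hoc
  Mann-Whitney power, study summary tables;
- **synthetic** — a parametric radius surrogate with analytic landmarks and
  axis, malunion induction, simulated surgery with injected residual
  errors, optical-scan noise, and whole-study generation with exact ground
  truth.

## CLI

```sh
radioplan simulate --n 16 --seed 7 --out study_dir/        # synthetic cohort
radioplan register --moving scan.stl --fixed plan.stl --trim auto --out reg.json
radioplan plan --malunited m.stl --healthy-mirrored h.stl --plane plane.json --out plan.json
radioplan measure --result r.stl --plan plan.json --landmarks lm.json --out errors.json
radioplan qa-ade --reference design.stl --scan scan.stl --out ade.json
radioplan qa-sterilisation --virtual v.stl --pre p.stl --post q.stl --out report.csv
radioplan noninfer --errors per_case.csv --margin-rotx 5 --margin-transz 2 --out ni.json
radioplan run --config study.yaml --out report_dir/        # full pipeline
```

`radioplan run` writes a reproducible bundle: per-case measured errors,
injected truth, Table-style summaries, both noninferiority decisions, the
scatter-plot data behind the margin plot, and a log of every seed.

## Conventions

All lengths are millimetres; angles are degrees at API boundaries. Plane
normals on osteotomy planes point distally; the positive cut side is the
distal fragment. Transforms serialise as 4×4 row-major homogeneous JSON
matrices. Every stochastic routine takes an explicit seed.
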