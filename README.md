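# scaffoldflow

Perfusion modelling of 3D-printed bone tissue-engineering scaffolds:
parametric 0/90 lay-down geometry, steady laminar blood flow through the
pore network on a voxel grid, and the derived design metrics — pressure
drop, Darcy permeability, wall shear stress (WSS) and a WSS-threshold
cell-viability indicator.

## The problem

Extrusion-printed bone scaffolds are stacks of cylindrical filaments laid
down in a 0/90 pattern; pore size, pore gradient and filament diameter
control how culture medium or blood perfuses the construct. Perfusion
matters twice: transport (nutrients in, waste out, governed by the
intrinsic permeability *k₀*) and mechanics (the wall shear stress the flow
exerts on attached cells — roughly 0–30 mPa stimulates marrow stromal
cells, while higher stresses are detrimental). This package predicts both
from the design parameters alone, so that candidate geometries can be
ranked before anything is printed.

The model, in the field's standard notation:

* **Geometry.** Porosity = 1 − V_material / V_domain; specific surface
  S = SA / V. Filament centre spacing within a layer is
  *pore + fibre diameter*; consecutive layers fuse (vertical pitch smaller
  than the fibre diameter).
* **Flow.** Steady incompressible Navier–Stokes, ρ(u·∇)u = −∇p + µ∇²u,
  ∇·u = 0, with F = 0, uniform inlet velocity, zero-resistance outlet and
  no-slip walls. At the modelled conditions (blood: ρ = 1056 kg/m³,
  µ = 0.0045 Pa·s; inlet 1–9 mm/s) the interstitial Reynolds number
  Re = ρud/µ is ≤ 0.95, firmly laminar.
* **Darcy.** k₀ = uµL/ΔP, valid while Re ≤ 8.6.
* **WSS.** τ_w = µ ∂u_t/∂n on the filament surface, and the viability
  indicator: the percentage of scaffold surface with τ_w < 30 mPa.

Four catalogue designs are built in: three 20 × 20 × 3.1 mm rectangular
scaffolds with uniform pores (300, 350, 450 µm; designs 1A/1B/1C) and an
elliptical 31 × 26.7 mm design with six concentric rings of radially
increasing pore size (476–979 µm; design 2).

## Worked example

```python
from scaffoldflow import (
    ScaffoldSpec, build_rectangular_scaffold, compute_geometry_metrics,
    FluidProperties, unit_cell_domain, velocity_sweep,
)
from scaffoldflow.metrics import reports_frame

spec = ScaffoldSpec.case_1a()                      # 300 um pores
print(f"porosity {100 * compute_geometry_metrics(build_rectangular_scaffold(spec)).porosity:.2f} %")

cell = unit_cell_domain(spec, target_spacing=0.055)   # one 0.63 mm period
reports = velocity_sweep(cell, FluidProperties.blood(),
                         pore_sizes=spec.pore_sizes, scaffold_id="1A")
print(reports_frame(reports)[["u_mm_s", "dP_Pa", "k0_m2", "Re", "viable_pct"]].to_string(index=False))
```

prints

```
porosity 56.11 %
 u_mm_s     dP_Pa        k0_m2     Re  viable_pct
    1.0  5.742802 2.423429e-09 0.0704   25.596944
    3.0 17.232059 2.422915e-09 0.2112    6.399236
    5.0 28.729167 2.422150e-09 0.3520    4.106972
    7.0 40.238025 2.421116e-09 0.4928    2.578797
    9.0 51.762336 2.419818e-09 0.6336    1.814709
```

Reading this: the 300 µm-pore design has a void fraction of 56 %; its
permeability (≈ 2.4 × 10⁻⁹ m²) is velocity-independent to 0.2 % across the
whole sweep, confirming the Darcy regime (every Re ≪ 8.6); pressure drop
grows linearly with inlet velocity; and the share of filament surface
below the 30 mPa viability threshold shrinks monotonically as the flow
speeds up.

The same study can be driven from the shell:

```sh
scaffoldflow demo configs/          # write ready-to-run YAML configs
scaffoldflow run configs/case1A.yaml
scaffoldflow build-geometry 2 --stl design2.stl
```

A run directory contains the STL geometry, the labelled voxel domain and
(optionally) velocity/pressure fields as legacy-ASCII VTK, per-velocity
metric CSVs, plot-data CSVs, a viability summary table and a JSON
manifest.

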