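# pbsplan

Margin-based and robust spot-weight optimization for proton
pencil-beam-scanning (PBS) plans, with water-equivalent-thickness (WET)
based beam-specific target volumes and scenario-based robustness
evaluation — all on synthetic abdominal phantoms.

## The problem

Stereotactic PBS proton therapy for pancreatic targets must deliver an
ablative prescription (33 Gy(RBE) in 5 fractions) to a tumor that abuts
the duodenum, a serial organ at risk, while remaining deliverable under
setup errors (~2 mm) and proton range uncertainty (~3.5% of the
water-equivalent depth). Planners handle this either by optimizing on an
expanded *optimization target volume* (OTV) or by robust optimization.
This package implements and compares three schemes on a controlled
phantom:

- **OTV_2mm / OTV_5mm** — uniform geometric expansion of the GTV;
- **OTV_WET** — a beam-specific volume: along each ray of a beam, the
  GTV interval is extended distally by `0.035 × WET_distal` and
  proximally by `0.035 × WET_proximal` (water-equivalent margins
  converted to geometric length through the local stopping power, plus
  the setup component along the beam axis), with a 2 mm lateral
  expansion in the beam's-eye view;
- **RO** — minimax robust optimization of the spot weights on the GTV:
  minimize `max_s f(w; s)` over perturbation scenarios `s` (setup shift
  + range scaling), where `f` is a quadratic penalty objective.

Plans are evaluated with:

- the **42-scenario passing rate**: 14 setup shifts (nominal, 5
  cardinal, 8 diagonal; each of magnitude 2 mm) × 3 range scalings
  (0.965, 1, 1.035); a scenario passes if ≥ 95% of GTV volume receives
  the full prescription;
- the **DVH bandwidth** over a separate 8-scenario set,
  `Wd = 2·sqrt(Σᵢ(Dᵢ − D_nom)² / (N−1)) / D_nom × 100%`;
- the **dose spread function** (DSF): the analytic derivative of a
  sigmoid fitted to the line dose sampled across the 100%-isodose /
  duodenum abutment, summarized by the full widths of its peak at 50%
  (FWHM) and 20% (FW20M) of maximum.

The dose engine is an analytic PBS model (single-peak Bragg curve ×
lateral Gaussian, exactly linear in spot weights) — adequate for the
margin/robustness logic under study, not a transport calculation; see
`docs/methods.md`.

## Worked example

```sh
python analysis/01_phantom_geometry.py
python analysis/02_wet_margins.py
python analysis/03_optimize_plans.py
python analysis/04_robustness.py
python analysis/05_dose_falloff.py
```

`03_optimize_plans.py` prints, for the default ~11 mL GTV seated 164 mm
beneath the posterior surface with two posterior-oblique beams
(gantry 210°/150°):

```
OTV_2mm   GTV V(Rx) 100.00%   D98 34.16 Gy(RBE)   duodenum V33  0.17 cm^3
OTV_5mm   GTV V(Rx) 100.00%   D98 34.01 Gy(RBE)   duodenum V33  0.78 cm^3
OTV_WET   GTV V(Rx) 100.00%   D98 34.06 Gy(RBE)   duodenum V33  1.54 cm^3
RO        GTV V(Rx) 100.00%   D98 33.92 Gy(RBE)   duodenum V33  0.84 cm^3
```

Every scheme meets the nominal goal (≥ 98% of the GTV at the full
33 Gy(RBE)); the 2 mm uniform margin spares the duodenum best (V33 well
under the 1 cm³ constraint) while the WET margin, which deliberately
irradiates the range-uncertainty margin, doses it most.
`04_robustness.py` then shows why the small margin is not deliverable:

```
 scheme  passing_rate_pct  worst_gtv_v_rx_pct  Wd_gtv_D98_pct
OTV_2mm         69.047619           78.954802       17.692530
OTV_5mm         97.619048           93.926554        0.319489
OTV_WET        100.000000           98.940678        1.995856
     RO        100.000000           96.610169        1.096194
```

Under a 3.5% range undershoot the OTV_2mm dose cloud pulls off the
distal GTV surface and coverage collapses; the beam-specific margin and
the robust plan both hold 100% of scenarios. `05_dose_falloff.py`
completes the trade-off: the 2 mm plan has the steepest falloff at the
duodenum abutment (FW20M 10.6 mm vs 11.9/13.8 mm for OTV_WET/RO).

A `pbsplan` CLI wraps the same pipeline
(`pbsplan run-study --out results/study`), with subcommands
`make-phantom`, `plan`, `evaluate`, `report`.

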