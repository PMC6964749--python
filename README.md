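# vmatqa

Toolkit for patient-specific quality assurance of VMAT prostate plans:
plan-complexity metrics, gamma-index dose-plane comparison, DVH and OVH
analysis with knowledge-based dose-volume prediction, cohort statistics, and
a synthetic cohort generator so the whole pipeline runs with no external
data.

## Modules

| Module | Purpose |
| --- | --- |
| `vmatqa.rtplan` | VMAT plan model (arcs → control points → MLC/jaw/meterset state), leaf-speed validation, versioned JSON plan format, optional DICOM RT Plan I/O (`pip install vmatqa[dicom]`) |
| `vmatqa.complexity` | MU normalized by fractional prescription, modulation complexity score (MCS), edge metric (EM, scaling factors C1/C2), mean leaf motion per degree (LM) |
| `vmatqa.gamma` | Gamma index for 2D dose planes: global/local normalization, 10% low-dose threshold, passing rates, setup-shift search, the seven standard criteria presets with TG-218 95/90 annotations, and an independent brute-force oracle |
| `vmatqa.dvh` | Cumulative DVHs, D_x / V_x, homogeneity and conformity indices, D95 renormalization |
| `vmatqa.ovh` | In-field overlap volume histograms and library-lookup dose-volume prediction at the 10/30/50/65/80% levels (clinical + Pareto database entries, JSONL) |
| `vmatqa.synthetic` | Prostate-like anatomies, two-arc 4°-spacing plans with a tunable modulation level (7 mm/deg leaf-speed limit), a fluence-convolution dose surrogate, and a delivery/measurement perturbation model with diode-array-like resampling |
| `vmatqa.stats` | Paired t / Wilcoxon with Shapiro-Wilk-based selection, replicate averaging, inter-delivery variation, Pearson metric-GPR correlations, report tables |

The dose engine is a deterministic surrogate (aperture fluence + Gaussian
penumbra), not a clinical dose calculation; it exists to exercise the
analysis machinery end to end.

## CLI

```bash
vmatqa simulate --n 31 --seed 42 --out cohort/           # synthetic cohort
vmatqa complexity cohort/pt000/reference.plan.json       # MU/Gy, MCS, EM, LM
vmatqa gamma cohort/pt000/reference.measured0.csv \
             cohort/pt000/reference.computed.csv \
             --dd 3 --dta 2 --norm global                 # gamma passing rate
vmatqa dvh dose.txt ptv.txt --rx 76 --metrics D2,D50,D98,Dmean,HI
vmatqa kbp-predict query_ovh.json --db db.jsonl --levels 10,30,50,65,80
vmatqa compare arm_a.csv arm_b.csv --out report.csv --alpha 0.05
```

Dose planes use a portable CSV grid (header `x0,y0,dx,dy,rows,cols`); 3D
grids and masks use a one-line JSON header followed by CSV rows; plans use a
versioned JSON schema (mm / deg / MU / Gy).

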