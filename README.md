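# misl

Quantification of tissue–CSF water exchange from magnetization-transfer
indirect spin labeling (MISL) MRI.

MISL labels water in brain parenchyma with a train of off-resonance
magnetization-transfer (MT) pulses and detects its exchange into
cerebrospinal fluid as a fractional drop ΔZ of the CSF signal on a
long-TE readout. The package is aimed at quantitative-MRI researchers who
want to turn control/label MISL volumes into tissue-to-CSF flow (TCF)
maps and regional statistics, and to validate every step against a
synthetic digital phantom.

The quantification rests on two closed forms. Tissue MT saturation builds
up as

    ΔZ_tissue(t) = α · (1 − e^(−R1ρ,tissue · t)),

giving the labeling efficiency α and the tissue rotating-frame rate
R1ρ,tissue from a multi-duration fit. In a CSF compartment receiving
tissue water at rate TCF (mL/100 mL/min),

    ΔZ = α · (TCF/6000) · (1/R1,CSF)
           · [1 + e^(−R1ρ·t_sat)·R1,CSF/R1,app − e^(−R1,CSF·t_sat)·R1ρ/R1,app],

with R1,app = R1ρ,tissue − R1,CSF; ΔZ is linear in TCF so the inversion
is exact. A single-pool Bloch simulator bounds the direct-saturation
confound of the labeling train on CSF itself, and a phantom generator
renders compartments of known TCF into noisy Rician control/label series
for end-to-end testing. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
from misl import MISLModelParams, SaturationScheme, tcf_from_delta_z
from misl.bloch import SimulationSettings, SpinPool, simulate_saturation

params = MISLModelParams(alpha=0.42, r1rho_tissue_s1=1.72, r1_csf_s1=0.23)

# invert measured group-mean CSF signal drops to flows
print(tcf_from_delta_z(params, 0.0447, 3.725))   # choroid plexus
print(tcf_from_delta_z(params, 0.0836, 3.725))   # perivascular spaces

# direct saturation of CSF by the labeling train itself
scheme = SaturationScheme()          # 50 sincgauss pulses, 3 uT, 50/25 ms
csf = SpinPool(t1_ms=4350, t2_ms=2000)
res = simulate_saturation(csf, scheme, SimulationSettings(offset_ppm=-10))
print(100 * res.ds_fraction)
```

prints

```
287.880381182792
538.4071558586446
0.25803866011532284
```

A 4.47% CSF signal drop next to the choroid plexus corresponds to a flow
of ≈288 mL of tissue water per 100 mL of CSF per minute, and the 8.36%
drop in perivascular spaces to ≈538 — rapid exchange, refreshing the
compartment several times per minute. The 0.26% direct-saturation
fraction at the −10 ppm labeling offset is an order of magnitude below
the 2–4% exchange signal, which is what makes the subtraction specific to
exchange.

The same operations are available from the shell:

```sh
misl make-phantom --out phantom/
misl quantify --control phantom/control_4d.nii.gz --label phantom/label_4d.nii.gz \
              --rois phantom/rois.nii.gz --brain-mask phantom/brain_mask.nii.gz \
              --out quant/
misl simulate-ds --offsets -20:1:20 --out zspec.csv
misl report --table regions.csv --analysis retest --out report/
```

`misl quantify` writes ΔS/ΔZ/TCF NIfTI maps, the CSF mask, a per-ROI
region table (CSV) and the resolved run configuration.

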