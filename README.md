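# tnedose

Internal dosimetry and radiosensitizer-window optimisation for
¹⁷⁷Lu-DOTATATE therapy.

¹⁷⁷Lu-DOTATATE (peptide receptor radionuclide therapy for somatostatin
receptor-positive neuroendocrine tumours) can in principle be potentiated by
a concomitant PARP inhibitor such as olaparib, which blocks repair of the
single-strand DNA breaks that ¹⁷⁷Lu β-particles predominantly cause. The
drug should be given when the tumour is still being irradiated but the
dose-limiting normal tissues (bone marrow first, kidneys second) are not:
the tissues' kinetics differ, so the timing of the drug window changes the
therapeutic ratio. `tnedose` is a pipeline for quantifying that trade-off
from sparse post-infusion imaging measurements. It is aimed at medical
physicists and modellers planning combination schedules.

## Model

For each tissue the absorbed-dose rate after infusion is described by a
biexponential,

    Ḋ(t) = C₁·e^{a·t} + C₂·e^{b·t},    a, b < 0,

fitted by constrained multi-start least squares to four samples at
2, 24, 48 and 168 h post injection (tumour: uptake shape, C₂ < 0, peaking
near 12 h; marrow and kidney: washout). Upstream quantification converts
measurements into dose rates:

* activity concentration → dose rate under local electron absorption,
  Ḋ = C·φₑ·Eₑ·k with Eₑ = 147 keV/decay and φₑ = 1 for ¹⁷⁷Lu
  (1 MBq/g ≈ 0.0848 Gy/h);
* SPECT partial-volume correction with a sigmoid recovery coefficient
  RC(d) = 1/(1+(a/d)^b) calibrated on phantom spheres;
* hybrid tumour quantification: the corrected 24 h SPECT concentration
  anchors the scale, background-subtracted planar ROI activities supply
  the kinetic shape;
* a two-compartment bone-marrow model combining a CF-scaled self-dose
  term with S-value cross-dose terms.

Doses over any interval follow in closed form,
D(t₁,t₂) = Σᵢ (Cᵢ/λᵢ)(e^{λᵢt₂} − e^{λᵢt₁}). A radiosensitizer given in a
window W with relative biological effectiveness RBE contributes an
*enhancement dose* ED = D(0,∞) + (RBE−1)·D(W), and the schedule is scored
by the tumour-to-normal-tissue enhanced dose ratio

    TNED = ED_tumour / ED_normal,

compared with the plain ratio TND = D_tumour/D_normal. Because ED is affine
in the RBE, TNED/TND = (1+(RBE_tu−1)f_tu)/(1+(RBE_nt−1)f_nt), where f is a
tissue's dose fraction inside the window — delaying the window start past
the marrow's fast washout raises TNED.

A synthetic-cohort generator produces phantom calibrations and patient
measurement sets with this kinetic structure (median total doses 0.30 /
4.5 / 27.3 Gy per 7.4 GBq for marrow / kidney / tumour), so the whole
pipeline is testable without imaging data.

## Worked example

```python
from tnedose import (
    TimeInterval, RBEWindow, uptake_fit_for_window_fraction,
    washout_fit_for_window_fraction, tned, interval_dose, total_dose,
)

window = TimeInterval(24.0, 672.0)           # 24 h to 28 d
tumour = uptake_fit_for_window_fraction(0.85, window, total=27.3)
marrow = washout_fit_for_window_fraction(0.62, window, total=0.30)

print(f"tumour curve: C1={tumour.C1:.4f} Gy/h, a={tumour.a:.5f} /h, "
      f"b={tumour.b:.3f} /h, peak at {tumour.peak_time:.1f} h")
print(f"tumour dose in window: {interval_dose(tumour, window):.2f} Gy "
      f"of {total_dose(tumour):.1f} Gy total")
res = tned(tumour, marrow, RBEWindow(window, rbe_tumour=2.0, rbe_normal=1.0))
print(f"TND = {res.tnd:.1f}, TNED_2/1 = {res.tned:.1f} "
      f"({res.relative_to_tnd:.0f}% of TND)")
```

prints

```
tumour curve: C1=0.1103 Gy/h, a=-0.00399 /h, b=-0.350 /h, peak at 12.9 h
tumour dose in window: 23.21 Gy of 27.3 Gy total
TND = 91.0, TNED_2/1 = 168.4 (185% of TND)
```

The tumour curve is tuned so 85% of its 27.3 Gy falls inside the drug
window; with RBE 2 applied to the tumour only, the enhanced dose ratio is
185% of the unenhanced one — an 85% gain from scheduling the drug after
the marrow's dose has largely been delivered.

The full pipeline runs from a shell:

```sh
tnedose all --seed 1 --out runs/demo          # synthetic 17-patient cohort
tnedose generate --seed 1 --out runs/demo     # or stage by stage
tnedose fit --inputs runs/demo/inputs --out runs/demo
tnedose dose-table --fits runs/demo/fits.json --out runs/demo
tnedose enhance --fits runs/demo/fits.json --out runs/demo
tnedose report --tned runs/demo/tned.csv --out runs/demo
```

Outputs are CSV tables (fits, per-interval dose table, per-patient
TND/TNED, cohort median/min/max summaries) and JSON (fits, window scan,
run manifest with seed and config hash). Reruns with the same config are
byte-identical.

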