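# fatseg

Adipose tissue segmentation and quantification from multi-echo spin-echo
(MSME) MRI of small animals at 7 T.

Weighted-image intensity alone is an unreliable marker of fat: signal
levels depend on the acquisition protocol and drift with field
inhomogeneity, so the brightest pixels are not necessarily adipose.  The
transverse relaxation time T2, by contrast, is a tissue property.  `fatseg`
therefore combines two parallel views of one multi-echo acquisition:

1. **Parametric path** — every pixel's echo train is fitted to the
   mono-exponential decay

   S_i(S0, T2) = S0 · exp(−Te_i / T2),  Te_i = i · te,

   by weighted least squares (weights w_i = I_i, the measured intensities,
   so near-noise-floor echoes count less), after baseline subtraction and
   a ≥ 5-valid-echo rule, giving a T2 map.
2. **Anatomical path** — the first-echo image (highest SNR in the train)
   is smoothed with an edge-preserving bilateral filter and partitioned
   into intensity-homogeneous regions by joint spatial–range mean shift,
   with no predefined cluster count.

The two paths meet in a **confidence image**: the fat peak T2,m of the T2
histogram is located by 1-D mean shift, and each pixel is weighted by

   w_p = exp(−(T2,p − T2,m)² / (2 σ²_SNR)),

where σ_SNR — the expected spread of fitted T2 at the image's SNR — comes
from a calibration curve σ_T2(SNR) = a·e^(−b·SNR) + c measured once on a
homogeneous lard phantom under noise injection.  Region scores aggregate
these weights, and regions above a score threshold form the fat mask, from
which area and volume follow.  Validation uses the overlap percentage
(intersection-over-union, in percent) against reference masks and linear
regression of per-slice volumes.

A synthetic-data module generates every input the pipeline needs —
homogeneous phantom stacks, mouse-like two-compartment slices with known
ground-truth fat masks, and noise at controlled SNR — so the whole method
is testable without scanner data.

## Worked example

Calibrate on a synthetic lard phantom, simulate a mouse slice at SNR 20,
extract fat, and score it against the known ground truth:

```
fatseg simulate --preset lard --size 48 --snr 0 --seed 1 --out-dir phantom
fatseg calibrate --phantom phantom/stack.nii \
    --signal-roi phantom/signal_roi.nii --background-roi phantom/background_roi.nii \
    --trials 100 --seed 2 --out calibration.json
fatseg simulate --preset mouse --size 128 --snr 20 --seed 3 --out-dir mouse
fatseg segment-fat --input mouse/stack.nii --calibration calibration.json --out-dir results
fatseg evaluate --mask results/fat_mask.nii --reference mouse/fat_mask.nii --out eval.csv
```

(The two ROI masks for `calibrate` are any signal/background masks; the
session above wrote them with `fatseg.synthdata.lard_signal_roi` and
`fatseg.calibrate.corner_background_mask`.)  This prints:

```
calibration curve a=40.1 b=0.146 c=2.08 -> calibration.json
fat area 3061 px (269.03 mm^3), outputs in results
OP = 91.33% (iou) -> eval.csv
```

`a`, `b`, `c` parametrize the σ_T2(SNR) curve: at this phantom's SNR range
the fitted-T2 spread falls from tens of ms at low SNR to ~2 ms at high
SNR.  The extracted fat mask covers 3061 pixels (269 mm³ for the 40×40 mm
field of view and 0.9 mm slice), and overlaps the simulated ground-truth
fat mask by 91.3 % intersection-over-union.  `results/` also holds the T2
map, confidence image, region label map, per-region score table and a run
manifest with seeds and input digests for bit-identical reruns.

Every subcommand is a thin wrapper over the library; the same pipeline is
one call in Python:

```python
from fatseg import run_pipeline, generate_stack, mouse_config
stack, labels, fat_truth = generate_stack(mouse_config(128, target_snr=20, rng_seed=3))
result = run_pipeline(stack, calibration_curve)
print(result.fat_area_pixels, result.fat_volume_mm3, result.snr)
```

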