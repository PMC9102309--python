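# wpdcca — motion-artifact correction for single-channel EEG and fNIRS

Wearable EEG and fNIRS recordings are routinely contaminated by motion
artifacts: temporally localized, high-amplitude, non-Gaussian excursions
caused by electrode or optode displacement.  Because both modalities are
often recorded from a *single* channel in ambulatory settings, multichannel
artifact-removal tools (ICA, CCA) cannot be applied directly.

`wpdcca` implements two correction methods for this setting, aimed at
researchers processing wearable neurophysiological recordings:

* **Single-stage WPD** — a level-*j* wavelet packet decomposition splits the
  signal into 2^*j* equal-width frequency sub-bands `S_{2^j-1}, D_1 …
  D_{2^j-1}` (at the default *j* = 4: 16 bands, `S15` the approximation).
  Artifact sub-bands are discarded and the remaining components summed.
* **Two-stage WPD-CCA** — the 16 sub-band signals are treated as a
  multichannel input `X` to canonical correlation analysis against the
  neighbour-sum surrogate `y_t = x_{t-1} + x_{t+1}`.  CCA solves

  ```
  Cxx⁻¹ Cxy Cyy⁻¹ Cyx ŵx = ρ² ŵx ,      Ŝ = W X ,
  ```

  yielding maximally autocorrelated, mutually uncorrelated sources ordered
  by canonical correlation ρ.  Artifact sources are zeroed, the matrix is
  re-mixed through `W⁻¹`, and the channels are summed back into one signal.

Two selection rules are available: reference-guided greedy rejection
(components are removed while removal strictly improves the Pearson
correlation with a simultaneously recorded "ground-truth" channel) and a
reference-free rule that simply drops the lowest-frequency approximation
sub-band, where motion energy concentrates.

Performance is quantified by the SNR improvement

```
ΔSNR = 10 log10( var(ref − corrupted) / var(ref − cleaned) )   [dB]
```

and the percentage reduction in motion artifacts

```
η = 100 · (1 − (ρ_clean − ρ_after) / (ρ_clean − ρ_before))     [%]
```

with the idealized convention ρ_clean = 1 by default.

Supported wavelet packets: `db1–db3`, `sym4–sym6`, `coif1–coif3`,
`fk4/fk6/fk8` (the Fejér-Korovkin filters are constructed internally from
their defining half-band polynomial and validated against orthonormality at
load time).  The two-stage method uses the Daubechies and Fejér-Korovkin
families.

A seedable generator produces paired clean/corrupted recordings that emulate
the two-channel benchmark protocol (≈9-minute records, EEG at 2048 Hz
processed at 256 Hz, fNIRS at 25 Hz, 10–25 s artifact bursts every 2
minutes), so the entire pipeline is testable without any data download.

## Worked example

```python
from wpdcca import SynthConfig, PipelineConfig, generate_paired, denoise

pair = generate_paired(SynthConfig(modality="EEG", seed=7))
cleaned, report = denoise(pair, PipelineConfig(method="wpd", wavelet="db1",
                                               selection="approx-drop"))
print(f"dSNR = {report.delta_snr_db:.2f} dB, eta = {report.eta_pct:.2f}%, "
      f"rho {report.rho_before:.3f} -> {report.rho_after:.3f}, "
      f"removed {report.extra['removed_components']}")
```

prints

```
dSNR = 10.96 dB, eta = 31.90%, rho 0.316 -> 0.534, removed [0]
```

meaning: the corrupted channel correlated 0.316 with the reference before
cleaning; dropping the approximation sub-band (component 0) removed the
planted low-frequency artifact, raising the correlation to 0.534 — a 31.9 %
reduction in motion artifacts — and shrinking the error variance by 10.96 dB.
The same record through the two-stage method
(`PipelineConfig(method="wpd-cca", wavelet="db1")`) prints
`dSNR = 9.91 dB, eta = 23.12%`; on strictly band-localized synthetic
artifacts the single-stage sub-band drop is already near-optimal, and the
rotated CCA basis cannot improve on it (see `docs/methods.md` for the
geometry and for how this differs on real recordings).

The same pipeline is available from the shell:

```bash
wpdcca generate --modality EEG --seed 7 -o pair.csv
wpdcca denoise -i pair.csv --fs 2048 --method wpd --wavelet db1 \
       --select approx-drop -o cleaned.csv --report report.json
wpdcca evaluate -i pair.csv --cleaned cleaned.csv --fs 2048
wpdcca batch pair1.csv pair2.csv --fs 2048 --wavelet db1 --select approx-drop
```

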