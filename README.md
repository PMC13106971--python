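# lumiphasor

Spectral-phasor analysis of **bioluminescence microscopy** — calibration,
pixelwise phasor transformation from sine/cosine-filtered camera channels,
phasor unmixing and clustering, and BRET-biosensor readout — together with
a synthetic four-channel microscope so that every stage of the pipeline can
be exercised and validated without real acquisitions.

## The problem

Bioluminescent reporters (luciferase–luciferin pairs, often fused to
fluorescent-protein acceptors as BRET probes) emit broad, heavily
overlapping spectra at very low photon rates. Conventional bandpass
filtering wastes photons and cannot separate reporters whose peaks differ
by ~10 nm. The spectral-phasor approach instead encodes the *entire*
emission spectrum into two numbers per pixel using a pair of optical
filters whose transmission varies sinusoidally with wavelength.

For an emission spectrum $I(\lambda)$ on a window
$[\lambda_0,\lambda_0+L]$, the first-harmonic **spectral phasor** is

$$
g = \frac{\int I(\lambda)\cos\!\big(2\pi(\lambda-\lambda_0)/L\big)\,d\lambda}{\int I(\lambda)\,d\lambda},
\qquad
s = \frac{\int I(\lambda)\sin\!\big(2\pi(\lambda-\lambda_0)/L\big)\,d\lambda}{\int I(\lambda)\,d\lambda}.
$$

On the instrument, each camera splits its light between a sinusoidal
encoding filter and an unfiltered reference sensor. After dark/bright
calibration the filtered-to-reference count ratio measures the mean filter
transmission of the pixel's spectrum, and the phasor follows pixelwise:

$$
g = 2\,\frac{I_{COS}/I_{INT(COS)} - F_{COS,min}}{F_{COS,max}-F_{COS,min}} - 1,
\qquad
s = 2\,\frac{I_{SIN}/I_{INT(SIN)} - F_{SIN,min}}{F_{SIN,max}-F_{SIN,min}} - 1 .
$$

Because the phasor is linear in photon counts, mixtures of reporters lie
on straight chords between pure-component phasors. This yields
two-component **linear unmixing** (fraction = position along the chord),
**GMM clustering** plus nearest-reference assignment for multiplexed
scenes, and a **BRET-efficiency** readout: a biosensor's phasor slides
along the donor→acceptor trajectory, and its clamped normalized projection
onto that chord (0 at donor, 1 at acceptor) is the acceptor photon
fraction.

Intended users: microscopists and image analysts working with
multiplexed bioluminescent reporters or BRET biosensors, and method
developers who need a fully controlled synthetic testbed for phasor
pipelines.

## Worked example

Two cells express a caspase-9 BRET sensor (NanoLuc donor → mNeonGreen
acceptor); one sensor is intact (BRET efficiency 0.8), one cleaved (0.2).
We render a photon-limited 20-frame acquisition, run the full calibration +
phasor pipeline, and read per-cell BRET efficiency back:

```python
import numpy as np
import lumiphasor as lp

library = lp.default_library()
filters = lp.make_filters(lp.DEFAULT_WINDOW, f_min=0.15, f_max=0.85)
refs = lp.reference_phasors(library)

spectra = lp.library_spectra(library)
sensors = {
    "intact":  lp.ReporterModel("intact",  spectra["NanoLuc"], spectra["mNeonGreen"], efficiency=0.8),
    "cleaved": lp.ReporterModel("cleaved", spectra["NanoLuc"], spectra["mNeonGreen"], efficiency=0.2),
}
scene = lp.Scene(48, 48, [
    lp.CellSpec((14, 14), 8, "intact",  500.0),   # photons/pixel/frame
    lp.CellSpec((34, 34), 8, "cleaved", 500.0),
])
camera = lp.CameraModel(dark_offset=100.0, read_noise_sd=1.5)

ph, truth = lp.simulate_phasor(scene, sensors, filters, camera,
                               n_frames=20, seed=1, noise=True, sigma=1.0)
ph.labels = (truth.labels * ph.mask).astype(np.int32)
axis = lp.BretAxis.from_spectra(spectra["NanoLuc"], spectra["mNeonGreen"])
print(lp.per_cell_stats(ph, axis=axis)
      [["cell_id", "area", "g", "s", "efficiency", "phase", "modulation"]]
      .round(3).to_string(index=False))
```

Output:

```
 cell_id  area      g     s  efficiency  phase  modulation
       1   197 -0.515 0.586       0.801  2.292       0.780
       2   197 -0.002 0.702       0.201  1.573       0.702
```

The intact sensor's phasor sits near the acceptor end of the
NanoLuc→mNeonGreen trajectory (recovered efficiency 0.801 vs true 0.8);
the cleaved sensor sits near the donor end (0.201 vs 0.2). `phase`
(radians) encodes each cell's mean emission color, `modulation` its
spectral narrowness.

## Command line

The same pipeline is scriptable from a shell:

```bash
lumiphasor simulate --scene sensor --seed 7 -o run/
lumiphasor calibrate --dark run/dark.tif --bright run/bright.tif \
                     --config run/config.txt -o run/cal.tif
lumiphasor phasor --input run/raw.tif --cal run/cal.tif \
                  --config run/config.txt -o run/out/
lumiphasor bret --phasor run/out/phasor.tif --refs run/references.csv \
                --donor NanoLuc --acceptor mNeonGreen -o run/bret/
lumiphasor report --phasor run/out/phasor.tif --refs run/references.csv -o run/report/
```

`simulate` writes a raw four-quadrant multi-page TIFF plus matching
dark/bright calibration stacks and ground truth; `report` renders a phasor
plot with reference cursors. All outputs are listed in a JSON manifest
with input checksums.

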