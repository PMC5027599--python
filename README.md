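# smlmbayes

Automatic, threshold-free identification of single-molecule emitters in
localization microscopy (SMLM/STORM/PALM) movies.

## The problem

SMLM reconstructs a super-resolution image by localizing sparse, blinking
fluorophores over thousands of camera frames. Every analysis package must
decide which detected spots are real emitters and which are background
fluctuations — usually via user-chosen intensity or SNR thresholds, which
bias the result. `smlmbayes` removes that choice: it fits **every** locally
brightest spot with a fixed-width 2D Gaussian PSF,

$$\mathrm{model}(x,y) = \frac{n_\mathrm{psf}}{2\pi s_0^2}
  \exp\!\Big(-\frac{(x-x_0)^2+(y-y_0)^2}{2 s_0^2}\Big) + n_b,$$

pools the integrated photoelectron counts $n_\mathrm{psf}$ of all candidates,
and exploits the fact that this pooled histogram is bimodal: a large
low-count mode of false (noise) spots and a high-count mode of true
emitters. The cut between them is found by unsupervised minimum-error
thresholding (the Kittler–Illingworth construction generalized to arbitrary
density pairs): for every candidate gray level $T$ both sides are fitted
with a false/true density pair and

$$J(T) = -\sum_{i\in\{0,1\}}\ \sum_{x \in R_{iT}} h(x)\,
  \big[\log P_{iT} + \log f_i(x\mid\theta_{iT})\big]$$

is minimized. Two density pairs are built in — Gaussian–Gaussian (`ggdm`)
and Weibull–Lognormal (`wldm`, matching single-fluorophore photon
statistics). The only inputs are experimental constants: camera offset and
gain, pixel size, magnification, NA and emission wavelength.

Because both the false and the true distribution are estimated, every
candidate also gets a **reliability** $R(n_\mathrm{psf}) =
NT/(NF+NT)$ — its posterior probability of being a true emitter — from
which a reliability map of the reconstruction can be rendered.

The package includes a synthetic SMLM movie generator with ground truth, a
tolerance-radius evaluation module (Jaccard/Precision/Recall/RMSD), and a
CLI (`smlmbayes simulate|analyze|threshold|render|evaluate`).

## Worked example

```python
import smlmbayes as sb
from smlmbayes.evaluate import fwhm_tolerance_nm, match_localizations
from smlmbayes.pipeline import fits_to_table

cam = sb.standard_camera()                     # 70 nm effective pixels, NA 1.49
movie, truth = sb.simulate_movie(sb.standard_scene(seed=1), cam)
res = sb.analyze_movie(movie, cam, model="wldm")
print(f"threshold {res.threshold_value:.1f} pe, "
      f"{len(res.accepted)} accepted of {len(res.fits)} candidates")

tol = fwhm_tolerance_nm(res.optics.s0_px, cam.pixel_size_sample_nm)
rep = match_localizations(truth, fits_to_table(res.accepted, cam), tol)
print(f"jaccard {rep.jaccard:.3f} precision {rep.precision:.3f} "
      f"recall {rep.recall:.3f} rmsd {rep.rmsd_nm:.1f} nm")
```

Output:

```
threshold 115.5 pe, 2005 accepted of 49912 candidates
jaccard 0.869 precision 1.000 recall 0.869 rmsd 21.3 nm
```

Of the ~50 000 locally brightest spots fitted across 200 frames (roughly
20× the 2 307 true activations), the automatic cut at ≈115 photoelectrons
keeps 2 005, nearly all of them true emitters (precision 1.0); the Jaccard
index 0.87 against ground truth sits at the optimum of the full threshold
sweep, and matched localizations are accurate to ~21 nm RMS.

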