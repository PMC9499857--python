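# ocumask

Facial videos recorded during ophthalmic examinations carry two kinds of
information at once: the ocular geometry and motion a clinician needs
(eyelid position, gaze, blink dynamics), and biometric identity the patient
never meant to share. `ocumask` implements a model-based "digital mask":
it fits parametric 3D face, eyelid and eyeball models to 2D features
extracted from each video frame, so that a reconstructed mesh sequence —
containing disease-relevant shape and motion but none of the original
appearance — can replace the identifiable video. The package also ships the
evaluation machinery such a system needs: normalized pixel reconstruction
errors, face-verification metrics for re-identification attacks, and the
clinical agreement statistics used to validate diagnosis from masked video.

## The model

Per frame, reconstruction proceeds in three stages, each a nonlinear
least-squares problem solved by damped Gauss–Newton:

1. **Face.** A bilinear face model generates vertices
   `M^f = C ×₂ w^fs ×₃ w^fm` from a core tensor `C ∈ R^{3N_F × N_fs × N_fm}`,
   a shape vector `w^fs` and a motion vector `w^fm`. Pose `(R, t)` and the
   weights minimise the reprojection error
   `Σᵢ ‖Lᵢ^face − Π(R M^f_{c(i)} + t)‖²` against detected face landmarks.
2. **Eyelid.** A linear model `M^e = M₀^e + Σ wᵢ^es Mᵢ^es + Σ wⱼ^em Mⱼ^em`
   is fitted to dense eyelid landmarks (a cubic `y = ax³ + bx² + cx + d` is
   least-squares fitted to sparse landmarks, then resampled uniformly in x)
   plus four semantic polylines (double fold, upper/lower eyelid, bulge
   boundary) through a point-to-polyline distance term, with `(R, t)` fixed
   from stage 1.
3. **Eyeball.** A sphere of radius `r_e` with an iris ring of planar radius
   `r_i` at offset `p_e`, rotated by gaze angles `(θ, φ)`, is registered to
   iris landmarks: `Σᵢ ‖Lᵢ^iris − Π(R(Rot(θ, φ) B + p_e) + t)‖²`. The
   statics `(r_e, r_i, p_e)` are estimated on the first frame from a
   face-scaled prior plus a circle fit to the iris landmarks, then frozen.

Shape-type parameters (`w^fs`, `w^es`, eyeball statics) are first-frame
only; later frames track the dynamics with quadratic temporal-smoothing
penalties (`λ‖x − x_prev‖²`) for sequence consistency.

Because production model assets are proprietary, the package includes a
first-class synthetic generator (`ocumask.synthetic`): seed-deterministic
assets with the same mathematical structure, plus trajectory motifs that
caricature clinical signs (gaze sweep, strabismic offset, ptotic droop,
nystagmus oscillation, blink) projected into landmark streams with
configurable noise and occlusion.

## Worked example

```python
from ocumask import (SyntheticAssetSpec, TrajectorySpec, fit_sequence,
                     generate_assets, generate_sequence)
from ocumask.evaluation import evaluate_sequence, summarize

assets = generate_assets(SyntheticAssetSpec(seed=7))
seq = generate_sequence(assets, TrajectorySpec(
    n_frames=40, motif="gaze_sweep", noise_sigma=0.5, seed=11))
result = fit_sequence(seq.observations, assets, seq.camera)
print(summarize(evaluate_sequence(seq.observations, result.states,
                                  assets, seq.camera)).to_string(index=False))
```

prints

```
   kind      ARE      MRE  n_records  n_excluded
eyeball 0.002678 0.007681       1520        0
 eyelid 0.002925 0.009494       8000        0
```

ARE/MRE are the mean/maximum reprojection error between detected landmarks
and the reconstruction, as a fraction of the inter-eye pixel distance: here
the fit tracks a ±20° gaze sweep under 0.5 px detector noise to within
~0.3% of the inter-eye distance on average. With zero noise the same
pipeline recovers all dynamic parameters to reprojection errors below 1e-4
and gaze angles to well under 0.1°.

The `examples/` directory holds one short script per capability
(reconstruction, error evaluation, privacy metrics, clinical agreement,
sample-size planning); each prints the numbers it computes and a line on
what they mean. A thin CLI mirrors the library:

```sh
ocumask simulate --motif blink --frames 30 --out-dir run/
ocumask fit --landmarks run/landmarks.jsonl --assets run/assets.npz --out-dir run/
ocumask evaluate --landmarks run/landmarks.jsonl --assets run/assets.npz \
    --params run/params.csv --out-dir run/
ocumask sample-size --k0 0.6 --k1 0.85 --rate1 0.3 --rate2 0.7 \
    --alpha 0.025 --power 0.9          # -> n = 82
```

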