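"""Normalized pixel error of a fit under detector noise.

Runs a gaze-sweep sequence with 0.5 px landmark noise, fits it, and prints
the per-kind average (ARE) and maximum (MRE) normalized reconstruction
errors — reprojection error divided by the inter-eye pixel distance, so the
numbers are camera-distance independent fractions.
"""

from ocumask import SyntheticAssetSpec, TrajectorySpec, fit_sequence, generate_assets, generate_sequence
from ocumask.evaluation import evaluate_sequence, summarize

assets = generate_assets(SyntheticAssetSpec(seed=7))
seq = generate_sequence(
    assets, TrajectorySpec(n_frames=40, motif="gaze_sweep", noise_sigma=0.5, seed=11)
)
result = fit_sequence(seq.observations, assets, seq.camera)
records = evaluate_sequence(seq.observations, result.states, assets, seq.camera)
summary = summarize(records)
print(summary.to_string(index=False))
print(
    "\nAn ARE of e.g. 0.003 means the reconstruction lands within 0.3% of the"
    "\ninter-eye distance of the detected landmarks, on average."
)
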