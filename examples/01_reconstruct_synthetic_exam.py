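"""Reconstruct a synthetic blink examination and compare with ground truth.

Builds the bundled synthetic model assets, synthesises a 30-frame blink
sequence (landmarks only, no pixels), runs the three-stage fit and prints
recovered against true eyelid-closure weights and gaze angles, then exports
the frame-0 eyelid mesh as OBJ.
"""

import numpy as np

from ocumask import (
    SyntheticAssetSpec,
    TrajectorySpec,
    fit_sequence,
    generate_assets,
    generate_sequence,
    reconstruct_eyelid,
)
from ocumask.io import write_mesh

assets = generate_assets(SyntheticAssetSpec(seed=7))
seq = generate_sequence(
    assets,
    TrajectorySpec(n_frames=30, motif="blink", seed=1,
                   params={"onset": 8, "width": 14}),
)
result = fit_sequence(seq.observations, assets, seq.camera)

print("frame  closure(true)  closure(fit)  theta_L(true)  theta_L(fit) [deg]")
for k in (0, 10, 15, 20, 29):
    t, f = seq.truth[k], result.states[k]
    print(
        f"{k:5d}  {t.eyelid['left'].motion[0]:13.4f}  {f.eyelid['left'].motion[0]:12.4f}"
        f"  {np.rad2deg(t.gaze['left'].theta):13.4f}  {np.rad2deg(f.gaze['left'].theta):12.4f}"
    )
# The fitted closure weight tracks the true blink profile; both gaze columns
# stay at zero because the eyes fixate during a blink.

verts = reconstruct_eyelid(assets.eyelid_models["left"], result.states[15].eyelid["left"])
write_mesh(verts, assets.eyelid_models["left"].topology, "eyelid_frame15.obj")
print("wrote eyelid_frame15.obj (mid-blink left eyelid mesh)")
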