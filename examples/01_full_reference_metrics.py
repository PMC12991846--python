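"""Score a degraded photoacoustic phantom with all eleven full-reference metrics.

Builds a vessel phantom, corrupts it with frame-averaging noise, and prints
each metric next to its direction.  Higher-is-better metrics fall as noise
grows; GMSD and MS-GMSD (deviation scores) rise instead.
"""

from paiq import (
    PhantomSpec, compute_all_fr, degrade_frame_averaging, generate_phantom,
    validate_pair,
)

phantom = generate_phantom(PhantomSpec(kind="vessel", size=128, seed=7))
noisy = degrade_frame_averaging(phantom, n_frames=256, seed=7)
pair = validate_pair(phantom, noisy)

print(f"{'metric':10s} {'value':>10s}  direction")
for r in compute_all_fr(pair):
    arrow = "higher is better" if r.higher_is_better else "lower is better"
    print(f"{r.metric:10s} {r.value:10.4f}  {arrow}")
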