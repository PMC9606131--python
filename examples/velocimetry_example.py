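"""Measure capillary RBC speed from a synthetic high-frame-rate movie.

Simulates a 200 Hz single-capillary capture in which unlabeled red blood
cells cast dark shadows moving through bright plasma at 1.1 mm/s, then
re-estimates the speed from two points 20 μm apart via the z-scored
unbiased cross-correlogram.
"""

import microcirc as mc

cfg = mc.KymographSimConfig(n_frames=2000, frame_rate=200.0, pixel_size=0.5,
                            rbc_speed=1.1, hematocrit=0.3, rbc_length=6.0,
                            noise_sd=8.0, seed=1)
stack, truth = mc.make_kymograph_movie(cfg)
lo, hi = truth.params["capillary_rows"]
cy = (lo + hi) // 2

est = mc.estimate_velocity(stack, p1=(30, cy), p2=(70, cy), radius=1, max_lag=25)

print(f"ground-truth speed : {cfg.rbc_speed:.3f} mm/s")
print(f"estimated speed    : {est.speed:.3f} mm/s ({est.direction})")
print(f"peak lag           : {est.lag:+.2f} frames over {est.separation:.0f} um")
print(f"peak correlation   : {est.peak_correlation:.3f}")
# The lag is the RBC transit time between the two sampling points in frame
# units; speed = separation / transit time. A peak correlation well above the
# noise floor (~1/sqrt(n_frames) ~ 0.02 here) marks a reliable measurement.
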