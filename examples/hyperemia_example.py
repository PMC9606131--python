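"""Quantify stimulus-evoked arterial dilation (functional hyperemia).

Simulates the awake whisker air-puff protocol — two 5-s stimuli at 30 s
and 65 s — on a 20 μm artery dilating by 15% and 12%, then measures the
per-frame FWHM diameter along a line across the vessel, normalizes it to
the 2-s pre-stimulus baseline, and reports peak percent change and
time-to-peak per stimulus.
"""

import numpy as np

import microcirc as mc

cfg = mc.HyperemiaSimConfig(dilation_amplitudes=(0.15, 0.12),
                            stimulus_onsets=(30.0, 65.0), seed=11)
stack, truth = mc.make_hyperemia_movie(cfg)
ny, nx = stack.frame_shape

trace = mc.diameter_timeseries(stack, p0=(nx // 2, 0), p1=(nx // 2, ny - 1),
                               vessel_label="artery")
trace = mc.normalize_to_baseline(trace, cfg.stimulus_onsets,
                                 baseline_seconds=2.0,
                                 stimulus_duration=cfg.stimulus_duration)
result = mc.hyperemia_metrics(trace)

print(f"baseline diameter  : {np.nanmean(trace.diameters[trace.times < 30]):.2f} um "
      f"(truth {cfg.baseline_diameter:.2f} um)")
for onset, peak, ttp, amp in zip(result.stimulus_onsets,
                                 result.peak_percent_change,
                                 result.time_to_peak, cfg.dilation_amplitudes):
    print(f"stimulus at {onset:4.0f} s : peak dilation {peak:5.2f}% "
          f"(configured {100 * amp:.0f}%), time to peak {ttp:.2f} s")
# Peak percent change is 100*(max N - 1) in a window from stimulus onset to
# 10 s past stimulus end; values within ~1 percentage point of the configured
# amplitudes show the edge detector resolves sub-pixel width changes.
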