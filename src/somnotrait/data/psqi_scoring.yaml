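# PSQI component scoring cut-points (default dialect follows the
# published instrument manual; edit to score another dialect).
#
# Band lists are upper bounds read left to right; a value <= bound gets
# that band's score.  Orientation of each rule is implemented in
# instruments.score_psqi and noted per key.

# Component 2 (latency): minutes banded 0-3 ...
latency_minutes_bands: [15, 30, 60]      # <=15 -> 0, <=30 -> 1, <=60 -> 2, else 3
# ... then minutes-band + frequency item summed and re-banded 0-3
latency_sum_bands: [0, 2, 4]             # 0 -> 0, 1-2 -> 1, 3-4 -> 2, 5-6 -> 3

# Component 3 (duration, hours): score 0 for long sleep, 3 for short
duration_hours_bands: [7, 6, 5]          # >7 -> 0, >=6 -> 1, >=5 -> 2, else 3

# Component 4 (habitual efficiency = reported duration / time in bed)
efficiency_bands: [0.85, 0.75, 0.65]     # >=0.85 -> 0, >=0.75 -> 1, >=0.65 -> 2, else 3

# Component 5 (disturbances): sum of the nine 0-3 frequency items
disturbance_sum_bands: [0, 9, 18]        # 0 -> 0, 1-9 -> 1, 10-18 -> 2, 19-27 -> 3

# Component 7 (daytime dysfunction): sleepiness + enthusiasm items
dysfunction_sum_bands: [0, 2, 4]         # 0 -> 0, 1-2 -> 1, 3-4 -> 2, 5-6 -> 3
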