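# Discrete exposure-response step functions: anchor received levels (dB re 1 uPa)
# for the 10% and 50% response probabilities, per variant and exposure context.
#
# PROVISIONAL / RECONSTRUCTED values. The published anchor tables live in
# supplementary material that is not transcribed here; these numbers follow the
# documented construction rules (ambient floor -> 1%, TTS onset -> 99%,
# TTS - 10 dB -> 90%, contexts ordered by decreasing sensitivity, upper-CI
# variants shifted toward higher sensitivity, high-severity variants toward
# lower) and are meant to be replaced with the published values when available.
#
# ambient_floor_db: ambient noise in the 3-4 kHz mid-frequency-sonar band at
#   sea state 3; tts_onset_db: TTS onset for low-frequency cetaceans.

ambient_floor_db: 90.0
tts_onset_db: 178.0

variants:
  moderate-median:
    DF_near:           {p10: 110.0, p50: 130.0}
    DF_far_other_near: {p10: 125.0, p50: 145.0}
    other_far:         {p10: 135.0, p50: 155.0}
  moderate-upperCI:
    DF_near:           {p10: 104.0, p50: 124.0}
    DF_far_other_near: {p10: 119.0, p50: 139.0}
    other_far:         {p10: 129.0, p50: 149.0}
  high-median:
    DF_near:           {p10: 118.0, p50: 140.0}
    DF_far_other_near: {p10: 133.0, p50: 152.0}
    other_far:         {p10: 142.0, p50: 160.0}
  high-upperCI:
    DF_near:           {p10: 112.0, p50: 134.0}
    DF_far_other_near: {p10: 127.0, p50: 146.0}
    other_far:         {p10: 136.0, p50: 154.0}
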