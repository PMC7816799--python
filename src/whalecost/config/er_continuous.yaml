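# Continuous exposure-response curves, summarised per dose bin by the
# posterior mean and standard deviation of the response probability.
#
# PROVISIONAL / RECONSTRUCTED values (synthetic stand-ins for posterior
# summaries published in supplementary material): the SPL curve rises with
# received level but stays below the discrete step functions at high levels;
# the range curve declines to ~0 beyond 5 km from the source.

spl:
  # 10-dB received-level bins keyed by their upper edge (dB re 1 uPa).
  # Below floor_db no response is simulated.
  floor_db: 90.0
  bins:
    - {upper: 100.0, mean: 0.02, sd: 0.02}
    - {upper: 110.0, mean: 0.05, sd: 0.03}
    - {upper: 120.0, mean: 0.10, sd: 0.05}
    - {upper: 130.0, mean: 0.20, sd: 0.08}
    - {upper: 140.0, mean: 0.35, sd: 0.10}
    - {upper: 150.0, mean: 0.45, sd: 0.12}
    - {upper: 160.0, mean: 0.50, sd: 0.12}
    - {upper: 170.0, mean: 0.55, sd: 0.15}
    - {upper: 180.0, mean: 0.60, sd: 0.15}

range:
  # distance-from-source bins keyed by their outer edge (km);
  # the last bin is open (> 5 km).
  bins:
    - {upper: 1.0, mean: 0.45, sd: 0.12}
    - {upper: 2.0, mean: 0.30, sd: 0.10}
    - {upper: 3.0, mean: 0.18, sd: 0.08}
    - {upper: 4.0, mean: 0.10, sd: 0.06}
    - {upper: 5.0, mean: 0.05, sd: 0.04}
    - {upper: inf, mean: 0.005, sd: 0.005}
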