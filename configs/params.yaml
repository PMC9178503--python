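# Default sweep-detection and clustering parameters.
# Angular quantities are degrees in the cue (landmark/stripe) frame.
kde_bin: 0.5          # grid spacing of the firing-rate analogue
kde_bandwidth: 8.0    # Gaussian kernel bandwidth
peak_fraction: 0.10   # sweep boundary: fraction of the peak density
min_sweep: 5.0        # smallest admissible sweep extent
max_sweep: 120.0      # largest admissible sweep extent
window_laps: 15       # proximity window in frame laps (centered)
proximity: 15.0       # proximity radius on wrapped sweep centers
min_proximal: 3       # minimum proximal sweeps for a sweep to survive
min_spikes: 4         # minimum spikes per sweep to survive
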