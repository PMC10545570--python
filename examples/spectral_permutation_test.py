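"""Test the valid, invalid, and difference time courses for rhythmicity.

Each grand-average course is quadratically detrended and Fourier
transformed; every frequency bin's amplitude is compared to the null
distribution of the maximum amplitude obtained by shuffling CTOA labels
within participants, which controls the familywise error rate across the
12 frequency bins (0.95-11.4 Hz).
"""

from denseior import (DesignConfig, EffectParams, NoiseParams, preprocess,
                      run_spectral_battery, simulate_cohort)

trials = simulate_cohort(DesignConfig(), EffectParams(), NoiseParams(),
                         master_seed=7)
*_, cm, _, diff = preprocess(trials)

battery = run_spectral_battery(cm.valid, cm.invalid,
                               diff.per_participant_diff, cm.ctoa,
                               n_perm=2000, seed=7)
for name, res in battery.items():
    flagged = [f"{f:.2f} Hz (p={p:.4f})"
               for f, p in zip(res.freqs, res.p) if p < 0.05]
    print(f"{name:>10}: 95% max-amplitude threshold "
          f"{res.threshold_95:.4f}; significant bins: "
          f"{', '.join(flagged) if flagged else 'none'}")
print("\nA significant bin means that frequency's amplitude exceeds what "
      "label shuffling produces in 95% of permutations, familywise. The "
      "generative 1.05 Hz component sits near the lowest (0.95 Hz) bin.")
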