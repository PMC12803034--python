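"""Bulk cleavage kinetics: mono-exponential fits and variant comparison.

Simulates gel-quantified cleavage time courses (fraction cleaved at the
0.5-120 min quench grid, three replicate reactions) for a fast and a
slow enzyme variant, fits Y = A (1 - exp(-kobs t)) per replicate, and
reports the rate fold-change with a propagated uncertainty.
"""

import aurbt as ab

fast = ab.simulate_cleavage_timecourse(A=0.85, kobs_per_min=0.28,
                                       noise_sd=0.02, n_reps=3, seed=4)
slow = ab.simulate_cleavage_timecourse(A=0.80, kobs_per_min=0.01,
                                       noise_sd=0.02, n_reps=3, seed=5)

for name, tc in (("fast variant", fast), ("slow variant", slow)):
    fit = ab.fit_monoexp(tc)
    print(f"{name}: kobs = {fit.kobs_mean:.4f} +/- {fit.kobs_sd:.4f} 1/min, "
          f"A = {fit.A_mean:.2f} (n = {int(fit.converged.sum())} replicates)")

fit_fast, fit_slow = ab.fit_monoexp(fast), ab.fit_monoexp(slow)
fold, sd = ab.rate_fold_change(fit_fast, fit_slow)
print(f"\nrate fold-change fast/slow: {fold:.1f} +/- {sd:.1f} "
      "(generated at 28-fold)")
print("a ~28-fold acceleration is the scale of difference that separates an "
      "engineered variant from wild type in a bulk cleavage assay.")
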