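#!/usr/bin/env python
"""Replicated end-to-end check: does the pipeline recover the planted law?

Simulates fresh 18-subject cohorts over several master seeds, runs the full
chain (clean, ODE detrend, 60 s windows, pooled fit) and compares the mean
fitted decay parameters with the generator's documented defaults
(tau = 19.6 beats/min, b = 1325 ms). A lighter replicate of the experiment
scripts/acceptance.py runs at 50 seeds.
"""

from hrvdecay.experiments import ensemble_recovery

OUT = "results/ensemble_recovery.csv"
N_SEEDS = 10


def main() -> None:
    ens = ensemble_recovery(n_seeds=N_SEEDS, n_subjects=18, master_seed=7)
    ens.to_csv(OUT, index=False)
    print(f"{N_SEEDS} replicate cohorts, full pipeline:")
    print(f"  mean fitted tau: {ens.tau.mean():.2f} beats/min (generator 19.6)")
    print(f"  mean fitted b:   {ens.b.mean():.0f} ms (generator 1325)")
    print(f"  mean SDRR division over +20 bpm: {ens.halving_20bpm.mean():.3f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
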