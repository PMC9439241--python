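"""Replicated whole-pipeline experiments on synthetic cohorts.

These drivers wire the full chain — simulate a cohort with artifact
contamination, clean, ODE-detrend, window at 60 s, fit the HR decay model —
and repeat it over many master seeds, so that pipeline fidelity (does the
analysis recover the generative decay parameters without attenuation?) can
be quantified rather than assumed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decay import compare_models, fit_decay
from .process import pooled_windows, process_subject
from .synthetic import ArtifactSpec, simulate_cohort


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def pooled_decay_fit(cohort, model: int = 1, effort_range: str = "full"):
    """Pool every subject's 60 s windows and fit one decay model."""
    tables = [process_subject(d)[0] for d in cohort]
    return fit_decay(pooled_windows(tables), model=model, effort_range=effort_range)


def ensemble_recovery(
    n_seeds: int = 50,
    n_subjects: int = 18,
    master_seed: int = 1,
    with_artifacts: bool = True,
) -> pd.DataFrame:
    """Pooled-cohort decay parameters over seeded replicate cohorts.

    Each replicate simulates ``n_subjects`` graded tests at the generator
    defaults (artifact contamination at the calibration rates unless
    disabled), runs the full pipeline, and fits the HR decay model on the
    pooled windows. Returns one row per replicate with the fitted halving
    constant ``tau`` (beats/min) and intercept ``b`` (ms).
    """
    rows = []
    for seed in derive_seeds(master_seed, n_seeds):
        artifacts = ArtifactSpec() if with_artifacts else None
        cohort = simulate_cohort(n_subjects, seed=seed, artifacts=artifacts)
        fit = pooled_decay_fit(cohort)
        rows.append({"seed": seed, "tau": fit.tau, "b": fit.b,
                     "halving_20bpm": 2.0 ** (20.0 / fit.tau)})
    return pd.DataFrame(rows)


def model_selection_rate(
    n_cohorts: int = 30,
    n_subjects: int = 6,
    master_seed: int = 2,
) -> float:
    """Fraction of replicate cohorts where the HR model wins both AIC races."""
    wins = 0
    for seed in derive_seeds(master_seed, n_cohorts):
        cohort = simulate_cohort(n_subjects, seed=seed, artifacts=None)
        tables = [process_subject(d)[0] for d in cohort]
        cmp = compare_models(pooled_windows(tables))
        best = cmp[cmp["rank"] == 1]
        wins += int((best[best.effort_range == "full"].model.iloc[0] == 1)
                    and (best[best.effort_range == "effort"].model.iloc[0] == 1))
    return wins / n_cohorts


def cleaning_rates(n_runs: int = 50, master_seed: int = 3) -> tuple[float, float]:
    """(mean detection rate, mean false-removal rate) at calibration rates."""
    from .preprocess import clean_rr
    from .protocol import make_protocol
    from .synthetic import draw_cohort_truths, inject_artifacts, simulate_subject

    seeds = derive_seeds(master_seed, n_runs)
    truths = draw_cohort_truths(3, seed=master_seed)
    det, fp = [], []
    for i, seed in enumerate(seeds):
        tr = truths[i % 3]
        proto = make_protocol(exhaustion_power_w=tr.exhaustion_power)
        d = simulate_subject(proto, tr, seed=seed)
        da = inject_artifacts(d, ArtifactSpec(seed=seed))
        injected = set(np.concatenate(list(da.artifact_idx.values())).tolist())
        _, rep = clean_rr(da.rr)
        removed = set(np.concatenate(
            [rep.removed_rule1, rep.removed_rule2, rep.removed_rule3]
        ).astype(int).tolist())
        det.append(len(injected & removed) / len(injected))
        fp.append(len(removed - injected) / (len(da.rr) - len(injected)))
    return float(np.mean(det)), float(np.mean(fp))
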