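"""Calibrate condition background-noise levels to the target cosine
similarity means (healthy voluntary 0.39, healthy imagined 0.27, stroke
voluntary 0.41).

For each condition this bisects ``background_noise_sd`` until the grand mean
cosine similarity over a calibration ensemble (several seeds x 10 datasets x
50 epochs) hits the target. Run once; the resulting constants are frozen
into ``mrcprel.synthetic.default_condition_params`` and not revisited.

Usage: python scripts/calibrate_similarity.py
"""

from dataclasses import replace

import numpy as np

from mrcprel import (
    CONDITIONS,
    SimulationConfig,
    default_condition_params,
    similarity_table,
    simulate_dataset,
)

TARGETS = {"healthy_voluntary": 0.39, "healthy_imagined": 0.27, "stroke_voluntary": 0.41}
SEEDS = (11, 23, 37)


def mean_cs(condition: str, noise_sd: float) -> float:
    vals = []
    for seed in SEEDS:
        params = replace(default_condition_params()[condition], background_noise_sd=noise_sd)
        cfg = SimulationConfig(seed=seed)
        cfg.condition_params[condition] = params
        for pid in range(cfg.n_datasets_per_condition):
            ds = simulate_dataset(condition, pid, cfg)
            vals.append(similarity_table(ds.epochs)["cs"].mean())
    return float(np.mean(vals))


def bisect(condition: str, target: float, lo: float = 1.0, hi: float = 60.0, iters: int = 18) -> float:
    # mean CS decreases monotonically in the noise SD
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mean_cs(condition, mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


if __name__ == "__main__":
    for cond in CONDITIONS:
        sd = bisect(cond, TARGETS[cond])
        print(f"{cond}: background_noise_sd = {sd:.2f} -> mean CS {mean_cs(cond, sd):.4f} (target {TARGETS[cond]})")
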