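#!/usr/bin/env python
"""Compare the four wavelength-selection algorithms on the desk-scale bank.

Runs SPA, Lasso, GA and Random Frog on the SG-preprocessed training spectra
for both freshness indices, reporting subset sizes, data-reduction
percentages and the collinearity of the selected bands.  Writes
results/wavelength_selection.csv.
"""

import time
from pathlib import Path

import pandas as pd

from salmonhsi.pipeline import RunConfig, run_pipeline
from salmonhsi.selection import (
    collinearity_score, ga_select, lasso_select, random_frog_select,
    spa_select,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 11) -> None:
    res = run_pipeline(RunConfig(seed=seed), until="preprocess")
    bank = res.bank
    tr = bank.rows("train")
    X = bank.mean_spectra[tr]
    groups = bank.labels.sample_id.to_numpy()[tr]
    rows = []
    for target in ("tvbn", "tvc"):
        y = bank.labels[target].to_numpy()[tr]
        selectors = {
            "spa": lambda: spa_select(X, y, k_min=5, k_max=30,
                                      wavelengths_nm=bank.wavelengths_nm),
            "lasso": lambda: lasso_select(X, y, groups=groups, seed=seed,
                                          wavelengths_nm=bank.wavelengths_nm),
            "ga": lambda: ga_select(X, y, pop_size=24, generations=20,
                                    groups=groups, seed=seed,
                                    wavelengths_nm=bank.wavelengths_nm),
            "random_frog": lambda: random_frog_select(
                X, y, n_iter=300, q_init=10, groups=groups, seed=seed,
                top_k=30, wavelengths_nm=bank.wavelengths_nm),
        }
        for name, fn in selectors.items():
            t0 = time.time()
            sub = fn()
            rows.append({
                "target": target, "selector": name, "n_bands": sub.size,
                "reduction_percent": sub.reduction_percent(X.shape[1]),
                "max_abs_correlation": collinearity_score(X, sub.band_indices),
                "seconds": round(time.time() - t0, 1),
            })
            print(f"{target}/{name}: {sub.size} bands "
                  f"({rows[-1]['reduction_percent']:.1f}% reduction, "
                  f"max |r| {rows[-1]['max_abs_correlation']:.2f})")
    tab = pd.DataFrame(rows)
    tab.to_csv(OUT / "wavelength_selection.csv", index=False)


if __name__ == "__main__":
    main()
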