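"""Wavelength selection over the band axis: SPA, Lasso, GA and Random Frog.

All selectors return a :class:`WavelengthSubset` — selected band indices in
ascending order, the selection order preserved in the trace, and an RMSE
evaluation trace.  Subset evaluation inside every stochastic selector uses
multiple linear regression under grouped cross-validation keyed by biological
sample id, never patch-level folds, so the leakage protection enforced at
split time is preserved during selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.model_selection import GroupKFold, KFold

__all__ = [
    "WavelengthSubset",
    "spa_select",
    "lasso_select",
    "ga_select",
    "random_frog_select",
    "collinearity_score",
]


@dataclass
class WavelengthSubset:
    band_indices: np.ndarray            # ascending, unique
    wavelengths_nm: np.ndarray | None
    rmsec_trace: np.ndarray             # RMSE per candidate subset size / iteration
    method: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    selection_order: np.ndarray | None = None   # order in which bands entered
    frequencies: np.ndarray | None = None       # random-frog inclusion frequencies

    def __post_init__(self) -> None:
        self.band_indices = np.asarray(self.band_indices, dtype=int)
        if self.band_indices.size == 0:
            raise ValueError("empty wavelength subset")
        if np.unique(self.band_indices).size != self.band_indices.size:
            raise ValueError("band indices must be unique")
        if np.any(np.diff(self.band_indices) <= 0):
            raise ValueError("band indices must be ascending")
        self.rmsec_trace = np.asarray(self.rmsec_trace, dtype=float)
        if self.rmsec_trace.size < 1:
            raise ValueError("trace must have length >= 1")

    @property
    def size(self) -> int:
        return self.band_indices.size

    def reduction_percent(self, n_bands_total: int) -> float:
        """Data reduction achieved: (1 - |subset| / B) * 100."""
        return (1.0 - self.size / n_bands_total) * 100.0


# ------------------------------------------------------------- helpers

def _ols_rmse(X: np.ndarray, y: np.ndarray, Xte=None, yte=None) -> float:
    """Least-squares fit with intercept; RMSE on (Xte, yte) or training data."""
    A = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    if Xte is None:
        resid = y - A @ coef
    else:
        resid = yte - np.column_stack([np.ones(len(Xte)), Xte]) @ coef
    return float(np.sqrt(np.mean(resid ** 2)))


def _grouped_cv_rmse(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray | None,
    n_folds: int = 3, seed: int = 0,
) -> float:
    """MLR RMSE under grouped K-fold (plain K-fold when groups are absent)."""
    if groups is not None:
        groups = np.asarray(groups)
        n_folds = min(n_folds, np.unique(groups).size)
        splitter = GroupKFold(n_splits=n_folds)
        folds = splitter.split(X, y, groups)
    else:
        splitter = KFold(n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed)
        folds = splitter.split(X, y)
    errs = []
    for tr, te in folds:
        errs.append(_ols_rmse(X[tr], y[tr], X[te], y[te]) ** 2 * len(te))
    return float(np.sqrt(sum(errs) / len(y)))


def collinearity_score(X: np.ndarray, subset) -> float:
    """Max absolute pairwise Pearson correlation among the selected columns."""
    subset = np.asarray(subset, dtype=int)
    if subset.size < 2:
        raise ValueError("need at least 2 selected bands")
    cols = np.asarray(X, dtype=float)[:, subset]
    if np.any(cols.std(axis=0) < 1e-12):
        raise ValueError("constant column: correlation undefined")
    r = np.corrcoef(cols, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return float(np.max(np.abs(r)))


# ------------------------------------------------------------- SPA

def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    k_min: int = 5,
    k_max: int = 30,
    wavelengths_nm: np.ndarray | None = None,
) -> WavelengthSubset:
    """Successive projections algorithm with an MLR/RMSEC evaluator.

    From every starting band a projection chain is grown: the next band is
    the one whose column has the largest norm after projection onto the
    orthogonal complement of the span of the bands already chosen — the
    mechanism that eliminates collinearity.  Every (start, k) chain prefix
    with k in [k_min, k_max] is scored by MLR root-mean-square error of
    calibration on the training data; the global minimiser wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if not (1 <= k_min <= k_max <= min(B, n - 1)):
        raise ValueError(f"need 1 <= k_min <= k_max <= min(B, N-1); got "
                         f"k_min={k_min}, k_max={k_max}, B={B}, N={n}")
    Xc = X - X.mean(axis=0)
    tol = 1e-10 * max(float(np.linalg.norm(Xc)), 1.0)

    best = (np.inf, None, None)          # (rmsec, chain, k)
    best_trace = None
    for start in range(B):
        R = Xc.copy()
        chain = [start]
        for _ in range(k_max - 1):
            u = R[:, chain[-1]]
            nu = u @ u
            if nu < tol ** 2:
                break
            R = R - np.outer(u, (u @ R) / nu)
            norms = np.linalg.norm(R, axis=0)
            norms[chain] = -1.0
            nxt = int(np.argmax(norms))
            if norms[nxt] < tol:
                break
            chain.append(nxt)
        if len(chain) < k_min:
            if B == 1 and k_min == 1:
                pass
            else:
                raise RuntimeError(
                    f"rank collapse before k_min={k_min} in the chain started "
                    f"at band {start}: {chain}")
        trace = np.full(k_max - k_min + 1, np.inf)
        for k in range(k_min, min(k_max, len(chain)) + 1):
            rmsec = _ols_rmse(X[:, chain[:k]], y)
            trace[k - k_min] = rmsec
            if rmsec < best[0]:
                best = (rmsec, list(chain[:k]), k)
                best_trace = trace
    rmsec, chain, k = best
    order = np.asarray(chain, dtype=int)
    idx = np.sort(order)
    return WavelengthSubset(
        band_indices=idx,
        wavelengths_nm=None if wavelengths_nm is None else np.asarray(wavelengths_nm)[idx],
        rmsec_trace=best_trace[: k - k_min + 1] if best_trace is not None else [rmsec],
        method="spa",
        params={"k_min": k_min, "k_max": k_max},
        selection_order=order,
    )


# ------------------------------------------------------------- Lasso

def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    alpha_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    groups: np.ndarray | None = None,
    seed: int = 0,
    wavelengths_nm: np.ndarray | None = None,
) -> WavelengthSubset:
    """L1 path over an alpha grid; alpha chosen by grouped-CV RMSE.

    Columns are standardised internally (train statistics of each fold are a
    refinement left out deliberately: the grid search is over a shared
    standardisation, as is conventional for screening).  The subset is the
    nonzero support at the winning alpha.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd < 1e-12):
        raise ValueError("constant column: standardisation undefined")
    Z = (X - mu) / sd
    if alpha_grid is None:
        alpha_max = float(np.max(np.abs(Z.T @ (y - y.mean())))) / len(y)
        alpha_grid = np.geomspace(alpha_max, alpha_max * 1e-4, 30)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if np.any(alpha_grid <= 0):
        raise ValueError("alphas must be positive")

    if groups is not None:
        g = np.asarray(groups)
        folds = list(GroupKFold(n_splits=min(cv_folds, np.unique(g).size)).split(Z, y, g))
    else:
        folds = list(KFold(n_splits=min(cv_folds, len(y)), shuffle=True,
                           random_state=seed).split(Z, y))
    trace = np.empty(alpha_grid.size)
    for i, a in enumerate(alpha_grid):
        sse, ntot = 0.0, 0
        for tr, te in folds:
            mdl = Lasso(alpha=a, max_iter=50_000)
            mdl.fit(Z[tr], y[tr])
            sse += float(np.sum((y[te] - mdl.predict(Z[te])) ** 2))
            ntot += len(te)
        trace[i] = np.sqrt(sse / ntot)
    best_alpha = float(alpha_grid[int(np.argmin(trace))])
    final = Lasso(alpha=best_alpha, max_iter=50_000).fit(Z, y)
    support = np.flatnonzero(np.abs(final.coef_) > 1e-10)
    if support.size == 0:
        raise ValueError(
            f"empty support at every alpha down to {alpha_grid.min():.3g}; "
            "retry with smaller alphas")
    return WavelengthSubset(
        band_indices=support,
        wavelengths_nm=None if wavelengths_nm is None else np.asarray(wavelengths_nm)[support],
        rmsec_trace=trace,
        method="lasso",
        params={"alpha": best_alpha, "cv_folds": cv_folds},
        seed=seed,
    )


# ------------------------------------------------------------- GA

def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    pop_size: int = 30,
    generations: int = 40,
    crossover_rate: float = 0.8,
    mutation_rate: float = 0.02,
    seed: int = 0,
    groups: np.ndarray | None = None,
    size_penalty: float = 0.0,
    wavelengths_nm: np.ndarray | None = None,
) -> WavelengthSubset:
    """Genetic algorithm over binary band masks.

    Fitness is the negative grouped-CV MLR RMSE minus a size penalty
    proportional to the selected fraction; tournament selection (k=3),
    uniform crossover, bit-flip mutation, elitism of one.  All-zero
    chromosomes are repaired by activating one random band.
    """
    if pop_size < 4:
        raise ValueError("pop_size must be >= 4")
    if not (0 < crossover_rate < 1) or not (0 < mutation_rate < 1):
        raise ValueError("rates must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    B = X.shape[1]
    rng = np.random.default_rng(seed)
    if size_penalty == 0.0:
        size_penalty = 0.05 * float(np.std(y))

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask[rng.integers(B)] = True
        return mask

    def fitness(mask: np.ndarray) -> float:
        rmse_cv = _grouped_cv_rmse(X[:, mask], y, groups, seed=seed)
        return -(rmse_cv + size_penalty * mask.mean())

    pop = [repair(rng.random(B) < 0.3) for _ in range(pop_size)]
    fits = np.array([fitness(m) for m in pop])
    trace = []
    for _ in range(generations):
        elite = pop[int(np.argmax(fits))].copy()
        nxt = [elite]
        while len(nxt) < pop_size:
            # tournament selection of two parents
            cand = rng.integers(pop_size, size=3)
            pa = pop[cand[np.argmax(fits[cand])]]
            cand = rng.integers(pop_size, size=3)
            pb = pop[cand[np.argmax(fits[cand])]]
            if rng.random() < crossover_rate:
                swap = rng.random(B) < 0.5
                child = np.where(swap, pa, pb)
            else:
                child = pa.copy()
            flip = rng.random(B) < mutation_rate
            child = repair(child ^ flip)
            nxt.append(child)
        pop = nxt
        fits = np.array([fitness(m) for m in pop])
        trace.append(-float(np.max(fits)))
    best_mask = pop[int(np.argmax(fits))]
    idx = np.flatnonzero(best_mask)
    return WavelengthSubset(
        band_indices=idx,
        wavelengths_nm=None if wavelengths_nm is None else np.asarray(wavelengths_nm)[idx],
        rmsec_trace=trace,
        method="ga",
        params={"pop_size": pop_size, "generations": generations,
                "crossover_rate": crossover_rate, "mutation_rate": mutation_rate,
                "size_penalty": size_penalty},
        seed=seed,
    )


def ga_fitness(X, y, mask, groups=None, size_penalty=0.0, seed: int = 0) -> float:
    """The GA's fitness of one mask, exposed for independent verification."""
    mask = np.asarray(mask, dtype=bool)
    rmse_cv = _grouped_cv_rmse(np.asarray(X, float)[:, mask],
                               np.asarray(y, float).ravel(), groups, seed=seed)
    return -(rmse_cv + size_penalty * mask.mean())


# ------------------------------------------------------------- Random Frog

def random_frog_select(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 500,
    q_init: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
    eta: float = 10.0,
    top_k: int | None = None,
    wavelengths_nm: np.ndarray | None = None,
) -> WavelengthSubset:
    """Reversible-jump MCMC-style subset search ("random frog").

    A candidate subset random-walks through grow / shrink / swap moves; an
    improving move is always accepted, a worsening one with probability
    (RMSE_old / RMSE_new) ** eta.  Per-band inclusion frequencies over the
    chain are the selector's output; the returned subset is the top-k most
    frequent bands (k = final subset size when top_k is None).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    B = X.shape[1]
    if not (1 <= q_init <= B):
        raise ValueError("q_init must lie in [1, B]")
    rng = np.random.default_rng(seed)
    current = set(rng.choice(B, size=q_init, replace=False).tolist())
    cur_rmse = _grouped_cv_rmse(X[:, sorted(current)], y, groups, seed=seed)
    counts = np.zeros(B)
    trace = np.empty(n_iter)
    accepted = 0
    for it in range(n_iter):
        prop = set(current)
        move = rng.integers(3)
        if move == 0 and len(prop) < B:                      # grow
            prop.add(int(rng.choice(sorted(set(range(B)) - prop))))
        elif move == 1 and len(prop) > 1:                    # shrink
            prop.remove(int(rng.choice(sorted(prop))))
        else:                                                # swap
            out_band = int(rng.choice(sorted(prop)))
            pool = sorted(set(range(B)) - prop)
            if pool:
                prop.remove(out_band)
                prop.add(int(rng.choice(pool)))
        if prop != current:
            new_rmse = _grouped_cv_rmse(X[:, sorted(prop)], y, groups, seed=seed)
            if new_rmse <= cur_rmse or rng.random() < (cur_rmse / new_rmse) ** eta:
                current, cur_rmse = prop, new_rmse
                accepted += 1
        for b in current:
            counts[b] += 1
        trace[it] = cur_rmse
    freqs = counts / n_iter
    if accepted == 0:
        import warnings
        warnings.warn(f"degenerate chain: acceptance rate 0/{n_iter}", stacklevel=2)
    k = top_k if top_k is not None else len(current)
    idx = np.sort(np.argsort(-freqs, kind="stable")[:k])
    return WavelengthSubset(
        band_indices=idx,
        wavelengths_nm=None if wavelengths_nm is None else np.asarray(wavelengths_nm)[idx],
        rmsec_trace=trace,
        method="random_frog",
        params={"n_iter": n_iter, "q_init": q_init, "eta": eta, "top_k": k},
        seed=seed,
        frequencies=freqs,
    )
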