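"""Evaluation surface: R², RMSE, interval MRE, paired residual t-test,
TVB-N/TVC co-evolution, and report assembly.

Metrics are computed per patch (the model-facing unit); a per-fillet view —
patch predictions averaged within each biological sample before scoring —
is offered alongside, since regulatory decisions are made per fillet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitReport",
    "r2_score",
    "rmse",
    "mre_in_interval",
    "paired_residual_ttest",
    "index_correlation",
    "build_report",
    "DEFAULT_MRE_INTERVALS",
]

#: Regulatory-limit brackets for localized error analysis: the TVB-N rejection
#: limit 25 mg/100 g and the TVC limits 4.67 / 5.0 lg CFU/g fall inside them.
DEFAULT_MRE_INTERVALS = {"tvbn": (20.0, 30.0), "tvc": (4.4, 5.3)}


@dataclass
class FitReport:
    target: str
    per_split: dict                      # split -> {"r2":, "rmse":, "n":}
    mre_by_interval: list = field(default_factory=list)   # (lo, hi, mre%)
    residual_test: tuple | None = None   # (t, p, description)
    per_fillet: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target": self.target, "split": s, **m} for s, m in self.per_split.items()
        ]
        return pd.DataFrame(rows)


def r2_score(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSres/SStot."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size or y.size < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot < 1e-300:
        raise ValueError("constant y: R2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sstot


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size or y.size < 1:
        raise ValueError("need equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mre_in_interval(y: np.ndarray, yhat: np.ndarray, lo: float, hi: float) -> float:
    """Mean relative error (%) over samples whose true value lies in [lo, hi]."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    sel = (y >= lo) & (y <= hi)
    if not sel.any():
        raise ValueError(f"no samples with y in [{lo}, {hi}]")
    ysel, psel = y[sel], yhat[sel]
    if np.any(ysel == 0):
        raise ValueError("relative error undefined at y = 0")
    return float(np.mean(np.abs(psel - ysel) / ysel) * 100.0)


def paired_residual_ttest(abs_res_a: np.ndarray, abs_res_b: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test on |residual| differences; two-sided p."""
    a = np.asarray(abs_res_a, dtype=float).ravel()
    b = np.asarray(abs_res_b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    d = a - b
    if np.std(d, ddof=1) < 1e-12 * (np.abs(d).max() + 1.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def index_correlation(labels, by_temperature: bool = True) -> dict:
    """Squared Pearson correlation between TVB-N and TVC.

    ``labels`` is a DataFrame with columns tvbn/tvc/temperature_c or a list
    of SpoilageLabels.  Returns {"overall": r2} plus one entry per
    temperature cohort when ``by_temperature``.
    """
    if isinstance(labels, pd.DataFrame):
        df = labels
    else:
        df = pd.DataFrame(
            [{"tvbn": l.tvbn, "tvc": l.tvc, "temperature_c": l.temperature_c}
             for l in labels]
        )
    def _r2(sub: pd.DataFrame) -> float:
        if len(sub) < 3:
            raise ValueError("need >= 3 samples per cohort")
        x, y = sub["tvbn"].to_numpy(), sub["tvc"].to_numpy()
        if np.std(x) < 1e-12 or np.std(y) < 1e-12:
            raise ValueError("constant index vector")
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    out = {"overall": _r2(df)}
    if by_temperature:
        for temp, sub in df.groupby("temperature_c"):
            out[int(temp)] = _r2(sub)
    return out


def evaluate_split(y: np.ndarray, yhat: np.ndarray) -> dict:
    return {"r2": r2_score(y, yhat), "rmse": rmse(y, yhat), "n": int(len(np.ravel(y)))}


def build_report(
    models: dict,
    datasets: dict,
    intervals: dict = DEFAULT_MRE_INTERVALS,
    n_bands_total: int | None = None,
) -> tuple[pd.DataFrame, list[FitReport]]:
    """Assemble the (preprocessing x model x split) evaluation table.

    ``models`` maps (method, model_kind, target) -> trained model;
    ``datasets`` maps (method, target) -> {split: (X, y, sample_ids)}.
    The returned long-format frame carries per-split R²/RMSE, interval MRE on
    the prediction split and, when the model records a wavelength subset, the
    band-reduction percentage (1 - |subset| / B) * 100.
    """
    rows, reports = [], []
    for (method, kind, target), model in models.items():
        splits = datasets[(method, target)]
        per_split, per_fillet = {}, {}
        mre_list = []
        for split, (X, y, sids) in splits.items():
            yhat = model.predict(X)
            per_split[split] = evaluate_split(y, yhat)
            if sids is not None:
                fr = pd.DataFrame({"sid": sids, "y": y, "yhat": yhat}).groupby("sid").mean()
                if len(fr) >= 2 and fr["y"].std() > 0:
                    per_fillet[split] = evaluate_split(fr["y"], fr["yhat"])
            if split == "prediction" and target in intervals:
                lo, hi = intervals[target]
                try:
                    mre_list.append((lo, hi, mre_in_interval(y, yhat, lo, hi)))
                except ValueError:
                    pass
        report = FitReport(target, per_split, mre_list, None, per_fillet)
        subset = getattr(model, "provenance", {}).get("subset")
        if subset is not None and n_bands_total:
            report.extras["reduction_percent"] = (
                (1.0 - len(subset.band_indices) / n_bands_total) * 100.0)
        reports.append(report)
        for split, m in per_split.items():
            rows.append({
                "preprocessing": method, "model": kind, "target": target,
                "split": split, **m,
                "reduction_percent": report.extras.get("reduction_percent", 0.0),
            })
    return pd.DataFrame(rows), reports
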