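"""Twelve chemometric preprocessing protocols and quantitative screening.

Row-wise protocols (SNV, MSC, Savitzky-Golay smoothing and derivatives,
moving average, wavelet denoising, baseline correction, min-max, vector
normalisation) are stateless per spectrum; column-wise protocols (mean
centering, standardisation) and MSC's reference spectrum carry statistics
that must be fitted on the training split only and frozen for validation /
prediction — :class:`Preprocessor` handles that fit/transform split.

Screening ranks protocols on three indicators: signal-to-noise ratio in dB
(signal = Savitzky-Golay smoothed component, noise = residual), coefficient
of variation across spectra (%), and baseline offset (distance of the
effective per-spectrum baseline from zero).  The composite is a rank sum
(SNR high, CV low, |offset| low).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, signal

__all__ = [
    "SpectraMatrix",
    "PreprocessQuality",
    "Preprocessor",
    "PREPROCESS_METHODS",
    "preprocess",
    "quality_metrics",
    "screen_protocols",
]

PREPROCESS_METHODS = (
    "msc", "sg", "snv", "moving_average", "deriv1", "deriv2", "wavelet",
    "mean_center", "standardize", "baseline", "minmax", "vector_norm",
)

_SG_WINDOW, _SG_ORDER = 11, 3          # defaults; also used by the SNR metric


@dataclass
class SpectraMatrix:
    """N spectra as rows over a shared wavelength grid, with provenance."""

    values: np.ndarray
    wavelengths_nm: np.ndarray
    provenance: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.shape[1] != self.wavelengths_nm.size:
            raise ValueError("band axis does not match wavelength vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra must be finite")

    @property
    def n_spectra(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, step: tuple) -> "SpectraMatrix":
        return SpectraMatrix(values, self.wavelengths_nm, self.provenance + (step,))


@dataclass
class PreprocessQuality:
    snr_db: float
    cv_percent: float
    baseline_offset: float
    saturated: bool = False


# ---------------------------------------------------------------- row-wise

def _snv(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd < 1e-12):
        raise ValueError("constant row: SNV undefined (zero variance)")
    return (x - x.mean(axis=1, keepdims=True)) / sd


def _msc(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    # per row regress x = a + b * reference, then invert the affine distortion
    ref = reference - reference.mean()
    denom = float(ref @ ref)
    if denom < 1e-12:
        raise ValueError("MSC reference is constant")
    xc = x - x.mean(axis=1, keepdims=True)
    b = (xc @ ref) / denom
    if np.any(np.abs(b) < 1e-12):
        raise ValueError("row orthogonal to MSC reference (zero slope)")
    a = x.mean(axis=1) - b * reference.mean()
    return (x - a[:, None]) / b[:, None]


def _minmax(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=1, keepdims=True)
    span = x.max(axis=1, keepdims=True) - lo
    if np.any(span < 1e-12):
        raise ValueError("constant row: min-max undefined")
    return (x - lo) / span


def _vector_norm(x: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(nrm < 1e-12):
        raise ValueError("zero row: vector normalisation undefined")
    return x / nrm


def _wavelet_denoise(x: np.ndarray, wavelet: str = "db4", level: int = 2) -> np.ndarray:
    out = np.empty_like(x)
    n = x.shape[1]
    for i, row in enumerate(x):
        coeffs = pywt.wavedec(row, wavelet, level=level)
        # universal threshold from the finest detail level
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if coeffs[-1].size else 0.0
        thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
        out[i] = pywt.waverec(coeffs, wavelet)[:n]
    return out


def _baseline_correct(x: np.ndarray, order: int = 2, n_iter: int = 10) -> np.ndarray:
    """Iterative polynomial baseline fitting, subtracted per row."""
    grid = np.linspace(-1.0, 1.0, x.shape[1])
    V = np.vander(grid, order + 1)
    out = np.empty_like(x)
    for i, row in enumerate(x):
        work = row.copy()
        base = work
        for _ in range(n_iter):
            coef, *_ = np.linalg.lstsq(V, work, rcond=None)
            base = V @ coef
            work = np.minimum(work, base)
        out[i] = row - base
    return out


# ---------------------------------------------------------------- dispatch

class Preprocessor:
    """One named protocol with fit/transform semantics.

    ``fit`` learns whatever statistics the protocol needs (column means/stds,
    the MSC reference) from the training split; ``transform`` applies the
    frozen protocol to any split.  Stateless protocols fit trivially.
    """

    def __init__(self, method: str, **params) -> None:
        if method not in PREPROCESS_METHODS:
            raise ValueError(f"unknown preprocessing method {method!r}")
        self.method = method
        self.params = dict(params)
        self._validate()
        self._state: dict = {}
        self.fitted = False

    def _validate(self) -> None:
        if self.method in ("sg", "deriv1", "deriv2"):
            w = self.params.setdefault("window", _SG_WINDOW)
            p = self.params.setdefault("polyorder", _SG_ORDER)
            if w % 2 == 0 or w <= p:
                raise ValueError("SG window must be odd and exceed the polyorder")
        elif self.method == "moving_average":
            if self.params.setdefault("window", 5) < 1:
                raise ValueError("moving-average window must be >= 1")
        elif self.method == "wavelet":
            self.params.setdefault("wavelet", "db4")
            if self.params.setdefault("level", 2) < 1:
                raise ValueError("wavelet level must be >= 1")
        elif self.method == "baseline":
            self.params.setdefault("order", 2)
            self.params.setdefault("n_iter", 10)

    def fit(self, spectra: SpectraMatrix) -> "Preprocessor":
        x = spectra.values
        if self.method == "msc":
            self._state["reference"] = self.params.get(
                "reference", x.mean(axis=0))
        elif self.method == "mean_center":
            self._state["mean"] = x.mean(axis=0)
        elif self.method == "standardize":
            mu, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
            if np.any(sd < 1e-12):
                raise ValueError("constant column: standardisation undefined")
            self._state["mean"], self._state["std"] = mu, sd
        self.fitted = True
        return self

    def transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        if not self.fitted:
            raise RuntimeError("fit the preprocessor before transforming")
        x = spectra.values
        m, p = self.method, self.params
        if m == "snv":
            out = _snv(x)
        elif m == "msc":
            out = _msc(x, np.asarray(self._state["reference"], dtype=float))
        elif m == "sg":
            out = signal.savgol_filter(x, p["window"], p["polyorder"], axis=1)
        elif m in ("deriv1", "deriv2"):
            out = signal.savgol_filter(
                x, p["window"], p["polyorder"],
                deriv=1 if m == "deriv1" else 2, axis=1)
        elif m == "moving_average":
            out = ndimage.uniform_filter1d(x, p["window"], axis=1, mode="nearest")
        elif m == "wavelet":
            out = _wavelet_denoise(x, p["wavelet"], p["level"])
        elif m == "mean_center":
            out = x - self._state["mean"]
        elif m == "standardize":
            out = (x - self._state["mean"]) / self._state["std"]
        elif m == "baseline":
            out = _baseline_correct(x, p["order"], p["n_iter"])
        elif m == "minmax":
            out = _minmax(x)
        elif m == "vector_norm":
            out = _vector_norm(x)
        else:  # pragma: no cover
            raise AssertionError(m)
        return spectra.with_values(out, (m, tuple(sorted(p.items()))))

    def fit_transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        return self.fit(spectra).transform(spectra)


def preprocess(spectra: SpectraMatrix, method: str, **params) -> SpectraMatrix:
    """Fit-and-apply a protocol on one matrix (see Preprocessor for split-safe use)."""
    return Preprocessor(method, **params).fit_transform(spectra)


# ---------------------------------------------------------------- screening

def quality_metrics(raw: SpectraMatrix, processed: SpectraMatrix) -> PreprocessQuality:
    """SNR (dB), coefficient of variation (%) and baseline offset.

    SNR separates each processed spectrum into a Savitzky-Golay smoothed
    signal component (window 11, order 3) and a residual noise component:
    ``10 * log10(P_signal / P_noise)``.  CV is the mean over bands of the
    across-spectra std / |mean| * 100.  Baseline offset is the mean over
    spectra of |median of the lowest decile of the row|.
    """
    if raw.values.shape != processed.values.shape:
        raise ValueError("raw and processed matrices must share a shape")
    x = processed.values
    window = min(_SG_WINDOW, x.shape[1] if x.shape[1] % 2 else x.shape[1] - 1)
    smooth = signal.savgol_filter(x, window, min(_SG_ORDER, window - 1), axis=1)
    p_signal = float(np.mean(smooth ** 2))
    p_noise = float(np.mean((x - smooth) ** 2))
    saturated = p_noise < 1e-15 * max(p_signal, 1.0)
    if p_signal < 1e-300:
        snr_db, saturated = -np.inf, True
    elif saturated:
        snr_db = np.inf
    else:
        snr_db = 10.0 * np.log10(p_signal / p_noise)

    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros_like(mu)
    ok = np.abs(mu) > 1e-12
    cv = float(np.mean(sd[ok] / np.abs(mu[ok])) * 100.0) if ok.any() else np.inf

    k = max(1, x.shape[1] // 10)
    lowest_decile = np.sort(x, axis=1)[:, :k]
    offset = float(np.mean(np.abs(np.median(lowest_decile, axis=1))))
    return PreprocessQuality(snr_db, cv, offset, saturated)


def screen_protocols(
    spectra: SpectraMatrix,
    methods=PREPROCESS_METHODS,
    **method_params,
) -> pd.DataFrame:
    """Rank protocols by rank-sum over (SNR desc, CV asc, |offset| asc).

    Returns a DataFrame sorted by composite rank with one row per method;
    ties share ranks, and the ranking is invariant to method order.
    """
    methods = list(methods)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to screen")
    rows = []
    for m in methods:
        try:
            proc = preprocess(spectra, m, **method_params.get(m, {}))
            q = quality_metrics(spectra, proc)
        except Exception as exc:
            raise RuntimeError(f"protocol {m!r} failed during screening: {exc}") from exc
        rows.append({"method": m, "snr_db": q.snr_db, "cv_percent": q.cv_percent,
                     "baseline_offset": q.baseline_offset, "saturated": q.saturated})
    tab = pd.DataFrame(rows).sort_values("method").reset_index(drop=True)
    tab["rank_snr"] = (-tab["snr_db"]).rank(method="average")
    tab["rank_cv"] = tab["cv_percent"].rank(method="average")
    tab["rank_offset"] = tab["baseline_offset"].abs().rank(method="average")
    tab["composite_rank"] = tab[["rank_snr", "rank_cv", "rank_offset"]].sum(axis=1)
    return tab.sort_values(["composite_rank", "method"]).reset_index(drop=True)
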