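"""Synthetic spoilage study: coupled TVB-N/TVC kinetics and fillet hypercubes.

The generator emulates the structure of a refrigerated salmon storage trial:
2 temperatures (4/8 degC) x 8 sampling days {0,1,2,3,5,7,9,11} x 30
replicate fillets, each imaged on both sides.  Freshness-index means follow
logistic growth curves calibrated so that the noise-free trajectories hit
the published study endpoints within 1 % and reproduce every published
integer-day regulatory-threshold crossing (TVB-N 25 mg/100 g; TVC 4.67 and
5.0 lg CFU/g).  Replicate labels add correlated multiplicative noise so
TVB-N and TVC co-evolve tightly within each temperature cohort.

Hypercubes use a physically-motivated forward model: a visible/SW-NIR
baseline reflectance shape (absorption trough 400-500 nm, peak 600-700 nm,
water band near 970 nm, overall maximum below 50 %) scaled down globally and
deformed locally as spoilage progresses, with per-pixel multiplicative /
additive scatter, a smooth spatial heterogeneity field and band noise.
Synthetic white/dark reference frames invert exactly under radiometric
calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from salmonhsi.hypercube import (
    CalibrationFrames, Hypercube, default_wavelength_grid, write_cube,
)
from salmonhsi.segmentation import SAMPLING_DAYS, RoiMask, SpoilageLabels

__all__ = [
    "LogisticParams",
    "KineticParams",
    "SpectralForwardParams",
    "StudyDesign",
    "DEFAULT_ANCHORS",
    "DEFAULT_CROSSINGS",
    "calibrate_kinetics",
    "default_kinetics",
    "first_crossing_day",
    "sample_labels",
    "spoilage_index",
    "generate_fillet_cube",
    "generate_experiment",
    "planted_signal_dataset",
    "ExperimentBundle",
]


# ---------------------------------------------------------------- kinetics

@dataclass(frozen=True)
class LogisticParams:
    """v(t) = v0 + (vmax - v0) / (1 + exp(-r (t - t_m)))."""

    v0: float
    vmax: float
    r: float          # day^-1
    t_m: float        # inflection day

    def __post_init__(self) -> None:
        if not (self.vmax > self.v0 >= 0):
            raise ValueError("need vmax > v0 >= 0")
        if self.r <= 0:
            raise ValueError("rate must be positive")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.v0 + (self.vmax - self.v0) / (1.0 + np.exp(-self.r * (t - self.t_m)))


@dataclass(frozen=True)
class KineticParams:
    """Logistic parameters per (index, storage temperature)."""

    series: dict  # (target, temperature_c) -> LogisticParams

    def trajectory(self, target: str, temperature_c: int, t) -> np.ndarray:
        return self.series[(target, temperature_c)](t)


#: Endpoint anchors of the emulated study: (day 0 value, day 11 value).
DEFAULT_ANCHORS = {
    ("tvbn", 4): (1.29, 55.67),
    ("tvbn", 8): (1.40, 70.38),
    ("tvc", 4): (2.16, 6.91),
    ("tvc", 8): (2.56, 8.03),
}

#: Regulatory-limit crossings: first integer day d with mean(d) > limit.
#: TVB-N limit 25 mg/100 g; TVC limits 4.67 (ready-to-eat) and 5.0 (marine fish).
DEFAULT_CROSSINGS = {
    ("tvbn", 4): [(25.0, 7)],
    ("tvbn", 8): [(25.0, 5)],
    ("tvc", 4): [(4.67, 7), (5.0, 8)],
    ("tvc", 8): [(4.67, 4), (5.0, 4)],
}

_HORIZON = 11  # days


def first_crossing_day(params: LogisticParams, limit: float,
                       horizon: int = _HORIZON) -> int | None:
    """Smallest integer day d in [0, horizon] with v(d) > limit."""
    for d in range(horizon + 1):
        if params(d) > limit:
            return d
    return None


def _solve_levels(anchors: tuple[float, float], r: float, t_m: float
                  ) -> LogisticParams | None:
    """Solve (v0, vmax) so the logistic hits both endpoint anchors exactly."""
    a0, a11 = anchors
    s0 = 1.0 / (1.0 + np.exp(r * t_m))
    s11 = 1.0 / (1.0 + np.exp(-r * (_HORIZON - t_m)))
    A = np.array([[1.0 - s0, s0], [1.0 - s11, s11]])
    det = np.linalg.det(A)
    if abs(det) < 1e-12:
        return None
    v0, vmax = np.linalg.solve(A, np.array([a0, a11]))
    if not (vmax > v0 >= 0.0):
        return None
    return LogisticParams(float(v0), float(vmax), float(r), float(t_m))


def _crossing_margin(p: LogisticParams, crossings) -> float:
    """Min normalised slack over all integer-day crossing constraints."""
    margin = np.inf
    for limit, day in crossings:
        margin = min(margin, (p(day) - limit) / limit)           # must exceed
        if day >= 1:
            margin = min(margin, (limit - p(day - 1)) / limit)   # must not yet
        else:
            return -np.inf
    return float(margin)


def calibrate_kinetics(
    anchors: dict = DEFAULT_ANCHORS,
    crossings: dict = DEFAULT_CROSSINGS,
) -> KineticParams:
    """Fit logistic mean trajectories to endpoint anchors and crossings.

    For each (index, temperature) series the rate r and inflection day t_m
    are searched on a grid; at each grid point (v0, vmax) are solved in
    closed form so both endpoint anchors are hit exactly.  Among feasible
    points — every integer-day threshold crossing satisfied — the smoothest
    trajectory (smallest growth rate) whose worst-case crossing margin stays
    above a 5 % robustness floor wins; if no point reaches the floor, the
    max-margin point is used.  Deterministic; raises on infeasibility.
    """
    rs = np.linspace(0.15, 2.5, 160)
    tms = np.linspace(0.5, 12.0, 231)
    margin_floor = 0.05
    series = {}
    for key, anc in anchors.items():
        best_margin, at_max_margin = -np.inf, None
        smoothest, smooth_margin = None, -np.inf
        for r in rs:
            for t_m in tms:
                p = _solve_levels(anc, r, t_m)
                if p is None:
                    continue
                m = _crossing_margin(p, crossings.get(key, []))
                if m > best_margin:
                    best_margin, at_max_margin = m, p
                if m >= margin_floor and (
                        smoothest is None or p.r < smoothest.r
                        or (p.r == smoothest.r and m > smooth_margin)):
                    smoothest, smooth_margin = p, m
        if at_max_margin is None or best_margin <= 0:
            raise RuntimeError(
                f"infeasible kinetic constraint set for {key}: "
                f"best margin {best_margin:.4f}")
        series[key] = smoothest if smoothest is not None else at_max_margin
    return KineticParams(series)


_DEFAULT_KINETICS: KineticParams | None = None


def default_kinetics() -> KineticParams:
    """The packaged default kinetics (calibrated once per process and cached)."""
    global _DEFAULT_KINETICS
    if _DEFAULT_KINETICS is None:
        _DEFAULT_KINETICS = calibrate_kinetics()
    return _DEFAULT_KINETICS


# ---------------------------------------------------------------- design

@dataclass(frozen=True)
class StudyDesign:
    temperatures: tuple[int, ...] = (4, 8)
    days: tuple[int, ...] = SAMPLING_DAYS
    replicates: int = 30
    sides: tuple[str, ...] = ("dorsal", "ventral")
    image_shape: tuple[int, int] = (80, 160)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate per design cell")
        if any(d not in SAMPLING_DAYS for d in self.days):
            raise ValueError(f"days must come from the sampling grid {SAMPLING_DAYS}")

    @property
    def n_samples(self) -> int:
        return len(self.temperatures) * len(self.days) * self.replicates

    @property
    def n_cubes(self) -> int:
        return self.n_samples * len(self.sides)


# ---------------------------------------------------------------- labels

def sample_labels(
    design: StudyDesign,
    params: KineticParams | None = None,
    rho: float = 0.9,
    tvbn_cv: float = 0.06,
    tvc_cv: float = 0.03,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-replicate freshness labels around the mean trajectories.

    Multiplicative log-normal noise, correlated between the two indices with
    coefficient ``rho`` (the same biological spoilage state drives both), is
    applied around the noise-free means; zero CVs reproduce the means
    exactly.  Deterministic given the seed.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    params = params or default_kinetics()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for temp in design.temperatures:
        for day in design.days:
            m_tvbn = float(params.trajectory("tvbn", temp, day))
            m_tvc = float(params.trajectory("tvc", temp, day))
            for rep in range(design.replicates):
                z1 = rng.standard_normal()
                z2 = rho * z1 + np.sqrt(1.0 - rho ** 2) * rng.standard_normal()
                tvbn = m_tvbn * np.exp(tvbn_cv * z1 - 0.5 * tvbn_cv ** 2)
                tvc = m_tvc * np.exp(tvc_cv * z2 - 0.5 * tvc_cv ** 2)
                rows.append({
                    "sample_id": f"T{temp}_D{day:02d}_R{rep:02d}",
                    "temperature_c": temp, "day": day, "replicate": rep,
                    "tvbn": tvbn, "tvc": tvc,
                })
    return pd.DataFrame(rows)


def labels_to_records(df: pd.DataFrame) -> dict[str, SpoilageLabels]:
    return {
        row.sample_id: SpoilageLabels(row.tvbn, row.tvc, int(row.temperature_c),
                                      int(row.day))
        for row in df.itertuples()
    }


# ---------------------------------------------------------------- spectra

@dataclass(frozen=True)
class SpectralForwardParams:
    """Forward model from spoilage state to percent reflectance.

    spectrum(lambda, s) = baseline(lambda) * (1 - alpha s)
                          - beta s G(lambda; 450) - gamma s G(lambda; 655)

    with s in [0, 1] the normalised spoilage index; per-pixel scatter
    a x + b (a log-normal, b normal), a smooth multiplicative heterogeneity
    field, and iid band noise.
    """

    base_offset: float = 16.0
    base_rise: float = 14.0            # VIS->NIR sigmoid amplitude
    rise_center_nm: float = 560.0
    rise_width_nm: float = 70.0
    trough_depth: float = 9.0          # 400-500 nm absorption trough
    trough_center_nm: float = 445.0
    trough_width_nm: float = 42.0
    peak_height: float = 5.0           # 600-700 nm peak shaping
    peak_center_nm: float = 655.0
    peak_width_nm: float = 55.0
    water_depth: float = 5.0           # NIR water band
    water_center_nm: float = 972.0
    water_width_nm: float = 45.0
    nir_decline: float = 3.0           # gradual decline beyond ~850 nm
    alpha: float = 0.15                # global spoilage decline
    beta: float = 5.0                  # trough deepening (band-specific)
    gamma: float = 4.0                 # peak attenuation (band-specific)
    scatter_sigma_a: float = 0.05      # log-normal multiplicative scatter
    scatter_sigma_b: float = 0.3       # additive offset, percent
    pixel_noise: float = 0.3           # band noise sd, percent
    heterogeneity: float = 0.02        # spatial field amplitude
    background_level: float = 2.0      # percent reflectance outside the fillet

    def baseline(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths_nm, dtype=float)
        sig = lambda x: 1.0 / (1.0 + np.exp(-x))
        g = lambda c, w: np.exp(-(((lam - c) / w) ** 2))
        return (self.base_offset
                + self.base_rise * sig((lam - self.rise_center_nm) / self.rise_width_nm)
                - self.trough_depth * g(self.trough_center_nm, self.trough_width_nm)
                + self.peak_height * g(self.peak_center_nm, self.peak_width_nm)
                - self.water_depth * g(self.water_center_nm, self.water_width_nm)
                - self.nir_decline * sig((lam - 850.0) / 80.0))

    def spectrum(self, wavelengths_nm: np.ndarray, s: float) -> np.ndarray:
        lam = np.asarray(wavelengths_nm, dtype=float)
        g = lambda c, w: np.exp(-(((lam - c) / w) ** 2))
        return (self.baseline(lam) * (1.0 - self.alpha * s)
                - self.beta * s * g(self.trough_center_nm, self.trough_width_nm)
                - self.gamma * s * g(self.peak_center_nm, self.peak_width_nm))


def spoilage_index(labels: SpoilageLabels, kinetics: KineticParams) -> float:
    """Normalised spoilage state s in [0, 1] blending the two indices.

    s = 0.5 tvbn/vmax_tvbn + 0.5 (tvc - v0_tvc)/(vmax_tvc - v0_tvc), with the
    kinetic parameters of the label's own temperature, clipped to [0, 1].
    """
    pb = kinetics.series[("tvbn", labels.temperature_c)]
    pc = kinetics.series[("tvc", labels.temperature_c)]
    s = 0.5 * labels.tvbn / pb.vmax + 0.5 * (labels.tvc - pc.v0) / (pc.vmax - pc.v0)
    return float(np.clip(s, 0.0, 1.0))


class ForwardModelRangeError(ValueError):
    """Noise-free reflectance left [0, 55] percent: misconfigured parameters."""


def _superellipse_mask(shape: tuple[int, int], rng: np.random.Generator,
                       exponent: float = 20.0) -> np.ndarray:
    """Fillet-block footprint: rounded rectangle with mild per-sample jitter."""
    rows, cols = shape
    cy, cx = rows / 2.0, cols / 2.0
    a = 0.425 * rows * (1.0 + 0.03 * (rng.random() - 0.5))
    b = 0.44 * cols * (1.0 + 0.03 * (rng.random() - 0.5))
    r = np.arange(rows)[:, None] - cy
    c = np.arange(cols)[None, :] - cx
    return (np.abs(r / a) ** exponent + np.abs(c / b) ** exponent) <= 1.0


def generate_fillet_cube(
    labels: SpoilageLabels,
    params: SpectralForwardParams | None = None,
    kinetics: KineticParams | None = None,
    shape: tuple[int, int] = (80, 160),
    wavelengths_nm: np.ndarray | None = None,
    seed: int = 0,
    sample_id: str = "",
    side: str = "dorsal",
    noise: bool = True,
) -> tuple[Hypercube, CalibrationFrames, RoiMask]:
    """One raw hypercube with its reference frames and ground-truth mask.

    ``noise=False`` drops scatter, heterogeneity and band noise, leaving the
    pure forward model (used for monotonicity checks and calibration
    round-trips).
    """
    params = params or SpectralForwardParams()
    kinetics = kinetics or default_kinetics()
    lam = default_wavelength_grid() if wavelengths_nm is None else np.asarray(wavelengths_nm)
    rng = np.random.default_rng(seed)
    rows, cols = shape
    mask = _superellipse_mask(shape, rng)
    s = spoilage_index(labels, kinetics)
    spec = params.spectrum(lam, s)
    if spec.min() < 0.0 or spec.max() > 55.0:
        raise ForwardModelRangeError(
            f"noise-free spectrum spans [{spec.min():.2f}, {spec.max():.2f}] % "
            "outside [0, 55]: forward-model parameters are misconfigured")

    refl = np.empty((rows, cols, lam.size))
    refl[...] = params.background_level
    if noise:
        refl += rng.normal(0.0, 0.15, size=refl.shape)
        a_px = np.exp(rng.normal(0.0, params.scatter_sigma_a, size=shape))
        b_px = rng.normal(0.0, params.scatter_sigma_b, size=shape)
        het = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=12.0)
        het_sd = het.std() or 1.0
        field = 1.0 + params.heterogeneity * het / het_sd
        gain = (a_px * field)[..., None]
        offs = b_px[..., None]
        eps = rng.normal(0.0, params.pixel_noise, size=(rows, cols, lam.size))
        fillet = gain * spec[None, None, :] + offs + eps
    else:
        fillet = np.broadcast_to(spec, (rows, cols, lam.size)).copy()
    refl[mask] = fillet[mask]
    refl = np.clip(refl, 0.0, None)

    # push-broom line references (cols x bands): lamp spectrum with a gentle
    # cross-track profile; dark frame near the sensor noise floor
    lamp = 2400.0 + 1400.0 * np.exp(-(((lam - 700.0) / 260.0) ** 2))
    profile = 1.0 + 0.03 * np.sin(2.0 * np.pi * np.arange(cols) / cols)
    white = profile[:, None] * lamp[None, :]
    dark = 95.0 + 3.0 * np.sin(2.0 * np.pi * np.arange(cols) / cols)[:, None] \
        * np.ones_like(lam)[None, :]
    refs = CalibrationFrames(white, dark)
    raw = dark[None, :, :] + refl / 100.0 * (white - dark)[None, :, :]
    cube = Hypercube(raw, lam, sample_id=sample_id, side=side, calibrated=False)
    return cube, refs, RoiMask(mask, threshold=10.0)


# ---------------------------------------------------------------- bundles

@dataclass
class ExperimentBundle:
    """Lazily generated full-factorial study: labels plus per-cube seeds."""

    design: StudyDesign
    labels: pd.DataFrame
    entries: list            # (index, sample_id, side, seed)
    kinetics: KineticParams
    spectral: SpectralForwardParams
    wavelengths_nm: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cubes(self) -> int:
        return len(self.entries)

    def load_cube(self, i: int, noise: bool = True
                  ) -> tuple[Hypercube, CalibrationFrames, RoiMask]:
        _, sample_id, side, seed = self.entries[i]
        row = self.labels.loc[self.labels.sample_id == sample_id].iloc[0]
        lab = SpoilageLabels(row.tvbn, row.tvc, int(row.temperature_c), int(row.day))
        return generate_fillet_cube(
            lab, self.spectral, self.kinetics, self.design.image_shape,
            self.wavelengths_nm, seed=seed, sample_id=sample_id, side=side,
            noise=noise)

    def labels_for(self, sample_id: str) -> SpoilageLabels:
        row = self.labels.loc[self.labels.sample_id == sample_id].iloc[0]
        return SpoilageLabels(row.tvbn, row.tvc, int(row.temperature_c), int(row.day))

    def write(self, out_dir) -> None:
        """Materialise the bundle layout: cubes/, refs/, labels.csv, manifest."""
        out = Path(out_dir)
        (out / "cubes").mkdir(parents=True, exist_ok=True)
        (out / "refs").mkdir(exist_ok=True)
        self.labels.to_csv(out / "labels.csv", index=False)
        for i, (_, sample_id, side, seed) in enumerate(self.entries):
            cube, refs, _ = self.load_cube(i)
            write_cube(cube, out / "cubes" / f"{sample_id}_{side}", dialect="envi")
            np.savez(out / "refs" / f"{sample_id}_{side}.npz",
                     white=refs.white, dark=refs.dark)
        manifest = {
            "design": {
                "temperatures": list(self.design.temperatures),
                "days": list(self.design.days),
                "replicates": self.design.replicates,
                "sides": list(self.design.sides),
                "image_shape": list(self.design.image_shape),
                "seed": self.design.seed,
            },
            "n_samples": self.n_samples,
            "n_cubes": self.n_cubes,
            "entry_seeds": [int(e[3]) for e in self.entries],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def generate_experiment(
    design: StudyDesign = StudyDesign(),
    kinetics: KineticParams | None = None,
    spectral: SpectralForwardParams | None = None,
    seed: int | None = None,
) -> ExperimentBundle:
    """Full-factorial synthetic study with bilateral cubes per sample.

    Cube pixel data are generated lazily (``bundle.load_cube``) from per-entry
    seeds derived from the master seed, so design-level bookkeeping is cheap
    even for the full 480-sample / 960-cube layout.
    """
    kinetics = kinetics or default_kinetics()
    spectral = spectral or SpectralForwardParams()
    master = design.seed if seed is None else seed
    labels = sample_labels(design, kinetics, seed=master)
    rng = np.random.default_rng([master, 0x5EED])
    entries = []
    for i, sample_id in enumerate(labels.sample_id):
        for side in design.sides:
            entries.append((len(entries), sample_id, side,
                            int(rng.integers(2 ** 31))))
    return ExperimentBundle(design, labels, entries, kinetics, spectral,
                            default_wavelength_grid())


# ---------------------------------------------------------------- planted

def planted_signal_dataset(
    n_samples: int = 200,
    n_bands: int = 60,
    planted_bands: tuple[int, ...] = (5, 17, 29, 41, 53),
    snr: float = 10.0,
    seed: int = 0,
    n_factors: int = 4,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Design with known informative bands for selector/attention tests.

    The planted columns are independent unit-variance signals; the response
    is a linear combination of them plus a mild quadratic term.  All other
    columns are mutually collinear distractors built from a few shared latent
    factors, conditionally independent of y.  ``snr`` sets the ratio of
    signal variance to response-noise variance.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    planted = np.asarray(planted_bands, dtype=int)
    if np.any(planted < 0) or np.any(planted >= n_bands):
        raise ValueError("planted bands must lie inside the band grid")
    rng = np.random.default_rng(seed)
    X = np.empty((n_samples, n_bands))
    factors = rng.standard_normal((n_samples, n_factors))
    mix = rng.standard_normal((n_factors, n_bands))
    X[:] = factors @ mix + 0.25 * rng.standard_normal((n_samples, n_bands))
    Xp = rng.standard_normal((n_samples, planted.size))
    X[:, planted] = Xp
    beta = rng.uniform(0.8, 1.5, size=planted.size) * rng.choice([-1, 1], planted.size)
    signal = Xp @ beta + 0.3 * ((Xp[:, 0] ** 2) - 1.0)
    noise_sd = float(np.std(signal)) / np.sqrt(snr)
    y = signal + rng.normal(0.0, noise_sd, size=n_samples)
    truth = {"planted_bands": planted, "beta": beta, "noise_sd": noise_sd}
    return X, y, truth
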