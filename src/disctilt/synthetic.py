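"""Synthetic traces, B-scan images and cohorts for end-to-end testing.

Three generators mirror the three kinds of study data:

* :func:`simulate_trace` — sine-shaped RPE traces with additive Gaussian
  plotting noise and optional low-order drift, emulating manually marked
  points on a circle-scan B-image;
* :func:`render_bscan` — a Gaussian-profile bright band painted along a
  trace, a minimal stand-in for the hyperreflective RPE band of a B-scan;
* :func:`simulate_cohort` — per-eye records (amplitude, ovality ratio,
  refraction, axial length, body height, duplicate rater measurements)
  with a specified Spearman correlation structure, via a Gaussian copula
  with the rank-to-linear conversion ``r = 2*sin(pi*rho_s/6)``.

Cohort defaults reproduce the study conditions of a young adult, mostly
myopic cohort of 126 right eyes: amplitude 37.0 +/- 17.5 px, ovality
ratio 0.89 +/- 0.11, spherical equivalent -4.71 +/- 3.41 D, axial length
25.4 +/- 1.5 mm, height 167.6 +/- 8.4 cm, and amplitude rank correlations
(-0.59 ovality, -0.29 refraction, 0.11 axial length, -0.39 height) with
refraction/axial-length correlation -0.82. Rater noise SDs (1.1 px within
rater, 5.0 px for the second rater) follow from the variance-components
identity ``sigma_e = sigma_s * sqrt((1 - ICC)/ICC)`` at the reference
reliabilities (0.996 intra, 0.959 inter).

All generators are pure functions of their spec (seeds explicit, no
global random state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import BScanImage, RPETrace, save_trace

__all__ = [
    "TraceSimSpec",
    "CohortSimSpec",
    "simulate_trace",
    "render_bscan",
    "simulate_cohort",
    "write_fixture_dir",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class TraceSimSpec:
    """Parameters of one synthetic RPE trace.

    ``b_true=None`` means one period per scan circumference
    (``2*pi/scan_width``), the anatomical expectation. The default phase
    ``pi/2`` puts the RPE high (small y) at both nasal scan ends and low
    in the temporal middle. ``noise_sd`` models manual plotting jitter;
    ``drift_amplitude`` adds a centered quadratic drift for traces that
    are not purely sinusoidal.
    """

    a_true: float = 37.0
    b_true: float | None = None
    c_true: float = np.pi / 2
    noise_sd: float = 2.0
    drift_amplitude: float = 0.0
    n_points: int = 64
    scan_width: int = 1024
    baseline: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        if self.scan_width < 2:
            raise ValueError("scan_width must be >= 2")


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters of a synthetic per-eye cohort.

    Target correlations are Spearman rank correlations; the latent
    Gaussian copula uses the conversion ``r = 2*sin(pi*rho/6)``.
    Unspecified covariate-covariate rank correlations follow a
    single-factor structure (products of the amplitude correlations)
    except the refraction/axial-length pair, which is set explicitly.
    """

    n_eyes: int = 126
    amplitude_mean: float = 37.0
    amplitude_sd: float = 17.5
    ovality_mean: float = 0.89
    ovality_sd: float = 0.11
    se_mean: float = -4.71
    se_sd: float = 3.41
    al_mean: float = 25.4
    al_sd: float = 1.5
    height_mean: float = 167.6
    height_sd: float = 8.4
    rho_amp_ovality: float = -0.59
    rho_amp_se: float = -0.29
    rho_amp_al: float = 0.11
    rho_amp_height: float = -0.39
    rho_se_al: float = -0.82
    rater_error_sd: float = 5.0
    intra_error_sd: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_amp_ovality", "rho_amp_se", "rho_amp_al", "rho_amp_height", "rho_se_al"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"|{name}| must be < 1")
        for name in ("amplitude_sd", "ovality_sd", "se_sd", "al_sd", "height_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_eyes < 3:
            raise ValueError("n_eyes must be >= 3")

    def spearman_target(self) -> np.ndarray:
        """Target 5x5 Spearman matrix (amplitude, ovality, SE, AL, height)."""
        amp = np.array(
            [self.rho_amp_ovality, self.rho_amp_se, self.rho_amp_al, self.rho_amp_height]
        )
        rho = np.eye(5)
        rho[0, 1:] = rho[1:, 0] = amp
        for i in range(4):
            for j in range(i + 1, 4):
                rho[i + 1, j + 1] = rho[j + 1, i + 1] = amp[i] * amp[j]
        rho[2, 3] = rho[3, 2] = self.rho_se_al  # refraction vs axial length
        return rho


def simulate_trace(spec: TraceSimSpec) -> RPETrace:
    """Draw one synthetic RPE trace: sine + drift + Gaussian noise.

    Deterministic under ``spec.seed``. ``x`` is a uniform grid of
    ``n_points`` over ``[0, scan_width - 1]``.
    """
    rng = np.random.default_rng(spec.seed)
    b = spec.b_true if spec.b_true is not None else TWO_PI / spec.scan_width
    x = np.linspace(0.0, spec.scan_width - 1.0, spec.n_points)
    drift = spec.drift_amplitude * (2.0 * x / spec.scan_width - 1.0) ** 2
    y = (
        spec.baseline
        + spec.a_true * np.sin(b * x - spec.c_true)
        + drift
        + rng.normal(0.0, spec.noise_sd, size=x.size)
    )
    return RPETrace(
        x=x, y=np.clip(y, 0.0, None), scan_width=spec.scan_width, eye_id=f"sim{spec.seed}"
    )


def render_bscan(
    trace: RPETrace,
    band_sigma: float = 3.0,
    peak: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_rows: int = 256,
) -> BScanImage:
    """Paint a Gaussian-profile bright band along a trace.

    The trace is linearly interpolated to every column of the scan; per
    column the band intensity is ``peak * exp(-(r - y)^2 / (2 sigma^2))``
    plus optional background Gaussian noise (clipped at zero). The band
    center is independent of the seed; only the noise field varies.
    """
    if np.any(trace.y < 0) or np.any(trace.y > n_rows - 1):
        raise ValueError("trace lies outside the image rows")
    rng = np.random.default_rng(seed)
    cols = np.arange(trace.scan_width, dtype=float)
    yc = np.interp(cols, trace.x, trace.y)
    rows = np.arange(n_rows, dtype=float)
    img = peak * np.exp(-((rows[:, None] - yc[None, :]) ** 2) / (2.0 * band_sigma**2))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return BScanImage(pixels=np.clip(img, 0.0, None), provenance="synthetic")


def _check_psd(matrix: np.ndarray, labels: list[str]) -> None:
    if np.min(np.linalg.eigvalsh(matrix)) >= -1e-10:
        return
    # identify a pair whose removal restores feasibility, for the error message
    for i in range(matrix.shape[0]):
        for j in range(i + 1, matrix.shape[1]):
            trial = matrix.copy()
            trial[i, j] = trial[j, i] = 0.0
            if np.min(np.linalg.eigvalsh(trial)) >= -1e-10:
                raise ValueError(
                    "target correlation matrix is not positive semidefinite; "
                    f"the ({labels[i]}, {labels[j]}) entry is infeasible with the others"
                )
    raise ValueError("target correlation matrix is not positive semidefinite")


_COLS = ["amplitude_true", "ovality_ratio", "spherical_equivalent", "axial_length", "body_height"]


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw a per-eye cohort table with the target rank-correlation structure.

    Latent standard-normal vectors are drawn with linear correlation
    ``2*sin(pi*rho_s/6)`` (which yields Spearman correlation ``rho_s``
    for a Gaussian copula), then scaled to the stated marginal means and
    SDs. The ovality ratio is truncated to be positive. Duplicate
    measurements are emitted as ``amplitude_rater1`` and
    ``amplitude_rater1_repeat`` (same rater, error SD ``intra_error_sd``)
    and ``amplitude_rater2`` (error SD ``rater_error_sd``);
    ``amplitude_mean`` averages the two raters. ``axis_class`` is
    'horizontal' when the ovality ratio exceeds 1, else 'vertical' (the
    modified-ratio construction places vertical discs below 1).
    """
    rho_s = spec.spearman_target()
    pear = 2.0 * np.sin(np.pi * rho_s / 6.0)
    np.fill_diagonal(pear, 1.0)
    _check_psd(pear, _COLS)
    rng = np.random.default_rng(spec.seed)
    # Cholesky with tiny jitter tolerance for semi-definite targets
    try:
        chol = np.linalg.cholesky(pear)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(pear + 1e-10 * np.eye(5))
    z = rng.standard_normal((spec.n_eyes, 5)) @ chol.T

    amp = spec.amplitude_mean + spec.amplitude_sd * z[:, 0]
    ovality = np.clip(spec.ovality_mean + spec.ovality_sd * z[:, 1], 1e-6, None)
    se = spec.se_mean + spec.se_sd * z[:, 2]
    al = spec.al_mean + spec.al_sd * z[:, 3]
    height = spec.height_mean + spec.height_sd * z[:, 4]

    r1a = amp + rng.normal(0.0, spec.intra_error_sd, spec.n_eyes)
    r1b = amp + rng.normal(0.0, spec.intra_error_sd, spec.n_eyes)
    r2 = amp + rng.normal(0.0, spec.rater_error_sd, spec.n_eyes)

    return pd.DataFrame(
        {
            "eye_id": [f"eye{i:03d}" for i in range(spec.n_eyes)],
            "amplitude_rater1": r1a,
            "amplitude_rater1_repeat": r1b,
            "amplitude_rater2": r2,
            "amplitude_mean": (r1a + r2) / 2.0,
            "amplitude_true": amp,
            "ovality_ratio": ovality,
            "axis_class": np.where(ovality > 1.0, "horizontal", "vertical"),
            "spherical_equivalent": se,
            "axial_length": al,
            "body_height": height,
        }
    )


def write_fixture_dir(
    path: str | Path,
    n_eyes: int = 10,
    seed: int = 0,
    trace_spec: TraceSimSpec | None = None,
    cohort_spec: CohortSimSpec | None = None,
    with_images: bool = True,
) -> Path:
    """Emit a complete toy dataset directory: traces/, images/, cohort.csv.

    Per-eye trace amplitudes/phases are drawn from the cohort defaults;
    truth values are recorded in ``truth.csv`` for test oracles.
    """
    import imageio.v3 as iio

    path = Path(path)
    (path / "traces").mkdir(parents=True, exist_ok=True)
    if with_images:
        (path / "images").mkdir(exist_ok=True)
    base = trace_spec or TraceSimSpec()
    cspec = cohort_spec or CohortSimSpec(n_eyes=max(n_eyes, 3), seed=seed)
    cohort = simulate_cohort(replace(cspec, n_eyes=max(n_eyes, 3), seed=seed)).iloc[:n_eyes]
    cohort.to_csv(path / "cohort.csv", index=False)

    rng = np.random.default_rng(seed + 1)
    rows = []
    for i in range(n_eyes):
        a = float(np.clip(cohort["amplitude_true"].iloc[i], 1.0, 100.0))
        c = float(rng.uniform(0, TWO_PI))
        spec_i = replace(base, a_true=a, c_true=c, seed=seed + 100 + i)
        tr = simulate_trace(spec_i)
        tr = RPETrace(tr.x, tr.y, tr.scan_width, eye_id=f"eye{i:03d}")
        save_trace(tr, path / "traces" / f"eye{i:03d}.csv")
        if with_images:
            img = render_bscan(tr, noise_sd=5.0, seed=seed + 200 + i)
            iio.imwrite(
                path / "images" / f"eye{i:03d}.png",
                np.clip(img.pixels, 0, 255).astype(np.uint8),
            )
        rows.append({"eye_id": f"eye{i:03d}", "a_true": a, "c_true": c})
    pd.DataFrame(rows).to_csv(path / "truth.csv", index=False)
    return path
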