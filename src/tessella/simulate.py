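"""Synthetic fundus photographs and cohorts.

No public dataset of graded tessellated-fundus photographs exists, so the
package ships a generator that emulates the mechanism the indices are
meant to capture: with a thick choroid, RPE/choroidal melanin hides the
large choroidal vessels and the posterior pole looks uniformly orange;
as the choroid thins the vessels show through, adding red, low-green
streaks — a tessellated appearance.

The renderer is deliberately schematic, not photorealistic:

* a uniform RPE background;
* a layer of roughly horizontal sinuous choroidal vessel bands,
  alpha-blended at an opacity proportional to a visibility parameter
  ``v in [0, 1]``;
* dark retinal arcade vessels, an optic disc and a macular pigment spot
  drawn strictly outside the analysis disk (the real analysis region is
  chosen to avoid them, so they must not contaminate the ROI);
* additive Gaussian sensor noise, clipped to [0, 255].

Visibility is a linear decreasing function of choroidal thickness, so a
cohort whose thickness spans the configured range produces the full sweep
from non-tessellated to strongly tessellated eyes.  Cohort covariates are
drawn from truncated normals at the configured moments; defaults emulate a
healthy young myopic cohort (n = 100, axial length 25.3 ± 1.4 mm,
subfoveal choroidal thickness 261.8 ± 84.9 µm, Spearman(AL, SFCT) ≈ −0.38).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import truncnorm

from .errors import ConfigError
from .image import FundusImage, Landmarks, write_landmarks_csv
from .indices import Grade

__all__ = [
    "RenderConfig",
    "CohortConfig",
    "SyntheticEye",
    "SyntheticCohort",
    "render_fundus",
    "visibility_from_ct",
    "generate_cohort",
]


@dataclass(frozen=True)
class RenderConfig:
    """Parameters of one rendered fundus photograph.

    Colors are 8-bit RGB triplets.  ``visibility`` scales the opacity of
    the choroidal vessel layer; 0 hides it entirely, 1 blends it at
    ``vessel_opacity``.
    """

    width: int = 800
    height: int = 600
    fovea: tuple[int, int] = (600, 300)
    disc_center: tuple[int, int] = (200, 300)
    background: tuple[float, float, float] = (180.0, 125.0, 75.0)
    vessel_color: tuple[float, float, float] = (200.0, 70.0, 60.0)
    n_vessels: int = 14
    vessel_width_range: tuple[float, float] = (8.0, 18.0)
    vessel_slope_sd: float = 0.05  # orientation scatter around horizontal
    vessel_wave_amplitude: float = 12.0  # px, sinuous wander of each band
    vessel_opacity: float = 0.8  # blend opacity at full visibility
    visibility: float = 0.5
    noise_sd: float = 2.0
    roi_diameter: float = 250.0  # kept clear of arcades/disc/macula
    seed: int = 0

    def __post_init__(self) -> None:
        for c in (*self.background, *self.vessel_color):
            if not (0 <= c <= 255):
                raise ConfigError("colors must lie in [0, 255]")
        if not (0.0 <= self.visibility <= 1.0):
            raise ConfigError(f"visibility must be in [0, 1], got {self.visibility}")
        if self.noise_sd < 0:
            raise ConfigError("noise SD must be >= 0")
        for name, (x, y) in (("fovea", self.fovea), ("disc_center", self.disc_center)):
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ConfigError(f"{name} {(x, y)} outside {self.width}x{self.height}")


@dataclass(frozen=True)
class CohortConfig:
    """Generative model of a cohort of eyes.

    Defaults emulate a 100-eye healthy young cohort: age 25.8 ± 3.9 y,
    axial length (AL) 25.3 ± 1.4 mm, spherical equivalent tied to AL at
    about −2.3 D/mm, subfoveal choroidal thickness (SFCT) 261.8 ± 84.9 µm
    decreasing in AL with target Spearman −0.382, nasal thickness (NCT)
    offset −17.8 µm from SFCT.  Tessellation visibility maps linearly from
    the thickness range; grades derive from visibility thresholds, and the
    three raters independently misgrade one step at ``rater_error_rate``.
    """

    n: int = 100
    age_mean: float = 25.8
    age_sd: float = 3.9
    age_range: tuple[float, float] = (22.0, 39.0)
    al_mean: float = 25.3
    al_sd: float = 1.4
    al_range: tuple[float, float] = (22.4, 30.4)
    se_slope_per_mm: float = -2.3  # diopters of myopia per mm of axial length
    se_mean: float = -4.6
    se_noise_sd: float = 1.0
    se_range: tuple[float, float] = (-13.0, 0.0)
    sfct_mean: float = 261.8
    sfct_sd: float = 84.9
    sfct_range: tuple[float, float] = (76.0, 500.0)
    target_rho_al_sfct: float = -0.382  # Spearman, realized within sampling noise
    nct_offset: float = -17.8
    nct_noise_sd: float = 30.0
    nct_range: tuple[float, float] = (76.0, 460.0)
    ct_visibility_range: tuple[float, float] = (76.0, 500.0)  # [ct_lo, ct_hi]
    grade_thresholds: tuple[float, float] = (0.60, 0.76)  # on v: NT | WT | ST
    rater_error_rate: float = 0.115  # expected Fleiss kappa ~ 0.67 at n = 100
    background_jitter_sd: float = 6.0  # per-eye RPE pigmentation scatter (RGB units)
    render: RenderConfig = field(default_factory=RenderConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 6:
            raise ConfigError("need n >= 6 so every grade is attainable")
        for lo, hi in (self.age_range, self.al_range, self.se_range,
                       self.sfct_range, self.nct_range, self.ct_visibility_range):
            if not lo < hi:
                raise ConfigError(f"range ({lo}, {hi}) must be ordered")
        if not (0.0 <= self.rater_error_rate <= 1.0):
            raise ConfigError("rater error rate must be a probability")
        t1, t2 = self.grade_thresholds
        if not (0.0 < t1 < t2 < 1.0):
            raise ConfigError("grade thresholds must satisfy 0 < t1 < t2 < 1")


def visibility_from_ct(ct: float, ct_lo: float, ct_hi: float) -> float:
    """Choroidal-vessel visibility from choroidal thickness.

    Linear and strictly decreasing on ``[ct_lo, ct_hi]``: a choroid of
    thickness ``ct_hi`` (thick) fully hides the vessels (v = 0), one of
    ``ct_lo`` (thin) exposes them fully (v = 1).  Clamped outside.
    """
    if not ct_lo < ct_hi:
        raise ValueError(f"need ct_lo < ct_hi, got {ct_lo}, {ct_hi}")
    return float(np.clip((ct_hi - ct) / (ct_hi - ct_lo), 0.0, 1.0))


def _band_mask(
    shape: tuple[int, int], center_y: np.ndarray, half_width: float
) -> tuple[int, int, np.ndarray]:
    """Mask of ``|y - center_y(x)| <= half_width`` restricted to its row span."""
    h, w = shape
    r0 = max(0, int(np.floor(center_y.min() - half_width)))
    r1 = min(h, int(np.ceil(center_y.max() + half_width)) + 1)
    if r0 >= r1:
        return 0, 0, np.zeros((0, w), dtype=bool)
    ys = np.arange(r0, r1, dtype=np.float64)[:, None]
    return r0, r1, np.abs(ys - center_y[None, :]) <= half_width


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float):
    h, w = shape
    ys = np.arange(h, dtype=np.float64)[:, None]
    xs = np.arange(w, dtype=np.float64)[None, :]
    return (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius * radius


def render_fundus(config: RenderConfig, eye_id: str = "synthetic") -> FundusImage:
    """Render one synthetic fundus photograph; same seed, same raster."""
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    # float32 buffer: plenty of headroom for 8-bit output, and the noise
    # pass over H x W x 3 dominates the render time
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = np.asarray(config.background, dtype=np.float32)

    # choroidal vessel layer: union of sinuous bands, blended at opacity ~ v
    xs = np.arange(w, dtype=np.float64)
    layer = np.zeros((h, w), dtype=bool)
    wlo, whi = config.vessel_width_range
    for _ in range(config.n_vessels):
        y0 = rng.uniform(0, h)
        slope = rng.normal(0.0, config.vessel_slope_sd)
        amp = rng.uniform(0.3, 1.0) * config.vessel_wave_amplitude
        wavelength = rng.uniform(0.3, 0.9) * w
        phase = rng.uniform(0, 2 * np.pi)
        width = rng.uniform(wlo, whi)
        cy = y0 + slope * (xs - w / 2.0) + amp * np.sin(2 * np.pi * xs / wavelength + phase)
        r0, r1, band = _band_mask((h, w), cy, width / 2.0)
        layer[r0:r1] |= band
    alpha = np.float32(config.visibility * config.vessel_opacity)
    if alpha > 0:
        vessel = np.asarray(config.vessel_color, dtype=np.float32)
        img[layer] += alpha * (vessel - img[layer])

    # keep-out disk: analysis region between fovea and disc must only see
    # background + choroidal layer + noise
    mx = (config.fovea[0] + config.disc_center[0]) / 2.0
    my = (config.fovea[1] + config.disc_center[1]) / 2.0
    keep_out = _disk_mask((h, w), (mx, my), config.roi_diameter / 2.0 + 2.0)

    # dark retinal arcade vessels (parabolic branches from the disc)
    arcade_color = np.array([120.0, 35.0, 30.0], dtype=np.float32)
    arcades = np.zeros((h, w), dtype=bool)
    dx0, dy0 = config.disc_center
    for sign in (-1.0, 1.0):
        curv = rng.uniform(0.0008, 0.0014)
        offset = rng.uniform(40.0, 60.0)
        width = rng.uniform(8.0, 12.0)
        cy = dy0 + sign * (offset + curv * (xs - dx0) ** 2)
        r0, r1, band = _band_mask((h, w), cy, width / 2.0)
        arcades[r0:r1] |= band
    arcades &= ~keep_out
    img[arcades] = arcade_color

    # optic disc (bright) and macular pigment spot (dark), outside the ROI
    disc = _disk_mask((h, w), (dx0, dy0), 52.0) & ~keep_out
    img[disc] = np.array([235.0, 190.0, 150.0], dtype=np.float32)
    macula = _disk_mask((h, w), config.fovea, 38.0) & ~keep_out
    img[macula] += np.float32(0.35) * (
        np.array([140.0, 90.0, 55.0], dtype=np.float32) - img[macula]
    )

    if config.noise_sd > 0:
        noise = rng.standard_normal(size=img.shape, dtype=np.float32)
        img += np.float32(config.noise_sd) * noise
    np.clip(img, 0, 255, out=img)
    np.rint(img, out=img)
    return FundusImage(pixels=img.astype(np.uint8), eye_id=eye_id)


@dataclass(frozen=True)
class SyntheticEye:
    """Ground truth for one simulated eye (indices not yet computed)."""

    eye_id: str
    age: float
    axial_length: float
    spherical_equivalent: float
    sfct: float
    nct: float
    visibility: float
    true_grade: Grade
    rater_grades: tuple[Grade, Grade, Grade]


@dataclass
class SyntheticCohort:
    """A generated cohort: ground-truth table, rendered images, landmarks."""

    eyes: list
    images: dict  # eye_id -> FundusImage
    landmarks: dict  # eye_id -> Landmarks
    config: CohortConfig

    def cohort_frame(self) -> pd.DataFrame:
        rows = [
            {
                "eye_id": e.eye_id,
                "age": e.age,
                "axial_length": e.axial_length,
                "spherical_equivalent": e.spherical_equivalent,
                "sfct": e.sfct,
                "nct": e.nct,
                "grade_rater1": str(e.rater_grades[0]),
                "grade_rater2": str(e.rater_grades[1]),
                "grade_rater3": str(e.rater_grades[2]),
            }
            for e in self.eyes
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        """Write per-eye PNGs, ``landmarks.csv`` and ``cohort.csv``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for eid, im in self.images.items():
            Image.fromarray(im.pixels, mode="RGB").save(out / f"{eid}.png")
        write_landmarks_csv(out / "landmarks.csv", self.landmarks)
        self.cohort_frame().to_csv(out / "cohort.csv", index=False)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _grade_from_v(v: float, thresholds: tuple[float, float]) -> Grade:
    t1, t2 = thresholds
    if v < t1:
        return Grade.NT
    if v < t2:
        return Grade.WT
    return Grade.ST


def _rater_grades(rng, true: Grade, error_rate: float) -> tuple[Grade, Grade, Grade]:
    """Three independent gradings; each misgrades one step at ``error_rate``.

    A draw where all three raters disagree has no majority; such a cohort
    never arises in practice, so the eye's gradings are redrawn (the redraw
    consumes the same substream, keeping the cohort deterministic).
    """
    while True:
        grades = []
        for _ in range(3):
            g = int(true)
            if rng.random() < error_rate:
                if g == 0:
                    g = 1
                elif g == 2:
                    g = 1
                else:
                    g = g + (1 if rng.random() < 0.5 else -1)
            grades.append(Grade(g))
        if any(grades.count(g) >= 2 for g in grades):
            return tuple(grades)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under the configured model.

    Covariates come from truncated normals; SFCT decreases in axial length
    with Gaussian scatter calibrated so the realized Spearman(AL, SFCT)
    tracks ``target_rho_al_sfct`` (the normal-score transform
    ``rho_pearson = 2 sin(pi rho_s / 6)`` sets the linear coefficient);
    NCT is SFCT plus a noisy offset; visibility, grades and images follow.
    A single master seed spawns one substream per eye plus one for the
    covariates, so any eye's data is reproducible in isolation.
    """
    cfg = config if config is not None else CohortConfig()
    master = np.random.SeedSequence(cfg.seed)
    cov_ss, *eye_ss = master.spawn(cfg.n + 1)
    rng = np.random.default_rng(cov_ss)

    n = cfg.n
    age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, size=n)
    al = _truncated_normal(rng, cfg.al_mean, cfg.al_sd, *cfg.al_range, size=n)

    se = cfg.se_mean + cfg.se_slope_per_mm * (al - cfg.al_mean)
    se = se + rng.normal(0.0, cfg.se_noise_sd, size=n)
    se = np.clip(se, *cfg.se_range)

    # Spearman -> Pearson for bivariate normal scores
    rho_p = 2.0 * np.sin(np.pi * cfg.target_rho_al_sfct / 6.0)
    beta = rho_p * cfg.sfct_sd / cfg.al_sd
    eps_sd = cfg.sfct_sd * np.sqrt(max(0.0, 1.0 - rho_p**2))
    sfct = cfg.sfct_mean + beta * (al - cfg.al_mean) + rng.normal(0.0, eps_sd, size=n)
    sfct = np.clip(sfct, *cfg.sfct_range)

    nct = sfct + cfg.nct_offset + rng.normal(0.0, cfg.nct_noise_sd, size=n)
    nct = np.clip(nct, *cfg.nct_range)

    ct_lo, ct_hi = cfg.ct_visibility_range
    width = len(str(n))
    eyes, images, landmarks = [], {}, {}
    for i in range(n):
        eid = f"eye{i + 1:0{width}d}"
        eye_rng = np.random.default_rng(eye_ss[i])
        v = visibility_from_ct(float(sfct[i]), ct_lo, ct_hi)
        true = _grade_from_v(v, cfg.grade_thresholds)
        # per-eye fundus pigmentation: independent of choroidal thickness,
        # which is what keeps index-thickness correlations away from +-1
        bg = np.clip(
            np.asarray(cfg.render.background)
            + eye_rng.normal(0.0, cfg.background_jitter_sd, size=3),
            0.0, 255.0,
        )
        raters = _rater_grades(eye_rng, true, cfg.rater_error_rate)
        render_seed = int(eye_ss[i].generate_state(1)[0] & 0x7FFFFFFF)
        rc = replace(
            cfg.render, background=tuple(bg), visibility=v, seed=render_seed
        )
        images[eid] = render_fundus(rc, eye_id=eid)
        landmarks[eid] = Landmarks(fovea=rc.fovea, disc_center=rc.disc_center)
        eyes.append(
            SyntheticEye(
                eye_id=eid,
                age=float(age[i]),
                axial_length=float(al[i]),
                spherical_equivalent=float(se[i]),
                sfct=float(sfct[i]),
                nct=float(nct[i]),
                visibility=v,
                true_grade=true,
                rater_grades=raters,
            )
        )
    return SyntheticCohort(eyes=eyes, images=images, landmarks=landmarks, config=cfg)
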