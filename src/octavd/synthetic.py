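"""Synthetic en face angiograms and eye-level cohorts with known truth.

Real OCTA studies of birdshot chorioretinopathy (BCR) rest on private
clinical images, so every downstream stage here is exercised against
synthetic data with exact ground truth:

* **Images** — a branching vessel network grown inward from the image
  border, kept out of a central avascular disk (the FAZ), rendered at two
  intensity levels and degraded with additive background noise,
  multiplicative speckle, and a radial brightness falloff toward the
  periphery.  The binary vessel mask, the FAZ polygon and the exact
  foreground fraction are returned alongside the image.
* **Cohorts** — per-eye outcome tables whose group means/SDs, sample
  sizes, covariate effects and within-patient (inter-eye) correlation are
  fully specified.  Defaults reproduce the summary statistics of a
  representative BCR case-control cohort (53 BCR eyes of 28 patients vs
  110 control eyes of 59 patients).

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .image import EnFaceImage, PolygonROI, VesselMask
from .register import SimilarityTransform, warp

__all__ = [
    "ParameterError",
    "GenerationError",
    "ImageParams",
    "SyntheticImageTruth",
    "generate_vessel_image",
    "GroupSpec",
    "CohortSpec",
    "generate_cohort",
    "reference_cohort_spec",
    "reference_covariate_effects",
    "LongitudinalPair",
    "generate_longitudinal_pair",
    "LongitudinalSpec",
    "generate_longitudinal_deltas",
    "reference_longitudinal_spec",
    "METRICS",
]

METRICS = ("whole_vd", "extrafaz_vd", "faz_area_pct")


class ParameterError(ValueError):
    """Invalid generator parameters."""


class GenerationError(RuntimeError):
    """Generation could not satisfy its target within bounded effort."""


# ---------------------------------------------------------------------------
# Angiogram generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageParams:
    """Knobs of the synthetic angiogram generator.

    ``size`` is the square side in px (256 matches the central crop of a
    512-px scan); ``target_density`` is the vessel foreground fraction
    the network grows toward; ``faz_radius`` the mean radius (px) of the
    avascular polygon.  Noise levels: ``additive_sd`` (gray levels of
    background noise), ``speckle_sd`` (relative SD of multiplicative
    speckle), ``falloff`` (fractional brightness loss at the corners).
    """

    size: int = 256
    mm_per_px: float = 6.0 / 512.0
    target_density: float = 0.33
    faz_radius: float = 20.0
    vessel_level: int = 200
    background_level: int = 50
    additive_sd: float = 8.0
    speckle_sd: float = 0.15
    falloff: float = 0.3
    plexus: str = "SCP"

    def validate(self) -> None:
        if self.size < 64:
            raise ParameterError("size must be >= 64 px")
        if not 0 < self.target_density <= 0.7:
            raise ParameterError("target_density must be in (0, 0.7]")
        if not 0 < self.faz_radius < self.size / 4:
            raise ParameterError("faz_radius must be < size/4")
        if not 0 <= self.background_level < self.vessel_level <= 255:
            raise ParameterError("need 0 <= background < vessel <= 255")
        if self.additive_sd < 0 or self.speckle_sd < 0 or not 0 <= self.falloff <= 1:
            raise ParameterError("noise levels must be non-negative, falloff in [0,1]")


@dataclass(frozen=True)
class SyntheticImageTruth:
    """Ground truth attached to a generated angiogram."""

    mask: VesselMask
    faz_polygon: PolygonROI
    true_whole_vd: float  # exact foreground fraction of mask, in [0, 1]
    params: ImageParams
    seed: int


_DISK_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    key = int(round(radius * 4))  # quarter-pixel granularity is plenty
    if key not in _DISK_CACHE:
        r = key / 4.0
        ri = int(math.ceil(r))
        yy, xx = np.mgrid[-ri:ri + 1, -ri:ri + 1]
        keep = yy ** 2 + xx ** 2 <= r ** 2
        _DISK_CACHE[key] = (yy[keep].copy(), xx[keep].copy())
    return _DISK_CACHE[key]


def _faz_polygon(rng: np.random.Generator, center: float,
                 radius: float, n_vertices: int = 24) -> PolygonROI:
    # Slightly irregular convex-ish outline, like a hand-traced FAZ.
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = radius * (1.0 + rng.uniform(-0.12, 0.12, size=n_vertices))
    verts = np.column_stack([center + r * np.cos(ang),
                             center + r * np.sin(ang)])
    return PolygonROI(verts)


def generate_vessel_image(params: ImageParams = ImageParams(), *,
                          seed: int = 0,
                          eye_id: str = "", visit_id: str = "",
                          max_strokes: int = 6000,
                          ) -> tuple[EnFaceImage, SyntheticImageTruth]:
    """Grow a branching vessel network and render it as an 8-bit angiogram.

    Vessel seeds start on the image border and random-walk inward with
    direction persistence, tapering thickness and occasional branching;
    growth batches are added until the foreground fraction reaches
    ``target_density``.  All pixels inside the FAZ polygon are cleared, so
    the mask never has foreground strictly inside the FAZ.  Rendering
    applies, in order: two-level intensity map, radial brightness falloff,
    multiplicative speckle, additive background noise, clip to [0, 255].

    Raises
    ------
    ParameterError
        On invalid parameters.
    GenerationError
        If the density target is unreachable within the bounded growth
        budget of ``max_strokes`` vessel strokes (names
        ``target_density``).
    """
    params.validate()
    if max_strokes < 1:
        raise ParameterError("max_strokes must be >= 1")
    rng = np.random.default_rng(seed)
    n = params.size
    center = (n - 1) / 2.0

    faz = _faz_polygon(rng, center, params.faz_radius)
    faz_raster = faz.raster((n, n))
    # Keep a small clearance band so strokes never clip the outline.
    yy, xx = np.mgrid[0:n, 0:n]
    faz_guard = (yy - center) ** 2 + (xx - center) ** 2 <= (
        1.25 * params.faz_radius + 2) ** 2

    mask = np.zeros((n, n), dtype=bool)
    total = n * n
    reached = _grow_network(mask, faz_guard, faz_raster, rng, n,
                            target=params.target_density,
                            max_strokes=max_strokes)
    mask[faz_raster] = False
    if not reached or mask.sum() / total < 0.9 * params.target_density:
        raise GenerationError(
            f"target_density={params.target_density} unreachable "
            f"within the bounded stroke budget")

    clean = np.where(mask, float(params.vessel_level),
                     float(params.background_level))
    if params.falloff > 0:
        r2 = ((yy - center) ** 2 + (xx - center) ** 2) / (2 * center ** 2)
        clean = clean * (1.0 - params.falloff * r2)
    img = clean
    if params.speckle_sd > 0:
        img = img * (1.0 + params.speckle_sd * rng.standard_normal((n, n)))
    if params.additive_sd > 0:
        img = img + params.additive_sd * rng.standard_normal((n, n))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    vmask = VesselMask(mask)
    truth = SyntheticImageTruth(
        mask=vmask, faz_polygon=faz,
        true_whole_vd=vmask.foreground_count / total,
        params=params, seed=seed)
    image = EnFaceImage(pixels, mm_per_px=params.mm_per_px,
                        plexus=params.plexus, eye_id=eye_id,
                        visit_id=visit_id)
    return image, truth


def _border_seed(rng: np.random.Generator,
                 n: int) -> tuple[float, float, float, float]:
    side = int(rng.integers(4))
    u = rng.uniform(0, n - 1)
    x, y = {0: (u, 0.0), 1: (u, n - 1.0), 2: (0.0, u), 3: (n - 1.0, u)}[side]
    inward = math.atan2((n - 1) / 2.0 - y, (n - 1) / 2.0 - x)
    return (x, y, inward + rng.normal(0, 0.4), rng.uniform(1.2, 2.6))


def _grow_network(mask: np.ndarray, faz_guard: np.ndarray,
                  excluded: np.ndarray,
                  rng: np.random.Generator, n: int, target: float,
                  max_strokes: int) -> bool:
    """Stamp random-walk vessel strokes until ``target`` density.

    Strokes start at the border pointing inward, branch occasionally, and
    stop at the frame edge or the avascular-zone guard band.  Density is
    tracked over pixels outside ``excluded`` (the avascular-zone raster,
    which is cleared afterwards), so the target refers to the *final*
    foreground fraction.  Returns True when that fraction reached the
    target within the stroke budget.
    """
    step = 2.0
    max_steps = 4 * n
    walks: list[tuple[float, float, float, float]] = []
    fg = int((mask & ~excluded).sum())
    total = mask.size
    for _ in range(max_strokes):
        if fg / total >= target:
            return True
        if not walks:
            walks.append(_border_seed(rng, n))
        x, y, ang, width = walks.pop()
        for _ in range(max_steps):
            oy, ox = _disk_offsets(width)
            py = np.clip(np.rint(y + oy).astype(int), 0, n - 1)
            px = np.clip(np.rint(x + ox).astype(int), 0, n - 1)
            # Edge clipping can fold several offsets onto one pixel;
            # deduplicate so the running count stays exact.
            flat = np.unique(py * n + px)
            py, px = flat // n, flat % n
            fg += int((~mask[py, px] & ~excluded[py, px]).sum())
            mask[py, px] = True
            if fg / total >= target:
                return True
            x += step * math.cos(ang)
            y += step * math.sin(ang)
            if not (0 <= x < n and 0 <= y < n):
                break
            if faz_guard[min(int(round(y)), n - 1), min(int(round(x)), n - 1)]:
                break  # vessels stop at the avascular zone
            ang += rng.normal(0, 0.22)
            width = max(0.9, width * 0.995)
            if rng.random() < 0.02 and len(walks) < 40:
                walks.append((x, y, ang + rng.choice([-1, 1]) *
                              rng.uniform(0.6, 1.2), width * 0.8))
    return fg / total >= target


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

TREATMENTS = ("none", "oral", "biologics", "dual")


@dataclass(frozen=True)
class GroupSpec:
    """Per-group cohort parameters: sample sizes, outcome moments and
    covariate distributions.

    ``metric_means``/``metric_sds`` map ``(plexus, metric)`` keys — e.g.
    ``("DCP", "whole_vd")`` — to the group mean/SD of that outcome.
    Covariates: age in years (truncated normal, 20-90), CST in µm
    (truncated 150-450), disease duration in months (truncated 0-300),
    treatment multinomial over (none, oral, biologics, dual).
    """

    name: str
    n_patients: int
    n_eyes: int
    metric_means: dict[tuple[str, str], float]
    metric_sds: dict[tuple[str, str], float]
    age_mean: float = 58.0
    age_sd: float = 15.0
    female_prob: float = 0.6
    logmar_mean: float = 0.04
    logmar_sd: float = 0.10
    cst_mean: float = 260.0
    cst_sd: float = 25.0
    duration_mean_months: float = 0.0
    duration_sd_months: float = 0.0
    treatment_probs: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    active_prob: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 1 or not (
                self.n_patients <= self.n_eyes <= 2 * self.n_patients):
            raise ParameterError(
                f"group {self.name}: need n_patients <= n_eyes <= 2*n_patients")
        if any(sd <= 0 for sd in self.metric_sds.values()):
            raise ParameterError(f"group {self.name}: metric SDs must be > 0")
        if abs(sum(self.treatment_probs) - 1.0) > 1e-9:
            raise ParameterError(f"group {self.name}: treatment probs must sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """Full two-group (or k-group) cohort recipe.

    ``rho`` is the within-patient inter-eye correlation of each outcome,
    implemented as a shared additive patient effect (compound symmetry):
    outcome = group mean + covariate effects + sd*(sqrt(rho)*b_patient +
    sqrt(1-rho)*e_eye) with b, e standard normal.

    ``covariate_effects`` maps ``(plexus, metric)`` to ``{covariate:
    slope}``; supported covariate names are ``age``, ``cst_um``,
    ``duration_months``, ``logmar``, ``active`` and treatment indicators
    ``treatment_none`` / ``treatment_oral`` / ``treatment_dual`` (current
    biologics is the reference category).  Effects are applied to
    *centered* covariates so that configured group means are preserved.
    """

    groups: tuple[GroupSpec, ...]
    rho: float = 0.5
    covariate_effects: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict)

    def validate(self) -> None:
        if not 0 <= self.rho < 1:
            raise ParameterError("rho must be in [0, 1)")
        for g in self.groups:
            g.validate()


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():  # resample tails; a few rounds suffice in practice
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(spec: CohortSpec, *, seed: int = 0) -> pd.DataFrame:
    """Draw an eye-level cohort table in long format.

    One row per (eye, plexus) with columns ``patient_id, eye, group, age,
    sex, logmar, cst_um, duration_months, treatment, active, plexus,
    whole_vd, extrafaz_vd, faz_area_pct``.  Eye counts match the recipe
    exactly: the first ``n_eyes - n_patients`` patients contribute both
    eyes (OD and OS), the rest one.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    frames = []
    for g in spec.groups:
        n_two = g.n_eyes - g.n_patients
        eyes_per_patient = [2] * n_two + [1] * (g.n_patients - n_two)

        age = _truncnorm(rng, g.age_mean, g.age_sd, 20, 90, g.n_patients)
        female = rng.random(g.n_patients) < g.female_prob
        duration = _truncnorm(rng, g.duration_mean_months,
                              g.duration_sd_months, 0, 300, g.n_patients)
        treatment = rng.choice(len(TREATMENTS), size=g.n_patients,
                               p=g.treatment_probs)

        rows = []
        for p_idx, n_eye in enumerate(eyes_per_patient):
            pid = f"{g.name}-{p_idx:03d}"
            for eye in ("OD", "OS")[:n_eye]:
                rows.append({
                    "patient_id": pid, "eye": eye, "group": g.name,
                    "age": age[p_idx], "sex": "F" if female[p_idx] else "M",
                    "duration_months": duration[p_idx],
                    "treatment": TREATMENTS[treatment[p_idx]],
                    "_p": p_idx,
                })
        eyes = pd.DataFrame(rows)
        n_e = len(eyes)
        eyes["logmar"] = rng.normal(g.logmar_mean, g.logmar_sd, n_e)
        eyes["cst_um"] = _truncnorm(rng, g.cst_mean, g.cst_sd, 150, 450, n_e)
        eyes["active"] = rng.random(n_e) < g.active_prob

        # Centered covariate design for the linear effects.  Centering at
        # the *realized* group mean (not the configured one, which differs
        # under asymmetric truncation) keeps each group's outcome mean
        # exactly at its configured value regardless of the effects.
        centered = {
            "age": eyes["age"] - eyes["age"].mean(),
            "cst_um": eyes["cst_um"] - eyes["cst_um"].mean(),
            "duration_months": (eyes["duration_months"]
                                - eyes["duration_months"].mean()),
            "logmar": eyes["logmar"] - eyes["logmar"].mean(),
            "active": (eyes["active"].astype(float)
                       - eyes["active"].astype(float).mean()),
        }
        for t in TREATMENTS:
            if t != "biologics":
                ind = (eyes["treatment"] == t).astype(float)
                centered[f"treatment_{t}"] = ind - ind.mean()

        metric_frames = []
        for plexus in ("SCP", "DCP"):
            sub = eyes.drop(columns="_p").copy()
            sub["plexus"] = plexus
            for metric in METRICS:
                key = (plexus, metric)
                mean = g.metric_means[key]
                sd = g.metric_sds[key]
                b = rng.standard_normal(g.n_patients)[eyes["_p"].to_numpy()]
                e = rng.standard_normal(n_e)
                val = mean + sd * (math.sqrt(spec.rho) * b
                                   + math.sqrt(1 - spec.rho) * e)
                for cov, beta in spec.covariate_effects.get(key, {}).items():
                    val = val + beta * centered[cov].to_numpy()
                sub[metric] = val
            metric_frames.append(sub)
        frames.append(pd.concat(metric_frames, ignore_index=True))
    return pd.concat(frames, ignore_index=True)


def reference_cohort_spec(*, covariate_effects: dict | None = None,
                          rho: float = 0.5) -> CohortSpec:
    """Cohort recipe matching a representative BCR case-control study.

    53 BCR eyes of 28 patients versus 110 age-matched control eyes of 59
    patients, with the published per-group means/SDs of the six outcomes
    (SCP/DCP x whole VD %, extra-FAZ VD %, FAZ area %) and covariate
    distributions (age, logMAR acuity, CST, disease duration, four-level
    treatment coding with biologics as reference).
    """
    bcr = GroupSpec(
        name="BCR", n_patients=28, n_eyes=53,
        metric_means={("SCP", "whole_vd"): 29.9, ("SCP", "extrafaz_vd"): 30.1,
                      ("SCP", "faz_area_pct"): 0.83,
                      ("DCP", "whole_vd"): 30.0, ("DCP", "extrafaz_vd"): 30.9,
                      ("DCP", "faz_area_pct"): 2.77},
        metric_sds={("SCP", "whole_vd"): 4.80, ("SCP", "extrafaz_vd"): 4.78,
                    ("SCP", "faz_area_pct"): 0.41,
                    ("DCP", "whole_vd"): 6.16, ("DCP", "extrafaz_vd"): 6.22,
                    ("DCP", "faz_area_pct"): 1.12},
        age_mean=60.04, age_sd=11.0, female_prob=19 / 28,
        logmar_mean=0.0717, logmar_sd=0.141,
        cst_mean=254.0, cst_sd=59.9,
        duration_mean_months=5.71 * 12, duration_sd_months=5.51 * 12,
        treatment_probs=(0.15, 0.40, 0.25, 0.20),
        active_prob=31 / 53)
    control = GroupSpec(
        name="control", n_patients=59, n_eyes=110,
        metric_means={("SCP", "whole_vd"): 33.2, ("SCP", "extrafaz_vd"): 33.4,
                      ("SCP", "faz_area_pct"): 0.83,
                      ("DCP", "whole_vd"): 39.1, ("DCP", "extrafaz_vd"): 39.9,
                      ("DCP", "faz_area_pct"): 2.17},
        metric_sds={("SCP", "whole_vd"): 4.40, ("SCP", "extrafaz_vd"): 4.43,
                    ("SCP", "faz_area_pct"): 0.35,
                    ("DCP", "whole_vd"): 3.45, ("DCP", "extrafaz_vd"): 3.50,
                    ("DCP", "faz_area_pct"): 0.75},
        age_mean=58.15, age_sd=16.2, female_prob=32 / 59,
        logmar_mean=0.0417, logmar_sd=0.0987,
        cst_mean=262.0, cst_sd=20.8)
    return CohortSpec(groups=(bcr, control), rho=rho,
                      covariate_effects=covariate_effects or {})


def reference_covariate_effects() -> dict[tuple[str, str], dict[str, float]]:
    """Published multivariable associations, usable as generating effects.

    Slopes per outcome: age (per year), CST (per µm), disease duration
    (per month), and the no-treatment-vs-biologics contrast.  When fed to
    :func:`generate_cohort` these act on centered covariates, so group
    means stay calibrated while the covariate share of variance adds on
    top of the configured residual SD.
    """
    return {
        ("SCP", "whole_vd"): {"duration_months": -0.16},
        ("SCP", "extrafaz_vd"): {"duration_months": -0.16},
        ("SCP", "faz_area_pct"): {"age": 0.011, "cst_um": -0.0020,
                                  "duration_months": -0.0099},
        ("DCP", "whole_vd"): {"age": -0.31, "cst_um": 0.027,
                              "duration_months": -0.18,
                              "treatment_none": -7.42},
        ("DCP", "extrafaz_vd"): {"age": -0.31, "cst_um": 0.026,
                                 "duration_months": -0.11,
                                 "treatment_none": -7.39},
        ("DCP", "faz_area_pct"): {"age": 0.050, "cst_um": -0.0053,
                                  "duration_months": -0.026,
                                  "treatment_none": 0.73},
    }


# ---------------------------------------------------------------------------
# Longitudinal generators
# ---------------------------------------------------------------------------

class LongitudinalPair(NamedTuple):
    baseline: EnFaceImage
    followup: EnFaceImage
    faz_baseline: PolygonROI
    faz_followup: PolygonROI  # scaled about centroid, then transformed
    transform: SimilarityTransform
    valid: np.ndarray  # in-frame mask of the transformed baseline


def generate_longitudinal_pair(image: EnFaceImage, faz: PolygonROI,
                               transform: SimilarityTransform, *,
                               faz_growth: float = 1.0,
                               noise_sd: float = 0.0,
                               seed: int = 0) -> LongitudinalPair:
    """Simulate a follow-up visit of ``image`` under a known misalignment.

    The follow-up is the similarity-transformed baseline with fresh
    additive Gaussian noise; the FAZ polygon is scaled by ``faz_growth``
    about its centroid (area scales by the square) and mapped into the
    follow-up frame.  The generating transform is returned exactly.

    Raises
    ------
    ParameterError
        If ``faz_growth < 1``.
    GenerationError
        If fewer than 25% of follow-up pixels remain in frame.
    """
    if faz_growth < 1.0:
        raise ParameterError("faz_growth must be >= 1")
    followup, valid = warp(image, transform)
    if valid.mean() < 0.25:
        raise GenerationError("transform moves the image (almost) fully "
                              "out of frame; < 25% valid pixels")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        px = followup.astype_float() + rng.normal(0, noise_sd, followup.shape)
        followup = followup.with_pixels(
            np.clip(np.rint(px), 0, 255).astype(np.uint8))
    faz_follow = PolygonROI(transform.apply(faz.scaled(faz_growth).vertices))
    return LongitudinalPair(image, followup, faz, faz_follow, transform, valid)


@dataclass(frozen=True)
class LongitudinalSpec:
    """Two-visit outcome recipe for a paired, clustered cohort.

    ``delta_means``/``delta_sds`` give the per-eye change (follow-up −
    baseline) distribution per ``(plexus, metric)``; ``rho`` is the
    within-patient correlation of the changes.
    """

    n_patients: int
    n_eyes: int
    baseline_means: dict[tuple[str, str], float]
    baseline_sds: dict[tuple[str, str], float]
    delta_means: dict[tuple[str, str], float]
    delta_sds: dict[tuple[str, str], float]
    rho: float = 0.5


def generate_longitudinal_deltas(spec: LongitudinalSpec, *,
                                 seed: int = 0) -> pd.DataFrame:
    """Draw per-eye two-visit outcomes and their paired differences.

    Returns one row per (eye, plexus) with ``patient_id``, baseline and
    follow-up values, and ``delta_<metric>`` columns ready for the
    clustered signed-rank test.
    """
    if not 0 <= spec.rho < 1:
        raise ParameterError("rho must be in [0, 1)")
    if not spec.n_patients <= spec.n_eyes <= 2 * spec.n_patients:
        raise ParameterError("need n_patients <= n_eyes <= 2*n_patients")
    rng = np.random.default_rng(seed)
    n_two = spec.n_eyes - spec.n_patients
    pat_of_eye = np.concatenate([np.repeat(np.arange(n_two), 2),
                                 np.arange(n_two, spec.n_patients)])
    eye_lab = ["OD", "OS"] * n_two + ["OD"] * (spec.n_patients - n_two)
    rows = pd.DataFrame({
        "patient_id": [f"L-{p:03d}" for p in pat_of_eye],
        "eye_id": [f"L-{p:03d}-{e}" for p, e in zip(pat_of_eye, eye_lab)],
        "eye": eye_lab,
    })
    frames = []
    for plexus in ("SCP", "DCP"):
        sub = rows.copy()
        sub["plexus"] = plexus
        for metric in METRICS:
            key = (plexus, metric)
            base = (spec.baseline_means[key]
                    + spec.baseline_sds[key] * rng.standard_normal(spec.n_eyes))
            b = rng.standard_normal(spec.n_patients)[pat_of_eye]
            e = rng.standard_normal(spec.n_eyes)
            delta = (spec.delta_means[key] + spec.delta_sds[key]
                     * (math.sqrt(spec.rho) * b
                        + math.sqrt(1 - spec.rho) * e))
            sub[f"baseline_{metric}"] = base
            sub[f"followup_{metric}"] = base + delta
            sub[f"delta_{metric}"] = delta
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def reference_longitudinal_spec() -> LongitudinalSpec:
    """Two-year follow-up recipe: 23 BCR eyes of 16 patients.

    Baseline moments follow the published longitudinal subgroup; change
    distributions are centered on the published 2-year shifts (stable
    vessel densities, enlarging DCP FAZ area) with change SDs chosen so
    the paired tests land in the published significance range at n = 23.
    """
    return LongitudinalSpec(
        n_patients=16, n_eyes=23,
        baseline_means={("SCP", "whole_vd"): 31.0, ("SCP", "extrafaz_vd"): 31.2,
                        ("SCP", "faz_area_pct"): 0.962,
                        ("DCP", "whole_vd"): 31.19, ("DCP", "extrafaz_vd"): 32.1,
                        ("DCP", "faz_area_pct"): 2.87},
        baseline_sds={("SCP", "whole_vd"): 5.21, ("SCP", "extrafaz_vd"): 5.25,
                      ("SCP", "faz_area_pct"): 0.42,
                      ("DCP", "whole_vd"): 5.93, ("DCP", "extrafaz_vd"): 5.98,
                      ("DCP", "faz_area_pct"): 0.66},
        delta_means={("SCP", "whole_vd"): -0.5, ("SCP", "extrafaz_vd"): -0.4,
                     ("SCP", "faz_area_pct"): 0.015,
                     ("DCP", "whole_vd"): -0.49, ("DCP", "extrafaz_vd"): -0.4,
                     ("DCP", "faz_area_pct"): 0.31},
        delta_sds={("SCP", "whole_vd"): 4.0, ("SCP", "extrafaz_vd"): 4.0,
                   ("SCP", "faz_area_pct"): 0.25,
                   ("DCP", "whole_vd"): 4.0, ("DCP", "extrafaz_vd"): 4.0,
                   ("DCP", "faz_area_pct"): 0.60},
        rho=0.5)
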