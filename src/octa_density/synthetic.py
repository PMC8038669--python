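"""Synthetic OCTA angiograms and synthetic exudative-AMD cohorts.

Clinical OCTA acquisitions are not redistributable, so every downstream
stage of the package is exercised against synthetic data with known
ground truth:

* vessel-network images drawn as branching random walks, with speckle
  noise, cyst-shaped avascular dropout (emulating intraretinal fluid) and
  SCP-correlated projection tails composited into the DCP;
* a case-control cohort of exudative age-related macular degeneration
  eyes — 22 with intraretinal fluid (IRF +/- SRF), 11 with subretinal
  fluid only (SRF), 11 healthy controls — whose per-eye perfusion (MPD)
  and vessel (MVD) densities follow published group means and standard
  deviations per plexus and timepoint (T0 = during exudation, T1 = after
  complete fluid resorption), and whose clinical covariates follow the
  published prevalences.

With ``recenter=True`` (the default) each group sample is affinely
rescaled so its sample mean and SD equal the target values exactly; the
downstream regression estimates then reproduce the published group
contrasts up to printed rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .density import _skeleton_length_px

__all__ = [
    "SyntheticAngiogramTruth",
    "CohortSpec",
    "DENSITY_REFERENCE",
    "COVARIATE_REFERENCE",
    "GROUP_SIZES",
    "generate_vessel_network",
    "add_cystic_dropout",
    "compose_dcp_with_tails",
    "generate_cohort",
]

GROUPS = ("IRF_SRF", "SRF", "HEALTHY")
GROUP_SIZES: Dict[str, int] = {"IRF_SRF": 22, "SRF": 11, "HEALTHY": 11}

#: (group, plexus, metric, timepoint) -> (mean, SD).  MPD in percent,
#: MVD in instrument density units.  Healthy eyes are imaged once (T0).
DENSITY_REFERENCE: Dict[Tuple[str, str, str, str], Tuple[float, float]] = {
    ("HEALTHY", "SCP", "MPD", "T0"): (44.4, 2.2),
    ("HEALTHY", "DCP", "MPD", "T0"): (34.1, 6.1),
    ("HEALTHY", "SCP", "MVD", "T0"): (19.7, 1.1),
    ("HEALTHY", "DCP", "MVD", "T0"): (16.2, 2.8),
    ("IRF_SRF", "SCP", "MPD", "T0"): (37.4, 4.1),
    ("IRF_SRF", "SCP", "MPD", "T1"): (40.1, 5.8),
    ("IRF_SRF", "DCP", "MPD", "T0"): (20.7, 7.8),
    ("IRF_SRF", "DCP", "MPD", "T1"): (27.5, 8.4),
    ("IRF_SRF", "SCP", "MVD", "T0"): (16.6, 1.9),
    ("IRF_SRF", "SCP", "MVD", "T1"): (18.1, 2.1),
    ("IRF_SRF", "DCP", "MVD", "T0"): (10.6, 3.7),
    ("IRF_SRF", "DCP", "MVD", "T1"): (12.7, 3.6),
    ("SRF", "SCP", "MPD", "T0"): (42.2, 2.3),
    ("SRF", "SCP", "MPD", "T1"): (41.4, 3.0),
    ("SRF", "DCP", "MPD", "T0"): (24.8, 6.9),
    ("SRF", "DCP", "MPD", "T1"): (23.8, 6.3),
    ("SRF", "SCP", "MVD", "T0"): (18.8, 1.3),
    ("SRF", "SCP", "MVD", "T1"): (18.3, 1.5),
    ("SRF", "DCP", "MVD", "T0"): (13.2, 2.9),
    ("SRF", "DCP", "MVD", "T1"): (12.2, 2.7),
}

#: Per-group covariate distributions.  Continuous covariates are
#: (mean, SD) of a normal truncated at zero; categorical covariates are
#: level -> prevalence.  Neovascular-subtype proportions are not reported
#: as cohort counts and are set to a type-1-dominant mix typical of
#: neovascular AMD.
COVARIATE_REFERENCE: Dict[str, dict] = {
    "IRF_SRF": {
        "age": (81.7, 8.3),
        "male_frac": 5 / 22,
        "disease_duration": (22.6, 26.1),
        "ivi_before": (9.1, 11.8),
        "ivi_between": (2.0, 1.0),
        "atrophy": 13 / 22,
        "fibrosis": 8 / 22,
        "regimen": {"PRN": 7 / 22, "TAE": 7 / 22, "naive": 8 / 22},
        "anti_vegf": {"aflibercept": 19 / 22, "ranibizumab": 3 / 22},
        "mnv_subtype": {"type1": 0.6, "type2": 0.2, "type3": 0.2},
    },
    "SRF": {
        "age": (79.9, 5.8),
        "male_frac": 5 / 11,
        "disease_duration": (33.7, 29.3),
        "ivi_before": (18.6, 16.9),
        "ivi_between": (1.3, 0.5),
        "atrophy": 2 / 11,
        "fibrosis": 1 / 11,
        "regimen": {"PRN": 1 / 11, "TAE": 7 / 11, "naive": 3 / 11},
        "anti_vegf": {"aflibercept": 1.0},
        "mnv_subtype": {"type1": 0.6, "type2": 0.2, "type3": 0.2},
    },
    "HEALTHY": {
        "age": (78.6, 2.8),
        "male_frac": 6 / 11,
    },
}

#: Correlation between the T0 and T1 draws of the same eye and metric.
#: Repeated measures of the same retina are strongly correlated; the
#: value only shapes the random-intercept variance, not the group means.
T0_T1_CORRELATION = 0.7

DEFAULT_BRANCH_PARAMS = {
    "width_px": (1, 4),  # vessel calibre range, pixels
    "branch_prob": 0.015,  # per-step probability of spawning a branch
    "max_branches": 500,  # total walker budget
    "step_jitter_deg": 9.0,  # angular diffusion per unit step
    "branch_angle_deg": 35.0,
    "max_steps": 1500,
    # a walker older than the grace period that meets an existing vessel
    # anastomoses with it (stops) with this probability, else crosses it
    # (crossings are genuine in an en-face projection of a 3-D plexus)
    "join_prob": 0.3,
    "join_grace_steps": 8,
}


@dataclass(frozen=True)
class SyntheticAngiogramTruth:
    """A synthetic angiogram together with its binary ground truth.

    ``truth_mpd`` is exactly the mean of ``truth_mask``; ``truth_mvd`` is
    the projected centerline length of the drawn tree per unit area
    (mm/mm^2), measured on the rasterized centerline union so that
    segments overlapping in the en-face projection are counted once.
    """

    image: np.ndarray
    truth_mask: np.ndarray
    truth_mpd: float
    truth_mvd: float
    plexus: str = "SCP"
    fov_mm: float = 6.0
    seed: int = 0
    centerline: Optional[np.ndarray] = None  # (N, 2) float rows of (row, col)

    def __post_init__(self) -> None:
        if self.image.shape != self.truth_mask.shape:
            raise ValueError("image and truth_mask must share dimensions")
        if self.truth_mvd < 0:
            raise ValueError("truth_mvd must be non-negative")
        if abs(self.truth_mpd - float(self.truth_mask.mean())) > 1e-12:
            raise ValueError("truth_mpd must equal the mean of truth_mask")


def _centerline_mvd(
    centerline: np.ndarray, shape: Tuple[int, int], fov_mm: float
) -> float:
    """Projected centerline length per unit area (mm/mm^2).

    The continuous walk is rasterized and measured as a union, so vessel
    segments that overlap in the en-face projection are counted once —
    the same convention a skeleton-based estimate can at best recover.
    """
    h, w = shape
    if len(centerline) == 0:
        return 0.0
    raster = np.zeros(shape, dtype=bool)
    ri = np.clip(np.round(centerline[:, 0]).astype(int), 0, h - 1)
    ci = np.clip(np.round(centerline[:, 1]).astype(int), 0, w - 1)
    raster[ri, ci] = True
    pixel_mm = fov_mm / w
    return _skeleton_length_px(raster) * pixel_mm / fov_mm**2


def _stamp_disk(mask: np.ndarray, r: float, c: float, radius: float) -> None:
    h, w = mask.shape
    rad = max(radius, 0.5)
    r0, r1 = int(np.floor(r - rad)), int(np.ceil(r + rad)) + 1
    c0, c1 = int(np.floor(c - rad)), int(np.ceil(c + rad)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, h), min(c1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= rad**2


def generate_vessel_network(
    seed: int,
    fov_mm: float = 6.0,
    grid: Tuple[int, int] = (500, 500),
    n_seeds: int = 120,
    branch_params: Optional[dict] = None,
    noise_level: float = 0.3,
    blur_sigma: float = 0.8,
    plexus: str = "SCP",
) -> SyntheticAngiogramTruth:
    """Draw a random branching vessel network with known ground truth.

    Walkers start on the image border heading inward and advance in unit
    steps with angular jitter, stamping disks of their calibre along the
    way; each step may spawn a branch.  The observed image is the raster
    mask under multiplicative speckle (uniform, +/- ``noise_level``)
    followed by a Gaussian blur; ``noise_level=0`` gives the noise-free
    image used by the ground-truth recovery harness.
    """
    h, w = grid
    if h < 64 or w < 64:
        raise ValueError("grid must be at least 64x64")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if fov_mm <= 0:
        raise ValueError("fov_mm must be positive")
    bp = dict(DEFAULT_BRANCH_PARAMS)
    if branch_params:
        bp.update(branch_params)
    wmin, wmax = bp["width_px"]
    if wmin < 1 or wmax < wmin:
        raise ValueError("width_px range must satisfy 1 <= wmin <= wmax")

    rng = np.random.default_rng(seed)
    mask = np.zeros(grid, dtype=bool)
    centerline: list[tuple[float, float]] = []
    jitter = np.deg2rad(bp["step_jitter_deg"])
    branch_angle = np.deg2rad(bp["branch_angle_deg"])

    # half the seeds enter from the border heading inward (feeding
    # vessels), half start inside the field (local capillary meshes)
    walkers = []
    for k in range(n_seeds):
        if k % 2 == 0:
            edge = rng.integers(4)
            t = rng.uniform(0, 1)
            if edge == 0:
                pos, ang = (0.0, t * (w - 1)), np.pi / 2
            elif edge == 1:
                pos, ang = (h - 1.0, t * (w - 1)), -np.pi / 2
            elif edge == 2:
                pos, ang = (t * (h - 1), 0.0), 0.0
            else:
                pos, ang = (t * (h - 1), w - 1.0), np.pi
            ang += rng.uniform(-0.6, 0.6)
        else:
            pos = (rng.uniform(0, h - 1), rng.uniform(0, w - 1))
            ang = rng.uniform(0, 2 * np.pi)
        width = float(rng.integers(wmin, wmax + 1))
        walkers.append((pos[0], pos[1], ang, width))

    budget = bp["max_branches"]
    grace = bp["join_grace_steps"]
    while walkers:
        r, c, ang, width = walkers.pop()
        # walkers run sequentially, so the mask snapshot taken here holds
        # every previously drawn vessel but none of this walker's own trail
        prior = mask.copy()
        for age in range(bp["max_steps"]):
            if not (0 <= r < h and 0 <= c < w):
                break
            ri = min(int(round(r)), h - 1)
            ci = min(int(round(c)), w - 1)
            joined = (
                age > grace
                and prior[ri, ci]
                and rng.uniform() < bp["join_prob"]
            )
            _stamp_disk(mask, r, c, width / 2.0)
            centerline.append((r, c))
            if joined:  # anastomose with the vessel met instead of crossing
                break
            ang += rng.normal(0.0, jitter)
            # direction convention: angle 0 walks along columns
            r += np.sin(ang)
            c += np.cos(ang)
            if budget > 0 and rng.uniform() < bp["branch_prob"]:
                budget -= 1
                child_ang = ang + rng.choice((-1, 1)) * branch_angle
                child_w = max(wmin, width - 1.0)
                walkers.append((r, c, child_ang, child_w))

    centerline_arr = np.array(centerline, dtype=float).reshape(-1, 2)
    truth_mvd = _centerline_mvd(centerline_arr, grid, fov_mm)

    img = mask.astype(float)
    if noise_level > 0:
        img = img * rng.uniform(1.0 - noise_level, 1.0 + noise_level, size=grid)
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
    img = np.clip(img, 0.0, 1.0)

    return SyntheticAngiogramTruth(
        image=img,
        truth_mask=mask,
        truth_mpd=float(mask.mean()),
        truth_mvd=truth_mvd,
        plexus=plexus,
        fov_mm=fov_mm,
        seed=seed,
        centerline=centerline_arr,
    )


def add_cystic_dropout(
    t: SyntheticAngiogramTruth,
    n_cysts: int,
    radius_px_range: Tuple[float, float] = (8.0, 40.0),
    seed: int = 0,
) -> SyntheticAngiogramTruth:
    """Clear vessels inside random elliptical cysts (intraretinal fluid).

    Intraretinal cystoid spaces co-localize with capillary dropout; the
    emulation clears both the ground-truth mask and the observed image
    inside ``n_cysts`` axis-aligned random ellipses, and recomputes the
    ground-truth densities.  With ``n_cysts=0`` the input is returned
    unchanged.  The output ``truth_mpd`` never exceeds the input's.
    """
    rmin, rmax = radius_px_range
    if rmin < 1 or rmax < rmin:
        raise ValueError("cyst radii must satisfy 1 <= rmin <= rmax")
    if n_cysts == 0:
        return t
    rng = np.random.default_rng(seed)
    h, w = t.truth_mask.shape
    hole = np.zeros((h, w), dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(n_cysts):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(rmin, rmax)  # column semi-axis
        b = rng.uniform(rmin, rmax)  # row semi-axis
        hole |= ((rr - cy) / b) ** 2 + ((cc - cx) / a) ** 2 <= 1.0

    mask = t.truth_mask & ~hole
    img = t.image.copy()
    img[hole] = 0.0

    centerline = t.centerline
    truth_mvd = t.truth_mvd
    if centerline is not None and len(centerline):
        ri = np.clip(np.round(centerline[:, 0]).astype(int), 0, h - 1)
        ci = np.clip(np.round(centerline[:, 1]).astype(int), 0, w - 1)
        keep = ~hole[ri, ci]
        centerline = centerline[keep]
        truth_mvd = _centerline_mvd(centerline, (h, w), t.fov_mm)

    return replace(
        t,
        image=img,
        truth_mask=mask,
        truth_mpd=float(mask.mean()),
        truth_mvd=truth_mvd,
        centerline=centerline,
    )


def compose_dcp_with_tails(
    dcp: SyntheticAngiogramTruth,
    scp: SyntheticAngiogramTruth,
    alpha: float,
) -> SyntheticAngiogramTruth:
    """Contaminate a DCP image with projection tails from the SCP.

    The observed DCP image becomes ``clip(dcp + alpha * scp, 0, 1)``; the
    ground truth is untouched because tails are artifact, not anatomy.
    """
    if dcp.image.shape != scp.image.shape:
        raise ValueError("DCP and SCP images must share dimensions")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    img = np.clip(dcp.image + alpha * scp.image, 0.0, 1.0)
    return replace(dcp, image=img)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic case-control cohort.

    Defaults reproduce the published study conditions: 22 IRF+/-SRF, 11
    SRF and 11 healthy eyes, density means/SDs per (group, plexus,
    metric, timepoint) and covariate prevalences per group.  With
    ``recenter=True`` each group's sample mean and SD are made exact by
    affine rescaling.
    """

    group_sizes: Dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    density_reference: Dict[Tuple[str, str, str, str], Tuple[float, float]] = field(
        default_factory=lambda: dict(DENSITY_REFERENCE)
    )
    covariate_reference: Dict[str, dict] = field(
        default_factory=lambda: {g: dict(v) for g, v in COVARIATE_REFERENCE.items()}
    )
    recenter: bool = True
    seed: int = 0
    t0_t1_correlation: float = T0_T1_CORRELATION

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError("group sizes must be >= 2")
        for key, (m, s) in self.density_reference.items():
            if s < 0:
                raise ValueError(f"negative SD for {key}")
        for g, cov in self.covariate_reference.items():
            for name in ("male_frac", "atrophy", "fibrosis"):
                if name in cov and not 0.0 <= cov[name] <= 1.0:
                    raise ValueError(f"prevalence {name} for {g} outside [0, 1]")
        if not -1.0 < self.t0_t1_correlation < 1.0:
            raise ValueError("t0_t1_correlation must lie in (-1, 1)")


def _exact_count_flags(n: int, prevalence: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean vector with round(prevalence * n) True entries, shuffled.

    Fixing the composition (rather than drawing per-eye Bernoullis) makes
    the synthetic covariate counts match the published cohort counts.
    """
    k = int(round(prevalence * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def _exact_count_categorical(
    n: int, levels: Dict[str, float], rng: np.random.Generator
) -> np.ndarray:
    names = list(levels)
    counts = [int(round(levels[name] * n)) for name in names]
    # largest-remainder fixup so counts sum to n
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmax([levels[m] for m in names]))] += 1
    out = np.repeat(names, counts)
    rng.shuffle(out)
    return out


def _truncated_normal(
    n: int, mean: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    draw = rng.normal(mean, sd, size=n)
    return np.clip(draw, 0.0, None)


def _recenter(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affine map making the sample mean and (n-1) SD exact."""
    xbar = x.mean()
    s = x.std(ddof=1)
    if s == 0:
        return np.full_like(x, mean)
    return mean + (x - xbar) * (sd / s)


#: Standard-normal draws for densities are clipped at +/- this many SDs
#: so that recentred samples stay non-negative even for the most variable
#: group (DCP MPD during exudation); recentering restores the exact SD.
_Z_CLIP = 2.2


def _correlated_pair(
    n: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    z0 = rng.standard_normal(n)
    z1 = rho * z0 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return np.clip(z0, -_Z_CLIP, _Z_CLIP), np.clip(z1, -_Z_CLIP, _Z_CLIP)


def generate_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Generate the synthetic cohort as a long table.

    One row per (eye, timepoint); healthy eyes appear only at T0.
    Columns: ``eye_id, group, timepoint, age, sex, disease_duration,
    ivi_before, ivi_between, atrophy, fibrosis, mnv_subtype, anti_vegf,
    regimen, scp_mpd, scp_mvd, dcp_mpd, dcp_mvd``.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    prefixes = {"IRF_SRF": "IRF", "SRF": "SRF", "HEALTHY": "H"}

    for group in GROUPS:
        n = spec.group_sizes.get(group, 0)
        if n == 0:
            continue
        cov = spec.covariate_reference[group]
        timepoints = ("T0",) if group == "HEALTHY" else ("T0", "T1")

        age = rng.normal(*cov["age"], size=n)
        male = _exact_count_flags(n, cov["male_frac"], rng)
        if group == "HEALTHY":
            duration = np.full(n, np.nan)
            ivi_before = np.zeros(n)
            ivi_between = np.zeros(n)
            atrophy = np.zeros(n, dtype=bool)
            fibrosis = np.zeros(n, dtype=bool)
            subtype = np.full(n, "none")
            anti_vegf = np.full(n, "none")
            regimen = np.full(n, "none")
        else:
            duration = _truncated_normal(n, *cov["disease_duration"], rng)
            ivi_before = np.round(_truncated_normal(n, *cov["ivi_before"], rng))
            ivi_between = np.round(_truncated_normal(n, *cov["ivi_between"], rng))
            atrophy = _exact_count_flags(n, cov["atrophy"], rng)
            fibrosis = _exact_count_flags(n, cov["fibrosis"], rng)
            subtype = _exact_count_categorical(n, cov["mnv_subtype"], rng)
            anti_vegf = _exact_count_categorical(n, cov["anti_vegf"], rng)
            regimen = _exact_count_categorical(n, cov["regimen"], rng)
            # treatment-naive eyes have no anti-VEGF history yet
            ivi_before[regimen == "naive"] = 0.0

        dens: Dict[str, Dict[str, np.ndarray]] = {}
        for plexus in ("SCP", "DCP"):
            for metric in ("MPD", "MVD"):
                col = f"{plexus.lower()}_{metric.lower()}"
                z0, z1 = _correlated_pair(n, spec.t0_t1_correlation, rng)
                per_tp: Dict[str, np.ndarray] = {}
                for tp, z in zip(("T0", "T1"), (z0, z1)):
                    key = (group, plexus, metric, tp)
                    if key not in spec.density_reference:
                        continue
                    m, s = spec.density_reference[key]
                    x = m + s * z
                    if spec.recenter:
                        x = _recenter(x, m, s)
                    else:
                        x = np.clip(x, 0.0, None)
                    per_tp[tp] = x
                dens[col] = per_tp

        for i in range(n):
            eye_id = f"{prefixes[group]}{i + 1:02d}"
            for tp in timepoints:
                rows.append(
                    {
                        "eye_id": eye_id,
                        "group": group,
                        "timepoint": tp,
                        "age": age[i],
                        "sex": "M" if male[i] else "F",
                        "disease_duration": duration[i],
                        "ivi_before": ivi_before[i],
                        "ivi_between": ivi_between[i],
                        "atrophy": bool(atrophy[i]),
                        "fibrosis": bool(fibrosis[i]),
                        "mnv_subtype": subtype[i],
                        "anti_vegf": anti_vegf[i],
                        "regimen": regimen[i],
                        **{
                            col: per_tp[tp][i]
                            for col, per_tp in dens.items()
                            if tp in per_tp
                        },
                    }
                )
    return pd.DataFrame(rows)
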