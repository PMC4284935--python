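"""Synthetic fundus photograph and cohort generator with known ground truth.

No public fundus dataset carries per-sector disc Hb ground truth, so the
pipeline is validated against a forward optical model that realizes every
qualitative premise of the measurement:

* disc tissue color is a linear two-endmember mix between a pale,
  achromatic endmember (tissue devoid of blood) and a red-dominant whole
  blood endmember, weighted by the true Hb fraction — so high-Hb areas
  reflect mainly red, low-Hb areas reflect red and green in similar
  proportion;
* the central retinal vessels carry 100% Hb (a shaded copy of the blood
  endmember: whole blood, lower albedo) and are drawn as a branching tree
  crossing the disc;
* a multiplicative illumination gradient, a lens (cataract) yellowing term
  that attenuates blue by κ and green by (κ+1)/2, and additive Gaussian
  sensor noise complete the image.

The model is deliberately *not* the inverse of the estimator (endmember
mixing here, vessel-normalized red–green contrast there), so recovery
experiments are non-circular.  The two endmembers share the same red
value, which makes the disc's red reflectance independent of Hb — the
pallor signal lives entirely in green, as it does in real discs where
pallor is a loss of redness *relative* to overall brightness.

Cohort-level defaults (group sizes, per-sector Hb means/SDs, RNFL
means/SDs, Hoehn-Yahr distribution) follow a reference clinical
case-control cohort of 155 Parkinson's and 91 healthy subjects, so a
simulated cohort pushed through the pipeline exercises the same
comparison tables a clinical study would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from onhcolor.exceptions import ValidationError
from onhcolor.io import FundusImage
from onhcolor.sectors import (
    N_SECTORS,
    SectorProfile,
    sector_labels,
)
from onhcolor.segmentation import DiscGeometry, DiscRegions, VesselMask

__all__ = [
    "PALE_ENDMEMBER",
    "BLOOD_ENDMEMBER",
    "VESSEL_SHADE",
    "BACKGROUND_COLOR",
    "HEALTHY_SECTOR_HB",
    "PD_SECTOR_HB",
    "RNFL_PARAMS",
    "SECTOR_AREA_WEIGHTS",
    "SubjectSpec",
    "RenderedSubject",
    "CohortParams",
    "CohortBundle",
    "render_fundus",
    "generate_cohort",
    "dilution_series",
    "true_mean_hb",
]

# ---------------------------------------------------------------------------
# forward-model constants

#: bloodless disc tissue: bright and achromatic (the pale cup look)
PALE_ENDMEMBER = np.array([0.86, 0.86, 0.86], dtype=np.float32)
#: whole blood at tissue albedo: red-dominant, same red as the pale endmember
BLOOD_ENDMEMBER = np.array([0.86, 0.20, 0.11], dtype=np.float32)
#: vessels are whole blood at lower albedo (darker, same chromaticity)
VESSEL_SHADE = 0.55
#: peripapillary retina (orange, darker than the disc)
BACKGROUND_COLOR = np.array([0.55, 0.25, 0.12], dtype=np.float32)

# per-sector Hb percentage (mean, sd) for the two groups, sectors 1..24
HEALTHY_SECTOR_HB = {
    "mean": np.array([74, 73, 68, 71, 74, 68, 64, 71, 69, 57, 58, 61,
                      57, 54, 58, 60, 64, 67, 67, 77, 76, 73, 84, 75], dtype=float),
    "sd": np.array([16, 14, 12, 15, 13, 12, 17, 11, 11, 16, 17, 13,
                    17, 17, 15, 17, 17, 14, 19, 14, 11, 17, 13, 12], dtype=float),
}
PD_SECTOR_HB = {
    "mean": np.array([70, 64, 56, 65, 64, 58, 60, 60, 56, 54, 49, 49,
                      52, 47, 46, 57, 57, 57, 66, 69, 65, 71, 71, 64], dtype=float),
    "sd": np.array([16, 16, 14, 18, 15, 24, 16, 14, 15, 12, 12, 12,
                    16, 16, 12, 15, 14, 19, 19, 16, 18, 19, 19, 17], dtype=float),
}

# RNFL thickness (µm): variable -> (healthy mean, healthy sd, PD mean, PD sd)
RNFL_PARAMS = {
    "cirrus_mean": (105, 10, 93, 10),
    "cirrus_superior": (139, 19, 115, 17),
    "cirrus_nasal": (80, 11, 73, 13),
    "cirrus_inferior": (134, 21, 119, 18),
    "cirrus_temporal": (66, 11, 65, 13),
    "cirrus_h1": (118, 23, 102, 15),
    "cirrus_h2": (101, 19, 86, 19),
    "cirrus_h3": (64, 10, 56, 11),
    "cirrus_h4": (75, 13, 62, 14),
    "cirrus_h5": (117, 22, 94, 16),
    "cirrus_h6": (149, 24, 130, 20),
    "cirrus_h7": (137, 26, 129, 24),
    "cirrus_h8": (70, 15, 68, 14),
    "cirrus_h9": (60, 10, 55, 10),
    "cirrus_h10": (78, 15, 75, 14),
    "cirrus_h11": (136, 23, 130, 22),
    "cirrus_h12": (126, 22, 119, 25),
    "spectralis_mean": (100, 10, 93, 10),
    "spectralis_superior": (123, 13, 115, 26),
    "spectralis_nasal": (73, 13, 71, 26),
    "spectralis_inferior": (133, 20, 122, 27),
    "spectralis_temporal": (71, 11, 64, 23),
    "spectralis_superonasal": (126, 17, 122, 18),
    "spectralis_inferonasal": (141, 18, 138, 18),
    "spectralis_inferotemporal": (108, 21, 99, 18),
    "spectralis_superotemporal": (113, 15, 103, 19),
}

#: area weight of each sector: rings split the disc 1/9 : 3/9 : 5/9,
#: wedges split each ring in 8
SECTOR_AREA_WEIGHTS = np.array(
    [w for _ in range(8) for w in (1.0 / 72.0, 3.0 / 72.0, 5.0 / 72.0)]
)


def true_mean_hb(sector_hb: np.ndarray) -> float:
    """Area-weighted whole-disc mean of a 24-sector Hb profile."""
    return float(np.dot(SECTOR_AREA_WEIGHTS, np.asarray(sector_hb, dtype=float)))


# ---------------------------------------------------------------------------
# subject specification and rendering

@dataclass
class SubjectSpec:
    """Everything needed to render one subject's fundus photograph."""

    subject_id: str = "synthetic"
    group: str = "healthy"
    eye: str = "right"
    true_sector_hb: np.ndarray = field(
        default_factory=lambda: HEALTHY_SECTOR_HB["mean"].copy()
    )
    center: tuple[float, float] = (256.0, 256.0)
    radius_x: float = 80.0
    radius_y: float = 80.0
    n_branches: int = 4
    trunk_halfwidth: int = 3
    branch_halfwidth: int = 2
    draw_vessels: bool = True
    illumination_amplitude: float = 0.1
    kappa: float = 1.0
    noise_sd: float = 0.01
    smooth_sigma: float = 3.0
    seed: int = 0
    image_size: tuple[int, int] = (512, 512)  # (H, W)

    def __post_init__(self) -> None:
        hb = np.asarray(self.true_sector_hb, dtype=float)
        if hb.shape != (N_SECTORS,):
            raise ValidationError("true_sector_hb must have 24 entries")
        if hb.min() < 0 or hb.max() > 100:
            raise ValidationError("true_sector_hb must lie in [0, 100]")
        if not 0.0 < self.kappa <= 1.0:
            raise ValidationError("kappa must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        self.true_sector_hb = hb

    @property
    def geometry(self) -> DiscGeometry:
        return DiscGeometry(
            center=self.center, radius_x=self.radius_x, radius_y=self.radius_y, eye=self.eye
        )


@dataclass
class RenderedSubject:
    """A rendered photograph together with its ground truth."""

    image: FundusImage
    disc: DiscGeometry
    vessel_mask: np.ndarray       # ground-truth vessels within the disc
    true_hb: np.ndarray           # smoothed Hb% field over the whole grid
    true_profile: SectorProfile   # sector means of true_hb over true tissue
    spec: SubjectSpec

    @property
    def regions(self) -> DiscRegions:
        interior = self.disc.interior_mask(self.image.shape)
        return DiscRegions(
            disc=self.disc,
            vessels=VesselMask(self.vessel_mask, low_confidence=False),
            tissue=interior & ~self.vessel_mask,
        )


def _draw_vessel_tree(spec: SubjectSpec, rng: np.random.Generator) -> np.ndarray:
    """Binary raster of a branching central vessel tree (may exit the disc)."""
    h, w = spec.image_size
    cx, cy = spec.center
    r_mean = 0.5 * (spec.radius_x + spec.radius_y)
    reach = 1.25 * r_mean

    def polyline(x0, y0, angle, length, wiggle_amp, wiggle_freq, phase):
        t = np.arange(0.0, length, 0.7)
        x = x0 + t * np.sin(angle) + wiggle_amp * np.sin(wiggle_freq * t / r_mean + phase)
        y = y0 - t * np.cos(angle)
        return x, y

    def stamp(canvas, xs, ys, halfwidth):
        ii = np.round(ys).astype(int)
        jj = np.round(xs).astype(int)
        ok = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
        if not ok.any():
            return
        ii, jj = ii[ok], jj[ok]
        # dilate only within the segment's bounding box
        i0, i1 = max(ii.min() - halfwidth, 0), min(ii.max() + halfwidth + 1, h)
        j0, j1 = max(jj.min() - halfwidth, 0), min(jj.max() + halfwidth + 1, w)
        path = np.zeros((i1 - i0, j1 - j0), dtype=bool)
        path[ii - i0, jj - j0] = True
        footprint = np.zeros((2 * halfwidth + 1, 2 * halfwidth + 1), dtype=bool)
        yy, xx = np.ogrid[-halfwidth : halfwidth + 1, -halfwidth : halfwidth + 1]
        footprint[yy * yy + xx * xx <= halfwidth * halfwidth + 1] = True
        canvas[i0:i1, j0:j1] |= ndimage.binary_dilation(path, structure=footprint)

    tree = np.zeros((h, w), dtype=bool)
    trunk_angles = (
        rng.normal(0.0, 0.08),            # superior trunk, near-vertical up
        np.pi + rng.normal(0.0, 0.08),    # inferior trunk, near-vertical down
    )
    for ang in trunk_angles:
        xs, ys = polyline(
            cx, cy, ang, reach,
            wiggle_amp=0.06 * r_mean, wiggle_freq=4.0, phase=rng.uniform(0, 2 * np.pi),
        )
        stamp(tree, xs, ys, spec.trunk_halfwidth)
    for b in range(spec.n_branches):
        trunk = trunk_angles[b % 2]
        t0 = rng.uniform(0.25, 0.55) * r_mean
        bx = cx + t0 * np.sin(trunk)
        by = cy - t0 * np.cos(trunk)
        side = 1 if (b // 2) % 2 == 0 else -1
        ang = trunk + side * rng.uniform(0.5, 1.1)
        xs, ys = polyline(
            bx, by, ang, 0.9 * r_mean,
            wiggle_amp=0.04 * r_mean, wiggle_freq=5.0, phase=rng.uniform(0, 2 * np.pi),
        )
        stamp(tree, xs, ys, spec.branch_halfwidth)
    return tree


def render_fundus(spec: SubjectSpec) -> RenderedSubject:
    """Render one subject: photograph plus pixel-exact ground truth.

    Deterministic given ``spec`` (including its seed): two calls produce
    bit-identical images.
    """
    h, w = spec.image_size
    disc = spec.geometry
    if not disc.inside((h, w)):
        raise ValidationError("disc geometry does not fit inside the canvas")
    rng = np.random.default_rng(spec.seed)

    margin = int(np.ceil(4.0 * spec.smooth_sigma)) + 2
    labels_full = sector_labels(disc, (h, w), clip=False, margin=margin)
    sector_vals = np.concatenate([[0.0], spec.true_sector_hb])  # label 0 unused
    hb_field = sector_vals[labels_full].astype(np.float32)
    if spec.smooth_sigma > 0:
        hb_field = ndimage.gaussian_filter(hb_field, spec.smooth_sigma)
    frac = hb_field / 100.0

    interior = disc.interior_mask((h, w))
    if spec.draw_vessels:
        vessels_all = _draw_vessel_tree(spec, rng)
    else:
        vessels_all = np.zeros((h, w), dtype=bool)
    vessel_in_disc = vessels_all & interior

    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = BACKGROUND_COLOR
    mix = PALE_ENDMEMBER[None, :] + frac[interior, None] * (
        BLOOD_ENDMEMBER - PALE_ENDMEMBER
    )[None, :]
    img[interior] = mix
    img[vessels_all] = VESSEL_SHADE * BLOOD_ENDMEMBER

    # slow multiplicative illumination gradient (left-right ramp)
    x = np.arange(w, dtype=np.float32)
    illum = 1.0 + spec.illumination_amplitude * (2.0 * x / (w - 1) - 1.0)
    img *= illum[None, :, None]

    # lens yellowing: blue attenuated by kappa, green about half as much
    img[..., 2] *= spec.kappa
    img[..., 1] *= (spec.kappa + 1.0) / 2.0

    if spec.noise_sd > 0:
        img += spec.noise_sd * rng.standard_normal(size=img.shape, dtype=np.float32)
    np.clip(img, 0.0, 1.0, out=img)

    fundus = FundusImage(img, bit_depth=8, eye=spec.eye, subject_id=spec.subject_id)

    # ground-truth sector profile over true tissue (vessels excluded)
    tissue = interior & ~vessel_in_disc
    lab_t = labels_full[tissue]
    vals_t = hb_field[tissue].astype(np.float64)
    counts = np.bincount(lab_t, minlength=N_SECTORS + 1)[1:]
    sums = np.bincount(lab_t, weights=vals_t, minlength=N_SECTORS + 1)[1:]
    sector_hb = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    profile = SectorProfile(
        mean_hb=float(vals_t.mean()),
        sector_hb=sector_hb,
        sector_pixel_counts=counts,
        subject_id=spec.subject_id,
        eye=spec.eye,
    )
    return RenderedSubject(
        image=fundus,
        disc=disc,
        vessel_mask=vessel_in_disc,
        true_hb=hb_field,
        true_profile=profile,
        spec=spec,
    )


def dilution_series(
    levels,
    base_spec: SubjectSpec | None = None,
) -> list[RenderedSubject]:
    """Render the same disc at a series of uniform Hb fractions.

    The geometry, vessel tree and noise realization are identical across
    levels (same seed); only the Hb field scales.  This is the in-silico
    analogue of photographing red-cell dilution series of known
    concentration, and the fixture behind the linearity checks.
    """
    if base_spec is None:
        base_spec = SubjectSpec(noise_sd=0.0)
    out = []
    for lv in levels:
        if not 0.0 <= lv <= 1.0:
            raise ValidationError(f"dilution level must be in [0, 1], got {lv}")
        spec = replace(
            base_spec,
            true_sector_hb=np.full(N_SECTORS, 100.0 * lv),
            subject_id=f"{base_spec.subject_id}_lvl{lv:g}",
        )
        out.append(render_fundus(spec))
    return out


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortParams:
    """Distributional parameters of the simulated case-control cohort.

    Defaults reproduce the summary tables of the reference cohort: 155 PD
    and 91 healthy subjects, per-sector disc Hb means/SDs per group, RNFL
    thickness means/SDs per device, and a Hoehn-Yahr stage of 2.68 (0.82)
    truncated to [1, 5] for the PD group.  ``lens_kappa=1`` reflects the
    cohort's inclusion criterion of transparent ocular media.
    """

    n_pd: int = 155
    n_healthy: int = 91
    healthy_sector_mean: np.ndarray = field(
        default_factory=lambda: HEALTHY_SECTOR_HB["mean"].copy())
    healthy_sector_sd: np.ndarray = field(
        default_factory=lambda: HEALTHY_SECTOR_HB["sd"].copy())
    pd_sector_mean: np.ndarray = field(
        default_factory=lambda: PD_SECTOR_HB["mean"].copy())
    pd_sector_sd: np.ndarray = field(
        default_factory=lambda: PD_SECTOR_HB["sd"].copy())
    rnfl_params: dict = field(default_factory=lambda: dict(RNFL_PARAMS))
    hoehn_yahr_mean: float = 2.68
    hoehn_yahr_sd: float = 0.82
    disease_duration_mean: float = 8.52
    disease_duration_sd: float = 2.10
    male_fraction: float = 0.59
    age_range_healthy: tuple[float, float] = (55.0, 79.0)
    age_range_pd: tuple[float, float] = (54.0, 80.0)
    image_size: tuple[int, int] = (512, 512)
    disc_radius_mean: float = 80.0
    disc_radius_sd: float = 5.0
    disc_radius_range: tuple[float, float] = (65.0, 95.0)
    center_jitter: float = 20.0
    lens_kappa: float = 1.0
    noise_sd: float = 0.01
    illumination_amplitude: float = 0.1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_healthy < 0 or self.n_pd + self.n_healthy < 1:
            raise ValidationError("cohort needs at least one subject")
        for arr in (self.healthy_sector_sd, self.pd_sector_sd):
            if np.asarray(arr, dtype=float).min() < 0:
                raise ValidationError("sector SDs must be >= 0")
        if not 0.0 < self.lens_kappa <= 1.0:
            raise ValidationError("lens_kappa must be in (0, 1]")


@dataclass
class CohortBundle:
    """A drawn cohort: ground-truth table plus renderable subject specs.

    ``truth`` holds one row per subject with the drawn (true) Hb profile,
    RNFL fields and covariates.  Images are rendered lazily, one subject
    at a time, via :meth:`render` — a 246-subject cohort of 512x512 floats
    would not fit comfortably in memory all at once.
    """

    truth: pd.DataFrame
    subjects: list[SubjectSpec]
    params: CohortParams

    def render(self, i: int) -> RenderedSubject:
        return render_fundus(self.subjects[i])

    def __len__(self) -> int:
        return len(self.subjects)


def generate_cohort(params: CohortParams | None = None) -> CohortBundle:
    """Draw a full simulated cohort from the group-level parameters.

    Per subject: true sector Hb values are drawn Normal(group mean_s,
    group sd_s) truncated (clipped) to [0, 100]; RNFL fields are drawn
    Normal per device parameter; Hoehn-Yahr (PD only) Normal(2.68, 0.82)
    truncated to [1, 5]; eye, sex, age and disc geometry are randomized.
    The master seed fans out per-subject seeds through a SeedSequence, so
    regenerated cohorts are value-identical.
    """
    if params is None:
        params = CohortParams()
    ss = np.random.SeedSequence(params.master_seed)
    n_total = params.n_healthy + params.n_pd
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n_total + 1)]
    draw_rng = np.random.default_rng(child_seeds[-1])

    h_img, w_img = params.image_size
    rows = []
    specs: list[SubjectSpec] = []
    groups = ["healthy"] * params.n_healthy + ["PD"] * params.n_pd
    for i, group in enumerate(groups):
        if group == "healthy":
            mu, sd = params.healthy_sector_mean, params.healthy_sector_sd
            age = draw_rng.uniform(*params.age_range_healthy)
        else:
            mu, sd = params.pd_sector_mean, params.pd_sector_sd
            age = draw_rng.uniform(*params.age_range_pd)
        sector_hb = np.clip(draw_rng.normal(mu, sd), 0.0, 100.0)
        eye = "right" if draw_rng.random() < 0.5 else "left"
        sex = "M" if draw_rng.random() < params.male_fraction else "F"
        rad_x = float(np.clip(
            draw_rng.normal(params.disc_radius_mean, params.disc_radius_sd),
            *params.disc_radius_range))
        rad_y = float(np.clip(
            draw_rng.normal(params.disc_radius_mean, params.disc_radius_sd),
            *params.disc_radius_range))
        jit = params.center_jitter
        center = (
            float(w_img / 2 + draw_rng.uniform(-jit, jit)),
            float(h_img / 2 + draw_rng.uniform(-jit, jit)),
        )
        subject_id = f"{'H' if group == 'healthy' else 'P'}{i:04d}"
        spec = SubjectSpec(
            subject_id=subject_id,
            group=group,
            eye=eye,
            true_sector_hb=sector_hb,
            center=center,
            radius_x=rad_x,
            radius_y=rad_y,
            illumination_amplitude=params.illumination_amplitude,
            kappa=params.lens_kappa,
            noise_sd=params.noise_sd,
            seed=child_seeds[i],
            image_size=params.image_size,
        )
        specs.append(spec)
        row = {
            "subject_id": subject_id,
            "group": group,
            "eye": eye,
            "sex": sex,
            "age": age,
            "mean_hb": true_mean_hb(sector_hb),
        }
        row.update({f"hb_{s + 1}": sector_hb[s] for s in range(N_SECTORS)})
        for name, (hm, hs, pm, psd) in params.rnfl_params.items():
            m, s_ = (hm, hs) if group == "healthy" else (pm, psd)
            row[name] = max(draw_rng.normal(m, s_), 0.0)
        if group == "PD":
            row["hoehn_yahr"] = float(np.clip(
                draw_rng.normal(params.hoehn_yahr_mean, params.hoehn_yahr_sd), 1.0, 5.0))
            row["disease_duration"] = float(np.clip(
                draw_rng.normal(params.disease_duration_mean, params.disease_duration_sd),
                2.0, 19.0))
        else:
            row["hoehn_yahr"] = np.nan
            row["disease_duration"] = np.nan
        rows.append(row)
    truth = pd.DataFrame(rows)
    return CohortBundle(truth=truth, subjects=specs, params=params)
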