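"""Synthetic basal-ganglia part-image generator.

Emulates the structure of the study data: each subject contributes six 2D
part images (three axial slices x two hemispheres) cropped around the basal
ganglia, where enlarged perivascular spaces (ePVS) appear as small bright
puncta on a textured tissue background. Counts per part are drawn
grade-first from the empirical grade distribution of the study cohort
(heavily skewed toward grades 1-2), then uniformly within the grade's count
bracket. Every part carries an exact binary mask of its puncta, so
connected-component counts, grades, and enhancement targets are all
ground-truthed.

The generator is fully seeded: the same (n_subjects, params, seed) triple
reproduces a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi

from .evaluate import GRADE_BRACKETS, grade_from_count

#: empirical per-part grade frequencies of the 456-image study cohort
STUDY_GRADE_PROBS = (4 / 456, 244 / 456, 138 / 456, 55 / 456, 15 / 456)


def desk_params() -> "PhantomParams":
    """Geometry scaled for CPU-scale experiments: parts rendered at 60x72
    (standardized downstream to 40x48), with puncta and confounders shrunk by
    the same factor as the default 120x140 -> 80x96 regime."""
    return PhantomParams(
        part_shape=(60, 72),
        puncta_radius_range=(1.0, 2.2),
        distractor_radius_range=(3.0, 5.0),
        border_margin=5,
        max_place_attempts=5000,
    )


class PlacementError(RuntimeError):
    """Raised when the requested number of disjoint puncta cannot be placed."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of the synthetic cohort.

    Intensity parameters are in raw scanner units on a ``bit_depth``-bit
    scale. Parts are emitted larger than the 80x96 working size so that
    downstream resizing is a real resampling step.
    """

    part_shape: tuple[int, int] = (120, 140)
    grade_probs: tuple[float, ...] = STUDY_GRADE_PROBS
    count_max: int = 48
    puncta_radius_range: tuple[float, float] = (1.2, 3.0)
    puncta_intensity_boost: float = 0.12
    tissue_mean: float = 20000.0
    tissue_sd: float = 1500.0
    noise_sd: float = 600.0
    bit_depth: int = 16
    texture_sigma: float = 6.0
    border_margin: int = 8
    max_place_attempts: int = 1000
    # per-part acquisition variability (uncalibrated scanner scaling, coil
    # inhomogeneity): multiplicative jitters drawn uniformly in 1 +/- jitter,
    # plus a smooth multiplicative bias field
    intensity_jitter: float = 0.2
    texture_jitter: float = 0.4
    noise_jitter: float = 0.4
    boost_jitter: float = 0.2
    bias_field_amplitude: float = 0.15
    bias_field_sigma: float = 20.0
    # non-ePVS hyperintense confounders (vessel/lacune-like structures that a
    # rater would not count): Poisson-many per part, larger than puncta,
    # excluded from the ground-truth mask
    distractor_rate: float = 4.0
    distractor_radius_range: tuple[float, float] = (3.5, 6.0)
    distractor_ecc_max: float = 4.0
    distractor_boost_range: tuple[float, float] = (1.0, 1.6)  # relative to puncta boost

    def __post_init__(self):
        probs = np.asarray(self.grade_probs, dtype=float)
        if probs.shape != (5,) or np.any(probs < 0):
            raise ValueError("grade_probs must be 5 nonnegative weights over grades 0-4")
        if probs.sum() <= 0:
            raise ValueError("grade_probs must not be all zero")
        if self.count_max < 40:
            raise ValueError("count_max must be >= 40 so grade 4 is reachable")
        if self.puncta_radius_range[0] < 1.0:
            raise ValueError("minimum puncta radius must be >= 1 pixel")
        if self.puncta_radius_range[0] > self.puncta_radius_range[1]:
            raise ValueError("puncta_radius_range must be (min, max) with min <= max")

    @property
    def normalized_grade_probs(self) -> np.ndarray:
        probs = np.asarray(self.grade_probs, dtype=float)
        return probs / probs.sum()

    @property
    def dynamic_range(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class PartImage:
    """One hemisphere x slice part: raw 16-bit grid, exact puncta mask,
    ground-truth count and its Potter grade."""

    subject_id: str
    slice_index: int  # 1..3
    hemisphere: str  # "left" | "right"
    raw: np.ndarray  # uint16 (rows, cols)
    mask: np.ndarray  # uint8, same shape
    count: int
    grade: int


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    parts: tuple[PartImage, ...]  # exactly 6: 3 slices x 2 hemispheres
    subject_grade: int  # max over the six part grades

    def __post_init__(self):
        if len(self.parts) != 6:
            raise ValueError(f"subject {self.subject_id} has {len(self.parts)} parts, expected 6")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_grade(params: PhantomParams, rng: np.random.Generator) -> int:
    return int(rng.choice(5, p=params.normalized_grade_probs))


def sample_count(params: PhantomParams, rng: np.random.Generator) -> int:
    """Draw a grade from grade_probs, then a count uniform within its bracket
    (grade 4: uniform on 41..count_max)."""
    grade = sample_grade(params, rng)
    lo, hi = GRADE_BRACKETS[grade]
    hi = params.count_max if hi is None else hi
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _jitter(base: float, jitter: float, rng) -> float:
    return base * rng.uniform(1.0 - jitter, 1.0 + jitter)


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    field = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _tissue_background(shape, params: PhantomParams, rng) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Textured tissue with per-part gain jitter and a multiplicative bias
    field; returns (background, bias_field, noise_sd, boost_scale) for this part."""
    mean = _jitter(params.tissue_mean, params.intensity_jitter, rng)
    sd = _jitter(params.tissue_sd, params.texture_jitter, rng)
    noise_sd = _jitter(params.noise_sd, params.noise_jitter, rng)
    boost = _jitter(params.puncta_intensity_boost, params.boost_jitter, rng)
    texture = _smooth_field(shape, params.texture_sigma, rng)
    bias = 1.0 + params.bias_field_amplitude * _smooth_field(shape, params.bias_field_sigma, rng)
    background = (mean + sd * texture) * bias
    return background, bias, noise_sd, boost


def _place_puncta(count, shape, params: PhantomParams, rng):
    """Greedy rejection sampling of non-overlapping elliptical puncta.

    Centers keep >= 2 px of clearance between mask boundaries so each
    punctum is its own 8-connected component.
    """
    rmin, rmax = params.puncta_radius_range
    margin = params.border_margin
    h, w = shape
    if h - 2 * margin <= 2 * rmax or w - 2 * margin <= 2 * rmax:
        raise PlacementError(f"part_shape {shape} too small for puncta placement")
    placed = []  # (cy, cx, a, b, theta) with a >= b semi-axes
    attempts = 0
    while len(placed) < count:
        if attempts >= params.max_place_attempts:
            raise PlacementError(
                f"could not place {count} disjoint puncta in {shape} "
                f"after {params.max_place_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(rmin, rmax)
        ecc = rng.uniform(1.0, 2.0)  # axis ratio a:b, at most 2:1
        a, b = r * np.sqrt(ecc), r / np.sqrt(ecc)
        theta = rng.uniform(0.0, np.pi)
        cy = rng.uniform(margin + a, h - 1 - margin - a)
        cx = rng.uniform(margin + a, w - 1 - margin - a)
        ok = True
        for py, px, pa, _, _ in placed:
            if np.hypot(cy - py, cx - px) < a + pa + 2.5:
                ok = False
                break
        if ok:
            placed.append((cy, cx, a, b, theta))
    return placed


def render_part(count: int, params: PhantomParams, rng: np.random.Generator):
    """Render one part: textured background + `count` bright puncta + noise.

    Returns (raw uint16 grid, mask uint8 grid); the mask has exactly `count`
    8-connected components.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    shape = tuple(params.part_shape)
    image, bias, noise_sd, boost = _tissue_background(shape, params, rng)
    mask = np.zeros(shape, dtype=np.uint8)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]

    def _elliptical_distance(cy, cx, a, b, theta):
        c, s = np.cos(theta), np.sin(theta)
        u = (yy - cy) * c + (xx - cx) * s
        v = -(yy - cy) * s + (xx - cx) * c
        return np.sqrt((u / a) ** 2 + (v / b) ** 2)

    puncta = _place_puncta(count, shape, params, rng)
    for cy, cx, a, b, theta in puncta:
        d = _elliptical_distance(cy, cx, a, b, theta)
        mask[d <= 1.0] = 1
        # bright core with an anti-aliased rim; the bias field applies to
        # puncta as well (they are part of the imaged tissue)
        profile = np.clip((1.3 - d) / 0.6, 0.0, 1.0)
        image += boost * params.dynamic_range * profile * bias

    # non-ePVS bright confounders: larger elongated structures a rater would
    # not count; kept clear of the puncta so the mask stays exact
    n_distract = int(rng.poisson(params.distractor_rate))
    dmin, dmax = params.distractor_radius_range
    h, w = shape
    for _ in range(n_distract):
        for _ in range(50):  # placement attempts per distractor; skip if crowded
            r = rng.uniform(dmin, dmax)
            ecc = rng.uniform(1.0, params.distractor_ecc_max)
            a, b = r * np.sqrt(ecc), r / np.sqrt(ecc)
            theta = rng.uniform(0.0, np.pi)
            cy = rng.uniform(a + 1, h - 2 - a)
            cx = rng.uniform(a + 1, w - 2 - a)
            if all(np.hypot(cy - py, cx - px) >= a + pa + 2.5 for py, px, pa, _, _ in puncta):
                d = _elliptical_distance(cy, cx, a, b, theta)
                profile = np.clip((1.3 - d) / 0.6, 0.0, 1.0)
                image += boost * rng.uniform(*params.distractor_boost_range) * params.dynamic_range * profile * bias
                break

    image += noise_sd * rng.standard_normal(shape)
    raw = np.clip(np.rint(image), 0, params.dynamic_range).astype(np.uint16)
    return raw, mask


def render_slice_with_roi(
    params: PhantomParams,
    rng: np.random.Generator,
    canvas_shape: tuple[int, int] = (200, 232),
    counts: tuple[int, int] = (6, 6),
):
    """Whole-slice emitter for exercising ROI cropping: a tissue canvas with
    two elliptical basal-ganglia-like ROIs (left, right), puncta inside each.

    Returns (slice raw uint16, roi_mask uint8, (left_count, right_count)).
    """
    h, w = canvas_shape
    canvas, _, noise_sd, boost = _tissue_background(canvas_shape, params, rng)
    roi = np.zeros(canvas_shape, dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    part_h, part_w = params.part_shape
    for side, count in zip(("left", "right"), counts):
        cx = w * 0.27 if side == "left" else w * 0.73
        cy = h * 0.5
        ry, rx = min(part_h, h) * 0.38, min(part_w, w // 2) * 0.38
        ellipse = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        roi[ellipse] = 1
        sub_rng_count = count
        placed = 0
        attempts = 0
        rmin, rmax = params.puncta_radius_range
        while placed < sub_rng_count and attempts < params.max_place_attempts:
            attempts += 1
            r = rng.uniform(rmin, rmax)
            py = rng.uniform(cy - ry * 0.7, cy + ry * 0.7)
            px = rng.uniform(cx - rx * 0.7, cx + rx * 0.7)
            d = np.sqrt((yy - py) ** 2 + (xx - px) ** 2) / r
            profile = np.clip((1.3 - d) / 0.6, 0.0, 1.0)
            canvas += boost * params.dynamic_range * profile
            placed += 1
    canvas += noise_sd * rng.standard_normal(canvas_shape)
    raw = np.clip(np.rint(canvas), 0, params.dynamic_range).astype(np.uint16)
    return raw, roi, counts


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

SLICES = (1, 2, 3)
HEMISPHERES = ("left", "right")


def generate_subject(subject_id: str, params: PhantomParams, rng: np.random.Generator) -> SubjectRecord:
    parts = []
    for slice_index in SLICES:
        for hemisphere in HEMISPHERES:
            count = sample_count(params, rng)
            raw, mask = render_part(count, params, rng)
            parts.append(
                PartImage(
                    subject_id=subject_id,
                    slice_index=slice_index,
                    hemisphere=hemisphere,
                    raw=raw,
                    mask=mask,
                    count=count,
                    grade=grade_from_count(count),
                )
            )
    return SubjectRecord(
        subject_id=subject_id,
        parts=tuple(parts),
        subject_grade=max(p.grade for p in parts),
    )


def generate_cohort(n_subjects: int, params: PhantomParams | None = None, seed: int = 0) -> list[SubjectRecord]:
    """Generate a seeded cohort of `n_subjects` x 6 part images."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    return [generate_subject(f"S{i + 1:04d}", params, rng) for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# Cohort I/O (16-bit TIFF parts + manifest CSV)
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "slice_index", "hemisphere", "count", "grade", "image_path", "mask_path"]


def write_cohort(records: list[SubjectRecord], outdir) -> "pathlib.Path":
    """Write per-part 16-bit TIFFs plus a manifest CSV; returns the manifest path."""
    import pathlib

    import pandas as pd
    import tifffile

    outdir = pathlib.Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for p in rec.parts:
            stem = f"{p.subject_id}_s{p.slice_index}_{p.hemisphere}"
            image_path = f"images/{stem}.tif"
            mask_path = f"masks/{stem}_mask.tif"
            tifffile.imwrite(outdir / image_path, p.raw)
            tifffile.imwrite(outdir / mask_path, p.mask)
            rows.append([p.subject_id, p.slice_index, p.hemisphere, p.count, p.grade, image_path, mask_path])
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def _load_grid(path):
    """Read a 2D image from TIFF or NIfTI (first slice of a 3D volume)."""
    import pathlib

    path = pathlib.Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib

        data = np.asanyarray(nib.load(path).dataobj)
        return data[..., 0] if data.ndim == 3 else data
    import tifffile

    return tifffile.imread(path)


def read_cohort(manifest_path) -> list[SubjectRecord]:
    """Rebuild SubjectRecords from a manifest CSV written by `write_cohort`."""
    import pathlib

    import pandas as pd

    manifest_path = pathlib.Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for subject_id, group in df.groupby("subject_id", sort=True):
        parts = []
        for _, row in group.sort_values(["slice_index", "hemisphere"]).iterrows():
            raw = _load_grid(base / row.image_path)
            mask = (_load_grid(base / row.mask_path) > 0).astype(np.uint8)
            parts.append(
                PartImage(
                    subject_id=str(subject_id),
                    slice_index=int(row.slice_index),
                    hemisphere=str(row.hemisphere),
                    raw=raw,
                    mask=mask,
                    count=int(row["count"]),
                    grade=int(row.grade),
                )
            )
        records.append(
            SubjectRecord(
                subject_id=str(subject_id),
                parts=tuple(parts),
                subject_grade=max(p.grade for p in parts),
            )
        )
    return records
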