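"""Procedural psoriasis-like image cohorts with exact ground truth.

The clinical imagery this tool targets is private, so the test bed is a
procedural generator that emulates its *structure*: several photographs
per body region per visit, each showing plaques on a skin-tone field,
with lesion bounding boxes and PASI subscores known exactly because they
are derived from the generator's own parameters.

Each of the four PASI subscales maps to one rendering knob:

===================  =========================  =======================
knob (all in [0,1])  visual effect              ground-truth subscore
===================  =========================  =======================
coverage_fraction    plaque pixel fraction      area band = band(100*f)
redness              interior shift toward red  erythema = floor(5x)
speckle_density      white speckle overlay      desquamation = floor(5x)
border_shading       darkened border ring       induration = floor(5x)
===================  =========================  =======================

(floor(5x) clamped to 0..4.)  Plaques are non-overlapping ellipses placed
by rejection sampling until their union covers the requested fraction of
pixels to within +/-2 percentage points; the final ellipse's radius is
bisected to land inside the tolerance.  All randomness flows from one
integer seed through ``numpy`` SeedSequence spawning, so cohorts are
bit-reproducible.  Photorealism is explicitly not a goal — recoverability
of the ground truth from the pixels is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .core import (
    Region,
    RegionAssessment,
    VisitAssessment,
    area_percent_to_band,
    compose_pasi,
    severity_band,
)

__all__ = [
    "LesionParams",
    "SyntheticVisit",
    "RegionSample",
    "GenerationError",
    "generate_region_images",
    "params_to_subscores",
    "plan_cohort",
    "generate_cohort",
    "load_manifest",
    "group_manifest",
]


class GenerationError(RuntimeError):
    pass


DEFAULT_SKIN_TONE = (205, 170, 148)

MANIFEST_COLUMNS = [
    "patient_id",
    "visit_id",
    "region",
    "image_path",
    "x0",
    "y0",
    "x1",
    "y1",
    "area_band",
    "erythema",
    "induration",
    "desquamation",
    "pasi",
    "split",
]


@dataclass(frozen=True)
class LesionParams:
    """Rendering knobs for one body region; see the module table."""

    coverage_fraction: float
    redness: float
    speckle_density: float
    border_shading: float
    skin_tone: tuple[int, int, int] = DEFAULT_SKIN_TONE
    lighting_jitter: float = 0.05

    def __post_init__(self) -> None:
        for name in ("coverage_fraction", "redness", "speckle_density", "border_shading"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.lighting_jitter < 0:
            raise ValueError("lighting_jitter must be >= 0")


@dataclass
class SyntheticVisit:
    """Ground-truth plan for one visit: per-region params + assessment."""

    patient_id: str
    visit_id: str
    params: dict[Region, LesionParams]
    truth: VisitAssessment
    seed: int
    split: str = "train"


@dataclass
class RegionSample:
    """One (visit, region) group from a manifest: the model's unit of work."""

    patient_id: str
    visit_id: str
    region: Region
    image_paths: list[str]
    boxes: list[list[tuple[int, int, int, int]]]  # per image
    assessment: RegionAssessment
    pasi: float
    split: str


def params_to_subscores(params: LesionParams, region: Region = Region.TRUNK) -> RegionAssessment:
    """Deterministic map from rendering knobs to PASI subscores."""

    def five_level(x: float) -> int:
        return int(min(4, max(0, math.floor(5.0 * x))))

    return RegionAssessment(
        region=region,
        area_band=area_percent_to_band(100.0 * params.coverage_fraction),
        erythema=five_level(params.redness),
        induration=five_level(params.border_shading),
        desquamation=five_level(params.speckle_density),
    )


def _place_ellipses(
    coverage: float,
    size: tuple[int, int],
    rng: np.random.Generator,
    tol_frac: float = 0.02,
    max_attempts: int = 1000,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Rejection-sample non-overlapping ellipses until the union covers
    ``coverage`` of the pixel grid within +/-tol_frac.  Returns the union
    mask and the per-ellipse masks."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    target = coverage * h * w
    tol = tol_frac * h * w
    union = np.zeros((h, w), dtype=bool)
    ellipses: list[np.ndarray] = []

    def raster(cy, cx, ry, rx):
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    for _ in range(max_attempts):
        deficit = target - union.sum()
        if deficit <= tol and (union.any() or coverage == 0):
            break
        # aim this ellipse at a random share of the remaining deficit
        # plaques may run off-frame (clipped), so near-full coverage is
        # reachable despite the non-overlap constraint; a large deficit is
        # seeded with one oversized centered ellipse that the bisection
        # below trims into the tolerance band
        if not union.any() and deficit > 0.4 * h * w:
            area = deficit * rng.uniform(1.8, 2.6)
            cy = h / 2 + rng.uniform(-0.05, 0.05) * h
            cx = w / 2 + rng.uniform(-0.05, 0.05) * w
            aspect = rng.uniform(0.9, 1.1)
        else:
            area = max(4.0, deficit * rng.uniform(0.3, 1.0))
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            if union[int(cy), int(cx)]:
                continue
            aspect = rng.uniform(0.6, 1.6)
        r = math.sqrt(area / math.pi)
        ry = min(max(1.5, r * aspect), 1.2 * h)
        rx = min(max(1.5, r / aspect), 1.2 * w)
        mask = raster(cy, cx, ry, rx)
        if (mask & union).any():
            continue
        overshoot = union.sum() + mask.sum() - target
        if overshoot > tol:
            # bisect a radial scale so the union lands inside the band
            lo_s, hi_s = 0.0, 1.0
            best = None
            for _ in range(24):
                s = 0.5 * (lo_s + hi_s)
                m = raster(cy, cx, max(1.0, ry * s), max(1.0, rx * s))
                if (m & union).any():
                    hi_s = s
                    continue
                total = union.sum() + m.sum()
                if total > target + tol:
                    hi_s = s
                elif total < target - tol:
                    lo_s = s
                    best = m  # still helps even if slightly short
                else:
                    best = m
                    break
            mask = best if best is not None else None
            if mask is None or not mask.any():
                continue
        union |= mask
        ellipses.append(mask)
    else:
        deficit = target - union.sum()
        if abs(deficit) > tol or (coverage > 0 and not union.any()):
            raise GenerationError(
                f"could not reach coverage {coverage:.3f} at size {size}"
            )
    if coverage > 0 and not union.any():
        raise GenerationError(f"coverage {coverage:.3f} produced no plaques")
    return union, ellipses


def _tight_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def generate_region_images(
    params: LesionParams,
    n_images: int,
    size: tuple[int, int] = (64, 80),
    seed: int = 0,
) -> list[tuple[np.ndarray, list[tuple[int, int, int, int]]]]:
    """Render ``n_images`` views of one region.

    All views share the same plaque layout, speckle pattern and skin
    texture (it is the same skin); each view applies its own seeded
    lighting/color jitter.  Boxes are axis-aligned, 0-based, half-open
    (x0, y0, x1, y1), one per plaque.  Deterministic in (params, seed).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    h, w = size
    if h < 8 or w < 8:
        raise GenerationError(f"image size {size} too small to render plaques")
    ss = np.random.SeedSequence([seed, 0x5EED])
    layout_rng = np.random.default_rng(ss.spawn(1)[0])
    view_rngs = [np.random.default_rng(c) for c in ss.spawn(n_images + 1)[1:]]

    last_err: Exception | None = None
    for retry in range(5):
        try:
            rng = layout_rng if retry == 0 else np.random.default_rng(
                np.random.SeedSequence([seed, 0x5EED, retry])
            )
            union, ellipses = _place_ellipses(params.coverage_fraction, size, rng)
            break
        except GenerationError as exc:
            last_err = exc
    else:
        raise GenerationError(f"generation failed after retries: {last_err}")
    boxes = [_tight_box(m) for m in ellipses]

    # -- shared appearance layers -------------------------------------
    tone = np.array(params.skin_tone, dtype=np.float64)
    texture = layout_rng.normal(0.0, 3.0, size=(h, w, 1))
    base = np.clip(tone[None, None, :] + texture, 0, 255)

    lesion = base.copy()
    shift = np.array(
        [12 + 55 * params.redness, -10 - 45 * params.redness, -8 - 40 * params.redness]
    )
    lesion = lesion + shift[None, None, :]

    if params.border_shading > 0 and union.any():
        interior = ndimage.binary_erosion(union, iterations=2)
        ring = union & ~interior
    else:
        ring = np.zeros_like(union)

    speckle = np.zeros((h, w), dtype=bool)
    if params.speckle_density > 0 and union.any():
        speckle = union & (
            layout_rng.random((h, w)) < 0.65 * params.speckle_density
        )

    canvas = base.copy()
    canvas[union] = lesion[union]
    canvas[ring] *= 1.0 - 0.5 * params.border_shading
    canvas[speckle] = 0.25 * canvas[speckle] + 0.75 * np.array([235.0, 230.0, 224.0])

    # -- per-view jitter ----------------------------------------------
    out = []
    for vr in view_rngs:
        gain = 1.0 + params.lighting_jitter * vr.uniform(-1, 1)
        cgain = 1.0 + 0.5 * params.lighting_jitter * vr.uniform(-1, 1, size=3)
        offset = 25.0 * params.lighting_jitter * vr.uniform(-1, 1)
        img = canvas * gain * cgain[None, None, :] + offset
        out.append((np.clip(np.rint(img), 0, 255).astype(np.uint8), list(boxes)))
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Subscore sampling ranges per severity band (inclusive), used as the
#: proposal distribution of the rejection sampler.
_BAND_RANGES = {
    "low": ((0, 3), (0, 2)),
    "medium": ((1, 4), (1, 3)),
    "high": ((2, 6), (1, 4)),
}

#: Area-band -> coverage-percent interval to draw from, kept strictly
#: inside each band so rendering tolerance cannot flip the band.
_BAND_PERCENT = {
    0: (0.0, 0.0),
    1: (3.0, 9.0),
    2: (12.0, 28.0),
    3: (32.0, 48.0),
    4: (52.0, 68.0),
    5: (72.0, 85.0),
    6: (90.0, 96.0),
}


def _sample_visit_in_band(band: str, rng: np.random.Generator) -> list[RegionAssessment]:
    (a_lo, a_hi), (s_lo, s_hi) = _BAND_RANGES[band]
    for _ in range(20000):
        regions = [
            RegionAssessment(
                region=r,
                area_band=int(rng.integers(a_lo, a_hi + 1)),
                erythema=int(rng.integers(s_lo, s_hi + 1)),
                induration=int(rng.integers(s_lo, s_hi + 1)),
                desquamation=int(rng.integers(s_lo, s_hi + 1)),
            )
            for r in Region
        ]
        if severity_band(compose_pasi(regions)) == band:
            return regions
    raise GenerationError(f"could not sample a visit in band {band!r}")


def _params_for_assessment(a: RegionAssessment, rng: np.random.Generator) -> LesionParams:
    lo, hi = _BAND_PERCENT[a.area_band]
    coverage = rng.uniform(lo, hi) / 100.0 if a.area_band > 0 else 0.0

    def knob(score: int) -> float:
        # floor(5x) == score  <=>  x in [score/5, (score+1)/5); stay inside
        return (score + rng.uniform(0.05, 0.95)) / 5.0

    return LesionParams(
        coverage_fraction=coverage,
        redness=knob(a.erythema),
        speckle_density=knob(a.desquamation),
        border_shading=knob(a.induration),
    )


_BAND_ORDER = {"high": 0, "medium": 1, "low": 2}


def plan_cohort(
    n_patients: int,
    visits_per_patient: int = 1,
    severity_mix: tuple[float, float, float] = (0.5, 0.28, 0.22),
    seed: int = 0,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> list[SyntheticVisit]:
    """Draw the ground truth of a cohort without rendering any pixels.

    Severity bands are drawn i.i.d. from ``severity_mix`` (low, medium,
    high) per visit, then each patient's bands are sorted from worst to
    best so successive visits follow an improvement trend; sorting keeps
    the marginal band proportions exact.  Splits are assigned per patient
    (70/15/15 train/val/test by default).
    """
    if abs(sum(severity_mix) - 1.0) > 1e-9:
        raise ValueError(f"severity_mix must sum to 1, got {severity_mix}")
    ss = np.random.SeedSequence([seed, 0xC0407])
    rng = np.random.default_rng(ss)
    bands = ("low", "medium", "high")

    # per-patient splits
    order = rng.permutation(n_patients)
    n_train = int(round(split_fractions[0] * n_patients))
    n_val = int(round(split_fractions[1] * n_patients))
    split_of = {}
    for i, p in enumerate(order):
        split_of[p] = "train" if i < n_train else ("val" if i < n_train + n_val else "test")

    visits: list[SyntheticVisit] = []
    for p in range(n_patients):
        drawn = [bands[rng.choice(3, p=np.asarray(severity_mix))] for _ in range(visits_per_patient)]
        drawn.sort(key=_BAND_ORDER.__getitem__)  # worst first -> improvement
        for v, band in enumerate(drawn):
            regions = _sample_visit_in_band(band, rng)
            params = {a.region: _params_for_assessment(a, rng) for a in regions}
            truth = VisitAssessment(
                patient_id=f"p{p:04d}", visit_id=f"v{v:02d}", regions=regions
            )
            vseed = int(np.random.SeedSequence([seed, p, v]).generate_state(1)[0] % (2**31))
            visits.append(
                SyntheticVisit(
                    patient_id=truth.patient_id,
                    visit_id=truth.visit_id,
                    params=params,
                    truth=truth,
                    seed=vseed,
                    split=split_of[p],
                )
            )
    return visits


def generate_cohort(
    out_dir: str | Path,
    n_patients: int,
    visits_per_patient: int = 1,
    severity_mix: tuple[float, float, float] = (0.5, 0.28, 0.22),
    seed: int = 0,
    n_images: int = 3,
    image_size: tuple[int, int] = (64, 80),
) -> tuple[Path, pd.DataFrame]:
    """Render a cohort to disk: PNG images plus a manifest CSV.

    The manifest has one row per lesion box (images without lesions get a
    single row with empty box fields) and carries the ground-truth
    subscores, the composed total PASI and the patient-level split.
    Returns (manifest_path, manifest_frame).
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise GenerationError(f"cannot create output dir {img_dir}: {exc}") from exc

    rows: list[dict] = []
    for visit in plan_cohort(n_patients, visits_per_patient, severity_mix, seed):
        for r_idx, region in enumerate(Region):
            a = visit.truth.region(region)
            rseed = int(
                np.random.SeedSequence([visit.seed, r_idx]).generate_state(1)[0] % (2**31)
            )
            rendered = generate_region_images(
                visit.params[region], n_images, image_size, seed=rseed
            )
            for k, (img, boxes) in enumerate(rendered):
                rel = f"images/{visit.patient_id}_{visit.visit_id}_{region.value}_{k}.png"
                path = out_dir / rel
                try:
                    Image.fromarray(img).save(path)
                except OSError as exc:
                    raise GenerationError(f"cannot write image {path}: {exc}") from exc
                common = {
                    "patient_id": visit.patient_id,
                    "visit_id": visit.visit_id,
                    "region": region.value,
                    "image_path": rel,
                    "area_band": a.area_band,
                    "erythema": a.erythema,
                    "induration": a.induration,
                    "desquamation": a.desquamation,
                    "pasi": visit.truth.pasi,
                    "split": visit.split,
                }
                if boxes:
                    for x0, y0, x1, y1 in boxes:
                        rows.append({**common, "x0": x0, "y0": y0, "x1": x1, "y1": y1})
                else:
                    rows.append({**common, "x0": None, "y0": None, "x1": None, "y1": None})

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path, manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return df


def group_manifest(df: pd.DataFrame, root: str | Path = ".") -> list[RegionSample]:
    """Collapse manifest rows into one RegionSample per (visit, region)."""
    root = Path(root)
    samples: list[RegionSample] = []
    for (pid, vid, region), g in df.groupby(
        ["patient_id", "visit_id", "region"], sort=True
    ):
        paths: list[str] = []
        boxes: list[list[tuple[int, int, int, int]]] = []
        for img_path, gi in g.groupby("image_path", sort=True):
            paths.append(str(root / img_path))
            bx = []
            for _, row in gi.iterrows():
                if pd.notna(row["x0"]):
                    bx.append(
                        (int(row["x0"]), int(row["y0"]), int(row["x1"]), int(row["y1"]))
                    )
            boxes.append(bx)
        first = g.iloc[0]
        samples.append(
            RegionSample(
                patient_id=str(pid),
                visit_id=str(vid),
                region=Region(region),
                image_paths=paths,
                boxes=boxes,
                assessment=RegionAssessment(
                    region=Region(region),
                    area_band=int(first["area_band"]),
                    erythema=int(first["erythema"]),
                    induration=int(first["induration"]),
                    desquamation=int(first["desquamation"]),
                ),
                pasi=float(first["pasi"]),
                split=str(first["split"]),
            )
        )
    return samples
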