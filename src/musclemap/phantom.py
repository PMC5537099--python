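"""Synthetic axial-CT phantoms with paired ground-truth label maps.

The generator emulates a single abdominal slice at the level of the third
lumbar vertebra, at the fidelity a segmentation network needs rather than
X-ray physics fidelity: an air background, an elliptical body with a
subcutaneous-fat rind, a closed muscle ring in the lean-tissue Hounsfield
range, and an "Inside" compartment containing visceral fat, organs whose HU
overlaps muscle, and a high-attenuation vertebral body.  The HU overlap
between muscle and organs is what defeats plain HU thresholding and is the
reason a learned segmenter is needed; the phantom reproduces exactly that
structure.

Label legend (fixed): 0 = Background, 1 = Muscle, 2 = Inside.  Subcutaneous
fat lies outside the muscle ring and is labeled Background.  Intramuscular
fat pockets keep the Muscle label while carrying fat-range HU, so that
HU-based post-processing has genuine work to do.  An optional subcutaneous
edema blob carries muscle-range HU under a Background label — the classic
false-positive mode of intensity-based muscle segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "HUImage",
    "LabelMap",
    "PhantomSample",
    "generate_phantom",
    "generate_phantom_sample",
    "generate_cohort",
    "stratified_split",
    "AIR_HU",
]

AIR_HU = -1000.0

#: Label indices, fixed across the package.
BACKGROUND, MUSCLE, INSIDE = 0, 1, 2


class PhantomSpecError(ValueError):
    """A PhantomSpec violates one of its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    ``habitus`` is a positive scale factor for body size and fat-rind
    thickness and stands in for a BMI category; noise is scaled by it as
    well, since larger patients yield noisier CT images.
    """

    image_size: int = 128
    pixel_spacing: float = 3.4  # mm/px; ~44 cm field of view at 128 px
    habitus: float = 1.0
    muscle_ring_thickness: float = 7.0  # px
    n_organs: int = 3
    organ_hu_range: tuple[float, float] = (-10.0, 120.0)
    fat_hu_range: tuple[float, float] = (-190.0, -30.0)
    muscle_hu_range: tuple[float, float] = (-29.0, 150.0)
    vertebra_hu: float = 400.0
    intramuscular_fat_fraction: float = 0.05
    edema_probability: float = 0.1
    noise_sd: float = 10.0  # HU, further scaled by habitus
    smoothing_sigma: float = 0.6  # px, partial-volume proxy

    def validate(self) -> None:
        def interval(name: str, iv: tuple[float, float]) -> None:
            if not iv[0] < iv[1]:
                raise PhantomSpecError(f"{name} must be a non-empty interval, got {iv}")

        if self.image_size % 32 != 0:
            raise PhantomSpecError(
                f"image_size must be divisible by 32, got {self.image_size}"
            )
        if self.pixel_spacing <= 0:
            raise PhantomSpecError("pixel_spacing must be positive")
        if self.habitus <= 0:
            raise PhantomSpecError("habitus must be positive")
        interval("organ_hu_range", self.organ_hu_range)
        interval("fat_hu_range", self.fat_hu_range)
        interval("muscle_hu_range", self.muscle_hu_range)
        f, m = self.fat_hu_range, self.muscle_hu_range
        if not (f[1] < m[0] or m[1] < f[0]):
            raise PhantomSpecError(
                f"fat_hu_range {f} and muscle_hu_range {m} must be disjoint"
            )
        o = self.organ_hu_range
        if o[1] < m[0] or m[1] < o[0]:
            raise PhantomSpecError(
                f"organ_hu_range {o} must intersect muscle_hu_range {m}"
            )
        if not 0.0 <= self.intramuscular_fat_fraction <= 1.0:
            raise PhantomSpecError("intramuscular_fat_fraction must be in [0, 1]")
        if not 0.0 <= self.edema_probability <= 1.0:
            raise PhantomSpecError("edema_probability must be in [0, 1]")
        if self.noise_sd < 0 or self.smoothing_sigma < 0:
            raise PhantomSpecError("noise_sd and smoothing_sigma must be >= 0")
        if self.muscle_ring_thickness < 2:
            raise PhantomSpecError("muscle_ring_thickness must be >= 2 px")


@dataclass(frozen=True)
class HUImage:
    """A 2D grid of Hounsfield units with isotropic pixel spacing in mm."""

    values: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("HUImage requires a 2D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("HUImage values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel class indices: 0 Background, 1 Muscle, 2 Inside."""

    classes: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.classes)
        if c.ndim != 2:
            raise ValueError("LabelMap requires a 2D array")
        if not np.isin(c, (BACKGROUND, MUSCLE, INSIDE)).all():
            raise ValueError("LabelMap values must be in {0, 1, 2}")
        object.__setattr__(self, "classes", c.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


@dataclass(frozen=True)
class PhantomSample:
    """A phantom with generator bookkeeping (pocket masks etc.) attached."""

    image: HUImage
    labels: LabelMap
    info: dict = field(default_factory=dict)


def _ellipse_mask(shape, cy, cx, ry, rx):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _texture(rng, n, base, sd, lo, hi):
    return np.clip(rng.normal(base, sd, size=n), lo, hi)


def generate_phantom_sample(spec: PhantomSpec, seed: int) -> PhantomSample:
    """Generate one phantom; deterministic in (spec, seed).

    Tissue HU is assigned region by region (a per-region base level plus
    clipped Gaussian texture, always inside the region's HU interval), then
    optionally blurred (partial-volume proxy) and corrupted with additive
    Gaussian noise whose SD scales with habitus.  Labels are never blurred.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x9E37]))
    s = spec.image_size
    h = spec.habitus

    # --- geometry -----------------------------------------------------------
    cy = s / 2 + rng.uniform(-0.015, 0.015) * s
    cx = s / 2 + rng.uniform(-0.015, 0.015) * s
    ry_body = 0.27 * s * h * (1 + rng.uniform(-0.04, 0.04))
    rx_body = 0.34 * s * h * (1 + rng.uniform(-0.04, 0.04))
    t_fat = (0.05 + 0.06 * max(h - 1.0, 0.0)) * s  # subcutaneous rind, px
    ry_mo, rx_mo = ry_body - t_fat, rx_body - t_fat  # muscle outer
    t = spec.muscle_ring_thickness
    ry_mi, rx_mi = ry_mo - t, rx_mo - t  # muscle inner
    if ry_mi <= 4 or rx_mi <= 4:
        raise PhantomSpecError(
            "geometry degenerate: muscle ring leaves no interior "
            f"(habitus={h}, ring thickness={t})"
        )

    body = _ellipse_mask((s, s), cy, cx, ry_body, rx_body)
    m_out = _ellipse_mask((s, s), cy, cx, ry_mo, rx_mo)
    m_in = _ellipse_mask((s, s), cy, cx, ry_mi, rx_mi)
    muscle = m_out & ~m_in
    subcut = body & ~m_out

    labels = np.zeros((s, s), dtype=np.uint8)
    labels[muscle] = MUSCLE
    labels[m_in] = INSIDE

    # --- Hounsfield units ---------------------------------------------------
    hu = np.full((s, s), AIR_HU)
    flo, fhi = spec.fat_hu_range
    mlo, mhi = spec.muscle_hu_range
    fat_base = np.clip(-100.0, flo + 5, fhi - 5)
    hu[subcut] = _texture(rng, subcut.sum(), fat_base, 12.0, flo, fhi)
    hu[m_in] = _texture(rng, m_in.sum(), fat_base, 12.0, flo, fhi)  # visceral fat
    muscle_base = float(np.clip(55.0, mlo, mhi))
    hu[muscle] = _texture(rng, muscle.sum(), muscle_base, 15.0, mlo, mhi)

    # organs: ellipses strictly inside the inner compartment, lean-tissue HU;
    # sized to occupy a substantial share of the interior, as bowel/liver/
    # kidneys do at L3 — this is what defeats plain HU thresholding
    olo, ohi = spec.organ_hu_range
    for _ in range(spec.n_organs):
        fy = rng.uniform(0.20, 0.45)
        fx = rng.uniform(0.20, 0.45)
        theta = rng.uniform(0, 2 * np.pi)
        rad = (1.0 - max(fy, fx) - 0.05) * np.sqrt(rng.uniform())
        ocy = cy + rad * np.sin(theta) * ry_mi
        ocx = cx + rad * np.cos(theta) * rx_mi
        o_ry = fy * ry_mi
        o_rx = fx * rx_mi
        om = _ellipse_mask((s, s), ocy, ocx, o_ry, o_rx) & m_in
        span = ohi - olo
        base = rng.uniform(olo + 0.15 * span, ohi - 0.15 * span)
        hu[om] = _texture(rng, om.sum(), base, 0.1 * span, olo, ohi)

    # vertebra: fixed posterior-midline blob inside the inner compartment
    vcy = cy + 0.60 * ry_mi
    vm = _ellipse_mask((s, s), vcy, cx, 0.22 * ry_mi, 0.16 * rx_mi) & m_in
    hu[vm] = np.clip(
        rng.normal(spec.vertebra_hu, 25.0, vm.sum()),
        spec.vertebra_hu - 80,
        spec.vertebra_hu + 150,
    )

    # intramuscular fat: small pockets, fat HU under a Muscle label
    imf_mask = np.zeros((s, s), dtype=bool)
    n_target = int(round(spec.intramuscular_fat_fraction * muscle.sum()))
    if n_target > 0:
        midx = np.flatnonzero(muscle.ravel())
        chosen: list[int] = []
        chosen_set: set[int] = set()
        yy, xx = np.unravel_index(midx, (s, s))
        while len(chosen) < n_target:
            k = rng.integers(len(midx))
            py, px = yy[k], xx[k]
            r = rng.uniform(1.0, 2.5)
            pocket = _ellipse_mask((s, s), py, px, r, r) & muscle
            for idx in np.flatnonzero(pocket.ravel()):
                if idx not in chosen_set:
                    chosen.append(idx)
                    chosen_set.add(idx)
        sel = np.array(chosen[:n_target])
        imf_mask.ravel()[sel] = True
        hu.ravel()[sel] = _texture(rng, n_target, fat_base, 10.0, flo + 10, fhi - 10)

    # subcutaneous edema: muscle-range HU, Background label
    edema_mask = np.zeros((s, s), dtype=bool)
    if rng.uniform() < spec.edema_probability:
        theta = rng.uniform(0, 2 * np.pi)
        ecy = cy + np.sin(theta) * (ry_mo + t_fat / 2)
        ecx = cx + np.cos(theta) * (rx_mo + t_fat / 2)
        er = max(t_fat * rng.uniform(0.6, 1.0), 2.0)
        edema_mask = _ellipse_mask((s, s), ecy, ecx, er, er) & subcut
        hu[edema_mask] = _texture(rng, edema_mask.sum(), muscle_base, 15.0, mlo, mhi)

    if spec.smoothing_sigma > 0:
        hu = ndimage.gaussian_filter(hu, spec.smoothing_sigma)
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd * h, size=hu.shape)

    info = {
        "habitus": h,
        "body_mask": body,
        "imf_mask": imf_mask,
        "imf_count": int(imf_mask.sum()),
        "edema_mask": edema_mask,
        "seed": int(seed),
    }
    return PhantomSample(HUImage(hu, spec.pixel_spacing), LabelMap(labels), info)


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[HUImage, LabelMap]:
    """Generate one phantom slice and its ground-truth label map."""
    sample = generate_phantom_sample(spec, seed)
    return sample.image, sample.labels


def generate_cohort(
    spec_ranges: Mapping[str, tuple[float, float]],
    n: int,
    seed: int,
    base_spec: PhantomSpec | None = None,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms balanced across habitus strata.

    ``spec_ranges`` maps stratum name -> (lo, hi) habitus interval, in a
    deterministic order.  Phantoms are assigned to strata round-robin, so
    per-stratum counts differ by at most one; each phantom draws its habitus
    uniformly from its stratum's interval.  Each sample's ``info`` carries
    its ``stratum`` tag.
    """
    if not spec_ranges:
        raise ValueError("spec_ranges must name at least one stratum")
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    strata = list(spec_ranges.items())
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    children = ss.spawn(n)
    out: list[PhantomSample] = []
    for i in range(n):
        name, (lo, hi) = strata[i % len(strata)]
        rng = np.random.default_rng(children[i])
        habitus = float(rng.uniform(lo, hi))
        child_seed = int(rng.integers(0, 2**31 - 1))
        sample = generate_phantom_sample(replace(base, habitus=habitus), child_seed)
        sample.info["stratum"] = name
        sample.info["index"] = i
        out.append(sample)
    return out


def stratified_split(
    cohort: Sequence[PhantomSample], test_per_stratum: int, seed: int
) -> tuple[list[PhantomSample], list[PhantomSample]]:
    """Hold out ``test_per_stratum`` phantoms per stratum, seeded.

    Mirrors a balanced patient-selection protocol: the held-out set has the
    same per-stratum size everywhere, and a fixed seed reproduces the same
    membership.  Raises if any stratum would be left without training
    members.
    """
    if test_per_stratum < 1:
        raise ValueError("test_per_stratum must be >= 1")
    by_stratum: dict[str, list[int]] = {}
    for i, sample in enumerate(cohort):
        by_stratum.setdefault(sample.info["stratum"], []).append(i)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x51]))
    test_idx: list[int] = []
    for name in by_stratum:  # insertion order: deterministic
        members = by_stratum[name]
        if len(members) <= test_per_stratum:
            raise ValueError(
                f"stratum {name!r} has {len(members)} members; "
                f"holding out {test_per_stratum} leaves no training members"
            )
        pick = rng.choice(len(members), size=test_per_stratum, replace=False)
        test_idx.extend(members[int(j)] for j in sorted(pick))
    test_set = set(test_idx)
    train = [s for i, s in enumerate(cohort) if i not in test_set]
    test = [s for i, s in enumerate(cohort) if i in test_set]
    return train, test
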