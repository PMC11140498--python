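"""Synthetic head-phantom examination generator.

Emulates a multi-institution head-CT study at desk scale: 2D grayscale
"axial" images of an elliptical head of textured tissue on a dark
background, with optional bright elliptical lesions (the contrast polarity
of acute blood on CT).  Three ``DomainSpec`` presets stand in for three
institutions: a small pixel-labeled training site, a large unlabeled
corpus, and an out-of-distribution test site that differs in noise level,
contrast and head aspect ratio.

Everything is driven by :class:`numpy.random.Generator` instances so the
same configuration and seed reproduce a bit-identical corpus.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DomainSpec",
    "ExamRecord",
    "StudyCorpus",
    "StudyConfig",
    "SplitConfig",
    "make_head_image",
    "make_exam",
    "make_domain_dataset",
    "make_study_corpus",
    "default_study_config",
]


@dataclass(frozen=True)
class DomainSpec:
    """Appearance parameters of one synthetic "institution".

    All intensities are on the [0, 1] grayscale of the generated images.

    Parameters
    ----------
    image_size:
        Side length of the square image grid, in pixels.
    head_axes_range:
        Range of the head-ellipse semi-axes as fractions of the image side.
    aspect_jitter:
        Multiplicative range applied independently to each semi-axis, so
        head length and width vary independently (aspect-ratio shift).
    tissue_mean, tissue_sd:
        Mean intensity of head tissue and the SD of its smooth texture.
    lesion_rate:
        Probability that an image of a positive examination carries >= 1
        lesion.
    lesion_count_max:
        Maximum number of lesions per lesion-bearing image.
    lesion_radius_range:
        Lesion radius range in pixels.
    lesion_intensity_offset:
        Range of the positive intensity added inside a lesion (bright
        blood analog); each lesion draws its own offset, emulating the
        spectrum from faint to conspicuous bleeds.
    artifact_rate:
        Probability an image carries bright non-lesion artifacts (beam-
        hardening-like speckle clusters).  Artifacts are never annotated
        in the mask; sites differ strongly in artifact burden.
    artifact_count_range, artifact_radius_range, artifact_intensity_offset:
        Geometry/intensity of the artifact speckles; artifact dots are
        smaller than lesions.
    noise_sd:
        SD of the additive pixel noise.
    contrast_gamma:
        Exponent applied to the whole image after noise; shifts the
        domain's global appearance the way different scanners/kernels do.
    """

    image_size: int = 64
    head_axes_range: tuple[float, float] = (0.30, 0.42)
    aspect_jitter: tuple[float, float] = (0.90, 1.10)
    tissue_mean: float = 0.45
    tissue_sd: float = 0.06
    lesion_rate: float = 0.6
    lesion_count_max: int = 2
    lesion_radius_range: tuple[float, float] = (2.5, 5.5)
    lesion_intensity_offset: tuple[float, float] = (0.12, 0.30)
    artifact_rate: float = 0.12
    artifact_count_range: tuple[int, int] = (2, 5)
    artifact_radius_range: tuple[float, float] = (0.8, 1.6)
    artifact_intensity_offset: tuple[float, float] = (0.10, 0.24)
    noise_sd: float = 0.04
    contrast_gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("head_axes_range", "aspect_jitter", "lesion_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be ordered and positive, got {(lo, hi)}")
        if not 0.0 <= self.lesion_rate <= 1.0:
            raise ValueError(f"lesion_rate must be in [0, 1], got {self.lesion_rate}")
        if self.lesion_count_max < 1:
            raise ValueError("lesion_count_max must be >= 1")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if not 0.0 <= self.tissue_mean <= 1.0:
            raise ValueError("tissue_mean must be in [0, 1]")
        lo, hi = self.lesion_intensity_offset
        if not 0 < lo <= hi:
            raise ValueError("lesion_intensity_offset range must be positive and ordered")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        if self.contrast_gamma <= 0:
            raise ValueError("contrast_gamma must be positive")


@dataclass
class ExamRecord:
    """One examination: an ordered stack of 2D images with optional masks.

    ``masks`` is ``None`` for the public view of unlabeled examinations;
    reference masks for those are held privately by the corpus.
    ``exam_label`` is true iff any mask pixel is positive.
    """

    exam_id: str
    images: list[np.ndarray]
    masks: list[np.ndarray] | None
    exam_label: bool
    domain_name: str

    def validate(self) -> None:
        if self.masks is not None:
            if len(self.masks) != len(self.images):
                raise ValueError("images and masks must be aligned")
            for img, msk in zip(self.images, self.masks):
                if img.shape != msk.shape:
                    raise ValueError("image/mask shape mismatch")
            derived = any(bool(m.any()) for m in self.masks)
            if derived != self.exam_label:
                raise ValueError("exam_label inconsistent with masks")
        for img in self.images:
            if not np.isfinite(img).all():
                raise ValueError("non-finite image values")


@dataclass
class StudyCorpus:
    """The four disjoint splits of a synthetic study.

    The ``unlabeled`` split's public records carry ``masks=None``; the
    true masks (needed only by the Oracle benchmark modes and by
    experiment analysis) are retained privately and accessible through
    :meth:`private_unlabeled_masks` / :meth:`private_unlabeled_image_labels`.
    """

    labeled: list[ExamRecord]
    unlabeled: list[ExamRecord]
    validation: list[ExamRecord]
    ood_test: list[ExamRecord]
    seed: int
    _unlabeled_masks: dict[str, list[np.ndarray]] = field(default_factory=dict, repr=False)

    def private_unlabeled_masks(self, exam_id: str) -> list[np.ndarray]:
        """Reference masks of an unlabeled exam (Oracle/evaluation use only)."""
        return self._unlabeled_masks[exam_id]

    def private_unlabeled_image_labels(self, exam_id: str) -> list[int]:
        """True per-image labels of an unlabeled exam (image-label Oracle)."""
        return [int(m.any()) for m in self._unlabeled_masks[exam_id]]

    def validate(self) -> None:
        ids: list[str] = []
        for split in (self.labeled, self.unlabeled, self.validation, self.ood_test):
            ids.extend(e.exam_id for e in split)
        if len(ids) != len(set(ids)):
            raise ValueError("splits are not disjoint by exam_id")
        for exam in self.unlabeled:
            if exam.masks is not None:
                raise ValueError("unlabeled split must not expose masks")


def _lesion_disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_head_image(
    spec: DomainSpec,
    force_positive: bool,
    rng: np.random.Generator,
    *,
    lesion_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one phantom image and its binary lesion mask.

    A textured elliptical head is placed on a dark background; lesions are
    bright discs fully inside the head.  Additive noise, then the domain's
    gamma exponent, then clipping to [0, 1].  ``lesion_rate`` overrides the
    spec's rate (used to force all-negative exams).
    """
    n = spec.image_size
    rate = spec.lesion_rate if lesion_rate is None else lesion_rate

    # head geometry: independent per-axis jitter shifts the aspect ratio
    a = rng.uniform(*spec.head_axes_range) * n * rng.uniform(*spec.aspect_jitter)
    b = rng.uniform(*spec.head_axes_range) * n * rng.uniform(*spec.aspect_jitter)
    cy = n / 2 + rng.uniform(-0.03, 0.03) * n
    cx = n / 2 + rng.uniform(-0.03, 0.03) * n
    rr, cc = np.ogrid[:n, :n]
    head = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0

    texture = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=2.0)
    texture *= spec.tissue_sd / max(texture.std(), 1e-12)
    image = np.where(head, spec.tissue_mean + texture, 0.04)

    mask = np.zeros((n, n), dtype=np.uint8)
    carries = force_positive or (rng.random() < rate)
    if carries:
        n_lesions = int(rng.integers(1, spec.lesion_count_max + 1))
        placed = 0
        for _ in range(n_lesions):
            disc = _place_lesion(spec, head, (a, b), (cy, cx), rng)
            if disc is None:
                continue
            image[disc] += rng.uniform(*spec.lesion_intensity_offset)
            mask[disc] = 1
            placed += 1
        if placed == 0:
            raise RuntimeError(
                "could not place any lesion inside the head; DomainSpec geometry "
                "(lesion_radius_range vs head_axes_range) is infeasible"
            )

    # artifacts: bright speckle clusters that are NOT lesions and never
    # enter the mask — the false-positive bait that distinguishes sites
    if rng.random() < spec.artifact_rate:
        n_art = int(rng.integers(spec.artifact_count_range[0], spec.artifact_count_range[1] + 1))
        u = rng.uniform(0, 2 * np.pi)
        r0 = rng.uniform(0.5, 0.85)
        ay = cy + r0 * a * np.sin(u)
        ax = cx + r0 * b * np.cos(u)
        for _ in range(n_art):
            jy = round(ay + rng.uniform(-3, 3))
            jx = round(ax + rng.uniform(-3, 3))
            rad = rng.uniform(*spec.artifact_radius_range)
            dot = _lesion_disc((n, n), (jy, jx), rad)
            dot &= head
            dot &= mask == 0  # artifacts never overwrite lesion pixels
            image[dot] += rng.uniform(*spec.artifact_intensity_offset)

    image = image + rng.normal(0.0, spec.noise_sd, size=(n, n))
    image = np.clip(image, 0.0, 1.0) ** spec.contrast_gamma
    return np.clip(image, 0.0, 1.0), mask


def _place_lesion(spec, head, axes, center, rng, max_tries: int = 50):
    """Sample a lesion disc fully inside the head; None if the draw fails."""
    a, b = axes
    cy, cx = center
    for _ in range(max_tries):
        radius = rng.uniform(*spec.lesion_radius_range)
        if radius >= min(a, b):
            continue  # lesion larger than head: resample
        # sample the center within the shrunken ellipse so the disc fits
        u = rng.uniform(0, 2 * np.pi)
        r = np.sqrt(rng.random())
        # integer centers so a radius-r lesion always rasterizes to the
        # full disc pixel set
        ly = round(cy + r * (a - radius) * np.sin(u))
        lx = round(cx + r * (b - radius) * np.cos(u))
        disc = _lesion_disc(head.shape, (ly, lx), radius)
        if disc.any() and head[disc].all():
            return disc
    return None


def make_exam(
    spec: DomainSpec,
    n_images: int,
    positive: bool,
    rng: np.random.Generator,
    *,
    exam_id: str = "exam",
    domain_name: str = "domain",
) -> ExamRecord:
    """Stack ``n_images`` phantom draws into one examination.

    A negative exam contains no lesions at all; a positive exam has at
    least one lesion-bearing image (others follow the spec's per-image
    lesion rate).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    images, masks = [], []
    forced = int(rng.integers(0, n_images)) if positive else -1
    for i in range(n_images):
        img, msk = make_head_image(
            spec,
            force_positive=(i == forced),
            rng=rng,
            lesion_rate=spec.lesion_rate if positive else 0.0,
        )
        images.append(img)
        masks.append(msk)
    label = any(bool(m.any()) for m in masks)
    rec = ExamRecord(exam_id, images, masks, label, domain_name)
    rec.validate()
    return rec


def make_domain_dataset(
    spec: DomainSpec,
    n_exams: int,
    positive_fraction: float,
    n_images: int,
    rng: np.random.Generator,
    *,
    domain_name: str = "domain",
    id_prefix: str = "exam",
) -> list[ExamRecord]:
    """Generate a shuffled dataset with an exact count of positive exams."""
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    n_pos = round(positive_fraction * n_exams)
    flags = np.array([True] * n_pos + [False] * (n_exams - n_pos))
    rng.shuffle(flags)
    return [
        make_exam(
            spec,
            n_images,
            positive=bool(flags[i]),
            rng=rng,
            exam_id=f"{id_prefix}-{i:04d}",
            domain_name=domain_name,
        )
        for i in range(n_exams)
    ]


@dataclass(frozen=True)
class SplitConfig:
    n_exams: int
    positive_fraction: float
    n_images: int


@dataclass(frozen=True)
class StudyConfig:
    """Full recipe for a three-institution synthetic study."""

    labeled_domain: DomainSpec
    unlabeled_domain: DomainSpec
    ood_domain: DomainSpec
    labeled: SplitConfig
    unlabeled: SplitConfig
    validation: SplitConfig
    ood_test: SplitConfig
    seed: int = 0


def default_study_config(seed: int = 0) -> StudyConfig:
    """Desk-scale default: 40 labeled exams (site A), 100 unlabeled exams of
    4 images = 400 unlabeled images (site B), 20 validation exams, 60
    out-of-distribution test exams (site C).

    Site C differs from site A in noise level, global contrast (gamma) and
    head aspect-ratio spread; site B is a mild intermediate shift.
    Positivity rates follow the clinical splits being emulated (26.9%
    labeled, 41.8% OOD test).
    """
    site_a = DomainSpec()
    # B sits between A and C in appearance (a broad multi-scanner corpus);
    # C extrapolates beyond B: darker gamma, more noise, squashed heads,
    # smaller and fainter lesions.
    site_b = dataclasses.replace(
        site_a,
        noise_sd=0.07,
        contrast_gamma=1.30,
        tissue_mean=0.50,
        aspect_jitter=(0.75, 1.05),
        lesion_intensity_offset=(0.11, 0.26),
        lesion_radius_range=(2.2, 5.0),
        artifact_rate=0.35,
    )
    site_c = dataclasses.replace(
        site_a,
        noise_sd=0.11,
        contrast_gamma=1.70,
        tissue_mean=0.57,
        aspect_jitter=(0.62, 0.98),
        lesion_intensity_offset=(0.10, 0.22),
        lesion_radius_range=(2.0, 4.5),
        artifact_rate=0.50,
    )
    return StudyConfig(
        labeled_domain=site_a,
        unlabeled_domain=site_b,
        ood_domain=site_c,
        labeled=SplitConfig(40, 0.269, 4),
        unlabeled=SplitConfig(100, 0.4, 4),
        validation=SplitConfig(20, 0.3, 4),
        ood_test=SplitConfig(60, 0.418, 4),
        seed=seed,
    )


def make_study_corpus(config: StudyConfig) -> StudyCorpus:
    """Generate the four disjoint splits of a study, fully seeded.

    The unlabeled split's public records have masks withheld; the masks
    are retained privately on the corpus for the Oracle training modes and
    for experiment analysis.
    """
    root = np.random.SeedSequence(config.seed)
    keys = root.spawn(4)
    labeled = make_domain_dataset(
        config.labeled_domain,
        config.labeled.n_exams,
        config.labeled.positive_fraction,
        config.labeled.n_images,
        np.random.default_rng(keys[0]),
        domain_name="site-a",
        id_prefix="lab",
    )
    unlabeled_full = make_domain_dataset(
        config.unlabeled_domain,
        config.unlabeled.n_exams,
        config.unlabeled.positive_fraction,
        config.unlabeled.n_images,
        np.random.default_rng(keys[1]),
        domain_name="site-b",
        id_prefix="unl",
    )
    validation = make_domain_dataset(
        config.labeled_domain,
        config.validation.n_exams,
        config.validation.positive_fraction,
        config.validation.n_images,
        np.random.default_rng(keys[2]),
        domain_name="site-a",
        id_prefix="val",
    )
    ood_test = make_domain_dataset(
        config.ood_domain,
        config.ood_test.n_exams,
        config.ood_test.positive_fraction,
        config.ood_test.n_images,
        np.random.default_rng(keys[3]),
        domain_name="site-c",
        id_prefix="ood",
    )

    private = {e.exam_id: e.masks for e in unlabeled_full}
    unlabeled_public = [
        ExamRecord(e.exam_id, e.images, None, e.exam_label, e.domain_name)
        for e in unlabeled_full
    ]
    corpus = StudyCorpus(
        labeled=labeled,
        unlabeled=unlabeled_public,
        validation=validation,
        ood_test=ood_test,
        seed=config.seed,
        _unlabeled_masks=private,
    )
    corpus.validate()
    return corpus
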