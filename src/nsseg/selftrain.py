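"""Noisy-student orchestration: ranker, pseudo-labels, student, Oracles.

The workflow: (a) train a teacher on the small pixel-labeled split;
(b) the teacher predicts every image of the large unlabeled split;
(c) images are ranked by predicted lesion probability; (d) only the top
C% are declared pseudo-positive — the ranker, which suppresses the
false-positive pseudo-labels a teacher would otherwise reinforce — and
their probability maps are trinarized with confidence thresholds
(> K_pos positive, < K_neg negative, ignore in between), while all other
images get all-negative masks; (e) a noised student, initialized from the
teacher's weights, trains on labeled and pseudo-labeled data mixed at a
fixed per-minibatch ratio.

Two Oracle benchmark modes use reference labels that a true
semi-supervised run would not have: the image-label Oracle supervises the
unlabeled split with true image labels through the classification branch
only (whole images as patches), and the pixel Oracle keeps the teacher's
pseudo masks but zeroes them on images whose true label is negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .dualnet import (
    IGNORE,
    NEG,
    POS,
    ExamPrediction,
    PatchNet,
    TrainConfig,
    TrainingSample,
    TriStateMask,
    predict_exam,
    train,
)
from .phantom import StudyCorpus

logger = logging.getLogger(__name__)

__all__ = [
    "RankerConfig",
    "PseudoDataset",
    "StudyConfigs",
    "rank_images",
    "select_positives",
    "trinarize",
    "build_pseudo_dataset",
    "mixed_minibatch",
    "run_noisy_student",
    "run_oracle_image",
    "run_oracle_pixel",
]


@dataclass(frozen=True)
class RankerConfig:
    """Ranker percentile threshold C and pixel confidence thresholds.

    Only the top C% of unlabeled images (by predicted lesion probability)
    become pseudo-positive.  Within those, pixels with confidence above
    ``k_pos`` are positive, below ``k_neg`` negative, in between ignored.
    """

    c: float = 10.0
    k_pos: float = 0.7
    k_neg: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.c < 100.0:
            raise ValueError("C must be in (0, 100)")
        if not 0.0 <= self.k_neg < self.k_pos <= 1.0:
            raise ValueError("need 0 <= k_neg < k_pos <= 1")


@dataclass
class PseudoEntry:
    image: np.ndarray
    mask: TriStateMask
    image_label: int
    exam_id: str
    image_index: int


@dataclass
class PseudoDataset:
    """Teacher-generated pseudo-labels for the unlabeled split."""

    entries: list[PseudoEntry]
    teacher_id: str
    ranker: RankerConfig

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        for e in self.entries:
            if e.image_label == 0 and (e.mask.grid != NEG).any():
                raise ValueError("negative pseudo image with non-NEG pixels")


@dataclass(frozen=True)
class StudyConfigs:
    """Bundle of configs for one full noisy-student run."""

    teacher: TrainConfig
    student: TrainConfig
    ranker: RankerConfig
    augment: object = None  # AugmentConfig; None disables student noise
    augment_teacher: bool = False
    aggregation_rule: str = "max_both"
    # image-level probability used by the ranker: the classification branch
    # integrates evidence over the whole image, so small artifact speckles
    # rank below true lesions
    ranking_rule: str = "class"


def rank_images(image_probs) -> np.ndarray:
    """Indices sorting probabilities high to low; stable under ties."""
    probs = np.asarray(image_probs, dtype=np.float64)
    if not np.isfinite(probs).all():
        raise ValueError("probabilities must be finite")
    return np.argsort(-probs, kind="stable")


def select_positives(image_probs, c: float) -> set[int]:
    """The floor(C/100 * N) highest-probability image indices."""
    probs = np.asarray(image_probs, dtype=np.float64)
    n_pos = int(np.floor(c / 100.0 * probs.size))
    if n_pos == 0:
        warnings.warn(
            f"ranker threshold C={c} selects 0 of {probs.size} images; "
            "all pseudo-labels will be negative",
            stacklevel=2,
        )
        return set()
    order = rank_images(probs)
    return set(int(i) for i in order[:n_pos])


def trinarize(prob_map: np.ndarray, ranker: RankerConfig) -> TriStateMask:
    """Threshold a probability map into {POS, NEG, IGNORE} states.

    Comparisons are strict, so values exactly at a threshold are ignored.
    """
    grid = np.full(prob_map.shape, IGNORE, dtype=np.int8)
    grid[prob_map > ranker.k_pos] = POS
    grid[prob_map < ranker.k_neg] = NEG
    return TriStateMask(grid)


def build_pseudo_dataset(
    teacher: dict[str, np.ndarray],
    unlabeled,
    ranker: RankerConfig,
    crop_size: int = 32,
    aggregation_rule: str = "max_both",
    teacher_id: str = "teacher",
    apply_ranker: bool = True,
) -> PseudoDataset:
    """Predict the whole unlabeled split and apply the ranker.

    Images are pooled globally across exams for the percentile selection.
    Pseudo-positive images keep their trinarized probability maps;
    everything else becomes all-negative with image label 0.  With
    ``apply_ranker=False`` (the ablation control) every image is treated
    as positive and trinarized, so the teacher's false positives are not
    suppressed.
    """
    if not unlabeled:
        raise ValueError("unlabeled split is empty")
    model = PatchNet.from_state(teacher)
    records = []  # (exam_id, image_index, image, image_prob, prob_map)
    for exam in unlabeled:
        pred = predict_exam(model, exam, crop_size=crop_size, rule=aggregation_rule)
        for i, (img, p, pm) in enumerate(zip(exam.images, pred.image_probs, pred.prob_maps)):
            records.append((exam.exam_id, i, img, p, pm))

    if apply_ranker:
        positives = select_positives([r[3] for r in records], ranker.c)
    else:
        positives = set(range(len(records)))
    entries = []
    for idx, (exam_id, i, img, _p, pm) in enumerate(records):
        if idx in positives:
            if not apply_ranker:
                entries.append(PseudoEntry(img, trinarize(pm, ranker), 1, exam_id, i))
                continue
            mask = trinarize(pm, ranker)
            if not (mask.grid == POS).any():
                logger.warning(
                    "pseudo-positive image %s[%d] has no pixel above K_pos=%.2f; "
                    "its patch labels will derive from the (all non-positive) mask",
                    exam_id,
                    i,
                    ranker.k_pos,
                )
            entries.append(PseudoEntry(img, mask, 1, exam_id, i))
        else:
            mask = TriStateMask(np.zeros(pm.shape, dtype=np.int8))
            entries.append(PseudoEntry(img, mask, 0, exam_id, i))
    ds = PseudoDataset(entries=entries, teacher_id=teacher_id, ranker=ranker)
    ds.validate()
    return ds


def mixed_minibatch(
    labeled_pool,
    pseudo_pool,
    mixing_ratio: float,
    batch_size: int,
    rng: np.random.Generator,
) -> list:
    """Draw one minibatch: round(ratio*B) labeled samples, the rest pseudo,
    each uniformly with replacement."""
    if not labeled_pool or not pseudo_pool:
        raise ValueError("both pools must be non-empty")
    if not 0.0 < mixing_ratio < 1.0:
        raise ValueError("mixing_ratio must be in (0, 1)")
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2 when mixing two pools")
    n_lab = round(mixing_ratio * batch_size)
    n_pse = batch_size - n_lab
    li = rng.integers(0, len(labeled_pool), size=n_lab)
    pi = rng.integers(0, len(pseudo_pool), size=n_pse)
    return [labeled_pool[i] for i in li] + [pseudo_pool[i] for i in pi]


# ---------------------------------------------------------------------------
# training pools
# ---------------------------------------------------------------------------


def labeled_pool_from_exams(exams) -> list[TrainingSample]:
    return [
        TrainingSample(image=img, mask=msk.astype(np.int8), source="labeled")
        for exam in exams
        for img, msk in zip(exam.images, exam.masks)
    ]


def pseudo_pool_from_dataset(pseudo: PseudoDataset) -> list[TrainingSample]:
    return [
        TrainingSample(image=e.image, mask=e.mask.grid, source="pseudo")
        for e in pseudo.entries
    ]


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


def run_noisy_student(corpus: StudyCorpus, configs: StudyConfigs):
    """Teacher -> ranked pseudo-labels -> noised student.

    Returns ``(teacher_state, student_state, pseudo)``.  The student is
    initialized from the teacher's weights and sees minibatches mixing
    labeled and pseudo pools at the configured ratio, with augmentation
    noise.  The returned states carry provenance metadata.
    """
    if not corpus.unlabeled:
        raise ValueError("corpus has no unlabeled split")
    labeled = labeled_pool_from_exams(corpus.labeled)
    t_hist: dict = {}
    teacher = train(
        None,
        labeled,
        None,
        configs.teacher,
        augment_config=configs.augment if configs.augment_teacher else None,
        rng=np.random.default_rng(configs.teacher.seed),
        history=t_hist,
    )
    teacher_id = f"teacher-seed{configs.teacher.seed}"
    pseudo = build_pseudo_dataset(
        teacher,
        corpus.unlabeled,
        configs.ranker,
        crop_size=configs.teacher.crop_size,
        aggregation_rule=configs.ranking_rule,
        teacher_id=teacher_id,
    )
    s_hist: dict = {"init_from": teacher_id}
    student = train(
        teacher,
        labeled,
        pseudo_pool_from_dataset(pseudo),
        configs.student,
        augment_config=configs.augment,
        rng=np.random.default_rng(configs.student.seed + 1),
        history=s_hist,
    )
    return teacher, student, pseudo


def run_oracle_image(corpus: StudyCorpus, configs: StudyConfigs) -> dict[str, np.ndarray]:
    """Image-label Oracle: unlabeled data supervised by true image labels.

    Pixel loss is active on the labeled split only.  Each unlabeled image
    enters training as a whole-image patch whose classification target is
    its true (privately retained) image label.
    """
    pool = []
    for exam in corpus.unlabeled:
        try:
            labels = corpus.private_unlabeled_image_labels(exam.exam_id)
        except KeyError as err:
            raise ValueError("private reference labels unavailable") from err
        for i, img in enumerate(exam.images):
            pool.append(
                TrainingSample(
                    image=img,
                    mask=np.zeros(img.shape, dtype=np.int8),
                    source="oracle_image",
                    pixel_loss=False,
                    whole_image=True,
                    label_override=labels[i],
                )
            )
    labeled = labeled_pool_from_exams(corpus.labeled)
    return train(
        None,
        labeled,
        pool,
        configs.student,
        augment_config=configs.augment,
        rng=np.random.default_rng(configs.student.seed + 2),
    )


def oracle_pixel_pool(corpus: StudyCorpus, pseudo: PseudoDataset) -> list[TrainingSample]:
    """Pixel-Oracle training pool: pseudo masks gated by true image labels."""
    label_lut = {
        exam.exam_id: corpus.private_unlabeled_image_labels(exam.exam_id)
        for exam in corpus.unlabeled
    }
    pool = []
    for e in pseudo.entries:
        true_label = label_lut[e.exam_id][e.image_index]
        if true_label == 0:
            mask = np.zeros(e.mask.shape, dtype=np.int8)
        else:
            mask = e.mask.grid
        pool.append(TrainingSample(image=e.image, mask=mask, source="oracle_pixel"))
    return pool


def run_oracle_pixel(
    corpus: StudyCorpus, configs: StudyConfigs, pseudo: PseudoDataset
) -> dict[str, np.ndarray]:
    """Pixel Oracle: pseudo masks, gated by the true image labels.

    Where the true image label is negative the pseudo mask is overridden
    to all-negative (suppressing teacher false positives); where positive,
    the tri-state pseudo mask is used unchanged.  Pixel loss is active on
    both splits; otherwise trains like the student.
    """
    pool = oracle_pixel_pool(corpus, pseudo)
    labeled = labeled_pool_from_exams(corpus.labeled)
    return train(
        None,
        labeled,
        pool,
        configs.student,
        augment_config=configs.augment,
        rng=np.random.default_rng(configs.student.seed + 3),
    )
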