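"""Persistence: corpora as PNG stacks + CSV manifest, checkpoints, YAML.

Images are written as 16-bit grayscale PNGs (intensity in [0,1] scaled to
[0, 65535]); masks as 8-bit PNGs with the raw state values {0,1,2}.  A
CSV manifest ties exams to splits, domains, labels and file paths.  All
writers are deterministic so a rerun with the same config and seed
produces bit-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import phantom
from .phantom import DomainSpec, ExamRecord, SplitConfig, StudyConfig, StudyCorpus

__all__ = [
    "save_corpus",
    "load_corpus",
    "save_checkpoint",
    "load_checkpoint",
    "study_config_from_yaml",
    "study_config_to_yaml",
]

_SPLITS = ("labeled", "unlabeled", "validation", "ood_test")


def _img_to_png(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16)


def _png_to_img(arr: np.ndarray) -> np.ndarray:
    return arr.astype(np.float64) / 65535.0


def save_corpus(corpus: StudyCorpus, out_dir) -> Path:
    """Write a corpus to ``out_dir``; returns the manifest path.

    Unlabeled exams are written without mask files, preserving the
    semi-supervised contract on disk.
    """
    out = Path(out_dir)
    rows = []
    for split in _SPLITS:
        for exam in getattr(corpus, split):
            edir = out / split / exam.exam_id
            edir.mkdir(parents=True, exist_ok=True)
            img_paths, msk_paths = [], []
            for i, img in enumerate(exam.images):
                p = edir / f"img_{i:02d}.png"
                iio.imwrite(p, _img_to_png(img))
                img_paths.append(str(p.relative_to(out)))
            if exam.masks is not None:
                for i, msk in enumerate(exam.masks):
                    p = edir / f"msk_{i:02d}.png"
                    iio.imwrite(p, msk.astype(np.uint8))
                    msk_paths.append(str(p.relative_to(out)))
            rows.append(
                {
                    "exam_id": exam.exam_id,
                    "split": split,
                    "domain": exam.domain_name,
                    "exam_label": int(exam.exam_label),
                    "n_images": len(exam.images),
                    "image_paths": ";".join(img_paths),
                    "mask_paths": ";".join(msk_paths),
                }
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_corpus(manifest_path) -> StudyCorpus:
    """Rebuild a corpus from a manifest written by :func:`save_corpus`.

    Unlabeled exams come back with ``masks=None`` (their reference masks
    are not on disk), so a loaded corpus supports the semi-supervised and
    evaluation paths but not the Oracle modes.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path, keep_default_na=False)
    splits: dict[str, list[ExamRecord]] = {s: [] for s in _SPLITS}
    for row in df.itertuples():
        images = [_png_to_img(iio.imread(root / p)) for p in row.image_paths.split(";")]
        masks = None
        if row.mask_paths:
            masks = [
                iio.imread(root / p).astype(np.uint8) for p in row.mask_paths.split(";")
            ]
        splits[row.split].append(
            ExamRecord(row.exam_id, images, masks, bool(row.exam_label), row.domain)
        )
    return StudyCorpus(
        labeled=splits["labeled"],
        unlabeled=splits["unlabeled"],
        validation=splits["validation"],
        ood_test=splits["ood_test"],
        seed=-1,
    )


def save_checkpoint(path, state: dict[str, np.ndarray], meta: dict | None = None) -> None:
    """Weights + JSON metadata (config, seed, provenance) in one .npz."""
    arrays = dict(state)
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta or {}, sort_keys=True).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    return state, meta


# ---------------------------------------------------------------------------
# YAML study configuration
# ---------------------------------------------------------------------------


def _spec_from_dict(d: dict) -> DomainSpec:
    d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return DomainSpec(**d)


def study_config_from_yaml(path_or_stream) -> StudyConfig:
    if isinstance(path_or_stream, (str, Path)):
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(path_or_stream)
    return StudyConfig(
        labeled_domain=_spec_from_dict(raw["domains"]["labeled"]),
        unlabeled_domain=_spec_from_dict(raw["domains"]["unlabeled"]),
        ood_domain=_spec_from_dict(raw["domains"]["ood"]),
        labeled=SplitConfig(**raw["splits"]["labeled"]),
        unlabeled=SplitConfig(**raw["splits"]["unlabeled"]),
        validation=SplitConfig(**raw["splits"]["validation"]),
        ood_test=SplitConfig(**raw["splits"]["ood_test"]),
        seed=int(raw.get("seed", 0)),
    )


def _spec_to_dict(spec: DomainSpec) -> dict:
    d = dataclasses.asdict(spec)
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def study_config_to_yaml(config: StudyConfig, path=None) -> str:
    doc = {
        "seed": config.seed,
        "domains": {
            "labeled": _spec_to_dict(config.labeled_domain),
            "unlabeled": _spec_to_dict(config.unlabeled_domain),
            "ood": _spec_to_dict(config.ood_domain),
        },
        "splits": {
            "labeled": dataclasses.asdict(config.labeled),
            "unlabeled": dataclasses.asdict(config.unlabeled),
            "validation": dataclasses.asdict(config.validation),
            "ood_test": dataclasses.asdict(config.ood_test),
        },
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
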