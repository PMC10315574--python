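"""Dataset machinery: augmentation, COCO-panoptic export, train/val split.

Each source image is expanded into 15 derivatives: the 16 combinations of
rotation {0, 90, 180, 270} x mirror {none, horizontal, vertical, both}
minus the identity.  Only 8 of the 16 are geometrically distinct (the
dihedral group of the square), so some derivatives coincide pixel-wise;
they are nevertheless kept as separate dataset entries so that bookkeeping
(15 per source) holds exactly.

Panoptic export follows the COCO panoptic convention: a PNG whose pixel
value encodes the segment id as id = R + 256 G + 256^2 B, plus a JSON
record with the category table and per-segment area/bbox entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .segmentation import SegmentMap, SegmentRecord, OUT_OF_PLATE_ID, AGAR_ID

__all__ = [
    "ManifestItem",
    "DatasetManifest",
    "TRANSFORM_NAMES",
    "augment_image",
    "export_panoptic",
    "decode_panoptic_png",
    "build_dataset",
    "split_dataset",
]

#: The 15 non-identity rotation x mirror combinations, in a fixed order.
TRANSFORM_NAMES = tuple(
    f"rot{rot}_{mir}"
    for rot in (0, 90, 180, 270)
    for mir in ("none", "h", "v", "hv")
    if not (rot == 0 and mir == "none")
)

_MAX_SEGMENT_ID = 256 ** 3 - 1


def _apply_transform(arr: np.ndarray, rot: int, mir: str) -> np.ndarray:
    out = np.rot90(arr, k=rot // 90, axes=(0, 1))
    if mir in ("h", "hv"):
        out = out[:, ::-1]
    if mir in ("v", "hv"):
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment_image(image: np.ndarray, segmap: SegmentMap
                  ) -> list[tuple[np.ndarray, SegmentMap, str]]:
    """Return the 15 rotation/mirror derivatives of an image + segment map.

    Masks follow the pixels exactly (90/270 rotations of non-square images
    swap dimensions for both).  Category records are copied unchanged.
    """
    if image.shape[:2] != segmap.labels.shape:
        raise ValueError("image and segment map must be aligned")
    out = []
    for name in TRANSFORM_NAMES:
        rot = int(name.split("_")[0][3:])
        mir = name.split("_")[1]
        img_t = _apply_transform(image, rot, mir)
        lab_t = _apply_transform(segmap.labels, rot, mir)
        records = {sid: SegmentRecord(r.id, r.supercategory, r.sublabel,
                                      r.n_colonies)
                   for sid, r in segmap.records.items()}
        out.append((img_t, SegmentMap(lab_t, records), name))
    return out


def _category_table(records: dict[int, SegmentRecord]) -> list[dict]:
    """Stable category ids: 1 out of plate, 2 agar, 10+k for 'k colonies'."""
    cats = {
        1: {"id": 1, "name": "out of plate", "supercategory": "background",
            "isthing": 0},
        2: {"id": 2, "name": "0 colonies", "supercategory": "background",
            "isthing": 0},
    }
    for r in records.values():
        if r.supercategory == "colonies":
            k = max(r.n_colonies, 1)
            cats[10 + k] = {"id": 10 + k,
                            "name": "1 colony" if k == 1 else f"{k} colonies",
                            "supercategory": "colonies", "isthing": 1}
    return [cats[i] for i in sorted(cats)]


def _category_id(record: SegmentRecord) -> int:
    if record.supercategory == "background":
        return OUT_OF_PLATE_ID if record.sublabel == "out of plate" else AGAR_ID
    return 10 + max(record.n_colonies, 1)


def export_panoptic(image: np.ndarray, segmap: SegmentMap, image_id: str,
                    out_dir) -> tuple[Path, Path]:
    """Write one (JSON, id-encoded PNG) panoptic annotation pair.

    Also writes the RGB image itself as ``<image_id>.png``.  Returns the
    (json, mask png) paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = segmap.labels.astype(np.int64)
    if labels.max() > _MAX_SEGMENT_ID:
        raise ValueError("segment id overflows the 24-bit panoptic encoding")

    rgb_ids = np.empty((*labels.shape, 3), dtype=np.uint8)
    rgb_ids[..., 0] = labels % 256
    rgb_ids[..., 1] = (labels // 256) % 256
    rgb_ids[..., 2] = labels // (256 ** 2)
    png_path = out_dir / f"{image_id}_panoptic.png"
    Image.fromarray(rgb_ids).save(png_path)

    img_path = out_dir / f"{image_id}.png"
    Image.fromarray(image).save(img_path)

    segments_info = []
    for sid in sorted(segmap.records):
        mask = labels == sid
        area = int(mask.sum())
        if area == 0:
            continue
        ys, xs = np.nonzero(mask)
        bbox = [int(xs.min()), int(ys.min()),
                int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1)]
        segments_info.append({"id": sid,
                              "category_id": _category_id(segmap.records[sid]),
                              "area": area, "bbox": bbox})
    ann = {
        "images": [{"id": image_id, "file_name": img_path.name,
                    "width": labels.shape[1], "height": labels.shape[0]}],
        "categories": _category_table(segmap.records),
        "annotations": [{"image_id": image_id, "file_name": png_path.name,
                         "segments_info": segments_info}],
    }
    json_path = out_dir / f"{image_id}_panoptic.json"
    json_path.write_text(json.dumps(ann, indent=1))
    return json_path, png_path


def decode_panoptic_png(path) -> np.ndarray:
    """Decode an id-encoded panoptic PNG back to an int32 label image."""
    rgb = np.asarray(Image.open(path)).astype(np.int64)
    return (rgb[..., 0] + 256 * rgb[..., 1] + 256 ** 2 * rgb[..., 2]
            ).astype(np.int32)


@dataclass(frozen=True)
class ManifestItem:
    """One dataset entry: a derivative image plus its annotation files."""

    image_path: str
    annotation_path: str
    mask_path: str
    source_id: str
    transform: str


@dataclass
class DatasetManifest:
    items: list[ManifestItem]

    def __len__(self) -> int:
        return len(self.items)

    def source_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.source_id, None)
        return list(seen)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps([asdict(i) for i in self.items],
                                         indent=1))

    @classmethod
    def from_json(cls, path) -> "DatasetManifest":
        return cls([ManifestItem(**d) for d in json.loads(Path(path).read_text())])


def build_dataset(sources: list[tuple[str, np.ndarray, SegmentMap]],
                  out_dir=None) -> DatasetManifest:
    """Augment every source 15-fold and export panoptic annotation pairs.

    ``sources`` are (source id, RGB image, segment map) triples.  When
    ``out_dir`` is None nothing is written and the manifest carries
    virtual paths — useful for bookkeeping and splitting without I/O.
    """
    items = []
    for src_id, image, segmap in sources:
        for img_t, seg_t, name in augment_image(image, segmap):
            entry_id = f"{src_id}_{name}"
            if out_dir is None:
                items.append(ManifestItem(f"{entry_id}.png",
                                          f"{entry_id}_panoptic.json",
                                          f"{entry_id}_panoptic.png",
                                          src_id, name))
            else:
                json_path, png_path = export_panoptic(img_t, seg_t, entry_id,
                                                      out_dir)
                items.append(ManifestItem(str(Path(out_dir) / f"{entry_id}.png"),
                                          str(json_path), str(png_path),
                                          src_id, name))
    return DatasetManifest(items)


def split_dataset(manifest: DatasetManifest, train_frac: float = 0.75,
                  seed: int = 0) -> tuple[DatasetManifest, DatasetManifest]:
    """Split into train/validation, keeping all derivatives of a source
    together.

    Sources are shuffled reproducibly and assigned to the training subset
    until it holds round(train_frac * n) items; with equally sized source
    groups (the 15-fold augmentation) the item split is exact.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if not manifest.items:
        raise ValueError("cannot split an empty manifest")
    sources = manifest.source_ids()
    rng = np.random.default_rng(seed)
    order = [sources[i] for i in rng.permutation(len(sources))]
    by_source = {s: [it for it in manifest.items if it.source_id == s]
                 for s in sources}
    target = round(train_frac * len(manifest))
    train: list[ManifestItem] = []
    val: list[ManifestItem] = []
    count = 0
    for s in order:
        group = by_source[s]
        if count < target:
            train.extend(group)
            count += len(group)
        else:
            val.extend(group)
    return DatasetManifest(train), DatasetManifest(val)
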