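"""Plate-photograph ingest: barcode decoding, well sampling, growth QC.

An incoming image is identified by its barcode and registered through the
two filled discs flanking the barcode strip (left disc larger, so a
180-degree rotated photograph still orients correctly).  The similarity
transform fitted to the two mark centroids predicts all 96 well centers;
each well's color is the mean RGB over a disc at its predicted center.

Growth-plate QC compares realized turbidity against the collection
catalog: growth in a catalogued-empty well is a ``contamination`` event,
no growth in a catalogued-occupied well is a ``growth_failure`` event.
Growth-failure wells are excluded from hit calling downstream so that a
missing culture is never mistaken for an oxidation phenotype.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import barcode
from .geometry import DEFAULT_GEOMETRY, PlateGeometry, SimilarityTransform, well_names
from .synth import BLANK_MEDIA_RGB, _disc_coords

__all__ = [
    "PlateImageRecord",
    "WellColorSample",
    "CollectionCatalog",
    "QCReport",
    "decode_plate",
    "sample_wells",
    "qc_growth_plate",
    "ingest_images",
    "load_image",
]

log = logging.getLogger(__name__)

DARK_THRESHOLD = 100.0  # gray level below which pixels count as barcode/mark ink


@dataclass
class PlateImageRecord:
    """Identification and registration result for one plate photograph."""

    path: str | None
    timestamp_h: float | None
    decoded_plate_id: str | None
    mark_centroids: tuple[np.ndarray, np.ndarray] | None
    transform: SimilarityTransform | None
    quality_flags: set = field(default_factory=set)


@dataclass
class WellColorSample:
    """Mean well-center color: raw ``C`` and white-referenced ``C_prime``."""

    well: str
    C: np.ndarray  # mean RGB, float, each channel in [0, 255]
    C_prime: np.ndarray  # C - (255, 255, 255)
    n_pixels: int


class CollectionCatalog:
    """(plate_id, well) -> mutant identity, control class and occupancy."""

    COLUMNS = ("plate_id", "well", "mutant_id", "control_class", "occupied")

    def __init__(self, entries: pd.DataFrame):
        missing = [c for c in ("plate_id", "well") if c not in entries.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        if entries.duplicated(["plate_id", "well"]).any():
            raise ValueError("catalog keys (plate_id, well) must be unique")
        self.entries = entries.set_index(["plate_id", "well"], drop=False)

    @classmethod
    def from_csv(cls, path) -> "CollectionCatalog":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.entries.reset_index(drop=True).to_csv(path, index=False)

    def lookup(self, plate_id: str, well: str) -> pd.Series:
        try:
            return self.entries.loc[(plate_id, well)]
        except KeyError as exc:
            raise KeyError(
                f"no catalog entry for plate {plate_id!r} well {well!r}"
            ) from exc

    def has_plate(self, plate_id: str) -> bool:
        return plate_id in self.entries.index.get_level_values(0)


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF plate photograph as an 8-bit RGB array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("image must be 8-bit RGB (H x W x 3, uint8)")
    return image


def _find_marks(gray: np.ndarray, geometry: PlateGeometry):
    """Locate the two registration discs among the dark blobs.

    Discs are selected by near-square bounding box and high fill fraction,
    which excludes the thin barcode bars; returns centroids as (x, y),
    larger disc first (= canonical left), plus an ambiguity indicator.
    """
    lab, n_lab = ndimage.label(gray < DARK_THRESHOLD)
    if n_lab == 0:
        return None, None, False
    r_small = min(geometry.mark_left[2], geometry.mark_right[2])
    min_area = 0.15 * np.pi * r_small**2
    areas = np.bincount(lab.ravel())[1:]
    slices = ndimage.find_objects(lab)
    candidates = []
    for i, (area, sl) in enumerate(zip(areas, slices)):
        if area < min_area or sl is None:
            continue
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        aspect = max(h, w) / max(1, min(h, w))
        if aspect > 1.5 or area / (h * w) < 0.6:
            continue
        mask = lab[sl] == i + 1
        cy, cx = ndimage.center_of_mass(mask)
        candidates.append(
            (int(area), np.array([cx + sl[1].start, cy + sl[0].start]))
        )
    if len(candidates) < 2:
        return None, None, False
    candidates.sort(key=lambda t: -t[0])
    ambiguous = len(candidates) > 2 and candidates[2][0] > 0.5 * candidates[1][0]
    return candidates[0][1], candidates[1][1], ambiguous


def _read_barcode(
    image: np.ndarray, transform: SimilarityTransform, geometry: PlateGeometry
) -> str | None:
    x0, y0, x1, y1 = geometry.barcode_box
    n = barcode.n_modules()
    xs = x0 + (np.arange(n) + 0.5) * (x1 - x0) / n
    yc = 0.5 * (y0 + y1)
    pts = transform.apply(np.column_stack([xs, np.full(n, yc)]))
    h, w = image.shape[:2]
    cols = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
    gray = image[rows, cols].mean(axis=1)
    return barcode.decode_bits((gray < 128).astype(np.uint8))


def decode_plate(
    image: np.ndarray,
    geometry: PlateGeometry = DEFAULT_GEOMETRY,
    path: str | None = None,
    timestamp_h: float | None = None,
) -> PlateImageRecord:
    """Identify and register a plate photograph.

    On success the record carries the decoded plate id, the two mark
    centroids and the canonical-to-image similarity transform.  Decode
    failures never raise: the record is returned with a
    ``barcode_unreadable`` flag and is skipped (with logging) downstream —
    absent data must not fabricate a phenotype.
    """
    image = _validate_rgb(image)
    gray = image.mean(axis=2)
    flags: set = set()
    big, small, ambiguous = _find_marks(gray, geometry)
    if big is None:
        flags.add("barcode_unreadable")
        log.warning("plate image %s: registration marks not found", path)
        return PlateImageRecord(path, timestamp_h, None, None, None, flags)
    if ambiguous:
        flags.add("ambiguous_marks")
    transform = SimilarityTransform.from_marks(big, small, geometry)
    plate_id = _read_barcode(image, transform, geometry)
    if plate_id is None:
        flags.add("barcode_unreadable")
        log.warning("plate image %s: barcode did not decode", path)
        return PlateImageRecord(path, timestamp_h, None, (big, small), None, flags)
    return PlateImageRecord(path, timestamp_h, plate_id, (big, small), transform, flags)


def sample_wells(
    record: PlateImageRecord,
    image: np.ndarray,
    radius_frac: float = 0.30,
    geometry: PlateGeometry = DEFAULT_GEOMETRY,
) -> list[WellColorSample]:
    """Mean RGB over a disc at each predicted well center (96 samples).

    ``radius_frac`` is the sampling-disc radius as a fraction of the well
    pitch; the disc is scaled by the registration transform.
    """
    if record.transform is None:
        raise ValueError("record has no registration transform (decode failed?)")
    if radius_frac <= 0:
        raise ValueError("radius_frac must be positive")
    image = _validate_rgb(image)
    h, w = image.shape[:2]
    radius = radius_frac * geometry.well_pitch * record.transform.scale
    samples = []
    for well, center in geometry.well_centers().items():
        cx, cy = record.transform.apply(np.asarray(center))
        if not (radius <= cx < w - radius and radius <= cy < h - radius):
            raise ValueError(
                f"predicted grid for plate {record.decoded_plate_id!r} exceeds "
                f"image bounds at well {well}"
            )
        rr, cc = _disc_coords(cx, cy, radius, image.shape[:2])
        pix = image[rr, cc].astype(float)
        C = pix.mean(axis=0)
        samples.append(
            WellColorSample(
                well=well, C=C, C_prime=C - 255.0, n_pixels=int(pix.shape[0])
            )
        )
    return samples


@dataclass
class QCReport:
    """Growth-plate QC outcome: per-well growth calls and event list."""

    plate_id: str
    grown: dict  # well -> bool
    events: list  # (well, "contamination" | "growth_failure")
    threshold: float

    @property
    def growth_failures(self) -> set:
        return {w for w, e in self.events if e == "growth_failure"}

    @property
    def contaminations(self) -> set:
        return {w for w, e in self.events if e == "contamination"}


def qc_growth_plate(
    record: PlateImageRecord,
    image: np.ndarray,
    catalog: CollectionCatalog,
    geometry: PlateGeometry = DEFAULT_GEOMETRY,
    blank_rgb: tuple[float, float, float] = BLANK_MEDIA_RGB,
    sigma_factor: float = 3.0,
    threshold_floor: float = 20.0,
) -> QCReport:
    """Check a storage plate for contamination and growth-failure events.

    Turbidity score = Euclidean RGB distance of the well-mean color from
    the blank-media reference.  The growth threshold is ``mean +
    sigma_factor * SD`` of the catalogued-empty wells' scores when at
    least three are available, and never below ``threshold_floor`` (which
    also serves alone on plates with no empty wells).
    """
    if record.decoded_plate_id is None:
        raise ValueError("cannot QC a plate whose barcode did not decode")
    plate_id = record.decoded_plate_id
    if not catalog.has_plate(plate_id):
        raise KeyError(f"plate {plate_id!r} not present in the collection catalog")
    samples = sample_wells(record, image, geometry=geometry)
    scores = {
        s.well: float(np.linalg.norm(s.C - np.asarray(blank_rgb, float)))
        for s in samples
    }
    occupied = {
        w: bool(catalog.lookup(plate_id, w)["occupied"]) for w in well_names()
    }
    empty_scores = np.array([scores[w] for w, occ in occupied.items() if not occ])
    if empty_scores.size >= 3:
        # median/MAD rather than mean/SD: a contaminated blank well must not
        # inflate the very threshold that should flag it
        center = float(np.median(empty_scores))
        sigma = 1.4826 * float(np.median(np.abs(empty_scores - center)))
        threshold = max(center + sigma_factor * sigma, threshold_floor)
    else:
        threshold = threshold_floor
    grown = {w: scores[w] > threshold for w in scores}
    events = []
    for w in well_names():
        if grown[w] and not occupied[w]:
            events.append((w, "contamination"))
        elif not grown[w] and occupied[w]:
            events.append((w, "growth_failure"))
    return QCReport(plate_id=plate_id, grown=grown, events=events, threshold=threshold)


def ingest_images(
    images: list[tuple[np.ndarray, str, float]],
    geometry: PlateGeometry = DEFAULT_GEOMETRY,
    radius_frac: float = 0.30,
) -> tuple[pd.DataFrame, list[PlateImageRecord]]:
    """Decode and sample a batch of (image, path, timestamp_h) records.

    Returns the long-format well-sample table (plate_id, well,
    timestamp_h, r, g, b, n_pixels) plus every image record, including the
    skipped unreadable ones.
    """
    rows, records = [], []
    for image, path, timestamp_h in images:
        rec = decode_plate(image, geometry=geometry, path=path, timestamp_h=timestamp_h)
        records.append(rec)
        if "barcode_unreadable" in rec.quality_flags:
            continue
        for s in sample_wells(rec, image, radius_frac=radius_frac, geometry=geometry):
            rows.append(
                {
                    "plate_id": rec.decoded_plate_id,
                    "well": s.well,
                    "timestamp_h": timestamp_h,
                    "r": s.C[0],
                    "g": s.C[1],
                    "b": s.C[2],
                    "n_pixels": s.n_pixels,
                }
            )
    return pd.DataFrame(rows), records


def read_acquisition_log(path) -> pd.DataFrame:
    """Sidecar acquisition log: columns ``path``, ``timestamp_h``."""
    df = pd.read_csv(path)
    for col in ("path", "timestamp_h"):
        if col not in df.columns:
            raise ValueError(f"acquisition log missing column {col!r}")
    return df
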