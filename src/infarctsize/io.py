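"""File formats: section images, seed documents, results tables, label masks.

Seed document schema (YAML, one file per batch)
-----------------------------------------------

.. code-block:: yaml

    sections:
      s1:                      # section_id
        heart: H1              # optional, default "heart"
        order: 3               # optional apex-to-base index
        size: [512, 512]       # optional [H, W]; enables bounds checks here
        tolerance: 60          # optional per-section tolerance override
        lumen: [[256, 256]]    # 0-based [row, col] seed pixels
        viable: [[256, 100]]
        exclude:               # optional closed polygons, >= 3 vertices
          - [[10, 10], [10, 40], [40, 40], [40, 10]]

Sections absent from the document get an empty :class:`SeedSet`.

Results tables hold one row per section with columns
``heart_id, section_id, area_pct, midline_pct`` plus one summary row per
heart (``section_id == "MEAN"``) carrying the arithmetic mean of each
method. CSV is the canonical format (comma separated, "." decimal, header
row, UTF-8); xlsx is a thin writer over the same table.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ImageFormatError, SeedFileError, ValidationError
from .types import Label, LabelMask, SectionImage, SeedSet

__all__ = [
    "load_section_image",
    "load_seed_file",
    "load_seed_document",
    "write_results",
    "read_results",
    "validate_results_table",
    "save_label_mask",
    "load_label_mask",
    "MEAN_ROW_ID",
]

#: Reserved section_id of per-heart summary rows in results tables.
MEAN_ROW_ID = "MEAN"

RESULT_COLUMNS = ["heart_id", "section_id", "area_pct", "midline_pct"]


def load_section_image(
    path: Union[str, Path], section_id: str, order_index: int = 0
) -> SectionImage:
    """Decode a TIFF/JPEG/PNG section photograph into a :class:`SectionImage`.

    Grayscale rasters are replicated to three channels; an alpha channel is
    dropped. The decoded array is used as-is (no recompression, no
    rescaling).
    """
    path = Path(path)
    try:
        px = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by plugin
        raise ImageFormatError(f"cannot decode image file {path}: {exc}") from exc
    px = np.asarray(px)
    if px.size == 0:
        raise ValidationError(f"image file {path} decodes to an empty raster")
    if px.ndim == 2:
        px = np.stack([px, px, px], axis=-1)
    elif px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    elif px.ndim != 3 or px.shape[2] != 3:
        raise ImageFormatError(
            f"image file {path} has unsupported shape {px.shape}; expected RGB"
        )
    if px.dtype != np.uint8:
        raise ImageFormatError(
            f"image file {path} is {px.dtype}; expected an 8-bit raster"
        )
    return SectionImage(pixels=px, section_id=section_id, order_index=order_index)


def _seed_pairs(entry, what: str, section_id: str) -> list[tuple[int, int]]:
    if entry is None:
        return []
    pairs = []
    for item in entry:
        if not isinstance(item, (list, tuple)) or len(item) != 2:
            raise SeedFileError(
                f"section {section_id!r}: {what} entry {item!r} is not [row, col]"
            )
        pairs.append((int(item[0]), int(item[1])))
    return pairs


def load_seed_document(
    path: Union[str, Path],
) -> tuple[dict[str, SeedSet], dict[str, dict]]:
    """Parse a seed document; returns ``(seed_map, metadata)``.

    ``metadata[section_id]`` holds the optional ``heart``/``order``/``size``
    keys, which the batch driver uses but :class:`SeedSet` does not carry.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise SeedFileError(f"malformed seed file {path}{where}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict) or not isinstance(doc.get("sections", {}), dict):
        raise SeedFileError(f"seed file {path}: top level must be a mapping "
                            "with a 'sections' mapping")
    seed_map: dict[str, SeedSet] = {}
    meta: dict[str, dict] = {}
    for section_id, entry in (doc.get("sections") or {}).items():
        section_id = str(section_id)
        entry = entry or {}
        if not isinstance(entry, dict):
            raise SeedFileError(f"section {section_id!r}: entry must be a mapping")
        known = {"heart", "order", "size", "tolerance", "lumen", "viable", "exclude"}
        unknown = set(entry) - known
        if unknown:
            raise SeedFileError(
                f"section {section_id!r}: unknown key(s) {sorted(unknown)}"
            )
        try:
            seeds = SeedSet(
                lumen_seeds=_seed_pairs(entry.get("lumen"), "lumen", section_id),
                viable_seeds=_seed_pairs(entry.get("viable"), "viable", section_id),
                exclusion_polygons=entry.get("exclude") or [],
                tolerance_override=entry.get("tolerance"),
            )
        except ValidationError as exc:
            raise ValidationError(f"section {section_id!r}: {exc}") from exc
        size = entry.get("size")
        if size is not None:
            if len(size) != 2:
                raise SeedFileError(f"section {section_id!r}: size must be [H, W]")
            seeds.validate_bounds((int(size[0]), int(size[1])), section_id)
        else:
            # negative coordinates are wrong regardless of image size
            for r, c in seeds.lumen_seeds + seeds.viable_seeds:
                if r < 0 or c < 0:
                    raise ValidationError(
                        f"section {section_id!r}: seed ({r}, {c}) has a negative "
                        "coordinate"
                    )
        seed_map[section_id] = seeds
        meta[section_id] = {
            k: entry[k] for k in ("heart", "order", "size") if k in entry
        }
    return seed_map, meta


def load_seed_file(path: Union[str, Path]) -> dict[str, SeedSet]:
    """Mapping section_id -> :class:`SeedSet` (see module docstring for schema).

    Query with ``mapping.get(section_id, SeedSet.empty())``: sections absent
    from the file have no seeds.
    """
    seed_map, _ = load_seed_document(path)
    return seed_map


def validate_results_table(table: pd.DataFrame) -> None:
    """Check the results-table invariants (columns, ranges, mean rows)."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"results table missing column(s) {missing}")
    for col in ("area_pct", "midline_pct"):
        vals = table[col].to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValidationError(f"{col} outside [0, 100]")
    for heart_id, grp in table.groupby("heart_id", sort=False):
        mean_rows = grp[grp["section_id"] == MEAN_ROW_ID]
        sect_rows = grp[grp["section_id"] != MEAN_ROW_ID]
        if len(mean_rows) != 1:
            raise ValidationError(
                f"heart {heart_id!r}: expected exactly one {MEAN_ROW_ID} row"
            )
        for col in ("area_pct", "midline_pct"):
            vals = sect_rows[col].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            stated = float(mean_rows[col].iloc[0])
            if vals.size == 0:
                if math.isfinite(stated):
                    raise ValidationError(
                        f"heart {heart_id!r}: {col} mean stated but no sections"
                    )
                continue
            if abs(stated - float(np.mean(vals))) > 1e-9:
                raise ValidationError(
                    f"heart {heart_id!r}: {col} summary row differs from the "
                    "mean of its section rows by more than 1e-9"
                )


def write_results(
    table: pd.DataFrame, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write a results table as CSV (canonical) or XLSX.

    ``format`` defaults to the file extension. Floats are written at full
    round-trip precision, so re-reading reproduces the table exactly.
    """
    validate_results_table(table)
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    out = table[RESULT_COLUMNS]
    if fmt == "csv":
        out.to_csv(path, index=False, encoding="utf-8")
    elif fmt == "xlsx":
        out.to_excel(path, index=False, engine="openpyxl")
    else:
        raise ValidationError(f"unsupported results format {fmt!r} (csv or xlsx)")


def read_results(path: Union[str, Path], format: Optional[str] = None) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    dtypes = {"heart_id": str, "section_id": str}
    if fmt == "csv":
        table = pd.read_csv(path, dtype=dtypes)
    elif fmt == "xlsx":
        table = pd.read_excel(path, dtype=dtypes, engine="openpyxl")
    else:
        raise ValidationError(f"unsupported results format {fmt!r} (csv or xlsx)")
    return table[RESULT_COLUMNS]


def save_label_mask(mask: LabelMask, path: Union[str, Path]) -> None:
    """Persist a label mask as a single-channel PNG with the Label codes."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ValidationError("label masks are stored as .png")
    iio.imwrite(path, mask.labels)


def load_label_mask(path: Union[str, Path]) -> LabelMask:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if arr.max(initial=0) > max(Label):
        raise ValidationError(f"{path} is not a label mask (codes 0..4)")
    return LabelMask(labels=arr.astype(np.uint8))
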