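"""File formats, configuration and run provenance.

One documented CSV dialect is used everywhere (comma-separated, mandatory
header, UTF-8, "." decimal, ``#`` comment lines); instrument list-file
exports vary by software version, so the package defines its own schema
rather than guessing.  Calibration ground-truthing workbooks (XLSX) are
read either from a single sheet with a ``morphotype`` column or from one
sheet per morphotype.  Every output file can carry the hash of the run
configuration that produced it, as a ``# config_hash=...`` comment.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationPair, TABLE1_COEFFICIENTS
from .morphometrics import Morphometrics, ParticleImage
from .shapes import MORPHOTYPES, generate_exact_calibration_pairs

logger = logging.getLogger("copemorph")

__all__ = [
    "MORPHOMETRICS_COLUMNS",
    "GROUND_TRUTH_COLUMNS",
    "read_particle_csv",
    "write_particle_csv",
    "write_ground_truth_csv",
    "read_s1_table",
    "write_synthetic_s1_table",
    "read_image",
    "write_image",
    "RunConfig",
    "config_hash",
]

MORPHOMETRICS_COLUMNS = (
    "particle_id",
    "area_px",
    "area_um2",
    "abd_diameter_um",
    "v_abd_um3",
    "feret_max_um",
    "feret_min_um",
    "length_um",
    "width_um",
    "v_lw_um3",
    "border_flag",
)

GROUND_TRUTH_COLUMNS = (
    "particle_id",
    "morphotype",
    "length_um",
    "width_um",
    "v_lw_um3",
    "area_um2",
    "seed",
)

_S1_COLUMNS = ("morphotype", "v_flowcam_um3", "v_microscopy_um3")


def write_particle_csv(records, path, config_hash: str | None = None) -> None:
    """Write per-particle measurement records in the documented schema."""
    rows = []
    for i, rec in enumerate(records):
        pid = rec.particle_id if rec.particle_id is not None else f"p{i:05d}"
        rows.append(
            {
                "particle_id": pid,
                "area_px": rec.area_px,
                "area_um2": rec.area_um2,
                "abd_diameter_um": rec.abd_diameter_um,
                "v_abd_um3": rec.v_abd_um3,
                "feret_max_um": rec.feret_max_um,
                "feret_min_um": rec.feret_min_um,
                "length_um": rec.length_um,
                "width_um": rec.width_um,
                "v_lw_um3": rec.v_lw_um3,
                "border_flag": bool(rec.border_flag),
            }
        )
    df = pd.DataFrame(rows, columns=MORPHOMETRICS_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_particle_csv(path) -> list[Morphometrics]:
    """Read a per-particle measurement CSV back into typed records.

    Rows with non-physical values (nonpositive areas, diameters or ferets,
    or feret_min above feret_max) are rejected with a warning naming their
    line numbers; the rest are kept.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MORPHOMETRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"missing mandatory column(s) {missing} in {path}; "
            f"expected header {list(MORPHOMETRICS_COLUMNS)}"
        )
    records: list[Morphometrics] = []
    bad_lines: list[int] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        ok = (
            row.area_px > 0
            and row.area_um2 > 0
            and row.abd_diameter_um > 0
            and row.v_abd_um3 > 0
            and row.feret_max_um >= row.feret_min_um > 0
            and row.length_um > 0
            and row.width_um > 0
            and row.v_lw_um3 > 0
        )
        if not ok:
            bad_lines.append(pos + 2)  # 1-based, after the header line
            continue
        records.append(
            Morphometrics(
                area_px=int(row.area_px),
                area_um2=float(row.area_um2),
                abd_diameter_um=float(row.abd_diameter_um),
                v_abd_um3=float(row.v_abd_um3),
                feret_max_um=float(row.feret_max_um),
                feret_min_um=float(row.feret_min_um),
                length_um=float(row.length_um),
                width_um=float(row.width_um),
                v_lw_um3=float(row.v_lw_um3),
                border_flag=bool(row.border_flag),
                particle_id=str(row.particle_id),
            )
        )
    if bad_lines:
        msg = f"rejected {len(bad_lines)} invalid row(s) at line(s) {bad_lines} in {path}"
        warnings.warn(msg)
        logger.warning(msg)
    return records


def write_ground_truth_csv(truths, path, config_hash: str | None = None) -> None:
    """Write generator ground truth (analytic dimensions) as CSV."""
    rows = [
        {
            "particle_id": f"p{i:05d}",
            "morphotype": t.morphotype,
            "length_um": t.true_length,
            "width_um": t.true_width,
            "v_lw_um3": t.true_v_lw,
            "area_um2": t.true_mask_area,
            "seed": t.seed,
        }
        for i, t in enumerate(truths)
    ]
    df = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def _normalize_label(label: str) -> str:
    return str(label).strip().lower().replace(" ", "_").replace("-", "_")


def read_s1_table(path, column_map: dict | None = None) -> dict[str, list[CalibrationPair]]:
    """Load a paired-biovolume ground-truthing workbook (XLSX).

    Two layouts are accepted: (a) a single sheet with columns
    ``morphotype, v_flowcam_um3, v_microscopy_um3``; (b) one sheet per
    morphotype, each with the two volume columns.  ``column_map`` renames
    nonstandard column headers, e.g. ``{"ABD volume": "v_flowcam_um3"}``.
    On a layout mismatch the error message echoes the sheets and columns
    actually observed.  All 7 morphotypes must be present.
    """
    sheets = pd.read_excel(path, sheet_name=None)
    if column_map:
        sheets = {name: df.rename(columns=column_map) for name, df in sheets.items()}
    observed = {name: list(df.columns) for name, df in sheets.items()}

    pairs: dict[str, list[CalibrationPair]] = {}
    single = [
        df for df in sheets.values() if set(_S1_COLUMNS).issubset(df.columns)
    ]
    if single:
        df = single[0]
        for label, sub in df.groupby("morphotype"):
            key = _normalize_label(label)
            pairs[key] = [
                CalibrationPair(float(f), float(m))
                for f, m in zip(sub["v_flowcam_um3"], sub["v_microscopy_um3"])
            ]
    else:
        vol_cols = {"v_flowcam_um3", "v_microscopy_um3"}
        per_sheet = {
            _normalize_label(name): df
            for name, df in sheets.items()
            if vol_cols.issubset(df.columns)
        }
        if not per_sheet:
            raise ValueError(
                "unrecognized workbook layout: expected a sheet with columns "
                f"{list(_S1_COLUMNS)} or one sheet per morphotype with "
                f"columns {sorted(vol_cols)}; observed layout: {observed}. "
                "Use column_map to adapt nonstandard headers."
            )
        for key, df in per_sheet.items():
            pairs[key] = [
                CalibrationPair(float(f), float(m))
                for f, m in zip(df["v_flowcam_um3"], df["v_microscopy_um3"])
            ]

    missing = [m for m in MORPHOTYPES if m not in pairs]
    if missing:
        raise ValueError(
            f"workbook is missing morphotype(s) {missing}; "
            f"present: {sorted(pairs)}; expected: {list(MORPHOTYPES)}"
        )
    for m in MORPHOTYPES:
        logger.info("loaded %d calibration pairs for %s", len(pairs[m]), m)
    return {m: pairs[m] for m in MORPHOTYPES}


def write_synthetic_s1_table(
    path,
    n: int = 100,
    sigma: float = 0.3,
    seed: int = 0,
    coefficients: dict | None = None,
) -> None:
    """Write a SYNTHETIC stand-in ground-truthing workbook.

    This is not instrument data: per morphotype it simulates ``n`` paired
    biovolumes from the log-linear calibration relation with the shipped
    reference coefficients as generating truth and residual scatter of
    scale ``sigma`` constructed orthogonal to the regressor, so re-fitting
    the calibration recovers the generating coefficients exactly.  Useful
    for exercising the loader and the full calibration path end to end.
    """
    coeffs = coefficients or TABLE1_COEFFICIENTS
    rng = np.random.default_rng(seed)
    frames = []
    for morph, (a, b) in coeffs.items():
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pair_list = generate_exact_calibration_pairs(a, b, sigma, n, seed=sub_seed)
        frames.append(
            pd.DataFrame(
                {
                    "morphotype": morph,
                    "v_flowcam_um3": [p[0] for p in pair_list],
                    "v_microscopy_um3": [p[1] for p in pair_list],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        df.to_excel(writer, sheet_name="pairs", index=False)


def read_image(path, pixel_size: float) -> ParticleImage:
    """Read a grayscale TIFF/PNG frame as a ParticleImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        grid = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        grid = iio.imread(path)
    grid = np.asarray(grid)
    if grid.ndim == 3:  # collapse RGB(A) to gray
        grid = grid[..., :3].mean(axis=-1)
    return ParticleImage(grid, pixel_size)


def write_image(image: ParticleImage, path) -> None:
    """Write a ParticleImage as 8-bit grayscale TIFF or PNG."""
    path = Path(path)
    grid = np.clip(np.asarray(image.grid), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, grid)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, grid)


@dataclass
class RunConfig:
    """Flat run configuration for the command-line pipeline."""

    pixel_size: float = 1.0  # um per pixel
    threshold: float = 128.0
    threshold_method: str = "fixed"
    min_esd_um: float = 30.0
    max_esd_um: float = 300.0
    n_angles: int = 180
    bins: int = 20
    calibration_source: str = "table1"  # or a path to fitted models (JSON)
    carbon_c: float | None = None
    carbon_k: float | None = None
    seed: int = 0
    output_dir: str = "copemorph_out"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.n_angles <= 0 or self.bins <= 0:
            raise ValueError("numeric config fields must be positive")
        if not (0 < self.min_esd_um < self.max_esd_um):
            raise ValueError("size gate must satisfy 0 < min_esd < max_esd")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` text config (``#`` comments allowed)."""
        values: dict = {}
        casts = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # noqa: F841
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            default = cls.__dataclass_fields__[key].default
            if isinstance(default, bool):
                values[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int) and not isinstance(default, bool):
                values[key] = int(val)
            elif isinstance(default, float) or default is None:
                try:
                    values[key] = float(val)
                except ValueError:
                    values[key] = val
            else:
                values[key] = val
        return cls(**values)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(mapping: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(mapping, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
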