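"""Readers and writers for the pipeline's tabular, image and ROI formats.

CSV dialect is fixed: UTF-8, comma separator, "." decimal point, no
thousands separators; scientific notation is accepted on read. Units are
carried in column names (_mg, _m2, _um) to prevent silent unit bugs.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .coupons import ArealDissolution, CouponRecord
from .errors import InsufficientDataError, InvalidInputError, SchemaError
from .phimaging import CalibrationPoint, DualChannelStack, PhProfile, RatioImage
from .seafloor import PolygonROI, ScaleBar
from .upscaling import SeepSite

COUPON_COLUMNS = [
    "coupon_id",
    "condition",
    "diameter_mm",
    "initial_mass_mg",
    "final_mass_mg",
    "hours_in_reactor",
]

SITE_COLUMNS = ["name", "seep_area_m2", "rock_area_m2", "reference"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_coupon_csv(path) -> list[CouponRecord]:
    """Read coupon harvest records, reporting malformed rows by line number."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, COUPON_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                CouponRecord(
                    coupon_id=str(row["coupon_id"]),
                    condition=str(row["condition"]),
                    diameter_mm=float(row["diameter_mm"]),
                    initial_mass_mg=float(row["initial_mass_mg"]),
                    final_mass_mg=float(row["final_mass_mg"]),
                    hours_in_reactor=float(row["hours_in_reactor"]),
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: header line and 1-based numbering
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def write_coupon_csv(records: list[CouponRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "coupon_id": r.coupon_id,
                "condition": r.condition,
                "diameter_mm": r.diameter_mm,
                "initial_mass_mg": r.initial_mass_mg,
                "final_mass_mg": r.final_mass_mg,
                "hours_in_reactor": r.hours_in_reactor,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_dissolution_csv(dissolutions: list[ArealDissolution], path) -> None:
    pd.DataFrame(
        [
            {
                "coupon_id": d.coupon_id,
                "condition": d.condition,
                "areal_amount_umol_cm2": d.areal_amount_umol_cm2,
                "surface_area_cm2": d.surface_area_cm2,
                "hours": d.hours,
                "flagged": d.flagged,
            }
            for d in dissolutions
        ]
    ).to_csv(path, index=False)


def read_sites_csv(path) -> list[SeepSite]:
    """Read seep-site areas; extra columns (printed fluxes etc.) are ignored."""
    df = pd.read_csv(path)
    _require_columns(df, SITE_COLUMNS, path)
    if df.empty:
        raise InsufficientDataError(f"{path}: no site rows")
    sites = []
    for idx, row in df.iterrows():
        try:
            sites.append(
                SeepSite(
                    name=str(row["name"]),
                    seep_area_m2=float(row["seep_area_m2"]),
                    rock_area_m2=float(row["rock_area_m2"]),
                    reference=str(row["reference"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
    return sites


def load_table1() -> pd.DataFrame:
    """The packaged six-site literature table (areas, published flux column).

    Columns: name, seep_area_m2, rock_area_m2, printed_flux_mol_yr,
    printed_flux_se_mol_yr, reference. The flux columns are the published
    per-site values and are used as *inputs* when reproducing the global
    extrapolation.
    """
    with resources.files("seepflux.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def load_table1_sites() -> list[SeepSite]:
    df = load_table1()
    return [
        SeepSite(
            name=r["name"],
            seep_area_m2=float(r["seep_area_m2"]),
            rock_area_m2=float(r["rock_area_m2"]),
            reference=r["reference"],
        )
        for _, r in df.iterrows()
    ]


def read_calibration_csv(path) -> list[CalibrationPoint]:
    """Read titration points from a CSV with header ph,ratio."""
    df = pd.read_csv(path)
    _require_columns(df, ["ph", "ratio"], path)
    return [
        CalibrationPoint(ph=float(r["ph"]), ratio=float(r["ratio"]))
        for _, r in df.iterrows()
    ]


def write_profile_csv(profile: PhProfile, path) -> None:
    pd.DataFrame(
        {"depth_um": profile.depths_um, "ph": profile.ph_values}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

def read_stack_tiff(
    path_488,
    path_561,
    voxel_size_um: tuple[float, float, float],
    background_488: float = 0.0,
    background_561: float = 0.0,
) -> DualChannelStack:
    """Load a dual-channel stack from two multi-page TIFFs (one per channel)."""
    a = tifffile.imread(path_488)
    b = tifffile.imread(path_561)
    return DualChannelStack(
        intensities_488=a,
        intensities_561=b,
        voxel_size_um=voxel_size_um,
        background_488=background_488,
        background_561=background_561,
    )


def write_stack_npz(stack: DualChannelStack, path) -> None:
    np.savez_compressed(
        path,
        intensities_488=stack.intensities_488,
        intensities_561=stack.intensities_561,
        voxel_size_um=np.asarray(stack.voxel_size_um),
        backgrounds=np.array([stack.background_488, stack.background_561]),
    )


def read_stack_npz(path) -> DualChannelStack:
    with np.load(path) as z:
        return DualChannelStack(
            intensities_488=z["intensities_488"],
            intensities_561=z["intensities_561"],
            voxel_size_um=tuple(z["voxel_size_um"].tolist()),
            background_488=float(z["backgrounds"][0]),
            background_561=float(z["backgrounds"][1]),
        )


def write_ratio_tiff(ratio_image: RatioImage, path) -> None:
    """Write the ratio image as 32-bit float TIFF with masked voxels = NaN."""
    tifffile.imwrite(path, ratio_image.ratios.astype(np.float32))


# ---------------------------------------------------------------------------
# ROIs and scale bars
# ---------------------------------------------------------------------------

def read_rois_geojson(path_or_obj) -> list[PolygonROI]:
    """Read polygon ROIs (pixel coordinates, role in feature properties)."""
    if isinstance(path_or_obj, (str, Path)):
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    else:
        obj = path_or_obj
    rois = []
    for feat in obj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise InvalidInputError(
                f"unsupported geometry type {geom.get('type')!r}; expected Polygon"
            )
        ring = geom["coordinates"][0]
        verts = [tuple(map(float, xy)) for xy in ring]
        if len(verts) > 3 and verts[0] == verts[-1]:
            verts = verts[:-1]
        props = feat.get("properties", {}) or {}
        rois.append(
            PolygonROI(
                vertices=verts,
                role=props.get("role", "rock"),
                label=str(props.get("label", "")),
            )
        )
    return rois


def write_rois_geojson(rois: list[PolygonROI], path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"role": r.role, "label": r.label},
            "geometry": {
                "type": "Polygon",
                "coordinates": [
                    [list(v) for v in r.vertices] + [list(r.vertices[0])]
                ],
            },
        }
        for r in rois
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_scalebars(config: dict) -> tuple[ScaleBar, ScaleBar]:
    """Build (foreground, background) scale bars from a config mapping.

    Expected keys: foreground/background, each with pixel_length and row,
    plus optional true_length_cm (default 10).
    """
    bars = []
    for key in ("foreground", "background"):
        if key not in config:
            raise SchemaError(f"scale-bar config missing {key!r} entry")
        entry = config[key]
        bars.append(
            ScaleBar(
                pixel_length=float(entry["pixel_length"]),
                row=float(entry["row"]),
                true_length_cm=float(entry.get("true_length_cm", 10.0)),
            )
        )
    return bars[0], bars[1]
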