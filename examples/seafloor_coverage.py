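"""Perspective-corrected mat/rock percent cover from a synthetic seafloor scene.

Builds a scene with a known per-row cm/px scale (the two-scale-bar
point-slope model), emits scale bars and total/rock/negative ROI polygons,
refits the perspective model from the bars alone, and measures coverage.
"""

from seepflux import coverage_fractions, fit_perspective_scale, measure_roi_area
from seepflux.io import read_rois_geojson
from seepflux.seafloor import PerspectiveScaleModel
from seepflux.synthetic import (
    RectROISpec,
    SeafloorSceneSpec,
    generate_seafloor_scene,
)

true_model = PerspectiveScaleModel(
    slope_m=-1.1111e-4, anchor_row=150.0, anchor_scale=0.1, image_size=(1333, 750)
)
spec = SeafloorSceneSpec(
    true_model=true_model,
    rois=(
        RectROISpec(rows=(100, 600), cols=(100, 1200), role="total_visible", label="total"),
        RectROISpec(rows=(200, 500), cols=(200, 800), role="rock", label="rock1"),
        RectROISpec(rows=(300, 400), cols=(300, 500), role="negative", label="neg1"),
    ),
)
bars, geojson, truth = generate_seafloor_scene(spec)

model = fit_perspective_scale(bars[0], bars[1], true_model.image_size)
rois = read_rois_geojson(geojson)
total = next(r for r in rois if r.role == "total_visible")
rocks = [r for r in rois if r.role == "rock"]
negatives = [r for r in rois if r.role == "negative"]

result = coverage_fractions(model, total, rocks, negatives)

print(f"scale at top/bottom row: {model.scale_at_row(0):.4f} / "
      f"{model.scale_at_row(749):.4f} cm/px")
print(f"total visible area:      {result.total_area_m2:.3f} m^2 "
      f"(true {truth['total'] * 1e-4:.3f})")
print(f"exposed carbonate rock:  {result.rock_area_m2:.3f} m^2")
print(f"mat-covered rock:        {result.mat_area_m2:.3f} m^2")
print(f"mat:rock coverage:       {result.mat_rock_fraction_pct:.2f} %")
print(f"rock:total coverage:     {result.rock_total_fraction_pct:.2f} %")
# The negative ROI (a mat-free window inside the rock polygon) is what
# separates rock area from mat-on-rock area.
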