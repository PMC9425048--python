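"""CT-based body composition: Hounsfield-unit segmentation to depot masses.

Slices taken at fixed spacing along the body are segmented into fat, lean
and bone by thresholding on a (scanner-convention, offset-rescaled)
Hounsfield-unit display scale; per-slice tissue areas are numerically
integrated into depot volumes and converted to masses through a linear
HU-to-density map. Compartment labels (carcass vs viscera, subcutaneous vs
intermuscular fat, rumen-content exclusion) are per-slice inputs, mirroring
the manual segmentation step of the measurement protocol.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: depot keys expected by assemble_composition (masses in kg)
DEPOTS = (
    "subcutaneous_fat",
    "intermuscular_fat",
    "visceral_fat",
    "carcass_lean",
    "total_bone",
    "nonfat_visceral",
)


def _default_density_coeffs() -> tuple[float, float]:
    # least-squares line through nominal (display-HU, g/cm^3) anchors for
    # fat, lean and bone on the 40-255 offset scale
    hu = np.array([77.5, 158.0, 228.0])
    dens = np.array([0.916, 1.056, 1.45])
    b, a = np.polyfit(hu, dens, 1)
    return float(a), float(b)


@dataclasses.dataclass(frozen=True)
class SegmentationConfig:
    """HU bands (inclusive edges) and the linear HU->density map."""

    hu_fat: tuple[int, int] = (40, 115)
    hu_lean: tuple[int, int] = (116, 200)
    hu_bone: tuple[int, int] = (201, 255)
    density_coeffs: tuple[float, float] = dataclasses.field(
        default_factory=_default_density_coeffs
    )  #: (intercept, slope): g/cm^3 = a + b*HU

    def __post_init__(self):
        bands = [self.hu_fat, self.hu_lean, self.hu_bone]
        for lo, hi in bands:
            if lo > hi:
                raise ValueError("HU band with lower bound above upper bound")
        for (_, hi), (lo, _) in zip(bands, bands[1:]):
            if hi >= lo:
                raise ValueError("HU bands must be disjoint and ordered")

    def density(self, hu: float) -> float:
        a, b = self.density_coeffs
        return a + b * hu


def segment_slice(
    raster: np.ndarray,
    config: SegmentationConfig,
    pixel_area_mm2: float,
) -> dict[str, dict[str, float]]:
    """Assign each pixel to fat/lean/bone/background by its HU band.

    Band edges are inclusive; anything outside all bands is background.
    Returns per tissue the pixel count, area (mm^2) and mean HU.
    """
    values = np.asarray(raster, dtype=float)
    out: dict[str, dict[str, float]] = {}
    assigned = np.zeros(values.shape, dtype=bool)
    for tissue, (lo, hi) in (
        ("fat", config.hu_fat),
        ("lean", config.hu_lean),
        ("bone", config.hu_bone),
    ):
        mask = (values >= lo) & (values <= hi)
        assigned |= mask
        n = int(mask.sum())
        out[tissue] = {
            "pixels": n,
            "area_mm2": n * pixel_area_mm2,
            "mean_hu": float(values[mask].mean()) if n else np.nan,
        }
    n_bg = int((~assigned).sum())
    out["background"] = {"pixels": n_bg, "area_mm2": n_bg * pixel_area_mm2, "mean_hu": np.nan}
    return out


def tissue_volume(per_slice_areas_mm2, spacing_mm: float) -> float:
    """Rectangular-rule volume: sum of slice areas times slice spacing, cm^3.

    Trapezoidal integration is available via :func:`tissue_volume_trapezoid`.
    """
    areas = np.asarray(per_slice_areas_mm2, dtype=float)
    if len(areas) < 1:
        raise ValueError("need at least one slice")
    return float(areas.sum() * spacing_mm / 1000.0)


def tissue_volume_trapezoid(per_slice_areas_mm2, spacing_mm: float) -> float:
    """Trapezoidal alternative to the rectangular rule (cm^3)."""
    areas = np.asarray(per_slice_areas_mm2, dtype=float)
    if len(areas) < 2:
        return tissue_volume(per_slice_areas_mm2, spacing_mm)
    return float(np.trapezoid(areas, dx=spacing_mm) / 1000.0)


def volume_to_mass(volume_cm3: float, mean_hu: float, config: SegmentationConfig) -> float:
    """kg = volume (cm^3) x density(mean HU) (g/cm^3) / 1000.

    ``mean_hu`` should be the area-weighted mean HU of the depot across its
    slices.
    """
    dens = config.density(mean_hu)
    if dens <= 0:
        raise ValueError(f"non-positive density {dens:.3g} at HU {mean_hu}")
    return volume_cm3 * dens / 1000.0


def area_weighted_hu(areas_mm2, mean_hus) -> float:
    """Mean HU across slices, weighted by slice area."""
    a = np.asarray(areas_mm2, dtype=float)
    h = np.asarray(mean_hus, dtype=float)
    ok = (a > 0) & np.isfinite(h)
    if not ok.any():
        return np.nan
    return float(np.average(h[ok], weights=a[ok]))


@dataclasses.dataclass
class CompositionRecord:
    """Depot masses (kg) with the derived carcass traits.

    Identities: carcass fat = subcutaneous + intermuscular; total fat =
    carcass fat + visceral; carcass weight = carcass fat + lean + bone;
    CT weight = carcass weight + visceral fat + non-fat visceral
    (fasted-equivalent body weight); dressing-out % = 100 * carcass weight /
    CT weight; fat:lean = total fat / carcass lean.
    """

    subcutaneous_fat: float
    intermuscular_fat: float
    visceral_fat: float
    carcass_lean: float
    total_bone: float
    nonfat_visceral: float
    carcass_fat: float
    total_fat: float
    carcass_weight: float
    ct_weight: float
    dressing_out_pct: float
    fat_lean_ratio: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def assemble_composition(masses: dict[str, float]) -> CompositionRecord:
    """Build the derived carcass traits from the six depot masses."""
    missing = [k for k in DEPOTS if k not in masses]
    if missing:
        raise ValueError(f"missing depot masses: {missing}")
    sub = float(masses["subcutaneous_fat"])
    inter = float(masses["intermuscular_fat"])
    visc = float(masses["visceral_fat"])
    lean = float(masses["carcass_lean"])
    bone = float(masses["total_bone"])
    nonfat = float(masses["nonfat_visceral"])
    carcass_fat = sub + inter
    total_fat = carcass_fat + visc
    carcass_weight = carcass_fat + lean + bone
    ct_weight = carcass_weight + visc + nonfat
    rec = CompositionRecord(
        subcutaneous_fat=sub,
        intermuscular_fat=inter,
        visceral_fat=visc,
        carcass_lean=lean,
        total_bone=bone,
        nonfat_visceral=nonfat,
        carcass_fat=carcass_fat,
        total_fat=total_fat,
        carcass_weight=carcass_weight,
        ct_weight=ct_weight,
        dressing_out_pct=100.0 * carcass_weight / ct_weight if ct_weight > 0 else np.nan,
        fat_lean_ratio=total_fat / lean if lean > 0 else np.nan,
    )
    # identity self-check: a violation here is a programming error
    assert abs(rec.carcass_fat - (sub + inter)) < 1e-9
    assert abs(rec.total_fat - (carcass_fat + visc)) < 1e-9
    assert abs(rec.carcass_weight - (carcass_fat + lean + bone)) < 1e-9
    assert abs(rec.ct_weight - (carcass_weight + visc + nonfat)) < 1e-9
    return rec


def _depot_of(compartment: str, tissue: str, subdepot: str | None) -> str | None:
    """Map (compartment, tissue, carcass-fat sub-label) to a depot key."""
    tissue = tissue.lower()
    compartment = compartment.lower()
    if tissue == "rumen_content":
        return None  # excluded, mirrors the manual rumen-content removal
    if compartment == "carcass":
        if tissue == "fat":
            if subdepot and subdepot.lower().startswith("sub"):
                return "subcutaneous_fat"
            return "intermuscular_fat"
        if tissue == "lean":
            return "carcass_lean"
        if tissue == "bone":
            return "total_bone"
    elif compartment == "viscera":
        if tissue == "fat":
            return "visceral_fat"
        if tissue == "bone":
            return "total_bone"
        if tissue == "lean":
            return "nonfat_visceral"
    return None


def process_stack(
    stack: pd.DataFrame,
    config: SegmentationConfig,
    spacing_mm: float = 30.0,
    per_depot_density: bool = True,
) -> tuple[dict[str, float], CompositionRecord]:
    """Integrate a per-slice tissue-area table into depot masses.

    ``stack`` columns: ``slice, compartment, tissue, area_mm2, mean_hu`` and
    optionally ``subdepot`` (subcutaneous/intermuscular for carcass fat).
    Rows with tissue ``rumen_content`` are excluded. When
    ``per_depot_density`` each depot's mass uses its own area-weighted mean
    HU; otherwise a single tissue-wide mean HU is used per tissue type.
    """
    df = stack.copy()
    if "subdepot" not in df:
        df["subdepot"] = None
    df["depot"] = [
        _depot_of(c, t, s)
        for c, t, s in zip(df["compartment"], df["tissue"], df["subdepot"])
    ]
    df = df[df["depot"].notna()]

    if not per_depot_density:
        tissue_hu = {
            t: area_weighted_hu(g["area_mm2"], g["mean_hu"])
            for t, g in df.groupby(df["tissue"].str.lower())
        }

    masses: dict[str, float] = {k: 0.0 for k in DEPOTS}
    for depot, grp in df.groupby("depot"):
        vol = tissue_volume(grp["area_mm2"], spacing_mm)
        if per_depot_density:
            hu = area_weighted_hu(grp["area_mm2"], grp["mean_hu"])
        else:
            hu = tissue_hu[grp["tissue"].str.lower().iloc[0]]
        masses[depot] = volume_to_mass(vol, hu, config) if np.isfinite(hu) else 0.0
    return masses, assemble_composition(masses)


def process_raster_stack(
    slices: list[dict],
    config: SegmentationConfig,
    spacing_mm: float = 30.0,
) -> tuple[dict[str, float], CompositionRecord]:
    """Segment a stack of labelled rasters and integrate to depot masses.

    Each slice dict carries ``raster`` (2-D HU array), ``compartment``
    ('carcass' or 'viscera'), ``pixel_area_mm2`` and, for carcass slices, an
    optional boolean ``subcutaneous_mask`` marking the subcutaneous region
    (fat outside the mask counts as intermuscular). Visceral slices may
    carry a boolean ``rumen_mask`` of pixels to exclude.
    """
    rows = []
    for k, sl in enumerate(slices):
        raster = np.asarray(sl["raster"], dtype=float)
        pixel_area = float(sl["pixel_area_mm2"])
        compartment = sl["compartment"]
        rumen = np.asarray(sl.get("rumen_mask", np.zeros(raster.shape, dtype=bool)))
        work = raster.copy()
        work[rumen] = -1e9  # excluded from every band
        seg = segment_slice(work, config, pixel_area)
        for tissue in ("fat", "lean", "bone"):
            lo, hi = getattr(config, f"hu_{tissue}")
            mask = (work >= lo) & (work <= hi)
            if compartment == "carcass" and tissue == "fat":
                sub_mask = np.asarray(
                    sl.get("subcutaneous_mask", np.zeros(raster.shape, dtype=bool))
                )
                for subdepot, m in (
                    ("subcutaneous", mask & sub_mask),
                    ("intermuscular", mask & ~sub_mask),
                ):
                    n = int(m.sum())
                    rows.append(
                        {
                            "slice": k,
                            "compartment": compartment,
                            "tissue": tissue,
                            "subdepot": subdepot,
                            "area_mm2": n * pixel_area,
                            "mean_hu": float(raster[m].mean()) if n else np.nan,
                        }
                    )
            else:
                rows.append(
                    {
                        "slice": k,
                        "compartment": compartment,
                        "tissue": tissue,
                        "subdepot": None,
                        "area_mm2": seg[tissue]["area_mm2"],
                        "mean_hu": seg[tissue]["mean_hu"],
                    }
                )
    table = pd.DataFrame(rows)
    return process_stack(table, config, spacing_mm)
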