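"""Portable accumulation chamber (PAC) gas traits.

A sheep sits in a sealed 827-L chamber for ~1 h while CH4, CO2 and O2
concentrations are read at ~0, 30 and 60 min. The concentration rise,
converted through the ideal-gas law at the recorded temperature and
pressure, gives a spot daily emission estimate. Because whole lots of 10
animals share pre-measurement handling (waiting time off feed), each trait
is rescaled so every lot mean equals the overall trait mean.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

R_L_KPA = 8.31446  #: gas constant, L*kPa/(mol*K)
MOLAR_MASS = {"ch4": 16.04, "co2": 44.01, "o2": 32.00}  #: g/mol
CHAMBER_VOLUME_L = 827.0  #: internal chamber volume


@dataclasses.dataclass
class EmissionEstimate:
    g_per_day: float
    slope_ppm_per_min: float
    negative_slope: bool  #: flagged, value retained


def emission_rate(
    minutes,
    concentration_ppm,
    molar_mass: float,
    *,
    chamber_volume_l: float = CHAMBER_VOLUME_L,
    animal_volume_l: float = 0.0,
    temp_k: float = 273.15,
    pressure_kpa: float = 101.325,
) -> EmissionEstimate:
    """Convert a timed concentration profile to grams of gas per day.

    The OLS slope of concentration (mole fraction) against time is scaled by
    the moles of gas in the free chamber volume (chamber minus animal,
    ideal gas at the recorded temperature and pressure) and the molar mass:

        g/day = slope[ppm/min] * 1e-6 * P*(V_chamber - V_animal)/(R*T)
                * M * 1440

    A negative fitted slope is retained but flagged.
    """
    t = np.asarray(minutes, dtype=float)
    c = np.asarray(concentration_ppm, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two timed readings")
    if temp_k <= 0 or pressure_kpa <= 0:
        raise ValueError("temperature and pressure must be positive")
    slope = np.polyfit(t, c, 1)[0]  # ppm per minute
    free_volume = chamber_volume_l - animal_volume_l
    if free_volume <= 0:
        raise ValueError("animal volume exceeds chamber volume")
    mol_air = pressure_kpa * free_volume / (R_L_KPA * temp_k)
    g_day = slope * 1e-6 * mol_air * molar_mass * 1440.0
    negative = bool(slope < 0)
    if negative:
        logger.warning("negative concentration slope (%.3g ppm/min); value retained", slope)
    return EmissionEstimate(float(g_day), float(slope), negative)


def scale_by_lot(values, lot_ids) -> np.ndarray:
    """Rescale each value by (value / lot mean) * grand mean.

    After scaling every lot mean equals the grand mean, removing lot-level
    nuisance (shared waiting time before measurement) while preserving the
    overall trait mean exactly.
    """
    x = np.asarray(values, dtype=float)
    lots = np.asarray(lot_ids)
    if len(x) != len(lots):
        raise ValueError("values and lot ids differ in length")
    grand = x.mean()
    out = np.empty_like(x)
    for lot in np.unique(lots):
        mask = lots == lot
        m = x[mask].mean()
        if m <= 0:
            raise ValueError(f"non-positive mean {m} in lot {lot!r}")
        out[mask] = x[mask] / m * grand
    return out


def molar_traits(ch4_g_day: float, co2_g_day: float) -> dict[str, float]:
    """Molar sum CH4+CO2 (mol/day) and the ratio CH4/(CH4+CO2) (mol/mol).

    The ratio is a methane-yield proxy with the molar gas sum standing in
    for intake. Both gases zero -> ratio undefined (NaN).
    """
    if ch4_g_day < 0 or co2_g_day < 0:
        raise ValueError("gas emissions must be non-negative")
    ch4_mol = ch4_g_day / MOLAR_MASS["ch4"]
    co2_mol = co2_g_day / MOLAR_MASS["co2"]
    total = ch4_mol + co2_mol
    ratio = ch4_mol / total if total > 0 else np.nan
    if total == 0:
        logger.warning("both gases zero: CH4/(CH4+CO2) undefined")
    return {"ch4_co2_mol_day": total, "ch4_ratio": ratio}


def process_pac_table(
    pac: pd.DataFrame,
    *,
    chamber_volume_l: float = CHAMBER_VOLUME_L,
    animal_volume_per_kg_l: float = 1.0,
    body_weight: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Derive per animal-round gas traits from a long PAC table.

    ``pac`` columns: ``animal, round, lot, chamber, gas, minutes,
    concentration_ppm, temp_K, pressure_kPa`` (one row per timed reading).
    ``body_weight``: optional ``animal, round, kg`` table; when present the
    animal's volume (~1 L per kg liveweight by default) is subtracted from
    the chamber volume.

    Returns a tidy table per animal-round with raw and lot-scaled CH4 and
    CO2 g/day, the molar sum and the CH4/(CH4+CO2) ratio. Scaling is per
    trait across the round's lots with the grand mean taken over all
    animal-rounds. O2 readings are parsed but no O2 trait is derived.
    """
    df = pac.copy()
    df["gas"] = df["gas"].astype(str).str.lower()
    bw = None
    if body_weight is not None:
        bw = body_weight.copy()
        bw["animal"] = bw["animal"].astype(str)
        bw = bw.set_index(["animal", "round"])["kg"]

    rows = []
    for (animal, rnd, lot, chamber), grp in df.groupby(["animal", "round", "lot", "chamber"]):
        animal = str(animal)
        vol_animal = 0.0
        if bw is not None and (animal, rnd) in bw.index:
            vol_animal = float(bw.loc[(animal, rnd)]) * animal_volume_per_kg_l
        rec: dict[str, object] = {
            "animal": animal,
            "round": rnd,
            "lot": lot,
            "chamber": chamber,
            "body_weight_kg": vol_animal / animal_volume_per_kg_l if vol_animal else np.nan,
        }
        for gas in ("ch4", "co2"):
            sub = grp[grp["gas"] == gas].sort_values("minutes")
            if len(sub) < 2:
                rec[f"{gas}_g_day"] = np.nan
                continue
            est = emission_rate(
                sub["minutes"],
                sub["concentration_ppm"],
                MOLAR_MASS[gas],
                chamber_volume_l=chamber_volume_l,
                animal_volume_l=vol_animal,
                temp_k=float(sub["temp_K"].iloc[0]),
                pressure_kpa=float(sub["pressure_kPa"].iloc[0]),
            )
            rec[f"{gas}_g_day"] = est.g_per_day
            rec[f"{gas}_flagged"] = est.negative_slope
        rows.append(rec)
    out = pd.DataFrame(rows)
    derived = out.apply(
        lambda r: molar_traits(max(r["ch4_g_day"], 0.0), max(r["co2_g_day"], 0.0)),
        axis=1,
        result_type="expand",
    )
    out = pd.concat([out, derived], axis=1)

    # lot scaling: per trait, lots contemporary within a round, grand mean
    # over every animal-round in the dataset
    out["round_lot"] = out["round"].astype(str) + ":" + out["lot"].astype(str)
    for trait in ("ch4_g_day", "co2_g_day", "ch4_co2_mol_day", "ch4_ratio"):
        ok = out[trait].notna()
        scaled = np.full(len(out), np.nan)
        scaled[ok.to_numpy()] = scale_by_lot(out.loc[ok, trait], out.loc[ok, "round_lot"])
        out[f"{trait}_scaled"] = scaled
    return out.drop(columns=["round_lot"])
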