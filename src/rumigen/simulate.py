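"""Synthetic study cohorts with known genetic ground truth.

Generates everything the trait-construction and REML stages consume — a
multi-flock, multi-cohort pedigree with genetically linked sires, true
direct and maternal breeding values under configurable covariance matrices,
fixed-effect structure (contemporary group, cohort-pen, birth-rearing rank,
age of dam, birthday deviation), feeder-event streams, noisy growth curves,
accumulation-chamber concentration profiles with lot-level nuisance, CT
slice stacks and ultrasound fat depths — while recording every phenotype
component exactly, so that parameter recovery validates the downstream
pipeline end to end.

Default true parameters are seeded from the published reference estimates
(see :mod:`rumigen.reference`), so recovery tests double as plausibility
checks against study-scale values.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd
import yaml

from . import reference
from .pedigree import PedigreeRecord, inbreeding_coefficients, _parent_indices

COHORT_YEARS = {"1": 2015, "2a": 2016, "2b": 2016, "3a": 2017, "3b": 2017}
COHORT_PENS = {"1": "ABCDE", "2a": "ABCDE", "2b": "ABCDE", "3a": "AB", "3b": "AB"}
FEED_BY_YEAR = {  # pellet dry matter fraction and MJ ME per kg DM per study year
    2015: (0.93, 10.9),
    2016: (0.94, 11.4),
    2017: (0.90, 10.8),
}

#: default genetic correlations between latent traits (reference seeded)
DEFAULT_RG = {
    ("rfi", "ch4"): -0.28,
    ("rfi", "visceral_fat"): -0.52,
    ("rfi", "subcutaneous_fat"): -0.33,
    ("rfi", "nonfat_visceral"): 0.64,
    ("ch4", "carcass_lean"): 0.54,
    ("co2", "carcass_lean"): 0.65,
    ("ch4", "co2"): 0.65,
    ("mmwt", "ch4"): 0.68,
    ("mmwt", "co2"): 0.62,
    ("adg", "ch4"): 0.34,
}
#: default phenotypic correlations (used to back out residual correlations)
DEFAULT_RP = {
    ("rfi", "ch4"): 0.03,
    ("rfi", "visceral_fat"): -0.11,
    ("rfi", "nonfat_visceral"): 0.33,
    ("ch4", "carcass_lean"): 0.28,
    ("co2", "carcass_lean"): 0.41,
    ("ch4", "co2"): 0.70,
    ("mmwt", "ch4"): 0.41,
    ("mmwt", "co2"): 0.45,
    ("adg", "ch4"): 0.27,
}

#: per-trait fixed effects (contemporary group applies to every trait)
DEFAULT_FIXED = {
    "mmwt": ("brr", "aod", "aod2", "bdev"),
    "adg": ("cohort_pen", "brr"),
    "rfi": (),
    "feed_intake": ("cohort_pen", "brr", "aod2"),
    "events_per_day": ("cohort_pen",),
    "feeding_rate": ("cohort_pen", "brr"),
    "ch4": ("brr", "aod2"),
    "co2": ("brr",),
    "c_start": ("cohort_pen",),
    "c_final": ("cohort_pen",),
}

REPEATED_TRAITS = ("ch4", "co2")  #: two accumulation-chamber rounds each


@dataclasses.dataclass
class PACSpec:
    chamber_volume_l: float = 827.0
    lot_size: int = 10
    session_min: float = 60.0
    lot_sd: float = 0.10  #: SD of the multiplicative log-normal lot nuisance
    conc_noise_frac: float = 0.01
    temp_k: float = 288.15
    pressure_kpa: float = 101.3
    round_days: tuple[int, int] = (21, 35)
    ch4_ambient_ppm: float = 2.0
    co2_ambient_ppm: float = 450.0
    o2_ambient_ppm: float = 209000.0
    animal_volume_per_kg_l: float = 1.0


@dataclasses.dataclass
class CTSpec:
    spacing_mm: float = 30.0
    n_slices: tuple[int, int] = (30, 32)
    carcass_fraction: float = 0.6
    hu_centers: dict = dataclasses.field(
        default_factory=lambda: {"fat": 77.0, "lean": 158.0, "bone": 228.0}
    )
    hu_sd: float = 8.0
    fov_mm: float = 450.0
    raster_size: int = 64
    rumen_area_mm2: float = 8000.0


@dataclasses.dataclass
class FeederSpec:
    day_cv: float = 0.08  #: day-to-day CV of an animal's intake
    duration_noise_frac: float = 0.10
    gamma_shape: float = 2.0  #: event-size spread within a day


@dataclasses.dataclass
class SimulationConfig:
    """Study-condition parameters for a synthetic cohort.

    Defaults emulate the study design: ~1000 phenotyped ewe lambs in five
    cohorts of three genetically linked flocks, sires with 10 progeny,
    twice-weekly weighing over a 42-day test, two chamber rounds 14 days
    apart in lots of 10, CT stacks of 30-32 slices at 30-mm spacing.
    """

    seed: int = 0
    n_sires: int = 100
    dams_per_sire: int = 5
    progeny_per_dam: int = 2
    sire_link_frac: float = 0.2
    flocks: tuple[str, ...] = ("A", "B", "C")
    cohorts: tuple[str, ...] = ("1", "2a", "2b", "3a", "3b")
    rfi_coefs: tuple[float, float, float] = (2.62, 0.6, 30.0)  #: b0, b1 (MMWT), b2 (ADG)
    weighing_noise_sd: float = 0.5  #: kg; overridden by weighing_noise_frac
    weighing_noise_frac: float | None = None  #: sd as a fraction of weight
    ultrasound_noise_sd: float = 0.3  #: mm
    genetic_correlations: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_RG))
    phenotypic_correlations: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_RP))
    cg_scale: float = 0.30  #: fixed-effect SDs as fractions of the trait SD
    pen_scale: float = 0.20
    brr_scale: float = 0.15
    aod_scale: float = 0.05
    bdev_scale: float = 0.01
    pac: PACSpec = dataclasses.field(default_factory=PACSpec)
    ct: CTSpec = dataclasses.field(default_factory=CTSpec)
    feeder: FeederSpec = dataclasses.field(default_factory=FeederSpec)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def default_trait_table() -> pd.DataFrame:
    """Latent trait set with true mean/SD/h2/maternal-h2/repeatability."""
    ref = reference.load_reference_traits().set_index("trait")
    names = [
        "mmwt", "adg", "rfi", "events_per_day", "feeding_rate",
        "ch4", "co2", "visceral_fat", "subcutaneous_fat", "intermuscular_fat",
        "carcass_lean", "total_bone", "nonfat_visceral", "c_start", "c_final",
    ]
    rows = []
    for name in names:
        r = ref.loc[name]
        rows.append(
            {
                "trait": name,
                "mean": float(r["mean"]),
                "sd": float(r["sd"]),
                "h2": float(r["h2"]),
                "mat_h2": float(r["maternal_h2"]) if pd.notna(r["maternal_h2"]) else 0.0,
                "repeatability": float(r["repeatability"])
                if pd.notna(r["repeatability"])
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def nearest_psd(mat: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    return (vecs * np.clip(vals, eps, None)) @ vecs.T


def build_covariances(
    traits: pd.DataFrame,
    rg: dict | None = None,
    rp: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """True (co)variance matrices from the trait table and correlation maps.

    Returns G (direct additive), M (maternal, diagonal), PE (permanent
    environment, repeated traits only) and E (residual). Residual
    correlations are backed out of the requested phenotypic correlations;
    G and E are PSD-projected.
    """
    rg = dict(DEFAULT_RG) if rg is None else rg
    rp = dict(DEFAULT_RP) if rp is None else rp
    names = traits.index.tolist()
    t = len(names)
    var_p = traits["sd"].to_numpy() ** 2
    var_a = traits["h2"].to_numpy() * var_p
    var_m = traits["mat_h2"].to_numpy() * var_p
    rep = traits["repeatability"].to_numpy()
    var_pe = np.where(
        np.isfinite(rep), np.clip(rep * var_p - var_a - var_m, 0.0, None), 0.0
    )
    var_e = np.clip(var_p - var_a - var_m - var_pe, 1e-12, None)

    def corr_of(pair_map, i, j):
        a, b = names[i], names[j]
        return pair_map.get((a, b), pair_map.get((b, a), 0.0))

    G = np.diag(var_a).astype(float)
    E = np.diag(var_e).astype(float)
    for i in range(t):
        for j in range(i + 1, t):
            rgij = corr_of(rg, i, j)
            G[i, j] = G[j, i] = rgij * np.sqrt(var_a[i] * var_a[j])
            rpij = corr_of(rp, i, j)
            if rpij != 0.0:
                cov_e = rpij * np.sqrt(var_p[i] * var_p[j]) - G[i, j]
                lim = 0.95 * np.sqrt(var_e[i] * var_e[j])
                E[i, j] = E[j, i] = float(np.clip(cov_e, -lim, lim))
    G = nearest_psd(G)
    E = nearest_psd(E)
    wrap = lambda m: pd.DataFrame(m, index=names, columns=names)
    return {
        "G": wrap(G),
        "M": wrap(np.diag(var_m)),
        "PE": wrap(np.diag(var_pe)),
        "E": wrap(E),
    }


# ---------------------------------------------------------------------------
# pedigree and breeding values


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator):
    """Three-generation pedigree with linked sires across cohorts/flocks.

    Returns (records, meta) where meta covers phenotyped progeny only with
    their flock, cohort, pen, sire, dam and fixed-effect covariates.
    """
    records: list[PedigreeRecord] = []
    n_gs = max(config.n_sires // 2, 2)
    n_gd = max(config.n_sires, 2)
    gs = [f"GS{i:04d}" for i in range(n_gs)]
    gd = [f"GD{i:04d}" for i in range(n_gd)]
    for a in gs + gd:
        records.append(PedigreeRecord(a, None, None, birth_year=2010))

    sires = [f"S{i:04d}" for i in range(config.n_sires)]
    for i, s in enumerate(sires):
        records.append(
            PedigreeRecord(
                s,
                sire_id=gs[int(rng.integers(n_gs))],
                dam_id=gd[int(rng.integers(n_gd))],
                birth_year=2012,
                flock=config.flocks[i % len(config.flocks)],
            )
        )
    n_dams = config.n_sires * config.dams_per_sire
    dams = [f"D{i:04d}" for i in range(n_dams)]
    for i, d in enumerate(dams):
        records.append(
            PedigreeRecord(
                d,
                sire_id=gs[int(rng.integers(n_gs))],
                dam_id=gd[int(rng.integers(n_gd))],
                birth_year=2012,
            )
        )

    n_linked = int(round(config.sire_link_frac * config.n_sires))
    meta_rows = []
    lamb = 0
    for i, s in enumerate(sires):
        flock = config.flocks[i % len(config.flocks)]
        base_cohort = config.cohorts[int(rng.integers(len(config.cohorts)))]
        if i < n_linked:  # link sire: progeny in a second cohort
            other = [c for c in config.cohorts if c != base_cohort]
            cohorts_for_sire = [base_cohort, other[int(rng.integers(len(other)))]]
        else:
            cohorts_for_sire = [base_cohort]
        my_dams = dams[i * config.dams_per_sire : (i + 1) * config.dams_per_sire]
        for k, d in enumerate(my_dams):
            cohort = cohorts_for_sire[k % len(cohorts_for_sire)]
            for _ in range(config.progeny_per_dam):
                animal = f"L{lamb:05d}"
                lamb += 1
                year = COHORT_YEARS.get(cohort, 2015)
                records.append(
                    PedigreeRecord(animal, s, d, birth_year=year, flock=flock, cohort=cohort)
                )
                pens = COHORT_PENS.get(cohort, "AB")
                meta_rows.append(
                    {
                        "animal": animal,
                        "sire": s,
                        "dam": d,
                        "flock": flock,
                        "cohort": cohort,
                        "birth_year": year,
                        "pen": pens[int(rng.integers(len(pens)))],
                        "cg": f"{year}-{flock}",
                        "brr": int(rng.choice([1, 2, 3], p=[0.3, 0.55, 0.15])),
                        "aod": int(rng.integers(2, 7)),
                        "bdev": float(np.round(rng.normal(0.0, 7.0), 1)),
                    }
                )
    meta = pd.DataFrame(meta_rows)
    meta["cohort_pen"] = meta["cohort"] + ":" + meta["pen"]
    return records, meta


def simulate_breeding_values(
    pedigree: list[PedigreeRecord],
    G_direct: np.ndarray,
    G_maternal: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Multivariate breeding values down the pedigree by Mendelian sampling.

    a_i = 0.5 a_sire + 0.5 a_dam + m_i with Var(m_i) = phi_i G, where
    phi_i = 1 - 0.25 (1 + F_sire) - 0.25 (1 + F_dam) (terms for known
    parents only), so that Cov(a_i, a_j) = a_ij G over the whole pedigree.
    Maternal values are generated the same way under G_maternal.
    """
    if rng is None:
        rng = np.random.default_rng()
    G_direct = np.atleast_2d(np.asarray(G_direct, dtype=float))
    mats = [G_direct]
    if G_maternal is not None:
        G_maternal = np.atleast_2d(np.asarray(G_maternal, dtype=float))
        mats.append(G_maternal)
    for mat in mats:
        if np.min(np.linalg.eigvalsh(0.5 * (mat + mat.T))) < -1e-8:
            raise ValueError("covariance matrix is not positive semi-definite")

    sire, dam = _parent_indices(pedigree)
    F = inbreeding_coefficients(pedigree)
    n = len(pedigree)

    def sqrt_psd(mat):
        vals, vecs = np.linalg.eigh(mat)
        return vecs * np.sqrt(np.clip(vals, 0.0, None))

    def run(G):
        t = G.shape[0]
        L = sqrt_psd(G)
        values = np.zeros((n, t))
        z = rng.standard_normal((n, t))
        for i in range(n):
            s, d = sire[i], dam[i]
            phi = 1.0
            mean = np.zeros(t)
            if s >= 0:
                phi -= 0.25 * (1.0 + F[s])
                mean += 0.5 * values[s]
            if d >= 0:
                phi -= 0.25 * (1.0 + F[d])
                mean += 0.5 * values[d]
            values[i] = mean + np.sqrt(phi) * (L @ z[i])
        return values

    bv = run(G_direct)
    mbv = run(G_maternal) if G_maternal is not None else None
    return bv, mbv


# ---------------------------------------------------------------------------
# full cohort: truth then raw data streams


@dataclasses.dataclass
class SyntheticCohort:
    """Raw data bundle plus exact ground truth for a simulated study."""

    config: SimulationConfig
    pedigree: list[PedigreeRecord]
    animals: pd.DataFrame  #: phenotyped animals with covariates
    truth: pd.DataFrame  #: per-animal phenotype components, exact
    trait_table: pd.DataFrame
    covariances: dict[str, pd.DataFrame]
    feeder_events: pd.DataFrame
    liveweights: pd.DataFrame
    pac: pd.DataFrame
    pac_body_weight: pd.DataFrame
    ct_stacks: pd.DataFrame  #: long per-slice tissue-area table
    ct_rasters: dict  #: animal -> slice dicts (raster fidelity mode), may be empty
    ultrasound: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path
        from .pedigree import pedigree_to_frame

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pedigree_to_frame(self.pedigree).to_csv(out / "pedigree.csv", index=False)
        self.animals.to_csv(out / "animals.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.feeder_events.to_csv(out / "feeder_events.csv", index=False)
        self.liveweights.to_csv(out / "liveweights.csv", index=False)
        self.pac.to_csv(out / "pac.csv", index=False)
        self.pac_body_weight.to_csv(out / "pac_body_weight.csv", index=False)
        self.ct_stacks.to_csv(out / "ct_stacks.csv", index=False)
        self.ultrasound.to_csv(out / "ultrasound.csv", index=False)
        (out / "config.yaml").write_text(self.config.to_yaml())


def _fixed_effect_contributions(
    meta: pd.DataFrame,
    traits: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-animal fixed-effect contribution for every trait (exact truth)."""
    out = pd.DataFrame(index=meta.index)
    aod_c = meta["aod"].to_numpy(dtype=float) - meta["aod"].mean()
    trait_sds = dict(zip(traits.index, traits["sd"]))
    trait_sds["feed_intake"] = 4.57  # derived energy-intake trait, own effects
    for trait, sd in trait_sds.items():
        effects = DEFAULT_FIXED.get(trait, ())
        contrib = np.zeros(len(meta))
        for col, scale in (("cg", config.cg_scale),):
            levels = meta[col].unique()
            values = dict(zip(levels, rng.normal(0.0, scale * sd, len(levels))))
            contrib += meta[col].map(values).to_numpy()
        if "cohort_pen" in effects:
            levels = meta["cohort_pen"].unique()
            values = dict(zip(levels, rng.normal(0.0, config.pen_scale * sd, len(levels))))
            contrib += meta["cohort_pen"].map(values).to_numpy()
        if "brr" in effects:
            values = dict(zip([1, 2, 3], rng.normal(0.0, config.brr_scale * sd, 3)))
            contrib += meta["brr"].map(values).to_numpy()
        if "aod" in effects:
            contrib += rng.normal(0.0, config.aod_scale * sd) * aod_c
        if "aod2" in effects:
            contrib += rng.normal(0.0, config.aod_scale * sd / 2.0) * (aod_c**2 - aod_c.var())
        if "bdev" in effects:
            contrib += rng.normal(0.0, config.bdev_scale * sd) * meta["bdev"].to_numpy()
        out[trait] = contrib
    return out


def simulate_truth(config: SimulationConfig, rng: np.random.Generator):
    """Pedigree, breeding values and exact phenotype components."""
    traits = default_trait_table()
    covs = build_covariances(
        traits, config.genetic_correlations, config.phenotypic_correlations
    )
    records, meta = simulate_pedigree(config, rng)
    bv, mbv = simulate_breeding_values(
        records, covs["G"].to_numpy(), covs["M"].to_numpy(), rng
    )
    pos = {r.animal_id: i for i, r in enumerate(records)}
    a_idx = meta["animal"].map(pos).to_numpy()
    d_idx = meta["dam"].map(pos).to_numpy()
    names = traits.index.tolist()
    fixed = _fixed_effect_contributions(meta, traits, config, rng)

    n = len(meta)
    E = covs["E"].to_numpy()
    PE = covs["PE"].to_numpy()
    Le = np.linalg.cholesky(E + 1e-12 * np.eye(len(names)))
    resid1 = rng.standard_normal((n, len(names))) @ Le.T
    resid2 = rng.standard_normal((n, len(names))) @ Le.T  # second chamber round
    pe = rng.standard_normal((n, len(names))) * np.sqrt(np.diag(PE))

    cols: dict[str, np.ndarray] = {}
    for k, t in enumerate(names):
        mu = traits.loc[t, "mean"]
        base = mu + fixed[t].to_numpy() + bv[a_idx, k] + mbv[d_idx, k] + pe[:, k]
        cols[f"{t}_mu"] = np.full(n, mu)
        cols[f"{t}_fixed"] = fixed[t].to_numpy()
        cols[f"{t}_bv"] = bv[a_idx, k]
        cols[f"{t}_mat"] = mbv[d_idx, k]
        cols[f"{t}_pe"] = pe[:, k]
        cols[f"{t}_resid"] = resid1[:, k]
        cols[t] = base + resid1[:, k]
        if t in REPEATED_TRAITS:
            cols[f"{t}_resid_r2"] = resid2[:, k]
            cols[f"{t}_r2"] = base + resid2[:, k]

    # guard physical positivity of scale traits
    for t in ("mmwt", "adg", "events_per_day", "feeding_rate", "ch4", "co2"):
        floor = 0.05 * traits.loc[t, "sd"] + 1e-6
        cols[t] = np.clip(cols[t], floor, None)
        if t in REPEATED_TRAITS:
            cols[f"{t}_r2"] = np.clip(cols[f"{t}_r2"], floor, None)

    # energy intake from the RFI model: EI = b0 + b1*MMWT + b2*ADG + F + C +
    # P + rfi; flock/cohort/pen enter through the feed-intake fixed pieces
    b0, b1, b2 = config.rfi_coefs
    cols["feed_intake_fixed"] = fixed["feed_intake"].to_numpy()
    cols["energy_intake"] = (
        b0 + b1 * cols["mmwt"] + b2 * cols["adg"] + cols["feed_intake_fixed"] + cols["rfi"]
    )
    truth = pd.concat([meta, pd.DataFrame(cols, index=meta.index)], axis=1)
    return records, truth, traits, covs


def _growth_params(truth: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Latent day-0 weight and daily gain from MMWT and ADG phenotypes."""
    w21 = truth["mmwt"].to_numpy() ** (4.0 / 3.0)
    adg = truth["adg"].to_numpy()
    return w21 - 21.0 * adg, adg


def simulate_phenotype_streams(
    records, truth, traits, covs, config: SimulationConfig, rng: np.random.Generator
) -> SyntheticCohort:
    """Raw measurement streams whose analysis recovers the latent truth."""
    n = len(truth)
    animals = truth["animal"].to_numpy()
    w0, adg = _growth_params(truth)

    # --- liveweights on the twice-weekly grid
    weigh_days = np.array([0, 3, 7, 10, 14, 17, 21, 24, 28, 31, 35, 38, 42])
    lw_rows = []
    for i in range(n):
        w = w0[i] + adg[i] * weigh_days
        if config.weighing_noise_frac is not None:
            noise = rng.normal(0.0, config.weighing_noise_frac * w)
        elif config.weighing_noise_sd > 0:
            noise = rng.normal(0.0, config.weighing_noise_sd, len(weigh_days))
        else:
            noise = np.zeros(len(weigh_days))
        for d, kg in zip(weigh_days, w + noise):
            lw_rows.append({"animal": animals[i], "day": int(d), "kg": kg})
    liveweights = pd.DataFrame(lw_rows)

    # --- feeder events: daily grams sum exactly to the day's latent intake
    year = truth["birth_year"].to_numpy()
    dm = np.array([FEED_BY_YEAR[y][0] for y in year])
    me = np.array([FEED_BY_YEAR[y][1] for y in year])
    grams_day_mean = truth["energy_intake"].to_numpy() / (dm * me) * 1000.0
    start = datetime.datetime(2016, 6, 1)
    fs = config.feeder
    ev_rows = []
    for i in range(n):
        lam = max(truth["events_per_day"].iloc[i], 1.0)
        rate = max(truth["feeding_rate"].iloc[i], 0.05)
        day_factor = (
            1.0 + fs.day_cv * rng.standard_normal(42) if fs.day_cv > 0 else np.ones(42)
        )
        day_factor = np.clip(day_factor, 0.2, None)
        day_factor *= 42.0 / day_factor.sum()  # mean over 42 days stays exact
        for d in range(42):
            grams = grams_day_mean[i] * day_factor[d]
            n_ev = max(int(rng.poisson(lam)), 1)
            weights = rng.gamma(fs.gamma_shape, 1.0, n_ev)
            weights /= weights.sum()
            starts = np.sort(rng.uniform(0, 20 * 3600, n_ev))
            for e in range(n_ev):
                g = grams * weights[e]
                dur = g / rate * (1.0 + fs.duration_noise_frac * rng.standard_normal())
                dur = float(np.clip(dur, 5.0, 3500.0))
                t0 = start + datetime.timedelta(days=d, seconds=float(starts[e]))
                ev_rows.append(
                    {
                        "animal": animals[i],
                        "feeder": int(rng.integers(1, 5)),
                        "entry": t0.isoformat(),
                        "exit": (t0 + datetime.timedelta(seconds=dur)).isoformat(),
                        "grams": g,
                    }
                )
    feeder_events = pd.DataFrame(ev_rows)

    # --- PAC rounds: linear concentration rise implied by the latent
    # emission times a shared lot nuisance factor
    pac_spec = config.pac
    pac_rows = []
    bw_rows = []
    gas_cols = {"ch4": ("ch4", 16.04), "co2": ("co2", 44.01)}
    for rnd, day in ((1, pac_spec.round_days[0]), (2, pac_spec.round_days[1])):
        for cohort, grp in truth.groupby("cohort"):
            idx = grp.index.to_numpy()
            perm = rng.permutation(len(idx))
            for lot_no, chunk in enumerate(
                np.array_split(perm, max(1, int(np.ceil(len(idx) / pac_spec.lot_size))))
            ):
                lot_id = f"{cohort}-r{rnd}-{lot_no:02d}"
                lot_factor = float(
                    np.exp(rng.normal(-0.5 * pac_spec.lot_sd**2, pac_spec.lot_sd))
                ) if pac_spec.lot_sd > 0 else 1.0
                temp = pac_spec.temp_k + (rng.normal(0, 3) if pac_spec.lot_sd > 0 else 0.0)
                pres = pac_spec.pressure_kpa + (
                    rng.normal(0, 1.5) if pac_spec.lot_sd > 0 else 0.0
                )
                t_mid = 30.0 + (rng.uniform(-3, 3) if pac_spec.conc_noise_frac > 0 else 0.0)
                t_end = 60.0 + (rng.uniform(-3, 3) if pac_spec.conc_noise_frac > 0 else 0.0)
                minutes = np.array([0.0, t_mid, t_end])
                for pos, j in enumerate(chunk):
                    row = truth.iloc[idx[j]]
                    bw = w0[idx[j]] + adg[idx[j]] * day
                    free_vol = pac_spec.chamber_volume_l - bw * pac_spec.animal_volume_per_kg_l
                    mol_air = pres * free_vol / (8.31446 * temp)
                    bw_rows.append({"animal": row["animal"], "round": rnd, "kg": bw})
                    for gas, (col, mmass) in gas_cols.items():
                        g_day = (row[col] if rnd == 1 else row[f"{col}_r2"]) * lot_factor
                        slope_ppm = g_day / 1440.0 / mmass / mol_air * 1e6
                        ambient = getattr(pac_spec, f"{gas}_ambient_ppm")
                        conc = ambient + slope_ppm * minutes
                        if pac_spec.conc_noise_frac > 0:
                            conc = conc * (
                                1.0 + pac_spec.conc_noise_frac * rng.standard_normal(3)
                            )
                        for t, c in zip(minutes, conc):
                            pac_rows.append(
                                {
                                    "animal": row["animal"],
                                    "round": rnd,
                                    "lot": lot_id,
                                    "chamber": pos + 1,
                                    "gas": gas,
                                    "minutes": t,
                                    "concentration_ppm": c,
                                    "temp_K": temp,
                                    "pressure_kPa": pres,
                                }
                            )
                    # O2 declines roughly in molar step with the CO2 produced
                    o2_slope = -pac_rows[-1]["concentration_ppm"] / max(t_end, 1.0) * 0.9
                    for t in minutes:
                        pac_rows.append(
                            {
                                "animal": row["animal"],
                                "round": rnd,
                                "lot": lot_id,
                                "chamber": pos + 1,
                                "gas": "o2",
                                "minutes": t,
                                "concentration_ppm": pac_spec.o2_ambient_ppm + o2_slope * t,
                                "temp_K": temp,
                                "pressure_kPa": pres,
                            }
                        )
    pac = pd.DataFrame(pac_rows)
    pac_bw = pd.DataFrame(bw_rows)

    # --- CT stacks
    ct = config.ct
    seg_centers = ct.hu_centers
    from .ct import SegmentationConfig

    seg_cfg = SegmentationConfig()
    stack_rows = []
    rasters: dict = {}
    for i in range(n):
        n_slices = int(rng.integers(ct.n_slices[0], ct.n_slices[1] + 1))
        n_car = int(round(ct.carcass_fraction * n_slices))
        n_vis = n_slices - n_car
        regions = {
            "carcass": (0, n_car),
            "viscera": (n_car, n_slices),
        }
        depot_region = {
            "subcutaneous_fat": ("carcass", "fat", "subcutaneous"),
            "intermuscular_fat": ("carcass", "fat", "intermuscular"),
            "carcass_lean": ("carcass", "lean", None),
            "total_bone": ("carcass", "bone", None),
            "visceral_fat": ("viscera", "fat", None),
            "nonfat_visceral": ("viscera", "lean", None),
        }
        for depot, (region, tissue, subdepot) in depot_region.items():
            lo, hi = regions[region]
            n_reg = hi - lo
            if n_reg <= 0:
                continue
            mass = max(float(truth[depot].iloc[i]), 0.05)
            hu_c = seg_centers[tissue]
            dens = seg_cfg.density(hu_c)
            vol_mm3 = mass / dens * 1e6
            L = n_reg * ct.spacing_mm
            z = (np.arange(n_reg) + 0.5) * ct.spacing_mm  # midpoint sampling
            areas = 6.0 * vol_mm3 / L**3 * z * (L - z)
            for k in range(n_reg):
                stack_rows.append(
                    {
                        "animal": animals[i],
                        "slice": lo + k,
                        "compartment": region,
                        "tissue": tissue,
                        "subdepot": subdepot,
                        "area_mm2": areas[k],
                        "mean_hu": hu_c + rng.normal(0.0, ct.hu_sd / 10.0),
                    }
                )
        # rumen contents on the middle visceral slices, to be excluded
        for k in range(n_car + n_vis // 4, n_car + 3 * n_vis // 4):
            stack_rows.append(
                {
                    "animal": animals[i],
                    "slice": k,
                    "compartment": "viscera",
                    "tissue": "rumen_content",
                    "subdepot": None,
                    "area_mm2": ct.rumen_area_mm2,
                    "mean_hu": 30.0,
                }
            )
    ct_stacks = pd.DataFrame(stack_rows)

    # --- ultrasound C fat depth (before and after the test)
    us_rows = []
    for i in range(n):
        us_rows.append(
            {
                "animal": animals[i],
                "c_start_mm": truth["c_start"].iloc[i]
                + rng.normal(0.0, config.ultrasound_noise_sd),
                "c_final_mm": truth["c_final"].iloc[i]
                + rng.normal(0.0, config.ultrasound_noise_sd),
            }
        )
    ultrasound = pd.DataFrame(us_rows)

    covariate_cols = [
        "animal", "sire", "dam", "flock", "cohort", "pen", "cohort_pen",
        "birth_year", "cg", "brr", "aod", "bdev",
    ]
    return SyntheticCohort(
        config=config,
        pedigree=records,
        animals=truth[covariate_cols].copy(),
        truth=truth,
        trait_table=traits,
        covariances=covs,
        feeder_events=feeder_events,
        liveweights=liveweights,
        pac=pac,
        pac_body_weight=pac_bw,
        ct_stacks=ct_stacks,
        ct_rasters={},
        ultrasound=ultrasound,
    )


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """One-stop generation of a full synthetic study dataset."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    records, truth, traits, covs = simulate_truth(config, rng)
    return simulate_phenotype_streams(records, truth, traits, covs, config, rng)


def raster_stack_for_animal(
    cohort: SyntheticCohort, animal: str, rng: np.random.Generator
) -> list[dict]:
    """Raster-fidelity CT stack for one animal (exercises segmentation).

    Pixels for each tissue are drawn inside its HU band (values ~ N(band
    centre, hu_sd), clipped to the band); carcass fat pixels carry a
    subcutaneous mask so segmentation can split the two carcass depots.
    """
    from .ct import SegmentationConfig

    ct = cohort.config.ct
    seg = SegmentationConfig()
    bands = {"fat": seg.hu_fat, "lean": seg.hu_lean, "bone": seg.hu_bone}
    pixel_area = (ct.fov_mm / ct.raster_size) ** 2
    table = cohort.ct_stacks[cohort.ct_stacks["animal"] == animal]
    slices = []
    for slice_no, grp in table.groupby("slice"):
        compartment = grp["compartment"].iloc[0]
        size = ct.raster_size
        raster = np.zeros((size, size))
        sub_mask = np.zeros((size, size), dtype=bool)
        rumen_mask = np.zeros((size, size), dtype=bool)
        cursor = 0
        flat = raster.reshape(-1)
        sub_flat = sub_mask.reshape(-1)
        rumen_flat = rumen_mask.reshape(-1)
        for row in grp.itertuples(index=False):
            n_pix = int(round(row.area_mm2 / pixel_area))
            if cursor + n_pix > flat.size:
                n_pix = flat.size - cursor
            if row.tissue == "rumen_content":
                # give rumen contents lean-band values; the mask excludes them
                lo, hi = bands["lean"]
                rumen_flat[cursor : cursor + n_pix] = True
            else:
                lo, hi = bands[row.tissue]
            centre = ct.hu_centers.get(row.tissue, 0.5 * (lo + hi))
            flat[cursor : cursor + n_pix] = np.clip(
                rng.normal(centre, ct.hu_sd, n_pix), lo, hi
            )
            if row.tissue == "fat" and row.subdepot == "subcutaneous":
                sub_flat[cursor : cursor + n_pix] = True
            cursor += n_pix
        slices.append(
            {
                "raster": raster,
                "compartment": compartment,
                "pixel_area_mm2": pixel_area,
                "subcutaneous_mask": sub_mask,
                "rumen_mask": rumen_mask,
            }
        )
    return slices


# ---------------------------------------------------------------------------
# small designs for REML validation


def half_sib_pedigree(n_sires: int, progeny_per_sire: int) -> list[PedigreeRecord]:
    """Balanced paternal half-sib families; dams unknown and unrelated."""
    records = [PedigreeRecord(f"S{i:04d}", None, None) for i in range(n_sires)]
    for i in range(n_sires):
        for j in range(progeny_per_sire):
            records.append(PedigreeRecord(f"P{i:04d}_{j:03d}", f"S{i:04d}", None))
    return records


def nested_maternal_pedigree(
    n_sires: int, dams_per_sire: int, progeny_per_dam: int
) -> list[PedigreeRecord]:
    """Dams nested in sires with multiple progeny each (maternal effects)."""
    records = [PedigreeRecord(f"S{i:04d}", None, None) for i in range(n_sires)]
    for i in range(n_sires):
        for k in range(dams_per_sire):
            dam = f"D{i:04d}_{k:02d}"
            records.append(PedigreeRecord(dam, None, None))
            for j in range(progeny_per_dam):
                records.append(PedigreeRecord(f"P{i:04d}_{k:02d}_{j:02d}", f"S{i:04d}", dam))
    return records


def simulate_trait_values(
    pedigree: list[PedigreeRecord],
    G: np.ndarray,
    E: np.ndarray,
    M: np.ndarray | None = None,
    mu: float | np.ndarray = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Direct phenotypes y = mu + a (+ m_dam) + e for REML validation.

    Only animals with a recorded sire or dam (the progeny generation) get
    phenotypes; founders serve as parents. Returns one row per phenotyped
    animal with the trait values and their true components.
    """
    if rng is None:
        rng = np.random.default_rng()
    G = np.atleast_2d(np.asarray(G, dtype=float))
    E = np.atleast_2d(np.asarray(E, dtype=float))
    t = G.shape[0]
    bv, mbv = simulate_breeding_values(pedigree, G, M, rng)
    pos = {r.animal_id: i for i, r in enumerate(pedigree)}
    rows = []
    Le = np.linalg.cholesky(E + 1e-12 * np.eye(t))
    for rec in pedigree:
        if rec.sire_id is None and rec.dam_id is None:
            continue
        i = pos[rec.animal_id]
        e = Le @ rng.standard_normal(t)
        y = np.atleast_1d(np.asarray(mu, dtype=float) * np.ones(t)) + bv[i] + e
        row = {"animal": rec.animal_id, "sire": rec.sire_id, "dam": rec.dam_id}
        if mbv is not None and rec.dam_id is not None:
            y = y + mbv[pos[rec.dam_id]]
            for k in range(t):
                row[f"mat{k + 1}"] = mbv[pos[rec.dam_id]][k]
        for k in range(t):
            row[f"y{k + 1}"] = y[k]
            row[f"bv{k + 1}"] = bv[i][k]
        rows.append(row)
    return pd.DataFrame(rows)
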