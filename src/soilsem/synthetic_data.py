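"""Synthetic soil-profile and manifest data with known ground truth.

The generator emulates the high-Andean grazing study design: 9 soil pits
(3 per land-use class — managed pasture MP, pristine grassland PG, pristine
forest PF), sampled in depth increments of 0-5, 5-10, 10-20, 20-30 and
30-40 cm, truncated where a pit hits bedrock, for a default total of
n = 39 increment observations.

Two generation routes are provided:

* the *direct* route (:func:`draw_latents` + :func:`emit_manifests`)
  produces manifest variables with exactly the statistical structure the
  structural equation model assumes — correlated exogenous latents,
  recursive structural equations, pit intercepts, Gaussian measurement
  error — so parameter recovery can be checked against known coefficients;
* the *profile* route (:func:`emit_profile_table`) back-transforms to a
  measurement-scale depth-increment table (bulk density, cations, isotope
  values, ...) calibrated to the published group-level values, so the
  indicator arithmetic can be exercised on realistic input.

All generators are pure functions of (design, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidDesignError
from .tables import (
    ANCHORS,
    EXOGENOUS,
    LAND_USES,
    LATENTS,
    MANIFEST_LATENTS,
    MANIFEST_NAMES,
    ManifestTable,
    validate_profile_table,
)

log = logging.getLogger("soilsem.synthetic_data")


def _clip(name: str, values, lo=None, hi=None):
    """Clip generated physical values into their invariant range, never
    silently: any binding clip is reported in the log."""
    arr = np.asarray(values, dtype=float)
    out = np.clip(arr, lo, hi)
    n_bound = int(np.sum(out != arr))
    if n_bound:
        log.info("clipped %d generated value(s) of %s into [%s, %s]",
                 n_bound, name, lo, hi)
    return out


DEFAULT_DEPTH_SCHEME: tuple[tuple[float, float], ...] = (
    (0.0, 5.0),
    (5.0, 10.0),
    (10.0, 20.0),
    (20.0, 30.0),
    (30.0, 40.0),
)

#: Per-pit bedrock depth (cm) for the default n = 39 preset.  The study
#: reports only the total increment count; six pits reach the full 40 cm
#: and the third pit of each land-use class hits bedrock at 20 cm, which
#: reproduces 6 x 5 + 3 x 3 = 39 observations.
DEFAULT_MAX_DEPTHS: dict[str, float] = {
    "MP1": 40.0, "MP2": 40.0, "MP3": 20.0,
    "PG1": 40.0, "PG2": 40.0, "PG3": 20.0,
    "PF1": 40.0, "PF2": 40.0, "PF3": 20.0,
}

#: Default structural path coefficients: the published posterior medians of
#: the four reported effects, used as generating ground truth for recovery
#: experiments.
DEFAULT_TRUE_PATHS: dict[tuple[str, str], float] = {
    ("acidification", "fertility"): -0.75,
    ("fertility", "microorganisms"): 0.71,
    ("weathering", "soc"): 0.69,
    ("acidification", "soc"): 0.44,
}


def _default_loadings() -> dict[str, float]:
    # anchors load at +1 (scale identification), other indicators at 0.8
    return {m: 1.0 if ANCHORS[l] == m else 0.8 for m, l in MANIFEST_LATENTS.items()}


def _default_error_sds() -> dict[str, float]:
    return {m: 0.5 for m in MANIFEST_NAMES}


def _default_shifts() -> dict[tuple[str, str], float]:
    # land use enters as mean shifts of the exogenous latents: pastoralism
    # accelerates weathering and acidification relative to pristine sites
    return {
        ("MP", "weathering"): 0.8,
        ("PG", "weathering"): -0.4,
        ("PF", "weathering"): -0.4,
        ("MP", "acidification"): 0.6,
        ("PG", "acidification"): -0.3,
        ("PF", "acidification"): -0.3,
    }


@dataclass(frozen=True)
class StudyDesign:
    """Enumeration of (pit, depth increment) rows.

    ``pits`` holds (pit_id, land_use, max_depth_cm) triples;
    ``depth_scheme`` the ordered increments.  ``rows`` enumerates one entry
    per retained (pit, increment) pair, increments beyond a pit's bedrock
    depth dropped.
    """

    pits: tuple[tuple[str, str, float], ...]
    depth_scheme: tuple[tuple[float, float], ...]

    @property
    def rows(self) -> tuple[tuple[str, str, float, float], ...]:
        out = []
        for pit_id, land_use, max_depth in self.pits:
            for top, bottom in self.depth_scheme:
                if bottom <= max_depth:
                    out.append((pit_id, land_use, top, bottom))
        return tuple(out)

    @property
    def n_obs(self) -> int:
        return len(self.rows)

    @property
    def pit_ids(self) -> tuple[str, ...]:
        return tuple(p for p, _, _ in self.pits)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["pit_id", "land_use", "depth_top", "depth_bottom"]
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of the generating model.

    Exogenous latents (weathering, acidification) have unit variance and
    correlation ``exo_correlation``; land use enters as latent mean shifts.
    Endogenous latents follow the structural equations with Gaussian noise
    of sd ``structural_sds``.  Manifests are pit intercept + loading x
    latent + Gaussian error.
    """

    true_paths: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PATHS)
    )
    true_loadings: dict[str, float] = field(default_factory=_default_loadings)
    exo_correlation: float = 0.5
    pit_intercept_sd: float = 0.3
    error_sds: dict[str, float] = field(default_factory=_default_error_sds)
    structural_sds: dict[str, float] = field(
        default_factory=lambda: {"fertility": 0.5, "microorganisms": 0.5, "soc": 0.5}
    )
    landuse_latent_shifts: dict[tuple[str, str], float] = field(
        default_factory=_default_shifts
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.exo_correlation < 1.0:
            raise ConfigurationError("exo_correlation must lie in (-1, 1)")
        if self.pit_intercept_sd < 0:
            raise ConfigurationError("pit_intercept_sd must be >= 0")
        for m, s in self.error_sds.items():
            if s <= 0:
                raise ConfigurationError(f"error sd for {m!r} must be positive")
        for m in self.true_loadings:
            if m not in MANIFEST_LATENTS:
                raise ConfigurationError(f"unknown manifest in loadings: {m!r}")
        for src, dst in self.true_paths:
            if src not in LATENTS or dst not in LATENTS:
                raise ConfigurationError(f"unknown latent in path {src}->{dst}")
            if dst in EXOGENOUS:
                raise ConfigurationError(f"path into exogenous latent {dst!r}")


def build_design(
    pits_per_use: int = 3,
    depth_scheme: tuple[tuple[float, float], ...] = DEFAULT_DEPTH_SCHEME,
    max_depths: dict[str, float] | None = None,
) -> StudyDesign:
    """Enumerate the study design.

    Parameters
    ----------
    pits_per_use
        Number of replicate pits per land-use class.
    depth_scheme
        Ordered (top, bottom) increments in cm; must be strictly increasing
        and contiguous from the surface.
    max_depths
        pit_id -> bedrock depth in cm; increments whose bottom exceeds it
        are dropped.  Defaults to the n = 39 preset when the default design
        is requested, otherwise to the deepest increment.
    """
    if pits_per_use < 1:
        raise InvalidDesignError("pits_per_use must be >= 1")
    prev = None
    for top, bottom in depth_scheme:
        if bottom <= top or (prev is not None and top < prev):
            raise InvalidDesignError("depth_scheme must be strictly increasing")
        prev = bottom
    full_depth = depth_scheme[-1][1]
    pit_ids = [f"{lu}{k}" for lu in LAND_USES for k in range(1, pits_per_use + 1)]
    if max_depths is None:
        if pits_per_use == 3 and tuple(depth_scheme) == DEFAULT_DEPTH_SCHEME:
            max_depths = dict(DEFAULT_MAX_DEPTHS)
        else:
            max_depths = {p: full_depth for p in pit_ids}
    pits = tuple(
        (p, p[:2], float(max_depths.get(p, full_depth))) for p in pit_ids
    )
    return StudyDesign(pits=pits, depth_scheme=tuple(depth_scheme))


def default_design() -> StudyDesign:
    """The n = 39 recovery preset: 9 pits, 3 truncated at 20 cm."""
    return build_design()


def _topological_order(
    paths: dict[tuple[str, str], float]
) -> list[str]:
    """Topological order of the endogenous latents; raises on cycles."""
    endo = [l for l in LATENTS if l not in EXOGENOUS]
    parents = {l: [s for (s, d) in paths if d == l] for l in endo}
    order: list[str] = []
    placed = set(EXOGENOUS)
    remaining = list(endo)
    while remaining:
        progressed = False
        for l in list(remaining):
            if all(p in placed for p in parents[l]):
                order.append(l)
                placed.add(l)
                remaining.remove(l)
                progressed = True
        if not progressed:
            raise ConfigurationError(
                f"structural path set is cyclic among {remaining}"
            )
    return order


def draw_latents(
    design: StudyDesign, cfg: GeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw the n x 5 latent score table.

    Exogenous latents are bivariate normal with unit variances and
    correlation ``cfg.exo_correlation``, plus land-use mean shifts;
    endogenous latents are computed in topological order from the
    structural equations plus Gaussian noise.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    rows = design.frame()
    n = len(rows)
    phi = cfg.exo_correlation
    chol = np.linalg.cholesky(np.array([[1.0, phi], [phi, 1.0]]))
    xi = rng.standard_normal((n, 2)) @ chol.T
    scores = {EXOGENOUS[0]: xi[:, 0], EXOGENOUS[1]: xi[:, 1]}
    shifts = cfg.landuse_latent_shifts
    for k, lat in enumerate(EXOGENOUS):
        shift = rows["land_use"].map(
            lambda lu: shifts.get((lu, lat), 0.0)
        ).to_numpy(dtype=float)
        scores[lat] = scores[lat] + shift
    for lat in _topological_order(cfg.true_paths):
        mean = np.zeros(n)
        for (src, dst), coef in cfg.true_paths.items():
            if dst == lat:
                mean = mean + coef * scores[src]
        sd = cfg.structural_sds.get(lat, 0.5)
        shift = rows["land_use"].map(
            lambda lu: shifts.get((lu, lat), 0.0)
        ).to_numpy(dtype=float)
        scores[lat] = mean + sd * rng.standard_normal(n) + shift
    out = rows[["pit_id", "land_use"]].copy()
    for lat in LATENTS:
        out[lat] = scores[lat]
    return out


def emit_manifests(
    latents: pd.DataFrame, cfg: GeneratorConfig, seed: int | None = None
) -> ManifestTable:
    """Emit the manifest table from latent scores.

    Each manifest m assigned to latent l is generated as
    ``alpha[pit, m] + loading_m * score_l + error``, with pit intercepts
    drawn N(0, pit_intercept_sd^2) per (pit, manifest).
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    pits = list(dict.fromkeys(latents["pit_id"]))
    pit_index = latents["pit_id"].map({p: i for i, p in enumerate(pits)}).to_numpy()
    n = len(latents)
    p = len(MANIFEST_NAMES)
    alpha = rng.normal(0.0, cfg.pit_intercept_sd, size=(len(pits), p))
    data = {}
    for k, m in enumerate(MANIFEST_NAMES):
        lat = MANIFEST_LATENTS[m]
        lam = cfg.true_loadings.get(m, 1.0)
        eps = rng.normal(0.0, cfg.error_sds[m], size=n)
        data[m] = alpha[pit_index, k] + lam * latents[lat].to_numpy() + eps
    return ManifestTable(
        data=pd.DataFrame(data),
        pit_id=latents["pit_id"].to_numpy(),
        land_use=latents["land_use"].to_numpy(),
    )


def simulate_manifests(
    design: StudyDesign | None = None,
    cfg: GeneratorConfig | None = None,
    seed: int | None = None,
) -> ManifestTable:
    """Convenience: draw latents and emit manifests in one call."""
    design = design or default_design()
    cfg = cfg or GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    lat = draw_latents(design, cfg)
    return emit_manifests(lat, cfg)


# ---------------------------------------------------------------------------
# measurement-scale profile generation
# ---------------------------------------------------------------------------

#: Group-level calibration centres.  Stocks are whole-profile targets per
#: square metre; concentrations are fine-earth based.  Values are centred
#: on the published group means of the field study.
LANDUSE_CALIBRATION: dict[str, dict[str, float]] = {
    #                 MP      PG      PF
    "soc_stock":    {"MP": 21.6, "PG": 15.3, "PF": 16.1},   # kg C m-2
    "cec_stock":    {"MP": 140.0, "PG": 180.0, "PF": 296.0},  # mol_c m-2
    "t50":          {"MP": 344.0, "PG": 288.0, "PF": 297.0},  # deg C
    "qco2":         {"MP": 115.5, "PG": 21.3, "PF": 27.2},  # ug CO2-C mg-1 Cmic d-1
    "d15n":         {"MP": 6.13, "PG": 3.78, "PF": 2.71},   # permil
    "root_d13c":    {"MP": -25.83, "PG": -26.57, "PF": -27.44},  # permil
    "d13c_enrich":  {"MP": 1.2, "PG": 2.2, "PF": 2.3},      # permil, soil - root
    "maoc_share":   {"MP": 55.7, "PG": 26.9, "PF": 15.2},   # % of SOC
    "maoc_fraction": {"MP": 130.3, "PG": 88.1, "PF": 76.0},  # g C kg-1 fraction
    "cpyro_share":  {"MP": 52.6, "PG": 35.3, "PF": 26.6},   # % of SOC
    "cmic_share":   {"MP": 0.62, "PG": 1.97, "PF": 1.75},   # % of SOC
    "nmic_share":   {"MP": 1.0, "PG": 4.1, "PF": 4.3},      # % of total N
    "p_mic":        {"MP": 6.0, "PG": 22.0, "PF": 19.0},    # mg kg-1
    "silt_clay_stock": {"MP": 87.5, "PG": 50.3, "PF": 36.8},  # kg m-2
    "ph":           {"MP": 4.3, "PG": 4.5, "PF": 4.6},
    "al_sat":       {"MP": 0.60, "PG": 0.38, "PF": 0.30},   # fraction of CEC
    "al_o":         {"MP": 6.0, "PG": 3.5, "PF": 3.2},      # g kg-1
    "fe_o":         {"MP": 5.0, "PG": 4.5, "PF": 4.3},      # g kg-1
    "p_bray":       {"MP": 8.0, "PG": 8.5, "PF": 8.0},      # mg kg-1
}

#: depth-decay shapes (multiplier per increment index, surface first).
_SOC_SHAPE = np.array([1.9, 1.5, 1.0, 0.65, 0.45])
_CEC_SHAPE = np.array([1.2, 1.1, 1.0, 0.9, 0.85])
_FLAT = np.ones(5)

ROOT_D13C = LANDUSE_CALIBRATION["root_d13c"]


def emit_profile_table(
    design: StudyDesign | None = None,
    cfg: GeneratorConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a measurement-scale ProfileTable.

    Profile stocks and group contrasts are calibrated to the published
    group means (e.g. MP SOC stock near 21.6 kg m-2, MP T50 near 344 C,
    MP effective CEC near 140 mol_c m-2).  Pit-level latent scores from
    the same seed stream modulate the weathering-, acidification-,
    fertility-, microorganism- and persistence-linked quantities so the
    profile route carries a (deliberately attenuated) imprint of the
    latent structure.
    """
    design = design or default_design()
    cfg = cfg or GeneratorConfig()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    latents = draw_latents(design, cfg, seed=seed)
    pit_mean = latents.groupby("pit_id", sort=False)[list(LATENTS)].mean()

    cal = LANDUSE_CALIBRATION
    records: list[dict] = []
    for pit_id, land_use, max_depth in design.pits:
        incs = [(t, b) for t, b in design.depth_scheme if b <= max_depth]
        k = len(incs)
        idx = np.arange(k)
        lz = pit_mean.loc[pit_id]

        thickness = np.array([b - t for t, b in incs])
        bd = 0.80 + 0.12 * idx + rng.normal(0.0, 0.03, k)
        bd = _clip("bulk_density", bd, 0.3, None)
        stone = _clip("stone_vol_fraction",
                      0.05 + 0.07 * idx + rng.normal(0.0, 0.01, k), 0.0, 0.45)
        # fine-earth mass per increment, kg m-2
        mass = bd * thickness * (1.0 - stone) * 10.0

        def conc_from_stock(target_kg_m2, shape, jitter=0.05):
            # concentration profile (per kg fine earth) whose stock matches
            # the target up to multiplicative jitter
            s = shape[:k]
            base = target_kg_m2 * s / float(np.sum(s * mass))
            return base * np.exp(rng.normal(0.0, jitter, k))

        soc_stock = cal["soc_stock"][land_use] * float(np.exp(0.05 * lz["soc"]))
        soc = conc_from_stock(soc_stock, _SOC_SHAPE) * 1000.0  # g C kg-1
        n_total = soc / (12.0 + rng.normal(0.0, 0.3, k))

        cec_stock = cal["cec_stock"][land_use]  # mol_c m-2
        # cmol_c kg-1: mol_c m-2 -> cmol_c m-2 is x100
        cec = conc_from_stock(cec_stock * 100.0, _CEC_SHAPE, jitter=0.03)
        al_sat = _clip("al_sat",
            cal["al_sat"][land_use] * (1.0 + 0.05 * lz["acidification"])
            + rng.normal(0.0, 0.02, k),
            0.02, 0.9,
        )
        al_ex = al_sat * cec
        h_ex = 0.05 * cec
        fe_ex = 0.01 * cec
        mn_ex = 0.01 * cec
        base = np.clip(cec - al_ex - h_ex - fe_ex - mn_ex, 0.0, None)
        ca_ex, mg_ex, k_ex, na_ex = (
            0.55 * base, 0.25 * base, 0.12 * base, 0.08 * base
        )

        ph = _clip("ph",
            cal["ph"][land_use] - 0.04 * lz["acidification"]
            + 0.03 * idx + rng.normal(0.0, 0.05, k),
            3.5, 6.5,
        )

        al_total = 70.0 + rng.normal(0.0, 3.0, k)
        fe_total = 45.0 + rng.normal(0.0, 2.0, k)
        al_o = _clip("al_o",
            cal["al_o"][land_use] * np.exp(0.08 * lz["weathering"])
            * np.exp(rng.normal(0.0, 0.06, k)),
            0.1, 0.5 * al_total.min(),
        )
        fe_o = _clip("fe_o",
            cal["fe_o"][land_use] * np.exp(0.05 * lz["weathering"])
            * np.exp(rng.normal(0.0, 0.06, k)),
            0.1, 0.4 * fe_total.min(),
        )
        fe_d = _clip("fe_d", fe_o + 3.0 + rng.normal(0.0, 0.3, k),
                      None, 0.8 * fe_total)

        silt_stock = cal["silt_clay_stock"][land_use] * np.exp(
            0.05 * lz["weathering"]
        )
        silt_pct = _clip("silt_pct",
            100.0 * silt_stock / float(mass.sum())
            * np.exp(rng.normal(0.0, 0.05, k)),
            1.0, 80.0,
        )

        cpyro = soc * cal["cpyro_share"][land_use] / 100.0 * np.exp(
            0.05 * lz["soc"] + rng.normal(0.0, 0.05, k)
        )
        maoc_soil = soc * cal["maoc_share"][land_use] / 100.0 * np.exp(
            0.05 * lz["soc"] + rng.normal(0.0, 0.04, k)
        )
        maoc_fraction = cal["maoc_fraction"][land_use] * np.exp(
            0.05 * lz["soc"] + rng.normal(0.0, 0.05, k)
        )

        p_total = 1000.0 + rng.normal(0.0, 50.0, k)
        # MP: depleted near the surface, enriched at depth
        if land_use == "MP":
            pshape = np.array([0.6, 0.7, 1.0, 1.3, 1.5])[:k]
        else:
            pshape = np.array([1.3, 1.2, 1.0, 0.8, 0.7])[:k]
        p_bray = _clip("p_bray",
            cal["p_bray"][land_use] * pshape
            * np.exp(0.05 * lz["fertility"] + rng.normal(0.0, 0.08, k)),
            0.2, None,
        )

        d15n = (
            cal["d15n"][land_use] - 0.15 * lz["fertility"]
            + 0.15 * idx + rng.normal(0.0, 0.25, k)
        )
        d13c = (
            ROOT_D13C[land_use] + cal["d13c_enrich"][land_use]
            + 0.05 * idx + rng.normal(0.0, 0.08, k)
        )

        c_mic = _clip("c_mic",
            soc * 1000.0 * cal["cmic_share"][land_use] / 100.0
            * np.exp(0.08 * lz["microorganisms"] + rng.normal(0.0, 0.08, k)),
            1.0, None,
        )  # mg C kg-1
        n_mic = _clip("n_mic",
            n_total * 1000.0 * cal["nmic_share"][land_use] / 100.0
            * np.exp(0.08 * lz["microorganisms"] + rng.normal(0.0, 0.08, k)),
            0.2, None,
        )
        p_mic = _clip("p_mic",
            cal["p_mic"][land_use]
            * np.exp(0.08 * lz["microorganisms"] + rng.normal(0.0, 0.10, k)),
            0.2, None,
        )
        # basal respiration chosen to reproduce the group qCO2 scale
        qco2 = cal["qco2"][land_use] * np.exp(
            0.05 * lz["microorganisms"] + rng.normal(0.0, 0.06, k)
        )
        basal_resp = qco2 * c_mic / 1000.0  # mg CO2-C kg-1 day-1

        t50 = (
            cal["t50"][land_use] * (1.0 + 0.01 * lz["soc"])
            + rng.normal(0.0, 4.0, k)
        )

        for j, (top, bottom) in enumerate(incs):
            records.append({
                "pit_id": pit_id, "land_use": land_use,
                "depth_top": top, "depth_bottom": bottom,
                "bulk_density": bd[j], "stone_vol_fraction": stone[j],
                "soc": soc[j], "n_total": n_total[j], "ph": ph[j],
                "ca_ex": ca_ex[j], "mg_ex": mg_ex[j], "k_ex": k_ex[j],
                "na_ex": na_ex[j], "al_ex": al_ex[j], "fe_ex": fe_ex[j],
                "mn_ex": mn_ex[j], "h_ex": h_ex[j],
                "al_o": al_o[j], "fe_o": fe_o[j], "fe_d": fe_d[j],
                "al_total": al_total[j], "fe_total": fe_total[j],
                "c_pyro": cpyro[j], "maoc_soil": maoc_soil[j],
                "maoc_fraction": maoc_fraction[j], "silt_pct": silt_pct[j],
                "p_bray": p_bray[j], "p_total": p_total[j],
                "d13c": d13c[j], "d15n": d15n[j],
                "basal_resp": basal_resp[j], "c_mic": c_mic[j],
                "n_mic": n_mic[j], "p_mic": p_mic[j], "t50": t50[j],
            })
    df = pd.DataFrame.from_records(records)
    return validate_profile_table(df)
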