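"""Derived soil indicators and manifest-variable construction.

Implements the arithmetic that turns raw depth-increment measurements into
the quantities used for whole-profile statistics and for the latent
measurement model: areal element stocks of the fine earth, mass-weighted
mean concentrations, effective cation exchange capacity and Al saturation,
proton concentration, carbon-isotope enrichment, chloroform-fumigation
microbial biomass, the metabolic quotient qCO2, organic-matter conversion,
thermal stability (T50) from a cumulative combustion curve, density-
fraction carbon shares with recovery accounting, and the assembly of the
19 manifest variables with their latent assignments.

Unit conventions
----------------
Concentrations are per kg fine earth (g kg-1 or mg kg-1 as stated), bulk
density in g cm-3, depth in cm, stocks in kg m-2 (or mol_c m-2 for
charge), qCO2 in ug CO2-C per mg microbial C per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    IncompleteCombustionError,
    NegativeFlushError,
    SchemaError,
)
from .tables import (
    MANIFEST_LATENTS,
    MANIFEST_NAMES,
    PROFILE_COLUMNS,
    ManifestTable,
)

#: chloroform-fumigation-extraction conversion factors (extractable flush
#: to microbial biomass)
CFE_FACTORS = {"C": 0.45, "N": 0.4}

#: conventional organic-matter : organic-carbon mass ratio
VAN_BEMMELEN = 1.724


def fine_earth_mass(
    bulk_density: float, thickness_cm: float, stone_vol_fraction: float
) -> float:
    """Fine-earth mass per square metre (kg m-2) of one depth increment.

    ``bulk_density`` (g cm-3) refers to the fine earth after volumetric
    correction for water, coarse fragments and roots; the stone volume
    fraction removes the space occupied by coarse fragments.
    """
    bulk_density = np.asarray(bulk_density, dtype=float)
    thickness_cm = np.asarray(thickness_cm, dtype=float)
    stone = np.asarray(stone_vol_fraction, dtype=float)
    if np.any(bulk_density <= 0):
        raise DomainError("bulk_density must be positive")
    if np.any(thickness_cm <= 0):
        raise DomainError("thickness must be positive")
    if np.any((stone < 0) | (stone >= 1)):
        raise DomainError("stone_vol_fraction must lie in [0, 1)")
    # g cm-3 * cm = g cm-2; x10 -> kg m-2 (10^4 cm2 m-2 / 10^3 g kg-1)
    return bulk_density * thickness_cm * (1.0 - stone) * 10.0


def areal_stock(
    concentration: float,
    bulk_density: float,
    thickness_cm: float,
    stone_vol_fraction: float,
) -> float:
    """Areal element stock (kg m-2) of a depth increment.

    ``concentration`` is in g per kg fine earth; the stock is the element
    mass of fine earth per square metre.
    """
    mass = fine_earth_mass(bulk_density, thickness_cm, stone_vol_fraction)
    return np.asarray(concentration, dtype=float) / 1000.0 * mass


def mass_weighted_mean(values, fine_earth_masses) -> float:
    """Soil-mass-weighted mean concentration over depth increments."""
    v = np.asarray(values, dtype=float)
    m = np.asarray(fine_earth_masses, dtype=float)
    if v.shape != m.shape or v.size == 0:
        raise DomainError("values and masses must have equal, non-zero length")
    if np.any(m < 0):
        raise DomainError("masses must be non-negative")
    total = m.sum()
    if total <= 0:
        raise DomainError("total mass must be positive")
    return float(np.sum(v * m) / total)


def cec_effective(cations) -> float:
    """Effective CEC (cmol_c kg-1): sum of the quantified exchangeable
    cations (Ca, Mg, K, Na, Al, Fe, Mn, H)."""
    c = np.asarray(cations, dtype=float)
    if np.any(c < 0):
        raise DomainError("cation charges must be non-negative")
    return float(c.sum())


def al_saturation(al_ex: float, cec: float) -> float:
    """Share of exchangeable Al on effective CEC, in [0, 1]."""
    if cec <= 0:
        raise DomainError("CEC must be positive")
    if al_ex < 0 or al_ex > cec:
        raise DomainError("exchangeable Al must lie in [0, CEC]")
    return float(al_ex / cec)


def proton_concentration(ph) -> float:
    """H+ concentration 10^-pH (mol-scale activity)."""
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise DomainError("pH must be finite")
    out = np.power(10.0, -ph)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IsotopeEnrichment:
    """Carbon-isotope enrichment of soil relative to plant input.

    ``enrichment`` is the non-negative magnitude in permil; ``signed``
    keeps the raw soil-minus-plant difference (positive when the soil is
    isotopically heavier, i.e. more microbially processed).
    """

    enrichment: float
    signed: float


def delta13c_enrichment(plant_d13c: float, soil_d13c: float) -> IsotopeEnrichment:
    """Delta-delta13C between plant input and soil carbon (permil)."""
    if not (np.isfinite(plant_d13c) and np.isfinite(soil_d13c)):
        raise DomainError("delta13C values must be finite")
    signed = float(soil_d13c - plant_d13c)
    return IsotopeEnrichment(enrichment=abs(signed), signed=signed)


def microbial_biomass_cfe(
    fumigated: float, unfumigated: float, element: str
) -> float:
    """Microbial biomass (mg kg-1) from chloroform fumigation extraction.

    The extractable flush (fumigated minus unfumigated) is divided by the
    conversion factor 0.45 for C or 0.4 for N.
    """
    if element not in CFE_FACTORS:
        raise DomainError(f"element must be one of {sorted(CFE_FACTORS)}")
    if unfumigated < 0:
        raise DomainError("extract concentrations must be non-negative")
    if fumigated < unfumigated:
        raise NegativeFlushError(
            f"fumigated extract ({fumigated}) below unfumigated ({unfumigated})"
        )
    return float((fumigated - unfumigated) / CFE_FACTORS[element])


def metabolic_quotient(basal_respiration: float, c_mic: float) -> float:
    """qCO2: basal respiration standardized to microbial biomass carbon.

    ``basal_respiration`` in ug CO2-C per g soil per day, ``c_mic`` in mg
    microbial C per g soil; the quotient is in ug CO2-C per mg C_mic per
    day (the same numeric scale as mg CO2-C kg-1 C_mic day-1 / 1000).
    """
    c_mic = np.asarray(c_mic, dtype=float)
    if np.any(c_mic <= 0):
        raise DomainError("microbial biomass C must be positive")
    out = np.asarray(basal_respiration, dtype=float) / c_mic
    return float(out) if out.ndim == 0 else out


def organic_matter_from_c(c_content) -> float:
    """Organic matter (g kg-1) from organic C via the van Bemmelen
    factor 1.724."""
    c = np.asarray(c_content, dtype=float)
    if np.any(c < 0):
        raise DomainError("carbon content must be non-negative")
    out = VAN_BEMMELEN * c
    return float(out) if out.ndim == 0 else out


def t50_from_thermogram(temperatures, cumulative_co2_fraction) -> float:
    """Temperature (deg C) at which half of SOC has evolved as CO2.

    Linearly interpolates the first upward crossing of 0.5 on the
    cumulative evolved-CO2 curve of a ramped combustion run.
    """
    t = np.asarray(temperatures, dtype=float)
    f = np.asarray(cumulative_co2_fraction, dtype=float)
    if t.shape != f.shape or t.size < 2:
        raise DomainError("temperature and fraction arrays must align (n >= 2)")
    if np.any(np.diff(t) <= 0):
        raise DomainError("temperatures must be strictly ascending")
    if np.any(np.diff(f) < 0) or np.any(f < 0) or np.any(f > 1):
        raise DomainError("cumulative fraction must be non-decreasing in [0, 1]")
    if f[-1] < 0.5:
        raise IncompleteCombustionError("cumulative CO2 never reaches 50%")
    idx = int(np.argmax(f >= 0.5))
    if idx == 0:
        return float(t[0])
    t0, t1 = t[idx - 1], t[idx]
    f0, f1 = f[idx - 1], f[idx]
    if f1 == f0:  # flat segment ending at exactly 0.5
        return float(t1)
    return float(t0 + (0.5 - f0) / (f1 - f0) * (t1 - t0))


@dataclass(frozen=True)
class FractionShares:
    """Per-fraction carbon shares (% of SOC) and recovery (%)."""

    shares: np.ndarray
    recovery: float
    recovery_ok: bool


def fraction_shares(
    fraction_c, total_soc: float, recovery_band: tuple[float, float] = (85.0, 115.0)
) -> FractionShares:
    """Carbon share of each density/size fraction and total C recovery.

    Shares are 100 * fraction C / total SOC; recovery is the summed share.
    ``recovery_ok`` flags whether recovery falls inside ``recovery_band``
    (a quality band, default 85-115%).
    """
    fc = np.asarray(fraction_c, dtype=float)
    if total_soc <= 0:
        raise DomainError("total SOC must be positive")
    if np.any(fc < 0):
        raise DomainError("fraction C must be non-negative")
    shares = 100.0 * fc / total_soc
    recovery = float(shares.sum())
    lo, hi = recovery_band
    return FractionShares(shares=shares, recovery=recovery,
                          recovery_ok=bool(lo <= recovery <= hi))


# ---------------------------------------------------------------------------
# profile summaries and manifest assembly
# ---------------------------------------------------------------------------

#: concentration columns summarised per pit (stock + weighted mean)
_SUMMARY_VARS = (
    "soc", "n_total", "c_pyro", "maoc_soil", "al_o", "fe_o", "fe_d",
)


def profile_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Whole-profile summaries per pit.

    For each pit: fine-earth mass, areal stocks (kg m-2) of the carbon and
    oxide pools, effective-CEC stock (mol_c m-2), and soil-mass-weighted
    mean concentrations — the analysis unit of the whole-profile
    statistics (stocks summed, concentrations mass-weighted).
    """
    _require_columns(profiles, PROFILE_COLUMNS)
    rows = []
    for (pit, lu), g in profiles.groupby(["pit_id", "land_use"], sort=False):
        thick = g["depth_bottom"] - g["depth_top"]
        mass = fine_earth_mass(
            g["bulk_density"].to_numpy(), thick.to_numpy(),
            g["stone_vol_fraction"].to_numpy(),
        )
        rec: dict = {"pit_id": pit, "land_use": lu,
                     "fine_earth_mass": float(mass.sum())}
        for v in _SUMMARY_VARS:
            conc = g[v].to_numpy()
            rec[f"{v}_stock"] = float(np.sum(conc / 1000.0 * mass))
            rec[f"{v}_wmean"] = mass_weighted_mean(conc, mass)
        cec = g[["ca_ex", "mg_ex", "k_ex", "na_ex", "al_ex", "fe_ex",
                 "mn_ex", "h_ex"]].sum(axis=1).to_numpy()
        # cmol_c kg-1 x kg m-2 -> cmol_c m-2; /100 -> mol_c m-2
        rec["cec_stock"] = float(np.sum(cec * mass) / 100.0)
        rec["cec_wmean"] = mass_weighted_mean(cec, mass)
        for v in ("t50", "d15n", "d13c", "ph", "p_bray", "silt_pct"):
            rec[f"{v}_wmean"] = mass_weighted_mean(g[v].to_numpy(), mass)
        rows.append(rec)
    return pd.DataFrame(rows)


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")


def build_manifest_table(profiles: pd.DataFrame) -> ManifestTable:
    """Assemble the 19 manifest variables from a ProfileTable, row-wise.

    Ratios (oxide/total, N/P), the proton concentration 10^-pH, Al
    saturation, the summed base cations, and qCO2 are computed here;
    measured quantities (silt %, d15N, P_Bray, biomass pools, T50, C_pyro,
    MAOC) pass through on their measurement scale.
    """
    _require_columns(profiles, PROFILE_COLUMNS)
    df = profiles
    cec = df[["ca_ex", "mg_ex", "k_ex", "na_ex", "al_ex", "fe_ex",
              "mn_ex", "h_ex"]].sum(axis=1)
    if (cec <= 0).any():
        bad = list(df.index[cec <= 0])
        raise DomainError(f"zero effective CEC in row(s) {bad}")
    if (df["p_total"] <= 0).any():
        bad = list(df.index[df["p_total"] <= 0])
        raise DomainError(f"zero total P in row(s) {bad}")
    for col in ("al_total", "fe_total"):
        if (df[col] <= 0).any():
            bad = list(df.index[df[col] <= 0])
            raise DomainError(f"zero {col} in row(s) {bad}")
    data = pd.DataFrame({
        "alo_altot": df["al_o"] / df["al_total"],
        "feo_fetot": df["fe_o"] / df["fe_total"],
        "fed_fetot": df["fe_d"] / df["fe_total"],
        "silt_pct": df["silt_pct"],
        "h_conc": proton_concentration(df["ph"].to_numpy()),
        "al_sat": df["al_ex"] / cec,
        # N and P total both per kg soil: g kg-1 vs mg kg-1 -> x1000
        "n_to_p": df["n_total"] * 1000.0 / df["p_total"],
        "d15n": df["d15n"],
        "p_bray": df["p_bray"],
        "base_cations": df["ca_ex"] + df["k_ex"] + df["mg_ex"],
        "basal_resp": df["basal_resp"],
        # basal mg kg-1 d-1 == ug g-1 d-1; c_mic mg kg-1 -> mg g-1
        "qco2": metabolic_quotient(
            df["basal_resp"].to_numpy(), df["c_mic"].to_numpy() / 1000.0
        ),
        "c_mic": df["c_mic"],
        "n_mic": df["n_mic"],
        "p_mic": df["p_mic"],
        "t50": df["t50"],
        "c_pyro": df["c_pyro"],
        "maoc_soil": df["maoc_soil"],
        "maoc_fraction": df["maoc_fraction"],
    })
    assert tuple(data.columns) == MANIFEST_NAMES
    assert all(MANIFEST_LATENTS[c] for c in data.columns)
    return ManifestTable(
        data=data.reset_index(drop=True),
        pit_id=df["pit_id"].to_numpy(),
        land_use=df["land_use"].to_numpy(),
    )
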