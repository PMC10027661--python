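"""Shared table containers and column registries.

Two tables travel through the pipeline:

* ``ProfileTable`` — long-format depth-increment soil records, one row per
  (pit, depth increment), holding the raw physical and chemical
  measurements (bulk density, stone fraction, element concentrations,
  exchangeable cations, isotope values, microbial measurements, thermal
  stability).
* ``ManifestTable`` — the n x 19 matrix of manifest variables that load on
  the five latent constructs (weathering, acidification, fertility,
  microorganisms, SOC persistence), plus pit and land-use labels.

The latent assignment of each manifest is fixed here in ``MANIFEST_LATENTS``;
the first manifest listed for each latent acts as the anchor whose loading
is fixed to +1 for scale identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError

LAND_USES = ("MP", "PG", "PF")

LATENTS = ("weathering", "acidification", "fertility", "microorganisms", "soc")
EXOGENOUS = ("weathering", "acidification")

#: manifest name -> latent construct, in Table-order.  The first manifest of
#: each latent is its anchor.  ``base_cations`` is the summed exchangeable
#: Ca + K + Mg charge (cmol_c kg-1), one manifest.
MANIFEST_LATENTS: dict[str, str] = {
    # weathering: pedogenic oxide ratios and texture
    "alo_altot": "weathering",
    "feo_fetot": "weathering",
    "fed_fetot": "weathering",
    "silt_pct": "weathering",
    # acidification: proton activity and Al saturation
    "h_conc": "acidification",
    "al_sat": "acidification",
    # fertility: nutrient status
    "n_to_p": "fertility",
    "d15n": "fertility",
    "p_bray": "fertility",
    "base_cations": "fertility",
    # microorganisms: biomass and activity
    "basal_resp": "microorganisms",
    "qco2": "microorganisms",
    "c_mic": "microorganisms",
    "n_mic": "microorganisms",
    "p_mic": "microorganisms",
    # SOC persistence: thermal/chemical/physical stabilization proxies
    "t50": "soc",
    "c_pyro": "soc",
    "maoc_soil": "soc",
    "maoc_fraction": "soc",
}

MANIFEST_NAMES: tuple[str, ...] = tuple(MANIFEST_LATENTS)

#: anchor manifest per latent (first listed manifest).
ANCHORS: dict[str, str] = {}
for _m, _l in MANIFEST_LATENTS.items():
    ANCHORS.setdefault(_l, _m)

#: ProfileTable columns (after the two label columns); all numeric.
PROFILE_VALUE_COLUMNS: tuple[str, ...] = (
    "depth_top",            # cm
    "depth_bottom",         # cm
    "bulk_density",         # g cm-3, fine-earth corrected
    "stone_vol_fraction",   # [0, 1)
    "soc",                  # g C kg-1 soil
    "n_total",              # g N kg-1 soil
    "ph",                   # in 0.01 M CaCl2
    "ca_ex", "mg_ex", "k_ex", "na_ex",          # cmol_c kg-1
    "al_ex", "fe_ex", "mn_ex", "h_ex",          # cmol_c kg-1
    "al_o", "fe_o", "fe_d",                     # g kg-1, oxalate/dithionite
    "al_total", "fe_total",                     # g kg-1
    "c_pyro",               # g C kg-1 soil, pyrophosphate-extractable
    "maoc_soil",            # g C kg-1 soil in the < 63 um fraction
    "maoc_fraction",        # g C kg-1 fraction in the < 63 um fraction
    "silt_pct",             # % of fine earth
    "p_bray",               # mg P kg-1
    "p_total",              # mg P kg-1
    "d13c",                 # permil V-PDB (of the < 63 um fraction)
    "d15n",                 # permil air
    "basal_resp",           # mg CO2-C kg-1 soil day-1
    "c_mic", "n_mic", "p_mic",                  # mg kg-1 soil
    "t50",                  # deg C
)

PROFILE_COLUMNS: tuple[str, ...] = ("pit_id", "land_use") + PROFILE_VALUE_COLUMNS
MANIFEST_COLUMNS: tuple[str, ...] = ("pit_id", "land_use") + MANIFEST_NAMES


def validate_profile_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a ProfileTable DataFrame against its invariants."""
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ProfileTable missing column(s): {missing}")
    if df[list(PROFILE_VALUE_COLUMNS)].isna().any().any():
        bad = df[list(PROFILE_VALUE_COLUMNS)].isna().any()
        raise SchemaError(f"missing values in columns: {list(bad[bad].index)}")
    if not (df["depth_top"] < df["depth_bottom"]).all():
        raise SchemaError("depth_top must be < depth_bottom in every row")
    if not (df["bulk_density"] > 0).all():
        raise SchemaError("bulk_density must be positive")
    sv = df["stone_vol_fraction"]
    if not ((sv >= 0) & (sv < 1)).all():
        raise SchemaError("stone_vol_fraction must lie in [0, 1)")
    if not (df["al_o"] <= df["al_total"]).all():
        raise SchemaError("oxalate-extractable Al exceeds total Al")
    if not (df["fe_o"] <= df["fe_total"]).all():
        raise SchemaError("oxalate-extractable Fe exceeds total Fe")
    return df


@dataclass
class ManifestTable:
    """n x p manifest matrix with latent assignments and row labels.

    Parameters
    ----------
    data
        DataFrame with one column per manifest variable, n rows.
    pit_id, land_use
        Row labels, length n.
    latent_map
        manifest name -> latent name; defaults to the Table-1 pattern.
    """

    data: pd.DataFrame
    pit_id: np.ndarray
    land_use: np.ndarray
    latent_map: dict[str, str] = field(default_factory=lambda: dict(MANIFEST_LATENTS))

    def __post_init__(self) -> None:
        self.pit_id = np.asarray(self.pit_id)
        self.land_use = np.asarray(self.land_use)
        n = len(self.data)
        if len(self.pit_id) != n or len(self.land_use) != n:
            raise SchemaError("pit_id/land_use length must match data rows")
        for col in self.data.columns:
            if col not in self.latent_map:
                raise ConfigurationError(
                    f"manifest {col!r} is not assigned to any latent"
                )
            if self.latent_map[col] not in LATENTS:
                raise ConfigurationError(
                    f"manifest {col!r} assigned to unknown latent "
                    f"{self.latent_map[col]!r}"
                )

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def manifests(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame with label columns first (for on-disk text form)."""
        out = self.data.copy()
        out.insert(0, "land_use", self.land_use)
        out.insert(0, "pit_id", self.pit_id)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ManifestTable":
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"ManifestTable missing column(s): {missing}")
        return cls(
            data=df[list(MANIFEST_NAMES)].reset_index(drop=True),
            pit_id=df["pit_id"].to_numpy(),
            land_use=df["land_use"].to_numpy(),
        )
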