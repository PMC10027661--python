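# Table schemas

All tables are UTF-8 comma-separated text with one header line and
decimal points.  The authoritative registry lives in
`soilsem.tables`; `soilsem.cli_io.read_table(path, schema_name)`
validates files against it.

## ProfileTable (`schema_name="profile"`)

One row per (soil pit, depth increment).

| column | unit | meaning |
|---|---|---|
| pit_id | – | pit label (e.g. MP1, PG3) |
| land_use | – | MP / PG / PF |
| depth_top, depth_bottom | cm | increment bounds, top < bottom |
| bulk_density | g cm⁻³ | fine-earth bulk density, > 0 |
| stone_vol_fraction | – | coarse-fragment volume share, in [0, 1) |
| soc, n_total | g kg⁻¹ | organic C and total N of fine earth |
| ph | – | in 0.01 M CaCl₂ |
| ca_ex, mg_ex, k_ex, na_ex, al_ex, fe_ex, mn_ex, h_ex | cmol_c kg⁻¹ | exchangeable cations |
| al_o, fe_o | g kg⁻¹ | oxalate-extractable Al, Fe (≤ totals) |
| fe_d | g kg⁻¹ | dithionite-extractable Fe |
| al_total, fe_total | g kg⁻¹ | total element contents |
| c_pyro | g kg⁻¹ | pyrophosphate-extractable C |
| maoc_soil | g C kg⁻¹ soil | C in the < 63 µm fraction per soil |
| maoc_fraction | g C kg⁻¹ fraction | C concentration within the < 63 µm fraction |
| silt_pct | % | silt + clay share of fine earth |
| p_bray, p_total | mg kg⁻¹ | plant-available and total P |
| d13c | ‰ V-PDB | δ¹³C of the < 63 µm fraction |
| d15n | ‰ air | δ¹⁵N of bulk soil |
| basal_resp | mg CO₂-C kg⁻¹ day⁻¹ | basal respiration |
| c_mic, n_mic, p_mic | mg kg⁻¹ | microbial biomass pools |
| t50 | °C | temperature at 50% cumulative CO₂ evolution |

## ManifestTable (`schema_name="manifest"`)

`pit_id`, `land_use`, then the 19 manifest columns in latent order:

* weathering: `alo_altot`, `feo_fetot`, `fed_fetot`, `silt_pct`
* acidification: `h_conc` (10^−pH), `al_sat`
* fertility: `n_to_p`, `d15n`, `p_bray`, `base_cations` (Ca+K+Mg, cmol_c kg⁻¹)
* microorganisms: `basal_resp`, `qco2`, `c_mic`, `n_mic`, `p_mic`
* SOC persistence: `t50`, `c_pyro`, `maoc_soil`, `maoc_fraction`

The first manifest of each latent is the anchor whose loading is fixed
to +1.

## Posterior draws table

Flat `(chain, iteration, parameter, value)` rows; parameter names follow
`gamma[src->dst]`, `lambda[manifest]`, `tau_eps[manifest]`,
`tau_zeta[latent]`, `phi`, `sigma_alpha`.

## Convergence report

`(parameter, rhat, ess, degenerate, pass)` rows plus the overall verdict
in the run manifest.
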