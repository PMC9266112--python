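"""Compute UTCI for one day step by step, then classify a whole year.

Shows the full input chain: wind components -> scalar wind, dew point ->
vapour pressure, radiation -> absorbed short-wave flux, ground/air
temperature -> long-wave fluxes, all combined into the mean radiant
temperature and finally the UTCI polynomial with its stress category.
"""

from utciclim import (GeneratorConfig, StationMeta, classify,
                      generate_station_series, longwave_fluxes,
                      mean_radiant_temperature, noon_solar_elevation,
                      rp_from_global, utci, vapor_pressure_from_dewpoint,
                      wind_speed)
from utciclim.pipeline import daily_utci, prepare_station_frame
from utciclim.utci import DEFAULT_SCHEME, aggregate_category_days

# --- one summer day by hand -------------------------------------------
Ta, Td, Tg, Rg = 28.0, 18.0, 31.0, 280.0   # degC, degC, degC, W/m2
V = wind_speed(1.5, 2.0)
e = vapor_pressure_from_dewpoint(Td)
Rp = rp_from_global(Rg, noon_solar_elevation(40.0, 190))
Lg, La = longwave_fluxes(Tg, Ta, e)
Tmrt = mean_radiant_temperature(Rp, Lg, La)
day = utci(Ta, V, e, Tmrt)
print(f"V = {V:.2f} m/s, e = {e:.2f} hPa, Rp = {Rp:.1f} W/m2")
print(f"Lg = {Lg:.1f}, La = {La:.1f} W/m2 -> Tmrt = {Tmrt:.1f} degC")
print(f"UTCI = {day.utci:.1f} degC -> category {day.category} "
      f"({DEFAULT_SCHEME.label(day.category)})")

# --- a full synthetic year --------------------------------------------
meta = StationMeta("DEMO40N", latitude=40.0, longitude=116.0, altitude=50.0)
frame = prepare_station_frame(
    meta, generate_station_series(meta, GeneratorConfig(years=1, seed=1)))
days = daily_utci(frame)
counts = aggregate_category_days(days)
print("\nday counts per stress category (one year):")
print(counts.to_string())
# Category 5 (9..26 degC) is "no thermal stress"; at a temperate station
# it should hold the largest share of the year.
assert classify(20.0) == 5
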