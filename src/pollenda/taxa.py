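"""Per-taxon source-term parameters.

Each supported tree genus (alder, birch, olive) ships with a versioned
YAML file under :mod:`pollenda.data` holding every coefficient of the
heat-sum development model and the meteorology-modulated release model:
cut-off temperature, standard seasonal release N_tot and its uncertainty
band, humidity/precipitation/wind release thresholds, grain properties,
and the taxon's season-wide assimilation window.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

TAXA = ("alder", "birch", "olive")


@dataclass(frozen=True)
class TaxonParams:
    name: str
    heatsum_type: str                 # "hourly-mean-T" | "daily-mean-T"
    heatsum_uncertainty: float        # delta_H, fraction
    heat_accumulation_start: tuple[int, int]   # (month, day)
    cutoff_temperature_C: float
    n_total: float                    # grains m-2 yr-1
    n_total_uncertainty: float        # delta_N, fraction
    release_time_s: float             # tau
    humidity_low_pct: float
    humidity_high_pct: float
    precip_threshold_mm_h: float
    wind_saturation_m_s: float
    wind_max_scale: float
    injection_height_m: tuple[float, float]
    grain_diameter_um: float
    grain_density_kg_m3: float
    assimilation_window: tuple[tuple[int, int], tuple[int, int]]
    lat_cut_south_deg: float | None = None

    def __post_init__(self) -> None:
        if not self.humidity_low_pct < self.humidity_high_pct:
            raise ValueError("humidity_low_pct must be below humidity_high_pct")
        if self.precip_threshold_mm_h <= 0 or self.release_time_s <= 0:
            raise ValueError("precip threshold and release time must be positive")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 < self.heatsum_uncertainty < 1:
            raise ValueError("heatsum_uncertainty must be a fraction in (0, 1)")
        if self.assimilation_window[0] >= self.assimilation_window[1]:
            raise ValueError("assimilation window start must precede its end")

    @property
    def hourly(self) -> bool:
        return self.heatsum_type == "hourly-mean-T"

    @property
    def cutoff_temperature_K(self) -> float:
        return self.cutoff_temperature_C + 273.15

    def start_date(self, year: int) -> pd.Timestamp:
        m, d = self.heat_accumulation_start
        return pd.Timestamp(year=year, month=m, day=d)

    def window(self, year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
        (m0, d0), (m1, d1) = self.assimilation_window
        return (pd.Timestamp(year, m0, d0), pd.Timestamp(year, m1, d1))


def load_taxon(name: str) -> TaxonParams:
    """Load the shipped parameter set for one of alder/birch/olive."""
    if name not in TAXA:
        raise KeyError(f"unknown taxon {name!r}; shipped: {TAXA}")
    text = resources.files("pollenda.data").joinpath(f"{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    raw["heat_accumulation_start"] = tuple(raw["heat_accumulation_start"])
    raw["injection_height_m"] = tuple(raw["injection_height_m"])
    raw["assimilation_window"] = tuple(tuple(x) for x in raw["assimilation_window"])
    return TaxonParams(**raw)
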