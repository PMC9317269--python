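"""Provisioning-service valuation by the market price method.

The provisioning value of an integrated paddy system is the gross market
value of its primary products — rice, fish, ducks and duck eggs — summed
over the evaluated area:

    V1 = Σ_i  yield_i × price_i × A

where yields are per-hectare (kg for rice/fish, head or egg counts for
poultry products), prices are per kg or per individual, and A is the
evaluated area in hm².  The value is gross by construction: production
costs are deliberately not netted out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .units import Money


@dataclass(frozen=True, slots=True)
class SiteProfile:
    """Physical description of the evaluated system.

    area_hm2:            evaluated area (hm² = hectare).
    growing_period_days: rice growing period (d).
    hot_days:            number of hot summer days (d), drives the cooling value.
    standing_water_days: days of standing water during the growth period (d).

    ``standing_water_days`` may legitimately be shorter than the growing
    period and is not constrained against it.
    """

    area_hm2: float
    growing_period_days: float
    hot_days: float
    standing_water_days: float

    def __post_init__(self) -> None:
        for name in ("area_hm2", "growing_period_days", "hot_days", "standing_water_days"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"SiteProfile.{name} must be >= 0, got {v}")


@dataclass(frozen=True, slots=True)
class ProductSpec:
    """One marketed product: per-area yield and unit price.

    ``yield_per_hm2`` is kg/hm² for biomass products and individuals/hm²
    for counted products (ducks, eggs); ``unit_price_cny`` is CNY per kg or
    per individual accordingly.  Modelling counted and weighed products the
    same way keeps the provisioning value a single homogeneous sum.
    """

    name: str
    yield_per_hm2: float
    unit_price_cny: float

    def __post_init__(self) -> None:
        if self.yield_per_hm2 < 0:
            raise ValueError(f"{self.name}: yield must be >= 0, got {self.yield_per_hm2}")
        if self.unit_price_cny < 0:
            raise ValueError(f"{self.name}: price must be >= 0, got {self.unit_price_cny}")


def product_revenue(p: ProductSpec, site: SiteProfile, year: int = 2020) -> Money:
    """Gross market value of one product over the whole site."""
    return Money(p.yield_per_hm2 * p.unit_price_cny * site.area_hm2, year)


def provisioning_value(
    products: Sequence[ProductSpec], site: SiteProfile, year: int = 2020
) -> tuple[Money, float]:
    """Total provisioning value V1 and its per-area intensity.

    Returns ``(V1, per_area)`` where ``per_area`` is CNY/hm² and
    ``V1 = per_area × area`` exactly.  An empty product list is rejected:
    a provisioning valuation of nothing is a configuration mistake, not a
    zero value.
    """
    if not products:
        raise ValueError("provisioning valuation requires at least one product")
    per_area = sum(p.yield_per_hm2 * p.unit_price_cny for p in products)
    return Money(per_area * site.area_hm2, year), per_area
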