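"""Cultural-service valuation, aggregation and scenario comparison.

The cultural (landscape/tourism) value V10 is either the festival share of
regional tourism revenue, V10 = (Nrff / Ntour) × Rz, or a published
per-area landscape-tourism value times the site area.

`aggregate` folds the ten per-service values into a total with percentage
shares (negative components yield negative shares), and
`compare_scenarios` differences two valuations service by service.
Published comparison tables are not always explicit about whether an added
proportion is relative to the baseline or to the new system, so the
convention is a named argument and is carried into every report row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .provisioning import SiteProfile
from .units import Money, YearMismatchError, rescale_money

Convention = Literal["relative_to_baseline", "relative_to_new"]

#: CICES V5.1 section names used to tag each valued service.
CICES_PROVISIONING = "Provisioning"
CICES_REGULATION = "Regulation & Maintenance"
CICES_CULTURAL = "Cultural"


@dataclass(frozen=True, slots=True)
class CulturalParams:
    """Inputs for the cultural-service value, in one of two forms.

    Ratio form: ``festival_visitors`` / ``total_tourists`` × ``tourism_revenue_cny``
    — the festival's pro-rata share of yearly tourism revenue.
    Unit-value form: ``unit_value_cny_per_hm2`` — a published per-area
    landscape-tourism value, multiplied by the site area.
    """

    unit_value_cny_per_hm2: float | None = None
    festival_visitors: float | None = None
    total_tourists: float | None = None
    tourism_revenue_cny: float | None = None

    def __post_init__(self) -> None:
        ratio_form = (
            self.festival_visitors is not None
            and self.total_tourists is not None
            and self.tourism_revenue_cny is not None
        )
        if self.unit_value_cny_per_hm2 is None and not ratio_form:
            raise ValueError(
                "cultural value needs either unit_value_cny_per_hm2 or the full "
                "(festival_visitors, total_tourists, tourism_revenue_cny) triple"
            )
        if ratio_form:
            if self.festival_visitors < 0 or self.total_tourists < 0 or self.tourism_revenue_cny < 0:
                raise ValueError("cultural ratio-form inputs must be >= 0")
            if self.festival_visitors > self.total_tourists:
                raise ValueError("festival visitors cannot exceed total tourists")
        if self.unit_value_cny_per_hm2 is not None and self.unit_value_cny_per_hm2 < 0:
            raise ValueError("cultural unit value must be >= 0")


def cultural_value(c: CulturalParams, site: SiteProfile, year: int = 2020) -> Money:
    """Cultural-service value V10 from whichever input form is present.

    The unit-value form takes precedence when both are supplied.
    """
    if c.unit_value_cny_per_hm2 is not None:
        return Money(c.unit_value_cny_per_hm2 * site.area_hm2, year)
    if c.total_tourists == 0:
        raise ZeroDivisionError("cultural ratio form requires total_tourists > 0")
    return Money(c.festival_visitors / c.total_tourists * c.tourism_revenue_cny, year)


@dataclass(frozen=True, slots=True)
class ServiceComponent:
    """One valued service: its monetary result and CICES section tag."""

    value: Money
    cices_section: str


@dataclass(frozen=True)
class ServiceValuation:
    """Per-service values with CICES tags, their total and percentage shares."""

    components: dict[str, ServiceComponent]
    total: Money
    shares_pct: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def component_value(self, label: str) -> Money:
        return self.components[label].value

    def in_scale(self, scale: str) -> dict[str, float]:
        """Component values rescaled for reporting (e.g. 万)."""
        return {k: rescale_money(c.value, scale) for k, c in self.components.items()}


def aggregate(
    components: Sequence[tuple[str, Money, str]],
    provenance: Mapping[str, str] | None = None,
) -> ServiceValuation:
    """Sum per-service values into a total and percentage shares.

    All components must share one price reference year.  Shares are
    amount / total × 100; a negative component (net gas debit) carries a
    negative share.
    """
    if not components:
        raise ValueError("cannot aggregate an empty component list")
    years = {m.reference_year for _, m, _ in components}
    if len(years) > 1:
        raise YearMismatchError(
            f"components reference multiple price years {sorted(years)}; "
            "adjust by price indices before aggregating"
        )
    labels = [label for label, _, _ in components]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate service labels in aggregation")
    total_amount = sum(m.amount for _, m, _ in components)
    total = Money(total_amount, years.pop())
    comp = {label: ServiceComponent(m, tag) for label, m, tag in components}
    if total_amount == 0:
        shares = {label: 0.0 for label in comp}
    else:
        shares = {label: c.value.amount / total_amount * 100.0 for label, c in comp.items()}
    return ServiceValuation(comp, total, shares, dict(provenance or {}))


@dataclass(frozen=True, slots=True)
class ComparisonRow:
    """Per-service scenario difference under a stated proportion convention."""

    label: str
    value_a: Money
    value_b: Money
    added: Money
    added_proportion_pct: float | None  # None when the divisor is zero


@dataclass(frozen=True)
class ScenarioComparison:
    """Service-by-service difference of two valuations (a = new, b = baseline)."""

    rows: dict[str, ComparisonRow]
    total: ComparisonRow
    convention: Convention


def _proportion(added: float, a: float, b: float, convention: Convention) -> float | None:
    divisor = b if convention == "relative_to_baseline" else a
    if divisor == 0:
        return None
    return added / divisor * 100.0


def compare_scenarios(
    a: ServiceValuation,
    b: ServiceValuation,
    convention: Convention = "relative_to_baseline",
) -> ScenarioComparison:
    """Difference two valuations with identical service labels.

    ``added = a − b`` per component and in total; the added proportion is
    added/b (``relative_to_baseline``, default) or added/a
    (``relative_to_new``).
    """
    if convention not in ("relative_to_baseline", "relative_to_new"):
        raise ValueError(f"unknown comparison convention {convention!r}")
    if set(a.components) != set(b.components):
        only_a = sorted(set(a.components) - set(b.components))
        only_b = sorted(set(b.components) - set(a.components))
        raise ValueError(
            f"scenario component labels differ (only in a: {only_a}; only in b: {only_b})"
        )
    rows: dict[str, ComparisonRow] = {}
    for label in a.components:
        va, vb = a.components[label].value, b.components[label].value
        added = va - vb
        rows[label] = ComparisonRow(
            label, va, vb, added, _proportion(added.amount, va.amount, vb.amount, convention)
        )
    added_total = a.total - b.total
    total = ComparisonRow(
        "total", a.total, b.total, added_total,
        _proportion(added_total.amount, a.total.amount, b.total.amount, convention),
    )
    return ScenarioComparison(rows, total, convention)


def valuation_from_printed(
    components_wan: Mapping[str, float],
    cices_tags: Mapping[str, str],
    reference_year: int,
) -> ServiceValuation:
    """Build a valuation directly from reported per-service values in 万 CNY.

    Used for baseline scenarios whose underlying parameters are not
    available, only their published component values.
    """
    comps = [
        (label, Money(v_wan * 1e4, reference_year), cices_tags.get(label, ""))
        for label, v_wan in components_wan.items()
    ]
    return aggregate(comps, provenance={label: "printed" for label in components_wan})
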