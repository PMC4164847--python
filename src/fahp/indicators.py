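"""Raw-value calculators for the quantitative ecological benefit leaves.

These functions turn field measurements into the raw leaf values consumed
by the evaluation pipeline (before standardization).  They are optional
front-ends: the pipeline accepts leaf values from any source — expert
assessment, forestry-bureau statistics, or these formulas.

Several source formulas reuse one-letter symbols with different meanings
(two distinct P_r's, several P_1/P_2's, n_i both as species counts and as
respondent counts).  Parameters are therefore namespaced per indicator with
descriptive keyword names; the mapping back to conventional symbols is
given in each docstring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .errors import MissingValueError, ValidationError


@dataclass(frozen=True)
class DiversitySample:
    """Per-species abundances for the diversity and stability indices.

    ``counts`` holds individual counts n_i per species; N is their total
    and the species richness counts only the nonzero entries.
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if any(c < 0 for c in counts):
            raise ValidationError("species counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        """N, the total number of individuals."""
        return sum(self.counts)

    @property
    def richness(self) -> int:
        """Number of species actually present (nonzero counts)."""
        return sum(1 for c in self.counts if c > 0)


def simpson_diversity(sample: DiversitySample) -> float:
    """Inverse Simpson concentration D2 = N(N-1) / sum_i n_i(n_i - 1).

    Equals 1 for a single-species stand (minimum diversity) and grows with
    evenness and richness.  Undefined when every species is a singleton.
    """
    n_total = sample.total
    if n_total < 2:
        raise ValidationError("Simpson index needs at least two individuals")
    denom = sum(c * (c - 1) for c in sample.counts)
    if denom == 0:
        raise ValidationError(
            "Simpson index undefined: every species is a singleton"
        )
    return n_total * (n_total - 1) / denom


def shannon_stability(sample: DiversitySample) -> float:
    """Shannon entropy D5 = -sum_i r_i ln r_i with r_i = n_i / N.

    Zero-count species are skipped; the value is bounded by ln(richness),
    attained at perfect evenness.
    """
    n_total = sample.total
    if n_total < 1:
        raise ValidationError("empty sample")
    h = 0.0
    for c in sample.counts:
        if c > 0:
            r = c / n_total
            h -= r * math.log(r)
    return h


def landscape_integrity(vitality: float, organization: float,
                        restoring_force: float) -> float:
    """Forest landscape integrity D1 = V * O * R.

    V is system vitality (metabolism / primary productivity); O the
    organization index and R the restoring-force index, both relative
    degrees on [0, 1].
    """
    for name, value in (("organization", organization),
                        ("restoring_force", restoring_force)):
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {value}")
    if vitality < 0:
        raise ValidationError("vitality must be non-negative")
    return vitality * organization * restoring_force


def plantation_productivity(
    trunk: float, branch: float, leaf: float, root: float,
    litter: float, understory: float, animal_intake: float,
) -> float:
    """Plantation productivity D3: sum of seven annual production terms.

    Conventional symbols P_s, P_b, P_l, P_r (net growth of trunks,
    branches, leaves, roots), P_n (litter), P_u (understory growth),
    P_h (animal intake), all as annual rates in a common unit.
    """
    terms = (trunk, branch, leaf, root, litter, understory, animal_intake)
    if any(t < 0 for t in terms):
        raise ValidationError("production terms must be non-negative")
    return float(sum(terms))


def restoration_force(recovery_time: float, max_cutting_intensity: float) -> float:
    """Fertility/restoration index D4 = M_s / F_t.

    M_s is the time to return from stress to steady state; F_t the maximum
    cutting intensity the forest can bear.
    """
    if max_cutting_intensity == 0:
        raise ZeroDivisionError("maximum bearable cutting intensity is zero")
    if recovery_time < 0 or max_cutting_intensity < 0:
        raise ValidationError("inputs must be non-negative")
    return recovery_time / max_cutting_intensity


class WaterConservation(NamedTuple):
    """D6 split into its flood-control and water-supply components."""

    flood_control: float   # D6a
    water_supply: float    # D6b

    @property
    def total(self) -> float:
        return self.flood_control + self.water_supply


def water_conservation(
    forest_areas: Sequence[float],
    flood_storages: Sequence[float],
    baseline_storage: float,
    dam_cost_per_m3: float,
    benefit_input_ratio: float,
    water_increment: float,
    irrigation_price: float,
    industrial_price: float,
    irrigation_coefficient: float,
    industrial_coefficient: float,
) -> WaterConservation:
    """Water-source conservation value D6 = D6a + D6b (monetary).

    D6a = sum_i m_i (H_i - H_0) * b * beta prices the extra flood storage
    of each forest type i (area m_i, storage H_i) over non-forest land
    (H_0) at the dam-construction cost b per m^3 times the benefit/input
    ratio beta.  D6b = T (P_1 a + P_2 eta) prices the incremental water
    yield T at irrigation and industrial supply prices P_1, P_2 with
    utilization coefficients a, eta.
    """
    if len(forest_areas) != len(flood_storages):
        raise MissingValueError(
            "forest_areas and flood_storages must have equal length"
        )
    d6a = sum(
        m * (h - baseline_storage) * dam_cost_per_m3 * benefit_input_ratio
        for m, h in zip(forest_areas, flood_storages)
    )
    d6b = water_increment * (
        irrigation_price * irrigation_coefficient
        + industrial_price * industrial_coefficient
    )
    return WaterConservation(flood_control=float(d6a), water_supply=float(d6b))


def soil_water_conservation(soil_retained: float, dredge_cost: float) -> float:
    """Soil and water conservation value D7 = K * P_r / 2.

    K is the soil mass forest land retains relative to bare land; P_r the
    average cost of dredging 1 t of sediment.
    """
    if soil_retained < 0 or dredge_cost < 0:
        raise ValidationError("inputs must be non-negative")
    return soil_retained * dredge_cost / 2.0


def air_purification(
    stocking_volume: float,
    net_growth_rate: float,
    dry_mass: float,
    oxygen_price: float,
    root_shoot_fraction: float,
    oxygen_per_tonne: float,
) -> float:
    """Oxygen-release (air purifying) value D8 = M L d P_y (1 + Z) K_l.

    M is the stocking volume, L the net growth rate, d the dry-wood mass,
    P_y the industrial oxygen price, Z the root-and-shoot share of annual
    growth, K_l the oxygen emitted per tonne of dry matter.
    """
    factors = (stocking_volume, net_growth_rate, dry_mass, oxygen_price,
               root_shoot_fraction, oxygen_per_tonne)
    if any(v < 0 for v in factors):
        raise ValidationError("inputs must be non-negative")
    return (stocking_volume * net_growth_rate * dry_mass * oxygen_price
            * (1.0 + root_shoot_fraction) * oxygen_per_tonne)


def soil_improvement(
    litter_rate: float,
    area: float,
    component_factors: Sequence[tuple[float, float, float]],
) -> float:
    """Soil-improving value D9 = G * S_1 * sum_i P_1i P_2i P_3i.

    G is litter production per unit area and year (t / (hm^2 a)), S_1 the
    forest area, and each triple (P_1i, P_2i, P_3i) the per-component
    content/recovery/price factors of the three fertilizing components
    (the source text leaves the three factors' individual meanings
    unspecified; they enter only as a product).
    """
    if litter_rate < 0 or area < 0:
        raise ValidationError("litter rate and area must be non-negative")
    if not component_factors:
        raise MissingValueError("at least one component factor triple required")
    return litter_rate * area * sum(p1 * p2 * p3
                                    for p1, p2, p3 in component_factors)


def future_generations_value(
    respondents: int,
    grade_counts: Sequence[int],
    grade_payments: Sequence[float],
) -> float:
    """Willingness-to-pay value D30 = sum_i N (n_i / n) x_i with n = N.

    A contingent-valuation survey of N respondents sorts willingness to
    pay into grades with n_i respondents and mean payment x_i (yuan per
    person); grade fractions use the total respondent count as divisor, so
    the value reduces to sum_i n_i x_i.
    """
    if len(grade_counts) != len(grade_payments):
        raise MissingValueError("grade counts and payments differ in length")
    if respondents < 1:
        raise ValidationError("need at least one respondent")
    if sum(grade_counts) > respondents:
        raise ValidationError("grade counts exceed the number of respondents")
    return sum(
        respondents * (n_i / respondents) * x_i
        for n_i, x_i in zip(grade_counts, grade_payments)
    )
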