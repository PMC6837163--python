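"""Carrier-based 2x2 association statistics and descriptive summaries.

Odds ratios follow the classical Altman (1991) formulation used by common
online calculators: OR = ad/bc with SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d),
a Wald 95% CI on the log scale, and a two-sided normal p-value from
z = ln(OR)/SE. When any cell of the table is zero, the Haldane-Anscombe
correction adds 0.5 to *all four* cells before every downstream quantity
(point estimate, SE, CI, z, p) and the result is flagged ``corrected``.

Tables are carrier-based: a cell counts subjects carrying at least one
qualifying allele, not alleles. Variants whose published risk requires
homozygosity are counted on homozygous carriers only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from scipy.stats import norm

from .catalog import GeneCatalog
from .datamodel import AnnotatedVariant, CohortManifest, GenotypeCall

__all__ = [
    "CarrierTable",
    "OddsResult",
    "SummaryStat",
    "carrier_table_from_calls",
    "mean_sd",
    "odds_ratio",
    "percentage",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up, matching how the source tables were formatted."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CarrierTable:
    """2x2 carrier counts: a/b case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("carrier table cells must be non-negative")

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_ctrl(self) -> int:
        return self.c + self.d

    @classmethod
    def from_denominators(cls, a: int, n_case: int, c: int, n_ctrl: int) -> "CarrierTable":
        if a > n_case or c > n_ctrl:
            raise ValueError("carrier count exceeds denominator")
        return cls(a, n_case - a, c, n_ctrl - c)

    def swapped(self) -> "CarrierTable":
        """Swap the case and control columns (maps OR to its reciprocal)."""
        return CarrierTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OddsResult:
    or_point: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    corrected: bool

    def rounded(self) -> tuple[float, float]:
        """(OR to 1 decimal, p to 2 decimals), the report precision."""
        return round_half_up(self.or_point, 1), round_half_up(self.p, 2)


def odds_ratio(table: CarrierTable, ci_level: float = 0.95) -> OddsResult:
    """Odds ratio with Wald CI and two-sided normal p for a carrier table."""
    if table.n_case == 0 or table.n_ctrl == 0:
        raise ValueError("both denominators must be positive")
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zcrit = float(norm.ppf(0.5 + ci_level / 2))
    log_or = math.log(or_point)
    z = log_or / se
    p = float(2 * norm.sf(abs(z)))
    return OddsResult(
        or_point=or_point,
        ci_low=math.exp(log_or - zcrit * se),
        ci_high=math.exp(log_or + zcrit * se),
        z=z,
        p=p,
        corrected=corrected,
    )


def carrier_table_from_calls(
    variant: AnnotatedVariant,
    calls: Iterable[GenotypeCall],
    manifest: CohortManifest,
    scope: str,
    catalog: Optional[GeneCatalog] = None,
) -> CarrierTable:
    """Count distinct case and control carriers of one variant.

    ``scope`` names a (case N, control N) denominator pair in the manifest —
    published tables mix denominators because different assays cover
    different gene sets. Counting is zygosity-agnostic unless the risk
    registry requires homozygosity for this variant, in which case only
    homozygous calls count (e.g. a risk genotype published as homozygous).
    """
    if scope not in manifest.denominators:
        raise KeyError(f"unknown denominator scope {scope!r}")
    n_case, n_ctrl = manifest.denominators[scope]
    hom_only = False
    if catalog is not None:
        entry = catalog.registry_entry(variant)
        hom_only = entry is not None and entry.risk_zygosity == "hom"
    case_carriers: set[str] = set()
    ctrl_carriers: set[str] = set()
    for call in calls:
        if call.key != variant.key:
            continue
        if hom_only and call.zygosity != "hom":
            continue
        subj = manifest.by_id(call.subject_id)
        if subj.cohort_group == "pd":
            case_carriers.add(subj.id)
        elif subj.is_control:
            ctrl_carriers.add(subj.id)
    return CarrierTable.from_denominators(len(case_carriers), n_case, len(ctrl_carriers), n_ctrl)


@dataclass(frozen=True)
class SummaryStat:
    n: int
    mean: float
    sd: Optional[float]  # None when n < 2
    units: str = "years"


def mean_sd(values: Sequence[float], units: str = "years") -> SummaryStat:
    """Arithmetic mean and sample SD (n-1 denominator)."""
    n = len(values)
    if n == 0:
        raise ValueError("mean_sd requires at least one value")
    mean = sum(values) / n
    if n < 2:
        return SummaryStat(n=n, mean=mean, sd=None, units=units)
    var = sum((x - mean) ** 2 for x in values) / (n - 1)
    return SummaryStat(n=n, mean=mean, sd=math.sqrt(var), units=units)


def percentage(k: int, n: int) -> float:
    """100*k/n rounded half-up to two decimals, the report convention."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * k / n, 2)
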