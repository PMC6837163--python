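"""Rare-damaging variant selection and the nested burden filters A-D.

The four filter levels form two nested chains (D <= B <= A and D <= C <= A):

* **A** — rare (max population MAF below the ceiling, strict ``<``) AND the
  consequence is loss-of-function or missense.
* **B** — A, but missense variants must additionally be called damaging by
  multiple lines of in-silico evidence (LoF passes unconditionally).
* **C** — A restricted to the core Parkinsonism gene list.
* **D** — C with the damaging-missense restriction of B.

Separately, ``select_rare_damaging`` applies the discovery rule used for
reporting individual variants: B-passing variants that are absent from the
control cohort. The two are distinct operations on purpose — the burden
statistic never conditions on control carriers, the per-variant discovery
list does.

Variants with an empty frequency map are treated as rare (an allele never
observed in any reference population cannot exceed the ceiling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .catalog import GeneCatalog
from .datamodel import AnnotatedVariant, VariantKey

__all__ = [
    "LOF_TERMS",
    "DamagingRule",
    "FilterLevel",
    "classify_consequence",
    "filter_level",
    "is_damaging_missense",
    "is_rare",
    "max_pop_maf",
    "passes_filter",
    "select_rare_damaging",
]

#: Annotation terms mapped to the loss-of-function class.  Covers both
#: SnpEff/SO vocabulary and legacy labels; anything unknown maps to "other".
LOF_TERMS = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "frameshift_variant",
        "frameshift",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "canonical_splice",
        "nonsense",
        "start_lost",
    }
)
MISSENSE_TERMS = frozenset({"missense_variant", "missense"})


def classify_consequence(variant: AnnotatedVariant) -> str:
    """Map the annotated consequence term to ``lof`` / ``missense`` / ``other``.

    Total and deterministic: unknown vocabulary falls through to ``other``.
    A combined SnpEff term like ``missense_variant&splice_region_variant`` is
    classified by its ``&``-separated components, LoF taking precedence.
    """
    terms = variant.consequence.split("&")
    if any(t in LOF_TERMS for t in terms):
        return "lof"
    if any(t in MISSENSE_TERMS for t in terms):
        return "missense"
    return "other"


def max_pop_maf(variant: AnnotatedVariant) -> float:
    """Maximum allele frequency over all populated reference populations.

    An empty frequency map yields 0.0: the variant is treated as rare.
    """
    if not variant.pop_mafs:
        return 0.0
    return max(variant.pop_mafs.values())


def is_rare(variant: AnnotatedVariant, ceiling: float = 0.01, strict: bool = True) -> bool:
    """Rarity test against the MAF ceiling in *every* population.

    Strict ``<`` by default (a variant at exactly 1% is not rare); the
    comparison operator is configurable because cohort pipelines differ on
    the boundary convention.
    """
    m = max_pop_maf(variant)
    return m < ceiling if strict else m <= ceiling


@dataclass(frozen=True)
class DamagingRule:
    """Operationalization of "multiple lines of computational evidence".

    A missense variant is damaging when at least ``min_damaging_votes``
    predictors call it damaging AND those calls make up at least
    ``min_fraction`` of the non-missing votes. LoF variants are exempt.
    """

    min_damaging_votes: int = 2
    min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_damaging_votes < 1:
            raise ValueError("min_damaging_votes must be positive")
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in [0,1]")


def is_damaging_missense(variant: AnnotatedVariant, rule: DamagingRule = DamagingRule()) -> bool:
    if classify_consequence(variant) != "missense":
        raise ValueError(
            f"is_damaging_missense called on non-missense variant {variant.key} "
            f"({variant.consequence})"
        )
    damaging = sum(1 for v in variant.predictor_votes if v == "damaging")
    informative = sum(1 for v in variant.predictor_votes if v != "missing")
    if informative == 0:
        return False
    return damaging >= rule.min_damaging_votes and damaging / informative >= rule.min_fraction


@dataclass(frozen=True)
class FilterLevel:
    label: str
    maf_ceiling: float = 0.01
    strict_maf: bool = True
    damaging_rule: DamagingRule = field(default_factory=DamagingRule)

    def __post_init__(self) -> None:
        if self.label not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown filter level {self.label!r}")
        if not 0.0 < self.maf_ceiling <= 1.0:
            raise ValueError("maf_ceiling must be in (0,1]")

    @property
    def requires_damaging(self) -> bool:
        return self.label in ("B", "D")

    @property
    def core_only(self) -> bool:
        return self.label in ("C", "D")


def filter_level(label: str, **kwargs) -> FilterLevel:
    return FilterLevel(label=label, **kwargs)


def passes_filter(
    variant: AnnotatedVariant, level: FilterLevel, catalog: GeneCatalog
) -> bool:
    """Evaluate one variant against one nested filter level."""
    if not is_rare(variant, level.maf_ceiling, level.strict_maf):
        return False
    cls = classify_consequence(variant)
    if cls == "other":
        return False
    if level.core_only and not catalog.is_core(variant.gene):
        return False
    if level.requires_damaging and cls == "missense":
        return is_damaging_missense(variant, level.damaging_rule)
    return True


def select_rare_damaging(
    variants: Iterable[AnnotatedVariant],
    control_carriers: Mapping[VariantKey, int],
    catalog: GeneCatalog,
    level: Optional[FilterLevel] = None,
) -> set[VariantKey]:
    """Discovery selection: B-passing variants with zero control carriers.

    ``control_carriers`` maps variant key -> number of distinct control
    subjects carrying the variant; keys absent from the map count as zero.
    """
    if level is None:
        level = FilterLevel("B")
    selected: set[VariantKey] = set()
    for v in variants:
        if passes_filter(v, level, catalog) and control_carriers.get(v.key, 0) == 0:
            selected.add(v.key)
    return selected


def filter_report_rows(
    variants: Sequence[AnnotatedVariant],
    catalog: GeneCatalog,
    levels: Optional[Mapping[str, FilterLevel]] = None,
) -> list[dict]:
    """Per-variant filter report: consequence class, max MAF, A-D booleans."""
    if levels is None:
        levels = {lab: FilterLevel(lab) for lab in "ABCD"}
    rows = []
    for v in variants:
        row = {
            "variant": str(v.key),
            "gene": v.gene,
            "consequence_class": classify_consequence(v),
            "max_maf": max_pop_maf(v),
            "votes": ",".join(v.predictor_votes) or ".",
        }
        for lab, lev in levels.items():
            row[f"pass_{lab}"] = passes_filter(v, lev, catalog)
        rows.append(row)
    return rows
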