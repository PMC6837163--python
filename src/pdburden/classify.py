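"""Four-way genetic-architecture classification of Parkinsonism patients.

Each patient's *qualifying variants* are the union of

1. rare damaging variants (filter-B passing, absent from controls) they
   carry,
2. registry risk variants carried at the registry's required zygosity, and
3. CNV events classified pathogenic or likely pathogenic,

de-duplicated by variant key. Classification precedence:

* two or more qualifying variants (anywhere in the panel, including two in
  the same gene) -> ``multi_hit``;
* exactly one: a pathogenic CNV, a rare damaging variant in a dominant (or
  dominant-like candidate) gene, or a homozygous rare damaging variant in a
  recessive gene -> ``monogenic``; a registry risk variant (or a rare
  damaging variant in a pure risk gene such as GBA) -> ``risk_only``;
  a heterozygous rare damaging variant in a recessive gene ->
  ``single_het_ar``;
* none -> ``unresolved``.

Registry risk variants are exempt from the rarity filter when counted as
co-occurrence hits — a common susceptibility allele still counts as a hit in
the oligogenic model even though it would never pass the rare-variant
filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .catalog import GeneCatalog
from .datamodel import AnnotatedVariant, CnvEvent, GenotypeCall, VariantKey
from .filters import FilterLevel, select_rare_damaging

__all__ = [
    "ARCHITECTURE_GROUPS",
    "QualifyingVariant",
    "classify_subject",
    "cooccurrence_count",
    "qualifying_variants",
]

ARCHITECTURE_GROUPS = ("monogenic", "risk_only", "multi_hit", "single_het_ar", "unresolved")
QUALIFYING_ORIGINS = ("rare_damaging", "registry_risk", "pathogenic_cnv")


@dataclass(frozen=True)
class QualifyingVariant:
    key: str  # variant key string, or a CNV label like "PRKN:exon 7:duplication"
    origin: str
    gene: str
    zygosity: str  # het/hom; CNV dosage events are recorded as het

    def __post_init__(self) -> None:
        if self.origin not in QUALIFYING_ORIGINS:
            raise ValueError(f"unknown qualifying origin {self.origin!r}")


def qualifying_variants(
    subject_id: str,
    calls: Iterable[GenotypeCall],
    variants: Mapping[VariantKey, AnnotatedVariant],
    cnv_events: Iterable[CnvEvent],
    catalog: GeneCatalog,
    rare_damaging: set[VariantKey],
) -> list[QualifyingVariant]:
    """Collect the subject's qualifying variants, de-duplicated by key.

    ``rare_damaging`` is the cohort-level discovery set from
    :func:`pdburden.filters.select_rare_damaging`. A variant that is both a
    registry hit and in the rare-damaging set is recorded once, with
    ``registry_risk`` origin taking precedence (its published-risk status is
    the stronger claim).
    """
    out: dict[str, QualifyingVariant] = {}
    for call in calls:
        if call.subject_id != subject_id:
            continue
        var = variants.get(call.key)
        if var is None:
            continue
        keystr = str(call.key)
        if catalog.is_registry_risk(var, call.zygosity):
            out[keystr] = QualifyingVariant(keystr, "registry_risk", var.gene, call.zygosity)
        elif call.key in rare_damaging and keystr not in out:
            out[keystr] = QualifyingVariant(keystr, "rare_damaging", var.gene, call.zygosity)
    for ev in cnv_events:
        if ev.subject_id != subject_id:
            continue
        if ev.clin_class in ("P", "LP"):
            keystr = f"{ev.gene}:{ev.region}:{ev.dosage}"
            out.setdefault(
                keystr, QualifyingVariant(keystr, "pathogenic_cnv", ev.gene, "het")
            )
    return sorted(out.values(), key=lambda q: q.key)


def classify_subject(
    qualifying: Sequence[QualifyingVariant],
    catalog: GeneCatalog,
    candidate_as_ad: bool = True,
) -> str:
    """Assign the architecture group from the qualifying-variant list.

    Permutation-invariant in the input; ``candidate_as_ad`` controls whether
    candidate genes behave like dominant genes for the monogenic call.
    """
    qs = list(qualifying)
    if len(qs) >= 2:
        return "multi_hit"
    if not qs:
        return "unresolved"
    q = qs[0]
    if q.origin == "pathogenic_cnv":
        return "monogenic"
    if q.origin == "registry_risk":
        return "risk_only"
    # rare damaging single hit: split on the gene's inheritance mode
    inheritance = catalog.lookup(q.gene).inheritance
    if inheritance == "AD" or (inheritance == "candidate" and candidate_as_ad):
        return "monogenic"
    if inheritance == "AR":
        return "monogenic" if q.zygosity == "hom" else "single_het_ar"
    # risk_only genes (e.g. GBA) and candidate genes under candidate_as_ad=False
    return "risk_only"


def cooccurrence_count(qualifying: Sequence[QualifyingVariant], include_risk: bool = True) -> int:
    """Number of co-occurring qualifying variants (no cap applied).

    ``include_risk=False`` restricts the count to rare damaging variants and
    pathogenic CNVs, excluding registry risk alleles — the alternative
    reading of "filtered variants" for the onset-age comparison.
    """
    if include_risk:
        return len(qualifying)
    return sum(1 for q in qualifying if q.origin != "registry_risk")


def classify_cohort(
    subject_ids: Iterable[str],
    calls: Sequence[GenotypeCall],
    variants: Mapping[VariantKey, AnnotatedVariant],
    cnv_events: Sequence[CnvEvent],
    catalog: GeneCatalog,
    control_carriers: Mapping[VariantKey, int],
    level: Optional[FilterLevel] = None,
    candidate_as_ad: bool = True,
) -> dict[str, tuple[str, list[QualifyingVariant]]]:
    """Classify every subject: id -> (group, qualifying variants)."""
    rare_dam = select_rare_damaging(variants.values(), control_carriers, catalog, level)
    calls_by_subject: dict[str, list[GenotypeCall]] = {}
    for c in calls:
        calls_by_subject.setdefault(c.subject_id, []).append(c)
    cnv_by_subject: dict[str, list[CnvEvent]] = {}
    for ev in cnv_events:
        cnv_by_subject.setdefault(ev.subject_id, []).append(ev)
    out = {}
    for sid in subject_ids:
        qs = qualifying_variants(
            sid,
            calls_by_subject.get(sid, []),
            variants,
            cnv_by_subject.get(sid, []),
            catalog,
            rare_dam,
        )
        out[sid] = (classify_subject(qs, catalog, candidate_as_ad), qs)
    return out
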