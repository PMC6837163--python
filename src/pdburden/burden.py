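"""Per-subject variant burden and the two cohort comparison tests.

Burden for one subject is the sum of hits over all panel genes for the calls
whose variant survives a given filter level: a heterozygous call contributes
1 hit, a homozygous call 2 hits. Burden is defined only for subjects assayed
by NGS (targeted panel or exome) because only there was the full gene panel
interrogated; Sanger/MLPA-only subjects raise.

Two tests operate on these quantities:

* a ties-corrected Kruskal-Wallis comparison of the burden distributions in
  the control, non-PD-neurodegenerative and PD groups (burdens are small
  integers, so ties dominate and the correction matters), and
* a classical one-way fixed-effects ANOVA of age at onset across patients
  carrying 0, 1 or 2 co-occurring qualifying variants; patients with three
  or more are excluded (and reported), since a singleton group carries no
  within-group information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .catalog import GeneCatalog
from .datamodel import AnnotatedVariant, CohortManifest, GenotypeCall, Subject, VariantKey
from .filters import FilterLevel, passes_filter

__all__ = [
    "AnovaResult",
    "BurdenResult",
    "KruskalResult",
    "aoo_vs_count_anova",
    "burden_comparison",
    "burden_matrix",
    "subject_burden",
]


@dataclass(frozen=True)
class BurdenResult:
    subject_id: str
    level: str
    burden: int


@dataclass(frozen=True)
class KruskalResult:
    h: float
    p: float
    group_sizes: tuple[int, ...]
    level: str = ""


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    group_means: tuple[float, ...]
    group_sizes: tuple[int, ...]
    excluded_ids: tuple[str, ...]


def subject_burden(
    subject: Subject,
    calls: Iterable[GenotypeCall],
    variants: Mapping[VariantKey, AnnotatedVariant],
    level: FilterLevel,
    catalog: GeneCatalog,
) -> BurdenResult:
    """Sum 1/2-weighted hits over the subject's filter-passing panel calls."""
    if not subject.is_ngs:
        raise ValueError(
            f"burden undefined for non-NGS assay ({subject.assay}) of subject {subject.id}"
        )
    total = 0
    for call in calls:
        if call.subject_id != subject.id:
            continue
        var = variants.get(call.key)
        if var is None:
            continue
        if not catalog.is_panel(var.gene):
            continue
        if passes_filter(var, level, catalog):
            total += call.hits
    return BurdenResult(subject_id=subject.id, level=level.label, burden=total)


def burden_matrix(
    manifest: CohortManifest,
    calls: Sequence[GenotypeCall],
    variants: Mapping[VariantKey, AnnotatedVariant],
    catalog: GeneCatalog,
    levels: Optional[Sequence[FilterLevel]] = None,
) -> dict[str, dict[str, int]]:
    """subject id -> {level label -> burden}, NGS-assayed subjects only."""
    if levels is None:
        levels = [FilterLevel(lab) for lab in "ABCD"]
    calls_by_subject: dict[str, list[GenotypeCall]] = {}
    for c in calls:
        calls_by_subject.setdefault(c.subject_id, []).append(c)
    out: dict[str, dict[str, int]] = {}
    for subj in manifest.subjects:
        if not subj.is_ngs:
            continue
        own = calls_by_subject.get(subj.id, [])
        out[subj.id] = {
            lev.label: subject_burden(subj, own, variants, lev, catalog).burden
            for lev in levels
        }
    return out


def burden_comparison(
    manifest: CohortManifest, burdens: Mapping[str, int], level: str = "A"
) -> KruskalResult:
    """Kruskal-Wallis H (ties-corrected) across control / neurodeg / PD.

    ``burdens`` maps subject id -> burden at one filter level; only NGS
    subjects present in the map enter the test. All three groups must be
    non-empty. When every burden in the pooled sample is identical there is
    no rank variation and the result is H = 0, p = 1.
    """
    groups = []
    for selector in (("control_healthy", "control_nonneuro", "control_mito"), ("neurodeg",), ("pd",)):
        vals = [
            burdens[s.id]
            for s in manifest.group(*selector)
            if s.is_ngs and s.id in burdens
        ]
        groups.append(vals)
    if any(len(g) == 0 for g in groups):
        raise ValueError("all three burden groups (control, neurodeg, pd) must be non-empty")
    pooled = [x for g in groups for x in g]
    sizes = tuple(len(g) for g in groups)
    if len(set(pooled)) == 1:
        return KruskalResult(h=0.0, p=1.0, group_sizes=sizes, level=level)
    h, p = stats.kruskal(*groups)
    return KruskalResult(h=float(h), p=float(p), group_sizes=sizes, level=level)


def aoo_vs_count_anova(
    subjects: Sequence[Subject],
    counts: Mapping[str, int],
    max_count: int = 2,
) -> AnovaResult:
    """One-way ANOVA of age at onset across co-occurrence counts 0..max_count.

    Patients with more than ``max_count`` qualifying variants are excluded
    from the test and returned in ``excluded_ids``. Classical fixed-effects
    (equal-variance) ANOVA; at least two groups must be non-empty.
    """
    groups: dict[int, list[float]] = {k: [] for k in range(max_count + 1)}
    excluded = []
    for s in subjects:
        if s.cohort_group != "pd" or s.aoo is None or s.id not in counts:
            continue
        k = counts[s.id]
        if k > max_count:
            excluded.append(s.id)
        else:
            groups[k].append(float(s.aoo))
    filled = {k: v for k, v in groups.items() if v}
    if len(filled) < 2:
        raise ValueError("ANOVA needs at least two non-empty count groups")
    arrays = [np.asarray(v) for v in filled.values()]
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(
        f=float(f),
        p=float(p),
        group_means=tuple(float(np.mean(a)) for a in arrays),
        group_sizes=tuple(len(a) for a in arrays),
        excluded_ids=tuple(sorted(excluded)),
    )
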