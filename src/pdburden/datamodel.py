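"""Shared domain types for the early-onset Parkinsonism cohort analysis.

The pipeline operates on four kinds of objects: annotated sequence variants,
cohort subjects, subject-variant genotype calls, and exon-dosage (CNV) events.
All types are plain frozen dataclasses so they hash, compare and serialize
predictably; validation happens in ``__post_init__`` so a constructed object
is always internally consistent.

Coordinates are 1-based and fully closed, as in VCF. Multi-allelic VCF
records are split at ingest, so a :class:`VariantKey` always carries a single
alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

__all__ = [
    "COHORT_GROUPS",
    "CONTROL_GROUPS",
    "AnnotatedVariant",
    "CnvEvent",
    "CohortManifest",
    "GenotypeCall",
    "Subject",
    "VariantKey",
]

#: Diagnostic groups. ``control_*`` subgroups are pooled into a single control
#: arm for the burden comparison.
COHORT_GROUPS = ("pd", "neurodeg", "control_healthy", "control_nonneuro", "control_mito")
CONTROL_GROUPS = ("control_healthy", "control_nonneuro", "control_mito")

STATUSES = ("sporadic", "familial", "not_applicable")
SEXES = ("m", "f", "unknown")
ASSAYS = ("sanger_mlpa", "ngs_panel", "wes")
NGS_ASSAYS = ("ngs_panel", "wes")
CLIN_CLASSES = ("P", "LP", "US", "LB", "B")
ZYGOSITIES = ("het", "hom")
DOSAGES = ("deletion", "duplication", "triplication")


@dataclass(frozen=True, order=True)
class VariantKey:
    """A normalized single-ALT variant identifier (1-based, VCF-style)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if "," in self.alt:
            raise ValueError("multi-allelic alt must be split before VariantKey construction")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # e.g. "GBA:1223:C>T"
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant with its functional annotation as consumed from the VCF.

    ``predictor_votes`` is the ordered tuple of in-silico tool calls
    (``damaging`` / ``tolerated`` / ``missing``); ``pop_mafs`` maps a
    population label to an allele frequency in [0, 1]. ``clin_class`` is an
    optional five-level pathogenicity label (P/LP/US/LB/B) consumed as input,
    never computed here. ``risk_flag`` marks membership in the registry of
    previously published risk variants and is set from the gene catalog.
    """

    key: VariantKey
    gene: str
    consequence: str
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    rsid: Optional[str] = None
    predictor_votes: tuple[str, ...] = ()
    pop_mafs: Mapping[str, float] = field(default_factory=dict)
    clin_class: Optional[str] = None
    risk_flag: bool = False

    def __post_init__(self) -> None:
        for vote in self.predictor_votes:
            if vote not in ("damaging", "tolerated", "missing"):
                raise ValueError(f"unknown predictor vote {vote!r}")
        for pop, maf in self.pop_mafs.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"pop MAF out of [0,1] for {pop}: {maf}")
        if self.clin_class is not None and self.clin_class not in CLIN_CLASSES:
            raise ValueError(f"unknown clinical class {self.clin_class!r}")

    def with_risk_flag(self, flag: bool) -> "AnnotatedVariant":
        return replace(self, risk_flag=flag)


@dataclass(frozen=True)
class Subject:
    id: str
    cohort_group: str
    status: str = "not_applicable"
    sex: str = "unknown"
    aoo: Optional[float] = None
    assay: str = "ngs_panel"

    def __post_init__(self) -> None:
        if self.cohort_group not in COHORT_GROUPS:
            raise ValueError(f"unknown cohort group {self.cohort_group!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.cohort_group == "pd" and self.aoo is None:
            raise ValueError(f"PD subject {self.id} lacks age at onset")
        if self.aoo is not None and not 0.0 <= self.aoo <= 120.0:
            raise ValueError(f"age at onset out of [0,120]: {self.aoo}")

    @property
    def is_control(self) -> bool:
        return self.cohort_group in CONTROL_GROUPS

    @property
    def is_ngs(self) -> bool:
        return self.assay in NGS_ASSAYS


@dataclass(frozen=True)
class GenotypeCall:
    """A non-reference genotype linking a subject to a variant.

    Zygosity is strictly binary: reference and missing genotypes are never
    stored, so every call contributes at least one burden hit.
    """

    subject_id: str
    key: VariantKey
    zygosity: str

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"zygosity must be het or hom, got {self.zygosity!r}")

    @property
    def hits(self) -> int:
        """Burden weight: heterozygous = 1 hit, homozygous = 2 hits."""
        return 1 if self.zygosity == "het" else 2


@dataclass(frozen=True)
class CnvEvent:
    """An MLPA-style exon dosage call (e.g. an exon 7 duplication)."""

    subject_id: str
    gene: str
    region: str
    dosage: str
    clin_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dosage not in DOSAGES:
            raise ValueError(f"unknown dosage {self.dosage!r}")
        if self.clin_class is not None and self.clin_class not in CLIN_CLASSES:
            raise ValueError(f"unknown clinical class {self.clin_class!r}")


@dataclass
class CohortManifest:
    """The cohort roster plus named (case N, control N) denominator pairs.

    Published carrier tables can mix denominators (a variant genotyped by
    Sanger in the full cohort versus one only visible on the NGS panel), so
    the manifest carries one denominator pair per *scope label* rather than a
    single cohort-wide N.
    """

    subjects: list[Subject]
    denominators: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        for label, (n_case, n_ctrl) in self.denominators.items():
            if n_case < 0 or n_ctrl < 0:
                raise ValueError(f"negative denominator in scope {label!r}")

    def __len__(self) -> int:
        return len(self.subjects)

    def by_id(self, subject_id: str) -> Subject:
        try:
            return self._index[subject_id]
        except AttributeError:
            self._index = {s.id: s for s in self.subjects}
            return self._index[subject_id]

    def ids(self) -> set[str]:
        return {s.id for s in self.subjects}

    def group(self, *groups: str) -> list[Subject]:
        return [s for s in self.subjects if s.cohort_group in groups]

    @property
    def cases(self) -> list[Subject]:
        return self.group("pd")

    @property
    def controls(self) -> list[Subject]:
        return self.group(*CONTROL_GROUPS)
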