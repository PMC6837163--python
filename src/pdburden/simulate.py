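"""Seeded synthetic cohort generator.

Generates a fully synthetic annotated cohort — multi-sample VCF, cohort
manifest and CNV table — with the statistical structure the analysis
assumes, so every pipeline stage can be exercised and calibrated without
external data. The default group sizes mirror the study design: 54
NGS-tested patients (plus 88 Sanger/MLPA-only), 106 non-PD neurodegenerative
patients and 124 controls.

Model, per seeded replicate:

* **Planted risk variants** — each registry variant is given a case and a
  control carrier fraction (defaults follow the published carrier counts);
  carriers are independent Bernoulli draws at the configured zygosity.
* **Planted rare damaging variants** — novel, control-absent damaging
  variants at per-group carrier fractions.
* **Background variants** — per panel gene, a Poisson number of neutral
  sites; each site gets population-frequency annotations drawn log-uniform
  over [1e-5, 0.5] (so both rare and common strata are exercised), a mixed
  consequence profile, and i.i.d. carriers at a small frequency identical
  across groups — the exchangeable null for the burden test.
* **Burden shift** — optional extra mean hits in the PD group, as
  per-subject Poisson singleton damaging variants (the planted alternative
  for power studies).
* **Age at onset** — ``clamp(Normal(mu0 + delta*hits, sigma), 25, 50)``
  where hits is the subject's planted qualifying-variant count; clamping
  (not rejection) keeps group sizes exact at the cost of edge inflation at
  extreme ``delta``. The familial label is Bernoulli with logistic
  probability increasing in hits.

Identical config and seed give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .catalog import GeneCatalog, default_catalog
from .datamodel import (
    AnnotatedVariant,
    CnvEvent,
    CohortManifest,
    GenotypeCall,
    Subject,
    VariantKey,
)
from .io import AnnotationConfig, write_cnv_table, write_manifest, write_vcf

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PlantedRisk",
    "PlantedRareDamaging",
    "SyntheticCohort",
    "generate",
    "generate_cohort",
    "recovery_report",
]


@dataclass(frozen=True)
class PlantedRisk:
    """A registry risk variant planted at known carrier fractions."""

    gene: str
    hgvs_p: str
    hgvs_c: str
    rsid: Optional[str]
    maf: float
    zygosity: str  # zygosity at which carriers are planted
    case_fraction: float
    control_fraction: float
    sanger_covered: bool  # visible in all patients, not only the NGS subset


@dataclass(frozen=True)
class PlantedRareDamaging:
    gene: str
    case_fraction: float
    control_fraction: float = 0.0
    neurodeg_fraction: float = 0.0


#: Default planted registry variants: carrier fractions equal to the
#: published carrier counts over their denominators.
DEFAULT_PLANTED_RISK = (
    PlantedRisk("GBA", "p.L483P", "c.1448T>C", "rs421016", 0.004, "het", 1 / 54, 0 / 137, False),
    PlantedRisk("GBA", "p.H294Q", "c.882T>G", "rs367968666", 0.004, "het", 1 / 54, 0 / 137, False),
    PlantedRisk("GBA", "p.E365K", "c.1093G>A", "rs2230288", 0.01, "het", 2 / 54, 1 / 137, False),
    PlantedRisk("GBA", "p.T408M", "c.1223C>T", "rs75548401", 0.004, "het", 5 / 54, 2 / 137, False),
    PlantedRisk("GBA", "p.N409S", "c.1226A>G", "rs76763715", 0.003, "het", 2 / 54, 1 / 137, False),
    PlantedRisk("LRRK2", "p.M1646T", "c.4937T>C", "rs35303786", 0.02, "het", 4 / 142, 0 / 137, True),
    PlantedRisk("LRRK2", "p.S1647T", "c.4939T>A", "rs11564148", 0.31, "hom", 21 / 142, 14 / 137, True),
    PlantedRisk("PINK1", "p.A340T", "c.1018G>A", "rs3738136", 0.05, "het", 4 / 142, 12 / 137, True),
    PlantedRisk("PINK1", "p.G411S", "c.1231G>A", "rs45478900", 0.008, "het", 2 / 142, 1 / 137, True),
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    pd_ngs: int = 54
    pd_sanger_only: int = 88
    neurodeg: int = 106
    control_healthy: int = 21
    control_nonneuro: int = 45
    control_mito: int = 58
    #: expected neutral background sites per panel gene
    background_sites_per_gene: float = 2.0
    #: expected background carriers per subject per gene (0 disables)
    background_rate: float = 0.02
    planted_risk: tuple[PlantedRisk, ...] = DEFAULT_PLANTED_RISK
    planted_rare_damaging: tuple[PlantedRareDamaging, ...] = ()
    #: onset-age model: baseline mean (years), SD, per-hit shift, window
    aoo_mu0: float = 41.0
    aoo_sigma: float = 6.9
    aoo_delta: float = -2.0
    aoo_bounds: tuple[float, float] = (25.0, 50.0)
    #: extra mean hits planted in the PD group (power studies)
    burden_shift: float = 0.0
    #: familial-label logistic model: P(familial) = sigmoid(a + b*hits)
    familial_alpha: float = -1.4
    familial_beta: float = 0.5
    plant_cnv: bool = False

    def __post_init__(self) -> None:
        for pr in self.planted_risk:
            if not (0 <= pr.case_fraction <= 1 and 0 <= pr.control_fraction <= 1):
                raise ValueError(f"planted fraction out of [0,1] for {pr.hgvs_p}")
        for pd_ in self.planted_rare_damaging:
            for f in (pd_.case_fraction, pd_.control_fraction, pd_.neurodeg_fraction):
                if not 0 <= f <= 1:
                    raise ValueError(f"planted fraction out of [0,1] for {pd_.gene}")
        for n in (self.pd_ngs, self.pd_sanger_only, self.neurodeg,
                  self.control_healthy, self.control_nonneuro, self.control_mito):
            if n < 0:
                raise ValueError("group sizes must be non-negative")


@dataclass
class GroundTruth:
    """Bookkeeping of what was planted, for recovery tests."""

    hits: dict[str, int]  # subject id -> planted qualifying-variant count
    carriers: dict[str, set[str]]  # variant key string -> carrier subject ids
    latent_aoo: dict[str, float]  # subject id -> pre-truncation onset age


@dataclass
class SyntheticCohort:
    manifest: CohortManifest
    variants: list[AnnotatedVariant]
    calls: list[GenotypeCall]
    cnv_events: list[CnvEvent]
    truth: GroundTruth


def _hgvs_pos_ref_alt(hgvs_c: str) -> tuple[int, str, str]:
    body = hgvs_c.removeprefix("c.")
    return int("".join(ch for ch in body if ch.isdigit())), body[-3], body[-1]


_BASES = ("A", "C", "G", "T")


def generate_cohort(config: GeneratorConfig, catalog: Optional[GeneCatalog] = None) -> SyntheticCohort:
    """Draw one synthetic cohort in memory (no file output)."""
    if catalog is None:
        catalog = default_catalog()
    rng = np.random.default_rng(config.seed)
    # --- subjects (ids are stable for given sizes) -------------------------
    pd_ids = [f"S{i:04d}" for i in range(1, config.pd_ngs + config.pd_sanger_only + 1)]
    ngs_pd = set(pd_ids[: config.pd_ngs])
    deg_ids = [f"N{i:04d}" for i in range(1, config.neurodeg + 1)]
    n_ctrl = config.control_healthy + config.control_nonneuro + config.control_mito
    ctrl_ids = [f"C{i:04d}" for i in range(1, n_ctrl + 1)]

    hits: dict[str, int] = {sid: 0 for sid in pd_ids}
    carriers: dict[str, set[str]] = {}
    variants: list[AnnotatedVariant] = []
    calls: list[GenotypeCall] = []

    def add_call(sid: str, key: VariantKey, zyg: str) -> None:
        calls.append(GenotypeCall(subject_id=sid, key=key, zygosity=zyg))
        carriers.setdefault(str(key), set()).add(sid)

    # --- planted registry risk variants ------------------------------------
    for pr in config.planted_risk:
        pos, ref, alt = _hgvs_pos_ref_alt(pr.hgvs_c)
        key = VariantKey(pr.gene, pos, ref, alt)
        var = AnnotatedVariant(
            key=key, gene=pr.gene, consequence="missense_variant",
            hgvs_c=pr.hgvs_c, hgvs_p=pr.hgvs_p, rsid=pr.rsid,
            predictor_votes=("tolerated", "tolerated", "tolerated"),
            pop_mafs={"gnomad": pr.maf, "kg_all": pr.maf},
        )
        variants.append(var)
        carriers.setdefault(str(key), set())
        eligible_cases = pd_ids if pr.sanger_covered else pd_ids[: config.pd_ngs]
        qualifies = True  # planted at the registry's own zygosity
        for sid in eligible_cases:
            if rng.random() < pr.case_fraction:
                add_call(sid, key, pr.zygosity)
                if qualifies:
                    hits[sid] += 1
        for sid in ctrl_ids:
            if rng.random() < pr.control_fraction:
                add_call(sid, key, pr.zygosity)

    # --- planted rare damaging variants -------------------------------------
    for idx, prd in enumerate(config.planted_rare_damaging):
        pos = 100000 + idx * 10
        key = VariantKey(prd.gene, pos, "A", "G")
        variants.append(AnnotatedVariant(
            key=key, gene=prd.gene, consequence="missense_variant",
            hgvs_c=f"c.{pos}A>G", hgvs_p=None, rsid=None,
            predictor_votes=("damaging", "damaging", "damaging"),
            pop_mafs={"gnomad": 1e-4},
        ))
        carriers.setdefault(str(key), set())
        for sid in pd_ids[: config.pd_ngs]:
            if rng.random() < prd.case_fraction:
                add_call(sid, key, "het")
                hits[sid] += 1
        for sid in deg_ids:
            if rng.random() < prd.neurodeg_fraction:
                add_call(sid, key, "het")
        for sid in ctrl_ids:
            if rng.random() < prd.control_fraction:
                add_call(sid, key, "het")

    # --- burden shift: per-subject singleton damaging variants in the PD arm
    if config.burden_shift > 0:
        panel = catalog.panel_genes
        shift_pos = 500000
        for sid in sorted(ngs_pd):
            k = rng.poisson(config.burden_shift)
            for _ in range(int(k)):
                gene = panel[int(rng.integers(len(panel)))]
                shift_pos += 1
                ref, alt = "C", "T"
                key = VariantKey(gene, shift_pos, ref, alt)
                variants.append(AnnotatedVariant(
                    key=key, gene=gene, consequence="missense_variant",
                    hgvs_c=f"c.{shift_pos}{ref}>{alt}",
                    predictor_votes=("damaging", "damaging", "damaging"),
                    pop_mafs={},
                ))
                add_call(sid, key, "het")
                hits[sid] += 1

    # --- neutral background -------------------------------------------------
    all_ids = pd_ids + deg_ids + ctrl_ids
    ngs_ids = sorted(ngs_pd) + deg_ids + ctrl_ids  # subjects with panel coverage
    if config.background_rate > 0 and config.background_sites_per_gene > 0:
        site_freq = min(0.5, config.background_rate / config.background_sites_per_gene)
        for gene in catalog.panel_genes:
            n_sites = rng.poisson(config.background_sites_per_gene)
            for s in range(int(n_sites)):
                pos = 1_000_000 + int(rng.integers(0, 900_000))
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                maf = float(np.exp(rng.uniform(np.log(1e-5), np.log(0.5))))
                u = rng.random()
                if u < 0.1:
                    csq = "stop_gained"
                    votes = ("missing", "missing", "missing")
                elif u < 0.8:
                    csq = "missense_variant"
                    votes = (("damaging",) * 3 if rng.random() < 0.3
                             else ("tolerated", "damaging", "tolerated"))
                else:
                    csq = "synonymous_variant"
                    votes = ("missing", "missing", "missing")
                key = VariantKey(gene, pos, str(ref), str(alt))
                if str(key) in carriers:
                    continue  # rare positional collision: skip
                variants.append(AnnotatedVariant(
                    key=key, gene=gene, consequence=csq,
                    hgvs_c=f"c.{pos}{ref}>{alt}",
                    predictor_votes=votes,
                    pop_mafs={"gnomad": maf, "kg_all": min(1.0, maf * 1.1)},
                ))
                carriers.setdefault(str(key), set())
                draws = rng.random(len(ngs_ids))
                hom_draws = rng.random(len(ngs_ids))
                for i in np.nonzero(draws < site_freq)[0]:
                    add_call(ngs_ids[int(i)], key, "hom" if hom_draws[i] < site_freq else "het")

    # --- CNV events ---------------------------------------------------------
    cnv_events: list[CnvEvent] = []
    if config.plant_cnv:
        sanger_pd = pd_ids[config.pd_ngs:]
        chosen = list(rng.choice(sanger_pd, size=min(5, len(sanger_pd)), replace=False))
        for sid in chosen[:4]:
            cnv_events.append(CnvEvent(sid, "PRKN", "exon 7", "duplication", "P"))
            hits[sid] += 1
        for sid in chosen[4:5]:
            cnv_events.append(CnvEvent(sid, "SNCA", "whole gene", "duplication", "P"))
            hits[sid] += 1

    # --- onset age, familial label, manifest --------------------------------
    lo, hi = config.aoo_bounds
    latent: dict[str, float] = {}
    subjects: list[Subject] = []
    for sid in pd_ids:
        h = hits[sid]
        raw = float(rng.normal(config.aoo_mu0 + config.aoo_delta * h, config.aoo_sigma))
        latent[sid] = raw
        aoo = float(min(hi, max(lo, raw)))
        p_fam = 1.0 / (1.0 + np.exp(-(config.familial_alpha + config.familial_beta * h)))
        status = "familial" if rng.random() < p_fam else "sporadic"
        sex = "m" if rng.random() < 0.55 else "f"
        assay = "ngs_panel" if sid in ngs_pd else "sanger_mlpa"
        subjects.append(Subject(id=sid, cohort_group="pd", status=status, sex=sex,
                                aoo=aoo, assay=assay))
    for sid in deg_ids:
        subjects.append(Subject(id=sid, cohort_group="neurodeg", status="not_applicable",
                                sex="m" if rng.random() < 0.5 else "f",
                                aoo=None, assay="ngs_panel"))
    groups = (["control_healthy"] * config.control_healthy
              + ["control_nonneuro"] * config.control_nonneuro
              + ["control_mito"] * config.control_mito)
    for sid, grp in zip(ctrl_ids, groups):
        subjects.append(Subject(id=sid, cohort_group=grp, status="not_applicable",
                                sex="m" if rng.random() < 0.5 else "f",
                                aoo=None, assay="wes"))
    n_pd = len(pd_ids)
    manifest = CohortManifest(
        subjects=subjects,
        denominators={"ngs": (config.pd_ngs, n_ctrl), "full": (n_pd, n_ctrl)},
    )
    truth = GroundTruth(hits=hits, carriers=carriers, latent_aoo=latent)
    return SyntheticCohort(manifest=manifest, variants=variants, calls=calls,
                           cnv_events=cnv_events, truth=truth)


def generate(
    config: GeneratorConfig,
    outdir: str | Path,
    catalog: Optional[GeneCatalog] = None,
    annotation: Optional[AnnotationConfig] = None,
) -> SyntheticCohort:
    """Generate a cohort and write VCF + manifest + CNV table to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config, catalog)
    sample_ids = [s.id for s in cohort.manifest.subjects]
    write_vcf(cohort.variants, cohort.calls, sample_ids, outdir / "cohort.vcf",
              annotation)
    write_manifest(cohort.manifest, outdir / "manifest.tsv")
    write_cnv_table(cohort.cnv_events, outdir / "cnv.tsv")
    return cohort


def recovery_report(
    truth: GroundTruth,
    variants: Sequence[AnnotatedVariant],
    calls: Sequence[GenotypeCall],
    qualifying_counts: Mapping[str, int],
) -> dict:
    """Compare pipeline outputs against the generator's bookkeeping.

    Carrier sets must match exactly (every planted carrier appears in the
    parsed genotypes). Qualifying counts are compared for the subjects in
    ``qualifying_counts``; with background disabled the match is exact, with
    background enabled spurious extra hits are possible and are reported,
    not hidden.
    """
    observed: dict[str, set[str]] = {}
    for c in calls:
        observed.setdefault(str(c.key), set()).add(c.subject_id)
    carrier_mismatches = {
        k: (sorted(v), sorted(observed.get(k, set())))
        for k, v in truth.carriers.items()
        if observed.get(k, set()) != v
    }
    count_mismatches = {
        sid: (truth.hits.get(sid, 0), n)
        for sid, n in qualifying_counts.items()
        if truth.hits.get(sid, 0) != n
    }
    return {
        "n_variants": len(variants),
        "n_carrier_mismatches": len(carrier_mismatches),
        "carrier_mismatches": carrier_mismatches,
        "n_count_mismatches": len(count_mismatches),
        "count_mismatches": count_mismatches,
        "exact": not carrier_mismatches and not count_mismatches,
    }
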