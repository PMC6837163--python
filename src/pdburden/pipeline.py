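"""End-to-end orchestration: ingest -> filter -> classify -> burden -> association.

A run is driven by a :class:`RunConfig` (usually loaded from YAML) and writes
a report bundle into the output directory:

* ``filter_report.tsv``   — per-variant consequence class, max MAF, A-D flags
* ``classification.tsv``  — per-patient architecture group and qualifying variants
* ``burden_matrix.tsv``   — per-subject burden at each filter level (NGS only)
* ``tests.json``          — Kruskal-Wallis per level and the onset-age ANOVA
* ``association.tsv``     — carrier tables, OR, CI, z, p per reported variant
* ``run_log.json``        — stage counts, seed, config echo

Stage counts in the log are non-increasing along the nested filter chains;
any module error propagates with stage context attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .assoc import carrier_table_from_calls, odds_ratio, round_half_up
from .burden import aoo_vs_count_anova, burden_comparison, burden_matrix
from .catalog import GeneCatalog, default_catalog, load_catalog
from .classify import classify_cohort, cooccurrence_count
from .datamodel import CohortManifest
from .filters import DamagingRule, FilterLevel, filter_report_rows, select_rare_damaging
from .io import (
    AnnotationConfig,
    read_annotated_vcf,
    read_cnv_table,
    read_manifest,
    write_results,
)

__all__ = ["PipelineError", "RunConfig", "run"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    vcf: str
    manifest: str
    out: str
    cnv: Optional[str] = None
    catalog: Optional[str] = None  # None -> shipped default panel
    registry: Optional[str] = None
    maf_ceiling: float = 0.01
    strict_maf: bool = True
    min_damaging_votes: int = 2
    min_damaging_fraction: float = 0.5
    candidate_as_ad: bool = True
    risk_in_count: bool = True
    scope_default: str = "ngs"
    scope_by_gene: dict = field(default_factory=dict)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ann = raw.pop("annotation", None)
        cfg = cls(**raw)
        if ann:
            cfg.annotation = AnnotationConfig(
                pop_maf_keys=ann.get("pop_maf_keys", AnnotationConfig().pop_maf_keys),
                predictor_keys=tuple(ann.get("predictor_keys", AnnotationConfig().predictor_keys)),
                predictor_vocab=ann.get("predictor_vocab", AnnotationConfig().predictor_vocab),
                clin_key=ann.get("clin_key", "CLNSIG"),
                hemizygous_as_hom=ann.get("hemizygous_as_hom", True),
            )
        return cfg

    def levels(self) -> dict[str, FilterLevel]:
        rule = DamagingRule(self.min_damaging_votes, self.min_damaging_fraction)
        return {
            lab: FilterLevel(lab, self.maf_ceiling, self.strict_maf, rule) for lab in "ABCD"
        }

    def scope_for(self, gene: str) -> str:
        return self.scope_by_gene.get(gene, self.scope_default)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run log as a dict."""
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def stage(name):
        report["stages"][name] = {}
        return report["stages"][name]

    # --- ingest -------------------------------------------------------------
    try:
        st = stage("ingest")
        catalog = (
            load_catalog(config.catalog, config.registry)
            if config.catalog
            else default_catalog()
        )
        manifest = read_manifest(config.manifest)
        variants_list, calls = read_annotated_vcf(
            config.vcf, manifest, config.annotation, catalog
        )
        cnv_events = read_cnv_table(config.cnv) if config.cnv else []
        st.update(
            n_subjects=len(manifest),
            n_pd=len(manifest.cases),
            n_controls=len(manifest.controls),
            n_variants=len(variants_list),
            n_calls=len(calls),
            n_cnv=len(cnv_events),
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc
    variants = {v.key: v for v in variants_list}

    # --- filters ------------------------------------------------------------
    try:
        st = stage("filters")
        levels = config.levels()
        rows = filter_report_rows(variants_list, catalog, levels)
        write_results(
            rows,
            outdir / "filter_report.tsv",
            precision={"max_maf": 6},
        )
        for lab in "ABCD":
            st[f"pass_{lab}"] = sum(1 for r in rows if r[f"pass_{lab}"])
        ctrl_ids = {s.id for s in manifest.controls}
        control_carriers: dict = {}
        for c in calls:
            if c.subject_id in ctrl_ids:
                control_carriers[c.key] = control_carriers.get(c.key, 0) + 1
        rare_damaging = select_rare_damaging(
            variants_list, control_carriers, catalog, levels["B"]
        )
        st["rare_damaging_selected"] = len(rare_damaging)
    except Exception as exc:
        raise PipelineError("filters", exc) from exc

    # --- classification -----------------------------------------------------
    try:
        st = stage("classification")
        classified = classify_cohort(
            [s.id for s in manifest.cases],
            calls,
            variants,
            cnv_events,
            catalog,
            control_carriers,
            levels["B"],
            config.candidate_as_ad,
        )
        counts = {
            sid: cooccurrence_count(qs, include_risk=config.risk_in_count)
            for sid, (_, qs) in classified.items()
        }
        write_results(
            [
                {
                    "subject_id": sid,
                    "group": grp,
                    "count": counts[sid],
                    "qualifying": ";".join(q.key for q in qs),
                }
                for sid, (grp, qs) in sorted(classified.items())
            ],
            outdir / "classification.tsv",
        )
        for grp in ("monogenic", "risk_only", "multi_hit", "single_het_ar", "unresolved"):
            st[grp] = sum(1 for g, _ in classified.values() if g == grp)
    except Exception as exc:
        raise PipelineError("classification", exc) from exc

    # --- burden + tests -------------------------------------------------------
    try:
        st = stage("burden")
        matrix = burden_matrix(manifest, calls, variants, catalog, list(levels.values()))
        write_results(
            [{"subject_id": sid, **row} for sid, row in sorted(matrix.items())],
            outdir / "burden_matrix.tsv",
        )
        st["n_ngs_subjects"] = len(matrix)
        st["n_excluded_non_ngs"] = len(manifest) - len(matrix)
        tests: dict = {"kruskal": {}, "anova": None}
        have_groups = (
            manifest.group("neurodeg")
            and manifest.controls
            and any(s.is_ngs for s in manifest.cases)
        )
        if have_groups:
            for lab in "ABCD":
                kw = burden_comparison(
                    manifest, {sid: row[lab] for sid, row in matrix.items()}, lab
                )
                tests["kruskal"][lab] = {
                    "H": kw.h, "p": kw.p, "group_sizes": list(kw.group_sizes)
                }
        else:
            log.info("burden comparison skipped: need control, neurodeg and PD groups")
        try:
            an = aoo_vs_count_anova(manifest.cases, counts)
            tests["anova"] = {
                "F": an.f,
                "p": an.p,
                "group_means": list(an.group_means),
                "group_sizes": list(an.group_sizes),
                "excluded_ids": list(an.excluded_ids),
            }
        except ValueError as exc:
            tests["anova"] = {"skipped": str(exc)}
        with open(outdir / "tests.json", "w") as fh:
            json.dump(tests, fh, indent=2, sort_keys=True)
        st["tests"] = tests
    except Exception as exc:
        raise PipelineError("burden", exc) from exc

    # --- association ----------------------------------------------------------
    try:
        st = stage("association")
        reportable = [
            v
            for v in variants_list
            if v.key in rare_damaging or catalog.registry_entry(v) is not None
        ]
        rows = []
        for v in sorted(reportable, key=lambda v: (v.gene, v.key.pos)):
            scope = config.scope_for(v.gene)
            if scope not in manifest.denominators:
                continue
            table = carrier_table_from_calls(v, calls, manifest, scope, catalog)
            if table.a == 0 and table.c == 0:
                continue
            res = odds_ratio(table)
            rows.append(
                {
                    "variant": str(v.key),
                    "gene": v.gene,
                    "hgvs_p": v.hgvs_p or "",
                    "scope": scope,
                    "case_carriers": f"{table.a}/{table.n_case}",
                    "control_carriers": f"{table.c}/{table.n_ctrl}",
                    "OR": round_half_up(res.or_point, 1),
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "z": res.z,
                    "p": round_half_up(res.p, 2),
                    "corrected": res.corrected,
                }
            )
        write_results(
            rows,
            outdir / "association.tsv",
            precision={"OR": 1, "ci_low": 2, "ci_high": 2, "z": 2, "p": 2},
        )
        st["n_rows"] = len(rows)
    except Exception as exc:
        raise PipelineError("association", exc) from exc

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
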