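"""Variant burden computation and the two group-comparison tests.

Oracles here are independent closed forms: the Kruskal-Wallis H is
recomputed from the rank formula with explicit tie correction, and the
ANOVA F from raw between/within sums of squares — neither goes through
scipy.
"""

import math

import numpy as np
import pytest

from pdburden.burden import (
    aoo_vs_count_anova,
    burden_comparison,
    burden_matrix,
    subject_burden,
)
from pdburden.datamodel import (
    AnnotatedVariant,
    CohortManifest,
    GenotypeCall,
    Subject,
    VariantKey,
)
from pdburden.filters import FilterLevel


def make_variant(gene, pos, maf, votes=("damaging",) * 3, consequence="missense_variant"):
    return AnnotatedVariant(
        key=VariantKey(gene, pos, "A", "G"), gene=gene, consequence=consequence,
        pop_mafs={"gnomad": maf}, predictor_votes=votes,
    )


def ngs_subject(sid, group="pd"):
    return Subject(id=sid, cohort_group=group, aoo=40.0 if group == "pd" else None,
                   assay="ngs_panel")


# --- independent oracles ----------------------------------------------------

def kruskal_h_oracle(groups):
    """Rank-formula H with tie correction, computed from first principles."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start:start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    from collections import Counter

    ties = sum(t ** 3 - t for t in Counter(pooled).values())
    correction = 1 - ties / (n ** 3 - n)
    return h / correction


def anova_f_oracle(groups):
    """One-way fixed-effects F from raw sums of squares."""
    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestSubjectBurden:
    def test_het_plus_hom_is_three_hits(self, catalog):
        v1 = make_variant("GBA", 100, 0.001)
        v2 = make_variant("PRKN", 200, 0.001)
        variants = {v1.key: v1, v2.key: v2}
        calls = [GenotypeCall("P1", v1.key, "het"), GenotypeCall("P1", v2.key, "hom")]
        res = subject_burden(ngs_subject("P1"), calls, variants, FilterLevel("A"), catalog)
        assert res.burden == 3

    def test_no_passing_calls_is_zero(self, catalog):
        v = make_variant("GBA", 100, 0.2)  # common -> fails every level
        res = subject_burden(ngs_subject("P1"), [GenotypeCall("P1", v.key, "hom")],
                             {v.key: v}, FilterLevel("A"), catalog)
        assert res.burden == 0

    def test_non_panel_gene_never_counts(self, catalog):
        v = make_variant("NOT_A_PANEL_GENE", 100, 0.001)
        res = subject_burden(ngs_subject("P1"), [GenotypeCall("P1", v.key, "het")],
                             {v.key: v}, FilterLevel("A"), catalog)
        assert res.burden == 0

    def test_sanger_only_subject_is_an_error(self, catalog):
        subj = Subject(id="P1", cohort_group="pd", aoo=40.0, assay="sanger_mlpa")
        with pytest.raises(ValueError, match="non-NGS"):
            subject_burden(subj, [], {}, FilterLevel("A"), catalog)

    def test_matches_bruteforce_double_loop(self, catalog):
        """200 random subjects vs explicit (call, filter) double loop."""
        from pdburden.filters import passes_filter

        rng = np.random.default_rng(7)
        genes = ["GBA", "LRRK2", "PRKN", "CP", "PANEL050", "OFF_PANEL"]
        pool = [make_variant(genes[int(rng.integers(len(genes)))], 100 + i,
                             float(rng.choice([1e-4, 5e-3, 0.02, 0.3])),
                             votes=tuple(rng.choice(["damaging", "tolerated"], 3)))
                for i in range(60)]
        variants = {v.key: v for v in pool}
        levels = {lab: FilterLevel(lab) for lab in "ABCD"}
        for i in range(200):
            sid = f"S{i}"
            picks = rng.choice(60, size=int(rng.integers(0, 8)), replace=False)
            calls = [GenotypeCall(sid, pool[j].key,
                                  "hom" if rng.random() < 0.2 else "het")
                     for j in picks]
            for lab, lev in levels.items():
                got = subject_burden(ngs_subject(sid), calls, variants, lev, catalog).burden
                want = 0
                for c in calls:  # brute force
                    v = variants[c.key]
                    if catalog.is_panel(v.gene) and passes_filter(v, lev, catalog):
                        want += 2 if c.zygosity == "hom" else 1
                assert got == want

    def test_burden_nesting_across_levels(self, catalog):
        rng = np.random.default_rng(11)
        genes = ["GBA", "LRRK2", "PRKN", "CP", "SPG11"]
        pool = [make_variant(genes[i % 5], 100 + i, float(rng.choice([1e-4, 0.02])),
                             votes=tuple(rng.choice(["damaging", "tolerated"], 3)))
                for i in range(40)]
        variants = {v.key: v for v in pool}
        for i in range(50):
            sid = f"S{i}"
            calls = [GenotypeCall(sid, v.key, "het")
                     for v in rng.choice(pool, size=6, replace=False)]
            b = {lab: subject_burden(ngs_subject(sid), calls, variants,
                                     FilterLevel(lab), catalog).burden
                 for lab in "ABCD"}
            assert b["D"] <= b["B"] <= b["A"]
            assert b["D"] <= b["C"] <= b["A"]


def three_group_manifest(n_ctrl, n_deg, n_pd):
    subjects = (
        [ngs_subject(f"C{i}", "control_healthy") for i in range(n_ctrl)]
        + [ngs_subject(f"N{i}", "neurodeg") for i in range(n_deg)]
        + [ngs_subject(f"P{i}", "pd") for i in range(n_pd)]
    )
    return CohortManifest(subjects=subjects)


class TestKruskal:
    def test_constant_burden_gives_h0_p1(self):
        m = three_group_manifest(3, 3, 3)
        burdens = {s.id: 2 for s in m.subjects}
        res = burden_comparison(m, burdens)
        assert res.h == 0.0 and res.p == 1.0

    def test_matches_rank_formula_oracle(self):
        m = three_group_manifest(3, 3, 3)
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        burdens = {}
        for prefix, vals in zip("CNP", groups):
            for i, v in enumerate(vals):
                burdens[f"{prefix}{i}"] = v
        res = burden_comparison(m, burdens)
        assert res.h == pytest.approx(kruskal_h_oracle(groups), rel=1e-12)
        assert res.group_sizes == (3, 3, 3)

    def test_matches_oracle_with_heavy_ties(self):
        rng = np.random.default_rng(3)
        m = three_group_manifest(20, 20, 20)
        burdens = {s.id: int(rng.integers(0, 4)) for s in m.subjects}
        groups = [[burdens[f"C{i}"] for i in range(20)],
                  [burdens[f"N{i}"] for i in range(20)],
                  [burdens[f"P{i}"] for i in range(20)]]
        res = burden_comparison(m, burdens)
        assert res.h == pytest.approx(kruskal_h_oracle(groups), rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        m = three_group_manifest(15, 15, 15)
        burdens = {s.id: int(rng.integers(0, 5)) for s in m.subjects}
        res1 = burden_comparison(m, burdens)
        res2 = burden_comparison(m, {k: v * 10 + 3 for k, v in burdens.items()})
        assert res1.h == pytest.approx(res2.h, rel=1e-12)
        assert res1.p == pytest.approx(res2.p, rel=1e-12)

    def test_empty_group_is_error(self):
        m = three_group_manifest(3, 0, 3)
        with pytest.raises(ValueError, match="non-empty"):
            burden_comparison(m, {s.id: 1 for s in m.subjects})

    def test_non_ngs_subjects_excluded(self):
        m = three_group_manifest(3, 3, 3)
        sanger = Subject(id="PX", cohort_group="pd", aoo=40.0, assay="sanger_mlpa")
        m2 = CohortManifest(subjects=m.subjects + [sanger])
        burdens = {s.id: i % 3 for i, s in enumerate(m.subjects)}
        res = burden_comparison(m2, burdens)
        assert sum(res.group_sizes) == 9


class TestAnova:
    def test_equal_means_give_f0(self):
        subjects = []
        counts = {}
        for k, vals in enumerate([[40, 42], [40, 42], [40, 42]]):
            for i, v in enumerate(vals):
                sid = f"S{k}_{i}"
                subjects.append(Subject(id=sid, cohort_group="pd", aoo=float(v)))
                counts[sid] = k
        res = aoo_vs_count_anova(subjects, counts)
        assert res.f == pytest.approx(0.0, abs=1e-12)

    def test_matches_sum_of_squares_oracle(self):
        groups = [[40, 42], [35, 37], [30, 32]]
        subjects, counts = [], {}
        for k, vals in enumerate(groups):
            for i, v in enumerate(vals):
                sid = f"S{k}_{i}"
                subjects.append(Subject(id=sid, cohort_group="pd", aoo=float(v)))
                counts[sid] = k
        res = aoo_vs_count_anova(subjects, counts)
        assert res.f == pytest.approx(anova_f_oracle(groups), rel=1e-12)
        assert res.group_means == (41.0, 36.0, 31.0)

    def test_triple_carrier_excluded_from_all_groups(self):
        subjects, counts = [], {}
        for k in (0, 0, 1, 1, 2, 2, 3):
            sid = f"S{len(subjects)}"
            subjects.append(Subject(id=sid, cohort_group="pd", aoo=30.0 + len(subjects)))
            counts[sid] = k
        res = aoo_vs_count_anova(subjects, counts)
        assert res.excluded_ids == ("S6",)
        assert sum(res.group_sizes) == 6

    def test_single_group_is_error(self):
        subjects = [Subject(id="S1", cohort_group="pd", aoo=40.0),
                    Subject(id="S2", cohort_group="pd", aoo=41.0)]
        with pytest.raises(ValueError):
            aoo_vs_count_anova(subjects, {"S1": 0, "S2": 0})


def test_burden_matrix_skips_sanger_subjects(fixture_cohort, catalog):
    fx = fixture_cohort
    variants = {v.key: v for v in fx.variants}
    matrix = burden_matrix(fx.manifest, fx.calls, variants, catalog)
    # 54 NGS patients + 137 exome controls
    assert len(matrix) == 54 + 137
    for row in matrix.values():
        assert row["D"] <= row["B"] <= row["A"]
        assert row["D"] <= row["C"] <= row["A"]
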