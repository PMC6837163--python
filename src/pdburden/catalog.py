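"""Gene panel catalog: membership, inheritance mode, core-PD flag and the
registry of previously published risk variants.

The shipped default catalog covers a 127-gene neurodegeneration panel. The
genes with a documented role in Parkinsonism carry real symbols and curated
inheritance modes; the remainder of the panel is filled with placeholder
symbols (``PANEL###``) so that panel-wide bookkeeping (e.g. the burden
denominator of 127 genes) is exercised realistically. Users can replace the
catalog with their own TSV.

The risk registry holds susceptibility variants previously published for PD,
each with a required zygosity: a variant only counts as a registry hit when
carried at (at least) that zygosity. Matching is by rsid or protein-level
HGVS, whichever is available.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .datamodel import AnnotatedVariant

__all__ = [
    "GeneCatalog",
    "GeneEntry",
    "RiskVariantEntry",
    "default_catalog",
    "load_catalog",
]

INHERITANCE_MODES = ("AD", "AR", "risk_only", "candidate")

#: The 17 genes linked to Mendelian Parkinsonism in OMIM/GeneReviews.
CORE_PD_GENES = (
    "GBA", "LRRK2", "PARK7", "PINK1", "PRKN", "SNCA", "VPS13C", "VPS35",
    "ATP13A2", "DNAJC6", "FBXO7", "SLC6A3", "SYNJ1", "DNAJC13", "CHCHD2",
    "PLA2G6", "EIF4G1",
)


@dataclass(frozen=True)
class GeneEntry:
    symbol: str
    inheritance: str
    core_pd: bool = False
    panel_member: bool = False

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        if self.core_pd and not self.panel_member:
            raise ValueError(f"core PD gene {self.symbol} must be a panel member")


@dataclass(frozen=True)
class RiskVariantEntry:
    gene: str
    hgvs_p: Optional[str] = None
    rsid: Optional[str] = None
    risk_zygosity: str = "het"

    def __post_init__(self) -> None:
        if self.hgvs_p is None and self.rsid is None:
            raise ValueError("registry entry needs at least one match key (hgvs_p or rsid)")
        if self.risk_zygosity not in ("het", "hom", "any"):
            raise ValueError(f"unknown risk zygosity {self.risk_zygosity!r}")

    def matches(self, variant: AnnotatedVariant) -> bool:
        if variant.gene != self.gene:
            return False
        if self.rsid is not None and variant.rsid is not None and variant.rsid == self.rsid:
            return True
        if self.hgvs_p is not None and variant.hgvs_p is not None:
            return _norm_hgvs_p(variant.hgvs_p) == _norm_hgvs_p(self.hgvs_p)
        return False

    def zygosity_ok(self, zygosity: str) -> bool:
        if self.risk_zygosity == "any":
            return True
        if self.risk_zygosity == "het":
            # a het-risk allele carried hom still exposes the risk allele
            return zygosity in ("het", "hom")
        return zygosity == "hom"


def _norm_hgvs_p(h: str) -> str:
    return h.removeprefix("p.").replace("(", "").replace(")", "").upper()


class GeneCatalog:
    """Panel membership, inheritance and the risk-variant registry.

    Lookup is total: an unknown symbol yields a non-panel candidate entry, so
    downstream code never branches on missing genes.
    """

    def __init__(self, genes: Iterable[GeneEntry], registry: Iterable[RiskVariantEntry] = ()):
        self._genes: dict[str, GeneEntry] = {}
        for g in genes:
            if g.symbol in self._genes:
                raise ValueError(f"duplicate gene symbol {g.symbol}")
            self._genes[g.symbol] = g
        self.registry: list[RiskVariantEntry] = list(registry)

    def __len__(self) -> int:
        return len(self._genes)

    @property
    def panel_size(self) -> int:
        return sum(1 for g in self._genes.values() if g.panel_member)

    @property
    def panel_genes(self) -> list[str]:
        return sorted(s for s, g in self._genes.items() if g.panel_member)

    @property
    def core_genes(self) -> set[str]:
        return {s for s, g in self._genes.items() if g.core_pd}

    def lookup(self, symbol: str) -> GeneEntry:
        return self._genes.get(
            symbol, GeneEntry(symbol, "candidate", core_pd=False, panel_member=False)
        )

    def is_core(self, symbol: str) -> bool:
        return self.lookup(symbol).core_pd

    def is_panel(self, symbol: str) -> bool:
        return self.lookup(symbol).panel_member

    def registry_entry(self, variant: AnnotatedVariant) -> Optional[RiskVariantEntry]:
        for entry in self.registry:
            if entry.matches(variant):
                return entry
        return None

    def is_registry_risk(self, variant: AnnotatedVariant, zygosity: str) -> bool:
        """True when the variant matches a registry entry at sufficient zygosity."""
        entry = self.registry_entry(variant)
        return entry is not None and entry.zygosity_ok(zygosity)


def _read_tsv(path_or_text) -> list[dict]:
    if hasattr(path_or_text, "read"):
        rows = csv.DictReader(path_or_text, delimiter="\t")
        return list(rows)
    with open(path_or_text, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


_BOOL = {"true": True, "1": True, "false": False, "0": False}


def load_catalog(
    genes_path: Union[str, Path], registry_path: Optional[Union[str, Path]] = None
) -> GeneCatalog:
    """Load a catalog from a gene TSV (symbol, inheritance, core_pd,
    panel_member) and an optional registry TSV (gene, hgvs_p, rsid,
    risk_zygosity). Empty registry cells mean "not available"."""
    genes = [
        GeneEntry(
            symbol=row["symbol"],
            inheritance=row["inheritance"],
            core_pd=_BOOL[row["core_pd"].strip().lower()],
            panel_member=_BOOL[row["panel_member"].strip().lower()],
        )
        for row in _read_tsv(genes_path)
    ]
    registry: list[RiskVariantEntry] = []
    if registry_path is not None:
        registry = [
            RiskVariantEntry(
                gene=row["gene"],
                hgvs_p=row.get("hgvs_p") or None,
                rsid=row.get("rsid") or None,
                risk_zygosity=row.get("risk_zygosity") or "het",
            )
            for row in _read_tsv(registry_path)
        ]
    return GeneCatalog(genes, registry)


def default_catalog() -> GeneCatalog:
    """The shipped 127-gene panel and nine-variant risk registry."""
    data = resources.files("pdburden.data")
    with resources.as_file(data / "gene_panel.tsv") as gp, resources.as_file(
        data / "risk_registry.tsv"
    ) as rr:
        return load_catalog(gp, rr)
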