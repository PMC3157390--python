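"""Curation of a published-association catalog into a testable SNP list.

The pipeline mirrors how replication panels are assembled from the NHGRI
GWAS catalog: significance and reporting filters, deduplication by study
size, LD pruning within phenotypes, proxy selection against the genotyping
platform, and a strand sanity check for ambiguous (A/T, C/G) variants.

Pipeline order: filter -> deduplicate -> prune_ld -> select_proxy ->
check_strand; :func:`curate` runs all five and records a reason for every
dropped or review-flagged entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "CatalogEntry",
    "LDTable",
    "PlatformManifest",
    "CuratedAssociation",
    "filter_entries",
    "deduplicate",
    "prune_ld",
    "select_proxy",
    "check_strand",
    "curate",
    "CurationReport",
]

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


@dataclass(frozen=True)
class CatalogEntry:
    """One published SNP-trait association as catalogued."""

    snp_id: str
    phenotype: str
    risk_allele: str
    other_allele: str
    raf_controls: float | None
    effect: float | None
    trait_type: str  # binary | quantitative
    p_value: float
    ancestry: str
    study_id: str
    n_cases: int = 0
    n_controls: int = 0
    single_snp: bool = True
    includes_this_cohort: bool = False

    def __post_init__(self) -> None:
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: risk and other allele identical")
        if self.trait_type == "binary" and self.effect is not None and self.effect <= 0:
            raise ValueError(f"{self.snp_id}: odds ratio must be positive")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"{self.snp_id}: p-value {self.p_value} outside (0,1]")

    @property
    def direction(self) -> str:
        """Published direction on the risk-allele scale: '+' unless the
        effect indicates protection (OR<1 or beta<0)."""
        if self.effect is None:
            return "+"
        if self.trait_type == "binary":
            return "+" if self.effect >= 1.0 else "-"
        return "+" if self.effect >= 0.0 else "-"


class LDTable:
    """Symmetric pairwise r-squared lookup; absent pairs are independent."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._pairs: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must be in [0,1], got {r2} for ({a},{b})")
        if a != b:
            self._pairs[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)), 0.0)

    def partners(self, snp: str):
        for pair, r2 in self._pairs.items():
            if snp in pair:
                (other,) = pair - {snp}
                yield other, r2


@dataclass(frozen=True)
class PlatformManifest:
    """SNPs assayed on the genotyping platform and their call rates."""

    call_rate: Mapping[str, float]

    @property
    def snp_ids(self) -> frozenset:
        return frozenset(self.call_rate)

    def callable(self, snp: str, call_min: float = 0.99) -> bool:
        return self.call_rate.get(snp, 0.0) >= call_min


@dataclass(frozen=True)
class CuratedAssociation:
    source: CatalogEntry
    test_snp: str
    proxy_r2: float
    strand_status: str  # confirmed | manual_review | undetermined

    def __post_init__(self) -> None:
        if self.proxy_r2 < 0.5 or self.proxy_r2 > 1.0:
            raise ValueError("proxy_r2 must be in [0.5, 1]")


@dataclass
class CurationReport:
    curated: list = field(default_factory=list)
    dropped: list = field(default_factory=list)  # (entry, reason)
    review: list = field(default_factory=list)  # CuratedAssociation needing manual strand check


def filter_entries(
    entries: Iterable[CatalogEntry],
    p_max: float = 1e-7,
    ancestry_label: str = "European",
) -> list[CatalogEntry]:
    """Keep genome-wide-significant (p <= p_max), effect-reporting,
    single-SNP, matching-ancestry entries from studies that did not include
    this cohort."""
    kept = []
    for e in entries:
        if e.p_value > p_max:
            continue
        if e.effect is None:
            continue
        if not e.single_snp:
            continue
        if e.ancestry != ancestry_label:
            continue
        if e.includes_this_cohort:
            continue
        kept.append(e)
    return kept


def _dedup_key(e: CatalogEntry):
    # survivor ordering: most cases, then smallest p, then study id
    return (-e.n_cases, e.p_value, e.study_id)


def deduplicate(entries: Iterable[CatalogEntry]) -> list[CatalogEntry]:
    """One entry per (snp, phenotype), keeping the study with the most
    cases (ties: smaller p, then lexicographic study id)."""
    groups: dict[tuple[str, str], list[CatalogEntry]] = {}
    order: list[tuple[str, str]] = []
    for e in entries:
        key = (e.snp_id, e.phenotype)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(e)
    return [min(groups[k], key=_dedup_key) for k in order]


def prune_ld(
    entries: Iterable[CatalogEntry],
    ld: LDTable,
    r2_block: float = 0.1,
) -> list[CatalogEntry]:
    """Keep one association per LD block and phenotype.

    Blocks are connected components of the graph joining SNPs with
    r^2 >= r2_block.  Within a block reported by a single study the
    smallest-p entry survives; across studies the entry with the most
    cases survives (ties as in deduplication).
    """
    entries = list(entries)
    by_pheno: dict[str, list[CatalogEntry]] = {}
    for e in entries:
        by_pheno.setdefault(e.phenotype, []).append(e)
    survivors: set[int] = set()
    for pheno_entries in by_pheno.values():
        g = nx.Graph()
        g.add_nodes_from(e.snp_id for e in pheno_entries)
        snps = [e.snp_id for e in pheno_entries]
        for i, a in enumerate(snps):
            for b in snps[i + 1 :]:
                if ld.r2(a, b) >= r2_block:
                    g.add_edge(a, b)
        by_snp = {e.snp_id: e for e in pheno_entries}
        for comp in nx.connected_components(g):
            members = [by_snp[s] for s in comp]
            if len({m.study_id for m in members}) == 1:
                best = min(members, key=lambda m: (m.p_value, m.snp_id))
            else:
                best = min(members, key=_dedup_key)
            survivors.add(id(best))
    return [e for e in entries if id(e) in survivors]


def select_proxy(
    entry: CatalogEntry,
    platform: PlatformManifest,
    ld: LDTable,
    r2_proxy: float = 0.5,
    call_min: float = 0.99,
) -> CuratedAssociation | None:
    """Assign the test SNP: the reported SNP itself if well-called on the
    platform, else the best available proxy with r^2 >= r2_proxy, else None
    (association untestable)."""
    if platform.callable(entry.snp_id, call_min):
        return CuratedAssociation(entry, entry.snp_id, 1.0, "manual_review")
    candidates = [
        (r2, snp)
        for snp, r2 in ld.partners(entry.snp_id)
        if r2 >= r2_proxy and platform.callable(snp, call_min)
    ]
    if not candidates:
        return None
    best_r2, best_snp = max(candidates, key=lambda t: (t[0], t[1]))
    # ties on r2 break to lexicographically last id via the max key; make
    # the choice explicit and deterministic: highest r2, then smallest id
    ties = sorted(snp for r2, snp in candidates if r2 == best_r2)
    return CuratedAssociation(entry, ties[0], best_r2, "manual_review")


def check_strand(
    entry: CatalogEntry,
    reference_freq: float | None,
    unresolvable: bool = False,
) -> str:
    """Strand sanity status from a reference-panel risk-allele frequency.

    Ambiguous allele pairs (A/T, C/G) and entries without reference data go
    to manual review; unambiguous SNPs are confirmed when the reported and
    reference frequencies are both below 0.35 or both above 0.65.
    ``unresolvable`` marks entries whose risk allele could not be
    determined even manually; they are excluded from testing.
    """
    for a in (entry.risk_allele, entry.other_allele):
        if a not in _VALID_ALLELES:
            raise ValueError(f"invalid allele {a!r} for {entry.snp_id}")
    if unresolvable:
        return "undetermined"
    if frozenset((entry.risk_allele, entry.other_allele)) in _AMBIGUOUS_PAIRS:
        return "manual_review"
    if reference_freq is None or entry.raf_controls is None:
        return "manual_review"
    raf, ref = entry.raf_controls, reference_freq
    if (raf < 0.35 and ref < 0.35) or (raf > 0.65 and ref > 0.65):
        return "confirmed"
    return "manual_review"


def curate(
    entries: Iterable[CatalogEntry],
    ld: LDTable,
    platform: PlatformManifest,
    reference_freqs: Mapping[str, float] | None = None,
    unresolvable: Iterable[str] = (),
    p_max: float = 1e-7,
    r2_block: float = 0.1,
    r2_proxy: float = 0.5,
    call_min: float = 0.99,
    ancestry_label: str = "European",
) -> CurationReport:
    """Full curation pipeline with per-entry drop reasons."""
    entries = list(entries)
    reference_freqs = reference_freqs or {}
    unresolvable = set(unresolvable)
    report = CurationReport()

    stage1 = filter_entries(entries, p_max=p_max, ancestry_label=ancestry_label)
    kept_ids = {id(e) for e in stage1}
    for e in entries:
        if id(e) not in kept_ids:
            report.dropped.append((e, "filtered"))

    stage2 = deduplicate(stage1)
    kept_ids = {id(e) for e in stage2}
    for e in stage1:
        if id(e) not in kept_ids:
            report.dropped.append((e, "duplicate"))

    stage3 = prune_ld(stage2, ld, r2_block=r2_block)
    kept_ids = {id(e) for e in stage3}
    for e in stage2:
        if id(e) not in kept_ids:
            report.dropped.append((e, "ld_pruned"))

    for e in stage3:
        cur = select_proxy(e, platform, ld, r2_proxy=r2_proxy, call_min=call_min)
        if cur is None:
            report.dropped.append((e, "no_proxy"))
            continue
        status = check_strand(e, reference_freqs.get(e.snp_id), e.snp_id in unresolvable)
        cur = CuratedAssociation(cur.source, cur.test_snp, cur.proxy_r2, status)
        if status == "undetermined":
            report.dropped.append((e, "strand_undetermined"))
        elif status == "manual_review":
            report.review.append(cur)
            report.curated.append(cur)
        else:
            report.curated.append(cur)
    return report
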