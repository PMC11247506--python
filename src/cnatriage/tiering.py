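"""Group assignment (1I / 1G / 2G / 2I / 3 / 4) and consensus fly orthology.

Surviving genes are prioritized for functional testing by where they sit in
the region catalogs and how strong their within-region evidence is:

* **2G** — the gene belongs to at least one amplification and at least one
  deletion across the catalogs; the TNBC-specific direction resolves the
  discrepancy and sets the role.
* **2I** — the gene belongs only to ISAR amplifications yet is deleted more
  often in TNBC; tested as a tumor suppressor (weaker evidence class).
* **1I** — ISAR member within the top Helios slots of its region.
* **1G** — GISTIC-only member with (1) significant positive copy-number /
  expression concordance, (2) an alteration-frequency rank within the top 3
  (regions of <= 12 genes) or top quartile (larger), and (3) a small (< 10
  gene) region.
* **3** — ISAR members in the extended Helios slice, or GISTIC members
  failing exactly one 1G condition.
* **4** — everything else.

Discrepancy classes take precedence over Group 1 (candidates with
inter-catalog disagreement are demoted to Group 2), hence the order
2G > 2I > 1I > 1G > 3 > 4.  Roles follow the TNBC direction: amplified =
oncogene, deleted = tumor suppressor.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cnatriage.core_io import CNARegionDef
from cnatriage.copy_number import AMP, DEL
from cnatriage.driver_filter import (
    AMPLIFIED,
    DELETED,
    NEGATIVE_SIG,
    POSITIVE_SIG,
    ConcordanceResult,
    DirectionCall,
)

G1I, G1G, G2G, G2I, G3, G4 = "G1I", "G1G", "G2G", "G2I", "G3", "G4"
ONCOGENE, TUMOR_SUPPRESSOR, BOTH = "oncogene", "tumor_suppressor", "both"

K_SMALL_DEFAULT = 3
QUARTILE_THRESHOLD_DEFAULT = 12
SMALL_REGION_MAX = 10  # 1G requires < 10-gene regions
HELIOS_TOP_K_DEFAULT = 3  # "top 1-3 by Helios" implemented as configurable top-k


@dataclass(frozen=True)
class GenePrioritization:
    symbol: str
    group: str
    role: str
    tnbc_direction: str
    region_ids: tuple[str, ...]
    helios_rank: int | None = None
    alt_freq_rank: int | None = None


@dataclass(frozen=True)
class OrthologCall:
    symbol: str
    fly_gene: str | None
    votes: Mapping[str, str]
    status: str  # unique | consensus | ambiguous | none


def rank_by_helios(region: CNARegionDef) -> list[str]:
    """Region members ordered by descending Helios score, ties lexicographic."""
    if region.helios is None or not region.helios:
        raise ValueError(f"region {region.region_id} has no Helios scores")
    scored = [m for m in region.members if m in region.helios]
    return sorted(scored, key=lambda g: (-region.helios[g], g))


def top_slice(
    region_size: int,
    k_small: int = K_SMALL_DEFAULT,
    quartile_threshold: int = QUARTILE_THRESHOLD_DEFAULT,
) -> int:
    """Number of top within-region slots: top 3 for small regions, top quartile above."""
    if region_size < 1:
        raise ValueError("region_size must be >= 1")
    if region_size <= quartile_threshold:
        return min(region_size, k_small)
    return math.ceil(region_size / 4)


def rank_by_alteration_frequency(
    region: CNARegionDef,
    calls: pd.DataFrame,
    samples: Sequence[str],
) -> list[str]:
    """Region members ordered by descending amp+del frequency among ``samples``."""
    present = [m for m in region.members if m in calls.index]
    cols = [s for s in samples if s in calls.columns]
    freqs = {}
    for gene in present:
        row = calls.loc[gene, cols]
        n_called = int((row != "").sum())
        n_alt = int(((row == AMP) | (row == DEL)).sum())
        freqs[gene] = n_alt / n_called if n_called else 0.0
    return sorted(present, key=lambda g: (-freqs[g], g))


@dataclass
class GeneEvidence:
    """Per-gene inputs to group assignment, assembled from the filter stage."""

    symbol: str
    tnbc_direction: str  # amplified | deleted
    concordance_relation: str
    regions: list[CNARegionDef] = field(default_factory=list)
    helios_rank: int | None = None  # best (1-based) rank across ISAR regions
    helios_top: bool = False  # within top-k Helios slots of some ISAR region
    helios_extended: bool = False  # within the extended (top-3/quartile) slice
    alt_freq_rank: int | None = None
    alt_freq_top: bool = False  # within top slice by alteration frequency
    in_small_region: bool = False  # some GISTIC region with < 10 genes


def assign_group(evidence: GeneEvidence) -> GenePrioritization:
    """Assign one surviving gene to its priority group.

    Precedence: 2G > 2I > 1I > 1G > 3 > 4 (see module docstring).  The
    assignment depends only on the gene's own evidence, so it is independent
    of the order genes are processed in.
    """
    if not evidence.regions:
        raise ValueError(f"gene {evidence.symbol} has no region membership")
    sources = {r.source for r in evidence.regions}
    isar_only = all(s.is_isar for s in sources)
    gistic_only = not any(s.is_isar for s in sources)
    in_amp = any(r.nominal_type == "amp" for r in evidence.regions)
    in_del = any(r.nominal_type == "del" for r in evidence.regions)

    role = ONCOGENE if evidence.tnbc_direction == AMPLIFIED else TUMOR_SUPPRESSOR

    # positive copy-number/expression relationship: expression moves *with*
    # copy number — higher in amplified carriers, lower in deleted carriers
    # (relation is coded relative to the altered group)
    concordant = (
        evidence.concordance_relation == POSITIVE_SIG
        if evidence.tnbc_direction == AMPLIFIED
        else evidence.concordance_relation == NEGATIVE_SIG
    )
    g1g_conditions = (
        concordant,
        evidence.alt_freq_top,
        evidence.in_small_region,
    )

    if in_amp and in_del:
        group = G2G
    elif isar_only and evidence.tnbc_direction == DELETED:
        group = G2I
    elif any(s.is_isar for s in sources) and evidence.helios_top:
        group = G1I
    elif gistic_only and all(g1g_conditions):
        group = G1G
    elif any(s.is_isar for s in sources) and evidence.helios_extended:
        group = G3
    elif gistic_only and sum(not c for c in g1g_conditions) == 1:
        group = G3
    else:
        group = G4

    return GenePrioritization(
        symbol=evidence.symbol,
        group=group,
        role=role,
        tnbc_direction=evidence.tnbc_direction,
        region_ids=tuple(r.region_id for r in evidence.regions),
        helios_rank=evidence.helios_rank,
        alt_freq_rank=evidence.alt_freq_rank,
    )


def build_evidence(
    symbol: str,
    regions: Sequence[CNARegionDef],
    direction: DirectionCall,
    concordance: ConcordanceResult,
    calls: pd.DataFrame,
    rank_samples: Sequence[str],
    helios_top_k: int = HELIOS_TOP_K_DEFAULT,
) -> GeneEvidence:
    """Assemble the group-assignment evidence for one gene.

    ``rank_samples`` are the samples used for alteration-frequency ranks
    (TNBC tumors by default, consistent with the TNBC-specific direction).
    """
    member_regions = [r for r in regions if symbol in r.members]
    ev = GeneEvidence(
        symbol=symbol,
        tnbc_direction=direction.direction,
        concordance_relation=concordance.relation,
        regions=member_regions,
    )
    for reg in member_regions:
        size = len(reg.members)
        if reg.source.is_isar and reg.helios:
            order = rank_by_helios(reg)
            if symbol in order:
                rank = order.index(symbol) + 1
                if ev.helios_rank is None or rank < ev.helios_rank:
                    ev.helios_rank = rank
                if rank <= min(helios_top_k, size):
                    ev.helios_top = True
                if rank <= top_slice(size):
                    ev.helios_extended = True
        if not reg.source.is_isar:
            order = rank_by_alteration_frequency(reg, calls, rank_samples)
            if symbol in order:
                rank = order.index(symbol) + 1
                if ev.alt_freq_rank is None or rank < ev.alt_freq_rank:
                    ev.alt_freq_rank = rank
                if rank <= top_slice(size):
                    ev.alt_freq_top = True
            if size < SMALL_REGION_MAX:
                ev.in_small_region = True
    return ev


def prioritize_genes(
    directions: Mapping[str, DirectionCall],
    concordance: Mapping[str, ConcordanceResult],
    regions: Sequence[CNARegionDef],
    calls: pd.DataFrame,
    rank_samples: Sequence[str],
    helios_top_k: int = HELIOS_TOP_K_DEFAULT,
) -> dict[str, GenePrioritization]:
    """Group assignment for every retained gene with region membership."""
    membership: dict[str, list[CNARegionDef]] = {}
    for reg in regions:
        for gene in reg.members:
            membership.setdefault(gene, []).append(reg)
    out: dict[str, GenePrioritization] = {}
    for gene, conc in concordance.items():
        if not conc.retained or gene not in membership:
            continue
        d = directions[gene]
        if d.direction not in (AMPLIFIED, DELETED):
            continue
        ev = build_evidence(
            gene, membership[gene], d, conc, calls, rank_samples, helios_top_k
        )
        out[gene] = assign_group(ev)
    return out


# ---------------------------------------------------------------------------
# consensus orthology

ORTHOLOG_SOURCES = ("DroID", "DIOPT", "HomoloGene", "Ensembl", "OrthoDB")


def consensus_ortholog(
    symbol: str,
    source_tables: Mapping[str, pd.DataFrame],
) -> OrthologCall:
    """Strict-majority vote over the top-scoring candidate of each source.

    Each source table has columns ``human``, ``fly`` and optionally ``score``;
    the top-scoring fly gene per source casts that source's vote.  A strict
    majority of the voting sources fixes the ortholog (``unique`` when all
    voters agree); without one the call is ``ambiguous`` and the gene is not
    testable; with no candidate anywhere the call is ``none``.
    """
    if not source_tables:
        raise ValueError("at least one ortholog source table is required")
    votes: dict[str, str] = {}
    for source, table in source_tables.items():
        rows = table[table["human"] == symbol]
        if rows.empty:
            continue
        if "score" in rows.columns:
            rows = rows.sort_values(["score", "fly"], ascending=[False, True])
        votes[source] = str(rows.iloc[0]["fly"])
    if not votes:
        return OrthologCall(symbol=symbol, fly_gene=None, votes={}, status="none")
    counts = Counter(votes.values())
    top_gene, top_n = counts.most_common(1)[0]
    if top_n * 2 > len(votes):
        status = "unique" if top_n == len(votes) else "consensus"
        return OrthologCall(symbol=symbol, fly_gene=top_gene, votes=votes, status=status)
    return OrthologCall(symbol=symbol, fly_gene=None, votes=votes, status="ambiguous")


def testable_genes(calls: Iterable[OrthologCall]) -> list[str]:
    """Genes with a clear fly ortholog (unique or consensus vote)."""
    return [c.symbol for c in calls if c.status in ("unique", "consensus")]
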