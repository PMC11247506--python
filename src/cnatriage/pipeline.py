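"""End-to-end triage: segments -> ACN -> calls -> filters -> groups."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from cnatriage import copy_number, driver_filter, tiering
from cnatriage.core_io import CNARegionDef, GeneAnnotation, SampleMeta, SegmentRecord
from cnatriage.driver_filter import ConcordanceResult, DirectionCall, FilterLedger
from cnatriage.tiering import GenePrioritization


@dataclass
class TriageResult:
    acn: pd.DataFrame
    calls: pd.DataFrame
    directions: dict[str, DirectionCall]
    concordance: dict[str, ConcordanceResult]
    ledger: FilterLedger
    prioritization: dict[str, GenePrioritization]


def run_triage(
    segments: Sequence[SegmentRecord],
    annotation: Sequence[GeneAnnotation],
    samples: Sequence[SampleMeta],
    expression: pd.DataFrame,
    regions: Sequence[CNARegionDef],
    germline_fold: Mapping[str, float] | None = None,
    amp_cut: float = copy_number.AMP_CUT_DEFAULT,
    del_cut: float = copy_number.DEL_CUT_DEFAULT,
    alpha: float = 0.05,
    sd_threshold: float = driver_filter.SD_THRESHOLD_DEFAULT,
    helios_top_k: int = tiering.HELIOS_TOP_K_DEFAULT,
) -> TriageResult:
    """Run purity adjustment, direction and concordance filters, and tiering.

    Only genes belonging to at least one region are carried through; the
    TNBC subset drives the binomial direction filter and the
    alteration-frequency ranks, while concordance uses all primary tumors.
    """
    region_genes = {g for r in regions for g in r.members}
    cna_annotation = [g for g in annotation if g.symbol in region_genes]
    purity = {s.sample_id: s.purity for s in samples if s.purity is not None}
    primary = [s.sample_id for s in samples if s.sample_class == "primary_tumor"]
    tnbc = [s.sample_id for s in samples if s.is_tnbc and s.sample_class == "primary_tumor"]

    acn = copy_number.build_acn_matrix(
        segments, cna_annotation, purity=purity, germline_fold=germline_fold
    )
    acn = acn[[c for c in acn.columns if c in primary]]
    calls = copy_number.build_call_matrix(acn, amp_cut=amp_cut, del_cut=del_cut)

    directions, concordance, ledger = driver_filter.run_driver_filter(
        calls,
        expression,
        tnbc_samples=tnbc,
        primary_samples=primary,
        alpha=alpha,
        sd_threshold=sd_threshold,
    )
    prioritization = tiering.prioritize_genes(
        directions,
        concordance,
        regions,
        calls,
        rank_samples=tnbc,
        helios_top_k=helios_top_k,
    )
    return TriageResult(
        acn=acn,
        calls=calls,
        directions=directions,
        concordance=concordance,
        ledger=ledger,
        prioritization=prioritization,
    )


def prioritization_table(result: TriageResult) -> pd.DataFrame:
    """Flat per-gene table of the triage outcome."""
    rows = []
    for sym, pri in sorted(result.prioritization.items()):
        d = result.directions[sym]
        c = result.concordance[sym]
        rows.append(
            (
                sym,
                pri.group,
                pri.role,
                pri.tnbc_direction,
                d.n_amp,
                d.n_del,
                d.p_binom,
                c.relation,
                c.p_bonferroni,
                pri.helios_rank,
                pri.alt_freq_rank,
                ";".join(pri.region_ids),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "symbol", "group", "role", "tnbc_direction", "n_amp", "n_del",
            "p_binom", "concordance", "p_bonferroni", "helios_rank",
            "alt_freq_rank", "region_ids",
        ],
    )
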