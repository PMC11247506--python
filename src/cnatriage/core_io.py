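"""Domain types, file readers/writers, symbol harmonization, germline masking.

Genomic convention: all in-memory coordinates are 1-based closed intervals
(GRCh37 gene coordinates come this way); BED inputs are converted at the
boundary by :func:`bed_to_closed` / :func:`closed_to_bed`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared tabular format."""


class ValidationError(ValueError):
    """Parsed records violate a structural invariant."""


# MAF variant-classification vocabulary accepted without an "unknown" flag.
# Includes both the canonical underscore spellings and the space-separated
# display spellings used in clustering encodings.
MAF_VOCABULARY = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Silent",
        "Splice_Site",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Translation_Start_Site",
        "RNA",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "Targeted_Region",
        "Missense Mutation",
        "In-frame Insertion",
        "In-frame Deletion",
        "Nonstop Mutation",
        "RNA Alteration",
        "Splice Site mutation",
        "Frameshift Insertion",
        "Frameshift Deletion",
        "Nonsense Mutation",
    }
)


class RegionSource(str, Enum):
    GISTIC_TOTAL_AMP = "GISTIC_total_amp"
    GISTIC_BASAL_AMP = "GISTIC_basal_amp"
    GISTIC_TOTAL_DEL = "GISTIC_total_del"
    GISTIC_BASAL_DEL = "GISTIC_basal_del"
    ISAR_TOTAL = "ISAR_total"
    ISAR_BASAL = "ISAR_basal"

    @property
    def is_isar(self) -> bool:
        return self in (RegionSource.ISAR_TOTAL, RegionSource.ISAR_BASAL)


ISAR_SOURCES = (RegionSource.ISAR_TOTAL, RegionSource.ISAR_BASAL)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus on GRCh37 with an optional fly ortholog."""

    symbol: str
    chrom: str
    start: int
    end: int
    fly_ortholog: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"gene {self.symbol}: empty chromosome")
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.symbol}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class CNARegionDef:
    """A recurrently altered region from GISTIC 2.0 or ISAR.

    ``helios`` carries per-gene driver-likelihood scores in [0, 1] for ISAR
    amplifications; it is an input annotation, never computed here.
    """

    region_id: str
    source: RegionSource
    nominal_type: str  # "amp" | "del"
    members: tuple[str, ...]
    helios: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.nominal_type not in ("amp", "del"):
            raise ValidationError(
                f"region {self.region_id}: nominal_type {self.nominal_type!r}"
            )
        if not self.members:
            raise ValidationError(f"region {self.region_id}: no members")
        if self.source.is_isar and self.nominal_type != "amp":
            raise ValidationError(
                f"region {self.region_id}: ISAR regions are amplifications"
            )
        if self.helios is not None:
            extra = set(self.helios) - set(self.members)
            if extra:
                raise ValidationError(
                    f"region {self.region_id}: helios keys not in members: {sorted(extra)}"
                )


@dataclass(frozen=True)
class SegmentRecord:
    """One SNP-array segment; ``log2_value`` 0 = diploid-normal signal."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_value: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start > end"
            )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    is_tnbc: bool
    purity: float | None = None
    sample_class: str = "primary_tumor"  # "primary_tumor" | "normal"

    def __post_init__(self) -> None:
        if self.purity is not None and not (0.0 < self.purity <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id}: purity {self.purity} outside (0, 1]"
            )
        if self.sample_class not in ("primary_tumor", "normal"):
            raise ValidationError(
                f"sample {self.sample_id}: sample_class {self.sample_class!r}"
            )


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    symbol: str
    variant_classification: str
    known_classification: bool = True


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    endpoint: str  # "OS" | "PFI"
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.endpoint not in ("OS", "PFI"):
            raise ValidationError(f"endpoint {self.endpoint!r} not OS/PFI")
        if self.time < 0:
            raise ValidationError(f"sample {self.sample_id}: negative time")


@dataclass
class SynonymTable:
    """Alias → consensus gene-symbol map; consensus symbols are fixed points."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for alias, consensus in self.mapping.items():
            if self.mapping.get(consensus, consensus) != consensus:
                raise ValidationError(
                    f"consensus symbol {consensus!r} is not a fixed point"
                )

    def resolve(self, symbol: str) -> str | None:
        """Consensus symbol for ``symbol``, or None when unmappable."""
        if symbol in self.mapping:
            return self.mapping[symbol]
        if symbol in self.mapping.values():
            return symbol
        return None


# ---------------------------------------------------------------------------
# coordinate conventions


def bed_to_closed(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED interval to 1-based closed."""
    if end0 <= start0:
        raise ValidationError(f"empty or inverted BED interval [{start0}, {end0})")
    return start0 + 1, end0


def closed_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based closed interval to 0-based half-open BED."""
    if end1 < start1:
        raise ValidationError(f"inverted interval {start1}-{end1}")
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# readers / writers

_MAF_COLUMNS = {
    "sample": ("Tumor_Sample_Barcode", "sample_id", "sample"),
    "symbol": ("Hugo_Symbol", "symbol", "gene"),
    "classification": ("Variant_Classification", "variant_classification"),
}


def _find_column(columns: Sequence[str], candidates: Sequence[str], role: str) -> str:
    for cand in candidates:
        if cand in columns:
            return cand
    raise FormatError(
        f"missing mandatory column for {role}; expected one of {list(candidates)}"
    )


def read_maf(path: str | Path) -> list[MutationRecord]:
    """Read a tab-delimited MAF into mutation records.

    Unknown variant classifications are retained with
    ``known_classification=False`` so downstream encoding can decide.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = list(df.columns)
    sample_col = _find_column(cols, _MAF_COLUMNS["sample"], "sample id")
    symbol_col = _find_column(cols, _MAF_COLUMNS["symbol"], "gene symbol")
    class_col = _find_column(cols, _MAF_COLUMNS["classification"], "variant classification")
    records = []
    for row in df.itertuples(index=False):
        classification = str(getattr(row, class_col))
        records.append(
            MutationRecord(
                sample_id=str(getattr(row, sample_col)),
                symbol=str(getattr(row, symbol_col)),
                variant_classification=classification,
                known_classification=classification in MAF_VOCABULARY,
            )
        )
    n_unknown = sum(not r.known_classification for r in records)
    if n_unknown:
        log.warning("read_maf: %d records with unknown classification", n_unknown)
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": [r.sample_id for r in records],
            "Hugo_Symbol": [r.symbol for r in records],
            "Variant_Classification": [r.variant_classification for r in records],
        }
    )
    # reconstruct column order expected by read_maf
    df = df[["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]]
    df.to_csv(path, sep="\t", index=False)


_SEG_COLUMNS = ("Sample", "Chromosome", "Start", "End", "Segment_Mean")


def read_segments(path: str | Path, validate: bool = True) -> list[SegmentRecord]:
    """Read a SEG-style table; rejects overlapping segments within a sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _SEG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in SEG file")
    records = [
        SegmentRecord(
            sample_id=str(r.Sample),
            chrom=str(r.Chromosome),
            start=int(r.Start),
            end=int(r.End),
            log2_value=float(r.Segment_Mean),
        )
        for r in df.itertuples(index=False)
    ]
    if validate:
        validate_segments(records)
    return records


def validate_segments(records: Sequence[SegmentRecord]) -> None:
    """Raise if segments of one sample/chromosome overlap."""
    by_key: dict[tuple[str, str], list[SegmentRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.sample_id, rec.chrom), []).append(rec)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments for {sample} on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def write_segments(records: Iterable[SegmentRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.chrom, r.start, r.end, r.log2_value) for r in records],
        columns=_SEG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("symbol", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in annotation file")
    out = []
    seen: set[str] = set()
    for r in df.itertuples(index=False):
        if r.symbol in seen:
            raise ValidationError(f"duplicate gene symbol {r.symbol!r} in annotation")
        seen.add(r.symbol)
        fly = getattr(r, "fly_ortholog", None)
        if fly is not None and (pd.isna(fly) or fly == ""):
            fly = None
        out.append(
            GeneAnnotation(
                symbol=str(r.symbol),
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                fly_ortholog=fly,
            )
        )
    return out


def write_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (g.symbol, g.chrom, g.start, g.end, g.fly_ortholog or "")
            for g in genes
        ],
        columns=["symbol", "chrom", "start", "end", "fly_ortholog"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[CNARegionDef]:
    """Read region definitions (long TSV: region_id, source, nominal_type, gene, helios)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("region_id", "source", "nominal_type", "gene"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in regions file")
    regions = []
    for rid, grp in df.groupby("region_id", sort=False):
        sources = grp["source"].unique()
        types = grp["nominal_type"].unique()
        if len(sources) != 1 or len(types) != 1:
            raise ValidationError(f"region {rid}: inconsistent source/nominal_type")
        helios: dict[str, float] | None = None
        if "helios" in grp.columns:
            scored = grp.dropna(subset=["helios"])
            scored = scored[scored["helios"] != ""]
            if len(scored):
                helios = {
                    str(r.gene): float(r.helios) for r in scored.itertuples(index=False)
                }
        regions.append(
            CNARegionDef(
                region_id=str(rid),
                source=RegionSource(sources[0]),
                nominal_type=str(types[0]),
                members=tuple(grp["gene"].astype(str)),
                helios=helios,
            )
        )
    return regions


def write_regions(regions: Iterable[CNARegionDef], path: str | Path) -> None:
    rows = []
    for reg in regions:
        for gene in reg.members:
            score = "" if reg.helios is None else reg.helios.get(gene, "")
            rows.append((reg.region_id, reg.source.value, reg.nominal_type, gene, score))
    pd.DataFrame(
        rows, columns=["region_id", "source", "nominal_type", "gene", "helios"]
    ).to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "is_tnbc", "sample_class"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in sample metadata")
    out = []
    for r in df.itertuples(index=False):
        purity = getattr(r, "purity", None)
        if purity is not None and (pd.isna(purity) or purity == ""):
            purity = None
        out.append(
            SampleMeta(
                sample_id=str(r.sample_id),
                is_tnbc=str(r.is_tnbc).lower() in ("1", "true", "yes"),
                purity=None if purity is None else float(purity),
                sample_class=str(r.sample_class),
            )
        )
    return out


def write_sample_meta(samples: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                s.sample_id,
                str(s.is_tnbc),
                "" if s.purity is None else s.purity,
                s.sample_class,
            )
            for s in samples
        ],
        columns=["sample_id", "is_tnbc", "purity", "sample_class"],
    ).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "endpoint", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in survival file")
    return [
        SurvivalRecord(
            sample_id=str(r.sample_id),
            endpoint=str(r.endpoint),
            time=float(r.time),
            event=str(r.event).lower() in ("1", "true", "yes"),
        )
        for r in df.itertuples(index=False)
    ]


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.endpoint, r.time, int(r.event)) for r in records],
        columns=["sample_id", "endpoint", "time", "event"],
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes × samples matrix of non-negative quantification values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError("expression matrix contains negative values")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_synonyms(path: str | Path) -> SynonymTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("alias", "consensus"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in synonym table")
    return SynonymTable({str(r.alias): str(r.consensus) for r in df.itertuples(index=False)})


def write_synonyms(table: SynonymTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.mapping.items()), columns=["alias", "consensus"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# symbol harmonization and germline masking


def harmonize_symbols(
    symbols: Sequence[str], synonym_table: SynonymTable
) -> tuple[list[str], list[str]]:
    """Map symbols to their consensus form.

    Returns ``(mapped, dropped)``: symbols with neither a synonym entry nor a
    consensus identity are dropped (reported, never raised), mirroring the
    accounting of candidates lost to nomenclature.
    """
    mapped: list[str] = []
    dropped: list[str] = []
    for sym in symbols:
        consensus = synonym_table.resolve(sym)
        if consensus is None:
            dropped.append(sym)
        else:
            mapped.append(consensus)
    if dropped:
        log.info(
            "harmonize_symbols: dropped %d of %d symbols", len(dropped), len(symbols)
        )
    return mapped, dropped


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def filter_germline_cnv_mask(
    genes: Sequence[GeneAnnotation],
    mask_intervals: Sequence[tuple[str, int, int]],
) -> tuple[list[GeneAnnotation], list[GeneAnnotation]]:
    """Remove genes whose full span lies inside known germline CNV intervals.

    ``mask_intervals`` are BED-style ``(chrom, start0, end0)`` triples.  A gene
    is removed iff its entire span is covered by the (merged) mask on its
    chromosome; partial overlap retains the gene.  Returns
    ``(retained, removed)``.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s0, e0 in mask_intervals:
        by_chrom.setdefault(chrom, []).append(bed_to_closed(s0, e0))
    merged = {chrom: _merge_intervals(ivs) for chrom, ivs in by_chrom.items()}

    retained, removed = [], []
    for gene in genes:
        covered = any(
            s <= gene.start and gene.end <= e for s, e in merged.get(gene.chrom, [])
        )
        (removed if covered else retained).append(gene)
    if removed:
        log.info(
            "filter_germline_cnv_mask: removed %d genes in germline CNV regions",
            len(removed),
        )
    return retained, removed
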