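"""Gene-level, purity- and germline-adjusted copy number and amp/del calls.

Segment log2 ratios are linearized (fold scale, 1 = diploid-normal), the
fraction of signal contributed by contaminating normal cells is removed using
the tumor-purity estimate, and the result is expressed as a fold change over
the germline copy number:

    ACN = ((OCN - (1 - TP)) / TP) / GCN

with OCN the observed linear fold in the tumor sample, TP the tumor purity in
(0, 1], and GCN the germline fold for that gene.  A value of 1 is substituted
for TP and/or GCN when unavailable, so ACN degrades gracefully to a plain
fold change.  ACN = 1 represents normal copy number throughout.

Discretization uses fold cutoffs 2**0.3 (amplified) and 2**-0.3 (deleted);
ties at a cutoff count as altered.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cnatriage.core_io import CNARegionDef, GeneAnnotation, SegmentRecord

AMP_CUT_DEFAULT: float = 2.0**0.3
DEL_CUT_DEFAULT: float = 2.0**-0.3
ACN_FLOOR: float = 1e-6  # impure samples can push the numerator negative

AMP, NEUTRAL, DEL = "amp", "neutral", "del"


class ConfigError(ValueError):
    pass


def log2_to_fold(log2_value: float | np.ndarray) -> float | np.ndarray:
    """Linearize a log2 copy ratio (0 -> fold 1)."""
    return np.power(2.0, log2_value)


def gene_copy_number(
    segments: Sequence[SegmentRecord], gene: GeneAnnotation
) -> float:
    """Log2 value of the unique segment fully covering the gene span.

    ``segments`` are the segments of a single sample.  Returns NaN when no
    single segment covers the whole gene (straddled or uncovered genes carry
    no usable value).
    """
    for seg in segments:
        if (
            seg.chrom == gene.chrom
            and seg.start <= gene.start
            and gene.end <= seg.end
        ):
            return seg.log2_value
    return float("nan")


def adjust_copy_number(
    ocn_fold: float | np.ndarray,
    purity: float | None = None,
    germline_fold: float | None = None,
    floor: float = ACN_FLOOR,
) -> float | np.ndarray:
    """Purity- and germline-adjusted copy number on the fold scale.

    Missing purity or germline fold are substituted with 1 (no adjustment).
    The result is clipped below at ``floor`` to keep downstream ratio/log math
    defined when noise drives the numerator negative.
    """
    ocn = np.asarray(ocn_fold, dtype=float)
    if np.any(ocn <= 0):
        raise ValueError("observed copy-number fold must be positive")
    tp = 1.0 if purity is None else float(purity)
    if not 0.0 < tp <= 1.0:
        raise ValueError(f"tumor purity {tp} outside (0, 1]")
    gcn = 1.0 if germline_fold is None else float(germline_fold)
    if gcn <= 0:
        raise ValueError(f"germline fold {gcn} must be positive")
    acn = ((ocn - (1.0 - tp)) / tp) / gcn
    acn = np.maximum(acn, floor)
    return float(acn) if np.isscalar(ocn_fold) else acn


def call_alteration(
    acn: float,
    amp_cut: float = AMP_CUT_DEFAULT,
    del_cut: float = DEL_CUT_DEFAULT,
) -> str:
    """Discretize an adjusted copy number into amp / neutral / del."""
    if not del_cut < 1.0 < amp_cut:
        raise ConfigError(f"cutoffs out of order: del {del_cut}, amp {amp_cut}")
    if np.isnan(acn):
        return ""
    if acn >= amp_cut:
        return AMP
    if acn <= del_cut:
        return DEL
    return NEUTRAL


def build_acn_matrix(
    segments: Sequence[SegmentRecord],
    genes: Sequence[GeneAnnotation],
    purity: Mapping[str, float] | None = None,
    germline_fold: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Genes × samples adjusted-copy-number matrix.

    ``purity`` maps sample id → tumor purity, ``germline_fold`` maps gene
    symbol → germline fold; missing entries default to 1.  Cells are NaN where
    no single segment of the sample fully covers the gene.
    """
    purity = purity or {}
    germline_fold = germline_fold or {}
    by_sample: dict[str, list[SegmentRecord]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)

    sample_ids = sorted(by_sample)
    out = np.full((len(genes), len(sample_ids)), np.nan)
    for j, sample in enumerate(sample_ids):
        segs = by_sample[sample]
        tp = purity.get(sample)
        for i, gene in enumerate(genes):
            log2 = gene_copy_number(segs, gene)
            if np.isnan(log2):
                continue
            out[i, j] = adjust_copy_number(
                float(log2_to_fold(log2)), tp, germline_fold.get(gene.symbol)
            )
    return pd.DataFrame(out, index=[g.symbol for g in genes], columns=sample_ids)


def build_call_matrix(
    acn_matrix: pd.DataFrame,
    amp_cut: float = AMP_CUT_DEFAULT,
    del_cut: float = DEL_CUT_DEFAULT,
) -> pd.DataFrame:
    """Genes × samples matrix with values in {amp, neutral, del} ('' = missing)."""
    if not del_cut < 1.0 < amp_cut:
        raise ConfigError(f"cutoffs out of order: del {del_cut}, amp {amp_cut}")
    vals = acn_matrix.to_numpy()
    calls = np.full(vals.shape, NEUTRAL, dtype=object)
    calls[vals >= amp_cut] = AMP
    calls[vals <= del_cut] = DEL
    calls[np.isnan(vals)] = ""
    return pd.DataFrame(calls, index=acn_matrix.index, columns=acn_matrix.columns)


def region_mean_acn(acn_matrix: pd.DataFrame, region: CNARegionDef) -> pd.Series:
    """Per-sample arithmetic mean ACN over the region's annotated members.

    Non-missing member values are averaged; a sample with every member missing
    stays NaN.  Members absent from the matrix are ignored; a region with no
    annotated member at all is an error.
    """
    members = [m for m in region.members if m in acn_matrix.index]
    if not members:
        raise ValueError(f"region {region.region_id}: no members in ACN matrix")
    return acn_matrix.loc[members].mean(axis=0, skipna=True)


def region_mean_matrix(
    acn_matrix: pd.DataFrame, regions: Iterable[CNARegionDef]
) -> pd.DataFrame:
    """Samples × regions matrix of region mean ACNs."""
    return pd.DataFrame(
        {reg.region_id: region_mean_acn(acn_matrix, reg) for reg in regions}
    )
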