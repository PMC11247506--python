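"""Mixed-type tumor clustering and per-gene survival analysis.

Mutation classes are mapped onto a 0–2 numeric scale (values below 1 mark
likely loss of function, above 1 likely gain) so they can sit next to region
mean copy numbers in one feature matrix.  Clustering is agglomerative, with
either Euclidean distance on the numeric encoding or Gower distance on the
mixed categorical/numeric representation.  Survival contrasts carriers of a
gene's TNBC-direction alteration against all other samples with the log-rank
test, Kaplan–Meier curves and a single-covariate Cox hazard ratio; raw
log-rank p-values are reported without FDR adjustment, as this analysis
complements the functional evidence rather than standing on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from cnatriage.core_io import MutationRecord, SurvivalRecord
from cnatriage.copy_number import AMP, DEL
from cnatriage.driver_filter import AMPLIFIED

# Numeric encoding of MAF variant classes for clustering, 0-2 scale.
MUTATION_ENCODING: dict[str, float] = {
    "Missense Mutation": 2.0,
    "In-frame Insertion": 1.9,
    "In-frame Deletion": 1.8,
    "Nonstop Mutation": 1.7,
    "RNA Alteration": 1.6,
    "Splice Site mutation": 0.3,
    "Frameshift Insertion": 0.2,
    "Frameshift Deletion": 0.1,
    "Nonsense Mutation": 0.0,
}

# Canonical underscore MAF spellings mapped to the display labels above.
_MAF_ALIASES: dict[str, str] = {
    "Missense_Mutation": "Missense Mutation",
    "In_Frame_Ins": "In-frame Insertion",
    "In_Frame_Del": "In-frame Deletion",
    "Nonstop_Mutation": "Nonstop Mutation",
    "RNA": "RNA Alteration",
    "Splice_Site": "Splice Site mutation",
    "Frame_Shift_Ins": "Frameshift Insertion",
    "Frame_Shift_Del": "Frameshift Deletion",
    "Nonsense_Mutation": "Nonsense Mutation",
}

NO_MUTATION_VALUE = 1.0  # neutral midpoint between loss (<1) and gain (>1)


def encode_mutation(classification: str | None) -> float:
    """Numeric encoding of one variant classification (absent -> neutral 1.0)."""
    if classification is None:
        return NO_MUTATION_VALUE
    label = _MAF_ALIASES.get(classification, classification)
    try:
        return MUTATION_ENCODING[label]
    except KeyError:
        raise KeyError(
            f"unknown variant classification {classification!r}; "
            f"valid labels: {sorted(MUTATION_ENCODING)}"
        ) from None


def _reconcile(values: list[float]) -> float:
    """Encode multiple mutations in one gene/sample: farthest from neutral wins,
    ties broken toward the lower value (loss dominates)."""
    return min(values, key=lambda v: (-abs(v - NO_MUTATION_VALUE), v))


def encode_mutation_matrix(
    mutations: list[MutationRecord],
    genes: list[str],
    samples: list[str],
) -> pd.DataFrame:
    """Samples × genes matrix of encoded mutation numerals."""
    cells: dict[tuple[str, str], list[float]] = {}
    gene_set, sample_set = set(genes), set(samples)
    for rec in mutations:
        if rec.symbol in gene_set and rec.sample_id in sample_set:
            try:
                val = encode_mutation(rec.variant_classification)
            except KeyError:
                continue  # non-encodable classes (e.g. Silent) are not clustered
            cells.setdefault((rec.sample_id, rec.symbol), []).append(val)
    out = pd.DataFrame(NO_MUTATION_VALUE, index=samples, columns=genes, dtype=float)
    for (sample, gene), vals in cells.items():
        out.loc[sample, gene] = _reconcile(vals)
    return out


def build_feature_matrix(
    region_mean_acns: pd.DataFrame,
    encoded_mutations: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Join region mean ACNs (samples × regions) with encoded mutations.

    Only samples present in both inputs are kept; returns the joined matrix
    and the number of excluded samples.
    """
    shared = region_mean_acns.index.intersection(encoded_mutations.index)
    if len(shared) == 0:
        raise ValueError("no samples with both copy-number and mutation data")
    n_excluded = (
        len(region_mean_acns.index.union(encoded_mutations.index)) - len(shared)
    )
    joined = pd.concat(
        [region_mean_acns.loc[shared], encoded_mutations.loc[shared]], axis=1
    )
    return joined, n_excluded


def gower_distance(
    row_a: np.ndarray | list,
    row_b: np.ndarray | list,
    feature_kinds: list[str],
    numeric_ranges: list[float],
) -> float:
    """Gower dissimilarity between two rows of mixed features, in [0, 1].

    Categorical features contribute a 0/1 mismatch; numeric features
    |a-b|/range.  Features missing (NaN) in either row are skipped with
    renormalization over the remaining features.
    """
    total, used = 0.0, 0
    for a, b, kind, rng in zip(row_a, row_b, feature_kinds, numeric_ranges):
        if kind == "numeric":
            if np.isnan(a) or np.isnan(b):
                continue
            total += 0.0 if rng == 0 else min(abs(a - b) / rng, 1.0)
        else:
            if a is None or b is None or (isinstance(a, float) and np.isnan(a)):
                continue
            total += 0.0 if a == b else 1.0
        used += 1
    if used == 0:
        raise ValueError("no shared non-missing features between rows")
    return total / used


def gower_matrix(
    frame: pd.DataFrame, feature_kinds: list[str] | None = None
) -> np.ndarray:
    """Condensed pairwise Gower distance over the rows of ``frame``.

    ``feature_kinds`` defaults to numeric for numeric dtypes, categorical
    otherwise.  Ranges are computed over the whole cohort.
    """
    if feature_kinds is None:
        feature_kinds = [
            "numeric" if pd.api.types.is_numeric_dtype(frame[c]) else "categorical"
            for c in frame.columns
        ]
    ranges = []
    for col, kind in zip(frame.columns, feature_kinds):
        if kind == "numeric":
            vals = frame[col].to_numpy(dtype=float)
            finite = vals[~np.isnan(vals)]
            ranges.append(float(finite.max() - finite.min()) if len(finite) else 0.0)
        else:
            ranges.append(0.0)
    rows = [frame.iloc[i].to_numpy() for i in range(len(frame))]
    n = len(rows)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[k] = gower_distance(rows[i], rows[j], feature_kinds, ranges)
            k += 1
    return out


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]
    metric: str  # euclidean | gower


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage_method: str = "average",
    feature_kinds: list[str] | None = None,
) -> ClusterResult:
    """Agglomerative clustering of samples (rows) with the requested metric."""
    if len(matrix) < 2:
        raise ValueError("clustering requires at least 2 samples")
    if metric == "euclidean":
        dists = pdist(matrix.to_numpy(dtype=float), metric="euclidean")
    elif metric == "gower":
        dists = gower_matrix(matrix, feature_kinds)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(dists, method=linkage_method)
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage=Z,
        leaf_order=[str(matrix.index[i]) for i in order],
        metric=metric,
    )


def cluster_to_newick(result: ClusterResult) -> str:
    """Newick serialization of the agglomerative tree (branch lengths = heights)."""
    tree = hierarchy.to_tree(result.linkage)
    labels = {i: name for i, name in enumerate(_original_labels(result))}

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def _original_labels(result: ClusterResult) -> list[str]:
    # leaf_order is a permutation of the original labels; invert it
    order = hierarchy.leaves_list(result.linkage)
    labels = [""] * len(result.leaf_order)
    for pos, original_idx in enumerate(order):
        labels[original_idx] = result.leaf_order[pos]
    return labels


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalResult:
    symbol: str
    endpoint: str
    n_altered: int
    n_other: int
    logrank_stat: float | None
    logrank_p: float | None
    hazard_ratio: float | None
    flagged: bool = False
    flag_reason: str = ""


def survival_stratify(
    calls: pd.DataFrame,
    gene: str,
    direction: str,
    survival_records: list[SurvivalRecord],
    endpoint: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split survival records by carrier status of the gene's TNBC-direction
    alteration.  Returns ``(altered, other)`` frames with time/event columns."""
    if endpoint not in ("OS", "PFI"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    target = AMP if direction == AMPLIFIED else DEL
    row = calls.loc[gene]
    altered_samples = set(row.index[row == target])
    rows = [
        (r.sample_id, r.time, int(r.event), r.sample_id in altered_samples)
        for r in survival_records
        if r.endpoint == endpoint and r.sample_id in row.index
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "time", "event", "altered"])
    return df[df["altered"]].copy(), df[~df["altered"]].copy()


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank statistic (chi-square, 1 df) and raw p-value."""
    if np.sum(events_a) + np.sum(events_b) == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_hazard_ratio(
    group_indicator: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
) -> float:
    """Hazard ratio for the altered-group indicator from a one-covariate Cox fit."""
    df = pd.DataFrame(
        {"time": times, "event": events, "altered": np.asarray(group_indicator, int)}
    )
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="time", event_col="event")
    return float(np.exp(fitter.params_["altered"]))


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan–Meier survival estimate (timeline and survival probability)."""
    km = KaplanMeierFitter()
    km.fit(times, events)
    sf = km.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
    )


def gene_survival_analysis(
    calls: pd.DataFrame,
    gene: str,
    direction: str,
    survival_records: list[SurvivalRecord],
    endpoint: str,
) -> SurvivalResult:
    """Log-rank + Cox contrast of altered vs non-altered carriers for one gene."""
    altered, other = survival_stratify(calls, gene, direction, survival_records, endpoint)
    if len(altered) == 0 or len(other) == 0:
        return SurvivalResult(
            symbol=gene,
            endpoint=endpoint,
            n_altered=len(altered),
            n_other=len(other),
            logrank_stat=None,
            logrank_p=None,
            hazard_ratio=None,
            flagged=True,
            flag_reason="empty group",
        )
    try:
        stat, p = logrank_test(
            altered["time"].to_numpy(),
            altered["event"].to_numpy(),
            other["time"].to_numpy(),
            other["event"].to_numpy(),
        )
    except ValueError:
        return SurvivalResult(
            symbol=gene,
            endpoint=endpoint,
            n_altered=len(altered),
            n_other=len(other),
            logrank_stat=None,
            logrank_p=None,
            hazard_ratio=None,
            flagged=True,
            flag_reason="no events",
        )
    both = pd.concat([altered, other])
    try:
        hr = cox_hazard_ratio(
            both["altered"].to_numpy(),
            both["time"].to_numpy(),
            both["event"].to_numpy(),
        )
        flagged, reason = False, ""
    except Exception:  # non-convergence
        hr, flagged, reason = None, True, "cox fit failed"
    return SurvivalResult(
        symbol=gene,
        endpoint=endpoint,
        n_altered=len(altered),
        n_other=len(other),
        logrank_stat=stat,
        logrank_p=p,
        hazard_ratio=hr,
        flagged=flagged,
        flag_reason=reason,
    )
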