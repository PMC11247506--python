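"""TNBC-specific binomial direction filter and expression-concordance filter.

The direction filter asks, gene by gene, whether the number of TNBC tumors
carrying the gene's majority alteration (amplification or deletion) is larger
than a background alteration rate can explain: an upper-tail binomial
probability P(X >= k) under Binomial(n_tnbc, p0), retained when p < alpha.
No multiple-testing correction is applied at this step — it is an extra
filter on top of region calls that already survived a recurrence algorithm.

The concordance filter checks that copy number and expression move together:
per gene, z-scored expression of altered vs non-altered primary tumors is
compared with Student's t (equal variances) or Welch's test (unequal),
Bonferroni-corrected.  Directional retention then keeps every gene except
deleted genes with significantly *increased* expression, for which no driver
mechanism exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cnatriage.copy_number import AMP, DEL

AMPLIFIED = "amplified"
DELETED = "deleted"
NOT_SIGNIFICANT = "not_significant"
AMBIGUOUS_TIE = "ambiguous_tie"

POSITIVE_SIG = "positive_sig"
NEGATIVE_SIG = "negative_sig"
NONSIG = "nonsig"

N_TNBC_DEFAULT = 110  # TNBC cohort size in the reference dataset
SD_THRESHOLD_DEFAULT = 0.25


@dataclass(frozen=True)
class DirectionCall:
    """Outcome of the TNBC binomial direction filter for one gene."""

    symbol: str
    n_amp: int
    n_del: int
    n_tnbc: int
    p_binom: float
    direction: str  # amplified | deleted | not_significant | ambiguous_tie


@dataclass(frozen=True)
class ConcordanceResult:
    """Outcome of the copy-number/expression concordance test for one gene."""

    symbol: str
    cna_type: str  # amplified | deleted
    test_used: str  # student_t | welch
    p_raw: float
    p_bonferroni: float
    relation: str  # positive_sig | negative_sig | nonsig
    retained: bool
    normality_flagged: bool = False


def direction_counts(
    calls: pd.DataFrame, tnbc_samples: list[str], gene: str
) -> tuple[int, int]:
    """Counts of amp and del calls for ``gene`` among TNBC primary tumors.

    Missing calls (empty string / NaN) are excluded from both counts.
    """
    if gene not in calls.index:
        raise KeyError(f"gene {gene!r} absent from call matrix")
    row = calls.loc[gene, [s for s in tnbc_samples if s in calls.columns]]
    return int((row == AMP).sum()), int((row == DEL).sum())


def binomial_direction_filter(
    n_amp: int,
    n_del: int,
    n: int = N_TNBC_DEFAULT,
    p0: float = 0.5,
    alpha: float = 0.05,
    symbol: str = "",
) -> DirectionCall:
    """Classify a gene's TNBC alteration direction by binomial tail probability.

    The majority direction is tested with the one-sided upper tail
    P(X >= k), k = max(n_amp, n_del), under Binomial(n, p0).  Equal non-zero
    counts are flagged ``ambiguous_tie`` and excluded downstream; the
    direction rule is stated only for strict majorities.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null probability p0={p0} outside (0, 1)")
    if n_amp + n_del > n:
        raise ValueError(f"counts {n_amp}+{n_del} exceed cohort size {n}")
    k = max(n_amp, n_del)
    if k > n:
        raise ValueError(f"count {k} exceeds cohort size {n}")
    # upper tail P(X >= k) = sf(k - 1)
    p = float(stats.binom.sf(k - 1, n, p0))
    if n_amp == n_del:
        direction = AMBIGUOUS_TIE if n_amp > 0 else NOT_SIGNIFICANT
    elif p >= alpha:
        direction = NOT_SIGNIFICANT
    else:
        direction = AMPLIFIED if n_amp > n_del else DELETED
    return DirectionCall(
        symbol=symbol, n_amp=n_amp, n_del=n_del, n_tnbc=n, p_binom=p, direction=direction
    )


def background_alteration_rate(calls: pd.DataFrame, direction: str) -> float:
    """Dataset-wide alteration frequency for one direction.

    Serves as the estimable null probability p0 for the binomial filter:
    total calls of that direction over total non-missing calls, across all
    genes and samples of the matrix passed in.
    """
    target = AMP if direction == AMPLIFIED else DEL
    vals = calls.to_numpy()
    present = (vals == AMP) | (vals == DEL) | (vals == "neutral")
    n_present = int(present.sum())
    if n_present == 0:
        raise ValueError("call matrix has no non-missing calls")
    return float((vals == target).sum() / n_present)


def sd_filter(
    expression: pd.DataFrame,
    threshold: float = SD_THRESHOLD_DEFAULT,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep genes whose expression standard deviation strictly exceeds ``threshold``.

    SD is the sample SD (n-1 denominator) of log2(1+x)-transformed
    quantifications by default.  Returns the retained (untransformed) matrix
    and the list of removed genes.
    """
    values = np.log2(1.0 + expression) if log_transform else expression
    sds = values.std(axis=1, ddof=1)
    keep = sds > threshold
    removed = list(expression.index[~keep])
    return expression.loc[keep], removed


def gene_zscores(
    expression: pd.DataFrame, gene: str | None = None, log_transform: bool = True
) -> pd.Series | pd.DataFrame:
    """Per-gene z-scores of (optionally log2(1+x)-transformed) expression.

    Sample SD (n-1).  With ``gene`` given, returns that gene's z vector;
    otherwise the full genes × samples z matrix.
    """
    values = np.log2(1.0 + expression) if log_transform else expression
    if gene is not None:
        row = values.loc[gene]
        sd = row.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"gene {gene!r} has zero expression SD")
        return (row - row.mean()) / sd
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = list(values.index[sd == 0])
        raise ValueError(f"zero expression SD for genes {bad[:5]}")
    return values.sub(mu, axis=0).div(sd, axis=0)


def _equal_variance(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> bool:
    """Two-sided F-ratio test of equal variances at ``alpha``."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return True
    if va == 0 or vb == 0:
        return False
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return min(p, 1.0) >= alpha


def concordance_test(
    z: pd.Series | np.ndarray,
    altered_set: set[str] | np.ndarray,
    cna_type: str,
    alpha: float = 0.05,
    m: int = 1,
    symbol: str = "",
    normality_alpha: float = 0.05,
) -> ConcordanceResult:
    """Compare expression z-scores of altered vs non-altered primary tumors.

    An F-ratio check selects Student's t (equal variances) or Welch's test,
    two-sided; p-values are Bonferroni-corrected with denominator ``m``.
    Groups of size >= 30 are taken as covered by the CLT; smaller groups are
    screened with Shapiro–Wilk and the result flagged when normality is
    doubtful (the parametric test is still reported).
    """
    z = pd.Series(z)
    if isinstance(altered_set, (set, frozenset, list, tuple)):
        mask = z.index.isin(list(altered_set))
    else:
        mask = np.asarray(altered_set, dtype=bool)
    a = z.to_numpy()[mask]
    b = z.to_numpy()[~mask]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both altered and non-altered groups must be non-empty")
    if len(a) == 1 and len(b) == 1:
        raise ValueError("cannot test two singleton groups")

    flagged = False
    for grp in (a, b):
        if 3 <= len(grp) < 30:
            if np.ptp(grp) > 0 and stats.shapiro(grp).pvalue < normality_alpha:
                flagged = True
        elif len(grp) < 3:
            flagged = True

    if len(a) == 1 or len(b) == 1:
        equal_var = False  # singleton forces Welch
    else:
        equal_var = _equal_variance(a, b)
    test_used = "student_t" if equal_var else "welch"
    if np.array_equal(np.sort(a), np.sort(b)):
        p_raw = 1.0  # identical multisets carry no signal
    else:
        p_raw = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        if np.isnan(p_raw):
            p_raw = 1.0
    p_bonf = min(1.0, p_raw * m)

    diff = float(np.mean(a) - np.mean(b))
    if p_bonf < alpha and diff > 0:
        relation = POSITIVE_SIG
    elif p_bonf < alpha and diff < 0:
        relation = NEGATIVE_SIG
    else:
        relation = NONSIG
    return ConcordanceResult(
        symbol=symbol,
        cna_type=cna_type,
        test_used=test_used,
        p_raw=p_raw,
        p_bonferroni=p_bonf,
        relation=relation,
        retained=retention_rule(cna_type, relation),
        normality_flagged=flagged,
    )


def retention_rule(cna_type: str, relation: str) -> bool:
    """Directional retention of concordance outcomes.

    Kept: positive concordance, non-significance, and amplified genes with
    *reduced* expression (amplification could silence a tumor suppressor
    through chromatin changes).  Dropped: deleted genes with significantly
    increased expression — no driver mechanism can raise expression of a
    deleted driver.
    """
    if cna_type not in (AMPLIFIED, DELETED):
        raise ValueError(f"unknown cna_type {cna_type!r}")
    if relation not in (POSITIVE_SIG, NEGATIVE_SIG, NONSIG):
        raise ValueError(f"unknown relation {relation!r}")
    return not (cna_type == DELETED and relation == POSITIVE_SIG)


@dataclass
class FilterLedger:
    """Counts of genes removed at each filtering step."""

    n_input: int = 0
    n_removed_binomial: int = 0
    n_removed_no_expression: int = 0
    n_removed_sd: int = 0
    n_removed_retention: int = 0
    n_retained: int = 0


def run_driver_filter(
    calls: pd.DataFrame,
    expression: pd.DataFrame,
    tnbc_samples: list[str],
    primary_samples: list[str] | None = None,
    p0_amp: float | None = None,
    p0_del: float | None = None,
    alpha: float = 0.05,
    sd_threshold: float = SD_THRESHOLD_DEFAULT,
) -> tuple[dict[str, DirectionCall], dict[str, ConcordanceResult], FilterLedger]:
    """Run the binomial direction filter then the concordance filter.

    ``p0_amp`` / ``p0_del`` default to the dataset-wide alteration frequency
    of the matching direction, estimated from the TNBC-restricted call matrix.
    Concordance is evaluated on primary tumors (default: all call-matrix
    columns), comparing each surviving gene's altered group against the rest;
    the Bonferroni denominator is the number of genes actually tested.
    """
    ledger = FilterLedger(n_input=len(calls.index))
    tnbc_present = [s for s in tnbc_samples if s in calls.columns]
    tnbc_calls = calls[tnbc_present]
    if p0_amp is None:
        p0_amp = background_alteration_rate(tnbc_calls, AMPLIFIED)
    if p0_del is None:
        p0_del = background_alteration_rate(tnbc_calls, DELETED)

    directions: dict[str, DirectionCall] = {}
    for gene in calls.index:
        n_amp, n_del = direction_counts(calls, tnbc_present, gene)
        p0 = p0_amp if n_amp >= n_del else p0_del
        p0 = min(max(p0, 1e-12), 1 - 1e-12)
        directions[gene] = binomial_direction_filter(
            n_amp, n_del, n=len(tnbc_present), p0=p0, alpha=alpha, symbol=gene
        )
    survivors = [
        g for g, d in directions.items() if d.direction in (AMPLIFIED, DELETED)
    ]
    ledger.n_removed_binomial = ledger.n_input - len(survivors)

    with_expr = [g for g in survivors if g in expression.index]
    ledger.n_removed_no_expression = len(survivors) - len(with_expr)
    expr = expression.loc[with_expr]
    expr_kept, removed_sd = sd_filter(expr, threshold=sd_threshold)
    ledger.n_removed_sd = len(removed_sd)

    primary = primary_samples or list(calls.columns)
    primary = [s for s in primary if s in expr_kept.columns]
    zmat = gene_zscores(expr_kept[primary])
    m = len(expr_kept.index)
    concordance: dict[str, ConcordanceResult] = {}
    for gene in expr_kept.index:
        d = directions[gene]
        target = AMP if d.direction == AMPLIFIED else DEL
        altered = (calls.loc[gene, primary] == target).to_numpy()
        if altered.sum() == 0 or altered.sum() == len(primary):
            # degenerate split: no comparison possible, keep as nonsig
            concordance[gene] = ConcordanceResult(
                symbol=gene,
                cna_type=d.direction,
                test_used="student_t",
                p_raw=1.0,
                p_bonferroni=1.0,
                relation=NONSIG,
                retained=True,
                normality_flagged=True,
            )
            continue
        concordance[gene] = concordance_test(
            zmat.loc[gene],
            altered,
            cna_type=d.direction,
            alpha=alpha,
            m=m,
            symbol=gene,
        )
    ledger.n_removed_retention = sum(not c.retained for c in concordance.values())
    ledger.n_retained = sum(c.retained for c in concordance.values())
    return directions, concordance, ledger
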