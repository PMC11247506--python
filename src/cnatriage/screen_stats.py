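"""Statistics of the transgenic fly genetic and drug screens.

A candidate gene is crossed into the ptc>Myc,p53-knockdown base model and
scored in three assays: whole-animal lethality (eclosion rate and relative
pupariation against the balancer-carrying siblings), wing-disc cell
translocation (counts of labeled cells outside the transgene domain), and
transgenic-tissue overgrowth (labeled-pixel fraction of the disc).  The
workflow is sequential: lines significantly increasing lethality in at least
two independent experiments become candidates; candidates are scored for
translocation; only translocation-negative candidates proceed to the more
laborious overgrowth assay.  Phenotype enhancement must clear a dual
criterion — p < 0.05 against the same-experiment controls *and* BH-FDR < 0.1
in the aggregate across experiments — and drivers are lethality hits with at
least one significant tissue phenotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

P_INDIVIDUAL = 0.05
FDR_AGGREGATE = 0.1
LETHALITY_ALPHA = 0.05
MIN_INDEPENDENT_EXPERIMENTS = 2

SCREEN_COLUMNS = [
    "line_id",
    "gene",
    "group",
    "direction",
    "experiment_id",
    "replicate_id",
    "assay",
    "empty_pupal_cases",
    "uneclosed_pupae",
    "tubby_pupae",
    "nontubby_pupae",
    "translocated_cells",
    "green_pixels",
    "disc_pixels",
]


@dataclass
class ScreenCall:
    gene: str
    group: str = ""
    lethality_hit: bool = False
    translocation_hit: bool = False
    overgrowth_hit: bool = False
    driver: bool = False
    lethality_pvalues: list[float] = field(default_factory=list)
    translocation_p: float | None = None
    translocation_fdr: float | None = None
    overgrowth_p: float | None = None
    overgrowth_fdr: float | None = None
    overgrowth_tested: bool = False


# ---------------------------------------------------------------------------
# elementary rates


def eclosion_rate(empty_pupal_cases: int, uneclosed_pupae: int) -> float:
    """Percent of pupae that eclosed: 100 * empty / (uneclosed + empty)."""
    total = empty_pupal_cases + uneclosed_pupae
    if total == 0:
        return float("nan")  # no pupae observed; undefined, flagged upstream
    return 100.0 * empty_pupal_cases / total


def relative_pupariation(nontubby: int, tubby: int) -> float:
    """Percent ratio of experimental to balancer pupae: 100 * non-tubby / tubby.

    Undefined (NaN) when no tubby siblings were produced — not calculated for
    balanced stocks.
    """
    if tubby == 0:
        return float("nan")
    return 100.0 * nontubby / tubby


def overgrowth_ratio(green_pixels: int, disc_pixels: int) -> float:
    """Fraction of the disc occupied by transgene-labeled tissue."""
    if disc_pixels <= 0:
        raise ValueError("disc_pixels must be positive")
    if green_pixels > disc_pixels:
        raise ValueError(
            f"green pixels {green_pixels} exceed disc pixels {disc_pixels}"
        )
    return green_pixels / disc_pixels


# ---------------------------------------------------------------------------
# two-group comparisons


SHAPIRO_MIN_N = 8  # below this, Shapiro–Wilk has essentially no power


def _normal_enough(values: np.ndarray, alpha: float = 0.05) -> bool:
    """Normality gate: n >= 30 passes outright (CLT); groups smaller than
    ``SHAPIRO_MIN_N`` are treated as non-normal (the test cannot tell);
    in between, Shapiro–Wilk at ``alpha`` decides."""
    if len(values) >= 30:
        return True
    if len(values) < SHAPIRO_MIN_N or np.ptp(values) == 0:
        return False
    return stats.shapiro(values).pvalue >= alpha


def compare_to_control(
    test_values: Sequence[float],
    control_values: Sequence[float],
    tail: str = "two-sided",
) -> tuple[str, float]:
    """Student's t when both groups look normal, Mann–Whitney U otherwise.

    ``tail``: "two-sided", "greater" (test > control) or "less".  Exact
    Mann–Whitney p-values are used when both groups have <= 10 observations
    and no ties; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(test_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 non-missing observations")

    parametric = _normal_enough(a) and _normal_enough(b)
    if parametric and (np.ptp(a) == 0 and np.ptp(b) == 0):
        parametric = False  # degenerate zero-variance case: fall back to ranks
    if parametric:
        res = stats.ttest_ind(a, b, alternative=tail)
        return "student_t", float(res.pvalue)
    method = "exact" if (len(a) <= 10 and len(b) <= 10) else "asymptotic"
    if np.array_equal(np.sort(a), np.sort(b)):
        return "mann_whitney", 1.0
    res = stats.mannwhitneyu(a, b, alternative=tail, method=method)
    return "mann_whitney", float(res.pvalue)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lethality_hit(per_experiment_pvalues: Sequence[float]) -> bool:
    """True iff >= 2 independent experiments reduced survival at p < 0.05."""
    return (
        sum(p < LETHALITY_ALPHA for p in per_experiment_pvalues)
        >= MIN_INDEPENDENT_EXPERIMENTS
    )


def phenotype_hit(per_experiment_p: float, aggregate_fdr: float) -> bool:
    """Dual criterion: p < 0.05 in the individual experiment and FDR < 0.1
    in the aggregate analysis."""
    return per_experiment_p < P_INDIVIDUAL and aggregate_fdr < FDR_AGGREGATE


def classify_driver(
    lethality: bool, translocation: bool, overgrowth: bool | None
) -> bool:
    """Driver = lethality hit with at least one enhanced tissue phenotype.

    ``overgrowth`` may be None when the assay was not run (it is only run for
    translocation-negative candidates).
    """
    return lethality and (translocation or bool(overgrowth))


def tally_hit_rates(
    calls: Iterable[ScreenCall],
) -> pd.DataFrame:
    """Per-group tested/driver counts and hit percentages.

    ``percent`` is rounded half-up to an integer for reporting; the raw
    fraction is kept alongside.  Empty groups are simply absent.
    """
    rows: dict[str, list[int]] = {}
    for call in calls:
        group = call.group or "ungrouped"
        n_tested, n_driver = rows.get(group, [0, 0])
        rows[group] = [n_tested + 1, n_driver + int(call.driver)]
    out = pd.DataFrame(
        [
            (
                grp,
                n_tested,
                n_driver,
                100.0 * n_driver / n_tested,
                int(math.floor(100.0 * n_driver / n_tested + 0.5)),
            )
            for grp, (n_tested, n_driver) in sorted(rows.items())
        ],
        columns=["group", "n_tested", "n_driver", "percent_raw", "percent"],
    )
    return out


def drug_rescue_test(
    drug_eclosion_rates: Sequence[float],
    vehicle_eclosion_rates: Sequence[float],
    drug_solvent: str = "DMSO",
    vehicle_solvent: str = "DMSO",
) -> tuple[float, str]:
    """Mann–Whitney comparison of a drug arm against its matched vehicle.

    The vehicle must share the drug's solvent (water-soluble drugs against a
    water control, DMSO-dissolved drugs against 0.1% DMSO food).  Returns the
    rank-test p-value and the direction of the median difference ("rescue"
    when the drug arm survives better, "worse" when it survives less,
    "none" for no difference).
    """
    if drug_solvent != vehicle_solvent:
        raise ValueError(
            f"solvent mismatch: drug in {drug_solvent!r}, vehicle {vehicle_solvent!r}"
        )
    a = np.asarray(drug_eclosion_rates, dtype=float)
    b = np.asarray(vehicle_eclosion_rates, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both arms need at least 2 replicates")
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
    else:
        method = "exact" if (len(a) <= 10 and len(b) <= 10) else "asymptotic"
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    diff = float(np.median(drug_eclosion_rates) - np.median(vehicle_eclosion_rates))
    direction = "rescue" if diff > 0 else ("worse" if diff < 0 else "none")
    return p, direction


# ---------------------------------------------------------------------------
# screen table I/O and full workflow


def read_screen_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"screen table missing columns: {missing}")
    counts = ["empty_pupal_cases", "uneclosed_pupae", "tubby_pupae", "nontubby_pupae"]
    if (df[counts].fillna(0) < 0).to_numpy().any():
        raise ValueError("screen counts must be non-negative")
    return df


def write_screen_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _per_line_lethality(
    table: pd.DataFrame, control_gene: str
) -> dict[str, list[float]]:
    """Minimum of the eclosion / pupariation one-sided p-values per line and
    experiment, against the same experiment's control replicates."""
    lethality = table[table["assay"] == "lethality"]
    pvals: dict[str, list[float]] = {}
    for exp_id, exp in lethality.groupby("experiment_id"):
        ctrl = exp[exp["gene"] == control_gene]
        if ctrl.empty:
            continue
        ctrl_ecl = [
            eclosion_rate(int(r.empty_pupal_cases), int(r.uneclosed_pupae))
            for r in ctrl.itertuples(index=False)
        ]
        ctrl_pup = [
            relative_pupariation(int(r.nontubby_pupae), int(r.tubby_pupae))
            for r in ctrl.itertuples(index=False)
        ]
        for line_id, grp in exp[exp["gene"] != control_gene].groupby("line_id"):
            ecl = [
                eclosion_rate(int(r.empty_pupal_cases), int(r.uneclosed_pupae))
                for r in grp.itertuples(index=False)
            ]
            pup = [
                relative_pupariation(int(r.nontubby_pupae), int(r.tubby_pupae))
                for r in grp.itertuples(index=False)
            ]
            candidates = []
            # reduced survival is one-sided: experimental arm *lower* than control
            for vals, cvals in ((ecl, ctrl_ecl), (pup, ctrl_pup)):
                vals = [v for v in vals if not np.isnan(v)]
                cvals_clean = [v for v in cvals if not np.isnan(v)]
                if len(vals) >= 2 and len(cvals_clean) >= 2:
                    _, p = compare_to_control(vals, cvals_clean, tail="less")
                    candidates.append(p)
            if candidates:
                pvals.setdefault(str(line_id), []).append(min(candidates))
    return pvals


def _phenotype_measurements(
    table: pd.DataFrame, assay: str
) -> pd.DataFrame:
    sub = table[table["assay"] == assay].copy()
    if assay == "translocation":
        sub["value"] = sub["translocated_cells"].astype(float)
    else:
        sub["value"] = [
            overgrowth_ratio(int(g), int(d))
            for g, d in zip(sub["green_pixels"], sub["disc_pixels"])
        ]
    return sub


def _per_line_phenotype(
    table: pd.DataFrame, assay: str, control_gene: str
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-line best individual-experiment p and aggregate p for one assay.

    One-tailed enhancement tests; lines whose mean does not exceed the control
    mean are not tested (p = 1).  Aggregate pools raw measurements across
    experiments; FDR is computed by the caller over all aggregate p-values.
    """
    sub = _phenotype_measurements(table, assay)
    per_exp: dict[str, float] = {}
    for exp_id, exp in sub.groupby("experiment_id"):
        ctrl_vals = exp.loc[exp["gene"] == control_gene, "value"].to_numpy()
        if len(ctrl_vals) < 2:
            continue
        for line_id, grp in exp[exp["gene"] != control_gene].groupby("line_id"):
            vals = grp["value"].to_numpy()
            if len(vals) < 2:
                continue
            if np.mean(vals) <= np.mean(ctrl_vals):
                p = 1.0  # only enhancement (mean > control) is tested
            else:
                _, p = compare_to_control(vals, ctrl_vals, tail="greater")
            key = str(line_id)
            per_exp[key] = min(per_exp.get(key, 1.0), p)

    aggregate: dict[str, float] = {}
    ctrl_all = sub.loc[sub["gene"] == control_gene, "value"].to_numpy()
    if len(ctrl_all) >= 2:
        for line_id, grp in sub[sub["gene"] != control_gene].groupby("line_id"):
            vals = grp["value"].to_numpy()
            if len(vals) < 2:
                continue
            if np.mean(vals) <= np.mean(ctrl_all):
                aggregate[str(line_id)] = 1.0
            else:
                _, p = compare_to_control(vals, ctrl_all, tail="greater")
                aggregate[str(line_id)] = p
    return per_exp, aggregate


def analyze_screen(
    table: pd.DataFrame, control_gene: str = "w"
) -> dict[str, ScreenCall]:
    """Full screen workflow: lethality gate, translocation, conditional
    overgrowth, dual significance criterion, driver classification.

    Returns per-gene calls (a gene is a hit when any of its lines is).
    """
    line_gene = dict(
        zip(table["line_id"].astype(str), table["gene"].astype(str))
    )
    line_group = dict(
        zip(table["line_id"].astype(str), table["group"].astype(str))
    )

    leth_p = _per_line_lethality(table, control_gene)
    line_leth = {line: lethality_hit(ps) for line, ps in leth_p.items()}

    trans_exp, trans_agg = _per_line_phenotype(table, "translocation", control_gene)
    trans_lines = sorted(trans_agg)
    trans_fdr = dict(zip(trans_lines, bh_fdr([trans_agg[l] for l in trans_lines])))
    line_trans = {
        line: phenotype_hit(trans_exp.get(line, 1.0), trans_fdr[line])
        for line in trans_lines
    }

    grow_exp, grow_agg = _per_line_phenotype(table, "overgrowth", control_gene)
    grow_lines = sorted(grow_agg)
    grow_fdr = dict(zip(grow_lines, bh_fdr([grow_agg[l] for l in grow_lines])))
    line_grow = {
        line: phenotype_hit(grow_exp.get(line, 1.0), grow_fdr[line])
        for line in grow_lines
    }

    calls: dict[str, ScreenCall] = {}
    for line, gene in line_gene.items():
        if gene == control_gene:
            continue
        call = calls.setdefault(gene, ScreenCall(gene=gene, group=line_group[line]))
        if line in leth_p:
            call.lethality_pvalues.extend(leth_p[line])
        if line_leth.get(line):
            call.lethality_hit = True
        if line in line_trans:
            call.translocation_hit = call.translocation_hit or line_trans[line]
            p, f = trans_exp.get(line, 1.0), trans_fdr[line]
            if call.translocation_p is None or p < call.translocation_p:
                call.translocation_p, call.translocation_fdr = p, f
        # overgrowth counts only for translocation-negative lines (workflow order)
        if line in line_grow and not line_trans.get(line, False):
            call.overgrowth_tested = True
            call.overgrowth_hit = call.overgrowth_hit or line_grow[line]
            p, f = grow_exp.get(line, 1.0), grow_fdr[line]
            if call.overgrowth_p is None or p < call.overgrowth_p:
                call.overgrowth_p, call.overgrowth_fdr = p, f
    for call in calls.values():
        call.driver = classify_driver(
            call.lethality_hit, call.translocation_hit, call.overgrowth_hit
        )
    return calls
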