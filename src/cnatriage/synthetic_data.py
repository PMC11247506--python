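"""Synthetic cohort and screen generator with planted ground truth.

The generator emits every input the triage pipeline consumes — SNP-array
segments, expression, MAF, sample metadata, survival endpoints, region
definitions, gene annotation, ortholog tables and screen replicate counts —
from a forward model that *inverts* the pipeline's purity adjustment:

    observed fold = TP * (tumor fold) + (1 - TP)

so that, absent noise, the adjustment recovers the planted tumor fold
exactly.  Planted drivers carry their alteration direction at a per-driver
clonal fraction among TNBC samples, couple expression to copy number with a
configurable dosage slope, and optionally carry a survival hazard; passengers
are altered at a background rate with no dosage coupling.  Decoy genes
(deleted-with-increased-expression, amplified-with-reduced-expression) are
planted deliberately to exercise the directional retention rules.

The defaults are the study conditions — 110 TNBC among 772 tumors, mean
purity 0.7, segment noise 0.1 on the log2 scale, TP53 mutated in 80% of TNBC,
eight screen replicates in two independent experiments — and are not tuned
per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from cnatriage import core_io
from cnatriage.core_io import (
    CNARegionDef,
    GeneAnnotation,
    MutationRecord,
    RegionSource,
    SampleMeta,
    SegmentRecord,
    SurvivalRecord,
)

FLY_PREFIX = "d"


@dataclass(frozen=True)
class RegionSpec:
    """Layout of one synthetic CNA region."""

    size: int
    source: RegionSource
    nominal_type: str  # amp | del
    driver_direction: str | None = "same"  # same | amplified | deleted | None
    decoy: str | None = None  # None | "deleted_up" | "amplified_down"


def default_region_layout() -> list[RegionSpec]:
    """Eight regions exercising every group-assignment path.

    Region 8 is an ISAR amplification whose planted driver is deleted in the
    TNBC subset (the 2I scenario); region 6's driver symbol is shared with a
    small GISTIC amplification (region 9), creating an amp+del membership
    (the 2G scenario).  Regions 6 and 7 carry a deleted-with-increased-
    expression decoy; region 2 an amplified-with-reduced-expression decoy.
    """
    return [
        RegionSpec(6, RegionSource.ISAR_TOTAL, "amp"),
        RegionSpec(8, RegionSource.ISAR_BASAL, "amp", decoy="amplified_down"),
        RegionSpec(14, RegionSource.ISAR_TOTAL, "amp"),
        RegionSpec(5, RegionSource.GISTIC_TOTAL_AMP, "amp"),
        RegionSpec(8, RegionSource.GISTIC_BASAL_AMP, "amp"),
        RegionSpec(6, RegionSource.GISTIC_TOTAL_DEL, "del", decoy="deleted_up"),
        RegionSpec(9, RegionSource.GISTIC_BASAL_DEL, "del", decoy="deleted_up"),
        RegionSpec(5, RegionSource.ISAR_BASAL, "amp", driver_direction="deleted"),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort and screen; defaults are the study scale."""

    seed: int = 0
    n_tnbc: int = 110
    n_other: int = 662
    region_layout: list[RegionSpec] = field(default_factory=default_region_layout)
    clonal_fraction_range: tuple[float, float] = (0.3, 0.8)
    passenger_alt_rate: float = 0.08  # region-direction background among TNBC
    passenger_opposite_rate: float = 0.03
    driver_rate_other: float = 0.10  # driver alteration rate outside TNBC
    dosage_slope: float = 3.0  # expression SDs per unit of (ACN - 1)
    purity_beta: tuple[float, float] = (7.0, 3.0)  # mean 0.7
    purity_missing_rate: float = 0.05
    segment_noise_sd: float = 0.1  # log2-scale
    segment_split_rate: float = 0.02  # gene straddles two segments -> missing
    tp53_mutation_rate: float = 0.8
    background_mutation_rate: float = 0.02
    n_low_sd_genes: int = 2
    survival_baseline_rate: float = 1.0 / 1500.0  # events per day
    survival_log_hr: float = np.log(2.0)
    n_survival_drivers: int = 2
    # screen
    screen_replicates: int = 8  # two biological replicates x four flips
    screen_experiments: int = 2
    control_eclosion: float = 0.85
    driver_lethality_effect: float = 0.3  # relative eclosion reduction
    control_translocation_mean: float = 5.0
    control_translocation_sd: float = 2.0
    translocation_effect_sds: float = 2.0
    control_overgrowth_mean: float = 0.20
    control_overgrowth_sd: float = 0.03
    overgrowth_effect_sds: float = 2.0

    def validate(self) -> None:
        lo, hi = self.clonal_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("clonal_fraction_range must lie in (0, 1]")
        for name in (
            "passenger_alt_rate",
            "passenger_opposite_rate",
            "driver_rate_other",
            "purity_missing_rate",
            "segment_split_rate",
            "tp53_mutation_rate",
            "background_mutation_rate",
            "driver_lethality_effect",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_tnbc < 2 or self.n_other < 0:
            raise ValueError("cohort sizes invalid")
        for spec in self.region_layout:
            if spec.size < 1:
                raise ValueError("region size must be >= 1")


def null_config(seed: int = 0) -> SimulationConfig:
    """No planted effects anywhere: drivers behave like passengers."""
    cfg = SimulationConfig(seed=seed)
    cfg.region_layout = [replace(s, driver_direction=None, decoy=None) for s in cfg.region_layout]
    cfg.dosage_slope = 0.0
    cfg.survival_log_hr = 0.0
    cfg.driver_lethality_effect = 0.0
    cfg.translocation_effect_sds = 0.0
    cfg.overgrowth_effect_sds = 0.0
    return cfg


def hard_config(seed: int = 0) -> SimulationConfig:
    """Weaker signal: low clonal fractions, shallow dosage, noisier segments."""
    cfg = SimulationConfig(seed=seed)
    cfg.clonal_fraction_range = (0.15, 0.35)
    cfg.dosage_slope = 1.0
    cfg.segment_noise_sd = 0.2
    return cfg


PRESETS = {"default": SimulationConfig, "null": null_config, "hard": hard_config}


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside the synthetic files."""

    gene_truth: pd.DataFrame  # symbol, region_id, is_driver, direction, ...
    sample_truth: pd.DataFrame  # sample_id, is_tnbc, purity
    tumor_fold: pd.DataFrame  # genes x samples planted tumor fold
    line_truth: pd.DataFrame | None = None  # screen lines, when simulated


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort; ``write`` materializes the input files."""

    segments: list[SegmentRecord]
    expression: pd.DataFrame
    mutations: list[MutationRecord]
    samples: list[SampleMeta]
    survival: list[SurvivalRecord]
    regions: list[CNARegionDef]
    annotation: list[GeneAnnotation]
    truth: PlantedTruth

    @property
    def tnbc_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.is_tnbc]

    @property
    def purity(self) -> dict[str, float]:
        return {s.sample_id: s.purity for s in self.samples if s.purity is not None}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        core_io.write_segments(self.segments, outdir / "segments.seg")
        core_io.write_expression(self.expression, outdir / "expression.tsv")
        core_io.write_maf(self.mutations, outdir / "mutations.maf")
        core_io.write_sample_meta(self.samples, outdir / "samples.tsv")
        core_io.write_survival(self.survival, outdir / "survival.tsv")
        core_io.write_regions(self.regions, outdir / "regions.tsv")
        core_io.write_annotation(self.annotation, outdir / "annotation.tsv")
        export_truth(self.truth, outdir)


def _amp_fold(direction: str) -> float:
    return 1.5 if direction == "amplified" else 0.5


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort with planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- genes, regions, annotation -------------------------------------
    gene_rows = []  # symbol, chrom, start, end, region_id, role
    regions: list[CNARegionDef] = []
    symbol_counter = 0
    driver_symbols: list[str] = []
    g2g_driver: str | None = None

    for r_idx, spec in enumerate(config.region_layout):
        chrom = f"chr{r_idx + 1}"
        region_id = f"R{r_idx + 1}"
        members: list[str] = []
        helios: dict[str, float] = {}
        driver_here = None
        decoy_here = None
        for g_idx in range(spec.size):
            symbol_counter += 1
            symbol = f"GENE{symbol_counter:03d}"
            start = 1 + g_idx * 20_000
            end = start + 9_999
            members.append(symbol)
            role = "passenger"
            if g_idx == 0 and spec.driver_direction is not None:
                role = "driver"
                driver_here = symbol
                driver_symbols.append(symbol)
            elif g_idx == 1 and spec.decoy is not None:
                role = spec.decoy
                decoy_here = symbol
            gene_rows.append((symbol, chrom, start, end, region_id, role))
        if spec.source.is_isar:
            for m in members:
                if m == driver_here:
                    helios[m] = float(rng.uniform(0.8, 1.0))
                else:
                    helios[m] = float(rng.uniform(0.0, 0.3))
        regions.append(
            CNARegionDef(
                region_id=region_id,
                source=spec.source,
                nominal_type=spec.nominal_type,
                members=tuple(members),
                helios=helios or None,
            )
        )
        del decoy_here

    # 2G scenario: the deleted driver of the first GISTIC del region also sits
    # in a small GISTIC amplification on the same chromosome.
    del_regions = [
        (i, r)
        for i, r in enumerate(regions)
        if r.nominal_type == "del" and config.region_layout[i].driver_direction
    ]
    if del_regions:
        i, reg = del_regions[0]
        shared = reg.members[0]
        regions.append(
            CNARegionDef(
                region_id=f"R{len(regions) + 1}",
                source=RegionSource.GISTIC_TOTAL_AMP,
                nominal_type="amp",
                members=(shared,),
            )
        )
        g2g_driver = shared

    # TP53-like mutation target and low-SD genes live outside CNA regions
    extra_genes = ["TP53"] + [
        f"LOWSD{i + 1:02d}" for i in range(config.n_low_sd_genes)
    ]
    for k, symbol in enumerate(extra_genes):
        gene_rows.append((symbol, "chr99", 1 + k * 20_000, 10_000 + k * 20_000, "", "extra"))

    genes = pd.DataFrame(
        gene_rows, columns=["symbol", "chrom", "start", "end", "region_id", "role"]
    ).set_index("symbol")
    cna_genes = genes[genes["region_id"] != ""]

    annotation = [
        GeneAnnotation(
            symbol=sym,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            fly_ortholog=f"{FLY_PREFIX}{sym}",
        )
        for sym, row in genes.iterrows()
    ]

    # --- samples ----------------------------------------------------------
    n = config.n_tnbc + config.n_other
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    is_tnbc = np.zeros(n, dtype=bool)
    is_tnbc[: config.n_tnbc] = True
    a, b = config.purity_beta
    purity = rng.beta(a, b, size=n)
    purity = np.clip(purity, 0.05, 1.0)
    purity_missing = rng.random(n) < config.purity_missing_rate

    samples = [
        SampleMeta(
            sample_id=sid,
            is_tnbc=bool(t),
            purity=None if miss else float(p),
            sample_class="primary_tumor",
        )
        for sid, t, p, miss in zip(sample_ids, is_tnbc, purity, purity_missing)
    ]

    # --- per-gene planted parameters --------------------------------------
    lo, hi = config.clonal_fraction_range
    gene_param_rows = []
    region_by_id = {r.region_id: r for r in regions}
    for sym, row in cna_genes.iterrows():
        region = region_by_id[row.region_id]
        spec = config.region_layout[int(row.region_id[1:]) - 1]
        if row.role == "driver":
            direction = (
                spec.driver_direction
                if spec.driver_direction in ("amplified", "deleted")
                else ("amplified" if region.nominal_type == "amp" else "deleted")
            )
            freq = float(rng.uniform(lo, hi))
            slope = config.dosage_slope
            is_driver = True
        elif row.role == "deleted_up":
            direction = "deleted"
            freq = float(rng.uniform(lo, hi))
            slope = -config.dosage_slope  # increased expression when deleted
            is_driver = False
        elif row.role == "amplified_down":
            direction = "amplified"
            freq = float(rng.uniform(lo, hi))
            slope = -config.dosage_slope  # reduced expression when amplified
            is_driver = False
        else:
            direction = "amplified" if region.nominal_type == "amp" else "deleted"
            freq = config.passenger_alt_rate
            slope = 0.0
            is_driver = False
        gene_param_rows.append((sym, row.region_id, row.role, is_driver, direction, freq, slope))
    gene_params = pd.DataFrame(
        gene_param_rows,
        columns=["symbol", "region_id", "role", "is_driver", "direction", "clonal_fraction", "dosage_slope"],
    ).set_index("symbol")

    # --- planted tumor folds ----------------------------------------------
    cna_symbols = list(cna_genes.index)
    tumor_fold = np.ones((len(cna_symbols), n))
    for i, sym in enumerate(cna_symbols):
        par = gene_params.loc[sym]
        rate_tnbc = par.clonal_fraction
        rate_other = (
            config.driver_rate_other if par.is_driver or par.role in ("deleted_up", "amplified_down")
            else config.passenger_alt_rate
        )
        rates = np.where(is_tnbc, rate_tnbc, rate_other)
        carrier = rng.random(n) < rates
        fold = _amp_fold(par.direction)
        tumor_fold[i, carrier] = fold
        # occasional opposite-direction background alterations
        opp = (rng.random(n) < config.passenger_opposite_rate) & ~carrier
        tumor_fold[i, opp] = _amp_fold(
            "deleted" if par.direction == "amplified" else "amplified"
        )
    tumor_fold_df = pd.DataFrame(tumor_fold, index=cna_symbols, columns=sample_ids)

    # --- segments ----------------------------------------------------------
    observed = purity[None, :] * tumor_fold + (1.0 - purity[None, :])
    log2_obs = np.log2(observed) + rng.normal(
        0.0, config.segment_noise_sd, size=observed.shape
    )
    split = rng.random(observed.shape) < config.segment_split_rate
    segments: list[SegmentRecord] = []
    for j, sid in enumerate(sample_ids):
        for i, sym in enumerate(cna_symbols):
            row = cna_genes.loc[sym]
            val = round(float(log2_obs[i, j]), 6)
            if split[i, j]:
                mid = (int(row.start) + int(row.end)) // 2
                segments.append(SegmentRecord(sid, row.chrom, int(row.start), mid, val))
                segments.append(SegmentRecord(sid, row.chrom, mid + 1, int(row.end), val))
            else:
                segments.append(
                    SegmentRecord(sid, row.chrom, int(row.start), int(row.end), val)
                )

    # --- expression ---------------------------------------------------------
    all_symbols = list(genes.index)
    mu = rng.uniform(4.0, 10.0, size=len(all_symbols))
    sd = np.ones(len(all_symbols))
    for k, sym in enumerate(all_symbols):
        if sym.startswith("LOWSD"):
            sd[k] = 0.05
    log_expr = mu[:, None] + sd[:, None] * rng.normal(size=(len(all_symbols), n))
    for i, sym in enumerate(cna_symbols):
        slope = gene_params.loc[sym, "dosage_slope"]
        if slope != 0.0:
            k = all_symbols.index(sym)
            log_expr[k] += slope * (tumor_fold[i] - 1.0) * sd[k]
    expression = pd.DataFrame(
        np.maximum(np.power(2.0, log_expr) - 1.0, 0.0),
        index=all_symbols,
        columns=sample_ids,
    ).round(4)

    # --- MAF -----------------------------------------------------------------
    encodable = [
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Nonstop_Mutation",
        "RNA",
    ]
    weights = np.array([0.45, 0.2, 0.1, 0.08, 0.07, 0.04, 0.03, 0.02, 0.01])
    mutations: list[MutationRecord] = []
    tp53_carriers = rng.random(n) < np.where(is_tnbc, config.tp53_mutation_rate, 0.3)
    for j, sid in enumerate(sample_ids):
        if tp53_carriers[j]:
            cls = str(rng.choice(encodable, p=weights / weights.sum()))
            mutations.append(MutationRecord(sid, "TP53", cls))
        for sym in driver_symbols:
            if rng.random() < config.background_mutation_rate:
                cls = str(rng.choice(encodable, p=weights / weights.sum()))
                mutations.append(MutationRecord(sid, sym, cls))

    # --- survival -------------------------------------------------------------
    survival_drivers = driver_symbols[: config.n_survival_drivers]
    log_hr = {sym: config.survival_log_hr for sym in survival_drivers}
    survival: list[SurvivalRecord] = []
    for endpoint in ("OS", "PFI"):
        hazard = np.full(n, config.survival_baseline_rate)
        for sym in survival_drivers:
            i = cna_symbols.index(sym)
            altered = tumor_fold[i] != 1.0
            hazard = hazard * np.where(altered, np.exp(config.survival_log_hr), 1.0)
        times = rng.exponential(1.0 / hazard)
        censor = rng.uniform(200.0, 3000.0, size=n)
        observed_t = np.minimum(times, censor)
        event = times <= censor
        for sid, t, e in zip(sample_ids, observed_t, event):
            survival.append(SurvivalRecord(sid, endpoint, round(float(t), 2), bool(e)))

    # --- truth -----------------------------------------------------------------
    gene_truth = gene_params.reset_index()
    gene_truth["log_hr"] = [log_hr.get(s, 0.0) for s in gene_truth["symbol"]]
    gene_truth["in_group2_scenario"] = gene_truth["symbol"] == g2g_driver
    sample_truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "is_tnbc": is_tnbc,
            "purity": purity,
            "purity_reported": ~purity_missing,
            "tp53_mutant": tp53_carriers,
        }
    )
    truth = PlantedTruth(
        gene_truth=gene_truth,
        sample_truth=sample_truth,
        tumor_fold=tumor_fold_df,
    )
    return SyntheticCohort(
        segments=segments,
        expression=expression,
        mutations=mutations,
        samples=samples,
        survival=survival,
        regions=regions,
        annotation=annotation,
        truth=truth,
    )


def make_ortholog_tables(
    annotation: list[GeneAnnotation],
    seed: int = 0,
    ambiguous_fraction: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Five-source ortholog vote tables consistent with the annotation.

    Most genes get unanimous votes for their annotated fly gene; a small
    fraction is made ambiguous (votes split with no strict majority).
    """
    rng = np.random.default_rng(seed)
    sources = ("DroID", "DIOPT", "HomoloGene", "Ensembl", "OrthoDB")
    rows: dict[str, list[tuple[str, str, float]]] = {s: [] for s in sources}
    for gene in annotation:
        if gene.fly_ortholog is None:
            continue
        if rng.random() < ambiguous_fraction:
            # 2-2-1 split: no strict majority
            alts = [gene.fly_ortholog, f"{gene.fly_ortholog}-alt", f"{gene.fly_ortholog}-alt2"]
            votes = [alts[0], alts[0], alts[1], alts[1], alts[2]]
        else:
            votes = [gene.fly_ortholog] * 5
        for src, fly in zip(sources, votes):
            rows[src].append((gene.symbol, fly, float(rng.uniform(0.5, 1.0))))
    return {
        src: pd.DataFrame(data, columns=["human", "fly", "score"])
        for src, data in rows.items()
    }


# ---------------------------------------------------------------------------
# screen simulation


def simulate_screen(
    config: SimulationConfig,
    genes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate fly-cross replicate tables for a prioritized gene list.

    ``genes`` needs columns ``symbol``, ``group``, ``direction`` and
    ``is_driver``.  Planted drivers reduce eclosion (and the non-tubby
    fraction) by ``driver_lethality_effect`` and shift one tissue phenotype by
    the configured number of control SDs; 70% of drivers act through
    translocation, the rest through overgrowth only.  Control crosses (gene
    ``w``) are drawn from the control distributions; balancer bookkeeping
    follows the Mendelian 1:1 expectation scaled by experimental-arm
    viability.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    rows = []
    line_truth_rows = []

    def lethality_rows(line_id, gene, group, direction, viability):
        for exp in range(1, config.screen_experiments + 1):
            for rep in range(1, config.screen_replicates + 1):
                total_prog = int(rng.poisson(90) + 10)
                nontubby = int(rng.binomial(total_prog, 0.5 * viability))
                tubby = total_prog - nontubby
                n_pupae = max(nontubby, 1)
                p_ecl = np.clip(
                    config.control_eclosion * viability + rng.normal(0.0, 0.03), 0.01, 1.0
                )
                empty = int(rng.binomial(n_pupae, p_ecl))
                rows.append(
                    (
                        line_id, gene, group, direction, f"E{exp}", f"rep{rep}",
                        "lethality", empty, n_pupae - empty, tubby, nontubby,
                        "", "", "",
                    )
                )

    def phenotype_rows(line_id, gene, group, direction, assay, shift_sds):
        for exp in range(1, config.screen_experiments + 1):
            for rep in range(1, config.screen_replicates + 1):
                if assay == "translocation":
                    val = rng.normal(
                        config.control_translocation_mean
                        + shift_sds * config.control_translocation_sd,
                        config.control_translocation_sd,
                    )
                    count = max(int(round(val)), 0)
                    rows.append(
                        (
                            line_id, gene, group, direction, f"E{exp}", f"rep{rep}",
                            "translocation", "", "", "", "", count, "", "",
                        )
                    )
                else:
                    disc = int(rng.normal(100_000, 5_000))
                    frac = np.clip(
                        rng.normal(
                            config.control_overgrowth_mean
                            + shift_sds * config.control_overgrowth_sd,
                            config.control_overgrowth_sd,
                        ),
                        0.0,
                        1.0,
                    )
                    rows.append(
                        (
                            line_id, gene, group, direction, f"E{exp}", f"rep{rep}",
                            "overgrowth", "", "", "", "", "", int(frac * disc), disc,
                        )
                    )

    # control line
    lethality_rows("L000", "w", "control", "overexpression", 1.0)
    phenotype_rows("L000", "w", "control", "overexpression", "translocation", 0.0)
    phenotype_rows("L000", "w", "control", "overexpression", "overgrowth", 0.0)
    line_truth_rows.append(("L000", "w", "control", False, "none", 0.0, 0.0, 0.0))

    for k, rec in enumerate(genes.itertuples(index=False), start=1):
        line_id = f"L{k:03d}"
        direction = "overexpression" if rec.direction == "amplified" else "rnai"
        if bool(rec.is_driver):
            viability = 1.0 - config.driver_lethality_effect
            mechanism = "translocation" if rng.random() < 0.7 else "overgrowth"
            trans_shift = (
                config.translocation_effect_sds if mechanism == "translocation" else 0.0
            )
            grow_shift = (
                config.overgrowth_effect_sds if mechanism == "overgrowth" else 0.0
            )
        else:
            viability, mechanism, trans_shift, grow_shift = 1.0, "none", 0.0, 0.0
        lethality_rows(line_id, rec.symbol, rec.group, direction, viability)
        phenotype_rows(line_id, rec.symbol, rec.group, direction, "translocation", trans_shift)
        phenotype_rows(line_id, rec.symbol, rec.group, direction, "overgrowth", grow_shift)
        line_truth_rows.append(
            (
                line_id, rec.symbol, rec.group, bool(rec.is_driver), mechanism,
                1.0 - viability, trans_shift, grow_shift,
            )
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "line_id", "gene", "group", "direction", "experiment_id", "replicate_id",
            "assay", "empty_pupal_cases", "uneclosed_pupae", "tubby_pupae",
            "nontubby_pupae", "translocated_cells", "green_pixels", "disc_pixels",
        ],
    )
    line_truth = pd.DataFrame(
        line_truth_rows,
        columns=[
            "line_id", "gene", "group", "is_driver", "mechanism",
            "lethality_effect", "translocation_shift_sds", "overgrowth_shift_sds",
        ],
    )
    return table, line_truth


def export_truth(truth: PlantedTruth, outdir: str | Path) -> None:
    """Write the planted ground truth as joinable TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.sample_truth.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
    if truth.line_truth is not None:
        truth.line_truth.to_csv(outdir / "truth_lines.tsv", sep="\t", index=False)


def read_truth(outdir: str | Path) -> PlantedTruth:
    outdir = Path(outdir)
    line_path = outdir / "truth_lines.tsv"
    return PlantedTruth(
        gene_truth=pd.read_csv(outdir / "truth_genes.tsv", sep="\t"),
        sample_truth=pd.read_csv(outdir / "truth_samples.tsv", sep="\t"),
        tumor_fold=pd.DataFrame(),
        line_truth=pd.read_csv(line_path, sep="\t") if line_path.exists() else None,
    )
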