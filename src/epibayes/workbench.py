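"""Scenario configuration, replication orchestration and file I/O.

A scenario bundles the simulation and analysis settings of one experimental
cell (QTL count, epistasis on/off, broad-sense heritability, models to fit,
prior mixing probabilities, convergence settings).  ``run_scenario`` runs
the full pipeline per replicate — simulate the base population, breed
half-sib training/test generations, thin the marker panel, sample the trait
architecture, calibrate the residual variance, fit each requested model and
evaluate it on the test generations — fully deterministically given the
master seed.

Two profiles are provided: the ``full`` profile simulates the full
52,273-SNP genome and analyses every 10th marker; the ``scaled`` profile
simulates the analysis panel (5,227 SNPs on the same 30 Morgan map, i.e.
the same marker density the thinned panel would have) directly, which
leaves the population-genetic and statistical properties of the analysis
essentially unchanged at a fraction of the cost.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design, evaluate, fbayesb, popsim, traitsim
from .design import EPISTASIS_SOURCES, SOURCE_FACTORS

__all__ = [
    "ScenarioConfig",
    "ReplicateResult",
    "PanelContext",
    "build_panel_context",
    "draw_trait",
    "simulate_population",
    "run_replicate",
    "run_scenario",
    "summarize",
    "true_genetic_values",
    "write_vcf",
    "write_dosage_tsv",
    "write_pedigree_tsv",
    "write_phenotypes_tsv",
    "load_genotypes",
    "GenotypeData",
]

_MAX_M2_EFFECTS = 1_000_000_000  # beyond this a pair sweep is not feasible


@dataclass
class ScenarioConfig:
    """Settings of one simulation-study cell.

    The defaults of everything the estimator and simulator consume follow
    the dairy-cattle study design: Ne = 100, 400 generations, 30 x 1 Morgan
    chromosomes, mutation rate 2.5e-3 per locus per transmitted gamete,
    two training and two test generations of 50 half-sib families with 20
    offspring, MAF filter 0.01, QTL eligibility MAF > 0.02, gamma_a =
    gamma_d = 0.005 (23 QTL) or 0.05 (230 QTL) with gamma = 1e-6 for the
    pair sources, and L = 1e-8 / k_max = 1000 for M0/M1 versus L = 1e-6 /
    k_max = 200 for M2.
    """

    n_qtl: int = 23
    epistasis: bool = False
    h2: float = 0.5
    models: tuple[str, ...] = ("M1",)
    n_markers: int = 52_273
    thin_step: int = 10
    maf_threshold: float = 0.01
    qtl_maf_threshold: float = 0.02
    n_chromosomes: int = 30
    chromosome_length: float = 1.0
    effective_size: int = 100
    mutation_rate: float = 2.5e-3
    n_generations: int = 400
    n_families: int = 50
    n_offspring: int = 20
    n_train_generations: int = 2
    n_test_generations: int = 2
    gamma_main: float | None = None
    gamma_epi: float = 1e-6
    L: float | None = None
    k_max: int | None = None
    n_replicates: int = 10
    seed: int = 1

    @classmethod
    def scaled(cls, **kw) -> "ScenarioConfig":
        """Desk-scale profile: simulate the 5,227-marker analysis panel directly."""
        kw.setdefault("n_markers", 5_227)
        kw.setdefault("thin_step", 1)
        return cls(**kw)

    @property
    def gammas(self) -> dict[str, float]:
        g_main = self.gamma_main
        if g_main is None:
            g_main = 0.005 if self.n_qtl <= 100 else 0.05
        return {"a": g_main, "d": g_main, "epi": self.gamma_epi}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["models"] = list(d["models"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class ReplicateResult:
    """Everything one replicate produced, for reporting and inspection."""

    replicate: int
    seed: int
    population: popsim.Population
    panel: np.ndarray               # thinned marker indices into the genome
    retained: np.ndarray            # post MAF-filter indices into the panel
    architecture: traitsim.TraitArchitecture
    truth: traitsim.OrthogonalTruth
    sigma_e2: float
    reports: dict[str, evaluate.EvaluationReport]
    fits: dict[str, fbayesb.FitResult]
    marker_summary: dict[str, float]


def true_genetic_values(oriented_panel: np.ndarray,
                        coding: design.OrthogonalCoding,
                        truth: traitsim.OrthogonalTruth,
                        arch: traitsim.TraitArchitecture) -> dict[str, np.ndarray]:
    """Per-source true genetic values for a set of individuals.

    Evaluates the standardized orthogonal truth at the QTL columns only
    (all other true effects are zero).  ``oriented_panel`` is the
    frequent-allele-count matrix over the full analysis panel.
    """
    qtl = np.asarray(arch.qtl)
    local = {int(q): i for i, q in enumerate(qtl)}
    blocks_q = design.build_design(oriented_panel[:, qtl], coding.subset(qtl))
    parts = {
        "a": blocks_q.Xa @ truth.g_a[qtl],
        "d": blocks_q.Xd @ truth.g_d[qtl],
    }
    for source in EPISTASIS_SOURCES:
        pairs = truth.epi_pairs.get(source)
        if pairs is None or len(pairs) == 0:
            continue
        vals = np.zeros(blocks_q.n_individuals)
        for (j, k), e in zip(pairs, truth.epi_effects[source]):
            lj, lk = local[int(j)], local[int(k)]
            vals += e * design.interaction_column(blocks_q, source, lj, lk)
        parts[source] = vals
    parts["total"] = np.sum(list(parts.values()), axis=0)
    return parts


@dataclass
class PanelContext:
    """A simulated population prepared for analysis on its marker panel."""

    population: popsim.Population
    panel: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    base_idx: np.ndarray
    base_stats: popsim.MarkerStats
    train_stats: popsim.MarkerStats
    oriented: np.ndarray
    coding: design.OrthogonalCoding
    retained: np.ndarray
    qtl_candidates: np.ndarray


def build_panel_context(pop: popsim.Population,
                        config: ScenarioConfig) -> PanelContext:
    """Thin the panel, freeze training-based coding, find QTL candidates."""
    gen0 = int(pop.generation.min())
    train_gens = gen0 + 1 + np.arange(config.n_train_generations)
    test_gens = train_gens[-1] + 1 + np.arange(config.n_test_generations)
    train_idx = pop.individuals_in(train_gens)
    test_idx = pop.individuals_in(test_gens)
    base_idx = pop.individuals_in([gen0])

    panel = popsim.thin_markers(pop.genome.n_markers, config.thin_step)
    geno_panel = pop.genotypes[:, panel]
    base_stats = popsim.compute_marker_stats(
        geno_panel, base_idx, config.maf_threshold)
    train_stats = popsim.compute_marker_stats(
        geno_panel, train_idx, config.maf_threshold)
    oriented = popsim.oriented_genotypes(geno_panel, train_stats)
    coding = design.orthogonal_coding(
        train_stats.p11, train_stats.p12, train_stats.p22)
    retained = np.where(train_stats.retained)[0]
    candidates = np.where(base_stats.maf > config.qtl_maf_threshold)[0]
    return PanelContext(pop, panel, train_idx, test_idx, base_idx, base_stats,
                        train_stats, oriented, coding, retained, candidates)


def draw_trait(ctx: PanelContext, config: ScenarioConfig, rng_arch, rng_epi):
    """Sample one trait architecture on a prepared panel and translate it.

    Returns ``(arch, truth, G_all, sigma_e2)`` with ``G_all`` the
    F-infinity genotypic values of every individual and ``sigma_e2``
    calibrated to the configured broad-sense heritability on the training
    individuals.
    """
    gamma_rate = 2.619 if config.n_qtl <= 100 else 8.282
    qtl = np.sort(rng_arch.choice(ctx.qtl_candidates, size=config.n_qtl,
                                  replace=False))
    a, d = traitsim.sample_main_effects(config.n_qtl, rng_arch,
                                        gamma_rate=gamma_rate)
    arch = traitsim.TraitArchitecture(qtl=qtl, a=a, d=d, h2_broad=config.h2)
    if config.epistasis:
        params = (traitsim.EPISTASIS_PARAMS_23 if config.n_qtl <= 100
                  else traitsim.EPISTASIS_PARAMS_230)
        npairs = 6 if config.n_qtl <= 100 else 57
        arch.epi_pairs, arch.epi_effects = traitsim.sample_epistatic_pairs(
            qtl, npairs, params, rng_epi)
    G_all = traitsim.genotypic_values_finf(ctx.oriented, arch)
    sigma_e2 = traitsim.calibrate_residual_variance(G_all[ctx.train_idx],
                                                    config.h2)
    arch.sigma_e2 = sigma_e2
    truth = traitsim.marginal_main_effects(arch, ctx.coding)
    return arch, truth, G_all, sigma_e2


def simulate_population(config: ScenarioConfig, rng_pop) -> popsim.Population:
    """Base population plus half-sib training/test generations."""
    genome = popsim.GenomeMap.uniform_random(
        config.n_markers, rng_pop, config.n_chromosomes, config.chromosome_length)
    base = popsim.simulate_base_population(
        genome, config.effective_size, config.mutation_rate,
        config.n_generations, rng_pop)
    return popsim.breed_structured_generations(
        base, config.n_families, config.n_offspring,
        config.n_train_generations, config.n_test_generations, rng_pop,
        mutation_rate=config.mutation_rate)


def run_replicate(config: ScenarioConfig, replicate: int,
                  seed_seq: np.random.SeedSequence) -> ReplicateResult:
    """Simulate, fit and evaluate one replicate of a scenario."""
    # independent child streams so with/without-epistasis runs of the same
    # master seed share the population, QTL placement and main effects
    ss_pop, ss_arch, ss_epi, ss_noise = seed_seq.spawn(4)
    rng_pop = np.random.default_rng(ss_pop)
    rng_arch = np.random.default_rng(ss_arch)
    rng_epi = np.random.default_rng(ss_epi)
    rng_noise = np.random.default_rng(ss_noise)
    rep_seed = int(seed_seq.generate_state(1)[0] & 0x7FFFFFFF)

    pop = simulate_population(config, rng_pop)
    ctx = build_panel_context(pop, config)
    train_idx, test_idx = ctx.train_idx, ctx.test_idx
    panel, oriented = ctx.panel, ctx.oriented
    train_stats, coding_full = ctx.train_stats, ctx.coding

    arch, truth, G_all, sigma_e2 = draw_trait(ctx, config, rng_arch, rng_epi)
    y = traitsim.simulate_phenotypes(G_all[train_idx], sigma_e2, rng_noise)

    retained = ctx.retained
    coding_fit = coding_full.subset(retained)
    blocks_train = design.build_design(oriented[train_idx][:, retained], coding_fit)
    blocks_test = design.build_design(oriented[test_idx][:, retained], coding_fit)

    true_test = true_genetic_values(oriented[test_idx], coding_full, truth, arch)
    true_comp = truth.components
    # realized narrow-sense heritability: additive share of the genetic
    # variance times the configured broad-sense heritability
    h2_realized = config.h2 * true_comp["a"] / sum(true_comp.values())

    marker_summary = {
        "het_mean": float(train_stats.het.mean()),
        "n_panel": int(len(panel)),
        "n_retained": int(len(retained)),
        "n_removed_maf": int(len(panel) - len(retained)),
    }

    scenario_tag = (f"{config.n_qtl}qtl-"
                    f"{'epi' if config.epistasis else 'noepi'}-H2{config.h2}")
    reports: dict[str, evaluate.EvaluationReport] = {}
    fits: dict[str, fbayesb.FitResult] = {}
    for model in config.models:
        counts = design.model_design(len(retained), model)
        if sum(counts.values()) > _MAX_M2_EFFECTS:
            raise ValueError(
                f"{model} with {len(retained)} markers means "
                f"{sum(counts.values()):,} effects; estimating billions of "
                "pair effects exceeds memory and runtime capacity — thin the "
                "panel first")
        fit = fbayesb.ice_fit(y, blocks_train, model, gammas=config.gammas,
                              L=config.L, k_max=config.k_max)
        fits[model] = fit
        pred = fbayesb.predict_dgv(blocks_test, fit.estimates)
        acc = evaluate.accuracy(pred["total"], true_test["total"])
        top10 = evaluate.top_fraction_accuracy(pred["a"], true_test["a"], 0.1)
        reports[model] = evaluate.EvaluationReport(
            scenario=scenario_tag, model=model, replicate=replicate,
            seed=rep_seed, accuracy=acc, top10_accuracy=top10,
            components_le=fit.variance_components(),
            components_empirical=evaluate.empirical_variance_components(pred),
            true_components=true_comp,
            sigma_e2_hat=fit.sigma_e2, sigma_e2_true=sigma_e2,
            h2_realized=h2_realized, converged=fit.converged,
            n_iter=fit.n_iter)

    return ReplicateResult(replicate=replicate, seed=rep_seed, population=pop,
                           panel=panel, retained=retained, architecture=arch,
                           truth=truth, sigma_e2=sigma_e2, reports=reports,
                           fits=fits, marker_summary=marker_summary)


def run_scenario(config: ScenarioConfig, *, keep_replicates: bool = False):
    """Run all replicates of a scenario.

    Returns ``(frame, replicates)`` where ``frame`` has one row per
    replicate x model and ``replicates`` is the list of
    :class:`ReplicateResult` (empty unless ``keep_replicates``).
    Deterministic given ``config.seed``.
    """
    # up-front feasibility check so a doomed scenario fails fast
    approx_m = config.n_markers // config.thin_step
    for model in config.models:
        if sum(design.model_design(approx_m, model).values()) > _MAX_M2_EFFECTS:
            raise ValueError(
                f"{model} on a ~{approx_m}-marker panel is not feasible: "
                "billions of pair effects exceed memory capacity")

    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rows = []
    results = []
    fingerprint = config.fingerprint()
    for rep, child in enumerate(children):
        res = run_replicate(config, rep, child)
        for model, report in res.reports.items():
            row = report.to_row()
            row.update(h2=config.h2, n_qtl=config.n_qtl,
                       epistasis=config.epistasis, fingerprint=fingerprint)
            row.update(res.marker_summary)
            rows.append(row)
        if keep_replicates:
            results.append(res)
    frame = pd.DataFrame(rows)
    return frame, results


_LAYOUT_COLUMNS = {
    "table2": ["var_a_le", "var_d_le", "var_aa_le", "var_ad_le", "var_da_le",
               "var_dd_le", "sigma_e2_hat", "accuracy"],
    "table3": ["additive_ratio_hat", "additive_ratio_true"],
    "table4": ["accuracy", "top10_accuracy"],
    "table5": ["var_a_le", "var_d_le", "var_aa_le", "var_ad_le", "var_da_le",
               "var_dd_le", "sigma_e2_hat", "accuracy"],
    "table6": ["var_a_le", "var_d_le", "var_a_emp", "var_d_emp", "var_epi_emp"],
}


def summarize(frame: pd.DataFrame, layout: str = "table2") -> pd.DataFrame:
    """Aggregate replicate rows into means and standard deviations.

    Only converged replicates enter the averages; the converged count is
    reported per cell.  Layouts mirror the simulation-study summary tables
    (estimated components, additive ratios, accuracy by heritability,
    empirical vs LE components).
    """
    if layout not in _LAYOUT_COLUMNS:
        raise ValueError(f"unknown layout {layout!r}")
    if frame.empty:
        return pd.DataFrame()
    ok = frame[frame["converged"]]
    keys = [c for c in ("scenario", "h2", "model") if c in ok.columns]
    cols = [c for c in _LAYOUT_COLUMNS[layout] if c in ok.columns]
    agg = ok.groupby(keys)[cols].agg(["mean", "std"])
    agg["n_converged"] = ok.groupby(keys).size()
    agg["n_total"] = frame.groupby(keys).size()
    return agg


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

@dataclass
class GenotypeData:
    """Genotypes loaded from disk: allele-1 dosage plus marker metadata."""

    ids: list[str]
    marker_ids: list[str]
    chromosome: np.ndarray
    position: np.ndarray  # 1-based
    dosage: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]


def _marker_coords(genome: popsim.GenomeMap):
    """1-based integer coordinates (chrom, pos) from the Morgan map."""
    chrom = genome.chromosome + 1
    within = genome.positions - genome.chromosome * genome.chromosome_length
    pos = np.floor(within * 1e6).astype(np.int64) + 1
    # enforce strictly increasing positions within each chromosome
    for c in np.unique(chrom):
        sel = np.where(chrom == c)[0]
        p = pos[sel]
        for i in range(1, len(p)):
            if p[i] <= p[i - 1]:
                p[i] = p[i - 1] + 1
        pos[sel] = p
    return chrom, pos


def _individual_ids(pop: popsim.Population):
    return [f"ind{i}" for i in range(pop.n_individuals)]


def write_vcf(path, pop: popsim.Population, individuals=None) -> None:
    """Write genotypes as a minimal uncompressed VCF 4.2 (unphased GT)."""
    idx = np.arange(pop.n_individuals) if individuals is None else np.asarray(individuals)
    geno = pop.genotypes[idx]
    chrom, pos = _marker_coords(pop.genome)
    ids = [f"ind{i}" for i in idx]
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in range(1, pop.genome.n_chromosomes + 1):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for j in range(pop.genome.n_markers):
            row = gt_strings[geno[:, j]]
            fh.write(f"{chrom[j]}\t{pos[j]}\tm{j + 1}\tA\tG\t.\t.\t.\tGT\t"
                     + "\t".join(row) + "\n")


def write_dosage_tsv(path, pop: popsim.Population, individuals=None) -> None:
    idx = np.arange(pop.n_individuals) if individuals is None else np.asarray(individuals)
    frame = pd.DataFrame(pop.genotypes[idx],
                         index=[f"ind{i}" for i in idx],
                         columns=[f"m{j + 1}" for j in range(pop.genome.n_markers)])
    frame.to_csv(path, sep="\t", index_label="id")


def write_pedigree_tsv(path, pop: popsim.Population) -> None:
    frame = pd.DataFrame({
        "id": _individual_ids(pop),
        "sire": [f"ind{s}" if s >= 0 else "." for s in pop.sire],
        "dam": [f"ind{d}" if d >= 0 else "." for d in pop.dam],
        "generation": pop.generation,
        "sex": np.where(pop.sex == 0, "M", "F"),
    })
    frame.to_csv(path, sep="\t", index=False)


def write_phenotypes_tsv(path, ids, y) -> None:
    pd.DataFrame({"id": ids, "y": y}).to_csv(path, sep="\t", index=False)


def load_genotypes(path, fmt: str | None = None,
                   impute_mean: bool = False) -> GenotypeData:
    """Load a dosage matrix from VCF 4.2 or a TSV dosage file.

    VCF records must be biallelic and diploid; missing genotypes raise
    unless ``impute_mean`` replaces them by the marker-mean dosage.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "tsv"
    if fmt == "vcf":
        return _load_vcf(path, impute_mean)
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        dosage = frame.to_numpy()
        if np.isnan(dosage).any():
            if not impute_mean:
                raise ValueError(f"missing genotypes in {path}")
            col_mean = np.nanmean(dosage, axis=0)
            nan_r, nan_c = np.where(np.isnan(dosage))
            dosage[nan_r, nan_c] = col_mean[nan_c]
        return GenotypeData(ids=[str(i) for i in frame.index],
                            marker_ids=[str(c) for c in frame.columns],
                            chromosome=np.zeros(frame.shape[1], dtype=np.int64),
                            position=np.arange(1, frame.shape[1] + 1),
                            dosage=dosage)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _load_vcf(path, impute_mean: bool) -> GenotypeData:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, marker_ids, chroms, poss = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {variant.CHROM}:{variant.POS} "
                f"({variant.ID}); only biallelic markers are supported")
        dos = np.empty(len(ids))
        for i, call in enumerate(variant.genotypes):
            alleles = call[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid call for sample {ids[i]} at "
                    f"{variant.CHROM}:{variant.POS}")
            if min(alleles) < 0:
                dos[i] = np.nan
            else:
                dos[i] = alleles[0] + alleles[1]
        if np.isnan(dos).any():
            if not impute_mean:
                raise ValueError(
                    f"missing genotype at {variant.CHROM}:{variant.POS}; "
                    "rerun with mean imputation enabled if intended")
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        rows.append(dos)
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(int(variant.CHROM))
        poss.append(variant.POS)
    return GenotypeData(ids=ids, marker_ids=marker_ids,
                        chromosome=np.array(chroms), position=np.array(poss),
                        dosage=np.array(rows).T)
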