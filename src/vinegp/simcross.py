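"""Synthetic biparental breeding populations with known truth.

This module emulates the data-generating process the rest of the pipeline
assumes: unrelated founders with phased haplotypes on a genetic map,
biparental crosses produced by Poisson (Haldane, no-interference) meiosis,
additive QTL trait architectures with a cross-level variance component,
partially replicated (p-rep) field designs with row/column/year effects,
a binary major-gene trait, and uniform genotype missingness.

Every operation is deterministic under a fixed seed. The
:class:`TruthTable` records true genotypic values and realized variance
components so that downstream estimators can be checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomat import GenotypeMatrix

__all__ = [
    "SimConfig",
    "FounderSet",
    "TraitArchitecture",
    "TruthTable",
    "simulate_founders",
    "simulate_cross",
    "simulate_trait",
    "simulate_phenotypes",
    "simulate_binary_trait",
    "degrade_genotypes",
    "simulate_program",
    "SyntheticProgram",
]


@dataclass
class SimConfig:
    """Genome and founder-panel configuration.

    ``map_length_cM`` is the genetic length of each chromosome; physical
    positions follow the fixed 1 cM = 1 Mb convention. Founder allele
    frequencies are drawn uniformly inside ``founder_maf_range``.
    """

    n_founders: int = 2
    n_chromosomes: int = 5
    snps_per_chromosome: int = 100
    map_length_cM: float = 100.0
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1 or self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("counts must be >= 1")
        if self.map_length_cM <= 0:
            raise ValueError("map_length_cM must be > 0")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must be ordered and within (0, 0.5]")


@dataclass
class FounderSet:
    """Phased founder haplotypes plus the marker map they live on.

    ``haplotypes`` has shape (n_founders, 2, n_snps) with alleles in {0, 1};
    ``markers`` carries chrom, 1-based bp pos, cM position and ref/alt;
    ``allele_freq`` is the per-SNP frequency each allele was drawn at.
    """

    haplotypes: np.ndarray
    markers: pd.DataFrame
    founder_ids: list[str]
    allele_freq: np.ndarray
    map_length_cM: float

    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(float)

    def as_genotype_matrix(self) -> GenotypeMatrix:
        ind = pd.DataFrame(
            {"cross": "", "set": "parent", "parent1": "", "parent2": ""},
            index=pd.Index(self.founder_ids, name="individual"),
        )
        return GenotypeMatrix(self.dosages(), self.markers.copy(), ind)


@dataclass
class TraitArchitecture:
    """Additive QTL architecture and variance configuration for one trait.

    ``target_h2`` is the broad-sense heritability on the genotype scale
    (genetic over genetic + residual; spatial and year variance excluded,
    matching how heritability is computed downstream).
    ``cross_variance_fraction`` is the share of the total genetic variance
    carried by cross (family) means.
    """

    name: str = "trait"
    n_qtl: int = 100
    qtl_effect_distribution: str = "gaussian"  # or "laplace", "equal"
    target_h2: float = 0.5
    cross_variance_fraction: float = 0.0
    spatial_row_var: float = 0.0
    spatial_col_var: float = 0.0
    year_var: float = 0.0
    residual_var: float = 1.0
    optimum_trait: bool = False
    mean: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must be in [0, 1]")
        if not 0.0 <= self.cross_variance_fraction < 1.0:
            raise ValueError("cross_variance_fraction must be in [0, 1)")
        for v in (self.spatial_row_var, self.spatial_col_var, self.year_var, self.residual_var):
            if v < 0:
                raise ValueError("variances must be >= 0")
        if self.qtl_effect_distribution not in ("gaussian", "laplace", "equal"):
            raise ValueError(f"unknown effect distribution {self.qtl_effect_distribution!r}")
        if self.target_h2 == 1.0 and self.residual_var > 0:
            raise ValueError("target_h2 = 1 is inconsistent with residual_var > 0")
        if self.residual_var == 0 and 0.0 < self.target_h2 < 1.0:
            raise ValueError("residual_var = 0 forces heritability 0 or 1")


@dataclass
class TruthTable:
    """True genotypic values, QTL effects and realized variance components."""

    trait: str
    values: pd.DataFrame  # index genotype; columns cross, set, g
    qtl: pd.DataFrame  # index marker; column effect
    components: dict = field(default_factory=dict)
    arch: TraitArchitecture | None = None

    @property
    def genotypic_values(self) -> pd.Series:
        return self.values["g"]

    @property
    def realized_h2(self) -> float:
        g = self.components["sigma2_g"]
        e = self.components["residual_var"]
        return g / (g + e) if (g + e) > 0 else 0.0


# ---------------------------------------------------------------------------
# founders and meiosis
# ---------------------------------------------------------------------------

def _build_map(config: SimConfig) -> pd.DataFrame:
    rows = []
    for c in range(config.n_chromosomes):
        m = config.snps_per_chromosome
        cm = (np.arange(m) + 0.5) * config.map_length_cM / m
        for j in range(m):
            rows.append(
                (
                    f"chr{c + 1}_snp{j + 1}",
                    f"chr{c + 1}",
                    int(round(cm[j] * 1e6)),  # 1 cM = 1 Mb
                    cm[j],
                    "A",
                    "T",
                )
            )
    return pd.DataFrame(
        rows, columns=["marker", "chrom", "pos", "cm", "ref", "alt"]
    ).set_index("marker")


def simulate_founders(config: SimConfig) -> FounderSet:
    """Draw phased founder haplotypes at frequencies inside the MAF range."""
    rng = np.random.default_rng(config.seed)
    markers = _build_map(config)
    n_snps = len(markers)
    lo, hi = config.founder_maf_range
    freq = rng.uniform(lo, hi, size=n_snps)
    hap = (rng.random((config.n_founders, 2, n_snps)) < freq).astype(np.int8)
    ids = [f"P{i + 1}" for i in range(config.n_founders)]
    return FounderSet(
        haplotypes=hap,
        markers=markers,
        founder_ids=ids,
        allele_freq=freq,
        map_length_cM=config.map_length_cM,
    )


def _gamete(hap_pair: np.ndarray, cm: np.ndarray, chrom_codes: np.ndarray,
            map_length: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete: Poisson crossovers, uniform positions, no interference."""
    out = np.empty(hap_pair.shape[1], dtype=np.int8)
    for c in np.unique(chrom_codes):
        sel = chrom_codes == c
        pos = cm[sel]
        n_xo = rng.poisson(map_length / 100.0)
        start = rng.integers(0, 2)
        if n_xo == 0:
            phase = np.full(sel.sum(), start)
        else:
            xo = np.sort(rng.uniform(0.0, map_length, size=n_xo))
            phase = (start + np.searchsorted(xo, pos)) % 2
        out[sel] = hap_pair[phase, sel]
    return out


def simulate_cross(
    founders: FounderSet,
    parent_a: str,
    parent_b: str,
    n_offspring: int,
    seed: int,
    cross_name: str | None = None,
    id_prefix: str | None = None,
) -> GenotypeMatrix:
    """Full-sib family from two founders under Haldane meiosis."""
    for p in (parent_a, parent_b):
        if p not in founders.founder_ids:
            raise KeyError(f"unknown parent id {p!r}")
    rng = np.random.default_rng(seed)
    ia = founders.founder_ids.index(parent_a)
    ib = founders.founder_ids.index(parent_b)
    cm = founders.markers["cm"].to_numpy()
    chrom_codes = pd.factorize(founders.markers["chrom"])[0]
    D = np.empty((n_offspring, len(cm)))
    for k in range(n_offspring):
        ga = _gamete(founders.haplotypes[ia], cm, chrom_codes, founders.map_length_cM, rng)
        gb = _gamete(founders.haplotypes[ib], cm, chrom_codes, founders.map_length_cM, rng)
        D[k] = ga + gb
    name = cross_name or f"{parent_a}x{parent_b}"
    prefix = id_prefix or name
    ind = pd.DataFrame(
        {"cross": name, "set": "TS", "parent1": parent_a, "parent2": parent_b},
        index=pd.Index([f"{prefix}_{k + 1:03d}" for k in range(n_offspring)], name="individual"),
    )
    return GenotypeMatrix(D, founders.markers.copy(), ind)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_trait(population: GenotypeMatrix, arch: TraitArchitecture, seed: int) -> TruthTable:
    """Additive QTL trait with a cross-level shift, scaled to the target H2.

    The genetic variance sigma2_g implied by ``target_h2`` and
    ``residual_var`` follows H2 = sigma2_g / (sigma2_g + residual_var); true
    values are rescaled so their realized (population) variance equals it
    exactly, and a Gaussian per-cross shift is scaled so the variance of
    cross means approximates ``cross_variance_fraction`` of sigma2_g.
    """
    if arch.n_qtl > population.n_markers:
        raise ValueError("n_qtl exceeds the number of markers")
    rng = np.random.default_rng(seed)
    n = population.n_individuals
    crosses = population.individuals["cross"].to_numpy()
    qtl_idx = np.sort(rng.choice(population.n_markers, size=arch.n_qtl, replace=False))
    if arch.qtl_effect_distribution == "gaussian":
        effects = rng.standard_normal(arch.n_qtl)
    elif arch.qtl_effect_distribution == "laplace":
        effects = rng.laplace(0.0, 1.0, arch.n_qtl)
    else:
        effects = rng.choice([-1.0, 1.0], size=arch.n_qtl)

    if arch.target_h2 == 0.0:
        g = np.zeros(n)
        effects = np.zeros_like(effects)
        sigma2_g = 0.0
    else:
        if arch.target_h2 == 1.0:
            sigma2_g = 1.0
        else:
            sigma2_g = arch.target_h2 / (1.0 - arch.target_h2) * arch.residual_var
        D = population.dosages[:, qtl_idx]
        if np.isnan(D).any():
            raise ValueError("population has missing dosages; simulate traits before degrading")
        g = D @ effects
        g = g - g.mean()
        cross_codes, cross_levels = pd.factorize(crosses)
        if arch.cross_variance_fraction > 0 and len(cross_levels) > 1:
            means = np.array([g[cross_codes == k].mean() for k in range(len(cross_levels))])
            between = g.copy()
            for k in range(len(cross_levels)):
                between[cross_codes == k] = means[k]
            vb = between.var()
            vw = (g - between).var()
            shift_lv = rng.standard_normal(len(cross_levels))
            shift = shift_lv[cross_codes]
            shift = shift - shift.mean()
            vs = shift.var()
            f = arch.cross_variance_fraction
            want = f / (1.0 - f) * vw
            if vs > 0 and want > vb:
                g = g + np.sqrt((want - vb) / vs) * shift
        cur = g.var()
        if cur <= 0:
            raise ValueError("no genetic variance at the sampled QTL (monomorphic?)")
        scale = np.sqrt(sigma2_g / cur)
        g = g * scale
        effects = effects * scale

    cross_codes, cross_levels = pd.factorize(crosses)
    between = np.array([g[cross_codes == k].mean() for k in range(len(cross_levels))])[cross_codes]
    sigma2_C = float(between.var())
    sigma2_G = float(max(g.var() - sigma2_C, 0.0))
    values = pd.DataFrame(
        {
            "cross": crosses,
            "set": population.individuals["set"].to_numpy(),
            "g": g,
        },
        index=population.individual_ids,
    )
    qtl = pd.DataFrame({"effect": effects}, index=population.marker_ids[qtl_idx])
    comps = {
        "sigma2_g": float(g.var()),
        "sigma2_G": sigma2_G,
        "sigma2_C": sigma2_C,
        "spatial_row_var": arch.spatial_row_var,
        "spatial_col_var": arch.spatial_col_var,
        "year_var": arch.year_var,
        "residual_var": arch.residual_var,
        "target_h2": arch.target_h2,
    }
    return TruthTable(trait=arch.name, values=values, qtl=qtl, components=comps, arch=arch)


def simulate_phenotypes(
    truth: TruthTable,
    design: dict,
    arch: TraitArchitecture,
    seed: int,
) -> pd.DataFrame:
    """Field records under a p-rep design with row/column/year effects.

    ``design`` needs ``years`` (labels), ``grid_rows``, ``grid_cols``,
    ``control_ids`` (genotypes replicated as checks) and ``control_reps``.
    Non-control genotypes get one plant; each plant keeps its grid cell
    across years. Crosses fill the grid contiguously, controls land on
    random cells.
    """
    years = list(design["years"])
    nrow, ncol = int(design["grid_rows"]), int(design["grid_cols"])
    control_ids = list(design.get("control_ids", []))
    control_reps = int(design.get("control_reps", 1))
    rng = np.random.default_rng(seed)

    genos = truth.values.index.to_list()
    unknown = set(control_ids) - set(genos)
    if unknown:
        raise ValueError(f"control ids not in truth table: {sorted(unknown)}")
    plants = []  # (genotype, cross)
    ordered = truth.values.sort_values("cross", kind="stable")
    for gid, row in ordered.iterrows():
        if gid in control_ids:
            continue
        plants.append(gid)
    control_plants = [gid for gid in control_ids for _ in range(control_reps)]
    n_plants = len(plants) + len(control_plants)
    if n_plants > nrow * ncol:
        raise ValueError(f"{n_plants} plants exceed the {nrow}x{ncol} grid")

    cells = [(r, c) for r in range(nrow) for c in range(ncol)]
    control_cells_idx = rng.choice(len(cells), size=len(control_plants), replace=False)
    control_cells = {int(i) for i in control_cells_idx}
    free_cells = [cells[i] for i in range(len(cells)) if i not in control_cells]
    plant_list = []
    for gid, cell_i in zip(control_plants, control_cells_idx):
        plant_list.append((gid, cells[int(cell_i)]))
    for gid, cell in zip(plants, free_cells):
        plant_list.append((gid, cell))

    row_eff = rng.normal(0.0, np.sqrt(arch.spatial_row_var), size=nrow)
    col_eff = rng.normal(0.0, np.sqrt(arch.spatial_col_var), size=ncol)
    year_eff = rng.normal(0.0, np.sqrt(arch.year_var), size=len(years))

    g = truth.genotypic_values
    cross = truth.values["cross"]
    sets = truth.values["set"]
    rows = []
    for (gid, (r, c)) in plant_list:
        for yi, yr in enumerate(years):
            eps = rng.normal(0.0, np.sqrt(arch.residual_var))
            val = arch.mean + g[gid] + row_eff[r] + col_eff[c] + year_eff[yi] + eps
            rows.append((gid, cross[gid], sets[gid], yr, r + 1, c + 1, truth.trait, val))
    rec = pd.DataFrame(
        rows, columns=["genotype", "cross", "set", "year", "row", "col", "trait", "value"]
    )
    return rec.sort_values(["genotype", "year"], kind="stable").reset_index(drop=True)


def simulate_binary_trait(
    population: GenotypeMatrix, major_locus: str, penetrance: float, seed: int = 0
) -> pd.Series:
    """Binary labels from a single major locus with the given penetrance.

    Carriers (dosage > 0) are labelled 1 with probability ``penetrance``,
    non-carriers with probability ``1 - penetrance``.
    """
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError("penetrance must be in [0, 1]")
    if major_locus not in population.marker_ids:
        raise KeyError(f"unknown marker id {major_locus!r}")
    j = population.marker_ids.get_loc(major_locus)
    d = population.dosages[:, j]
    if np.isnan(d).any():
        raise ValueError("major locus has missing calls; impute or simulate before degrading")
    rng = np.random.default_rng(seed)
    p1 = np.where(d > 0, penetrance, 1.0 - penetrance)
    labels = (rng.random(len(d)) < p1).astype(int)
    return pd.Series(labels, index=population.individual_ids, name="label")


def degrade_genotypes(
    population: GenotypeMatrix, missing_rate: float, seed: int
) -> GenotypeMatrix:
    """Mask each dosage entry independently with probability ``missing_rate``."""
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    D = population.dosages.copy()
    mask = rng.random(D.shape) < missing_rate
    D[mask] = np.nan
    return GenotypeMatrix(D, population.markers.copy(), population.individuals.copy())


# ---------------------------------------------------------------------------
# whole-program generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticProgram:
    """A full synthetic breeding program: genotypes, phenotypes, truth."""

    genotypes: GenotypeMatrix  # parents + TS + VS, possibly with missing calls
    phenotypes: pd.DataFrame  # long format, TS + control plants only
    truth: dict  # trait name -> TruthTable (all individuals)
    binary_labels: pd.Series | None = None
    binary_locus: str | None = None
    founders: FounderSet | None = None


def simulate_program(
    config: SimConfig,
    crosses: list[dict],
    traits: list[TraitArchitecture],
    years: list,
    grid_rows: int,
    grid_cols: int,
    control_parents: list[str] | None = None,
    control_reps: int = 5,
    missing_rate: float = 0.0,
    binary_penetrance: float | None = None,
    seed: int = 0,
) -> SyntheticProgram:
    """Simulate a two-set breeding program of biparental crosses sharing parents.

    ``crosses`` entries are dicts with keys ``parent_a``, ``parent_b``,
    ``n_ts`` and ``n_vs``. Parents are genotyped (set ``parent``); TS
    individuals are genotyped and phenotyped together with replicated
    control parents; VS individuals are genotyped only.
    """
    rng = np.random.default_rng(seed)
    founders = simulate_founders(config)
    mats = [founders.as_genotype_matrix()]
    for ci, spec in enumerate(crosses):
        n_tot = int(spec["n_ts"]) + int(spec["n_vs"])
        fam = simulate_cross(
            founders,
            spec["parent_a"],
            spec["parent_b"],
            n_tot,
            seed=int(rng.integers(2**31 - 1)),
            cross_name=f"{spec['parent_a']}x{spec['parent_b']}",
            id_prefix=f"C{ci + 1}",
        )
        sets = np.array(["TS"] * int(spec["n_ts"]) + ["VS"] * int(spec["n_vs"]))
        fam.individuals["set"] = sets
        mats.append(fam)
    geno = GenotypeMatrix(
        np.vstack([m.dosages for m in mats]),
        founders.markers.copy(),
        pd.concat([m.individuals for m in mats]),
    )

    control_ids = list(control_parents or [])
    pheno_rows = geno.individuals["set"].isin(["TS"]).to_numpy()
    pheno_rows |= np.asarray(geno.individual_ids.isin(control_ids))
    pheno_pop = geno.take_individuals(np.flatnonzero(pheno_rows))

    truth: dict[str, TruthTable] = {}
    phenos = []
    for arch in traits:
        t_all = simulate_trait(geno, arch, seed=int(rng.integers(2**31 - 1)))
        truth[arch.name] = t_all
        t_pheno = TruthTable(
            trait=t_all.trait,
            values=t_all.values.loc[pheno_pop.individual_ids],
            qtl=t_all.qtl,
            components=t_all.components,
            arch=arch,
        )
        rec = simulate_phenotypes(
            t_pheno,
            {
                "years": years,
                "grid_rows": grid_rows,
                "grid_cols": grid_cols,
                "control_ids": control_ids,
                "control_reps": control_reps,
            },
            arch,
            seed=int(rng.integers(2**31 - 1)),
        )
        phenos.append(rec)
    phenotypes = pd.concat(phenos, ignore_index=True) if phenos else pd.DataFrame()

    binary_labels = None
    binary_locus = None
    if binary_penetrance is not None:
        # pick the most informative (highest-variance) marker as the major locus
        var = np.nanvar(geno.dosages, axis=0)
        binary_locus = str(geno.marker_ids[int(np.argmax(var))])
        binary_labels = simulate_binary_trait(
            geno, binary_locus, binary_penetrance, seed=int(rng.integers(2**31 - 1))
        )

    if missing_rate > 0:
        geno = degrade_genotypes(geno, missing_rate, seed=int(rng.integers(2**31 - 1)))

    return SyntheticProgram(
        genotypes=geno,
        phenotypes=phenotypes,
        truth=truth,
        binary_labels=binary_labels,
        binary_locus=binary_locus,
        founders=founders,
    )
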