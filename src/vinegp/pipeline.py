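"""End-to-end orchestration: QC -> genotypic values -> prediction -> index.

A within-population run takes raw genotypes (training set, validation set
and parents), long-format phenotypes of the training set, and an ideotype,
and executes:

1. optional marker-assisted pre-filter of validation candidates on major
   loci (e.g. mildew-resistance genes),
2. genotype QC (marker missingness, individual missingness, within-cross
   mean imputation, MAF filter), marker PCA and per-cross Mahalanobis
   outlier removal,
3. per-trait mixed-model selection, REML fit, heritability, BLUP
   extraction and deregression (raw-mean fallback for one-year traits),
4. repeated K-fold cross-validated predictive ability for each method,
   choice of the best method per trait, refit on the whole training set,
   validation-set prediction and second deregression,
5. optional binary major-gene trait (logistic lasso) accuracy and
   validation-set class prediction,
6. the multitrait genotype-ideotype distance index on the deregressed
   validation predictions, weighted by predictive ability.

Every stage draws its seed from the master seed through a stable hash, so
a run is reproducible end to end and stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genopred, phenomodel, selindex
from .genomat import (
    GenotypeMatrix,
    compute_grm,
    detect_outliers,
    filter_individuals,
    filter_markers,
    impute_missing,
    intersect_markers,
    pca_markers,
)
from .io import write_table

__all__ = [
    "RunConfig",
    "RunReport",
    "stage_seed",
    "mas_prefilter",
    "run_within_population",
    "run_across_population",
    "make_report",
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fanned out from the master seed."""
    h = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class RunConfig:
    """All knobs of a within-population run (defaults mirror the pipeline's
    standard thresholds: 10% marker missingness, 50% individual
    missingness, 1% MAF, 1% outlier alpha, K=5 folds, R=10 repetitions)."""

    seed: int = 0
    out_dir: str | None = None
    # QC
    max_missing_marker: float = 0.10
    max_missing_individual: float = 0.50
    min_maf: float = 0.01
    outlier_alpha: float = 0.01
    outlier_components: int = 5
    run_outlier_detection: bool = True
    # phenotype model
    random_terms: list = field(default_factory=lambda: ["genotype", "cross", "row", "col"])
    fixed_terms: list = field(default_factory=lambda: ["year"])
    select_model: bool = True
    selection_alpha: float = 0.05
    # cross-validation
    cv_k: int = 5
    cv_r: int = 10
    methods: list = field(default_factory=lambda: ["gblup", "lasso"])
    lasso_n_lambda: int = 100
    lasso_inner_folds: int = 5
    lasso_lambda_min_ratio: float = 1e-2
    # selection index
    n_select: int = 15
    min_pa: float = 0.0
    use_pa_weights: bool = True
    # MAS pre-filter of validation candidates: list of (marker id, min dosage)
    mas_loci: list = field(default_factory=list)


@dataclass
class RunReport:
    """Per-trait summaries plus the population-level tables a run produces."""

    trait_table: pd.DataFrame
    genotypic_corr: pd.DataFrame
    pa_h2_correlation: float
    pca_explained: np.ndarray
    ts_vs_relatedness: float
    selection: pd.DataFrame | None
    selected: list
    binary_accuracy: float | None
    qc_table: pd.DataFrame
    genovalues: dict  # trait -> phenomodel.GenotypicValues
    predictions: dict  # trait -> genopred.PredictionSet
    cv_results: dict  # (trait, method) -> genopred.CVResult
    seeds: dict
    n_factors: int | None = None

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        write_table(self.trait_table, os.path.join(out_dir, "trait_table.tsv"))
        write_table(self.genotypic_corr.reset_index(),
                    os.path.join(out_dir, "genotypic_correlations.tsv"))
        write_table(self.qc_table, os.path.join(out_dir, "qc_report.tsv"))
        if self.selection is not None:
            write_table(self.selection.reset_index(), os.path.join(out_dir, "selection.tsv"))
        for trait, gv in sorted(self.genovalues.items()):
            write_table(gv.frame.reset_index(),
                        os.path.join(out_dir, f"genovalues_{trait}.tsv"))
        for trait, ps in sorted(self.predictions.items()):
            write_table(ps.frame.reset_index(names="genotype"),
                        os.path.join(out_dir, f"predictions_{trait}.tsv"))
        meta = {
            "pa_h2_correlation": _round(self.pa_h2_correlation),
            "ts_vs_relatedness": _round(self.ts_vs_relatedness),
            "binary_accuracy": _round(self.binary_accuracy),
            "pca_explained": [_round(v) for v in np.asarray(self.pca_explained)],
            "selected": list(map(str, self.selected)),
            "n_factors": self.n_factors,
            "seeds": self.seeds,
        }
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _round(x, nd: int = 10):
    if x is None:
        return None
    x = float(x)
    return None if not np.isfinite(x) else round(x, nd)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def mas_prefilter(G: GenotypeMatrix, loci: list) -> GenotypeMatrix:
    """Keep individuals meeting every (marker, minimum dosage) requirement.

    A missing call at a required locus fails the requirement. The count of
    removed individuals is logged via a warning-free return; callers can
    compare dimensions.
    """
    if not loci:
        return G.copy()
    keep = np.ones(G.n_individuals, dtype=bool)
    for marker, min_dosage in loci:
        if marker not in G.marker_ids:
            raise KeyError(f"unknown marker id {marker!r} in MAS pre-filter")
        j = G.marker_ids.get_loc(marker)
        d = G.dosages[:, j]
        ok = np.where(np.isnan(d), False, d >= min_dosage)
        keep &= ok
    return G.take_individuals(np.flatnonzero(keep))


def _qc_stage(geno: GenotypeMatrix, config: RunConfig):
    """Marker and individual filters, imputation, MAF filter, outliers."""
    g1, rep_miss = filter_markers(geno, max_missing=config.max_missing_marker, min_maf=0.0)
    g2, rep_ind = filter_individuals(g1, max_missing=config.max_missing_individual)
    g3 = impute_missing(g2)
    g4, rep_maf = filter_markers(g3, max_missing=1.0, min_maf=config.min_maf)

    outliers = []
    pca = None
    if config.run_outlier_detection:
        q = config.outlier_components
        n_comp = min(10, max(q, 2), g4.n_individuals - 1, g4.n_markers)
        pca = pca_markers(g4, n_components=n_comp)
        crosses = g4.individuals["cross"]
        counts = crosses.value_counts()
        eligible = crosses.isin(counts.index[counts > q + 1]) & (crosses != "")
        if eligible.any():
            sub = pca.scores.loc[eligible.to_numpy()]
            rep_out = detect_outliers(
                sub, crosses[eligible.to_numpy()], alpha=config.outlier_alpha,
                n_components=q,
            )
            outliers = rep_out.outliers_removed
            if outliers:
                flagged_ids = {o[0] for o in outliers}
                keep = ~g4.individual_ids.isin(flagged_ids)
                g4 = g4.take_individuals(np.flatnonzero(keep))
    qc_rows = [
        ("markers_removed_missing", rep_miss.markers_removed_missing),
        ("individuals_removed_missing", rep_ind.individuals_removed),
        ("markers_removed_maf", rep_maf.markers_removed_maf),
        ("outliers_removed", len(outliers)),
        ("markers_kept", g4.n_markers),
        ("individuals_kept", g4.n_individuals),
    ]
    qc_table = pd.DataFrame(qc_rows, columns=["key", "value"])
    return g4, qc_table, pca, outliers


def _trait_values(pheno: pd.DataFrame, trait: str, config: RunConfig):
    """Mixed-model genotypic values for one trait, or the one-year fallback."""
    rec = pheno[pheno["trait"] == trait].dropna(subset=["value"])
    n_years = rec["year"].nunique()
    if n_years < 2:
        gv = phenomodel.one_year_values(rec, trait=trait)
        return gv, None, float("nan"), {"one_year": True}
    full = phenomodel.LMMSpec(
        trait=trait, fixed=list(config.fixed_terms), random=list(config.random_terms)
    )
    spec = (
        phenomodel.select_effects(rec, full, alpha=config.selection_alpha)
        if config.select_model
        else full
    )
    if "genotype" not in spec.random:
        # non-genetic trait: fall back to raw means, flagged
        gv = phenomodel.one_year_values(rec, trait=trait)
        gv.one_year = False
        return gv, spec, 0.0, {"one_year": False, "non_genetic": True}
    fit = phenomodel.fit_lmm(rec, spec, reml=True)
    h2 = phenomodel.heritability(fit.varcomp)
    gv = phenomodel.deregress(phenomodel.extract_blups(fit))
    return gv, spec, h2, {"one_year": False, "non_genetic": False}


def run_within_population(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    config: RunConfig,
    ideotype: selindex.IdeotypeSpec | dict | None = None,
    binary_labels: pd.Series | None = None,
) -> RunReport:
    """Execute the full within-population analysis; see the module docstring."""
    seeds = {s: stage_seed(config.seed, s) for s in ("qc", "cv", "refit", "binary")}

    if config.mas_loci:
        vs_mask = (geno.individuals["set"] == "VS").to_numpy()
        vs = mas_prefilter(geno.take_individuals(np.flatnonzero(vs_mask)), config.mas_loci)
        keep_ids = list(geno.individual_ids[~vs_mask]) + list(vs.individual_ids)
        keep = geno.individual_ids.isin(keep_ids)
        geno = geno.take_individuals(np.flatnonzero(keep))

    geno_qc, qc_table, pca, outliers = _qc_stage(geno, config)
    flagged = {o[0] for o in outliers}
    if flagged:
        pheno = pheno[~pheno["genotype"].isin(flagged)]

    traits = sorted(pheno["trait"].unique())
    genovalues, specs, h2s, trait_flags = {}, {}, {}, {}
    for trait in traits:
        gv, spec, h2, flags = _trait_values(pheno, trait, config)
        genovalues[trait] = gv
        specs[trait] = spec
        h2s[trait] = h2
        trait_flags[trait] = flags

    # training matrix: genotyped individuals with genotypic values
    cv_results = {}
    best_methods = {}
    predictions = {}
    vs_idx = np.flatnonzero((geno_qc.individuals["set"] == "VS").to_numpy())
    G_vs = geno_qc.take_individuals(vs_idx)
    rng_cv = np.random.default_rng(seeds["cv"])
    for trait in traits:
        gv = genovalues[trait]
        vals = gv.frame["drgBLUP"].dropna()
        ids = geno_qc.individual_ids.intersection(vals.index)
        if len(ids) < 3 * config.cv_k:
            warnings.warn(f"too few genotyped values for trait {trait!r}; skipped")
            continue
        rows = geno_qc.individual_ids.get_indexer(ids)
        X = geno_qc.dosages[rows]
        y = vals.loc[ids].to_numpy()
        for method in config.methods:
            kw = {}
            if method == "lasso":
                kw["n_lambda"] = config.lasso_n_lambda
                kw["inner_folds"] = config.lasso_inner_folds
                kw["lambda_min_ratio"] = config.lasso_lambda_min_ratio
            cv_results[(trait, method)] = genopred.cross_validate(
                y, X, method=method, k=config.cv_k, r=config.cv_r,
                seed=stage_seed(config.seed, f"cv:{trait}:{method}"),
                trait=trait, **kw,
            )
        if len(config.methods) == 1:
            best = config.methods[0]
        else:
            best = genopred.select_best_method(
                cv_results[(trait, config.methods[0])],
                cv_results[(trait, config.methods[1])],
            )
        best_methods[trait] = best
        # refit on the whole TS and predict the validation set
        kw = {}
        if best == "lasso":
            kw["n_lambda"] = config.lasso_n_lambda
            kw["inner_folds"] = config.lasso_inner_folds
            kw["lambda_min_ratio"] = config.lasso_lambda_min_ratio
            kw["random_state"] = stage_seed(config.seed, f"refit:{trait}")
        est = genopred._METHODS[best](**kw).fit(X, y)
        est.marker_ids_ = list(geno_qc.marker_ids)
        if G_vs.n_individuals:
            preds = genopred.predict_validation(est, G_vs, trait=trait)
            preds = genopred.deregress_predictions(est, preds, G_vs)
            preds.method = best
            predictions[trait] = preds

    # binary major-gene trait
    binary_accuracy = None
    if binary_labels is not None:
        ids = geno_qc.individual_ids.intersection(binary_labels.dropna().index)
        ids = ids[geno_qc.individuals.loc[ids, "set"] != "VS"]
        rows = geno_qc.individual_ids.get_indexer(ids)
        cv_bin = genopred.cross_validate(
            binary_labels.loc[ids].to_numpy(), geno_qc.dosages[rows],
            method="logistic_lasso", k=config.cv_k, r=config.cv_r,
            seed=seeds["binary"], trait="binary",
        )
        cv_results[("binary", "logistic_lasso")] = cv_bin
        binary_accuracy = cv_bin.mean_pa
        if G_vs.n_individuals:
            est = genopred.LogisticMarkerLasso(
                random_state=stage_seed(config.seed, "refit:binary")
            ).fit(geno_qc.dosages[rows], binary_labels.loc[ids].to_numpy())
            est.marker_ids_ = list(geno_qc.marker_ids)
            predictions["binary"] = genopred.predict_validation(est, G_vs, trait="binary")

    # selection index on deregressed validation predictions
    selection_frame, selected, n_factors = None, [], None
    if ideotype is not None and G_vs.n_individuals:
        spec = (
            ideotype
            if isinstance(ideotype, selindex.IdeotypeSpec)
            else selindex.IdeotypeSpec.from_dict(ideotype, min_pa_threshold=config.min_pa)
        )
        cols = {}
        for trait in spec.traits.index:
            if trait in predictions and trait != "binary":
                cols[trait] = predictions[trait].frame["deregressed"]
        if len(cols) >= 2:
            values = pd.DataFrame(cols).dropna()
            traits_tbl = spec.traits.loc[list(cols)].copy()
            if config.use_pa_weights:
                traits_tbl["weight"] = [
                    max(cv_results[(t, best_methods[t])].mean_pa, 0.0) for t in cols
                ]
            spec_used = selindex.IdeotypeSpec(traits_tbl, min_pa_threshold=config.min_pa)
            try:
                mg = selindex.MGIDI(
                    ideotype=spec_used, n_select=min(config.n_select, len(values))
                ).fit(values)
                selection_frame = mg.result_.frame
                selected = mg.selected_
                n_factors = mg.factor_model_.n_factors
            except ValueError as exc:
                warnings.warn(f"selection index skipped: {exc}")

    report = make_report(
        traits=traits,
        genovalues=genovalues,
        specs=specs,
        h2s=h2s,
        trait_flags=trait_flags,
        cv_results=cv_results,
        best_methods=best_methods,
        predictions=predictions,
        pheno=pheno,
        geno=geno_qc,
        pca=pca,
        qc_table=qc_table,
        selection=selection_frame,
        selected=selected,
        n_factors=n_factors,
        binary_accuracy=binary_accuracy,
        seeds=seeds,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def make_report(
    *,
    traits,
    genovalues,
    specs,
    h2s,
    trait_flags,
    cv_results,
    best_methods,
    predictions,
    pheno,
    geno,
    pca,
    qc_table,
    selection,
    selected,
    n_factors,
    binary_accuracy,
    seeds,
) -> RunReport:
    """Assemble the per-trait table and population-level summaries."""
    rows = []
    for trait in traits:
        gv = genovalues[trait]
        rec = pheno[pheno["trait"] == trait].dropna(subset=["value"])
        raw_means = rec.groupby("genotype")["value"].mean()
        common = gv.frame.index.intersection(raw_means.index)
        drg = gv.frame.loc[common, "drgBLUP"]
        ok = drg.notna()
        corr_raw = (
            float(np.corrcoef(drg[ok], raw_means.loc[common][ok])[0, 1])
            if ok.sum() >= 3 and drg[ok].std() > 0
            else float("nan")
        )
        spec = specs.get(trait)
        row = {
            "trait": trait,
            "h2": h2s.get(trait, float("nan")),
            "one_year": trait_flags[trait].get("one_year", False),
            "non_genetic": trait_flags[trait].get("non_genetic", False),
            "cross_retained": bool(spec and "cross" in spec.random),
            "model": "+".join(spec.random) if spec else "raw_mean",
            "best_method": best_methods.get(trait, ""),
            "corr_drg_raw": corr_raw,
        }
        for (t, method), cv in cv_results.items():
            if t == trait:
                row[f"pa_{method}"] = cv.mean_pa
                row[f"se_{method}"] = cv.se
        rows.append(row)
    trait_table = pd.DataFrame(rows)

    # genotypic correlations between deregressed BLUPs
    drg_mat = pd.DataFrame(
        {t: genovalues[t].frame["drgBLUP"] for t in traits if t in genovalues}
    )
    genotypic_corr = drg_mat.corr() if drg_mat.shape[1] >= 2 else pd.DataFrame()
    genotypic_corr.index.name = "trait"

    pa_col = [
        (row.get(f"pa_{best_methods[row['trait']]}", np.nan), row["h2"])
        for row in rows
        if row["trait"] in best_methods
    ]
    pa_h2 = float("nan")
    finite = [(a, b) for a, b in pa_col if np.isfinite(a) and np.isfinite(b)]
    if len(finite) >= 3:
        arr = np.array(finite)
        if arr[:, 0].std() > 0 and arr[:, 1].std() > 0:
            pa_h2 = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])

    ts_vs_rel = float("nan")
    sets = geno.individuals["set"].to_numpy()
    if (sets == "VS").any() and (sets == "TS").any() and not np.isnan(geno.dosages).any():
        K = compute_grm(geno).values
        ts_rows = np.flatnonzero(sets == "TS")
        vs_rows = np.flatnonzero(sets == "VS")
        ts_vs_rel = float(K[np.ix_(ts_rows, vs_rows)].mean())

    return RunReport(
        trait_table=trait_table,
        genotypic_corr=genotypic_corr,
        pa_h2_correlation=pa_h2,
        pca_explained=(pca.explained_variance_ratio if pca is not None else np.array([])),
        ts_vs_relatedness=ts_vs_rel,
        selection=selection,
        selected=selected,
        binary_accuracy=binary_accuracy,
        qc_table=qc_table,
        genovalues=genovalues,
        predictions=predictions,
        cv_results=cv_results,
        seeds=seeds,
        n_factors=n_factors,
    )


# ---------------------------------------------------------------------------
# across-population prediction
# ---------------------------------------------------------------------------

def run_across_population(
    target_geno: GenotypeMatrix,
    target_values: pd.DataFrame,
    sources: list[dict],
    methods: list[str] = ("gblup", "lasso"),
    seed: int = 0,
    cv_k: int = 5,
    cv_r: int = 10,
    trait_map: dict | None = None,
) -> pd.DataFrame:
    """Train on external populations and predict the target's genotypic values.

    ``sources`` entries are dicts with ``name``, ``genotypes`` (imputed
    :class:`GenotypeMatrix`) and ``values`` (genotype x trait deregressed
    BLUPs). Markers are intersected by map position (allele orientation
    harmonized); for each common trait both methods are fit on the source
    and evaluated against the target's deregressed BLUPs. Target genotypes
    that are also in the training source are excluded from the evaluation;
    if the source is the target itself the PA falls back to the
    within-population cross-validation scheme. A ``union`` source pools all
    sources (duplicate individuals removed) when more than one is given.

    Returns a long table (source, trait, method, pa, n_train, n_markers,
    relatedness) with a ``best`` flag per source x trait.
    """
    if np.isnan(target_geno.dosages).any():
        raise ValueError("target genotypes must be imputed")
    source_list = list(sources)
    if len(source_list) > 1:
        union = _union_source(source_list)
        source_list = source_list + [union]
    trait_map = trait_map or {}
    rows = []
    for src in source_list:
        Gs: GenotypeMatrix = src["genotypes"]
        vals: pd.DataFrame = src["values"]
        if np.isnan(Gs.dosages).any():
            raise ValueError(f"source {src['name']!r} genotypes must be imputed")
        Gt, Gs2 = intersect_markers(target_geno, Gs)
        common_traits = [
            t for t in target_values.columns
            if trait_map.get(t, t) in vals.columns
        ]
        if not common_traits:
            raise ValueError(f"no common traits with source {src['name']!r}")
        # additive relatedness between source and target from the joint GRM
        joint = GenotypeMatrix(
            np.vstack([Gt.dosages, Gs2.dosages]),
            Gt.markers.copy(),
            pd.concat([
                Gt.individuals.assign(_role="target"),
                Gs2.individuals.assign(_role="source"),
            ]).pipe(_dedup_index),
        )
        K = compute_grm(joint).values
        nt = Gt.n_individuals
        relatedness = float(K[:nt, nt:].mean())
        for trait in common_traits:
            s_trait = trait_map.get(trait, trait)
            y_src = vals[s_trait].dropna()
            src_ids = Gs2.individual_ids.intersection(y_src.index)
            y_tgt = target_values[trait].dropna()
            tgt_ids = Gt.individual_ids.intersection(y_tgt.index)
            overlap = tgt_ids.intersection(src_ids)
            eval_ids = tgt_ids.difference(overlap)
            pas = {}
            for method in methods:
                if len(eval_ids) >= 3:
                    est = genopred._METHODS[method](
                        **(
                            {"random_state": stage_seed(seed, f"across:{src['name']}:{trait}")}
                            if method == "lasso" else {}
                        )
                    )
                    rows_s = Gs2.individual_ids.get_indexer(src_ids)
                    est.fit(Gs2.dosages[rows_s], y_src.loc[src_ids].to_numpy())
                    rows_t = Gt.individual_ids.get_indexer(eval_ids)
                    pred = est.predict(Gt.dosages[rows_t])
                    obs = y_tgt.loc[eval_ids].to_numpy()
                    pa = (
                        float(np.corrcoef(obs, pred)[0, 1])
                        if np.std(obs) > 0 and np.std(pred) > 0
                        else float("nan")
                    )
                    n_train = len(src_ids)
                else:
                    # source is (essentially) the target: within-population CV
                    rows_t = Gt.individual_ids.get_indexer(tgt_ids)
                    cv = genopred.cross_validate(
                        y_tgt.loc[tgt_ids].to_numpy(), Gt.dosages[rows_t],
                        method=method, k=cv_k, r=cv_r,
                        seed=stage_seed(seed, f"cv:{trait}:{method}"),
                        trait=trait,
                    )
                    pa = cv.mean_pa
                    n_train = len(tgt_ids)
                pas[method] = pa
                rows.append({
                    "source": src["name"],
                    "trait": trait,
                    "method": method,
                    "pa": pa,
                    "n_train": n_train,
                    "n_markers": Gt.n_markers,
                    "relatedness": relatedness,
                })
            best = max(pas, key=lambda m: (np.nan_to_num(pas[m], nan=-2.0), m == "gblup"))
            for r in rows[-len(methods):]:
                r["best"] = r["method"] == best
    return pd.DataFrame(rows)


def _dedup_index(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        df = df.copy()
        df.index = [
            f"{idx}#{i}" if dup else idx
            for i, (idx, dup) in enumerate(zip(df.index, df.index.duplicated()))
        ]
    return df


def _union_source(sources: list[dict]) -> dict:
    """Pool all sources over their common markers, dropping duplicate ids."""
    common = sources[0]["genotypes"]
    for src in sources[1:]:
        common, _ = intersect_markers(common, src["genotypes"])
    aligned = [intersect_markers(common, src["genotypes"])[1] for src in sources]
    seen = set()
    keep_parts, val_parts = [], []
    for src, g in zip(sources, aligned):
        mask = ~g.individual_ids.isin(list(seen))
        seen.update(g.individual_ids)
        keep_parts.append(g.take_individuals(np.flatnonzero(mask)))
        val_parts.append(src["values"])
    geno = GenotypeMatrix(
        np.vstack([g.dosages for g in keep_parts]),
        keep_parts[0].markers.copy(),
        pd.concat([g.individuals for g in keep_parts]),
    )
    values = pd.concat(val_parts)
    values = values[~values.index.duplicated(keep="first")]
    return {"name": "union", "genotypes": geno, "values": values}
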