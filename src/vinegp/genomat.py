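"""Genotype containers, quality control, relatedness and population structure.

The central container is :class:`GenotypeMatrix`: an individuals x markers
dosage matrix (counts of the alternate allele, 0/1/2, ``NaN`` for missing
calls) together with a marker map (chromosome, 1-based bp position, ref/alt
alleles) and individual metadata (cross of origin, training/validation-set
membership, parent ids).

Operations mirror the QC applied to genotyping-by-sequencing SNP tables in
biparental breeding populations: marker/individual missingness filters, a
minor-allele-frequency filter, deterministic within-cross mean imputation,
the VanRaden additive genomic relationship matrix, marker PCA, per-cross
Mahalanobis outlier detection on PCA scores, and coordinate-based marker
intersection between populations genotyped separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "RelationshipMatrix",
    "PCAResult",
    "filter_markers",
    "filter_individuals",
    "impute_missing",
    "compute_grm",
    "pca_markers",
    "detect_outliers",
    "intersect_markers",
]


MARKER_COLUMNS = ["chrom", "pos", "ref", "alt"]
INDIVIDUAL_COLUMNS = ["cross", "set", "parent1", "parent2"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix with marker map and individual metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_individuals, n_markers)
        Alternate-allele dosages in {0, 1, 2}; ``NaN`` marks missing calls.
        Imputation may introduce fractional values.
    markers : DataFrame indexed by unique marker id
        Columns ``chrom`` (str), ``pos`` (1-based bp, int), ``ref``, ``alt``.
    individuals : DataFrame indexed by unique individual id
        Columns ``cross``, ``set`` (one of ``TS``/``VS``/``parent``),
        ``parent1``, ``parent2``.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        n, m = self.dosages.shape
        if len(self.individuals) != n:
            raise ValueError(
                f"{len(self.individuals)} individual rows for {n} dosage rows"
            )
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker rows for {m} dosage columns")
        if self.markers.index.has_duplicates:
            raise ValueError("marker ids must be unique")
        if self.individuals.index.has_duplicates:
            raise ValueError("individual ids must be unique")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def individual_ids(self) -> pd.Index:
        return self.individuals.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.markers.index

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), self.markers.copy(), self.individuals.copy()
        )

    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], self.markers.iloc[idx], self.individuals.copy()
        )

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx, :], self.markers.copy(), self.individuals.iloc[idx]
        )

    def subset_set(self, which: str) -> "GenotypeMatrix":
        """Restrict to individuals whose ``set`` label equals ``which``."""
        keep = np.flatnonzero((self.individuals["set"] == which).to_numpy())
        return self.take_individuals(keep)

    def allele_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per marker (non-missing calls)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class QCReport:
    """Bookkeeping of a QC step: what was removed and under which thresholds."""

    markers_removed_missing: int = 0
    markers_removed_maf: int = 0
    individuals_removed: int = 0
    outliers_removed: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("markers_removed_missing", self.markers_removed_missing),
            ("markers_removed_maf", self.markers_removed_maf),
            ("individuals_removed", self.individuals_removed),
            ("n_outliers_removed", len(self.outliers_removed)),
        ] + sorted(self.thresholds.items())
        return pd.DataFrame(rows, columns=["key", "value"])


@dataclass
class RelationshipMatrix:
    """Additive genomic relationship matrix (VanRaden centering)."""

    values: np.ndarray
    ids: pd.Index
    allele_freq: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PCAResult:
    """Marker-PCA scores, loadings and explained-variance fractions."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_markers(
    G: GenotypeMatrix, max_missing: float = 0.10, min_maf: float = 0.01
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers by missingness, then by minor allele frequency.

    Markers with a missing-call fraction strictly above ``max_missing`` are
    removed first; MAF is then computed on the non-missing calls of the
    survivors and markers with MAF strictly below ``min_maf`` are removed.
    """
    if G.n_markers == 0 or G.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    miss_frac = G.missing_mask.mean(axis=0)
    keep_missing = miss_frac <= max_missing
    n_removed_missing = int((~keep_missing).sum())
    G1 = G.take_markers(np.flatnonzero(keep_missing))
    if G1.n_markers == 0:
        raise ValueError("all markers removed by the missingness filter")
    maf = G1.maf()
    # a marker with no observed call has undefined MAF; treat as failing
    keep_maf = np.nan_to_num(maf, nan=-1.0) >= min_maf
    n_removed_maf = int((~keep_maf).sum())
    G2 = G1.take_markers(np.flatnonzero(keep_maf))
    if G2.n_markers == 0:
        raise ValueError("all markers removed by the MAF filter")
    report = QCReport(
        markers_removed_missing=n_removed_missing,
        markers_removed_maf=n_removed_maf,
        thresholds={"max_missing_marker": max_missing, "min_maf": min_maf},
    )
    return G2, report


def filter_individuals(
    G: GenotypeMatrix, max_missing: float = 0.50
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove individuals with a missing fraction above ``max_missing``."""
    if G.n_markers == 0 or G.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    miss_frac = G.missing_mask.mean(axis=1)
    keep = miss_frac <= max_missing
    if not keep.any():
        raise ValueError("all individuals removed by the missingness filter")
    G1 = G.take_individuals(np.flatnonzero(keep))
    report = QCReport(
        individuals_removed=int((~keep).sum()),
        thresholds={"max_missing_individual": max_missing},
    )
    return G1, report


def impute_missing(G: GenotypeMatrix, strategy: str = "within_cross_mean") -> GenotypeMatrix:
    """Replace missing dosages by the within-cross mean (global-mean fallback).

    Deterministic by construction; imputed values may be fractional. A marker
    with no observed call anywhere raises, naming the marker.
    """
    if strategy not in ("within_cross_mean", "global_mean"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    D = G.dosages.copy()
    mask = np.isnan(D)
    if not mask.any():
        return G.copy()
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        global_mean = np.nanmean(D, axis=0)
    dead = np.isnan(global_mean)
    if dead.any():
        bad = G.marker_ids[np.flatnonzero(dead)[0]]
        raise ValueError(f"marker {bad!r} has no observed call; cannot impute")
    if strategy == "within_cross_mean":
        crosses = G.individuals["cross"].to_numpy()
        for cr in pd.unique(crosses):
            rows = np.flatnonzero(crosses == cr)
            block = D[rows, :]
            bm = np.isnan(block)
            if not bm.any():
                continue
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cross_mean = np.nanmean(block, axis=0)
            fill = np.where(np.isnan(cross_mean), global_mean, cross_mean)
            block[bm] = np.broadcast_to(fill, block.shape)[bm]
            D[rows, :] = block
    else:
        D[mask] = np.broadcast_to(global_mean, D.shape)[mask]
    return GenotypeMatrix(D, G.markers.copy(), G.individuals.copy())


# ---------------------------------------------------------------------------
# relatedness and structure
# ---------------------------------------------------------------------------

def compute_grm(G: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden additive GRM: K = ZZ' / (2 * sum p_j (1 - p_j)).

    Dosages are centered by twice the observed allele frequency per marker.
    Requires a complete (imputed) matrix.
    """
    D = G.dosages
    if np.isnan(D).any():
        raise ValueError("missing dosages; impute before computing the GRM")
    p = D.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM denominator is zero")
    Z = D - 2.0 * p
    K = (Z @ Z.T) / denom
    return RelationshipMatrix(values=K, ids=G.individual_ids, allele_freq=p)


def pca_markers(G: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of the column-centered dosage matrix via SVD.

    Scores are ordered by decreasing variance; explained-variance fractions
    are relative to the total variance of the centered matrix.
    """
    D = G.dosages
    if np.isnan(D).any():
        raise ValueError("missing dosages; impute before PCA")
    Z = D - D.mean(axis=0)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = s.max(initial=0.0) * max(Z.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    scores = U[:, :n_components] * s[:n_components]
    total_var = float(np.sum(s**2))
    evr = (s[:n_components] ** 2) / total_var
    return PCAResult(
        scores=pd.DataFrame(
            scores,
            index=G.individual_ids,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        explained_variance_ratio=evr,
        loadings=Vt[:n_components].T,
    )


def detect_outliers(
    scores: PCAResult | pd.DataFrame,
    crosses: pd.Series | np.ndarray,
    alpha: float = 0.01,
    n_components: int = 5,
) -> QCReport:
    """Per-cross Mahalanobis outlier flagging on leading PCA dimensions.

    Within each cross the squared Mahalanobis distance of every member to the
    within-cross mean (sample covariance) on the first ``n_components`` score
    dimensions is referred to a chi-square distribution with ``n_components``
    degrees of freedom; members with upper-tail p-value below ``alpha`` are
    flagged.
    """
    S = scores.scores if isinstance(scores, PCAResult) else scores
    q = n_components
    if q > S.shape[1]:
        raise ValueError(f"n_components={q} exceeds available score dimensions")
    X = S.to_numpy()[:, :q]
    crosses = pd.Series(np.asarray(crosses), index=S.index)
    flagged = []
    for cr, idx in crosses.groupby(crosses).groups.items():
        rows = S.index.get_indexer(idx)
        if len(rows) <= q + 1:
            raise ValueError(
                f"cross {cr!r} has {len(rows)} members; needs more than {q + 1} "
                "for a stable within-cross covariance (reduce n_components)"
            )
        block = X[rows]
        mu = block.mean(axis=0)
        cov = np.cov(block, rowvar=False, ddof=1)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0 or not np.isfinite(logdet):
            raise ValueError(
                f"singular within-cross covariance for {cr!r}; use fewer components"
            )
        d2 = np.einsum("ij,ij->i", (block - mu) @ np.linalg.inv(cov), block - mu)
        pvals = stats.chi2.sf(d2, df=q)
        for r, dd, pv in zip(rows, d2, pvals):
            if pv < alpha:
                flagged.append((S.index[r], cr, float(np.sqrt(dd)), float(pv)))
    return QCReport(
        outliers_removed=flagged,
        thresholds={"outlier_alpha": alpha, "outlier_components": q},
    )


# ---------------------------------------------------------------------------
# marker intersection between populations
# ---------------------------------------------------------------------------

def intersect_markers(
    A: GenotypeMatrix, B: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two populations to markers shared by map position.

    Markers match on (chromosome, bp position) with consistent alleles;
    when ref/alt are swapped in B the match is kept and B's dosages are
    flipped to ``2 - dosage``. Outputs carry identical marker order.
    """
    key_a = {
        (row.chrom, row.pos): i for i, row in enumerate(A.markers.itertuples(index=False))
    }
    idx_a, idx_b, flip_b = [], [], []
    for j, row in enumerate(B.markers.itertuples(index=False)):
        i = key_a.get((row.chrom, row.pos))
        if i is None:
            continue
        ra = A.markers.iloc[i]
        if (ra["ref"], ra["alt"]) == (row.ref, row.alt):
            idx_a.append(i), idx_b.append(j), flip_b.append(False)
        elif (ra["ref"], ra["alt"]) == (row.alt, row.ref):
            idx_a.append(i), idx_b.append(j), flip_b.append(True)
        # inconsistent alleles: not a match
    if not idx_a:
        raise ValueError("no common markers between the two populations")
    # order by A's map for both outputs
    order = np.argsort(idx_a, kind="stable")
    idx_a = np.asarray(idx_a)[order]
    idx_b = np.asarray(idx_b)[order]
    flip_b = np.asarray(flip_b)[order]
    A2 = A.take_markers(idx_a)
    B2 = B.take_markers(idx_b)
    if flip_b.any():
        D = B2.dosages
        D[:, flip_b] = 2.0 - D[:, flip_b]
        M = B2.markers.copy()
        cols_ref = M["ref"].to_numpy().copy()
        M.loc[M.index[flip_b], "ref"] = M["alt"].to_numpy()[flip_b]
        M.loc[M.index[flip_b], "alt"] = cols_ref[flip_b]
        B2 = GenotypeMatrix(D, M, B2.individuals)
    return A2, B2
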