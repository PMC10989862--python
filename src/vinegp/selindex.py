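"""Multitrait genotype-ideotype distance index (MGIDI).

Given per-genotype (predicted, deregressed) genotypic values for several
traits and an ideotype declaring, per trait, whether breeders want it
maximized, minimized or near an optimum, the index

1. replaces optimum traits by |value - optimum| (direction becomes
   minimize),
2. rescales every trait to 0-100 with 100 at the desired pole, and
   multiplies each column by its weight (predictive abilities are the
   natural weights; traits under a weight threshold are excluded),
3. runs an exploratory factor analysis on the correlation matrix of the
   rescaled traits (Kaiser retention: eigenvalue >= 1; varimax rotation;
   regression factor scores), and
4. ranks genotypes by the Euclidean distance of their factor scores to the
   scores of the ideal genotype (rescaled 100 everywhere); small distance
   is good, and the squared per-factor shares give a strength/weakness
   profile of each selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "IdeotypeSpec",
    "FactorModel",
    "MGIDIResult",
    "MGIDI",
    "apply_optimum_transform",
    "rescale_traits",
    "factor_analysis",
    "compute_mgidi",
    "select_top",
]

_DIRECTIONS = ("maximize", "minimize", "optimum")


@dataclass
class IdeotypeSpec:
    """Per-trait selection direction, optimum value and weight.

    ``traits`` is indexed by trait name with columns ``direction``
    (maximize / minimize / optimum), ``optimum`` (NaN unless direction is
    optimum) and ``weight`` (>= 0; predictive abilities in practice).
    Traits whose weight falls below ``min_pa_threshold`` are excluded
    before the index is computed.
    """

    traits: pd.DataFrame
    min_pa_threshold: float = 0.0

    def __post_init__(self) -> None:
        t = self.traits
        for col in ("direction", "optimum", "weight"):
            if col not in t.columns:
                raise ValueError(f"ideotype table lacks column {col!r}")
        bad = ~t["direction"].isin(_DIRECTIONS)
        if bad.any():
            raise ValueError(f"unknown direction for traits {list(t.index[bad])}")
        need_opt = t["direction"] == "optimum"
        if t.loc[need_opt, "optimum"].isna().any():
            missing = list(t.index[need_opt & t["optimum"].isna()])
            raise ValueError(f"optimum value missing for traits {missing}")
        if t.loc[~need_opt, "optimum"].notna().any():
            extra = list(t.index[~need_opt & t["optimum"].notna()])
            raise ValueError(f"optimum given for non-optimum traits {extra}")
        if (t["weight"] < 0).any():
            raise ValueError("weights must be >= 0")

    @classmethod
    def from_dict(cls, d: dict, min_pa_threshold: float = 0.0) -> "IdeotypeSpec":
        rows = {}
        for trait, cfg in d.items():
            rows[trait] = {
                "direction": cfg.get("direction", "maximize"),
                "optimum": cfg.get("optimum", np.nan),
                "weight": cfg.get("weight", 1.0),
            }
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "trait"
        return cls(frame, min_pa_threshold=min_pa_threshold)


@dataclass
class FactorModel:
    """Rotated factor solution plus the pieces that map new rows to scores."""

    n_factors: int
    loadings: pd.DataFrame  # traits x factors (varimax-rotated)
    communalities: pd.Series
    uniquenesses: pd.Series
    scores: pd.DataFrame  # genotypes x factors
    rescaled: pd.DataFrame  # weighted 0-100 matrix the model was built on
    col_means: pd.Series
    col_sds: pd.Series
    score_operator: np.ndarray  # traits x factors; standardized row -> scores


@dataclass
class MGIDIResult:
    """Distances to the ideotype, ranks, and per-factor contributions."""

    frame: pd.DataFrame  # index genotype; columns MGIDI, rank, contrib_<factor>
    ideotype_scores: np.ndarray
    n_factors: int
    traits: list = field(default_factory=list)

    @property
    def mgidi(self) -> pd.Series:
        return self.frame["MGIDI"]

    @property
    def ranks(self) -> pd.Series:
        return self.frame["rank"]


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------

def apply_optimum_transform(
    values: pd.DataFrame, spec: IdeotypeSpec
) -> tuple[pd.DataFrame, IdeotypeSpec]:
    """Replace optimum traits by |value - optimum|, relabelled as minimize."""
    out = values.copy()
    traits = spec.traits.copy()
    for trait, row in spec.traits.iterrows():
        if row["direction"] != "optimum":
            continue
        if trait not in out.columns:
            raise ValueError(f"trait {trait!r} absent from the value matrix")
        out[trait] = (out[trait] - row["optimum"]).abs()
        traits.loc[trait, "direction"] = "minimize"
        traits.loc[trait, "optimum"] = np.nan
    return out, replace(spec, traits=traits)


def rescale_traits(values: pd.DataFrame, spec: IdeotypeSpec) -> pd.DataFrame:
    """Rescale each trait to 0-100 toward its desired pole; apply weights.

    maximize: 100 (x - min) / (max - min); minimize: 100 (max - x) /
    (max - min). Traits with weight below the configured threshold (or zero) are
    dropped; remaining columns are multiplied by their weight. Errors on a
    constant trait (zero range), naming it.
    """
    if (spec.traits["direction"] == "optimum").any():
        raise ValueError("apply_optimum_transform before rescaling")
    keep = [
        t for t, row in spec.traits.iterrows()
        if row["weight"] > 0 and row["weight"] >= spec.min_pa_threshold
    ]
    if not keep:
        raise ValueError("no traits left after the weight threshold")
    missing = [t for t in keep if t not in values.columns]
    if missing:
        raise ValueError(f"traits absent from the value matrix: {missing}")
    out = {}
    for trait in keep:
        x = values[trait].astype(float)
        lo, hi = x.min(), x.max()
        if hi - lo == 0:
            raise ValueError(f"trait {trait!r} is constant; cannot rescale")
        if spec.traits.loc[trait, "direction"] == "maximize":
            r = 100.0 * (x - lo) / (hi - lo)
        else:
            r = 100.0 * (hi - x) / (hi - lo)
        out[trait] = r * spec.traits.loc[trait, "weight"]
    return pd.DataFrame(out, index=values.index)


def _varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    R = np.eye(k)
    total = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        grad = loadings.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        new = s.sum()
        if new <= total * (1.0 + tol):
            break
        total = new
    return loadings @ R


def factor_analysis(rescaled: pd.DataFrame) -> FactorModel:
    """Eigen factor solution of the trait correlation matrix.

    Retains factors with eigenvalue >= 1 (always at least one), rotates the
    loadings by varimax, and computes regression-method scores; the score
    operator is built in the retained eigen-space so a rank-deficient
    correlation matrix (perfectly collinear traits) is still handled.
    """
    if rescaled.shape[1] < 2:
        raise ValueError("factor analysis needs at least two traits")
    if rescaled.shape[0] < 3:
        raise ValueError("factor analysis needs at least three genotypes")
    X = rescaled.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0) or not np.all(np.isfinite(sds)):
        bad = list(rescaled.columns[(sds == 0) | ~np.isfinite(sds)])
        raise ValueError(f"singular correlation matrix (constant traits {bad}); prune traits")
    Xstd = (X - means) / sds
    R = np.corrcoef(Xstd, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("singular correlation matrix; prune collinear traits")
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = max(int(np.sum(evals >= 1.0)), 1)
    lam = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0.0, None))
    rot = _varimax(lam)
    # deterministic sign: each factor's loading sum is non-negative
    signs = np.where(rot.sum(axis=0) >= 0, 1.0, -1.0)
    rot = rot * signs
    # regression scores through the retained eigen-space (pseudo-inverse when
    # the correlation matrix is rank deficient): R^+ Lambda = V_k D_k^{-1/2} Q
    Q = np.linalg.lstsq(lam, rot, rcond=None)[0]  # rotation (incl. signs)
    op = evecs[:, :k] @ (Q / np.sqrt(np.clip(evals[:k], 1e-12, None))[:, None])
    scores = Xstd @ op
    comm = (rot**2).sum(axis=1)
    fac_names = [f"FA{i + 1}" for i in range(k)]
    return FactorModel(
        n_factors=k,
        loadings=pd.DataFrame(rot, index=rescaled.columns, columns=fac_names),
        communalities=pd.Series(comm, index=rescaled.columns),
        uniquenesses=pd.Series(1.0 - comm, index=rescaled.columns),
        scores=pd.DataFrame(scores, index=rescaled.index, columns=fac_names),
        rescaled=rescaled,
        col_means=pd.Series(means, index=rescaled.columns),
        col_sds=pd.Series(sds, index=rescaled.columns),
        score_operator=op,
    )


def compute_mgidi(fm: FactorModel, spec: IdeotypeSpec | None = None) -> MGIDIResult:
    """Euclidean distance of every genotype to the ideotype in score space.

    The ideotype sits at rescaled value 100 on every (weighted) trait and is
    mapped through the same standardization and score operator as the data.
    Ranks are ascending in distance with a stable tie-break on genotype id;
    per-factor contributions are the squared-distance shares (sum to 1).
    """
    # rescaling puts the desired pole at 100 * weight, attained column-wise
    ideal = fm.rescaled.to_numpy().max(axis=0)
    ideal_std = (ideal - fm.col_means.to_numpy()) / fm.col_sds.to_numpy()
    f_ideal = ideal_std @ fm.score_operator
    diff = fm.scores.to_numpy() - f_ideal
    sq = diff**2
    d = np.sqrt(sq.sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(d[:, None] > 0, sq / sq.sum(axis=1, keepdims=True),
                           1.0 / fm.n_factors)
    order = np.lexsort((fm.scores.index.astype(str), d))
    rank = np.empty(len(d), dtype=int)
    rank[order] = np.arange(1, len(d) + 1)
    frame = pd.DataFrame({"MGIDI": d, "rank": rank}, index=fm.scores.index)
    for i, name in enumerate(fm.scores.columns):
        frame[f"contrib_{name}"] = contrib[:, i]
    frame.index.name = "genotype"
    return MGIDIResult(
        frame=frame,
        ideotype_scores=f_ideal,
        n_factors=fm.n_factors,
        traits=list(fm.rescaled.columns),
    )


def select_top(result: MGIDIResult, n_sel: int = 15) -> list:
    """The n_sel genotypes with the lowest MGIDI (stable id tie-break)."""
    n = len(result.frame)
    if n_sel > n:
        raise ValueError(f"n_sel={n_sel} exceeds population size {n}")
    ordered = result.frame.sort_values("rank").index
    return list(ordered[:n_sel])


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class MGIDI(BaseEstimator):
    """Multitrait genotype-ideotype distance index as a fit/transform step.

    Parameters
    ----------
    ideotype : IdeotypeSpec or dict
        Per-trait direction/optimum/weight (dict accepted for convenience).
    n_select : int
        Size of the selected set exposed as ``selected_``.

    Attributes (after fit)
    ----------------------
    factor_model_ : FactorModel
    result_ : MGIDIResult
    mgidi_, ranks_ : Series per genotype
    selected_ : list of the n_select best genotypes
    """

    def __init__(self, ideotype=None, n_select: int = 15):
        self.ideotype = ideotype
        self.n_select = n_select

    def _spec(self) -> IdeotypeSpec:
        if isinstance(self.ideotype, IdeotypeSpec):
            return self.ideotype
        if isinstance(self.ideotype, dict):
            return IdeotypeSpec.from_dict(self.ideotype)
        raise ValueError("ideotype must be an IdeotypeSpec or a dict")

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._spec()
        values, spec2 = apply_optimum_transform(X, spec)
        rescaled = rescale_traits(values, spec2)
        fm = factor_analysis(rescaled)
        res = compute_mgidi(fm, spec2)
        self.spec_ = spec2
        self.factor_model_ = fm
        self.result_ = res
        self.mgidi_ = res.mgidi
        self.ranks_ = res.ranks
        self.contributions_ = res.frame.filter(like="contrib_")
        self.selected_ = select_top(res, min(self.n_select, len(res.frame)))
        return self

    def transform(self, X: pd.DataFrame = None) -> pd.DataFrame:
        """Return the per-genotype distance table computed at fit time."""
        return self.result_.frame
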