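"""Per-trait mixed models: REML variance components, BLUPs and deregression.

The model for a trait observed over years on a lightly replicated (p-rep)
grid is

    y = mu + year (fixed) + genotype + cross + row + col [+ extras] + e,

with every non-year term a random intercept with its own variance. Variance
components are estimated by REML; the restricted likelihood is profiled
over the residual variance and optimized over log variance ratios with
derivative-free bounded search, so only small (q x q) solves are needed per
evaluation, where q is the total number of random-effect levels.

Broad-sense heritability is computed on the genotype scale as
H2 = (s2_genotype + s2_cross) / (s2_genotype + s2_cross + s2_residual);
spatial and year variances are excluded. Genotypic values are the sum of
genotype and cross BLUPs (when the cross term survives model selection),
with the prediction error variance (PEV) of each BLUP taken from the
conditional variance of the corresponding random level. Deregression
divides each BLUP by its reliability 1 - PEV/s2_g to undo shrinkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "LMMSpec",
    "VarianceComponents",
    "FittedLMM",
    "GenotypicValues",
    "TraitSummary",
    "fit_lmm",
    "select_effects",
    "heritability",
    "extract_blups",
    "deregress",
    "one_year_values",
]

_LOG_GAMMA_BOUNDS = (-15.0, 10.0)


@dataclass
class LMMSpec:
    """Model specification for one trait.

    ``fixed`` lists fixed terms beyond the always-present intercept
    (currently only ``year``); ``random`` lists categorical record columns
    that enter as independent random intercepts.
    """

    trait: str
    fixed: list[str] = field(default_factory=lambda: ["year"])
    random: list[str] = field(default_factory=lambda: ["genotype", "cross", "row", "col"])
    flags: dict = field(default_factory=dict)

    def without_random(self, term: str) -> "LMMSpec":
        return replace(self, random=[t for t in self.random if t != term],
                       flags=dict(self.flags))

    def without_fixed(self, term: str) -> "LMMSpec":
        return replace(self, fixed=[t for t in self.fixed if t != term],
                       flags=dict(self.flags))


@dataclass
class VarianceComponents:
    """Estimated variances per random term plus the residual."""

    components: dict  # term -> sigma^2
    residual: float

    def __getitem__(self, term: str) -> float:
        return self.components[term]

    @property
    def sigma2_g(self) -> float:
        """Total genetic variance: genotype plus cross."""
        return self.components.get("genotype", 0.0) + self.components.get("cross", 0.0)

    def as_dict(self) -> dict:
        d = dict(self.components)
        d["residual"] = self.residual
        return d


@dataclass
class FittedLMM:
    spec: LMMSpec
    varcomp: VarianceComponents
    beta: pd.Series
    loglik: float  # restricted (or full-ML) log-likelihood, up to constants
    reml: bool
    converged: bool
    blups: dict  # term -> Series indexed by level
    pev: dict  # term -> Series indexed by level
    cond_cov: dict  # (term, term) -> DataFrame of conditional covariances
    nobs: int
    rank_x: int
    geno_cross: pd.Series  # genotype level -> cross label


@dataclass
class GenotypicValues:
    """Per-genotype BLUP, PEV, reliability and deregressed BLUP."""

    trait: str
    frame: pd.DataFrame  # index genotype; columns BLUP, PEV, reliability, drgBLUP
    sigma2_g: float
    one_year: bool = False
    excluded: dict = field(default_factory=dict)  # genotype -> reason


@dataclass
class TraitSummary:
    trait: str
    h2: float
    cross_retained: bool
    one_year: bool
    corr_drg_raw: float


# ---------------------------------------------------------------------------
# design construction and the profiled likelihood
# ---------------------------------------------------------------------------

def _sorted_codes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, codes = np.unique(values.astype(str), return_inverse=True)
    return codes, levels


class _MixedDesign:
    """Cross-products of the fixed/random design; likelihood evaluations."""

    def __init__(self, records: pd.DataFrame, spec: LMMSpec):
        rec = records
        if "trait" in rec.columns and spec.trait:
            rec = rec[rec["trait"] == spec.trait]
        rec = rec.dropna(subset=["value"])
        if len(rec) == 0:
            raise ValueError(f"no records for trait {spec.trait!r}")
        # sort for record-order invariance
        rec = rec.sort_values(list(rec.columns.intersection(
            ["genotype", "year", "row", "col"])), kind="stable").reset_index(drop=True)
        self.records = rec
        y = rec["value"].to_numpy(dtype=float)
        n = len(y)

        cols = [np.ones(n)]
        names = ["(intercept)"]
        for term in spec.fixed:
            if term not in rec.columns:
                raise ValueError(f"fixed term {term!r} not in records")
            codes, levels = _sorted_codes(rec[term].to_numpy())
            if len(levels) < 2:
                raise ValueError(f"fixed term {term!r} has a single level")
            for li in range(1, len(levels)):
                cols.append((codes == li).astype(float))
                names.append(f"{term}[{levels[li]}]")
        X = np.column_stack(cols)
        self.X, self.fixed_names = X, names

        self.blocks = []  # (term, levels, codes)
        z_cols = []
        for term in spec.random:
            if term not in rec.columns:
                raise ValueError(f"random term {term!r} not in records")
            codes, levels = _sorted_codes(rec[term].to_numpy())
            if len(levels) < 2:
                raise ValueError(f"random term {term!r} has a single level")
            Zk = np.zeros((n, len(levels)))
            Zk[np.arange(n), codes] = 1.0
            self.blocks.append((term, levels, codes))
            z_cols.append(Zk)
        self.K = len(self.blocks)
        self.block_sizes = [len(b[1]) for b in self.blocks]
        if self.K:
            Z = np.concatenate(z_cols, axis=1)
            self.ZtZ = Z.T @ Z
            self.ZtX = Z.T @ X
            self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = y @ y
        self.y = y
        self.n = n
        self.p = np.linalg.matrix_rank(X)

    def _expand(self, gammas: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [np.full(sz, g) for sz, g in zip(self.block_sizes, gammas)]
        ) if self.K else np.empty(0)

    def _core(self, gammas: np.ndarray):
        """Pieces of H^{-1}-quadratics for H = I + sum_k gamma_k Z_k Z_k'."""
        if self.K == 0 or np.all(gammas == 0):
            XtHX, XtHy, yHy, logdetM = self.XtX, self.Xty, self.yty, 0.0
            M_chol, s = None, None
        else:
            s = np.sqrt(self._expand(gammas))
            M = self.ZtZ * np.outer(s, s)
            M[np.diag_indices_from(M)] += 1.0
            M_chol = cho_factor(M, lower=True)
            logdetM = 2.0 * np.sum(np.log(np.diag(M_chol[0])))
            SZtX = s[:, None] * self.ZtX
            SZty = s * self.Zty
            XtHX = self.XtX - SZtX.T @ cho_solve(M_chol, SZtX)
            XtHy = self.Xty - SZtX.T @ cho_solve(M_chol, SZty)
            yHy = self.yty - SZty @ cho_solve(M_chol, SZty)
        sign, logdet_xhx = np.linalg.slogdet(XtHX)
        beta = np.linalg.solve(XtHX, XtHy)
        quad = max(yHy - XtHy @ beta, 1e-300)
        return beta, quad, logdetM, logdet_xhx, XtHX, M_chol, s

    def neg2loglik(self, gammas: np.ndarray, reml: bool = True) -> float:
        beta, quad, logdetM, logdet_xhx, *_ = self._core(gammas)
        n, p = self.n, self.p
        if reml:
            s2 = quad / (n - p)
            return (n - p) * (np.log(2 * np.pi * s2) + 1.0) + logdetM + logdet_xhx
        s2 = quad / n
        return n * (np.log(2 * np.pi * s2) + 1.0) + logdetM

    def solve(self, gammas: np.ndarray, reml: bool = True):
        """Estimates at fixed gamma: beta, s2e, BLUPs, PEVs (with the
        genotype-cross conditional covariance), loglik."""
        beta, quad, logdetM, logdet_xhx, XtHX, M_chol, s = self._core(gammas)
        n, p = self.n, self.p
        s2e = quad / (n - p) if reml else quad / n
        blups, pevs = {}, {}
        cond_cov = {}
        if self.K:
            # Z'H^{-1}(y - X beta) and the conditional variance of each level
            Zte = self.Zty - self.ZtX @ beta
            if M_chol is not None:
                Zte = Zte - (self.ZtZ * s) @ cho_solve(M_chol, s * Zte)
                B = self.ZtZ - (self.ZtZ * s) @ cho_solve(M_chol, s[:, None] * self.ZtZ)
                Cx = self.ZtX - (self.ZtZ * s) @ cho_solve(M_chol, s[:, None] * self.ZtX)
            else:
                B, Cx = self.ZtZ, self.ZtX
            W = np.linalg.solve(XtHX, Cx.T)
            ZPZ = B - Cx @ W  # times 1/s2e is Z' P Z
            gam_full = self._expand(gammas)
            u = gam_full * Zte
            pev_full = s2e * (gam_full - gam_full**2 * np.diag(ZPZ))
            off = 0
            offsets = {}
            for (term, levels, _), sz, g in zip(self.blocks, self.block_sizes, gammas):
                blups[term] = pd.Series(u[off:off + sz], index=levels, name=term)
                pevs[term] = pd.Series(
                    np.clip(pev_full[off:off + sz], 0.0, None), index=levels, name=term
                )
                offsets[term] = (off, off + sz, g)
                off += sz
            # conditional covariance between genotype and cross levels: the
            # off-diagonal block of Var(u_hat - u) = G - G Z'PZ G
            if "genotype" in offsets and "cross" in offsets:
                g0, g1, gam_g = offsets["genotype"]
                c0, c1, gam_c = offsets["cross"]
                block = -s2e * gam_g * gam_c * ZPZ[g0:g1, c0:c1]
                cond_cov[("genotype", "cross")] = pd.DataFrame(
                    block, index=blups["genotype"].index,
                    columns=blups["cross"].index,
                )
        ll = -0.5 * self.neg2loglik(gammas, reml=reml)
        return beta, s2e, blups, pevs, cond_cov, ll


def _optimize_gammas(design: _MixedDesign, reml: bool) -> tuple[np.ndarray, bool]:
    K = design.K
    if K == 0:
        return np.empty(0), True
    lo, hi = _LOG_GAMMA_BOUNDS
    obj = lambda phi: design.neg2loglik(np.exp(phi), reml=reml)
    if K == 1:
        res = optimize.minimize_scalar(
            lambda p: obj(np.array([p])), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        phi = np.array([res.x])
        ok = True
    else:
        res = optimize.minimize(
            obj, x0=np.zeros(K), method="Powell",
            bounds=[(lo, hi)] * K,
            options={"xtol": 1e-8, "ftol": 1e-12, "maxfev": 40000},
        )
        phi, ok = res.x.copy(), bool(res.success)
        # cyclic 1-D polish for tight component accuracy
        for _ in range(2):
            for k in range(K):
                def obj_k(p, k=k):
                    ph = phi.copy()
                    ph[k] = p
                    return obj(ph)
                r = optimize.minimize_scalar(
                    obj_k, bounds=(lo, hi), method="bounded", options={"xatol": 1e-11}
                )
                phi[k] = r.x
    return np.exp(phi), ok


def fit_lmm(records: pd.DataFrame, spec: LMMSpec, reml: bool = True) -> FittedLMM:
    """REML (or ML) fit of the random-intercept mixed model for one trait."""
    design = _MixedDesign(records, spec)
    gammas, ok = _optimize_gammas(design, reml=reml)
    if not ok:
        raise RuntimeError(
            f"variance-component optimization did not converge for {spec.trait!r} "
            f"(last gammas {gammas})"
        )
    beta, s2e, blups, pevs, cond_cov, ll = design.solve(gammas, reml=reml)
    comps = {term: float(g * s2e) for (term, _, _), g in zip(design.blocks, gammas)}
    vc = VarianceComponents(components=comps, residual=float(s2e))
    rec = design.records
    if "genotype" in rec.columns and "cross" in rec.columns:
        geno_cross = rec.drop_duplicates("genotype").set_index("genotype")["cross"]
    else:
        geno_cross = pd.Series(dtype=object)
    return FittedLMM(
        spec=spec,
        varcomp=vc,
        beta=pd.Series(beta, index=design.fixed_names),
        loglik=float(ll),
        reml=reml,
        converged=ok,
        blups=blups,
        pev=pevs,
        cond_cov=cond_cov,
        nobs=design.n,
        rank_x=design.p,
        geno_cross=geno_cross.astype(str),
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def select_effects(
    records: pd.DataFrame, full_spec: LMMSpec, alpha: float = 0.05
) -> LMMSpec:
    """Backward elimination of random terms (REML LRT) and the fixed year term.

    Each random term is tested by a likelihood-ratio test against a
    chi-square with one degree of freedom; the least significant term with
    p >= alpha is dropped and the procedure repeats. If the genotype term
    itself is dropped the trait is flagged non-genetic and only fixed-effect
    selection is retained. The year fixed effect is tested with a Wald
    F-test (residual denominator df) on the maximum-likelihood fit.
    """
    spec = replace(full_spec, random=list(full_spec.random),
                   fixed=list(full_spec.fixed), flags=dict(full_spec.flags))
    while spec.random:
        full_fit = fit_lmm(records, spec, reml=True)
        pvals = {}
        for term in spec.random:
            red = fit_lmm(records, spec.without_random(term), reml=True)
            lrt = max(2.0 * (full_fit.loglik - red.loglik), 0.0)
            pvals[term] = stats.chi2.sf(lrt, df=1)
        worst = max(pvals, key=lambda t: (pvals[t], t))
        if pvals[worst] >= alpha:
            spec = spec.without_random(worst)
        else:
            break
    spec.flags["genotype_retained"] = "genotype" in spec.random
    spec.flags["cross_retained"] = "cross" in spec.random

    if "year" in spec.fixed:
        ml_fit = fit_lmm(records, spec, reml=False)
        design = _MixedDesign(records, spec)
        gammas = np.array(
            [ml_fit.varcomp[t] / ml_fit.varcomp.residual for t in spec.random]
        )
        _, quad, _, _, XtHX, _, _ = design._core(gammas)
        s2 = quad / design.n
        cov_beta = s2 * np.linalg.inv(XtHX)
        sel = [i for i, nm in enumerate(design.fixed_names) if nm.startswith("year[")]
        b = ml_fit.beta.to_numpy()[sel]
        C = cov_beta[np.ix_(sel, sel)]
        fstat = float(b @ np.linalg.solve(C, b)) / len(sel)
        df2 = design.n - design.p
        p_year = stats.f.sf(fstat, len(sel), df2)
        if p_year >= alpha:
            spec = spec.without_fixed("year")
        spec.flags["year_retained"] = "year" in spec.fixed
    return spec


# ---------------------------------------------------------------------------
# genotypic values
# ---------------------------------------------------------------------------

def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability (s2_G + s2_C) / (s2_G + s2_C + s2_e)."""
    denom = vc.sigma2_g + vc.residual
    if denom <= 0:
        raise ValueError("zero total variance; heritability undefined")
    return vc.sigma2_g / denom


def extract_blups(fit: FittedLMM) -> GenotypicValues:
    """Genotypic value per genotype: genotype BLUP (+ cross BLUP if retained).

    The PEV of the sum adds the two conditional variances; their conditional
    covariance is ignored (documented approximation). Reliability is
    1 - PEV / s2_g with s2_g the total genetic variance.
    """
    if "genotype" not in fit.blups:
        raise ValueError(
            "genotype term absent from the fitted model; use the one-year/raw "
            "fallback for this trait"
        )
    g_blup = fit.blups["genotype"]
    g_pev = fit.pev["genotype"]
    blup = g_blup.copy()
    pev = g_pev.copy()
    if "cross" in fit.blups:
        cr = fit.geno_cross.reindex(g_blup.index)
        blup = blup + fit.blups["cross"].reindex(cr.to_numpy()).to_numpy()
        pev = pev + fit.pev["cross"].reindex(cr.to_numpy()).to_numpy()
        cov = fit.cond_cov.get(("genotype", "cross"))
        if cov is not None:
            # PEV of the sum includes twice the conditional covariance of the
            # genotype and cross BLUPs (usually negative: shared information)
            own = np.array([
                cov.at[gid, cj] for gid, cj in zip(g_blup.index, cr.to_numpy())
            ])
            pev = np.clip(pev + 2.0 * own, 0.0, None)
    sigma2_g = fit.varcomp.sigma2_g
    rel = 1.0 - pev / sigma2_g if sigma2_g > 0 else pd.Series(np.nan, index=blup.index)
    frame = pd.DataFrame(
        {"BLUP": blup, "PEV": pev, "reliability": rel, "drgBLUP": np.nan}
    )
    frame.index.name = "genotype"
    return GenotypicValues(trait=fit.spec.trait, frame=frame, sigma2_g=float(sigma2_g))


def deregress(values: GenotypicValues) -> GenotypicValues:
    """Deregress BLUPs: drgBLUP = BLUP / (1 - PEV / s2_g).

    Genotypes whose reliability is not positive (PEV >= s2_g) get a missing
    deregressed value and are recorded with a reason.
    """
    if values.sigma2_g <= 0:
        raise ValueError("sigma2_g must be positive to deregress")
    frame = values.frame.copy()
    rel = 1.0 - frame["PEV"] / values.sigma2_g
    frame["reliability"] = rel
    good = rel > 0
    excluded = dict(values.excluded)
    if (~good).any():
        for gid in frame.index[~good]:
            excluded[gid] = "reliability <= 0 (PEV >= sigma2_g)"
        warnings.warn(
            f"{(~good).sum()} genotype(s) excluded from deregression for trait "
            f"{values.trait!r}: PEV >= sigma2_g",
            stacklevel=2,
        )
    frame["drgBLUP"] = np.where(good, frame["BLUP"] / rel, np.nan)
    return GenotypicValues(
        trait=values.trait,
        frame=frame,
        sigma2_g=values.sigma2_g,
        one_year=values.one_year,
        excluded=excluded,
    )


def one_year_values(records: pd.DataFrame, trait: str | None = None) -> GenotypicValues:
    """Raw-data fallback for traits phenotyped a single year.

    Each genotype's value is its single observation, or the mean over
    replicates for controls. PEV and reliability are undefined.
    """
    rec = records
    if "trait" in rec.columns and trait:
        rec = rec[rec["trait"] == trait]
    rec = rec.dropna(subset=["value"])
    means = rec.groupby("genotype")["value"].mean().sort_index()
    frame = pd.DataFrame(
        {"BLUP": means, "PEV": np.nan, "reliability": np.nan, "drgBLUP": means}
    )
    frame.index.name = "genotype"
    name = trait
    if not name and "trait" in rec.columns and len(rec):
        name = str(rec["trait"].iloc[0])
    return GenotypicValues(
        trait=name or "",
        frame=frame,
        sigma2_g=float("nan"),
        one_year=True,
    )
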