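"""Genotype-environment association in the native range.

Two complementary scans, as is standard in landscape genomics:

* a latent-factor scan on individual dosages — per-locus least-squares
  regression of genotype on the standardized climate variables plus
  ``n_latent`` latent factors that absorb neutral population structure
  (the factors come from the SVD of the genotype matrix residualized on
  the environmental design, the frequentist "lfmm2" construction); z-scores
  are recalibrated by the genomic inflation factor and converted to
  Benjamini-Hochberg q-values per variable;

* a population-based (partial) redundancy analysis — constrained ordination
  of population allele frequencies on climate, optionally after removing
  conditioning covariates (geographic coordinates and refugial ancestry),
  with a permutation test on the constrained inertia and a +/-k standard
  deviation outlier rule on the locus loadings of the first axis.

A pRDA-based variance partition splits the explained inertia into unique
climate, geography and demography fractions plus their confounded overlap.
Candidates from the two scans are intersected/united and an "adaptively
enriched" RDA on the combined candidates provides the environmental-variable
scores that the offset module extrapolates over climate rasters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genio import ENV_VARIABLES, GenotypeMatrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# environment standardization
# --------------------------------------------------------------------------

@dataclass
class Standardization:
    """Per-variable mean and sd recorded over the native range."""

    mean: pd.Series
    sd: pd.Series

    def apply(self, env: pd.DataFrame) -> pd.DataFrame:
        return (env[self.mean.index] - self.mean) / self.sd


def standardize_env(env: pd.DataFrame,
                    max_abs_corr: float = 0.7) -> tuple[pd.DataFrame,
                                                        Standardization]:
    """Centre and scale environmental variables; warn on collinear pairs
    (|r| >= ``max_abs_corr``)."""
    std = Standardization(mean=env.mean(), sd=env.std(ddof=1))
    if (std.sd <= 0).any():
        bad = list(std.sd.index[std.sd <= 0])
        raise ValueError(f"constant environmental variables: {bad}")
    z = std.apply(env)
    corr = z.corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    hot = np.abs(corr[iu]) >= max_abs_corr
    if hot.any():
        pairs = [(env.columns[i], env.columns[j])
                 for i, j, h in zip(*iu, hot) if h]
        logger.warning("collinear variable pairs (|r| >= %.2f): %s",
                       max_abs_corr, pairs)
    return z, std


# --------------------------------------------------------------------------
# latent-factor scan
# --------------------------------------------------------------------------

@dataclass
class LfmmResult:
    """Per-locus, per-variable effect sizes and calibrated significance."""

    effects: pd.DataFrame       # loci x variables
    z: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_latent: int
    gif: pd.Series              # genomic inflation factor per variable

    def candidates(self, q_threshold: float = 0.1) -> set[str]:
        """Loci whose smallest q-value over variables passes the cut."""
        return set(self.q.index[(self.q.min(axis=1) < q_threshold)])


def _impute_center(d: np.ndarray) -> np.ndarray:
    mu = np.nanmean(d, axis=0)
    return np.where(np.isnan(d), mu, d) - mu


def lfmm_scan(g: GenotypeMatrix | np.ndarray, env: pd.DataFrame,
              n_latent: int = 2, seed: int = 0) -> LfmmResult:
    """Latent-factor least-squares genotype-environment scan.

    ``env`` must be row-aligned with the samples of ``g`` and standardized.
    Missing dosages are mean-imputed for the factor estimation and the
    per-locus regressions (they carry no signal either way).
    """
    d = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    locus_ids = (g.locus_ids if isinstance(g, GenotypeMatrix)
                 else [f"L{j}" for j in range(d.shape[1])])
    X = env.to_numpy(dtype=float)
    n, L = d.shape
    if X.shape[0] != n:
        raise ValueError("env rows must align with samples")
    if n_latent >= min(n, L):
        raise ValueError("n_latent must be < min(n_samples, n_loci)")

    Y = _impute_center(d)

    # latent factors: SVD of the genotype matrix with the environmental
    # design projected off, so the factors model structure orthogonal to
    # the tested predictors and cannot swallow the association signal;
    # structure collinear with a predictor inflates that predictor's z
    # background instead and is handled by the genomic-inflation rescaling
    D_env = np.column_stack([np.ones(n), X])
    Q_env, _ = np.linalg.qr(D_env)
    if n_latent > 0:
        resid = Y - Q_env @ (Q_env.T @ Y)
        u, _, _ = np.linalg.svd(resid, full_matrices=False)
        U = u[:, :n_latent]
        D = np.column_stack([D_env, U])
    else:
        D = D_env

    # vectorized per-locus OLS of dosage on [1, env, factors]
    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ (D.T @ Y)                   # p x L
    fitted = D @ beta
    dof = n - D.shape[1]
    sigma2 = np.sum((Y - fitted) ** 2, axis=0) / dof
    se = np.sqrt(np.outer(np.diag(DtD_inv), sigma2))
    env_rows = slice(1, 1 + X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        zmat = (beta[env_rows] / se[env_rows]).T   # loci x vars
    zmat = np.where(np.isfinite(zmat), zmat, 0.0)  # monomorphic loci

    cols = list(env.columns)
    z_df = pd.DataFrame(zmat, index=locus_ids, columns=cols)
    gif = z_df.pow(2).median() / stats.chi2.ppf(0.5, 1)
    gif = gif.clip(lower=1e-8)
    z_cal = z_df / np.sqrt(gif)
    p_df = pd.DataFrame(stats.chi2.sf(z_cal.to_numpy() ** 2, df=1),
                        index=locus_ids, columns=cols)
    q_df = p_df.apply(lambda col: multipletests(col, method="fdr_bh")[1])
    logger.info("lfmm scan: %d loci, %d variables, GIF %s", L, len(cols),
                dict(gif.round(2)))
    return LfmmResult(
        effects=pd.DataFrame(beta[env_rows].T, index=locus_ids, columns=cols),
        z=z_cal, p=p_df, q=q_df, n_latent=n_latent, gif=gif,
    )


# --------------------------------------------------------------------------
# (partial) redundancy analysis
# --------------------------------------------------------------------------

@dataclass
class RdaResult:
    """Constrained-ordination result with inertia bookkeeping."""

    loadings: pd.DataFrame      # loci x axes (response weights, V columns)
    env_scores: pd.DataFrame    # variables x axes (corr with lc site scores)
    site_scores: pd.DataFrame   # sites x axes (lc: fitted site scores)
    eigvals: np.ndarray         # constrained inertia per axis
    total_inertia: float
    perm_p: float | None
    condition_cols: list[str] = field(default_factory=list)

    @property
    def constrained_inertia(self) -> float:
        return float(self.eigvals.sum())

    @property
    def r_squared(self) -> float:
        return self.constrained_inertia / self.total_inertia


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0)


def _residualize(a: np.ndarray, z: np.ndarray) -> np.ndarray:
    D = np.column_stack([np.ones(len(a)), z])
    q, _ = np.linalg.qr(D)
    return a - q @ (q.T @ a)


def rda(freqs: pd.DataFrame, env: pd.DataFrame,
        condition: pd.DataFrame | None = None, n_permutations: int = 999,
        seed: int = 0) -> RdaResult:
    """(Partial) redundancy analysis of allele frequencies on predictors.

    Rows of ``freqs``/``env``/``condition`` are sites (populations).
    Missing frequency cells are mean-imputed (logged).  With a condition
    block, response and predictors are first residualized on it; the
    constrained axes are the SVD of the fitted values of the multivariate
    regression of (residualized) response on (residualized) predictors.
    Inertia is measured as sum of squares / (n - 1); the permutation test
    permutes rows of the residualized predictors.
    """
    if not freqs.index.equals(env.index):
        env = env.reindex(freqs.index)
    Y = freqs.to_numpy(dtype=float)
    if np.isnan(Y).any():
        n_bad = int(np.isnan(Y).sum())
        logger.info("mean-imputing %d missing frequency cells", n_bad)
        mu = np.nanmean(Y, axis=0)
        Y = np.where(np.isnan(Y), mu, Y)
    X = env.to_numpy(dtype=float)
    n = Y.shape[0]
    Yc = _center(Y)
    total = float(np.sum(Yc ** 2)) / (n - 1)

    cond_cols: list[str] = []
    if condition is not None:
        Z = condition.reindex(freqs.index).to_numpy(dtype=float)
        cond_cols = list(condition.columns)
        # collinearity of predictors with the conditioning design
        collinear = []
        for j, name in enumerate(env.columns):
            res = _residualize(X[:, [j]], Z)
            if np.sum(res ** 2) < 1e-10 * max(np.sum(X[:, j] ** 2), 1e-30):
                collinear.append(name)
        if len(collinear) == len(env.columns):
            # fully self-conditioned model: nothing left to constrain
            logger.warning("all predictors lie in the conditioning design; "
                           "constrained inertia is 0")
            axes: list[str] = []
            return RdaResult(
                loadings=pd.DataFrame(index=freqs.columns, columns=axes,
                                      dtype=float),
                env_scores=pd.DataFrame(index=env.columns, columns=axes,
                                        dtype=float),
                site_scores=pd.DataFrame(index=freqs.index, columns=axes,
                                         dtype=float),
                eigvals=np.zeros(0), total_inertia=total, perm_p=None,
                condition_cols=cond_cols,
            )
        if collinear:
            raise ValueError(
                f"predictors {collinear} are collinear with the "
                f"conditioning design {cond_cols}")
        Yr = _residualize(Yc, Z)
        Xr = _residualize(_center(X), Z)
    else:
        Yr = Yc
        Xr = _center(X)

    def fit_inertia(Xmat: np.ndarray) -> float:
        q, _ = np.linalg.qr(Xmat)
        return float(np.sum((q.T @ Yr) ** 2)) / (n - 1)

    qx, _ = np.linalg.qr(Xr)
    Yhat = qx @ (qx.T @ Yr)
    u, s, vt = np.linalg.svd(Yhat, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * (s[0] if s.size and s[0] > 0 else 1.0)))
    rank = min(rank, X.shape[1])
    eig = (s[:rank] ** 2) / (n - 1)
    V = vt[:rank].T                           # loci x axes
    lc = u[:, :rank] * s[:rank]               # fitted (lc) site scores

    # env-variable scores: correlation of predictors with lc site scores
    scores = np.zeros((X.shape[1], rank))
    for a in range(rank):
        for j in range(X.shape[1]):
            sx = np.std(Xr[:, j])
            sl = np.std(lc[:, a])
            if sx > 0 and sl > 0:
                scores[j, a] = np.corrcoef(Xr[:, j], lc[:, a])[0, 1]

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        obs = float(eig.sum())
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if fit_inertia(Xr[perm]) >= obs - 1e-12:
                hits += 1
        perm_p = (1.0 + hits) / (1.0 + n_permutations)

    axes = [f"RDA{a+1}" for a in range(rank)]
    return RdaResult(
        loadings=pd.DataFrame(V, index=freqs.columns, columns=axes),
        env_scores=pd.DataFrame(scores, index=env.columns, columns=axes),
        site_scores=pd.DataFrame(lc, index=freqs.index, columns=axes),
        eigvals=eig, total_inertia=total, perm_p=perm_p,
        condition_cols=cond_cols,
    )


def prda(freqs: pd.DataFrame, env: pd.DataFrame, condition: pd.DataFrame,
         n_permutations: int = 999, seed: int = 0) -> RdaResult:
    """Partial RDA conditioned on geography and ancestry (thin wrapper)."""
    return rda(freqs, env, condition=condition,
               n_permutations=n_permutations, seed=seed)


# --------------------------------------------------------------------------
# variance partitioning
# --------------------------------------------------------------------------

@dataclass
class VariancePartition:
    """Inertia decomposition over climate, geography and demography.

    ``full`` is the inertia constrained by all three blocks together;
    each unique term conditions on the other two; ``confounded`` is the
    jointly explained remainder and ``unexplained`` the residual.
    Proportions are fractions of total inertia and sum to 1.
    """

    total: float
    full: float
    climate: float
    geography: float
    demography: float
    #: bias-corrected (Ezekiel-adjusted) unique fractions of total variance,
    #: filled by :func:`variance_partition`; raw semipartial fractions carry
    #: an O(n_predictors / n_sites) positive bias under the null
    adjusted: dict[str, float] | None = None

    @property
    def confounded(self) -> float:
        return self.full - (self.climate + self.geography + self.demography)

    @property
    def unexplained(self) -> float:
        return self.total - self.full

    def as_table(self) -> pd.DataFrame:
        rows = [
            ("full_model", self.full),
            ("climate_unique", self.climate),
            ("geography_unique", self.geography),
            ("demography_unique", self.demography),
            ("confounded", self.confounded),
            ("unexplained", self.unexplained),
            ("total", self.total),
        ]
        df = pd.DataFrame(rows, columns=["component", "inertia"])
        df["proportion_of_total"] = df["inertia"] / self.total
        return df.set_index("component")

    @classmethod
    def from_inertias(cls, total: float, full: float, climate: float,
                      geography: float, demography: float
                      ) -> "VariancePartition":
        """Bookkeeping from already-computed inertias (e.g., a published
        decomposition) without re-running the ordinations."""
        return cls(total=total, full=full, climate=climate,
                   geography=geography, demography=demography)


def variance_partition(freqs: pd.DataFrame, climate: pd.DataFrame,
                       geography: pd.DataFrame, demography: pd.DataFrame,
                       seed: int = 0) -> VariancePartition:
    """pRDA-based decomposition of explained inertia into unique and
    confounded fractions of climate, geography and demography."""
    for name, block in (("climate", climate), ("geography", geography),
                        ("demography", demography)):
        if block.shape[1] == 0:
            raise ValueError(f"empty predictor block: {name}")
    all_pred = pd.concat([climate, geography, demography], axis=1)
    full = rda(freqs, all_pred, n_permutations=0, seed=seed)
    uc = rda(freqs, climate, condition=pd.concat([geography, demography],
                                                 axis=1), n_permutations=0)
    ug = rda(freqs, geography, condition=pd.concat([climate, demography],
                                                   axis=1), n_permutations=0)
    ud = rda(freqs, demography, condition=pd.concat([climate, geography],
                                                    axis=1), n_permutations=0)

    # adjusted unique fractions: adjR2(all) - adjR2(other two blocks)
    n = freqs.shape[0]

    def adj(r2: float, p: int) -> float:
        if n - 1 - p <= 0:      # no residual df: correction undefined
            return np.nan
        return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - p)

    def r2_of(blocks: list[pd.DataFrame]) -> tuple[float, int]:
        X = pd.concat(blocks, axis=1)
        return rda(freqs, X, n_permutations=0).r_squared, X.shape[1]

    adj_full = adj(full.r_squared, all_pred.shape[1])
    adjusted = {}
    for name, others in (("climate", [geography, demography]),
                         ("geography", [climate, demography]),
                         ("demography", [climate, geography])):
        r2_red, p_red = r2_of(others)
        adjusted[name] = adj_full - adj(r2_red, p_red)
    adjusted["full"] = adj_full

    return VariancePartition(
        total=full.total_inertia, full=full.constrained_inertia,
        climate=uc.constrained_inertia, geography=ug.constrained_inertia,
        demography=ud.constrained_inertia, adjusted=adjusted,
    )


# --------------------------------------------------------------------------
# outliers and candidate sets
# --------------------------------------------------------------------------

def rda_outliers(r: RdaResult, axis: int = 1, sd: float = 2.5) -> set[str]:
    """Loci whose loading on the chosen axis is beyond ``sd`` standard
    deviations of the loading distribution."""
    name = f"RDA{axis}"
    if name not in r.loadings.columns:
        raise ValueError(f"axis {axis} not present")
    load = r.loadings[name]
    dev = (load - load.mean()).abs()
    return set(load.index[dev > sd * load.std(ddof=1)])


@dataclass
class CandidateSet:
    """Candidate loci from the two scans and their set algebra."""

    lfmm_loci: set[str]
    rda_loci: set[str]

    @property
    def shared(self) -> set[str]:
        return self.lfmm_loci & self.rda_loci

    @property
    def combined(self) -> set[str]:
        return self.lfmm_loci | self.rda_loci


def combine_candidates(lfmm_set: set[str], rda_set: set[str]) -> CandidateSet:
    return CandidateSet(lfmm_loci=set(lfmm_set), rda_loci=set(rda_set))


def strongest_variable(freqs: pd.DataFrame, env: pd.DataFrame,
                       loci: set[str] | list[str]) -> pd.Series:
    """Per-locus environmental variable with the largest |correlation|.

    Ties break deterministically to the first variable in canonical order
    (the order of ``env``'s columns).
    """
    out = {}
    X = env.to_numpy(dtype=float)
    for locus in sorted(loci):
        y = freqs[locus].to_numpy(dtype=float)
        best, best_r = env.columns[0], -1.0
        for j, name in enumerate(env.columns):
            sx, sy = np.std(X[:, j]), np.std(y)
            rr = abs(np.corrcoef(X[:, j], y)[0, 1]) if sx > 0 and sy > 0 else 0.0
            if rr > best_r + 1e-15:
                best, best_r = name, rr
        out[locus] = best
    return pd.Series(out, name="strongest_variable")


def enriched_rda(freqs: pd.DataFrame, env: pd.DataFrame,
                 candidates: set[str] | list[str],
                 n_permutations: int = 0, seed: int = 0) -> RdaResult:
    """Unconditioned RDA restricted to the candidate loci; its axis-1
    environmental-variable scores feed the genotype-environment index."""
    cand = [c for c in freqs.columns if c in set(candidates)]
    if not cand:
        raise ValueError("empty candidate set")
    return rda(freqs[cand], env, n_permutations=n_permutations, seed=seed)
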