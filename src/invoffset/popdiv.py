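"""Per-population diversity metrics and status/ancestry regression models.

Metrics are computed per variant site and averaged over variant sites only
(the reduced-representation convention), so values are comparable between
runs of this pipeline but not to genome-wide nucleotide diversity:

* Ho — fraction of heterozygotes among non-missing genotypes;
* He — 2p(1-p) from the population allele frequency;
* Pi — sample-size-corrected heterozygosity (n/(n-1)) * 2p(1-p) with n the
  number of non-missing allele copies;
* Pa — count of loci carrying an allele observed in the focal population
  and in no other population.

The regression stage asks whether diversity tracks recent introduction
history (population status) or refugial ancestry (admixture proportion to
the western cluster, entered with a quadratic term to capture the
admixture-peak hump): OLS for Ho/He/Pi with F-tests on nested models,
Poisson GLM with deviance likelihood-ratio tests for the private-allele
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .genio import GenotypeMatrix

logger = logging.getLogger(__name__)


def allele_frequencies(g: GenotypeMatrix, groups: pd.Series) -> pd.DataFrame:
    """ALT-allele frequency per population per locus.

    ``groups`` maps each of ``g.sample_ids`` to a population id.  Frequency
    is the ALT count over non-missing allele copies; cells where a
    population has no genotyped sample are NaN.
    """
    groups = pd.Series(groups).reindex(g.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a population assignment")
    out = {}
    for pop, idx in groups.groupby(groups).groups.items():
        rows = [g.sample_ids.index(s) for s in idx]
        d = g.dosages[rows, :]
        if d.shape[0] == 0:
            raise ValueError(f"empty population {pop}")
        alt = np.nansum(d, axis=0)
        n = 2.0 * np.sum(~np.isnan(d), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[pop] = np.where(n > 0, alt / n, np.nan)
    return pd.DataFrame(out, index=g.locus_ids).T.sort_index()


def diversity_metrics(g: GenotypeMatrix, groups: pd.Series) -> pd.DataFrame:
    """Ho, He, Pi (means over variant sites) and Pa per population."""
    groups = pd.Series(groups).reindex(g.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a population assignment")
    pops = sorted(groups.unique())
    sample_rows = {p: np.array([i for i, s in enumerate(g.sample_ids)
                                if groups[s] == p]) for p in pops}

    # presence of each allele per population, for private-allele counting
    has_ref = np.zeros((len(pops), g.n_loci), dtype=bool)
    has_alt = np.zeros((len(pops), g.n_loci), dtype=bool)

    recs = []
    for k, p in enumerate(pops):
        d = g.dosages[sample_rows[p], :]
        n_geno = np.sum(~np.isnan(d), axis=0)
        n_alleles = 2.0 * n_geno
        alt = np.nansum(d, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_alleles > 0, alt / n_alleles, np.nan)
            ho = np.where(n_geno > 0,
                          np.nansum(d == 1.0, axis=0) / n_geno, np.nan)
        he = 2.0 * freq * (1.0 - freq)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(n_alleles > 1,
                          he * n_alleles / (n_alleles - 1.0), np.nan)
        has_ref[k] = alt < n_alleles
        has_alt[k] = alt > 0
        has_ref[k] &= n_alleles > 0
        has_alt[k] &= n_alleles > 0
        recs.append({
            "population_id": p,
            "Ho": float(np.nanmean(ho)),
            "He": float(np.nanmean(he)),
            "Pi": float(np.nanmean(pi)),
            "n_samples": int(len(sample_rows[p])),
        })
        if np.all(n_geno < 2):
            logger.warning("population %s has <2 genotyped samples at every "
                           "locus; Pi undefined", p)

    div = pd.DataFrame(recs).set_index("population_id")
    # private alleles: allele present in focal pop, absent everywhere else
    pa = np.zeros(len(pops), dtype=int)
    for k in range(len(pops)):
        others_ref = np.any(np.delete(has_ref, k, axis=0), axis=0)
        others_alt = np.any(np.delete(has_alt, k, axis=0), axis=0)
        private = (has_ref[k] & ~others_ref) | (has_alt[k] & ~others_alt)
        pa[k] = int(private.sum())
    div["Pa"] = pa
    return div[["Ho", "He", "Pi", "Pa", "n_samples"]]


@dataclass
class DiversityModelFit:
    """LRT summary for one diversity metric ~ status + qW + qW^2."""

    response: str
    family: str                      # "gaussian" or "poisson"
    coefficients: pd.Series
    status_stat: float               # F (gaussian) or LRT chi2 (poisson)
    status_p: float
    ancestry_stat: float
    ancestry_p: float
    r_squared: float | None          # gaussian only
    deviance: float | None           # poisson only
    status_means: pd.DataFrame       # fitted mean with 95% CI per status


def _status_means_ols(fit, data: pd.DataFrame) -> pd.DataFrame:
    rows = []
    qbar = data["qW"].mean()
    for st in sorted(data["status"].unique()):
        new = pd.DataFrame({"status": [st], "qW": [qbar]})
        pred = fit.get_prediction(new).summary_frame(alpha=0.05)
        rows.append((st, pred["mean"][0], pred["mean_ci_lower"][0],
                     pred["mean_ci_upper"][0]))
    return pd.DataFrame(rows, columns=["status", "mean", "lo", "hi"]
                        ).set_index("status")


def _status_means_poisson(fit, data: pd.DataFrame) -> pd.DataFrame:
    """Wald intervals on the log link, exponentiated."""
    rows = []
    qbar = data["qW"].mean()
    for st in sorted(data["status"].unique()):
        new = pd.DataFrame({"status": [st], "qW": [qbar]})
        pred = fit.get_prediction(new)
        eta = float(np.clip(pred.linpred.predicted_mean[0], -700, 700))
        se = float(min(pred.linpred.se[0], 700))
        rows.append((st, np.exp(eta), np.exp(max(eta - 1.96 * se, -700)),
                     np.exp(min(eta + 1.96 * se, 700))))
    return pd.DataFrame(rows, columns=["status", "mean", "lo", "hi"]
                        ).set_index("status")


def fit_diversity_models(div: pd.DataFrame, qw: pd.Series,
                         status: pd.Series) -> dict[str, DiversityModelFit]:
    """Fit metric ~ status + qW + qW^2 for each diversity metric.

    Ho/He/Pi: OLS with F-tests dropping the status block and the ancestry
    block (qW + qW^2) from the full model.  Pa: Poisson log-link GLM with
    deviance likelihood-ratio chi-square tests on the same nested pairs.
    """
    data = div.copy()
    data["qW"] = pd.Series(qw).reindex(div.index)
    data["status"] = pd.Series(status).reindex(div.index)
    if data[["qW", "status"]].isna().any().any():
        raise ValueError("qW/status missing for some populations")
    n_params = 2 + len(data["status"].unique())
    if len(data) <= n_params:
        raise ValueError("fewer populations than model parameters")

    full = "{y} ~ C(status) + qW + I(qW**2)"
    no_status = "{y} ~ qW + I(qW**2)"
    no_anc = "{y} ~ C(status)"

    fits: dict[str, DiversityModelFit] = {}
    for y in ("Ho", "He", "Pi"):
        f_full = smf.ols(full.format(y=y), data).fit()
        f_ns = smf.ols(no_status.format(y=y), data).fit()
        f_na = smf.ols(no_anc.format(y=y), data).fit()
        fs, ps, _ = f_full.compare_f_test(f_ns)
        fa, pa_, _ = f_full.compare_f_test(f_na)
        r2 = float(f_full.rsquared) if np.var(data[y]) > 1e-18 else 0.0
        fits[y] = DiversityModelFit(
            response=y, family="gaussian", coefficients=f_full.params,
            status_stat=float(fs), status_p=float(ps),
            ancestry_stat=float(fa), ancestry_p=float(pa_),
            r_squared=r2, deviance=None,
            status_means=_status_means_ols(f_full, data),
        )

    g_full = smf.glm(full.format(y="Pa"), data,
                     family=sm.families.Poisson()).fit()
    g_ns = smf.glm(no_status.format(y="Pa"), data,
                   family=sm.families.Poisson()).fit()
    g_na = smf.glm(no_anc.format(y="Pa"), data,
                   family=sm.families.Poisson()).fit()
    lr_status = max(g_ns.deviance - g_full.deviance, 0.0)
    lr_anc = max(g_na.deviance - g_full.deviance, 0.0)
    df_status = len(data["status"].unique()) - 1
    fits["Pa"] = DiversityModelFit(
        response="Pa", family="poisson", coefficients=g_full.params,
        status_stat=float(lr_status),
        status_p=float(stats.chi2.sf(lr_status, df_status)),
        ancestry_stat=float(lr_anc),
        ancestry_p=float(stats.chi2.sf(lr_anc, 2)),
        r_squared=None, deviance=float(g_full.deviance),
        status_means=_status_means_poisson(g_full, data),
    )
    return fits
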