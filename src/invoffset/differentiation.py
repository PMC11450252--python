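"""Population differentiation: pairwise Fst, population-specific (beta) Fst,
neighbour-joining tree and classical multidimensional scaling.

Pairwise Fst uses the Weir & Cockerham (1984) theta estimator as a
multi-locus ratio of sums of the variance components a (among populations),
b (among individuals within populations) and c (within individuals),
restricted to loci polymorphic in the pair.

Population-specific Fst uses the Weir & Goudet (2017) allele-matching
estimator: beta_i = (M_i - M_b) / (1 - M_b), with M_i the probability that
two distinct allele copies drawn from population i match and M_b the mean
matching probability between pairs of populations, both accumulated as
ratios of sums over loci.  Large pairwise Fst reflects structure between a
pair; a large beta flags a population diverged from the common ancestral
allele pool (e.g., founder-bottlenecked introductions).

Tree and ordination overlays are delegated to scikit-bio (Saitou-Nei NJ
with negative branch lengths clamped to zero; PCoA, i.e., classical MDS,
on the raw Fst matrix — no linearization by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import pcoa
from skbio.tree import nj

from .genio import GenotypeMatrix

logger = logging.getLogger(__name__)


def _pop_arrays(g: GenotypeMatrix, groups: pd.Series) -> dict[str, np.ndarray]:
    groups = pd.Series(groups).reindex(g.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a population assignment")
    return {p: g.dosages[np.array([i for i, s in enumerate(g.sample_ids)
                                   if groups[s] == p]), :]
            for p in sorted(groups.unique())}


def wc_fst_components(pair: list[np.ndarray]) -> tuple[float, float]:
    """Weir & Cockerham (1984) variance components summed over loci.

    ``pair`` holds one dosage matrix (samples x loci, NaN missing) per
    population.  Returns (sum_a, sum_a+b+c) over loci genotyped in every
    population and polymorphic overall; theta = sum_a / sum_abc.
    """
    r = len(pair)
    n = np.stack([np.sum(~np.isnan(d), axis=0).astype(float) for d in pair])
    alt = np.stack([np.nansum(d, axis=0) for d in pair])
    het = np.stack([np.nansum(d == 1.0, axis=0).astype(float) for d in pair])

    valid = np.all(n >= 1, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        h = het / n
    nbar = n.mean(axis=0)
    pbar = np.sum(n * p, axis=0) / (r * nbar)
    poly = valid & (pbar > 0) & (pbar < 1)

    n_, p_, h_ = n[:, poly], p[:, poly], h[:, poly]
    nbar, pbar = nbar[poly], pbar[poly]
    nc = (r * nbar - np.sum(n_ ** 2, axis=0) / (r * nbar)) / (r - 1.0)
    s2 = np.sum(n_ * (p_ - pbar) ** 2, axis=0) / ((r - 1.0) * nbar)
    hbar = np.sum(n_ * h_, axis=0) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1.0) / r * s2
                                     - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.sum(a[ok])), float(np.sum((a + b + c)[ok]))


def pairwise_fst(g: GenotypeMatrix, groups: pd.Series) -> pd.DataFrame:
    """Weir & Cockerham pairwise Fst matrix over populations."""
    pops = _pop_arrays(g, groups)
    names = list(pops)
    if len(names) < 2:
        raise ValueError("need at least 2 populations")
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            num, den = wc_fst_components([pops[a], pops[b]])
            if den == 0.0:
                logger.warning("no usable loci for pair (%s, %s)", a, b)
                fst = np.nan
            else:
                fst = num / den
            out.loc[a, b] = out.loc[b, a] = fst
    return out


def population_specific_fst(g: GenotypeMatrix,
                            groups: pd.Series) -> pd.Series:
    """Weir & Goudet allele-matching beta per population.

    beta_i = (sum_l M_il - sum_l M_b,l) / (sum_l 1 - sum_l M_b,l) with
    within-population matching M_i computed on distinct allele copies and
    M_b the mean between-population matching over ordered pairs.
    """
    pops = _pop_arrays(g, groups)
    names = list(pops)
    if len(names) < 2:
        raise ValueError("beta Fst needs >= 2 populations")
    n = np.stack([2.0 * np.sum(~np.isnan(pops[p]), axis=0) for p in names])
    x = np.stack([np.nansum(pops[p], axis=0) for p in names])  # ALT copies

    valid = np.all(n >= 2, axis=0)
    n, x = n[:, valid], x[:, valid]
    y = n - x                                                 # REF copies
    with np.errstate(invalid="ignore", divide="ignore"):
        m_within = (x * (x - 1) + y * (y - 1)) / (n * (n - 1))
    r = len(names)
    m_between = np.zeros(n.shape[1])
    for i in range(r):
        for j in range(i + 1, r):
            m_between += (x[i] * x[j] + y[i] * y[j]) / (n[i] * n[j])
    m_between /= r * (r - 1) / 2.0

    denom = np.sum(1.0 - m_between)
    betas = (np.sum(m_within, axis=1) - np.sum(m_between)) / denom
    return pd.Series(betas, index=names, name="beta_fst")


@dataclass
class NJTree:
    """Unrooted NJ tree over populations (scikit-bio TreeNode inside)."""

    tree: TreeNode
    n_clamped: int            # negative branch lengths clamped to zero

    def to_newick(self) -> str:
        return str(self.tree)


def nj_tree(d: pd.DataFrame, impute_mean: bool = False) -> NJTree:
    """Saitou-Nei neighbour joining on a pairwise-Fst (or any) distance
    matrix; missing cells abort unless ``impute_mean``."""
    if d.shape[0] < 3:
        raise ValueError("NJ needs at least 3 populations")
    m = d.to_numpy(dtype=float).copy()
    if np.isnan(m).any():
        if not impute_mean:
            raise ValueError("missing distance cells; set impute_mean=True")
        fill = np.nanmean(m[~np.eye(len(m), dtype=bool)])
        m[np.isnan(m)] = fill
        logger.warning("imputed missing distance cells with mean %.4f", fill)
    np.fill_diagonal(m, 0.0)
    m = np.maximum(m, 0.0)            # tiny negative Fst -> 0 distance
    dm = DistanceMatrix((m + m.T) / 2.0, ids=list(d.index))
    raw = nj(dm, neg_as_zero=False)
    n_clamped = sum(1 for node in raw.traverse()
                    if node.length is not None and node.length < 0)
    tree = nj(dm, neg_as_zero=True)
    if n_clamped:
        logger.info("clamped %d negative NJ branch lengths", n_clamped)
    return NJTree(tree=tree, n_clamped=n_clamped)


def classical_mds(d: pd.DataFrame, n_axes: int = 2) -> pd.DataFrame:
    """Classical MDS (principal coordinates) of a symmetric distance matrix.

    Double-centred Gram-matrix eigendecomposition via scikit-bio PCoA;
    negative eigenvalues are dropped (a warning notes the truncation).
    """
    m = d.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    m = np.maximum((m + m.T) / 2.0, 0.0)
    np.fill_diagonal(m, 0.0)
    res = pcoa(DistanceMatrix(m, ids=list(d.index)), method="eigh",
               warn_neg_eigval=False)
    pos = int(np.sum(res.eigvals > 1e-12))
    if n_axes > pos:
        logger.warning("only %d positive eigenvalues; truncating axes", pos)
        n_axes = pos
    scores = res.samples.iloc[:, :n_axes]
    scores.index = list(d.index)
    scores.columns = [f"MDS{i+1}" for i in range(n_axes)]
    return scores
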