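"""Dual-pathway gene-level association with permutation significance.

Two complementary pathways test every gene against a quantitative trait:

* **Reverse (enrichment) pathway** -- split the population into
  phenotypically *deviant* and non-deviant lines (|z| above a threshold
  relative to a reference center) and ask whether gene carriers are
  enriched among the deviant lines.  Two statistics are available: the
  literal one-cell form chi2 = (Obs - Exp)^2 / Exp with Obs the number of
  deviant carriers and Exp the independence expectation, and the standard
  1-df 2x2 contingency chi-square (the default, which has a calibrated
  null).

* **Forward (burden regression) pathway** -- ordinary least squares of the
  trait on a per-line gene burden predictor (impact-weighted sum, raw
  count, or 0/1 presence), with a two-sided t-test on the slope.

Significance is controlled family-wise by permutation: the trait (or the
deviant labels) is permuted across lines, the most extreme per-gene
statistic is recorded per permutation, and the threshold is an upper order
statistic of those maxima.  Candidates are genes ranked in the top K of
*both* pathways that also clear *both* permutation thresholds; they can
then be prioritized by tissue expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .burden import GeneBurdenMatrix

logger = logging.getLogger(__name__)


@dataclass
class DeviantSplit:
    """Partition of the (non-reference) population by phenotypic deviance."""

    trait: str
    center: float
    sd: float
    z_threshold: float
    center_mode: str
    deviant: pd.Index
    non_deviant: pd.Index

    @property
    def lines(self) -> pd.Index:
        return self.deviant.append(self.non_deviant)


@dataclass
class PermutationThreshold:
    """Family-wise threshold from the permutation max-statistic null.

    ``threshold`` is the k-th largest of the per-permutation maxima with
    k = floor(alpha * (n_perm + 1)), so that under exchangeability the
    probability that the observed maximum exceeds it is ~alpha.
    """

    threshold: float
    pathway: str
    n_perm: int
    alpha: float
    maxima: np.ndarray
    seed: int
    pointwise: pd.Series | None = None


@dataclass
class AssociationResult:
    """Per-gene statistics from both pathways for one trait.

    ``table`` columns: gene_id, n_carriers, chi2, p_chi2, slope, se, t,
    p_reg, rank_chi2, rank_reg, in_top_k_chi2, in_top_k_reg, candidate.
    """

    trait: str
    table: pd.DataFrame
    chi2_threshold: PermutationThreshold | None = None
    reg_threshold: PermutationThreshold | None = None
    k_top: int = 300
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Deviant split (reverse pathway grouping)


def deviant_lines(
    phenotypes: pd.DataFrame,
    trait: str,
    center_mode: str = "population",
    z_threshold: float = 1.5,
) -> DeviantSplit:
    """Label lines whose trait deviates from the reference center.

    A line is deviant when |value - center| / sd >= z_threshold.  The
    center is the mutant-population mean (``center_mode='population'``) or
    the wild-type mean (``'wild_type'``); the scale is always the
    mutant-population standard deviation.  Wild-type reference rows are
    excluded from the split itself.
    """
    if center_mode not in ("population", "wild_type"):
        raise ValueError("center_mode must be 'population' or 'wild_type'")
    if trait not in phenotypes.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")

    is_wt = phenotypes["is_wt"] if "is_wt" in phenotypes.columns else pd.Series(
        False, index=phenotypes.index
    )
    pop = phenotypes.loc[~is_wt].set_index("line_id")[trait].astype(float)
    if center_mode == "wild_type":
        wt = phenotypes.loc[is_wt, trait].astype(float)
        if wt.empty:
            raise ValueError("center_mode='wild_type' but no wild-type rows present")
        center = float(wt.mean())
    else:
        center = float(pop.mean())
    sd = float(pop.std(ddof=1))

    if sd == 0 or np.isnan(sd):
        if z_threshold > 0:
            warnings.warn(f"trait {trait!r} is constant; deviant set is empty")
            deviant = pop.index[:0]
        else:
            deviant = pop.index
    else:
        z = (pop - center).abs() / sd
        deviant = pop.index[z >= z_threshold]
    non_deviant = pop.index.difference(deviant, sort=False)
    return DeviantSplit(trait=trait, center=center, sd=sd,
                        z_threshold=z_threshold, center_mode=center_mode,
                        deviant=pd.Index(deviant), non_deviant=pd.Index(non_deviant))


# ---------------------------------------------------------------------------
# Reverse pathway: carrier enrichment among deviant lines


def _chi2_from_counts(obs: np.ndarray, carriers: np.ndarray, n_dev: int,
                      n_lines: int, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized enrichment statistic for all genes at once.

    ``obs``: deviant carriers per gene; ``carriers``: total carriers per
    gene.  Returns (statistic, valid) where invalid genes (undefined
    statistic) carry NaN.
    """
    obs = obs.astype(float)
    carriers = carriers.astype(float)
    if mode == "literal":
        exp = n_dev * carriers / n_lines
        valid = exp > 0
        stat = np.full_like(obs, np.nan)
        stat[valid] = (obs[valid] - exp[valid]) ** 2 / exp[valid]
        return stat, valid
    if mode == "contingency":
        a = obs
        b = carriers - obs
        c = n_dev - obs
        d = n_lines - carriers - c
        n = float(n_lines)
        row1 = a + b
        row2 = c + d
        col1 = a + c
        col2 = b + d
        denom = row1 * row2 * col1 * col2
        valid = denom > 0
        stat = np.full_like(obs, np.nan)
        stat[valid] = n * (a[valid] * d[valid] - b[valid] * c[valid]) ** 2 / denom[valid]
        return stat, valid
    raise ValueError("mode must be 'literal' or 'contingency'")


def enrichment_chi2(
    burden: GeneBurdenMatrix,
    split: DeviantSplit,
    mode: str = "contingency",
) -> pd.DataFrame:
    """Per-gene enrichment of carriers among phenotypically deviant lines.

    Returns a DataFrame indexed by gene with columns obs, exp, n_carriers,
    chi2, p_chi2; genes whose statistic is undefined (zero expectation or a
    degenerate margin) carry NaN and are flagged in ``skipped``.
    """
    missing = split.lines.difference(burden.lines)
    if len(missing):
        raise ValueError(f"split lines missing from burden matrix: {list(missing)[:5]}")
    lines = split.lines
    B = burden.binary[lines].to_numpy()
    dev_mask = np.asarray(lines.isin(split.deviant))
    n_lines = len(lines)
    n_dev = int(dev_mask.sum())

    carriers = B.sum(axis=1)
    obs = B[:, dev_mask].sum(axis=1)
    stat, valid = _chi2_from_counts(obs, carriers, n_dev, n_lines, mode)
    exp = n_dev * carriers.astype(float) / n_lines

    p = np.full(len(stat), np.nan)
    p[valid] = stats.chi2.sf(stat[valid], df=1)
    out = pd.DataFrame(
        {
            "obs": obs,
            "exp": exp,
            "n_carriers": carriers,
            "chi2": stat,
            "p_chi2": p,
            "skipped": ~valid,
        },
        index=burden.genes,
    )
    n_skip = int((~valid).sum())
    if n_skip:
        logger.info("enrichment_chi2: %d genes skipped (undefined statistic)", n_skip)
    return out


# ---------------------------------------------------------------------------
# Forward pathway: burden regression


def _predictor_matrix(burden: GeneBurdenMatrix, predictor: str) -> pd.DataFrame:
    if predictor == "weighted":
        return burden.weighted
    if predictor == "count":
        return burden.counts
    if predictor == "binary":
        return burden.binary
    raise ValueError("predictor must be 'weighted', 'count' or 'binary'")


def _ols_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Simple-regression slope/se/t/p of y on each row of X, closed form."""
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=1)
    sxy = xc @ yc
    syy = float(yc @ yc)
    valid = sxx > 0
    slope = np.full(X.shape[0], np.nan)
    se = np.full(X.shape[0], np.nan)
    slope[valid] = sxy[valid] / sxx[valid]
    rss = syy - np.where(valid, slope * sxy, 0.0)
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / (n - 2)
    se[valid] = np.sqrt(sigma2[valid] / sxx[valid])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    p = np.full(X.shape[0], np.nan)
    finite = valid & np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df=n - 2)
    # perfect fits: se == 0 -> infinite t, p = 0
    exact = valid & ~np.isfinite(t) & (se == 0)
    p[exact] = 0.0
    return slope, se, t, p, valid


def burden_regression(
    burden: GeneBurdenMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    predictor: str = "weighted",
) -> pd.DataFrame:
    """OLS of the trait on each gene's per-line burden, with slope t-test.

    Wild-type rows are excluded; the line universe is the intersection of
    the burden matrix columns and the phenotyped lines.  Genes whose
    predictor has zero variance are skipped (NaN, flagged).
    """
    is_wt = phenotypes["is_wt"] if "is_wt" in phenotypes.columns else pd.Series(
        False, index=phenotypes.index
    )
    pheno = phenotypes.loc[~is_wt].set_index("line_id")[trait].astype(float).dropna()
    lines = burden.lines.intersection(pheno.index)
    if len(lines) < 3:
        raise ValueError("fewer than 3 lines with both burden and phenotype")
    X = _predictor_matrix(burden, predictor)[lines].to_numpy(dtype=float)
    y = pheno[lines].to_numpy()

    slope, se, t, p, valid = _ols_stats(X, y)
    out = pd.DataFrame(
        {
            "slope": slope,
            "se": se,
            "t": t,
            "p_reg": p,
            "n": len(lines),
            "skipped": ~valid,
        },
        index=burden.genes,
    )
    n_skip = int((~valid).sum())
    if n_skip:
        logger.info("burden_regression: %d genes with zero-variance predictor skipped",
                    n_skip)
    return out


# ---------------------------------------------------------------------------
# Permutation threshold


def permutation_threshold(
    burden: GeneBurdenMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    pathway: str = "regression",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    predictor: str = "weighted",
    mode: str = "contingency",
    center_mode: str = "population",
    z_threshold: float = 1.5,
    pointwise: bool = False,
) -> PermutationThreshold:
    """Family-wise statistic threshold from phenotype-label permutation.

    The trait values (regression pathway) or deviant labels (chi-square
    pathway) are permuted across lines ``n_perm`` times; per permutation
    the most extreme per-gene statistic (|t| or chi2) is recorded, and the
    threshold is the k-th largest of these maxima with
    k = floor(alpha * (n_perm + 1)).  With ``pointwise=True`` per-gene
    (1 - alpha) null quantiles are returned as well.
    """
    if n_perm < 1 / alpha:
        warnings.warn("n_perm < 1/alpha: the threshold quantile is poorly resolved")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))

    is_wt = phenotypes["is_wt"] if "is_wt" in phenotypes.columns else pd.Series(
        False, index=phenotypes.index
    )
    pheno = phenotypes.loc[~is_wt].set_index("line_id")[trait].astype(float).dropna()
    lines = burden.lines.intersection(pheno.index)
    y = pheno[lines].to_numpy()
    n = len(lines)

    if np.std(y) == 0:
        warnings.warn("phenotype is constant; permutation threshold is infinite")
        return PermutationThreshold(threshold=np.inf, pathway=pathway,
                                    n_perm=n_perm, alpha=alpha,
                                    maxima=np.full(n_perm, np.inf), seed=seed)

    if pathway == "regression":
        X = _predictor_matrix(burden, predictor)[lines].to_numpy(dtype=float)
        stats_mat = _perm_reg_stats(X, y, n_perm, rng)
    elif pathway == "chi2":
        split = deviant_lines(phenotypes, trait, center_mode, z_threshold)
        dev = np.asarray(lines.isin(split.deviant), dtype=np.float64)
        B = burden.binary[lines].to_numpy(dtype=np.float64)
        stats_mat = _perm_chi2_stats(B, dev, n_perm, rng, mode)
    else:
        raise ValueError("pathway must be 'regression' or 'chi2'")

    maxima = np.nanmax(stats_mat, axis=0)
    k = max(1, int(np.floor(alpha * (n_perm + 1))))
    threshold = float(np.sort(maxima)[::-1][k - 1])
    pw = None
    if pointwise:
        q = np.nanquantile(stats_mat, 1 - alpha, axis=1)
        pw = pd.Series(q, index=burden.genes)
    return PermutationThreshold(threshold=threshold, pathway=pathway,
                                n_perm=n_perm, alpha=alpha, maxima=maxima,
                                seed=seed, pointwise=pw)


def _perm_reg_stats(X: np.ndarray, y: np.ndarray, n_perm: int,
                    rng: np.random.Generator) -> np.ndarray:
    """|t| of the per-gene slope for every permutation (genes x perms)."""
    n = len(y)
    yc = y - y.mean()
    Yp = np.empty((n, n_perm))
    for j in range(n_perm):
        Yp[:, j] = yc[rng.permutation(n)]
    xc = X - X.mean(axis=1, keepdims=True)
    sxx = (xc ** 2).sum(axis=1)
    syy = float(yc @ yc)
    valid = (sxx > 0) & (syy > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ Yp) / np.sqrt(np.outer(sxx, np.full(n_perm, syy)))
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    t = np.abs(t)
    t[~valid, :] = np.nan
    return t


def _perm_chi2_stats(B: np.ndarray, dev: np.ndarray, n_perm: int,
                     rng: np.random.Generator, mode: str) -> np.ndarray:
    """Chi-square statistic for every permuted deviant labeling."""
    n = len(dev)
    n_dev = int(dev.sum())
    D = np.empty((n, n_perm))
    for j in range(n_perm):
        D[:, j] = dev[rng.permutation(n)]
    carriers = B.sum(axis=1)
    obs = B @ D  # genes x perms
    out = np.empty_like(obs)
    for j in range(n_perm):
        stat, _ = _chi2_from_counts(obs[:, j], carriers, n_dev, n, mode)
        out[:, j] = stat
    return out


# ---------------------------------------------------------------------------
# Candidate selection


def associate(
    burden: GeneBurdenMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    k_top: int = 300,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    predictor: str = "weighted",
    mode: str = "contingency",
    center_mode: str = "population",
    z_threshold: float = 1.5,
) -> AssociationResult:
    """Run both pathways, permutation thresholds, and candidate calling."""
    split = deviant_lines(phenotypes, trait, center_mode, z_threshold)
    chi2_tab = enrichment_chi2(burden, split, mode=mode)
    reg_tab = burden_regression(burden, phenotypes, trait, predictor=predictor)

    chi2_thr = permutation_threshold(
        burden, phenotypes, trait, pathway="chi2", n_perm=n_perm, alpha=alpha,
        seed=seed, mode=mode, center_mode=center_mode, z_threshold=z_threshold,
    )
    reg_thr = permutation_threshold(
        burden, phenotypes, trait, pathway="regression", n_perm=n_perm,
        alpha=alpha, seed=seed, predictor=predictor,
    )

    table = pd.concat(
        [chi2_tab[["obs", "exp", "n_carriers", "chi2", "p_chi2"]],
         reg_tab[["slope", "se", "t", "p_reg", "n"]]],
        axis=1,
    )
    result = AssociationResult(
        trait=trait, table=table, chi2_threshold=chi2_thr, reg_threshold=reg_thr,
        k_top=k_top,
        params=dict(predictor=predictor, mode=mode, center_mode=center_mode,
                    z_threshold=z_threshold, n_perm=n_perm, alpha=alpha,
                    seed=seed),
    )
    intersect_candidates(result, k=k_top)
    return result


def intersect_candidates(result: AssociationResult, k: int = 300) -> list[str]:
    """Top-K intersection of the two pathways, filtered by both thresholds.

    Genes are ranked per pathway by p ascending (ties broken by gene id);
    candidates are genes in both top-K lists whose statistics exceed both
    permutation thresholds.  Updates ``result.table`` in place with rank,
    top-K, and candidate columns, and returns the sorted candidate list.
    """
    table = result.table
    n_tested = int(table["p_chi2"].notna().sum())
    if k > n_tested:
        warnings.warn(f"k={k} exceeds {n_tested} tested genes; clipping")
        k = n_tested

    # deterministic ranking: p ascending, gene id lexicographic on ties
    for p_col, rank_col in (("p_chi2", "rank_chi2"), ("p_reg", "rank_reg")):
        sub = table[[p_col]].dropna().reset_index()
        gene_col = sub.columns[0]
        sub = sub.sort_values([p_col, gene_col], kind="mergesort")
        ranks = pd.Series(np.arange(1, len(sub) + 1), index=sub[gene_col])
        table[rank_col] = ranks.reindex(table.index)

    top_chi2 = set(table.index[table["rank_chi2"] <= k])
    top_reg = set(table.index[table["rank_reg"] <= k])
    table["in_top_k_chi2"] = table.index.isin(top_chi2)
    table["in_top_k_reg"] = table.index.isin(top_reg)

    beyond = pd.Series(True, index=table.index)
    if result.chi2_threshold is not None:
        beyond &= table["chi2"] > result.chi2_threshold.threshold
    if result.reg_threshold is not None:
        beyond &= table["t"].abs() > result.reg_threshold.threshold
    table["candidate"] = (
        table["in_top_k_chi2"] & table["in_top_k_reg"] & beyond.fillna(False)
    )
    result.k_top = k
    return sorted(table.index[table["candidate"]])


def prioritize_by_expression(
    candidates: list[str],
    expression: pd.DataFrame,
    tissues: list[str],
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Rank candidates by their peak FPKM over tissues of interest.

    ``expression`` is a genes x tissues FPKM matrix.  Candidates absent
    from the matrix are retained but flagged (``missing_expression``) and
    sorted last; present candidates below ``min_fpkm`` in every named
    tissue are dropped.
    """
    unknown = set(tissues) - set(expression.columns)
    if unknown:
        raise KeyError(f"unknown tissues: {sorted(unknown)}")
    rows = []
    for gene in candidates:
        if gene in expression.index:
            peak = float(expression.loc[gene, tissues].max())
            if peak >= min_fpkm:
                rows.append((gene, peak, False))
        else:
            rows.append((gene, np.nan, True))
    out = pd.DataFrame(rows, columns=["gene_id", "max_fpkm", "missing_expression"])
    out = out.sort_values(["missing_expression", "max_fpkm", "gene_id"],
                          ascending=[True, False, True], kind="mergesort")
    return out.reset_index(drop=True)
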