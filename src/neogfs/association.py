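"""Per-family Pearson association with a phenotype and the global
distribution-shift tests.

Three layers:

* per-family Pearson r against a species-aligned phenotype vector, with a
  two-sided p from the t transform and Benjamini–Hochberg FDR across families;
* a Monte-Carlo permutation null for the MEAN of the per-family correlations
  (the "joint" scheme permutes species jointly across all families, which
  preserves the inter-family covariance that the mean inherits and is
  equivalent to permuting the phenotype);
* summary tests of the distribution shift: a Z-score of the observed mean r
  against the permutation null (one-tailed upper) and a sign chi-square of
  positive versus negative correlations against equal expectation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import GeneFamilyMatrix


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: a vector with zero variance (or too few points)."""


@dataclass(frozen=True)
class AssociationResult:
    """One family's correlation with the phenotype.

    ``r`` is the Pearson correlation, ``p`` its two-sided p-value with
    ``n - 2`` degrees of freedom, ``q`` the BH-adjusted p across all families
    tested together and ``n`` the number of species used. Degenerate families
    (undefined correlation) carry NaN in ``r``/``p``/``q``.
    """

    family_id: str
    r: float
    p: float
    q: float
    n: int

    @property
    def is_defined(self) -> bool:
        return math.isfinite(self.r)


@dataclass(frozen=True)
class NullDistribution:
    """Permutation null of the mean per-family correlation."""

    replicate_means: np.ndarray
    n_replicates: int
    seed: int | None
    scheme: str


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value
    (t transform, ``df = n - 2``). Requires n >= 3 and variance in both."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise UndefinedCorrelationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Rows scaled to mean 0, sd 1 (ddof=1); zero-variance rows become NaN."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, (X - mu) / sd, np.nan)


def matrix_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``X`` with ``y`` (NaN for zero-variance rows)."""
    n = X.shape[1]
    Z = _standardize_rows(X)
    w = _standardize_rows(y[None, :])[0]
    return Z @ w / (n - 1)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t transform ``t = r sqrt((n-2)/(1-r^2))``."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def family_associations(matrix: GeneFamilyMatrix, phenotype: Sequence[float],
                        absent_policy: Literal["zero", "drop"] = "zero",
                        ) -> list[AssociationResult]:
    """Correlate every family's sizes with the phenotype.

    ``absent_policy="zero"`` keeps every species, counting absence as size 0;
    ``"drop"`` restricts each family to the species where it has members (n
    then varies per family and families left degenerate are reported NaN and
    excluded from the joint BH correction).
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (matrix.n_species,):
        raise ValueError(
            f"phenotype length {y.shape} does not match {matrix.n_species} species"
        )
    if np.ptp(y) == 0:
        raise UndefinedCorrelationError("phenotype has zero variance")

    sizes = matrix.sizes.astype(float)
    rs = np.full(matrix.n_families, np.nan)
    ps = np.full(matrix.n_families, np.nan)
    ns = np.zeros(matrix.n_families, dtype=int)
    if absent_policy == "zero":
        rs = matrix_pearson(sizes, y)
        ps = _p_from_r(rs, matrix.n_species)
        ps = np.where(np.isnan(rs), np.nan, ps)
        ns[:] = matrix.n_species
    elif absent_policy == "drop":
        for i in range(matrix.n_families):
            mask = sizes[i] > 0
            ns[i] = int(mask.sum())
            if ns[i] < 3 or np.ptp(sizes[i, mask]) == 0 or np.ptp(y[mask]) == 0:
                continue
            rs[i], ps[i] = pearson_r(sizes[i, mask], y[mask])
        if np.isnan(rs).any():
            warnings.warn(
                f"{int(np.isnan(rs).sum())} families have undefined correlation "
                "under the drop policy; reported as NaN", stacklevel=2)
    else:
        raise ValueError("absent_policy must be 'zero' or 'drop'")

    qs = np.full(matrix.n_families, np.nan)
    valid = ~np.isnan(ps)
    if valid.any():
        qs[valid] = bh_fdr(ps[valid])
    return [
        AssociationResult(f, float(r), float(p), float(q), int(n))
        for f, r, p, q, n in zip(matrix.family_ids, rs, ps, qs, ns)
    ]


def permutation_null(matrix: GeneFamilyMatrix, phenotype: Sequence[float],
                     n_replicates: int = 10_000,
                     scheme: Literal["joint", "per_family"] = "joint",
                     seed: int | None = None,
                     exhaustive: bool = False) -> NullDistribution:
    """Monte-Carlo permutation null of the mean per-family Pearson r.

    Each replicate permutes the species assignment of the sizes and records
    the mean of the per-family correlations. ``joint`` applies one species
    permutation to every family (equivalently permutes the phenotype);
    ``per_family`` shuffles every family independently. ``exhaustive=True``
    (joint only, small species counts) enumerates all n! permutations instead
    of sampling. The seed expands into one RNG substream per replicate.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (matrix.n_species,):
        raise ValueError("phenotype length does not match matrix species")
    if np.ptp(y) == 0:
        raise UndefinedCorrelationError("phenotype has zero variance")
    n = matrix.n_species
    Z = _standardize_rows(matrix.sizes.astype(float))
    if np.isnan(Z).any():
        raise UndefinedCorrelationError(
            "matrix contains zero-variance families; filter first")
    w = _standardize_rows(y[None, :])[0]
    zbar = Z.mean(axis=0)  # mean r is linear in the permuted phenotype (joint)

    if exhaustive:
        if scheme != "joint":
            raise ValueError("exhaustive enumeration only supports the joint scheme")
        if n > 8:
            raise ValueError("exhaustive enumeration limited to <= 8 species")
        perms = np.array(list(itertools.permutations(range(n))))
        means = (zbar @ w[perms].T) / (n - 1)
        return NullDistribution(np.asarray(means), len(perms), seed, "joint")

    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    if n_replicates < 100:
        warnings.warn("fewer than 100 permutation replicates gives an unstable null",
                      stacklevel=2)
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    if scheme == "joint":
        perm = np.empty((n_replicates, n), dtype=np.intp)
        for i, child in enumerate(children):
            perm[i] = np.random.default_rng(child).permutation(n)
        means = (zbar @ w[perm].T) / (n - 1)
    elif scheme == "per_family":
        means = np.empty(n_replicates)
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            means[i] = np.mean(rng.permuted(Z, axis=1) @ w) / (n - 1)
    else:
        raise ValueError("scheme must be 'joint' or 'per_family'")
    return NullDistribution(np.asarray(means), n_replicates, seed, scheme)


def normal_upper_tail_p(z: float) -> float:
    """Upper-tail standard-normal probability (the one-tailed Z -> p convention)."""
    return float(stats.norm.sf(z))


def zscore_shift_test(observed_mean_r: float,
                      null: NullDistribution) -> tuple[float, float, float]:
    """Z-score test of the observed mean correlation against its permutation null.

    Returns ``(z, p_one_tailed, p_empirical)``: the standardized shift, its
    upper-tail normal probability, and the add-one-corrected empirical rank
    probability ``(1 + #{null >= observed}) / (1 + n_replicates)``.
    """
    means = np.asarray(null.replicate_means, dtype=float)
    sd = means.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate permutation null (zero standard deviation)")
    z = (observed_mean_r - means.mean()) / sd
    p_emp = (1 + int((means >= observed_mean_r).sum())) / (1 + len(means))
    return float(z), normal_upper_tail_p(z), float(p_emp)


def sign_chisq_counts(n_pos: int, n_neg: int) -> tuple[float, float, int, int]:
    """Pearson chi-square of (n_pos, n_neg) against equal expected counts, df=1."""
    total = n_pos + n_neg
    if total == 0:
        raise ValueError("no non-zero correlations to test")
    chi2 = (n_pos - n_neg) ** 2 / total
    return float(chi2), float(stats.chi2.sf(chi2, df=1)), n_pos, n_neg


def sign_chisq(results: Sequence[AssociationResult]) -> tuple[float, float, int, int]:
    """Sign test of the correlation distribution: chi-square of the counts of
    positive versus negative per-family r against a 50/50 split. Families with
    exactly zero or undefined r are excluded from both counts."""
    rs = np.array([res.r for res in results if res.is_defined])
    n_pos = int((rs > 0).sum())
    n_neg = int((rs < 0).sum())
    return sign_chisq_counts(n_pos, n_neg)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
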