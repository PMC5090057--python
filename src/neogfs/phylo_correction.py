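"""Confound- and phylogeny-corrected association.

The correction runs in a fixed order: (1) residualize the target phenotype and
every family's sizes against the confounding covariates by ordinary least
squares across species; (2) transform both residual vectors into Felsenstein
phylogenetically independent contrasts (PIC) on the time-calibrated tree;
(3) correlate the two contrast sets with a Pearson correlation forced through
the origin (contrasts have expectation zero by construction, so no intercept
is estimated and the correlation df is ``n_contrasts - 1``).

Felsenstein's pruning at an internal node joining children with values
``x1, x2`` and (adjusted) branch lengths ``v1, v2``::

    contrast          = (x1 - x2) / sqrt(v1 + v2)
    ancestral value   = (x1/v1 + x2/v2) / (1/v1 + 1/v2)
    parent branch    += v1 * v2 / (v1 + v2)

Because every contrast is linear in the tip values, the whole transform is a
fixed ``(n_tips - 1) x n_tips`` matrix for a given tree, which lets thousands
of families be transformed with one matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .association import AssociationResult, UndefinedCorrelationError, bh_fdr
from .data_io import GeneFamilyMatrix, PhenotypeTable, Phylogeny


@dataclass(frozen=True)
class ContrastSet:
    """Standardized independent contrasts, one per internal node."""

    contrasts: np.ndarray
    node_ids: tuple[str, ...]

    @property
    def df(self) -> int:
        return len(self.contrasts)


def ols_residuals(response: Sequence[float], covariates: np.ndarray,
                  add_intercept: bool = True) -> np.ndarray:
    """Residuals of an ordinary least-squares fit of ``response`` on the
    covariate columns (intercept added by default).

    The residuals are orthogonal to every design column; a rank-deficient
    design raises with the indices of the collinear columns.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    if len(y) <= X.shape[1]:
        raise ValueError(f"need more observations ({len(y)}) than parameters ({X.shape[1]})")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate dependent columns via the pivoted QR diagonal
        _, R, piv = _qr_pivot(X)
        bad = sorted(piv[rank:].tolist())
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _qr_pivot(X: np.ndarray):
    import scipy.linalg

    Q, R, piv = scipy.linalg.qr(X, pivoting=True)
    return Q, R, np.asarray(piv)


def _prepared_tree(tree: Phylogeny) -> Phylogeny:
    """Bifurcating copy with strictly positive branch lengths.

    Multifurcations are resolved arbitrarily with zero-length branches, then
    every zero length is replaced by ``1e-10 x tree height`` so the pruning
    denominators stay positive.
    """
    clone = tree.clone()
    clone.tree.resolve_polytomies()
    eps = 1e-10 * max(tree.height, 1e-12)
    for edge in clone.tree.preorder_edge_iter():
        if edge.head_node is clone.tree.seed_node:
            continue
        if edge.length is None or edge.length == 0:
            edge.length = eps
        elif edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return clone


def _prune(tree: Phylogeny, tip_values: dict[str, np.ndarray]):
    """Run Felsenstein pruning bottom-up.

    ``tip_values`` maps tip label -> value vector (scalars as length-1 arrays);
    returns (contrast rows, node ids, denominators sqrt(v1+v2)). Works on any
    vector payload, which is how the linear contrast operator is extracted.
    """
    work = _prepared_tree(tree)
    contrasts: list[np.ndarray] = []
    node_ids: list[str] = []
    counter = 0
    for node in work.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label.replace(" ", "_")
            if label not in tip_values:
                raise ValueError(f"tip {label!r} has no trait value")
            node.value = np.asarray(tip_values[label], dtype=float)
            node.v = float(node.edge.length)
            continue
        children = node.child_nodes()
        assert len(children) == 2  # guaranteed by _prepared_tree
        c1, c2 = children
        v1, v2 = c1.v, c2.v
        counter += 1
        node_ids.append(f"node{counter}")
        contrasts.append((c1.value - c2.value) / np.sqrt(v1 + v2))
        node.value = (c1.value / v1 + c2.value / v2) / (1.0 / v1 + 1.0 / v2)
        extra = v1 * v2 / (v1 + v2)
        node.v = (float(node.edge.length) if node.parent_node is not None else 0.0) + extra
    return np.array(contrasts), tuple(node_ids)


def independent_contrasts(tree: Phylogeny, trait, species: Sequence[str] | None = None,
                          ) -> ContrastSet:
    """Felsenstein phylogenetically independent contrasts of a tip trait.

    ``trait`` is either a mapping tip label -> value or a vector aligned with
    ``species``. Returns one standardized contrast per internal node
    (``n_tips - 1`` for a bifurcating tree).
    """
    if isinstance(trait, dict):
        tip_values = {k: np.atleast_1d(v) for k, v in trait.items()}
    else:
        if species is None:
            raise ValueError("species order required when trait is a vector")
        vec = np.asarray(trait, dtype=float)
        tip_values = {s: np.atleast_1d(v) for s, v in zip(species, vec)}
    contrasts, node_ids = _prune(tree, tip_values)
    return ContrastSet(contrasts[:, 0], node_ids)


def contrasts_matrix(tree: Phylogeny, species: Sequence[str]
                     ) -> tuple[np.ndarray, tuple[str, ...]]:
    """The linear operator L with ``contrasts = L @ tip_values`` for tips in
    ``species`` order."""
    n = len(species)
    eye = np.eye(n)
    tip_values = {s: eye[i] for i, s in enumerate(species)}
    L, node_ids = _prune(tree, tip_values)
    return L, node_ids


def corr_through_origin(u, v) -> tuple[float, float]:
    """Pearson correlation forced through the origin (uncentred cosine),
    with a two-sided p from the t transform at ``df = n - 1``."""
    a = u.contrasts if isinstance(u, ContrastSet) else np.asarray(u, dtype=float)
    b = v.contrasts if isinstance(v, ContrastSet) else np.asarray(v, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("contrast sets must align and contain >= 2 contrasts")
    na, nb = np.sqrt(np.sum(a * a)), np.sqrt(np.sum(b * b))
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError("all-zero contrast vector")
    r = float(np.clip(np.sum(a * b) / (na * nb), -1.0, 1.0))
    df = len(a) - 1
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def corrected_association(matrix: GeneFamilyMatrix, table: PhenotypeTable,
                          tree: Phylogeny, target: str = "nr",
                          covariates: Sequence[str] = ("ei", "mlsp"),
                          ) -> list[AssociationResult]:
    """Per-family association between the target phenotype and family size
    after removing the covariates and the phylogenetic signal.

    Both the target and every family's sizes are residualized against the same
    covariates across species, both residual vectors are transformed into
    independent contrasts on the tree, and each family's contrasts are
    correlated with the target's through the origin. BH-FDR is applied across
    all families with a defined correlation.
    """
    if target in covariates:
        raise ValueError(f"target {target!r} cannot appear among its covariates")
    species = matrix.species_ids
    if set(species) != set(table.species):
        raise ValueError("matrix and phenotype table species differ")
    tips = set(tree.tip_labels)
    if set(species) != tips:
        raise ValueError("matrix species and tree tips differ")
    aligned = table.reordered(species)

    C = np.column_stack([aligned.trait(c) for c in covariates])
    resid_target = ols_residuals(aligned.trait(target), C)

    X = np.column_stack([np.ones(len(species)), C])
    beta, *_ = np.linalg.lstsq(X, matrix.sizes.T.astype(float), rcond=None)
    resid_fams = matrix.sizes.astype(float) - (X @ beta).T

    L, _ = contrasts_matrix(tree, species)
    pic_target = L @ resid_target
    pic_fams = resid_fams @ L.T

    df = L.shape[0] - 1
    norms_t = np.sqrt(np.sum(pic_target ** 2))
    norms_f = np.sqrt(np.sum(pic_fams ** 2, axis=1))
    if norms_t == 0:
        raise UndefinedCorrelationError("target contrasts are all zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.clip(pic_fams @ pic_target / (norms_f * norms_t), -1.0, 1.0)
    rs = np.where(norms_f > 0, rs, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ts = rs * np.sqrt(df / (1.0 - rs * rs))
    ps = np.where(np.abs(rs) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(ts), df))
    ps = np.where(np.isnan(rs), np.nan, ps)

    qs = np.full(len(rs), np.nan)
    valid = ~np.isnan(ps)
    if valid.any():
        qs[valid] = bh_fdr(ps[valid])
    n_contrasts = L.shape[0]
    return [
        AssociationResult(f, float(r), float(p), float(q), n_contrasts)
        for f, r, p, q in zip(matrix.family_ids, rs, ps, qs)
    ]
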