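"""Synthetic phylogenies, phenotypes, family-size matrices, annotations and
expression with known ground truth.

The generators emulate the shape of the real inputs — a 28-tip time tree,
correlated Brownian phenotypes, a families x species count matrix in which a
known fraction of families grows with the neocortex ratio, GO-style terms that
oversample those planted families, and a BrainSpan-like cortical expression
matrix with an early-development elevation for genes of planted families — so
every pipeline stage can be tested against a planted truth. Every generator is
a pure function of its seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .data_io import (AnnotationMap, ExpressionDataset, GeneFamilyMatrix,
                      PhenotypeRecord, PhenotypeTable, Phylogeny, pcw_to_years)

# default trait covariance for (log Nr, Ei, log MLSP): moderate positive
# Nr-Ei coupling reproduces the real identifiability problem (a family driven
# by Nr also correlates with Ei until the shared variance is removed)
DEFAULT_TRAIT_COV = np.array([
    [0.25, 0.15, 0.10],
    [0.15, 0.25, 0.10],
    [0.10, 0.10, 0.25],
])
DEFAULT_TRAIT_ROOT = (0.0, -2.0, 3.0)

# BrainSpan-like sampling design: 13 ages (3 prenatal, in post-conception
# weeks) x 11 cortical regions = 143 samples
BRAINSPAN_AGES_YEARS = tuple(
    [pcw_to_years(w) for w in (16, 24, 37)]
    + [4 / 12, 1.0, 3.0, 8.0, 13.0, 19.0, 21.0, 30.0, 36.0, 37.0]
)
BRAINSPAN_REGIONS = ("A1C", "DFC", "IPC", "ITC", "M1C", "MFC",
                     "OFC", "S1C", "STC", "V1C", "VFC")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    planted_family_ids: set[str] = field(default_factory=set)
    beta: float = 0.0
    planted_terms: set[str] = field(default_factory=set)
    expression_effect: float = 1.0
    seeds: dict[str, int | None] = field(default_factory=dict)
    family_ids: list[str] = field(default_factory=list)
    gene_families: dict[str, str] = field(default_factory=dict)

    def genes_of_planted_families(self) -> set[str]:
        return {g for g, f in self.gene_families.items()
                if f in self.planted_family_ids}


def simulate_tree(n_tips: int, seed: int | None = None) -> Phylogeny:
    """Yule (pure-birth) tree with ``n_tips`` extant tips, rescaled to unit
    height (hence ultrametric); tips labelled sp1..spN."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"sp{i + 1}" for i in range(n_tips)])
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=rng)
    # the simulator stops at the n-th speciation, leaving a zero-length cherry;
    # extend every tip by the Exp(n * birth_rate) waiting time to the next
    # (uncounted) event so the tree stays ultrametric with positive branches
    extra = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    phylo = Phylogeny(tree)
    height = phylo.height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return Phylogeny(tree)


def _brownian_on_tree(tree: Phylogeny, chol: np.ndarray, root: np.ndarray,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Multivariate Brownian motion along the tree; returns tip label -> value."""
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.asarray(root, dtype=float)
        else:
            bl = float(node.edge.length or 0.0)
            step = chol @ rng.standard_normal(chol.shape[0]) * np.sqrt(bl)
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label.replace(" ", "_")] = values[id(node)]
    return out


def simulate_traits(tree: Phylogeny, covariance: np.ndarray | None = None,
                    seed: int | None = None,
                    root: Sequence[float] = DEFAULT_TRAIT_ROOT) -> PhenotypeTable:
    """Correlated Brownian phenotypes on the tree.

    The three Brownian coordinates are (log Nr, Ei, log MLSP); Nr and MLSP are
    exponentiated onto their natural positive scales, and brain/neocortex
    volumes are back-computed so that ``compute_nr(volumes)`` returns the
    simulated Nr exactly.
    """
    cov = DEFAULT_TRAIT_COV if covariance is None else np.asarray(covariance, float)
    if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be a symmetric 3x3 matrix")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive-definite") from exc
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tips = _brownian_on_tree(tree, chol, np.asarray(root, float), rng)
    records = []
    for label in tree.tip_labels:
        log_nr, ei, log_mlsp = tips[label]
        nr = float(np.exp(log_nr))
        brain = 50.0 * float(np.exp(ei + 3.0))  # any positive scale works
        neo = brain * nr / (1.0 + nr)
        records.append(PhenotypeRecord(
            species_id=label, brain_volume=brain, neocortex_volume=neo,
            nr=nr, ei=float(ei), mlsp=float(np.exp(log_mlsp))))
    return PhenotypeTable(records)


def simulate_gfs(table: PhenotypeTable, tree: Phylogeny, n_families: int = 1000,
                 frac_planted: float = 0.1, beta: float = 1.5,
                 baseline_log_mean: float = 1.0, phylo_noise_sd: float = 0.3,
                 overdispersion: float = 0.0, seed: int | None = None,
                 ) -> tuple[GeneFamilyMatrix, SyntheticTruth]:
    """Count-valued family sizes with a planted Nr effect.

    Family j in species i has size ``Poisson(exp(a_j + beta_j z(Nr_i) + e_ij))``
    where ``z`` standardizes Nr across species, ``beta_j = beta`` for a
    uniformly chosen ``frac_planted`` of families (0 otherwise), ``a_j`` is a
    family-specific baseline and ``e_ij`` is Brownian noise on the tree so
    unplanted families are still phylogenetically autocorrelated.
    ``overdispersion > 0`` gamma-mixes the Poisson rate (negative binomial).
    """
    if n_families < 10:
        raise ValueError("need at least 10 families")
    if not 0 <= frac_planted <= 1:
        raise ValueError("frac_planted must lie in [0, 1]")
    species = table.species
    if set(species) != set(tree.tip_labels):
        raise ValueError("table species and tree tips differ")
    nr = table.trait("nr")
    z = (nr - nr.mean()) / nr.std(ddof=1)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    n_planted = int(round(frac_planted * n_families))
    planted_idx = rng.choice(n_families, size=n_planted, replace=False)
    betas = np.zeros(n_families)
    betas[planted_idx] = beta
    a = rng.normal(baseline_log_mean, 0.5, size=n_families)

    # Brownian species noise: covariance = shared path length (ultrametric tree)
    C = _shared_path_matrix(tree, species) * phylo_noise_sd ** 2
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(len(species)))
    eps = rng.standard_normal((n_families, len(species))) @ chol.T

    log_mu = a[:, None] + betas[:, None] * z[None, :] + eps
    mu = np.exp(log_mu)
    if overdispersion > 0:
        mu = mu * rng.gamma(1.0 / overdispersion, overdispersion, size=mu.shape)
    sizes = rng.poisson(mu)
    family_ids = [f"FAM{j:05d}" for j in range(n_families)]
    truth = SyntheticTruth(
        planted_family_ids={family_ids[j] for j in planted_idx},
        beta=beta,
        seeds={"gfs": seed},
        family_ids=list(family_ids),
    )
    return GeneFamilyMatrix(family_ids, list(species), sizes), truth


def _shared_path_matrix(tree: Phylogeny, species: Sequence[str]) -> np.ndarray:
    """Shared root-to-MRCA path length for every species pair."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label.replace(" ", "_"): t for t in tree.tree.taxon_namespace}
    depths = tree.tip_depths()
    n = len(species)
    C = np.zeros((n, n))
    for i, si in enumerate(species):
        for j, sj in enumerate(species):
            if i == j:
                C[i, j] = depths[si]
            elif j > i:
                d = pdm.patristic_distance(taxa[si], taxa[sj])
                C[i, j] = C[j, i] = 0.5 * (depths[si] + depths[sj] - d)
    return C


def simulate_annotations(matrix: GeneFamilyMatrix, truth: SyntheticTruth,
                         n_terms: int = 10, term_size_range: tuple[int, int] = (220, 380),
                         n_planted_terms: int = 3, planted_bias: float = 10.0,
                         frac_unannotated: float = 0.2, seed: int | None = None,
                         ) -> tuple[AnnotationMap, SyntheticTruth]:
    """GO-style term map with planted over-representation.

    ``n_terms`` terms draw members without replacement from the annotatable
    pool; the first ``n_planted_terms`` weight planted families by
    ``planted_bias`` so they concentrate the planted signal. A
    ``frac_unannotated`` fraction of families is excluded from every term and
    ends up in the not-annotated bucket.
    """
    if n_planted_terms > n_terms:
        raise ValueError("n_planted_terms cannot exceed n_terms")
    if planted_bias <= 0:
        raise ValueError("planted_bias must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    families = np.array(matrix.family_ids)
    n_unannot = int(round(frac_unannotated * len(families)))
    unannotated = set(rng.choice(families, size=n_unannot, replace=False))
    pool = np.array([f for f in families if f not in unannotated])
    lo, hi = term_size_range
    if hi > len(pool):
        raise ValueError(f"term sizes up to {hi} infeasible with pool of {len(pool)}")
    planted = np.isin(pool, list(truth.planted_family_ids))
    pairs: list[tuple[str, str]] = []
    planted_terms: set[str] = set()
    for t in range(n_terms):
        term = f"GO:{t + 1:07d}"
        size = int(rng.integers(lo, hi + 1))
        if t < n_planted_terms:
            w = np.where(planted, planted_bias, 1.0)
            members = rng.choice(pool, size=size, replace=False, p=w / w.sum())
            planted_terms.add(term)
        else:
            members = rng.choice(pool, size=size, replace=False)
        pairs.extend((str(f), term) for f in members)
    truth.planted_terms = planted_terms
    truth.seeds["annotations"] = seed
    return AnnotationMap(pairs), truth


def simulate_expression(truth: SyntheticTruth, n_genes_per_family: int = 2,
                        ages: Sequence[float] | None = None,
                        regions: Sequence[str] | None = None,
                        early_multiplier: float = 1.5,
                        seed: int | None = None) -> ExpressionDataset:
    """BrainSpan-like expression: one sample per (age, region) pair, log-normal
    per-gene baselines, and genes of planted families elevated by
    ``early_multiplier`` in samples at or before 13 years."""
    ages = list(BRAINSPAN_AGES_YEARS if ages is None else ages)
    regions = list(BRAINSPAN_REGIONS if regions is None else regions)
    if len(set(ages)) < 2 or not (min(ages) <= 13.0 < max(ages)):
        raise ValueError("ages must span both sides of the 13-year maturation point")
    if early_multiplier < 1:
        raise ValueError("early_multiplier must be >= 1")
    if not truth.family_ids:
        raise ValueError("truth carries no family ids (run simulate_gfs first)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes, gene_families = [], {}
    for fam in truth.family_ids:
        for k in range(n_genes_per_family):
            g = f"{fam}_g{k + 1}"
            genes.append(g)
            gene_families[g] = fam
    sample_ids, meta_rows = [], []
    for age in ages:
        for region in regions:
            sample_ids.append(f"s_{age:+07.3f}_{region}")
            meta_rows.append((age, region))
    baseline = rng.lognormal(mean=2.0, sigma=1.0, size=len(genes))
    noise = rng.lognormal(mean=0.0, sigma=0.3, size=(len(genes), len(sample_ids)))
    values = baseline[:, None] * noise
    planted_gene = np.array([gene_families[g] in truth.planted_family_ids
                             for g in genes])
    early = np.array([age <= 13.0 for age, _ in meta_rows])
    values[np.ix_(planted_gene, early)] *= early_multiplier
    frame = pd.DataFrame(values, index=genes, columns=sample_ids)
    meta = pd.DataFrame(meta_rows, columns=["age_years", "region"],
                        index=pd.Index(sample_ids, name="sample_id"))
    truth.expression_effect = early_multiplier
    truth.gene_families = gene_families
    truth.seeds["expression"] = seed
    return ExpressionDataset(frame, meta)


def simulate_bundle(seed: int | None = None, n_tips: int = 28,
                    n_families: int = 1000, frac_planted: float = 0.1,
                    beta: float = 1.5, early_multiplier: float = 1.5,
                    **gfs_kwargs) -> dict:
    """The default ("paperlike") synthetic study: tree, phenotypes, family
    sizes, annotations and expression generated from one master seed."""
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)]
    tree = simulate_tree(n_tips, seed=sub[0])
    table = simulate_traits(tree, seed=sub[1])
    matrix, truth = simulate_gfs(table, tree, n_families=n_families,
                                 frac_planted=frac_planted, beta=beta,
                                 seed=sub[2], **gfs_kwargs)
    # term sizes scale with the family count (22-38% of families each) so the
    # bundle stays feasible away from the default size
    size_range = (max(5, int(0.22 * n_families)), max(8, int(0.38 * n_families)))
    annotations, truth = simulate_annotations(matrix, truth,
                                              term_size_range=size_range,
                                              seed=sub[3])
    expression = simulate_expression(truth, early_multiplier=early_multiplier,
                                     seed=sub[4])
    truth.seeds["master"] = seed
    return {"tree": tree, "table": table, "matrix": matrix, "truth": truth,
            "annotations": annotations, "expression": expression}
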