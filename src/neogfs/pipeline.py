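"""End-to-end orchestration: filter -> associate -> correct -> enrich -> expression.

``run_pipeline`` consumes validated input files, runs every stage in the
analysis order, writes per-stage TSV/JSON outputs plus a deterministic
``summary.json`` and a replay log of the per-stage RNG seeds. All
multiple-testing gates use BH-FDR at ``fdr_alpha``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .association import (family_associations, permutation_null, sign_chisq,
                          zscore_shift_test)
from .data_io import (read_annotations, read_expression, read_gfs,
                      read_phenotypes, read_tree)
from .enrichment import build_term_map, enrichment_test
from .expression import normalize_samples, paired_wilcoxon, window_means
from .gfs import filter_families
from .phylo_correction import corrected_association


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Inputs, constants and thresholds of one pipeline run.

    The defaults are the analysis constants used throughout: families present
    in >= 6 species, 10 000 permutation replicates, terms with >= 200 families,
    1000 enrichment resamples, the 13-year maturation split and FDR < 0.05.
    """

    out_dir: str
    phenotypes: str
    gfs: str
    tree: str | None = None
    annotations: str | None = None
    expression: str | None = None
    expression_meta: str | None = None
    gene_map: str | None = None
    target: str = "nr"
    covariates: tuple[str, ...] = ("ei", "mlsp")
    n_perm: int = 10_000
    n_samples: int = 1000
    min_species: int = 6
    min_families: int = 200
    cutoff_years: float = 13.0
    fdr_alpha: float = 0.05
    absent_policy: str = "zero"
    scheme: str = "joint"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_perm", "n_samples", "min_species", "min_families"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _stage_seeds(seed: int | None) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(2)
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(("permutation", "enrichment"), children)}


def write_association_tsv(results, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("family_id\tr\tp\tq\tn\n")
        for res in results:
            fh.write(f"{res.family_id}\t{res.r:.6g}\t{res.p:.6g}\t{res.q:.6g}\t{res.n}\n")


def write_enrichment_tsv(results, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tn_background\tobserved_adjusted\tnull_mean\tp\tq\n")
        for res in results:
            fh.write(f"{res.term}\t{res.n_background}\t{res.observed_adjusted_count:.6g}"
                     f"\t{res.null_mean:.6g}\t{res.p_empirical:.6g}\t{res.q:.6g}\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the run directory.

    Stages whose inputs are not configured (tree, annotations, expression) are
    skipped, except that correction requires a tree: asking for the full
    pipeline without one is a configuration error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"config": {**asdict(config), "covariates": list(config.covariates)},
                     "version": __version__, "stage_seeds": seeds}
    log_lines = [f"neogfs {__version__}", f"master seed: {config.seed}",
                 *(f"seed[{k}] = {v}" for k, v in seeds.items())]

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    if config.tree is None:
        raise PipelineError("stage 'correct' failed: no tree configured "
                            "(phylogenetic correction requires a Newick tree)")

    table = stage("read_phenotypes", lambda: read_phenotypes(config.phenotypes))
    matrix = stage("read_gfs", lambda: read_gfs(config.gfs))
    tree = stage("read_tree", lambda: read_tree(config.tree))

    filtered, report = stage("filter", lambda: filter_families(matrix, config.min_species))
    from .data_io import write_gfs
    write_gfs(filtered, out / "filtered_gfs.tsv")
    (out / "filter_report.json").write_text(json.dumps(report.as_dict()) + "\n")
    summary["filter"] = report.as_dict()

    aligned = table.reordered(filtered.species_ids)
    phenotype = aligned.trait(config.target)
    results = stage("associate", lambda: family_associations(
        filtered, phenotype, absent_policy=config.absent_policy))
    write_association_tsv(results, out / f"associations_{config.target}.tsv")
    rs = np.array([r.r for r in results if r.is_defined])
    null = stage("permutation_null", lambda: permutation_null(
        filtered, phenotype, n_replicates=config.n_perm, scheme=config.scheme,
        seed=seeds["permutation"]))
    z, p_one, p_emp = stage("zscore", lambda: zscore_shift_test(float(rs.mean()), null))
    chi2, chi2_p, n_pos, n_neg = stage("sign_chisq", lambda: sign_chisq(results))
    n_sig = sum(1 for r in results
                if r.is_defined and r.r > 0 and r.q < config.fdr_alpha)
    summary["association"] = {
        "mean_r": float(rs.mean()), "z": z, "p_one_tailed": p_one,
        "p_empirical": p_emp, "chi2": chi2, "chi2_p": chi2_p,
        "n_pos": n_pos, "n_neg": n_neg, "n_significant_positive": n_sig,
    }

    corrected = stage("correct", lambda: corrected_association(
        filtered, table, tree, target=config.target, covariates=config.covariates))
    write_association_tsv(corrected, out / f"corrected_{config.target}.tsv")
    sig_families = [r.family_id for r in corrected
                    if r.is_defined and r.r > 0 and r.q < config.fdr_alpha]
    summary["corrected"] = {"n_significant_positive": len(sig_families)}

    if config.annotations is not None and sig_families:
        annotations = stage("read_annotations",
                            lambda: read_annotations(config.annotations))
        term_map = stage("build_term_map", lambda: build_term_map(
            annotations, filtered.family_ids, min_families=config.min_families))
        enriched = stage("enrich", lambda: enrichment_test(
            sig_families, filtered.family_ids, term_map,
            n_samples=config.n_samples, seed=seeds["enrichment"]))
        write_enrichment_tsv(enriched, out / "enrichment.tsv")
        summary["enrichment"] = {
            "n_terms_tested": len(enriched),
            "significant_terms": sorted(r.term for r in enriched
                                        if r.q < config.fdr_alpha),
        }

    if config.expression is not None and config.expression_meta is not None:
        dataset = stage("read_expression", lambda: read_expression(
            config.expression, config.expression_meta))
        normalized = stage("normalize", lambda: normalize_samples(dataset))
        gene_subset = None
        if config.gene_map is not None and sig_families:
            import pandas as pd

            mapping = pd.read_csv(config.gene_map, sep="\t")
            keep = set(sig_families)
            gene_subset = set(mapping.loc[mapping["family_id"].isin(keep), "gene_id"])
        summaries = stage("window_means", lambda: window_means(
            normalized, cutoff_years=config.cutoff_years, gene_subset=gene_subset))
        with open(out / "expression_windows.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_id\tmean_before\tmean_after\tn_before\tn_after\n")
            for s in summaries:
                fh.write(f"{s.gene_id}\t{s.mean_before:.6g}\t{s.mean_after:.6g}"
                         f"\t{s.n_samples_before}\t{s.n_samples_after}\n")
        stat, p = stage("wilcoxon", lambda: paired_wilcoxon(summaries, "greater"))
        _, p_two = stage("wilcoxon", lambda: paired_wilcoxon(summaries, "two_sided"))
        summary["expression"] = {"statistic": stat, "p_greater": p,
                                 "p_two_sided": p_two, "n_genes": len(summaries)}

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
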