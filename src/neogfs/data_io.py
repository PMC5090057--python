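"""Readers, writers and validated containers for every file format the pipeline touches.

Formats are deliberately plain: CSV for phenotypes and sample metadata, TSV for
the gene-family-size matrix, annotations and expression, Newick for the tree.
Every reader validates on entry and every ``write_*``/``read_*`` pair
round-trips losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd


class DataFormatError(ValueError):
    """A file does not conform to the expected layout (columns, Newick syntax...)."""


class ValidationError(ValueError):
    """A file parsed but its content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ("species", "brain_volume", "neocortex_volume", "nr", "ei", "mlsp")
TRAIT_NAMES = ("nr", "ei", "mlsp")


@dataclass(frozen=True)
class PhenotypeRecord:
    """One species' brain phenotype measures.

    ``brain_volume`` is the TOTAL brain volume in cm^3 and ``neocortex_volume``
    the neocortex volume in cm^3, so the neocortex ratio is
    ``neocortex / (brain - neocortex)`` (Dunbar's Nr). ``ei`` is the
    encephalization index (log-scale residual of brain mass on body mass) and
    ``mlsp`` the maximum lifespan in years.
    """

    species_id: str
    brain_volume: float
    neocortex_volume: float
    nr: float
    ei: float
    mlsp: float
    common_name: str = ""

    def __post_init__(self) -> None:
        if not (self.brain_volume > 0 and self.neocortex_volume > 0):
            raise ValidationError(
                f"{self.species_id}: volumes must be positive "
                f"(brain={self.brain_volume}, neocortex={self.neocortex_volume})"
            )
        if self.neocortex_volume >= self.brain_volume:
            raise ValidationError(
                f"{self.species_id}: neocortex volume ({self.neocortex_volume}) must be "
                f"smaller than total brain volume ({self.brain_volume})"
            )
        if self.mlsp <= 0:
            raise ValidationError(f"{self.species_id}: mlsp must be positive")
        for name in ("nr", "ei", "mlsp"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{self.species_id}: {name} is not finite")


class PhenotypeTable:
    """Species-aligned access to phenotype records.

    Order of records is preserved from the source file; ``trait(name)`` returns
    a vector aligned with ``species``.
    """

    def __init__(self, records: Sequence[PhenotypeRecord]):
        self.records = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.species_id in seen:
                raise ValidationError(f"duplicate species: {rec.species_id}")
            seen.add(rec.species_id)

    @property
    def species(self) -> list[str]:
        return [rec.species_id for rec in self.records]

    def trait(self, name: str) -> np.ndarray:
        if name not in TRAIT_NAMES:
            raise KeyError(f"unknown trait {name!r}; expected one of {TRAIT_NAMES}")
        return np.array([getattr(rec, name) for rec in self.records], dtype=float)

    def record(self, species_id: str) -> PhenotypeRecord:
        for rec in self.records:
            if rec.species_id == species_id:
                return rec
        raise KeyError(species_id)

    def reordered(self, species_order: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable([self.record(s) for s in species_order])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "common_name": [r.common_name for r in self.records],
                "brain_volume": [r.brain_volume for r in self.records],
                "neocortex_volume": [r.neocortex_volume for r in self.records],
                "nr": [r.nr for r in self.records],
                "ei": [r.ei for r in self.records],
                "mlsp": [r.mlsp for r in self.records],
            }
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PhenotypeRecord]:
        return iter(self.records)


def _numeric_column(frame: pd.DataFrame, column: str, path: str) -> np.ndarray:
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = values.isna() & frame[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataFormatError(
            f"{path}: non-numeric value {frame[column].iloc[row]!r} in column "
            f"{column!r} at data row {row + 1}"
        )
    return values.to_numpy(dtype=float)


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype CSV.

    Required columns: ``species, brain_volume, neocortex_volume, ei, mlsp``.
    ``nr`` is optional and recomputed from the volumes when absent;
    ``common_name`` is carried through when present.
    """
    frame = pd.read_csv(path, dtype=str)
    required = [c for c in PHENOTYPE_COLUMNS if c != "nr"]
    for column in required:
        if column not in frame.columns:
            raise DataFormatError(f"{path}: missing required column {column!r}")
    brain = _numeric_column(frame, "brain_volume", str(path))
    neo = _numeric_column(frame, "neocortex_volume", str(path))
    ei = _numeric_column(frame, "ei", str(path))
    mlsp = _numeric_column(frame, "mlsp", str(path))
    if "nr" in frame.columns:
        nr = _numeric_column(frame, "nr", str(path))
    else:
        nr = neo / (brain - neo)
    common = frame["common_name"] if "common_name" in frame.columns else [""] * len(frame)
    records = [
        PhenotypeRecord(
            species_id=str(sp),
            brain_volume=float(b),
            neocortex_volume=float(n),
            nr=float(r),
            ei=float(e),
            mlsp=float(m),
            common_name=str(c),
        )
        for sp, b, n, r, e, m, c in zip(frame["species"], brain, neo, nr, ei, mlsp, common)
    ]
    return PhenotypeTable(records)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def load_phenotype_table() -> PhenotypeTable:
    """Load the packaged 28-species mammalian phenotype table.

    Brain and neocortex volumes, the neocortex ratio Nr, encephalization index
    Ei and maximum lifespan, compiled from the comparative literature for the
    28 mammals with fully sequenced genomes used throughout this package.
    """
    ref = resources.files("neogfs.data") / "phenotypes_28species.csv"
    with resources.as_file(ref) as p:
        return read_phenotypes(p)


# ---------------------------------------------------------------------------
# Gene-family-size matrix
# ---------------------------------------------------------------------------


@dataclass
class GeneFamilyMatrix:
    """Families x species matrix of gene-family sizes (non-negative integer counts)."""

    family_ids: list[str]
    species_ids: list[str]
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        if self.sizes.shape != (len(self.family_ids), len(self.species_ids)):
            raise ValidationError(
                f"size matrix shape {self.sizes.shape} does not match "
                f"{len(self.family_ids)} families x {len(self.species_ids)} species"
            )
        if len(set(self.family_ids)) != len(self.family_ids):
            raise ValidationError("duplicate family ids")
        if not np.issubdtype(self.sizes.dtype, np.integer):
            if not np.all(self.sizes == np.floor(self.sizes)):
                raise ValidationError("family sizes must be integer counts")
            self.sizes = self.sizes.astype(np.int64)
        if (self.sizes < 0).any():
            raise ValidationError("family sizes must be non-negative")

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def subset(self, family_ids: Sequence[str]) -> "GeneFamilyMatrix":
        index = {f: i for i, f in enumerate(self.family_ids)}
        rows = [index[f] for f in family_ids]
        return GeneFamilyMatrix(list(family_ids), list(self.species_ids), self.sizes[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sizes, index=pd.Index(self.family_ids, name="family_id"),
                            columns=self.species_ids)


def read_gfs(path) -> GeneFamilyMatrix:
    """Read a TSV gene-family-size matrix: first column family_id, one column
    per species, integer cells; an empty cell means 0."""
    with open(path, encoding="utf-8") as handle:
        lines = [line.rstrip("\n") for line in handle if line.strip("\n") != ""]
    if not lines:
        raise DataFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "family_id":
        raise DataFormatError(f"{path}: first column must be 'family_id', got {header[0]!r}")
    n_cols = len(header)
    for i, line in enumerate(lines[1:], start=2):
        if len(line.split("\t")) != n_cols:
            raise DataFormatError(f"{path}: ragged row at line {i} "
                                  f"({len(line.split(chr(9)))} fields, expected {n_cols})")
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    species = list(frame.columns[1:])
    raw = frame.iloc[:, 1:].replace("", "0")
    try:
        sizes = raw.astype(float).to_numpy()
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-numeric cell in size matrix: {exc}") from exc
    if not np.all(sizes == np.floor(sizes)):
        raise ValidationError(f"{path}: family sizes must be integer counts")
    return GeneFamilyMatrix(list(frame.iloc[:, 0]), species, sizes.astype(np.int64))


def write_gfs(matrix: GeneFamilyMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted time-calibrated tree with tip labels matching species ids."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate tip labels in tree")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise DataFormatError("tree has an edge without a branch length")
            if edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label.replace(" ", "_") for leaf in self.tree.leaf_node_iter()]

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label.replace(" ", "_")] = d
        return depths

    @property
    def height(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = list(self.tip_depths().values())
        return (max(depths) - min(depths)) <= rel_tol * max(depths)

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree(path) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise DataFormatError(f"{path}: cannot parse Newick: {exc}") from exc
    return Phylogeny(tree)


def tree_from_newick(newick: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise DataFormatError(f"cannot parse Newick: {exc}") from exc
    return Phylogeny(tree)


def write_tree(phylogeny: Phylogeny, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(phylogeny.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


class AnnotationMap:
    """A flat family -> term map stored as a set of unique (family, term) pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: set[tuple[str, str]] = {(str(f), str(t)) for f, t in pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def families(self) -> set[str]:
        return {f for f, _ in self.pairs}

    @property
    def terms(self) -> set[str]:
        return {t for _, t in self.pairs}

    def terms_for_family(self, family_id: str) -> set[str]:
        return {t for f, t in self.pairs if f == family_id}

    def families_for_term(self, term_id: str) -> set[str]:
        return {f for f, t in self.pairs if t == term_id}


def read_annotations(path) -> AnnotationMap:
    """Read a two-column TSV of (family_id, term_id) pairs; header optional,
    empty file allowed (every family then falls in the 'not annotated' bucket)."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for i, line in enumerate(handle):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataFormatError(f"{path}: expected 2 columns at line {i + 1}, "
                                      f"got {len(fields)}")
            if i == 0 and fields == ["family_id", "term_id"]:
                continue
            pairs.append((fields[0], fields[1]))
    return AnnotationMap(pairs)


def write_annotations(annotations: AnnotationMap, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("family_id\tterm_id\n")
        for family, term in sorted(annotations.pairs):
            handle.write(f"{family}\t{term}\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Genes x samples expression values plus per-sample metadata.

    ``meta`` is indexed by sample id with columns ``age_years`` (prenatal ages
    negative, relative to birth) and ``region``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing[:5]}")
        for col in ("age_years", "region"):
            if col not in self.meta.columns:
                raise DataFormatError(f"metadata missing column {col!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")
        self.meta = self.meta.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_expression(matrix_path, meta_path) -> ExpressionDataset:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, index_col="sample_id")
    return ExpressionDataset(values, meta)


def write_expression(dataset: ExpressionDataset, matrix_path, meta_path) -> None:
    frame = dataset.values.copy()
    frame.index.name = "gene_id"
    frame.to_csv(matrix_path, sep="\t")
    dataset.meta.rename_axis("sample_id").to_csv(meta_path)


def pcw_to_years(post_conception_weeks: float) -> float:
    """Convert a prenatal age in post-conception weeks to years relative to
    birth at 40 weeks (prenatal ages come out negative)."""
    return (post_conception_weeks - 40.0) / 52.0
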