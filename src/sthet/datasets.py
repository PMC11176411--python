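"""Domain containers and readers/writers for spatial transcriptomics artifacts.

The package works with four kinds of external input: a genes x spots
count matrix (Matrix Market triplet with id sidecars, or dense delimited
text), per-spot spatial coordinates, per-spot histological region
labels, and optional per-spot histology feature vectors; plus three
interaction-knowledge tables (protein-protein pairs, regulator->target
pairs, ligand->receptor pairs).  Everything is validated up front --
malformed inputs raise typed errors, never a silent partial load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """A structural problem in an input artifact."""


class AlignmentError(ValidationError):
    """Row counts or identifiers disagree between input files."""


@dataclass
class SpatialDataset:
    """A spot x gene expression dataset with spatial and regional annotation.

    ``counts`` is stored genes x spots (matching the common Matrix Market
    layout for expression data); ``coords`` is spots x 2 in whatever
    length unit the platform reports; ``regions`` holds one integer
    histological-region code per spot in a contiguous 1..K range.
    """

    counts: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray
    regions: np.ndarray
    histo_features: np.ndarray | None = None
    normalized: np.ndarray | None = None  # spots x genes, library-normalized log1p
    hvgs: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.regions = np.asarray(self.regions, dtype=np.int64)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise AlignmentError(
                f"{len(self.gene_ids)} gene ids for {n_genes} count rows")
        if len(self.spot_ids) != n_spots:
            raise AlignmentError(
                f"{len(self.spot_ids)} spot ids for {n_spots} count columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.spot_ids)) != n_spots:
            raise ValidationError("duplicate spot identifiers")
        if np.any(self.counts < 0):
            raise ValidationError("negative entries in count matrix")
        if self.coords.shape != (n_spots, 2):
            raise AlignmentError(
                f"coords shape {self.coords.shape} != ({n_spots}, 2)")
        if self.regions.shape != (n_spots,):
            raise AlignmentError(
                f"{self.regions.shape[0]} region labels for {n_spots} spots")
        labels = np.unique(self.regions)
        expected = np.arange(1, labels.size + 1)
        if not np.array_equal(labels, expected):
            mapping = {int(old): int(new) for new, old in enumerate(labels, start=1)}
            logger.warning("remapping non-contiguous region codes: %s", mapping)
            self.regions = np.array([mapping[int(r)] for r in self.regions])
        if self.histo_features is not None:
            self.histo_features = np.asarray(self.histo_features, dtype=np.float64)
            if self.histo_features.shape[0] != n_spots:
                raise AlignmentError(
                    f"{self.histo_features.shape[0]} histology rows for {n_spots} spots")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_regions(self) -> int:
        return int(self.regions.max())

    def normalized_matrix(self) -> np.ndarray:
        if self.normalized is None:
            raise ValidationError("dataset has not been normalized yet")
        return self.normalized

    def hvg_indices(self) -> np.ndarray:
        if self.hvgs is None:
            raise ValidationError("no HVG selection stored on this dataset")
        index = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([index[g] for g in self.hvgs], dtype=np.int64)


@dataclass
class InteractionKB:
    """Gene-gene interaction knowledge: PPI (unordered), GRN and LRP (ordered).

    The ligand-receptor list keeps its load order; the 1-based position of
    each pair is the stable index that later labels the columns of the
    communication-strength matrix H.
    """

    ppi: set[frozenset]
    grn: set[tuple[str, str]]
    lrp: list[tuple[str, str]]

    def __post_init__(self):
        for pair in self.ppi:
            if len(pair) != 2:
                raise ValidationError(f"self-pair in PPI: {set(pair)}")
        for a, b in list(self.grn) + list(self.lrp):
            if a == b:
                raise ValidationError(f"self-pair ({a}, {b})")
        if len(set(self.lrp)) != len(self.lrp):
            raise ValidationError("duplicate ligand-receptor pairs")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for pair in self.ppi:
            out.update(pair)
        for a, b in self.grn:
            out.update((a, b))
        for a, b in self.lrp:
            out.update((a, b))
        return out

    def flag_missing(self, gene_ids: list[str]) -> set[str]:
        """KB genes absent from the dataset (kept, but excluded from graphs)."""
        missing = self.genes() - set(gene_ids)
        if missing:
            logger.info("%d KB genes absent from dataset", len(missing))
        return missing


@dataclass
class EmbeddingSet:
    """Learned per-spot representations: hierarchical R1, semantic R2, R = R1||R2."""

    R1: np.ndarray
    R2: np.ndarray
    spot_ids: list[str]
    latent_cell: np.ndarray | None = None
    G: np.ndarray | None = None
    gene_ids: list[str] | None = None

    @property
    def R(self) -> np.ndarray:
        return np.hstack([self.R1, self.R2])

    def __post_init__(self):
        if self.R1.shape[0] != self.R2.shape[0]:
            raise AlignmentError("R1 and R2 have different numbers of spots")
        if self.R1.shape[0] != len(self.spot_ids):
            raise AlignmentError("embedding rows do not match spot ids")
        for name, arr in (("R1", self.R1), ("R2", self.R2)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite entries in {name}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, **kwargs)


def _read_counts(counts_path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        mat = spio.mmread(counts_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        features = counts_path.with_name("features.tsv")
        barcodes = counts_path.with_name("barcodes.tsv")
        for sidecar in (features, barcodes):
            if not sidecar.exists():
                raise ValidationError(f"missing sidecar file {sidecar}")
        gene_ids = features.read_text().split()
        spot_ids = barcodes.read_text().split()
        return np.asarray(mat, dtype=np.float64), gene_ids, spot_ids
    df = _read_table(counts_path, index_col=0)
    return df.to_numpy(dtype=np.float64), [str(g) for g in df.index], [str(s) for s in df.columns]


def read_spatial_dataset(counts_path: str | Path,
                         coords_path: str | Path,
                         regions_path: str | Path,
                         histo_path: str | Path | None = None) -> SpatialDataset:
    """Load and validate a dataset from its on-disk artifacts.

    Spots present in the counts but missing from the coordinate or region
    tables raise an :class:`AlignmentError` naming the offending file;
    they are never silently dropped.
    """
    counts, gene_ids, spot_ids = _read_counts(counts_path)

    def _aligned(path, n_cols_min) -> pd.DataFrame:
        df = _read_table(path, index_col=0)
        df.index = df.index.map(str)
        missing = [s for s in spot_ids if s not in df.index]
        if missing:
            raise AlignmentError(
                f"{Path(path).name}: {len(missing)} spots missing "
                f"(first: {missing[0]!r})")
        if df.shape[1] < n_cols_min:
            raise ValidationError(f"{Path(path).name}: expected >= {n_cols_min} columns")
        return df.loc[spot_ids]

    coords = _aligned(coords_path, 2).iloc[:, :2].to_numpy(dtype=np.float64)
    regions = _aligned(regions_path, 1).iloc[:, 0].to_numpy(dtype=np.int64)
    histo = None
    if histo_path is not None:
        histo = _aligned(histo_path, 1).to_numpy(dtype=np.float64)
    return SpatialDataset(counts=counts, gene_ids=gene_ids, spot_ids=spot_ids,
                          coords=coords, regions=regions, histo_features=histo)


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and len(header.split()) < 2:
            raise ValidationError(f"{Path(path).name}:1: expected two columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.replace(",", "\t").split("\t")
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) < 2:
                raise ValidationError(
                    f"{Path(path).name}:{lineno}: expected two columns, got {len(fields)}")
            pairs.append((fields[0], fields[1]))
    return pairs


def read_interaction_kb(ppi_path: str | Path, grn_path: str | Path,
                        lrp_path: str | Path) -> InteractionKB:
    """Load the three interaction tables, de-duplicating and dropping self-pairs."""
    ppi_rows = _read_pairs(ppi_path)
    ppi = {frozenset(p) for p in ppi_rows if p[0] != p[1]}
    if len(ppi) < len(ppi_rows):
        logger.info("collapsed %d duplicate/self PPI rows", len(ppi_rows) - len(ppi))

    grn_rows = _read_pairs(grn_path)
    grn = {p for p in grn_rows if p[0] != p[1]}

    lrp_rows = [p for p in _read_pairs(lrp_path) if p[0] != p[1]]
    seen: set[tuple[str, str]] = set()
    lrp: list[tuple[str, str]] = []
    for p in lrp_rows:
        if p not in seen:
            seen.add(p)
            lrp.append(p)
    if len(lrp) < len(lrp_rows):
        logger.info("collapsed %d duplicate LRP rows", len(lrp_rows) - len(lrp))
    return InteractionKB(ppi=ppi, grn=grn, lrp=lrp)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_spatial_dataset(ds: SpatialDataset, outdir: str | Path,
                          fmt: str = "dense") -> dict[str, Path]:
    """Write a dataset back to disk in either supported counts format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if fmt == "dense":
        paths["counts"] = outdir / "counts.tsv"
        pd.DataFrame(ds.counts, index=ds.gene_ids, columns=ds.spot_ids).to_csv(
            paths["counts"], sep="\t")
    elif fmt == "mtx":
        paths["counts"] = outdir / "matrix.mtx"
        spio.mmwrite(str(paths["counts"]), sparse.coo_matrix(ds.counts))
        (outdir / "features.tsv").write_text("\n".join(ds.gene_ids) + "\n")
        (outdir / "barcodes.tsv").write_text("\n".join(ds.spot_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    paths["coords"] = outdir / "coords.tsv"
    pd.DataFrame(ds.coords, index=ds.spot_ids, columns=["x", "y"]).to_csv(
        paths["coords"], sep="\t", index_label="spot_id")
    paths["regions"] = outdir / "regions.tsv"
    pd.DataFrame({"region": ds.regions}, index=ds.spot_ids).to_csv(
        paths["regions"], sep="\t", index_label="spot_id")
    if ds.histo_features is not None:
        paths["histo"] = outdir / "histology.tsv"
        pd.DataFrame(ds.histo_features, index=ds.spot_ids).to_csv(
            paths["histo"], sep="\t", index_label="spot_id")
    return paths


def write_interaction_kb(kb: InteractionKB, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["ppi"] = outdir / "ppi.tsv"
    with open(paths["ppi"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for pair in sorted(tuple(sorted(p)) for p in kb.ppi):
            fh.write(f"{pair[0]}\t{pair[1]}\n")
    paths["grn"] = outdir / "grn.tsv"
    with open(paths["grn"], "w") as fh:
        fh.write("regulator\ttarget\n")
        for a, b in sorted(kb.grn):
            fh.write(f"{a}\t{b}\n")
    paths["lrp"] = outdir / "lrp.tsv"
    with open(paths["lrp"], "w") as fh:
        fh.write("ligand\treceptor\n")
        for a, b in kb.lrp:
            fh.write(f"{a}\t{b}\n")
    return paths


def write_matrix_tsv(matrix: np.ndarray, index: list[str], path: str | Path,
                     prefix: str = "dim") -> None:
    cols = [f"{prefix}{i + 1}" for i in range(matrix.shape[1])]
    pd.DataFrame(matrix, index=index, columns=cols).to_csv(
        path, sep="\t", index_label="id", float_format="%.17g")


__all__ = [
    "SpatialDataset", "InteractionKB", "EmbeddingSet",
    "ValidationError", "AlignmentError",
    "read_spatial_dataset", "read_interaction_kb",
    "write_spatial_dataset", "write_interaction_kb", "write_matrix_tsv",
    "replace", "field",
]
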