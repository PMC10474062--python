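"""Readers and writers for the plain-text formats the pipeline touches.

Counts travel as TSV (genes x samples, first column gene ids) or
MatrixMarket with sidecar row/column id files; sample annotations as TSV;
gene sets as GMT (set name, description, then tab-separated gene ids).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class GeneSetCollection:
    """Named gene-id sets, e.g. a planted informative set plus decoys."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-samples count matrix with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(path: str | Path, genes_path: str | Path, samples_path: str | Path) -> pd.DataFrame:
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    df = pd.DataFrame(mat, index=genes, columns=samples)
    df.index.name = "gene_id"
    return df


def write_counts_mtx(counts: pd.DataFrame, path: str | Path, genes_path: str | Path, samples_path: str | Path) -> None:
    scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(counts.to_numpy()))
    Path(genes_path).write_text("\n".join(counts.index.astype(str)) + "\n")
    Path(samples_path).write_text("\n".join(counts.columns.astype(str)) + "\n")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read per-sample factors: sample_id, leukemic, genotype, condition."""
    ann = pd.read_csv(path, sep="\t", index_col=0)
    required = {"leukemic", "genotype", "condition"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    return ann


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, `name<TAB>description<TAB>gene...`."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and at least one gene")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, genes in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, fixed separators)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
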