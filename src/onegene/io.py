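"""Readers and writers for expression matrices and class label files.

Two dialects are supported:

* plain tab-delimited matrix (first column gene id, header row of sample
  ids) plus a two-column ``sample<TAB>class`` label file;
* GCT v1.2 plus a categorical two-class CLS file (the Broad layout).

Both round-trip losslessly: values survive at full double precision
(written with ``repr``-style %.17g), and gene row order — the order number
used for tie-breaking — is preserved.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .data import DatasetError, ExpressionDataset

__all__ = [
    "read_expression_tsv",
    "read_gct_cls",
    "write_dataset",
    "FormatError",
]


class FormatError(ValueError):
    """Raised on malformed input files."""


def _read_labels_file(path_labels: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path_labels, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path_labels}:{lineno}: expected 'sample<TAB>class', "
                    f"got {line!r}"
                )
            sid, cls = parts[0].strip(), parts[1].strip()
            if sid in mapping:
                raise FormatError(f"{path_labels}: duplicate sample id {sid!r}")
            mapping[sid] = cls
    if not mapping:
        raise FormatError(f"{path_labels}: no labels found")
    return mapping


def _align_labels(sample_ids: list[str], mapping: dict[str, str],
                  source: str) -> np.ndarray:
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise FormatError(
            f"{source}: samples missing from label file: {missing[:5]}"
        )
    labels = np.array([mapping[s] for s in sample_ids], dtype=object)
    uniq = sorted(set(map(str, labels)))
    if len(uniq) != 2:
        raise FormatError(
            f"{source}: exactly two classes required among matrix samples, "
            f"found {len(uniq)}: {uniq}"
        )
    return labels


def read_expression_tsv(path_matrix: str, path_labels: str) -> ExpressionDataset:
    """Read a tab-delimited matrix plus label file.

    The matrix file must have a header row of sample ids and a first column
    of gene ids.  Labels are aligned to matrix columns by sample id, never by
    file order.  Missing values are rejected.
    """
    try:
        df = pd.read_csv(path_matrix, sep="\t", header=0, index_col=0,
                         dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path_matrix}: cannot parse: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path_matrix}: no sample columns found")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            try:
                if cell == "" or cell.upper() in ("NA", "NAN"):
                    raise ValueError("missing value")
                values[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path_matrix}: non-numeric cell at gene "
                    f"{gene_ids[i]!r}, sample {sample_ids[j]!r}: {cell!r}"
                ) from None
    labels = _align_labels(sample_ids, _read_labels_file(path_labels),
                           path_matrix)
    try:
        return ExpressionDataset(
            gene_ids, sample_ids, values, labels,
            metadata={"source": path_matrix, "labels_source": path_labels,
                      "format": "tsv"},
        )
    except DatasetError as exc:
        raise FormatError(str(exc)) from exc


def read_gct_cls(path_gct: str, path_cls: str) -> ExpressionDataset:
    """Read a GCT v1.2 matrix plus a categorical two-class CLS file."""
    with open(path_gct, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3 or not lines[0].startswith("#1.2"):
        raise FormatError(f"{path_gct}: missing '#1.2' version line")
    dims = lines[1].split("\t")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise FormatError(f"{path_gct}: malformed dimensions line") from None
    header = lines[2].split("\t")
    if len(header) < 3 or header[0] != "Name":
        raise FormatError(f"{path_gct}: header must start 'Name\\tDescription'")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path_gct}: dims declare {n_samples} samples but header has "
            f"{len(sample_ids)}"
        )
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_genes:
        raise FormatError(
            f"{path_gct}: dims declare {n_genes} genes but body has "
            f"{len(body)} rows"
        )
    gene_ids, descriptions = [], []
    values = np.empty((n_genes, n_samples), dtype=float)
    for i, ln in enumerate(body):
        parts = ln.split("\t")
        if len(parts) != n_samples + 2:
            raise FormatError(f"{path_gct}: row {i + 4} has {len(parts)} fields")
        gene_ids.append(parts[0])
        descriptions.append(parts[1])
        try:
            values[i] = [float(v) for v in parts[2:]]
        except ValueError:
            raise FormatError(
                f"{path_gct}: non-numeric value in row for gene {parts[0]!r}"
            ) from None

    labels = _read_cls(path_cls, n_samples)
    try:
        return ExpressionDataset(
            gene_ids, sample_ids, values, labels,
            metadata={"source": path_gct, "labels_source": path_cls,
                      "format": "gct", "descriptions": descriptions},
        )
    except DatasetError as exc:
        raise FormatError(str(exc)) from exc


def _read_cls(path_cls: str, n_samples: int) -> np.ndarray:
    with open(path_cls, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path_cls}: expected 3 lines (counts, names, labels)")
    counts = lines[0].split()
    try:
        n_declared, n_classes = int(counts[0]), int(counts[1])
    except (ValueError, IndexError):
        raise FormatError(f"{path_cls}: malformed first line") from None
    if n_classes != 2:
        raise FormatError(f"{path_cls}: two-class CLS required, got {n_classes}")
    if n_declared != n_samples:
        raise FormatError(
            f"{path_cls}: declares {n_declared} samples, matrix has {n_samples}"
        )
    if not lines[1].startswith("#"):
        raise FormatError(f"{path_cls}: second line must start with '#'")
    names = lines[1][1:].split()
    if len(names) != 2:
        raise FormatError(f"{path_cls}: expected two class names, got {names}")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path_cls}: {len(tokens)} labels for {n_samples} samples"
        )
    # Tokens are either 0/1 indices into the names line, or the names.
    if all(t in ("0", "1") for t in tokens):
        labels = [names[int(t)] for t in tokens]
    elif all(t in names for t in tokens):
        labels = tokens
    else:
        raise FormatError(f"{path_cls}: labels must be 0/1 or the class names")
    return np.array(labels, dtype=object)


def write_dataset(dataset: ExpressionDataset, fmt: str, *,
                  matrix_path: str, labels_path: str) -> tuple[str, str]:
    """Write a dataset as ``tsv`` (matrix + label file) or ``gct`` (+ CLS).

    Returns the pair of paths written.  Refuses to write a dataset with no
    genes; a single sample per class is allowed (training-size minimums are
    the evaluation layer's concern, not the serializer's).
    """
    if fmt not in ("tsv", "gct"):
        raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'gct')")
    if dataset.n_genes == 0:
        raise DatasetError("refusing to write dataset with no genes")
    for p in (matrix_path, labels_path):
        parent = os.path.dirname(os.path.abspath(p))
        if not os.path.isdir(parent):
            raise FileNotFoundError(f"output directory does not exist: {parent}")

    if fmt == "tsv":
        with open(matrix_path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\t" + "\t".join(dataset.sample_ids) + "\n")
            for i, gid in enumerate(dataset.gene_ids):
                row = "\t".join("%.17g" % v for v in dataset.values[i])
                fh.write(f"{gid}\t{row}\n")
        with open(labels_path, "w", encoding="utf-8") as fh:
            for sid, lab in zip(dataset.sample_ids, dataset.labels):
                fh.write(f"{sid}\t{lab}\n")
    else:
        desc = dataset.metadata.get("descriptions")
        if not isinstance(desc, list) or len(desc) != dataset.n_genes:
            desc = ["na"] * dataset.n_genes
        with open(matrix_path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{dataset.n_genes}\t{dataset.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(dataset.sample_ids) + "\n")
            for i, gid in enumerate(dataset.gene_ids):
                row = "\t".join("%.17g" % v for v in dataset.values[i])
                fh.write(f"{gid}\t{desc[i]}\t{row}\n")
        c1, c2 = dataset.classes
        idx = {c1: "0", c2: "1"}
        with open(labels_path, "w", encoding="utf-8") as fh:
            fh.write(f"{dataset.n_samples} 2 1\n")
            fh.write(f"# {c1} {c2}\n")
            fh.write(" ".join(idx[str(v)] for v in dataset.labels) + "\n")
    return matrix_path, labels_path
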