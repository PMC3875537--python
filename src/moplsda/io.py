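"""Readers and writers for microarray text formats (GCT, CLS, TSV).

Parsers are deliberately strict: ragged rows, non-numeric cells, duplicate
identifiers and dimension mismatches raise :class:`ParseError` naming the
offending line, because these formats circulate in many hand-edited
variants and silent coercion corrupts gene panels downstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .matrix import ExpressionMatrix
from .opls import OplsModel

MODEL_SCHEMA_VERSION = 1


class ParseError(ValueError):
    """A file violated its declared format; the message names the location."""


def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


# -- expression matrices ---------------------------------------------------

def read_expression(path, format: str = "gct", state: str = "raw") -> ExpressionMatrix:
    """Read a gene x sample matrix from a GCT or plain TSV file.

    TSV layout: first row ``gene_id<TAB>sample ids...``, one gene per row.
    GCT layout: ``#1.2`` version line, ``n_genes<TAB>n_samples``, then a
    header ``Name<TAB>Description<TAB>sample ids...`` and one row per gene.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if format == "gct":
        return _parse_gct(lines, path, state)
    if format == "tsv":
        return _parse_matrix_tsv(lines, path, state)
    raise ValueError(f"unknown expression format {format!r}")


def _parse_values(fields: list[str], path: Path, lineno: int, n_expected: int,
                  offset: int) -> np.ndarray:
    if len(fields) != n_expected + offset:
        raise ParseError(
            f"{path}:{lineno}: expected {n_expected + offset} columns, "
            f"found {len(fields)}"
        )
    try:
        return np.array([float(v) for v in fields[offset:]])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None


def _check_dup_genes(gene_ids: list[str], linenos: list[int], path: Path) -> None:
    seen: dict[str, int] = {}
    for g, ln in zip(gene_ids, linenos):
        if g in seen:
            raise ParseError(
                f"{path}:{ln}: duplicate gene id {g!r} (first seen on line {seen[g]})"
            )
        seen[g] = ln


def _parse_gct(lines: list[str], path: Path, state: str) -> ExpressionMatrix:
    if len(lines) < 3:
        raise ParseError(f"{path}: GCT needs at least 3 header lines")
    if not lines[0].startswith("#1."):
        raise ParseError(f"{path}:1: missing GCT version line (expected '#1.2')")
    dims = _split(lines[1])
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:2: malformed dimensions line {lines[1]!r}") from None
    header = _split(lines[2])
    if len(header) != n_samples + 2:
        raise ParseError(
            f"{path}:3: header names {len(header) - 2} samples, "
            f"dimensions line declares {n_samples}"
        )
    sample_ids = header[2:]
    rows = [ln for ln in lines[3:] if ln.strip()]
    if len(rows) != n_genes:
        raise ParseError(
            f"{path}: {len(rows)} data rows but dimensions line declares {n_genes}"
        )
    gene_ids, linenos, values = [], [], []
    for i, ln in enumerate(rows):
        fields = _split(ln)
        values.append(_parse_values(fields, path, i + 4, n_samples, offset=2))
        gene_ids.append(fields[0])
        linenos.append(i + 4)
    _check_dup_genes(gene_ids, linenos, path)
    return ExpressionMatrix(values=np.vstack(values), gene_ids=gene_ids,
                            sample_ids=sample_ids, state=state)


def _parse_matrix_tsv(lines: list[str], path: Path, state: str) -> ExpressionMatrix:
    rows = [ln for ln in lines if ln.strip()]
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one gene row")
    header = _split(rows[0])
    sample_ids = header[1:]
    gene_ids, linenos, values = [], [], []
    for i, ln in enumerate(rows[1:]):
        fields = _split(ln)
        values.append(_parse_values(fields, path, i + 2, len(sample_ids), offset=1))
        gene_ids.append(fields[0])
        linenos.append(i + 2)
    _check_dup_genes(gene_ids, linenos, path)
    return ExpressionMatrix(values=np.vstack(values), gene_ids=gene_ids,
                            sample_ids=sample_ids, state=state)


def write_expression(m: ExpressionMatrix, path, format: str = "gct") -> None:
    path = Path(path)
    with path.open("w") as fh:
        if format == "gct":
            fh.write("#1.2\n")
            fh.write(f"{m.n_genes}\t{m.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(m.sample_ids) + "\n")
            for g, row in zip(m.gene_ids, m.values):
                fh.write(g + "\tna\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        elif format == "tsv":
            fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
            for g, row in zip(m.gene_ids, m.values):
                fh.write(g + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        else:
            raise ValueError(f"unknown expression format {format!r}")


# -- class labels ----------------------------------------------------------

def read_labels(path, format: str = "cls",
                sample_ids: list[str] | None = None) -> dict[str, str]:
    """Read sample class labels from a CLS file or a two-column TSV.

    CLS is positional, so ``sample_ids`` (the expression matrix's sample
    order) is required for it.  TSV rows are ``sample_id<TAB>class``; when
    ``sample_ids`` is given, every sample must be covered.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if format == "cls":
        if sample_ids is None:
            raise ValueError("CLS labels are positional; sample_ids is required")
        return _parse_cls(lines, path, sample_ids)
    if format == "tsv":
        labels: dict[str, str] = {}
        for i, ln in enumerate(lines):
            fields = _split(ln)
            if len(fields) != 2:
                raise ParseError(f"{path}:{i + 1}: expected 2 columns, found {len(fields)}")
            if fields[0] in labels:
                raise ParseError(f"{path}:{i + 1}: duplicate sample id {fields[0]!r}")
            labels[fields[0]] = fields[1]
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in labels]
            if missing:
                raise ParseError(f"{path}: no class label for samples {missing[:10]}")
        return labels
    raise ValueError(f"unknown label format {format!r}")


def _parse_cls(lines: list[str], path: Path, sample_ids: list[str]) -> dict[str, str]:
    if len(lines) < 3:
        raise ParseError(f"{path}: CLS needs 3 lines (counts, class names, labels)")
    counts = lines[0].split()
    try:
        n_samples, n_classes = int(counts[0]), int(counts[1])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: malformed CLS count line {lines[0]!r}") from None
    names_line = lines[1].split()
    if not names_line or names_line[0] != "#":
        raise ParseError(f"{path}:2: CLS class-name line must start with '#'")
    class_names = names_line[1:]
    if len(class_names) != n_classes:
        raise ParseError(
            f"{path}:2: {len(class_names)} class names but header declares {n_classes}"
        )
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise ParseError(
            f"{path}:3: {len(tokens)} labels but header declares {n_samples}"
        )
    if len(sample_ids) != n_samples:
        raise ParseError(
            f"{path}: CLS declares {n_samples} samples, matrix has {len(sample_ids)}"
        )
    labels: dict[str, str] = {}
    for i, (s, tok) in enumerate(zip(sample_ids, tokens)):
        if tok in class_names:
            labels[s] = tok
        else:
            try:
                labels[s] = class_names[int(tok)]
            except (ValueError, IndexError):
                raise ParseError(f"{path}:3: unknown class token {tok!r} "
                                 f"at position {i + 1}") from None
    return labels


def write_labels(labels: dict[str, str], path, format: str = "cls",
                 sample_ids: list[str] | None = None) -> None:
    path = Path(path)
    if sample_ids is None:
        sample_ids = list(labels)
    if format == "cls":
        class_names: list[str] = []
        for s in sample_ids:
            if labels[s] not in class_names:
                class_names.append(labels[s])
        idx = {c: i for i, c in enumerate(class_names)}
        with path.open("w") as fh:
            fh.write(f"{len(sample_ids)} {len(class_names)} 1\n")
            fh.write("# " + " ".join(class_names) + "\n")
            fh.write(" ".join(str(idx[labels[s]]) for s in sample_ids) + "\n")
    elif format == "tsv":
        with path.open("w") as fh:
            for s in sample_ids:
                fh.write(f"{s}\t{labels[s]}\n")
    else:
        raise ValueError(f"unknown label format {format!r}")


# -- model serialization ---------------------------------------------------

def save_model(model: OplsModel, path) -> None:
    """Serialize a fitted model to a single JSON document (versioned schema)."""
    doc = {
        "schema": "moplsda.opls_model",
        "schema_version": MODEL_SCHEMA_VERSION,
        "positive_class": model.positive_class,
        "n_ortho": model.n_ortho,
        "b": model.b,
        "y_mean": model.y_mean,
        "r2x": model.r2x,
        "r2y": model.r2y,
        "q2y": model.q2y,
        "press": model.press,
        "ss": model.ss,
        "gene_ids": model.gene_ids,
        "w": model.w.tolist(),
        "t": model.t.tolist(),
        "p": model.p.tolist(),
        "W_o": model.W_o.tolist(),
        "T_o": model.T_o.tolist(),
        "P_o": model.P_o.tolist(),
        "x_means": model.x_means.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> OplsModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "moplsda.opls_model":
        raise ParseError(f"{path}: not a serialized OPLS-DA model")
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ParseError(
            f"{path}: schema version {doc.get('schema_version')} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    n_genes = len(doc["w"])
    n_ortho = doc["n_ortho"]

    def arr2(key, rows):
        a = np.asarray(doc[key], dtype=float)
        return a.reshape(rows, n_ortho) if a.size else np.zeros((rows, n_ortho))

    return OplsModel(
        w=np.asarray(doc["w"], dtype=float),
        t=np.asarray(doc["t"], dtype=float),
        p=np.asarray(doc["p"], dtype=float),
        W_o=arr2("W_o", n_genes),
        T_o=arr2("T_o", len(doc["t"])),
        P_o=arr2("P_o", n_genes),
        b=doc["b"], n_ortho=n_ortho,
        x_means=np.asarray(doc["x_means"], dtype=float),
        y_mean=doc["y_mean"], r2x=doc["r2x"], r2y=doc["r2y"],
        positive_class=doc["positive_class"], gene_ids=doc["gene_ids"],
        q2y=doc["q2y"], press=doc["press"], ss=doc["ss"],
    )
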