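"""Disk I/O: class-labelled text corpora and the per-document feature table.

A corpus on disk is one directory per class, each holding UTF-8 ``.txt``
files; the directory name is the class label and ``doc_id`` is
``"<label>/<filename>"``. An optional sidecar ``<name>.tags`` file (one
whitespace-separated tag per token of the whitespace-split text) supplies
pre-computed annotation, bypassing the automatic tagger.

The feature table is canonically CSV (RFC-4180 via pandas), with an XLSX
writer for spreadsheet workflows.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from entrotext.corpus import Corpus, Document
from entrotext.features import FEATURE_COLUMNS

_TABLE_COLUMNS = ("doc_id", "class_label", *FEATURE_COLUMNS)


def load_corpus(root: str | Path) -> Corpus:
    """Read a per-class directory tree into a Corpus.

    Requires at least two class directories with at least one ``.txt`` file
    each (pairwise analysis is meaningless below two classes). Traversal is
    lexicographic, so reloading the same tree yields the same document order
    regardless of file-system ordering.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"corpus root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(
            f"corpus root {root} has {len(class_dirs)} class directories; "
            "need >= 2 for pairwise analysis"
        )
    documents: list[Document] = []
    for class_dir in class_dirs:
        label = class_dir.name
        txt_files = sorted(class_dir.glob("*.txt"))
        if not txt_files:
            raise ValueError(f"class directory {label!r} contains no .txt files")
        for txt in txt_files:
            try:
                raw = txt.read_text(encoding="utf-8")
            except UnicodeDecodeError as exc:
                raise ValueError(f"file {txt} is not valid UTF-8") from exc
            tokens = tags = None
            sidecar = txt.with_suffix(".tags")
            if sidecar.exists():
                tokens = raw.split()
                tags = sidecar.read_text(encoding="utf-8").split()
                if len(tags) != len(tokens):
                    raise ValueError(
                        f"sidecar {sidecar} has {len(tags)} tags for "
                        f"{len(tokens)} tokens"
                    )
            documents.append(
                Document(
                    doc_id=f"{label}/{txt.name}",
                    class_label=label,
                    raw_text=raw,
                    tokens=tokens,
                    tags=tags,
                )
            )
    return Corpus(documents=documents)


def write_corpus(corpus: Corpus, out_dir: str | Path, sidecar_tags: bool = True) -> Path:
    """Write a corpus as per-class directories of .txt (and .tags) files."""
    out_dir = Path(out_dir)
    for doc in corpus:
        class_dir = out_dir / doc.class_label
        class_dir.mkdir(parents=True, exist_ok=True)
        name = doc.doc_id.split("/", 1)[-1]
        if not name.endswith(".txt"):
            name += ".txt"
        (class_dir / name).write_text(doc.raw_text + "\n", encoding="utf-8")
        if sidecar_tags and doc.tags is not None:
            (class_dir / name).with_suffix(".tags").write_text(
                " ".join(doc.tags) + "\n", encoding="utf-8"
            )
    return out_dir


def write_feature_table(table: pd.DataFrame, path: str | Path, format: str | None = None) -> Path:
    """Write a feature table to CSV or XLSX with the fixed column order."""
    path = Path(path)
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing column(s) {missing}")
    out = table.loc[:, list(_TABLE_COLUMNS)]
    if format is None:
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if format == "csv":
        out.to_csv(path, index=False)
    elif format == "xlsx":
        out.to_excel(path, index=False, engine="openpyxl")
    else:
        raise ValueError(f"unknown format {format!r} (use 'csv' or 'xlsx')")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table, validating columns, numeric types and finiteness."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path, engine="openpyxl")
    else:
        table = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    table = table.loc[:, list(_TABLE_COLUMNS)]
    for col in FEATURE_COLUMNS:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = table.loc[numeric.isna(), "doc_id"]
        if not bad.empty:
            raise ValueError(
                f"non-numeric or missing value in column {col!r} for "
                f"doc_id {bad.iloc[0]!r}"
            )
        table[col] = numeric
    if table["doc_id"].duplicated().any():
        dup = table.loc[table["doc_id"].duplicated(), "doc_id"].iloc[0]
        raise ValueError(f"duplicate doc_id {dup!r} in {path}")
    return table
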