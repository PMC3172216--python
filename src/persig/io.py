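"""Readers and writers for the plain-text formats the pipeline touches.

Conventions (documented bit-exactly):

* Expression matrices are tab-separated, UNIX newlines, no quoting.  The
  first column holds feature ids, the header row holds sample ids.  Leading
  ``#key=value`` comment lines carry metadata; the ``#scale=`` key records
  the value scale and round-trips through :func:`write_expression_tsv` /
  :func:`read_expression_tsv`.
* Missing values are written as ``NA``.
* Gene identifiers are case-insensitive symbols and are uppercased on
  ingest.  If uppercasing makes two rows collide, the row with the highest
  inter-quartile range is kept (the most informative probe) and a warning is
  emitted.
* Sample annotations are TSV with columns ``sample_id`` plus any of
  ``condition``, ``time``, ``subset``.
* Detection flags are a 0/1 TSV with the same layout as the matrix.
* Gene sets use the standard GMT format: ``name<TAB>description<TAB>member...``.

All readers validate rather than coerce: malformed input raises
:class:`~persig.datasets.FormatError` naming the file, line and field.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from .datasets import (
    ExpressionDataset,
    FormatError,
    GeneSetCollection,
    GeneSignature,
    InputError,
)

logger = logging.getLogger(__name__)

#: float format used by all writers; 17 significant digits round-trips
#: IEEE doubles exactly.
FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_metadata_lines(path: str) -> tuple[dict[str, str], int]:
    """Parse leading '#key=value' lines; return (metadata, n_header_lines)."""
    meta: dict[str, str] = {}
    n = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].rstrip("\n")
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            n += 1
    return meta, n


def _collapse_duplicate_symbols(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Collapse rows sharing an (uppercased) symbol, keeping the highest-IQR row."""
    if not df.index.has_duplicates:
        return df
    iqr = df.quantile(0.75, axis=1) - df.quantile(0.25, axis=1)
    order = np.argsort(-iqr.to_numpy(), kind="stable")
    keep = ~df.index[order].duplicated()
    kept_positions = np.sort(order[keep])
    n_dropped = len(df) - kept_positions.size
    logger.warning(
        "%s: %d rows collapsed after uppercasing symbols (kept highest-IQR row)",
        path, n_dropped,
    )
    return df.iloc[kept_positions]


def read_expression_tsv(
    path: str,
    annotations_path: str | None = None,
    detection_path: str | None = None,
    scale: str | None = None,
) -> ExpressionDataset:
    """Read an expression matrix TSV (plus optional annotations/detection).

    The scale tag is taken from a ``#scale=`` metadata line if present,
    overridden by the explicit ``scale`` argument; it defaults to "linear".
    """
    if not os.path.exists(path):
        raise FormatError(f"{path}: file not found")
    meta, n_meta = _read_metadata_lines(path)
    try:
        df = pd.read_csv(
            path, sep="\t", skiprows=n_meta, header=0, index_col=0,
            dtype=str, na_values=["NA"], keep_default_na=False,
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: unreadable TSV ({exc})") from exc
    if df.index.isnull().any():
        raise FormatError(f"{path}: empty feature id encountered")
    # numeric parsing with coordinates on failure
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isnull() & df[col].notnull()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        values[col] = converted
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique()
        raise FormatError(f"{path}: duplicate feature ids {list(dups[:5])}")
    values.index = values.index.str.upper()
    values = _collapse_duplicate_symbols(values, path)
    values.index.name = None
    values.columns.name = None

    annotations = None
    if annotations_path is not None:
        annotations = read_annotations_tsv(annotations_path)
    detection = None
    if detection_path is not None:
        detection = _read_detection_tsv(detection_path, values)
    tag = scale or meta.get("scale", "linear")
    try:
        return ExpressionDataset(values, tag, annotations, detection)
    except InputError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_detection_tsv(path: str, values: pd.DataFrame) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"{path}: file not found")
    _, n_meta = _read_metadata_lines(path)
    det = pd.read_csv(path, sep="\t", skiprows=n_meta, header=0, index_col=0)
    det.index = det.index.astype(str).str.upper()
    det = det[~det.index.duplicated()]
    det.index.name = None
    det.columns.name = None
    if not set(values.index).issubset(det.index) or list(det.columns) != list(values.columns):
        raise FormatError(f"{path}: detection matrix not aligned with value matrix")
    det = det.loc[values.index, values.columns]
    bad = ~det.isin([0, 1]).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: detection flag must be 0/1; found {det.iat[i, j]!r} "
            f"at row {det.index[i]!r}, column {det.columns[j]!r}"
        )
    return det.astype(bool)


def read_annotations_tsv(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"{path}: file not found")
    ann = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                      keep_default_na=False)
    if "sample_id" not in ann.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    if ann["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id rows")
    return ann.set_index("sample_id")


def write_expression_tsv(dataset: ExpressionDataset, path: str) -> None:
    """Write an expression matrix; inverse of :func:`read_expression_tsv`."""
    if dataset.n_samples == 0 or dataset.n_features == 0:
        raise InputError("refusing to write an empty expression matrix")
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#scale={dataset.scale}\n")
        dataset.values.to_csv(
            fh, sep="\t", index_label="feature_id", float_format=FLOAT_FMT,
            na_rep="NA", lineterminator="\n",
        )


def write_annotations_tsv(annotations: pd.DataFrame, path: str) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA",
                       lineterminator="\n")


def write_detection_tsv(detection: pd.DataFrame, path: str) -> None:
    detection.astype(int).to_csv(path, sep="\t", index_label="feature_id",
                                 lineterminator="\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members...)."""
    if not os.path.exists(path):
        raise FormatError(f"{path}: file not found")
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, found {len(fields)}"
                )
            name, desc, *members = fields
            members = [m.strip().upper() for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

def write_signature_tsv(signature: GeneSignature, path: str,
                        metadata_path: str | None = None) -> None:
    """Write a signature as TSV (gene, direction, weight) + JSON metadata."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tdirection\tweight\n")
        for gene, row in signature.entries.iterrows():
            fh.write(f"{gene}\t{int(row['direction'])}\t"
                     + (FLOAT_FMT % row["weight"]) + "\n")
    if metadata_path is not None:
        meta = {
            "name": signature.name,
            "time": signature.time,
            "fdr": signature.fdr,
            "fold": signature.fold,
            "n_genes": len(signature),
            "n_up": signature.n_up,
            "n_down": signature.n_down,
        }
        with open(metadata_path, "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_signature_tsv(path: str, name: str | None = None,
                       metadata_path: str | None = None) -> GeneSignature:
    if not os.path.exists(path):
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "direction", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["gene"].str.upper().duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    entries = pd.DataFrame(
        {"direction": df["direction"].astype(int).to_numpy(),
         "weight": df["weight"].astype(float).to_numpy()},
        index=pd.Index(list(df["gene"].str.upper())),
    )
    meta: dict = {}
    if metadata_path is not None and os.path.exists(metadata_path):
        with open(metadata_path, "rt", encoding="utf-8") as fh:
            meta = json.load(fh)
    return GeneSignature(
        name=name or meta.get("name", os.path.basename(path)),
        entries=entries,
        time=meta.get("time"),
        fdr=meta.get("fdr"),
        fold=meta.get("fold"),
    )


def write_json(obj, path: str) -> None:
    """Deterministic JSON dump (sorted keys, fixed separators)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)!r}")
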