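"""Reading and writing tabular datasets and mask files.

CSV: UTF-8, comma-separated, header row; an empty cell or ``NA`` is
missing; feature kinds are inferred (a column is numeric iff every
non-missing cell parses as a float).  ARFF: the standard WEKA dialect with
``?`` as missing; ``@attribute ... numeric`` vs ``{a,b,c}`` carries the
kind explicitly, so ARFF round trips preserve kinds exactly.

Mask files are plain text: line 1 the bitstring, following lines the
selected feature names.
"""

from __future__ import annotations

import csv
import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    NOMINAL,
    NUMERIC,
    Dataset,
    FeatureMask,
    InvalidInputError,
    dataset_from_frame,
)


class ParseError(ValueError):
    """Malformed input file; message carries the 1-based line number."""


def _split_label(frame: pd.DataFrame, label: str | None):
    if label is None or label not in frame.columns:
        if label is not None:
            raise InvalidInputError(f"label column {label!r} not found")
        return frame, None
    labels = frame[label].to_numpy(dtype=object)
    if pd.Series(labels).isna().any():
        raise ParseError(f"label column {label!r} contains missing values")
    return frame.drop(columns=[label]), labels


def read_csv(path, label: str | None = "label") -> Dataset:
    """Read a CSV dataset; ``label`` names the label column (None = none)."""
    frame = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=["", "NA"],
        skip_blank_lines=True,
    )
    feat, labels = _split_label(frame, label if label in frame.columns else None)
    return dataset_from_frame(feat, labels=labels)


def write_csv(ds: Dataset, path, label: str = "label") -> None:
    frame = ds.frame.copy()
    # full-precision reprs so numeric cells round-trip exactly
    for name, kind in zip(ds.feature_names, ds.feature_kinds):
        if kind == NUMERIC:
            frame[name] = [
                "" if pd.isna(v) else repr(float(v)) for v in frame[name]
            ]
    if ds.labels is not None:
        frame[label] = ds.labels
    frame.to_csv(path, index=False, na_rep="")


_ATTR_RE = re.compile(r"@attribute\s+(?:'([^']+)'|\"([^\"]+)\"|(\S+))\s+(.+)", re.I)


def read_arff(path, label: str | None = "label") -> Dataset:
    """Read a WEKA-dialect ARFF file."""
    names: list[str] = []
    kinds: list[str] = []
    categories: list[list | None] = []
    rows: list[list] = []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if not in_data:
                if low.startswith("@relation"):
                    continue
                if low.startswith("@attribute"):
                    m = _ATTR_RE.match(line)
                    if not m:
                        raise ParseError(f"line {lineno}: bad @attribute: {line}")
                    name = next(g for g in m.groups()[:3] if g is not None)
                    decl = m.group(4).strip()
                    names.append(name)
                    if decl.startswith("{"):
                        if not decl.endswith("}"):
                            raise ParseError(
                                f"line {lineno}: unterminated nominal spec"
                            )
                        cats = [
                            c.strip().strip("'\"")
                            for c in decl[1:-1].split(",")
                            if c.strip()
                        ]
                        kinds.append(NOMINAL)
                        categories.append(cats)
                    elif decl.lower() in ("numeric", "real", "integer"):
                        kinds.append(NUMERIC)
                        categories.append(None)
                    else:
                        # string/date and friends are treated as nominal
                        kinds.append(NOMINAL)
                        categories.append(None)
                    continue
                if low.startswith("@data"):
                    in_data = True
                    continue
                raise ParseError(f"line {lineno}: unexpected header line: {line}")
            else:
                parsed = next(csv.reader([line], skipinitialspace=True))
                if len(parsed) != len(names):
                    raise ParseError(
                        f"line {lineno}: {len(parsed)} values for "
                        f"{len(names)} attributes"
                    )
                rows.append([
                    np.nan if v.strip() == "?" else v.strip().strip("'\"")
                    for v in parsed
                ])
    if not names:
        raise ParseError("line 1: no @attribute declarations found")
    frame = pd.DataFrame(rows, columns=names, dtype=object)
    lab = None
    classes = None
    if label is not None and label in names:
        j = names.index(label)
        lab = frame[label].to_numpy(dtype=object)
        if pd.Series(lab).isna().any():
            raise ParseError(f"label column {label!r} contains missing values")
        classes = categories[j]  # declared order carries the class order
        frame = frame.drop(columns=[label])
        del names[j], kinds[j], categories[j]
    return dataset_from_frame(frame, labels=lab, classes=classes, feature_kinds=kinds)


def _arff_quote(token: str) -> str:
    s = str(token)
    if re.search(r"[\s,{}'\"%]", s) or s == "?":
        return "'" + s.replace("'", r"\'") + "'"
    return s


def write_arff(ds: Dataset, path, relation: str = "dataset", label: str = "label") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@relation {_arff_quote(relation)}\n\n")
        for name, kind in zip(ds.feature_names, ds.feature_kinds):
            if kind == NUMERIC:
                fh.write(f"@attribute {_arff_quote(name)} numeric\n")
            else:
                cats = sorted(
                    {str(v) for v in ds.frame[name].dropna()}
                )
                decl = "{" + ",".join(_arff_quote(c) for c in cats) + "}"
                fh.write(f"@attribute {_arff_quote(name)} {decl}\n")
        if ds.labels is not None:
            classes = [str(c) for c in ds.classes]
            decl = "{" + ",".join(_arff_quote(c) for c in classes) + "}"
            fh.write(f"@attribute {_arff_quote(label)} {decl}\n")
        fh.write("\n@data\n")
        lab = ds.labels
        for i in range(ds.n_instances):
            cells = []
            for name, kind in zip(ds.feature_names, ds.feature_kinds):
                v = ds.frame.at[i, name]
                if pd.isna(v):
                    cells.append("?")
                elif kind == NUMERIC:
                    cells.append(repr(float(v)))
                else:
                    cells.append(_arff_quote(v))
            if lab is not None:
                cells.append(_arff_quote(lab[i]))
            fh.write(",".join(cells) + "\n")


def read_table(path, format: str | None = None, label: str | None = "label") -> Dataset:
    """Dispatch on ``format`` or the file extension (.csv / .arff)."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "csv":
        return read_csv(path, label=label)
    if fmt == "arff":
        return read_arff(path, label=label)
    raise InvalidInputError(f"unknown table format {fmt!r}")


def write_table(ds: Dataset, path, format: str | None = None, label: str = "label") -> None:
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "csv":
        write_csv(ds, path, label=label)
    elif fmt == "arff":
        write_arff(ds, path, label=label)
    else:
        raise InvalidInputError(f"unknown table format {fmt!r}")


def write_mask(path, mask: FeatureMask, feature_names) -> None:
    """Line 1: the bitstring; then one selected feature name per line."""
    if len(mask) != len(feature_names):
        raise InvalidInputError("mask length does not match feature names")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(mask.to_bitstring() + "\n")
        for j in mask.indices():
            fh.write(str(feature_names[j]) + "\n")


def read_mask(path) -> tuple[FeatureMask, list[str]]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not set(lines[0]) <= {"0", "1"}:
        raise ParseError("line 1: expected a 0/1 bitstring")
    mask = FeatureMask.from_bitstring(lines[0])
    names = [ln for ln in lines[1:] if ln]
    return mask, names
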