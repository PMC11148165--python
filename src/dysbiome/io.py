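"""Reading and writing the pipeline's tab-separated table formats.

All writers emit a leading ``# dysbiome-<kind>-v1`` comment so files are
self-describing; readers tolerate (and skip) any leading ``#`` comment lines.
TSV is canonical: UTF-8, tab-delimited, ``.`` decimal separator. Count
parsing is strict — a negative or fractional cell is an error naming the
offending sample and taxon, never silently coerced.

The compartment-specific dysbiosis-index coefficient tables published with
the source cohort study are packaged verbatim under
``dysbiome/data/dysbiosis_index`` and loaded with :func:`load_paper_model`.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    COMPARTMENTS,
    CountTable,
    FormatError,
    validate_annotations,
    validate_metadata,
)
from .dysbiosis import DysbiosisIndexModel

FORMAT_VERSION = "v1"

_TRANSPOSED_FIRST_HEADERS = {"taxon", "taxon_id", "genus", "otu", "otu_id", "asv"}


def _version_line(kind: str) -> str:
    return f"# dysbiome-{kind}-{FORMAT_VERSION}"


def write_count_table(table: CountTable, path: str | Path) -> None:
    path = Path(path)
    tag = f"\tcompartment={table.compartment}" if table.compartment else ""
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_version_line("counts") + tag + "\n")
        fh.write("sample_id\t" + "\t".join(table.taxon_ids) + "\n")
        for sid, row in zip(table.sample_ids, table.counts):
            fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_count_table(path: str | Path, compartment: str | None = None) -> CountTable:
    """Read a samples × taxa TSV of integer counts.

    The first header cell is the sample-id column name; the remaining header
    cells are taxon ids. A header starting with a taxon-like column name
    (``taxon_id``, ``genus``, ...) is rejected as transposed rather than
    silently flipped.
    """
    path = Path(path)
    header: list[str] | None = None
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    file_compartment: str | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.split("\t"):
                    if tok.startswith("compartment="):
                        file_compartment = tok.split("=", 1)[1]
                continue
            cells = line.split("\t")
            if header is None:
                if cells[0].strip().lower() in _TRANSPOSED_FIRST_HEADERS:
                    raise FormatError(
                        f"{path}: header starts with {cells[0]!r} — table looks "
                        "transposed (taxa in rows); expected samples in rows"
                    )
                header = cells
                continue
            if len(cells) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            sample_ids.append(cells[0])
            parsed = []
            for taxon, cell in zip(header[1:], cells[1:]):
                try:
                    value = int(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: count for sample {cells[0]!r}, taxon "
                        f"{taxon!r} is {cell!r} — counts must be integers"
                    ) from None
                if value < 0:
                    raise FormatError(
                        f"{path}:{lineno}: count for sample {cells[0]!r}, taxon "
                        f"{taxon!r} is {value} — counts must be non-negative"
                    )
                parsed.append(value)
            rows.append(parsed)
    if header is None:
        raise FormatError(f"{path}: empty count table (no header row)")
    return CountTable(
        counts=np.asarray(rows, dtype=np.int64).reshape(len(rows), len(header) - 1),
        sample_ids=sample_ids,
        taxon_ids=header[1:],
        compartment=compartment or file_compartment,
    )


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_version_line("metadata") + "\n")
        meta.to_csv(fh, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "subject_id": str})
    return validate_metadata(meta)


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    validate_annotations(ann)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_version_line("annotations") + "\n")
        ann.to_csv(fh, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a taxon-annotation TSV (oxygen / pathogenicity / origin classes).

    An empty file (header only, or nothing at all) yields an empty frame with
    a warning; any category string outside the closed vocabularies is an
    error listing the allowed values.
    """
    try:
        ann = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        ann = pd.DataFrame(columns=["taxon_id", "oxygen_class", "pathogenicity_class", "origin_compartment"])
    if len(ann) == 0:
        warnings.warn(f"{path}: no taxon annotations found", stacklevel=2)
        if ann.shape[1] == 0:
            ann = pd.DataFrame(
                columns=["taxon_id", "oxygen_class", "pathogenicity_class", "origin_compartment"]
            )
        return validate_annotations(ann)
    if "taxon_id" not in ann.columns:
        raise FormatError(f"{path}: annotation table is missing the 'taxon_id' column")
    return validate_annotations(ann)


# ---------------------------------------------------------------------------
# dysbiosis-index coefficient tables
# ---------------------------------------------------------------------------

def read_coefficient_table(path: str | Path) -> pd.DataFrame:
    """Read a coefficient TSV with columns term / b1 / b2.

    ``b1`` is the Intermediate-vs-High log-odds coefficient vector, ``b2``
    the Low-vs-High one. Exactly one ``Intercept`` row is required and term
    names must be unique.
    """
    coef = pd.read_csv(path, sep="\t", comment="#", dtype={"term": str})
    missing = [c for c in ("term", "b1", "b2") if c not in coef.columns]
    if missing:
        raise FormatError(f"{path}: coefficient table missing columns {missing}")
    if list(coef["term"]).count("Intercept") != 1:
        raise FormatError(f"{path}: coefficient table must have exactly one Intercept row")
    if coef["term"].duplicated().any():
        dups = sorted(coef.loc[coef["term"].duplicated(), "term"])
        raise FormatError(f"{path}: duplicate coefficient terms {dups}")
    return coef


def _model_from_coefficients(coef: pd.DataFrame, compartment: str, feature_space: dict) -> DysbiosisIndexModel:
    intercept = coef["term"] == "Intercept"
    features = coef.loc[~intercept]
    return DysbiosisIndexModel(
        compartment=compartment,
        feature_names=list(features["term"]),
        b1=np.concatenate([coef.loc[intercept, "b1"].to_numpy(float), features["b1"].to_numpy(float)]),
        b2=np.concatenate([coef.loc[intercept, "b2"].to_numpy(float), features["b2"].to_numpy(float)]),
        feature_space=feature_space,
    )


def load_paper_model(compartment: str) -> DysbiosisIndexModel:
    """Load the packaged published dysbiosis-index model for a compartment.

    The oral model has an intercept plus 7 taxon terms; the lung model an
    intercept, the Shannon index, and 11 taxon terms; the gut model an
    intercept, the Shannon index, and 5 taxon terms. Taxon terms are matched
    exactly on the published spellings (e.g. ``Pasteurellaceae_uncl``);
    remapping of caller taxon names is the caller's responsibility.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}")
    ref = resources.files("dysbiome.data.dysbiosis_index") / f"{compartment}.tsv"
    with resources.as_file(ref) as path:
        coef = read_coefficient_table(path)
    feature_space = {
        "clr_pseudocount": 0.5,
        "shannon_variant": "rarefied_mean",
        "taxon_feature": "clr_abundance",
        "source": "published_coefficients",
    }
    return _model_from_coefficients(coef, compartment, feature_space)


def write_model(model: DysbiosisIndexModel, path: str | Path) -> None:
    payload = {
        "format": f"dysbiome-model-{FORMAT_VERSION}",
        "compartment": model.compartment,
        "feature_names": model.feature_names,
        "b1": [float(v) for v in model.b1],
        "b2": [float(v) for v in model.b2],
        "feature_space": model.feature_space,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_model(path: str | Path) -> DysbiosisIndexModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return DysbiosisIndexModel(
        compartment=payload["compartment"],
        feature_names=list(payload["feature_names"]),
        b1=np.asarray(payload["b1"], dtype=float),
        b2=np.asarray(payload["b2"], dtype=float),
        feature_space=payload.get("feature_space", {}),
    )


def write_distance_matrix(sample_ids: list[str], matrix: np.ndarray, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_version_line("distances") + "\n")
        fh.write("sample_id\t" + "\t".join(sample_ids) + "\n")
        for sid, row in zip(sample_ids, matrix):
            fh.write(sid + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")
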