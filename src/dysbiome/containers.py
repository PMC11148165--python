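"""Core in-memory containers for multicompartment microbiome analysis.

The unit of data every stage consumes is a :class:`CountTable`: a
samples-by-taxa matrix of non-negative integer 16S read counts at the genus
level, tagged with the body compartment it was sampled from (oral cavity,
lung, or gut). Sample metadata and taxon annotations are carried as validated
:class:`pandas.DataFrame` objects with closed category vocabularies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("oral", "lung", "gut")
INTERVALS = ("baseline", "middle", "late")
SPECIMEN_TYPES = ("oral_swab", "ETA", "BAL", "rectal_swab", "stool")
OXYGEN_CLASSES = (
    "obligate_anaerobe",
    "aerobe",
    "facultative_anaerobe",
    "microaerophile",
    "variable",
    "unclassifiable",
)
PATHOGENICITY_CLASSES = ("respiratory_pathogen", "oral_commensal", "other")
ORIGIN_COMPARTMENTS = ("oral", "gut", "either")

#: Required columns of a sample-metadata frame.
METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "compartment",
    "interval",
    "day_from_intubation",
    "specimen_type",
    "soiled_flag",
    "qpcr_copies",
)

#: Required columns of a taxon-annotation frame.
ANNOTATION_COLUMNS = ("taxon_id", "oxygen_class", "pathogenicity_class", "origin_compartment")


class FormatError(ValueError):
    """Raised when an on-disk or in-memory table violates a format invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CountTable:
    """Samples × taxa non-negative integer count matrix.

    Parameters
    ----------
    counts
        ``(n_samples, n_taxa)`` integer array of reads.
    sample_ids, taxon_ids
        Ordered, unique identifiers for the rows and columns.
    compartment
        Body compartment the samples come from (``oral``/``lung``/``gut``),
        or ``None`` for mixed or unspecified tables.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    compartment: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D samples × taxa matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples × {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise FormatError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized composition; rows with zero depth stay all-zero."""
        depth = self.total_counts().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / depth[:, None]
        rel[depth == 0, :] = 0.0
        return rel

    # -- subsetting -----------------------------------------------------
    def select_samples(self, keep: Iterable[str]) -> "CountTable":
        keep = list(keep)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in keep]
        return replace(self, counts=self.counts[rows], sample_ids=keep)

    def select_taxa(self, keep: Iterable[str]) -> "CountTable":
        keep = list(keep)
        index = {t: j for j, t in enumerate(self.taxon_ids)}
        missing = [t for t in keep if t not in index]
        if missing:
            raise KeyError(f"unknown taxon ids: {missing[:5]}")
        cols = [index[t] for t in keep]
        return replace(self, counts=self.counts[:, cols], taxon_ids=keep)

    # -- pandas bridge --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, compartment: str | None = None) -> "CountTable":
        return cls(
            counts=frame.to_numpy(),
            sample_ids=list(frame.index.astype(str)),
            taxon_ids=list(frame.columns.astype(str)),
            compartment=compartment,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and self.compartment == other.compartment
            and np.array_equal(self.counts, other.counts)
        )


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame against the closed vocabularies.

    Returns the frame (with ``sample_id`` as a column, not index). Extra
    columns — e.g. biomarker concentrations — are allowed and preserved.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    _check_unique(list(meta["sample_id"].astype(str)), "sample")
    bad = set(meta["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise FormatError(f"unknown compartment values {sorted(bad)}; allowed: {COMPARTMENTS}")
    bad = set(meta["interval"]) - set(INTERVALS)
    if bad:
        raise FormatError(f"unknown interval values {sorted(bad)}; allowed: {INTERVALS}")
    bad = set(meta["specimen_type"]) - set(SPECIMEN_TYPES)
    if bad:
        raise FormatError(f"unknown specimen types {sorted(bad)}; allowed: {SPECIMEN_TYPES}")
    if (meta["qpcr_copies"].astype(float) < 0).any():
        raise FormatError("qpcr_copies must be non-negative")
    return meta


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a taxon-annotation frame (oxygen / pathogenicity / origin)."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotations missing required columns: {missing}")
    _check_unique(list(ann["taxon_id"].astype(str)), "taxon")
    for col, allowed in (
        ("oxygen_class", OXYGEN_CLASSES),
        ("pathogenicity_class", PATHOGENICITY_CLASSES),
        ("origin_compartment", ORIGIN_COMPARTMENTS),
    ):
        bad = set(ann[col]) - set(allowed)
        if bad:
            raise FormatError(f"unknown {col} values {sorted(bad)}; allowed values: {allowed}")
    return ann
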