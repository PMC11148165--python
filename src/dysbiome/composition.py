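"""Clinically motivated composition summaries.

Taxa are aggregated by two annotation schemes — oxygen requirement (obligate
anaerobes, aerobes, facultative anaerobes, microaerophiles, variable,
unclassifiable) and plausible respiratory pathogenicity (respiratory
pathogens, oral commensals, other) — because anaerobe depletion and pathogen
enrichment are the composition-level signatures of ICU dysbiosis. Two
per-sample flags capture the cohort's ecological events of interest:
gut-origin enrichment (>30% relative abundance of gut-origin taxa in an
oral/lung sample) and single-taxon dominance (>50%). Both cutoffs are
strict inequalities.

Class CLR aggregates are computed by CLR-transforming the class-summed
composition, not by summing per-taxon CLR values (CLR is not additive).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    CountTable,
    OXYGEN_CLASSES,
    PATHOGENICITY_CLASSES,
    validate_annotations,
)

_SCHEMES = {
    "oxygen": ("oxygen_class", OXYGEN_CLASSES, "unclassifiable"),
    "pathogenicity": ("pathogenicity_class", PATHOGENICITY_CLASSES, "other"),
}


def filter_low_abundance(
    table: CountTable, rel_min: float = 1e-4, prevalence_min: float = 0.05
) -> CountTable:
    """Drop singleton taxa and taxa that never reach abundance in enough samples.

    A taxon is kept iff its total count exceeds 1 and it attains relative
    abundance >= ``rel_min`` in at least ``prevalence_min`` of samples. The
    operation is idempotent.
    """
    rel = table.relative_abundance()
    totals = table.counts.sum(axis=0)
    prevalence = (rel >= rel_min).mean(axis=0)
    keep = (totals > 1) & (prevalence >= prevalence_min)
    if not keep.any():
        raise ValueError("low-abundance filter removed every taxon")
    return table.select_taxa([t for t, k in zip(table.taxon_ids, keep) if k])


def aggregate_class_abundance(
    table: CountTable,
    annotations: pd.DataFrame,
    scheme: str = "oxygen",
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample class-level relative abundances and CLR aggregates.

    Returns ``(shares, clr)``: both frames are samples × classes; shares sum
    to 1 per sample (the classes partition the taxa). Unannotated taxa fall
    into the scheme's catch-all bucket with a warning.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(_SCHEMES)}")
    column, classes, bucket = _SCHEMES[scheme]
    validate_annotations(annotations)
    lookup = annotations.set_index("taxon_id")[column]
    missing = [t for t in table.taxon_ids if t not in lookup.index]
    if missing:
        warnings.warn(
            f"{len(missing)} taxa lack annotations; assigning them to {bucket!r}",
            stacklevel=2,
        )
    taxon_class = np.array([lookup.get(t, bucket) for t in table.taxon_ids])
    rel = table.relative_abundance()
    shares = pd.DataFrame(
        {c: rel[:, taxon_class == c].sum(axis=1) for c in classes}, index=table.sample_ids
    )
    class_counts = np.column_stack(
        [table.counts[:, taxon_class == c].sum(axis=1) for c in classes]
    )
    log = np.log(class_counts + pseudocount)
    clr = pd.DataFrame(
        log - log.mean(axis=1, keepdims=True), index=table.sample_ids, columns=classes
    )
    return shares, clr


def gut_origin_enrichment(
    rel_abundance: np.ndarray | pd.Series,
    annotations: pd.DataFrame,
    taxon_ids: list[str] | None = None,
    threshold: float = 0.30,
) -> bool:
    """True iff gut-origin taxa hold strictly more than ``threshold`` of the sample."""
    if isinstance(rel_abundance, pd.Series):
        taxon_ids = list(rel_abundance.index)
        rel_abundance = rel_abundance.to_numpy(dtype=float)
    if taxon_ids is None:
        raise ValueError("taxon_ids required when rel_abundance is a bare array")
    origin = annotations.set_index("taxon_id")["origin_compartment"]
    mask = np.array([origin.get(t, "either") == "gut" for t in taxon_ids])
    return bool(rel_abundance[mask].sum() > threshold)


def dominance_flag(
    rel_abundance: np.ndarray | pd.Series,
    taxon_id: str,
    taxon_ids: list[str] | None = None,
    threshold: float = 0.50,
) -> bool:
    """True iff one taxon holds strictly more than ``threshold`` of the sample."""
    if isinstance(rel_abundance, pd.Series):
        taxon_ids = list(rel_abundance.index)
        rel_abundance = rel_abundance.to_numpy(dtype=float)
    if taxon_ids is None or taxon_id not in taxon_ids:
        raise KeyError(f"taxon {taxon_id!r} not present in the table")
    return bool(rel_abundance[taxon_ids.index(taxon_id)] > threshold)


def biomarker_correlations(
    clr: pd.DataFrame, biomarkers: pd.DataFrame, min_pairs: int = 3
) -> pd.DataFrame:
    """Pairwise Pearson correlations between taxa CLR values and biomarkers.

    Complete-case per pair; Benjamini-Hochberg adjustment across all defined
    pairs. Constant biomarkers (or too few paired observations) are reported
    with NaN statistics and excluded from the adjustment.
    """
    shared = clr.index.intersection(biomarkers.index)
    rows = []
    for taxon in clr.columns:
        for marker in biomarkers.columns:
            x = clr.loc[shared, taxon].astype(float)
            y = biomarkers.loc[shared, marker].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < min_pairs or np.isclose(y[ok].std(ddof=0), 0) or np.isclose(
                x[ok].std(ddof=0), 0
            ):
                rows.append((taxon, marker, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append((taxon, marker, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["taxon", "biomarker", "r", "p"])
    out["p_adj"] = np.nan
    defined = out["p"].notna()
    if defined.any():
        out.loc[defined, "p_adj"] = multipletests(out.loc[defined, "p"], method="fdr_bh")[1]
    return out
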