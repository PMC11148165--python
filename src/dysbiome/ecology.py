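"""Community-ecology primitives: QC, diversity, ordination, and PERMANOVA.

The conventions follow the 16S analysis the package reproduces: samples with
fewer than 1000 high-quality reads are dropped; alpha diversity is the
Shannon index (natural log) averaged over 100 random rarefactions to 1000
reads; compositions are centered-log-ratio (CLR) transformed with a 0.5
pseudocount; beta diversity is Bray-Curtis, ordinated by principal
coordinates and compared by permutational ANOVA with Bonferroni correction.

Bray-Curtis on raw CLR values is ill-defined (CLR values are negative), so
the default mode operates on relative abundances; a ``clr_shifted`` mode
that min-shifts the CLR matrix to non-negative values is provided for
compatibility with pipelines that compute it that way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import CountTable


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removals: list[tuple[str, str]] = field(default_factory=list)  # (sample_id, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removals, columns=["sample_id", "reason"])


@dataclass
class DiversityResult:
    sample_id: str
    mean_shannon: float
    depth: int
    n_subsamples: int


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with sample ids")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric within 1e-12")
        np.fill_diagonal(self.matrix, 0.0)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int


def qc_filter(
    table: CountTable,
    metadata: pd.DataFrame | None = None,
    min_reads: int = 1000,
) -> tuple[CountTable, QCReport]:
    """Drop low-depth samples and, for the gut compartment, unsoiled swabs.

    A sample is retained when its read total is ``>= min_reads`` (the
    threshold is inclusive). Gut samples flagged ``soiled_flag == False`` in
    the metadata are removed regardless of depth because unsoiled rectal
    swabs under-represent gut microbiota.
    """
    depth = table.total_counts()
    removals: list[tuple[str, str]] = []
    keep: list[str] = []
    soiled: dict[str, bool] = {}
    compartment_of: dict[str, str] = {}
    if metadata is not None:
        meta = metadata.set_index(metadata["sample_id"].astype(str))
        missing = [s for s in table.sample_ids if s not in meta.index]
        if missing:
            raise ValueError(f"metadata does not cover samples: {missing[:5]}")
        soiled = meta["soiled_flag"].astype(bool).to_dict()
        compartment_of = meta["compartment"].astype(str).to_dict()
    for sid, n in zip(table.sample_ids, depth):
        comp = compartment_of.get(sid, table.compartment)
        if comp == "gut" and metadata is not None and not soiled.get(sid, True):
            removals.append((sid, "unsoiled"))
        elif n < min_reads:
            removals.append((sid, f"low_depth<{min_reads}"))
        else:
            keep.append(sid)
    if not keep:
        raise ValueError("no samples passed QC")
    report = QCReport(n_input=table.n_samples, n_retained=len(keep), removals=removals)
    return table.select_samples(keep), report


def shannon_index(counts: np.ndarray) -> float:
    """Shannon entropy (nats) of one count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def rarefied_shannon(
    counts: np.ndarray,
    depth: int = 1000,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    sample_id: str = "",
) -> DiversityResult:
    """Mean Shannon index over repeated rarefactions of one sample.

    Subsampling is without replacement (multivariate hypergeometric), so a
    sample whose total equals ``depth`` is returned unchanged by every
    rarefaction. The caller must QC first: totals below ``depth`` are an
    error rather than silently skipped.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("rarefied_shannon operates on one sample's count vector")
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample total {total} < rarefaction depth {depth}; QC filter first")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(counts.astype(np.int64), depth, size=reps)
    p = sub / depth
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    values = -plogp.sum(axis=1)
    return DiversityResult(
        sample_id=sample_id,
        mean_shannon=float(values.mean()),
        depth=depth,
        n_subsamples=reps,
    )


def shannon_table(
    table: CountTable, depth: int = 1000, reps: int = 100, seed: int = 0
) -> pd.Series:
    """Per-sample rarefied Shannon indices (independent substream per sample)."""
    rng = np.random.default_rng(seed)
    out = {
        sid: rarefied_shannon(row, depth=depth, reps=reps, seed=rng, sample_id=sid).mean_shannon
        for sid, row in zip(table.sample_ids, table.counts)
    }
    return pd.Series(out, name="shannon")


def clr_transform(table: CountTable | np.ndarray, pseudocount: float = 0.5):
    """Centered log-ratio transform with additive pseudocount.

    Each row x maps to ``ln(x + c) - mean_t ln(x + c)``; rows therefore sum
    to zero. Given a :class:`CountTable` the result is a labeled DataFrame,
    given an array a plain array.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = table.counts if isinstance(table, CountTable) else np.asarray(table)
    logx = np.log(counts + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    if isinstance(table, CountTable):
        return pd.DataFrame(clr, index=table.sample_ids, columns=table.taxon_ids)
    return clr


def bray_curtis(
    abundance: np.ndarray | pd.DataFrame,
    mode: str = "relative",
    sample_ids: list[str] | None = None,
) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities, d = Σ|x−y| / Σ(x+y)."""
    if isinstance(abundance, pd.DataFrame):
        sample_ids = sample_ids or list(abundance.index.astype(str))
        abundance = abundance.to_numpy(dtype=float)
    else:
        abundance = np.asarray(abundance, dtype=float)
        sample_ids = sample_ids or [f"S{i}" for i in range(abundance.shape[0])]
    if mode == "relative":
        if np.any(abundance < 0):
            raise ValueError("relative mode requires non-negative abundances")
    elif mode == "clr_shifted":
        abundance = abundance - abundance.min()
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'relative' or 'clr_shifted'")
    d = squareform(pdist(abundance, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # all-zero rows give 0/0; treat as identical
    return DistanceMatrix(sample_ids=sample_ids, matrix=d)


def pcoa(d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates by Gower double-centering of ``-d²/2``.

    Returns coordinates for the positive eigenvalues (columns sorted by
    descending eigenvalue) and the full eigenvalue spectrum, negative values
    included (reported, not corrected).
    """
    n = len(d.sample_ids)
    a = -0.5 * d.matrix**2
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-10, 1e-10 * abs(eigvals[0]) if n else 0.0)
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    return coords, eigvals


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(among-group SS, within-group SS) of the distance decomposition."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        block = d2[np.ix_(members, members)]
        ss_within += block[np.triu_indices(len(members), k=1)].sum() / len(members)
    return ss_total - ss_within, ss_within


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss_among, ss_within = _permanova_ss(d2, codes, n_groups)
    n = d2.shape[0]
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    The p-value uses the add-one permutation convention,
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``, so p is always in
    (0, 1].
    """
    labels = np.asarray(labels)
    if len(labels) != len(d.sample_ids):
        raise ValueError("labels length must match distance matrix")
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if np.min(np.bincount(codes)) < 2:
        raise ValueError("each group needs at least two samples")
    d2 = d.matrix**2
    n = d2.shape[0]
    ss_among, ss_within = _permanova_ss(d2, codes, len(groups))
    f_obs = (ss_among / (len(groups) - 1)) / (ss_within / (n - len(groups)))
    r2 = ss_among / (ss_among + ss_within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, len(groups)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p=float(p), n_permutations=n_perm)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, m·p)."""
    p_values = list(p_values)
    m = m if m is not None else len(p_values)
    return [min(1.0, m * p) for p in p_values]
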