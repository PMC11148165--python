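"""Compartment-specific Dysbiosis Index: a multinomial-logit cluster classifier.

The index maps a sample's CLR-transformed taxon abundances (and optionally
its Shannon index) to probabilities of membership in the High-, Intermediate-
and Low-Diversity DMM clusters. With High-Diversity as the reference
category and linear predictors

    X = exp(b1 · [1, f]),   Y = exp(b2 · [1, f]),

the class probabilities are P(H) = 1/(1+X+Y), P(I) = X/(1+X+Y) and
P(L) = Y/(1+X+Y); the predicted cluster is the argmax. Evaluation is
overflow-safe via log-sum-exp, which is algebraically identical.

Feature selection approximates the Markov blanket of the cluster label by
stability selection: L1-penalized multinomial fits on repeated subsamples,
keeping features selected in at least 70% of fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logsumexp
from scipy.stats import beta, f_oneway
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

CLASS_ORDER = ("High", "Intermediate", "Low")
#: argmax ties resolve toward the clinically conservative end
_TIE_ORDER = ("Low", "Intermediate", "High")


@dataclass
class DysbiosisIndexModel:
    compartment: str
    feature_names: list[str]
    b1: np.ndarray  # Intercept + per-feature, Intermediate vs High
    b2: np.ndarray  # Intercept + per-feature, Low vs High
    feature_space: dict = field(default_factory=dict)
    ridge_refit: bool = False

    def __post_init__(self) -> None:
        self.b1 = np.asarray(self.b1, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        expected = len(self.feature_names) + 1
        if self.b1.shape != (expected,) or self.b2.shape != (expected,):
            raise ValueError("coefficient vectors must align to Intercept + feature_names")
        if not (np.all(np.isfinite(self.b1)) and np.all(np.isfinite(self.b2))):
            raise ValueError("coefficients must be finite")


@dataclass
class ClusterPrediction:
    p_high: float
    p_intermediate: float
    p_low: float
    label: str


def _align_features(model: DysbiosisIndexModel, features, fill_missing: bool) -> np.ndarray:
    if isinstance(features, dict):
        features = pd.Series(features)
    if isinstance(features, pd.Series):
        missing = [f for f in model.feature_names if f not in features.index]
        if missing and not fill_missing:
            raise KeyError(
                f"features missing for model terms {missing}; pass fill_missing=True "
                "to zero-fill deliberately"
            )
        vec = np.array([float(features.get(f, 0.0)) for f in model.feature_names])
    else:
        vec = np.asarray(features, dtype=float)
        if vec.shape != (len(model.feature_names),):
            raise ValueError(
                f"expected {len(model.feature_names)} features in model order, got shape {vec.shape}"
            )
    if np.any(np.isnan(vec)):
        raise ValueError("NaN feature value passed to predict")
    return vec


def predict(
    model: DysbiosisIndexModel, features, fill_missing: bool = False
) -> ClusterPrediction:
    """Closed-form class probabilities for one sample.

    ``features`` may be a dict/Series keyed by feature name (order-free) or
    an array already aligned to ``model.feature_names``.
    """
    f = _align_features(model, features, fill_missing)
    eta1 = model.b1[0] + model.b1[1:] @ f
    eta2 = model.b2[0] + model.b2[1:] @ f
    logits = np.array([0.0, eta1, eta2])
    log_p = logits - logsumexp(logits)
    p_high, p_inter, p_low = np.exp(log_p)
    probs = {"High": p_high, "Intermediate": p_inter, "Low": p_low}
    best = max(_TIE_ORDER, key=lambda c: probs[c])  # first max in tie order wins
    return ClusterPrediction(
        p_high=float(p_high), p_intermediate=float(p_inter), p_low=float(p_low), label=best
    )


def predict_table(
    model: DysbiosisIndexModel, features: pd.DataFrame, fill_missing: bool = False
) -> pd.DataFrame:
    """Per-sample probabilities and labels for a feature matrix (rows = samples)."""
    rows = []
    for sid, row in features.iterrows():
        pred = predict(model, row, fill_missing=fill_missing)
        rows.append((sid, pred.p_high, pred.p_intermediate, pred.p_low, pred.label))
    return pd.DataFrame(
        rows, columns=["sample_id", "P_high", "P_intermediate", "P_low", "label"]
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# derivation: top taxa, split, selection, fitting, evaluation
# ---------------------------------------------------------------------------

def top_taxa(table, n: int = 50, by: str = "relative") -> list[str]:
    """Top-n taxa ranked by mean relative abundance (or mean CLR value)."""
    from .ecology import clr_transform  # local import to avoid cycle at module load

    if by == "relative":
        score = table.relative_abundance().mean(axis=0)
    elif by == "clr":
        score = clr_transform(table).to_numpy().mean(axis=0)
    else:
        raise ValueError("by must be 'relative' or 'clr'")
    order = np.argsort(-score, kind="stable")[: min(n, table.n_taxa)]
    return [table.taxon_ids[j] for j in order]


def stratified_split(
    labels, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seed-reproducible stratified train/test index split."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def select_features(
    features: pd.DataFrame,
    labels,
    alpha: float = 0.1,
    method: str = "mb_surrogate",
    n_subsamples: int = 50,
    subsample_fraction: float = 0.5,
    threshold: float = 0.7,
    C: float = 0.2,
    seed: int = 0,
) -> list[str]:
    """Select the features informative for the 3-class cluster label.

    Default ``mb_surrogate`` performs stability selection over L1-penalized
    multinomial logistic fits on standardized features: a feature is kept if
    it receives a nonzero coefficient in at least ``threshold`` of
    ``n_subsamples`` half-sample fits. The ``ci_tests`` alternative keeps
    features whose one-way ANOVA association with the label is significant
    at level ``alpha`` both marginally and after residualizing on the
    strongest selected feature (a pairwise conditional-independence screen).
    """
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("labels are degenerate: need >= 2 classes to select features")
    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    if method == "mb_surrogate":
        rng = np.random.default_rng(seed)
        Xs = StandardScaler().fit_transform(X)
        hits = np.zeros(X.shape[1])
        n = X.shape[0]
        m = max(10, int(round(subsample_fraction * n)))
        for _ in range(n_subsamples):
            idx = rng.choice(n, size=m, replace=False)
            while len(np.unique(y[idx])) < len(classes):
                idx = rng.choice(n, size=m, replace=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf = LogisticRegression(
                    penalty="l1", C=C, solver="saga", max_iter=500, tol=1e-3,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                clf.fit(Xs[idx], y[idx])
            hits += (np.abs(clf.coef_) > 1e-8).any(axis=0)
        freq = hits / n_subsamples
        selected = [names[j] for j in range(len(names)) if freq[j] >= threshold]
    elif method == "ci_tests":
        pvals = np.array(
            [f_oneway(*(X[y == g, j] for g in range(len(classes)))).pvalue for j in range(X.shape[1])]
        )
        marginal = np.flatnonzero(pvals < alpha)
        if len(marginal) == 0:
            return []
        anchor = marginal[np.argmin(pvals[marginal])]
        selected = [names[anchor]]
        xa = X[:, anchor]
        xa_design = np.column_stack([np.ones_like(xa), xa])
        for j in marginal:
            if j == anchor:
                continue
            resid = X[:, j] - xa_design @ np.linalg.lstsq(xa_design, X[:, j], rcond=None)[0]
            p_cond = f_oneway(*(resid[y == g] for g in range(len(classes)))).pvalue
            if p_cond < alpha:
                selected.append(names[j])
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return selected


def _check_design(X: np.ndarray, names: list[str]) -> None:
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR fingers the dependent columns
        from scipy.linalg import qr

        _, r, piv = qr(design, pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [piv[i] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        cols = ["Intercept" if i == 0 else names[i - 1] for i in bad]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {cols}")


def fit_mlr(
    features: pd.DataFrame,
    labels,
    reference: str = "High",
    compartment: str = "lung",
    feature_space: dict | None = None,
) -> DysbiosisIndexModel:
    """Maximum-likelihood multinomial logit with High-Diversity reference.

    On quasi-separation (non-convergence or runaway coefficients) the model
    is refit with a small ridge penalty and flagged ``ridge_refit``.
    """
    labels = np.asarray(labels)
    present = set(labels)
    if not set(CLASS_ORDER) <= present:
        raise ValueError(f"need all three classes {CLASS_ORDER}; got {sorted(present)}")
    if len(features) <= features.shape[1] + 1:
        raise ValueError("need n > number of features + 1 to fit the multinomial model")
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    _check_design(X, names)
    order = [reference] + [c for c in CLASS_ORDER if c != reference]
    code = {c: i for i, c in enumerate(order)}
    y = np.array([code[c] for c in labels])
    exog = sm.add_constant(X, has_constant="add")
    ridge = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MNLogit(y, exog).fit(method="newton", maxiter=200, disp=False)
        params = fit.params.to_numpy() if hasattr(fit.params, "to_numpy") else np.asarray(fit.params)
        if (
            not fit.mle_retvals.get("converged", True)
            or not np.all(np.isfinite(params))
            or np.max(np.abs(params)) > 30
        ):
            raise np.linalg.LinAlgError("quasi-separation")
        b1 = params[:, 0]
        b2 = params[:, 1]
    except (np.linalg.LinAlgError, ValueError):
        ridge = True
        clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
        clf.fit(X, y)
        coef = np.column_stack([clf.intercept_, clf.coef_])  # (3, p+1) softmax parameterization
        b1 = coef[1] - coef[0]
        b2 = coef[2] - coef[0]
    return DysbiosisIndexModel(
        compartment=compartment,
        feature_names=names,
        b1=b1,
        b2=b2,
        feature_space=feature_space or {},
        ridge_refit=ridge,
    )


def evaluate_accuracy(
    model: DysbiosisIndexModel, features: pd.DataFrame, labels
) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """Test-set accuracy with an exact (Clopper-Pearson) binomial 95% CI."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty test set")
    preds = predict_table(model, features)["label"].to_numpy()
    correct = int((preds == labels).sum())
    n = len(labels)
    acc = correct / n
    lo = 0.0 if correct == 0 else float(beta.ppf(0.025, correct, n - correct + 1))
    hi = 1.0 if correct == n else float(beta.ppf(0.975, correct + 1, n - correct))
    confusion = pd.crosstab(
        pd.Series(labels, name="true"), pd.Series(preds, name="predicted")
    ).reindex(index=CLASS_ORDER, columns=CLASS_ORDER, fill_value=0)
    return acc, (lo, hi), confusion


@dataclass
class DerivedIndex:
    model: DysbiosisIndexModel
    selected_features: list[str]
    accuracy: float
    ci: tuple[float, float]
    confusion: pd.DataFrame
    n_train: int
    n_test: int


def derive_index(
    table,
    labels,
    shannon: pd.Series,
    compartment: str = "lung",
    top_n: int = 50,
    test_fraction: float = 0.2,
    clr_pseudocount: float = 0.5,
    selection_method: str = "mb_surrogate",
    seed: int = 0,
) -> DerivedIndex:
    """End-to-end index derivation from a labeled count table.

    Top-``top_n`` taxa by mean relative abundance are CLR-transformed and
    joined with the Shannon index; the data are split 80/20 stratified by
    label; features are selected on the training set only; the multinomial
    model is fit on the training set and scored on the held-out 20%.
    """
    from .ecology import clr_transform

    labels = np.asarray(labels)
    taxa = top_taxa(table, n=top_n, by="relative")
    clr = clr_transform(table, pseudocount=clr_pseudocount)[taxa]
    feats = clr.copy()
    feats["ShannonIndex"] = shannon.reindex(clr.index).to_numpy()
    train_idx, test_idx = stratified_split(labels, test_fraction=test_fraction, seed=seed)
    selected = select_features(
        feats.iloc[train_idx], labels[train_idx], method=selection_method, seed=seed
    )
    if not selected:
        warnings.warn("no features passed selection; falling back to the full set", stacklevel=2)
        selected = list(feats.columns)
    model = fit_mlr(
        feats.iloc[train_idx][selected],
        labels[train_idx],
        compartment=compartment,
        feature_space={
            "clr_pseudocount": clr_pseudocount,
            "shannon_variant": "rarefied_mean",
            "top_n": top_n,
            "selection": selection_method,
        },
    )
    acc, ci, confusion = evaluate_accuracy(model, feats.iloc[test_idx][selected], labels[test_idx])
    return DerivedIndex(
        model=model,
        selected_features=selected,
        accuracy=acc,
        ci=ci,
        confusion=confusion,
        n_train=len(train_idx),
        n_test=len(test_idx),
    )
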