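"""Study orchestration: train on control castes, classify queen-removal
individuals, and run the phenotype-linkage and gene-set statistics.

The classifier is trained on queens (response 1) and control workers
(response 0) from queenright colonies; the optimized model is then applied to
individuals sampled after queen removal, whose continuous estimates place
them between the two castes. Downstream, estimates are regressed on
phenotypic queenness, ovarian development, dominance and age (and on
age-residualized phenotypes), QR time points are compared by rank test, and
the selected gene set is compared against other gene sets by Jaccard index
and a one-sided hypergeometric overlap test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as cstats
from .preprocess import (Scaler, apply_standardize, filter_low_counts, normalize,
                         standardize)
from .rfe import RFETrace, SelectedModel, run_rfe, select_optimal
from .svm import KernelSpec, grid_search, predict, study_scaled_gamma

__all__ = [
    "TrainedClassifier",
    "ClassificationReport",
    "train_caste_classifier",
    "classify_samples",
    "compare_qr_timepoints",
    "fit_phenotype_models",
    "phenotype_queenness",
    "compare_gene_sets",
]

LABELS = {"control_worker": 0.0, "queen": 1.0}


@dataclass
class TrainedClassifier:
    """Everything needed to score new samples on the training scale."""

    selected: SelectedModel
    trace: RFETrace
    scaler: Scaler               # over the full post-filter universe
    universe: list[str]          # genes surviving the expression filter
    pseudocount: float
    train_sample_ids: list[str]
    all_genes_cv_error: float
    training_estimates: pd.Series
    grid_result: object | None = None


@dataclass
class ClassificationReport:
    """Per-sample classifier estimates plus per-group summaries."""

    estimates: pd.DataFrame       # sample_id, group, estimate
    summaries: pd.DataFrame       # per group: n, mean, sd, min, max

    @classmethod
    def build(cls, estimates: pd.DataFrame) -> "ClassificationReport":
        if estimates["sample_id"].duplicated().any():
            raise ValueError("duplicate sample in classification report")
        g = estimates.groupby("group", sort=True)["estimate"]
        summaries = pd.DataFrame({
            "n": g.size(), "mean": g.mean(), "sd": g.std(ddof=1),
            "min": g.min(), "max": g.max(),
        })
        return cls(estimates=estimates.reset_index(drop=True), summaries=summaries)


def _training_matrix(counts, samples, pseudocount):
    absent = set(samples["sample_id"]) - set(counts.columns)
    if absent:
        raise ValueError(f"sample(s) missing from count matrix: {sorted(absent)[:5]}")
    counts = counts[list(samples["sample_id"])]
    filtered = filter_low_counts(counts, samples)
    expr = normalize(filtered, pseudocount=pseudocount)
    train = samples.loc[samples["group"].isin(LABELS)]
    if not (samples["group"] == "queen").any():
        raise ValueError("no queen samples available for training")
    if not (samples["group"] == "control_worker").any():
        raise ValueError("no control_worker samples available for training")
    train_ids = list(train["sample_id"])
    scaler, z = standardize(expr[train_ids])
    X = z.T  # samples x genes
    y = train.set_index("sample_id").loc[X.index, "group"].map(LABELS).astype(float)
    return filtered, scaler, X, y


def train_caste_classifier(counts: pd.DataFrame, samples: pd.DataFrame, *,
                           kernel: KernelSpec | None = None, C: float = 2.0 ** 5,
                           epsilon: float = 0.1, k: int = 3, repeats: int = 20,
                           stop_size: int = 100, seed: int = 0,
                           grid=None, pseudocount: float = 1.0
                           ) -> TrainedClassifier:
    """Filter, normalize, standardize, (optionally) grid-search, and run RFE.

    ``kernel=None`` selects a radial kernel with the study-scaled gamma for
    the post-filter gene count. When ``grid`` is given it is evaluated first
    and its winning (kernel, C) pair replaces the fixed operating point. CV
    folds are capped at the training sample count (with a warning) so
    degenerate designs still run.
    """
    filtered, scaler, X, y = _training_matrix(counts, samples, pseudocount)
    n_train, n_genes = X.shape
    if k > n_train:
        warnings.warn(f"k={k} exceeds {n_train} training samples; using "
                      f"{n_train}-fold CV", stacklevel=2)
        k = n_train
    if grid is not None:
        gr = grid_search(X.to_numpy(), y.to_numpy(), grid, k=k, repeats=repeats,
                         seed=seed, epsilon=epsilon, sample_ids=list(X.index))
        kernel, C = gr.selected
    else:
        gr = None
        if kernel is None:
            kernel = KernelSpec(kind="radial", gamma=study_scaled_gamma(n_genes))
    trace = run_rfe(X, y, kernel, C, epsilon, k=k, repeats=repeats,
                    stop_size=stop_size, seed=seed)
    selected = select_optimal(trace, X, y)
    selected.model.scaler = Scaler(mean=scaler.mean.loc[selected.genes],
                                   sd=scaler.sd.loc[selected.genes],
                                   dropped=list(scaler.dropped))
    selected.model.normalization = {"pseudocount": float(pseudocount),
                                    "transform": "log2-cpm",
                                    "universe_size": len(filtered.index)}
    train_est = pd.Series(
        predict(selected.model, X[selected.genes].to_numpy()),
        index=X.index, name="estimate")
    return TrainedClassifier(
        selected=selected,
        trace=trace,
        scaler=scaler,
        universe=[str(g) for g in filtered.index],
        pseudocount=pseudocount,
        train_sample_ids=list(X.index),
        all_genes_cv_error=trace.iterations[0].cv_error,
        training_estimates=train_est,
        grid_result=gr,
    )


def classify_samples(trained: TrainedClassifier, counts: pd.DataFrame,
                     samples: pd.DataFrame, subset=None) -> ClassificationReport:
    """Score samples with the trained model using *training* statistics only.

    ``subset`` may be a list of group labels or of sample ids; default is
    every sample in ``samples``. Query counts are restricted to the trained
    gene universe, CPM-normalized with their own depths, standardized by the
    training scaler, and passed through the selected model. Estimates are not
    clipped.
    """
    model = trained.selected.model
    missing = [g for g in model.gene_ids if g not in counts.index]
    if missing:
        raise ValueError(f"{len(missing)} model gene(s) absent from query counts: "
                         f"{missing[:5]}")
    if subset is None:
        chosen = samples
    else:
        subset = list(subset)
        if set(subset) <= set(samples["group"]):
            chosen = samples.loc[samples["group"].isin(subset)]
        else:
            chosen = samples.loc[samples["sample_id"].isin(subset)]
    if chosen.empty:
        raise ValueError("no samples selected for classification")
    universe = [g for g in trained.universe if g in counts.index]
    if len(universe) < len(trained.universe):
        warnings.warn(
            f"{len(trained.universe) - len(universe)} universe gene(s) absent "
            "from query counts; depths computed over the available genes",
            stacklevel=2)
    expr = normalize(counts.loc[universe, list(chosen["sample_id"])],
                     pseudocount=trained.pseudocount)
    z = apply_standardize(model.scaler, expr)
    est = predict(model, z.T.to_numpy())
    frame = pd.DataFrame({
        "sample_id": list(chosen["sample_id"]),
        "group": list(chosen["group"]),
        "estimate": est,
    })
    return ClassificationReport.build(frame)


def compare_qr_timepoints(report: ClassificationReport) -> dict:
    """Two-sided Wilcoxon rank-sum of estimates: day 3 vs day 12 after removal."""
    est = report.estimates
    x = est.loc[est["group"] == "qr_day3", "estimate"].to_numpy()
    y = est.loc[est["group"] == "qr_day12", "estimate"].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("report must contain both qr_day3 and qr_day12 samples")
    w, p, method = cstats.wilcoxon_rank_sum(x, y)
    return {
        "W": w, "p_value": p, "method": method,
        "qr_day3_mean": float(np.mean(x)), "qr_day3_sd": float(np.std(x, ddof=1)),
        "qr_day12_mean": float(np.mean(y)), "qr_day12_sd": float(np.std(y, ddof=1)),
        "n_qr_day3": int(x.size), "n_qr_day12": int(y.size),
    }


_PHENO_MODELS = (
    ("queenness", "queenness", False),
    ("ovarian_index", "ovarian_index", False),
    ("dominance", "dominance", False),
    ("age", "age", False),
    ("resid_queenness_on_age", "queenness", True),
    ("resid_ovarian_on_age", "ovarian_index", True),
    ("resid_dominance_on_age", "dominance", True),
)


def fit_phenotype_models(report: ClassificationReport, samples: pd.DataFrame
                         ) -> pd.DataFrame:
    """OLS of classifier estimates on each phenotype, and on age residuals.

    The residual models regress the estimate on the residuals of an OLS of
    the phenotype on age, asking whether the phenotype predicts caste-like
    expression beyond what age alone explains. Zero-variance predictors are
    flagged rather than fitted.
    """
    pheno_cols = samples[["sample_id", "age", "ovarian_index", "dominance",
                          "queenness"]].reset_index(drop=True)
    merged = report.estimates.merge(pheno_cols, on="sample_id", how="left")
    rows = []
    for name, col, residualize in _PHENO_MODELS:
        cols = ["estimate", col] if col == "age" else ["estimate", col, "age"]
        sub = merged[cols].dropna()
        flag = ""
        slope = stderr = p = r = np.nan
        n = len(sub)
        if n < 3:
            flag = "too_few_samples"
        else:
            x = sub[col].to_numpy(dtype=float)
            if residualize:
                if np.ptp(sub["age"].to_numpy(dtype=float)) == 0:
                    flag = "zero_variance"
                else:
                    x = cstats.residuals_on(x, sub["age"].to_numpy(dtype=float))
            if not flag:
                if np.ptp(x) == 0:
                    flag = "zero_variance"
                else:
                    fit = cstats.ols(sub["estimate"].to_numpy(dtype=float), x)
                    slope, stderr = fit.slope, fit.stderr
                    p, r = fit.p_value, fit.pearson_r
        rows.append({"model": name, "predictor": col,
                     "residualized_on_age": residualize, "n": n,
                     "slope": slope, "stderr": stderr, "p_value": p,
                     "pearson_r": r, "flag": flag})
    return pd.DataFrame(rows)


def phenotype_queenness(samples: pd.DataFrame,
                        train_groups=("queen", "control_worker"),
                        ridge: float = 0.0) -> pd.DataFrame:
    """Fill the queenness column from a logistic model on ovarian + dominance.

    A maximum-likelihood logistic regression of caste (queen = 1) on ovarian
    index and dominance is fitted on the training groups and applied to every
    sample with both phenotypes, including QR individuals. With ``ridge = 0``
    and completely separable phenotypes a warning is issued and a minimal
    ridge penalty is applied automatically. Fitted coefficients (raw scale)
    are stored in ``result.attrs['queenness_model']``.
    """
    from sklearn.linear_model import LogisticRegression

    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    train = samples.loc[samples["group"].isin(train_groups)].dropna(
        subset=["ovarian_index", "dominance"])
    if train.empty or train["group"].nunique() < 2:
        raise ValueError("training groups must include both castes with phenotypes")
    y = (train["group"] == "queen").to_numpy(dtype=float)
    feats = ["ovarian_index", "dominance"]
    Xraw = train[feats].to_numpy(dtype=float)
    mu, sd = Xraw.mean(axis=0), Xraw.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (Xraw - mu) / sd

    def _fit(lam):
        if lam == 0:
            clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=5000,
                                     tol=1e-10)
        else:
            clf = LogisticRegression(penalty="l2", C=1.0 / lam, solver="lbfgs",
                                     max_iter=5000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xz, y)
        return clf

    lam = ridge
    clf = _fit(lam)
    # a divergent MLE (complete separation) pins every fitted probability at
    # its label; detect via residuals, not coefficient magnitude
    if lam == 0 and np.max(np.abs(y - clf.predict_proba(Xz)[:, 1])) < 1e-2:
        warnings.warn("complete separation in phenotype logistic model; "
                      "applying minimal ridge penalty", stacklevel=2)
        lam = 1e-4
        clf = _fit(lam)

    coef_std = clf.coef_.ravel()
    coef_raw = coef_std / sd
    intercept_raw = float(clf.intercept_[0] - np.sum(coef_std * mu / sd))

    out = samples.copy()
    scored = samples.dropna(subset=["ovarian_index", "dominance"])
    Xq = (scored[feats].to_numpy(dtype=float) - mu) / sd
    out.loc[scored.index, "queenness"] = clf.predict_proba(Xq)[:, 1]
    out.attrs["queenness_model"] = {
        "intercept": intercept_raw,
        "coef": {f: float(c) for f, c in zip(feats, coef_raw)},
        "ridge": float(lam),
    }
    return out


def compare_gene_sets(svm_set, other, universe) -> cstats.OverlapResult:
    """Jaccard index and one-sided hypergeometric overlap of two gene sets.

    The universe should be the post-filter gene list (the genes that could
    have been selected); both sets must be subsets of it.
    """
    return cstats.overlap_result(set(svm_set), set(other), set(universe))
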