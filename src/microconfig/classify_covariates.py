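"""Random-forest configuration classification, differential-abundance
screening, and covariate (drug / diet / demographic) modelling.

The classifier operates on rank-normalised genus abundances and reports the
out-of-bag (OOB) error together with per-sample vote fractions and a signed
importance ranking.  Differential abundance is screened with a clearly
labelled rank-based stand-in (Wilcoxon / Kruskal-Wallis on rank-normalised
abundances with BH correction) — NOT a bias-corrected compositional model;
externally computed results can be imported instead.  Covariate screening
fits one logistic model per exposure with a fixed adjuster set,
likelihood-ratio p per term and BH q across the model's terms, with explicit
quasi-separation flagging and an optional penalised refit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm

from .stats_core import benjamini_hochberg, cohens_d
from .tables_io import AbundanceTable
from .transforms import rank_normalize_table

logger = logging.getLogger(__name__)

DA_STANDIN_NOTE = "rank-based stand-in (NOT ANCOMBC)"

#: fixed adjuster set for the covariate logistic models
DEFAULT_ADJUSTERS = (
    "age", "age_at_diagnosis", "gender", "hurley", "surgery",
    "antibiotics_last_year", "anti_tnf_current", "anti_tnf_previous",
    "immunomodulator",
)


@dataclass
class ClassifierReport:
    oob_error: float
    votes: pd.DataFrame               # per training sample, class vote fractions
    importance: pd.DataFrame          # genus, importance, direction
    predicted_fraction: dict          # class -> fraction of predict_on samples
    predictions: pd.Series | None
    classes: list
    n_trees: int
    seed: int


@dataclass
class CovariateModelReport:
    exposure: str
    table: pd.DataFrame               # term, estimate, std_error, z_value, p_lr, q
    separation: bool
    penalized: pd.Series | None = None
    converged: bool = True


def rf_classify(
    table: AbundanceTable,
    labels: pd.Series,
    predict_on=None,
    n_trees: int = 500,
    seed: int = 0,
    top_m: int = 15,
) -> ClassifierReport:
    """Random forest on rank-normalised abundances with OOB error reporting.

    ``labels`` must cover exactly two classes with >= 5 samples each.
    ``predict_on`` names additional samples in ``table``; each is assigned the
    majority-vote class and the per-class predicted fractions are reported
    (e.g. the fraction of a held-out patient group with a Crohn's-like
    configuration).  Importance is the mean decrease in impurity, signed by
    which class has the higher mean abundance.
    """
    from sklearn.ensemble import RandomForestClassifier

    labels = labels.dropna()
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if min((labels == c).sum() for c in classes) < 5:
        raise ValueError("each class needs >= 5 samples")
    ranked = rank_normalize_table(table.data)
    x_train = ranked.loc[labels.index].to_numpy()
    y_train = labels.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(x_train, y_train)
    oob_error = 1.0 - float(forest.oob_score_)
    votes = pd.DataFrame(forest.oob_decision_function_, index=labels.index,
                         columns=forest.classes_)

    means = {c: x_train[y_train == c].mean(axis=0) for c in classes}
    direction = np.where(means[classes[0]] >= means[classes[1]],
                         classes[0], classes[1])
    importance = (
        pd.DataFrame({
            "genus_id": table.genus_ids,
            "importance": forest.feature_importances_,
            "direction": direction,
        })
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    if top_m:
        importance = importance.head(top_m)

    predictions = None
    predicted_fraction: dict = {}
    if predict_on is not None:
        held = [s for s in predict_on if s in table.data.index]
        if held:
            proba = forest.predict_proba(ranked.loc[held].to_numpy())
            pred = forest.classes_[np.argmax(proba, axis=1)]
            predictions = pd.Series(pred, index=held, name="predicted_class")
            predicted_fraction = {
                c: float((pred == c).mean()) for c in forest.classes_
            }
    return ClassifierReport(
        oob_error=oob_error, votes=votes, importance=importance,
        predicted_fraction=predicted_fraction, predictions=predictions,
        classes=list(forest.classes_), n_trees=n_trees, seed=seed,
    )


def differential_abundance_standin(table: AbundanceTable, labels: pd.Series,
                                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-genus rank tests between groups, BH-corrected across genera.

    This is a simple rank-based screen (Wilcoxon for two groups,
    Kruskal-Wallis for three) on rank-normalised abundances.  It is labelled
    as such in the output and is NOT a compositional bias-corrected model.
    Constant genera are excluded with a warning.  Direction is the group with
    the higher median relative abundance.
    """
    from .stats_core import kruskal_wallis, wilcoxon_rank_sum
    from .tables_io import to_relative

    labels = labels.dropna()
    levels = sorted(labels.unique())
    if len(levels) not in (2, 3):
        raise ValueError("differential_abundance_standin needs 2 or 3 groups")
    rel = to_relative(table).data.loc[labels.index]
    ranked = rank_normalize_table(rel)
    rows = []
    skipped = 0
    for genus in rel.columns:
        x = ranked[genus].to_numpy()
        if np.unique(x).size == 1:
            skipped += 1
            continue
        if len(levels) == 2:
            res = wilcoxon_rank_sum(x[labels == levels[0]], x[labels == levels[1]])
        else:
            res = kruskal_wallis(x, labels.to_numpy())
        medians = {lv: float(rel.loc[labels == lv, genus].median()) for lv in levels}
        rows.append({
            "genus_id": genus,
            "statistic": res.statistic,
            "p": res.p,
            "direction": max(medians, key=medians.get),
            "method": DA_STANDIN_NOTE,
        })
    if skipped:
        warnings.warn(f"{skipped} constant genera excluded from the DA screen",
                      stacklevel=2)
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    out.attrs["method"] = DA_STANDIN_NOTE
    return out


def write_da_results(results: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# method: {results.attrs.get('method', 'unknown')}\n")
        results.to_csv(fh, sep="\t", index=False)


def import_external_da_results(path) -> pd.DataFrame:
    """Normalise an externally computed differential-abundance table
    (e.g. an ANCOMBC export) into the internal schema
    (genus_id, effect, p, q)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    rename = {}
    for want, aliases in {
        "genus_id": ("genus_id", "genus", "taxon", "feature"),
        "effect": ("effect", "lfc", "log_fold_change", "beta", "estimate"),
        "p": ("p", "pval", "p_value", "pvalue"),
        "q": ("q", "qval", "q_value", "padj", "p_adj"),
    }.items():
        found = [c for c in frame.columns if c.lower() in aliases]
        if not found:
            raise ValueError(f"external DA table is missing a {want!r} column")
        rename[found[0]] = want
    out = frame.rename(columns=rename)[["genus_id", "effect", "p", "q"]].copy()
    out["method"] = "external"
    return out


def _encode_column(col: pd.Series) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy(dtype=float)
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.astype(str).unique())
        if len(levels) > 2:
            raise ValueError(f"multi-level categorical {col.name!r}; encode it first")
        return (col.astype(str) == levels[-1]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def covariate_logistic(
    outcome: pd.Series,
    exposure: str,
    metadata: pd.DataFrame,
    adjusters=DEFAULT_ADJUSTERS,
    min_prevalence: float = 0.20,
    cohens_d_threshold: float = 0.5,
    penalized_refit: bool = True,
) -> CovariateModelReport:
    """One-exposure logistic model of a two-level configuration label.

    Pre-screens the exposure: a binary exposure must be present in at least
    ``min_prevalence`` of the samples; a continuous exposure (e.g. a diet
    frequency) must have |Cohen's d| >= ``cohens_d_threshold`` between the
    outcome groups.  The model is outcome ~ adjusters + exposure with
    maximum-likelihood fit, per-term likelihood-ratio p, BH q across the
    model's terms, and a quasi-separation flag (any |estimate| > 10 with
    SE > 100); when flagged, an L2-penalised refit supplies a finite
    exposure estimate.
    """
    outcome = outcome.dropna()
    levels = sorted(outcome.unique())
    if len(levels) != 2:
        raise ValueError(f"outcome must have two levels, got {levels}")
    meta = metadata.loc[outcome.index]
    y = (outcome == levels[1]).to_numpy(dtype=float)

    expo_raw = meta[exposure]
    expo = _encode_column(expo_raw)
    is_binary = set(np.unique(expo[~np.isnan(expo)])) <= {0.0, 1.0}
    if is_binary:
        prevalence = float(np.nanmean(expo))
        if prevalence < min_prevalence:
            raise ValueError(
                f"exposure {exposure!r} prevalence {prevalence:.2f} below "
                f"{min_prevalence:.2f}"
            )
    else:
        d = cohens_d(expo[y == 1], expo[y == 0])
        if abs(d) < cohens_d_threshold:
            raise ValueError(
                f"exposure {exposure!r} |Cohen's d| {abs(d):.2f} below "
                f"{cohens_d_threshold:.2f}"
            )

    terms = [a for a in adjusters if a in meta.columns and a != exposure]
    cols = {"Intercept": np.ones(len(y))}
    for t in terms:
        cols[t] = _encode_column(meta[t])
    cols[exposure] = expo
    x = pd.DataFrame(cols, index=outcome.index).astype(float)
    if x.isna().any().any():
        keep = ~x.isna().any(axis=1)
        x, y = x.loc[keep], y[keep.to_numpy()]

    def fit(design: pd.DataFrame):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, design.to_numpy())
            try:
                return model.fit(disp=0, maxiter=200, method="newton")
            except Exception:
                return model.fit(disp=0, maxiter=500, method="bfgs")

    full = fit(x)
    params = pd.Series(full.params, index=x.columns)
    bse = pd.Series(full.bse, index=x.columns)
    separation = bool(((params.abs() > 10) & (bse > 100)).any())
    converged = bool(getattr(full, "mle_retvals", {}).get("converged", True))
    if not converged and not separation:
        raise RuntimeError(
            f"logistic fit for exposure {exposure!r} did not converge "
            f"(no separation detected): {getattr(full, 'mle_retvals', {})}"
        )

    rows = []
    for term in [c for c in x.columns if c != "Intercept"]:
        reduced = fit(x.drop(columns=term))
        lr = 2.0 * (full.llf - reduced.llf)
        p = float(ss.chi2.sf(max(lr, 0.0), df=1))
        rows.append({
            "term": term,
            "estimate": float(params[term]),
            "std_error": float(bse[term]),
            "z_value": float(params[term] / bse[term]) if bse[term] > 0 else np.nan,
            "p_lr": p,
        })
    table = pd.DataFrame(rows)
    table["q"] = benjamini_hochberg(table["p_lr"].to_numpy())
    table = pd.concat([
        pd.DataFrame([{"term": "Intercept", "estimate": float(params["Intercept"]),
                       "std_error": float(bse["Intercept"]),
                       "z_value": float(params["Intercept"] / bse["Intercept"])
                       if bse["Intercept"] > 0 else np.nan,
                       "p_lr": np.nan, "q": np.nan}]),
        table,
    ], ignore_index=True)

    penalized = None
    if separation and penalized_refit:
        from sklearn.linear_model import LogisticRegression

        lr_model = LogisticRegression(C=1.0, max_iter=1000)
        design = x.drop(columns="Intercept")
        lr_model.fit(design.to_numpy(), y)
        penalized = pd.Series(lr_model.coef_[0], index=design.columns,
                              name="penalized_estimate")
    return CovariateModelReport(exposure=exposure, table=table,
                                separation=separation, penalized=penalized,
                                converged=converged)


def screen_covariates(
    outcome: pd.Series,
    metadata: pd.DataFrame,
    exposures: list,
    adjusters=DEFAULT_ADJUSTERS,
    min_prevalence: float = 0.20,
    cohens_d_threshold: float = 0.5,
) -> pd.DataFrame:
    """Fit one logistic model per candidate exposure, skipping those that
    fail the prevalence / effect-size pre-screen (logged)."""
    rows = []
    for expo in exposures:
        try:
            report = covariate_logistic(
                outcome, expo, metadata, adjusters=adjusters,
                min_prevalence=min_prevalence,
                cohens_d_threshold=cohens_d_threshold,
            )
        except ValueError as exc:
            logger.info("skipping exposure %r: %s", expo, exc)
            continue
        sub = report.table[report.table["term"] == expo].copy()
        sub.insert(0, "exposure", expo)
        sub["separation"] = report.separation
        rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["exposure", "term", "estimate", "std_error",
                                     "z_value", "p_lr", "q", "separation"])
    return pd.concat(rows, ignore_index=True)


def taxon_covariate_correlations(
    table: AbundanceTable,
    covariates: pd.DataFrame,
    taxa: list,
    q_threshold: float = 0.1,
):
    """Spearman rho for every (taxon, covariate) pair with a BH-masked grid.

    Returns (rho, q, mask) DataFrames (taxa x covariates); the mask is True
    where q < ``q_threshold``.  Constant covariates are dropped with a warning.
    """
    common = table.data.index.intersection(covariates.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 shared samples")
    missing = set(taxa) - set(table.genus_ids)
    if missing:
        raise ValueError(f"taxa not in table: {sorted(missing)[:5]}")
    cov = covariates.loc[common].copy()
    for col in list(cov.columns):
        enc = _encode_column(cov[col])
        if np.unique(enc[~np.isnan(enc)]).size < 2:
            warnings.warn(f"dropping constant covariate {col!r}", stacklevel=2)
            cov = cov.drop(columns=col)
        else:
            cov[col] = enc
    rho = pd.DataFrame(index=taxa, columns=cov.columns, dtype=float)
    pval = pd.DataFrame(index=taxa, columns=cov.columns, dtype=float)
    for g in taxa:
        x = table.data.loc[common, g].to_numpy(dtype=float)
        for c in cov.columns:
            yv = cov[c].to_numpy(dtype=float)
            mask = ~np.isnan(yv)
            res = ss.spearmanr(x[mask], yv[mask])
            rho.loc[g, c] = float(res.statistic)
            pval.loc[g, c] = float(res.pvalue)
    q = pd.DataFrame(
        benjamini_hochberg(pval.to_numpy().ravel()).reshape(pval.shape),
        index=pval.index, columns=pval.columns,
    )
    return rho, q, q < q_threshold
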