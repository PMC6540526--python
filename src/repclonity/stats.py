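"""Survival and association inference for repertoire measurements.

The central analysis asks whether a per-sample repertoire measurement (for
instance species evenness) carries prognostic information for overall
survival: a Cox proportional-hazards model is fit with the measurement
alone (univariable) and together with the clinical covariates tissue site,
sex, age at diagnosis and stage (multivariable), and the measurement's
contribution is judged by a nested likelihood-ratio test,

    2 * (LL_full - LL_reduced)  ~  chi-square(df = added terms).

Continuous measurements are z-scored before fitting, so hazard ratios are
per standard deviation of the measurement. Partial-likelihood ties use
Efron's approximation.

The module also provides the surrounding screen: Mann-Whitney U group
comparisons, one-way ANOVA with Benjamini-Hochberg correction across a
measurement panel, Spearman correlation matrices, one-sided Fisher and
chi-square enrichment tests, Kaplan-Meier curves, and the heatmap-style
hierarchical clustering of the measurement panel with its fixed missing-
value imputation rules (missing metric -> 0, evenness -> 1, V-region
identity -> median).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from ._errors import RepclonityError

__all__ = [
    "CoxResult", "NestedTestResult", "fit_cox", "fit_cox_null",
    "likelihood_ratio_test", "km_curves", "mann_whitney",
    "anova_across_groups", "bh_adjust", "spearman_matrix", "fisher_one_sided",
    "chi_squared_enrichment", "ClusterResult", "cluster_measurements",
]


@dataclass
class CoxResult:
    """A fitted Cox proportional-hazards model."""

    terms: list[str]
    coefs: pd.Series
    hazard_ratios: pd.Series
    standard_errors: pd.Series
    wald_p: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    samples: list[str] = field(default_factory=list, repr=False)


@dataclass
class NestedTestResult:
    """Likelihood-ratio comparison of two nested Cox models."""

    statistic: float
    df: int
    p_value: float


_DUMMY_COVARIATES = ("sex", "stage", "tissue_site")


def _design_matrix(clinical: pd.DataFrame, covariates: list[str],
                   stage_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Encode covariates: age continuous; sex/stage/tissue_site as 0/1
    indicator columns with the first (sorted) level as reference."""
    parts = []
    for cov in covariates:
        if cov not in clinical.columns:
            raise RepclonityError(f"clinical table lacks covariate {cov!r}")
        col = clinical[cov]
        if cov == "age":
            parts.append(col.astype(float).rename("age"))
        elif cov in _DUMMY_COVARIATES:
            if cov == "stage" and stage_map is not None:
                col = col.map(lambda v: stage_map.get(v, v))
            cats = sorted(col.dropna().astype(str).unique())
            dummies = pd.get_dummies(
                pd.Categorical(col.astype(str), categories=cats),
                prefix=cov, drop_first=True, dtype=float)
            dummies.index = clinical.index
            parts.append(dummies)
        else:
            parts.append(col.astype(float).rename(cov))
    if not parts:
        return pd.DataFrame(index=clinical.index)
    return pd.concat(parts, axis=1)


def fit_cox(measurement: pd.Series | None, clinical: pd.DataFrame,
            covariates: list[str] = (), zscore: bool = True,
            stage_map: dict[str, str] | None = None) -> CoxResult:
    """Fit a Cox PH model of overall survival on a repertoire measurement
    and/or clinical covariates.

    ``measurement`` is z-scored before fitting (hazard ratios are per SD).
    Rows with a missing measurement or covariate are dropped. On complete
    separation / non-convergence a warning is raised and the model is refit
    with a small ridge penalty.
    """
    df = _design_matrix(clinical, list(covariates), stage_map=stage_map)
    if measurement is not None:
        name = measurement.name or "measurement"
        m = measurement.reindex(clinical.index).astype(float)
        df = pd.concat([m.rename(name), df], axis=1)
    df["os_time"] = clinical["os_time"].astype(float)
    df["os_event"] = clinical["os_event"].astype(int)
    df = df.dropna()
    if df.empty or df.shape[1] <= 2:
        raise RepclonityError("no terms to fit")
    if int(df["os_event"].sum()) < 1:
        raise RepclonityError("no events in the cohort; Cox model undefined")
    terms = [c for c in df.columns if c not in ("os_time", "os_event")]
    for term in terms:
        if df[term].nunique() <= 1:
            raise RepclonityError(f"term {term!r} is constant")
    if measurement is not None and zscore:
        name = measurement.name or "measurement"
        df[name] = (df[name] - df[name].mean()) / df[name].std(ddof=1)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="os_time", event_col="os_event")
    except ConvergenceError as err:
        warnings.warn(f"Cox fit did not converge ({err}); refitting with a "
                      "small ridge penalty", stacklevel=2)
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(df, duration_col="os_time", event_col="os_event")
    return CoxResult(
        terms=terms,
        coefs=cph.params_,
        hazard_ratios=np.exp(cph.params_),
        standard_errors=cph.standard_errors_,
        wald_p=cph.summary["p"],
        log_likelihood=float(cph.log_likelihood_),
        n=int(df.shape[0]),
        n_events=int(df["os_event"].sum()),
        samples=list(df.index),
    )


def fit_cox_null(clinical: pd.DataFrame, samples: list[str] | None = None
                 ) -> CoxResult:
    """The empty (no-covariate) Cox model's Efron partial log-likelihood.

    With all risk scores equal to 1, a distinct event time with d tied
    events and risk-set size n contributes -sum_{j=0}^{d-1} log(n - j).
    """
    df = clinical if samples is None else clinical.loc[samples]
    times = df["os_time"].to_numpy(dtype=float)
    events = df["os_event"].to_numpy(dtype=int)
    if events.sum() < 1:
        raise RepclonityError("no events in the cohort; Cox model undefined")
    ll = 0.0
    for t in np.unique(times[events == 1]):
        d = int(((times == t) & (events == 1)).sum())
        n_risk = int((times >= t).sum())
        ll -= sum(math.log(n_risk - j) for j in range(d))
    return CoxResult(terms=[], coefs=pd.Series(dtype=float),
                     hazard_ratios=pd.Series(dtype=float),
                     standard_errors=pd.Series(dtype=float),
                     wald_p=pd.Series(dtype=float), log_likelihood=ll,
                     n=int(df.shape[0]), n_events=int(events.sum()),
                     samples=list(df.index))


def likelihood_ratio_test(full: CoxResult, reduced: CoxResult) -> NestedTestResult:
    """Nested LRT: 2(LL_full − LL_reduced) against chi-square(Δterms)."""
    if not set(reduced.terms) <= set(full.terms):
        raise RepclonityError("models are not nested: reduced terms "
                              f"{set(reduced.terms) - set(full.terms)} absent from full")
    if (full.n, full.n_events) != (reduced.n, reduced.n_events):
        raise RepclonityError("nested models were fit on different samples")
    df = len(full.terms) - len(reduced.terms)
    if df == 0:
        return NestedTestResult(statistic=0.0, df=0, p_value=1.0)
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    stat = max(stat, 0.0)  # clamp solver-tolerance negatives
    return NestedTestResult(statistic=stat, df=df,
                            p_value=float(sps.chi2.sf(stat, df)))


def km_curves(clinical: pd.DataFrame, grouping: pd.Series) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit survival estimate per group."""
    grouping = grouping.reindex(clinical.index)
    curves = {}
    for group in sorted(grouping.dropna().unique()):
        idx = grouping == group
        if idx.sum() == 0:
            raise RepclonityError(f"empty group {group!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(clinical.loc[idx, "os_time"], clinical.loc[idx, "os_event"],
                label=str(group))
        curves[str(group)] = kmf.survival_function_
    if not curves:
        raise RepclonityError("grouping has no non-missing groups")
    return curves


def mann_whitney(group_a, group_b, sided: str = "two-sided"
                 ) -> tuple[float, float]:
    """Mann-Whitney U. Exact null distribution when both groups have at most
    12 observations and there are no ties; otherwise the normal
    approximation with tie correction."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise RepclonityError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and a.size <= 12 and b.size <= 12:
        method = "exact"
    else:
        method = "asymptotic"
    if np.unique(pooled).size == 1:
        return float(a.size * b.size / 2.0), 1.0  # all values tied
    res = sps.mannwhitneyu(a, b, alternative=sided, method=method,
                           use_continuity=False)
    return float(res.statistic), min(float(res.pvalue), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def anova_across_groups(measurements: pd.DataFrame, grouping: pd.Series
                        ) -> pd.DataFrame:
    """One-way ANOVA of each measurement (column) across groups, with BH
    q-values over the measurement panel."""
    grouping = grouping.reindex(measurements.index)
    rows = []
    for col in measurements.columns:
        values = measurements[col]
        groups = [values[(grouping == g) & values.notna()].to_numpy()
                  for g in sorted(grouping.dropna().unique())]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            raise RepclonityError(
                f"measurement {col!r}: need >=2 groups with >=2 samples")
        if all(np.ptp(g) == 0 for g in groups) and \
                np.ptp(np.concatenate(groups)) == 0:
            f_stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p = sps.f_oneway(*groups)
        rows.append({"measurement": col, "F": float(f_stat), "p": float(p)})
    out = pd.DataFrame(rows).set_index("measurement")
    out["q"] = bh_adjust(out["p"])
    return out


def spearman_matrix(measurements: pd.DataFrame, min_pairs: int = 3
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p over pairwise-complete observations.

    Cells with fewer than ``min_pairs`` complete pairs are NaN (warned)."""
    cols = list(measurements.columns)
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            pair = measurements[[ci, cj]].dropna()
            if pair.shape[0] < min_pairs:
                warnings.warn(f"fewer than {min_pairs} complete pairs for "
                              f"({ci}, {cj}); reporting NA", stacklevel=2)
                r = p = np.nan
            else:
                r, p = sps.spearmanr(pair[ci], pair[cj])
            rho.loc[ci, cj] = rho.loc[cj, ci] = r
            pval.loc[ci, cj] = pval.loc[cj, ci] = p
    return rho, pval


def fisher_one_sided(table, direction: str = "greater") -> float:
    """One-sided Fisher exact p (hypergeometric tail in ``direction``)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise RepclonityError("Fisher test needs a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise RepclonityError("Fisher test undefined with a zero margin")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    return float(sps.fisher_exact(t, alternative=direction)[1])


def chi_squared_enrichment(contingency) -> tuple[float, float]:
    """Pearson chi-square test of independence, no continuity correction;
    warns when any expected cell count is below 5."""
    t = np.asarray(contingency, dtype=float)
    if t.sum() == 0:
        raise RepclonityError("chi-square undefined for an all-zero table")
    res = sps.chi2_contingency(t, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("chi-square expected count < 5 in at least one cell; "
                      "the asymptotic p-value may be unreliable", stacklevel=2)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# measurement-panel clustering with fixed imputation rules

IMPUTE_EVENNESS = 1.0
IMPUTE_DEFAULT = 0.0


@dataclass
class ClusterResult:
    imputed: pd.DataFrame
    scaled: pd.DataFrame
    sample_linkage: np.ndarray
    measurement_linkage: np.ndarray
    sample_clusters: pd.Series


def _impute_rule(name: str) -> str:
    lowered = name.lower()
    if "evenness" in lowered:
        return "one"
    if "identity" in lowered:
        return "median"
    return "zero"


def impute_measurements(measurements: pd.DataFrame,
                        rules: dict[str, str] | None = None) -> pd.DataFrame:
    """Replace missing values per measurement: evenness -> 1, V-region
    identity -> the measurement's median, every other metric -> 0.

    ``rules`` overrides the name-based rule per column with one of
    {"zero", "one", "median"}.
    """
    out = measurements.copy().astype(float)
    for col in out.columns:
        rule = (rules or {}).get(col, _impute_rule(str(col)))
        if rule == "one":
            fill = 1.0
        elif rule == "median":
            fill = float(out[col].median())
        elif rule == "zero":
            fill = 0.0
        else:
            raise ValueError(f"unknown imputation rule {rule!r}")
        out[col] = out[col].fillna(fill)
    return out


def cluster_measurements(measurements: pd.DataFrame, k: int = 4,
                         rules: dict[str, str] | None = None) -> ClusterResult:
    """Heatmap-style two-way clustering of the samples × measurements panel.

    Missing values are imputed by the fixed rules above, each measurement is
    scaled to unit SD and median-centered, and average-linkage Euclidean
    hierarchical clustering is run on both axes; sample clusters are cut at
    ``k`` groups.
    """
    if measurements.shape[0] < 2 or measurements.shape[1] < 2:
        raise RepclonityError("clustering needs >=2 samples and >=2 measurements")
    measurements = measurements.astype(float)
    all_missing = [c for c in measurements.columns
                   if measurements[c].isna().all()]
    if all_missing:
        warnings.warn(f"dropping all-missing measurement(s): {all_missing}",
                      stacklevel=2)
        measurements = measurements.drop(columns=all_missing)
    imputed = impute_measurements(measurements, rules=rules)
    sd = imputed.std(ddof=1)
    scaled = imputed.div(sd.replace(0.0, 1.0))
    scaled = scaled.sub(scaled.median())
    sample_link = hierarchy.linkage(scaled.to_numpy(), method="average",
                                    metric="euclidean")
    meas_link = hierarchy.linkage(scaled.to_numpy().T, method="average",
                                  metric="euclidean")
    labels = hierarchy.fcluster(sample_link, t=k, criterion="maxclust")
    return ClusterResult(imputed=imputed, scaled=scaled,
                         sample_linkage=sample_link,
                         measurement_linkage=meas_link,
                         sample_clusters=pd.Series(labels, index=scaled.index,
                                                   name="cluster"))
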