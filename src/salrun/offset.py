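"""Climate GEA, correlation gating, gradient-forest turnover, and offsets.

The genomic-offset workflow: (1) PCA of the 19 standardized present-day
bioclim-style variables, with future values projected onto the same axes;
(2) a (partial) RDA of genotypes against climate PC1–3 to obtain per-SNP
climate loadings; (3) a gate correlating run-timing axis-1 loadings with
climate axis-1 loadings over shared loci at a Bonferroni alpha of 0.05/3;
(4) per-locus random forests (500 regression trees) of population allele
frequency on a decorrelated climate-predictor set, whose split-point impurity
reductions accumulate into monotone turnover functions; (5) the genomic
offset per site is the Euclidean distance between present and future climate
after mapping through the turnover functions, and the environmental offset
the same distance in raw climate PC1–2 space.

Sites are populations (a deliberately small-n regime: 11 in the study
design), so forests use a minimum leaf of 2 and mtry = ceil(p/3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .association import _prepare, _residualize, top_fraction

log = logging.getLogger(__name__)

ALPHA_BONF_TRAITS = 3  # three run-timing phenotypes tested


def bonferroni_alpha(n_tests: int = ALPHA_BONF_TRAITS, alpha: float = 0.05) -> float:
    """Per-test threshold alpha/n, e.g. 0.05/3 -> 0.0167 at 4 decimal places."""
    return round(alpha / n_tests, 4)


# ---------------------------------------------------------------------------
# Climate PCA


@dataclass
class ClimatePCA:
    mean: pd.Series
    sd: pd.Series
    components: np.ndarray  # n_pcs x variables
    explained_var: np.ndarray
    variables: list[str]

    def transform(self, wide: pd.DataFrame) -> pd.DataFrame:
        z = (wide[self.variables] - self.mean) / self.sd
        scores = z.to_numpy() @ self.components.T
        cols = [f"PC{i + 1}" for i in range(self.components.shape[0])]
        return pd.DataFrame(scores, index=wide.index, columns=cols)


def climate_pca(present: pd.DataFrame, n_pcs: int = 3) -> ClimatePCA:
    """PCA of present-day climate (sites x variables), standardized by the
    present-day mean and sd; future tables are projected with
    :meth:`ClimatePCA.transform` onto the same axes.

    Constant variables are dropped with a warning; fewer than 3 sites is an
    error (the covariance is degenerate).
    """
    if len(present) < 3:
        raise ValueError("climate PCA needs >= 3 sites")
    sd = present.std(ddof=1)
    keep = sd[sd > 0].index.tolist()
    dropped = [v for v in present.columns if v not in keep]
    if dropped:
        log.warning("climate_pca: dropping constant variables %s", dropped)
    mean = present[keep].mean()
    z = ((present[keep] - mean) / sd[keep]).to_numpy()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    for k in range(n_pcs):  # sign: first nonzero component weight positive
        nz = np.flatnonzero(np.abs(vt[k]) > 1e-12)
        if nz.size and vt[k, nz[0]] < 0:
            vt[k] *= -1
    return ClimatePCA(
        mean=mean, sd=sd[keep], components=vt[:n_pcs],
        explained_var=s[:n_pcs] ** 2 / (z**2).sum(), variables=keep,
    )


# ---------------------------------------------------------------------------
# Genotype-environment association (multi-predictor RDA)


@dataclass
class GEAResult:
    snp_scores: np.ndarray  # loadings on constrained axis 1
    constrained_var: float
    candidates: np.ndarray
    conditioned: bool


def gea_rda(
    g,
    climate_pcs: np.ndarray,
    condition: np.ndarray | None = None,
    top: float = 0.01,
    scale: bool = True,
) -> GEAResult:
    """RDA of genotypes on climate PCs (multi-predictor partial RDA).

    Fitted values are the projection of the (residualized) genotype matrix
    onto the span of the (residualized) predictors; axis-1 SNP loadings come
    from the SVD of the fitted matrix.
    """
    preds = np.atleast_2d(np.asarray(climate_pcs, dtype=float))
    if preds.shape[0] != np.shape(g.dosages if hasattr(g, "dosages") else g)[0]:
        preds = preds.T
    x, _ = _prepare(g, np.zeros(preds.shape[0]), scale)
    preds = preds - preds.mean(axis=0)
    if condition is not None:
        cond = np.atleast_2d(np.asarray(condition, dtype=float))
        if cond.shape[0] != x.shape[0]:
            cond = cond.T
        x = _residualize(x, cond)
        preds = _residualize(preds, cond)
    beta, *_ = np.linalg.lstsq(preds, x, rcond=None)
    fitted = preds @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    loadings = vt[0] * s[0]
    nz = np.flatnonzero(np.abs(loadings) > 1e-12)
    if nz.size and loadings[nz[0]] < 0:
        loadings = -loadings
    total = float((x**2).sum())
    return GEAResult(
        snp_scores=loadings,
        constrained_var=float((s**2).sum()) / total if total > 0 else 0.0,
        candidates=top_fraction(np.abs(loadings), top),
        conditioned=condition is not None,
    )


# ---------------------------------------------------------------------------
# Correlation gate


@dataclass
class CorrelationGate:
    r: float
    p: float
    method: str  # "pearson" or "spearman"
    n_shared: int
    alpha_bonf: float
    passed: bool


def correlate_loadings(
    trait_loadings: pd.Series,
    climate_loadings: pd.Series,
    alpha: float = 0.05,
    n_tests: int = ALPHA_BONF_TRAITS,
) -> CorrelationGate:
    """Correlate trait-axis and climate-axis loadings over shared loci.

    Pearson when both vectors pass a Shapiro–Wilk normality check at 0.05,
    Spearman otherwise; the gate passes iff p < alpha/n_tests (0.05/3).
    """
    shared = trait_loadings.index.intersection(climate_loadings.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared loci between trait and climate loadings")
    a = trait_loadings.loc[shared].to_numpy(dtype=float)
    b = climate_loadings.loc[shared].to_numpy(dtype=float)
    normal = (
        len(a) >= 3
        and stats.shapiro(a).pvalue > 0.05
        and stats.shapiro(b).pvalue > 0.05
    )
    if normal:
        r, p = stats.pearsonr(a, b)
        method = "pearson"
    else:
        r, p = stats.spearmanr(a, b)
        method = "spearman"
    thr = bonferroni_alpha(n_tests, alpha)
    return CorrelationGate(
        r=float(r), p=float(p), method=method, n_shared=len(shared),
        alpha_bonf=thr, passed=bool(p < thr),
    )


# ---------------------------------------------------------------------------
# Predictor decorrelation


def decorrelate_predictors(
    present: pd.DataFrame,
    importance: pd.Series,
    threshold: float = 0.7,
) -> list[str]:
    """Iteratively drop the lower-importance member of the most-correlated
    variable pair until no pair exceeds |r| > threshold.

    ``importance`` ranks each variable's weight in explaining genomic
    variation at run-timing loci (from a preliminary forest on all
    variables); variables absent from the ranking — e.g. dropped by the
    preliminary forest for having no importance at all — count as zero.
    """
    variables = [v for v in present.columns]
    importance = importance.reindex(variables).fillna(0.0)
    live = list(variables)
    while True:
        if len(live) < 2:
            break
        corr = present[live].corr().abs()
        worst, pair = threshold, None
        for a, b in combinations(live, 2):
            v = corr.loc[a, b]
            if v > worst:
                worst, pair = v, (a, b)
        if pair is None:
            break
        a, b = pair
        victim = a if importance[a] < importance[b] else b
        live.remove(victim)
    return live


# ---------------------------------------------------------------------------
# Gradient forest


@dataclass
class TurnoverModel:
    """Per-predictor cumulative-importance (turnover) functions.

    ``functions`` maps each predictor to (breakpoints, cumulative values): a
    non-decreasing right-continuous step function starting at 0 whose total
    rise equals the predictor's normalized importance share (shares sum to 1
    over predictors with any importance).
    """

    functions: dict[str, tuple[np.ndarray, np.ndarray]]
    r2: pd.Series  # per-locus out-of-bag R²
    retained_loci: list[str]
    predictor_importance: pd.Series
    n_trees: int
    training_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    def evaluate(self, predictor: str, x) -> np.ndarray:
        """F(x): cumulative importance at or below x (clamped to the range)."""
        bp, cum = self.functions[predictor]
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if predictor in self.training_range:
            lo, hi = self.training_range[predictor]
            if ((x < lo) | (x > hi)).any():
                log.warning("turnover evaluation outside training range for %s; clamped",
                            predictor)
        if bp.size == 0:
            return np.zeros_like(x)
        idx = np.searchsorted(bp, x, side="right")
        padded = np.concatenate([[0.0], cum])
        return padded[idx]

    def to_json_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "predictor_importance": self.predictor_importance.to_dict(),
            "retained_loci": list(self.retained_loci),
            "functions": {
                v: {"breakpoints": bp.tolist(), "cumulative": cum.tolist()}
                for v, (bp, cum) in self.functions.items()
            },
        }


def _harvest_splits(forest: RandomForestRegressor, variables: list[str]):
    """(variable, threshold, impurity reduction) for every split in the forest."""
    splits = []
    for est in forest.estimators_:
        t = est.tree_
        w = t.weighted_n_node_samples
        for node in range(t.node_count):
            f = t.feature[node]
            if f < 0:
                continue
            left, right = t.children_left[node], t.children_right[node]
            delta = w[node] * t.impurity[node] - w[left] * t.impurity[left] - w[right] * t.impurity[right]
            if delta > 0:
                splits.append((variables[f], float(t.threshold[node]), float(delta)))
    return splits


def fit_gradient_forest(
    allele_freqs: pd.DataFrame,
    predictors: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    min_samples_leaf: int = 2,
) -> TurnoverModel:
    """Per-locus random forests of allele frequency on climate predictors.

    ``allele_freqs`` is loci x sites; ``predictors`` sites x variables. Each
    locus gets its own forest of ``n_trees`` regression trees (bootstrap
    rows, mtry = ceil(p/3), minimum leaf ``min_samples_leaf``); the per-locus
    cross-validated R² is the out-of-bag 1 − MSE/Var. Each predictor's
    weight per locus comes from permutation (accuracy) importance; the split
    impurity reductions, located at each split's predictor threshold, give
    the *shape* of the turnover function along the predictor's gradient.
    Turnover functions aggregate over loci with R² > 0, weighted by R², and
    are normalized so the total rise across predictors is 1. Predictors with
    zero total importance are removed and the forests rebuilt without them.
    """
    sites = predictors.index
    if len(sites) < max(5, 2 * min_samples_leaf):
        raise ValueError(f"gradient forest needs >= {max(5, 2 * min_samples_leaf)} sites")
    variables = list(predictors.columns)
    freqs = allele_freqs[sites].to_numpy(dtype=float)

    def _fit_all(X, variables, base_seed):
        r2, per_locus_splits, per_locus_imp = {}, {}, {}
        mtry = max(1, math.ceil(len(variables) / 3))
        for i, locus in enumerate(allele_freqs.index):
            y = freqs[i]
            if np.var(y) == 0:
                r2[locus] = -np.inf  # monomorphic across sites: no signal by definition
                per_locus_splits[locus] = []
                per_locus_imp[locus] = {}
                continue
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=mtry,
                min_samples_leaf=min_samples_leaf,
                bootstrap=True,
                oob_score=True,
                random_state=(base_seed + i) % (2**31 - 1),
                n_jobs=1,
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny-n OOB coverage warnings
                forest.fit(X, y)
            r2[locus] = float(forest.oob_score_)
            per_locus_splits[locus] = _harvest_splits(forest, variables)
            per_locus_imp[locus] = _permutation_importance(
                forest, X, y, variables, (base_seed + i) % (2**31 - 1)
            )
        return pd.Series(r2), per_locus_splits, per_locus_imp

    X = predictors.to_numpy(dtype=float)
    r2, per_locus_splits, per_locus_imp = _fit_all(X, variables, seed)
    retained = [l for l in allele_freqs.index if r2[l] > 0]

    # aggregate importance; drop zero-importance predictors and rebuild once
    totals = _aggregate_importance(per_locus_imp, r2, retained, variables)
    dead = [v for v in variables if totals.get(v, 0.0) == 0.0]
    if dead and len(dead) < len(variables):
        live = [v for v in variables if v not in dead]
        log.info("gradient forest: rebuilding without zero-importance predictors %s", dead)
        X = predictors[live].to_numpy(dtype=float)
        variables = live
        r2, per_locus_splits, per_locus_imp = _fit_all(X, variables, seed)
        retained = [l for l in allele_freqs.index if r2[l] > 0]

    functions, importance = _build_turnover(
        per_locus_splits, per_locus_imp, r2, retained, variables
    )
    training_range = {
        v: (float(predictors[v].min()), float(predictors[v].max())) for v in variables
    }
    return TurnoverModel(
        functions=functions,
        r2=r2,
        retained_loci=retained,
        predictor_importance=importance,
        n_trees=n_trees,
        training_range=training_range,
    )


def _permutation_importance(forest, X, y, variables, seed):
    """Per-predictor increase in out-of-bag MSE when the predictor is permuted.

    OOB evaluation keeps memorized training structure from crediting noise
    predictors the way train-set permutation importance would.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    X32 = np.asarray(X, dtype=np.float32)
    oob_masks = []
    for samples in forest.estimators_samples_:
        m = np.ones(n, dtype=bool)
        m[samples] = False
        oob_masks.append(m)

    def oob_mse(Xq):
        preds = np.zeros(n)
        cnt = np.zeros(n)
        for est, m in zip(forest.estimators_, oob_masks):
            if m.any():
                p = est.tree_.predict(Xq).ravel()
                preds[m] += p[m]
                cnt[m] += 1
        ok = cnt > 0
        return float(np.mean((preds[ok] / cnt[ok] - y[ok]) ** 2))

    base = oob_mse(X32)
    imp = {}
    for j, v in enumerate(variables):
        Xp = X32.copy()
        Xp[:, j] = Xp[rng.permutation(n), j]
        imp[v] = max(oob_mse(Xp) - base, 0.0)
    return imp


def _aggregate_importance(per_locus_imp, r2, retained, variables) -> dict[str, float]:
    totals = {v: 0.0 for v in variables}
    for locus in retained:
        imp = per_locus_imp[locus]
        w_total = sum(imp.values())
        if w_total <= 0:
            continue
        for v, w in imp.items():
            totals[v] += r2[locus] * w / w_total
    return totals


def _build_turnover(per_locus_splits, per_locus_imp, r2, retained, variables):
    """Distribute each locus's R²-weighted predictor importance along the
    predictor's split positions (split-impurity shares give the shape)."""
    weighted: dict[str, list[tuple[float, float]]] = {v: [] for v in variables}
    for locus in retained:
        imp = per_locus_imp[locus]
        imp_total = sum(imp.values())
        if imp_total <= 0:
            continue
        splits = per_locus_splits[locus]
        for v in variables:
            mass = r2[locus] * imp.get(v, 0.0) / imp_total
            if mass <= 0:
                continue
            v_splits = [(t, d) for u, t, d in splits if u == v]
            shape_total = sum(d for _, d in v_splits)
            if shape_total <= 0:
                continue
            for t, d in v_splits:
                weighted[v].append((t, mass * d / shape_total))
    grand = sum(w for pairs in weighted.values() for _, w in pairs)
    functions, importance = {}, {}
    for v in variables:
        pairs = sorted(weighted[v])
        if not pairs or grand <= 0:
            functions[v] = (np.array([]), np.array([]))
            importance[v] = 0.0
            continue
        bp = np.array([t for t, _ in pairs])
        vals = np.array([w for _, w in pairs]) / grand
        ubp, inv = np.unique(bp, return_inverse=True)
        agg = np.zeros(ubp.size)
        np.add.at(agg, inv, vals)
        functions[v] = (ubp, np.cumsum(agg))
        importance[v] = float(vals.sum())
    return functions, pd.Series(importance, name="importance")


# ---------------------------------------------------------------------------
# Offsets


@dataclass
class OffsetResult:
    genomic_offset: pd.Series  # per site, >= 0
    most_important_variable: str
    n_runs: int
    environmental_offset: pd.Series | None = None


def genomic_offset(
    model: TurnoverModel,
    present: pd.DataFrame,
    future: pd.DataFrame,
) -> pd.Series:
    """Euclidean distance between turnover-transformed present and future
    climate, per site. Zero when future equals present; symmetric; a metric
    in the transformed space."""
    sites = present.index
    sq = np.zeros(len(sites))
    for v in model.functions:
        if v not in present.columns:
            continue
        fp = model.evaluate(v, present[v].to_numpy())
        ff = model.evaluate(v, future.loc[sites, v].to_numpy())
        sq += (ff - fp) ** 2
    return pd.Series(np.sqrt(sq), index=sites, name="genomic_offset")


def environmental_offset(present: pd.DataFrame, future: pd.DataFrame,
                         n_pcs: int = 2) -> pd.Series:
    """Euclidean distance between present and future positions in climate
    PC1–2 space (axes fitted on the standardized present-day table)."""
    pca = climate_pca(present, n_pcs=n_pcs)
    sp = pca.transform(present)
    sf = pca.transform(future.loc[present.index])
    d = np.sqrt(((sf.to_numpy() - sp.to_numpy()) ** 2).sum(axis=1))
    return pd.Series(d, index=present.index, name="environmental_offset")


def multi_run_protocol(
    allele_freqs: pd.DataFrame,
    predictors_present: pd.DataFrame,
    predictors_future: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    n_initial: int = 3,
    n_full: int = 10,
) -> OffsetResult:
    """Stability protocol over forest runs.

    Three independently-seeded forests are fitted; if their top-ranked
    predictor agrees, the first run's offsets are reported. Otherwise ten
    runs are fitted and the modal top predictor and the mean offsets across
    all ten are reported.
    """
    seeds = [seed + 1000 * k for k in range(n_full)]
    models, offsets, tops = [], [], []
    for s in seeds[:n_initial]:
        m = fit_gradient_forest(allele_freqs, predictors_present, n_trees=n_trees, seed=s)
        models.append(m)
        offsets.append(genomic_offset(m, predictors_present, predictors_future))
        tops.append(m.predictor_importance.idxmax())
    if len(set(tops)) == 1:
        return OffsetResult(genomic_offset=offsets[0],
                            most_important_variable=tops[0], n_runs=n_initial)
    for s in seeds[n_initial:]:
        m = fit_gradient_forest(allele_freqs, predictors_present, n_trees=n_trees, seed=s)
        offsets.append(genomic_offset(m, predictors_present, predictors_future))
        tops.append(m.predictor_importance.idxmax())
    modal = pd.Series(tops).mode().iloc[0]
    mean_offset = pd.concat(offsets, axis=1).mean(axis=1)
    mean_offset.name = "genomic_offset"
    return OffsetResult(genomic_offset=mean_offset,
                        most_important_variable=modal, n_runs=n_full)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum comparison of R² distributions


def compare_r2_distributions(r2_trait, r2_background) -> float:
    """Two-sided Wilcoxon rank-sum p comparing per-locus cross-validated R²
    of run-timing loci vs background climate loci.

    Exact tie-aware enumeration when both samples have n <= 10; otherwise the
    tie-corrected normal approximation (scipy ``ranksums`` equivalent).
    """
    a = np.asarray(list(r2_trait), dtype=float)
    b = np.asarray(list(r2_background), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size <= 10 and b.size <= 10:
        return _exact_ranksum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Enumerate all assignments of the pooled sample to group A; two-sided p
    for the rank-sum statistic, tie-aware via midranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = a.size
    obs = ranks[:n_a].sum()
    mu = n_a * (pooled.size + 1) / 2.0
    obs_dev = abs(obs - mu)
    count = total = 0
    for combo in combinations(range(pooled.size), n_a):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mu) >= obs_dev - 1e-9:
            count += 1
    return count / total
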