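"""Gradient forest: per-SNP regression forests aggregated into monotone
turnover functions of climate.

For every SNP a random-forest regression of allele frequency on the climate
predictors is fitted.  Each split in each tree reduces impurity; those
reductions are binned along the value range of the predictor that was split
on, normalised by the empirical density of split opportunities (where the
data lie), accumulated into a cumulative-importance step function
``F_p(x)``, and weighted across SNPs by each SNP's out-of-bag R².  ``F_p``
maps a predictor value to expected compositional (allele-frequency)
turnover; the transformed climate space is the arena in which genomic
offsets are Euclidean distances.

SNPs with non-positive out-of-bag R² carry no information the forest can
validate; their R² is clamped to 0 and they are excluded from turnover
aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .climate import ClimateMetricTable

__all__ = ["TurnoverModel", "filter_maf", "folded_maf", "fit", "fraction_predicted"]


def folded_maf(freqs: pd.DataFrame) -> pd.Series:
    """Folded minor-allele frequency per SNP: min(mean freq, 1 - mean freq)."""
    m = freqs.mean(axis=0)
    return np.minimum(m, 1.0 - m)


def filter_maf(freqs: pd.DataFrame, threshold: float = 0.10) -> pd.DataFrame:
    """Keep SNPs whose folded MAF exceeds ``threshold`` (strict)."""
    if not 0.0 < threshold < 0.5:
        raise ValueError("MAF threshold must lie in (0, 0.5)")
    keep = folded_maf(freqs) > threshold
    if not keep.any():
        warnings.warn("MAF filter removed every SNP")
    return freqs.loc[:, keep]


@dataclass
class TurnoverModel:
    """Fitted gradient-forest model.

    Per predictor ``p``: bin edges over the training range and the
    cumulative-importance values at the right edge of each bin, defining a
    right-continuous non-decreasing step function with ``F_p(min) = 0`` and
    ``F_p(max)`` equal to the predictor's aggregate importance.
    """

    predictors: list[str]
    bin_edges: dict[str, np.ndarray]
    cum_importance: dict[str, np.ndarray]
    snp_r2: pd.Series
    importance: pd.Series
    n_trees: int
    seed: int
    hyperparams: dict = field(default_factory=dict)

    @property
    def training_min(self) -> pd.Series:
        return pd.Series({p: self.bin_edges[p][0] for p in self.predictors})

    @property
    def training_max(self) -> pd.Series:
        return pd.Series({p: self.bin_edges[p][-1] for p in self.predictors})

    def turnover(self, predictor: str, x) -> np.ndarray:
        """Evaluate ``F_p`` at values ``x`` (clamped to the training range)."""
        edges = self.bin_edges[predictor]
        cum = self.cum_importance[predictor]
        xc = np.clip(np.asarray(x, dtype=float), edges[0], edges[-1])
        steps = np.concatenate(([0.0], cum))  # value after k full bins
        k = np.searchsorted(edges[1:], xc, side="right")
        return steps[k]

    def transform(self, x) -> np.ndarray:
        """Map climate vector(s) to transformed genomic-composition space.

        ``x`` may be a mapping/Series (one site) or a DataFrame (sites x
        predictors); values outside the training range are clamped.  Returns
        an array of shape ``(n_predictors,)`` or ``(n_sites, n_predictors)``.
        """
        if isinstance(x, pd.DataFrame):
            missing = [p for p in self.predictors if p not in x.columns]
            if missing:
                raise KeyError(f"predictors missing from input: {missing}")
            return np.column_stack([self.turnover(p, x[p].to_numpy()) for p in self.predictors])
        if isinstance(x, (dict, pd.Series)):
            missing = [p for p in self.predictors if p not in x]
            if missing:
                raise KeyError(f"predictors missing from input: {missing}")
            return np.array([float(self.turnover(p, x[p])) for p in self.predictors])
        raise TypeError("x must be a Series/dict or DataFrame keyed by predictor name")

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "bin_edges": {p: self.bin_edges[p].tolist() for p in self.predictors},
            "cum_importance": {p: self.cum_importance[p].tolist() for p in self.predictors},
            "snp_r2": self.snp_r2.to_dict(),
            "importance": self.importance.to_dict(),
            "n_trees": self.n_trees,
            "seed": self.seed,
            "hyperparams": self.hyperparams,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TurnoverModel":
        return cls(
            predictors=list(d["predictors"]),
            bin_edges={p: np.asarray(v, float) for p, v in d["bin_edges"].items()},
            cum_importance={p: np.asarray(v, float) for p, v in d["cum_importance"].items()},
            snp_r2=pd.Series(d["snp_r2"]),
            importance=pd.Series(d["importance"]),
            n_trees=int(d["n_trees"]),
            seed=int(d["seed"]),
            hyperparams=dict(d.get("hyperparams", {})),
        )


def _split_importances(rf: RandomForestRegressor, n_samples: int):
    """(feature, threshold, impurity-decrease) triples over all trees.

    The decrease is the node-weighted impurity reduction divided by the
    training sample count, so per-SNP decreases sum to the forest's total
    explained impurity on the same scale across SNPs.
    """
    feats, thrs, gains = [], [], []
    for est in rf.estimators_:
        t = est.tree_
        internal = t.children_left != -1
        if not internal.any():
            continue
        l, r = t.children_left[internal], t.children_right[internal]
        w = t.weighted_n_node_samples
        gain = (
            w[internal] * t.impurity[internal]
            - w[l] * t.impurity[l]
            - w[r] * t.impurity[r]
        ) / n_samples
        feats.append(t.feature[internal])
        thrs.append(t.threshold[internal])
        gains.append(gain)
    if not feats:
        return (np.array([], int), np.array([]), np.array([]))
    return np.concatenate(feats), np.concatenate(thrs), np.concatenate(gains)


def _oob_r2(rf: RandomForestRegressor, y: np.ndarray) -> float:
    pred = rf.oob_prediction_
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def fit(
    freqs: pd.DataFrame,
    metrics: ClimateMetricTable | pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    n_bins: int = 201,
    max_features: float = 1 / 3,
) -> TurnoverModel:
    """Fit the gradient-forest turnover model.

    Parameters
    ----------
    freqs
        Landraces x SNPs allele-frequency matrix, rows aligned with the
        metric table's sites.
    metrics
        Climate predictors at the same sites.
    n_trees
        Trees per SNP forest.
    n_bins
        Bins along each predictor's training range for the turnover step
        functions.
    """
    X_df = metrics.metrics if isinstance(metrics, ClimateMetricTable) else metrics
    if len(freqs) != len(X_df):
        raise ValueError("freqs and metrics must describe the same sites")
    if len(freqs) < 20:
        raise ValueError("need at least 20 landraces to fit a turnover model")
    predictors = list(X_df.columns)
    X_all = X_df.to_numpy(float)
    # constant predictors can never be split on; excluding them up front keeps
    # every other turnover function invariant to their presence
    varying = [j for j in range(X_all.shape[1]) if np.ptp(X_all[:, j]) > 0]
    active = [predictors[j] for j in varying]
    X = X_all[:, varying]
    n, p = X.shape
    if p == 0:
        raise ValueError("all predictors are constant")

    edges = {}
    dens = {}
    for j, name in enumerate(active):
        lo, hi = float(X[:, j].min()), float(X[:, j].max())
        e = np.linspace(lo, hi, n_bins + 1)
        edges[name] = e
        counts, _ = np.histogram(X[:, j], bins=e)
        # density of split opportunities, smoothed and scaled to mean 1
        d = (counts + 0.5) / (n + 0.5 * n_bins) * n_bins
        dens[name] = d

    agg = {name: np.zeros(n_bins) for name in active}
    raw_importance = np.zeros(p)
    r2 = np.zeros(freqs.shape[1])

    snp_seeds = np.random.SeedSequence(seed).generate_state(freqs.shape[1]) % (2**31 - 1)
    mf = max(1, int(round(max_features * p)))
    for s, snp in enumerate(freqs.columns):
        y = freqs[snp].to_numpy(float)
        if np.ptp(y) == 0.0:
            r2[s] = 0.0
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=mf,
            bootstrap=True,
            oob_score=True,
            random_state=int(snp_seeds[s]),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree fits may leave some OOB rows empty
            rf.fit(X, y)
        r2_s = max(0.0, _oob_r2(rf, y))
        r2[s] = r2_s
        if r2_s <= 0.0:
            continue
        feat, thr, gain = _split_importances(rf, n)
        total = float(gain.sum())
        if total <= 0.0:
            continue
        scale = r2_s / total  # partition the SNP's R2 across its splits
        for j, name in enumerate(active):
            m = feat == j
            if not m.any():
                continue
            b = np.clip(np.digitize(thr[m], edges[name]) - 1, 0, n_bins - 1)
            np.add.at(agg[name], b, gain[m] * scale)
            raw_importance[j] += float(gain[m].sum()) * scale

    n_predictive = int((r2 > 0).sum())
    denom = max(n_predictive, 1)
    importance = pd.Series(0.0, index=predictors)
    importance[active] = raw_importance / denom

    cum = {}
    for j, name in enumerate(active):
        shaped = agg[name] / dens[name]
        c = np.cumsum(shaped)
        total = c[-1]
        if total > 0:
            c = c * (importance[name] / total)  # F_p(max) = aggregate importance
        cum[name] = c
    # constant predictors: single degenerate bin, identically-zero turnover
    for j, name in enumerate(predictors):
        if name not in cum:
            x0 = float(X_all[0, j])
            edges[name] = np.array([x0, x0])
            cum[name] = np.zeros(1)

    return TurnoverModel(
        predictors=predictors,
        bin_edges=edges,
        cum_importance=cum,
        snp_r2=pd.Series(r2, index=freqs.columns),
        importance=importance,
        n_trees=n_trees,
        seed=seed,
        hyperparams={
            "n_bins": n_bins,
            "max_features": max_features,
            "bootstrap": True,
            "max_depth": None,
        },
    )


def fraction_predicted(model: TurnoverModel) -> tuple[float, int, int]:
    """Fraction (and counts) of SNPs with positive out-of-bag R²."""
    n_pos = int((model.snp_r2 > 0).sum())
    n_all = int(model.snp_r2.size)
    return n_pos / n_all, n_pos, n_all
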