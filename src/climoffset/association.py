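"""Latent-factor association of allele frequencies with flowering time.

Pool-level genotype–phenotype association with correction for unobserved
population structure: latent factors are the top-K principal components of
the centred frequency matrix, each SNP's effect on the phenotype is tested
conditional on those factors (ridge/low-rank LFMM family), and z-scores are
recalibrated with a genomic-inflation factor before two-sided p-values and
Benjamini–Hochberg FDR selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gf import TurnoverModel

__all__ = ["AssociationResult", "choose_k", "lfmm_fit", "fdr_select",
           "compare_r2", "pca_freqs"]

#: theoretical median of a 1-df chi-square, used for genomic control
CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, df=1)


@dataclass
class AssociationResult:
    """Per-SNP association statistics and the FDR-selected set."""

    table: pd.DataFrame  # columns: effect, z, p, q, selected
    k: int
    gif: float
    alpha: float
    extras: dict = field(default_factory=dict)

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def pca_freqs(freqs: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centred (not scaled) allele-frequency matrix.

    Returns landrace scores on every component and the variance-explained
    fractions, which sum to 1 over all components.
    """
    if len(freqs) < 3:
        raise ValueError("need at least 3 landraces for a PCA")
    X = freqs.to_numpy(float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=freqs.index, columns=cols), frac


def choose_k(freqs: pd.DataFrame, k_max: int = 10) -> int:
    """Number of latent factors from the PCA screeplot: the elbow by the
    largest successive eigenvalue drop, capped at ``k_max``.  Warns when the
    spectrum shows little structure (top eigenvalue < 1.5x the median)."""
    _, frac = pca_freqs(freqs)
    ev = frac[: k_max + 1]
    if ev.size < 2:
        return 1
    if frac[0] < 1.5 * np.median(frac[frac > 0]):
        warnings.warn("eigenvalue spectrum nearly flat; latent structure is weak")
    drops = ev[:-1] - ev[1:]
    return int(np.argmax(drops)) + 1


def lfmm_fit(
    freqs: pd.DataFrame,
    phenotype: pd.Series,
    k: int,
    alpha: float = 0.05,
    calibrate: bool = True,
) -> AssociationResult:
    """Latent-factor association of each SNP with the phenotype.

    Factors are the top-``k`` principal-component scores of the centred
    frequency matrix; for each SNP the frequency is regressed on
    [1, phenotype, factors] and the phenotype coefficient is tested.  With
    ``k = 0`` this reduces to a simple linear regression per SNP.  When
    ``calibrate`` is set, squared z-scores are divided by the genomic
    inflation factor (median chi2 / theoretical median) before p-values.
    """
    pheno = phenotype.loc[freqs.index]
    if pheno.isna().any():
        raise ValueError("phenotype must be complete for all landraces used")
    n = len(freqs)
    if k >= n:
        raise ValueError("number of latent factors must be smaller than n landraces")

    Y = freqs.to_numpy(float)
    x = pheno.to_numpy(float)
    design = [np.ones(n), x]
    if k > 0:
        scores, _ = pca_freqs(freqs)
        design.extend(scores.iloc[:, :k].to_numpy(float).T)
    D = np.column_stack(design)
    q = D.shape[1]

    # one least-squares solve shared by all SNPs (common design matrix)
    beta, _, rank, _ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    dof = max(n - rank, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    DtD_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.maximum(sigma2 * DtD_inv[1, 1], 1e-300))
    effect = beta[1]
    z = effect / se

    gif = 1.0
    if calibrate:
        gif = float(np.median(z**2) / CHI2_MEDIAN_1DF)
        gif = max(gif, 1e-12)
    z_cal = z / np.sqrt(gif)
    p = 2.0 * stats.norm.sf(np.abs(z_cal))

    selected, qvals = fdr_select(p, alpha)
    table = pd.DataFrame(
        {"effect": effect, "z": z, "z_calibrated": z_cal, "p": p, "q": qvals,
         "selected": selected},
        index=freqs.columns,
    )
    return AssociationResult(table=table, k=k, gif=gif, alpha=alpha)


def fdr_select(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up selection at FDR ``alpha``.

    Returns the boolean selection mask and the BH-adjusted q-values
    (monotone non-decreasing in sorted-p order).
    """
    p = np.asarray(pvalues, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, q


def compare_r2(model: TurnoverModel, selected_snps) -> dict:
    """Compare turnover-model predictability (per-SNP R²) of an associated
    SNP set against all SNPs with a two-sided Wilcoxon rank-sum test."""
    selected_snps = pd.Index(selected_snps)
    if len(selected_snps) == 0:
        raise ValueError("selected SNP set is empty")
    missing = selected_snps.difference(model.snp_r2.index)
    if len(missing) > 0:
        raise ValueError(f"selected SNPs not in model: {list(missing[:5])}")
    r2_sel = model.snp_r2.loc[selected_snps].to_numpy(float)
    r2_all = model.snp_r2.to_numpy(float)
    stat, p = stats.ranksums(r2_sel, r2_all)
    return {
        "mean_r2_selected": float(r2_sel.mean()),
        "mean_r2_all": float(r2_all.mean()),
        "wilcoxon_stat": float(stat),
        "p": float(p),
        "n_selected": int(r2_sel.size),
        "n_all": int(r2_all.size),
    }
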