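"""Cross-validated prediction accuracy and correlation inference.

Implements the validation loop used to judge a genomic-prediction model on
a small panel: the lines are split once into k folds; for each fold a full
GBLUP model (training-only allele frequencies, GRM, REML, BLUP, SNP
back-solve) is fitted on the other k-1 folds and the held-out lines are
scored from the exported SNP coefficients.  Accuracy is the Pearson
correlation between the scores and the observed line means, with 95 %
Fisher-z confidence intervals and a two-sided t-test p-value per fold.

A trait's prediction is called significant under a two-tier rule: at least
one fold must beat the multiplicity-adjusted threshold (default 0.001) and
every fold must beat the nominal 0.05 level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypePanel, PhenotypeTable
from .kinship import allele_frequencies, compute_grm
from .mixed_model import (
    SNPEffectModel,
    backsolve_snp_effects,
    blup_breeding_values,
    reml_fit,
)

__all__ = [
    "FoldAssignment",
    "CVReport",
    "kfold_split",
    "score_lines",
    "pearson_r",
    "fisher_ci",
    "corr_pvalue",
    "cross_validate",
    "significance_decision",
    "trait_correlation_matrix",
]


@dataclass
class FoldAssignment:
    """A k-fold partition of the lines; labels run 1..k, sizes differ by <= 1."""

    k: int
    labels: np.ndarray
    seed: int | None

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)

    def sizes(self) -> dict[int, int]:
        return {f: int((self.labels == f).sum()) for f in range(1, self.k + 1)}


def kfold_split(sample_ids, k: int = 5, seed: int | None = None) -> FoldAssignment:
    """Uniformly random fold labels, deterministic given ``seed``.

    The first ``n mod k`` folds receive one extra line, so fold sizes are
    ceil(n/k) or floor(n/k) (e.g. 149 lines in 5 folds -> 30,30,30,30,29).
    """
    n = len(sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of lines ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=np.int64)
    base, extra = divmod(n, k)
    start = 0
    for f in range(1, k + 1):
        size = base + (1 if f <= extra else 0)
        labels[perm[start:start + size]] = f
        start += size
    return FoldAssignment(k=k, labels=labels, seed=seed)


def score_lines(model: SNPEffectModel, panel: GenotypePanel) -> np.ndarray:
    """Score every line in ``panel`` with a trained coefficient model.

    score = sum_i b_i * d_i, where d_i is the line's dosage of the scored
    allele (missing calls imputed at 2p from the model's stored training
    frequency).  Coefficients whose scored allele matches the panel's
    *other* allele are flipped (d -> 2 - d); SNPs absent from the panel or
    with irreconcilable alleles are excluded with a warning, and more than
    50 % exclusions is an error.
    """
    panel_pos = {s: i for i, s in enumerate(panel.snp_ids)}
    m = len(model.snp_ids)
    cols, flips, keep = [], [], []
    n_absent = n_mismatch = 0
    for i, sid in enumerate(model.snp_ids):
        j = panel_pos.get(sid)
        if j is None:
            n_absent += 1
            continue
        if model.scored_allele[i] == panel.allele1[j]:
            flip = False
        elif model.scored_allele[i] == panel.allele2[j]:
            flip = True
        else:
            n_mismatch += 1
            continue
        cols.append(j)
        flips.append(flip)
        keep.append(i)
    n_excl = n_absent + n_mismatch
    if n_excl > 0.5 * m:
        raise ValueError(
            f"{n_excl}/{m} model SNPs unusable in this panel "
            f"({n_absent} absent, {n_mismatch} allele mismatches)"
        )
    if n_excl:
        warnings.warn(
            f"excluded {n_excl}/{m} model SNPs ({n_absent} absent from panel, "
            f"{n_mismatch} allele mismatches)"
        )
    cols = np.asarray(cols, dtype=np.intp)
    keep = np.asarray(keep, dtype=np.intp)
    flips = np.asarray(flips, dtype=bool)
    d = panel.dosages[:, cols]
    d = np.where(flips[None, :], 2.0 - d, d)
    imput = 2.0 * model.frequencies[keep]
    d = np.where(np.isnan(d), imput[None, :], d)
    return d @ model.coefficients[keep]


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; rejects degenerate input explicitly."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} has zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh r +/- z / sqrt(n-3))."""
    if n < 4:
        raise ValueError("Fisher-z interval needs n >= 4")
    if abs(r) >= 1.0:
        return (float(r), float(r))  # degenerate
    z = stats.norm.ppf((1.0 + level) / 2.0)
    half = z / np.sqrt(n - 3)
    zr = np.arctanh(r)
    return (float(np.tanh(zr - half)), float(np.tanh(zr + half)))


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for H0: rho = 0 via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: p-value exactly 0 (degenerate)")
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class SignificanceVerdict:
    significant: bool
    n_below_nominal: int
    n_below_adjusted: int
    n_models: int


def significance_decision(
    pvalues, nominal: float = 0.05, adjusted: float = 0.001
) -> SignificanceVerdict:
    """Two-tier rule: min(p) < adjusted AND every p < nominal."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    return SignificanceVerdict(
        significant=bool((p.min() < adjusted) and (p < nominal).all()),
        n_below_nominal=int((p < nominal).sum()),
        n_below_adjusted=int((p < adjusted).sum()),
        n_models=int(p.size),
    )


@dataclass
class CVReport:
    """Per-fold and per-trait cross-validation results."""

    folds: pd.DataFrame  # trait, fold, n_train, n_test, r, ci_low, ci_high, p_value, converged
    summary: pd.DataFrame  # trait, mean_r, n_below_nominal, n_below_adjusted, significant
    k: int
    seed: int | None

    def to_tsv(self, path) -> None:
        self.folds.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        out = {
            "k": self.k,
            "seed": self.seed,
            "traits": self.summary.set_index("trait").to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2, default=float)


def cross_validate(
    panel: GenotypePanel,
    phenos: PhenotypeTable,
    traits=None,
    k: int = 5,
    seed: int | None = None,
    diagonal: str = "yang",
    grm_missing_max: float = 0.02,
    nominal: float = 0.05,
    adjusted: float = 0.001,
    return_models: bool = False,
) -> CVReport:
    """k-fold cross-validation of GBLUP prediction, one shared partition.

    Every training-set quantity (allele frequencies, GRM, variance
    components, SNP effects) is computed from the training lines only; test
    lines are scored from the exported coefficients, so the evaluation is
    leak-free by construction.  Folds whose REML fit fails to converge are
    flagged and excluded from the per-trait mean.
    """
    if traits is None:
        traits = phenos.traits
    folds = kfold_split(panel.sample_ids, k=k, seed=seed)
    rows = []
    models: dict[tuple[str, int], SNPEffectModel] = {}
    for trait in traits:
        means_all = phenos.line_means(trait, sample_ids=panel.sample_ids)
        if len(means_all) != panel.n_samples:
            raise ValueError(f"trait {trait!r}: phenotypes missing for some lines")
        yfull = means_all.to_numpy(dtype=float)
        for f in range(1, k + 1):
            test_idx = folds.fold_indices(f)
            train_idx = np.setdiff1d(np.arange(panel.n_samples), test_idx)
            train_panel = panel.subset(samples=train_idx)
            test_panel = panel.subset(samples=test_idx)
            y_train = yfull[train_idx]
            y_test = yfull[test_idx]

            grm = compute_grm(train_panel, diagonal=diagonal,
                              grm_missing_max=grm_missing_max)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vc = reml_fit(y_train, grm)
                blup = blup_breeding_values(vc, y_train, grm, compute_pev=False)
                p = allele_frequencies(train_panel)
                model = backsolve_snp_effects(blup, vc, train_panel, p)
                scores = score_lines(model, test_panel)
            if return_models:
                models[(trait, f)] = model
            r = pearson_r(scores, y_test)
            lo, hi = fisher_ci(r, len(y_test))
            pv = corr_pvalue(r, len(y_test))
            rows.append(
                {
                    "trait": trait,
                    "fold": f,
                    "n_train": len(train_idx),
                    "n_test": len(test_idx),
                    "r": r,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": pv,
                    "converged": vc.converged,
                }
            )
            if not vc.converged:
                warnings.warn(
                    f"trait {trait!r} fold {f}: REML did not converge; "
                    "fold excluded from the trait mean"
                )
    df = pd.DataFrame(rows)
    summaries = []
    for trait in traits:
        sub = df[(df["trait"] == trait) & df["converged"]]
        verdict = significance_decision(sub["p_value"], nominal, adjusted)
        summaries.append(
            {
                "trait": trait,
                "mean_r": float(sub["r"].mean()),
                "n_folds_used": len(sub),
                "n_below_nominal": verdict.n_below_nominal,
                "n_below_adjusted": verdict.n_below_adjusted,
                "significant": verdict.significant,
            }
        )
    report = CVReport(folds=df, summary=pd.DataFrame(summaries), k=k, seed=seed)
    if return_models:
        return report, models
    return report


def trait_correlation_matrix(phenos: PhenotypeTable, sample_ids=None) -> pd.DataFrame:
    """Pairwise Pearson correlation between trait line-means."""
    traits = phenos.traits
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    cols = {}
    for t in traits:
        m = phenos.line_means(t, sample_ids=sample_ids)
        if m.to_numpy().std() == 0:
            raise ValueError(f"trait {t!r} is constant across lines")
        cols[t] = m
    df = pd.DataFrame(cols)
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
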