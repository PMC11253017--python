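"""Single-GRM linear mixed model: REML variance components, GBLUP breeding
values, and back-solved per-SNP coefficients.

Model
-----
For the n-vector of per-line mean phenotypes y,

    y = 1 mu + g + e,      g ~ N(0, A sigma_g^2),   e ~ N(0, I sigma_e^2),

with A the genomic relationship matrix.  Variance components maximize the
restricted log-likelihood

    lR = -1/2 [ (n-1) log 2pi + log|V| + log|1' V^-1 1| + y' P y ],

where V = A sigma_g^2 + I sigma_e^2 and P = V^-1 - V^-1 1 (1'V^-1 1)^-1 1'V^-1.
A one-time eigendecomposition A = U L U' reduces every likelihood, gradient
and average-information evaluation to O(n) diagonal arithmetic, which also
makes brute-force likelihood-grid validation cheap.

The optimizer is AI-REML (average information as approximate Hessian) with
a few EM warm-up iterations and an EM fallback whenever an AI step leaves
the feasible region or decreases the likelihood.  Components are floored at
1e-6 * Var(y) so V stays invertible; hitting the floor is flagged.

Narrow-sense heritability is reported as h2 = V(G)/V(P), where V(G) is the
genetic variance realized across the sampled lines,

    V(G) = sigma_g^2 * (tr A - 1'A 1 / n) / (n - 1),

i.e. the expected sample variance of g under g ~ N(0, A sigma_g^2).  When
the GRM diagonal averages 1 this reduces to the familiar
sigma_g^2 / (sigma_g^2 + sigma_e^2); for fully inbred panels, whose GRM
diagonal averages about 2 under the 2p(1-p) standardization, the plain
ratio would understate the genetic fraction of variance roughly twofold.
The standard error of h2 follows by the delta method.

BLUP breeding values follow the standard mixed-model expressions

    mu_hat = (1'V^-1 1)^-1 1'V^-1 y,      g_hat = sigma_g^2 A V^-1 (y - 1 mu_hat),

and per-SNP coefficients are obtained by back-solving the equivalent ridge
SNP-BLUP representation: with W the column-standardized dosage matrix,

    u_hat = (sigma_g^2 / m) W' V^-1 (y - 1 mu_hat),

which, when A = W W'/m, satisfies W u_hat = g_hat exactly.  Coefficients are
stored per counted-allele dosage unit (b_i = u_hat_i / sd_i) together with
the training allele frequencies so any genotyped line can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .genotype_io import GenotypePanel
from .kinship import GRM

__all__ = [
    "VarianceComponents",
    "BreedingValues",
    "SNPEffectModel",
    "reml_fit",
    "blup_breeding_values",
    "backsolve_snp_effects",
    "ridge_snp_blup",
]


@dataclass
class VarianceComponents:
    """REML estimates for the single-GRM model, in trait units squared."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    se_sigma_g2: float
    se_sigma_e2: float
    se_h2: float
    loglik: float
    n_iterations: int
    converged: bool
    message: str = ""
    loglik_path: list = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d.pop("loglik_path")
        return d


@dataclass
class BreedingValues:
    """BLUP genetic values (deviations from the fitted mean).

    ``vinv_residual`` caches V^-1 (y - 1 mu_hat) from the fit; the SNP
    back-solve consumes it so the two stages stay algebraically consistent.
    """

    sample_ids: np.ndarray
    bv: np.ndarray
    mu: float
    pev: np.ndarray | None = None
    vinv_residual: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"FID": self.sample_ids, "IID": self.sample_ids, "BV": self.bv}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SNPEffectModel:
    """Per-SNP, per-allele scoring coefficients with their frequencies.

    ``coefficients[i]`` is the change in predicted genetic value per copy of
    ``scored_allele[i]``; ``frequencies[i]`` is the training-set frequency of
    that allele, used to impute missing calls as dosage 2p when scoring.
    """

    snp_ids: np.ndarray
    scored_allele: np.ndarray
    other_allele: np.ndarray
    coefficients: np.ndarray
    frequencies: np.ndarray
    mu: float
    n_train: int
    sigma_g2: float
    sigma_e2: float

    def to_frame(self, include_frequency: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "allele": self.scored_allele,
                "coefficient": self.coefficients,
            }
        )
        if include_frequency:
            df["frequency"] = self.frequencies
        return df

    def to_tsv(self, path, include_frequency: bool = True) -> None:
        # %.17g round-trips float64 exactly, so exported coefficients score
        # identically to the in-memory model
        self.to_frame(include_frequency).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path, other_allele=None) -> "SNPEffectModel":
        """Load a score file written by :meth:`to_tsv`.

        The file carries no metadata, so ``mu`` and the variance components
        are zeroed; scoring only needs coefficients and frequencies.
        """
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        m = len(df)
        freq = (
            df["frequency"].to_numpy(dtype=float)
            if "frequency" in df
            else np.full(m, np.nan)
        )
        return cls(
            snp_ids=df["snp_id"].to_numpy(dtype=object),
            scored_allele=df["allele"].to_numpy(dtype=object),
            other_allele=(
                np.asarray(other_allele, dtype=object)
                if other_allele is not None
                else np.full(m, "?", dtype=object)
            ),
            coefficients=df["coefficient"].to_numpy(dtype=float),
            frequencies=freq,
            mu=0.0,
            n_train=0,
            sigma_g2=np.nan,
            sigma_e2=np.nan,
        )


# ---------------------------------------------------------------------------
# REML


def _check_aligned(y: np.ndarray, A: GRM | np.ndarray):
    y = np.asarray(y, dtype=float).ravel()
    if isinstance(A, GRM):
        ids = A.sample_ids
        mat = A.matrix
    else:
        mat = np.asarray(A, dtype=float)
        ids = None
    if mat.shape[0] != mat.shape[1] or mat.shape[0] != y.size:
        raise ValueError("y and A are not index-aligned")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("A is not symmetric")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    return y, mat, ids


class _RotatedREML:
    """Likelihood machinery in the eigenbasis of A."""

    def __init__(self, y: np.ndarray, A: np.ndarray):
        lam, U = eigh(A)
        self.lam = np.clip(lam, 0.0, None)  # clip tiny negative float noise
        self.yt = U.T @ y
        self.xt = U.T @ np.ones_like(y)
        self.n = y.size
        self.U = U

    def loglik(self, sg: float, se: float) -> float:
        d = sg * self.lam + se
        dinv = 1.0 / d
        xdx = np.sum(self.xt**2 * dinv)
        xdy = np.sum(self.xt * self.yt * dinv)
        ypy = np.sum(self.yt**2 * dinv) - xdy**2 / xdx
        return -0.5 * (
            (self.n - 1) * np.log(2.0 * np.pi)
            + np.sum(np.log(d))
            + np.log(xdx)
            + ypy
        )

    def _p_apply(self, dinv, xdx, v):
        return dinv * v - dinv * self.xt * (np.sum(self.xt * v * dinv) / xdx)

    def derivatives(self, sg: float, se: float):
        """Score vector and average-information matrix at (sg, se)."""
        d = sg * self.lam + se
        dinv = 1.0 / d
        xdx = np.sum(self.xt**2 * dinv)
        r = self._p_apply(dinv, xdx, self.yt)  # P y in rotated basis
        # traces of P V_i
        corr_g = np.sum(self.lam * dinv**2 * self.xt**2) / xdx
        corr_e = np.sum(dinv**2 * self.xt**2) / xdx
        tr_pa = np.sum(self.lam * dinv) - corr_g
        tr_p = np.sum(dinv) - corr_e
        ypapy = np.sum(self.lam * r**2)
        yppy = np.sum(r**2)
        score = np.array([-0.5 * (tr_pa - ypapy), -0.5 * (tr_p - yppy)])
        a = self.lam * r  # A P y
        pa = self._p_apply(dinv, xdx, a)
        pr = self._p_apply(dinv, xdx, r)
        ai = 0.5 * np.array(
            [
                [np.sum(a * pa), np.sum(a * pr)],
                [np.sum(a * pr), np.sum(r * pr)],
            ]
        )
        return score, ai, (tr_pa, tr_p, ypapy, yppy)


def reml_fit(
    y: np.ndarray,
    A: GRM | np.ndarray,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
    n_em: int = 3,
) -> VarianceComponents:
    """Estimate (sigma_g^2, sigma_e^2) by AI-REML with EM warm-up/fallback.

    Requires n >= 10 lines and a non-constant y.  Non-convergence after
    ``max_iter`` returns ``converged=False`` with diagnostics rather than
    raising.  Standard errors come from the inverse average-information
    matrix at the optimum; se(h2) by the delta method.
    """
    y, mat, _ = _check_aligned(y, A)
    n = y.size
    if n < 10:
        raise ValueError(f"REML needs at least 10 lines, got {n}")
    vy = y.var(ddof=1)
    if vy <= 0:
        raise ValueError("y has zero variance")

    rot = _RotatedREML(y, mat)
    if rot.lam.max() - rot.lam.min() < 1e-9 * max(rot.lam.max(), 1.0):
        # A proportional to I: only sigma_g^2 + sigma_e^2 is identified.
        warnings.warn(
            "relationship matrix is (numerically) a multiple of the identity; "
            "only the total variance is identified — returning an equal split"
        )
        c = rot.lam.mean() if rot.lam.mean() > 0 else 1.0
        # total variance tau solves the one-parameter REML problem exactly
        xdx = np.sum(rot.xt**2)
        ypy = np.sum(rot.yt**2) - np.sum(rot.xt * rot.yt) ** 2 / xdx
        tau = ypy / (n - 1)
        sg = tau / (c + 1.0)
        se_ = tau - sg * c
        ll = rot.loglik(sg, se_)
        return VarianceComponents(
            sigma_g2=sg, sigma_e2=se_, h2=sg * c / (sg * c + se_),
            se_sigma_g2=np.nan, se_sigma_e2=np.nan, se_h2=np.nan,
            loglik=ll, n_iterations=0, converged=True,
            message="unidentifiable: A ~ I, equal-split solution",
        )

    floor = 1e-6 * vy
    theta = np.array([vy / 2.0, vy / 2.0])
    ll = rot.loglik(*theta)
    ll_path = [float(ll)]
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        score, ai, traces = rot.derivatives(*theta)
        use_em = it <= n_em
        new = None
        if not use_em:
            try:
                delta = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                cand = theta + delta
                # step-halve while infeasible or likelihood-decreasing
                for _ in range(20):
                    if np.all(cand >= floor) and rot.loglik(*cand) >= ll - 1e-12:
                        new = cand
                        break
                    delta = delta / 2.0
                    cand = theta + delta
        if new is None:
            # EM step: theta_i += theta_i^2 (y'P V_i P y - tr(P V_i)) / n
            tr_pa, tr_p, ypapy, yppy = traces
            new = np.array(
                [
                    theta[0] + theta[0] ** 2 * (ypapy - tr_pa) / n,
                    theta[1] + theta[1] ** 2 * (yppy - tr_p) / n,
                ]
            )
            new = np.maximum(new, floor)
            # EM is ascent in exact arithmetic; guard against float edge cases
            for _ in range(20):
                if rot.loglik(*new) >= ll - 1e-12:
                    break
                new = (new + theta) / 2.0
        new_ll = rot.loglik(*new)
        dll = new_ll - ll
        rel = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), floor))
        theta, ll = new, new_ll
        ll_path.append(float(ll))
        if abs(dll) < tol_loglik and rel < tol_param:
            converged = True
            break
    if not converged:
        message = f"no convergence in {max_iter} iterations (|dll| last step {abs(dll):.2e})"
        warnings.warn("REML did not converge: " + message)
    if np.any(theta <= floor * (1 + 1e-9)):
        message = (message + "; " if message else "") + "variance component at lower bound"

    # genetic-variance scale of this sample: V(G) = sigma_g^2 * c_a
    c_a = float((np.trace(mat) - mat.sum() / n) / (n - 1))
    vg = theta[0] * c_a
    h2 = float(vg / (vg + theta[1]))

    _, ai, _ = rot.derivatives(*theta)
    try:
        cov = np.linalg.inv(ai)
        se_g = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_e = float(np.sqrt(max(cov[1, 1], 0.0)))
        s = vg + theta[1]
        grad = np.array([c_a * theta[1], -vg]) / s**2
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se_g = se_e = se_h2 = np.nan

    return VarianceComponents(
        sigma_g2=float(theta[0]),
        sigma_e2=float(theta[1]),
        h2=h2,
        se_sigma_g2=se_g,
        se_sigma_e2=se_e,
        se_h2=se_h2,
        loglik=float(ll),
        n_iterations=it,
        converged=converged,
        message=message,
        loglik_path=ll_path,
    )


# ---------------------------------------------------------------------------
# BLUP


def blup_breeding_values(
    vc: VarianceComponents,
    y: np.ndarray,
    A: GRM | np.ndarray,
    compute_pev: bool = True,
) -> BreedingValues:
    """BLUP of the genomic values given fitted variance components."""
    if not vc.converged:
        warnings.warn("variance components did not converge; BLUPs may be unreliable")
    y, mat, ids = _check_aligned(y, A)
    n = y.size
    v = vc.sigma_g2 * mat + vc.sigma_e2 * np.eye(n)
    try:
        vinv_y = np.linalg.solve(v, y)
        vinv_1 = np.linalg.solve(v, np.ones(n))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "V is numerically singular; consider a small diagonal jitter on A"
        ) from err
    mu = float(np.sum(vinv_y) / np.sum(vinv_1))
    r = vinv_y - mu * vinv_1  # = V^-1 (y - 1 mu)
    g = vc.sigma_g2 * (mat @ r)
    pev = None
    if compute_pev:
        vinv_a = np.linalg.solve(v, vc.sigma_g2 * mat)
        # P Asg = V^-1 Asg - V^-1 1 (1'V^-1 1)^-1 1' V^-1 Asg
        p_a = vinv_a - np.outer(vinv_1, vinv_1 @ (vc.sigma_g2 * mat)) / np.sum(vinv_1)
        pev = np.diag(vc.sigma_g2 * mat - (vc.sigma_g2 * mat) @ p_a).copy()
    if ids is None:
        ids = np.array([str(i) for i in range(n)], dtype=object)
    return BreedingValues(sample_ids=ids, bv=g, mu=mu, pev=pev, vinv_residual=r)


def backsolve_snp_effects(
    bv: BreedingValues,
    vc: VarianceComponents,
    panel: GenotypePanel,
    p: np.ndarray,
) -> SNPEffectModel:
    """Back-solve per-SNP coefficients from fitted breeding values.

    ``panel`` must be the training panel the GRM was built from and ``p``
    its allele frequencies.  Missing dosages are imputed at their mean 2p
    before standardizing; monomorphic SNPs get coefficient 0 with a warning.
    """
    if bv.vinv_residual is None:
        raise ValueError("BreedingValues lack the cached V^-1 residual; refit BLUP")
    if len(bv.sample_ids) != panel.n_samples or not np.array_equal(
        bv.sample_ids, panel.sample_ids
    ):
        raise ValueError("breeding values and panel sample ids do not match")
    p = np.asarray(p, dtype=float)
    if p.size != panel.n_snps:
        raise ValueError("allele frequency vector does not match panel SNPs")
    poly = (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic SNP(s) assigned coefficient 0"
        )
    # divide by the number of SNPs that actually carry signal, matching the
    # GRM denominator (monomorphic SNPs are skipped there too)
    m = int(poly.sum())
    if m == 0:
        raise ValueError("no polymorphic SNPs to back-solve")
    sd = np.sqrt(np.where(poly, 2.0 * p * (1.0 - p), 1.0))
    x = np.nan_to_num(panel.dosages - 2.0 * p[None, :])  # missing -> 0 deviation
    w = np.where(poly[None, :], x / sd[None, :], 0.0)
    u = (vc.sigma_g2 / m) * (w.T @ bv.vinv_residual)
    b = np.where(poly, u / sd, 0.0)
    return SNPEffectModel(
        snp_ids=panel.snp_ids.copy(),
        scored_allele=panel.allele1.copy(),
        other_allele=panel.allele2.copy(),
        coefficients=b,
        frequencies=p.copy(),
        mu=bv.mu,
        n_train=panel.n_samples,
        sigma_g2=vc.sigma_g2,
        sigma_e2=vc.sigma_e2,
    )


def ridge_snp_blup(
    y: np.ndarray, panel: GenotypePanel, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge SNP-BLUP on standardized dosages (independent GBLUP oracle).

    Solves effects = (W'W + lam * m * I)^-1 W'(y - ybar) and returns
    (effects, genomic values W @ effects).  Requires a complete (no
    missingness) panel.  With lam = sigma_e^2 / sigma_g^2 and the GRM taken
    as W W'/m, the genomic values equal the GBLUP breeding values.
    """
    y = np.asarray(y, dtype=float).ravel()
    if panel.missing_mask().any():
        raise ValueError("ridge SNP-BLUP requires a panel without missing calls")
    from .kinship import allele_frequencies

    p = allele_frequencies(panel)
    poly = (p > 0) & (p < 1)
    sd = np.sqrt(np.where(poly, 2.0 * p * (1.0 - p), 1.0))
    w = np.where(poly[None, :], (panel.dosages - 2.0 * p[None, :]) / sd[None, :], 0.0)
    w = w[:, poly]
    m = int(poly.sum())
    lhs = w.T @ w + lam * m * np.eye(m)
    rhs = w.T @ (y - y.mean())
    try:
        effects = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("singular ridge system; using pseudo-inverse")
        effects = np.linalg.pinv(lhs) @ rhs
    full = np.zeros(panel.n_snps)
    full[poly] = effects
    return full, w @ effects
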