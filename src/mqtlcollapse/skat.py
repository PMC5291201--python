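"""Weighted variance-component score test for quantitative traits.

The region test used throughout this package is a kernel-based score test:
methylation ``y`` is modelled as

    y_i = alpha_0 + alpha' X_i + beta' G_i + eps_i,

where the per-variant effects ``beta_j`` are treated as random with mean 0 and
variance ``w_j^2 * tau``.  Testing ``tau = 0`` yields a quadratic-form score
statistic ``Q = r' G W^2 G' r / (2 sigma^2)`` whose null distribution is a
positive mixture of 1-df chi-square variables weighted by the eigenvalues of
the covariate-projected weighted kernel.  Tail probabilities of that mixture
are computed by numerical inversion of the characteristic function (Imhof's
method), with a moment-matched non-central chi-square approximation as a
far-tail fallback.  Per-variant weights are the Beta(a1, a2) density evaluated
at the minor allele frequency, which up-weights rarer variants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

__all__ = [
    "WeightSpec",
    "NullModel",
    "KernelTestResult",
    "beta_weights",
    "fit_null",
    "kernel_statistic",
    "quadform_pvalue",
    "skat_test",
    "permutation_pvalue",
    "single_variant_regression",
    "burden_test",
]

P_FLOOR = 1e-300
EIGEN_REL_TOL = 1e-10


@dataclass(frozen=True)
class WeightSpec:
    """Beta-density MAF weighting scheme.

    ``w_j = Beta.pdf(maf_j; a1, a2)``.  The defaults (1, 25) strongly
    up-weight rare variants; ``a1 = a2 = 1`` gives flat weights.
    """

    a1: float = 1.0
    a2: float = 25.0
    custom_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("Beta weight shape parameters must be positive")


@dataclass
class NullModel:
    """Covariate-only OLS fit reused across many region tests.

    Holds the residual vector, the residual variance estimate
    ``sigma2 = RSS / (n - rank)`` and an orthonormal basis ``q_basis`` of the
    design column space, sufficient to project genotype columns onto the
    covariate-orthogonal space.
    """

    residuals: np.ndarray
    sigma2: float
    q_basis: np.ndarray
    coef: np.ndarray
    rank: int

    @property
    def n_samples(self) -> int:
        return self.residuals.shape[0]

    def project(self, G: np.ndarray) -> np.ndarray:
        """Return ``(I - H) G``: genotypes residualized on the null design."""
        return G - self.q_basis @ (self.q_basis.T @ G)


@dataclass
class KernelTestResult:
    Q: float
    eigenvalues: np.ndarray
    p_value: float
    p_method: str
    n_variants: int
    n_samples: int
    dropped_variants: list = field(default_factory=list)


def beta_weights(mafs: np.ndarray, spec: WeightSpec | None = None) -> np.ndarray:
    """Per-variant weights: the Beta(a1, a2) density at each folded MAF."""
    spec = spec or WeightSpec()
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("MAF values must lie in (0, 0.5]")
    if spec.custom_weights is not None:
        w = np.asarray(spec.custom_weights, dtype=float)
        if w.shape != mafs.shape:
            raise ValueError("custom_weights length must match number of variants")
        return w
    return stats.beta.pdf(mafs, spec.a1, spec.a2)


def _design_matrix(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("covariate rows must match sample count")
    return np.column_stack([np.ones(n), X])


def fit_null(y: np.ndarray, covariates: np.ndarray | None = None) -> NullModel:
    """Fit the covariate-only linear model by OLS.

    An intercept is always included.  Raises on rank-deficient designs and on
    degenerate (near-zero) residual variance, both of which make the score
    test undefined.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X = _design_matrix(n, covariates)
    if n <= X.shape[1] + 1:
        raise ValueError("too few samples for the null design")
    q, r_mat = np.linalg.qr(X)
    diag = np.abs(np.diag(r_mat))
    if np.any(diag < 1e-10 * max(diag.max(), 1.0)):
        bad = np.where(diag < 1e-10 * max(diag.max(), 1.0))[0].tolist()
        raise ValueError(f"rank-deficient null design; collinear columns {bad}")
    coef = np.linalg.solve(r_mat, q.T @ y)
    resid = y - X @ coef
    rank = X.shape[1]
    rss = float(resid @ resid)
    sigma2 = rss / (n - rank)
    if sigma2 < 1e-12 * max(float(y @ y) / n, 1e-12):
        raise ValueError("degenerate residual variance: outcome is exactly linear in covariates")
    return NullModel(residuals=resid, sigma2=sigma2, q_basis=q, coef=coef, rank=rank)


def kernel_statistic(
    null: NullModel, G: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray, list]:
    """Quadratic-form statistic and its null mixture spectrum.

    ``Q = || W G' r ||^2 / (2 sigma2)`` with the weighted linear kernel
    ``K = G diag(w^2) G'``.  The returned eigenvalues are those of
    ``(1/2) W G' (I-H) G W`` so that under the null ``Q ~ sum_i lambda_i
    chi2_1`` (any common rescaling of the pair would leave the tail
    probability unchanged).  Zero-variance genotype columns are dropped with
    a record; an all-zero matrix is an error.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    w = np.asarray(w, dtype=float)
    if G.shape[1] != w.shape[0]:
        raise ValueError("weight vector length must equal number of genotype columns")
    if G.shape[0] != null.n_samples:
        raise ValueError("genotype rows must align with the null model samples")
    variances = G.var(axis=0)
    keep = variances > 0
    dropped = np.where(~keep)[0].tolist()
    if not np.any(keep):
        raise ValueError("no testable variants: all genotype columns have zero variance")
    G = G[:, keep]
    w = w[keep]
    Gc = G - G.mean(axis=0)  # column centering; no-op once projected on an intercept
    score = w * (Gc.T @ null.residuals)
    Q = float(score @ score) / (2.0 * null.sigma2)
    Gt = null.project(Gc) * w  # (I-H) G W, n x p
    half_gram = 0.5 * (Gt.T @ Gt)
    lam = np.linalg.eigvalsh(half_gram)
    lam = np.clip(lam, 0.0, None)
    if lam.max() <= 0:
        raise ValueError("kernel spectrum is identically zero")
    lam = lam[lam > EIGEN_REL_TOL * lam.max()]
    return Q, lam[::-1], dropped


def _imhof_tail(q: float, lam: np.ndarray) -> tuple[float, float]:
    """P(sum lam_i chi2_1 >= q) by numerical inversion of the CF (Imhof)."""

    def phase(u: float) -> float:
        return 0.5 * np.sum(np.arctan(lam * u))

    def envelope(u: float) -> float:
        return math.exp(-0.25 * np.sum(np.log1p((lam * u) ** 2))) / u

    def integrand(u: float) -> float:
        return math.sin(phase(u) - 0.5 * q * u) * envelope(u)

    # sin(theta) = sin(phi - qu/2); beyond a cut point split into sin/cos
    # components of frequency q/2 so the oscillatory tail can be handled by
    # the dedicated Fourier-integral routine (QAWF)
    cut = max(1.0 / lam.max(), 2.0 * math.pi / q)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        head, err1 = integrate.quad(integrand, 0.0, cut, limit=200)
        tail_cos, err2 = integrate.quad(
            lambda u: math.sin(phase(u)) * envelope(u),
            cut,
            np.inf,
            weight="cos",
            wvar=0.5 * q,
            limit=200,
        )
        tail_sin, err3 = integrate.quad(
            lambda u: math.cos(phase(u)) * envelope(u),
            cut,
            np.inf,
            weight="sin",
            wvar=0.5 * q,
            limit=200,
        )
    val = head + tail_cos - tail_sin
    return 0.5 + val / math.pi, err1 + err2 + err3


def _liu_tail(q: float, lam: np.ndarray) -> float:
    """Moment-matched (non-central) chi-square tail approximation.

    Matches the first two moments and the skewness (or, when infeasible, the
    kurtosis) of the mixture to a non-central chi-square, then evaluates its
    survivor function.  Monotone in ``q`` and stable on the log scale down to
    the p-value floor.
    """
    c1 = float(np.sum(lam))
    c2 = float(np.sum(lam**2))
    c3 = float(np.sum(lam**3))
    c4 = float(np.sum(lam**4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s1**2
    mu_x = df + delta
    sigma_x = math.sqrt(2.0 * (df + 2.0 * delta))
    t_star = (q - c1) / math.sqrt(2.0 * c2)
    x = t_star * sigma_x + mu_x
    if x <= 0:
        return 1.0
    if delta > 0:
        return float(stats.ncx2.sf(x, df, delta))
    return float(stats.chi2.sf(x, df))


def quadform_pvalue(
    q: float, eigenvalues: np.ndarray, min_floor: float = P_FLOOR
) -> tuple[float, str]:
    """Tail probability of a positive mixture of 1-df chi-squares.

    Primary route is Imhof-style characteristic-function inversion; when the
    inversion is numerically unreliable (tiny tails, integration error
    comparable to the value) the moment-matched approximation is used.
    Returns ``(p, method)`` with p floored at ``min_floor``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("empty eigenvalue spectrum")
    if np.any(lam < -1e-12):
        raise ValueError("negative eigenvalues in spectrum")
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("eigenvalue spectrum has no positive entries")
    if q <= 0:
        return 1.0, "exact_quadform"
    if lam.max() - lam.min() <= 1e-12 * lam.max():
        # equal eigenvalues: the mixture is an exact scaled chi-square
        p = float(stats.chi2.sf(q / lam.mean(), lam.size))
        return min(max(p, min_floor), 1.0), "exact_quadform"
    try:
        p, abserr = _imhof_tail(q, lam)
    except Exception:
        p, abserr = np.nan, np.inf
    reliable = (
        np.isfinite(p)
        and p > 1e-10
        and p <= 1.0 + 1e-8
        and abserr < max(1e-9, 0.01 * abs(p))
    )
    if reliable:
        return float(min(max(p, min_floor), 1.0)), "exact_quadform"
    p = _liu_tail(q, lam)
    return float(min(max(p, min_floor), 1.0)), "moment_matched"


def skat_test(
    y: np.ndarray,
    covariates: np.ndarray | None,
    G: np.ndarray,
    weight_spec: WeightSpec | None = None,
    mafs: np.ndarray | None = None,
    null: NullModel | None = None,
) -> KernelTestResult:
    """End-to-end region test.

    ``mafs`` default to folded allele frequencies computed from the dosage
    columns themselves; pass a pre-fitted ``null`` to reuse one covariate fit
    across many regions for the same probe.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if null is None:
        null = fit_null(y, covariates)
    if mafs is None:
        freqs = G.mean(axis=0) / 2.0
        mafs = np.minimum(freqs, 1.0 - freqs)
        mafs = np.clip(mafs, 1e-8, 0.5)
    w = beta_weights(np.asarray(mafs, dtype=float), weight_spec)
    Q, lam, dropped = kernel_statistic(null, G, w)
    p, method = quadform_pvalue(Q, lam)
    return KernelTestResult(
        Q=Q,
        eigenvalues=lam,
        p_value=p,
        p_method=method,
        n_variants=G.shape[1] - len(dropped),
        n_samples=null.n_samples,
        dropped_variants=dropped,
    )


def permutation_pvalue(
    y: np.ndarray,
    covariates: np.ndarray | None,
    G: np.ndarray,
    weight_spec: WeightSpec | None = None,
    n_perm: int = 999,
    seed: int = 0,
    mafs: np.ndarray | None = None,
) -> float:
    """Permutation oracle for the kernel test.

    Permutes the null-model residuals and recomputes the full statistic on
    each permuted outcome — re-projecting onto the covariate-orthogonal
    space and re-estimating the residual variance, exactly as the observed
    statistic was computed (with intercept-only covariates both steps are
    no-ops, since permutation preserves the mean and sum of squares).
    Returns ``(1 + #{Q_perm >= Q_obs}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    null = fit_null(y, covariates)
    if mafs is None:
        freqs = G.mean(axis=0) / 2.0
        mafs = np.clip(np.minimum(freqs, 1.0 - freqs), 1e-8, 0.5)
    w = beta_weights(np.asarray(mafs, dtype=float), weight_spec)
    variances = G.var(axis=0)
    G = G[:, variances > 0]
    w = w[variances > 0]
    if G.shape[1] == 0:
        raise ValueError("no testable variants")
    Gc = G - G.mean(axis=0)
    Gt = null.project(Gc)
    r = null.residuals
    q_obs = float(np.sum((w * (Gt.T @ r)) ** 2)) / (2.0 * null.sigma2)
    rng = np.random.default_rng(seed)
    n = r.shape[0]
    rss = float(r @ r)
    n_ge = 0
    chunk = max(1, min(n_perm, int(2e7 // n)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((m, n)), axis=1)
        R = r[idx]  # m x n of permuted residuals
        proj = R @ null.q_basis  # m x rank
        scores = (R @ Gt) * w  # m x p; Gt already covariate-orthogonal
        sigma2 = (rss - np.sum(proj**2, axis=1)) / (n - null.rank)
        q_perm = np.sum(scores**2, axis=1) / (2.0 * sigma2)
        n_ge += int(np.sum(q_perm >= q_obs))
        done += m
    return (1 + n_ge) / (1 + n_perm)


def single_variant_regression(
    y: np.ndarray, covariates: np.ndarray | None, g: np.ndarray
) -> dict:
    """OLS effect of a single dosage column: slope, SE, two-sided t-test p."""
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if g.var() <= 0:
        raise ValueError("zero-variance genotype")
    n = y.shape[0]
    X = np.column_stack([_design_matrix(n, covariates), g])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("genotype is collinear with covariates")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * xtx_inv[-1, -1])
    beta = float(coef[-1])
    tval = beta / se
    p = 2.0 * float(stats.t.sf(abs(tval), dof))
    return {"beta": beta, "se": se, "p": max(p, P_FLOOR), "t": tval, "df": dof}


def burden_test(
    y: np.ndarray,
    covariates: np.ndarray | None,
    G: np.ndarray,
    weights: np.ndarray | None = None,
) -> dict:
    """Weighted burden (sum) test: regress y on the weighted dosage sum.

    Used as an internal contrast: with mixed-sign effects within a region the
    burden sum cancels while the variance-component test does not.
    """
    G = np.asarray(G, dtype=float)
    if weights is None:
        weights = np.ones(G.shape[1])
    burden = G @ np.asarray(weights, dtype=float)
    return single_variant_regression(y, covariates, burden)
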