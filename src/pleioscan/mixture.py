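"""Causal-mixture models of polygenic architecture and cross-trait overlap.

Univariate model (per trait, applied to LD-pruned z-scores):

    z ~ (1 - π) · N(0, σ0²)  +  π · N(0, σ0² + n·σβ²)

with polygenicity π (proportion of causal SNPs), discoverability σβ²
(variance of causal effects on the standardized-genotype scale) and null SD
σ0 (σ0 > 1 captures uniform inflation). The likelihood deliberately omits
any LD/heterozygosity convolution — it is intended for pruned SNP sets where
that convolution is removed by construction.

Bivariate model: the four-component mixture null / trait-1-specific /
trait-2-specific / shared over (z1, z2), with the per-trait margins fixed at
the univariate estimates (π1s + π12 = π̂1, etc.). The free parameters are the
shared-component probability π12 and its effect correlation ρ12. Fitting is
two-stage, mirroring the standard causal-mixture workflow, which keeps the
optimization low-dimensional and stable.

Derived overlap summaries: causal-variant counts, the Dice coefficient
2·π12/(π1 + π2), the model-implied genetic correlation
rg = ρ12·π12/√(π1·π2), the number of causal SNPs explaining 90% of
heritability per trait, and an AIC comparison against the no-overlap
(π12 = 0) model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit, logsumexp

from .exceptions import ConfigurationError, DegenerateInputError, FitError

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)
#: multistart fits within this many log-likelihood units of the best are
#: considered equivalent; the smallest-π one is reported (parsimony tie-break)
_LL_TIE_WINDOW = 2.0


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the four-component bivariate causal mixture."""

    pi1s: float
    pi2s: float
    pi12: float
    sigma_b1_sq: float
    sigma_b2_sq: float
    rho12: float
    sigma01: float = 1.0
    sigma02: float = 1.0

    def __post_init__(self):
        pis = (self.pi1s, self.pi2s, self.pi12)
        if any(p < -1e-12 for p in pis) or sum(pis) > 1 + 1e-12:
            raise ConfigurationError(f"invalid component probabilities {pis}")
        if abs(self.rho12) > 1 + 1e-12:
            raise ConfigurationError(f"|rho12| must be <= 1, got {self.rho12}")

    @property
    def pi1(self) -> float:
        return self.pi1s + self.pi12

    @property
    def pi2(self) -> float:
        return self.pi2s + self.pi12


# --------------------------------------------------------------------------- #
# univariate model
# --------------------------------------------------------------------------- #
def _norm_logpdf(z: np.ndarray, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var) + z * z / var)


@dataclass
class UnivariateMixtureFit:
    """Results of a univariate causal-mixture fit."""

    pi: float
    sigma_b_sq: float
    sigma0: float
    n: float
    llf: float
    k_params: int
    nobs: int
    converged: bool
    starts: list = field(default_factory=list, repr=False)

    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.llf

    def summary(self) -> str:
        return (
            "Univariate causal mixture\n"
            "-------------------------\n"
            f"SNPs (pruned):     {self.nobs}\n"
            f"polygenicity π:    {self.pi:.3e}\n"
            f"discoverability σβ²: {self.sigma_b_sq:.3e}  (n·σβ² = {self.n * self.sigma_b_sq:.2f})\n"
            f"null SD σ0:        {self.sigma0:.4f}\n"
            f"log-likelihood:    {self.llf:.2f}"
        )


class UnivariateCausalMixture:
    """Two-component scale mixture for one trait's pruned z-scores."""

    def __init__(self, z: np.ndarray, n: float):
        z = np.asarray(z, dtype=float)
        if len(z) < 10:
            raise DegenerateInputError("need at least 10 z-scores")
        if np.all(z == 0):
            raise DegenerateInputError("all z-scores are zero")
        self.z = z
        self.n = float(n)
        self._z2 = z * z

    def loglike(self, pi: float, sigma_b_sq: float, sigma0: float) -> float:
        v0 = sigma0 * sigma0
        v1 = v0 + self.n * sigma_b_sq
        comp = np.stack([
            np.log1p(-pi) + _norm_logpdf(self.z, v0) if pi < 1 else np.full_like(self.z, -np.inf),
            (np.log(pi) if pi > 0 else -np.inf) + _norm_logpdf(self.z, v1),
        ])
        return float(np.sum(logsumexp(comp, axis=0)))

    def _neg_ll(self, theta: np.ndarray) -> float:
        pi = expit(theta[0])
        sigma_b_sq = np.exp(theta[1])
        sigma0 = np.exp(theta[2])
        if not np.isfinite(pi * sigma_b_sq * sigma0):
            return np.inf
        return -self.loglike(pi, sigma_b_sq, sigma0)

    def fit(self, n_starts: int = 5, seed: int = 0) -> UnivariateMixtureFit:
        """Multistart Nelder-Mead in (logit π, log σβ², log σ0) coordinates."""
        rng = np.random.default_rng(seed)
        var_z = float(np.var(self.z))
        excess = max(var_z - 1.0, 0.05)
        pi_starts = [1e-4, 1e-3, 1e-2, 5e-2, 3e-3][:n_starts]
        while len(pi_starts) < n_starts:
            pi_starts.append(10 ** rng.uniform(-4, -1))
        results = []
        for pi0 in pi_starts:
            s0 = excess / (pi0 * self.n)  # matches the observed excess variance
            theta0 = np.array([logit(pi0), np.log(max(s0, 1e-10)), 0.0])
            theta0[1:] += 0.05 * rng.standard_normal(2)
            res = optimize.minimize(
                self._neg_ll, theta0, method="Nelder-Mead",
                options={"maxiter": 800, "xatol": 1e-4, "fatol": 1e-3},
            )
            results.append(res)
        finite = [r for r in results if np.isfinite(r.fun)]
        if not finite:
            raise FitError("univariate mixture failed from every start",
                           {"results": results})
        best = min(r.fun for r in finite)
        # parsimony tie-break: among near-equivalent optima keep the smallest π
        # (on null-like data the (π→0, σβ²→0) ridge makes the argmax arbitrary)
        tied = [r for r in finite if r.fun <= best + _LL_TIE_WINDOW]
        winner = min(tied, key=lambda r: r.x[0])
        pi = float(expit(winner.x[0]))
        return UnivariateMixtureFit(
            pi=pi,
            sigma_b_sq=float(np.exp(winner.x[1])),
            sigma0=float(np.exp(winner.x[2])),
            n=self.n,
            llf=-float(winner.fun),
            k_params=3,
            nobs=len(self.z),
            converged=any(r.success for r in finite),
            starts=[(-float(r.fun), float(expit(r.x[0]))) for r in results],
        )


def fit_univariate(z: np.ndarray, n: float, n_starts: int = 5, seed: int = 0) -> UnivariateMixtureFit:
    """Convenience wrapper: fit the univariate causal mixture to pruned z-scores."""
    return UnivariateCausalMixture(z, n).fit(n_starts=n_starts, seed=seed)


# --------------------------------------------------------------------------- #
# bivariate model
# --------------------------------------------------------------------------- #
def _bivar_logpdf(z1, z2, v1, v2, cov) -> np.ndarray:
    det = v1 * v2 - cov * cov
    quad = (v2 * z1 * z1 - 2 * cov * z1 * z2 + v1 * z2 * z2) / det
    return -0.5 * (2 * _LOG_2PI + np.log(det) + quad)


class BivariateCausalMixture:
    """Four-component bivariate mixture with margins fixed at univariate fits."""

    def __init__(
        self,
        z1: np.ndarray,
        z2: np.ndarray,
        fit1: UnivariateMixtureFit,
        fit2: UnivariateMixtureFit,
    ):
        z1 = np.asarray(z1, float)
        z2 = np.asarray(z2, float)
        if len(z1) != len(z2):
            raise ConfigurationError("z1 and z2 must be the same length")
        self.z1, self.z2 = z1, z2
        self.fit1, self.fit2 = fit1, fit2
        self.pi12_lo = max(0.0, fit1.pi + fit2.pi - 1.0)
        self.pi12_hi = min(fit1.pi, fit2.pi)
        if self.pi12_lo > self.pi12_hi:
            raise ConfigurationError(
                f"margin infeasibility: π̂1 + π̂2 - 1 = {self.pi12_lo:.3g} exceeds "
                f"min(π̂1, π̂2) = {self.pi12_hi:.3g}")

    def loglike(self, pi12: float, rho12: float,
                z1: np.ndarray | None = None, z2: np.ndarray | None = None) -> float:
        z1 = self.z1 if z1 is None else z1
        z2 = self.z2 if z2 is None else z2
        f1, f2 = self.fit1, self.fit2
        v01 = f1.sigma0**2
        v02 = f2.sigma0**2
        s1 = f1.n * f1.sigma_b_sq
        s2 = f2.n * f2.sigma_b_sq
        w = np.array([
            1.0 - f1.pi - f2.pi + pi12,   # null
            f1.pi - pi12,                  # trait-1-specific
            f2.pi - pi12,                  # trait-2-specific
            pi12,                          # shared
        ])
        w = np.clip(w, 0.0, 1.0)
        cov = rho12 * np.sqrt(s1 * s2)
        parts = []
        variances = [
            (v01, v02, 0.0),
            (v01 + s1, v02, 0.0),
            (v01, v02 + s2, 0.0),
            (v01 + s1, v02 + s2, cov),
        ]
        for wk, (va, vb, c) in zip(w, variances):
            if wk <= 0:
                continue
            if c == 0.0:
                lp = _norm_logpdf(z1, va) + _norm_logpdf(z2, vb)
            else:
                lp = _bivar_logpdf(z1, z2, va, vb, c)
            parts.append(np.log(wk) + lp)
        return float(np.sum(logsumexp(np.stack(parts), axis=0)))

    def _neg_ll(self, theta: np.ndarray) -> float:
        pi12 = self.pi12_lo + (self.pi12_hi - self.pi12_lo) * expit(theta[0])
        rho = np.tanh(theta[1])
        ll = self.loglike(pi12, rho)
        return -ll if np.isfinite(ll) else np.inf

    def fit(self, n_starts: int = 3, seed: int = 0) -> "BivariateMixtureResults":
        rng = np.random.default_rng(seed)
        frac_starts = [0.5, 0.9, 0.1, 0.3, 0.7][:n_starts]
        rho_starts = [0.5, 0.9, -0.5, 0.0, 0.8][:n_starts]
        results = []
        for f0, r0 in zip(frac_starts, rho_starts):
            theta0 = np.array([logit(f0), np.arctanh(r0 * 0.999)])
            theta0 += 0.02 * rng.standard_normal(2)
            res = optimize.minimize(
                self._neg_ll, theta0, method="Nelder-Mead",
                options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-3},
            )
            results.append(res)
        finite = [r for r in results if np.isfinite(r.fun)]
        if not finite:
            raise FitError("bivariate mixture failed from every start", {"results": results})
        best = min(finite, key=lambda r: r.fun)
        tied = [r for r in finite if r.fun <= best.fun + _LL_TIE_WINDOW]
        winner = min(tied, key=lambda r: r.x[0])  # prefer smaller π12 among ties
        pi12 = float(self.pi12_lo + (self.pi12_hi - self.pi12_lo) * expit(winner.x[0]))
        rho12 = float(np.tanh(winner.x[1]))
        params = MixtureParams(
            pi1s=self.fit1.pi - pi12,
            pi2s=self.fit2.pi - pi12,
            pi12=pi12,
            sigma_b1_sq=self.fit1.sigma_b_sq,
            sigma_b2_sq=self.fit2.sigma_b_sq,
            rho12=rho12,
            sigma01=self.fit1.sigma0,
            sigma02=self.fit2.sigma0,
        )
        return BivariateMixtureResults(
            model=self, params=params, llf=-float(winner.fun), k_params=2,
            nobs=len(self.z1), n1=self.fit1.n, n2=self.fit2.n,
        )

    def fit_constrained_null(self) -> "BivariateMixtureResults":
        """The no-overlap model: π12 = 0 with margins fixed (no free parameters)."""
        ll = self.loglike(0.0, 0.0)
        params = MixtureParams(
            pi1s=self.fit1.pi, pi2s=self.fit2.pi, pi12=0.0,
            sigma_b1_sq=self.fit1.sigma_b_sq, sigma_b2_sq=self.fit2.sigma_b_sq,
            rho12=0.0, sigma01=self.fit1.sigma0, sigma02=self.fit2.sigma0,
        )
        return BivariateMixtureResults(
            model=self, params=params, llf=ll, k_params=0,
            nobs=len(self.z1), n1=self.fit1.n, n2=self.fit2.n,
        )


# --------------------------------------------------------------------------- #
# results / summaries
# --------------------------------------------------------------------------- #
def causal_fraction_for_heritability(share: float = 0.9) -> float:
    """Smallest fraction of i.i.d. Gaussian causal effects whose expected
    summed squared effects reach ``share`` of the total.

    Squared standardized effects are χ²₁-distributed; the tail-mean identity
    E[X·1(X > x)] = P(χ²₃ > x) for X ~ χ²₁ turns the defining equation
    E[X·1(X > x)]/E[X] = share into a χ² quantile lookup.
    """
    if not 0.0 < share < 1.0:
        raise ConfigurationError("share must be in (0, 1)")
    x = stats.chi2.ppf(1.0 - share, df=3)
    return float(stats.chi2.sf(x, df=1))


@dataclass
class OverlapSummary:
    """Derived polygenic-overlap quantities (Venn-diagram numbers)."""

    shared: float
    specific1: float
    specific2: float
    dice: float
    rg: float
    n90_1: float
    n90_2: float
    m: int
    aic_delta: float | None = None
    se_shared: float | None = None
    se_specific1: float | None = None
    se_specific2: float | None = None

    @property
    def total1(self) -> float:
        return self.shared + self.specific1

    @property
    def total2(self) -> float:
        return self.shared + self.specific2


def summarize_overlap(params: MixtureParams, m: int, n1: float, n2: float) -> OverlapSummary:
    """Counts, Dice coefficient, rg and n90 from fitted mixture parameters."""
    pi1, pi2 = params.pi1, params.pi2
    shared = params.pi12 * m
    specific1 = params.pi1s * m
    specific2 = params.pi2s * m
    denom = pi1 + pi2
    dice = 2.0 * params.pi12 / denom if denom > 0 else 0.0
    if pi1 > 0 and pi2 > 0:
        rg = params.rho12 * params.pi12 / np.sqrt(pi1 * pi2)
    else:
        rg = np.nan  # undefined when a trait has no causal component
    q90 = causal_fraction_for_heritability(0.9)
    return OverlapSummary(
        shared=shared, specific1=specific1, specific2=specific2,
        dice=float(dice), rg=float(rg),
        n90_1=pi1 * m * q90, n90_2=pi2 * m * q90, m=m,
    )


def compare_models_aic(full: "BivariateMixtureResults",
                       constrained: "BivariateMixtureResults") -> float:
    """AIC(constrained) − AIC(full); positive favors the overlap model.

    Comparing a results object against itself yields exactly 0.
    """
    return (2 * constrained.k_params - 2 * constrained.llf) - (2 * full.k_params - 2 * full.llf)


@dataclass
class BivariateMixtureResults:
    model: BivariateCausalMixture = field(repr=False)
    params: MixtureParams
    llf: float
    k_params: int
    nobs: int
    n1: float
    n2: float
    se_pi12: float | None = None
    se_rho12: float | None = None
    bootstrap_params: list = field(default_factory=list, repr=False)

    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.llf

    def bootstrap(self, n_boot: int = 20, seed: int = 0) -> "BivariateMixtureResults":
        """SNP-resampling bootstrap of (π12, ρ12); margins held at the point fits."""
        rng = np.random.default_rng(seed)
        m = self.model
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(m.z1), size=len(m.z1))
            boot = BivariateCausalMixture(m.z1[idx], m.z2[idx], m.fit1, m.fit2)
            res = boot.fit(n_starts=2, seed=int(rng.integers(2**31)))
            draws.append((res.params.pi12, res.params.rho12))
        draws = np.array(draws)
        self.bootstrap_params = draws.tolist()
        self.se_pi12 = float(np.std(draws[:, 0], ddof=1))
        self.se_rho12 = float(np.std(draws[:, 1], ddof=1))
        return self

    def overlap_summary(self, m: int) -> OverlapSummary:
        summ = summarize_overlap(self.params, m, self.n1, self.n2)
        if self.se_pi12 is not None:
            summ.se_shared = self.se_pi12 * m
            summ.se_specific1 = self.se_pi12 * m  # margins fixed: var(π1s) = var(π12)
            summ.se_specific2 = self.se_pi12 * m
        return summ

    def summary(self, m: int | None = None) -> str:
        p = self.params
        lines = [
            "Bivariate causal mixture",
            "========================",
            f"SNPs (pruned):       {self.nobs}",
            f"π1 (total, trait 1): {p.pi1:.3e}   π2 (total, trait 2): {p.pi2:.3e}",
            f"π12 (shared):        {p.pi12:.3e}" +
            (f"  (SE {self.se_pi12:.2e})" if self.se_pi12 is not None else ""),
            f"ρ12 (shared corr):   {p.rho12:+.3f}" +
            (f"  (SE {self.se_rho12:.2f})" if self.se_rho12 is not None else ""),
            f"log-likelihood:      {self.llf:.2f}  (AIC {self.aic:.2f})",
        ]
        if m is not None:
            s = self.overlap_summary(m)
            lines += [
                f"causal counts (of {m} SNPs): shared {s.shared:.0f}, "
                f"specific {s.specific1:.0f} / {s.specific2:.0f}",
                f"Dice coefficient:    {s.dice:.3f}",
                f"rg (model-implied):  {s.rg:+.3f}",
                f"n90 (90% heritability): {s.n90_1:.0f} / {s.n90_2:.0f}",
            ]
        return "\n".join(lines)

    def plot_venn(self, m: int, ax=None):
        """Proportional two-circle overlap diagram of causal-variant counts."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.patches import Circle

        s = self.overlap_summary(m)
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        r1 = np.sqrt(max(s.total1, 1e-9))
        r2 = np.sqrt(max(s.total2, 1e-9))
        scale = 1.0 / max(r1, r2)
        r1, r2 = r1 * scale, r2 * scale
        d = (r1 + r2) * (1.0 - s.dice)
        ax.add_patch(Circle((0, 0), r1, alpha=0.4, color="C0"))
        ax.add_patch(Circle((d, 0), r2, alpha=0.4, color="C3"))
        ax.text(-r1 / 2, 0, f"{s.specific1 / 1e3:.1f}K", ha="center")
        ax.text(d + r2 / 2, 0, f"{s.specific2 / 1e3:.1f}K", ha="center")
        ax.text(d / 2, 0, f"{s.shared / 1e3:.1f}K", ha="center")
        ax.set_xlim(-1.5, d + 1.5)
        ax.set_ylim(-1.5, 1.5)
        ax.set_aspect("equal")
        ax.axis("off")
        return ax
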