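"""Joint log-density of the hierarchical negative-binomial model.

The model has three levels:

1. Counts: ``Y_ij ~ NB(mu_ij, phi_j)`` with ``log mu_ij = alpha_j +
   x_i beta_j + log z_i`` (mean-dispersion parameterization,
   ``Var = mu + mu^2/phi``).
2. Family shrinkage: ``(alpha_j, beta_j)`` for OTU j in family f follow a
   bivariate normal with family means ``(mu_alpha_f, mu_beta_f)`` and
   covariance built from family SDs ``(sigma_alpha_f, sigma_beta_f)``
   and a correlation ``omega`` shared across families.
3. Hyperpriors: family means are normal around global means
   ``(mu_alpha, mu_beta)`` with SDs ``(sigma_alpha, sigma_beta)``;
   ``(mu_alpha, mu_beta) ~ N(0,1)``; all SDs have Exponential(1) priors;
   ``omega`` is uniform on (-1, 1).

Dispersions are regularized through ``phi_j ~ lognormal(mu_phi_j,
sigma_phi^2)`` with location ``mu_phi_j = a1 * mean_i(mu_ij) + a0``, a
linear trend in the OTU's average fitted mean; ``(a1, a0) ~ N(0,1)`` and
``sigma_phi ~ Exponential(1)``.  The trend location depends on the
current ``mu_ij``, so it is recomputed inside every density evaluation.

:class:`UnconstrainedDensity` exposes the density on an unconstrained
parameter vector (log / atanh transforms with Jacobian corrections,
non-centered innovations for the normal levels) together with its
analytic gradient; this is the target handed to the sampler.
:func:`joint_log_density` is the readable natural-scale density used for
cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

__all__ = [
    "nb_log_pmf",
    "linear_predictor",
    "dispersion_trend_location",
    "ParameterState",
    "joint_log_density",
    "UnconstrainedDensity",
]

_LOG2PI = math.log(2.0 * math.pi)
# guard against exp overflow in extreme sampler excursions
_ETA_MAX = 40.0


def nb_log_pmf(y, mu, phi):
    """Log pmf of the negative binomial in mean-dispersion form.

    ``P(Y=y)`` with mean ``mu`` and dispersion ``phi`` such that
    ``Var(Y) = mu + mu^2 / phi``; ``phi -> inf`` recovers the Poisson.
    Vectorized over all arguments.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ValueError("nb_log_pmf requires mu > 0 and phi > 0")
    if np.any(y < 0) or np.any(np.mod(y, 1) != 0):
        raise ValueError("nb_log_pmf requires non-negative integer y")
    out = (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1.0)
        + phi * (np.log(phi) - np.log(phi + mu))
        + y * (np.log(mu) - np.log(phi + mu))
    )
    return out if out.ndim else float(out)


def linear_predictor(alpha, beta, x, z):
    """Mean ``mu = exp(alpha + x * beta + log z)`` of one count.

    ``z`` is the subject library size acting as a multiplicative offset
    for sequencing depth.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("offset z must be positive")
    return np.exp(np.asarray(alpha, float) + np.asarray(x, float) * np.asarray(beta, float)) * z


def dispersion_trend_location(mu_row_mean, a1, a0):
    """Lognormal location ``mu_phi = a1 * mean(mu) + a0`` of a dispersion."""
    return a1 * np.asarray(mu_row_mean, dtype=float) + a0


@dataclass
class ParameterState:
    """All model parameters on their natural scale.

    Arrays are indexed per OTU (``alpha``, ``beta``, ``phi``) or per
    family (``mu_alpha_fam`` etc.).
    """

    mu_alpha: float
    mu_beta: float
    sigma_alpha: float
    sigma_beta: float
    omega: float
    a1: float
    a0: float
    sigma_phi: float
    mu_alpha_fam: np.ndarray
    mu_beta_fam: np.ndarray
    sigma_alpha_fam: np.ndarray
    sigma_beta_fam: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    phi: np.ndarray

    def validate(self) -> None:
        pos = [self.sigma_alpha, self.sigma_beta, self.sigma_phi]
        if min(pos) <= 0 or np.any(self.sigma_alpha_fam <= 0) or np.any(
            self.sigma_beta_fam <= 0
        ) or np.any(self.phi <= 0):
            raise ValueError("scale parameters must be strictly positive")
        if not abs(self.omega) < 1:
            raise ValueError("omega must lie in (-1, 1)")


def _norm_logpdf(x, loc, scale):
    z = (np.asarray(x, float) - loc) / scale
    return -0.5 * z * z - np.log(scale) - 0.5 * _LOG2PI


def joint_log_density(state: ParameterState, Y, x, logz, fam_idx) -> float:
    """Natural-scale joint log density (likelihood plus all priors).

    Reference implementation: clear, term by term, no transform
    Jacobians.  The sampler target in :class:`UnconstrainedDensity`
    must equal this plus its change-of-variable corrections; a test
    asserts that identity.
    """
    state.validate()
    Y = np.asarray(Y, dtype=float)
    x = np.asarray(x, dtype=float)
    logz = np.asarray(logz, dtype=float)
    fam_idx = np.asarray(fam_idx)
    n_subj = Y.shape[0]

    eta = state.alpha[None, :] + x[:, None] * state.beta[None, :] + logz[:, None]
    mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    lp = float(np.sum(nb_log_pmf(Y, mu, state.phi[None, :])))

    # level 2: bivariate normal of (alpha_j, beta_j) around family means
    saf = state.sigma_alpha_fam[fam_idx]
    sbf = state.sigma_beta_fam[fam_idx]
    om = state.omega
    da = (state.alpha - state.mu_alpha_fam[fam_idx]) / saf
    db = (state.beta - state.mu_beta_fam[fam_idx]) / sbf
    quad = (da * da - 2.0 * om * da * db + db * db) / (1.0 - om * om)
    lp += float(
        np.sum(
            -0.5 * quad
            - np.log(saf)
            - np.log(sbf)
            - 0.5 * np.log(1.0 - om * om)
            - _LOG2PI
        )
    )

    # level 3: family means around global means; hyperpriors
    lp += float(np.sum(_norm_logpdf(state.mu_alpha_fam, state.mu_alpha, state.sigma_alpha)))
    lp += float(np.sum(_norm_logpdf(state.mu_beta_fam, state.mu_beta, state.sigma_beta)))
    lp += float(_norm_logpdf(state.mu_alpha, 0.0, 1.0) + _norm_logpdf(state.mu_beta, 0.0, 1.0))
    lp += -state.sigma_alpha - state.sigma_beta  # Exponential(1)
    lp += -float(np.sum(state.sigma_alpha_fam)) - float(np.sum(state.sigma_beta_fam))
    lp += math.log(0.5) if abs(om) < 1 else -math.inf  # omega ~ U(-1, 1)

    # mean-dispersion regularization
    m = mu.mean(axis=0)
    mu_phi = dispersion_trend_location(m, state.a1, state.a0)
    logphi = np.log(state.phi)
    lp += float(
        np.sum(
            -logphi
            - np.log(state.sigma_phi)
            - 0.5 * _LOG2PI
            - 0.5 * ((logphi - mu_phi) / state.sigma_phi) ** 2
        )
    )
    lp += float(_norm_logpdf(state.a1, 0.0, 1.0) + _norm_logpdf(state.a0, 0.0, 1.0))
    lp += -state.sigma_phi
    del n_subj
    return lp


class UnconstrainedDensity:
    """Sampler target: log density and gradient on R^D.

    Layout of the parameter vector (D = 8 + 4*F + 3*J)::

        [mu_alpha, mu_beta, log sigma_alpha, log sigma_beta,
         atanh(omega), a1, a0, log sigma_phi,
         <family alpha block (F)>, <family beta block (F)>,
         log sigma_alpha_f (F), log sigma_beta_f (F),
         <OTU alpha block (J)>, <OTU beta block (J)>, log phi (J)]

    Positive parameters are log-transformed and omega
    atanh-transformed, with Jacobian corrections, so the density is
    smooth on all of R^D.  Two mathematically identical
    parameterizations of the normal hierarchy are available:

    ``centered``
        The family and OTU blocks hold the family means and the
        per-OTU ``(alpha_j, beta_j)`` directly.  Preferred when the
        counts are informative about every OTU (the usual regime
        here), where it leaves the posterior close to independent
        across OTUs.
    ``non-centered``
        The blocks hold standard-normal innovations; family means are
        ``mu + sigma * v`` and OTU effects are the family mean plus
        the Cholesky factor of the family covariance applied to
        ``(u_alpha, u_beta)``.  Preferred for very sparse data where
        the hierarchy scales would otherwise funnel.
    """

    def __init__(self, Y, x, z, fam_idx, centered: bool = True):
        Y = np.asarray(Y)
        if Y.ndim != 2:
            raise ValueError("Y must be 2-D (subjects x OTUs)")
        self.Y = Y.astype(np.float64)
        self.n_subj, self.n_otu = Y.shape
        self.x = np.asarray(x, dtype=np.float64)
        if self.x.shape[0] != self.n_subj:
            raise ValueError("covariate length must match number of subjects")
        z = np.asarray(z, dtype=np.float64)
        if np.any(z <= 0):
            raise ValueError("library sizes must be positive")
        self.logz = np.log(z)
        self.fam = np.asarray(fam_idx, dtype=np.int64)
        if self.fam.shape[0] != self.n_otu:
            raise ValueError("family index length must match number of OTUs")
        self.n_fam = int(self.fam.max()) + 1 if self.n_otu else 0
        self.centered = bool(centered)
        # In the centered parameterization the vector stores sheared
        # intercepts a' = a + xbar * b at every level (unit Jacobian), so
        # the posterior of (a', b) is nearly uncorrelated even when the
        # covariate is far from centered; natural (a, b) are recovered in
        # unpack.  The non-centered branch keeps plain coordinates.
        self.shear = float(self.x.mean()) if self.centered else 0.0

        # counts are integers with many repeats: evaluate the gamma-function
        # terms on unique (count, OTU) pairs only, weighted by multiplicity
        uvals, uj, uw = [], [], []
        for j in range(self.n_otu):
            vals, cnt = np.unique(self.Y[:, j], return_counts=True)
            uvals.append(vals)
            uj.append(np.full(len(vals), j))
            uw.append(cnt)
        self._uv = np.concatenate(uvals)
        self._uj = np.concatenate(uj)
        self._uw = np.concatenate(uw).astype(np.float64)
        self._lgam_y1 = -float(self._uw @ gammaln(self._uv + 1.0))
        # fixed pieces of sum_ij Y_ij * eta_ij (valid while eta is unclipped)
        self._colY = self.Y.sum(axis=0)
        self._xY = self.x @ self.Y
        self._lzY = float(self.logz @ self.Y.sum(axis=1))
        self._sum_x = float(self.x.sum())

        F, J = self.n_fam, self.n_otu
        self.dim = 8 + 4 * F + 3 * J
        s = 8
        self.sl_fa = slice(s, s + F)
        self.sl_fb = slice(s + F, s + 2 * F)
        self.sl_lsaf = slice(s + 2 * F, s + 3 * F)
        self.sl_lsbf = slice(s + 3 * F, s + 4 * F)
        s += 4 * F
        self.sl_oa = slice(s, s + J)
        self.sl_ob = slice(s + J, s + 2 * J)
        self.sl_lphi = slice(s + 2 * J, s + 3 * J)

    # -- parameter bookkeeping -------------------------------------------------

    def unpack(self, th: np.ndarray) -> ParameterState:
        """Map an unconstrained vector to natural-scale parameters."""
        fam = self.fam
        sa, sb = math.exp(th[2]), math.exp(th[3])
        om = math.tanh(th[4])
        saf = np.exp(th[self.sl_lsaf])
        sbf = np.exp(th[self.sl_lsbf])
        if self.centered:
            sh = self.shear
            mu_af = th[self.sl_fa] - sh * th[self.sl_fb]
            mu_bf = th[self.sl_fb].copy()
            alpha = th[self.sl_oa] - sh * th[self.sl_ob]
            beta = th[self.sl_ob].copy()
        else:
            mu_af = th[0] + sa * th[self.sl_fa]
            mu_bf = th[1] + sb * th[self.sl_fb]
            ua = th[self.sl_oa]
            ub = th[self.sl_ob]
            alpha = mu_af[fam] + saf[fam] * ua
            beta = mu_bf[fam] + sbf[fam] * (
                om * ua + math.sqrt(1.0 - om * om) * ub
            )
        return ParameterState(
            mu_alpha=float(th[0] - self.shear * th[1]),
            mu_beta=float(th[1]),
            sigma_alpha=sa,
            sigma_beta=sb,
            omega=om,
            a1=float(th[5]),
            a0=float(th[6]),
            sigma_phi=math.exp(th[7]),
            mu_alpha_fam=mu_af,
            mu_beta_fam=mu_bf,
            sigma_alpha_fam=saf,
            sigma_beta_fam=sbf,
            alpha=alpha,
            beta=beta,
            phi=np.exp(th[self.sl_lphi]),
        )

    def pack(self, state: ParameterState) -> np.ndarray:
        """Inverse of :meth:`unpack` (used by tests and initialization)."""
        state.validate()
        th = np.empty(self.dim)
        th[0] = state.mu_alpha + self.shear * state.mu_beta
        th[1] = state.mu_beta
        th[2], th[3] = math.log(state.sigma_alpha), math.log(state.sigma_beta)
        th[4] = math.atanh(state.omega)
        th[5], th[6] = state.a1, state.a0
        th[7] = math.log(state.sigma_phi)
        th[self.sl_lsaf] = np.log(state.sigma_alpha_fam)
        th[self.sl_lsbf] = np.log(state.sigma_beta_fam)
        th[self.sl_lphi] = np.log(state.phi)
        if self.centered:
            sh = self.shear
            th[self.sl_fa] = state.mu_alpha_fam + sh * state.mu_beta_fam
            th[self.sl_fb] = state.mu_beta_fam
            th[self.sl_oa] = state.alpha + sh * state.beta
            th[self.sl_ob] = state.beta
        else:
            th[self.sl_fa] = (state.mu_alpha_fam - state.mu_alpha) / state.sigma_alpha
            th[self.sl_fb] = (state.mu_beta_fam - state.mu_beta) / state.sigma_beta
            fam = self.fam
            om = state.omega
            s = math.sqrt(1.0 - om * om)
            ua = (state.alpha - state.mu_alpha_fam[fam]) / state.sigma_alpha_fam[fam]
            resid_b = (state.beta - state.mu_beta_fam[fam]) / state.sigma_beta_fam[fam]
            th[self.sl_oa] = ua
            th[self.sl_ob] = (resid_b - om * ua) / s
        return th

    def log_jacobian(self, th: np.ndarray) -> float:
        """Change-of-variable correction relating this density to
        :func:`joint_log_density` at the unpacked state."""
        om = math.tanh(th[4])
        lsaf = th[self.sl_lsaf]
        lsbf = th[self.sl_lsbf]
        jac = float(th[2] + th[3] + th[7])  # global scales
        jac += float(np.sum(lsaf) + np.sum(lsbf))  # family scales
        jac += math.log(1.0 - om * om)  # atanh transform
        jac += float(np.sum(th[self.sl_lphi]))  # log phi
        if not self.centered:
            jac += self.n_fam * float(th[2] + th[3])  # family-mean innovations
            # OTU innovations: log|det L_f| summed over OTUs
            jac += float(np.sum(lsaf[self.fam]) + np.sum(lsbf[self.fam]))
            jac += 0.5 * self.n_otu * math.log(1.0 - om * om)
        return jac

    def initial_vector(
        self,
        rng: np.random.Generator,
        jitter: float = 0.1,
        strategy: str = "moment",
    ) -> np.ndarray:
        """Starting point for one chain, jittered uniformly per chain.

        ``strategy='prior'`` starts at the prior center (means and
        innovations 0, scales 1, omega 0, log phi 0).  The default
        ``'moment'`` additionally seeds the intercepts from the
        observed per-OTU mean rates, which shortens the initial
        transient considerably; slopes, correlations and dispersions
        still start at the prior center.
        """
        th = rng.uniform(-jitter, jitter, size=self.dim)
        if strategy == "prior":
            return th
        if strategy != "moment":
            raise ValueError("strategy must be 'prior' or 'moment'")
        z = np.exp(self.logz)
        rate = (self.Y / z[:, None]).mean(axis=0)
        rate = np.clip(rate, 1e-3, None)
        alpha_hat = np.log(rate)
        # one Newton step of the per-OTU Poisson regression from beta=0
        xc = self.x - self.x.mean()
        score = xc @ (self.Y / z[:, None])
        info = rate * float(xc @ xc)
        beta_hat = np.clip(score / np.maximum(info, 1e-8), -2.0, 2.0)
        nf = np.maximum(1, np.bincount(self.fam, minlength=self.n_fam))
        mu_af = np.bincount(self.fam, weights=alpha_hat, minlength=self.n_fam) / nf
        mu_bf = np.bincount(self.fam, weights=beta_hat, minlength=self.n_fam) / nf
        mu_a = float(alpha_hat.mean())
        mu_b = float(beta_hat.mean())
        th[0] += mu_a + self.shear * mu_b
        th[1] += mu_b
        if self.centered:
            sh = self.shear
            th[self.sl_fa] += mu_af + sh * mu_bf
            th[self.sl_fb] += mu_bf
            th[self.sl_oa] += alpha_hat + sh * beta_hat
            th[self.sl_ob] += beta_hat
        else:
            # scales start at 1, so innovations carry the raw residuals
            th[self.sl_fa] += mu_af - mu_a
            th[self.sl_fb] += mu_bf - mu_b
            th[self.sl_oa] += alpha_hat - mu_af[self.fam]
            th[self.sl_ob] += beta_hat - mu_bf[self.fam]
        return th

    # -- density ---------------------------------------------------------------

    def logp_grad(self, th: np.ndarray) -> tuple[float, np.ndarray]:
        Y, x, logz, fam = self.Y, self.x, self.logz, self.fam
        N, J, F = self.n_subj, self.n_otu, self.n_fam

        if not np.all(np.isfinite(th)) or np.max(np.abs(th)) > 200.0:
            return -math.inf, np.zeros_like(th)

        mu_a, mu_b = th[0] - self.shear * th[1], th[1]
        sa, sb = math.exp(th[2]), math.exp(th[3])
        w = th[4]
        om = math.tanh(w)
        # log(1 - tanh(w)^2) = -2 log cosh(w), stable for large |w|
        log_s2 = -2.0 * (abs(w) + math.log1p(math.exp(-2.0 * abs(w))) - math.log(2.0))
        s2 = math.exp(log_s2)
        s = math.exp(0.5 * log_s2)
        a1, a0 = th[5], th[6]
        sphi = math.exp(th[7])
        saf = np.exp(th[self.sl_lsaf])
        sbf = np.exp(th[self.sl_lsbf])
        lphi = th[self.sl_lphi]
        phi = np.exp(lphi)

        if self.centered:
            sh = self.shear
            mu_af = th[self.sl_fa] - sh * th[self.sl_fb]
            mu_bf = th[self.sl_fb]
            alpha = th[self.sl_oa] - sh * th[self.sl_ob]
            beta = th[self.sl_ob]
        else:
            va = th[self.sl_fa]
            vb = th[self.sl_fb]
            ua = th[self.sl_oa]
            ub = th[self.sl_ob]
            mu_af = mu_a + sa * va
            mu_bf = mu_b + sb * vb
            alpha = mu_af[fam] + saf[fam] * ua
            rot = om * ua + s * ub
            beta = mu_bf[fam] + sbf[fam] * rot

        # ---- negative binomial likelihood over all (subject, OTU) pairs
        eta = np.multiply.outer(x, beta)
        eta += alpha[None, :]
        eta += logz[:, None]
        clipped = float(np.max(np.abs(eta))) > _ETA_MAX
        if clipped:
            np.clip(eta, -_ETA_MAX, _ETA_MAX, out=eta)
        mu = np.exp(eta)
        denom = phi[None, :] + mu
        L = np.log(denom)
        # B = (Y + phi) / (phi + mu); the eta-gradient is A = phi * (B - 1)
        B = (Y + phi[None, :]) / denom
        sumB = B.sum(axis=0)
        xB = x @ B
        sumL = L.sum(axis=0)
        YL = float(np.einsum("ij,ij->", Y, L))
        if clipped:
            sum_y_eta = float(np.einsum("ij,ij->", Y, eta))
        else:
            sum_y_eta = float(alpha @ self._colY + beta @ self._xY) + self._lzY

        lgam = self._uw @ gammaln(self._uv + phi[self._uj])
        lik = (
            lgam
            - N * float(gammaln(phi).sum())
            + self._lgam_y1
            + N * float((phi * lphi).sum())
            + sum_y_eta
            - (YL + float(phi @ sumL))
        )

        galpha = phi * (sumB - N)
        gbeta = phi * (xB - self._sum_x)
        dig = np.bincount(
            self._uj, weights=self._uw * digamma(self._uv + phi[self._uj]), minlength=J
        )
        gphi = dig - N * digamma(phi) + N * (lphi + 1.0) - sumL - sumB

        # ---- mean-dispersion regularization (location depends on mu)
        m = mu.mean(axis=0)
        Sx = (x @ mu) / N
        mu_phi = a1 * m + a0
        r = (lphi - mu_phi) / sphi
        lp = lik + float(-0.5 * np.sum(r * r)) - J * th[7] - 0.5 * J * _LOG2PI
        c = (r / sphi) * a1
        galpha = galpha + c * m
        gbeta = gbeta + c * Sx
        g_lphi = phi * gphi - r / sphi

        # ---- priors shared by both parameterizations
        lp += -0.5 * (mu_a * mu_a + mu_b * mu_b) - _LOG2PI
        lp += -0.5 * (a1 * a1 + a0 * a0) - _LOG2PI
        lp += -sa + th[2] - sb + th[3] - sphi + th[7]
        lp += float(np.sum(-saf + th[self.sl_lsaf]) + np.sum(-sbf + th[self.sl_lsbf]))
        lp += log_s2 + math.log(0.5)

        g = np.empty_like(th)
        g[5] = float(np.sum((r / sphi) * m)) - a1
        g[6] = float(np.sum(r / sphi)) - a0
        g[7] = float(np.sum(r * r)) - J - sphi + 1.0
        g[self.sl_lphi] = g_lphi

        if self.centered:
            # bivariate normal of (alpha, beta) around family means
            safj = saf[fam]
            sbfj = sbf[fam]
            da = (alpha - mu_af[fam]) / safj
            db = (beta - mu_bf[fam]) / sbfj
            qa = da - om * db
            qb = db - om * da
            q = (da * qa + db * qb) / s2
            lp += float(
                -0.5 * np.sum(q)
                - np.sum(np.log(safj))
                - np.sum(np.log(sbfj))
                - 0.5 * J * log_s2
                - J * _LOG2PI
            )
            ea = (mu_af - mu_a) / sa
            eb = (mu_bf - mu_b) / sb
            lp += float(-0.5 * np.sum(ea * ea) - F * th[2] - 0.5 * np.sum(eb * eb) - F * th[3])
            lp += -F * _LOG2PI

            t_a = qa / (s2 * safj)
            t_b = qb / (s2 * sbfj)
            # gradients in natural coordinates, then the shear chain rule:
            # d/d b' = d/d b - xbar * d/d a
            ga_nat = galpha - t_a
            gb_nat = gbeta - t_b
            g[self.sl_oa] = ga_nat
            g[self.sl_ob] = gb_nat - sh * ga_nat
            gfa_nat = np.bincount(fam, weights=t_a, minlength=F) - ea / sa
            gfb_nat = np.bincount(fam, weights=t_b, minlength=F) - eb / sb
            g[self.sl_fa] = gfa_nat
            g[self.sl_fb] = gfb_nat - sh * gfa_nat
            g0_nat = float(np.sum(ea)) / sa - mu_a
            g[0] = g0_nat
            g[1] = float(np.sum(eb)) / sb - mu_b - sh * g0_nat
            g[2] = float(np.sum(ea * ea)) - F - sa + 1.0
            g[3] = float(np.sum(eb * eb)) - F - sb + 1.0
            g[4] = float(np.sum(da * db - om * (q - 1.0))) - 2.0 * om
            g[self.sl_lsaf] = (
                np.bincount(fam, weights=da * qa / s2, minlength=F)
                - np.bincount(fam, minlength=F)
                + 1.0
                - saf
            )
            g[self.sl_lsbf] = (
                np.bincount(fam, weights=db * qb / s2, minlength=F)
                - np.bincount(fam, minlength=F)
                + 1.0
                - sbf
            )
        else:
            lp += float(-0.5 * (np.sum(ua * ua) + np.sum(ub * ub))) - J * _LOG2PI
            lp += float(-0.5 * (np.sum(va * va) + np.sum(vb * vb))) - F * _LOG2PI

            Sa_f = np.bincount(fam, weights=galpha, minlength=F)
            Sb_f = np.bincount(fam, weights=gbeta, minlength=F)
            g[0] = Sa_f.sum() - mu_a
            g[1] = Sb_f.sum() - mu_b
            g[2] = sa * float(va @ Sa_f) - sa + 1.0
            g[3] = sb * float(vb @ Sb_f) - sb + 1.0
            gb_s = gbeta * sbf[fam]
            g[4] = float(np.sum(gb_s * (ua * s2 - om * s * ub))) - 2.0 * om
            g[self.sl_fa] = sa * Sa_f - va
            g[self.sl_fb] = sb * Sb_f - vb
            g[self.sl_lsaf] = (
                saf * np.bincount(fam, weights=galpha * ua, minlength=F) + 1.0 - saf
            )
            g[self.sl_lsbf] = (
                sbf * np.bincount(fam, weights=gbeta * rot, minlength=F) + 1.0 - sbf
            )
            g[self.sl_oa] = galpha * saf[fam] + gb_s * om - ua
            g[self.sl_ob] = gb_s * s - ub
        return lp, g

    def logp(self, th: np.ndarray) -> float:
        return self.logp_grad(th)[0]
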