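"""Non-hierarchical comparators: per-OTU maximum-likelihood NB regression.

The standard analysis fits each OTU separately by maximum likelihood
(the glm.nb-style model: NB counts, log link, library-size offset) and
tests the slope with a Wald test.  :class:`NegativeBinomialGLM` wraps
statsmodels' NB-2 ML routine per OTU and collects estimates, standard
errors, dispersions and convergence flags; OTUs where the optimizer
fails or where all counts are zero are flagged rather than dropped
silently.

The Bayesian comparator without phylogenetic structure lives in
:func:`phylonb.hierarchical.fit_bhm_nophylo` (it is the one-family
special case of the hierarchical model) and is re-exported here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .hierarchical import fit_bhm_nophylo, significance_threshold
from .io import CountMatrix, CovariateVector

__all__ = ["GlmFitResult", "NegativeBinomialGLM", "fit_nb_glm", "fit_bhm_nophylo"]

# treat NB fits that drift to (near-)zero overdispersion as Poisson-like
PHI_CAP = 1e8


class GlmFitResult(pd.DataFrame):
    """Per-OTU GLM results table.

    Columns: ``otu_id, intercept, slope, se_intercept, se_slope, phi,
    p_value, ci_lower, ci_upper, converged, estimable``.  Plain
    DataFrame subclass so all pandas tooling applies.
    """

    @property
    def _constructor(self):
        return GlmFitResult


class NegativeBinomialGLM(BaseEstimator):
    """Per-OTU ML negative-binomial regression with offset.

    Fits ``Y_ij ~ NB(exp(a_j + b_j x_i + log z_i), phi_j)`` for each
    OTU j independently by maximum likelihood and reports Wald
    inference for the slope.  ``results_`` holds a
    :class:`GlmFitResult` after :meth:`fit`.
    """

    def __init__(self, maxiter: int = 100, phi_cap: float = PHI_CAP):
        self.maxiter = maxiter
        self.phi_cap = phi_cap

    def fit(self, X, Y, offset=None, otu_ids=None):
        from statsmodels.discrete.discrete_model import NegativeBinomial as _NB

        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        Y = np.asarray(Y)
        n, J = Y.shape
        if offset is None:
            offset = Y.sum(axis=1)
        log_off = np.log(np.asarray(offset, dtype=float))
        if otu_ids is None:
            otu_ids = [f"otu{j + 1}" for j in range(J)]
        exog = np.column_stack([np.ones(n), X])

        rows = []
        for j in range(J):
            y = Y[:, j]
            row = {
                "otu_id": otu_ids[j],
                "intercept": np.nan,
                "slope": np.nan,
                "se_intercept": np.nan,
                "se_slope": np.nan,
                "phi": np.nan,
                "p_value": np.nan,
                "ci_lower": np.nan,
                "ci_upper": np.nan,
                "converged": False,
                "estimable": True,
            }
            if not y.any():
                row["estimable"] = False
                rows.append(row)
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = _NB(y, exog, offset=log_off, loglike_method="nb2")
                    res = model.fit(disp=0, maxiter=self.maxiter)
                a_disp = float(res.params[-1])  # alpha = 1/phi
                se = res.bse
                converged = bool(res.mle_retvals.get("converged", False))
                params = np.asarray(res.params[:2], dtype=float)
                se2 = np.asarray(se[:2], dtype=float)
                pval = float(res.pvalues[1])
                phi = min(self.phi_cap, 1.0 / max(a_disp, 1.0 / self.phi_cap))
                if not converged or a_disp < 1e-6:
                    # dispersion at the Poisson boundary: the NB optimizer
                    # cannot settle; a Poisson GLM gives the limit fit
                    import statsmodels.api as sm

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pres = sm.GLM(
                            y, exog, family=sm.families.Poisson(), offset=log_off
                        ).fit()
                    if pres.llf >= res.llf - 1e-6 or not np.isfinite(res.llf):
                        params = np.asarray(pres.params, dtype=float)
                        se2 = np.asarray(pres.bse, dtype=float)
                        pval = float(pres.pvalues[1])
                        phi = self.phi_cap
                        converged = bool(pres.converged)
                slope, se_slope = float(params[1]), float(se2[1])
                if not np.isfinite(se_slope) or se_slope <= 0:
                    converged = False
                row.update(
                    intercept=float(params[0]),
                    slope=slope,
                    se_intercept=float(se2[0]),
                    se_slope=se_slope,
                    phi=phi,
                    p_value=pval,
                    ci_lower=slope - 1.959963984540054 * se_slope,
                    ci_upper=slope + 1.959963984540054 * se_slope,
                    converged=converged,
                )
            except Exception:
                pass  # flagged non-converged below
            rows.append(row)

        self.results_ = GlmFitResult(rows)
        self.n_features_in_ = 1
        return self

    def summarize(self, n_batches: int = 1) -> pd.DataFrame:
        """Association-style table matching the Bayesian output schema."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "results_")
        res = self.results_
        thresh = significance_threshold(n_batches)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = res["slope"] / res["se_slope"]
        out = pd.DataFrame(
            {
                "otu_id": res["otu_id"],
                "beta_mean": res["slope"],
                "beta_sd": res["se_slope"],
                "z": z,
                "ci_lower": res["ci_lower"],
                "ci_upper": res["ci_upper"],
                "p_value": res["p_value"],
                "converged": res["converged"],
                "significant": (np.abs(z) > thresh) & res["converged"],
            }
        )
        return out


def fit_nb_glm(counts: CountMatrix, x: CovariateVector) -> GlmFitResult:
    """Per-OTU NB regression on container types (slope on x, offset log z)."""
    x = x.align(counts.subject_ids)
    est = NegativeBinomialGLM()
    est.fit(x.values, counts.counts, offset=counts.totals, otu_ids=counts.otu_ids)
    return est.results_
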