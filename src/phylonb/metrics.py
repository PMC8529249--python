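"""Performance measures for slope estimation on simulated data.

Four measures compare estimated slopes with the generating truth: mean
squared error, bias (estimated minus true), coverage of nominal 95%
intervals, and the false discovery rate.  An OTU counts as truly null
when it belongs to the family generated with slope mean zero; its
realized slope is then a small N(0, 0.1) perturbation around zero, so
"null" is a property of the generating family, not of the realized
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["mse", "bias", "coverage95", "fdr", "EvalReport", "evaluate_method"]


def _pair(est, truth):
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {truth.shape}")
    return est, truth


def mse(est, truth) -> float:
    """Mean squared error between estimated and true slopes."""
    est, truth = _pair(est, truth)
    return float(np.mean((est - truth) ** 2))


def bias(est, truth) -> float:
    """Mean of (estimated - true)."""
    est, truth = _pair(est, truth)
    return float(np.mean(est - truth))


def coverage95(lower, upper, truth) -> float:
    """Fraction of OTUs whose interval contains the true slope."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.any(lower > upper):
        raise ValueError("inverted interval (lower > upper)")
    return float(np.mean((lower <= truth) & (truth <= upper)))


def fdr(significant, is_null) -> float:
    """False discovery rate: null discoveries / all discoveries.

    Returns 0 when nothing is declared significant.
    """
    significant = np.asarray(significant, dtype=bool)
    is_null = np.asarray(is_null, dtype=bool)
    n_disc = int(significant.sum())
    if n_disc == 0:
        return 0.0
    return float((significant & is_null).sum() / n_disc)


def literal_null_ratio(significant, is_null) -> float:
    """Companion debug quantity: all true nulls / false discoveries.

    Not a rate (it can exceed 1); reported alongside :func:`fdr` for
    comparison with alternative bookkeeping conventions.
    """
    significant = np.asarray(significant, dtype=bool)
    is_null = np.asarray(is_null, dtype=bool)
    n_false = int((significant & is_null).sum())
    if n_false == 0:
        return float("nan")
    return float(is_null.sum() / n_false)


@dataclass
class EvalReport:
    """Long-format collection of per-(scenario, method) measures."""

    rows: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def evaluate_method(
    scenario: str,
    method: str,
    est,
    lower,
    upper,
    significant,
    truth_beta,
    is_null,
    keep=None,
) -> dict:
    """All four measures for one (scenario, method) fit.

    ``keep`` masks OTUs that enter the estimation metrics (e.g. GLM
    fits that converged); excluded OTUs are counted, not imputed.
    """
    est = np.asarray(est, dtype=float)
    n_total = est.shape[0]
    keep = np.ones(n_total, dtype=bool) if keep is None else np.asarray(keep, bool)
    truth_beta = np.asarray(truth_beta, dtype=float)
    return {
        "scenario": scenario,
        "method": method,
        "mse": mse(est[keep], truth_beta[keep]),
        "bias": bias(est[keep], truth_beta[keep]),
        "coverage": coverage95(
            np.asarray(lower)[keep], np.asarray(upper)[keep], truth_beta[keep]
        ),
        "fdr": fdr(np.asarray(significant)[keep], np.asarray(is_null)[keep]),
        "n_evaluated": int(keep.sum()),
        "n_excluded": int(n_total - keep.sum()),
    }
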