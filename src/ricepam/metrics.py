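"""Model evaluation statistics: R², RMSE and relative RMSE.

Two R² forms are provided.  The default, ``eq9``, is the regression
sum-of-squares ratio Σ(ŷᵢ−ȳ)² / Σ(yᵢ−ȳ)² with ȳ the mean of the
*measured* values.  For predictions that are OLS-with-intercept fitted
values this coincides exactly with the conventional
1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)²; for out-of-sample predictions the two differ and
``eq9`` can exceed 1, so the ``conventional`` form is exposed for
transfer-style evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConstantResponseError, RicePamError

R2_FORMS = ("eq9", "conventional")


def _check_pair(y, yhat, min_n=1):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise RicePamError(f"length mismatch: y has {y.size}, yhat has {yhat.size}")
    if y.size < min_n:
        raise RicePamError(f"need at least {min_n} observations, got {y.size}")
    return y, yhat


def r_squared(y, yhat, form: str = "eq9") -> float:
    """Coefficient of determination between measured y and predicted yhat."""
    if form not in R2_FORMS:
        raise RicePamError(f"unknown R² form {form!r}; choose from {R2_FORMS}")
    y, yhat = _check_pair(y, yhat, min_n=2)
    ybar = y.mean()
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot == 0:
        raise ConstantResponseError("constant response: variance of y is zero")
    if form == "eq9":
        return float(np.sum((yhat - ybar) ** 2)) / ss_tot
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y, yhat) -> float:
    """Root mean square error, in the units of y."""
    y, yhat = _check_pair(y, yhat, min_n=1)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rrmse(y, yhat) -> float:
    """Relative RMSE: 100 * RMSE / mean(y), in percent."""
    y, yhat = _check_pair(y, yhat, min_n=1)
    ybar = y.mean()
    if ybar == 0:
        raise RicePamError("zero-mean response: rRMSE undefined")
    return 100.0 * rmse(y, yhat) / ybar


@dataclass(frozen=True)
class EvalReport:
    """Bundle of the three evaluation statistics for one model."""

    r2: float
    rmse: float
    rrmse: float
    n: int
    form: str = "eq9"

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(y, yhat, form: str = "eq9") -> EvalReport:
    """Compute R² (chosen form), RMSE and rRMSE in one report."""
    y_arr, _ = _check_pair(y, yhat, min_n=2)
    return EvalReport(
        r2=r_squared(y, yhat, form=form),
        rmse=rmse(y, yhat),
        rrmse=rrmse(y, yhat),
        n=int(y_arr.size),
        form=form,
    )
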