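"""Second-order response-surface model on coded factors, with full ANOVA.

The response surface is the 10-term quadratic polynomial

    y = b0 + b1*x1 + b2*x2 + b3*x3
        + b11*x1^2 + b22*x2^2 + b33*x3^2
        + b12*x1*x2 + b13*x1*x3 + b23*x2*x3

fit by ordinary least squares to coded (-1/0/+1) factor levels.  The ANOVA
panel follows the Design-Expert conventions used throughout the response
surface literature:

* per-term sums of squares are partial (Type III): the increase in residual
  SS when the term is dropped and the model refit;
* the residual is split into lack of fit and pure error, the latter from
  replicate groups (the center runs of a BBD);
* predicted R^2 comes from PRESS via the hat-matrix leave-one-out identity;
* "adequate precision" is the signal-to-noise ratio
  (max fitted - min fitted) / sqrt(p * MSE / n) over the design points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import AnovaError, SingularDesignError

#: Names of the 10 model-matrix columns, in fit order.
TERM_NAMES = ["const", "x1", "x2", "x3", "x1^2", "x2^2", "x3^2", "x1*x2", "x1*x3", "x2*x3"]


def quadratic_model_matrix(coded) -> np.ndarray:
    """Expand (n, 3) coded points into the (n, 10) quadratic model matrix."""
    x = np.asarray(coded, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
    return np.column_stack(
        [np.ones(len(x)), x1, x2, x3, x1**2, x2**2, x3**2, x1 * x2, x1 * x3, x2 * x3]
    )


def significance_verdict(p: float) -> str:
    """Classify a p-value: <0.001 exceptionally, <0.01 highly, <0.05 significant."""
    if p < 0.001:
        return "exceptionally significant"
    if p < 0.01:
        return "highly significant"
    if p < 0.05:
        return "significant"
    return "not significant"


@dataclass
class AnovaTable:
    """Design-Expert-shaped ANOVA panel for a quadratic response surface."""

    response: str
    terms: pd.DataFrame  # source, coefficient, SS, DF, MS, F, p, verdict
    model_ss: float
    model_df: int
    model_f: float
    model_p: float
    residual_ss: float
    residual_df: int
    lack_of_fit_ss: float
    lack_of_fit_df: int
    lack_of_fit_f: float
    lack_of_fit_p: float
    pure_error_ss: float
    pure_error_df: int
    total_ss: float
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    cv_pct: float
    adeq_precision: float

    @property
    def model_ms(self) -> float:
        return self.model_ss / self.model_df

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df

    def to_frame(self) -> pd.DataFrame:
        """Full panel as a tidy frame (term rows plus summary rows)."""
        rows = [
            {
                "source": "Model",
                "coefficient": np.nan,
                "SS": self.model_ss,
                "DF": self.model_df,
                "MS": self.model_ms,
                "F": self.model_f,
                "p": self.model_p,
                "verdict": significance_verdict(self.model_p),
            }
        ]
        rows.extend(self.terms.to_dict("records"))
        rows.append(
            {
                "source": "Lack of Fit",
                "coefficient": np.nan,
                "SS": self.lack_of_fit_ss,
                "DF": self.lack_of_fit_df,
                "MS": self.lack_of_fit_ss / self.lack_of_fit_df,
                "F": self.lack_of_fit_f,
                "p": self.lack_of_fit_p,
                "verdict": significance_verdict(self.lack_of_fit_p),
            }
        )
        rows.append(
            {
                "source": "Pure Error",
                "coefficient": np.nan,
                "SS": self.pure_error_ss,
                "DF": self.pure_error_df,
                "MS": self.pure_error_ss / self.pure_error_df,
                "F": np.nan,
                "p": np.nan,
                "verdict": "",
            }
        )
        rows.append(
            {
                "source": "Cor Total",
                "coefficient": np.nan,
                "SS": self.total_ss,
                "DF": self.model_df + self.residual_df,
                "MS": np.nan,
                "F": np.nan,
                "p": np.nan,
                "verdict": "",
            }
        )
        return pd.DataFrame(rows)

    def summary_stats(self) -> dict:
        return {
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "pred_r2": self.pred_r2,
            "press": self.press,
            "cv_pct": self.cv_pct,
            "adeq_precision": self.adeq_precision,
        }

    def to_text(self) -> str:
        """Aligned plain-text rendering mirroring the published panel layout."""
        df = self.to_frame().copy()
        for c in ("SS", "MS", "F"):
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.4g}")
        df["p"] = df["p"].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
        df["coefficient"] = df["coefficient"].map(
            lambda v: "" if pd.isna(v) else f"{v:.4g}"
        )
        lines = [f"ANOVA for quadratic model for {self.response}"]
        lines.append(df.to_string(index=False))
        s = self.summary_stats()
        lines.append(
            f"R2 {s['r2']:.4f}  Adj R2 {s['adj_r2']:.4f}  Pred R2 {s['pred_r2']:.4f}  "
            f"Adeq Precision {s['adeq_precision']:.4f}  C.V.% {s['cv_pct']:.2f}"
        )
        return "\n".join(lines)


class QuadraticSurface(RegressorMixin, BaseEstimator):
    """OLS quadratic response-surface regressor on coded factors.

    Parameters
    ----------
    response : str
        Label used in reports ("TPC", "TFC", ...).

    Attributes
    ----------
    coef_ : ndarray of shape (10,)
        Coefficients ordered as :data:`TERM_NAMES`.
    intercept_ : float
        ``coef_[0]``, for convenience.
    """

    def __init__(self, response: str = "y"):
        self.response = response

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n, 3) coded factor levels")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) < 10:
            raise SingularDesignError("need >= 10 runs to fit 10 coefficients")
        M = quadratic_model_matrix(X)
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise SingularDesignError("quadratic model matrix is rank-deficient")
        beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
        self.coef_ = beta
        self.intercept_ = float(beta[0])
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return quadratic_model_matrix(X) @ self.coef_

    def coefficients(self) -> dict:
        check_is_fitted(self, "coef_")
        return dict(zip(TERM_NAMES, (float(b) for b in self.coef_)))

    def stationary_point(self) -> np.ndarray:
        """Coded point where the fitted surface gradient vanishes."""
        check_is_fitted(self, "coef_")
        b = self.coef_
        A = np.array(
            [
                [2 * b[4], b[7], b[8]],
                [b[7], 2 * b[5], b[9]],
                [b[8], b[9], 2 * b[6]],
            ]
        )
        return np.linalg.solve(A, -b[1:4])

    def anova(self, replicate_groups=None) -> AnovaTable:
        """Full ANOVA panel for the fitted model.

        Parameters
        ----------
        replicate_groups : array-like of group labels, optional
            Marks replicated runs for the pure-error split.  By default
            all exact duplicate coded rows form a group (the BBD centers).
        """
        check_is_fitted(self, "coef_")
        X, y = self.X_, self.y_
        n, p = len(y), 10
        M = quadratic_model_matrix(X)
        yhat = M @ self.coef_
        resid = y - yhat
        sse = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        ssm = sst - sse
        df_model, df_resid = p - 1, n - p

        # pure error from replicate groups
        if replicate_groups is None:
            _, groups = np.unique(M, axis=0, return_inverse=True)
        else:
            _, groups = np.unique(np.asarray(replicate_groups), return_inverse=True)
        sspe, dfpe = 0.0, 0
        for g in np.unique(groups):
            yg = y[groups == g]
            if len(yg) > 1:
                sspe += float(np.sum((yg - yg.mean()) ** 2))
                dfpe += len(yg) - 1
        if dfpe < 1:
            raise AnovaError("no replicated runs: pure error / lack of fit undefined")
        sslof = sse - sspe
        dflof = df_resid - dfpe
        if dflof < 1:
            raise AnovaError("no lack-of-fit degrees of freedom left")

        mse = sse / df_resid
        f_model = (ssm / df_model) / mse if mse > 0 else float("inf")
        p_model = float(stats.f.sf(f_model, df_model, df_resid)) if mse > 0 else 0.0
        ms_pe = sspe / dfpe
        if ms_pe > 0:
            f_lof = (sslof / dflof) / ms_pe
            p_lof = float(stats.f.sf(f_lof, dflof, dfpe))
        else:
            # replicates agree exactly (e.g. noise-free synthetic data):
            # the lack-of-fit ratio is undefined
            f_lof = float("nan")
            p_lof = float("nan")

        # partial (Type III) SS per non-intercept term: drop-and-refit
        rows = []
        for j in range(1, p):
            Mr = np.delete(M, j, axis=1)
            br, _, _, _ = np.linalg.lstsq(Mr, y, rcond=None)
            sse_r = float(np.sum((y - Mr @ br) ** 2))
            ssj = sse_r - sse
            fj = ssj / mse if mse > 0 else float("inf")
            pj = float(stats.f.sf(fj, 1, df_resid)) if mse > 0 else 0.0
            rows.append(
                {
                    "source": TERM_NAMES[j],
                    "coefficient": float(self.coef_[j]),
                    "SS": ssj,
                    "DF": 1,
                    "MS": ssj,
                    "F": fj,
                    "p": pj,
                    "verdict": significance_verdict(pj),
                }
            )

        # PRESS via the hat-matrix leave-one-out identity
        H = M @ np.linalg.solve(M.T @ M, M.T)
        lev = np.diag(H)
        if np.any(1 - lev <= 0):
            raise AnovaError("a leverage of 1 makes PRESS undefined")
        press = float(np.sum((resid / (1 - lev)) ** 2))

        r2 = 1 - sse / sst
        return AnovaTable(
            response=self.response,
            terms=pd.DataFrame(rows),
            model_ss=ssm,
            model_df=df_model,
            model_f=f_model,
            model_p=p_model,
            residual_ss=sse,
            residual_df=df_resid,
            lack_of_fit_ss=sslof,
            lack_of_fit_df=dflof,
            lack_of_fit_f=f_lof,
            lack_of_fit_p=p_lof,
            pure_error_ss=sspe,
            pure_error_df=dfpe,
            total_ss=sst,
            r2=r2,
            adj_r2=1 - (1 - r2) * (n - 1) / (n - p),
            pred_r2=1 - press / sst,
            press=press,
            cv_pct=100.0 * np.sqrt(mse) / y.mean(),
            adeq_precision=(
                float((yhat.max() - yhat.min()) / np.sqrt(p * mse / n))
                if mse > 0
                else float("inf")
            ),
        )

    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        return json.dumps(
            {"response": self.response, "coefficients": self.coefficients()},
            indent=2,
        )

    @classmethod
    def from_coefficients(cls, coefficients, response: str = "y") -> "QuadraticSurface":
        """Build a predict-only model from known coefficients.

        ``coefficients`` may be a 10-vector in :data:`TERM_NAMES` order or a
        mapping of term name to value.  ``anova`` is unavailable on such a
        model (no data attached).
        """
        model = cls(response=response)
        if isinstance(coefficients, dict):
            beta = np.array([coefficients[t] for t in TERM_NAMES], dtype=float)
        else:
            beta = np.asarray(coefficients, dtype=float)
        if beta.shape != (10,):
            raise ValueError("need exactly 10 coefficients")
        model.coef_ = beta
        model.intercept_ = float(beta[0])
        model.n_features_in_ = 3
        return model

    @classmethod
    def from_json(cls, text: str) -> "QuadraticSurface":
        payload = json.loads(text)
        return cls.from_coefficients(payload["coefficients"], payload.get("response", "y"))
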