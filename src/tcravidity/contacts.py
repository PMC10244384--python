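"""Linear model linking modeled TCR-pMHC atomic contacts to binding half-life.

The model is a simplification of a binding free-energy estimate:

    T1/2 (s) = K + gamma * n_apolar + delta * n_polar

where ``n_apolar`` and ``n_polar`` count favorable non-polar and polar
contacts in the modeled TCR-pMHC interface, ``gamma`` and ``delta`` weight
them, and ``K`` absorbs contributions independent of contact counts. The
three parameters are fitted by ordinary least squares against measured
half-lives — no weighting, no regularisation, intercept always included.
Predictions are a plain linear evaluation and may be negative; they are
reported as-is and flagged, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import ContactCounts

_COLUMNS = ("complex_id", "n_apolar", "n_polar", "halflife_s")


def predict_halflife(
    k: float, gamma: float, delta: float, n_apolar, n_polar
) -> Union[float, np.ndarray]:
    """Evaluate T1/2 = K + gamma*n_apolar + delta*n_polar (scalar or vectorised)."""
    result = k + gamma * np.asarray(n_apolar, dtype=float) + delta * np.asarray(
        n_polar, dtype=float
    )
    return float(result) if np.ndim(result) == 0 else result


class ContactHalfLifeModel:
    """OLS model of half-life on apolar and polar contact counts.

    Parameters
    ----------
    table
        DataFrame with columns ``complex_id``, ``n_apolar``, ``n_polar`` and
        ``halflife_s``, or any object coercible to one. Rows with missing
        half-life are excluded from fitting (they can still be predicted).
    """

    def __init__(self, table: pd.DataFrame):
        table = pd.DataFrame(table)
        missing = [c for c in _COLUMNS[:3] if c not in table.columns]
        if missing:
            raise ValueError(f"contact table lacks required columns {missing}")
        if "halflife_s" not in table.columns:
            table = table.assign(halflife_s=np.nan)
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[ContactCounts]) -> "ContactHalfLifeModel":
        rows = [
            (r.complex_id, r.n_apolar, r.n_polar, r.halflife_s) for r in records
        ]
        return cls(pd.DataFrame(rows, columns=_COLUMNS))

    def fit(self) -> "ContactHalfLifeResults":
        data = self.table.dropna(subset=["halflife_s"])
        if len(data) < 3:
            raise ValueError(
                f"need at least 3 complexes with measured half-life, have {len(data)}"
            )
        x = data[["n_apolar", "n_polar"]].to_numpy(dtype=float)
        for col_idx, name in enumerate(("n_apolar", "n_polar")):
            if np.ptp(x[:, col_idx]) == 0:
                raise ValueError(
                    f"design is rank deficient: column {name!r} is constant"
                )
        design = sm.add_constant(x, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "design is rank deficient: n_apolar and n_polar are collinear"
            )
        ols = sm.OLS(data["halflife_s"].to_numpy(dtype=float), design).fit()
        return ContactHalfLifeResults(model=self, _sm_results=ols, nobs=len(data))


@dataclass
class ContactHalfLifeResults:
    """Fitted contact model: parameters, uncertainties and diagnostics."""

    model: ContactHalfLifeModel
    _sm_results: "sm.regression.linear_model.RegressionResultsWrapper"
    nobs: int

    @property
    def k(self) -> float:
        return float(self._sm_results.params[0])

    @property
    def gamma(self) -> float:
        return float(self._sm_results.params[1])

    @property
    def delta(self) -> float:
        return float(self._sm_results.params[2])

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._sm_results.params, index=["k", "gamma", "delta"])

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._sm_results.bse, index=["k", "gamma", "delta"])

    @property
    def rsquared(self) -> float:
        return float(self._sm_results.rsquared)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._sm_results.resid)

    @property
    def resid_sd(self) -> float:
        dof = max(self.nobs - 3, 1)
        return float(np.sqrt(np.sum(self.resid**2) / dof))

    def predict(self, n_apolar, n_polar) -> Union[float, np.ndarray]:
        """Predicted half-life; negative predictions are flagged with a warning."""
        pred = predict_halflife(self.k, self.gamma, self.delta, n_apolar, n_polar)
        if np.any(np.asarray(pred) < 0):
            import warnings

            warnings.warn(
                "predicted half-life is negative for at least one complex; the "
                "linear contact model extrapolates below its physical range",
                UserWarning,
                stacklevel=2,
            )
        return pred

    def summary(self) -> str:
        lines = [
            "Contact-count half-life model (OLS)",
            f"  n complexes:  {self.nobs}",
            f"  K     (s):            {self.k: .4f}  (SE {self.bse['k']:.4f})",
            f"  gamma (s/apolar ct):  {self.gamma: .4f}  (SE {self.bse['gamma']:.4f})",
            f"  delta (s/polar ct):   {self.delta: .4f}  (SE {self.bse['delta']:.4f})",
            f"  R^2:          {self.rsquared:.4f}",
            f"  residual SD:  {self.resid_sd:.4f} s",
        ]
        return "\n".join(lines)

    def to_keyvalues(self) -> dict[str, float]:
        return {
            "k": self.k,
            "gamma": self.gamma,
            "delta": self.delta,
            "r_squared": self.rsquared,
            "residual_sd": self.resid_sd,
            "n": self.nobs,
        }
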