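"""PLS regression of activities on molecular-field descriptors.

The modelling surface follows the model/results idiom: :class:`FieldPLS`
holds the design (a descriptor matrix or a :class:`~fieldqsar.fields.FieldBlock`)
and the pIC50 vector; :meth:`FieldPLS.fit` returns a
:class:`FieldPLSResults` carrying the fitted state and the conventional
QSAR statistics —

* q²  — leave-one-out cross-validated predictivity,
  ``1 - PRESS_loo / sum((y - ybar)^2)``;
* ONC — the component count maximising q² (ties go to the smaller count);
* r²  — non-cross-validated ``1 - RSS/TSS``;
* SEE — ``sqrt(RSS / (n - c - 1))``;
* F   — ``(r²/c) / ((1-r²)/(n-c-1))``;
* per-field-kind contributions — the normalised share of
  ``sum_j |coef_j| * std_j`` belonging to each field kind.

The latent-variable decomposition itself is scikit-learn's NIPALS
(``PLSRegression(scale=False)``): X and y are mean-centred, never
variance-scaled (block scaling, when wanted, happens upstream in the field
assembly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .fields import FieldBlock

__all__ = ["FieldPLS", "FieldPLSResults", "CrossValResult", "ContourSet"]


def _as_matrix(X):
    if isinstance(X, FieldBlock):
        return X.matrix(), X
    return np.asarray(X, dtype=float), None


def _fit_core(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the centred design rank {rank}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when comps ~ rank
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X, y)
    return pls


@dataclass
class CrossValResult:
    """Leave-one-out cross-validation summary across component counts."""

    q2: float
    onc: int
    y_mean: float
    per_fold_predictions: np.ndarray  # LOO predictions at the ONC
    q2_by_components: dict  # candidate count -> q2

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_components": list(self.q2_by_components),
             "q2": list(self.q2_by_components.values())}
        )


@dataclass
class ContourSet:
    """StDev*Coeff lattice values with favoured/disfavoured point sets."""

    stdev_coeff: np.ndarray  # per retained column
    kind_labels: np.ndarray
    favored_threshold: dict
    disfavored_threshold: dict
    favored_points: dict  # kind label -> column indices (into retained cols)
    disfavored_points: dict


class FieldPLS:
    """PLS model of activity on field descriptors.

    Parameters
    ----------
    endog : (n,) array-like
        Activities (pIC50) of the modelled compounds.
    exog : array-like or FieldBlock
        Descriptor matrix; a FieldBlock contributes only its retained
        columns and remembers which field kind each column belongs to.
    """

    def __init__(self, endog, exog, compound_ids: Optional[Sequence[str]] = None):
        X, block = _as_matrix(exog)
        y = np.asarray(endog, dtype=float).reshape(-1)
        if X.shape[0] != y.shape[0]:
            raise ValueError(f"{X.shape[0]} descriptor rows vs {y.shape[0]} activities")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 compounds")
        self.exog = X
        self.endog = y
        self.block = block
        if compound_ids is None and block is not None:
            compound_ids = block.compound_ids
        self.compound_ids = list(compound_ids) if compound_ids is not None else None

    @classmethod
    def from_dataset(cls, dataset, block: FieldBlock, train_only: bool = True):
        """Build from a QsarDataset and a FieldBlock sharing compound ids."""
        pic50 = dataset.pic50()
        ids = [r.compound_id for r in dataset.records if not (train_only and r.is_test)]
        row = {cid: i for i, cid in enumerate(block.compound_ids)}
        missing = [c for c in ids if c not in row]
        if missing:
            raise ValueError(f"no descriptors for compounds: {missing}")
        X = block.matrix()[[row[c] for c in ids]]
        model = cls(pic50.loc[ids].to_numpy(), X, compound_ids=ids)
        model.block = block
        return model

    # -- cross-validation ------------------------------------------------
    def loo_cross_validate(self, max_components: int = 10) -> CrossValResult:
        """LOO predictions for 1..max_components latent variables; the ONC
        maximises q² with ties resolved toward fewer components."""
        X, y = self.exog, self.endog
        n = len(y)
        if n < 3:
            raise ValueError("LOO cross-validation needs at least 3 compounds")
        if max_components >= n - 1:
            warnings.warn(
                f"max_components={max_components} truncated to {n - 2} (n={n})",
                stacklevel=2,
            )
            max_components = n - 2
        rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
        max_components = max(1, min(max_components, rank))
        y_mean = float(y.mean())
        tss = float(np.sum((y - y_mean) ** 2))
        if tss == 0:
            raise ValueError("degenerate data: zero activity variance")
        preds = np.zeros((max_components, n))
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            Xi, yi = X[keep], y[keep]
            sub_rank = np.linalg.matrix_rank(Xi - Xi.mean(axis=0))
            for c in range(1, max_components + 1):
                cc = min(c, int(sub_rank))
                pls = _fit_core(Xi, yi, cc)
                preds[c - 1, i] = float(pls.predict(X[i][None, :]).ravel()[0])
        q2s = {
            c: 1.0 - float(np.sum((y - preds[c - 1]) ** 2)) / tss
            for c in range(1, max_components + 1)
        }
        onc = min(q2s, key=lambda c: (-q2s[c], c))
        return CrossValResult(
            q2=q2s[onc],
            onc=onc,
            y_mean=y_mean,
            per_fold_predictions=preds[onc - 1].copy(),
            q2_by_components=q2s,
        )

    # -- fitting ---------------------------------------------------------
    def fit(
        self, n_components: Optional[int] = None, max_components: int = 10
    ) -> "FieldPLSResults":
        """Fit the model.  When ``n_components`` is omitted it is selected by
        LOO cross-validation (the ONC) and the cross-validation result is
        attached to the returned results object."""
        cv = None
        if n_components is None:
            cv = self.loo_cross_validate(max_components=max_components)
            n_components = cv.onc
        pls = _fit_core(self.exog, self.endog, n_components)
        return FieldPLSResults(self, pls, n_components, cv)


class FieldPLSResults:
    """Fitted PLS state plus the QSAR summary statistics."""

    def __init__(self, model: FieldPLS, pls: PLSRegression, n_components: int, cv):
        self.model = model
        self._pls = pls
        self.n_components = int(n_components)
        self.cv = cv
        y = model.endog
        yhat = self.fittedvalues
        rss = float(np.sum((y - yhat) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        self.r2 = 1.0 - rss / tss if tss > 0 else 0.0
        n, c = len(y), self.n_components
        dof = n - c - 1
        self.see = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
        denom = (1.0 - self.r2) / dof if dof > 0 else float("nan")
        self.f_value = float((self.r2 / c) / denom) if dof > 0 and denom > 0 else float("inf")

    # -- basic accessors -------------------------------------------------
    @property
    def coefficients(self) -> np.ndarray:
        return self._pls.coef_.reshape(-1)

    @property
    def intercept(self) -> float:
        return float(self._pls.intercept_.reshape(-1)[0])

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def q2(self) -> Optional[float]:
        return None if self.cv is None else self.cv.q2

    @property
    def onc(self) -> Optional[int]:
        return None if self.cv is None else self.cv.onc

    def predict(self, X_new) -> np.ndarray:
        X_new, _ = _as_matrix(X_new)
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.model.exog.shape[1]:
            raise ValueError(
                f"column mismatch: model has {self.model.exog.shape[1]} descriptors, "
                f"got {X_new.shape[1]}"
            )
        return self._pls.predict(X_new).reshape(-1)

    # -- field contributions ---------------------------------------------
    def field_contributions(self) -> dict:
        """Fractional contribution of each field kind: the per-kind share of
        ``sum_j |coef_j| * std_j`` over the training columns, normalised to 1.
        Without field-kind metadata the single pseudo-kind 'X' is reported."""
        coefs = np.abs(self.coefficients)
        stds = self.model.exog.std(axis=0, ddof=0)
        weights = coefs * stds
        if self.model.block is None:
            return {"X": 1.0}
        labels = self.model.block.kind_labels()[self.model.block.column_mask]
        total = weights.sum()
        if total == 0:
            uniq = list(dict.fromkeys(labels))
            return {k: 1.0 / len(uniq) for k in uniq}
        out = {}
        for k in dict.fromkeys(labels):
            out[k] = float(weights[labels == k].sum() / total)
        return out

    # -- contours ----------------------------------------------------------
    def stdev_coeff_contours(
        self, favored_fraction: float = 0.8, disfavored_fraction: float = 0.2
    ) -> ContourSet:
        """StDev*Coeff contour extraction.

        Per retained column the value is ``std(column) * coefficient``.
        Within each field kind the columns are placed on a cumulative
        contribution scale: sorted by signed value, each column accounts for
        its share of the total absolute StDev*Coeff mass.  Columns whose
        cumulative share exceeds ``favored_fraction`` (and whose value is
        positive) form the favoured set — activity rises where the field
        value rises; columns below ``disfavored_fraction`` with negative
        values form the disfavoured set.  The two sets are disjoint whenever
        ``disfavored_fraction < favored_fraction``.
        """
        if self.model.block is None:
            raise ValueError("contours need a FieldBlock-backed model")
        values = self.coefficients * self.model.exog.std(axis=0, ddof=0)
        labels = self.model.block.kind_labels()[self.model.block.column_mask]
        favored, disfavored, fav_thr, dis_thr = {}, {}, {}, {}
        for k in dict.fromkeys(labels):
            idx = np.where(labels == k)[0]
            v = values[idx]
            total = np.abs(v).sum()
            if total == 0:
                warnings.warn(f"all-zero StDev*Coeff for field {k}", stacklevel=2)
                favored[k] = np.array([], dtype=int)
                disfavored[k] = np.array([], dtype=int)
                fav_thr[k] = dis_thr[k] = float("nan")
                continue
            order = np.argsort(v, kind="stable")  # ascending signed value
            cum = np.cumsum(np.abs(v[order])) / total
            fav_sel = (cum > favored_fraction) & (v[order] > 0)
            dis_sel = (cum <= disfavored_fraction) & (v[order] < 0)
            favored[k] = np.sort(idx[order[fav_sel]])
            disfavored[k] = np.sort(idx[order[dis_sel]])
            fav_thr[k] = float(v[order][fav_sel].min()) if fav_sel.any() else float("nan")
            dis_thr[k] = float(v[order][dis_sel].max()) if dis_sel.any() else float("nan")
        return ContourSet(
            stdev_coeff=values,
            kind_labels=labels,
            favored_threshold=fav_thr,
            disfavored_threshold=dis_thr,
            favored_points=favored,
            disfavored_points=disfavored,
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = ["PLS field-QSAR results", "=" * 34]
        n, c = len(self.model.endog), self.n_components
        lines.append(f"compounds:          {n}")
        lines.append(f"components:         {c}" + ("" if self.cv is None else "  (ONC by LOO)"))
        if self.cv is not None:
            lines.append(f"q2 (LOO):           {self.cv.q2:8.3f}")
        lines.append(f"r2:                 {self.r2:8.3f}")
        lines.append(f"SEE:                {self.see:8.3f}")
        lines.append(f"F:                  {self.f_value:8.3f}")
        contrib = self.field_contributions()
        if contrib:
            lines.append("field contributions:")
            for k, v in contrib.items():
                lines.append(f"    {k:<12s} {v:6.3f}")
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Observed-vs-fitted scatter with the y = x guide line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        y, yhat = self.model.endog, self.fittedvalues
        ax.scatter(y, yhat, s=18, color="k")
        lo, hi = min(y.min(), yhat.min()), max(y.max(), yhat.max())
        ax.plot([lo, hi], [lo, hi], "r-", lw=1)
        ax.set_xlabel("observed pIC50")
        ax.set_ylabel("fitted pIC50")
        return ax
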