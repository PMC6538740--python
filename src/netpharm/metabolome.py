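"""Plasma metabolomics downstream statistics.

Positive intensity matrices (samples x metabolite features, with group
labels and pooled-QC flags) are analysed with:

* PCA on centred, unit-variance data via the singular value
  decomposition, with a deterministic sign convention (each loading
  vector's largest-magnitude entry is made positive);
* two-class PLS-DA fitted by NIPALS, from which per-feature variable
  importance in projection (VIP) scores are computed as

      VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ),

  where w_a are the unit-norm X-weights and SSY_a the response variance
  explained by component a; the identity sum_j VIP_j^2 = p holds for
  every fitted model;
* differential-feature selection by the conjunction VIP > 1.0 and
  two-sided unpaired t-test p < 0.05 on log intensities (half-minimum
  imputation of nonpositive values, natural log);
* named-set ("Venn") logic: per-contrast exclusive members and arbitrary
  boolean combinations given as expressions such as ``(A & B) - C``.
"""

from __future__ import annotations

import ast
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_adjust

__all__ = [
    "IntensityMatrix",
    "PcaResult",
    "PlsModel",
    "pca",
    "plsda_vip",
    "select_differential",
    "venn_specific",
    "venn_expression",
]


@dataclass
class IntensityMatrix:
    """Samples x features positive intensities with group and QC labels."""

    intensities: pd.DataFrame      # index: sample_id, columns: feature ids
    groups: pd.Series              # index: sample_id -> group label
    is_qc: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.intensities.columns.duplicated().any():
            raise ValueError("feature ids must be unique")
        self.groups = self.groups.reindex(self.intensities.index)
        if self.is_qc is None:
            self.is_qc = pd.Series(False, index=self.intensities.index)
        else:
            self.is_qc = self.is_qc.reindex(self.intensities.index).fillna(False)

    def biological(self) -> "IntensityMatrix":
        """Drop pooled-QC injections."""
        keep = ~self.is_qc.astype(bool)
        return IntensityMatrix(
            self.intensities.loc[keep], self.groups.loc[keep], self.is_qc.loc[keep]
        )


def impute_half_min(X: pd.DataFrame) -> pd.DataFrame:
    """Replace missing/nonpositive entries by half the feature minimum
    over positive observations (features with no positive value are left
    untouched and will be dropped by zero-variance handling)."""
    X = X.copy()
    for col in X.columns:
        v = X[col]
        bad = v.isna() | (v <= 0)
        if bad.any():
            pos = v[~bad]
            if len(pos):
                X.loc[bad, col] = pos.min() / 2.0
    return X


def _preprocess(X: np.ndarray, center: bool, scale: bool):
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Z = X - mu
    sd = Z.std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
    keep = sd > 0 if scale else np.ones(X.shape[1], dtype=bool)
    return Z[:, keep] / np.where(sd[keep] == 0, 1, sd[keep]), keep


@dataclass
class PcaResult:
    scores: pd.DataFrame           # samples x components
    loadings: pd.DataFrame         # features x components
    explained: np.ndarray          # variance fractions, sums to 1


def pca(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    center: bool = True,
    scale: bool = True,
) -> PcaResult:
    """PCA by SVD of the centred (and unit-variance-scaled) matrix.

    Zero-variance features are dropped with a warning under scaling.
    Component signs are fixed so each loading vector's
    largest-magnitude entry is positive.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    X = matrix.to_numpy(dtype=float)
    Z, keep = _preprocess(X, center, scale)
    if not keep.all():
        dropped = list(matrix.columns[~keep])
        warnings.warn(
            f"dropped {len(dropped)} zero-variance feature(s): {dropped[:5]}",
            stacklevel=2,
        )
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for a in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[a]))
        if vt[a, j] < 0:
            vt[a] = -vt[a]
            u[:, a] = -u[:, a]
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    k = n_components or len(s)
    k = min(k, len(s))
    comps = [f"PC{i+1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(u[:, :k] * s[:k], index=matrix.index, columns=comps),
        loadings=pd.DataFrame(
            vt[:k].T, index=matrix.columns[keep], columns=comps
        ),
        explained=explained[:k],
    )


@dataclass
class PlsModel:
    """Two-class PLS-DA fit (NIPALS) with per-feature VIP scores."""

    weights: pd.DataFrame          # features x components, unit-norm columns
    scores: pd.DataFrame           # samples x components, mutually orthogonal
    y_loadings: np.ndarray         # per component
    ssy: np.ndarray                # response variance explained per component
    vip: pd.Series                 # per feature
    features: pd.Index


def _nipals_pls1(Z: np.ndarray, y: np.ndarray, n_components: int):
    """PLS1 by NIPALS with X-deflation; returns W, T, q, SSY per component."""
    n, p = Z.shape
    Xa, ya = Z.copy(), y.copy()
    W, T, Q, SSY = [], [], [], []
    for _ in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_load = Xa.T @ t / tt
        q = float(ya @ t / tt)
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q * t
        W.append(w)
        T.append(t)
        Q.append(q)
        SSY.append(q * q * tt)
    return (np.array(W).T, np.array(T).T, np.array(Q), np.array(SSY))


def plsda_vip(
    matrix: pd.DataFrame, groups: pd.Series, n_components: int = 2
) -> PlsModel:
    """Fit a two-class PLS-DA and score features by VIP.

    Data are centred and unit-variance scaled; the response is the
    centred class indicator.  ``n_components`` is truncated (with a
    warning) when it exceeds the available rank.
    """
    groups = groups.reindex(matrix.index)
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError(f"PLS-DA needs exactly 2 groups; got {levels}")
    y = (groups == levels[1]).to_numpy(dtype=float)
    y = y - y.mean()
    X = matrix.to_numpy(dtype=float)
    Z, keep = _preprocess(X, center=True, scale=True)
    features = matrix.columns[keep]
    max_rank = min(Z.shape[0] - 1, Z.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank; truncated to {max_rank}",
            stacklevel=2,
        )
        n_components = max_rank
    W, T, Q, SSY = _nipals_pls1(Z, y, n_components)
    if W.size == 0:
        raise ValueError("PLS-DA found no predictive component (constant response?)")
    p = len(features)
    vip = np.sqrt(p * (SSY * W**2).sum(axis=1) / SSY.sum())
    comps = [f"LV{i+1}" for i in range(W.shape[1])]
    return PlsModel(
        weights=pd.DataFrame(W, index=features, columns=comps),
        scores=pd.DataFrame(T, index=matrix.index, columns=comps),
        y_loadings=Q,
        ssy=SSY,
        vip=pd.Series(vip, index=features, name="vip"),
        features=features,
    )


def select_differential(
    matrix: pd.DataFrame,
    groups: pd.Series,
    n_components: int = 2,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    log_transform: bool = True,
    adjust: bool = False,
) -> pd.DataFrame:
    """Differential features: VIP > threshold AND t-test p < alpha.

    The t-test is a two-sided unpaired equal-variance test on natural-log
    intensities (after half-minimum imputation); ``adjust=True`` applies
    BH and gates on q instead of p.  Returns a per-feature table with
    ``vip, p, (q,) selected``; the selected set is
    ``table.index[table.selected]``.
    """
    groups = groups.reindex(matrix.index)
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups; got {levels}")
    X = impute_half_min(matrix)
    Xt = np.log(X) if log_transform else X
    model = plsda_vip(Xt, groups, n_components)
    in_a = (groups == levels[0]).to_numpy()
    in_b = (groups == levels[1]).to_numpy()
    arr = Xt.to_numpy(dtype=float)
    tt = stats.ttest_ind(arr[in_a], arr[in_b], axis=0, equal_var=True)
    out = pd.DataFrame(
        {"vip": model.vip.reindex(matrix.columns), "p": tt.pvalue},
        index=matrix.columns,
    )
    crit = out["p"] < alpha
    if adjust:
        out["q"] = bh_adjust(np.nan_to_num(out["p"].to_numpy(), nan=1.0))
        crit = out["q"] < alpha
    out["selected"] = (out["vip"] > vip_threshold) & crit & out["vip"].notna()
    return out


def venn_specific(sets_by_contrast: dict[str, set]) -> dict[str, set]:
    """Exclusive members of each named set (present in it, absent from
    every other)."""
    if len(sets_by_contrast) < 2:
        raise ValueError("need at least 2 named sets")
    out = {}
    for name, members in sets_by_contrast.items():
        others = set().union(
            *(m for k, m in sets_by_contrast.items() if k != name)
        )
        out[name] = set(members) - others
    return out


_ALLOWED_OPS = {ast.BitAnd: "and", ast.BitOr: "or", ast.Sub: "diff", ast.BitXor: "xor"}


def _eval_set_expr(node: ast.AST, sets: dict[str, set]) -> set:
    if isinstance(node, ast.Expression):
        return _eval_set_expr(node.body, sets)
    if isinstance(node, ast.Name):
        if node.id not in sets:
            raise ValueError(f"unknown set name: {node.id!r}")
        return set(sets[node.id])
    if isinstance(node, ast.BinOp) and type(node.op) in _ALLOWED_OPS:
        left = _eval_set_expr(node.left, sets)
        right = _eval_set_expr(node.right, sets)
        op = _ALLOWED_OPS[type(node.op)]
        if op == "and":
            return left & right
        if op == "or":
            return left | right
        if op == "xor":
            return left ^ right
        return left - right
    raise ValueError(f"unsupported expression element: {ast.dump(node)}")


def venn_expression(sets_by_contrast: dict[str, set], expression: str) -> set:
    """Evaluate a boolean set expression over named sets.

    Operators: ``&`` intersection, ``|`` union, ``-`` difference, ``^``
    symmetric difference; parentheses as usual.  Example:
    ``"(combo & pd1) - gqd"`` for members common to two contrasts but
    absent from a third.
    """
    tree = ast.parse(expression, mode="eval")
    return _eval_set_expr(tree, sets_by_contrast)
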