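"""Multivariate statistics: standardization, correlation screens, canonical
correlation analysis, and percentage attribution of canonical weights.

Canonical correlation analysis (CCA) finds weight vectors b (for the
independent set X, n x p) and a (for the dependent set Y, n x q) that
maximize corr(Xb, Ya). Successive pairs maximize the correlation subject to
orthogonality with earlier canonical variables, yielding min(p, q) canonical
correlations R_1 >= R_2 >= ... The joint significance of pairs k..m is
tested with Wilks' lambda, Lambda_k = prod_{i>=k} (1 - R_i^2), via
Bartlett's chi-square approximation.

The attribution step converts the first pair's weights into per-side
percentage contributions, percent_j = |w_j| / sum|w| * 100 — the share of
each personal variable in the canonical cognitive-load relationship.

The model/results API follows the statsmodels idiom::

    model = CanonicalCorrelation.from_dataframes(df_x, df_y)
    res = model.fit()
    print(res.summary())
    res.attribution(pair=1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateColumnError,
    DegenerateInputError,
    InsufficientSampleError,
    InvalidParameterError,
    NumericalError,
)

DEFAULT_RIDGE: float = 1e-8


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizedMatrix:
    """Z-scored data matrix with the original column means/SDs retained."""

    values: np.ndarray
    column_names: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


def _as_matrix(
    matrix: np.ndarray | pd.DataFrame, column_names: list[str] | None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns) if column_names is None else list(column_names)
        return matrix.to_numpy(dtype=float), names
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise InvalidParameterError("expected a 2-D matrix")
    if column_names is None:
        names = [f"x{j}" for j in range(arr.shape[1])]
    else:
        names = list(column_names)
    return arr, names


def zscore_normalize(
    matrix: np.ndarray | pd.DataFrame, column_names: list[str] | None = None
) -> StandardizedMatrix:
    """Column-wise z-score standardization, z = (x - mean) / SD (sample SD).

    Means and SDs are stored for back-transformation. A constant column is a
    hard error naming the column: it carries no information and would divide
    by zero.
    """
    arr, names = _as_matrix(matrix, column_names)
    if arr.shape[0] < 3:
        raise InsufficientSampleError(f"need n >= 3 rows, got {arr.shape[0]}")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    constant = np.flatnonzero(sds == 0)
    if constant.size:
        raise DegenerateColumnError(
            f"constant column(s): {[names[j] for j in constant]}"
        )
    return StandardizedMatrix(
        values=(arr - means) / sds,
        column_names=names,
        column_means=means,
        column_sds=sds,
    )


# ---------------------------------------------------------------------------
# correlation screens
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    """Pairwise or partial correlation matrix with two-sided p-values."""

    r: pd.DataFrame
    p_values: pd.DataFrame
    n: int
    kind: str

    def annotate(self, alpha: float = 0.001) -> pd.DataFrame:
        """Correlations rendered to 3 decimals, starred where p < alpha."""
        out = self.r.round(3).astype(str)
        return out.where(self.p_values >= alpha, out + " *")


def _pearson_p(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p-value of a (partial) correlation via the t distribution."""
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(df / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(rr) >= 1.0, 0.0, p)


def correlation_screen(
    X: StandardizedMatrix | np.ndarray | pd.DataFrame,
    Y: StandardizedMatrix | np.ndarray | pd.DataFrame | None = None,
    kind: str = "pairwise",
    fdr: bool = False,
) -> CorrelationReport:
    """Correlation screen between (or within) variable sets.

    kind="pairwise": Pearson product-moment r with two-sided t-test p-values.
    kind="partial": partial correlations from the inverse correlation matrix
    of all variables jointly, each pair conditioned on every other variable,
    with the matching t-test (df = n - k - 2, k conditioning variables).
    With ``Y=None`` a square within-set report is returned.

    ``fdr=True`` applies Benjamini-Hochberg across the off-diagonal cells.
    """
    if kind not in ("pairwise", "partial"):
        raise InvalidParameterError(f"kind must be 'pairwise' or 'partial', got {kind!r}")
    if not isinstance(X, StandardizedMatrix):
        X = zscore_normalize(X)
    if Y is not None and not isinstance(Y, StandardizedMatrix):
        Y = zscore_normalize(Y)
    if Y is not None and Y.n != X.n:
        raise InvalidParameterError(f"mismatched sample counts {X.n} != {Y.n}")

    n = X.n
    if Y is None:
        joint = X.values
        row_names = col_names = X.column_names
        p_rows = p_cols = X.p
        row_idx = col_idx = np.arange(X.p)
    else:
        joint = np.hstack([X.values, Y.values])
        row_names, col_names = X.column_names, Y.column_names
        p_rows, p_cols = X.p, Y.p
        row_idx = np.arange(X.p)
        col_idx = np.arange(X.p, X.p + Y.p)

    p_total = joint.shape[1]
    corr_full = np.corrcoef(joint, rowvar=False)

    if kind == "pairwise":
        r_block = corr_full[np.ix_(row_idx, col_idx)]
        pvals = _pearson_p(r_block, n - 2)
    else:
        if n <= p_total + 2:
            raise InsufficientSampleError(
                f"partial correlation needs n > p + 2 ({n} <= {p_total + 2})"
            )
        try:
            precision = np.linalg.inv(corr_full)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular correlation matrix: {exc}") from exc
        d = np.sqrt(np.diag(precision))
        partial = -precision / np.outer(d, d)
        np.fill_diagonal(partial, 1.0)
        r_block = partial[np.ix_(row_idx, col_idx)]
        pvals = _pearson_p(r_block, n - (p_total - 2) - 2)

    if Y is None:
        np.fill_diagonal(pvals, 0.0)

    if fdr:
        off = ~np.eye(p_rows, p_cols, dtype=bool) if p_rows == p_cols and Y is None else np.ones_like(pvals, dtype=bool)
        flat = pvals[off]
        order = np.argsort(flat)
        m = len(flat)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((flat[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        pvals = pvals.copy()
        pvals[off] = np.clip(adj, 0.0, 1.0)

    return CorrelationReport(
        r=pd.DataFrame(r_block, index=row_names, columns=col_names),
        p_values=pd.DataFrame(pvals, index=row_names, columns=col_names),
        n=n,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# Wilks' lambda
# ---------------------------------------------------------------------------

def wilks_lambda(
    R: np.ndarray, n: int, p: int, q: int, k: int = 1
) -> tuple[float, float, int, float]:
    """Wilks' lambda and Bartlett chi-square test for canonical pairs k..m.

    Lambda_k = prod_{i=k..m} (1 - R_i^2); chi2 = -(n - 1 - (p+q+1)/2) ln
    Lambda_k with df = (p-k+1)(q-k+1). A canonical correlation of exactly 1
    gives Lambda = 0 and an infinite statistic, returned explicitly.

    ``k`` is 1-based. Returns (lambda, chi2, df, p_value).
    """
    R = np.asarray(R, dtype=float)
    if np.any((R < 0) | (R > 1)):
        raise InvalidParameterError("canonical correlations must lie in [0, 1]")
    m = len(R)
    if not 1 <= k <= m:
        raise InvalidParameterError(f"pair index k={k} outside 1..{m}")
    lam = float(np.prod(1.0 - R[k - 1 :] ** 2))
    df = (p - k + 1) * (q - k + 1)
    scale = n - 1 - (p + q + 1) / 2.0
    if lam <= 0.0:
        return 0.0, float("inf"), df, 0.0
    chi2 = -scale * float(np.log(lam))
    p_value = float(stats.chi2.sf(chi2, df))
    return lam, chi2, df, p_value


# ---------------------------------------------------------------------------
# canonical correlation model
# ---------------------------------------------------------------------------

def _inv_sqrt_psd(C: np.ndarray, label: str) -> np.ndarray:
    """Inverse matrix square root of a symmetric PD matrix via eigh."""
    w, V = np.linalg.eigh(C)
    if w.min() <= 0:
        raise NumericalError(
            f"{label} covariance not positive definite beyond ridge repair "
            f"(min eigenvalue {w.min():.3e}, condition {w.max() / abs(w.min()):.3e})"
        )
    cond = w.max() / w.min()
    if cond > 1e14:
        raise NumericalError(f"{label} covariance ill-conditioned (condition {cond:.3e})")
    return (V * (1.0 / np.sqrt(w))) @ V.T


class CanonicalCorrelation:
    """Canonical correlation model between two multivariate sets.

    Parameters
    ----------
    x : array-like or DataFrame, n x p
        Independent set (here: the programmers' personal variables).
    y : array-like or DataFrame, n x q
        Dependent set (here: the eye-movement cognitive-load features).
    standardize : bool
        Z-score both sets before fitting (default). Canonical correlations
        are scale-invariant either way, but the weights — and therefore the
        percentage attributions — are reported on standardized variables.
    ridge : float
        Added to the diagonals of the within-set covariance matrices for
        conditioning.
    """

    def __init__(
        self,
        x,
        y,
        x_names: list[str] | None = None,
        y_names: list[str] | None = None,
        standardize: bool = True,
        ridge: float = DEFAULT_RIDGE,
    ) -> None:
        if standardize:
            self.x = zscore_normalize(x, x_names)
            self.y = zscore_normalize(y, y_names)
        else:
            xv, xn = _as_matrix(x, x_names)
            yv, yn = _as_matrix(y, y_names)
            self.x = StandardizedMatrix(xv - xv.mean(0), xn, xv.mean(0), xv.std(0, ddof=1))
            self.y = StandardizedMatrix(yv - yv.mean(0), yn, yv.mean(0), yv.std(0, ddof=1))
        if self.x.n != self.y.n:
            raise InvalidParameterError(
                f"mismatched sample counts {self.x.n} != {self.y.n}"
            )
        if self.x.n <= self.x.p + self.y.p:
            raise InsufficientSampleError(
                f"need n > p + q ({self.x.n} <= {self.x.p + self.y.p})"
            )
        if ridge < 0:
            raise InvalidParameterError("ridge must be >= 0")
        self.ridge = float(ridge)

    @classmethod
    def from_dataframes(
        cls, df_x: pd.DataFrame, df_y: pd.DataFrame, **kwargs
    ) -> "CanonicalCorrelation":
        """Build the model from two aligned DataFrames (index-joined)."""
        common = df_x.index.intersection(df_y.index)
        return cls(df_x.loc[common], df_y.loc[common], **kwargs)

    def fit(self) -> "CCAResults":
        """Solve for all min(p, q) canonical pairs.

        The generalized eigenproblem is solved through the singular value
        decomposition of Cxx^(-1/2) Cxy Cyy^(-1/2); singular values are the
        canonical correlations, and back-transformed singular vectors the
        weights, rescaled so every canonical variable has unit sample
        variance. The X-side weight vector's largest-magnitude entry is made
        positive; the Y-side sign follows so corr(U_k, V_k) = +R_k.
        """
        Xc, Yc = self.x.values, self.y.values
        n, p, q = self.x.n, self.x.p, self.y.p
        Cxx = (Xc.T @ Xc) / (n - 1) + self.ridge * np.eye(p)
        Cyy = (Yc.T @ Yc) / (n - 1) + self.ridge * np.eye(q)
        Cxy = (Xc.T @ Yc) / (n - 1)

        Cxx_isqrt = _inv_sqrt_psd(Cxx, "X")
        Cyy_isqrt = _inv_sqrt_psd(Cyy, "Y")
        K = Cxx_isqrt @ Cxy @ Cyy_isqrt
        U, s, Vt = np.linalg.svd(K)
        m = min(p, q)
        b = Cxx_isqrt @ U[:, :m]   # X-side weights, columns per pair
        a = Cyy_isqrt @ Vt.T[:, :m]  # Y-side weights

        # unit-variance canonical variables
        Uscores = Xc @ b
        Vscores = Yc @ a
        for k in range(m):
            su = Uscores[:, k].std(ddof=1)
            sv = Vscores[:, k].std(ddof=1)
            if su > 0:
                b[:, k] /= su
                Uscores[:, k] /= su
            if sv > 0:
                a[:, k] /= sv
                Vscores[:, k] /= sv
            # sign convention
            j = int(np.argmax(np.abs(b[:, k])))
            if b[j, k] < 0:
                b[:, k] *= -1
                Uscores[:, k] *= -1
            if np.corrcoef(Uscores[:, k], Vscores[:, k])[0, 1] < 0:
                a[:, k] *= -1
                Vscores[:, k] *= -1

        # canonical correlations as the realized score correlations: the
        # ridge biases the singular values by O(ridge) but not the scores
        R = np.clip(
            np.array(
                [np.corrcoef(Uscores[:, k], Vscores[:, k])[0, 1] for k in range(m)]
            ),
            0.0,
            1.0,
        )

        wilks = np.empty(m)
        chi2 = np.empty(m)
        dfs = np.empty(m, dtype=int)
        pvals = np.empty(m)
        for k in range(1, m + 1):
            wilks[k - 1], chi2[k - 1], dfs[k - 1], pvals[k - 1] = wilks_lambda(
                R, n, p, q, k
            )

        return CCAResults(
            model=self,
            corr=R,
            x_weights=b,
            y_weights=a,
            x_scores=Uscores,
            y_scores=Vscores,
            wilks=wilks,
            chi2=chi2,
            df=dfs,
            p_values=pvals,
        )


@dataclass
class CCAResults:
    """Fitted canonical correlation analysis.

    ``x_weights`` (p x m) and ``y_weights`` (q x m) hold one weight vector
    per canonical pair, on standardized variables; ``x_scores``/``y_scores``
    are the unit-variance canonical variables; ``corr`` the canonical
    correlations in descending order; ``wilks``/``chi2``/``df``/``p_values``
    the Bartlett test of pairs k..m for each starting pair k.
    """

    model: CanonicalCorrelation
    corr: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    wilks: np.ndarray
    chi2: np.ndarray
    df: np.ndarray
    p_values: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.corr)

    @property
    def x_names(self) -> list[str]:
        return self.model.x.column_names

    @property
    def y_names(self) -> list[str]:
        return self.model.y.column_names

    def attribution(self, pair: int = 1) -> "AttributionReport":
        """Percentage contribution of each variable in canonical pair ``pair``
        (1-based), percent_j = |w_j| / sum |w| * 100 per side."""
        if not 1 <= pair <= self.n_pairs:
            raise InvalidParameterError(
                f"pair {pair} outside 1..{self.n_pairs}"
            )
        b = np.abs(self.x_weights[:, pair - 1])
        a = np.abs(self.y_weights[:, pair - 1])
        if b.sum() == 0 or a.sum() == 0:
            raise DegenerateInputError("all-zero canonical weight vector")
        return AttributionReport(
            x_side_percent=pd.Series(100.0 * b / b.sum(), index=self.x_names),
            y_side_percent=pd.Series(100.0 * a / a.sum(), index=self.y_names),
            pair_used=pair,
        )

    def summary(self) -> str:
        """Plain-text summary table of pairs, R, Wilks and Bartlett tests."""
        lines = [
            "Canonical Correlation Analysis",
            f"n = {self.model.x.n}, p = {self.model.x.p}, q = {self.model.y.p}",
            "",
            f"{'pair':>4} {'R':>8} {'Wilks':>8} {'chi2':>10} {'df':>4} {'p':>10}",
        ]
        for k in range(self.n_pairs):
            lines.append(
                f"{k + 1:>4} {self.corr[k]:>8.3f} {self.wilks[k]:>8.3f} "
                f"{self.chi2[k]:>10.3f} {self.df[k]:>4d} {self.p_values[k]:>10.3g}"
            )
        lines.append("")
        att = self.attribution(pair=1)
        lines.append("First-pair attribution (percent of |weights| per side):")
        for name, val in att.x_side_percent.items():
            lines.append(f"  X  {name:<28s} {val:7.3f}%")
        for name, val in att.y_side_percent.items():
            lines.append(f"  Y  {name:<28s} {val:7.3f}%")
        return "\n".join(lines)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Machine-readable tables (weights, correlations, tests)."""
        pairs = [f"pair{k + 1}" for k in range(self.n_pairs)]
        return {
            "correlations": pd.DataFrame(
                {
                    "R": self.corr,
                    "wilks": self.wilks,
                    "chi2": self.chi2,
                    "df": self.df,
                    "p_value": self.p_values,
                },
                index=pairs,
            ),
            "x_weights": pd.DataFrame(self.x_weights, index=self.x_names, columns=pairs),
            "y_weights": pd.DataFrame(self.y_weights, index=self.y_names, columns=pairs),
        }


@dataclass
class AttributionReport:
    """Per-side percentage contribution of each variable (one canonical pair).

    Each side sums to 100; entries are non-negative.
    """

    x_side_percent: pd.Series
    y_side_percent: pd.Series
    pair_used: int = 1

    def __post_init__(self) -> None:
        for side in (self.x_side_percent, self.y_side_percent):
            if not np.isclose(side.sum(), 100.0, atol=1e-6):
                raise DegenerateInputError("attribution side does not sum to 100")
            if (side < 0).any():
                raise DegenerateInputError("negative attribution percentage")

    def to_dict(self) -> dict:
        return {
            "pair_used": self.pair_used,
            "x_side_percent": {k: float(v) for k, v in self.x_side_percent.items()},
            "y_side_percent": {k: float(v) for k, v in self.y_side_percent.items()},
        }


def cca_fit(
    X: StandardizedMatrix | np.ndarray | pd.DataFrame,
    Y: StandardizedMatrix | np.ndarray | pd.DataFrame,
    ridge: float = DEFAULT_RIDGE,
) -> CCAResults:
    """Functional wrapper: fit a :class:`CanonicalCorrelation` model."""
    if isinstance(X, StandardizedMatrix):
        X = X.to_frame()
    if isinstance(Y, StandardizedMatrix):
        Y = Y.to_frame()
    return CanonicalCorrelation(X, Y, ridge=ridge).fit()


def attribute_percent(result: CCAResults, pair: int = 1) -> AttributionReport:
    """Functional wrapper for :meth:`CCAResults.attribution`."""
    return result.attribution(pair=pair)
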