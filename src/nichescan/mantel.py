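"""Pairwise distance matrices and (partial) Mantel permutation tests.

Distances come in three kinds: genetic (mean pairwise F_ST at a locus
subset), environmental (one-dimensional Euclidean distance on a single
variable, i.e. ``|x_i - x_j|``), and geographic (straight-line distance
between site coordinates).  The Mantel statistic is the Pearson
correlation over the off-diagonal upper triangle; its null distribution
is obtained by simultaneous row/column permutation of one matrix.  All
p-values are one-tailed for positive association (isolation increases
with distance) and use the +1/(n+1) convention so they are never zero.

The partial Mantel test conditions on a third matrix (geography) using
residual permutation: the entries of A and B are each regressed on C,
the residual matrix of A is permuted, and the correlation of residuals
is recomputed for every permutation.  The observed statistic equals the
usual first-order partial correlation
``r_p = (r_AB - r_AC r_BC) / sqrt((1-r_AC^2)(1-r_BC^2))``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between labelled sites.

    Parameters
    ----------
    ids
        Site labels, in matrix order.
    values
        Square symmetric array with zero diagonal and finite,
        non-negative entries.
    kind
        One of ``"genetic"``, ``"environmental:<variable>"``,
        ``"geographic"`` (free-form kinds are allowed).
    """

    ids: list
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids length does not match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v
        self.ids = list(self.ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries as a flat vector (row-major)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def align(self, ids: Sequence) -> "DistanceMatrix":
        """Return a copy reordered/subset to ``ids``."""
        index = {s: i for i, s in enumerate(self.ids)}
        try:
            order = [index[s] for s in ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"site {exc.args[0]!r} not in distance matrix") from exc
        return DistanceMatrix(list(ids), self.values[np.ix_(order, order)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str = "generic") -> "DistanceMatrix":
        return cls(list(frame.index), frame.to_numpy(dtype=float), kind)

    def to_csv(self, path) -> None:
        """Square labelled CSV; the kind travels in a header comment."""
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\n")
            self.to_frame().to_csv(fh)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            frame = pd.read_csv(fh, index_col=0)
        kind = header.split("=", 1)[1] if "=" in header else "generic"
        return cls.from_frame(frame, kind)


@dataclass
class MantelResult:
    """Outcome of a simple or partial Mantel permutation test."""

    r: float
    p_one_tailed: float
    n_randomizations: int
    r_p: Optional[float] = None
    conditioned_on: Optional[str] = None
    exhaustive: bool = False


def distance_matrix(
    sites: pd.DataFrame,
    kind: str,
    variable: Optional[str] = None,
    site_col: str = "site_id",
    coord_cols: tuple[str, str] = ("x_km", "y_km"),
) -> DistanceMatrix:
    """Build a per-variable environmental or geographic distance matrix.

    Environmental distance is the absolute difference on a single named
    variable; geographic distance is straight-line Euclidean distance
    between site coordinates.  Sites with missing values on the relevant
    columns are dropped with a warning.
    """
    import warnings

    df = sites.copy()
    if kind == "environmental":
        if variable is None:
            raise ValueError("environmental distance requires a variable name")
        if variable not in df.columns:
            raise KeyError(f"variable {variable!r} not found in site table")
        cols = [variable]
        label = f"environmental:{variable}"
    elif kind == "geographic":
        cols = list(coord_cols)
        for c in cols:
            if c not in df.columns:
                raise KeyError(f"coordinate column {c!r} not found in site table")
        label = "geographic"
    else:
        raise ValueError(f"unknown distance kind {kind!r}")

    bad = df[cols].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} site(s) with missing values for {label}",
            stacklevel=2,
        )
        df = df.loc[~bad]

    ids = list(df[site_col])
    if kind == "environmental":
        x = df[variable].to_numpy(dtype=float)
        mat = np.abs(x[:, None] - x[None, :])
    else:
        xy = df[list(coord_cols)].to_numpy(dtype=float)
        diff = xy[:, None, :] - xy[None, :, :]
        mat = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(ids, mat, label)


def _check_pair(a: DistanceMatrix, b: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(a.ids) != set(b.ids):
        raise ValueError("distance matrices cover different site sets")
    b = b.align(a.ids)
    if a.n < 4:
        raise ValueError("Mantel test requires at least 4 sites")
    return a.values, b.values


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    return float(xc @ yc) / denom


def _permuted_correlations(
    A: np.ndarray,
    b_vec: np.ndarray,
    n_rand: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlations of row/col-permuted A with fixed vectorised B."""
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    bc = b_vec - b_vec.mean()
    b_ss = float(bc @ bc)
    out = np.empty(n_rand)
    for i in range(n_rand):
        perm = rng.permutation(n)
        av = A[np.ix_(perm, perm)][iu]
        ac = av - av.mean()
        out[i] = float(ac @ bc) / math.sqrt(float(ac @ ac) * b_ss)
    return out


def _exhaustive_correlations(A: np.ndarray, b_vec: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    if n > 8:
        raise ValueError("exhaustive enumeration limited to 8 sites")
    iu = np.triu_indices(n, k=1)
    bc = b_vec - b_vec.mean()
    b_ss = float(bc @ bc)
    vals = []
    for perm in itertools.permutations(range(n)):
        idx = np.asarray(perm)
        av = A[np.ix_(idx, idx)][iu]
        ac = av - av.mean()
        vals.append(float(ac @ bc) / math.sqrt(float(ac @ ac) * b_ss))
    return np.asarray(vals)


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_rand: int = 3000,
    seed: Optional[int] = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Simple Mantel test of matrix correlation.

    The observed statistic is the Pearson correlation of the upper
    triangles; the null permutes rows and columns of ``a``
    simultaneously.  With ``exhaustive=True`` all n! permutations are
    enumerated (identity included) and the p-value is the exact
    proportion of permutations with r at least as large as observed.
    """
    A, B = _check_pair(a, b)
    iu = np.triu_indices(a.n, k=1)
    a_vec, b_vec = A[iu], B[iu]
    r = _corr(a_vec, b_vec)

    if exhaustive:
        perm_r = _exhaustive_correlations(A, b_vec)
        # >= includes the identity permutation, so p is never zero
        p = float(np.sum(perm_r >= r - 1e-12)) / perm_r.size
        return MantelResult(r=r, p_one_tailed=p, n_randomizations=perm_r.size, exhaustive=True)

    rng = np.random.default_rng(seed)
    perm_r = _permuted_correlations(A, b_vec, n_rand, rng)
    p = (float(np.sum(perm_r >= r - 1e-12)) + 1.0) / (n_rand + 1.0)
    return MantelResult(r=r, p_one_tailed=p, n_randomizations=n_rand)


def _residual_matrix(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of the entries of Y regressed on the entries of X.

    The least-squares fit uses the upper-triangle pairs; the residual is
    applied elementwise so the result stays a symmetric matrix with zero
    diagonal (the diagonal residual of 0 on 0 is the negated intercept,
    which never enters the statistic and is zeroed for tidiness).
    """
    n = Y.shape[0]
    iu = np.triu_indices(n, k=1)
    x, y = X[iu], Y[iu]
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("constant conditioning matrix")
    beta = float(xc @ (y - y.mean())) / denom
    alpha = y.mean() - beta * x.mean()
    R = Y - (alpha + beta * X)
    np.fill_diagonal(R, 0.0)
    return R


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_rand: int = 3000,
    seed: Optional[int] = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    Uses residual permutation: A and B are each regressed on C over the
    site pairs, the residual matrix of A is row/column permuted, and the
    correlation with the fixed residuals of B is recomputed for each
    permutation.  The observed statistic equals the first-order partial
    correlation r_p.
    """
    A, B = _check_pair(a, b)
    C = c.align(a.ids).values
    iu = np.triu_indices(a.n, k=1)
    a_vec, b_vec, c_vec = A[iu], B[iu], C[iu]

    r_ab = _corr(a_vec, b_vec)
    r_ac = _corr(a_vec, c_vec)
    r_bc = _corr(b_vec, c_vec)
    if abs(r_ac) >= 1.0 - 1e-12 or abs(r_bc) >= 1.0 - 1e-12:
        raise ValueError("conditioning matrix perfectly correlated; partial r undefined")
    r_p = (r_ab - r_ac * r_bc) / math.sqrt((1 - r_ac**2) * (1 - r_bc**2))

    RA = _residual_matrix(A, C)
    RB = _residual_matrix(B, C)
    rb_vec = RB[iu]

    if exhaustive:
        perm_r = _exhaustive_correlations(RA, rb_vec)
        p = float(np.sum(perm_r >= r_p - 1e-12)) / perm_r.size
        return MantelResult(
            r=r_ab, r_p=float(r_p), p_one_tailed=p,
            n_randomizations=perm_r.size, conditioned_on=c.kind, exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    perm_r = _permuted_correlations(RA, rb_vec, n_rand, rng)
    p = (float(np.sum(perm_r >= r_p - 1e-12)) + 1.0) / (n_rand + 1.0)
    return MantelResult(
        r=r_ab, r_p=float(r_p), p_one_tailed=p,
        n_randomizations=n_rand, conditioned_on=c.kind,
    )


def mantel_suite(
    genetic: DistanceMatrix,
    sites: pd.DataFrame,
    variables: Sequence[str],
    n_rand: int = 3000,
    seed: Optional[int] = None,
    flag_threshold: float = 0.001,
    species_id: str = "",
    site_col: str = "site_id",
) -> pd.DataFrame:
    """Simple and partial Mantel tests of a genetic matrix against each
    environmental variable, conditioning the partial test on geography.

    Returns a long-format table with one row per variable: r, r_p, the
    one-tailed permutation p for the partial test, a Holm-adjusted
    column, and a significance flag at ``flag_threshold``.
    """
    from statsmodels.stats.multitest import multipletests

    sub = sites[sites[site_col].isin(genetic.ids)]
    geo = distance_matrix(sub, "geographic", site_col=site_col)
    rows = []
    for i, var in enumerate(variables):
        env = distance_matrix(sub, "environmental", variable=var, site_col=site_col)
        env = env.align(genetic.ids)
        var_seed = None if seed is None else int(seed) + 104729 * (i + 1)
        try:
            simple = mantel(genetic, env, n_rand=n_rand, seed=var_seed)
            part = partial_mantel(genetic, env, geo.align(genetic.ids),
                                  n_rand=n_rand, seed=var_seed)
        except ValueError:
            continue  # constant variable over these sites
        rows.append({
            "species_id": species_id,
            "variable": var,
            "r": simple.r,
            "p_simple": simple.p_one_tailed,
            "r_p": part.r_p,
            "p_partial": part.p_one_tailed,
            "n_rand": n_rand,
            "conditioned_on": "geographic",
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_holm"] = multipletests(table["p_partial"], method="holm")[1]
        table["significant"] = table["p_partial"] < flag_threshold
    return table
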