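"""Recursive path analysis with observed variables.

Implements the SEM stage of the pipeline for acyclic path diagrams over
observed (composite) variables: standardized path coefficients from
per-equation least squares on z-scored data, a model-implied covariance
assembled from the coefficients, and the usual covariance-structure fit
indices (chi-square, CFI against the independence baseline, RMSEA, AIC).
For recursive observed-variable models these per-equation estimates
coincide with covariance-based maximum likelihood.

Composites for the path diagram (growth indicators, community axes) are
built with :func:`composite_pc1` — the first principal component of a small
indicator block, or the first principal coordinate of a Bray-Curtis matrix
for community submatrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable
from .diversity import bray_curtis, pcoa

__all__ = [
    "PathSpec",
    "PathModel",
    "PathModelResults",
    "composite_pc1",
    "fit_path_model",
    "compare_models",
]


@dataclass
class PathSpec:
    """Directed acyclic path diagram: variables and cause -> effect edges."""

    variables: list[str]
    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("path spec needs at least one edge")
        declared = set(self.variables)
        for cause, effect in self.edges:
            if cause not in declared or effect not in declared:
                raise ValueError(f"edge {cause} -> {effect} uses undeclared variable")
        self._toposort()  # raises on cycles

    @classmethod
    def from_strings(cls, edge_strings: list[str], variables: list[str] | None = None):
        """Parse edges given as ``"cause -> effect"`` strings."""
        edges = []
        seen: list[str] = []
        for s in edge_strings:
            parts = [p.strip() for p in s.split("->")]
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"cannot parse edge {s!r}; expected 'cause -> effect'")
            edges.append((parts[0], parts[1]))
            for p in parts:
                if p not in seen:
                    seen.append(p)
        return cls(variables if variables is not None else seen, edges)

    def parents(self, var: str) -> list[str]:
        return [c for c, e in self.edges if e == var]

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.variables if self.parents(v)]

    @property
    def exogenous(self) -> list[str]:
        return [v for v in self.variables if not self.parents(v)]

    def _toposort(self) -> list[str]:
        remaining = {v: set(self.parents(v)) for v in self.variables}
        order = []
        while remaining:
            free = [v for v, deps in remaining.items() if not deps]
            if not free:
                raise ValueError("path spec contains a cycle")
            for v in free:
                order.append(v)
                del remaining[v]
            for deps in remaining.values():
                deps -= set(free)
        return order


@dataclass
class PathCoefficient:
    cause: str
    effect: str
    estimate: float
    se: float
    p_value: float


@dataclass
class PathModelResults:
    """Standardized path coefficients and covariance-structure fit indices."""

    coefficients: list[PathCoefficient]
    chi_square: float
    df: int
    p_chi: float
    cfi: float
    rmsea: float
    aic: float
    n_samples: int
    n_free_params: int
    just_identified: bool = False
    spec: PathSpec | None = None

    def coef(self, cause: str, effect: str) -> PathCoefficient:
        for c in self.coefficients:
            if c.cause == cause and c.effect == effect:
                return c
        raise KeyError(f"no path {cause} -> {effect}")

    def summary(self) -> str:
        lines = [
            "Recursive path model (standardized estimates)",
            "-" * 56,
            f"{'path':<28}{'coef':>8}{'se':>8}{'p':>10}",
        ]
        for c in self.coefficients:
            lines.append(
                f"{c.cause + ' -> ' + c.effect:<28}{c.estimate:>8.3f}"
                f"{c.se:>8.3f}{c.p_value:>10.4f}"
            )
        lines += [
            "-" * 56,
            f"chi2 = {self.chi_square:.4f}  (df = {self.df}, p = {self.p_chi:.4f})"
            + ("  [just-identified]" if self.just_identified else ""),
            f"CFI = {self.cfi:.4f}   RMSEA = {self.rmsea:.4f}   AIC = {self.aic:.2f}",
            f"n = {self.n_samples}, free parameters = {self.n_free_params}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "coefficients": [
                {"cause": c.cause, "effect": c.effect, "estimate": c.estimate,
                 "se": c.se, "p_value": c.p_value}
                for c in self.coefficients
            ],
            "fit": {
                "chi_square": self.chi_square,
                "df": self.df,
                "p_chi": self.p_chi,
                "CFI": self.cfi,
                "RMSEA": self.rmsea,
                "AIC": self.aic,
                "just_identified": self.just_identified,
            },
            "n_samples": self.n_samples,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class PathModel:
    """Recursive path model bound to a samples x variables data frame."""

    data: pd.DataFrame
    spec: PathSpec
    _z: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = [v for v in self.spec.variables if v not in self.data.columns]
        if missing:
            raise ValueError(f"data lacks variables: {missing}")
        n, p = len(self.data), len(self.spec.variables)
        if n <= p:
            raise ValueError("need more samples than variables")
        sub = self.data[self.spec.variables].astype(float)
        sd = sub.std(ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant variables: {list(sd.index[sd == 0])}")
        self._z = (sub - sub.mean()) / sd

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, edges: list[str]) -> "PathModel":
        return cls(data, PathSpec.from_strings(edges))

    def fit(self) -> PathModelResults:
        z = self._z
        n = len(z)
        names = self.spec.variables
        p = len(names)
        idx = {v: i for i, v in enumerate(names)}
        s_mat = np.cov(z.to_numpy(), rowvar=False, ddof=1)
        s_mat = np.atleast_2d(s_mat)

        # per-equation OLS on standardized data
        b_mat = np.zeros((p, p))  # b[effect, cause]
        psi = np.zeros(p)  # residual variances of endogenous vars
        coefs: list[PathCoefficient] = []
        exact_fit = False
        for effect in self.spec.endogenous:
            parents = self.spec.parents(effect)
            x = z[parents].to_numpy()
            y = z[effect].to_numpy()
            k = len(parents)
            xtx = x.T @ x
            beta = np.linalg.solve(xtx, x.T @ y)
            resid = y - x @ beta
            dof = n - k - 1
            sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
            if sigma2 <= np.finfo(float).eps * 100:
                exact_fit = True
                se = np.zeros(k)
            else:
                se = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx)))
            for j, cause in enumerate(parents):
                if exact_fit and se[j] == 0:
                    pv = 0.0 if abs(beta[j]) > 0 else 1.0
                else:
                    t = beta[j] / se[j]
                    pv = 2 * stats.t.sf(abs(t), dof)
                coefs.append(
                    PathCoefficient(cause, effect, float(beta[j]), float(se[j]), float(pv))
                )
                b_mat[idx[effect], idx[cause]] = beta[j]
            psi[idx[effect]] = float(resid @ resid) / (n - 1)

        # model-implied covariance: Sigma = (I-B)^-1 Psi (I-B)^-T, where Psi
        # carries residual variances for endogenous vars and the sample
        # covariances among exogenous vars
        exo = [idx[v] for v in self.spec.exogenous]
        psi_mat = np.diag(psi)
        for i in exo:
            for j in exo:
                psi_mat[i, j] = s_mat[i, j]
        inv_imb = np.linalg.inv(np.eye(p) - b_mat)
        sigma = inv_imb @ psi_mat @ inv_imb.T

        n_edges = len(self.spec.edges)
        n_exo = len(exo)
        n_endo = p - n_exo
        # free params: path coefficients + endogenous residual variances +
        # exogenous (co)variances
        q = n_edges + n_endo + n_exo * (n_exo + 1) // 2
        n_moments = p * (p + 1) // 2
        df = n_moments - q

        if df > 0:
            sign_s, logdet_s = np.linalg.slogdet(s_mat)
            sign_m, logdet_m = np.linalg.slogdet(sigma)
            if sign_s <= 0 or sign_m <= 0:
                raise ValueError("singular sample or implied covariance matrix")
            f_ml = logdet_m + float(np.trace(s_mat @ np.linalg.inv(sigma))) - logdet_s - p
            f_ml = max(f_ml, 0.0)
            chi2 = (n - 1) * f_ml
            p_chi = float(stats.chi2.sf(chi2, df))
            rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
            # independence baseline: all variables uncorrelated
            diag = np.diag(np.diag(s_mat))
            _, logdet_d = np.linalg.slogdet(diag)
            f_base = (
                logdet_d + float(np.trace(s_mat @ np.linalg.inv(diag))) - logdet_s - p
            )
            chi2_base = (n - 1) * max(f_base, 0.0)
            df_base = p * (p - 1) // 2
            num = max(chi2 - df, 0.0)
            den = max(chi2_base - df_base, num, np.finfo(float).eps)
            cfi = float(1.0 - num / den)
        else:
            # saturated / just-identified: implied moments reproduce S exactly
            chi2, p_chi, rmsea, cfi = 0.0, 1.0, 0.0, 1.0

        aic = float(chi2 + 2 * q)
        return PathModelResults(
            coefficients=coefs,
            chi_square=float(chi2),
            df=int(df),
            p_chi=p_chi,
            cfi=cfi,
            rmsea=rmsea,
            aic=aic,
            n_samples=n,
            n_free_params=q,
            just_identified=(df == 0),
            spec=self.spec,
        )


def fit_path_model(data: pd.DataFrame, spec: PathSpec) -> PathModelResults:
    """Fit a recursive path model; convenience wrapper around PathModel."""
    return PathModel(data, spec).fit()


def compare_models(results: list[PathModelResults]) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending) with delta-AIC."""
    if len(results) < 2:
        raise ValueError("need at least 2 fitted models to compare")
    ns = {r.n_samples for r in results}
    if len(ns) > 1:
        raise ValueError("models fitted on different sample sizes are not comparable")
    rows = [
        {"model": i, "AIC": r.aic, "chi_square": r.chi_square, "df": r.df,
         "CFI": r.cfi, "RMSEA": r.rmsea}
        for i, r in enumerate(results)
    ]
    df = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    df["delta_AIC"] = df["AIC"] - df["AIC"].iloc[0]
    return df


def composite_pc1(matrix, method: str = "pca", variables: list[str] | None = None):
    """First-axis score vector for a composite variable.

    ``method="pca"``: first principal component of the z-scored columns,
    sign-oriented so the first column's loading is positive.
    ``method="pcoa-on-bray"``: first principal coordinate of the Bray-Curtis
    matrix of an abundance (sub)matrix; `matrix` may be an AbundanceTable.
    """
    if method == "pca":
        if isinstance(matrix, pd.DataFrame):
            cols = variables if variables is not None else list(matrix.columns)
            x = matrix[cols].to_numpy(dtype=float)
        else:
            x = np.asarray(matrix, dtype=float)
        if x.ndim != 2 or x.shape[1] < 2:
            raise ValueError("PCA composite needs >= 2 variables")
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant variable in composite block")
        zx = (x - x.mean(axis=0)) / sd
        u, s, vt = np.linalg.svd(zx, full_matrices=False)
        scores = u[:, 0] * s[0]
        if vt[0, 0] < 0:  # orient: first declared variable loads positively
            scores = -scores
        return scores
    if method == "pcoa-on-bray":
        if isinstance(matrix, AbundanceTable):
            table = matrix
        else:
            raise ValueError("pcoa-on-bray requires an AbundanceTable")
        ord_res = pcoa(bray_curtis(table), n_axes=1)
        return ord_res.coordinates[:, 0]
    raise ValueError(f"unknown composite method {method!r}")
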