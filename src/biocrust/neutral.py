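"""Sloan neutral community model: fit, partition, bootstrap.

The model predicts an ASV's detection frequency across samples from its
mean relative abundance under purely neutral dispersal. With metacommunity
relative abundance p, local community size N (reads per sample after
rarefaction) and migration probability m, the stationary distribution of
local relative abundance is Beta(N*m*p, N*m*(1-p)); an ASV is detected when
its local abundance exceeds the detection limit d = 1/N, so

    f_hat(p) = 1 - I_d(N*m*p, N*m*(1-p))

with I the regularized incomplete beta function. m is estimated by bounded
nonlinear least squares of observed frequencies on f_hat; R^2 measures how
much of the frequency-abundance relationship neutrality explains. ASVs are
partitioned as above / neutral / below the 95% band around the prediction
(Wilson score interval with n = number of samples).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .abundance import AbundanceTable

__all__ = [
    "NeutralCommunityModel",
    "NCMResults",
    "occurrence_frequency",
    "ncm_predict",
    "fit_ncm",
    "ncm_report",
]


def occurrence_frequency(table: AbundanceTable) -> pd.DataFrame:
    """Per-ASV mean relative abundance p and detection fraction f.

    ASVs absent from every sample are dropped. Returns a DataFrame indexed
    by asv_id with columns ``p`` and ``f``.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rel = table.relative_abundance()
    p = rel.mean(axis=0)
    f = (table.counts > 0).mean(axis=0)
    keep = p > 0
    return pd.DataFrame(
        {"p": p[keep], "f": f[keep]},
        index=[a for a, k in zip(table.asv_ids, keep) if k],
    )


def ncm_predict(p, Nm: float, d: float) -> np.ndarray:
    """Predicted detection frequency 1 - BetaCDF(d; Nm*p, Nm*(1-p))."""
    p = np.asarray(p, dtype=float)
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not (0 < d < 1):
        raise ValueError("detection limit must lie in (0, 1)")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("relative abundances must lie in (0, 1)")
    a = Nm * p
    b = Nm * (1.0 - p)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite beta parameters")
    return 1.0 - special.betainc(a, b, d)


def _wilson_band(f_hat: np.ndarray, n: int, z: float = 1.959963984540054):
    """Wilson score 95% interval around predicted frequencies, n trials."""
    denom = 1.0 + z**2 / n
    centre = (f_hat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(f_hat * (1 - f_hat) / n + z**2 / (4 * n**2))
    lo = np.clip(centre - half, 0, 1)
    hi = np.clip(centre + half, 0, 1)
    # the Wilson interval always contains the point estimate; enforce it
    # against floating-point round-off at the extremes
    return np.minimum(lo, f_hat), np.maximum(hi, f_hat)


def _fit_m(p: np.ndarray, f: np.ndarray, N: float, d: float, starts=(0.01, 0.1, 0.5)):
    """Bounded least-squares estimate of migration probability m."""

    def sse(log_m: float) -> float:
        m = np.exp(log_m)
        resid = f - ncm_predict(p, N * m, d)
        return float((resid**2).sum())

    best = optimize.minimize_scalar(
        sse,
        bounds=(np.log(1e-6), np.log(1.0 - 1e-12)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    # the bounded search takes no start point; probe each start and refine
    # locally if it beats the global search (guards against local minima)
    for m0 in starts:
        if sse(np.log(m0)) < best.fun:
            refined = optimize.minimize_scalar(
                sse,
                bounds=(max(np.log(1e-6), np.log(m0) - 2),
                        min(np.log(1.0 - 1e-12), np.log(m0) + 2)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if refined.fun < best.fun:
                best = refined
    if not np.isfinite(best.fun):
        raise RuntimeError(
            f"NCM optimisation failed (last objective {best.fun})"
        )
    return float(np.exp(best.x)), float(best.fun)


@dataclass
class NCMResults:
    """Fitted neutral-model parameters, uncertainty and ASV partition."""

    m: float
    Nm: float
    N: float
    R2: float
    detection_limit: float
    m_ci: tuple[float, float]
    Nm_ci: tuple[float, float]
    R2_ci: tuple[float, float]
    n_boot: int
    seed: int | None
    partition: pd.DataFrame  # asv_id index; p, f, f_hat, band_low, band_high, label
    group: str | None = None

    @property
    def partition_counts(self) -> dict[str, int]:
        counts = self.partition["label"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("above", "neutral", "below")}

    def summary(self) -> str:
        pc = self.partition_counts
        lines = [
            "Sloan neutral community model fit"
            + (f" (group {self.group})" if self.group else ""),
            "-" * 46,
            f"  m (migration probability) : {self.m:.6g}",
            f"  Nm                         : {self.Nm:.6g}  "
            f"[95% CI {self.Nm_ci[0]:.6g}, {self.Nm_ci[1]:.6g}]",
            f"  R^2                        : {self.R2:.4f}  "
            f"[95% CI {self.R2_ci[0]:.4f}, {self.R2_ci[1]:.4f}]",
            f"  N (mean sample depth)      : {self.N:.6g}",
            f"  detection limit d = 1/N    : {self.detection_limit:.3g}",
            f"  ASVs fitted                : {len(self.partition)}",
            f"  partition above/neutral/below : "
            f"{pc['above']}/{pc['neutral']}/{pc['below']}",
            f"  bootstrap replicates       : {self.n_boot}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "m": self.m,
            "Nm": self.Nm,
            "N": self.N,
            "R2": self.R2,
            "detection_limit": self.detection_limit,
            "m_ci": list(self.m_ci),
            "Nm_ci": list(self.Nm_ci),
            "R2_ci": list(self.R2_ci),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "partition_counts": self.partition_counts,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_partition_tsv(self, path) -> None:
        self.partition.to_csv(path, sep="\t", index_label="asv_id")

    def plot(self, ax=None):
        """Frequency vs abundance scatter with the fitted curve and band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        part = self.partition.sort_values("p")
        colors = {"above": "tab:red", "neutral": "0.2", "below": "tab:green"}
        for label, sub in part.groupby("label"):
            ax.scatter(np.log10(sub["p"]), sub["f"], s=8, alpha=0.6,
                       color=colors.get(label, "0.5"), label=label)
        ax.plot(np.log10(part["p"]), part["f_hat"], color="tab:blue", lw=1.5)
        ax.plot(np.log10(part["p"]), part["band_low"], "--", color="tab:blue", lw=1)
        ax.plot(np.log10(part["p"]), part["band_high"], "--", color="tab:blue", lw=1)
        ax.set_xlabel("log10 mean relative abundance")
        ax.set_ylabel("occurrence frequency")
        ax.set_title(f"NCM fit: Nm={self.Nm:.3g}, R²={self.R2:.3f}")
        ax.legend(frameon=False, fontsize=8)
        return ax


@dataclass
class NeutralCommunityModel:
    """Sloan neutral model bound to an abundance table.

    ``fit()`` returns :class:`NCMResults`. The table should already be
    rarefied so that N (mean sample depth) is constant across samples.
    """

    table: AbundanceTable
    group: str | None = None
    _freq: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._freq = occurrence_frequency(self.table)
        informative = ((self._freq["f"] > 0) & (self._freq["f"] < 1)).sum()
        if informative < 10:
            warnings.warn(
                f"only {informative} ASVs with 0 < f < 1; the fit may be unstable",
                stacklevel=2,
            )
        if (self._freq["f"] == 1).all():
            raise ValueError("every ASV is detected in every sample; m unidentifiable")

    def fit(self, n_boot: int = 1000, seed: int | None = None) -> NCMResults:
        freq = self._freq
        p = freq["p"].to_numpy()
        f = freq["f"].to_numpy()
        N = float(self.table.sample_sums().mean())
        d = 1.0 / N
        n_samples = self.table.n_samples

        m_hat, sse = _fit_m(p, f, N, d)
        sst = float(((f - f.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else float("nan")

        f_hat = ncm_predict(p, N * m_hat, d)
        lo, hi = _wilson_band(f_hat, n_samples)
        label = np.where(f > hi, "above", np.where(f < lo, "below", "neutral"))
        partition = pd.DataFrame(
            {"p": p, "f": f, "f_hat": f_hat, "band_low": lo, "band_high": hi,
             "label": label},
            index=freq.index,
        )

        # bootstrap over ASVs; refit from the full-data optimum
        rng = np.random.default_rng(seed)
        ms, r2s = [], []
        n_asv = len(p)
        for _ in range(n_boot):
            idx = rng.integers(0, n_asv, n_asv)
            pb, fb = p[idx], f[idx]
            try:
                mb, sseb = _fit_m(pb, fb, N, d, starts=(m_hat,))
            except RuntimeError:
                continue
            sstb = float(((fb - fb.mean()) ** 2).sum())
            ms.append(mb)
            r2s.append(1.0 - sseb / sstb if sstb > 0 else np.nan)
        if ms:
            m_ci = tuple(np.percentile(ms, [2.5, 97.5]))
            r2_ci = tuple(np.nanpercentile(r2s, [2.5, 97.5]))
        else:
            m_ci = (float("nan"), float("nan"))
            r2_ci = (float("nan"), float("nan"))

        return NCMResults(
            m=m_hat,
            Nm=N * m_hat,
            N=N,
            R2=r2,
            detection_limit=d,
            m_ci=(float(m_ci[0]), float(m_ci[1])),
            Nm_ci=(float(N * m_ci[0]), float(N * m_ci[1])),
            R2_ci=(float(r2_ci[0]), float(r2_ci[1])),
            n_boot=n_boot,
            seed=seed,
            partition=partition,
            group=self.group,
        )


def fit_ncm(
    table: AbundanceTable,
    n_boot: int = 1000,
    seed: int | None = None,
    group: str | None = None,
) -> NCMResults:
    """Convenience wrapper: build the model and fit in one call."""
    return NeutralCommunityModel(table, group=group).fit(n_boot=n_boot, seed=seed)


def ncm_report(fits: dict[str, NCMResults], sort_by: str = "R2") -> pd.DataFrame:
    """Comparison table across groups, sortable by R^2 (descending).

    Descending R^2 orders groups from most stochastic (dispersal-dominated)
    to most deterministic community assembly.
    """
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for group, res in fits.items():
        pc = res.partition_counts
        rows.append(
            {
                "group": group,
                "m": res.m,
                "Nm": res.Nm,
                "R2": res.R2,
                "Nm_ci_low": res.Nm_ci[0],
                "Nm_ci_high": res.Nm_ci[1],
                "n_above": pc["above"],
                "n_neutral": pc["neutral"],
                "n_below": pc["below"],
            }
        )
    df = pd.DataFrame(rows)
    if sort_by:
        df = df.sort_values(sort_by, ascending=False).reset_index(drop=True)
    return df
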