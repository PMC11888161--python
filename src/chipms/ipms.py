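"""Label-free IP-MS differential statistics.

The stage takes an already-quantified protein x sample matrix of log2
intensities (iBAQ-style quantification and protein inference are upstream)
and applies:

1. down-shifted Gaussian imputation of missing values — each missing cell
   is replaced by a draw from Normal(mu - shift*sigma, (width*sigma)^2)
   where mu, sigma are the mean and sd of the observed values in the
   imputation scope (per sample column by default). Defaults shift=1.8,
   width=0.8 model limit-of-detection (MNAR) missingness;
2. a two-group test on log2 intensities — ordinary pooled-variance t, or a
   moderated t in which each protein's variance is shrunk toward an
   empirical-Bayes prior fitted across proteins;
3. Benjamini-Hochberg adjustment; and
4. threshold filtering (default log2FC > 2 and raw p < 0.05, both strict).

The moderated test replaces the per-protein pooled variance s^2 (d degrees
of freedom) by the posterior (d*s^2 + d0*s0^2) / (d + d0) and refers
t = log2FC / (s_post * sqrt(1/n1 + 1/n2)) to a t distribution with d + d0
degrees of freedom. The prior (s0^2, d0) is fitted by method of moments on
the marginal scaled-F distribution of the observed s^2 (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "IntensityMatrix",
    "ImputationParams",
    "read_intensity_tsv",
    "read_group_map",
    "impute_missing",
    "fit_variance_prior",
    "differential_test",
    "bh_adjust",
    "filter_hits",
    "write_differential_table",
]

DEFAULT_FC_THRESHOLD = 2.0  # log2 scale
DEFAULT_P_THRESHOLD = 0.05

GROUPS = ("treatment", "control")


@dataclass
class IntensityMatrix:
    """Protein x sample log2 intensities with a missingness mask.

    ``values`` is a proteins x samples DataFrame (NaN where missing);
    ``groups`` maps each sample name to "treatment" or "control";
    ``missing_mask`` records which cells were missing on input and is kept
    as provenance through imputation.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    missing_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        unknown = set(self.groups.values()) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group label(s) {sorted(unknown)}; expected {GROUPS}")
        missing_samples = [s for s in self.values.columns if s not in self.groups]
        if missing_samples:
            raise ValueError(f"samples without a group label: {missing_samples}")
        if self.missing_mask is None:
            self.missing_mask = self.values.isna()

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def require_group_sizes(self, minimum: int = 2) -> None:
        for g in GROUPS:
            n = len(self.samples_in(g))
            if n < minimum:
                raise ValueError(f"group {g!r} has {n} sample(s); >= {minimum} required")


@dataclass(frozen=True)
class ImputationParams:
    """Down-shifted Gaussian imputation settings (shift/width in sigma units)."""

    shift: float = 1.8
    width: float = 0.8
    scope: str = "per_sample"  # or "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("imputation width must be > 0")
        if self.scope not in ("per_sample", "global"):
            raise ValueError(f"unknown imputation scope {self.scope!r}")


def read_intensity_tsv(path: str | Path, groups: dict[str, str]) -> IntensityMatrix:
    """Read a TSV matrix: first column protein ID, blank cells = missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return IntensityMatrix(values=df.astype(float), groups=groups)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> group TSV (no header required)."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample, group)")
    if set(raw.iloc[0, :2]) == {"sample", "group"}:
        raw = raw.iloc[1:]
    return dict(zip(raw.iloc[:, 0].astype(str), raw.iloc[:, 1].astype(str)))


def impute_missing(m: IntensityMatrix, params: ImputationParams) -> IntensityMatrix:
    """Replace missing cells with down-shifted Gaussian draws.

    Every missing cell becomes an independent draw from
    Normal(mu - shift*sigma, (width*sigma)^2), with mu/sigma the observed
    mean and sd of the scope (each sample column, or the whole matrix).
    Observed cells are untouched; the original missing mask is retained.
    """
    values = m.values.copy()
    mask = m.values.isna()
    rng = np.random.default_rng(params.seed)
    if params.scope == "global":
        scopes = [(None, values.to_numpy().ravel(), mask.to_numpy().ravel())]
    else:
        scopes = [(col, values[col].to_numpy(), mask[col].to_numpy()) for col in values.columns]
    for name, vec, miss in scopes:
        observed = vec[~miss]
        if miss.any():
            if observed.size < 2:
                scope_name = "global" if name is None else f"sample {name!r}"
                raise ValueError(f"imputation scope {scope_name} has {observed.size} observed value(s); >= 2 required")
            mu = float(observed.mean())
            sigma = float(observed.std(ddof=1))
            draws = rng.normal(mu - params.shift * sigma, params.width * sigma, size=int(miss.sum()))
            vec[miss] = draws
        if name is None:
            values.iloc[:, :] = vec.reshape(values.shape)
        else:
            values[name] = vec
    return IntensityMatrix(values=values, groups=dict(m.groups), missing_mask=m.values.isna())


def fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (s0^2, d0).

    Under the hierarchical model s^2 | sigma^2 ~ sigma^2 chi^2_d / d with a
    scaled inverse-chi-square prior on sigma^2, the marginal of s^2 is
    s0^2 * F(d, d0), whose squared coefficient of variation is
    CV^2 = 2 (d + d0 - 2) / (d (d0 - 4)). Matching the sample CV^2 of the
    observed per-protein variances gives d0; s0^2 follows from the mean.
    When the observed variances are no more dispersed than chi-square
    sampling alone allows, d0 is infinite: complete shrinkage to the common
    variance (returned as d0 = inf).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size < 2:
        raise ValueError("need >= 2 finite per-protein variances to fit a prior")
    m = float(s2.mean())
    if m <= 0:
        # all-zero variances: no dispersion information at all
        return 0.0, np.inf
    cv2 = float(s2.var(ddof=1)) / (m * m)
    denom = cv2 * d - 2.0
    if denom <= 0:
        return m, np.inf
    d0 = (2.0 * d + 4.0 * cv2 * d - 4.0) / denom
    if d0 <= 4.0:
        # moment solution outside its validity region; fall back to a heavy
        # tail just above the variance-existence boundary
        d0 = 4.0 + 1e-6
    s0_2 = m * (d0 - 2.0) / d0
    return s0_2, d0


def differential_test(m: IntensityMatrix, moderation: str = "moderated") -> pd.DataFrame:
    """Two-group differential test on a complete log2 intensity matrix.

    Returns a DataFrame indexed by protein with columns log2FC (treatment
    minus control mean), t, df, p (two-sided), and zero_variance. Run
    ``impute_missing`` first or supply complete data. p-values are not yet
    adjusted; see ``bh_adjust`` / ``filter_hits``.
    """
    if moderation not in ("moderated", "ordinary"):
        raise ValueError(f"moderation must be 'moderated' or 'ordinary', got {moderation!r}")
    m.require_group_sizes(2)
    if m.values.isna().to_numpy().any():
        raise ValueError("matrix contains missing values; run impute_missing first")
    t_cols = m.samples_in("treatment")
    c_cols = m.samples_in("control")
    x = m.values[t_cols].to_numpy(dtype=float)
    y = m.values[c_cols].to_numpy(dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    d = n1 + n2 - 2
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    s2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / d

    if moderation == "moderated":
        s0_2, d0 = fit_variance_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df_eff = np.inf
        else:
            s2_post = (d * s2 + d0 * s0_2) / (d + d0)
            df_eff = d + d0
    else:
        s2_post = s2
        df_eff = float(d)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    zero_var = se == 0.0
    t_stat = np.zeros_like(log2fc)
    np.divide(log2fc, se, out=t_stat, where=~zero_var)
    if np.isinf(df_eff):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_eff)
    p = np.minimum(p, 1.0)
    p[zero_var] = 1.0
    t_stat[zero_var] = 0.0
    if zero_var.any():
        log.warning("%d protein(s) with zero variance in both groups: t=0, p=1", int(zero_var.sum()))
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "t": t_stat,
            "df": np.inf if np.isinf(df_eff) else float(df_eff),
            "p": p,
            "zero_variance": zero_var,
        },
        index=m.values.index.rename("protein"),
    )


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_(j) >= p_(i) of p_(j) * n / rank(j), capped at 1;
    input order is preserved in the output.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def filter_hits(
    table: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Mark hits: log2FC strictly above and raw p strictly below threshold.

    Adds/overwrites ``q`` (BH-adjusted p, reported alongside) and ``hit``.
    Rows are retained — filtering marks, it does not delete.
    """
    if not (np.isfinite(fc_threshold) and np.isfinite(p_threshold)):
        raise ValueError("thresholds must be finite")
    out = table.copy()
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["hit"] = (out["log2FC"] > fc_threshold) & (out["p"] < p_threshold)
    else:
        out["q"] = pd.Series(dtype=float)
        out["hit"] = pd.Series(dtype=bool)
    return out


def write_differential_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write protein, log2FC, t, p, q, hit as TSV (fixed numeric formatting)."""
    cols = ["log2FC", "t", "p", "q", "hit"]
    out = table[cols].copy()
    with open(path, "w") as fh:
        fh.write("protein\tlog2FC\tt\tp\tq\thit\n")
        for protein, row in out.iterrows():
            fh.write(
                f"{protein}\t{row['log2FC']:.4f}\t{row['t']:.4f}\t{row['p']:.6g}\t"
                f"{row['q']:.6g}\t{str(bool(row['hit'])).lower()}\n"
            )
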