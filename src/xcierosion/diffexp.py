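"""Two-group differential expression between Low- and High-XIST strata.

The fold change is the difference of group means of log2 values (for a
two-group design this is exactly the linear-model coefficient).  Two tests
are available:

* ``moderated_t`` (default): empirical-Bayes variance moderation.  Per-gene
  pooled variances s_g^2 with d_g residual df are shrunk toward a prior
  s_0^2 with d_0 prior df; (d_0, s_0^2) are estimated by moment matching on
  the log variances (using digamma/trigamma identities of the scaled-F
  distribution of s_g^2), and the moderated t uses the posterior variance
  (d_0 s_0^2 + d_g s_g^2)/(d_0 + d_g) with d_0 + d_g degrees of freedom.
* ``welch``: Welch's unequal-variance t per gene.

Multiple testing uses Storey q-values by default (pi0 estimated by a cubic
smoother over a lambda grid), with Benjamini-Hochberg (pi0 = 1) as the
fallback.  Genes with fewer than ``min_obs_per_group`` non-missing values
in either group are emitted with missing statistics and excluded from FDR.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .proteomics_quant import welch_t


@dataclass
class DEConfig:
    test: str = "moderated_t"
    q_threshold: float = 0.05
    min_obs_per_group: int = 3
    fdr_method: str = "storey"
    log2_pseudocount: float = 0.01  # for TPM layers only

    def __post_init__(self):
        if self.test not in ("moderated_t", "welch"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.fdr_method not in ("storey", "bh"):
            raise ValueError(f"unknown fdr_method {self.fdr_method!r}")
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.min_obs_per_group < 2:
            raise ValueError("min_obs_per_group must be >= 2")


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate the prior df d0 and prior variance s0^2 from per-gene
    sample variances by moment matching on log variances.

    Returns (d0, s0_squared); d0 may be ``inf`` (complete shrinkage) when
    the observed spread of log variances is no wider than sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    resid = e_var - np.mean(special.polygamma(1, d / 2.0))
    if resid > 0:
        d0 = 2.0 * _trigamma_inverse(resid)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return float(d0), float(s0_sq)


def moderated_t_table(
    a: np.ndarray, b: np.ndarray, prior_df: float | None = None
) -> pd.DataFrame:
    """Moderated t over genes: ``a`` and ``b`` are gene x sample arrays of
    log2 values (NaN = missing).  ``prior_df`` overrides the estimated d0
    (0 recovers the ordinary pooled-variance t).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.isfinite(a).sum(axis=1)
    nb = np.isfinite(b).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)
    df = na + nb - 2.0
    pooled = np.where(
        df > 0,
        ((na - 1) * np.nan_to_num(var_a) + (nb - 1) * np.nan_to_num(var_b)) / np.maximum(df, 1),
        np.nan,
    )
    if prior_df is None:
        d0, s0_sq = squeeze_variances(pooled, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = squeeze_variances(pooled, df)
    if np.isinf(d0):
        post = np.full_like(pooled, s0_sq)
        total_df = np.full_like(pooled, np.inf)
    else:
        post = (d0 * s0_sq + df * pooled) / (d0 + df)
        total_df = d0 + df
    se = np.sqrt(post * (1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nb, 1)))
    t = (mean_a - mean_b) / se
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return pd.DataFrame(
        {
            "log2_fc": mean_a - mean_b,
            "t_stat": t,
            "df": total_df,
            "p_value": p,
            "n_a": na,
            "n_b": nb,
            "prior_df": d0,
            "prior_var": s0_sq,
        }
    )


# ---------------------------------------------------------------------------
# FDR


def qvalues(p_values, method: str = "storey") -> np.ndarray:
    """q-values from p-values.

    ``storey``: pi0 estimated by a cubic polynomial smoother of
    pi0(lambda) over lambda in {0.05, 0.10, ..., 0.95}, evaluated at the
    largest lambda and clipped to (0, 1].  ``bh``: pi0 = 1 (step-up).
    Then q_(i) = min_{j >= i} pi0 * m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
        if m < 100:
            # too few tests for a stable smoother; conservative choice
            pi0 = 1.0
        else:
            coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
            pi0 = float(np.polyval(coeffs, lambdas.max()))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m * pi0 / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# driver


def run_de(
    matrix: pd.DataFrame,
    group_low: list[str],
    group_high: list[str],
    config: DEConfig | None = None,
    layer: str | None = None,
) -> pd.DataFrame:
    """Per-gene Low-vs-High differential expression on one layer.

    ``log2_fc`` is mean(log2 Low) - mean(log2 High); TPM layers are
    transformed as log2(x + pseudocount), copy-number layers as log2(x)
    with non-positive values treated as missing.
    """
    config = config or DEConfig()
    layer = layer or matrix.attrs.get("layer", "rna_tpm")
    missing = [l for l in list(group_low) + list(group_high) if l not in matrix.columns]
    if missing:
        raise ValueError(f"line(s) absent from matrix: {missing}")
    values = matrix[list(group_low) + list(group_high)].to_numpy(dtype=float)
    if layer == "rna_tpm":
        logged = np.log2(values + config.log2_pseudocount)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = np.where(values > 0, np.log2(np.maximum(values, 1e-300)), np.nan)
    a = logged[:, : len(group_low)]
    b = logged[:, len(group_low):]

    if config.test == "moderated_t":
        table = moderated_t_table(a, b)
    else:
        rows = []
        for i in range(a.shape[0]):
            ai = a[i][np.isfinite(a[i])]
            bi = b[i][np.isfinite(b[i])]
            if len(ai) >= 2 and len(bi) >= 2:
                t, df, p = welch_t(ai, bi)
                fc = ai.mean() - bi.mean()
            else:
                t = df = p = fc = np.nan
            rows.append({"log2_fc": fc, "t_stat": t, "df": df, "p_value": p,
                         "n_a": len(ai), "n_b": len(bi)})
        table = pd.DataFrame(rows)

    table.index = matrix.index
    table = table.rename(columns={"n_a": "n_low", "n_b": "n_high"})
    eligible = (table["n_low"] >= config.min_obs_per_group) & (
        table["n_high"] >= config.min_obs_per_group
    ) & np.isfinite(table["p_value"])
    table.loc[~eligible, ["log2_fc", "t_stat", "df", "p_value"]] = np.nan
    table["q_value"] = np.nan
    if eligible.any():
        table.loc[eligible, "q_value"] = qvalues(
            table.loc[eligible, "p_value"].to_numpy(), method=config.fdr_method
        )
    direction = np.where(
        (table["q_value"] <= config.q_threshold) & (table["log2_fc"] > 0),
        "up",
        np.where(
            (table["q_value"] <= config.q_threshold) & (table["log2_fc"] < 0), "down", "ns"
        ),
    )
    table["direction"] = direction
    table["layer"] = "rna" if layer == "rna_tpm" else "protein"
    return table
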