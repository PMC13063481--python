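"""Lightweight negative-binomial differential expression across stage
transitions.

This stage is a deliberately simplified stand-in for full GLM-based count
packages: TMM-style normalization, a method-of-moments common dispersion
with configurable shrinkage, and an exact-style conditional NB test on
summed pseudo-counts.  Directional agreement on synthetic truth -- not
numerical parity with any external package -- is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests


@dataclass
class CountMatrix:
    """Feature x sample counts with a sample -> stage design map."""

    counts: pd.DataFrame
    sample_stage: Mapping[str, str]
    level: str = "cluster"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative entries in count matrix")
        missing = [s for s in self.counts.columns if s not in self.sample_stage]
        if missing:
            raise ValueError(f"samples without a stage: {missing}")

    def samples_for(self, stage: str) -> list:
        return [s for s in self.counts.columns if self.sample_stage[s] == stage]


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample scaling factors: library size x trimmed-mean-of-M-values
    composition factor, anchored so the factors multiply to 1.

    Features with a zero in either the sample or the reference are excluded
    from trimming; M-values are double-trimmed (30% on M, 5% on A by
    default) and combined with inverse delta-method weights.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = [c for c, n in zip(counts.columns, lib) if n == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    # reference: sample whose upper quartile of scaled counts is most typical
    uq = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    tmm = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        keep = (y[:, j] > 0) & (y[:, ref] > 0)
        if not keep.any():
            continue
        yj, yr = y[keep, j], y[keep, ref]
        m = np.log2((yj / lib[j]) / (yr / lib[ref]))
        a = 0.5 * np.log2((yj / lib[j]) * (yr / lib[ref]))
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not sel.any():
            sel = np.ones_like(m, dtype=bool)
        w = (lib[j] - yj[sel]) / (lib[j] * yj[sel]) + (lib[ref] - yr[sel]) / (
            lib[ref] * yr[sel]
        )
        inv = np.zeros_like(w)
        nz = w > 0
        inv[nz] = 1.0 / w[nz]
        w = inv
        tmm[j] = 2 ** (np.sum(w * m[sel]) / np.sum(w)) if w.sum() > 0 else 1.0
    eff = lib * tmm
    factors = eff / np.exp(np.mean(np.log(eff)))
    return pd.Series(factors, index=counts.columns, name="factor")


@dataclass(frozen=True)
class DEResult:
    feature: str
    contrast: str
    logFC: float
    p: float
    p_adj: float
    call: int


def _nb_logpmf(k: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    if dispersion < 1e-10:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / dispersion
    return stats.nbinom.logpmf(k, r, r / (r + mean))


def _exact_nb_p(sa: int, sb: int, n_a: int, n_b: int, dispersion: float) -> float:
    """Two-sided conditional test of group sums: P over the conditional
    distribution of (SA | SA + SB) of outcomes no more probable than the
    observed one.  Group sums of n iid NB(mu, phi) are NB(n mu, phi / n)."""
    total = sa + sb
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    a = np.arange(total + 1)
    logp = _nb_logpmf(a, n_a * mu, dispersion / n_a) + _nb_logpmf(
        total - a, n_b * mu, dispersion / n_b
    )
    norm = logsumexp(logp)
    extreme = logp <= logp[sa] + 1e-10
    return float(np.exp(logsumexp(logp[extreme]) - norm))


def _dispersions(z: np.ndarray, groups: Sequence[np.ndarray], shrink: float) -> np.ndarray:
    """Method-of-moments per-feature dispersion shrunk toward the common
    (median) value.  ``z`` is the normalized count matrix."""
    per_feature = np.full(z.shape[0], np.nan)
    for i in range(z.shape[0]):
        ests = []
        for idx in groups:
            g = z[i, idx]
            m = g.mean()
            if m > 0 and len(g) > 1:
                ests.append(max((g.var(ddof=1) - m) / m**2, 0.0))
        if ests:
            per_feature[i] = float(np.mean(ests))
    common = float(np.nanmedian(per_feature)) if np.isfinite(per_feature).any() else 0.0
    per_feature = np.where(np.isnan(per_feature), common, per_feature)
    return shrink * common + (1 - shrink) * per_feature


def nb_test(
    m: CountMatrix,
    contrast: tuple,
    alpha: float = 0.05,
    shrink_weight: float = 0.7,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Differential expression for one stage contrast (stageA -> stageB).

    Per feature: counts are scaled by TMM-anchored effective factors, summed
    within groups, and compared with an exact-style conditional NB test;
    log2 fold changes (B relative to A) use a 0.5 prior count; p-values are
    Holm-adjusted across the features of this contrast and calls are the
    logFC sign where p_adj <= alpha, else 0.
    """
    stage_a, stage_b = contrast
    samples_a = m.samples_for(stage_a)
    samples_b = m.samples_for(stage_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(f"contrast {stage_a}->{stage_b}: need >= 2 samples per stage")
    cols = samples_a + samples_b
    sub = m.counts[cols]
    factors = tmm_factors(sub)
    z = sub.to_numpy(dtype=float) / factors.to_numpy()
    idx_a = np.arange(len(samples_a))
    idx_b = np.arange(len(samples_a), len(cols))
    disp = _dispersions(z, [idx_a, idx_b], shrink_weight)

    sa = np.rint(z[:, idx_a].sum(axis=1)).astype(int)
    sb = np.rint(z[:, idx_b].sum(axis=1)).astype(int)
    mean_a = sa / len(samples_a)
    mean_b = sb / len(samples_b)
    logfc = np.log2(mean_b + prior_count) - np.log2(mean_a + prior_count)
    pvals = np.array(
        [
            _exact_nb_p(int(sa[i]), int(sb[i]), len(samples_a), len(samples_b), disp[i])
            for i in range(len(sub))
        ]
    )
    all_zero = (sa + sb) == 0
    pvals[all_zero] = 1.0
    logfc[all_zero] = 0.0
    p_adj = multipletests(pvals, method="holm")[1] if len(pvals) else np.array([])
    calls = np.where((p_adj <= alpha) & (logfc != 0), np.sign(logfc), 0).astype(int)
    return pd.DataFrame(
        {
            "feature": sub.index,
            "contrast": f"{stage_a}->{stage_b}",
            "logFC": logfc,
            "p": pvals,
            "p_adj": p_adj,
            "call": calls,
        }
    ).reset_index(drop=True)


def run_contrasts(
    m: CountMatrix, transitions: Sequence[tuple], alpha: float = 0.05, **kwargs
) -> pd.DataFrame:
    """Run :func:`nb_test` for an ordered list of stage transitions; Holm
    correction stays within each contrast (x level) family."""
    return pd.concat(
        [nb_test(m, t, alpha=alpha, **kwargs) for t in transitions], ignore_index=True
    )


def transition_report(
    results_by_level: Mapping[str, pd.DataFrame], transitions: Sequence[str]
) -> pd.DataFrame:
    """Proportion of up / down / unchanged features per (level, transition).

    ``results_by_level`` maps a level name to a results frame (as returned by
    :func:`run_contrasts`); ``transitions`` are contrast strings "A->B".
    Proportions sum to 1 per row; raw counts are included.
    """
    rows = []
    for level, df in results_by_level.items():
        for tr in transitions:
            sub = df[df["contrast"] == tr]
            n = len(sub)
            n_up = int((sub["call"] == 1).sum())
            n_down = int((sub["call"] == -1).sum())
            n_flat = n - n_up - n_down
            rows.append(
                {
                    "level": level,
                    "transition": tr,
                    "n": n,
                    "n_up": n_up,
                    "n_down": n_down,
                    "n_unchanged": n_flat,
                    "prop_up": n_up / n if n else 0.0,
                    "prop_down": n_down / n if n else 0.0,
                    "prop_unchanged": n_flat / n if n else 1.0,
                }
            )
    return pd.DataFrame(rows)
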