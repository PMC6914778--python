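"""Dual-reporter partitioning of cell-to-cell expression variation.

Given paired per-cell intensities of two reporters, cells are first grouped
by cell fate (experiment x intestine ring by default) and each channel is
divided by its group mean, removing the ring-specific ratiometric setpoint
(recorded as the relative gain ``A``).  On the normalized pairs the
classic dual-reporter moment estimators split CV^2 into

    uncorrelated = mean((x_i - y_i)^2) / (2 mean(x) mean(y))
    correlated   = (mean(x_i y_i) - mean(x) mean(y)) / (mean(x) mean(y))

For a Type I pair (two colors of the same gene) uncorrelated variation is
intrinsic noise eta2(gamma).  For a Type II pair (two distinct genes)
correlated variation is general expression-capacity variation eta2(G) and
uncorrelated variation minus the average Type I intrinsic noise of the two
promoters is pathway/signaling noise eta2(P).  All moments use plain means
(population convention), which makes ``correlated + uncorrelated =
(CV^2(x) + CV^2(y)) / 2`` an exact algebraic identity on mean-1 data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .synth import CHANNELS

GROUP_COLS = ("experiment_id", "ring")
MIN_GROUP_SIZE = 5
ALPHA = 0.05


# ---------------------------------------------------------------------------
# elementary statistics


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation (the paper-wide convention)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate input: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def correlated_uncorrelated(x, y) -> Tuple[float, float]:
    """One-pass dual-reporter moment estimators on paired intensities.

    Returns ``(correlated, uncorrelated)``.  Inputs are expected to be
    group-normalized (positive means); the denominators use the supplied
    values' means directly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    mx = x.mean()
    my = y.mean()
    if mx <= 0 or my <= 0:
        raise ValueError("invalid normalization: nonpositive channel mean")
    denom = mx * my
    uncorrelated = float(np.mean((x - y) ** 2) / (2.0 * denom))
    correlated = float((np.mean(x * y) - denom) / denom)
    return correlated, uncorrelated


# ---------------------------------------------------------------------------
# group normalization


@dataclass(frozen=True)
class GainFit:
    """Relative gain/setpoint between the two channels of one group."""
    group: tuple
    a_value: float          # gain of channel_b relative to channel_a
    mean_a: float
    mean_b: float
    n: int
    estimator: str = "mean_ratio"


def _tls_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Total-least-squares (major-axis) slope through the centroid."""
    xc = x - x.mean()
    yc = y - y.mean()
    cov = np.cov(np.vstack([xc, yc]), bias=True)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[0] == 0:
        raise ValueError("degenerate TLS fit: vertical major axis")
    return float(major[1] / major[0])


def normalize_by_group(cells: pd.DataFrame,
                       channels: Sequence[str] = CHANNELS,
                       group_cols: Sequence[str] = GROUP_COLS,
                       min_group_size: int = MIN_GROUP_SIZE,
                       gain_estimator: str = "mean_ratio",
                       ) -> Tuple[pd.DataFrame, List[GainFit], List[tuple]]:
    """Divide each channel by its group mean; group means become exactly 1.

    Returns ``(normalized, gains, skipped)``: the normalized table (groups
    below ``min_group_size`` or with a zero channel mean dropped), one
    :class:`GainFit` per retained group, and a log of skipped groups with
    reasons.
    """
    channels = list(channels)
    group_cols = list(group_cols)
    pieces: List[pd.DataFrame] = []
    gains: List[GainFit] = []
    skipped: List[tuple] = []
    for key, grp in cells.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        if n < min_group_size:
            skipped.append((key, f"group size {n} < {min_group_size}"))
            continue
        means = {ch: grp[ch].mean() for ch in channels}
        if any(m == 0 for m in means.values()):
            skipped.append((key, "zero group mean (division undefined)"))
            continue
        if gain_estimator == "mean_ratio":
            a_value = means[channels[1]] / means[channels[0]]
        elif gain_estimator == "tls":
            a_value = _tls_slope(grp[channels[0]].to_numpy(float),
                                 grp[channels[1]].to_numpy(float))
        else:
            raise ValueError("gain_estimator must be 'mean_ratio' or 'tls'")
        gains.append(GainFit(group=key, a_value=float(a_value),
                             mean_a=float(means[channels[0]]),
                             mean_b=float(means[channels[1]]),
                             n=n, estimator=gain_estimator))
        norm = grp.copy()
        for ch in channels:
            norm[ch] = grp[ch] / means[ch]
        pieces.append(norm)
    if pieces:
        normalized = pd.concat(pieces).sort_index()
    else:
        normalized = cells.iloc[0:0].copy()
    return normalized, gains, skipped


# ---------------------------------------------------------------------------
# decomposition results


@dataclass
class DecompositionResult:
    """Per-group variance partitions plus aggregates and replicates."""
    kind: str                      # "typeI" or "typeII"
    per_group: pd.DataFrame
    aggregate: Dict[str, float]
    per_experiment: pd.DataFrame   # unweighted group means within experiment
    gains: List[GainFit] = field(default_factory=list)
    skipped: List[tuple] = field(default_factory=list)


def _finish(kind: str, rows: List[dict], group_cols: Sequence[str],
            value_cols: Sequence[str], gains, skipped) -> DecompositionResult:
    per_group = pd.DataFrame(rows)
    if per_group.empty:
        raise ValueError("no groups met the minimum size; nothing to "
                         "decompose")
    aggregate = {c: float(per_group[c].mean()) for c in value_cols}
    aggregate["n_groups"] = int(len(per_group))
    aggregate["n_cells"] = int(per_group["n"].sum())
    if "clamped" in per_group.columns:
        aggregate["eta2_P"] = float(per_group["eta2_P"].mean())
    if "experiment_id" in per_group.columns:
        per_experiment = (per_group
                          .groupby("experiment_id", sort=True)[list(value_cols)]
                          .mean().reset_index())
    else:
        per_experiment = pd.DataFrame()
    return DecompositionResult(kind=kind, per_group=per_group,
                               aggregate=aggregate,
                               per_experiment=per_experiment,
                               gains=gains, skipped=skipped)


def decompose_type1(cells: pd.DataFrame,
                    channels: Sequence[str] = CHANNELS,
                    group_cols: Sequence[str] = GROUP_COLS,
                    min_group_size: int = MIN_GROUP_SIZE,
                    pre_normalized: bool = False) -> DecompositionResult:
    """Type I partition: uncorrelated variation is intrinsic noise.

    ``correlated`` holds the combined capacity + pathway term (G and P are
    not separable when both channels share one promoter).
    """
    if pre_normalized:
        norm, gains, skipped = cells, [], []
        grouped = norm.groupby(list(group_cols), sort=True)
    else:
        norm, gains, skipped = normalize_by_group(
            cells, channels, group_cols, min_group_size)
        grouped = norm.groupby(list(group_cols), sort=True)
    rows = []
    for key, grp in grouped:
        key = key if isinstance(key, tuple) else (key,)
        corr, uncorr = correlated_uncorrelated(grp[channels[0]],
                                               grp[channels[1]])
        row = dict(zip(group_cols, key))
        row.update(n=len(grp), correlated=corr, uncorrelated=uncorr,
                   eta2_gamma=uncorr)
        rows.append(row)
    return _finish("typeI", rows, group_cols,
                   ("eta2_gamma", "correlated", "uncorrelated"),
                   gains, skipped)


GammaLookup = Mapping[str, "float | Mapping[int, float]"]


def gamma_for(gamma_lookup: GammaLookup, promoter: str, ring=None
              ) -> Tuple[float, str]:
    """Look up a promoter's Type I intrinsic noise, ring-matched if possible.

    Falls back to the across-ring mean when the exact ring has no Type I
    estimate; the source of the value is returned alongside it.
    """
    if promoter not in gamma_lookup:
        raise KeyError(
            f"no Type I intrinsic-noise estimate for promoter {promoter!r}; "
            f"available: {sorted(gamma_lookup)}")
    entry = gamma_lookup[promoter]
    if isinstance(entry, Mapping):
        if ring is not None and ring in entry:
            return float(entry[ring]), "ring-matched"
        return float(np.mean(list(entry.values()))), "across-ring mean"
    return float(entry), "scalar"


def decompose_type2(cells: pd.DataFrame,
                    pair: Tuple[str, str],
                    gamma_lookup: GammaLookup,
                    channels: Sequence[str] = CHANNELS,
                    group_cols: Sequence[str] = GROUP_COLS,
                    min_group_size: int = MIN_GROUP_SIZE,
                    pre_normalized: bool = False) -> DecompositionResult:
    """Type II partition into eta2(G), eta2(P) and the subtracted eta2(gamma).

    ``correlated`` is eta2(G).  The average Type I intrinsic noise of the two
    promoters is subtracted from the uncorrelated variation to give
    ``eta2_P_raw``; negative overshoot is clamped to zero in ``eta2_P`` with
    ``clamped`` flagged, the raw value preserved.
    """
    prom_a, prom_b = pair
    if pre_normalized:
        norm, gains, skipped = cells, [], []
    else:
        norm, gains, skipped = normalize_by_group(
            cells, channels, group_cols, min_group_size)
    rows = []
    for key, grp in norm.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        ring = dict(zip(group_cols, key)).get("ring")
        corr, uncorr = correlated_uncorrelated(grp[channels[0]],
                                               grp[channels[1]])
        g_a, src_a = gamma_for(gamma_lookup, prom_a, ring)
        g_b, src_b = gamma_for(gamma_lookup, prom_b, ring)
        gamma_bar = 0.5 * (g_a + g_b)
        raw = uncorr - gamma_bar
        row = dict(zip(group_cols, key))
        row.update(n=len(grp), correlated=corr, uncorrelated=uncorr,
                   eta2_G=corr, eta2_gamma=gamma_bar,
                   eta2_P_raw=raw, eta2_P=max(raw, 0.0),
                   clamped=raw < 0.0,
                   gamma_source=f"{src_a}/{src_b}")
        rows.append(row)
    return _finish("typeII", rows, group_cols,
                   ("eta2_G", "eta2_P_raw", "eta2_gamma",
                    "correlated", "uncorrelated"),
                   gains, skipped)


def pooled_vs_grouped(cells: pd.DataFrame,
                      pair: Tuple[str, str],
                      gamma_lookup: GammaLookup | None = None,
                      channels: Sequence[str] = CHANNELS,
                      min_group_size: int = MIN_GROUP_SIZE) -> dict:
    """Quantify the signaling-noise inflation caused by pooling rings.

    Computes eta2(P) with ring-wise normalization/grouping and again with
    all rings of an experiment pooled before normalization.  Ring-specific
    setpoint ratios masquerade as pathway noise in the pooled estimate, so
    pooled >= grouped whenever setpoint ratios differ between rings.
    """
    if gamma_lookup is None:
        gamma_lookup = {pair[0]: 0.0, pair[1]: 0.0}
    n_rings = cells["ring"].nunique()
    grouped = decompose_type2(cells, pair, gamma_lookup, channels,
                              group_cols=("experiment_id", "ring"),
                              min_group_size=min_group_size)
    pooled = decompose_type2(cells, pair, gamma_lookup, channels,
                             group_cols=("experiment_id",),
                             min_group_size=min_group_size)
    report = {
        "eta2_P_grouped": grouped.aggregate["eta2_P"],
        "eta2_P_pooled": pooled.aggregate["eta2_P"],
        "inflation": pooled.aggregate["eta2_P"] - grouped.aggregate["eta2_P"],
        "n_rings": int(n_rings),
    }
    if n_rings < 2:
        report["warning"] = ("single ring present: pooled and grouped "
                             "estimates coincide by construction")
    return report


# ---------------------------------------------------------------------------
# statistical comparisons between variation bins


def _is_normalish(values: np.ndarray) -> bool:
    if np.ptp(values) == 0:
        return False  # Shapiro-Wilk undefined on constant data
    return stats.shapiro(values).pvalue >= ALPHA


def compare_bins(bins: Mapping[str, Sequence[float]],
                 alpha: float = ALPHA) -> dict:
    """Compare replicate eta^2 values between variation bins.

    Two bins: two-tailed two-sample t-test; three or more: one-way ANOVA
    with Tukey HSD pairwise contrasts.  A Shapiro-Wilk pre-check (per bin,
    alpha 0.05) reroutes to Mann-Whitney / Kruskal-Wallis when normality is
    rejected; the chosen method is recorded in the report.
    """
    names = list(bins)
    data = [np.asarray(bins[k], dtype=float) for k in names]
    if len(data) < 2:
        raise ValueError("need at least 2 bins")
    for name, vals in zip(names, data):
        if vals.size < 3:
            raise ValueError(f"bin {name!r} needs >= 3 replicate values")
    pooled = np.concatenate(data)
    if np.ptp(pooled) == 0:
        raise ValueError("zero variance, test undefined")

    normal = all(_is_normalish(v) for v in data)
    report: dict = {"bins": names, "normal": normal, "alpha": alpha,
                    "contrasts": []}
    if len(data) == 2:
        if normal:
            res = stats.ttest_ind(data[0], data[1])
            report.update(method="two-tailed t-test",
                          statistic=float(res.statistic),
                          pvalue=float(res.pvalue))
        else:
            res = stats.mannwhitneyu(data[0], data[1],
                                     alternative="two-sided")
            report.update(method="Mann-Whitney U",
                          statistic=float(res.statistic),
                          pvalue=float(res.pvalue))
    else:
        if normal:
            res = stats.f_oneway(*data)
            report.update(method="one-way ANOVA + Tukey HSD",
                          statistic=float(res.statistic),
                          pvalue=float(res.pvalue))
            hsd = stats.tukey_hsd(*data)
            for i in range(len(data)):
                for j in range(i + 1, len(data)):
                    p = float(hsd.pvalue[i, j])
                    report["contrasts"].append({
                        "bins": (names[i], names[j]),
                        "statistic": float(hsd.statistic[i, j]),
                        "pvalue": p,
                        "significant": p < alpha,
                    })
        else:
            res = stats.kruskal(*data)
            report.update(method="Kruskal-Wallis",
                          statistic=float(res.statistic),
                          pvalue=float(res.pvalue))
            for i in range(len(data)):
                for j in range(i + 1, len(data)):
                    mwu = stats.mannwhitneyu(data[i], data[j],
                                             alternative="two-sided")
                    report["contrasts"].append({
                        "bins": (names[i], names[j]),
                        "statistic": float(mwu.statistic),
                        "pvalue": float(mwu.pvalue),
                        "significant": float(mwu.pvalue) < alpha,
                    })
    report["significant"] = report["pvalue"] < alpha
    return report


def combined_scatter(type1_tables: Sequence[pd.DataFrame],
                     type2_tables: Sequence[pd.DataFrame],
                     channels: Sequence[str] = CHANNELS) -> pd.DataFrame:
    """Pool normalized cells from all experiments into one global point set.

    Inputs must already be per-group mean-1 normalized; the output has one
    ``(x, y, experiment_type)`` row per cell, the overlay in which Type II
    clouds surround the tighter Type I diagonal.
    """
    frames = []
    for kind, tables in (("typeI", type1_tables), ("typeII", type2_tables)):
        for tbl in tables:
            frames.append(pd.DataFrame({
                "x": tbl[channels[0]].to_numpy(float),
                "y": tbl[channels[1]].to_numpy(float),
                "experiment_type": kind,
            }))
    if not frames:
        return pd.DataFrame(columns=["x", "y", "experiment_type"])
    return pd.concat(frames, ignore_index=True)
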