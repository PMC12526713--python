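"""Feature catalog, summary statistics and two-stage feature selection.

Each of the 80 base parameters (40 spectral, 32 coherence, 8 entropy) is a
per-window time series; collapsing it with four summary statistics — mean,
coefficient of variation CV = s/mean, kurtosis k = sum((x-mean)^4)/(n s^4)
and interquartile range Q3-Q1 — yields the canonical 320-column feature
matrix (patients x features).

Selection mirrors common practice for small physiological cohorts: a
two-sided Mann-Whitney U test per feature at raw alpha (no multiple-testing
correction), then a greedy Spearman de-correlation pass that drops, from
every remaining pair with |rho| >= rho_max, the member with the larger mean
absolute correlation to all others.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import PipelineConfig
from .spectral import COHERENCE_PAIRS

logger = logging.getLogger("emgwean")

SIGNALS = ("EDR", "HRV", "EMGe", "EMGi")
BANDS = ("LF", "HF")
SPECTRAL_STATS = ("Hp", "P", "Fp", "Us", "Ds")
COH_STATS = ("Pcoh", "RMScoh", "Fpcoh", "Hpcoh", "Uscoh", "Dscoh")
ENTROPY_STATS = ("SampEn", "ApEn")
SUMMARY_STATS = ("mean", "cv", "kurt", "iqr")


def base_catalog(fixed_freqs=(0.02, 0.04)) -> list[str]:
    """The 80 canonical base parameter names, in canonical order."""
    names = [f"{p}{b}{s}" for s in SIGNALS for b in BANDS
             for p in SPECTRAL_STATS]
    names += [f"{p}{pair}" for pair, _, _ in COHERENCE_PAIRS
              for p in COH_STATS]
    names += [f"Hpcoh{pair}_{j:g}Hz" for pair, _, _ in COHERENCE_PAIRS
              for j in fixed_freqs]
    names += [f"{e}{s}" for s in SIGNALS for e in ENTROPY_STATS]
    return names


def feature_catalog(fixed_freqs=(0.02, 0.04)) -> list[str]:
    """The 320 canonical feature names: summary statistic x base parameter."""
    return [f"{stat}_{base}" for base in base_catalog(fixed_freqs)
            for stat in SUMMARY_STATS]


def summarize(values) -> dict:
    """Mean, CV, kurtosis and IQR of one parameter series.

    Uses the sample standard deviation (n-1), linear-interpolation
    (type-7) quartiles, and the direct fourth-moment kurtosis formula.
    CV and kurtosis are NaN for (near-)zero mean and zero variance
    respectively.  Non-finite input values are dropped first; fewer than
    two finite values is an error.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 finite values")
    mean = float(x.mean())
    s = float(x.std(ddof=1))
    cv = float("nan") if abs(mean) < 1e-12 * max(s, 1.0) else s / mean
    kurt = (float("nan") if s == 0
            else float(np.sum((x - mean) ** 4) / (n * s ** 4)))
    q1, q3 = np.percentile(x, [25.0, 75.0], method="linear")
    return {"mean": mean, "cv": cv, "kurt": kurt, "iqr": float(q3 - q1)}


def build_feature_matrix(cohort_params: dict, catalog=None) -> pd.DataFrame:
    """Assemble the patients x 320 feature matrix.

    ``cohort_params`` maps patient_id -> (group, {base name -> ParamSeries});
    every patient must provide every base parameter of the catalog.
    """
    base = catalog or base_catalog()
    rows = []
    for pid, (group, series) in cohort_params.items():
        missing = [b for b in base if b not in series]
        if missing:
            raise ValueError(
                f"patient {pid} missing base parameter(s) {missing[:3]}"
            )
        row = {"patient_id": pid, "group": group}
        for b in base:
            stats_ = summarize(series[b].values)
            for stat in SUMMARY_STATS:
                row[f"{stat}_{b}"] = stats_[stat]
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("patient_id", kind="stable")
    cols = ["patient_id", "group"] + [f"{stat}_{b}" for b in base
                                      for stat in SUMMARY_STATS]
    return df[cols].reset_index(drop=True)


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in ("patient_id", "group")]


def significance_filter(matrix: pd.DataFrame, alpha: float = 0.05
                        ) -> tuple[list[str], pd.Series]:
    """Two-sided Mann-Whitney U per feature; keep p < alpha.

    Constant features get p = 1 by convention; NaN entries are dropped
    pairwise.  Returns (significant names, p-values for all features).
    """
    groups = matrix["group"].to_numpy()
    if not {"success", "failure"} <= set(groups):
        raise ValueError("both outcome classes must be present")
    pvals = {}
    for col in feature_columns(matrix):
        x = matrix.loc[groups == "success", col].dropna().to_numpy()
        y = matrix.loc[groups == "failure", col].dropna().to_numpy()
        if x.size < 1 or y.size < 1 or np.ptp(np.concatenate([x, y])) == 0:
            pvals[col] = 1.0
            continue
        pvals[col] = float(stats.mannwhitneyu(x, y,
                                              alternative="two-sided").pvalue)
    pser = pd.Series(pvals)
    sig = [c for c in pser.index if pser[c] < alpha]
    logger.info("significance filter: %d/%d features at alpha=%g",
                len(sig), pser.size, alpha)
    return sig, pser


def spearman_filter(matrix: pd.DataFrame, significant: list[str],
                    rho_max: float = 0.6,
                    pvalues: pd.Series | None = None) -> list[str]:
    """Greedy de-correlation of the significant feature set.

    While any pair has |rho| >= rho_max, drop the member with the larger
    mean |rho| to all remaining features (ties resolved toward the larger
    p-value, then catalog order).  The survivors satisfy pairwise
    |rho| < rho_max.
    """
    if not significant:
        return []
    kept = list(significant)
    if len(kept) == 1:
        return kept
    sub = matrix[kept]
    rho = sub.corr(method="spearman").abs().to_numpy()
    np.fill_diagonal(rho, 0.0)
    idx = list(range(len(kept)))
    while True:
        r = rho[np.ix_(idx, idx)]
        if r.size == 0 or np.nanmax(r) < rho_max:
            break
        mean_rho = np.nanmean(r, axis=1)
        worst = np.flatnonzero(mean_rho == mean_rho.max())
        if worst.size > 1 and pvalues is not None:
            pv = np.array([pvalues.get(kept[idx[w]], 0.0) for w in worst])
            worst = worst[pv == pv.max()]
        drop = idx[int(worst[-1])]  # later catalog position on final ties
        idx.remove(drop)
    out = [kept[i] for i in idx]
    logger.info("spearman filter: retained %d/%d features (|rho|<%g)",
                len(out), len(kept), rho_max)
    return out


def select_features(matrix: pd.DataFrame,
                    cfg: PipelineConfig | None = None) -> dict:
    """Two-stage selection; returns names, p-values and the rho matrix."""
    cfg = cfg or PipelineConfig()
    sig, pvals = significance_filter(matrix, cfg.alpha)
    retained = spearman_filter(matrix, sig, cfg.rho_max, pvals)
    rho = (matrix[sig].corr(method="spearman") if sig
           else pd.DataFrame())
    return {"significant": sig, "p_values": pvals, "retained": retained,
            "rho": rho}
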