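"""Statistical layer: normality screening, method comparison, factor tables.

Mirrors the analysis plan of a sector-validation study: a Kolmogorov-Smirnov
screen for non-normal metric distributions, Kruskal-Wallis comparisons of the
correlation indices between imaging methods, and point-biserial Pearson
correlations of candidate predictive factors (lesion localisation, relative
lesion volume, Gleason score, PSA, SUVmax) with per-lesion DSC.  Volume
strata are "at least x%" threshold indicators.  No multiple-testing
correction is applied by default (the analysis is exploratory); a
Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "normality_screen",
    "compare_methods",
    "factor_table",
    "factor_correlation",
    "factor_correlation_table",
    "simulate_dsc_factor_cohort",
]

#: relative-volume threshold indicators ("at least x% of the prostate")
VOLUME_THRESHOLDS = (0.05, 0.10, 0.15, 0.20)
#: PSA strata bounds, ng/mL
PSA_EDGES = (10.0, 20.0)
#: SUVmax strata: ~2, ~3, >= 4
SUV_EDGES = (2.5, 3.5)

GLEASON_STRATA = ("6", "7a", "7b", "8")
REGION_STRATA = ("apex", "mid", "base")


@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    group_labels: tuple = ()
    n_per_group: tuple = ()
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def normality_screen(values, label: str = "") -> StatResult:
    """One-sample KS test of the values against a normal with their mean/SD.

    Degenerate (constant) samples are flagged and the test is skipped
    (statistic and p reported as NaN).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    m, s = float(x.mean()), float(x.std(ddof=1))
    if s == 0:
        return StatResult(test="kolmogorov_smirnov", statistic=math.nan,
                          p_value=math.nan, group_labels=(label,),
                          n_per_group=(len(x),), flags=["degenerate_constant"])
    stat, p = sps.kstest(x, "norm", args=(m, s))
    return StatResult(test="kolmogorov_smirnov", statistic=float(stat),
                      p_value=float(p), group_labels=(label,),
                      n_per_group=(len(x),))


def compare_methods(groups: dict[str, np.ndarray]) -> StatResult:
    """Kruskal-Wallis comparison of a metric across contouring methods."""
    labels = tuple(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 3 for a in arrays):
        raise ValueError("each group needs n >= 3")
    concat = np.concatenate(arrays)
    if np.all(concat == concat[0]):
        # all observations identical across groups: no evidence of difference
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*arrays)
    return StatResult(test="kruskal_wallis", statistic=float(stat),
                      p_value=float(p), group_labels=labels,
                      n_per_group=tuple(len(a) for a in arrays))


def factor_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-lesion factor table: DSC plus the stratum of every candidate factor.

    Expects columns ``dsc``, ``region``, ``volume_fraction``, ``gleason``,
    ``psa_ng_ml``, ``suvmax``; adds categorical stratum columns and the
    volume-threshold indicator columns ``vol_ge_<pct>``.
    """
    df = records.copy()
    required = {"dsc", "region", "volume_fraction", "gleason", "psa_ng_ml", "suvmax"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"factor table needs columns {sorted(missing)}")
    for t in VOLUME_THRESHOLDS:
        df[f"vol_ge_{int(round(t * 100))}"] = (df["volume_fraction"] >= t).astype(int)
    df["psa_stratum"] = pd.cut(df["psa_ng_ml"],
                               [-np.inf, *PSA_EDGES, np.inf],
                               labels=["<=10", "10-20", ">20"]).astype(str)
    df["suv_stratum"] = pd.cut(df["suvmax"],
                               [-np.inf, *SUV_EDGES, np.inf],
                               labels=["2", "3", ">=4"]).astype(str)
    return df


def _point_biserial(indicator: np.ndarray, dsc: np.ndarray) -> tuple[float, float]:
    ind = np.asarray(indicator, dtype=float)
    y = np.asarray(dsc, dtype=float)
    keep = ~(np.isnan(ind) | np.isnan(y))
    ind, y = ind[keep], y[keep]
    if ind.std() == 0 or y.std() == 0:
        return math.nan, math.nan
    r, p = sps.pearsonr(ind, y)
    return float(r), float(p)


def factor_correlation(table: pd.DataFrame, factor: str, stratum: str) -> StatResult:
    """Point-biserial Pearson r of one factor stratum with per-lesion DSC.

    ``factor`` is one of ``localisation``, ``volume``, ``gleason``, ``psa``,
    ``suvmax``; ``stratum`` names the row (e.g. ``"base"``, ``0.15``,
    ``"7b"``, ``">20"``).  A single-class indicator is undefined and flagged.
    """
    if factor == "localisation":
        ind = (table["region"].astype(str) == str(stratum)).to_numpy(int)
    elif factor == "volume":
        ind = (table["volume_fraction"] >= float(stratum)).to_numpy(int)
    elif factor == "gleason":
        ind = (table["gleason"].astype(str) == str(stratum)).to_numpy(int)
    elif factor == "psa":
        ind = (table["psa_stratum"] == str(stratum)).to_numpy(int)
    elif factor == "suvmax":
        ind = (table["suv_stratum"] == str(stratum)).to_numpy(int)
    else:
        raise ValueError(f"unknown factor {factor!r}")
    flags = []
    if ind.min() == ind.max():
        flags.append("single_class_indicator")
        r = p = math.nan
    else:
        r, p = _point_biserial(ind, table["dsc"].to_numpy())
    return StatResult(test="pearson_point_biserial", statistic=r, p_value=p,
                      group_labels=(factor, str(stratum)),
                      n_per_group=(int(ind.sum()), int(len(ind) - ind.sum())),
                      flags=flags)


_TABLE_ROWS = (
    [("localisation", s) for s in REGION_STRATA]
    + [("volume", t) for t in VOLUME_THRESHOLDS]
    + [("gleason", g) for g in GLEASON_STRATA]
    + [("psa", s) for s in ("<=10", "10-20", ">20")]
    + [("suvmax", s) for s in ("2", "3", ">=4")]
)


def factor_correlation_table(table: pd.DataFrame, method_col: str = "method",
                             bh_adjust: bool = False) -> pd.DataFrame:
    """Factor-by-method table of Pearson r and p (one row per factor stratum)."""
    rows = []
    for method, grp in table.groupby(method_col, sort=False):
        ft = factor_table(grp) if "psa_stratum" not in grp.columns else grp
        for factor, stratum in _TABLE_ROWS:
            res = factor_correlation(ft, factor, stratum)
            rows.append({"method": method, "factor": factor,
                         "stratum": str(stratum), "r": res.statistic,
                         "p": res.p_value, "n_in": res.n_per_group[0],
                         "flags": ";".join(res.flags)})
    out = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_bh"] = adj
    return out


def simulate_dsc_factor_cohort(n_lesions: int = 33, seed: int = 0,
                               dsc_floor: float = 0.20, dsc_gain: float = 0.60,
                               volume_midpoint: float = 0.15,
                               volume_width: float = 0.03,
                               dsc_noise_sd: float = 0.08,
                               volume_fraction_range: tuple[float, float]
                               = (0.01, 0.75),
                               small_focus_prob: float = 0.25,
                               small_focus_range: tuple[float, float]
                               = (0.01, 0.05)) -> pd.DataFrame:
    """Lightweight per-lesion cohort whose DSC degrades for small lesions.

    Lesion volume fractions, Gleason scores, PSA and SUVmax are drawn from
    the same clinical distributions the imaging phantom uses; per-lesion DSC
    follows a logistic volume response
    ``dsc = floor + gain / (1 + exp(-(v - midpoint) / width)) + noise``
    clipped to [0, 1]: below a critical relative volume (the partial-volume
    regime of the scanner) every lesion delineates poorly, with a steep
    transition around ``volume_midpoint``.  Used for stochastic calibration
    of the factor-correlation analysis without rendering images.  Unlike the
    imaging phantom's dominant-lesion selection, the cohort here represents
    *all* biopsy-confirmed lesions: with probability ``small_focus_prob`` a
    lesion is a small non-dominant focus (satellite-sized, below 5% of the
    gland), so every volume-threshold indicator has both classes populated.
    """
    from .phantom import GLEASON_LEVELS, CohortSpec, _lognormal

    spec = CohortSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_lesions):
        if rng.random() < small_focus_prob:
            v = float(rng.uniform(*small_focus_range))
        else:
            v = _lognormal(rng, spec.volume_fraction_median,
                           spec.volume_fraction_sigma, *volume_fraction_range)
        dsc = dsc_floor + dsc_gain / (1.0 + np.exp(-(v - volume_midpoint)
                                                   / volume_width))
        dsc = float(np.clip(dsc + rng.normal(0.0, dsc_noise_sd), 0.0, 1.0))
        rows.append({
            "lesion_id": i, "dsc": dsc, "volume_fraction": v,
            "region": rng.choice(REGION_STRATA),
            "gleason": GLEASON_LEVELS[rng.choice(len(spec.gleason_probs),
                                                 p=spec.gleason_probs)],
            "psa_ng_ml": _lognormal(rng, spec.psa_median, spec.psa_sigma,
                                    *spec.psa_range),
            "suvmax": _lognormal(rng, spec.suvmax_median, spec.suvmax_sigma,
                                 *spec.suvmax_range),
        })
    return pd.DataFrame(rows)
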