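"""One-way ANOVA and Tukey HSD across sampling locations.

Both tests are computed from their defining formulas: ANOVA from the
between/within sums of squares, Tukey's honestly-significant-difference
from the studentized-range quantile q(alpha; k, df) applied to
sqrt(MS_within / n_h) with n_h the harmonic mean group size
(Tukey-Kramer form for unbalanced designs).  The studentized-range
quantiles for alpha in {0.05, 0.01} ship as an embedded table (k <= 10,
df from 2 to 120 plus the asymptote) with interpolation linear in 1/df;
the F-distribution tail probability comes from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from ._errors import ValidationError

__all__ = ["AnovaResult", "TukeyResult", "oneway_anova", "tukey_hsd", "studentized_range_q"]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: Mapping[str, float]
    ms_within: float
    ms_between: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    critical_difference: float
    significant: bool


@dataclass(frozen=True)
class TukeyResult:
    pairwise: tuple[PairwiseComparison, ...]
    alpha: float
    q_critical: float
    ms_within: float
    df_within: int


def _validated_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValidationError(f"need at least 2 groups, got {len(groups)}")
    arrays = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValidationError(f"group {name!r} needs at least 2 values")
        arrays[name] = arr
    return arrays


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from explicit sums of squares.

    F = MS_between / MS_within with MS_between = SSB/(k-1) over group
    means and MS_within = SSW/(N-k) over within-group deviations; the
    p-value is the upper tail of F(k-1, N-k).
    """
    arrays = _validated_groups(groups)
    all_values = np.concatenate(list(arrays.values()))
    grand_mean = all_values.mean()
    n_total = all_values.size
    k = len(arrays)

    ssb = sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays.values())
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays.values())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ssb / df_between
    ms_within = ssw / df_within
    if ms_within == 0.0:
        if ms_between == 0.0:
            raise ValidationError("F undefined: zero between- and within-group variance")
        f_stat = math.inf
        p_value = 0.0
    else:
        f_stat = ms_between / ms_within
        p_value = float(_sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
        group_means={name: float(a.mean()) for name, a in arrays.items()},
        ms_within=float(ms_within),
        ms_between=float(ms_between),
    )


# Studentized-range quantiles q(1-alpha; k, df): standard published table
# values, k = 2..10, df = 2..20, 24, 30, 40, 60, 120 and the asymptote.
_Q_DF = (2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20,
         24, 30, 40, 60, 120, math.inf)

_Q_TABLE = {
    0.05: {
        2: (6.0849, 4.5007, 3.9265, 3.6354, 3.4605, 3.3441, 3.2612, 3.1992, 3.1511,
            3.1127, 3.0813, 3.0552, 3.0332, 3.0143, 2.9980, 2.9837, 2.9712, 2.9600,
            2.9500, 2.9188, 2.8882, 2.8582, 2.8288, 2.8000, 2.7718),
        3: (8.3308, 5.9096, 5.0402, 4.6017, 4.3392, 4.1649, 4.0410, 3.9485, 3.8768,
            3.8196, 3.7729, 3.7341, 3.7014, 3.6734, 3.6491, 3.6280, 3.6093, 3.5927,
            3.5779, 3.5317, 3.4864, 3.4421, 3.3987, 3.3561, 3.3145),
        4: (9.7980, 6.8245, 5.7571, 5.2183, 4.8956, 4.6813, 4.5288, 4.4149, 4.3266,
            4.2561, 4.1987, 4.1509, 4.1105, 4.0760, 4.0461, 4.0200, 3.9970, 3.9766,
            3.9583, 3.9013, 3.8454, 3.7907, 3.7371, 3.6846, 3.6332),
        5: (10.8811, 7.5017, 6.2870, 5.6731, 5.3049, 5.0601, 4.8858, 4.7554, 4.6543,
            4.5736, 4.5077, 4.4529, 4.4066, 4.3670, 4.3327, 4.3027, 4.2763, 4.2528,
            4.2319, 4.1663, 4.1021, 4.0391, 3.9774, 3.9169, 3.8577),
        6: (11.7343, 8.0371, 6.7064, 6.0329, 5.6284, 5.3591, 5.1672, 5.0235, 4.9120,
            4.8230, 4.7502, 4.6897, 4.6385, 4.5947, 4.5568, 4.5237, 4.4944, 4.4685,
            4.4452, 4.3727, 4.3015, 4.2316, 4.1632, 4.0960, 4.0301),
        7: (12.4349, 8.4783, 7.0526, 6.3299, 5.8953, 5.6057, 5.3991, 5.2444, 5.1242,
            5.0281, 4.9496, 4.8842, 4.8290, 4.7816, 4.7406, 4.7048, 4.6731, 4.6450,
            4.6199, 4.5413, 4.4642, 4.3885, 4.3141, 4.2412, 4.1696),
        8: (13.0273, 8.8525, 7.3465, 6.5823, 6.1222, 5.8153, 5.5962, 5.4319, 5.3042,
            5.2021, 5.1187, 5.0491, 4.9903, 4.9399, 4.8962, 4.8580, 4.8243, 4.7944,
            4.7676, 4.6838, 4.6014, 4.5205, 4.4411, 4.3630, 4.2863),
        9: (13.5390, 9.1766, 7.6015, 6.8014, 6.3192, 5.9973, 5.7673, 5.5947, 5.4605,
            5.3531, 5.2653, 5.1921, 5.1301, 5.0770, 5.0310, 4.9907, 4.9552, 4.9236,
            4.8954, 4.8069, 4.7199, 4.6345, 4.5504, 4.4678, 4.3865),
        10: (13.9885, 9.4620, 7.8263, 6.9947, 6.4931, 6.1579, 5.9183, 5.7384, 5.5984,
             5.4863, 5.3946, 5.3181, 5.2534, 5.1979, 5.1498, 5.1077, 5.0705, 5.0375,
             5.0079, 4.9152, 4.8241, 4.7345, 4.6463, 4.5595, 4.4741),
    },
    0.01: {
        2: (14.0358, 8.2603, 6.5112, 5.7023, 5.2431, 4.9490, 4.7452, 4.5960, 4.4820,
            4.3923, 4.3198, 4.2600, 4.2099, 4.1673, 4.1306, 4.0987, 4.0707, 4.0460,
            4.0239, 3.9555, 3.8891, 3.8247, 3.7622, 3.7016, 3.6428),
        3: (19.0189, 10.6185, 8.1198, 6.9757, 6.3305, 5.9193, 5.6354, 5.4280, 5.2702,
            5.1460, 5.0459, 4.9635, 4.8945, 4.8359, 4.7855, 4.7418, 4.7034, 4.6694,
            4.6392, 4.5456, 4.4549, 4.3672, 4.2822, 4.1999, 4.1203),
        4: (22.2937, 12.1695, 9.1729, 7.8042, 7.0333, 6.5424, 6.2038, 5.9567, 5.7686,
            5.6208, 5.5016, 5.4036, 5.3215, 5.2518, 5.1919, 5.1399, 5.0942, 5.0539,
            5.0180, 4.9068, 4.7992, 4.6951, 4.5944, 4.4970, 4.4028),
        5: (24.7172, 13.3243, 9.9583, 8.4215, 7.5560, 7.0050, 6.6248, 6.3473, 6.1361,
            5.9701, 5.8363, 5.7262, 5.6340, 5.5558, 5.4885, 5.4301, 5.3788, 5.3336,
            5.2933, 5.1684, 5.0476, 4.9308, 4.8178, 4.7085, 4.6028),
        6: (26.6290, 14.2407, 10.5832, 8.9131, 7.9723, 7.3730, 6.9594, 6.6574, 6.4275,
            6.2468, 6.1011, 5.9812, 5.8808, 5.7956, 5.7223, 5.6586, 5.6028, 5.5535,
            5.5095, 5.3735, 5.2418, 5.1145, 4.9913, 4.8722, 4.7570),
        7: (28.2006, 14.9978, 11.1009, 9.3209, 8.3177, 7.6784, 7.2369, 6.9145, 6.6690,
            6.4759, 6.3202, 6.1920, 6.0847, 5.9936, 5.9152, 5.8471, 5.7874, 5.7346,
            5.6876, 5.5420, 5.4012, 5.2648, 5.1330, 5.0055, 4.8822),
        8: (29.5301, 15.6410, 11.5418, 9.6687, 8.6125, 7.9390, 7.4738, 7.1339, 6.8749,
            6.6713, 6.5069, 6.3717, 6.2583, 6.1621, 6.0793, 6.0074, 5.9443, 5.8886,
            5.8389, 5.6850, 5.5361, 5.3920, 5.2525, 5.1176, 4.9872),
        9: (30.6794, 16.1990, 11.9251, 9.9715, 8.8693, 8.1662, 7.6803, 7.3251, 7.0544,
            6.8414, 6.6696, 6.5280, 6.4095, 6.3087, 6.2221, 6.1468, 6.0807, 6.0223,
            5.9703, 5.8092, 5.6531, 5.5020, 5.3558, 5.2143, 5.0775),
        10: (31.6894, 16.6908, 12.2637, 10.2393, 9.0966, 8.3674, 7.8632, 7.4945, 7.2133,
             6.9921, 6.8136, 6.6664, 6.5432, 6.4384, 6.3483, 6.2700, 6.2013, 6.1406,
             6.0865, 5.9187, 5.7563, 5.5989, 5.4466, 5.2992, 5.1566),
    },
}


def studentized_range_q(alpha: float, k: int, df: int) -> float:
    """Upper-alpha studentized-range quantile q(alpha; k, df).

    Table lookup for alpha in {0.05, 0.01} and 2 <= k <= 10, with
    interpolation linear in 1/df between tabulated degrees of freedom.
    """
    if alpha not in _Q_TABLE:
        raise ValidationError(
            f"alpha must be one of {sorted(_Q_TABLE)}, got {alpha}"
        )
    if not 2 <= k <= 10:
        raise ValidationError(f"number of groups must be in [2, 10], got {k}")
    if df < 2:
        raise ValidationError(f"within degrees of freedom must be >= 2, got {df}")
    row = _Q_TABLE[alpha][k]
    dfs = _Q_DF
    if df >= dfs[-2] * 10:  # effectively asymptotic
        return row[-1]
    for i, tab_df in enumerate(dfs):
        if df == tab_df:
            return row[i]
        if df < tab_df:
            lo_df, hi_df = dfs[i - 1], tab_df
            lo_q, hi_q = row[i - 1], row[i]
            # interpolate linearly in 1/df (standard for these tables)
            t = (1.0 / df - 1.0 / lo_df) / (1.0 / hi_df - 1.0 / lo_df)
            return lo_q + t * (hi_q - lo_q)
    # df beyond last finite entry: interpolate toward the asymptote
    lo_df, lo_q = dfs[-2], row[-2]
    t = (1.0 / df - 1.0 / lo_df) / (0.0 - 1.0 / lo_df)
    return lo_q + t * (row[-1] - lo_q)


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD post-hoc test on all group pairs.

    The critical difference is q(alpha; k, df_within) * sqrt(MS_within/n_h)
    with n_h the harmonic mean group size (Tukey-Kramer); a pair is
    significant when |mean difference| exceeds it.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    arrays = _validated_groups(groups)
    anova = oneway_anova(groups)
    k = len(arrays)
    n_h = k / sum(1.0 / a.size for a in arrays.values())
    q_crit = studentized_range_q(alpha, k, anova.df_within)
    critical = q_crit * math.sqrt(anova.ms_within / n_h)
    names = list(arrays)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrays[names[i]].mean() - arrays[names[j]].mean())
            pairs.append(
                PairwiseComparison(
                    group_a=names[i],
                    group_b=names[j],
                    mean_difference=diff,
                    critical_difference=critical,
                    significant=abs(diff) > critical,
                )
            )
    return TukeyResult(
        pairwise=tuple(pairs),
        alpha=alpha,
        q_critical=q_crit,
        ms_within=anova.ms_within,
        df_within=anova.df_within,
    )
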