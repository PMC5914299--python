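"""Agreement and correlation statistics for density comparisons.

Pearson correlation (two-tailed p from the t distribution with n−2 df)
and classical Bland–Altman agreement: mean difference, its SD (n−1
denominator) and 95% limits of agreement at mean ± 1.96·SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io_formats import EyeRecord

LOA_Z = 1.96


@dataclass
class AgreementReport:
    n_pairs: int
    pearson_r: float
    p_value: float
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float


def _check_pair(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-tailed p-value."""
    x, y = _check_pair(x, y, 3)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(x, y) -> AgreementReport:
    """Bland–Altman agreement of paired measurements (differences x − y)."""
    x, y = _check_pair(x, y, 2)
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    r, p = (float("nan"), float("nan"))
    if len(x) >= 3 and np.std(x) > 0 and np.std(y) > 0:
        r, p = pearson(x, y)
    return AgreementReport(
        n_pairs=len(x), pearson_r=r, p_value=p,
        mean_difference=mean_d, sd_difference=sd_d,
        loa_low=mean_d - LOA_Z * sd_d, loa_high=mean_d + LOA_Z * sd_d,
    )


def inter_eye_pairs(records: list[EyeRecord], field: str
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pair right-eye (OD) and left-eye (OS) values of the same subject
    for a given density field; subjects missing either value are dropped."""
    od: dict[int, float] = {}
    os_: dict[int, float] = {}
    for r in records:
        v = getattr(r, field)
        if v is None:
            continue
        (od if r.eye == "OD" else os_)[r.subject_id] = float(v)
    common = sorted(set(od) & set(os_))
    return (np.array([od[s] for s in common]),
            np.array([os_[s] for s in common]))
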