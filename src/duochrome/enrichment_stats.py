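"""Pooled two-proportion z-test across AD strata, with FDR control.

For one AD stratum, let x be the number of T>G (or another class's) mismatch
sites and n the total mismatch sites on each platform. The statistic is

    z = (p1 - p2) / sqrt( p_pooled (1 - p_pooled) (1/n1 + 1/n2) )

with p_pooled = (x1 + x2)/(n1 + n2) and a two-sided p-value from the standard
normal. No continuity correction is applied. q-values are Benjamini-Hochberg
by default (Storey's estimator optional); a stratum is significant when
q < 0.05. AD = 1 strata are tested but flagged as disregarded: single-read
mismatches are dominated by ordinary sequencing/alignment error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .mismatch_profiler import ADMatrix

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ProportionTest:
    p_nova: float
    p_hiseq: float
    p_pooled: float
    n_nova: int
    n_hiseq: int
    z: float
    p_value: float
    q_value: float | None = None
    ad: int | None = None


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> ProportionTest:
    """Pooled-variance two-proportion z-test (platform 1 minus platform 2).

    Degenerate strata where the pooled proportion is 0 or 1 carry no
    information about a difference: z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("require 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        z, p = 0.0, 1.0
    else:
        se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
        z = (p1 - p2) / se
        p = 2.0 * norm.sf(abs(z))
    return ProportionTest(
        p_nova=p1, p_hiseq=p2, p_pooled=pooled, n_nova=n1, n_hiseq=n2,
        z=z, p_value=p,
    )


def proportion_difference(p1: float, p2: float) -> float:
    """Signed difference p1 - p2; positive means an excess on platform 1."""
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise ValueError("proportions must lie in [0, 1]")
    return p1 - p2


def _storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey's q-values with a single-lambda pi0 estimate."""
    m = len(p)
    pi0 = min(1.0, (p > lam).sum() / ((1.0 - lam) * m))
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def fdr_qvalues(
    p_values, alpha: float = DEFAULT_ALPHA, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """(q-values, significance flags at q < alpha), in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        _, q, _, _ = multipletests(p, method="fdr_bh")
    elif method == "storey":
        q = _storey_qvalues(p)
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    return q, q < alpha


def per_ad_enrichment(
    nova: ADMatrix,
    hiseq: ADMatrix,
    sbs_class: str = "T>G",
    ad_range=None,
    alpha: float = DEFAULT_ALPHA,
    fdr_method: str = "bh",
    disregard_ad1: bool = True,
) -> pd.DataFrame:
    """Per-AD enrichment table for one platform pair and one SBS class.

    Each testable stratum contributes x = class count and n = total mismatch
    sites per platform to the z-test. q-values are computed jointly across
    the testable strata of this comparison (the multiple-testing family is
    one platform pair). Strata empty on either platform are untestable; the
    AD = 1 row is computed but flagged ``disregarded`` and excluded from
    both the family and the significance calls.
    """
    if nova.ad_max != hiseq.ad_max:
        raise ValueError("AD matrices must share ad_max")
    ads = list(ad_range) if ad_range is not None else list(nova.counts.columns)
    rows = []
    for ad in ads:
        n1, n2 = nova.total_at(ad), hiseq.total_at(ad)
        row = {
            "ad": ad,
            "x_nova": nova.count(sbs_class, ad),
            "n_nova": n1,
            "x_hiseq": hiseq.count(sbs_class, ad),
            "n_hiseq": n2,
            "disregarded": disregard_ad1 and ad == 1,
            "untestable": n1 == 0 or n2 == 0,
        }
        if not row["untestable"]:
            t = two_proportion_z(row["x_nova"], n1, row["x_hiseq"], n2)
            row.update(
                p_nova=t.p_nova, p_hiseq=t.p_hiseq, p_pooled=t.p_pooled,
                diff=proportion_difference(t.p_nova, t.p_hiseq),
                z=t.z, p_value=t.p_value,
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("ad")
    table["q_value"] = np.nan
    table["significant"] = False
    family = table.index[~table["untestable"] & ~table["disregarded"]]
    if len(family):
        q, sig = fdr_qvalues(table.loc[family, "p_value"], alpha=alpha, method=fdr_method)
        table.loc[family, "q_value"] = q
        table.loc[family, "significant"] = sig
    return table
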