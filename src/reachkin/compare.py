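"""Model comparison and descriptive summaries.

AICc, Akaike weights and likelihood-ratio tests over the nested beta-GLMM
ladder, plus the per-condition descriptive table (RT, MD, TPV%) in the shape
conventional for this paradigm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .betaglmm import ModelFit
from .segment import ANTICIPATION, OMISSION, VALID_CORRECT, VALID_INCORRECT


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion.

    AICc = -2·loglik + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError("AICc needs n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized relative evidence exp(-Δ/2) / Σ exp(-Δ/2)."""
    v = np.asarray(aicc_values, dtype=float)
    if v.size < 2 or not np.all(np.isfinite(v)):
        raise ValueError("need at least two finite AICc values")
    delta = v - v.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def lrt_ladder(fits: list[ModelFit]) -> pd.DataFrame:
    """Likelihood-ratio tests between adjacent nested fits.

    chi² = 2(loglik_big − loglik_small), clipped at 0 against numerical
    jitter; Δdf is the parameter-count difference; p from the chi-square
    upper tail.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("fits must share the same data")
    rows = []
    for small, big in zip(fits[:-1], fits[1:]):
        if big.k <= small.k:
            raise ValueError("fits must be ordered small to big")
        stat = max(0.0, 2.0 * (big.loglik - small.loglik))
        ddf = big.k - small.k
        rows.append(dict(comparison=f"{small.name} vs {big.name}",
                         chi2=stat, ddf=ddf, p=float(chi2.sf(stat, ddf))))
    return pd.DataFrame(rows)


def model_comparison(fits: list[ModelFit]) -> pd.DataFrame:
    """Per-model Df, log-likelihood, AICc, Akaike weight and ladder LRT."""
    w = akaike_weights([f.aicc for f in fits])
    lrt = lrt_ladder(fits)
    rows = []
    for i, f in enumerate(fits):
        rows.append(dict(model=f.name, df=f.k, loglik=f.loglik, aicc=f.aicc,
                         aicc_weight=float(w[i]),
                         chi2=float(lrt["chi2"][i - 1]) if i > 0 else np.nan,
                         p=float(lrt["p"][i - 1]) if i > 0 else np.nan))
    return pd.DataFrame(rows)


def _stats(x: pd.Series) -> dict:
    x = x.dropna()
    if len(x) == 0:
        return dict(n=0, min=np.nan, max=np.nan, mean=np.nan, sd=np.nan)
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0  # single trial: SD 0 by convention
    return dict(n=int(len(x)), min=float(x.min()), max=float(x.max()),
                mean=float(x.mean()), sd=sd)


def descriptives(kin: pd.DataFrame) -> dict:
    """Per-condition descriptive statistics of correct trials.

    RT and MD summarize all correct responses; TPV% additionally requires the
    trial to have survived the 5–95% inclusion band.  Also returns global
    validity counts and the number of TPV exclusions.
    """
    counts = dict(
        correct=int((kin["validity"] == VALID_CORRECT).sum()),
        incorrect=int((kin["validity"] == VALID_INCORRECT).sum()),
        omission=int((kin["validity"] == OMISSION).sum()),
        anticipation=int((kin["validity"] == ANTICIPATION).sum()),
        tpv_excluded=int(((kin["validity"] == VALID_CORRECT) & (~kin["retained"])).sum()),
    )
    rows = []
    for cond, grp in kin[kin["validity"] == VALID_CORRECT].groupby("condition"):
        row = dict(condition=cond)
        for label, col in (("rt", "rt_ms"), ("md", "md_ms")):
            for key, val in _stats(grp[col]).items():
                row[f"{label}_{key}"] = val
        tpv = grp.loc[grp["retained"], "tpv_pct"]
        for key, val in _stats(tpv).items():
            row[f"tpv_{key}"] = val
        rows.append(row)
    return dict(by_condition=pd.DataFrame(rows), counts=counts)
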