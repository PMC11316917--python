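"""Multifunctionality, group–function correlations and size regressions.

The ecosystem multifunctionality index is the averaging form: each
measured function is z-scored across samples and the per-sample mean of
the z-scores is the index.  The *R value* of an organism group in a
(crop, treatment) stratum is the Spearman correlation between the
group's relative abundance and multifunctionality across that stratum's
samples; the *D value* is the treated-stratum R minus the control R.
Every "vs body size" panel is an ordinary least-squares regression on
log10 body size.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CommunityTable

logger = logging.getLogger(__name__)


@dataclass
class LinkRecord:
    group: str
    crop: str
    treatment: str
    r_value: float
    p_value: float
    per_function_rho: dict = field(default_factory=dict)


@dataclass
class DeltaRecord:
    group: str
    crop: str
    treatment: str
    d_value: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def multifunctionality(f: pd.DataFrame) -> pd.Series:
    """Averaging multifunctionality index: mean of per-function z-scores.

    Constant functions carry no information and are dropped with a
    warning; with none left the index is undefined.
    """
    if f.shape[0] < 2:
        raise ValueError("multifunctionality needs at least 2 samples")
    sd = f.std(ddof=0)
    keep = sd[sd > 0].index
    dropped = [c for c in f.columns if c not in keep]
    if dropped:
        logger.warning("dropping constant functions: %s", dropped)
    if len(keep) == 0:
        raise ValueError("all functions constant")
    z = (f[keep] - f[keep].mean()) / f[keep].std(ddof=0)
    return z.mean(axis=1)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks.

    p-value from the exact permutation distribution for n <= 9, else
    the t approximation with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero variance in ranks: rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        rxc = rx - rx.mean()
        denom = math.sqrt((rxc**2).sum() * ((ry - ry.mean()) ** 2).sum())
        perms = np.fromiter(
            itertools.chain.from_iterable(itertools.permutations(ry)),
            dtype=float,
        ).reshape(-1, n)
        rp = (perms - ry.mean()) @ rxc / denom
        p = float((np.abs(rp) >= abs(rho) - 1e-12).mean())
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, float(p)


def r_values(
    groups: CommunityTable,
    functions: pd.DataFrame,
    meta: pd.DataFrame,
    min_samples: int = 4,
) -> list[LinkRecord]:
    """Per-group R values and per-function rhos in each stratum.

    A stratum is a (crop, treatment) cell; multifunctionality is
    z-scored within the stratum.  Groups with constant abundance in a
    stratum yield no record (logged).
    """
    records = []
    for (crop, tr), sub in meta.groupby(["crop", "treatment"], sort=True):
        sids = [s for s in sub.index if s in functions.index
                and s in groups.data.index]
        if len(sids) < min_samples:
            logger.warning("stratum (%s, %s): only %d samples, skipped",
                           crop, tr, len(sids))
            continue
        mf = multifunctionality(functions.loc[sids])
        fz = functions.loc[sids]
        for g in groups.taxon_ids:
            ab = groups.data.loc[sids, g].to_numpy()
            if np.ptp(ab) == 0:
                logger.info("group %s constant in stratum (%s, %s)", g, crop, tr)
                continue
            rho, p = spearman_rho(ab, mf.to_numpy())
            per_fn = {}
            for fn in fz.columns:
                col = fz[fn].to_numpy()
                if np.ptp(col) == 0:
                    continue
                per_fn[fn] = spearman_rho(ab, col)[0]
            records.append(LinkRecord(g, crop, tr, rho, p, per_fn))
    return records


def d_values(links: list[LinkRecord], control: str = "control") -> list[DeltaRecord]:
    """D = R(treated) - R(control), per group, crop and treatment."""
    ctrl = {(l.group, l.crop): l.r_value for l in links if l.treatment == control}
    out = []
    for l in links:
        if l.treatment == control:
            continue
        key = (l.group, l.crop)
        if key not in ctrl:
            raise ValueError(f"no control R value for group {l.group!r} ({l.crop})")
        out.append(DeltaRecord(l.group, l.crop, l.treatment, l.r_value - ctrl[key]))
    return out


def size_regression(metric_per_group, group_sizes) -> RegressionResult:
    """OLS of a per-group metric on log10 body size.

    ``metric_per_group`` and ``group_sizes`` are mappings (or Series)
    keyed by group; only groups present in both with finite values
    enter.  Two-sided slope p-value from the t distribution (n-2 df).
    """
    metric = pd.Series(metric_per_group, dtype=float)
    sizes = pd.Series(group_sizes, dtype=float)
    common = metric.index.intersection(sizes.index)
    x = np.log10(sizes[common].to_numpy())
    y = metric[common].to_numpy()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 groups with finite metric and size")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 body size")
    if np.ptp(y) == 0:
        # flat response: slope 0 with no explained variance
        return RegressionResult(slope=0.0, intercept=float(y[0]), r2=0.0,
                                p_value=1.0, n=len(x))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def rho_matrix(links: list[LinkRecord], treatment: str, crop: str | None = None
               ) -> pd.DataFrame:
    """Groups × functions Spearman-rho matrix for one stratum (heat-map
    ready); with ``crop=None`` rhos are averaged over crops."""
    recs = [l for l in links if l.treatment == treatment
            and (crop is None or l.crop == crop)]
    if not recs:
        raise ValueError(f"no records for treatment {treatment!r}")
    df = pd.DataFrame([l.per_function_rho for l in recs],
                      index=[l.group for l in recs])
    if crop is None:
        df = df.groupby(level=0).mean()
    return df.sort_index()


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (opt-in for rho matrices)."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float))


def link_frame(links: list[LinkRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"group": l.group, "crop": l.crop, "treatment": l.treatment,
             "r_value": l.r_value, "p_value": l.p_value}
            for l in links
        ]
    )


def delta_frame(deltas: list[DeltaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"group": d.group, "crop": d.crop, "treatment": d.treatment,
             "d_value": d.d_value}
            for d in deltas
        ]
    )
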