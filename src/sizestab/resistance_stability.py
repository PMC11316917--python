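"""Community resistance and stability statistics.

Resistance follows the bounded Orwin–Wardle index

    RS = 1 - 2|D0| / (C0 + |D0|),    D0 = C0 - P0,

where C0 is the control value of the response variable (here an organism
group's relative abundance in the paired control sample) and P0 the
value under disturbance.  RS is 1 when the disturbed value equals the
control, 0 when the response is completely lost, and approaches -1 as
the disturbed value grows far beyond the control.

Stability descriptors:

* tolerance width — abundance-weighted standard deviation of an
  environmental covariate, i.e. how broad a slice of the gradient a
  group occupies;
* nonsynchronization — ``1 - phi`` with the community-synchrony variance
  ratio ``phi = Var(sum_i x_i) / (sum_i SD(x_i))**2`` over member taxa
  (rows) across disturbance conditions (columns).  High values mean
  member taxa respond asynchronously, buffering the aggregate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import CommunityTable

logger = logging.getLogger(__name__)


@dataclass
class ResistanceRecord:
    group: str
    crop: str
    treatment: str
    rs_mean: float
    rs_sd: float
    rs_per_pair: list[float]
    n_pairs: int
    low_n: bool = False


@dataclass
class StabilityRecord:
    group: str
    crop: str
    tolerance_width: float
    nonsynchronization: float


def orwin_wardle_rs(c0, p0):
    """Orwin–Wardle resistance index; accepts scalars or arrays.

    Undefined (NaN) where ``c0 == 0``; invariant to common rescaling of
    (c0, p0).
    """
    c0 = np.asarray(c0, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if (c0 < 0).any() or (p0 < 0).any():
        raise ValueError("c0 and p0 must be non-negative")
    d0 = np.abs(c0 - p0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = np.where(c0 > 0, 1.0 - 2.0 * d0 / (c0 + d0), np.nan)
    return rs if rs.ndim else float(rs)


def group_resistance(
    groups: CommunityTable,
    meta: pd.DataFrame,
    treatment: str,
    control: str = "control",
) -> list[ResistanceRecord]:
    """Per-group, per-crop resistance of abundance to one treatment.

    For each field with both a control and a treated sample, RS is
    computed from the group's abundance in the pair; fields whose
    control abundance is zero are skipped with a log message.  Records
    with fewer than 3 valid pairs carry a ``low_n`` flag.
    """
    records = []
    for crop, sub in meta.groupby("crop", sort=True):
        subr = sub.reset_index()
        ctrl = subr[subr["treatment"] == control].set_index("field_id")
        trt = subr[subr["treatment"] == treatment].set_index("field_id")
        fields = [f for f in trt.index if f in ctrl.index]
        skipped = set(trt.index) - set(fields)
        if skipped:
            logger.info("crop %s: %d fields missing a control pair", crop, len(skipped))
        for g in groups.taxon_ids:
            c0s = groups.data.loc[ctrl.loc[fields, "sample_id"], g].to_numpy()
            p0s = groups.data.loc[trt.loc[fields, "sample_id"], g].to_numpy()
            ok = c0s > 0
            n_skip = int((~ok).sum())
            if n_skip:
                logger.info("group %s (%s/%s): %d zero-control pairs skipped",
                            g, crop, treatment, n_skip)
            rs = orwin_wardle_rs(c0s[ok], p0s[ok])
            rs_list = np.atleast_1d(rs).tolist()
            n = len(rs_list)
            records.append(
                ResistanceRecord(
                    group=g,
                    crop=crop,
                    treatment=treatment,
                    rs_mean=float(np.mean(rs_list)) if n else float("nan"),
                    rs_sd=float(np.std(rs_list, ddof=1)) if n > 1 else float("nan"),
                    rs_per_pair=rs_list,
                    n_pairs=n,
                    low_n=n < 3,
                )
            )
            if n < 3:
                logger.warning("group %s (%s/%s): only %d valid pairs", g, crop,
                               treatment, n)
    return records


def tolerance_width(abund, env) -> float:
    """Abundance-weighted standard deviation of an environmental covariate.

    ``W = sqrt(sum_j a_j (e_j - e_bar)^2 / sum_j a_j)`` with the
    abundance-weighted mean ``e_bar``.  Scale-invariant in the
    abundances; zero iff all abundance mass sits at one value of the
    covariate.
    """
    a = np.asarray(abund, dtype=float)
    e = np.asarray(env, dtype=float)
    if a.shape != e.shape:
        raise ValueError("abundance and env vectors must align")
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    if not np.isfinite(e).all():
        raise ValueError("env covariate must be finite")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero abundance: tolerance width undefined")
    ebar = (a * e).sum() / total
    return float(np.sqrt((a * (e - ebar) ** 2).sum() / total))


def synchrony(x: np.ndarray) -> float:
    """Loreau–de Mazancourt community synchrony ``phi`` (rows = taxa)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a taxa x conditions matrix with >=2 conditions")
    sds = x.std(axis=1, ddof=0)
    if not (sds > 0).any():
        raise ValueError("all taxa constant: synchrony undefined")
    agg_var = x.sum(axis=0).var(ddof=0)
    return float(agg_var / sds.sum() ** 2)


def nonsynchronization(x: np.ndarray) -> float:
    """``1 - phi``: 0 when taxa move in perfect proportion, 1 when the
    aggregate is constant while members vary."""
    return 1.0 - synchrony(x)


def group_stability(
    taxa_rel: CommunityTable,
    ann: pd.DataFrame,
    meta: pd.DataFrame,
    env_col: str = "env_gradient",
    treatment_order: tuple | None = None,
) -> list[StabilityRecord]:
    """Tolerance width and nonsynchronization for every organism group.

    Tolerance width uses the group's summed relative abundance across
    all samples of a crop against the chosen covariate.
    Nonsynchronization is computed per field from the member-taxon ×
    ordered-treatment matrix and averaged over fields with at least one
    varying taxon.
    """
    if treatment_order is None:
        treatment_order = tuple(dict.fromkeys(meta["treatment"]))
    grouped = ann[ann["group"].notna()]
    records = []
    for crop, sub in meta.groupby("crop", sort=True):
        env = sub[env_col]
        for g in sorted(grouped["group"].unique()):
            members = [t for t in grouped[grouped["group"] == g].index
                       if t in taxa_rel.data.columns]
            if not members:
                continue
            block = taxa_rel.data.loc[sub.index, members]
            gab = block.sum(axis=1)
            try:
                w = tolerance_width(gab.to_numpy(), env.to_numpy())
            except ValueError:
                w = float("nan")
            phis = []
            for fid, fsub in sub.groupby("field_id"):
                sids = [
                    fsub.index[fsub["treatment"] == tr][0]
                    for tr in treatment_order
                    if (fsub["treatment"] == tr).any()
                ]
                if len(sids) < 2:
                    continue
                mat = taxa_rel.data.loc[sids, members].to_numpy().T
                try:
                    phis.append(nonsynchronization(mat))
                except ValueError:
                    continue
            records.append(
                StabilityRecord(
                    group=g,
                    crop=crop,
                    tolerance_width=w,
                    nonsynchronization=float(np.mean(phis)) if phis else float("nan"),
                )
            )
    return records


def resistance_frame(records: list[ResistanceRecord]) -> pd.DataFrame:
    """Long-format DataFrame of resistance records (one row per record)."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "crop": r.crop,
                "treatment": r.treatment,
                "rs_mean": r.rs_mean,
                "rs_sd": r.rs_sd,
                "n_pairs": r.n_pairs,
                "low_n": r.low_n,
            }
            for r in records
        ]
    )
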