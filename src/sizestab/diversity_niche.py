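"""Shannon diversity, Levins niche breadth and generalist/specialist calls.

Niche breadth follows Levins: for taxon *i* with proportions ``P_ij`` of
its total abundance across habitats *j*, ``B_i = 1 / sum_j P_ij**2``;
``B`` ranges from 1 (all abundance in one habitat) to the number of
habitats (perfectly even).  A habitat is a sample by default.

Generalists and specialists are called per taxon against a permutation
null that preserves sequencing effort: each permutation redistributes
the taxon's total count over samples by a multinomial draw with
probabilities proportional to the observed sample depths.  A taxon whose
observed breadth exceeds the upper empirical quantile of its null
distribution is a generalist (more even across habitats than sequencing
noise alone allows); below the lower quantile, a specialist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import CommunityTable

logger = logging.getLogger(__name__)


@dataclass
class GSLabel:
    taxon_id: str
    label: str  # generalist | specialist | neutral
    observed_b: float
    null_low: float
    null_high: float
    low_power: bool = False


@dataclass
class NicheRecord:
    group: str
    crop: str
    shannon_mean: float
    breadth_mean: float
    prop_generalists: float
    prop_specialists: float
    n_taxa: int


def shannon(abund) -> float:
    """Shannon entropy ``H = -sum p ln p`` over the nonzero entries."""
    a = np.asarray(abund, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def levins_breadth(p) -> float:
    """Levins B = 1 / sum(P_ij^2) for a normalized proportion vector."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("input must sum to 1 (caller normalizes)")
    return float(1.0 / (p**2).sum())


def _breadth_rows(counts: np.ndarray) -> np.ndarray:
    """Levins B per row of a (taxa|draws) x habitats count matrix."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals
        b = 1.0 / (p**2).sum(axis=1)
    return b


def community_breadth(t: CommunityTable, members) -> float:
    """Abundance-weighted mean Levins breadth of a group's member taxa.

    Weights are each taxon's total relative abundance; members absent
    from every sample contribute nothing.
    """
    members = [m for m in members if m in t.data.columns]
    if not members:
        raise ValueError("empty member set")
    block = t.data[members].to_numpy(dtype=float)
    totals = block.sum(axis=0)
    live = totals > 0
    if not live.any():
        raise ValueError("no member has nonzero abundance")
    b = _breadth_rows(block.T[live])
    w = totals[live] / totals[live].sum()
    return float((b * w).sum())


def classify_generalists(
    t: CommunityTable,
    n_perm: int = 999,
    ci: float = 0.95,
    seed: int | None = None,
    min_count: int = 20,
) -> list[GSLabel]:
    """Permutation-null generalist/specialist labels for every taxon.

    Taxa with total count below ``min_count`` are labeled neutral with a
    ``low_power`` flag and excluded from group proportions downstream.
    Reproducible given ``seed``.
    """
    if t.mode != "counts":
        raise ValueError("classification requires a counts-mode table")
    if t.n_samples < 2:
        raise ValueError("niche breadth is undefined for a single sample")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    counts = t.values
    depths = counts.sum(axis=1)
    probs = depths / depths.sum()
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    labels = []
    for j, taxon in enumerate(t.taxon_ids):
        col = counts[:, j]
        total = int(col.sum())
        if total < min_count:
            labels.append(GSLabel(taxon, "neutral", float("nan"),
                                  float("nan"), float("nan"), low_power=True))
            continue
        b_obs = float(levins_breadth(col / total))
        null = rng.multinomial(total, probs, size=n_perm)
        b_null = _breadth_rows(null)
        null_lo, null_hi = np.quantile(b_null, [lo_q, hi_q])
        if b_obs > null_hi:
            label = "generalist"
        elif b_obs < null_lo:
            label = "specialist"
        else:
            label = "neutral"
        labels.append(GSLabel(taxon, label, b_obs, float(null_lo), float(null_hi)))
    return labels


def group_gs_proportions(labels: list[GSLabel], ann: pd.DataFrame) -> pd.DataFrame:
    """Per-group generalist/specialist proportions over classifiable taxa.

    Low-power taxa are excluded from the denominator; groups without any
    classifiable taxon get NaN proportions.
    """
    grouped = ann[ann["group"].notna()]
    by_group: dict[str, list[GSLabel]] = {g: [] for g in sorted(grouped["group"].unique())}
    for lab in labels:
        if lab.taxon_id in grouped.index:
            by_group[grouped.at[lab.taxon_id, "group"]].append(lab)
    rows = []
    for g, labs in by_group.items():
        usable = [l for l in labs if not l.low_power]
        n = len(usable)
        if n == 0:
            logger.warning("group %r has no classifiable taxa", g)
            rows.append((g, float("nan"), float("nan"), 0))
            continue
        ng = sum(l.label == "generalist" for l in usable)
        ns = sum(l.label == "specialist" for l in usable)
        rows.append((g, ng / n, ns / n, n))
    return pd.DataFrame(
        rows, columns=["group", "prop_generalists", "prop_specialists", "n_taxa"]
    ).set_index("group")


def group_niche_summary(
    t_counts: CommunityTable,
    ann: pd.DataFrame,
    meta: pd.DataFrame,
    n_perm: int = 999,
    ci: float = 0.95,
    seed: int | None = None,
    min_count: int = 20,
    labels_by_crop: dict | None = None,
) -> list[NicheRecord]:
    """Per-group, per-crop Shannon, breadth and G/S proportions.

    Shannon is computed per sample over the group's member taxa and
    averaged over the crop's samples; breadth and the classification use
    all samples of the crop (habitat = sample within crop).  Precomputed
    labels can be passed via ``labels_by_crop`` to avoid re-running the
    permutation null.
    """
    grouped = ann[ann["group"].notna()]
    records = []
    for crop, sub in meta.groupby("crop", sort=True):
        sub_t = t_counts.subset_samples(sub.index)
        if labels_by_crop is not None and crop in labels_by_crop:
            labels = labels_by_crop[crop]
        else:
            labels = classify_generalists(sub_t, n_perm=n_perm, ci=ci, seed=seed,
                                          min_count=min_count)
        props = group_gs_proportions(labels, ann)
        for g in sorted(grouped["group"].unique()):
            members = [m for m in grouped[grouped["group"] == g].index
                       if m in sub_t.data.columns]
            if not members:
                continue
            block = sub_t.data[members].to_numpy(dtype=float)
            hs = [shannon(row) for row in block if row.sum() > 0]
            try:
                breadth = community_breadth(sub_t, members)
            except ValueError:
                breadth = float("nan")
            records.append(
                NicheRecord(
                    group=g,
                    crop=crop,
                    shannon_mean=float(np.mean(hs)) if hs else float("nan"),
                    breadth_mean=breadth,
                    prop_generalists=float(props.at[g, "prop_generalists"]),
                    prop_specialists=float(props.at[g, "prop_specialists"]),
                    n_taxa=int(props.at[g, "n_taxa"]),
                )
            )
    return records


def gs_label_frame(labels: list[GSLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_id": l.taxon_id,
                "label": l.label,
                "observed_b": l.observed_b,
                "null_low": l.null_low,
                "null_high": l.null_high,
                "low_power": l.low_power,
            }
            for l in labels
        ]
    ).set_index("taxon_id")
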