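"""Tabular I/O and the core data model.

The exchange object throughout the package is :class:`CommunityTable`, a
samples × taxa abundance matrix in either ``counts`` or ``relative`` mode.
Companion tables are plain :class:`pandas.DataFrame` objects with fixed
column contracts:

* annotation — indexed by ``taxon_id`` with columns ``domain``
  (bacteria/fungi/protist), ``group`` (one of the configured organism
  groups; empty for taxa outside every group) and ``body_size_um``
  (characteristic linear dimension, µm).
* metadata — indexed by ``sample_id`` with columns ``field_id``, ``crop``,
  ``treatment`` plus any number of ``env_*`` covariate columns.  Every
  disturbed sample must have a control sample from the same field and crop
  (the pairing requirement behind the resistance index).
* functions — indexed by ``sample_id``, one numeric column per measured
  soil function.

TSV is the canonical on-disk format (samples in rows, first column is the
sample id); BIOM is accepted as a secondary community-table format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAINS = ("bacteria", "fungi", "protist")
CROPS = ("maize", "rice")

_REL_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input table violates the data-model contract."""


@dataclass
class CommunityTable:
    """Samples × taxa abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample ids as index and taxon ids as columns.
        Entries are non-negative counts or proportions.
    mode
        ``"counts"`` or ``"relative"``.  In relative mode every row must
        sum to 1 (all-zero rows are disallowed).
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate taxon ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(self.data)
            raise ValidationError(f"non-numeric cell at {bad}")
        if np.isnan(values).any():
            bad = _first_offender(self.data, np.isnan(values))
            raise ValidationError(f"missing value at {bad}")
        if (values < 0).any():
            bad = _first_offender(self.data, values < 0)
            raise ValidationError(f"negative abundance at {bad}")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            off = np.abs(sums - 1.0) > _REL_TOL
            if off.any():
                sid = self.data.index[int(np.flatnonzero(off)[0])]
                raise ValidationError(
                    f"relative-mode row {sid!r} sums to {sums[off][0]!r}, not 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def subset_taxa(self, taxa) -> "CommunityTable":
        taxa = [t for t in taxa if t in self.data.columns]
        return CommunityTable(self.data[taxa], mode=self.mode)

    def subset_samples(self, samples) -> "CommunityTable":
        return CommunityTable(self.data.loc[list(samples)], mode=self.mode)


def _first_offender(df: pd.DataFrame, mask: np.ndarray) -> str:
    i, j = np.argwhere(mask)[0]
    return f"(sample={df.index[i]!r}, taxon={df.columns[j]!r})"


def _first_non_numeric(df: pd.DataFrame) -> str:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = coerced.isna() & ~raw_na
        if bad.any():
            return f"(sample={df.index[bad.argmax()]!r}, taxon={col!r})"
    return "(unknown)"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_community(path, format: str = "tsv") -> CommunityTable:
    """Read a community table (counts mode) from TSV or BIOM.

    TSV dialect: taxa as columns, samples as rows, first column the
    sample id.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # malformed header / ragged rows
            raise ValidationError(f"malformed community table {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise ValidationError(f"community table {path} has no taxon columns")
        return CommunityTable(df, mode="counts")
    if format == "biom":
        import biom  # ships with scikit-bio

        table = biom.load_table(str(path))
        df = table.to_dataframe(dense=True).T  # biom stores taxa × samples
        return CommunityTable(df.astype(float), mode="counts")
    raise ValueError(f"unknown format {format!r}")


def write_community(t: CommunityTable, path) -> None:
    t.data.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path) -> pd.DataFrame:
    """Read a taxon annotation TSV (taxon_id, domain, group, body_size_um)."""
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str, "group": str})
    required = {"taxon_id", "domain", "group", "body_size_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation missing columns {sorted(missing)}")
    df = df.set_index("taxon_id")
    return validate_annotation(df)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if ann.index.has_duplicates:
        raise ValidationError("duplicate taxon ids in annotation")
    bad_dom = set(ann["domain"]) - set(DOMAINS)
    if bad_dom:
        raise ValidationError(f"unknown domains {sorted(bad_dom)}")
    grouped = ann["group"].notna()
    sizes = ann.loc[grouped, "body_size_um"]
    if (sizes <= 0).any() or not np.isfinite(np.log10(sizes.to_numpy())).all():
        raise ValidationError("body_size_um must be positive and finite")
    # every group maps to exactly one domain and one size
    per_group = ann.loc[grouped].groupby("group")[["domain", "body_size_um"]].nunique()
    conflict = per_group[(per_group > 1).any(axis=1)]
    if len(conflict):
        raise ValidationError(
            f"groups with inconsistent domain/size: {list(conflict.index)}"
        )
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "field_id": str})
    required = {"sample_id", "field_id", "crop", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns {sorted(missing)}")
    df = df.set_index("sample_id")
    return validate_metadata(df)


def validate_metadata(meta: pd.DataFrame, control: str = "control") -> pd.DataFrame:
    if meta.index.has_duplicates:
        raise ValidationError("duplicate sample ids in metadata")
    dup = meta.groupby(["crop", "field_id", "treatment"]).size()
    if (dup > 1).any():
        key = dup[dup > 1].index[0]
        raise ValidationError(f"(field, treatment) occurs more than once: {key}")
    controls = meta[meta["treatment"] == control]
    have = set(zip(controls["crop"], controls["field_id"]))
    need = set(zip(meta["crop"], meta["field_id"]))
    orphans = need - have
    if orphans:
        raise ValidationError(
            f"fields lacking a {control!r} sample: {sorted(orphans)[:5]}"
        )
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_functions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValidationError("function table has no function columns")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("function table has non-numeric cells")
    return df


def write_functions(f: pd.DataFrame, path) -> None:
    f.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def to_relative(t: CommunityTable) -> CommunityTable:
    """Convert a counts-mode table to per-sample relative abundance."""
    if t.mode != "counts":
        raise ValidationError("to_relative expects a counts-mode table")
    sums = t.values.sum(axis=1)
    if (sums <= 0).any():
        sid = t.data.index[int(np.argmin(sums > 0))]
        raise ValidationError(f"sample {sid!r} has zero total count")
    return CommunityTable(t.data.div(sums, axis=0), mode="relative")


def to_domain_relative(t: CommunityTable, ann: pd.DataFrame) -> CommunityTable:
    """Renormalize taxon proportions within each domain, per sample.

    16S and 18S libraries are sequenced separately, so proportions are
    only comparable within a marker; this puts each domain's taxa on its
    own simplex.  Taxa absent from the annotation are dropped.
    """
    if t.mode != "relative":
        raise ValidationError("to_domain_relative expects a relative-mode table")
    known = [c for c in t.data.columns if c in ann.index]
    out = {}
    for domain in DOMAINS:
        cols = [c for c in known if ann.at[c, "domain"] == domain]
        if not cols:
            continue
        block = t.data[cols]
        tot = block.sum(axis=1)
        if (tot <= 0).any():
            sid = block.index[int(np.argmin(tot.to_numpy() > 0))]
            raise ValidationError(f"sample {sid!r} has zero {domain} abundance")
        out[domain] = block.div(tot, axis=0)
    if not out:
        raise ValidationError("no annotated taxa")
    df = pd.concat(out.values(), axis=1)
    # rows now sum to the number of represented domains; flag as counts-free
    df = df / len(out)
    return CommunityTable(df, mode="relative")


def aggregate_groups(t: CommunityTable, ann: pd.DataFrame) -> CommunityTable:
    """Sum taxon proportions into organism groups.

    Unannotated (or ungrouped) taxa are dropped with a logged count, so
    group rows need not sum to 1.  Mass is conserved over the annotated
    taxa: per sample, the group sums equal the summed member proportions.
    """
    if t.mode != "relative":
        raise ValidationError("aggregate_groups expects a relative-mode table")
    grouped = ann[ann["group"].notna()]
    member = {c: grouped.at[c, "group"] for c in t.data.columns if c in grouped.index}
    dropped = t.n_taxa - len(member)
    if dropped:
        logger.info("aggregate_groups: dropped %d unannotated/ungrouped taxa", dropped)
    if not member:
        raise ValidationError("no annotated taxa to aggregate")
    groups = sorted(grouped["group"].unique())
    out = pd.DataFrame(0.0, index=t.data.index, columns=groups)
    agg = t.data[list(member)].T.groupby(pd.Series(member)).sum().T
    out[agg.columns] = agg
    empty = [g for g in groups if g not in agg.columns or out[g].sum() == 0]
    for g in empty:
        logger.warning("group %r has no member taxa in the table", g)
    return CommunityTable(out, mode="counts")  # not a simplex; treat as raw scores


def group_table(ann: pd.DataFrame) -> pd.DataFrame:
    """Collapse an annotation to one row per group (domain, body_size_um)."""
    grouped = ann[ann["group"].notna()]
    gt = (
        grouped.groupby("group")[["domain", "body_size_um"]]
        .first()
        .sort_index()
    )
    return gt


def coverage_filter(
    t: CommunityTable, ann: pd.DataFrame, threshold: float = 0.6
) -> tuple[list[str], dict]:
    """Sequence-coverage group-selection filter.

    Per domain, coverage is the mean relative abundance captured by the
    configured groups divided by the domain's total mean relative
    abundance.  Returns the selected group list and a per-domain report
    ``{domain: {"coverage": float|None, "passed": bool|None}}``.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if t.mode != "relative":
        raise ValidationError("coverage_filter expects a relative-mode table")
    known = [c for c in t.data.columns if c in ann.index]
    mean_ab = t.data[known].mean(axis=0)
    report = {}
    for domain in DOMAINS:
        cols = [c for c in known if ann.at[c, "domain"] == domain]
        if not cols:
            report[domain] = {"coverage": None, "passed": None}
            logger.warning("coverage_filter: no taxa for domain %r", domain)
            continue
        total = mean_ab[cols].sum()
        sel = [c for c in cols if pd.notna(ann.at[c, "group"])]
        cov = float(mean_ab[sel].sum() / total) if total > 0 else None
        report[domain] = {
            "coverage": cov,
            "passed": (cov >= threshold) if cov is not None else None,
        }
    selected = sorted(ann.loc[ann["group"].notna(), "group"].unique())
    return selected, report


def rarefy(t: CommunityTable, depth: int, seed: int | None = None) -> CommunityTable:
    """Opt-in rarefaction: subsample each sample to ``depth`` reads.

    Samples below ``depth`` are dropped with a log message.  Not used by
    the default pipeline (relative abundance is the normalization).
    """
    if t.mode != "counts":
        raise ValidationError("rarefy expects a counts-mode table")
    rng = np.random.default_rng(seed)
    keep, rows = [], []
    for sid, row in zip(t.data.index, t.values):
        total = int(row.sum())
        if total < depth:
            logger.info("rarefy: dropping %r (depth %d < %d)", sid, total, depth)
            continue
        sub = rng.multivariate_hypergeometric(row.astype(int), depth)
        keep.append(sid)
        rows.append(sub)
    if not keep:
        raise ValidationError("rarefy: no sample reaches the requested depth")
    return CommunityTable(
        pd.DataFrame(rows, index=keep, columns=t.data.columns), mode="counts"
    )


# ---------------------------------------------------------------------------
# default organism-group lookup
# ---------------------------------------------------------------------------

def default_group_table() -> pd.DataFrame:
    """Built-in 24-group lookup (12 bacterial, 7 fungal, 5 protistan).

    Body sizes are synthetic fixture values on a literature-plausible
    scale (µm, characteristic linear dimension), intended for simulation
    and testing; analyses of real data should supply a curated lookup.
    """
    rows = [
        # group, domain, body_size_um
        ("Actinobacteria", "bacteria", 0.6),
        ("Alphaproteobacteria", "bacteria", 0.9),
        ("Betaproteobacteria", "bacteria", 0.8),
        ("Gammaproteobacteria", "bacteria", 1.2),
        ("Deltaproteobacteria", "bacteria", 1.0),
        ("Firmicutes", "bacteria", 1.1),
        ("Bacteroidetes", "bacteria", 0.7),
        ("Acidobacteria", "bacteria", 0.8),
        ("Chloroflexi", "bacteria", 1.3),
        ("Planctomycetes", "bacteria", 1.5),
        ("Verrucomicrobia", "bacteria", 0.9),
        ("Nitrospirae", "bacteria", 1.0),
        ("Ascomycota", "fungi", 5.0),
        ("Basidiomycota", "fungi", 8.0),
        ("Mortierellomycota", "fungi", 6.0),
        ("Chytridiomycota", "fungi", 3.5),
        ("Glomeromycota", "fungi", 12.0),
        ("Rozellomycota", "fungi", 2.5),
        ("Zoopagomycota", "fungi", 7.0),
        ("Cercozoa", "protist", 20.0),
        ("Ciliophora", "protist", 120.0),
        ("Amoebozoa", "protist", 50.0),
        ("Ochrophyta", "protist", 30.0),
        ("Apicomplexa", "protist", 15.0),
    ]
    df = pd.DataFrame(rows, columns=["group", "domain", "body_size_um"])
    return df.set_index("group")
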