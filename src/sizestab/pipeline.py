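"""End-to-end orchestration: validate → resistance → niche → assembly → link.

:func:`analyze_bundle` is the in-memory pipeline over a data bundle
(community, annotation, metadata, functions); :func:`run_all` wraps it
with file I/O, stage TSVs, and a JSON manifest recording the config
hash, seed streams and output checksums, so reruns with identical
config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly_models import group_assembly
from .diversity_niche import (
    classify_generalists,
    group_niche_summary,
    gs_label_frame,
)
from .function_link import (
    RegressionResult,
    d_values,
    delta_frame,
    link_frame,
    r_values,
    rho_matrix,
    size_regression,
)
from .io_tables import (
    aggregate_groups,
    coverage_filter,
    group_table,
    read_annotation,
    read_community,
    read_functions,
    read_metadata,
    to_domain_relative,
    to_relative,
    validate_metadata,
    write_annotation,
    write_community,
    write_functions,
    write_metadata,
)
from .resistance_stability import (
    group_resistance,
    group_stability,
    resistance_frame,
)
from .synthetic_community import Bundle, SynthConfig, generate_bundle

logger = logging.getLogger(__name__)

STAGES = ("validate", "resistance", "niche", "assembly", "link")


@dataclass
class PipelineConfig:
    synthesize: bool = True
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    community: str | None = None
    annotation: str | None = None
    metadata: str | None = None
    functions: str | None = None
    coverage_threshold: float = 0.6
    control: str = "control"
    n_perm: int = 999
    n_null: int = 200
    ci: float = 0.95
    min_count: int = 20
    metric: str = "bray"
    stages: tuple = STAGES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResults:
    coverage: dict
    resistance: pd.DataFrame
    stability: pd.DataFrame
    niche: pd.DataFrame
    gs_labels: pd.DataFrame
    links: list
    deltas: list
    regressions: dict  # name -> RegressionResult
    assembly: pd.DataFrame | None = None


def load_bundle(cfg: PipelineConfig) -> Bundle:
    if cfg.synthesize:
        synth_cfg = SynthConfig(**{**cfg.synth, "seed": cfg.synth.get("seed", cfg.seed)})
        return generate_bundle(synth_cfg)
    missing = [n for n in ("community", "annotation", "metadata")
               if getattr(cfg, n) is None]
    if missing:
        raise ValueError(f"missing input paths: {missing}")
    community = read_community(cfg.community)
    annotation = read_annotation(cfg.annotation)
    metadata = validate_metadata(read_metadata(cfg.metadata), control=cfg.control)
    functions = read_functions(cfg.functions) if cfg.functions else None
    return Bundle(community, annotation, metadata, functions, None)


def analyze_bundle(
    bundle: Bundle,
    cfg: PipelineConfig | None = None,
) -> PipelineResults:
    """Run every analysis stage on an in-memory bundle."""
    cfg = cfg or PipelineConfig()
    community, ann, meta, functions = (
        bundle.community, bundle.annotation, bundle.metadata, bundle.functions,
    )
    if "link" in cfg.stages and functions is None:
        raise ValueError("function_link stage enabled but no function table given")
    ss = np.random.SeedSequence(cfg.seed)
    seed_perm, seed_null = ss.spawn(2)

    rel = to_relative(community)
    _, coverage = coverage_filter(rel, ann, threshold=cfg.coverage_threshold)
    dom_rel = to_domain_relative(rel, ann)
    groups_tab = aggregate_groups(dom_rel, ann)
    sizes = group_table(ann)["body_size_um"]

    treatments = [t for t in dict.fromkeys(meta["treatment"]) if t != cfg.control]

    # --- resistance & stability --------------------------------------
    resistance = pd.DataFrame(columns=["group", "crop", "treatment", "rs_mean",
                                       "rs_sd", "n_pairs", "low_n"])
    stability = pd.DataFrame()
    if "resistance" in cfg.stages:
        res_records = []
        for tr in treatments:
            res_records.extend(
                group_resistance(groups_tab, meta, tr, control=cfg.control)
            )
        resistance = resistance_frame(res_records)
        env_cols = [c for c in meta.columns if c.startswith("env")]
        stability = pd.DataFrame(
            [dataclasses.asdict(r) for r in group_stability(
                dom_rel, ann, meta,
                env_col=env_cols[0] if env_cols else meta.columns[-1],
                treatment_order=tuple(dict.fromkeys(meta["treatment"])),
            )]
        )

    # --- diversity / niche / generalists -----------------------------
    niche, gs_labels = pd.DataFrame(), pd.DataFrame()
    if "niche" in cfg.stages:
        labels_by_crop, gs_frames = {}, []
        for crop, sub in meta.groupby("crop", sort=True):
            labels = classify_generalists(
                community.subset_samples(sub.index), n_perm=cfg.n_perm, ci=cfg.ci,
                seed=seed_perm, min_count=cfg.min_count,
            )
            labels_by_crop[crop] = labels
            frame = gs_label_frame(labels)
            frame.insert(0, "crop", crop)
            gs_frames.append(frame)
        gs_labels = pd.concat(gs_frames)
        niche_records = group_niche_summary(
            community, ann, meta, min_count=cfg.min_count,
            labels_by_crop=labels_by_crop,
        )
        niche = pd.DataFrame([dataclasses.asdict(r) for r in niche_records])

    # --- assembly ------------------------------------------------------
    assembly = None
    if "assembly" in cfg.stages:
        assembly = group_assembly(
            community, ann, meta, n_null=cfg.n_null, metric=cfg.metric,
            seed=seed_null.generate_state(1)[0] % (2**31),
        )

    # --- function linkage ---------------------------------------------
    links, deltas = [], []
    if "link" in cfg.stages:
        if functions is None:
            raise ValueError("function_link stage enabled but no function table given")
        links = r_values(groups_tab, functions, meta)
        deltas = d_values(links, control=cfg.control)

    regressions = headline_regressions(
        resistance, niche, links, deltas, sizes, control=cfg.control
    )
    return PipelineResults(
        coverage=coverage,
        resistance=resistance,
        stability=stability,
        niche=niche,
        gs_labels=gs_labels,
        links=links,
        deltas=deltas,
        regressions=regressions,
        assembly=assembly,
    )


def headline_regressions(
    resistance: pd.DataFrame,
    niche: pd.DataFrame,
    links: list,
    deltas: list,
    sizes: pd.Series,
    control: str = "control",
) -> dict:
    """The six body-size regressions behind the headline panels.

    Per-group metrics are averaged over crops (and, for resistance and
    D values, over disturbance treatments) before regressing on log10
    body size.
    """
    out: dict[str, RegressionResult] = {}
    if len(resistance):
        rs = resistance.groupby("group")["rs_mean"].mean()
        out["resistance"] = size_regression(rs, sizes)
    if len(niche):
        per_group = niche.groupby("group")
        out["shannon"] = size_regression(per_group["shannon_mean"].mean(), sizes)
        out["breadth"] = size_regression(per_group["breadth_mean"].mean(), sizes)
        out["generalists"] = size_regression(
            per_group["prop_generalists"].mean(), sizes
        )
    if links:
        lf = link_frame(links)
        ctrl = lf[lf["treatment"] == control].groupby("group")["r_value"].mean()
        out["r_value_control"] = size_regression(ctrl, sizes)
    if deltas:
        df = delta_frame(deltas)
        out["d_value"] = size_regression(df.groupby("group")["d_value"].mean(), sizes)
    return out


def regressions_frame(regressions: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"metric": name, **dataclasses.asdict(r)}
            for name, r in regressions.items()
        ]
    ).set_index("metric")


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Execute all configured stages, write outputs and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle(cfg)
    if cfg.synthesize:
        write_community(bundle.community, outdir / "community.tsv")
        write_annotation(bundle.annotation, outdir / "annotation.tsv")
        write_metadata(bundle.metadata, outdir / "metadata.tsv")
        write_functions(bundle.functions, outdir / "functions.tsv")
        bundle.truth.to_json(outdir / "truth.json")

    try:
        results = analyze_bundle(bundle, cfg)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    files = {}
    with open(outdir / "validation.json", "w") as fh:
        json.dump(
            {
                "n_samples": bundle.community.n_samples,
                "n_taxa": bundle.community.n_taxa,
                "coverage": results.coverage,
                "coverage_threshold": cfg.coverage_threshold,
            },
            fh, indent=1,
        )
    files["validation"] = "validation.json"

    results.resistance.to_csv(outdir / "resistance.tsv", sep="\t", index=False)
    results.stability.to_csv(outdir / "stability.tsv", sep="\t", index=False)
    results.niche.to_csv(outdir / "niche.tsv", sep="\t", index=False)
    results.gs_labels.to_csv(outdir / "gs_labels.tsv", sep="\t")
    files.update(resistance="resistance.tsv", stability="stability.tsv",
                 niche="niche.tsv", gs_labels="gs_labels.tsv")
    if results.assembly is not None:
        results.assembly.to_csv(outdir / "assembly.tsv", sep="\t", index=False)
        files["assembly"] = "assembly.tsv"
    if results.links:
        link_frame(results.links).to_csv(outdir / "links.tsv", sep="\t", index=False)
        delta_frame(results.deltas).to_csv(outdir / "d_values.tsv", sep="\t",
                                           index=False)
        rho_matrix(results.links, cfg.control).to_csv(
            outdir / "rho_control.tsv", sep="\t"
        )
        files.update(links="links.tsv", d_values="d_values.tsv",
                     rho_control="rho_control.tsv")
    regressions_frame(results.regressions).to_csv(outdir / "regressions.tsv",
                                                  sep="\t")
    files["regressions"] = "regressions.tsv"

    manifest = {
        "version": __version__,
        "config_hash": cfg.content_hash(),
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "outputs": {
            name: hashlib.sha256((outdir / fn).read_bytes()).hexdigest()
            for name, fn in files.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
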