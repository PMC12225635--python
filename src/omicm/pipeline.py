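"""End-to-end pipeline: simulate → fit → features → stats → embed/classify.

Configuration comes from a strict YAML (unknown keys are rejected by
name), every random stage takes an explicit seed, and each run writes a
manifest with per-stage counts so cells in = cells out + cells excluded
can be audited afterwards.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .acquisition import FAD, NADH, AcquisitionSpec, gaussian_irf
from .cellquant import aggregate_cells
from .decay import FitOptions, fit_image
from .multivar import train_classifier, umap_embed
from .simulate import (
    CohortDesign,
    GroupDesign,
    MixtureDistribution,
    TruthDistribution,
    sample_cohort,
)
from .stats import glass_delta, summarize_groups, ttest_unpaired

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "compare_to_reference"]

_TOP_KEYS = {"acquisition", "simulate", "fit", "aggregate", "stats",
             "classify", "embed", "output_dir", "write_cubes"}
_ACQ_KEYS = {"width", "height", "n_bins", "window_ns", "irf_fwhm_ps"}
_SIM_KEYS = {"seed", "groups", "cell_radius_px"}
_GROUP_KEYS = {"label", "n_fields", "n_cells_per_field", "meta", "nadh", "fad"}
_FIT_KEYS = {"min_photons", "fit_shift", "objective"}
_AGG_KEYS = {"min_pixels"}
_STATS_KEYS = {"variable", "group_by", "reference", "alpha"}
_CLS_KEYS = {"enabled", "label_column", "positive_label", "test_fraction", "seed"}
_EMB_KEYS = {"enabled", "seed", "n_neighbors", "min_dist", "metric"}
_DIST_KEYS = {f.name for f in dataclasses.fields(TruthDistribution)} | {
    "mixture_weights", "components"
}


def _check_keys(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(
            f"unknown configuration key(s) in {context}: {sorted(unknown)}"
        )


def _parse_distribution(d: dict, context: str):
    _check_keys(d, _DIST_KEYS, context)
    if "components" in d or "mixture_weights" in d:
        comps = [
            TruthDistribution(**{k: _tupled(k, v) for k, v in c.items()})
            for c in d.get("components", [])
        ]
        return MixtureDistribution(
            components=tuple(comps), weights=tuple(d["mixture_weights"])
        )
    return TruthDistribution(**{k: _tupled(k, v) for k, v in d.items()})


def _tupled(key: str, value):
    return tuple(value) if key.endswith("_range") else value


@dataclass
class PipelineConfig:
    acquisition: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    aggregate: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    embed: dict = field(default_factory=dict)
    output_dir: str = "omicm_run"
    write_cubes: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys(raw, _TOP_KEYS, "top level")
        _check_keys(raw.get("acquisition", {}), _ACQ_KEYS, "acquisition")
        _check_keys(raw.get("simulate", {}), _SIM_KEYS, "simulate")
        for g in raw.get("simulate", {}).get("groups", []):
            _check_keys(g, _GROUP_KEYS, f"simulate.groups[{g.get('label')}]")
        _check_keys(raw.get("fit", {}), _FIT_KEYS, "fit")
        _check_keys(raw.get("aggregate", {}), _AGG_KEYS, "aggregate")
        _check_keys(raw.get("stats", {}), _STATS_KEYS, "stats")
        _check_keys(raw.get("classify", {}), _CLS_KEYS, "classify")
        _check_keys(raw.get("embed", {}), _EMB_KEYS, "embed")
        return cls(**raw)

    def acquisition_spec(self, channel: str = NADH) -> AcquisitionSpec:
        return AcquisitionSpec(channel=channel, **self.acquisition)

    def cohort_design(self) -> CohortDesign:
        sim = self.simulate
        groups = []
        for g in sim.get("groups", []):
            dists = {}
            for ch_key, ch in (("nadh", NADH), ("fad", FAD)):
                if ch_key in g:
                    dists[ch] = _parse_distribution(
                        g[ch_key], f"group {g.get('label')!r} {ch_key}"
                    )
            groups.append(GroupDesign(
                label=g["label"],
                distributions=dists,
                n_fields=g.get("n_fields", 1),
                n_cells_per_field=g.get("n_cells_per_field", 10),
                meta=g.get("meta", {}),
            ))
        return CohortDesign(groups=tuple(groups), seed=sim.get("seed", 0))

    def fit_options(self) -> FitOptions:
        return FitOptions(**self.fit)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(raw)


def compare_to_reference(
    table: pd.DataFrame,
    variable: str,
    group_by: str,
    reference,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tidy per-group summary with Glass's Δ and t-test vs a reference group."""
    summary = summarize_groups(table, variable, group_by)
    ref_values = table.loc[table[group_by] == reference, variable].to_numpy()
    rows = []
    for _, srow in summary.iterrows():
        label = srow[group_by]
        rec = {
            "group": label, "n": int(srow["n"]),
            "mean": srow["mean"], "sd": srow["sd"],
            "delta_vs_reference": np.nan, "category": "",
            "t": np.nan, "p": np.nan,
        }
        if label != reference and ref_values.size >= 2:
            values = table.loc[table[group_by] == label, variable].to_numpy()
            es = glass_delta(ref_values, values, str(reference), str(label))
            rec["delta_vs_reference"] = es.signed_delta
            rec["category"] = es.category
            if values.size >= 2:
                tt = ttest_unpaired(ref_values, values, alpha=alpha)
                rec["t"], rec["p"] = tt.statistic, tt.p_value
        rows.append(rec)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    Outputs (feature CSV, stats CSV, classifier JSON, embedding CSV,
    manifest JSON) land under ``config.output_dir``.  Identical config ⇒
    identical outputs.
    """
    from . import io as omio

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": f"omicm {_pkg_version}",
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    design = config.cohort_design()
    base_spec = config.acquisition_spec()
    mask_kwargs = {}
    if "cell_radius_px" in config.simulate:
        mask_kwargs["cell_radius_px"] = config.simulate["cell_radius_px"]
    fields = sample_cohort(design, base_spec, mask_kwargs=mask_kwargs)
    n_truth_cells = sum(len(f.truth.cells) for f in fields)
    manifest["stages"]["simulate"] = {
        "n_fields": len(fields),
        "n_cells": n_truth_cells,
        "seed": design.seed,
    }
    logger.info("simulated %d fields, %d cells", len(fields), n_truth_cells)

    truth_frames = [f.truth.to_frame() for f in fields]
    if truth_frames:
        pd.concat(truth_frames, ignore_index=True).to_csv(
            out / "ground_truth.csv", index=False
        )

    opts = config.fit_options()
    min_pixels = config.aggregate.get("min_pixels", 10)
    tables = []
    n_fit_pixels = 0
    n_excluded = 0
    group_meta = {g.label: g.meta for g in design.groups}
    for f in fields:
        pmaps = {}
        for ch, cube in f.cubes.items():
            if config.write_cubes:
                omio.write_decay_tiff(cube, out / f"{f.field_id}_{ch}.tif")
            irf = gaussian_irf(cube.spec.irf_fwhm_ps, cube.spec)
            pmaps[ch] = fit_image(cube, irf, opts, pixel_mask=f.masks.whole_cell)
            n_fit_pixels += int(pmaps[ch].valid.sum())
        omio.write_maskset(f.masks, out / "masks", prefix=f"{f.field_id}_")
        meta = {"field": f.field_id, **group_meta.get(f.group, {})}
        meta.setdefault("line", f.group)
        tab = aggregate_cells(
            pmaps[NADH], pmaps[FAD], f.masks, meta, min_pixels=min_pixels
        )
        tab.insert(5, "group", f.group)
        n_excluded += tab.attrs.get("n_excluded", 0)
        tables.append(tab)
    features = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    )
    features.to_csv(out / "features.csv", index=False)
    manifest["stages"]["fit"] = {"n_valid_pixels": n_fit_pixels,
                                 "min_photons": opts.min_photons}
    manifest["stages"]["features"] = {
        "n_cells_in": n_truth_cells,
        "n_cells_emitted": len(features),
        "n_cells_excluded": n_excluded,
    }

    stats_cfg = config.stats
    if stats_cfg and len(features):
        stats_table = compare_to_reference(
            features,
            stats_cfg.get("variable", "nadh_tm"),
            stats_cfg.get("group_by", "group"),
            stats_cfg.get("reference", design.groups[0].label),
            alpha=stats_cfg.get("alpha", 0.05),
        )
        stats_table.to_csv(out / "stats.csv", index=False)
        manifest["stages"]["stats"] = {"n_groups": len(stats_table)}

    cls_cfg = config.classify
    if cls_cfg.get("enabled", False) and len(features):
        report = train_classifier(
            features,
            label_column=cls_cfg.get("label_column", "group"),
            positive_label=cls_cfg.get("positive_label"),
            test_fraction=cls_cfg.get("test_fraction", 0.3),
            seed=cls_cfg.get("seed", 0),
        )
        (out / "classifier.json").write_text(json.dumps(report.to_dict(), indent=1))
        manifest["stages"]["classify"] = {"auc": report.auc, "seed": report.seed}

    emb_cfg = config.embed
    if emb_cfg.get("enabled", False) and len(features):
        params = {k: v for k, v in emb_cfg.items() if k not in ("enabled", "seed")}
        emb = umap_embed(features, params=params, seed=emb_cfg.get("seed", 0))
        coords = pd.DataFrame(emb.coordinates, columns=["umap1", "umap2"])
        coords.to_csv(out / "embedding.csv", index=False)
        manifest["stages"]["embed"] = {"n_rows": len(coords), "seed": emb.seed}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
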