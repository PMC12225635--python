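"""Synthetic TCSPC lifetime-image data with known ground truth.

Emulates what the two-photon FLIM instrument and segmentation deliver:
elliptical cells with interior nuclei laid out in a field of view,
per-pixel photon-count decays formed by convolving each cell's
bi-exponential decay with a Gaussian IRF and Poisson-sampling, and cohort
designs in which groups of fields differ in their lifetime-parameter
distributions (maturation-day shifts, cell-line differences, optional
bimodal mixtures).  Every operation is a pure function of its arguments
including the seed, and the generated ground truth is the oracle for
parameter-recovery tests downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .acquisition import CHANNELS, FAD, NADH, AcquisitionSpec, IRF, gaussian_irf
from .cellquant import MaskSet
from .decay import DecayCube, model_decay, tau_mean

__all__ = [
    "DecayTruth",
    "TruthDistribution",
    "MixtureDistribution",
    "GroupDesign",
    "CohortDesign",
    "SimGroundTruth",
    "FieldSim",
    "make_cell_masks",
    "render_decay_cube",
    "sample_cohort",
    "sample_feature_table",
    "default_group",
]


@dataclass(frozen=True)
class DecayTruth:
    """True decay parameters of one cell in one channel.

    ``amplitude`` is the expected total signal photons over the cell's
    whole-cell region; ``background_rate`` is expected background photons
    per bin per pixel (the C term of the decay model).
    """

    tau1_ns: float
    tau2_ns: float
    alpha1: float
    amplitude: float = 50_000.0
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.tau1_ns <= self.tau2_ns:
            raise ValueError("need 0 < tau1_ns <= tau2_ns")
        if not 0.0 <= self.alpha1 <= 1.0:
            raise ValueError("alpha1 must lie in [0, 1]")
        if self.amplitude < 0 or self.background_rate < 0:
            raise ValueError("amplitude and background_rate must be >= 0")

    @property
    def alpha2(self) -> float:
        return 1.0 - self.alpha1

    @property
    def tau_m_ns(self) -> float:
        return tau_mean(self.alpha1, self.tau1_ns, self.tau2_ns)


@dataclass(frozen=True)
class TruthDistribution:
    """Independent truncated-normal sampling of per-cell decay parameters.

    Defaults follow literature-typical autofluorescence ranges: short
    (free NAD(P)H / bound FAD) lifetimes of a few hundred ps, long
    components of a few ns.
    """

    tau1_mean: float = 0.4
    tau1_sd: float = 0.05
    tau1_range: tuple[float, float] = (0.2, 0.8)
    tau2_mean: float = 2.5
    tau2_sd: float = 0.3
    tau2_range: tuple[float, float] = (1.5, 4.0)
    alpha1_mean: float = 0.7
    alpha1_sd: float = 0.05
    alpha1_range: tuple[float, float] = (0.0, 1.0)
    amplitude: float = 50_000.0
    background_rate: float = 0.0

    def sample(self, rng: np.random.Generator) -> DecayTruth:
        tau1 = float(np.clip(rng.normal(self.tau1_mean, self.tau1_sd), *self.tau1_range))
        tau2 = float(np.clip(rng.normal(self.tau2_mean, self.tau2_sd), *self.tau2_range))
        if tau2 < tau1:
            tau1, tau2 = tau2, tau1
        a1 = float(np.clip(rng.normal(self.alpha1_mean, self.alpha1_sd), *self.alpha1_range))
        return DecayTruth(tau1, tau2, a1, self.amplitude, self.background_rate)

    def shifted(self, **deltas: float) -> "TruthDistribution":
        """New distribution with means offset (e.g. a maturation shift)."""
        kwargs = {}
        for key, dv in deltas.items():
            kwargs[f"{key}_mean"] = getattr(self, f"{key}_mean") + dv
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MixtureDistribution:
    """Finite mixture over TruthDistributions (e.g. bimodal tau_m cohorts)."""

    components: tuple[TruthDistribution, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights) or not self.components:
            raise ValueError("components and weights must be non-empty and aligned")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be non-negative")
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")

    def sample(self, rng: np.random.Generator) -> DecayTruth:
        k = rng.choice(len(self.components), p=np.asarray(self.weights))
        return self.components[k].sample(rng)


def default_group(channel: str) -> TruthDistribution:
    """Literature-typical defaults for a channel's lifetime distribution."""
    if channel == NADH:
        return TruthDistribution()
    if channel == FAD:
        return TruthDistribution(
            tau2_mean=2.8, tau2_range=(1.8, 4.5), alpha1_mean=0.75
        )
    raise ValueError(f"unknown channel {channel!r}")


@dataclass(frozen=True)
class GroupDesign:
    """One cohort arm: label, per-channel sampling, and field layout."""

    label: str
    distributions: dict  # channel -> TruthDistribution | MixtureDistribution
    n_fields: int = 1
    n_cells_per_field: int = 10
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch in self.distributions:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r} in group {self.label!r}")
        if self.n_fields < 1 or self.n_cells_per_field < 0:
            raise ValueError("n_fields >= 1 and n_cells_per_field >= 0 required")


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[GroupDesign, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")


@dataclass
class SimGroundTruth:
    """Per-cell true decay parameters for one simulated field of view."""

    field_id: str
    group: str
    cells: dict  # cell_id -> {channel -> DecayTruth}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, per_ch in sorted(self.cells.items()):
            for ch, t in per_ch.items():
                rows.append({
                    "cell_id": cid, "field": self.field_id, "group": self.group,
                    "channel": ch, "tau1_ns": t.tau1_ns, "tau2_ns": t.tau2_ns,
                    "alpha1": t.alpha1, "amplitude": t.amplitude,
                    "background_rate": t.background_rate,
                })
        return pd.DataFrame(rows)


@dataclass
class FieldSim:
    """One simulated field: per-channel cubes, masks and ground truth."""

    field_id: str
    group: str
    cubes: dict  # channel -> DecayCube
    masks: MaskSet
    truth: SimGroundTruth


class GeometryError(RuntimeError):
    """Non-overlapping cell placement failed at the requested geometry."""


def make_cell_masks(
    n_cells: int,
    spec: AcquisitionSpec,
    seed: int,
    cell_radius_px: float = 12.0,
    radius_jitter: float = 0.2,
    axis_ratio_max: float = 1.8,
    nucleus_scale: float = 0.45,
    max_attempts_per_cell: int = 200,
) -> MaskSet:
    """Place non-overlapping elliptical cells with interior nuclei.

    Cells are ellipses with jittered area and axis ratio; each nucleus is
    a concentric, co-oriented ellipse scaled by ``nucleus_scale`` and
    clipped to its cell so nuclear pixels are always cell pixels of the
    same label.  Deterministic given ``seed``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    whole = np.zeros((h, w), dtype=np.uint16)
    nucs = np.zeros((h, w), dtype=np.uint16)
    for lab in range(1, n_cells + 1):
        placed = False
        for _ in range(max_attempts_per_cell):
            r_major = cell_radius_px * (1.0 + radius_jitter * rng.uniform(-1, 1))
            ratio = rng.uniform(1.0, axis_ratio_max)
            r_minor = r_major / ratio
            theta = rng.uniform(0, np.pi)
            margin = r_major + 1
            if 2 * margin >= min(h, w):
                raise GeometryError(
                    f"cell radius {r_major:.1f}px does not fit a {h}x{w} field"
                )
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            rr, cc = _draw_ellipse(cy, cx, r_major, r_minor,
                                   shape=(h, w), rotation=theta)
            if rr.size == 0 or np.any(whole[rr, cc] != 0):
                continue
            whole[rr, cc] = lab
            nr, nc = _draw_ellipse(cy, cx, r_major * nucleus_scale,
                                   r_minor * nucleus_scale,
                                   shape=(h, w), rotation=theta)
            keep = whole[nr, nc] == lab  # clip to own cell
            nucs[nr[keep], nc[keep]] = lab
            placed = True
            break
        if not placed:
            raise GeometryError(
                f"could not place cell {lab} of {n_cells} in a {h}x{w} field "
                f"after {max_attempts_per_cell} attempts"
            )
    from .cellquant import derive_cytoplasm

    return derive_cytoplasm(whole, nucs)


class MissingTruthError(KeyError):
    """A mask label lacks ground-truth decay parameters."""


def render_decay_cube(
    masks: MaskSet,
    truth: SimGroundTruth,
    spec: AcquisitionSpec,
    seed: int,
    irf: IRF | None = None,
    expectation_only: bool = False,
) -> DecayCube:
    """Forward-simulate a photon-count cube from per-cell ground truth.

    Each cell's expected signal (``amplitude`` photons) is spread
    uniformly over its whole-cell pixels, shaped in time by the IRF-
    convolved bi-exponential, and added to the uniform background rate;
    the cube is then Poisson-sampled (or returned as the expectation).
    """
    if masks.shape != (spec.height, spec.width):
        raise ValueError(
            f"mask geometry {masks.shape} does not match spec "
            f"({spec.height}, {spec.width})"
        )
    irf = irf or gaussian_irf(spec.irf_fwhm_ps, spec)
    ch = spec.channel
    expected = np.zeros((spec.height, spec.width, spec.n_bins), dtype=float)
    bg_rates = []
    for lab in masks.labels:
        cid = int(lab)
        if cid not in truth.cells or ch not in truth.cells[cid]:
            raise MissingTruthError(
                f"no {ch} ground truth for cell {cid} in field {truth.field_id}"
            )
        t = truth.cells[cid][ch]
        region = masks.whole_cell == lab
        n_px = int(region.sum())
        per_px = t.amplitude / n_px if n_px else 0.0
        curve = model_decay(t.tau1_ns, t.tau2_ns, t.alpha1, per_px, 0.0, irf, spec)
        expected[region] += curve
        bg_rates.append(t.background_rate)
    background = float(np.mean(bg_rates)) if bg_rates else 0.0
    expected += background
    if expectation_only:
        counts = expected
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.int64)
    return DecayCube(counts=counts, spec=spec, field_id=truth.field_id)


def sample_cohort(
    design: CohortDesign,
    spec: AcquisitionSpec,
    mask_kwargs: dict | None = None,
) -> list[FieldSim]:
    """Simulate every field of every group in a cohort design.

    Per-cell parameters are drawn i.i.d. from each group's per-channel
    distributions; masks, truths and cubes are all derived from
    ``design.seed`` through independent spawned streams, so the whole
    cohort is reproducible from the design alone.
    """
    mask_kwargs = mask_kwargs or {}
    fields: list[FieldSim] = []
    for g_idx, group in enumerate(design.groups):
        for f_idx in range(group.n_fields):
            ss = np.random.SeedSequence(
                design.seed, spawn_key=(g_idx, f_idx)
            )
            mask_seed, truth_seed, *cube_seeds = [
                int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 + len(CHANNELS))
            ]
            field_id = f"{group.label}_f{f_idx}"
            masks = make_cell_masks(group.n_cells_per_field, spec, mask_seed, **mask_kwargs)
            rng = np.random.default_rng(truth_seed)
            cells = {}
            for lab in masks.labels:
                per_ch = {}
                for ch in group.distributions:
                    per_ch[ch] = group.distributions[ch].sample(rng)
                cells[int(lab)] = per_ch
            truth = SimGroundTruth(field_id=field_id, group=group.label, cells=cells)
            cubes = {}
            for ch, cseed in zip(group.distributions, cube_seeds):
                ch_spec = replace(spec, channel=ch)
                cubes[ch] = render_decay_cube(masks, truth, ch_spec, cseed)
            fields.append(FieldSim(field_id, group.label, cubes, masks, truth))
    return fields


def sample_feature_table(design: CohortDesign) -> pd.DataFrame:
    """Draw per-cell OMI feature rows directly from the cohort design.

    Bypasses image rendering and fitting: each cell's eight variables are
    computed from a draw of its true decay parameters.  This is the
    idealized (noise-floor) feature table a perfect fitter would produce,
    used for cohort-level statistics, embedding and classifier studies at
    scales where per-pixel fitting is beside the point.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for group in design.groups:
        dists = group.distributions
        for ch in (NADH, FAD):
            if ch not in dists:
                raise ValueError(f"group {group.label!r} lacks a {ch} distribution")
        n = group.n_fields * group.n_cells_per_field
        for i in range(n):
            nadh = dists[NADH].sample(rng)
            fad = dists[FAD].sample(rng)
            row = {
                "cell_id": i + 1,
                "field": f"{group.label}_f{i // max(group.n_cells_per_field, 1)}",
                "line": group.meta.get("line", group.label),
                "day": group.meta.get("day", ""),
                "substrate": group.meta.get("substrate", ""),
                "group": group.label,
                "nadh_tm": nadh.tau_m_ns, "nadh_t1": nadh.tau1_ns,
                "nadh_t2": nadh.tau2_ns, "nadh_a1": nadh.alpha1,
                "fad_tm": fad.tau_m_ns, "fad_t1": fad.tau1_ns,
                "fad_t2": fad.tau2_ns, "fad_a1": fad.alpha1,
            }
            rows.append(row)
    return pd.DataFrame(rows)
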