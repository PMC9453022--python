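"""Synthetic two-group resting-state cohorts with planted degree effects.

The generator emulates already-preprocessed BOLD data: each atlas region
carries one latent signal, and every voxel's series is

    x_v(t) = w_region * s_region(t) + noise_sd * eps_v(t)

with all series finally mean-centered.  The within-region coupling ``w``
equals ``base_coupling`` everywhere except in the designated effect
regions of group 1, where it is raised by ``effect_size``.  Stronger
coupling raises within-region correlations and therefore the degree
centrality of those voxels — a known, planted group difference in the
DC maps, with group 2 as the reference condition.

Group 1 plays the MCI role (MoCA drawn below 26), group 2 the nMCI role
(MoCA >= 26).  A separate generator draws tabular region-feature sets
from published per-group Gaussian parameters.

Latent signals are iid Gaussian by default; an optional Butterworth
band-pass (e.g. 0.01-0.08 Hz at TR = 2 s) shapes their spectrum like
filtered resting-state data.  Degree centrality depends only on the
correlation structure, so band-limiting is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .grids import ToyAtlas, ToyGeometry
from .reference import FeatureStats, SELECTED_DC_FEATURES

__all__ = [
    "CohortSpec",
    "SubjectRecording",
    "simulate_subject",
    "simulate_cohort",
    "simulate_feature_table",
    "subject_seed",
    "participants_frame",
    "write_participants_tsv",
]


@dataclass
class CohortSpec:
    """Design of a synthetic two-group cohort.

    ``effect_size`` is the increment added to the within-region signal
    coupling of ``effect_regions`` in group 1 only; ``effect_size=0``
    makes the group label causally inert (a null cohort).
    """

    n_group1: int = 51
    n_group2: int = 48
    n_timepoints: int = 240
    effect_regions: tuple[int, ...] = ()
    effect_size: float = 0.0
    base_coupling: float = 0.7
    noise_sd: float = 1.0
    signal_band_hz: tuple[float, float] | None = None
    sampling_interval_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.n_timepoints < 8:
            raise ValueError("need at least 8 timepoints")
        for name in ("effect_size", "base_coupling", "noise_sd"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def validate_against(self, atlas: ToyAtlas) -> None:
        extra = set(self.effect_regions) - set(atlas.region_ids)
        if extra:
            raise ValueError(f"effect_regions {sorted(extra)} not in the atlas")


@dataclass
class SubjectRecording:
    """One simulated participant: BOLD matrix, group label and MoCA score."""

    subject_id: str
    group: int
    bold: "MaskedBOLD"  # noqa: F821 - imported lazily to avoid a cycle
    moca: float

    def __post_init__(self) -> None:
        if self.group not in (1, 2):
            raise ValueError(f"group must be 1 or 2, got {self.group}")
        impaired = self.moca < 26.0
        if impaired != (self.group == 1):
            raise ValueError(
                f"MoCA {self.moca} inconsistent with group {self.group} "
                "under the MoCA<26 impairment rule"
            )


def subject_seed(master_seed: int, subject_index: int) -> np.random.SeedSequence:
    """Reproducible, platform-stable per-subject seed stream."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(subject_index,))


def _band_limit(series: np.ndarray, band: tuple[float, float], tr_s: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass, then re-standardise each row."""
    nyq = 0.5 / tr_s
    lo, hi = band
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} invalid for sampling interval {tr_s}s")
    sos = signal.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    out = signal.sosfiltfilt(sos, series, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (out - out.mean(axis=-1, keepdims=True)) / sd


def simulate_subject(
    geometry: ToyGeometry,
    atlas: ToyAtlas,
    group: int,
    spec: CohortSpec,
    subject_seed_seq: np.random.SeedSequence | int,
    subject_id: str = "sub-001",
) -> SubjectRecording:
    """Draw one subject's masked BOLD matrix under the cohort's generative law."""
    from .dc import MaskedBOLD  # local import: dc depends on grids, not on us

    spec.validate_against(atlas)
    if group not in (1, 2):
        raise ValueError(f"group must be 1 or 2, got {group}")
    rng = np.random.default_rng(subject_seed_seq)

    coords = geometry.mask_coordinates()
    region_of_voxel = atlas.labels[tuple(coords.T)]
    if np.any(region_of_voxel == 0):
        raise ValueError("atlas leaves some in-mask voxels unlabeled")
    rid_to_idx = {rid: k for k, rid in enumerate(atlas.region_ids)}
    voxel_region_idx = np.array([rid_to_idx[rid] for rid in region_of_voxel])

    t = spec.n_timepoints
    latents = rng.standard_normal((atlas.n_regions, t))
    if spec.signal_band_hz is not None:
        latents = _band_limit(latents, spec.signal_band_hz, spec.sampling_interval_s)

    coupling = np.full(atlas.n_regions, spec.base_coupling)
    if group == 1:
        for rid in spec.effect_regions:
            coupling[rid_to_idx[rid]] += spec.effect_size

    data = coupling[voxel_region_idx][:, None] * latents[voxel_region_idx]
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)
    data = data - data.mean(axis=1, keepdims=True)

    moca = float(rng.uniform(18.0, 25.0) if group == 1 else rng.uniform(26.0, 30.0))
    return SubjectRecording(
        subject_id=subject_id,
        group=group,
        bold=MaskedBOLD(data=data, geometry=geometry, voxel_index=coords),
        moca=moca,
    )


def simulate_cohort(
    geometry: ToyGeometry,
    atlas: ToyAtlas,
    spec: CohortSpec,
    out_dir: str | Path | None = None,
) -> tuple[list[SubjectRecording], pd.DataFrame]:
    """Simulate the full two-group cohort; optionally write participants.tsv."""
    recordings: list[SubjectRecording] = []
    n_total = spec.n_group1 + spec.n_group2
    for idx in range(n_total):
        group = 1 if idx < spec.n_group1 else 2
        rec = simulate_subject(
            geometry,
            atlas,
            group,
            spec,
            subject_seed(spec.seed, idx),
            subject_id=f"sub-{idx + 1:03d}",
        )
        recordings.append(rec)
    participants = participants_frame(recordings)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_participants_tsv(participants, out_dir / "participants.tsv")
    return recordings, participants


def participants_frame(recordings: list[SubjectRecording]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recordings],
            "group": [r.group for r in recordings],
            "moca": [r.moca for r in recordings],
        }
    )


def write_participants_tsv(participants: pd.DataFrame, path: str | Path) -> None:
    participants.to_csv(path, sep="\t", index=False, float_format="%.10g")


def simulate_feature_table(
    feature_stats: tuple[FeatureStats, ...] = SELECTED_DC_FEATURES,
    n1: int = 51,
    n2: int = 48,
    seed: int = 0,
    sd_override: float | None = None,
):
    """Draw a subjects x features table from per-group Gaussian parameters.

    Each subject's value for each feature is an independent draw from
    that feature's group-specific Normal.  ``sd_override`` (mainly for
    tests) replaces every SD, 0 collapsing each draw onto its mean.
    Returns a :class:`neurodc.features.FeatureTable` with MCI labels on
    group 1.
    """
    from .features import FeatureTable

    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    if len(feature_stats) == 0:
        raise ValueError("feature_stats is empty")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xF7A8,)))
    n = n1 + n2
    matrix = np.empty((n, len(feature_stats)))
    for k, fs in enumerate(feature_stats):
        sd1 = fs.mci_sd if sd_override is None else sd_override
        sd2 = fs.nmci_sd if sd_override is None else sd_override
        matrix[:n1, k] = fs.mci_mean + sd1 * rng.standard_normal(n1)
        matrix[n1:, k] = fs.nmci_mean + sd2 * rng.standard_normal(n2)
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
    labels = ["MCI"] * n1 + ["nMCI"] * n2
    return FeatureTable(
        matrix=matrix,
        region_names=[fs.name for fs in feature_stats],
        subject_ids=subject_ids,
        labels=labels,
    )
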