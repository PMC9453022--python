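"""Atlas region-mean feature extraction from smoothed zDC maps.

Each subject's smoothed zDC map is reduced to one value per atlas
region — the arithmetic mean over the region's in-mask voxels — and the
cohort's vectors are stacked into a subjects x regions table with
binary cognitive-impairment labels (MCI iff MoCA < 26, strictly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dc import DCMap
from .grids import ToyAtlas

__all__ = [
    "FeatureTable",
    "extract_region_means",
    "build_feature_table",
    "read_feature_tsv",
]

MCI_MOCA_CUTOFF = 26.0


def _quantize(matrix: np.ndarray) -> np.ndarray:
    """Fix values at 10 significant decimal digits (the TSV precision)."""
    return np.array(
        [[float(f"{v:.10g}") for v in row] for row in np.atleast_2d(matrix)]
    )


@dataclass
class FeatureTable:
    """Subjects x regions matrix of region-mean zDC, with MCI labels.

    Values are stored at 10 significant digits — the precision of the
    on-disk TSV — so write/read round-trips are exact.
    """

    matrix: np.ndarray
    region_names: list[str]
    subject_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = _quantize(np.asarray(self.matrix, dtype=float))
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains missing/non-finite values")
        n, p = self.matrix.shape
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids/labels length must match matrix rows")
        if len(self.region_names) != p:
            raise ValueError("region_names length must match matrix columns")
        bad = set(self.labels) - {"MCI", "nMCI"}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Binary labels with MCI as the positive class (1)."""
        return np.array([1 if l == "MCI" else 0 for l in self.labels])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.region_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def write_tsv(self, path: str | Path, manifest: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        if manifest:
            manifest_path = path.with_suffix(".columns.json")
            manifest_path.write_text(
                json.dumps({"columns": self.region_names}, indent=2) + "\n"
            )

    def select_columns(self, names: list[str]) -> "FeatureTable":
        idx = [self.region_names.index(n) for n in names]
        return FeatureTable(
            matrix=self.matrix[:, idx],
            region_names=list(names),
            subject_ids=list(self.subject_ids),
            labels=list(self.labels),
        )


def read_feature_tsv(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t")
    region_names = [c for c in df.columns if c not in ("subject_id", "label")]
    return FeatureTable(
        matrix=df[region_names].to_numpy(dtype=float),
        region_names=region_names,
        subject_ids=df["subject_id"].astype(str).tolist(),
        labels=df["label"].tolist(),
    )


def extract_region_means(zdc_map: DCMap, atlas: ToyAtlas) -> np.ndarray:
    """Mean smoothed zDC per atlas region, in ``region_ids`` order."""
    if atlas.labels.shape != zdc_map.geometry.shape:
        raise ValueError("atlas and map geometries disagree")
    labels_at_voxels = atlas.labels[tuple(zdc_map.voxel_index.T)]
    means = np.empty(atlas.n_regions)
    for k, rid in enumerate(atlas.region_ids):
        sel = labels_at_voxels == rid
        if not np.any(sel):
            raise ValueError(f"region {rid} ({atlas.region_names[k]}) has no in-mask voxels")
        means[k] = zdc_map.values[sel].mean()
    return means


def build_feature_table(
    zdc_maps: dict[str, DCMap],
    atlas: ToyAtlas,
    participants: pd.DataFrame,
) -> FeatureTable:
    """Stack per-subject region means into a labelled feature table.

    Rows follow the participant-table order; the label is MCI iff the
    subject's MoCA score is strictly below 26.  Map/table id mismatches
    are reported in full.
    """
    table_ids = participants["subject_id"].astype(str).tolist()
    missing = [sid for sid in table_ids if sid not in zdc_maps]
    extra = [sid for sid in zdc_maps if sid not in set(table_ids)]
    if missing or extra:
        raise ValueError(
            f"subject id mismatch between maps and participant table: "
            f"missing maps for {missing}, unmatched maps {extra}"
        )
    matrix = np.vstack([extract_region_means(zdc_maps[sid], atlas) for sid in table_ids])
    moca = participants["moca"].to_numpy(dtype=float)
    labels = ["MCI" if m < MCI_MOCA_CUTOFF else "nMCI" for m in moca]
    return FeatureTable(
        matrix=matrix,
        region_names=list(atlas.region_names),
        subject_ids=table_ids,
        labels=labels,
    )
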