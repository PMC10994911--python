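"""I/O for susceptibility maps, atlas parcellations, ROI samples and cohort tables.

Volumes are NIfTI-1 (read through nibabel); all tabular formats are
tab-separated UTF-8 with a header row:

* region table: ``region_id  name  abbreviation  network``
* ROI-sample table (long format): ``subject_id  region_id  value``
* cohort table: ``subject_id  group  age  gender  education``

All volumes entering one analysis must share a single voxel grid; no
resampling is performed here (spatial normalization happens upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    CatalogError,
    CompletenessError,
    DimensionError,
    FormatError,
)

#: The eight functional systems used to label regions and edges.
FUNCTIONAL_NETWORKS = ("VN", "SMN", "DAN", "SVAN", "LN", "FPN", "DMN", "SN")

#: Regions with fewer in-mask voxels than this are flagged degenerate.
DEFAULT_MIN_VOXELS = 10


@dataclass
class SusceptibilityMap:
    """A 3D susceptibility volume with its voxel-to-world transform.

    Units (ppb or ppm) are carried as metadata only; nothing in the
    pipeline converts them.
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units_label: str = "ppb"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise DimensionError("susceptibility map must be a 3D volume")


@dataclass
class AtlasParcellation:
    """Integer label volume (0 = background) plus its region catalog.

    ``region_table`` is indexed by region id with columns ``name``,
    ``abbreviation`` and ``network`` (one of :data:`FUNCTIONAL_NETWORKS`
    for brain atlases; arbitrary strings are accepted).
    """

    labels: np.ndarray
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.round(self.labels)
            if not np.allclose(self.labels, rounded):
                raise FormatError("atlas volume has non-integer labels")
            self.labels = rounded.astype(np.int64)
        ids = np.asarray(sorted(self.region_table.index))
        n = ids.size
        if n < 2 or not np.array_equal(ids, np.arange(1, n + 1)):
            raise CatalogError(
                "region ids must be contiguous 1..N with N >= 2; got %s" % ids
            )
        in_volume = np.unique(self.labels)
        unknown = set(in_volume[in_volume > 0]) - set(ids.tolist())
        if unknown:
            raise CatalogError(f"labels {sorted(unknown)} missing from region table")

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    @property
    def region_ids(self) -> list[int]:
        return sorted(int(i) for i in self.region_table.index)

    def network_partition(self) -> dict[int, str]:
        """Region id -> functional-network assignment."""
        return {int(i): str(r["network"]) for i, r in self.region_table.iterrows()}


@dataclass
class SusceptibilityROISamples:
    """Per-region bags of voxel susceptibility values for one subject.

    Regions with fewer than ``min_voxels`` values are listed in
    ``degenerate`` but their values are kept; downstream density
    estimation decides whether to raise.
    """

    subject_id: str
    region_values: dict[int, np.ndarray]
    degenerate: frozenset[int] = frozenset()
    min_voxels: int = DEFAULT_MIN_VOXELS

    def __post_init__(self) -> None:
        self.region_values = {
            int(r): np.asarray(v, dtype=float) for r, v in self.region_values.items()
        }
        self.degenerate = frozenset(
            r for r, v in self.region_values.items() if v.size < self.min_voxels
        )

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.region_values)


@dataclass
class CohortDesign:
    """Subject-level design table: group labels plus the adjustment covariates."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "group", "age", "gender", "education")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"cohort table missing columns {missing}")
        if self.table["subject_id"].duplicated().any():
            raise FormatError("cohort table has duplicate subject ids")
        self.table = self.table.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].astype(str).tolist()

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].astype(str).unique())


# ---------------------------------------------------------------------------
# Volume loading and ROI extraction
# ---------------------------------------------------------------------------

def read_region_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("region_id", "name", "abbreviation", "network"):
        if col not in df.columns:
            raise FormatError(f"region table missing column {col!r}")
    return df.set_index("region_id")


def load_map_and_atlas(map_path, mask_path, atlas_path, region_table_path):
    """Read a susceptibility map, gray-matter mask and atlas from NIfTI files.

    Returns ``(SusceptibilityMap, AtlasParcellation, mask)`` where ``mask``
    is a boolean volume on the shared grid.  Raises :class:`DimensionError`
    on any grid-shape mismatch and :class:`CatalogError` when the atlas
    volume uses a label absent from the region table.
    """
    map_img = nib.load(str(map_path))
    mask_img = nib.load(str(mask_path))
    atlas_img = nib.load(str(atlas_path))
    shapes = {map_img.shape, mask_img.shape, atlas_img.shape}
    if len(shapes) != 1:
        raise DimensionError(
            f"volume shapes differ: map {map_img.shape}, mask {mask_img.shape}, "
            f"atlas {atlas_img.shape}"
        )
    smap = SusceptibilityMap(
        voxels=np.asarray(map_img.get_fdata(), dtype=float),
        affine=np.asarray(map_img.affine),
    )
    atlas = AtlasParcellation(
        labels=np.asarray(atlas_img.get_fdata()),
        region_table=read_region_table(region_table_path),
    )
    mask = np.asarray(mask_img.get_fdata()) > 0
    return smap, atlas, mask


def extract_roi_samples(
    smap: SusceptibilityMap,
    atlas: AtlasParcellation,
    mask: np.ndarray,
    subject_id: str = "subject",
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> SusceptibilityROISamples:
    """Collect in-mask voxel values per atlas region.

    Voxels are taken in row-major (C) scan order, so repeated extractions
    are bit-identical.  Regions whose in-mask voxel count is below
    ``min_voxels`` (including empty regions) are flagged degenerate, not
    dropped.
    """
    mask = np.asarray(mask).astype(bool)
    if not (smap.voxels.shape == atlas.labels.shape == mask.shape):
        raise DimensionError("map, atlas and mask must share one grid shape")
    region_values = {}
    for r in atlas.region_ids:
        sel = (atlas.labels == r) & mask
        region_values[r] = smap.voxels[sel]  # boolean indexing is C-ordered
    return SusceptibilityROISamples(
        subject_id=subject_id, region_values=region_values, min_voxels=min_voxels
    )


# ---------------------------------------------------------------------------
# Tabular ROI samples and cohort tables
# ---------------------------------------------------------------------------

def write_roi_table(samples: list[SusceptibilityROISamples], path) -> None:
    """Write ROI samples in long format with full float precision."""
    frames = []
    for s in samples:
        for r in s.region_ids:
            v = s.region_values[r]
            frames.append(
                pd.DataFrame(
                    {"subject_id": s.subject_id, "region_id": r, "value": v}
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_roi_table(path, min_voxels: int = DEFAULT_MIN_VOXELS):
    """Read a long-format ROI table into per-subject sample objects.

    Every subject must have every region observed anywhere in the file;
    a missing (subject, region) pair raises :class:`CompletenessError`.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("subject_id", "region_id", "value"):
        if col not in df.columns:
            raise FormatError(f"ROI table missing column {col!r}")
    all_regions = set(int(r) for r in df["region_id"].unique())
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        have = {int(r) for r in grp["region_id"].unique()}
        missing = all_regions - have
        if missing:
            raise CompletenessError(
                f"subject {sid!r} is missing regions {sorted(missing)}"
            )
        region_values = {
            int(r): g["value"].to_numpy(dtype=float)
            for r, g in grp.groupby("region_id", sort=True)
        }
        out.append(
            SusceptibilityROISamples(
                subject_id=str(sid), region_values=region_values, min_voxels=min_voxels
            )
        )
    return out


def write_cohort_table(design: CohortDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> CohortDesign:
    return CohortDesign(table=pd.read_csv(path, sep="\t"))
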