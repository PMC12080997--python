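"""Rat-brain parcellation metadata and regional time-series extraction.

The parcellation is the 48-region Schiffer-style rat atlas used throughout
the package: 23 bilateral regions (hemispheres kept separate, consecutive
matrix positions) plus the midline periaqueductal gray and septum. Every
connectome, component table and effect table in the package is ordered by
the ``position`` column of this table.

The cerebellum serves as the reference tissue for DVR-1 quantification and
is deliberately *not* part of the 48 analysis regions; label volumes may
carry it under :data:`REFERENCE_LABEL`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionRecord",
    "RegionTable",
    "Atlas",
    "NetworkDefinition",
    "REFERENCE_LABEL",
    "REFERENCE_ID",
    "ABBREVIATION_ALIASES",
    "SALIENCE_NETWORK",
    "SUBCORTICAL_NETWORK",
    "load_region_table",
    "extract_regional_timeseries",
    "build_toy_atlas",
]

#: Integer label reserved for the cerebellar reference tissue in label volumes.
REFERENCE_LABEL = 49
#: Region-id string used for the reference tissue in time-series tables.
REFERENCE_ID = "Cer"

#: Alternative abbreviations seen in the literature for regions of this table.
ABBREVIATION_ALIASES = {"CPu": "Str", "Hypo": "Hyp", "Hipp": "CA1"}

N_REGIONS = 48


@dataclass(frozen=True)
class RegionRecord:
    """One hemisphere-resolved parcellation region."""

    name: str
    hemisphere: str  # "left" | "right" | "midline"
    volume_mm3: float
    matrix_position: int
    abbreviation: str

    @property
    def region_id(self) -> str:
        """Unique id: abbreviation plus hemisphere suffix for bilateral regions."""
        if self.hemisphere == "left":
            return f"{self.abbreviation}-L"
        if self.hemisphere == "right":
            return f"{self.abbreviation}-R"
        return self.abbreviation


class RegionTable:
    """The ordered 48-region parcellation table.

    Rows are sorted by matrix position; positions must be the contiguous
    integers 1..48 and bilateral regions must occupy consecutive positions.
    """

    def __init__(self, records: Sequence[RegionRecord]):
        records = sorted(records, key=lambda r: r.matrix_position)
        positions = [r.matrix_position for r in records]
        if positions != list(range(1, len(records) + 1)):
            dupes = {p for p in positions if positions.count(p) > 1}
            raise ValueError(
                f"matrix positions must be contiguous 1..{len(records)}; "
                f"offending positions: {sorted(dupes) or positions}"
            )
        for rec in records:
            if rec.volume_mm3 <= 0:
                raise ValueError(f"non-positive volume for region {rec.region_id}")
            if rec.hemisphere not in ("left", "right", "midline"):
                raise ValueError(f"bad hemisphere {rec.hemisphere!r} in {rec.name}")
        # bilateral pairs must be adjacent (left then right)
        by_abbr: dict[str, list[RegionRecord]] = {}
        for rec in records:
            by_abbr.setdefault(rec.abbreviation, []).append(rec)
        for abbr, group in by_abbr.items():
            if len(group) == 2:
                left, right = group
                if (left.hemisphere, right.hemisphere) != ("left", "right") or (
                    right.matrix_position != left.matrix_position + 1
                ):
                    raise ValueError(f"bilateral region {abbr} not at consecutive positions")
            elif len(group) > 2:
                raise ValueError(f"abbreviation {abbr} appears {len(group)} times")
        self.records: tuple[RegionRecord, ...] = tuple(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.records]

    @property
    def positions(self) -> list[int]:
        return [r.matrix_position for r in self.records]

    def lookup(self, abbr: str, hemisphere: str | None = None) -> RegionRecord:
        """Find a region by abbreviation (aliases accepted) and hemisphere.

        For bilateral regions ``hemisphere`` is required unless exactly one
        row matches.
        """
        abbr = ABBREVIATION_ALIASES.get(abbr, abbr)
        hits = [r for r in self.records if r.abbreviation == abbr]
        if hemisphere is not None:
            hits = [r for r in hits if r.hemisphere == hemisphere]
        if not hits:
            raise KeyError(f"no region with abbreviation {abbr!r}" +
                           (f" in hemisphere {hemisphere!r}" if hemisphere else ""))
        if len(hits) > 1:
            raise KeyError(f"abbreviation {abbr!r} is bilateral; pass hemisphere=")
        return hits[0]

    def by_position(self, position: int) -> RegionRecord:
        return self.records[position - 1]

    def resolve_members(self, abbreviations: Iterable[str]) -> list[RegionRecord]:
        """Expand abbreviations (aliases accepted) to hemisphere-resolved rows."""
        out: list[RegionRecord] = []
        for abbr in abbreviations:
            canon = ABBREVIATION_ALIASES.get(abbr, abbr)
            hits = [r for r in self.records if r.abbreviation == canon]
            if not hits:
                raise KeyError(f"network member {abbr!r} matches no region")
            out.extend(hits)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [r.name for r in self.records],
                "hemisphere": [r.hemisphere for r in self.records],
                "volume_mm3": [r.volume_mm3 for r in self.records],
                "position": [r.matrix_position for r in self.records],
                "abbreviation": [r.abbreviation for r in self.records],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class NetworkDefinition:
    """A named set of regions, by abbreviation (both hemispheres implied)."""

    name: str
    member_abbreviations: list[str]

    def __post_init__(self):
        if not self.member_abbreviations:
            raise ValueError(f"network {self.name!r} has no members")

    def member_ids(self, table: RegionTable) -> list[str]:
        return [r.region_id for r in table.resolve_members(self.member_abbreviations)]

    def member_positions(self, table: RegionTable) -> list[int]:
        return [r.matrix_position for r in table.resolve_members(self.member_abbreviations)]


# SERT networks identified in the baseline cohort: the salience-like network of
# serotonergic projection targets and the subcortical network of high-SERT
# regions around the raphe/midbrain.
SALIENCE_NETWORK = NetworkDefinition(
    "salience", ["Str", "Cg", "NAc", "Amyg", "Ins", "mPFC"]
)
SUBCORTICAL_NETWORK = NetworkDefinition(
    "subcortical", ["VTA", "Th", "MB", "PAG", "Hyp"]
)


def load_region_table(path=None) -> RegionTable:
    """Load the packaged 48-region parcellation table (or a TSV mirroring it).

    The TSV has columns region, hemisphere, volume_mm3, position,
    abbreviation, one row per hemisphere-resolved region.
    """
    if path is None:
        source = resources.files("molconn.data").joinpath("region_table.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"region", "hemisphere", "volume_mm3", "position", "abbreviation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    records = [
        RegionRecord(
            name=row.region,
            hemisphere=row.hemisphere,
            volume_mm3=float(row.volume_mm3),
            matrix_position=int(row.position),
            abbreviation=row.abbreviation,
        )
        for row in df.itertuples()
    ]
    return RegionTable(records)


@dataclass
class Atlas:
    """An integer label volume plus its region table.

    Nonzero voxel labels are matrix positions (1..48); the value
    :data:`REFERENCE_LABEL` marks the cerebellar reference tissue.
    """

    label_volume: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    region_table: RegionTable

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        labels = set(np.unique(self.label_volume)) - {0, REFERENCE_LABEL}
        known = set(self.region_table.positions)
        unknown = labels - known
        if unknown:
            raise ValueError(f"labels with no region-table row: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape

    def mask(self, include_reference: bool = False) -> np.ndarray:
        """Boolean in-brain mask (labelled voxels)."""
        m = self.label_volume > 0
        if not include_reference:
            m &= self.label_volume != REFERENCE_LABEL
        return m

    def voxel_indices(self, position: int) -> tuple[np.ndarray, ...]:
        return np.nonzero(self.label_volume == position)


def extract_regional_timeseries(image, atlas: Atlas, regions=None):
    """Mean in-region time series for each requested region.

    Parameters
    ----------
    image : DynamicImage
        4D series on the same voxel grid as the atlas.
    atlas : Atlas
    regions : sequence of int, optional
        Matrix positions to extract (may include ``REFERENCE_LABEL``);
        defaults to all 48 plus the reference label when present.

    Returns
    -------
    RegionalTimeSeries
        One row per region, entry (r, t) the arithmetic mean of frame t
        over voxels labelled r.
    """
    from .kinetics import RegionalTimeSeries  # local import to avoid cycle

    data = image.data
    if data.shape[:3] != atlas.shape:
        raise ValueError(
            f"grid mismatch: image {data.shape[:3]} vs atlas {atlas.shape}"
        )
    if regions is None:
        present = set(np.unique(atlas.label_volume))
        regions = list(atlas.region_table.positions)
        if REFERENCE_LABEL in present:
            regions.append(REFERENCE_LABEL)
    empty = [int(r) for r in regions if not np.any(atlas.label_volume == r)]
    if empty:
        raise ValueError(f"regions with zero labelled voxels: {empty}")

    n_frames = data.shape[3]
    flat = data.reshape(-1, n_frames)
    labels_flat = atlas.label_volume.ravel()
    values = np.empty((len(regions), n_frames), dtype=float)
    ids = []
    for i, pos in enumerate(regions):
        values[i] = flat[labels_flat == pos].mean(axis=0)
        if pos == REFERENCE_LABEL:
            ids.append(REFERENCE_ID)
        else:
            ids.append(atlas.region_table.by_position(int(pos)).region_id)
    return RegionalTimeSeries(
        values=values,
        region_ids=ids,
        frame_mid_min=image.frame_mid_min,
        modality=image.modality,
    )


def build_toy_atlas(block: tuple[int, int, int] = (3, 3, 3),
                    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
                    include_reference: bool = True,
                    region_table: RegionTable | None = None) -> Atlas:
    """A coarse block-parcellation label volume for simulation and tests.

    The 48 regions (plus the cerebellar reference when requested) are laid
    out as equal rectangular blocks on a 7 x 7 grid of blocks in a single
    slab. This is a synthetic stand-in geometry: block adjacency carries no
    anatomical meaning.
    """
    if region_table is None:
        region_table = load_region_table()
    n_labels = N_REGIONS + (1 if include_reference else 0)
    grid = 7
    bx, by, bz = block
    shape = (grid * bx, grid * by, bz)
    vol = np.zeros(shape, dtype=np.int16)
    for label in range(1, n_labels + 1):
        idx = label - 1
        gx, gy = divmod(idx, grid)
        vol[gx * bx:(gx + 1) * bx, gy * by:(gy + 1) * by, :] = label
    return Atlas(label_volume=vol, voxel_size_mm=voxel_size_mm, region_table=region_table)
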