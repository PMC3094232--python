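"""Data model and readers/writers for marker maps, inversion regions and shared counts.

Coordinates are megabases, 0-based, half-open ``[start, end)`` per arm.
Overlapping inversions (e.g. 2Rb/2Rc/2Rd/2Ru in *An. gambiae*) are kept as
distinct regions; each arm additionally carries a single aggregate *outside*
region whose length is the complement of the union of its inversions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("armdyn")

OUTSIDE = "outside"

MARKER_COLUMNS = ["species", "arm", "marker", "homolog_group", "position_mb", "source", "arm_length_mb"]
REGION_COLUMNS = ["species", "arm", "region_id", "start_mb", "end_mb", "arm_length_mb"]

_FLOAT_FMT = "%.4f"


class ArmdynError(ValueError):
    """Raised on invalid inputs (malformed tables, violated invariants)."""


@dataclass(frozen=True)
class Marker:
    marker_id: str
    homolog_group: str
    position: float
    source: str = "physical"  # physical | in-silico


@dataclass
class MarkerMap:
    """Ordered, positioned single-copy markers on one arm of one species."""

    species: str
    arm: str
    arm_length: float
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arm_length <= 0:
            raise ArmdynError(f"arm_length must be positive, got {self.arm_length}")
        self.markers = sorted(self.markers, key=lambda m: m.position)
        seen_ids: set[str] = set()
        seen_groups: set[str] = set()
        for m in self.markers:
            if not (0.0 <= m.position <= self.arm_length):
                raise ArmdynError(
                    f"marker {m.marker_id!r} position {m.position} outside "
                    f"[0, {self.arm_length}] on {self.species} {self.arm}"
                )
            if m.marker_id in seen_ids:
                raise ArmdynError(f"duplicate marker_id {m.marker_id!r} on {self.species} {self.arm}")
            if m.homolog_group in seen_groups:
                raise ArmdynError(
                    f"duplicate homolog_group {m.homolog_group!r} for species "
                    f"{self.species} (single-copy assumption)"
                )
            seen_ids.add(m.marker_id)
            seen_groups.add(m.homolog_group)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.markers], dtype=float)

    @property
    def homolog_groups(self) -> list[str]:
        return [m.homolog_group for m in self.markers]

    def position_of_group(self, homolog_group: str) -> float:
        for m in self.markers:
            if m.homolog_group == homolog_group:
                return m.position
        raise KeyError(homolog_group)

    def __len__(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class Region:
    region_id: str
    kind: str  # inversion | outside
    start: float | None
    end: float | None
    length: float


def _union_length(intervals: Sequence[tuple[float, float]]) -> float:
    if not intervals:
        return 0.0
    ivs = sorted(intervals)
    total = 0.0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


@dataclass
class ArmRegionSet:
    """Inversion intervals on one arm plus the derived aggregate outside region.

    The outside region is not an interval: it is the complement of the union of
    the (possibly overlapping) inversions, carried as a single region whose
    length is ``L - |union of inversions|``.
    """

    species: str
    arm: str
    arm_length: float
    inversions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arm_length <= 0:
            raise ArmdynError(f"arm_length must be positive, got {self.arm_length}")
        ids = set()
        for r in self.inversions:
            if r.kind != "inversion":
                raise ArmdynError(f"region {r.region_id!r}: only inversions may be supplied; outside is derived")
            if r.start is None or r.end is None or not (0.0 <= r.start < r.end <= self.arm_length):
                raise ArmdynError(
                    f"region {r.region_id!r}: need 0 <= start < end <= {self.arm_length}, "
                    f"got [{r.start}, {r.end})"
                )
            if r.region_id in ids or r.region_id == OUTSIDE:
                raise ArmdynError(f"duplicate or reserved region_id {r.region_id!r}")
            ids.add(r.region_id)

    @classmethod
    def from_intervals(cls, species: str, arm: str, arm_length: float,
                       intervals: Iterable[tuple[str, float, float]]) -> "ArmRegionSet":
        regs = [Region(rid, "inversion", s, e, e - s) for rid, s, e in intervals]
        return cls(species, arm, arm_length, regs)

    @property
    def outside_length(self) -> float:
        return self.arm_length - _union_length([(r.start, r.end) for r in self.inversions])

    @property
    def outside(self) -> Region:
        return Region(OUTSIDE, "outside", None, None, self.outside_length)

    def regions(self, include_outside: bool = True) -> list[Region]:
        regs = list(self.inversions)
        if include_outside:
            regs.append(self.outside)
        return regs

    def region_ids(self, include_outside: bool = True) -> list[str]:
        return [r.region_id for r in self.regions(include_outside)]

    def fractions(self, include_outside: bool = True) -> np.ndarray:
        """Fractional region lengths f_i = |region| / L (outside last)."""
        return np.array([r.length / self.arm_length for r in self.regions(include_outside)])

    def membership(self, positions: np.ndarray, include_outside: bool = True) -> np.ndarray:
        """Boolean matrix (..., n_regions): half-open [start, end) membership.

        A position inside two overlapping inversions is a member of each; it
        belongs to the outside region iff it lies in no inversion.
        """
        pos = np.asarray(positions, dtype=float)
        if self.inversions:
            starts = np.array([r.start for r in self.inversions])
            ends = np.array([r.end for r in self.inversions])
            inv = (pos[..., None] >= starts) & (pos[..., None] < ends)
        else:
            inv = np.zeros(pos.shape + (0,), dtype=bool)
        if not include_outside:
            return inv
        out = ~inv.any(axis=-1, keepdims=True)
        return np.concatenate([inv, out], axis=-1)


@dataclass
class HomologTable:
    """Homolog groups with one marker id per species (single-copy)."""

    rows: dict[str, dict[str, str]]  # homolog_group -> {species: marker_id}

    @classmethod
    def from_maps(cls, *maps: MarkerMap) -> "HomologTable":
        rows: dict[str, dict[str, str]] = {}
        for mm in maps:
            for m in mm.markers:
                rows.setdefault(m.homolog_group, {})[mm.species] = m.marker_id
        return cls(rows)

    def shared_groups(self, species: Sequence[str]) -> list[str]:
        return [g for g, r in self.rows.items() if all(s in r for s in species)]

    def validate_against(self, maps: Mapping[str, MarkerMap]) -> None:
        for g, r in self.rows.items():
            for sp, mid in r.items():
                if sp in maps and mid not in {m.marker_id for m in maps[sp].markers}:
                    raise ArmdynError(f"homolog group {g!r}: marker {mid!r} not found in map of {sp!r}")


@dataclass
class SharedCountTable:
    """Observed co-location counts O_{i,j} of shared homologs for one arm pair.

    Region axis order matches ``ArmRegionSet.regions()`` (inversions first,
    outside last). Because inversions may overlap, rows/columns carry no sum
    constraint; with disjoint inversions the full matrix sums to N.
    """

    species1: str
    species2: str
    arm1: str
    arm2: str
    region_ids1: list[str]
    region_ids2: list[str]
    O: np.ndarray          # (n1, n2) int counts
    f1: np.ndarray         # (n1,) fractions
    f2: np.ndarray         # (n2,) fractions
    n_homologs: int

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O)
        if self.O.shape != (len(self.region_ids1), len(self.region_ids2)):
            raise ArmdynError("O shape does not match region id lists")
        if (self.O < 0).any() or (self.O > self.n_homologs).any():
            raise ArmdynError("counts must lie in [0, N]")

    @property
    def inversion_index1(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.region_ids1) if r != OUTSIDE])

    @property
    def inversion_index2(self) -> np.ndarray:
        return np.array([j for j, r in enumerate(self.region_ids2) if r != OUTSIDE])

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, r1 in enumerate(self.region_ids1):
            for j, r2 in enumerate(self.region_ids2):
                recs.append({"region1": r1, "region2": r2, "O": int(self.O[i, j]),
                             "f1": self.f1[i], "f2": self.f2[j]})
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Readers / writers (TSV dialects)
# ---------------------------------------------------------------------------

def _arm_length_for(df_row, arm_lengths, path) -> float:
    key = (df_row["species"], df_row["arm"])
    if arm_lengths is not None and key in arm_lengths:
        return float(arm_lengths[key])
    if "arm_length_mb" in df_row and not pd.isna(df_row["arm_length_mb"]):
        return float(df_row["arm_length_mb"])
    raise ArmdynError(
        f"{path}: no arm length for {key}; supply an arm_length_mb column or the arm_lengths mapping"
    )


def read_marker_table(path, arm_lengths: Mapping[tuple[str, str], float] | None = None,
                      ) -> dict[tuple[str, str], MarkerMap]:
    """Read a tab-separated marker table into validated per-(species, arm) maps.

    Required header columns: species, arm, marker, homolog_group, position_mb,
    source. Arm lengths come from an optional arm_length_mb column or the
    ``arm_lengths`` mapping. Rows may appear in any order; output maps are
    sorted by position.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "arm": str, "marker": str,
                                            "homolog_group": str, "source": str})
    required = {"species", "arm", "marker", "homolog_group", "position_mb", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ArmdynError(f"{path}: missing columns {sorted(missing)}")

    maps: dict[tuple[str, str], MarkerMap] = {}
    for key, sub in df.groupby(["species", "arm"], sort=False):
        L = _arm_length_for(sub.iloc[0], arm_lengths, path)
        markers = []
        for idx, row in sub.iterrows():
            pos = float(row["position_mb"])
            if not (0.0 <= pos <= L):
                raise ArmdynError(
                    f"{path}: row {idx + 2}: marker {row['marker']!r} position {pos} "
                    f"outside [0, {L}] on {key[0]} {key[1]}"
                )
            markers.append(Marker(str(row["marker"]), str(row["homolog_group"]), pos, str(row["source"])))
        try:
            maps[key] = MarkerMap(key[0], key[1], L, markers)
        except ArmdynError as exc:
            rows = ", ".join(str(i + 2) for i in sub.index)
            raise ArmdynError(f"{path}: rows {rows}: {exc}") from exc

    # single-copy assumption across arms of one species
    for sp in df["species"].unique():
        dup = df[df["species"] == sp]["homolog_group"].duplicated()
        if dup.any():
            row = df[df["species"] == sp][dup].index[0]
            raise ArmdynError(f"{path}: row {row + 2}: duplicate (species, homolog_group) for {sp!r}")
    return maps


def write_marker_table(maps: Iterable[MarkerMap], path) -> None:
    recs = []
    for mm in maps:
        for m in mm.markers:
            recs.append((mm.species, mm.arm, m.marker_id, m.homolog_group, m.position, m.source, mm.arm_length))
    df = pd.DataFrame(recs, columns=MARKER_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_region_table(path, arm_lengths: Mapping[tuple[str, str], float] | None = None,
                      known_arms: Iterable[str] | None = None,
                      ) -> dict[tuple[str, str], ArmRegionSet]:
    """Read a BED-like inversion table; the outside region is synthesized per arm.

    Columns: species, arm, region_id, start_mb, end_mb (+ optional arm_length_mb).
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "arm": str, "region_id": str})
    required = {"species", "arm", "region_id", "start_mb", "end_mb"}
    missing = required - set(df.columns)
    if missing:
        raise ArmdynError(f"{path}: missing columns {sorted(missing)}")
    if known_arms is not None:
        bad = set(df["arm"]) - set(known_arms)
        if bad:
            raise ArmdynError(f"{path}: unknown arm(s) {sorted(bad)}")

    out: dict[tuple[str, str], ArmRegionSet] = {}
    for key, sub in df.groupby(["species", "arm"], sort=False):
        L = _arm_length_for(sub.iloc[0], arm_lengths, path)
        ivs = []
        for idx, row in sub.iterrows():
            s, e = float(row["start_mb"]), float(row["end_mb"])
            if s >= e:
                raise ArmdynError(f"{path}: row {idx + 2}: start {s} >= end {e}")
            ivs.append((str(row["region_id"]), s, e))
        out[key] = ArmRegionSet.from_intervals(key[0], key[1], L, ivs)
    return out


def write_region_table(region_sets: Iterable[ArmRegionSet], path) -> None:
    recs = []
    for rs in region_sets:
        for r in rs.inversions:
            recs.append((rs.species, rs.arm, r.region_id, r.start, r.end, rs.arm_length))
    df = pd.DataFrame(recs, columns=REGION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Shared-count construction
# ---------------------------------------------------------------------------

def count_shared(map1: MarkerMap, map2: MarkerMap,
                 regions1: ArmRegionSet, regions2: ArmRegionSet,
                 homologs: HomologTable | None = None) -> SharedCountTable:
    """Count homolog groups co-located in each region pair of one arm pair.

    O_{i,j} = number of homolog groups whose species-1 marker lies in region i
    and whose species-2 marker lies in region j (half-open membership; a marker
    inside two overlapping inversions counts in each). Markers with no homolog
    in the partner species carry no sharing information and are dropped.
    """
    if homologs is None:
        homologs = HomologTable.from_maps(map1, map2)
    shared = homologs.shared_groups([map1.species, map2.species])
    groups1 = set(map1.homolog_groups)
    groups2 = set(map2.homolog_groups)
    shared = [g for g in shared if g in groups1 and g in groups2]
    if not shared:
        raise ArmdynError(
            f"no shared homologs on arm pair {map1.species}/{map1.arm} x {map2.species}/{map2.arm}"
        )
    pos1 = np.array([map1.position_of_group(g) for g in shared])
    pos2 = np.array([map2.position_of_group(g) for g in shared])
    m1 = regions1.membership(pos1)   # (N, n1)
    m2 = regions2.membership(pos2)   # (N, n2)
    O = np.einsum("ni,nj->ij", m1.astype(np.int64), m2.astype(np.int64))
    return SharedCountTable(
        species1=map1.species, species2=map2.species, arm1=map1.arm, arm2=map2.arm,
        region_ids1=regions1.region_ids(), region_ids2=regions2.region_ids(),
        O=O, f1=regions1.fractions(), f2=regions2.fractions(), n_homologs=len(shared),
    )
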