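"""Cortical parcellation atlas and functional-network node sets.

The analysis uses a 360-parcel cortical parcellation in which every parcel
carries a functional-network assignment.  Two composite networks are
analyzed: the salience network (SN; cingulo-opercular + orbito-affective
parcels, 62 nodes) and the cognitive control network (CCN; dorsal attention
+ frontoparietal parcels, 73 nodes).

The published assignment table cannot be redistributed, so
:func:`synthetic_atlas` builds a stand-in with the correct network
cardinalities; :func:`load_atlas` accepts a real assignment table in the
same three-column schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from msnpipe.errors import ValidationError

N_REGIONS = 360

ATLAS_COLUMNS = ("region_id", "hemisphere", "functional_network")

# Functional-network cardinalities per hemisphere-pooled atlas.
NETWORK_SIZES = {
    "Cingulo-opercular": 56,
    "Orbito-affective": 6,
    "Dorsal attention": 23,
    "Frontoparietal": 50,
}


@dataclass(frozen=True)
class NetworkDefinition:
    """A named composite network: a set of functional-network labels."""

    name: str
    member_networks: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_networks:
            raise ValidationError(f"network definition {self.name!r} has no member networks")


SN_DEFINITION = NetworkDefinition("SN", frozenset({"Cingulo-opercular", "Orbito-affective"}))
CCN_DEFINITION = NetworkDefinition("CCN", frozenset({"Dorsal attention", "Frontoparietal"}))


@dataclass(frozen=True)
class ParcelAtlas:
    """360 cortical parcels with hemisphere and functional-network labels.

    The row order of ``table`` defines the canonical 0-based node indexing
    used by every similarity matrix downstream; ``region_id`` strings are
    the external contract.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ATLAS_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"atlas table missing columns: {missing}")
        extra = [c for c in t.columns if c not in ATLAS_COLUMNS]
        if extra:
            raise ValidationError(f"atlas table has unknown columns: {extra}")
        if len(t) != N_REGIONS:
            raise ValidationError(f"atlas must have exactly {N_REGIONS} regions, got {len(t)}")
        dup = t["region_id"].duplicated()
        if dup.any():
            lines = (t.index[dup] + 2).tolist()  # +2: header line + 1-based
            raise ValidationError(f"duplicate region_id at file lines {lines}")
        bad_hemi = ~t["hemisphere"].isin(["L", "R"])
        if bad_hemi.any():
            lines = (t.index[bad_hemi] + 2).tolist()
            raise ValidationError(f"hemisphere must be L or R; bad values at lines {lines}")
        if t[list(ATLAS_COLUMNS)].isna().any().any():
            raise ValidationError("atlas table contains missing values")

    @property
    def region_ids(self) -> list[str]:
        return self.table["region_id"].tolist()

    @property
    def networks(self) -> set[str]:
        return set(self.table["functional_network"].unique())

    def network_nodes(self, definition: NetworkDefinition) -> list[int]:
        """Sorted 0-based node indices of the parcels in a composite network.

        Raises :class:`LookupError` if a member label is absent from the atlas.
        """
        unknown = definition.member_networks - self.networks
        if unknown:
            raise LookupError(
                f"network definition {definition.name!r} references labels absent "
                f"from the atlas: {sorted(unknown)}"
            )
        mask = self.table["functional_network"].isin(definition.member_networks)
        return sorted(self.table.index[mask].tolist())


def load_atlas(path: str | Path) -> ParcelAtlas:
    """Read a tab-delimited atlas table (region_id, hemisphere, functional_network)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"atlas file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str).reset_index(drop=True)
    return ParcelAtlas(table)


def network_nodes(atlas: ParcelAtlas, definition: NetworkDefinition) -> list[int]:
    """Module-level convenience wrapper around :meth:`ParcelAtlas.network_nodes`."""
    return atlas.network_nodes(definition)


def synthetic_atlas() -> ParcelAtlas:
    """Deterministic synthetic parcellation with realistic network cardinalities.

    Parcels are labelled ``L_0001 .. L_0180`` and ``R_0001 .. R_0180``.
    Functional networks are assigned in contiguous blocks split evenly
    across hemispheres: 56 cingulo-opercular, 6 orbito-affective, 23 dorsal
    attention, 50 frontoparietal, remainder "Other".  This is a synthetic
    stand-in for the published assignment table, which is not redistributed.
    """
    per_hemi: dict[str, list[str]] = {"L": [], "R": []}
    for name, size in NETWORK_SIZES.items():
        left = size // 2
        per_hemi["L"].extend([name] * left)
        per_hemi["R"].extend([name] * (size - left))
    half = N_REGIONS // 2
    for hemi in ("L", "R"):
        per_hemi[hemi].extend(["Other"] * (half - len(per_hemi[hemi])))
    rows = [
        {"region_id": f"{hemi}_{i + 1:04d}", "hemisphere": hemi, "functional_network": label}
        for hemi in ("L", "R")
        for i, label in enumerate(per_hemi[hemi])
    ]
    return ParcelAtlas(pd.DataFrame(rows, columns=list(ATLAS_COLUMNS)))


def save_atlas(atlas: ParcelAtlas, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)
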