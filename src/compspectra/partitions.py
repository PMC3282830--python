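"""Partition schemes (charsets) and taxon-group definitions.

Coordinates are 1-based inclusive in every user-facing definition and report,
matching the convention of NEXUS charsets; 0-based indices are used only
internally. NEXUS ``SETS`` blocks (including the ``\\3`` codon-stride
notation) are parsed with Bio.Nexus; a simple TSV dialect is provided for
scripting.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml
from Bio.Nexus import Nexus

from .errors import ConfigurationError, PartitionError


@dataclass
class PartitionScheme:
    """Named column blocks over an alignment.

    blocks maps a block name to a sorted tuple of 1-based column indices;
    frames optionally annotates a block with the codon position (1/2/3) of its
    first column.
    """

    blocks: dict[str, tuple[int, ...]]
    frames: dict[str, int] = field(default_factory=dict)
    allow_overlap: bool = False

    def __post_init__(self):
        cleaned = {}
        for name, cols in self.blocks.items():
            cols = tuple(sorted(set(int(c) for c in cols)))
            if not cols:
                raise PartitionError(f"block {name!r} selects no columns")
            if cols[0] < 1:
                raise PartitionError(f"block {name!r} has a column < 1")
            cleaned[name] = cols
        self.blocks = cleaned
        for name, frame in self.frames.items():
            if name not in self.blocks:
                raise PartitionError(f"frame given for unknown block {name!r}")
            if frame not in (1, 2, 3):
                raise PartitionError(f"frame for block {name!r} must be 1, 2 or 3")
        if not self.allow_overlap:
            seen: dict[int, str] = {}
            for name, cols in self.blocks.items():
                for c in cols:
                    if c in seen:
                        raise PartitionError(
                            f"column {c} appears in blocks {seen[c]!r} and {name!r} "
                            "(pass allow_overlap=True if intended)"
                        )
                    seen[c] = name

    @classmethod
    def from_ranges(
        cls,
        ranges: Mapping[str, Sequence[tuple[int, int] | tuple[int, int, int]]],
        frames: Optional[Mapping[str, int]] = None,
        allow_overlap: bool = False,
    ) -> "PartitionScheme":
        """Build from 1-based inclusive (start, stop[, step]) ranges per block."""
        blocks = {}
        for name, rs in ranges.items():
            cols: list[int] = []
            for r in rs:
                if len(r) == 2:
                    start, stop, step = r[0], r[1], 1
                else:
                    start, stop, step = r
                if start < 1 or stop < start or step < 1:
                    raise PartitionError(f"bad range {r!r} in block {name!r}")
                cols.extend(range(start, stop + 1, step))
            blocks[name] = tuple(cols)
        return cls(blocks, dict(frames or {}), allow_overlap)

    def columns(self, name: str) -> tuple[int, ...]:
        """Sorted 1-based columns of one block."""
        try:
            return self.blocks[name]
        except KeyError:
            raise PartitionError(f"unknown block {name!r}") from None

    def frame(self, name: str) -> Optional[int]:
        self.columns(name)
        return self.frames.get(name)

    def codon_position_columns(self, name: str, position: int) -> tuple[int, ...]:
        """1-based columns of a block at one codon position (1, 2 or 3).

        Positions are counted relative to the block's annotated frame and the
        block's own column order, not global coordinates, so genes
        concatenated at arbitrary offsets keep their reading frames.
        """
        if position not in (1, 2, 3):
            raise ConfigurationError("codon position must be 1, 2 or 3")
        frame = self.frames.get(name)
        if frame is None:
            raise ConfigurationError(f"block {name!r} has no codon-frame annotation")
        cols = self.columns(name)
        return tuple(
            c for i, c in enumerate(cols) if ((i + frame - 1) % 3) + 1 == position
        )

    def validate(self, length: int) -> None:
        for name, cols in self.blocks.items():
            if cols[-1] > length:
                raise PartitionError(
                    f"block {name!r} extends to column {cols[-1]} "
                    f"beyond alignment length {length}"
                )

    def total_columns(self) -> tuple[int, ...]:
        out: set[int] = set()
        for cols in self.blocks.values():
            out.update(cols)
        return tuple(sorted(out))


def read_charsets_nexus(path, frames: Optional[Mapping[str, int]] = None) -> PartitionScheme:
    """Parse charsets from a NEXUS SETS block (``charset cox1 = 1-1534;``).

    Codon subsetting via stride notation (``1-99\\3``) is supported. Frames
    are not expressible in standard NEXUS charsets, so they may be supplied
    separately.
    """
    nex = Nexus.Nexus(str(path))
    if not nex.charsets:
        raise PartitionError(f"no charsets found in {path}")
    blocks = {
        name: tuple(p + 1 for p in positions)  # Bio.Nexus is 0-based
        for name, positions in nex.charsets.items()
    }
    return PartitionScheme(blocks, dict(frames or {}), allow_overlap=True)


def read_charsets_tsv(path) -> PartitionScheme:
    """Parse a TSV charset table: ``block<TAB>ranges[<TAB>frame]``.

    ranges is a comma-separated list of 1-based ``start-stop`` or
    ``start-stop\\step`` items; frame, if present, is 1, 2 or 3.
    """
    blocks: dict[str, list[tuple[int, int, int]]] = {}
    frames: dict[str, int] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise PartitionError(f"{path}:{lineno}: expected 'block<TAB>ranges'")
        name, ranges = parts[0], parts[1]
        rs = []
        for item in ranges.split(","):
            item = item.strip()
            step = 1
            if "\\" in item:
                item, step_s = item.split("\\")
                step = int(step_s)
            if "-" in item:
                start_s, stop_s = item.split("-")
                start, stop = int(start_s), int(stop_s)
            else:
                start = stop = int(item)
            rs.append((start, stop, step))
        blocks[name] = rs
        if len(parts) >= 3 and parts[2].strip():
            frames[name] = int(parts[2])
    if not blocks:
        raise PartitionError(f"no charsets found in {path}")
    return PartitionScheme.from_ranges(blocks, frames, allow_overlap=True)


@dataclass
class TaxonGroups:
    """Taxon group assignments, a focal set, and named ingroup hypotheses.

    groups maps a group name (e.g. a family) to its taxon set. focal is the
    taxon set under study (entries in the source file may be group names,
    which are expanded). Each hypothesis names the groups forming the
    *ingroup* side of a directed split.
    """

    groups: dict[str, frozenset[str]]
    focal: frozenset[str] = frozenset()
    hypotheses: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.groups = {g: frozenset(t) for g, t in self.groups.items()}
        members: dict[str, str] = {}
        for g, taxa in self.groups.items():
            for t in taxa:
                if t in members:
                    raise ConfigurationError(
                        f"taxon {t!r} assigned to groups {members[t]!r} and {g!r}"
                    )
                members[t] = g
        self.focal = frozenset(self._expand(self.focal))
        self.hypotheses = {h: tuple(gs) for h, gs in self.hypotheses.items()}
        for h, gs in self.hypotheses.items():
            taxa = self.hypothesis_taxa(h)
            if self.focal and not taxa <= self.focal:
                raise ConfigurationError(
                    f"hypothesis {h!r} names taxa outside the focal set"
                )

    def _expand(self, names: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for n in names:
            if n in self.groups:
                out.update(self.groups[n])
            else:
                out.add(n)
        return out

    def group_of(self, taxon: str) -> Optional[str]:
        for g, taxa in self.groups.items():
            if taxon in taxa:
                return g
        return None

    def hypothesis_taxa(self, name: str) -> frozenset[str]:
        try:
            group_names = self.hypotheses[name]
        except KeyError:
            raise ConfigurationError(f"unknown hypothesis {name!r}") from None
        taxa: set[str] = set()
        for g in group_names:
            if g not in self.groups:
                raise ConfigurationError(
                    f"hypothesis {name!r} names unknown group {g!r}"
                )
            taxa.update(self.groups[g])
        return frozenset(taxa)

    def validate(self, taxa: Iterable[str]) -> None:
        """Check every listed taxon occurs in the given alignment taxon set."""
        known = set(taxa)
        listed = set().union(*self.groups.values()) if self.groups else set()
        listed |= self.focal
        unknown = listed - known
        if unknown:
            raise ConfigurationError(
                f"taxa not present in the alignment: {sorted(unknown)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "TaxonGroups":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        groups = {str(g): frozenset(map(str, taxa)) for g, taxa in (data.get("groups") or {}).items()}
        focal = frozenset(map(str, data.get("focal") or []))
        hypotheses = {str(h): tuple(map(str, gs)) for h, gs in (data.get("hypotheses") or {}).items()}
        return cls(groups, focal, hypotheses)

    def to_yaml(self, path) -> None:
        data = {
            "groups": {g: sorted(t) for g, t in self.groups.items()},
            "focal": sorted(self.focal),
            "hypotheses": {h: list(gs) for h, gs in self.hypotheses.items()},
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
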