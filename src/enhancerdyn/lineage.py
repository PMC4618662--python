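"""Enhancer activity and TF occupancy across a hematopoietic lineage tree.

Activity of an enhancer in a cell type is defined as overlap (>= 1 bp, with
a small flank absorbing summit offsets) between the enhancer region and that
cell type's H3K27Ac/H3K4Me1 peak calls; occupancy uses the cell type's
C/EBPα peak calls the same way.  The lineage tree (e.g. LT-HSC at the root,
myeloid and lymphoid branches below) is user-supplied configuration; the
tree of hematopoiesis used throughout the examples ships as a preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classes import EnhancerRecord, overlap_with_factor
from .genome import PeakSet, ValidationError

#: Preset hematopoietic lineage: child -> parent (root has parent None).
HEMATOPOIESIS_TREE: dict[str, str | None] = {
    "LT-HSC": None,
    "MPP": "LT-HSC",
    "CMP": "MPP",
    "GMP": "CMP",
    "Gn": "GMP",
    "MPhi": "GMP",
    "MEP": "CMP",
    "Ery": "MEP",
    "CLP": "MPP",
    "B": "CLP",
    "T": "CLP",
}


@dataclass
class LineageTree:
    """Rooted cell-type tree with optional per-type peak-file bindings."""

    parents: dict[str, str | None]
    peak_files: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [c for c, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {roots}")
        for child, parent in self.parents.items():
            if parent is not None and parent not in self.parents:
                raise ValidationError(f"parent {parent!r} of {child!r} not in tree")
        # acyclicity: walking up from every node must reach the root
        for node in self.parents:
            seen = set()
            cur: str | None = node
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"cycle detected at {cur!r}")
                seen.add(cur)
                cur = self.parents[cur]

    @property
    def root(self) -> str:
        return next(c for c, p in self.parents.items() if p is None)

    def children(self, node: str) -> list[str]:
        return [c for c, p in self.parents.items() if p == node]

    def leaves(self) -> list[str]:
        has_child = set(p for p in self.parents.values() if p is not None)
        return [c for c in self.parents if c not in has_child]

    def root_to_leaf_paths(self) -> list[list[str]]:
        """All root-to-leaf paths in depth-first order."""
        paths: list[list[str]] = []

        def dfs(node: str, path: list[str]) -> None:
            path = path + [node]
            kids = self.children(node)
            if not kids:
                paths.append(path)
            for k in kids:
                dfs(k, path)

        dfs(self.root, [])
        return paths


def read_tree(path: str | Path) -> LineageTree:
    """Parse a 'child: parent' tree config (parent '-' or empty = root)."""
    parents: dict[str, str | None] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'child: parent'")
        child, _, parent = (s.strip() for s in line.partition(":"))
        parents[child] = parent if parent not in ("", "-", "none", "None") else None
    return LineageTree(parents)


def activity_fractions(
    records: Sequence[EnhancerRecord],
    peaks_by_type: Mapping[str, PeakSet],
    flank: int = 500,
    classes: tuple[str, ...] = ("pre_existing", "de_novo"),
    by: str = "final_class",
) -> pd.DataFrame:
    """Cell type x class table of overlap fractions (mark-decorated activity)."""
    rows = {}
    for cell_type, peaks in peaks_by_type.items():
        rows[cell_type] = overlap_with_factor(records, peaks, flank, classes, by)
    table = pd.DataFrame.from_dict(rows, orient="index")[list(classes)]
    bad = table.stack().dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValidationError("fractions out of [0, 1]")
    return table


def occupancy_fractions(
    records: Sequence[EnhancerRecord],
    cebpa_peaks_by_type: Mapping[str, PeakSet],
    flank: int = 500,
    classes: tuple[str, ...] = ("pre_existing", "de_novo"),
    by: str = "final_class",
) -> pd.DataFrame:
    """Same contract as activity_fractions, over TF (C/EBPα) peak sets."""
    return activity_fractions(records, cebpa_peaks_by_type, flank, classes, by)


def trajectory_report(tree: LineageTree, activity: pd.DataFrame) -> dict:
    """Per root-to-leaf path, the ordered series of class fractions.

    Serializable to JSON: {"paths": [{"path": [...], "series": [{cell_type,
    <class fractions>}, ...]}, ...]}.
    """
    missing = [n for n in tree.parents if n not in activity.index]
    if missing:
        raise ValidationError(f"cell types missing from activity table: {missing}")
    report = {"paths": []}
    for path in tree.root_to_leaf_paths():
        series = []
        for node in path:
            entry = {"cell_type": node}
            entry.update({str(c): float(activity.loc[node, c]) for c in activity.columns})
            series.append(entry)
        report["paths"].append({"path": path, "series": series})
    return report
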