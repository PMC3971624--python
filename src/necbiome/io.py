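"""Data model and readers/writers for the cohort analysis.

The analysis consumes five tabular/tree inputs: an OTU count table
(samples x OTUs), a taxonomy map (OTU -> ranked Greengenes-style lineage),
a rooted phylogeny over the OTUs (Newick), per-sample metadata (infant,
day of life, outcome group, onset day), and per-infant urinary metabolite
values (alanine, histidine, pyridoxine in relative NMR units).

All identifiers are case-sensitive.  Day of life counts the birth day as
day 0 (a convention, configurable nowhere else: the two study windows are
days 4-9 and 10-16 inclusive under this numbering).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "OtuTable",
    "TaxonomyMap",
    "SampleRecord",
    "MetaboliteRecord",
    "Window",
    "WINDOW_1",
    "WINDOW_2",
    "RANKS",
    "FormatError",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "read_metabolites",
    "write_metabolites",
    "select_analysis_samples",
    "check_tree_consistency",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Window:
    """A postnatal sampling period, inclusive on both ends."""

    label: str
    first_day: int
    last_day: int

    def __post_init__(self) -> None:
        if self.first_day > self.last_day:
            raise ValueError(
                f"window {self.label!r}: first_day {self.first_day} > last_day {self.last_day}"
            )

    def contains(self, day: int) -> bool:
        return self.first_day <= day <= self.last_day


#: The two study windows: early (days 4-9) and late (days 10-16) colonization.
WINDOW_1 = Window("days_4_9", 4, 9)
WINDOW_2 = Window("days_10_16", 10, 16)


class OtuTable:
    """Integer OTU counts per sample: the substrate of all community analysis.

    Rows are samples, columns OTUs.  Counts are non-negative integers and
    every sample has at least one read.
    """

    def __init__(self, sample_ids: Sequence[str], otu_ids: Sequence[str], counts) -> None:
        counts = np.asarray(counts)
        sample_ids = list(map(str, sample_ids))
        otu_ids = list(map(str, otu_ids))
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError("duplicate sample ids in OTU table")
        if len(set(otu_ids)) != len(otu_ids):
            raise FormatError("duplicate OTU ids in OTU table")
        if counts.shape != (len(sample_ids), len(otu_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(sample_ids)} samples x {len(otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise FormatError("OTU counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = map(int, np.argwhere(counts < 0)[0])
            raise FormatError(
                f"negative count at sample {sample_ids[i]!r}, OTU {otu_ids[j]!r}"
            )
        row_sums = counts.sum(axis=1)
        if np.any(row_sums == 0):
            empty = sample_ids[int(np.argmin(row_sums))]
            raise FormatError(f"sample {empty!r} has zero total reads")
        self.sample_ids = sample_ids
        self.otu_ids = otu_ids
        self.counts = counts.astype(np.int64)
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}
        self._otu_index = {o: j for j, o in enumerate(otu_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """Count vector (over all OTUs) for one sample."""
        return self.counts[self._sample_index[sample_id]]

    def sample_depth(self, sample_id: str) -> int:
        return int(self.sample_counts(sample_id).sum())

    def relative_abundance(self, sample_id: str) -> np.ndarray:
        v = self.sample_counts(sample_id).astype(float)
        return v / v.sum()

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self._sample_index[s] for s in sample_ids]
        return OtuTable(list(sample_ids), self.otu_ids, self.counts[idx])

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        idx = [self._otu_index[o] for o in otu_ids]
        return OtuTable(self.sample_ids, list(otu_ids), self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._sample_index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"<OtuTable {len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs>"


@dataclass(frozen=True)
class Lineage:
    """Ranked taxonomic assignment; unassigned ranks are None.

    Assignment is prefix-closed: once a rank is unassigned, all deeper
    ranks are unassigned too.
    """

    kingdom: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None

    def at(self, rank: str) -> str | None:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, "class_" if rank == "class" else rank)

    @property
    def n_assigned(self) -> int:
        return sum(self.at(r) is not None for r in RANKS)


class TaxonomyMap:
    """OTU id -> :class:`Lineage`."""

    def __init__(self, lineages: dict[str, Lineage]) -> None:
        self._lineages = dict(lineages)

    def __getitem__(self, otu_id: str) -> Lineage:
        return self._lineages[otu_id]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def otu_ids(self) -> list[str]:
        return list(self._lineages)

    def items(self):
        return self._lineages.items()

    def check_covers(self, table: OtuTable) -> None:
        missing = [o for o in table.otu_ids if o not in self._lineages]
        if missing:
            raise FormatError(f"taxonomy missing {len(missing)} OTUs, e.g. {missing[0]!r}")


@dataclass(frozen=True)
class SampleRecord:
    """One stool sample: who, when, and the infant's outcome.

    ``onset_day`` is the NEC diagnosis day for cases and the death day for
    non-NEC deaths; absent for controls.
    """

    sample_id: str
    infant_id: str
    day_of_life: int
    group: str  # "NEC" | "control" | "non_NEC_death"
    onset_day: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ("NEC", "control", "non_NEC_death"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "NEC" and self.onset_day is None:
            raise ValueError(f"NEC sample {self.sample_id!r} lacks onset_day")
        if self.onset_day is not None and self.onset_day <= 0:
            raise ValueError(f"onset_day must be > 0, got {self.onset_day}")
        if self.day_of_life < 0:
            raise ValueError("day_of_life must be >= 0")


@dataclass(frozen=True)
class MetaboliteRecord:
    """Urinary NMR metabolite values for one infant on one day (relative units)."""

    infant_id: str
    day_of_life: int
    alanine: float
    histidine: float
    pyridoxine: float

    def __post_init__(self) -> None:
        for name in ("alanine", "histidine", "pyridoxine"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0 for infant {self.infant_id!r}")


# ---------------------------------------------------------------------------
# OTU table


def read_otu_table(path, samples_as_rows: bool = True) -> OtuTable:
    """Read a tab-separated OTU count table.

    First column holds sample ids (or OTU ids with ``samples_as_rows=False``),
    header row the OTU ids.  File order is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if not samples_as_rows:
        df = df.T
    sample_ids = [str(s) for s in df.index]
    otu_ids = [str(o) for o in df.columns]
    counts = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {cell!r} at sample {sample_ids[i]!r}, "
                    f"OTU {otu_ids[j]!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"negative count {value} at sample {sample_ids[i]!r}, OTU {otu_ids[j]!r}"
                )
            counts[i, j] = value
    return OtuTable(sample_ids, otu_ids, counts)


def write_otu_table(table: OtuTable, path) -> None:
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Taxonomy


def _parse_lineage(text: str, greengenes: bool = True) -> Lineage:
    parts = [p.strip() for p in text.split(";")]
    if len(parts) > len(RANKS):
        raise FormatError(f"lineage has {len(parts)} ranks (max {len(RANKS)}): {text!r}")
    names: list[str | None] = []
    for i, part in enumerate(parts):
        if greengenes:
            prefix = _RANK_PREFIXES[i]
            if not part.startswith(prefix):
                raise FormatError(
                    f"rank {i + 1} of lineage {text!r} lacks prefix {prefix!r}"
                )
            name = part[len(prefix):].strip()
        else:
            name = part
        names.append(name or None)
    names += [None] * (len(RANKS) - len(names))
    # enforce prefix-closure: an assigned rank below an unassigned one is malformed
    seen_gap = False
    for name in names:
        if name is None:
            seen_gap = True
        elif seen_gap:
            raise FormatError(f"lineage {text!r} assigns a rank below an unassigned one")
    return Lineage(*names)


def read_taxonomy(path, greengenes: bool = True) -> TaxonomyMap:
    """Read a two-column TSV of OTU id and lineage string.

    The default dialect is Greengenes rank prefixes ("k__Bacteria; p__...");
    ``greengenes=False`` accepts plain semicolon-separated rank names.
    """
    lineages: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0]:
                raise FormatError(f"{path}:{lineno}: expected 'otu_id<TAB>lineage'")
            otu_id, lineage = fields
            if otu_id in lineages:
                raise FormatError(f"{path}:{lineno}: duplicate OTU id {otu_id!r}")
            lineages[otu_id] = _parse_lineage(lineage, greengenes=greengenes)
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        for otu_id, lin in tax.items():
            parts = [
                f"{pref}{lin.at(rank) or ''}"
                for pref, rank in zip(_RANK_PREFIXES, RANKS)
            ]
            fh.write(f"{otu_id}\t{'; '.join(parts)}\n")


# ---------------------------------------------------------------------------
# Tree


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths.

    Every non-root node must carry a branch length; a missing root length is
    set to 0.  Negative lengths are rejected.
    """
    tree = TreeNode.read(str(path), format="newick")
    if tree.length is None:
        tree.length = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(
                f"node {node.name or '<internal>'} has no branch length"
            )
        if not np.isfinite(node.length) or node.length < 0:
            raise FormatError(
                f"node {node.name or '<internal>'} has invalid branch length {node.length}"
            )
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def check_tree_consistency(table: OtuTable, tree: TreeNode) -> None:
    """Require every OTU of the table to appear as exactly one tree leaf."""
    leaf_names = [t.name for t in tree.tips()]
    if len(set(leaf_names)) != len(leaf_names):
        raise FormatError("tree has duplicate leaf names")
    leaves = set(leaf_names)
    missing = [o for o in table.otu_ids if o not in leaves]
    if missing:
        raise FormatError(f"OTU {missing[0]!r} absent from tree ({len(missing)} missing)")


# ---------------------------------------------------------------------------
# Metadata and metabolites


def read_metadata(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "infant_id": str})
    required = {"sample_id", "infant_id", "day_of_life", "group", "onset_day"}
    if not required.issubset(df.columns):
        raise FormatError(f"metadata must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        onset = None if pd.isna(row.onset_day) else int(row.onset_day)
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                infant_id=str(row.infant_id),
                day_of_life=int(row.day_of_life),
                group=str(row.group),
                onset_day=onset,
            )
        )
    return records


def write_metadata(records: Iterable[SampleRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "infant_id": r.infant_id,
                "day_of_life": r.day_of_life,
                "group": r.group,
                "onset_day": "" if r.onset_day is None else r.onset_day,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_metabolites(path) -> list[MetaboliteRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"infant_id": str})
    required = {"infant_id", "day_of_life", "alanine", "histidine", "pyridoxine"}
    if not required.issubset(df.columns):
        raise FormatError(f"metabolite table must have columns {sorted(required)}")
    return [
        MetaboliteRecord(
            infant_id=str(r.infant_id),
            day_of_life=int(r.day_of_life),
            alanine=float(r.alanine),
            histidine=float(r.histidine),
            pyridoxine=float(r.pyridoxine),
        )
        for r in df.itertuples(index=False)
    ]


def write_metabolites(records: Iterable[MetaboliteRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "infant_id": r.infant_id,
                "day_of_life": r.day_of_life,
                "alanine": r.alanine,
                "histidine": r.histidine,
                "pyridoxine": r.pyridoxine,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Analysis-sample selection


def select_analysis_samples(
    records: Sequence[SampleRecord], window: Window
) -> list[SampleRecord]:
    """Select at most one pre-onset sample per infant within a window.

    Samples collected on or after the infant's onset day (NEC diagnosis or
    death) are excluded first; among an infant's remaining in-window samples
    the earliest is kept, ensuring statistical independence across infants.
    Output order follows first appearance of each infant in the input.
    """
    best: dict[str, SampleRecord] = {}
    order: list[str] = []
    for rec in records:
        if not window.contains(rec.day_of_life):
            continue
        if rec.onset_day is not None and rec.day_of_life >= rec.onset_day:
            continue
        if rec.infant_id not in best:
            best[rec.infant_id] = rec
            order.append(rec.infant_id)
        elif rec.day_of_life < best[rec.infant_id].day_of_life:
            best[rec.infant_id] = rec
    return [best[i] for i in order]
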