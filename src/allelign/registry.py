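"""The persistent variant registry: authoritative allele orientation per site.

A registry is a directory of chromosome-level parquet partitions plus a JSON
manifest.  It starts empty and grows monotonically: the first dataset
realigned against it fixes the orientation of every site it contributes, and
later datasets are classified against (never allowed to rewrite) that record.

The registry key is genomic position alone — ``(chrom, pos)`` — so a site can
host exactly one registered allele pair.  A later dataset presenting a
different pair at a registered site is an ALLELE_MISMATCH, reported but never
registered.

Partitions are loaded lazily and independently: classifying chr7 records
touches only the chr7 partition file.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .core import CHROMOSOMES, VariantRecord, chromosome_sort_key
from .errors import (
    DuplicatePositionInBatch,
    PathNotWritable,
    RegistryExists,
    RegistryNotFound,
)

__all__ = ["MatchClass", "Registry", "RegistryEntry"]

_PARTITION_COLUMNS = ["pos", "ref", "alt", "first_seen_dataset", "first_seen_id"]
_MANIFEST = "manifest.json"


class MatchClass(str, Enum):
    """Classification of a dataset variant against the registry.

    Exhaustive and mutually exclusive for any (record, registry) pair:

    - FORWARD: an entry at (chrom, pos) with (ref, alt) == (a2, a1)
    - REVERSE: an entry with (ref, alt) == (a1, a2) — marked for realignment
    - NOVEL_POSITION: no entry at (chrom, pos) — registered for addition
    - ALLELE_MISMATCH: an entry exists but the allele pair matches in neither
      orientation
    """

    FORWARD = "FORWARD"
    REVERSE = "REVERSE"
    NOVEL_POSITION = "NOVEL_POSITION"
    ALLELE_MISMATCH = "ALLELE_MISMATCH"


@dataclass(frozen=True)
class RegistryEntry:
    """The authoritative orientation of one biallelic SNP."""

    chrom: str
    pos: int
    ref: str
    alt: str
    first_seen_dataset: str
    first_seen_id: str


def _empty_partition() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pos": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=object),
            "alt": pd.Series(dtype=object),
            "first_seen_dataset": pd.Series(dtype=object),
            "first_seen_id": pd.Series(dtype=object),
        }
    )


class Registry:
    """Chromosome-partitioned on-disk variant database.

    Use :meth:`create` / :meth:`load` instead of the constructor.  A single
    writer per registry is assumed; parallelism belongs across chromosomes
    within one run or across distinct registries.
    """

    def __init__(self, root: Union[str, Path], name: str):
        self.root = Path(root)
        self.name = name
        self._partitions: dict[str, pd.DataFrame] = {}  # lazy cache

    # ---------------------------------------------------------------- layout

    @property
    def path(self) -> Path:
        return self.root / self.name

    def partition_path(self, chrom: str) -> Path:
        return self.path / f"chr{chrom}.parquet"

    @property
    def manifest_path(self) -> Path:
        return self.path / _MANIFEST

    @property
    def loaded_chromosomes(self) -> tuple[str, ...]:
        """Chromosomes whose partitions are currently in memory (lazy-load bookkeeping)."""
        return tuple(self._partitions)

    # ------------------------------------------------------------- lifecycle

    @classmethod
    def create(cls, root: Union[str, Path], name: str, force: bool = False) -> "Registry":
        """Create an empty registry ``<root>/<name>`` on disk."""
        root = Path(root)
        target = root / name
        if target.exists():
            if not force:
                raise RegistryExists(f"registry already exists: {target}")
            for f in target.glob("chr*.parquet"):
                f.unlink()
            if (target / _MANIFEST).exists():
                (target / _MANIFEST).unlink()
        try:
            target.mkdir(parents=True, exist_ok=True)
            probe = target / ".write_probe"
            probe.write_text("")
            probe.unlink()
        except OSError as exc:
            raise PathNotWritable(f"cannot write under {root}: {exc}") from None
        reg = cls(root, name)
        manifest = {
            "name": name,
            "created": datetime.now(timezone.utc).isoformat(),
            "datasets": [],
        }
        reg.manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        return reg

    @classmethod
    def load(cls, root: Union[str, Path], name: str) -> "Registry":
        reg = cls(root, name)
        if not reg.manifest_path.exists():
            raise RegistryNotFound(f"no registry named {name!r} under {root}")
        return reg

    def manifest(self) -> dict:
        return json.loads(self.manifest_path.read_text())

    def append_manifest_run(self, entry: dict) -> None:
        """Record one realign run (append-only; entries are never rewritten)."""
        manifest = self.manifest()
        manifest["datasets"].append(entry)
        self.manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    @property
    def identity(self) -> str:
        """Stable identifier used to check that composites share a registry."""
        return f"{self.path.resolve()}"

    # ------------------------------------------------------------ partitions

    def partition(self, chrom: str) -> pd.DataFrame:
        """The (pos-sorted) entry table for one chromosome; loaded lazily."""
        if chrom not in self._partitions:
            p = self.partition_path(chrom)
            if p.exists():
                self._partitions[chrom] = pd.read_parquet(p)
            else:
                self._partitions[chrom] = _empty_partition()
        return self._partitions[chrom]

    def _write_partition(self, chrom: str, frame: pd.DataFrame) -> None:
        frame = frame.sort_values("pos", kind="mergesort").reset_index(drop=True)
        self._partitions[chrom] = frame
        frame.to_parquet(self.partition_path(chrom), index=False)

    def n_entries(self, chrom: Optional[str] = None) -> int:
        if chrom is not None:
            return len(self.partition(chrom))
        total = 0
        for c in CHROMOSOMES:
            if self.partition_path(c).exists():
                total += len(self.partition(c))
        return total

    def entries(self) -> pd.DataFrame:
        """All entries across chromosomes, in natural chromosome order."""
        frames = []
        for c in CHROMOSOMES:
            if self.partition_path(c).exists():
                part = self.partition(c).copy()
                part.insert(0, "chrom", c)
                frames.append(part)
        if not frames:
            out = _empty_partition()
            out.insert(0, "chrom", pd.Series(dtype=object))
            return out
        return pd.concat(frames, ignore_index=True)

    # -------------------------------------------------------- classification

    def classify(self, rec: VariantRecord) -> MatchClass:
        """Classify a single record (see :class:`MatchClass`)."""
        part = self.partition(rec.chrom)
        hit = part[part["pos"].to_numpy() == rec.pos]
        if hit.empty:
            return MatchClass.NOVEL_POSITION
        ref, alt = hit.iloc[0]["ref"], hit.iloc[0]["alt"]
        if (ref, alt) == (rec.a2, rec.a1):
            return MatchClass.FORWARD
        if (ref, alt) == (rec.a1, rec.a2):
            return MatchClass.REVERSE
        return MatchClass.ALLELE_MISMATCH

    def classify_frame(self, df: pd.DataFrame) -> pd.Series:
        """Vectorized classification of a chrom/pos/a1/a2 frame.

        Returns a Series of :class:`MatchClass` values aligned to ``df``'s
        index.  Only the partitions of chromosomes present in ``df`` are read.
        """
        out = pd.Series(index=df.index, dtype=object)
        for chrom, sub in df.groupby("chrom", sort=False):
            part = self.partition(chrom)
            merged = sub[["pos", "a1", "a2"]].merge(
                part[["pos", "ref", "alt"]], on="pos", how="left"
            )
            merged.index = sub.index
            novel = merged["ref"].isna()
            fwd = (merged["ref"] == merged["a2"]) & (merged["alt"] == merged["a1"])
            rev = (merged["ref"] == merged["a1"]) & (merged["alt"] == merged["a2"])
            cls = np.where(
                novel,
                MatchClass.NOVEL_POSITION.value,
                np.where(
                    fwd,
                    MatchClass.FORWARD.value,
                    np.where(rev, MatchClass.REVERSE.value, MatchClass.ALLELE_MISMATCH.value),
                ),
            )
            out.loc[sub.index] = cls
        return out.map(MatchClass)

    # ---------------------------------------------------------- registration

    def register_novel(
        self,
        records: Union[pd.DataFrame, Iterable[VariantRecord]],
        dataset_label: str,
    ) -> int:
        """Add NOVEL_POSITION records to the registry; returns the count added.

        The orientation recorded is the dataset's own: ref = a2, alt = a1.
        Growth is strictly monotonic — existing entries are never touched.

        Raises
        ------
        DuplicatePositionInBatch
            If two input records share (chrom, pos); clean() must resolve
            duplications before registration.
        ValueError
            If any record's position is already registered (it is not novel).
        """
        if isinstance(records, pd.DataFrame):
            df = records
        else:
            df = pd.DataFrame(
                [
                    {"chrom": r.chrom, "pos": r.pos, "a1": r.a1, "a2": r.a2, "id": r.dataset_id}
                    for r in records
                ]
            )
        if df.empty:
            return 0
        if df.duplicated(subset=["chrom", "pos"]).any():
            dup = df[df.duplicated(subset=["chrom", "pos"], keep=False)].iloc[0]
            raise DuplicatePositionInBatch(
                f"batch contains repeated position {dup['chrom']}:{dup['pos']}"
            )
        added = 0
        ids = df["id"] if "id" in df.columns else pd.Series("", index=df.index)
        for chrom in sorted(df["chrom"].unique(), key=chromosome_sort_key):
            sub = df[df["chrom"] == chrom]
            part = self.partition(chrom)
            clash = sub["pos"].isin(part["pos"])
            if clash.any():
                pos = sub.loc[clash, "pos"].iloc[0]
                raise ValueError(
                    f"position {chrom}:{pos} is already registered; "
                    "only NOVEL_POSITION records may be added"
                )
            new = pd.DataFrame(
                {
                    "pos": sub["pos"].to_numpy(np.int64),
                    "ref": sub["a2"].to_numpy(),
                    "alt": sub["a1"].to_numpy(),
                    "first_seen_dataset": dataset_label,
                    "first_seen_id": ids.loc[sub.index].to_numpy(),
                }
            )
            self._write_partition(chrom, pd.concat([part, new], ignore_index=True))
            added += len(new)
        return added
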