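"""merge (combine per-chromosome reports) and intersect (common SNP set).

After each dataset has been realigned chromosome by chromosome, *merge*
concatenates its per-chromosome identified/reassigned reports into one
composite report with per-chromosome count bookkeeping.  *intersect* then
takes the composites of two or more datasets — all realigned against the
same registry — and computes the maximal set of canonical indices common to
every dataset, plus per-dataset extract lists keyed by each dataset's
original variant IDs (directly usable to subset genotype files).

Because realign already harmonized orientation, intersection is plain string
intersection on canonical indices; encountering an index and its reverse
across composites would indicate a realign defect and raises immediately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .core import chromosome_sort_key, reverse_index
from .errors import (
    DuplicateChromosomeReport,
    MixedDatasetLabels,
    RegistryMismatch,
    SingleDatasetWarning,
)
from .io import read_report, write_report

__all__ = [
    "CompositeReport",
    "IntersectionSet",
    "merge_reports",
    "intersect_datasets",
    "write_intersection",
]


def _site_key(canonical: str) -> tuple[int, int, str]:
    chrom, pos, rest = canonical.split(":", 2)
    return (chromosome_sort_key(chrom), int(pos), rest)


@dataclass
class CompositeReport:
    """Dataset-level union of per-chromosome realign reports.

    ``identified`` maps canonical index → original dataset ID; ``inverted``
    is the subset of indices whose records were reassigned (flipped).
    """

    dataset_label: str
    registry: str
    identified: dict[str, str]
    inverted: set[str]
    per_chrom_counts: dict[str, tuple[int, int]]

    @property
    def identified_set(self) -> set[str]:
        return set(self.identified)

    def write(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        rows = pd.DataFrame(
            {
                "canonical_index": list(self.identified),
                "original_id": [self.identified[k] for k in self.identified],
            }
        )
        rows["inverted"] = rows["canonical_index"].isin(self.inverted).astype(int)
        rows = rows.sort_values(
            "canonical_index", key=lambda s: s.map(_site_key), kind="mergesort"
        )
        with open(path, "w") as fh:
            fh.write(f"# dataset={self.dataset_label}\n")
            fh.write(f"# registry={self.registry}\n")
            fh.write(
                "# per_chrom="
                + json.dumps({c: list(v) for c, v in self.per_chrom_counts.items()})
                + "\n"
            )
            rows.to_csv(fh, sep="\t", index=False)
        return path

    @classmethod
    def read(cls, path: Union[str, Path]) -> "CompositeReport":
        frame, meta = read_report(path)
        identified = dict(zip(frame["canonical_index"], frame["original_id"]))
        inverted = set(frame.loc[frame["inverted"].astype(int) == 1, "canonical_index"])
        per_chrom = {
            c: tuple(v) for c, v in json.loads(meta.get("per_chrom", "{}")).items()
        }
        return cls(
            dataset_label=meta["dataset"],
            registry=meta["registry"],
            identified=identified,
            inverted=inverted,
            per_chrom_counts=per_chrom,
        )


def merge_reports(identified_reports: Sequence[Union[str, Path]]) -> CompositeReport:
    """Combine one dataset's per-chromosome identified reports.

    Each path must be a ``chr<C>.identified.tsv`` written by realign; the
    sibling ``chr<C>.reassigned.tsv`` is read alongside to populate the
    inverted set.  All reports must carry the same dataset label and no
    chromosome may appear twice.
    """
    labels: set[str] = set()
    registries: set[str] = set()
    seen_chroms: set[str] = set()
    identified: dict[str, str] = {}
    inverted: set[str] = set()
    per_chrom: dict[str, tuple[int, int]] = {}

    for path in identified_reports:
        path = Path(path)
        frame, meta = read_report(path)
        labels.add(meta["dataset"])
        registries.add(meta["registry"])
        if len(labels) > 1:
            raise MixedDatasetLabels(
                f"reports from different datasets supplied to one merge: {sorted(labels)}"
            )
        chrom = meta["chrom"]
        if chrom in seen_chroms:
            raise DuplicateChromosomeReport(f"chromosome {chrom} supplied twice")
        seen_chroms.add(chrom)

        sibling = path.with_name(path.name.replace(".identified.", ".reassigned."))
        inv_frame, _ = read_report(sibling)

        for idx, oid in zip(frame["canonical_index"], frame["original_id"]):
            identified[idx] = oid
        inverted.update(inv_frame["canonical_index"])
        per_chrom[chrom] = (len(frame), len(inv_frame))

    if len(registries) > 1:
        raise RegistryMismatch(
            f"reports realigned against different registries: {sorted(registries)}"
        )
    return CompositeReport(
        dataset_label=labels.pop() if labels else "",
        registry=registries.pop() if registries else "",
        identified=identified,
        inverted=inverted,
        per_chrom_counts=per_chrom,
    )


@dataclass
class IntersectionSet:
    """The maximal set of canonical indices common to all datasets."""

    members: set[str]
    n_datasets: int

    def sorted_members(self) -> list[str]:
        return sorted(self.members, key=_site_key)


def intersect_datasets(composites: Sequence[CompositeReport]) -> IntersectionSet:
    """Intersect the identified sets of all composites.

    All composites must stem from the same registry (checked via the
    provenance recorded in the report headers).  A single composite yields
    itself with a :class:`SingleDatasetWarning`.  Finding a canonical index
    and its reverse anywhere in the union means orientations were not
    harmonized and raises ``RuntimeError``.
    """
    if not composites:
        raise ValueError("no composites supplied")
    registries = {c.registry for c in composites}
    if len(registries) > 1:
        raise RegistryMismatch(
            f"composites stem from different registries: {sorted(registries)}"
        )

    union: set[str] = set()
    for comp in composites:
        union |= comp.identified_set
    for idx in union:
        if reverse_index(idx) in union:
            raise RuntimeError(
                f"orientation conflict in harmonized reports: {idx} and its "
                "reverse both present — realign output is inconsistent"
            )

    if len(composites) == 1:
        warnings.warn(
            "intersection of a single dataset is that dataset's identified set",
            SingleDatasetWarning,
            stacklevel=2,
        )
        return IntersectionSet(members=composites[0].identified_set, n_datasets=1)

    members = set.intersection(*(c.identified_set for c in composites))
    return IntersectionSet(members=members, n_datasets=len(composites))


def write_intersection(
    intersection: IntersectionSet,
    composites: Sequence[CompositeReport],
    out: Union[str, Path],
) -> dict[str, Path]:
    """Write the sorted index list plus per-dataset extract lists.

    Returns a map of output name → path.  Extract lists hold each dataset's
    original variant IDs for the intersected sites, one per line, for direct
    use with genotype-subsetting tools.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    members = intersection.sorted_members()
    main = out / "intersection.txt"
    main.write_text("".join(m + "\n" for m in members))
    paths["intersection"] = main

    for comp in composites:
        lst = out / f"{comp.dataset_label}.extract.txt"
        ids = [comp.identified[m] for m in members]
        lst.write_text("".join(i + "\n" for i in ids))
        paths[comp.dataset_label] = lst
    return paths
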