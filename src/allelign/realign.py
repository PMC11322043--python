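"""The three-stage realign pipeline: clean → register → align.

*clean* identifies valid biallelic SNPs and resolves duplication and
multiple-indexing issues via a graph formulation: variant positions are
nodes, and each dataset ID occurring at two or more distinct positions
contributes edges connecting those positions.  Every position incident to at
least one edge is invalid — some ID points to it and to somewhere else — and
all of its rows are removed.

*register* reformulates each surviving variant as its canonical
``CHR:POS:REF:ALT`` index and compares it against the registry: FORWARD
records are already consistent, REVERSE records are marked for realignment,
NOVEL_POSITION records are queued for addition, and ALLELE_MISMATCH records
are reported and excluded.

*align* flips the REVERSE records (swapping alleles and, for summary
statistics, negating betas / taking reciprocal odds ratios / complementing
effect-allele frequencies), registers the novel records, and writes the
realigned output plus per-chromosome report files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import (
    DatasetSpec,
    VariantRecord,
    canonical_index_series,
    chromosome_sort_key,
    normalize_chromosome,
)
from .errors import EmptyInputWarning, NonFiniteStatistic
from .io import FLOAT_FORMAT, read_dataset, write_report
from .registry import MatchClass, Registry

__all__ = [
    "CleanResult",
    "AlignResult",
    "clean",
    "flip_record",
    "flip_frame",
    "realign_dataset",
    "write_reassignment_file",
]

REPORT_KINDS = (
    "identified",
    "reassigned",
    "duplicates",
    "invalid",
    "nonbiallelic",
    "mismatched",
)

#: Name of the canonical-index column appended to realigned outputs.
INDEX_COLUMN = "CANONICAL_ID"


@dataclass
class CleanResult:
    """Partition of the input rows into the four clean buckets.

    ``valid`` ∪ ``invalid_multi_indexed`` ∪ ``duplicates`` ∪ ``non_biallelic``
    covers every input row exactly once.  Within ``valid``, (chrom, pos) is
    unique and every dataset ID maps to exactly one position.
    """

    valid: pd.DataFrame
    invalid_multi_indexed: pd.DataFrame
    duplicates: pd.DataFrame
    non_biallelic: pd.DataFrame

    @property
    def n_input(self) -> int:
        return (
            len(self.valid)
            + len(self.invalid_multi_indexed)
            + len(self.duplicates)
            + len(self.non_biallelic)
        )


def clean(df: pd.DataFrame) -> CleanResult:
    """Partition a standardized variant frame into the four clean buckets.

    Precedence of rules, applied in order:

    1. rows failing the biallelic-SNP allele test → ``non_biallelic``;
    2. positions linked by a multi-position dataset ID (the graph rule):
       ALL rows at such positions → ``invalid_multi_indexed``;
    3. exact-identity duplicates (same chrom, pos and allele pair): the first
       occurrence in file order survives, the rest → ``duplicates``;
    4. positions still carrying more than one distinct allele pair
       (multiallelic by rows): all their rows → ``invalid_multi_indexed``.

    Never raises: every problem is routed to a report bucket.
    """
    allele_ok = (
        df["a1"].isin(list("ACGT")) & df["a2"].isin(list("ACGT")) & (df["a1"] != df["a2"])
    )
    non_biallelic = df[~allele_ok]
    work = df[allele_ok]

    # Graph rule: an ID at >=2 distinct positions invalidates all of them.
    # Connected components are irrelevant here — incidence to any edge is
    # already disqualifying — so a position multimap suffices.
    positions = work[["chrom", "pos"]].apply(tuple, axis=1) if len(work) else pd.Series(dtype=object)
    if len(work):
        per_id = positions.groupby(work["id"]).nunique()
        bad_ids = set(per_id[per_id >= 2].index)
        bad_positions = set(positions[work["id"].isin(bad_ids)])
        invalid_mask = positions.isin(bad_positions)
    else:
        invalid_mask = pd.Series(dtype=bool)
    invalid = work[invalid_mask] if len(work) else work
    work = work[~invalid_mask] if len(work) else work

    dup_mask = (
        work.duplicated(subset=["chrom", "pos", "a1", "a2"], keep="first")
        if len(work)
        else pd.Series(dtype=bool)
    )
    duplicates = work[dup_mask] if len(work) else work
    work = work[~dup_mask] if len(work) else work

    # Multiallelic by rows: distinct surviving allele pairs at one position.
    if len(work):
        multi_mask = work.duplicated(subset=["chrom", "pos"], keep=False)
        invalid = pd.concat([invalid, work[multi_mask]])
        work = work[~multi_mask]

    return CleanResult(
        valid=work,
        invalid_multi_indexed=invalid,
        duplicates=duplicates,
        non_biallelic=non_biallelic,
    )


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise NonFiniteStatistic(f"cannot flip records with non-finite {what}")


def flip_record(rec: VariantRecord, effect_scale: str = "none") -> VariantRecord:
    """Swap a record's allele orientation, transforming its statistics.

    Effect size is negated (beta scale) or inverted (odds-ratio scale);
    effect-allele frequency becomes its complement; the p-value and position
    are untouched (two-sided tests are allele-labeling invariant).  Applying
    the flip twice recovers the input to within 1e-12 on statistics.
    """
    stats = dict(rec.stats) if rec.stats else None
    if stats:
        if "effect_size" in stats:
            es = float(stats["effect_size"])
            _check_finite(np.asarray([es]), "effect_size")
            if effect_scale == "beta":
                stats["effect_size"] = -es
            elif effect_scale == "odds_ratio":
                if es == 0:
                    raise NonFiniteStatistic("cannot invert an odds ratio of 0")
                stats["effect_size"] = 1.0 / es
        if "effect_allele_freq" in stats:
            freq = float(stats["effect_allele_freq"])
            _check_finite(np.asarray([freq]), "effect_allele_freq")
            stats["effect_allele_freq"] = 1.0 - freq
    return replace(rec, a1=rec.a2, a2=rec.a1, stats=stats)


def flip_frame(df: pd.DataFrame, effect_scale: str = "none") -> pd.DataFrame:
    """Vectorized :func:`flip_record` over a standardized frame."""
    out = df.copy()
    out["a1"], out["a2"] = df["a2"], df["a1"]
    if "effect_size" in out.columns and effect_scale != "none":
        es = out["effect_size"].to_numpy(float)
        _check_finite(es, "effect_size")
        if effect_scale == "beta":
            out["effect_size"] = -es
        else:  # odds_ratio
            if np.any(es == 0):
                raise NonFiniteStatistic("cannot invert an odds ratio of 0")
            out["effect_size"] = 1.0 / es
    if "effect_allele_freq" in out.columns:
        freq = out["effect_allele_freq"].to_numpy(float)
        _check_finite(freq, "effect_allele_freq")
        out["effect_allele_freq"] = 1.0 - freq
    return out


@dataclass
class AlignResult:
    """Outcome of one realign run for one dataset."""

    dataset_label: str
    format: str
    n_input_rows: int
    n_identified: int  # |CleanResult.valid|
    n_reassigned: int  # REVERSE records flipped into registry orientation
    n_registered: int  # NOVEL_POSITION records added to the registry
    n_duplicates: int
    n_invalid: int
    n_non_biallelic: int
    n_mismatched: int
    n_palindromic: int  # A/T and C/G pairs among valid (warning count only)
    realigned_records: pd.DataFrame  # standardized, registry orientation, + canonical_index
    mismatched: pd.DataFrame
    reassignment_rows: pd.DataFrame  # (id, new_alt, chrom, pos), genotype inputs
    clean_result: CleanResult
    output_dir: Optional[Path] = None
    outputs: dict = field(default_factory=dict)


def _sorted_by_site(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(chromosome_sort_key)
    return df.assign(_ck=key).sort_values(["_ck", "pos"], kind="mergesort").drop(columns="_ck")


_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def realign_dataset(
    spec: DatasetSpec,
    registry: Registry,
    outdir: Optional[Union[str, Path]] = None,
    chrom: Optional[str] = None,
) -> AlignResult:
    """Run clean → register → align for one dataset and write its artifacts.

    Parameters
    ----------
    spec
        Input description (path, dialect, column roles, effect scale).
    registry
        The registry defining (and extended with) authoritative orientation.
    outdir
        Where to write realigned output and reports; omit for in-memory use.
    chrom
        Restrict processing to one chromosome (external parallelization).
    """
    raw, std = read_dataset(spec)
    if chrom is not None:
        code = normalize_chromosome(chrom)
        std = std[std["chrom"] == code]
        raw = raw.loc[std.index]

    cr = clean(std)
    valid = cr.valid

    if len(valid) == 0:
        warnings.warn(
            f"{spec.dataset_label}: no valid biallelic SNPs in input",
            EmptyInputWarning,
            stacklevel=2,
        )

    if len(valid):
        cls = registry.classify_frame(valid)
        fwd = cls == MatchClass.FORWARD
        rev = cls == MatchClass.REVERSE
        novel = cls == MatchClass.NOVEL_POSITION
        mism = cls == MatchClass.ALLELE_MISMATCH
    else:
        fwd = rev = novel = mism = pd.Series(dtype=bool)

    effect_scale = spec.effect_scale if spec.format == "sumstats" else "none"
    flipped = flip_frame(valid[rev], effect_scale) if rev.any() else valid.iloc[0:0]

    novel_df = valid[novel]
    n_registered = registry.register_novel(novel_df, spec.dataset_label) if len(novel_df) else 0

    harmonized = pd.concat([valid[fwd], flipped, novel_df]) if len(valid) else valid
    harmonized = _sorted_by_site(harmonized) if len(harmonized) else harmonized
    harmonized = harmonized.copy()
    harmonized["canonical_index"] = (
        canonical_index_series(harmonized) if len(harmonized) else pd.Series(dtype=object)
    )

    mismatched = valid[mism] if len(valid) else valid
    n_palindromic = (
        int(valid.apply(lambda r: (r["a1"], r["a2"]) in _PALINDROMES, axis=1).sum())
        if len(valid)
        else 0
    )

    if rev.any() and spec.format in ("pvar", "bim"):
        reassign = _sorted_by_site(flipped)[["id", "a1", "chrom", "pos"]].rename(
            columns={"a1": "new_alt"}
        )
    else:
        reassign = pd.DataFrame(columns=["id", "new_alt", "chrom", "pos"])

    result = AlignResult(
        dataset_label=spec.dataset_label,
        format=spec.format,
        n_input_rows=len(std),
        n_identified=len(valid),
        n_reassigned=int(rev.sum()),
        n_registered=n_registered,
        n_duplicates=len(cr.duplicates),
        n_invalid=len(cr.invalid_multi_indexed),
        n_non_biallelic=len(cr.non_biallelic),
        n_mismatched=int(mism.sum()),
        n_palindromic=n_palindromic,
        realigned_records=harmonized,
        mismatched=mismatched,
        reassignment_rows=reassign.reset_index(drop=True),
        clean_result=cr,
    )

    if outdir is not None:
        _write_artifacts(result, spec, registry, raw, std, Path(outdir))

    registry.append_manifest_run(
        {
            "dataset_label": spec.dataset_label,
            "format": spec.format,
            "path": str(spec.path),
            "counts": {
                "identified": result.n_identified,
                "reassigned": result.n_reassigned,
                "registered": result.n_registered,
                "invalid": result.n_invalid,
                "duplicates": result.n_duplicates,
                "mismatched": result.n_mismatched,
            },
        }
    )
    return result


def write_reassignment_file(result: AlignResult, path: Union[str, Path]) -> Path:
    """Write the PLINK2-consumable allele reassignment list.

    Two headerless tab-separated columns — original variant ID and desired
    ALT allele — covering exactly the REVERSE-classified variants, sorted by
    (chrom, pos).  An empty file is written when nothing was reassigned.
    """
    path = Path(path)
    rows = result.reassignment_rows
    with open(path, "w") as fh:
        for _, row in rows.iterrows():
            fh.write(f"{row['id']}\t{row['new_alt']}\n")
    return path


def _report_frame(df: pd.DataFrame) -> pd.DataFrame:
    """canonical_index + original id (+ freq when present) for report TSVs."""
    if not len(df):
        return pd.DataFrame(columns=["canonical_index", "original_id"])
    out = pd.DataFrame(
        {
            "canonical_index": df["canonical_index"]
            if "canonical_index" in df.columns
            else canonical_index_series(df),
            "original_id": df["id"],
        },
        index=df.index,
    )
    if "effect_allele_freq" in df.columns:
        out["effect_allele_freq"] = df["effect_allele_freq"]
    return out


def _write_artifacts(
    result: AlignResult,
    spec: DatasetSpec,
    registry: Registry,
    raw: pd.DataFrame,
    std: pd.DataFrame,
    outdir: Path,
) -> None:
    label = spec.dataset_label
    ddir = outdir / label
    ddir.mkdir(parents=True, exist_ok=True)
    result.output_dir = ddir

    cr = result.clean_result
    harmonized = result.realigned_records
    flipped_idx = _flipped_index(result, std)
    buckets = {
        "identified": _report_frame(harmonized),
        "reassigned": _report_frame(harmonized.loc[flipped_idx]),
        "duplicates": _report_frame(cr.duplicates),
        "invalid": _report_frame(cr.invalid_multi_indexed),
        "nonbiallelic": cr.non_biallelic[["chrom", "pos", "id", "a1", "a2"]]
        if len(cr.non_biallelic)
        else pd.DataFrame(columns=["chrom", "pos", "id", "a1", "a2"]),
        "mismatched": _report_frame(result.mismatched),
    }

    chroms = sorted(std["chrom"].unique(), key=chromosome_sort_key)
    for kind, frame in buckets.items():
        frame = frame.copy()
        chrom_of = (
            std.loc[frame.index, "chrom"]
            if len(frame)
            else pd.Series(dtype=object)
        )
        for c in chroms:
            sub = frame[chrom_of == c] if len(frame) else frame
            if len(sub) and kind != "nonbiallelic":
                sub = sub.loc[std.loc[sub.index].sort_values("pos", kind="mergesort").index]
            path = ddir / f"chr{c}.{kind}.tsv"
            write_report(sub, path, dataset=label, registry=registry.identity, chrom=c)
        result.outputs[kind] = [ddir / f"chr{c}.{kind}.tsv" for c in chroms]

    realigned_path = _write_realigned(result, spec, raw, std, ddir)
    result.outputs["realigned"] = realigned_path

    if spec.format in ("pvar", "bim"):
        reassign_path = ddir / f"{label}.reassignment.tsv"
        write_reassignment_file(result, reassign_path)
        result.outputs["reassignment"] = reassign_path

    summary = pd.DataFrame(
        [
            ("input_rows", result.n_input_rows),
            ("identified", result.n_identified),
            ("reassigned", result.n_reassigned),
            ("registered", result.n_registered),
            ("duplicates", result.n_duplicates),
            ("invalid_multi_indexed", result.n_invalid),
            ("non_biallelic", result.n_non_biallelic),
            ("mismatched", result.n_mismatched),
            ("palindromic", result.n_palindromic),
        ],
        columns=["metric", "count"],
    )
    summary_path = ddir / f"{label}.summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    result.outputs["summary"] = summary_path


def _flipped_index(result: AlignResult, std: pd.DataFrame) -> pd.Index:
    """Row indices (into the input frame) of the REVERSE-classified records."""
    harm = result.realigned_records
    if not len(harm):
        return pd.Index([])
    # a record was flipped iff its harmonized a1 differs from its input a1
    orig_a1 = std.loc[harm.index, "a1"]
    return harm.index[harm["a1"] != orig_a1]


def _format_float(v: float) -> str:
    return ("%s" % (FLOAT_FORMAT % v)) if np.isfinite(v) else ""


def _write_realigned(
    result: AlignResult,
    spec: DatasetSpec,
    raw: pd.DataFrame,
    std: pd.DataFrame,
    ddir: Path,
) -> Path:
    harmonized = result.realigned_records
    out = raw.loc[harmonized.index].copy()
    label = spec.dataset_label

    if spec.format == "sumstats":
        cols = spec.columns
        out[cols["effect_allele"]] = harmonized["a1"].to_numpy()
        out[cols["other_allele"]] = harmonized["a2"].to_numpy()
        for role in ("effect_size", "effect_allele_freq"):
            if role in cols and role in harmonized.columns:
                out[cols[role]] = [
                    _format_float(v) for v in harmonized[role].to_numpy(float)
                ]
        if INDEX_COLUMN in out.columns:
            out = out.drop(columns=INDEX_COLUMN)
        out[INDEX_COLUMN] = harmonized["canonical_index"].to_numpy()
        path = ddir / f"{label}.realigned.tsv"
        out.to_csv(path, sep=spec.delimiter, index=False)
        return path

    if spec.format == "pvar":
        out["REF"] = harmonized["a2"].to_numpy()
        out["ALT"] = harmonized["a1"].to_numpy()
        if INDEX_COLUMN in out.columns:
            out = out.drop(columns=INDEX_COLUMN)
        out[INDEX_COLUMN] = harmonized["canonical_index"].to_numpy()
        path = ddir / f"{label}.realigned.pvar"
        header = "#" + "\t".join(out.columns) + "\n"
        with open(path, "w") as fh:
            fh.write(header)
            out.to_csv(fh, sep="\t", index=False, header=False)
        return path

    # bim keeps its rigid six-column layout; the canonical-index mapping
    # lives in the identified report
    out["A1"] = harmonized["a1"].to_numpy()
    out["A2"] = harmonized["a2"].to_numpy()
    path = ddir / f"{label}.realigned.bim"
    out.to_csv(path, sep="\t", index=False, header=False)
    return path
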