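"""Synthetic cohort generator with oracle truth, plus a minimal PRS scorer.

The generator emulates the discordance found between real genomic datasets:
the same underlying variants indexed under different schemas (``chr``-prefixed
vs bare chromosome labels, rsIDs vs ``CHR_POS_REF_ALT`` concatenations) and
with arbitrarily swapped REF/ALT (effect/other) allele assignments.  Planted
inversions swap the allele columns AND complement the effect-allele frequency
AND negate the beta, so each corrupted file is internally self-consistent —
only cross-dataset comparison reveals the inversion, exactly the failure mode
harmonization exists to fix.

Cohort roles in a generated set:

- ``cohortA``: tab-separated summary statistics (rs-style IDs, bare
  chromosome labels).  Realigned first, it defines registry orientation.
  Planted data-quality corruptions (multi-indexed IDs, exact duplicate rows)
  live here.
- ``cohortB``: a PLINK2 ``.pvar`` with ``chr``-prefixed chromosomes and
  ``CHR_POS_REF_ALT`` IDs, a planted fraction of shared variants inverted,
  and an accompanying genotype dosage matrix.
- ``cohortC``...: further summary-statistic cohorts in yet another dialect
  (comma-separated, ``Chr``-prefixed), each with its own inverted subset.

Genotype dosages are two independent draws per sample at the variant's
effect-allele frequency (Hardy–Weinberg); no linkage disequilibrium is
simulated, since LD is irrelevant to harmonization correctness and would
obscure the oracle checks.

Everything is deterministic given the seed: the same call produces
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .core import DatasetSpec, chromosome_sort_key
from .errors import InfeasibleCounts, InvalidRate, MissingVariant

__all__ = [
    "FixtureTruth",
    "CohortSet",
    "generate_cohort_set",
    "generate_cohort_pair",
    "prs_score",
    "recorded_dosages",
    "apply_reassignment",
    "realigned_variant_map",
    "load_weights",
]

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureTruth:
    """Oracle record of everything the generator planted."""

    shared_set: set[str]  # canonical indices present in every cohort
    flipped_sets: dict[str, set[str]]  # cohort label -> inverted canonical indices
    multi_indexed_ids: set[str]  # IDs planted at >=2 positions (cohortA)
    duplicate_ids: set[str]  # IDs whose rows were planted twice (cohortA)
    effects: pd.DataFrame  # canonical index -> true beta, eaf

    def n_flipped(self, label: str) -> int:
        return len(self.flipped_sets.get(label, set()))


@dataclass
class CohortSet:
    """A generated bundle of cohort files plus oracle truth."""

    outdir: Path
    labels: list[str]
    paths: dict[str, Path]
    specs: dict[str, DatasetSpec]
    genotypes: pd.DataFrame  # samples x variants, true-orientation dosages
    truth: FixtureTruth
    liability: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def _draw_sites(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """n globally unique (chrom, pos) sites with allele pairs and statistics."""
    pos_pool = np.unique(rng.integers(1, 250_000_000, size=max(2 * n, 1024)))
    while len(pos_pool) < n:  # pragma: no cover - astronomically unlikely
        extra = rng.integers(1, 250_000_000, size=n)
        pos_pool = np.unique(np.concatenate([pos_pool, extra]))
    rng.shuffle(pos_pool)
    pos = pos_pool[:n]
    chrom = rng.integers(1, 23, size=n).astype(str)
    a_idx = rng.integers(0, 4, size=n)
    b_idx = (a_idx + rng.integers(1, 4, size=n)) % 4
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "a1": _BASES[a_idx],  # effect / ALT role in true orientation
            "a2": _BASES[b_idx],  # other / REF role
            "beta": rng.normal(0.0, 0.1, size=n),
            "eaf": rng.uniform(0.05, 0.95, size=n),
            "pval": rng.uniform(1e-8, 1.0, size=n),
        }
    )


def _canonical(sites: pd.DataFrame) -> pd.Series:
    """True-orientation canonical indices (flips never change the true index)."""
    return (
        sites["chrom"] + ":" + sites["pos"].astype(str) + ":" + sites["a2"] + ":" + sites["a1"]
    )


def _sorted_sites(sites: pd.DataFrame) -> pd.DataFrame:
    key = sites["chrom"].map(chromosome_sort_key)
    return sites.assign(_k=key).sort_values(["_k", "pos"], kind="mergesort").drop(columns="_k")


_FLOAT = "%.10g"


def generate_cohort_set(
    seed: int,
    n_variants: int = 12_000,
    n_shared: int = 10_000,
    flip_rate: float = 0.434,
    n_multi_indexed: int = 25,
    n_duplicates: int = 25,
    n_samples: int = 500,
    n_cohorts: int = 2,
    outdir: Union[str, Path] = ".",
    heritability: float = 0.5,
) -> CohortSet:
    """Generate ``n_cohorts`` discordantly-indexed cohorts with oracle truth.

    ``n_variants`` is each cohort's variant count; ``n_shared`` of them are
    common to all cohorts and the remainder are cohort-private.  Each cohort
    after the first has ``round(flip_rate * n_shared)`` of the shared
    variants planted in inverted orientation.  The default flip rate matches
    the discordance scale observed between real prostate-cancer cohorts,
    where 43.4% of cross-dataset common variants differed in allele
    assignment.
    """
    if not (0.0 <= flip_rate <= 1.0):
        raise InvalidRate(f"flip_rate must be within [0, 1], got {flip_rate}")
    if n_shared > n_variants:
        raise InfeasibleCounts(f"n_shared ({n_shared}) exceeds n_variants ({n_variants})")
    n_private = n_variants - n_shared
    if n_duplicates > max(n_private, n_shared):
        raise InfeasibleCounts("not enough rows available to duplicate")
    if n_cohorts < 2:
        raise InfeasibleCounts("need at least 2 cohorts")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    total = n_shared + n_cohorts * n_private + 2 * n_multi_indexed
    sites = _draw_sites(rng, total)
    sites["canonical"] = _canonical(sites)

    shared = sites.iloc[:n_shared]
    privates = [
        sites.iloc[n_shared + k * n_private : n_shared + (k + 1) * n_private]
        for k in range(n_cohorts)
    ]
    mi_sites = sites.iloc[n_shared + n_cohorts * n_private :]

    labels = ["cohort" + chr(ord("A") + k) for k in range(n_cohorts)]
    n_flip = round(flip_rate * n_shared)
    flipped_sets: dict[str, set[str]] = {labels[0]: set()}
    flip_masks: dict[str, np.ndarray] = {}
    for label in labels[1:]:
        pick = rng.choice(n_shared, size=n_flip, replace=False)
        mask = np.zeros(n_shared, dtype=bool)
        mask[pick] = True
        flip_masks[label] = mask
        flipped_sets[label] = set(shared["canonical"].to_numpy()[mask])

    paths: dict[str, Path] = {}
    specs: dict[str, DatasetSpec] = {}

    # ----- cohortA: tab-separated sumstats, rs IDs, planted corruptions -----
    a_sites = pd.concat([shared, privates[0]], ignore_index=True)
    a_ids = ["rs" + str(i + 1) for i in range(len(a_sites))]
    a_rows = pd.DataFrame(
        {
            "CHR": a_sites["chrom"],
            "BP": a_sites["pos"],
            "SNP": a_ids,
            "EA": a_sites["a1"],
            "OA": a_sites["a2"],
            "BETA": a_sites["beta"],
            "EAF": a_sites["eaf"],
            "P": a_sites["pval"],
        }
    )
    mi_ids: list[str] = []
    if n_multi_indexed:
        mi = mi_sites.reset_index(drop=True)
        mi_rows = pd.DataFrame(
            {
                "CHR": mi["chrom"],
                "BP": mi["pos"],
                "SNP": ["mi" + str(j // 2 + 1) for j in range(len(mi))],
                "EA": mi["a1"],
                "OA": mi["a2"],
                "BETA": mi["beta"],
                "EAF": mi["eaf"],
                "P": mi["pval"],
            }
        )
        mi_ids = sorted(set(mi_rows["SNP"]))
        a_rows = pd.concat([a_rows, mi_rows], ignore_index=True)
    dup_ids: list[str] = []
    if n_duplicates:
        pool = a_rows.iloc[n_shared : n_shared + n_private] if n_private else a_rows.iloc[:n_shared]
        dup_rows = pool.iloc[:n_duplicates]
        dup_ids = list(dup_rows["SNP"])
        a_rows = pd.concat([a_rows, dup_rows], ignore_index=True)

    a_path = outdir / "cohortA.sumstats.tsv"
    a_rows.to_csv(a_path, sep="\t", index=False, float_format=_FLOAT)
    paths[labels[0]] = a_path
    specs[labels[0]] = DatasetSpec(
        path=str(a_path),
        format="sumstats",
        dataset_label=labels[0],
        columns={
            "chrom": "CHR",
            "pos": "BP",
            "id": "SNP",
            "effect_allele": "EA",
            "other_allele": "OA",
            "effect_size": "BETA",
            "effect_allele_freq": "EAF",
            "p_value": "P",
        },
        effect_scale="beta",
        delimiter="\t",
    )

    # ----- cohortB: .pvar, chr-prefixed, CHR_POS_REF_ALT IDs, inversions -----
    b_label = labels[1]
    b_sites = pd.concat([shared, privates[1]], ignore_index=True)
    b_flip = np.concatenate([flip_masks[b_label], np.zeros(n_private, dtype=bool)])
    b_ref = np.where(b_flip, b_sites["a1"], b_sites["a2"])
    b_alt = np.where(b_flip, b_sites["a2"], b_sites["a1"])
    b = pd.DataFrame(
        {
            "chrom": b_sites["chrom"],
            "pos": b_sites["pos"],
            "ref": b_ref,
            "alt": b_alt,
            "canonical": b_sites["canonical"],
            "eaf": b_sites["eaf"],
        }
    )
    b = _sorted_sites(b)
    b_id = (
        b["chrom"].astype(str)
        + "_"
        + b["pos"].astype(str)
        + "_"
        + b["ref"]
        + "_"
        + b["alt"]
    )
    b_path = outdir / "cohortB.pvar"
    with open(b_path, "w") as fh:
        fh.write("##source=allelign-simulate\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        pd.DataFrame(
            {
                "#CHROM": "chr" + b["chrom"].astype(str),
                "POS": b["pos"],
                "ID": b_id,
                "REF": b["ref"],
                "ALT": b["alt"],
            }
        ).to_csv(fh, sep="\t", index=False, header=False)
    paths[b_label] = b_path
    specs[b_label] = DatasetSpec(
        path=str(b_path), format="pvar", dataset_label=b_label
    )

    # ----- further cohorts: comma-separated sumstats, Chr-prefixed ----------
    for k in range(2, n_cohorts):
        label = labels[k]
        c_sites = pd.concat([shared, privates[k]], ignore_index=True)
        c_flip = np.concatenate([flip_masks[label], np.zeros(n_private, dtype=bool)])
        c = pd.DataFrame(
            {
                "chromosome": "Chr" + c_sites["chrom"].astype(str),
                "position": c_sites["pos"],
                "variant_id": "v" + c_sites["chrom"].astype(str) + "." + c_sites["pos"].astype(str),
                "allele1": np.where(c_flip, c_sites["a2"], c_sites["a1"]),
                "allele2": np.where(c_flip, c_sites["a1"], c_sites["a2"]),
                "effect": np.where(c_flip, -c_sites["beta"], c_sites["beta"]),
                "freq1": np.where(c_flip, 1.0 - c_sites["eaf"], c_sites["eaf"]),
                "pvalue": c_sites["pval"],
            }
        )
        c_path = outdir / f"{label}.sumstats.csv"
        c.to_csv(c_path, sep=",", index=False, float_format=_FLOAT)
        paths[label] = c_path
        specs[label] = DatasetSpec(
            path=str(c_path),
            format="sumstats",
            dataset_label=label,
            columns={
                "chrom": "chromosome",
                "pos": "position",
                "id": "variant_id",
                "effect_allele": "allele1",
                "other_allele": "allele2",
                "effect_size": "effect",
                "effect_allele_freq": "freq1",
                "p_value": "pvalue",
            },
            effect_scale="beta",
            delimiter=",",
        )

    # ----- genotypes for cohortB (true-orientation effect-allele dosages) ---
    dosages = rng.binomial(2, b["eaf"].to_numpy(), size=(n_samples, len(b)))
    genotypes = pd.DataFrame(
        dosages,
        index=[f"S{i + 1:04d}" for i in range(n_samples)],
        columns=list(b["canonical"]),
    )

    # genetic liability over the shared set, plus Gaussian environmental noise
    shared_cols = [c for c in genotypes.columns if c in set(shared["canonical"])]
    beta_map = dict(zip(shared["canonical"], shared["beta"]))
    g = genotypes[shared_cols].to_numpy(float) @ np.array([beta_map[c] for c in shared_cols])
    var_g = float(np.var(g))
    if 0.0 < heritability < 1.0 and var_g > 0:
        sigma = np.sqrt(var_g * (1.0 - heritability) / heritability)
    else:
        sigma = 0.0
    liability = pd.Series(g + rng.normal(0.0, sigma, size=n_samples), index=genotypes.index)

    truth = FixtureTruth(
        shared_set=set(shared["canonical"]),
        flipped_sets=flipped_sets,
        multi_indexed_ids=set(mi_ids),
        duplicate_ids=set(dup_ids),
        effects=pd.DataFrame(
            {"beta": sites["beta"].to_numpy(), "eaf": sites["eaf"].to_numpy()},
            index=sites["canonical"],
        ),
    )

    truth_rows = sites[["canonical", "beta", "eaf"]].copy()
    truth_rows["in_shared"] = truth_rows["canonical"].isin(truth.shared_set).astype(int)
    for label in labels[1:]:
        truth_rows[f"flipped_in_{label}"] = (
            truth_rows["canonical"].isin(flipped_sets[label]).astype(int)
        )
    truth_rows.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format=_FLOAT)

    return CohortSet(
        outdir=outdir,
        labels=labels,
        paths=paths,
        specs=specs,
        genotypes=genotypes,
        truth=truth,
        liability=liability,
    )


def generate_cohort_pair(
    seed: int,
    n_variants: int = 12_000,
    n_shared: int = 10_000,
    flip_rate: float = 0.434,
    n_multi_indexed: int = 25,
    n_duplicates: int = 25,
    n_samples: int = 500,
    outdir: Union[str, Path] = ".",
) -> tuple[Path, Path, pd.DataFrame, FixtureTruth]:
    """Generate one sumstats + one .pvar cohort; returns (paths, dosages, truth)."""
    cs = generate_cohort_set(
        seed,
        n_variants=n_variants,
        n_shared=n_shared,
        flip_rate=flip_rate,
        n_multi_indexed=n_multi_indexed,
        n_duplicates=n_duplicates,
        n_samples=n_samples,
        n_cohorts=2,
        outdir=outdir,
    )
    return cs.paths["cohortA"], cs.paths["cohortB"], cs.genotypes, cs.truth


# -------------------------------------------------------------------- scoring


def prs_score(
    genotypes: pd.DataFrame,
    weights: Union[pd.Series, pd.DataFrame, Mapping[str, float]],
) -> pd.Series:
    """Per-sample polygenic score: Σ_j beta_j × dosage_ij.

    ``weights`` maps canonical index → effect size (a Series/dict, or a
    DataFrame with ``canonical_index`` and ``effect_size`` columns).  Every
    weighted variant must be a genotype column.
    """
    if isinstance(weights, pd.DataFrame):
        w = pd.Series(
            weights["effect_size"].to_numpy(float),
            index=weights["canonical_index"].to_numpy(),
        )
    elif isinstance(weights, pd.Series):
        w = weights.astype(float)
    else:
        w = pd.Series(weights, dtype=float)
    missing = [c for c in w.index if c not in genotypes.columns]
    if missing:
        raise MissingVariant(
            f"{len(missing)} weighted variant(s) absent from the genotype matrix, "
            f"e.g. {missing[0]}"
        )
    cols = list(w.index)
    scores = genotypes[cols].to_numpy(float) @ w.to_numpy()
    return pd.Series(scores, index=genotypes.index)


def recorded_dosages(cohorts: CohortSet, label: str = "cohortB") -> pd.DataFrame:
    """Dosages as the named cohort's file records them.

    For variants planted in inverted orientation the file's ALT is the true
    other allele, so the recorded dosage of the file's ALT is ``2 − d``.
    This is what a naive (unharmonized) analysis would feed into a PRS.
    """
    out = cohorts.genotypes.copy()
    flipped = [c for c in out.columns if c in cohorts.truth.flipped_sets.get(label, set())]
    out[flipped] = 2 - out[flipped]
    return out


def apply_reassignment(
    genotypes: pd.DataFrame,
    reassignment: Union[str, Path, pd.DataFrame],
    id_to_canonical: Mapping[str, str],
) -> pd.DataFrame:
    """Apply an allele reassignment list to a dosage matrix (d → 2 − d).

    ``reassignment`` is the two-column headerless TSV written by realign (or
    an equivalent frame with an ``id`` column); ``id_to_canonical`` maps the
    dataset's original variant IDs to the matrix's canonical-index columns.
    """
    if isinstance(reassignment, (str, Path)):
        try:
            rows = pd.read_csv(
                reassignment, sep="\t", header=None, names=["id", "new_alt"], dtype=str
            )
        except pd.errors.EmptyDataError:
            rows = pd.DataFrame(columns=["id", "new_alt"])
    else:
        rows = reassignment
    out = genotypes.copy()
    cols = [id_to_canonical[i] for i in rows["id"] if i in id_to_canonical]
    cols = [c for c in cols if c in out.columns]
    out[cols] = 2 - out[cols]
    return out


def realigned_variant_map(realigned_pvar: Union[str, Path]) -> dict[str, str]:
    """original ID → canonical index, from a realigned .pvar's CANONICAL_ID column."""
    with open(realigned_pvar) as fh:
        lines = [ln for ln in fh if not ln.startswith("##")]
    import io as _io

    frame = pd.read_csv(_io.StringIO("".join(lines)), sep="\t", dtype=str)
    frame.columns = [c.lstrip("#") for c in frame.columns]
    return dict(zip(frame["ID"], frame["CANONICAL_ID"]))


def load_weights(
    realigned_sumstats: Union[str, Path],
    effect_col: str = "BETA",
    delimiter: str = "\t",
    index_col: str = "CANONICAL_ID",
) -> pd.DataFrame:
    """Scoring weights from a realigned summary-statistics file."""
    frame = pd.read_csv(realigned_sumstats, sep=delimiter)
    return pd.DataFrame(
        {
            "canonical_index": frame[index_col].astype(str),
            "effect_size": frame[effect_col].astype(float),
        }
    )
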