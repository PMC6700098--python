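"""OTU-table data model and post-clustering preprocessing.

Everything downstream of OTU picking lives here: reading/writing count
tables (tab-delimited or BIOM JSON), low-abundance filtering, rarefaction,
taxonomy aggregation, relative abundance, Shannon diversity, Bray-Curtis
dissimilarity and a permutational test of community composition
(PERMANOVA).

Counts are always taxa x samples, integer, non-negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "OtuTable",
    "ClinicalRecord",
    "RarefactionResult",
    "PermanovaResult",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "records_from_frame",
    "filter_low_abundance",
    "rarefy",
    "rarefy_mean",
    "aggregate_taxonomy",
    "relative_abundance",
    "shannon_diversity",
    "bray_curtis",
    "permanova",
]

RANK_INDEX = {
    "kingdom": 0,
    "phylum": 1,
    "class": 2,
    "order": 3,
    "family": 4,
    "genus": 5,
    "species": 6,
}

RANK_PREFIXES = {"k__", "d__", "p__", "c__", "o__", "f__", "g__", "s__"}


class OtuTableError(ValueError):
    """Malformed or invalid OTU table input."""


@dataclass
class OtuTable:
    """Integer count matrix (taxa x samples) with taxonomy lineages.

    Parameters
    ----------
    taxon_ids
        Unique opaque taxon identifiers, one per row.
    lineages
        Semicolon-delimited taxonomy string per taxon (may be empty).
    sample_ids
        Unique sample identifiers, one per column.
    counts
        Non-negative integer matrix of shape ``(len(taxon_ids), len(sample_ids))``.
    """

    taxon_ids: list[str]
    lineages: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix (taxa x samples)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise OtuTableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise OtuTableError("counts must be non-negative")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise OtuTableError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(self.lineages) != len(self.taxon_ids):
            raise OtuTableError("one lineage string required per taxon")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise OtuTableError("taxon_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise OtuTableError("sample_ids must be unique")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            taxon_ids=list(self.taxon_ids),
            lineages=list(self.lineages),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx].copy(),
        )

    def select_taxa(self, keep: np.ndarray) -> "OtuTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return OtuTable(
            taxon_ids=[self.taxon_ids[i] for i in idx],
            lineages=[self.lineages[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :].copy(),
        )

    def abundance_of(self, taxon_id: str) -> np.ndarray:
        """Relative abundance (count / sample sum) of one taxon across samples."""
        i = self.taxon_ids.index(taxon_id)
        sums = self.sample_sums()
        if np.any(sums == 0):
            bad = [s for s, t in zip(self.sample_ids, sums) if t == 0]
            raise OtuTableError(f"zero-sum samples: {bad}")
        return self.counts[i] / sums

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.lineages == other.lineages
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class ClinicalRecord:
    """Per-sample clinical metadata for one stool sampling of one subject."""

    sample_id: str
    subject_id: str
    cohort: Literal["discovery", "validation"]
    ppi_use: bool
    child_pugh: int
    meld: float
    followup_months: float
    event: Literal["liver_death", "censored"]
    censor_reason: str | None = None
    calprotectin: float | None = None
    zonulin: float | None = None
    lps: float | None = None

    def __post_init__(self) -> None:
        if self.followup_months < 0:
            raise ValueError("followup_months must be non-negative")
        if self.event == "liver_death" and self.censor_reason not in (None, ""):
            raise ValueError("liver_death events cannot carry a censor_reason")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    return "biom" if path.suffix.lower() == ".biom" else "tsv"


def read_otu_table(path: str | Path, format: str | None = None) -> OtuTable:
    """Read an OTU table from a tab-delimited file or BIOM (JSON dialect).

    TSV layout: taxa as rows, samples as columns, first column the taxon id,
    final column ``taxonomy`` with a semicolon-delimited lineage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "biom":
        return _read_biom_json(path)
    raise ValueError(f"unknown OTU table format: {fmt!r}")


def _read_tsv(path: Path) -> OtuTable:
    try:
        df = pd.read_csv(path, sep="\t", comment=None, skiprows=lambda i: False,
                         dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise OtuTableError(f"cannot parse {path}: {exc}") from exc
    # A leading '#OTU ID' header line (QIIME convention) parses fine as a column
    if df.shape[1] < 2:
        raise OtuTableError(f"{path}: expected taxon id, >=1 sample, taxonomy columns")
    cols = list(df.columns)
    has_tax = cols[-1].strip().lower() == "taxonomy"
    sample_cols = cols[1:-1] if has_tax else cols[1:]
    if not sample_cols:
        raise OtuTableError(f"{path}: no sample columns found")
    taxon_ids = df.iloc[:, 0].astype(str).tolist()
    lineages = df[cols[-1]].astype(str).tolist() if has_tax else [""] * len(taxon_ids)
    counts = np.empty((len(taxon_ids), len(sample_cols)), dtype=np.int64)
    for j, c in enumerate(sample_cols):
        for i, raw in enumerate(df[c]):
            try:
                val = float(raw)
            except ValueError:
                raise OtuTableError(
                    f"{path}: non-numeric count {raw!r} at row {i + 2}, column {c!r}"
                ) from None
            if val < 0:
                raise OtuTableError(
                    f"{path}: negative count {raw!r} at row {i + 2}, column {c!r}"
                )
            if val != int(val):
                raise OtuTableError(
                    f"{path}: non-integer count {raw!r} at row {i + 2}, column {c!r}"
                )
            counts[i, j] = int(val)
    return OtuTable(taxon_ids, lineages, [str(c) for c in sample_cols], counts)


def _read_biom_json(path: Path) -> OtuTable:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise OtuTableError(f"{path}: invalid BIOM JSON at line {exc.lineno}") from exc
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise OtuTableError(f"{path}: BIOM record missing {key!r}")
    n_taxa, n_samples = doc["shape"]
    taxon_ids = [str(r["id"]) for r in doc["rows"]]
    lineages = []
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy", "")
        lineages.append("; ".join(tax) if isinstance(tax, list) else str(tax))
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for rec in doc["data"]:
            i, j, v = rec
            if v < 0 or v != int(v):
                raise OtuTableError(f"{path}: invalid count {v} in sparse record {rec}")
            counts[int(i), int(j)] = int(v)
    elif doc["matrix_type"] == "dense":
        arr = np.asarray(doc["data"], dtype=float)
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise OtuTableError(f"{path}: dense matrix has negative/non-integer counts")
        counts = arr.astype(np.int64)
    else:
        raise OtuTableError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    return OtuTable(taxon_ids, lineages, sample_ids, counts)


def write_otu_table(table: OtuTable, path: str | Path, format: str | None = None) -> Path:
    """Write a table as TSV (taxa rows, taxonomy last) or BIOM JSON."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        df = table.to_dataframe().copy()
        df.insert(len(df.columns), "taxonomy", table.lineages)
        df.index.name = "#OTU ID"
        df.to_csv(path, sep="\t")
    elif fmt == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "oralmark",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [
                {"id": t, "metadata": {"taxonomy": lin.split(";")}}
                for t, lin in zip(table.taxon_ids, table.lineages)
            ],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": [
                [int(i), int(j), int(table.counts[i, j])]
                for i, j in zip(*np.nonzero(table.counts))
            ],
        }
        path.write_text(json.dumps(doc))
    else:
        raise ValueError(f"unknown OTU table format: {fmt!r}")
    return path


METADATA_REQUIRED = [
    "sample_id", "subject_id", "cohort", "ppi_use", "child_pugh", "meld",
    "followup_months", "event",
]
METADATA_OPTIONAL = ["censor_reason", "calprotectin", "zonulin", "lps"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical metadata CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise OtuTableError(f"metadata missing required columns: {missing}")
    df["ppi_use"] = df["ppi_use"].map(
        {True: True, False: False, "True": True, "False": False, 1: True, 0: False,
         "1": True, "0": False, "true": True, "false": False}
    )
    if df["ppi_use"].isna().any():
        raise OtuTableError("ppi_use column must be boolean")
    bad = ~df["event"].isin(["liver_death", "censored"])
    if bad.any():
        raise OtuTableError(
            f"event must be liver_death/censored; offending rows: {list(df.index[bad])}"
        )
    for c in METADATA_OPTIONAL:
        if c not in df.columns:
            df[c] = np.nan
    return df


def records_from_frame(df: pd.DataFrame) -> list[ClinicalRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                subject_id=str(row["subject_id"]),
                cohort=row["cohort"],
                ppi_use=bool(row["ppi_use"]),
                child_pugh=int(row["child_pugh"]),
                meld=float(row["meld"]),
                followup_months=float(row["followup_months"]),
                event=row["event"],
                censor_reason=(None if pd.isna(row.get("censor_reason"))
                               else str(row["censor_reason"]) or None),
                calprotectin=(None if pd.isna(row.get("calprotectin"))
                              else float(row["calprotectin"])),
                zonulin=None if pd.isna(row.get("zonulin")) else float(row["zonulin"]),
                lps=None if pd.isna(row.get("lps")) else float(row["lps"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Filtering and normalisation
# ---------------------------------------------------------------------------

def filter_low_abundance(
    table: OtuTable,
    min_prevalence: int = 2,
    min_fraction: float = 0.0005,
    subject_of_sample: dict[str, str] | None = None,
) -> OtuTable:
    """Drop rare taxa before biomarker screening.

    A taxon is removed when it is present (count > 0) in fewer than
    ``min_prevalence`` samples, or when its share of all reads falls below
    ``min_fraction`` (default 0.05%; a taxon at exactly 0.05% is retained —
    the boundary is read strictly).

    ``subject_of_sample`` switches prevalence counting from samples to
    subjects (relevant when subjects contribute repeated samplings).
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        raise OtuTableError("cannot filter an empty table")
    grand = table.counts.sum()
    if grand == 0:
        raise OtuTableError("table contains no reads")
    present = table.counts > 0
    if subject_of_sample is None:
        prevalence = present.sum(axis=1)
    else:
        subjects = np.array([subject_of_sample[s] for s in table.sample_ids])
        prevalence = np.array(
            [len(set(subjects[row])) for row in present]
        )
    fraction = table.taxon_sums() / grand
    keep = (prevalence >= min_prevalence) & (fraction >= min_fraction)
    if not keep.any():
        import warnings

        warnings.warn("low-abundance filter removed every taxon", stacklevel=2)
    return table.select_taxa(keep)


@dataclass
class RarefactionResult:
    """Rarefied table plus the samples dropped for insufficient depth."""

    table: OtuTable
    dropped: list[str]
    depth: int
    seed: int


def rarefy(table: OtuTable, depth: int, seed: int) -> RarefactionResult:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (and listed in the
    result), never imputed. Each retained column is one multivariate-
    hypergeometric draw; the draw is deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep_cols, dropped = [], []
    new_counts = []
    for j, sid in enumerate(table.sample_ids):
        if sums[j] < depth:
            dropped.append(sid)
            continue
        col = table.counts[:, j]
        if sums[j] == depth:
            new_counts.append(col.copy())
        else:
            new_counts.append(rng.multivariate_hypergeometric(col, depth))
        keep_cols.append(sid)
    counts = (np.column_stack(new_counts) if new_counts
              else np.zeros((table.n_taxa, 0), dtype=np.int64))
    out = OtuTable(list(table.taxon_ids), list(table.lineages), keep_cols,
                   counts.astype(np.int64))
    return RarefactionResult(table=out, dropped=dropped, depth=depth, seed=seed)


def rarefy_mean(table: OtuTable, depth: int, seed: int, n_draws: int = 10) -> np.ndarray:
    """Mean counts over ``n_draws`` independent rarefactions (sensitivity analysis).

    Returns a float matrix over the samples that meet ``depth``; the single-draw
    :func:`rarefy` is the default analysis path.
    """
    acc = None
    kept: list[str] | None = None
    for k in range(n_draws):
        res = rarefy(table, depth, seed + k)
        mat = res.table.counts.astype(float)
        if acc is None:
            acc, kept = mat, res.table.sample_ids
        else:
            acc += mat
    assert acc is not None
    return acc / n_draws


def _rank_labels(lineage: str, rank: str) -> str | None:
    """Extract the label at ``rank`` from a semicolon-delimited lineage."""
    idx = RANK_INDEX[rank]
    parts = [p.strip() for p in lineage.split(";")]
    # strip greengenes/SILVA-style prefixes like g__ / f__
    cleaned = []
    for p in parts:
        if len(p) >= 3 and p[:3].lower() in RANK_PREFIXES:
            cleaned.append(p[3:].strip())
        else:
            cleaned.append(p)
    if idx >= len(cleaned) or not cleaned[idx]:
        return None
    if rank == "species" and idx >= 1 and cleaned[idx - 1]:
        # species labels are qualified by genus unless already binomial
        if not cleaned[idx].startswith(cleaned[idx - 1]):
            return f"{cleaned[idx - 1]} {cleaned[idx]}"
    return cleaned[idx]


def aggregate_taxonomy(table: OtuTable, rank: str) -> OtuTable:
    """Sum counts over taxa sharing the label at ``rank``.

    Taxa unclassified at that rank are pooled into an ``unclassified_<rank>``
    bin so the grand total is conserved.
    """
    if rank not in ("family", "genus", "species"):
        raise ValueError(f"rank must be family/genus/species, got {rank!r}")
    labels = []
    for lin in table.lineages:
        lab = _rank_labels(lin, rank)
        labels.append(lab if lab is not None else f"unclassified_{rank}")
    order: list[str] = []
    seen = {}
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(order)
            order.append(lab)
    counts = np.zeros((len(order), table.n_samples), dtype=np.int64)
    for i, lab in enumerate(labels):
        counts[seen[lab]] += table.counts[i]
    lineages = [f"aggregated at {rank}" if not lab.startswith("unclassified_")
                else f"unclassified at {rank}" for lab in order]
    return OtuTable(order, lineages, list(table.sample_ids), counts)


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Per-sample fractions (columns sum to 1)."""
    sums = table.sample_sums()
    zero = sums == 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise OtuTableError(f"zero-sum samples: {bad}")
    return table.counts / sums


def shannon_diversity(counts: Iterable[float]) -> float:
    """Shannon entropy H = -sum p ln p (nats) of one sample's counts."""
    c = np.asarray(list(counts), dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("sample has no reads")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sums = table.sample_sums()
    if np.any(sums == 0):
        bad = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise OtuTableError(f"zero-sum samples: {bad}")
    condensed = pdist(table.counts.T.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    degenerate: bool = False


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        return np.inf
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dm: DistanceMatrix,
    grouping: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F is computed from among/within sums of squared distances and the
    p-value from ``n_perm`` label permutations:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm). Deterministic given ``seed``.
    """
    labels = np.asarray(list(grouping))
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("grouping must contain at least two groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _permanova_f(d2, codes, len(uniq))
    if not np.isfinite(f_obs):
        return PermanovaResult(np.nan, np.nan, n_perm, degenerate=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, len(uniq)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(p), n_perm)
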