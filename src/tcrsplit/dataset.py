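"""Interaction data model, VDJdb-style table I/O, and shuffled negatives.

A dataset is an ordered, de-duplicated collection of (peptide, CDR3-beta)
records with a binary binding label.  Negative (non-binding) examples are
produced by shuffling observed peptide/CDR3-beta combinations, under the
standard assumption that a random pairing is unlikely to bind.
"""

from __future__ import annotations

import fnmatch
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, InfeasibleError, SchemaError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: default mapping from schema roles to VDJdb export column names; for cdr3b
#: several candidate names are tried in order.
DEFAULT_COLUMN_MAP: dict[str, Sequence[str]] = {
    "peptide": ("antigen.epitope", "peptide"),
    "cdr3b": ("cdr3.beta", "cdr3", "cdr3b"),
    "cdr3a": ("cdr3.alpha", "cdr3a"),
    "mhc_allele": ("mhc.a", "mhc_allele"),
    "label": ("label",),
}

CANONICAL_COLUMNS = ("peptide", "cdr3b", "cdr3a", "mhc_allele", "label", "source")


def is_valid_sequence(s: object) -> bool:
    """True if *s* is a non-empty string over the 20 standard residues."""
    return isinstance(s, str) and len(s) > 0 and set(s) <= _AA_SET


@dataclass(frozen=True)
class InteractionRecord:
    """One (peptide, CDR3-beta) pair with a binary binding label.

    ``source`` records provenance: ``observed`` rows come from an input table
    or a generator; ``shuffled`` rows are synthetic negatives and always carry
    ``label=0``.
    """

    peptide: str
    cdr3b: str
    cdr3a: Optional[str] = None
    mhc_allele: Optional[str] = None
    label: int = 1
    source: str = "observed"

    def __post_init__(self) -> None:
        if not is_valid_sequence(self.peptide):
            raise ValueError(f"invalid peptide sequence: {self.peptide!r}")
        if not is_valid_sequence(self.cdr3b):
            raise ValueError(f"invalid cdr3b sequence: {self.cdr3b!r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.source not in ("observed", "shuffled"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "shuffled" and self.label != 0:
            raise ValueError("shuffled records must carry label=0")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.peptide, self.cdr3b, self.label)


@dataclass(frozen=True)
class InteractionDataset:
    """Ordered collection of records with per-peptide multiplicities.

    Duplicate (peptide, cdr3b, label) triples are collapsed on construction
    so that a repeated row can never leak across splits.
    """

    records: tuple[InteractionRecord, ...]
    peptide_counts: Mapping[str, int] = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = Counter(r.peptide for r in self.records)
        object.__setattr__(self, "peptide_counts", dict(counts))

    @classmethod
    def from_records(cls, records: Iterable[InteractionRecord]) -> "InteractionDataset":
        seen: set[tuple[str, str, int]] = set()
        kept: list[InteractionRecord] = []
        for r in records:
            if r.key not in seen:
                seen.add(r.key)
                kept.append(r)
        return cls(records=tuple(kept))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def unique_peptides(self) -> tuple[str, ...]:
        """Unique peptides in first-appearance order."""
        out, seen = [], set()
        for r in self.records:
            if r.peptide not in seen:
                seen.add(r.peptide)
                out.append(r.peptide)
        return tuple(out)

    @property
    def unique_cdr3b(self) -> tuple[str, ...]:
        out, seen = [], set()
        for r in self.records:
            if r.cdr3b not in seen:
                seen.add(r.cdr3b)
                out.append(r.cdr3b)
        return tuple(out)


@dataclass(frozen=True)
class ReadReport:
    """Row accounting for :func:`read_interaction_table`."""

    n_rows: int
    n_kept: int
    n_dropped: int
    dropped_reasons: Mapping[str, int]


def _resolve_column(df: pd.DataFrame, role: str, candidates: Sequence[str],
                    required: bool) -> Optional[str]:
    for name in candidates:
        if name in df.columns:
            return name
    if required:
        raise SchemaError(
            f"no column for role {role!r}; tried {list(candidates)}; "
            f"available: {list(df.columns)}"
        )
    return None


def read_interaction_table(
    path: str | Path,
    column_map: Optional[Mapping[str, str | Sequence[str]]] = None,
) -> tuple[InteractionDataset, ReadReport]:
    """Read a tab-separated VDJdb-style table into an :class:`InteractionDataset`.

    ``column_map`` maps schema roles (``peptide``, ``cdr3b``, optionally
    ``cdr3a``, ``mhc_allele``, ``label``) to column names; unmapped roles fall
    back to :data:`DEFAULT_COLUMN_MAP`.  Sequences are upper-cased; rows whose
    peptide or cdr3b fails the 20-letter alphabet check are dropped and
    counted in the returned :class:`ReadReport`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"empty table: {path}") from exc
    if df.empty:
        raise EmptyDatasetError(f"no data rows in table: {path}")

    cmap = {k: (v,) if isinstance(v, str) else tuple(v)
            for k, v in (column_map or {}).items()}
    for role, cands in DEFAULT_COLUMN_MAP.items():
        cmap.setdefault(role, cands)

    pep_col = _resolve_column(df, "peptide", cmap["peptide"], required=True)
    cdr_col = _resolve_column(df, "cdr3b", cmap["cdr3b"], required=True)
    cdr3a_col = _resolve_column(df, "cdr3a", cmap["cdr3a"], required=False)
    mhc_col = _resolve_column(df, "mhc_allele", cmap["mhc_allele"], required=False)
    label_col = _resolve_column(df, "label", cmap["label"], required=False)
    source_col = "source" if "source" in df.columns else None

    reasons: Counter = Counter()
    records: list[InteractionRecord] = []
    # positional access: itertuples would mangle dotted VDJdb column names
    pep_vals = df[pep_col].astype(str).str.strip().str.upper()
    cdr_vals = df[cdr_col].astype(str).str.strip().str.upper()
    for i in range(len(df)):
        pep, cdr = pep_vals.iat[i], cdr_vals.iat[i]
        if not is_valid_sequence(pep) or pep == "NAN":
            reasons["invalid_peptide"] += 1
            continue
        if not is_valid_sequence(cdr) or cdr == "NAN":
            reasons["invalid_cdr3b"] += 1
            continue
        cdr3a = df[cdr3a_col].iat[i] if cdr3a_col else None
        cdr3a = None if (cdr3a is None or pd.isna(cdr3a)) else str(cdr3a).strip().upper()
        if cdr3a is not None and not is_valid_sequence(cdr3a):
            cdr3a = None
        mhc = df[mhc_col].iat[i] if mhc_col else None
        mhc = None if (mhc is None or pd.isna(mhc)) else str(mhc).strip()
        label = 1
        if label_col is not None and not pd.isna(df[label_col].iat[i]):
            try:
                label = int(float(df[label_col].iat[i]))
            except ValueError:
                reasons["invalid_label"] += 1
                continue
        source = "observed"
        if source_col is not None and not pd.isna(df[source_col].iat[i]):
            source = str(df[source_col].iat[i]).strip()
        try:
            records.append(InteractionRecord(pep, cdr, cdr3a, mhc, label, source))
        except ValueError:
            reasons["invalid_record"] += 1

    ds = InteractionDataset.from_records(records)
    n_dropped = len(df) - len(records)
    report = ReadReport(
        n_rows=len(df), n_kept=len(records), n_dropped=n_dropped,
        dropped_reasons=dict(reasons),
    )
    return ds, report


def write_interaction_table(ds: InteractionDataset, path: str | Path) -> Path:
    """Write the canonical tab-separated table (fixed column set)."""
    path = Path(path)
    rows = [
        {
            "peptide": r.peptide,
            "cdr3b": r.cdr3b,
            "cdr3a": r.cdr3a if r.cdr3a is not None else "",
            "mhc_allele": r.mhc_allele if r.mhc_allele is not None else "",
            "label": r.label,
            "source": r.source,
        }
        for r in ds.records
    ]
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
    return path


def filter_dataset(
    ds: InteractionDataset,
    require_cdr3b: bool = True,
    require_peptide: bool = True,
    mhc_class_pattern: Optional[str] = None,
) -> InteractionDataset:
    """Keep records with the required fields and an MHC allele matching a
    shell-style pattern (e.g. ``"HLA-A*"``).

    Record validation already guarantees non-empty peptide/cdr3b, so the
    require flags matter when records are built permissively upstream; the
    dataset invariants (counts, de-duplication) are recomputed on return.
    """
    kept = []
    for r in ds.records:
        if require_peptide and not is_valid_sequence(r.peptide):
            continue
        if require_cdr3b and not is_valid_sequence(r.cdr3b):
            continue
        if mhc_class_pattern is not None:
            if r.mhc_allele is None or not fnmatch.fnmatchcase(r.mhc_allele, mhc_class_pattern):
                continue
        kept.append(r)
    return InteractionDataset.from_records(kept)


def generate_negatives(
    ds: InteractionDataset,
    n_negatives: Optional[int] = None,
    seed: int = 0,
) -> InteractionDataset:
    """Augment a positives-only dataset with shuffled non-binding pairs.

    Draws ``n_negatives`` (default: one per positive, i.e. a balanced
    dataset) distinct (peptide, cdr3b) combinations that do not occur among
    the positives, labels them 0 with ``source="shuffled"``, and appends them.
    Peptides and CDR3-beta strings are reused from the positives, never
    invented.  Rejection sampling with a retry cap is used first; if the
    positive set is dense enough to defeat it, the remaining non-positive
    combinations are enumerated exhaustively, which guarantees exactness.
    """
    if any(r.label != 1 for r in ds.records):
        raise ValueError("generate_negatives expects a positives-only dataset")
    if n_negatives is None:
        n_negatives = len(ds.records)
    if n_negatives < 0:
        raise ValueError("n_negatives must be non-negative")
    if n_negatives == 0:
        return ds

    peptides = sorted(ds.unique_peptides)
    cdr3bs = sorted(ds.unique_cdr3b)
    positive_pairs = {(r.peptide, r.cdr3b) for r in ds.records}
    capacity = len(peptides) * len(cdr3bs) - len(positive_pairs)
    if n_negatives > capacity:
        raise InfeasibleError(
            f"requested {n_negatives} negatives but only {capacity} "
            f"non-positive combinations exist"
        )

    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    chosen_set: set[tuple[str, str]] = set()
    max_attempts = max(1000, 20 * n_negatives)
    attempts = 0
    while len(chosen) < n_negatives and attempts < max_attempts:
        attempts += 1
        pair = (peptides[rng.integers(len(peptides))],
                cdr3bs[rng.integers(len(cdr3bs))])
        if pair in positive_pairs or pair in chosen_set:
            continue
        chosen.append(pair)
        chosen_set.add(pair)
    if len(chosen) < n_negatives:
        remaining = [
            (p, c) for p in peptides for c in cdr3bs
            if (p, c) not in positive_pairs and (p, c) not in chosen_set
        ]
        idx = rng.choice(len(remaining), size=n_negatives - len(chosen), replace=False)
        chosen.extend(remaining[i] for i in sorted(idx))

    negatives = [
        InteractionRecord(peptide=p, cdr3b=c, label=0, source="shuffled")
        for p, c in chosen
    ]
    return InteractionDataset.from_records(list(ds.records) + negatives)
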