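"""Pairwise peptide distances: edit, BLOSUM-alignment, and C-alpha RMSD.

Three complementary views of peptide dissimilarity feed the distance split:

* **Levenshtein** — unit-cost string edit distance between sequences.
* **BLOSUM** — a pseudo-distance derived from Needleman-Wunsch global
  alignment scores under a BLOSUM substitution matrix with affine gaps:
  ``d(a, b) = S(a, a) + S(b, b) - 2 S(a, b)``, clamped at zero.  The
  self-alignment terms make the self-distance exactly zero and the
  subtraction makes the quantity symmetric, which a raw similarity is not.
* **RMSD** — C-alpha root-mean-square deviation after optimal rigid
  (Kabsch) superposition of the residues matched by the global sequence
  alignment, with optional PyMOL-style outlier rejection cycles.

All three are assembled into symmetric zero-diagonal matrices over the
unique peptides, from which a per-peptide row aggregate (median by default)
summarises how far each peptide sits from the rest of the dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import (
    AlphabetError,
    DegenerateStructureError,
    NoOverlapError,
    TcrSplitError,
)
from .structures import PeptideStructure

METRICS = ("levenshtein", "blosum", "rmsd")
AGGREGATORS = ("median", "mean", "min")

# relative tolerance for symmetry / zero-diagonal assertions
SYM_RTOL = 1e-9


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring parameters.

    Gap convention (Biopython's): a gap run of length L costs
    ``gap_open + (L - 1) * gap_extend``.  Defaults are the ubiquitous
    BLOSUM62 with open -10 / extend -1.
    """

    substitution_matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError(
                f"require gap_open <= gap_extend < 0, got "
                f"open={self.gap_open}, extend={self.gap_extend}"
            )

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        try:
            aligner.substitution_matrix = substitution_matrices.load(
                self.substitution_matrix_name
            )
        except FileNotFoundError as exc:
            raise TcrSplitError(
                f"unknown substitution matrix {self.substitution_matrix_name!r}"
            ) from exc
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


DEFAULT_PARAMS = AlignmentParams()


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        raise ValueError("levenshtein_distance requires non-empty sequences")
    return int(edlib.align(a, b, task="distance", mode="NW")["editDistance"])


def _check_alphabet(seq: str, alphabet: str) -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise AlphabetError(
            f"residues {sorted(bad)} absent from substitution matrix alphabet"
        )


def global_alignment_score(a: str, b: str,
                           params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Optimal Needleman-Wunsch global alignment score with affine gaps."""
    if not a or not b:
        raise ValueError("global_alignment_score requires non-empty sequences")
    aligner = params.make_aligner()
    alphabet = str(aligner.substitution_matrix.alphabet)
    _check_alphabet(a, alphabet)
    _check_alphabet(b, alphabet)
    return float(aligner.score(a, b))


def blosum_distance(a: str, b: str,
                    params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Alignment-score pseudo-distance S(a,a) + S(b,b) - 2 S(a,b), >= 0."""
    if a == b:
        return 0.0
    saa = global_alignment_score(a, a, params)
    sbb = global_alignment_score(b, b, params)
    sab = global_alignment_score(a, b, params)
    return max(0.0, saa + sbb - 2.0 * sab)


def pair_ca_atoms(x: PeptideStructure, y: PeptideStructure,
                  params: AlignmentParams = DEFAULT_PARAMS) -> list[tuple[int, int]]:
    """Residue index pairs from the match columns of the optimal global
    sequence alignment of ``x.sequence`` and ``y.sequence``.

    Indices are strictly increasing in both structures.  Ties among optimal
    alignments resolve to the aligner's first reported alignment.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("pair_ca_atoms requires non-empty structures")
    aligner = params.make_aligner()
    alignment = aligner.align(x.sequence, y.sequence)[0]
    pairs: list[tuple[int, int]] = []
    blocks_x, blocks_y = alignment.aligned
    for (xs, xe), (ys, _ye) in zip(blocks_x, blocks_y):
        pairs.extend((xi, ys + (xi - xs)) for xi in range(xs, xe))
    if not pairs:
        raise NoOverlapError(
            "optimal alignment has no match columns; structures cannot be paired"
        )
    return pairs


def kabsch_superpose(p: np.ndarray, q: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set *p* onto *q*.

    Returns ``(rotation, translation, rmsd)`` such that
    ``p @ rotation.T + translation`` best fits *q*.  The rotation is proper
    (determinant +1); reflections are excluded by flipping the sign of the
    smallest singular vector when needed.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must be equal-shape (n, 3) arrays")
    n = p.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")

    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rotation = vt.T @ np.diag(diag) @ u.T
    translation = qc - rotation @ pc
    diff = p0 @ rotation.T - q0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return rotation, translation, rmsd


def ca_rmsd(x: PeptideStructure, y: PeptideStructure,
            params: AlignmentParams = DEFAULT_PARAMS,
            refine_cycles: int = 5, outlier_cutoff: float = 2.0,
            degenerate_policy: str = "error") -> float:
    """C-alpha RMSD after alignment-guided Kabsch superposition.

    Up to ``refine_cycles`` rejection rounds remove matched pairs deviating
    by more than ``outlier_cutoff`` Angstrom and re-superpose (PyMOL
    ``align``-style), stopping early when nothing is removed or fewer than 3
    pairs would remain.  ``refine_cycles=0`` gives the plain superposition
    RMSD over all matched pairs.  Symmetric in (x, y): the pair is
    canonicalized by sequence order before alignment so tie-breaks cannot
    differ under swap.

    For very dissimilar sequences the optimal alignment can have fewer than
    3 match columns; ``degenerate_policy`` then selects between raising
    (``"error"``, the default) and pairing residues positionally from the
    N-terminus (``"prefix"``), which whole-matrix builds use so one
    pathological pair cannot abort the computation.
    """
    if (y.sequence, y.source_id) < (x.sequence, x.source_id):
        x, y = y, x
    pairs = pair_ca_atoms(x, y, params)
    if len(pairs) < 3:
        if degenerate_policy == "prefix" and min(len(x), len(y)) >= 3:
            pairs = [(i, i) for i in range(min(len(x), len(y)))]
        else:
            raise DegenerateStructureError(
                f"only {len(pairs)} matched C-alpha pairs; need >= 3"
            )
    xi = np.array([i for i, _ in pairs])
    yi = np.array([j for _, j in pairs])
    p = x.ca_coords[xi]
    q = y.ca_coords[yi]

    rotation, _t, rmsd = kabsch_superpose(p, q)
    for _ in range(max(0, refine_cycles)):
        pc, qc = p.mean(axis=0), q.mean(axis=0)
        dev = np.linalg.norm((p - pc) @ rotation.T - (q - qc), axis=1)
        keep = dev <= outlier_cutoff
        if keep.all() or keep.sum() < 3:
            break
        p, q = p[keep], q[keep]
        rotation, _t, rmsd = kabsch_superpose(p, q)
    return rmsd


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise peptide distances under one named metric."""

    peptides: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "peptides", tuple(self.peptides))
        n = len(self.peptides)
        if values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {values.shape}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if len(set(self.peptides)) != n:
            raise ValueError("peptides must be unique")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("distances must be finite and non-negative")
        scale = max(1.0, float(np.abs(values).max()))
        if not np.allclose(values, values.T, rtol=SYM_RTOL, atol=SYM_RTOL * scale):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=SYM_RTOL * scale):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.peptides)

    def index_of(self, peptide: str) -> int:
        return self.peptides.index(peptide)

    def submatrix(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        ri = [self.peptides.index(p) for p in rows]
        ci = [self.peptides.index(p) for p in cols]
        return self.values[np.ix_(ri, ci)]


@dataclass(frozen=True)
class AggregatedDistanceVector:
    """Per-peptide aggregate of distances to all *other* peptides."""

    peptides: tuple[str, ...]
    values: np.ndarray
    aggregator: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "peptides", tuple(self.peptides))
        if values.shape != (len(self.peptides),):
            raise ValueError("values must be one aggregate per peptide")
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"unknown aggregator {self.aggregator!r}")

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.peptides, self.values.tolist()))


def build_distance_matrix(
    peptides: Sequence[str],
    metric: str,
    structures: Optional[Mapping[str, PeptideStructure]] = None,
    params: AlignmentParams = DEFAULT_PARAMS,
    refine_cycles: int = 5,
    outlier_cutoff: float = 2.0,
) -> DistanceMatrix:
    """Fill the upper triangle with the chosen pairwise distance and mirror.

    ``metric="rmsd"`` requires a structure for every peptide.  Peptides must
    be unique.
    """
    peptides = list(peptides)
    n = len(peptides)
    if len(set(peptides)) != n:
        raise ValueError("peptides must be unique")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "rmsd":
        if structures is None:
            raise TcrSplitError("rmsd metric requires structures")
        missing = [p for p in peptides if p not in structures]
        if missing:
            raise TcrSplitError(
                f"missing structures for {len(missing)} peptides, e.g. {missing[:3]}"
            )

    values = np.zeros((n, n), dtype=float)
    if metric == "levenshtein":
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = levenshtein_distance(peptides[i], peptides[j])
    elif metric == "blosum":
        # cache self-alignment scores: d = Saa + Sbb - 2 Sab
        aligner = params.make_aligner()
        alphabet = str(aligner.substitution_matrix.alphabet)
        for p in peptides:
            _check_alphabet(p, alphabet)
        self_scores = np.array([aligner.score(p, p) for p in peptides])
        for i in range(n):
            for j in range(i + 1, n):
                sab = aligner.score(peptides[i], peptides[j])
                values[i, j] = max(0.0, self_scores[i] + self_scores[j] - 2.0 * sab)
    else:  # rmsd
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = ca_rmsd(
                    structures[peptides[i]], structures[peptides[j]],
                    params=params, refine_cycles=refine_cycles,
                    outlier_cutoff=outlier_cutoff, degenerate_policy="prefix",
                )
    values += values.T
    return DistanceMatrix(peptides=tuple(peptides), values=values, metric=metric)


def aggregate_rowwise(m: DistanceMatrix,
                      aggregator: str = "median") -> AggregatedDistanceVector:
    """Row-wise aggregate of each peptide's distances, diagonal excluded.

    Median (the default) tolerates local clusters: a peptide close to a few
    others but far from most still gets a large aggregate.  Min is the
    stringent variant where a single close neighbour keeps the aggregate low.
    """
    if m.n < 2:
        raise ValueError("aggregation requires at least 2 peptides")
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    n = m.n
    off_diag = m.values[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    fn = {"median": np.median, "mean": np.mean, "min": np.min}[aggregator]
    return AggregatedDistanceVector(
        peptides=m.peptides, values=fn(off_diag, axis=1), aggregator=aggregator
    )


def write_distance_matrix(m: DistanceMatrix, path: str | Path,
                          params: Optional[AlignmentParams] = None) -> Path:
    """Serialize as a labelled TSV plus a JSON sidecar (``<path>.meta.json``)."""
    from . import __version__

    path = Path(path)
    df = pd.DataFrame(m.values, index=list(m.peptides), columns=list(m.peptides))
    df.to_csv(path, sep="\t", index_label="peptide")
    meta = {
        "metric": m.metric,
        "n_peptides": m.n,
        "tool": "tcrsplit",
        "version": __version__,
    }
    if params is not None:
        meta["alignment_params"] = {
            "substitution_matrix_name": params.substitution_matrix_name,
            "gap_open": params.gap_open,
            "gap_extend": params.gap_extend,
        }
    Path(f"{path}.meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a matrix written by :func:`write_distance_matrix`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="peptide")
    meta_path = Path(f"{path}.meta.json")
    metric = "levenshtein"
    if meta_path.exists():
        metric = json.loads(meta_path.read_text()).get("metric", metric)
    values = df.to_numpy(dtype=float)
    # guard against asymmetric rounding from text serialization
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(peptides=tuple(df.index), values=values, metric=metric)
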