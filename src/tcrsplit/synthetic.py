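"""Synthetic TCR-peptide fixtures with the statistical shape the method assumes.

The generator emulates the features of a curated viral peptide/CDR3-beta
table that the splitting protocols actually exploit:

* random peptides of length 8-11 over the 20-letter alphabet, with
  per-peptide record counts drawn from a heavy-tailed (Zipf) distribution —
  most peptides occur fewer than 10 times while a few dominate;
* paired CDR3-beta strings (C...F framing) drawn per peptide without
  replacement, so no (peptide, cdr3b, label) triple repeats;
* binary labels, either fair coins or keyed to a latent per-peptide binding
  propensity — the memorizable signal that separates a random split from a
  peptide-disjoint one;
* one C-alpha trace per peptide on an ideal helical (or extended) backbone
  with isotropic Gaussian jitter, written as standard PDB.  Geometry is
  idealized on purpose: the splitter consumes distances, not physics, and
  a backbone independent of sequence is exactly what is needed to study
  shape vs. sequence metrics in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .dataset import AMINO_ACIDS, InteractionDataset, InteractionRecord, write_interaction_table
from .errors import InfeasibleError, TcrSplitError
from .structures import PeptideStructure, write_peptide_pdb

#: cap on per-peptide counts in skewed mode (keeps fixtures desk-sized)
SKEWED_COUNT_CAP = 500
#: constant per-peptide count in uniform mode
UNIFORM_COUNT = 10
#: Zipf exponent for the skewed count distribution; gives a median count of
#: about 2 with a heavy right tail, mirroring curated interaction tables
ZIPF_EXPONENT = 1.7

_STRUCTURE_MODELS = ("helix_jitter", "extended_jitter")
_COUNT_DISTRIBUTIONS = ("skewed_powerlaw", "uniform")
_LABEL_MODELS = ("random", "peptide_keyed")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_peptides: int = 100
    length_range: tuple[int, int] = (8, 11)
    count_distribution: str = "skewed_powerlaw"
    n_cdr3b: int = 1000
    label_model: str = "peptide_keyed"
    structure_model: str = "helix_jitter"
    jitter_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (5 <= lo <= hi <= 20):
            raise ValueError("length_range must lie within [5, 20]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_peptides < 2:
            raise ValueError("need at least 2 peptides")
        if self.count_distribution not in _COUNT_DISTRIBUTIONS:
            raise ValueError(f"unknown count_distribution {self.count_distribution!r}")
        if self.label_model not in _LABEL_MODELS:
            raise ValueError(f"unknown label_model {self.label_model!r}")
        if self.structure_model not in _STRUCTURE_MODELS:
            raise ValueError(f"unknown structure_model {self.structure_model!r}")
        if self.n_cdr3b < 1:
            raise ValueError("n_cdr3b must be positive")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def generate_peptides(spec: FixtureSpec) -> tuple[list[str], dict[str, int]]:
    """Unique random peptides with per-peptide record counts.

    Skewed mode draws counts from a Zipf law truncated at
    :data:`SKEWED_COUNT_CAP` (and at the CDR3 pool size); uniform mode gives
    every peptide :data:`UNIFORM_COUNT` records.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    peptides: list[str] = []
    seen: set[str] = set()
    attempts, cap = 0, 100 * spec.n_peptides
    while len(peptides) < spec.n_peptides:
        attempts += 1
        if attempts > cap:
            raise InfeasibleError(
                f"cannot generate {spec.n_peptides} unique peptides of "
                f"length {lo}-{hi}"
            )
        pep = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        if pep not in seen:
            seen.add(pep)
            peptides.append(pep)

    count_cap = min(SKEWED_COUNT_CAP, spec.n_cdr3b)
    if spec.count_distribution == "uniform":
        counts = {p: min(UNIFORM_COUNT, count_cap) for p in peptides}
    else:
        draws = np.minimum(rng.zipf(ZIPF_EXPONENT, size=spec.n_peptides), count_cap)
        counts = {p: int(c) for p, c in zip(peptides, draws)}
    return peptides, counts


def _ideal_backbone(n: int, model: str) -> np.ndarray:
    """Ideal C-alpha trace: alpha-helix (rise 1.5 A, 100 deg/residue,
    radius 2.3 A) or extended zigzag strand (~3.8 A C-alpha spacing)."""
    i = np.arange(n, dtype=float)
    if model == "helix_jitter":
        theta = np.deg2rad(100.0) * i
        return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
    # extended strand: x advances, y alternates for a ~3.8 A chord
    return np.column_stack([3.63 * i, 1.1 * (i % 2), np.zeros(n)])


#: chain correlation of the jitter field; neighbouring residues displace
#: together so bond geometry survives jitter sds up to ~1 Angstrom
JITTER_AR1_RHO = 0.9


def _smooth_jitter(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Isotropic Gaussian displacement field, AR(1)-correlated along the
    chain, with marginal per-coordinate sd *sd*."""
    out = np.empty((n, 3))
    out[0] = rng.normal(0.0, sd, size=3)
    innov_sd = sd * np.sqrt(1.0 - JITTER_AR1_RHO ** 2)
    for i in range(1, n):
        out[i] = JITTER_AR1_RHO * out[i - 1] + rng.normal(0.0, innov_sd, size=3)
    return out


def generate_structures(
    peptides: Sequence[str], spec: FixtureSpec
) -> dict[str, PeptideStructure]:
    """One jittered ideal-backbone C-alpha trace per peptide.

    An isotropic Gaussian displacement of marginal sd ``jitter_sd`` Angstrom,
    correlated along the chain, is added to the ideal curve: uncorrelated
    per-residue noise would violate the consecutive C-alpha spacing bound at
    realistic amplitudes, whereas a smooth field deforms the backbone while
    keeping bonds intact.  A draw that still violates the spacing invariant
    is regenerated (up to 10 tries) before erroring.
    """
    if not peptides:
        raise ValueError("peptides must be non-empty")
    rng = np.random.default_rng(spec.seed + 1)  # independent of sequence stream
    out: dict[str, PeptideStructure] = {}
    for pep in peptides:
        ideal = _ideal_backbone(len(pep), spec.structure_model)
        for attempt in range(10):
            coords = ideal + _smooth_jitter(rng, len(pep), spec.jitter_sd)
            ps = PeptideStructure(sequence=pep, ca_coords=coords,
                                  source_id=f"synthetic-{pep}")
            try:
                ps.validate_geometry()
            except ValueError:
                continue
            out[pep] = ps
            break
        else:
            raise TcrSplitError(
                f"jitter_sd={spec.jitter_sd} incompatible with backbone "
                f"geometry for peptide {pep}"
            )
    return out


def latent_propensity(peptide: str, seed: int) -> float:
    """Deterministic latent binding propensity in [0.1, 0.9].

    Derived from a CRC32 of the peptide mixed with the seed, so it can be
    recomputed from (peptide, seed) alone without threading state through
    the generator.
    """
    stream = np.random.default_rng(
        (zlib.crc32(peptide.encode()) ^ (seed & 0x7FFFFFFF)) & 0x7FFFFFFF
    )
    return float(0.1 + 0.8 * stream.random())


def generate_interactions(
    peptides: Sequence[str],
    counts: Mapping[str, int],
    spec: FixtureSpec,
) -> InteractionDataset:
    """Records per peptide with CDR3-beta partners and binary labels.

    CDR3-beta strings come from a shared pool of ``n_cdr3b`` C...F-framed
    random sequences; partners are drawn per peptide without replacement so
    counts are respected exactly.  Labels: ``random`` is a fair coin;
    ``peptide_keyed`` draws Bernoulli(:func:`latent_propensity`) per record,
    creating peptide-level signal a model can memorize.
    """
    rng = np.random.default_rng(spec.seed + 2)
    pool = []
    seen: set[str] = set()
    while len(pool) < spec.n_cdr3b:
        cdr = "C" + _random_sequence(rng, int(rng.integers(8, 15))) + "F"
        if cdr not in seen:
            seen.add(cdr)
            pool.append(cdr)

    records: list[InteractionRecord] = []
    for pep in peptides:
        count = counts[pep]
        if count > len(pool):
            raise InfeasibleError(
                f"peptide count {count} exceeds CDR3 pool size {len(pool)}"
            )
        partners = rng.choice(len(pool), size=count, replace=False)
        if spec.label_model == "peptide_keyed":
            p_bind = latent_propensity(pep, spec.seed)
        else:
            p_bind = 0.5
        labels = rng.random(count) < p_bind
        records.extend(
            InteractionRecord(peptide=pep, cdr3b=pool[int(k)], label=int(lab))
            for k, lab in zip(partners, labels)
        )
    return InteractionDataset.from_records(records)


def generate_positive_interactions(
    peptides: Sequence[str],
    counts: Mapping[str, int],
    spec: FixtureSpec,
) -> InteractionDataset:
    """Positives-only records (every label 1), same partner machinery as
    :func:`generate_interactions`.

    This is the synthetic stand-in for a curated interaction export, which
    lists binders only; non-binders are added afterwards by shuffling
    (:func:`tcrsplit.dataset.generate_negatives`).
    """
    rng = np.random.default_rng(spec.seed + 2)
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < spec.n_cdr3b:
        cdr = "C" + _random_sequence(rng, int(rng.integers(8, 15))) + "F"
        if cdr not in seen:
            seen.add(cdr)
            pool.append(cdr)
    records: list[InteractionRecord] = []
    for pep in peptides:
        count = counts[pep]
        if count > len(pool):
            raise InfeasibleError(
                f"peptide count {count} exceeds CDR3 pool size {len(pool)}"
            )
        partners = rng.choice(len(pool), size=count, replace=False)
        records.extend(
            InteractionRecord(peptide=pep, cdr3b=pool[int(k)], label=1)
            for k in partners
        )
    return InteractionDataset.from_records(records)


def generate_study_dataset(
    spec: FixtureSpec, n_negatives: Optional[int] = None
) -> tuple[InteractionDataset, dict[str, PeptideStructure]]:
    """The full synthetic analogue of the study pipeline's input: a
    positives-only interaction table balanced with shuffled negatives, plus
    one structure per peptide.

    Shuffled negatives spread roughly uniformly over peptides, so after
    augmentation each peptide's record count is its skewed positive count
    plus a near-constant negative share — the count profile the splitters
    actually see.  The per-peptide positive rate then varies with the
    positive count, which is exactly the peptide-level signal a memorizing
    predictor can exploit on a random split.
    """
    from .dataset import generate_negatives

    peptides, counts = generate_peptides(spec)
    structures = generate_structures(peptides, spec)
    positives = generate_positive_interactions(peptides, counts, spec)
    ds = generate_negatives(positives, n_negatives=n_negatives,
                            seed=spec.seed + 3)
    return ds, structures


def generate_fixture(
    spec: FixtureSpec, outdir: Optional[str | Path] = None
) -> tuple[InteractionDataset, dict[str, PeptideStructure]]:
    """Full bundle: interactions plus structures; optionally written to disk
    (canonical TSV, one PDB per peptide, manifest JSON)."""
    peptides, counts = generate_peptides(spec)
    structures = generate_structures(peptides, spec)
    ds = generate_interactions(peptides, counts, spec)
    if outdir is not None:
        from . import __version__

        outdir = Path(outdir)
        (outdir / "pdb").mkdir(parents=True, exist_ok=True)
        write_interaction_table(ds, outdir / "interactions.tsv")
        for pep, ps in structures.items():
            write_peptide_pdb(ps, outdir / "pdb" / f"{pep}.pdb")
        manifest = {
            "tool": "tcrsplit", "version": __version__,
            "spec": {
                "n_peptides": spec.n_peptides,
                "length_range": list(spec.length_range),
                "count_distribution": spec.count_distribution,
                "n_cdr3b": spec.n_cdr3b,
                "label_model": spec.label_model,
                "structure_model": spec.structure_model,
                "jitter_sd": spec.jitter_sd,
                "seed": spec.seed,
            },
            "n_records": len(ds),
        }
        (outdir / "fixture_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return ds, structures
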