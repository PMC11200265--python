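"""Molecular featurization and structural-diversity statistics.

Molecules enter as SMILES strings and are converted to extended-connectivity
fingerprints (ECFPs, a.k.a. Morgan fingerprints): hashed binary vectors of
circular atom neighborhoods. Defaults are 1024 bits at radius 2, the standard
configuration for zero-shot QSAR benchmarking. Substructure enumeration and
hashing are delegated to RDKit; this module owns the contract (determinism,
length, error behaviour) and the diversity summaries built on top (Tanimoto
similarity, Bemis-Murcko scaffolds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .exceptions import DimensionError, InsufficientDataError, InvalidMoleculeError

RDLogger.DisableLog("rdApp.*")

DEFAULT_N_BITS = 1024
DEFAULT_RADIUS = 2


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: an identifier plus its SMILES line notation."""

    id: str
    smiles: str


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary circular-substructure vector.

    ``bits`` is a uint8 array of 0/1 of length ``n_bits``; the fingerprint is
    a deterministic function of the molecular graph (canonicalization
    invariant), not of the particular SMILES spelling.
    """

    bits: np.ndarray
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or bits.shape[0] != self.n_bits:
            raise DimensionError(
                f"fingerprint has {bits.shape} bits, expected ({self.n_bits},)"
            )
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    @property
    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidMoleculeError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparsable SMILES: {smiles!r}")
    return mol


def ecfp(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    include_chirality: bool = False,
) -> Fingerprint:
    """Extended-connectivity fingerprint of a molecule.

    Parameters
    ----------
    smiles
        SMILES string; must parse to a valid molecular graph.
    radius
        Neighborhood radius (number of bond hops); radius 2 corresponds to
        the classical ECFP4 diameter.
    n_bits
        Hash length of the binary vector (>= 8).
    include_chirality
        Whether stereochemistry participates in the atom-environment hashing.
        Off by default: 2D connectivity only.

    Raises
    ------
    InvalidMoleculeError
        If the SMILES does not parse; the message names the offending string.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if n_bits < 8:
        raise ValueError(f"n_bits must be >= 8, got {n_bits}")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=include_chirality
    )
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(gen.GetFingerprint(mol).GetOnBits())] = 1
    return Fingerprint(bits=arr, n_bits=n_bits, radius=radius)


def ecfp_batch(
    records: list[MoleculeRecord],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    include_chirality: bool = False,
) -> tuple[dict[str, Fingerprint], dict[str, str]]:
    """Fingerprint a batch, reporting per-row failures instead of dropping rows.

    Returns ``(fingerprints, errors)`` where ``errors`` maps the record id to
    the failure message. Callers decide whether any failure is fatal.
    """
    out: dict[str, Fingerprint] = {}
    errors: dict[str, str] = {}
    for rec in records:
        try:
            out[rec.id] = ecfp(rec.smiles, radius, n_bits, include_chirality)
        except (InvalidMoleculeError, ValueError) as exc:
            errors[rec.id] = str(exc)
    return out, errors


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b| of two fingerprints.

    Two all-zero fingerprints are defined to have similarity 1.0 (identical
    objects); this convention is deliberate and tested.
    """
    if a.n_bits != b.n_bits:
        raise DimensionError(
            f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}"
        )
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 1.0
    return inter / union


def mean_pairwise_tanimoto(fps: list[Fingerprint]) -> tuple[float, float]:
    """Mean and standard deviation of Tanimoto over all unordered pairs.

    The SD is the population standard deviation over the n*(n-1)/2 distinct
    pairs (ddof=0), so two items give SD 0 rather than NaN.
    """
    if len(fps) < 2:
        raise InsufficientDataError(
            f"need at least 2 fingerprints, got {len(fps)}"
        )
    sims = [
        tanimoto(fps[i], fps[j])
        for i in range(len(fps))
        for j in range(i + 1, len(fps))
    ]
    sims = np.asarray(sims, dtype=float)
    return float(sims.mean()), float(sims.std(ddof=0))


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES: ring systems plus linkers.

    Side chains are removed; an acyclic molecule has the empty scaffold ``""``.
    """
    mol = _mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def unique_scaffold_fraction(
    ranked: list[MoleculeRecord], top_fraction: float
) -> float:
    """Fraction of all unique Murcko scaffolds found in the top slice.

    ``ranked`` must be ordered by descending score. The top slice holds
    ``floor(top_fraction * N)`` molecules (at least one), so a 20% slice of a
    1000-compound screen is exactly the top 200.
    """
    if not ranked:
        raise InsufficientDataError("ranked list is empty")
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    scaffolds = [murcko_scaffold(rec.smiles) for rec in ranked]
    k = max(1, int(math.floor(top_fraction * len(ranked) + 1e-9)))
    return len(set(scaffolds[:k])) / len(set(scaffolds))
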