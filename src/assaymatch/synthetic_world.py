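"""Synthetic assay-molecule worlds with known latent structure.

Real zero-shot benchmarks pair each molecule with the free-text protocol of
an assay; here both modalities are generated from a shared latent space so
that zero-shot generalization, modality ablations and conformal coverage can
be measured without any external download, and against a known ground truth.

Generative model, per world:

* each assay k carries a unit concept vector a_k in R^latent_dim. Concepts
  are drawn in anti-correlated pairs (a, -a): two assays probing the same
  axis in opposite directions, like an agonist and an antagonist screen.
  This makes the molecular modality alone uninformative across the pooled
  pair table — the label depends on which assay the molecule is paired with —
  so any cross-assay signal must come through the text modality.
* each assay gets ``mols_per_assay`` fresh molecules with latent coordinates
  m ~ N(0, I).
* activity: label = 1 with probability sigmoid(<a_k, m>/temperature + b_k),
  where the per-assay bias b_k is solved by bisection so the realized
  prevalence hits ``target_prevalence`` (both classes always present).
* the observed text embedding of assay k is a_k plus isotropic noise
  (sd ``text_noise_sd``); the observed fingerprint of a molecule is the sign
  pattern of a fixed random projection of m plus noise (sd ``mol_noise_sd``)
  into ``n_bits`` bits, shared across the whole world.
* a fraction of assays is held out; held-out assays share no id, molecule or
  text with the training assays, mirroring assay-disjoint benchmark splits.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GenerationError


@dataclass(frozen=True)
class WorldConfig:
    """Generator settings; defaults define the standard test conditions."""

    n_assays: int = 240
    mols_per_assay: int = 50
    latent_dim: int = 8
    text_noise_sd: float = 0.1
    mol_noise_sd: float = 0.1
    target_prevalence: float = 0.3
    temperature: float = 0.25
    n_bits: int = 512
    seed: int = 0
    heldout_assay_fraction: float = 1 / 3

    def __post_init__(self):
        if self.n_assays < 4:
            raise ConfigurationError("n_assays must be >= 4")
        if self.mols_per_assay < 20:
            raise ConfigurationError("mols_per_assay must be >= 20")
        if not 0 < self.target_prevalence < 1:
            raise ConfigurationError("target_prevalence must be in (0, 1)")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        if not 0 < self.heldout_assay_fraction < 1:
            raise ConfigurationError("heldout_assay_fraction must be in (0, 1)")


@dataclass
class SyntheticWorld:
    """One generated world: assays, molecules, labelled pairs, and the split."""

    config: WorldConfig
    assay_ids: list[str]
    concepts: np.ndarray  # (n_assays, latent_dim), unit rows
    text_embeddings: dict[str, np.ndarray]
    mol_ids: list[str]
    mol_latents: np.ndarray  # (M, latent_dim)
    fingerprints: np.ndarray  # (M, n_bits) uint8
    pairs: pd.DataFrame  # mol_id, assay_id, label
    train_assays: list[str]
    heldout_assays: list[str]
    _mol_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._mol_index:
            self._mol_index = {mid: i for i, mid in enumerate(self.mol_ids)}

    def pair_arrays(self, pairs: pd.DataFrame | None = None):
        """(X_mol, X_text, y) feature arrays for a pair table (default: all)."""
        pairs = self.pairs if pairs is None else pairs
        rows = [self._mol_index[m] for m in pairs["mol_id"]]
        X_mol = self.fingerprints[rows].astype(np.float64)
        X_text = np.array([self.text_embeddings[a] for a in pairs["assay_id"]])
        y = pairs["label"].to_numpy(dtype=np.int64)
        return X_mol, X_text, y


def _bisect_bias(s_over_T: np.ndarray, u: np.ndarray, target_count: int) -> float:
    """Bias b with #{u_i < sigmoid(s_i + b)} == target_count, by bisection.

    The count is a monotone step function of b; u_i are the pre-drawn
    uniforms that decide the labels, so the bias targets the *realized*
    prevalence, not just its expectation.
    """

    def count(b: float) -> int:
        return int(np.sum(u < 1.0 / (1.0 + np.exp(-(s_over_T + b)))))

    lo, hi = -30.0, 30.0
    if not count(lo) <= target_count <= count(hi):
        raise GenerationError("prevalence target infeasible within bias bounds")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if count(mid) >= target_count:
            hi = mid
        else:
            lo = mid
    if count(hi) != target_count:
        raise GenerationError("bisection failed to hit the prevalence target")
    return hi


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a world; byte-identical for identical configs."""
    ss = np.random.SeedSequence(config.seed)
    r_concept, r_text, r_mol, r_label, r_proj, r_split = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    K, n_per, d = config.n_assays, config.mols_per_assay, config.latent_dim

    # concepts in anti-correlated pairs
    concepts = np.empty((K, d))
    for k in range(0, K, 2):
        a = r_concept.standard_normal(d)
        a /= np.linalg.norm(a)
        concepts[k] = a
        if k + 1 < K:
            concepts[k + 1] = -a

    assay_ids = [f"A{k:04d}" for k in range(K)]
    text_embeddings = {
        aid: concepts[k] + r_text.normal(0.0, config.text_noise_sd, size=d)
        for k, aid in enumerate(assay_ids)
    }

    M = K * n_per
    mol_latents = r_mol.standard_normal((M, d))
    mol_ids = [f"M{i:06d}" for i in range(M)]
    projection = r_proj.standard_normal((config.n_bits, d))
    noisy = mol_latents + r_mol.normal(0.0, config.mol_noise_sd, size=(M, d))
    fingerprints = (noisy @ projection.T > 0.0).astype(np.uint8)

    target_count = int(round(config.target_prevalence * n_per))
    target_count = min(max(target_count, 1), n_per - 1)  # both classes per assay
    rows = []
    for k, aid in enumerate(assay_ids):
        sl = slice(k * n_per, (k + 1) * n_per)
        s_over_T = mol_latents[sl] @ concepts[k] / config.temperature
        u = r_label.random(n_per)
        b = _bisect_bias(s_over_T, u, target_count)
        labels = (u < 1.0 / (1.0 + np.exp(-(s_over_T + b)))).astype(np.int64)
        for j, mid in enumerate(mol_ids[sl]):
            rows.append((mid, aid, int(labels[j])))
    pairs = pd.DataFrame(rows, columns=["mol_id", "assay_id", "label"])

    n_heldout = max(1, int(round(config.heldout_assay_fraction * K)))
    heldout_idx = np.sort(r_split.choice(K, size=n_heldout, replace=False))
    heldout = [assay_ids[i] for i in heldout_idx]
    train = [a for a in assay_ids if a not in set(heldout)]

    return SyntheticWorld(
        config=config,
        assay_ids=assay_ids,
        concepts=concepts,
        text_embeddings=text_embeddings,
        mol_ids=mol_ids,
        mol_latents=mol_latents,
        fingerprints=fingerprints,
        pairs=pairs,
        train_assays=train,
        heldout_assays=heldout,
    )


def zero_shot_split(world: SyntheticWorld) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assay-disjoint partition of the pair table (train, held-out)."""
    heldout = set(world.heldout_assays)
    mask = world.pairs["assay_id"].isin(heldout)
    return (
        world.pairs[~mask].reset_index(drop=True),
        world.pairs[mask].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Export in the same TSV formats the CLI consumes
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Write pairs.tsv (with fingerprint bitstrings), embeddings.tsv, split.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs_path = outdir / "pairs.tsv"
    emb_path = outdir / "embeddings.tsv"
    split_path = outdir / "split.json"

    fp_strings = ["".join(map(str, row)) for row in world.fingerprints]
    fp_by_mol = dict(zip(world.mol_ids, fp_strings))
    out = world.pairs.copy()
    out.insert(0, "id", out.pop("mol_id"))
    out["fp"] = [fp_by_mol[m] for m in out["id"]]
    out.to_csv(pairs_path, sep="\t", index=False)

    emb = pd.DataFrame.from_dict(
        {a: v for a, v in world.text_embeddings.items()}, orient="index"
    )
    emb.columns = [f"e{i}" for i in range(emb.shape[1])]
    emb.index.name = "assay_id"
    emb.to_csv(emb_path, sep="\t", float_format="%.10g")

    split_path.write_text(
        json.dumps(
            {
                "train_assays": world.train_assays,
                "heldout_assays": world.heldout_assays,
                "config": asdict(world.config),
            },
            indent=1,
        )
    )
    return {"pairs": pairs_path, "embeddings": emb_path, "split": split_path}
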