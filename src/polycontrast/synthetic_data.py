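"""Synthetic polymer corpora, property tasks and embedding fixtures.

Repeat units are assembled from a library of divalent backbone fragments
(alkylene, ether, ester, amide, arylene units) with optional monovalent side
groups grafted onto backbone carbons, then capped with the two ``[*]``
connection tokens. Fragment assembly guarantees chemical validity and gives
structural descriptors genuine variance, so property tasks built on them are
learnable.

Property labels are smooth functions of structural descriptors plus Gaussian
noise: y = descriptors · coefficients + N(0, sd). Descriptors are functions
of the molecular graph, so every enumerated rendering of a polymer receives
the same label — which is exactly what makes enumeration a
semantics-preserving augmentation testable end to end.

Embedding fixtures provide matrices with analytically known alignment and
uniformity for metric tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .polymer_smiles import HOMOPOLYMER_PROFILE, PolymerSmiles, canonicalize, validate

logger = logging.getLogger("polycontrast")


@dataclass(frozen=True)
class FragmentLibrary:
    """Divalent backbones and monovalent side groups with sampling weights.

    Backbone fragments are written so that plain left-to-right concatenation
    of any sequence, capped with ``[*]`` at both ends, is a valid SMILES.
    Side groups are inserted as a branch on a backbone carbon, ``C(<side>)``.
    """

    backbones: tuple = (
        "C", "CC", "CCC", "CO", "CCO", "CN",
        "CC(=O)O", "CC(=O)N", "CS", "c1ccccc1", "C1CCCCC1",
    )
    side_groups: tuple = ("C", "F", "Cl", "O", "C(=O)O", "c1ccccc1", "C#N", "OC")
    backbone_weights: tuple | None = None
    side_group_weights: tuple | None = None
    min_units: int = 2
    max_units: int = 5
    side_group_prob: float = 0.35

    def _weights(self, items, weights) -> np.ndarray:
        if weights is None:
            return np.full(len(items), 1.0 / len(items))
        w = np.asarray(weights, dtype=float)
        return w / w.sum()


DEFAULT_LIBRARY = FragmentLibrary()


def generate_polymers(n: int, library: FragmentLibrary = DEFAULT_LIBRARY,
                      rng: np.random.Generator | None = None) -> list[PolymerSmiles]:
    """Sample n valid two-star repeat units; duplicates allowed but logged."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    bw = library._weights(library.backbones, library.backbone_weights)
    sw = library._weights(library.side_groups, library.side_group_weights)
    out: list[str] = []
    while len(out) < n:
        k = int(rng.integers(library.min_units, library.max_units + 1))
        units = []
        for _ in range(k):
            frag = library.backbones[int(rng.choice(len(library.backbones), p=bw))]
            units.append(frag)
            if rng.random() < library.side_group_prob:
                side = library.side_groups[int(rng.choice(len(library.side_groups), p=sw))]
                units.append(f"C({side})")
        s = "[*]" + "".join(units) + "[*]"
        report = validate(s, HOMOPOLYMER_PROFILE)
        if not report.ok:  # fragment grammar should preclude this
            raise RuntimeError(f"generator produced invalid repeat unit {s!r}: {report.errors}")
        out.append(s)
    dup = len(out) - len(set(out))
    if dup:
        logger.info("generate_polymers: %d duplicate repeat unit(s) in corpus", dup)
    return out


# ---------------------------------------------------------------------------
# Descriptors & property tasks
# ---------------------------------------------------------------------------

DESCRIPTOR_NAMES = ("n_aromatic_atoms", "n_heteroatoms", "n_rings", "n_heavy_atoms")


def descriptors(s: PolymerSmiles) -> np.ndarray:
    """Graph-level structural descriptors (invariant to SMILES rendering).

    Columns: aromatic-atom count, heteroatom count (non-C/H, connection
    points excluded), ring count, heavy-atom count (connection points
    excluded).
    """
    mol = Chem.MolFromSmiles(canonicalize(s))
    if mol is None:
        raise ValueError(f"cannot compute descriptors for {s!r}")
    n_arom = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    n_het = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (0, 1, 6))
    n_rings = mol.GetRingInfo().NumRings()
    n_heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
    return np.array([n_arom, n_het, n_rings, n_heavy], dtype=float)


def descriptor_matrix(polymers: Sequence[PolymerSmiles]) -> np.ndarray:
    return np.vstack([descriptors(s) for s in polymers])


@dataclass
class SyntheticTaskSpec:
    """A property task: y = descriptors[:, :k] · coefficients + N(0, sd)."""

    coefficients: tuple = (1.0, -0.8, 2.5)
    noise_sd: float = 0.0
    seed: int = 0
    name: str = "synthetic_property"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def signal(polymers: Sequence[PolymerSmiles], spec: SyntheticTaskSpec) -> np.ndarray:
    """Noise-free descriptor signal for a task."""
    coeffs = np.asarray(spec.coefficients, dtype=float)
    D = descriptor_matrix(polymers)[:, : coeffs.size]
    return D @ coeffs


def generate_property_dataset(polymers: Sequence[PolymerSmiles],
                              spec: SyntheticTaskSpec) -> pd.DataFrame:
    """CSV-ready (smiles, y) frame; the noise draw is seeded by the task spec."""
    rng = np.random.default_rng(spec.seed)
    base = signal(polymers, spec)
    y = base + rng.normal(0.0, spec.noise_sd, size=base.size)
    return pd.DataFrame({"smiles": list(polymers), "y": y})


def make_noise_sd(polymers: Sequence[PolymerSmiles], spec: SyntheticTaskSpec,
                  noise_frac: float = 0.05) -> float:
    """Noise sd as a fraction of the signal's standard deviation."""
    return float(noise_frac * np.std(signal(polymers, spec)))


# ---------------------------------------------------------------------------
# Embedding fixtures
# ---------------------------------------------------------------------------

FIXTURE_STRUCTURES = ("identical", "antipodal_pair", "gaussian_clusters")


def generate_embedding_fixture(n: int, d: int, structure: str,
                               rng: np.random.Generator | None = None,
                               n_clusters: int = 4, cluster_sd: float = 0.05,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Paired embedding matrices with known metric behaviour.

    identical: E2 is a copy of E1 (alignment 0; uniformity 0 per side iff all
    rows coincide, which this structure does not impose). antipodal_pair: a
    single unit pair (u, -u) — alignment 4, two-point uniformity -8 at t=2.
    gaussian_clusters: positives drawn from the same cluster centre, so
    within-pair distances are small against cross-cluster distances.
    """
    if n < 1 or d < 1:
        raise ValueError("n and d must be at least 1")
    if structure not in FIXTURE_STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; choose from {FIXTURE_STRUCTURES}")
    rng = rng if rng is not None else np.random.default_rng(0)
    if structure == "identical":
        E1 = rng.normal(size=(n, d))
        return E1, E1.copy()
    if structure == "antipodal_pair":
        u = rng.normal(size=d)
        u /= np.linalg.norm(u)
        return u[None, :], -u[None, :]
    centres = rng.normal(size=(n_clusters, d))
    centres /= np.linalg.norm(centres, axis=1, keepdims=True)
    assign = rng.integers(0, n_clusters, size=n)
    E1 = centres[assign] + rng.normal(0.0, cluster_sd, size=(n, d))
    E2 = centres[assign] + rng.normal(0.0, cluster_sd, size=(n, d))
    return E1, E2
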