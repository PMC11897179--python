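"""Synthetic benchmarks with known geometry, plus dataset and design utilities.

The benchmark emulates the geometry that makes reliability adjustment hard:
each property has its own training cloud of binary fingerprint-like vectors,
and the clouds overlap only partially.  A candidate that sits inside one
cloud scores high reliability for that property and low for the others;
"bridge" candidates between clouds score moderate reliability everywhere.
Raising all reliability levels therefore empties the AD overlap — the
trade-off the DSS objective negotiates.

Property oracles are deterministic monotone functions of the Tanimoto
similarity to each property's cloud center, so every downstream quantity is
exactly reproducible and small grids can be enumerated for brute-force
validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit import Chem

from .chem import Fingerprint, Molecule, ReferenceSet, max_tanimoto, morgan_fingerprint, tanimoto
from .generator import DesignRecord, DesignRun, PoolGenerator
from .models import PropertyDataset, PropertyModel
from .optimizer import DesignContext, DSSConfig, ScalerConfig
from .rewards import DesirabilitySpec


# ---------------------------------------------------------------------------
# Synthetic benchmark
# ---------------------------------------------------------------------------

@dataclass
class _SimilarityOracle:
    """Deterministic property oracle: value rises linearly with similarity
    to the property's cloud center (0 at similarity 0, ``scale`` at 1)."""

    center: Fingerprint
    scale: float = 10.0

    def __call__(self, fp: Fingerprint) -> float:
        return self.scale * tanimoto(fp, self.center)


@dataclass
class SyntheticBenchmark:
    """k property clouds, deterministic oracles, and a finite candidate pool."""

    k: int
    separation: float
    centers: list[Fingerprint]
    clouds: list[ReferenceSet]
    oracles: list[_SimilarityOracle]
    pool: list[tuple[str, Fingerprint]]
    seed: int
    value_scale: float = 10.0

    def models(self) -> list[PropertyModel]:
        return [
            PropertyModel(
                predict_fn=self.oracles[i],
                ad_refs=self.clouds[i],
                property_name=f"property_{i}",
                units="a.u.",
                nbits=self.centers[i].nbits,
                radius=self.centers[i].radius,
            )
            for i in range(self.k)
        ]

    def desirabilities(self, mu_fraction: float = 0.3, sigma_fraction: float = 0.15) -> list[DesirabilitySpec]:
        """Saturating-high desirabilities on the oracle scale.

        The default target (30% of the scale) is reachable by bridge
        candidates between clouds, so the benchmark rewards the AD overlap
        rather than only the cloud cores.
        """
        return [
            DesirabilitySpec(
                shape="max_gaussian",
                mu=mu_fraction * self.value_scale,
                sigma_v=sigma_fraction * self.value_scale,
            )
            for _ in range(self.k)
        ]

    def context(
        self,
        scalers: Sequence[ScalerConfig] | None = None,
        top_fraction: float = 0.10,
        weights: Sequence[float] | None = None,
        seed: int = 0,
        desirabilities: Sequence[DesirabilitySpec] | None = None,
    ) -> DesignContext:
        """Pool-generator design context for this benchmark."""
        scalers = list(scalers) if scalers else [ScalerConfig(sigma=0.25) for _ in range(self.k)]
        w = np.asarray(weights, dtype=float) if weights is not None else np.ones(self.k)
        return DesignContext(
            models=self.models(),
            desirabilities=list(desirabilities) if desirabilities else self.desirabilities(),
            weights=w,
            generator=PoolGenerator(self.pool),
            dss_config=DSSConfig(scalers=scalers, top_fraction=top_fraction),
            budget=len(self.pool),
            seed=seed,
        )

    def cross_cloud_mts(self) -> np.ndarray:
        """Median MTS of each cloud's members against every other cloud."""
        out = np.zeros((self.k, self.k))
        for i in range(self.k):
            for j in range(self.k):
                if i == j:
                    out[i, j] = 1.0
                    continue
                vals = [max_tanimoto(fp, self.clouds[j]) for fp in self.clouds[i].fingerprints]
                out[i, j] = float(np.median(vals))
        return out


def _random_bits(rng: np.random.Generator, pool: np.ndarray, n: int) -> frozenset[int]:
    return frozenset(int(b) for b in rng.choice(pool, size=min(n, pool.size), replace=False))


def make_benchmark(
    k: int = 3,
    separation: float = 0.7,
    n_per_cloud: int = 40,
    d: int = 256,
    seed: int = 0,
    noise: float = 0.2,
    n_bridge: int = 20,
    n_cloudlike: int = 10,
    n_junk: int = 10,
) -> SyntheticBenchmark:
    """Build a synthetic benchmark with controllable inter-cloud overlap.

    ``separation`` in [0, 1] is the fraction of each cloud center's bits that
    are unique to that property (0: all clouds share one center; 1: disjoint
    centers).  Cloud members copy their center with bit-flip noise ``noise``.
    The candidate pool holds bridge candidates (bit unions drawn from every
    center — the AD-overlap region), cloud-like candidates near single
    centers, and junk candidates far from all training data.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if d < 64:
        raise ValueError("fingerprint dimension d must be >= 64")
    if not (0.0 <= separation <= 1.0):
        raise ValueError("separation must be in [0, 1]")
    if n_per_cloud < 1:
        raise ValueError("n_per_cloud must be >= 1")

    rng = np.random.default_rng(seed)
    b = max(16, d // 8)  # bits per center
    n_shared = round((1.0 - separation) * b)
    all_indices = rng.permutation(d)
    shared_core = all_indices[:n_shared]
    cursor = n_shared
    centers: list[Fingerprint] = []
    for i in range(k):
        unique = all_indices[cursor : cursor + (b - n_shared)]
        cursor += b - n_shared
        if cursor > d:
            raise ValueError("d too small for the requested k/separation (centers overflow)")
        centers.append(Fingerprint(bits=frozenset(int(x) for x in np.concatenate([shared_core, unique])), nbits=d, radius=0))

    def perturb(center: Fingerprint) -> Fingerprint:
        bits = set(center.bits)
        for bit in list(bits):
            if rng.random() < noise:
                bits.discard(bit)
        n_add = rng.binomial(b, noise)
        bits.update(int(x) for x in rng.choice(d, size=n_add, replace=False))
        if not bits:
            bits = {int(rng.integers(d))}
        return Fingerprint(bits=frozenset(bits), nbits=d, radius=0)

    clouds = [
        ReferenceSet(fingerprints=[perturb(c) for _ in range(n_per_cloud)])
        for c in centers
    ]
    oracles = [_SimilarityOracle(center=c) for c in centers]

    pool: list[tuple[str, Fingerprint]] = []
    take = max(1, b // max(k, 1))  # bits taken from each center for bridges
    for j in range(n_bridge):
        bits: set[int] = set()
        for c in centers:
            bits.update(int(x) for x in rng.choice(sorted(c.bits), size=take, replace=False))
        pool.append((f"bridge_{j}", Fingerprint(bits=frozenset(bits), nbits=d, radius=0)))
    for j in range(n_cloudlike):
        i = int(rng.integers(k))
        pool.append((f"cloud{i}_{j}", perturb(centers[i])))
    for j in range(n_junk):
        bits = frozenset(int(x) for x in rng.choice(d, size=b, replace=False))
        pool.append((f"junk_{j}", Fingerprint(bits=bits, nbits=d, radius=0)))

    return SyntheticBenchmark(
        k=k,
        separation=separation,
        centers=centers,
        clouds=clouds,
        oracles=oracles,
        pool=pool,
        seed=seed,
    )


def make_planted_benchmark(k: int = 3, d: int = 256, seed: int = 0) -> SyntheticBenchmark:
    """Benchmark whose DSS landscape argmax is known analytically.

    All k properties share one single-fingerprint reference set R (so every
    candidate has identical reliability s for all properties).  The pool
    holds one candidate at s = 0.7 whose oracle values saturate its
    desirability (reward 1 inside the AD) and decoys at s = 0.3.  Because
    the Scaler is strictly increasing below its center and the top-X% mean
    is the pool maximum, the exact DSS argmax on any grid is the largest
    grid value <= 0.7 on every axis.
    """
    rng = np.random.default_rng(seed)
    base = rng.choice(d, size=100, replace=False)
    R = Fingerprint(bits=frozenset(int(x) for x in base), nbits=d, radius=0)
    refs = ReferenceSet(fingerprints=[R])
    good = Fingerprint(bits=frozenset(int(x) for x in base[:70]), nbits=d, radius=0)
    pool: list[tuple[str, Fingerprint]] = [("planted_optimum", good)]
    for j in range(9):
        decoy = Fingerprint(bits=frozenset(int(x) for x in base[j : j + 30]), nbits=d, radius=0)
        pool.append((f"decoy_{j}", decoy))
    center = R
    return SyntheticBenchmark(
        k=k,
        separation=0.0,
        centers=[center] * k,
        clouds=[refs] * k,
        oracles=[_SimilarityOracle(center=center) for _ in range(k)],
        pool=pool,
        seed=seed,
    )


# Desirability saturating at the planted candidate's oracle value (10 * 0.7):
PLANTED_DESIRABILITY = DesirabilitySpec(shape="max_gaussian", mu=7.0, sigma_v=1.5)


# ---------------------------------------------------------------------------
# Dataset utility: cross-dataset similarity removal
# ---------------------------------------------------------------------------

def remove_cross_similar(
    datasets: list[PropertyDataset],
    threshold: float = 0.5,
    radius: int = 2,
    nbits: int = 2048,
) -> tuple[list[PropertyDataset], int]:
    """Drop molecules that bridge training datasets.

    A molecule is removed from its dataset iff its MTS against the union of
    the *other* datasets' molecules (the original, pre-removal unions, so the
    result is order-independent) exceeds ``threshold``.  Returns the filtered
    datasets and the total number of removed records.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    fps_per_dataset = [
        [morgan_fingerprint(m, radius=radius, nbits=nbits) for m in ds.molecules]
        for ds in datasets
    ]
    filtered, removed = [], 0
    for i, ds in enumerate(datasets):
        other = [fp for j, fps in enumerate(fps_per_dataset) if j != i for fp in fps]
        refs = ReferenceSet(fingerprints=other)
        kept = []
        for record, fp in zip(ds.records, fps_per_dataset[i]):
            if max_tanimoto(fp, refs) > threshold:
                removed += 1
            else:
                kept.append(record)
        filtered.append(PropertyDataset(records=kept, property_name=ds.property_name, units=ds.units))
    return filtered, removed


# ---------------------------------------------------------------------------
# Post-design filters and selection
# ---------------------------------------------------------------------------

def lipinski_filter(mol: Molecule) -> bool:
    """Rule-of-five filter: MW <= 500, cLogP <= 5, HBD <= 5, HBA <= 10."""
    rdmol = Chem.MolFromSmiles(mol.smiles)
    return (
        Descriptors.MolWt(rdmol) <= 500.0
        and Crippen.MolLogP(rdmol) <= 5.0
        and Lipinski.NumHDonors(rdmol) <= 5
        and Lipinski.NumHAcceptors(rdmol) <= 10
    )


class NoValidMoleculesError(ValueError):
    pass


def select_representatives(
    run: DesignRun,
    k: int = 20,
    seed: int = 0,
    radius: int = 2,
    nbits: int = 2048,
) -> list[DesignRecord]:
    """Cluster the run's valid molecules (k-means on fingerprints) and keep
    the highest-reward molecule of each cluster.

    Ties within a cluster break by canonical-SMILES lexicographic order so
    selection is deterministic.
    """
    from sklearn.cluster import KMeans

    from .models import fingerprint_matrix

    unique = run.unique_valid()
    if not unique:
        raise NoValidMoleculesError("design run has no valid molecules")
    if len(unique) <= k:
        return sorted(unique, key=lambda r: (-r.reward, r.smiles))
    fps = [morgan_fingerprint(Molecule(r.smiles, 1), radius=radius, nbits=nbits) for r in unique]
    X = fingerprint_matrix(fps)
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    chosen: dict[int, DesignRecord] = {}
    for rec, lab in zip(unique, labels):
        cur = chosen.get(lab)
        better = cur is None or rec.reward > cur.reward or (
            rec.reward == cur.reward and rec.smiles < cur.smiles
        )
        if better:
            chosen[lab] = rec
    return sorted(chosen.values(), key=lambda r: (-r.reward, r.smiles))


# ---------------------------------------------------------------------------
# Small programmatic SMILES corpus (for demos and generator tests)
# ---------------------------------------------------------------------------

def example_corpus(n_max: int = 200, seed: int = 0) -> list[str]:
    """A small, programmatically generated corpus of valid drug-like-ish
    SMILES (substituted chains and rings); no external data required."""
    backbones = ["C" * i for i in range(2, 7)] + ["c1ccccc1", "C1CCCCC1", "c1ccncc1"]
    substituents = ["", "O", "N", "Cl", "F", "C(=O)O", "OC", "NC"]
    corpus = []
    for bb in backbones:
        for sub in substituents:
            smi = bb + sub if sub else bb
            mol = Chem.MolFromSmiles(smi)
            if mol is not None:
                corpus.append(Chem.MolToSmiles(mol))
    for a in ("C", "CC", "CCC"):
        for b in ("O", "N", "CO", "C(C)O"):
            mol = Chem.MolFromSmiles(a + b)
            if mol is not None:
                corpus.append(Chem.MolToSmiles(mol))
    rng = np.random.default_rng(seed)
    corpus = sorted(set(corpus))
    if len(corpus) > n_max:
        corpus = [corpus[i] for i in sorted(rng.choice(len(corpus), size=n_max, replace=False))]
    return corpus
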