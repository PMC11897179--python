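"""Shared fixtures: small molecule sets, synthetic datasets, toy policies."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from reliamol import (
    Fingerprint,
    Molecule,
    PropertyDataset,
    PropertyModel,
    ReferenceSet,
    canonicalize,
    train_policy,
)


def random_fingerprint(rng: np.random.Generator, nbits: int = 256, density: float = 0.1) -> Fingerprint:
    n_on = max(1, rng.binomial(nbits, density))
    bits = frozenset(int(b) for b in rng.choice(nbits, size=n_on, replace=False))
    return Fingerprint(bits=bits, nbits=nbits, radius=0)


def generated_molecules(n: int) -> list[Molecule]:
    """Programmatically enumerate n distinct valid molecules (no data files)."""
    seen: dict[str, Molecule] = {}
    cores = ["C", "CC", "CCC", "CCCC", "CCCCC", "c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCNCC1"]
    subs = ["", "O", "N", "Cl", "F", "OC", "NC", "C(=O)O", "C(=O)N", "C#N", "S", "OCC", "NCC", "Br"]
    for core in cores:
        for s1 in subs:
            for s2 in subs:
                smi = core + s1 + s2
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                can = Chem.MolToSmiles(mol)
                if can not in seen:
                    seen[can] = canonicalize(can)
                if len(seen) >= n:
                    return list(seen.values())
    raise RuntimeError(f"could only enumerate {len(seen)} molecules")


@pytest.fixture(scope="session")
def molecule_pool() -> list[Molecule]:
    return generated_molecules(250)


@pytest.fixture(scope="session")
def bitcount_dataset(molecule_pool) -> PropertyDataset:
    """Target is a deterministic function of fingerprint on-bit count."""
    from reliamol import morgan_fingerprint

    records = [(m, 0.05 * morgan_fingerprint(m).n_on) for m in molecule_pool[:200]]
    return PropertyDataset(records=records, property_name="bitcount", units="a.u.")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20241001)


def oracle_model(refs: ReferenceSet, value: float = 5.0, name: str = "p") -> PropertyModel:
    """A model with a constant oracle predictor and explicit AD references."""
    nbits = refs.fingerprints[0].nbits if len(refs) else 2048
    radius = refs.fingerprints[0].radius if len(refs) else 2
    return PropertyModel(
        predict_fn=lambda fp: value,
        ad_refs=refs,
        property_name=name,
        nbits=nbits,
        radius=radius,
    )


TOY_CORPUS = [
    "CCO", "CCC", "CCN", "CCCO", "CCCN", "c1ccccc1", "CCOC", "CCNC",
    "CC(C)O", "CC(C)N", "CCCC", "CCCCO", "CCCCN", "c1ccncc1", "CC(=O)O",
    "CCC(=O)O", "CCOCC", "CNC", "COC", "CCCl",
]


@pytest.fixture(scope="session")
def toy_policy():
    return train_policy(TOY_CORPUS, order=3)
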