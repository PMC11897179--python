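"""Per-property prediction models whose training fingerprints define the AD.

A :class:`PropertyModel` couples a fingerprint-input regressor with the
reference set of its training fingerprints.  The reference set is what makes
the model's predictions auditable: ``reliability(model, mol)`` is the maximum
Tanimoto similarity (MTS) between the molecule and the training data, the
score ``s`` that the gated reward compares against the reliability level ρ.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold

from .chem import (
    DEFAULT_NBITS,
    DEFAULT_RADIUS,
    Fingerprint,
    Molecule,
    ReferenceSet,
    max_tanimoto,
    morgan_fingerprint,
)


class EmptyDatasetError(ValueError):
    pass


class TooFewRecordsError(ValueError):
    pass


@dataclass
class PropertyDataset:
    """Training data for one property: molecules with measured values."""

    records: list[tuple[Molecule, float]]
    property_name: str = "property"
    units: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def molecules(self) -> list[Molecule]:
        return [m for m, _ in self.records]

    @property
    def values(self) -> np.ndarray:
        return np.asarray([v for _, v in self.records], dtype=float)


def fingerprint_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Dense 0/1 feature matrix for a list of fingerprints."""
    if not fps:
        return np.zeros((0, DEFAULT_NBITS))
    X = np.zeros((len(fps), fps[0].nbits), dtype=np.float32)
    for i, fp in enumerate(fps):
        X[i, sorted(fp.bits)] = 1.0
    return X


@dataclass
class PropertyModel:
    """A fitted regressor plus the AD reference set of its training data.

    ``predict_fn`` maps a :class:`Fingerprint` to a property value; the
    implementation is pluggable (gradient boosting by default, or a
    deterministic oracle for synthetic benchmarks).  Predictions and
    reliabilities are memoized per fingerprint, which makes repeated
    evaluation of a fixed candidate pool at different reliability levels
    cheap.
    """

    predict_fn: Callable[[Fingerprint], float]
    ad_refs: ReferenceSet
    property_name: str = "property"
    units: str = ""
    radius: int = DEFAULT_RADIUS
    nbits: int = DEFAULT_NBITS
    seed: int | None = None
    _pred_cache: dict = field(default_factory=dict, repr=False)
    _rel_cache: dict = field(default_factory=dict, repr=False)

    def _fingerprint(self, mol: Molecule | Fingerprint) -> Fingerprint:
        if isinstance(mol, Fingerprint):
            return mol
        return morgan_fingerprint(mol, radius=self.radius, nbits=self.nbits)

    def predict(self, mol: Molecule | Fingerprint) -> float:
        fp = self._fingerprint(mol)
        if fp.bits not in self._pred_cache:
            self._pred_cache[fp.bits] = float(self.predict_fn(fp))
        return self._pred_cache[fp.bits]

    def reliability(self, mol: Molecule | Fingerprint) -> float:
        """MTS between the molecule and the training data: s ∈ [0, 1]."""
        fp = self._fingerprint(mol)
        if fp.bits not in self._rel_cache:
            self._rel_cache[fp.bits] = max_tanimoto(fp, self.ad_refs)
        return self._rel_cache[fp.bits]


def predict(model: PropertyModel, mol: Molecule | Fingerprint) -> float:
    return model.predict(mol)


def reliability(model: PropertyModel, mol: Molecule | Fingerprint) -> float:
    return model.reliability(mol)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

_LGBM_DEFAULTS = dict(
    n_estimators=200,
    num_leaves=31,
    learning_rate=0.1,
    min_child_samples=5,
    deterministic=True,
    force_row_wise=True,
    verbose=-1,
    n_jobs=1,
)


def _fit_lightgbm(X: np.ndarray, y: np.ndarray, seed: int):
    import lightgbm as lgb

    reg = lgb.LGBMRegressor(random_state=seed, **_LGBM_DEFAULTS)
    reg.fit(X, y)
    return reg


def train_model(
    data: PropertyDataset,
    seed: int = 0,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
) -> PropertyModel:
    """Fit a gradient-boosting regressor on Morgan fingerprints.

    The returned model carries one training fingerprint per record as its AD
    reference set.  Fitting is reproducible given ``seed``.  A constant-target
    dataset triggers a warning (the model degenerates to that constant).
    """
    if len(data) == 0:
        raise EmptyDatasetError("cannot train on an empty dataset")
    fps = [morgan_fingerprint(m, radius=radius, nbits=nbits) for m in data.molecules]
    y = data.values
    if np.allclose(y, y[0]):
        warnings.warn(
            f"all target values identical for {data.property_name!r}; "
            "model degenerates to a constant",
            stacklevel=2,
        )
        const = float(y[0])
        predict_fn = lambda fp: const  # noqa: E731
    else:
        booster = _fit_lightgbm(fingerprint_matrix(fps), y, seed)
        predict_fn = _BoosterPredictor(booster, nbits)
    refs = ReferenceSet(fingerprints=fps)
    return PropertyModel(
        predict_fn=predict_fn,
        ad_refs=refs,
        property_name=data.property_name,
        units=data.units,
        radius=radius,
        nbits=nbits,
        seed=seed,
    )


class _BoosterPredictor:
    """Fingerprint → value adapter around a fitted LightGBM regressor."""

    def __init__(self, regressor, nbits: int):
        self.regressor = regressor
        self.nbits = nbits

    def __call__(self, fp: Fingerprint) -> float:
        X = np.zeros((1, self.nbits), dtype=np.float32)
        X[0, sorted(fp.bits)] = 1.0
        return float(self.regressor.predict(X)[0])

    def model_string(self) -> str:
        booster = getattr(self.regressor, "booster_", self.regressor)
        return booster.model_to_string()


def cross_validate(
    data: PropertyDataset,
    k: int = 5,
    seed: int = 0,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
) -> dict:
    """k-fold cross-validation of the property regressor (R² and MAE per fold)."""
    if len(data) < k:
        raise TooFewRecordsError(f"need at least k={k} records, got {len(data)}")
    fps = [morgan_fingerprint(m, radius=radius, nbits=nbits) for m in data.molecules]
    X = fingerprint_matrix(fps)
    y = data.values
    folds = []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold_idx, (train_idx, test_idx) in enumerate(kf.split(X)):
        reg = _fit_lightgbm(X[train_idx], y[train_idx], seed)
        pred = reg.predict(X[test_idx])
        folds.append(
            {
                "fold": fold_idx,
                "n_test": len(test_idx),
                "test_indices": test_idx.tolist(),
                "r2": float(r2_score(y[test_idx], pred)),
                "mae": float(mean_absolute_error(y[test_idx], pred)),
            }
        )
    return {
        "folds": folds,
        "mean_r2": float(np.mean([f["r2"] for f in folds])),
        "mean_mae": float(np.mean([f["mae"] for f in folds])),
    }


# ---------------------------------------------------------------------------
# Persistence: text-only model directories
# ---------------------------------------------------------------------------

def save_model(model: PropertyModel, directory: str | Path) -> None:
    """Persist a model as (LightGBM text model, fingerprint CSV, metadata JSON).

    Only LightGBM-backed and constant predictors round-trip; oracle-backed
    benchmark models are in-memory objects.  Fingerprints are stored as
    comma-free, space-separated set-bit indices so ``ad_refs`` survives
    bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "property_name": model.property_name,
        "units": model.units,
        "radius": model.radius,
        "nbits": model.nbits,
        "seed": model.seed,
    }
    if isinstance(model.predict_fn, _BoosterPredictor):
        (directory / "model.lgbm.txt").write_text(model.predict_fn.model_string())
        meta["backend"] = "lightgbm"
    elif getattr(model.predict_fn, "__name__", "") == "<lambda>":
        # constant model: recover the constant from any fingerprint
        meta["backend"] = "constant"
        meta["constant"] = model.predict_fn(Fingerprint(frozenset(), model.nbits, model.radius))
    else:
        raise TypeError("only LightGBM-backed or constant models can be persisted")
    lines = ["id,bits"]
    for ident, fp in zip(model.ad_refs.source_ids, model.ad_refs.fingerprints):
        lines.append(f"{ident},{' '.join(str(b) for b in sorted(fp.bits))}")
    (directory / "ad_refs.csv").write_text("\n".join(lines) + "\n")
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> PropertyModel:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    radius, nbits = meta["radius"], meta["nbits"]
    fps, ids = [], []
    for line in (directory / "ad_refs.csv").read_text().splitlines()[1:]:
        ident, _, bitstr = line.partition(",")
        bits = frozenset(int(b) for b in bitstr.split()) if bitstr.strip() else frozenset()
        fps.append(Fingerprint(bits=bits, nbits=nbits, radius=radius))
        ids.append(ident)
    if meta["backend"] == "lightgbm":
        import lightgbm as lgb

        booster = lgb.Booster(model_str=(directory / "model.lgbm.txt").read_text())
        predict_fn = _BoosterPredictor(booster, nbits)
    else:
        const = float(meta["constant"])
        predict_fn = lambda fp: const  # noqa: E731
    return PropertyModel(
        predict_fn=predict_fn,
        ad_refs=ReferenceSet(fingerprints=fps, source_ids=ids),
        property_name=meta["property_name"],
        units=meta["units"],
        radius=radius,
        nbits=nbits,
        seed=meta.get("seed"),
    )


def dataset_from_csv(path: str | Path, property_name: str = "property", units: str = "") -> PropertyDataset:
    from .chem import read_smiles_csv

    rows = read_smiles_csv(path, smiles_column="smiles", value_column="value")
    return PropertyDataset(
        records=[(mol, val) for _, mol, val in rows],
        property_name=property_name,
        units=units,
    )
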