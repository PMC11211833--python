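"""On-disk contracts: HDF5 feature bags, CSV manifests, prototype files
and model checkpoints.

Bag container: one HDF5 file per slide with datasets ``features``
(n x d1) and ``coords`` (n x 2) and attributes ``bag_id``,
``patch_size`` and ``label`` (omitted when unknown). Coordinates are
0-based, x before y, top-left origin at level 0. Manifests are plain
CSV with columns bag_id, label, split, path (labels 0/1, 1 = positive).
Prototype files hold the L x d1 matrix plus stage-1 provenance; model
checkpoints hold every parameter array, the prototype mode and a schema
version that loaders refuse to ignore. All round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .bags import FeatureBag
from .clustering import PrototypeSet, SimilarityConfig
from .errors import CheckpointError, DataError, DimensionError, FormatError
from .model import ModelConfig, ModelState
from .synthetic import Cohort

__all__ = [
    "write_feature_bag",
    "read_feature_bag",
    "write_manifest",
    "read_manifest",
    "write_cohort",
    "load_cohort",
    "save_prototypes",
    "load_prototypes",
    "save_checkpoint",
    "load_checkpoint",
    "load_config_yaml",
]

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# feature bags
# --------------------------------------------------------------------------

def write_feature_bag(bag: FeatureBag, path) -> Path:
    bag.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features)
        f.create_dataset("coords", data=bag.coords)
        f.attrs["bag_id"] = bag.bag_id
        f.attrs["patch_size"] = bag.patch_size
        if bag.label is not None:
            f.attrs["label"] = int(bag.label)
    return path


def read_feature_bag(path) -> FeatureBag:
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise FormatError(f"cannot open bag file {path}: {e}") from e
    with f:
        for name in ("features", "coords"):
            if name not in f:
                raise FormatError(f"{name}: dataset missing in {path}")
        features = f["features"][...]
        coords = f["coords"][...]
        bag_id = str(f.attrs.get("bag_id", path.stem))
        patch_size = int(f.attrs.get("patch_size", 256))
        label = int(f.attrs["label"]) if "label" in f.attrs else None
    try:
        return FeatureBag(bag_id=bag_id, features=features, coords=coords,
                          label=label, patch_size=patch_size)
    except DataError as e:
        raise FormatError(str(e)) from e


# --------------------------------------------------------------------------
# manifests / cohorts
# --------------------------------------------------------------------------

MANIFEST_COLUMNS = ["bag_id", "label", "split", "path"]


def write_manifest(manifest: pd.DataFrame, path) -> Path:
    path = Path(path)
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"bag_id": str, "split": str, "path": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    if df["bag_id"].duplicated().any():
        raise FormatError("bag_id: duplicate identifiers in manifest")
    return df


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write every bag as HDF5 plus manifest.csv; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for bag in cohort.bags:
        p = out_dir / f"{bag.bag_id}.h5"
        write_feature_bag(bag, p)
        paths.append(p.name)
    manifest = cohort.manifest.copy()
    manifest["path"] = paths
    return write_manifest(manifest, out_dir / "manifest.csv")


def load_cohort(manifest_path) -> Cohort:
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent
    bags = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = root / p
        if not p.exists():
            raise FormatError(f"path: bag file not found: {p}")
        bags.append(read_feature_bag(p))
    return Cohort(bags=bags, manifest=manifest)


# --------------------------------------------------------------------------
# prototypes
# --------------------------------------------------------------------------

def save_prototypes(protos: PrototypeSet, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("prototypes", data=protos.embeddings)
        g = f.create_group("provenance")
        g.create_dataset("stage1_counts", data=np.asarray(protos.stage1_counts, dtype=np.int64))
        g.create_dataset(
            "bag_ids", data=np.array(protos.bag_ids, dtype=h5py.string_dtype())
        )
        g.attrs["sim_config"] = json.dumps(
            {
                "beta": protos.sim_config.beta,
                "damping": protos.sim_config.damping,
                "max_iter": protos.sim_config.max_iter,
                "convergence_iter": protos.sim_config.convergence_iter,
                "preference": protos.sim_config.preference,
                "jitter": protos.sim_config.jitter,
                "max_bag_instances": protos.sim_config.max_bag_instances,
            }
        )
    return path


def load_prototypes(path, expected_d1: int | None = None) -> PrototypeSet:
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise FormatError(f"cannot open prototype file {path}: {e}") from e
    with f:
        if "prototypes" not in f:
            raise FormatError("prototypes: dataset missing")
        emb = f["prototypes"][...]
        counts = list(f["provenance/stage1_counts"][...])
        bag_ids = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["provenance/bag_ids"][...]]
        cfg = SimilarityConfig(**json.loads(f["provenance"].attrs["sim_config"]))
    if expected_d1 is not None and emb.shape[1] != expected_d1:
        raise DimensionError(
            f"prototype width {emb.shape[1]} does not match expected d1={expected_d1}"
        )
    return PrototypeSet(embeddings=emb, stage1_counts=[int(c) for c in counts],
                        bag_ids=bag_ids, sim_config=cfg)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(state: ModelState, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config"] = yaml.safe_dump(dict(state.config.__dict__))
        f.attrs["prototype_mode"] = state.config.prototype_mode
        f.attrs["prototype_learnable"] = state.prototype_learnable
        g = f.create_group("params")
        for k, v in state.params.items():
            g.create_dataset(k, data=v.data)
        if state.prototypes is not None:
            f.create_dataset("prototypes", data=state.prototypes.data)
    return path


def load_checkpoint(path) -> ModelState:
    from .autograd import Tensor

    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise CheckpointError(f"cannot open checkpoint {path}: {e}") from e
    with f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise CheckpointError(
                f"unknown checkpoint schema version {version} (expected {SCHEMA_VERSION})"
            )
        try:
            cfg = ModelConfig(**yaml.safe_load(f.attrs["config"]))
            params = {k: Tensor(f["params"][k][...], requires_grad=True)
                      for k in f["params"]}
            learnable = bool(f.attrs.get("prototype_learnable", False))
            protos = None
            if "prototypes" in f:
                protos = Tensor(f["prototypes"][...], requires_grad=learnable)
        except (KeyError, OSError) as e:
            raise CheckpointError(f"malformed checkpoint {path}: {e}") from e
    return ModelState(params=params, prototypes=protos, config=cfg,
                      prototype_learnable=learnable)


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config: YAML must define a mapping")
    return cfg
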