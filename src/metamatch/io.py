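"""On-disk containers: dataset directories and HDF5 model files.

A dataset lives in a directory with two files:

* ``fc.h5`` — one P x P symmetric FC matrix per participant under
  ``/fc/<participant_id>``, plus the participant order, the train/validation
  split, and container attributes (edge order convention, size class,
  version);
* ``phenotypes.csv`` — a ``participant_id`` column plus one column per
  phenotype; an empty cell means missing.

``read_dataset`` aligns the two by participant id (CSV row order on disk is
irrelevant) and returns a :class:`~metamatch.data.SourceDataset` whose
features are the normalized lower-triangle vectors; the raw vectors are kept
on the ``raw_features`` attribute.

Trained models serialize to a single HDF5 file with a ``type`` and
``version`` attribute; round-trips preserve predictions bit-identically.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .data import PhenotypeTable, SourceDataset
from .exceptions import FileFormatError, ValidationError
from .features import devectorize, normalize_features, vectorize_lower_triangle
from .learners import KRRModel, LRRModel
from .mlp import MLPModel
from .stacking import AdaptedModel, BaseLearnerBundle, MultilayerModel, StackingModel

__all__ = ["write_dataset", "read_dataset", "save_model", "load_model",
           "write_importance_csv"]

CONTAINER_VERSION = "1"
EDGE_ORDER = "strict-lower-triangle, row-major over rows i>j"

_STR = h5py.string_dtype(encoding="utf-8")


def _write_strs(group: h5py.Group, name: str, values: list[str]) -> None:
    group.create_dataset(name, data=np.array(values, dtype=object), dtype=_STR)


def _read_strs(group: h5py.Group, name: str) -> list[str]:
    raw = group[name][()]
    return [v.decode("utf-8") if isinstance(v, bytes) else str(v) for v in raw]


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


def write_dataset(dataset: SourceDataset, path: str) -> None:
    """Write a dataset directory (``fc.h5`` + ``phenotypes.csv``)."""
    os.makedirs(path, exist_ok=True)
    raw = getattr(dataset, "raw_features", dataset.features)
    ids = dataset.phenotypes.participant_ids
    with h5py.File(os.path.join(path, "fc.h5"), "w") as f:
        f.attrs["version"] = CONTAINER_VERSION
        f.attrs["edge_order"] = EDGE_ORDER
        f.attrs["size_class"] = dataset.size_class
        f.attrs["name"] = dataset.name
        _write_strs(f, "participant_order", ids)
        if dataset.train_idx is not None:
            f.create_dataset("train_idx", data=np.asarray(dataset.train_idx))
            f.create_dataset("val_idx", data=np.asarray(dataset.val_idx))
        grp = f.create_group("fc")
        for pid, vec in zip(ids, raw):
            grp.create_dataset(pid, data=devectorize(vec))
    dataset.phenotypes.to_frame().to_csv(
        os.path.join(path, "phenotypes.csv"), index=False
    )


def read_dataset(path: str) -> SourceDataset:
    """Read a dataset directory, aligning FC and phenotypes by participant id."""
    fc_path = os.path.join(path, "fc.h5")
    csv_path = os.path.join(path, "phenotypes.csv")
    for p in (fc_path, csv_path):
        if not os.path.exists(p):
            raise FileFormatError(f"missing container file {p}")
    try:
        with h5py.File(fc_path, "r") as f:
            version = f.attrs.get("version")
            if version != CONTAINER_VERSION:
                raise FileFormatError(
                    f"container version {version!r} != supported {CONTAINER_VERSION!r}"
                )
            ids = _read_strs(f, "participant_order")
            name = str(f.attrs.get("name", os.path.basename(path)))
            size_class = str(f.attrs.get("size_class", "medium"))
            raw = np.stack(
                [vectorize_lower_triangle(f["fc"][pid][()]).values for pid in ids]
            )
            train_idx = f["train_idx"][()] if "train_idx" in f else None
            val_idx = f["val_idx"][()] if "val_idx" in f else None
    except OSError as err:
        raise FileFormatError(f"cannot read {fc_path}: {err}") from err

    # round_trip parsing keeps the CSV <-> float64 mapping bit-exact
    table = PhenotypeTable.from_frame(
        pd.read_csv(csv_path, float_precision="round_trip")
    )
    fc_ids, csv_ids = set(ids), set(table.participant_ids)
    if fc_ids != csv_ids:
        raise ValidationError(
            f"participant id mismatch between fc.h5 and phenotypes.csv: "
            f"{len(fc_ids - csv_ids)} only in fc.h5, "
            f"{len(csv_ids - fc_ids)} only in phenotypes.csv"
        )
    order = {pid: i for i, pid in enumerate(table.participant_ids)}
    perm = np.array([order[pid] for pid in ids])
    table = PhenotypeTable(
        table.values[perm], table.mask[perm], ids, table.phenotype_names
    )
    ds = SourceDataset(
        name, normalize_features(raw), table, size_class=size_class,
        train_idx=train_idx, val_idx=val_idx,
    )
    ds.raw_features = raw
    return ds


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def _write_mlp(g: h5py.Group, m: MLPModel) -> None:
    g.attrs["kind"] = "mlp"
    g.attrs["n_layers"] = len(m.weights)
    g.attrs["dropout_rate"] = m.dropout_rate
    for i, (w, b) in enumerate(zip(m.weights, m.biases)):
        g.create_dataset(f"w{i}", data=w)
        g.create_dataset(f"b{i}", data=b)


def _read_mlp(g: h5py.Group) -> MLPModel:
    n = int(g.attrs["n_layers"])
    return MLPModel(
        [g[f"w{i}"][()] for i in range(n)],
        [g[f"b{i}"][()] for i in range(n)],
        float(g.attrs["dropout_rate"]),
    )


def _write_lrr(g: h5py.Group, m: LRRModel) -> None:
    g.attrs["kind"] = "lrr"
    g.attrs["intercept"] = m.intercept
    g.attrs["lam"] = m.lam
    g.attrs["target_name"] = m.target_name
    g.create_dataset("weights", data=m.weights)


def _read_lrr(g: h5py.Group) -> LRRModel:
    return LRRModel(
        g["weights"][()], float(g.attrs["intercept"]), float(g.attrs["lam"]),
        str(g.attrs["target_name"]),
    )


def _write_krr(g: h5py.Group, m: KRRModel) -> None:
    g.attrs["kind"] = "krr"
    g.attrs["lam"] = m.lam
    g.create_dataset("train_features", data=m.train_features)
    g.create_dataset("y_means", data=m.y_means)
    _write_strs(g, "target_names", m.target_names)
    for j, (s, a) in enumerate(zip(m.supports, m.dual_coefs)):
        g.create_dataset(f"support{j}", data=s)
        g.create_dataset(f"alpha{j}", data=a)


def _read_krr(g: h5py.Group) -> KRRModel:
    names = _read_strs(g, "target_names")
    return KRRModel(
        float(g.attrs["lam"]),
        g["train_features"][()],
        [g[f"support{j}"][()] for j in range(len(names))],
        [g[f"alpha{j}"][()] for j in range(len(names))],
        g["y_means"][()],
        names,
    )


def _write_labels(g: h5py.Group, name: str, labels: list[tuple[str, str, str]]) -> None:
    flat = [part for lab in labels for part in lab]
    _write_strs(g, name, flat)


def _read_labels(g: h5py.Group, name: str) -> list[tuple[str, str, str]]:
    flat = _read_strs(g, name)
    return [tuple(flat[i : i + 3]) for i in range(0, len(flat), 3)]


def _write_stacker(g: h5py.Group, m: StackingModel) -> None:
    g.attrs["kind"] = "stacking"
    g.attrs["target_name"] = m.target_name
    _write_labels(g, "input_labels", m.input_labels)
    _write_krr(g.create_group("krr"), m.krr)


def _read_stacker(g: h5py.Group) -> StackingModel:
    return StackingModel(
        _read_krr(g["krr"]),
        _read_labels(g, "input_labels"),
        str(g.attrs["target_name"]),
    )


def _write_bundle(g: h5py.Group, b: BaseLearnerBundle) -> None:
    g.attrs["kind"] = "bundle"
    g.attrs["dataset_name"] = b.dataset_name
    g.attrs["size_class"] = b.size_class
    _write_strs(g, "phenotype_names", b.phenotype_names)
    g.create_dataset("target_means", data=b.target_means)
    g.create_dataset("target_sds", data=b.target_sds)
    if b.mlp is not None:
        _write_mlp(g.create_group("mlp"), b.mlp)
    lg = g.create_group("lrr")
    for j, m in enumerate(b.lrr):
        _write_lrr(lg.create_group(str(j)), m)


def _read_bundle(g: h5py.Group) -> BaseLearnerBundle:
    names = _read_strs(g, "phenotype_names")
    return BaseLearnerBundle(
        str(g.attrs["dataset_name"]),
        str(g.attrs["size_class"]),
        names,
        _read_mlp(g["mlp"]) if "mlp" in g else None,
        [_read_lrr(g["lrr"][str(j)]) for j in range(len(names))],
        g["target_means"][()],
        g["target_sds"][()],
    )


def _write_multilayer(g: h5py.Group, m: MultilayerModel) -> None:
    g.attrs["kind"] = "multilayer"
    bg = g.create_group("bundles")
    for i, b in enumerate(m.bundles):
        _write_bundle(bg.create_group(str(i)), b)
    bg.attrs["n"] = len(m.bundles)
    sg = g.create_group("stackers")
    for name, stackers in m.stackers.items():
        dg = sg.create_group(name)
        dg.attrs["n"] = len(stackers)
        for j, s in enumerate(stackers):
            _write_stacker(dg.create_group(str(j)), s)


def _read_multilayer(g: h5py.Group) -> MultilayerModel:
    bg = g["bundles"]
    bundles = [_read_bundle(bg[str(i)]) for i in range(int(bg.attrs["n"]))]
    stackers = {}
    for name in g["stackers"]:
        dg = g["stackers"][name]
        stackers[name] = [
            _read_stacker(dg[str(j)]) for j in range(int(dg.attrs["n"]))
        ]
    return MultilayerModel(bundles, stackers)


_MODEL_TYPES = {
    MLPModel: ("mlp", _write_mlp),
    LRRModel: ("lrr", _write_lrr),
    KRRModel: ("krr", _write_krr),
    StackingModel: ("stacking", _write_stacker),
    BaseLearnerBundle: ("bundle", _write_bundle),
    MultilayerModel: ("multilayer", _write_multilayer),
}

_MODEL_READERS = {
    "mlp": _read_mlp,
    "lrr": _read_lrr,
    "krr": _read_krr,
    "stacking": _read_stacker,
    "bundle": _read_bundle,
    "multilayer": _read_multilayer,
}


def save_model(model, path: str) -> None:
    """Serialize any trained model object to one HDF5 file."""
    if isinstance(model, AdaptedModel):
        with h5py.File(path, "w") as f:
            f.attrs["version"] = CONTAINER_VERSION
            f.attrs["edge_order"] = EDGE_ORDER
            f.attrs["type"] = "adapted"
            f.attrs["variant"] = model.variant
            f.attrs["include_xl_lrr"] = model.include_xl_lrr
            _write_multilayer(f.create_group("model"), model.model)
            _write_stacker(f.create_group("stacker"), model.stacker)
        return
    for cls, (kind, writer) in _MODEL_TYPES.items():
        if isinstance(model, cls):
            with h5py.File(path, "w") as f:
                f.attrs["version"] = CONTAINER_VERSION
                f.attrs["edge_order"] = EDGE_ORDER
                f.attrs["type"] = kind
                writer(f, model)
            return
    raise ValidationError(f"cannot serialize object of type {type(model).__name__}")


def load_model(path: str):
    """Load a model written by :func:`save_model`."""
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("version")
            if version != CONTAINER_VERSION:
                raise FileFormatError(
                    f"model version {version!r} != supported {CONTAINER_VERSION!r}"
                )
            kind = str(f.attrs.get("type"))
            if kind == "adapted":
                return AdaptedModel(
                    str(f.attrs["variant"]),
                    _read_multilayer(f["model"]),
                    _read_stacker(f["stacker"]),
                    bool(f.attrs["include_xl_lrr"]),
                )
            if kind not in _MODEL_READERS:
                raise FileFormatError(f"unknown model type {kind!r}")
            return _MODEL_READERS[kind](f)
    except OSError as err:
        raise FileFormatError(f"cannot read model file {path}: {err}") from err


def write_importance_csv(map_values: np.ndarray, path: str) -> None:
    """Importance map as tidy CSV rows (edge_i, edge_j, value), canonical order."""
    from .features import n_parcels

    v = np.asarray(map_values, dtype=float).ravel()
    p = n_parcels(v.size)
    rows, cols = np.tril_indices(p, k=-1)
    pd.DataFrame({"edge_i": rows, "edge_j": cols, "value": v}).to_csv(
        path, index=False
    )
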