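"""Dataset manifests, prediction tables, configs and feature-matrix files.

All tabular artifacts are UTF-8 comma-separated files with a header row; the
manifest carries its generator seed in ``# key: value`` comment lines above
the header. Feature matrices are stored as ``.npz`` arrays with a JSON
sidecar recording slide id, seed and the source patch indices.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MANIFEST_COLUMNS = [
    "wsi_id", "position_row", "position_col",
    "path_10x", "path_20x", "path_40x",
    "patho_label", "thymoma_type", "split",
]


def write_manifest(path, rows: list, seed: int | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a manifest; rejects slide-level split leakage."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    leaky = (
        df.groupby("wsi_id")["split"].nunique()
    )
    leaky = leaky[leaky > 1]
    if len(leaky):
        raise ValueError(
            f"slide-level split leakage: WSIs present in multiple splits: "
            f"{sorted(leaky.index.tolist())}")
    return df


def read_manifest_seed(path) -> int | None:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "seed:" in line:
                return int(line.split("seed:")[1].strip())
    return None


def load_patch_arrays(df: pd.DataFrame, root) -> dict:
    """Load the PNG triplets referenced by a manifest into training arrays."""
    from PIL import Image

    root = Path(root)
    out = {"img10": [], "img20": [], "img40": [], "label": []}
    for _, row in df.iterrows():
        for key, col in (("img10", "path_10x"), ("img20", "path_20x"),
                         ("img40", "path_40x")):
            p = root / row[col]
            try:
                arr = np.asarray(Image.open(p), dtype=np.float64) / 255.0
            except OSError as exc:
                raise OSError(f"failed reading patch image {p}: {exc}") from exc
            out[key].append(arr)
        out["label"].append(int(row["patho_label"]))
    return {k: np.asarray(v) for k, v in out.items()}


def write_predictions(path, ids, true_labels, predicted_labels, probs,
                      prefix: str = "prob") -> Path:
    """Predictions CSV: id, true_label, predicted_label, probability columns."""
    probs = np.asarray(probs, dtype=np.float64)
    cols = {f"{prefix}_{k}": probs[:, k] for k in range(probs.shape[1])}
    df = pd.DataFrame({
        "id": ids,
        "true_label": np.asarray(true_labels),
        "predicted_label": np.asarray(predicted_labels),
        **cols,
    })
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["id", "true_label", "predicted_label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"predictions file {path} is missing columns: {missing}")
    prob_cols = [c for c in df.columns if c.startswith("prob_")]
    if prob_cols:
        sums = df[prob_cols].sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-4):
            warnings.warn(
                f"probability columns in {path} do not sum to 1 +- 1e-4",
                stacklevel=2)
    return df


def save_yaml_config(path, obj) -> Path:
    path = Path(path)
    data = obj.to_dict() if hasattr(obj, "to_dict") else dict(obj)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path


def load_yaml_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def save_feature_matrix(path, fm) -> Path:
    """Binary array + JSON sidecar (slide id, seed, source patch indices)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    np.savez(path, data=fm.data)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump({
            "slide_id": fm.slide_id,
            "seed": fm.seed,
            "source_indices": np.asarray(fm.source_indices).tolist(),
        }, fh)
    return path


def load_feature_matrix(path):
    from .wt import FeatureMatrix

    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    with np.load(path) as z:
        data = z["data"]
    sidecar = path.with_suffix(".json")
    meta = {"slide_id": "", "seed": None, "source_indices": []}
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta = json.load(fh)
    return FeatureMatrix(data=data, slide_id=meta["slide_id"],
                         source_indices=np.asarray(meta["source_indices"]),
                         seed=meta["seed"])
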