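"""File formats: annotation CSVs, adjacency CSVs, heatmaps, image loading.

Annotation tables come in two auto-detected dialects:

* long form — ``image_id,labels`` with ``|``-separated label names;
* wide form — ``image_id`` plus one binary 0/1 column per label.

Label order is fixed by first appearance (wide form: column order) and
recorded in every export so matrices align across runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .dame import AnnotationMatrix

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> tuple[AnnotationMatrix, list[str]]:
    """Parse an annotation CSV (either dialect); returns the binary matrix
    and the image ids in file order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an image id column plus labels")
    body = df.iloc[:, 1:]
    is_wide = df.shape[1] > 2 or body.apply(
        lambda col: col.isin(["0", "1"]).all()).all()
    ids = df.iloc[:, 0].tolist()
    if is_wide:
        labels = list(body.columns)
        values = body.astype(int).to_numpy()
    else:
        labels: list[str] = []
        rows = []
        for cell in body.iloc[:, 0]:
            active = [t for t in cell.split("|") if t]
            for name in active:
                if name not in labels:
                    labels.append(name)
            rows.append(active)
        values = np.zeros((len(rows), len(labels)), dtype=np.int64)
        index = {name: j for j, name in enumerate(labels)}
        for i, active in enumerate(rows):
            for name in active:
                values[i, index[name]] = 1
    return AnnotationMatrix(values=values, label_order=labels), ids


def write_annotations(annotations: AnnotationMatrix, ids: list[str],
                      path: str | Path) -> None:
    lines = ["image_id,labels"]
    for image_id, row in zip(ids, annotations.values):
        active = [annotations.label_order[j] for j in np.flatnonzero(row)]
        lines.append(f"{image_id},{'|'.join(active)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix_csv(matrix: np.ndarray, labels: list[str],
                     path: str | Path) -> None:
    """C x C matrix as CSV with a header row and column of label names."""
    pd.DataFrame(np.asarray(matrix), index=labels, columns=labels).to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), list(df.columns)


def write_heatmap(matrix: np.ndarray, labels: list[str], path: str | Path,
                  title: str = "") -> None:
    """Adjacency heatmap PNG (darker = stronger association)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(labels) * 0.45),) * 2)
    im = ax.imshow(np.asarray(matrix), cmap="Blues")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def load_image(path: str | Path, size: int, normalize: bool = False
               ) -> np.ndarray:
    """Read a PNG/JPEG, resize to ``size`` x ``size``, return (3, H, W) in
    [0, 1]; optional ImageNet channel normalization."""
    with Image.open(path) as img:
        img = img.convert("RGB").resize((size, size), Image.BILINEAR)
        arr = np.asarray(img, dtype=np.float64) / 255.0
    arr = arr.transpose(2, 0, 1)
    if normalize:
        arr = (arr - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]
    return arr


def load_dataset(data_dir: str | Path, size: int, normalize: bool = False
                 ) -> tuple[np.ndarray, AnnotationMatrix, list[str]]:
    """Load ``images/`` + ``labels.csv`` as produced by the synth generator."""
    data_dir = Path(data_dir)
    csv_path = data_dir / "labels.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"no labels.csv under {data_dir}")
    annotations, ids = read_annotations(csv_path)
    img_dir = data_dir / "images"
    images = []
    for image_id in ids:
        candidates = [img_dir / f"{image_id}{ext}"
                      for ext in (".png", ".jpg", ".jpeg")]
        found = next((c for c in candidates if c.exists()), None)
        if found is None:
            raise FileNotFoundError(f"image {image_id} not found in {img_dir}")
        images.append(load_image(found, size, normalize))
    return np.stack(images), annotations, ids
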