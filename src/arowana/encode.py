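"""Image encoding of SNP matrices for the convolutional network.

A haplotype (or diploid genotype) matrix is turned into a fixed-shape
float tensor: rows are sorted lexicographically within each deme block to
remove arbitrary sample ordering, columns beyond the data width are
zero-padded (or randomly subsampled down when the data are wider), and
values are scaled into [0, 1].  Diploid data use the half-step code
{0, 0.5, 1}; missing genotypes are imputed to a fixed code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simulate import HaplotypeDataset

__all__ = ["EncoderConfig", "ImageTensor", "matrix_to_image", "make_training_tensors"]


@dataclass(frozen=True)
class EncoderConfig:
    rows_fixed: int = 26
    cols_fixed: int = 1661
    sort_scope: str = "within-deme"      # or "global"
    ploidy_mode: str = "haploid"         # or "diploid-collapsed"
    missing_value: float = 0.5
    position_channel: bool = False
    subsample_seed: int = 0              # used only when truncating wide matrices

    def __post_init__(self) -> None:
        if self.rows_fixed < 2:
            raise ValueError("rows_fixed must be >= 2")
        if self.cols_fixed < 1:
            raise ValueError("cols_fixed must be >= 1")
        if self.sort_scope not in ("within-deme", "global"):
            raise ValueError(f"unknown sort_scope {self.sort_scope!r}")
        if self.ploidy_mode not in ("haploid", "diploid-collapsed"):
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")


@dataclass
class ImageTensor:
    """Fixed-shape network input with its target and scaling record."""

    values: np.ndarray                   # (rows_fixed, cols_fixed, channels)
    label: int | np.ndarray | None = None
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("values must be (rows, cols, channels)")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("tensor values must lie in [0, 1]")


def _lex_sort_rows(block: np.ndarray) -> np.ndarray:
    if block.shape[0] <= 1:
        return block
    # np.lexsort sorts by last key first; feed columns reversed for
    # left-to-right lexicographic order
    order = np.lexsort(block.T[::-1])
    return block[order]


def matrix_to_image(
    dataset: HaplotypeDataset | np.ndarray,
    config: EncoderConfig,
    *,
    deme_labels: np.ndarray | None = None,
    label: int | np.ndarray | None = None,
) -> ImageTensor:
    """Encode one dataset as a fixed-shape image tensor.

    Accepts a :class:`HaplotypeDataset` or a raw numeric matrix (rows =
    samples) with explicit ``deme_labels``; NaN entries are treated as
    missing.  Deme-1 rows form the top block, deme-2 rows the bottom one;
    each block is sorted lexicographically (unless ``sort_scope='global'``).
    """
    if isinstance(dataset, HaplotypeDataset):
        matrix = dataset.matrix.astype(np.float64)
        labels = dataset.deme_labels
    else:
        matrix = np.asarray(dataset, dtype=np.float64)
        if deme_labels is None:
            raise ValueError("deme_labels required for a raw matrix")
        labels = np.asarray(deme_labels)
    if matrix.size == 0:
        raise ValueError("empty matrix cannot be encoded")

    if config.ploidy_mode == "diploid-collapsed":
        if matrix.shape[0] % 2:
            raise ValueError("diploid-collapsed mode needs an even haplotype count")
        matrix = (matrix[0::2] + matrix[1::2]) / 2.0
        labels = labels[0::2]

    scale = 2.0 if np.nanmax(matrix) > 1.0 else 1.0  # 0/1/2 genotypes -> [0,1]
    matrix = matrix / scale
    matrix = np.where(np.isnan(matrix), config.missing_value, matrix)

    if matrix.shape[0] > config.rows_fixed:
        raise ValueError(
            f"{matrix.shape[0]} rows exceed rows_fixed={config.rows_fixed}"
        )

    n_cols = matrix.shape[1]
    if n_cols > config.cols_fixed:
        rng = np.random.default_rng(config.subsample_seed)
        keep = np.sort(rng.choice(n_cols, size=config.cols_fixed, replace=False))
        matrix = matrix[:, keep]
        n_cols = config.cols_fixed

    if config.sort_scope == "global":
        matrix = _lex_sort_rows(matrix)
    else:
        blocks = [_lex_sort_rows(matrix[labels == d]) for d in (0, 1)]
        matrix = np.concatenate([b for b in blocks if b.size], axis=0)

    out = np.zeros((config.rows_fixed, config.cols_fixed), dtype=np.float32)
    out[: matrix.shape[0], :n_cols] = matrix
    channels = [out]
    if config.position_channel:
        pos = np.zeros(config.cols_fixed, dtype=np.float32)
        if isinstance(dataset, HaplotypeDataset) and dataset.positions.size:
            pos[: min(n_cols, dataset.positions.size)] = dataset.positions[:n_cols]
        channels.append(np.broadcast_to(pos, out.shape).copy())
    values = np.stack(channels, axis=-1)
    return ImageTensor(values=values, label=label, normalization={"scale": scale})


def make_training_tensors(
    datasets: Sequence[tuple[HaplotypeDataset, int]],
    config: EncoderConfig,
    train_n: int,
    test_n: int,
    rng_seed: int,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Encode labeled datasets and split them class-balanced.

    ``train_n``/``test_n`` are per-class counts.  Returns
    ``((X_train, y_train), (X_test, y_test))`` with X of shape
    (n, rows, cols, channels); the split is stratified, disjoint and
    shuffled deterministically by ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    by_class: dict[int, list[np.ndarray]] = {}
    for ds, lab in datasets:
        by_class.setdefault(int(lab), []).append(matrix_to_image(ds, config).values)
    for lab, items in sorted(by_class.items()):
        if len(items) < train_n + test_n:
            raise ValueError(
                f"class {lab} has {len(items)} datasets; "
                f"{train_n}+{test_n} per class required"
            )
    train_X, train_y, test_X, test_y = [], [], [], []
    for lab in sorted(by_class):
        items = by_class[lab]
        order = rng.permutation(len(items))
        for i in order[:train_n]:
            train_X.append(items[i]); train_y.append(lab)
        for i in order[train_n: train_n + test_n]:
            test_X.append(items[i]); test_y.append(lab)
    tr_order = rng.permutation(len(train_X))
    te_order = rng.permutation(len(test_X))
    X_train = np.stack(train_X)[tr_order]
    y_train = np.asarray(train_y)[tr_order]
    X_test = np.stack(test_X)[te_order]
    y_test = np.asarray(test_y)[te_order]
    return (X_train, y_train), (X_test, y_test)
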