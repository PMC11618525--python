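"""Training-set separability audit: pHash fingerprints + Kohonen map.

A perceptual hash collapses each image to 32x32 pixels and thresholds at
the median, yielding a 1024-bit fingerprint.  A self-organizing map trained
on these fingerprints projects them onto a 2-D cell grid; if the labeled
classes occupy distinct connected regions of the map, the training set is
separable enough to feed the classifier.  This is a necessary condition,
not a sufficient one — a clean map does not guarantee classifier quality.

The hash is the median-threshold variant (the 32x32 reduction itself is the
code), not the DCT perceptual hash, so fingerprints are comparable only
within this package.  Median ties resolve upward: a pixel equal to the
median maps to 1, hence a constant image hashes to all ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as sk_resize

from .image_io import ImageFrame

__all__ = ["PHashCode", "KohonenSOM", "SOMReport", "phash", "audit"]

PHASH_SIDE = 32
PHASH_BITS = PHASH_SIDE * PHASH_SIDE  # 1024


@dataclass(frozen=True)
class PHashCode:
    """1024-bit binary fingerprint of one image (row-major bit order)."""

    bits: str
    source_label: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.bits) != PHASH_BITS or set(self.bits) - {"0", "1"}:
            raise ValueError(f"bits must be a {PHASH_BITS}-char binary string")

    def to_vector(self) -> np.ndarray:
        return np.frombuffer(self.bits.encode(), dtype=np.uint8).astype(np.float64) - ord("0")

    def hamming(self, other: "PHashCode") -> int:
        return sum(a != b for a, b in zip(self.bits, other.bits))


def phash(frame: ImageFrame, label: Optional[str] = None) -> PHashCode:
    """Median-threshold perceptual hash of a frame.

    Bilinear collapse to 32x32, threshold each pixel at the reduced image's
    median (>= median -> 1).  Deterministic; invariant to any global affine
    intensity change that preserves the ordering around the median.
    """
    if frame.pixels.size == 0:
        raise ValueError("cannot hash an empty frame")
    small = sk_resize(
        frame.pixels,
        (PHASH_SIDE, PHASH_SIDE),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    median = np.median(small)
    bits = (small >= median).astype(np.uint8).ravel()
    return PHashCode(bits="".join("1" if b else "0" for b in bits), source_label=label)


# ---------------------------------------------------------------------------
# Self-organizing map
# ---------------------------------------------------------------------------


class KohonenSOM:
    """Plain Kohonen self-organizing map on unit-hypercube vectors.

    Online training: per epoch the samples are visited in a seeded random
    order; the best-matching unit (BMU, Euclidean) and its Gaussian
    neighborhood move toward the sample.  Learning rate and neighborhood
    radius both decay exponentially over epochs from their initial values
    (defaults: rate 0.5, radius = half the grid).  Bit-for-bit reproducible
    for a fixed (data, grid, epochs, seed).
    """

    def __init__(
        self,
        grid_rows: int = 10,
        grid_cols: int = 10,
        dim: int = PHASH_BITS,
        learning_rate: float = 0.5,
        radius: Optional[float] = None,
        seed: int = 0,
    ) -> None:
        if grid_rows < 2 or grid_cols < 2:
            raise ValueError("SOM grid must be at least 2x2")
        self.grid_rows = grid_rows
        self.grid_cols = grid_cols
        self.dim = dim
        self.learning_rate = learning_rate
        self.radius = radius if radius is not None else max(grid_rows, grid_cols) / 2.0
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._w = rng.uniform(0.0, 1.0, size=(grid_rows * grid_cols, dim))
        rr, cc = np.meshgrid(
            np.arange(grid_rows), np.arange(grid_cols), indexing="ij"
        )
        self._cell_r = rr.ravel().astype(float)
        self._cell_c = cc.ravel().astype(float)
        self._rng = rng

    @property
    def weights(self) -> np.ndarray:
        """Codebook as a (grid_rows, grid_cols, dim) view."""
        return self._w.reshape(self.grid_rows, self.grid_cols, self.dim)

    def bmu(self, x: np.ndarray) -> tuple[int, int]:
        idx = int(np.argmin((self._w**2).sum(axis=1) - 2.0 * (self._w @ x)))
        return divmod(idx, self.grid_cols)

    def train(self, data: np.ndarray, epochs: int = 500) -> "KohonenSOM":
        data32 = np.asarray(data, dtype=np.float32)
        if data32.ndim != 2 or data32.shape[1] != self.dim:
            raise ValueError(f"data must be (n, {self.dim})")
        n = data32.shape[0]
        # radius decays to ~1 cell by the final epoch
        time_const = epochs / max(np.log(self.radius), 1e-9)
        w = self._w.astype(np.float32)
        outer = np.empty_like(w)
        sqnorms = (w.astype(np.float64) ** 2).sum(axis=1).astype(np.float32)
        xsq = (data32**2).sum(axis=1)
        # squared pairwise cell distances on the grid, (cells, cells)
        cell_d2 = (
            (self._cell_r[:, None] - self._cell_r[None, :]) ** 2
            + (self._cell_c[:, None] - self._cell_c[None, :]) ** 2
        ).astype(np.float32)
        for epoch in range(epochs):
            lr = self.learning_rate * np.exp(-epoch / epochs)
            rad = max(self.radius * np.exp(-epoch / time_const), 0.5)
            h_by_bmu = (lr * np.exp(-cell_d2 / (2.0 * rad * rad))).astype(np.float32)
            om_by_bmu = 1.0 - h_by_bmu
            for i in self._rng.permutation(n):
                x = data32[i]
                wx = w @ x
                bmu_idx = int(np.argmin(sqnorms - 2.0 * wx))
                h = h_by_bmu[bmu_idx]
                om = om_by_bmu[bmu_idx]
                # w' = (1-h) w + h x, with |w'|^2 updated in closed form
                w *= om[:, None]
                np.multiply(h[:, None], x[None, :], out=outer)
                w += outer
                sqnorms = om * om * sqnorms + 2.0 * h * om * wx + h * h * xsq[i]
        self._w = w.astype(np.float64)
        return self

    def u_matrix(self) -> np.ndarray:
        """Mean distance of each cell's codebook vector to its 4-neighbors."""
        w = self.weights
        out = np.zeros((self.grid_rows, self.grid_cols))
        counts = np.zeros_like(out)
        for dr, dc in ((0, 1), (1, 0)):
            a = w[: self.grid_rows - dr, : self.grid_cols - dc]
            b = w[dr:, dc:]
            d = np.sqrt(((a - b) ** 2).sum(axis=2))
            out[: self.grid_rows - dr, : self.grid_cols - dc] += d
            out[dr:, dc:] += d
            counts[: self.grid_rows - dr, : self.grid_cols - dc] += 1
            counts[dr:, dc:] += 1
        return out / counts


# ---------------------------------------------------------------------------
# Audit
# ---------------------------------------------------------------------------


@dataclass
class SOMReport:
    """Outcome of the separability audit.

    ``n_clusters`` counts 4-connected regions of same-majority-label cells
    after unmapped cells inherit the label of the nearest sample in
    codebook space (sparse mappings would otherwise fragment the regions);
    a separable K-class set should show exactly K such regions.  ``purity``
    is the fraction of images whose BMU-cell majority matches their own
    label.  ``separable`` flags purity >= 0.75 together with one region per
    label — the documented pass rule of this audit.
    """

    grid_rows: int
    grid_cols: int
    bmu_map: list[tuple[int, int]]
    n_clusters: int
    purity: float
    separable: bool
    majority_labels: list[list[Optional[str]]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "grid": [self.grid_rows, self.grid_cols],
            "n_clusters": self.n_clusters,
            "purity": self.purity,
            "separable": self.separable,
        }


PURITY_PASS = 0.75


def audit(
    codes: Sequence[PHashCode],
    grid: tuple[int, int] = (10, 10),
    epochs: int = 500,
    seed: int = 0,
) -> SOMReport:
    """Train a SOM on labeled fingerprints and test class separability.

    Requires at least 10 codes spanning at least 2 labels.  Cells with no
    mapped image carry no majority; ties within a cell resolve to the
    lexicographically smallest label (deterministic).
    """
    labels = [c.source_label for c in codes]
    if any(lbl is None for lbl in labels):
        raise ValueError("every code must carry a source_label")
    distinct = sorted(set(labels))
    if len(distinct) < 2:
        raise ValueError("separability is undefined for a single label")
    if len(codes) < 10:
        raise ValueError("need at least 10 codes to audit")

    data = np.stack([c.to_vector() for c in codes])
    som = KohonenSOM(grid[0], grid[1], dim=data.shape[1], seed=seed)
    som.train(data, epochs=epochs)
    bmus = [som.bmu(x) for x in data]

    counts: dict[tuple[int, int], dict[str, int]] = {}
    for (r, c), lbl in zip(bmus, labels):
        counts.setdefault((r, c), {}).setdefault(lbl, 0)
        counts[(r, c)][lbl] += 1

    majority: list[list[Optional[str]]] = [
        [None] * grid[1] for _ in range(grid[0])
    ]
    for (r, c), tally in counts.items():
        best = max(tally.values())
        majority[r][c] = min(lbl for lbl, n in tally.items() if n == best)

    hits = sum(1 for (r, c), lbl in zip(bmus, labels) if majority[r][c] == lbl)
    purity = hits / len(codes)

    # cells no image mapped to get the label of the nearest sample in
    # codebook space, so sparse mappings do not fragment the regions
    full = [row[:] for row in majority]
    for r in range(grid[0]):
        for c in range(grid[1]):
            if full[r][c] is None:
                d2 = ((data - som.weights[r, c]) ** 2).sum(axis=1)
                full[r][c] = labels[int(np.argmin(d2))]

    n_clusters = 0
    for lbl in distinct:
        binary = np.array(
            [[1 if full[r][c] == lbl else 0 for c in range(grid[1])] for r in range(grid[0])]
        )
        _, n_regions = ndimage.label(binary)  # 4-connectivity default
        n_clusters += int(n_regions)

    separable = purity >= PURITY_PASS and n_clusters == len(distinct)
    return SOMReport(
        grid_rows=grid[0],
        grid_cols=grid[1],
        bmu_map=bmus,
        n_clusters=n_clusters,
        purity=purity,
        separable=separable,
        majority_labels=majority,
    )
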