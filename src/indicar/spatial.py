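"""Areal neighbourhood structures and the Leroux CAR precision family.

A spatial random effect ``b = (b_1, ..., b_M)`` over ``M`` regions is modelled
as multivariate normal with mean zero and precision matrix

.. math::

    D^{-} = \\sigma^{-2}\\{(1 - \\lambda) I + \\lambda R\\},

where ``R`` is the intrinsic autoregression matrix (the graph Laplacian of the
region adjacency graph): ``R[j, j] = m_j``, the number of neighbours of region
``j``, and ``R[j, j'] = -1`` exactly when ``j`` and ``j'`` are neighbours.

The mixing weight ``lambda`` interpolates between independent random effects
(``lambda = 0``) and the intrinsic autoregression (``lambda = 1``).  Because
``R`` is singular (its rows sum to zero), the covariance ``D = (D^-)^{-1}``
only exists for ``lambda < 1``; estimation therefore restricts ``lambda`` to
``[0, 1 - 1e-6]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import AdjacencyError, SingularityError

#: Largest admissible spatial-dependence parameter: keeps the precision
#: matrix invertible so that the covariance D exists.
LAMBDA_MAX = 1.0 - 1e-6


@dataclass(frozen=True)
class LerouxParams:
    """Random-effect parameters ``theta = (sigma2, lam)``.

    Parameters
    ----------
    sigma2
        Overdispersion parameter ``sigma^2 > 0``: the marginal variance scale
        of the spatial random effect.
    lam
        Spatial dependence parameter ``lambda`` in ``[0, 1]``.  Values of 1
        are representable (intrinsic autoregression) but the covariance is
        only defined for ``lam < 1``.
    """

    sigma2: float
    lam: float

    def __post_init__(self):
        if not np.isfinite(self.sigma2) or self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2!r}")
        if not np.isfinite(self.lam) or not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must lie in [0, 1], got {self.lam!r}")

    @property
    def sigma(self) -> float:
        """Standard-deviation scale ``sigma = sqrt(sigma2)``."""
        return float(np.sqrt(self.sigma2))


@dataclass
class AdjacencyStructure:
    """Symmetric neighbour relation over ``M`` regions.

    ``neighbours[j]`` is a sorted integer array with the (0-based) indices of
    the neighbours of region ``j``; ``region_labels`` fixes the canonical
    region ordering used by every matrix and table in the package.
    """

    neighbours: list
    region_labels: list

    def __post_init__(self):
        m = len(self.region_labels)
        if len(self.neighbours) != m:
            raise AdjacencyError(
                f"{len(self.neighbours)} neighbour lists for {m} region labels"
            )
        if len(set(self.region_labels)) != m:
            raise AdjacencyError("region labels are not unique")
        nb = []
        for j, idx in enumerate(self.neighbours):
            a = np.unique(np.asarray(idx, dtype=np.intp))
            if a.size and (a.min() < 0 or a.max() >= m):
                raise AdjacencyError(f"region {j}: neighbour index out of range")
            if np.any(a == j):
                raise AdjacencyError(f"region {j} lists itself as a neighbour")
            nb.append(a)
        for j, a in enumerate(nb):
            for k in a:
                if j not in nb[k]:
                    raise AdjacencyError(
                        f"asymmetric adjacency: {j} -> {int(k)} has no reverse edge"
                    )
        self.neighbours = nb
        isolated = [self.region_labels[j] for j, a in enumerate(nb) if a.size == 0]
        if isolated:
            warnings.warn(
                f"{len(isolated)} isolated region(s) with no neighbours: "
                f"{isolated[:5]}{'...' if len(isolated) > 5 else ''}",
                stacklevel=2,
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_neighbours(self) -> np.ndarray:
        """Per-region neighbour counts ``m_j``."""
        return np.array([a.size for a in self.neighbours], dtype=np.intp)

    @property
    def label_index(self) -> dict:
        """Mapping from external region label to canonical 0-based position."""
        return {lab: j for j, lab in enumerate(self.region_labels)}

    def edges(self):
        """Iterate over unordered neighbour pairs ``(j, k)`` with ``j < k``."""
        for j, a in enumerate(self.neighbours):
            for k in a:
                if j < k:
                    yield j, int(k)


def lattice_adjacency(rows: int, cols: int) -> AdjacencyStructure:
    """Rook adjacency on a ``rows x cols`` lattice grid.

    Two cells are neighbours when they share a border (not merely a corner),
    so interior cells have 4 neighbours, edge cells 3 and corner cells 2.
    Region labels are ``"r<i>c<j>"`` in row-major order.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {rows}x{cols}")
    labels = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
    neighbours = []
    for i in range(rows):
        for j in range(cols):
            nb = []
            if i > 0:
                nb.append((i - 1) * cols + j)
            if i < rows - 1:
                nb.append((i + 1) * cols + j)
            if j > 0:
                nb.append(i * cols + j - 1)
            if j < cols - 1:
                nb.append(i * cols + j + 1)
            neighbours.append(np.array(sorted(nb), dtype=np.intp))
    with warnings.catch_warnings():
        if rows * cols == 1:  # the 1x1 grid is legitimately isolated
            warnings.simplefilter("ignore")
        return AdjacencyStructure(neighbours=neighbours, region_labels=labels)


def build_structure_matrix(adj: AdjacencyStructure) -> np.ndarray:
    """Intrinsic autoregression matrix ``R`` for an adjacency structure.

    ``R[j, j] = m_j`` and ``R[j, j'] = -1`` iff ``j ~ j'``.  Every row sums to
    zero and ``R`` is symmetric positive semi-definite.
    """
    m = adj.n_regions
    R = np.zeros((m, m))
    for j, a in enumerate(adj.neighbours):
        R[j, j] = a.size
        R[j, a] = -1.0
    return R


def leroux_precision(theta: LerouxParams, R: np.ndarray) -> np.ndarray:
    """Leroux CAR precision ``sigma^-2 {(1 - lambda) I + lambda R}``.

    Positive definite whenever ``theta.lam < 1`` (positive semi-definite at
    the intrinsic limit ``lam = 1``).
    """
    R = np.asarray(R, dtype=float)
    m = R.shape[0]
    return ((1.0 - theta.lam) * np.eye(m) + theta.lam * R) / theta.sigma2


def leroux_covariance(theta: LerouxParams, R: np.ndarray) -> np.ndarray:
    """Covariance ``D = [sigma^-2 {(1 - lambda) I + lambda R}]^{-1}``.

    Raises
    ------
    SingularityError
        If ``theta.lam`` exceeds :data:`LAMBDA_MAX`, in which case the
        precision is (numerically) singular; use ``lam = 1 - eps`` instead.
    """
    if theta.lam > LAMBDA_MAX:
        raise SingularityError(
            f"lam={theta.lam} makes the Leroux precision singular; "
            f"use lam <= {LAMBDA_MAX} (e.g. 1 - 1e-6)"
        )
    P = leroux_precision(theta, R)
    c, low = cho_factor(P, lower=True)
    D = cho_solve((c, low), np.eye(P.shape[0]))
    return 0.5 * (D + D.T)


def write_adjacency(adj: AdjacencyStructure, path) -> None:
    """Write an adjacency structure as an edge-list text file.

    The first non-comment line lists every region label (canonical order),
    so isolated regions survive a round-trip; each following line is one
    undirected edge ``label_a label_b``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# indicar adjacency: first line = region labels, then edges\n")
        fh.write(" ".join(str(lab) for lab in adj.region_labels) + "\n")
        for j, k in adj.edges():
            fh.write(f"{adj.region_labels[j]} {adj.region_labels[k]}\n")


def read_adjacency(path) -> AdjacencyStructure:
    """Read an adjacency structure written by :func:`write_adjacency`.

    Unknown labels in an edge raise :class:`AdjacencyError`; duplicate edges
    are ignored with a warning.
    """
    labels = None
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if labels is None:
                labels = line.split()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise AdjacencyError(
                    f"{path}:{lineno}: expected 'label_a label_b', got {line!r}"
                )
            edges.append((parts[0], parts[1], lineno))
    if labels is None:
        raise AdjacencyError(f"{path}: no header line with region labels")
    index = {lab: j for j, lab in enumerate(labels)}
    seen = set()
    neighbours = [set() for _ in labels]
    for a, b, lineno in edges:
        for lab in (a, b):
            if lab not in index:
                raise AdjacencyError(f"{path}:{lineno}: unknown region label {lab!r}")
        if a == b:
            raise AdjacencyError(f"{path}:{lineno}: self-loop on {a!r}")
        key = (min(a, b), max(a, b))
        if key in seen:
            warnings.warn(f"{path}:{lineno}: duplicate edge {a} {b} ignored", stacklevel=2)
            continue
        seen.add(key)
        neighbours[index[a]].add(index[b])
        neighbours[index[b]].add(index[a])
    return AdjacencyStructure(
        neighbours=[np.array(sorted(s), dtype=np.intp) for s in neighbours],
        region_labels=list(labels),
    )
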