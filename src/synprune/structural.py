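"""Structural plasticity: periodic deletion and creation of synapses.

Connection matrices have rows = source neurons and columns = target
neurons; a zero entry is an absent synapse.  New synapses are always
created in the same column where synapses were deleted, so no target
neuron is ever starved of input.  Four rules of increasing complexity
operate on these matrices, applied once per structural-plasticity
interval (every 50 input examples during training):

``basic``
    Delete every synapse weaker than a threshold ``theta_w``, recreate
    the same number per column at uniformly random free positions.

``bookkeeping``
    Instead of deleting immediately, increment a per-synapse counter
    while the synapse is weak and walk the counter back toward zero
    while it has recovered; delete only when the counter exceeds
    ``theta_c``.  Newly created synapses start at ``-grace`` so they get
    a period of grace before they can accumulate deletions.

``bookkeeping_pruning``
    Like ``bookkeeping``, but a per-column target count decays
    exponentially (factor ``lam`` per application) down to a floor of
    half the initial count, so the network is sparsified over time;
    over-full columns lose their weakest synapses.

``spatial_pruning``
    Like ``bookkeeping_pruning``, but new positions are drawn from a
    probability distribution P = exp(W * G) obtained by convolving the
    connection matrix with a wrapped 2-D Gaussian filter, so new
    synapses cluster near existing strong ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ColumnFullError",
    "ConnectionMatrix",
    "StructuralParams",
    "BookkeepingState",
    "PlacementDistribution",
    "prune_basic",
    "bookkeeping_update",
    "pruning_schedule_step",
    "wrapped_gaussian_profile",
    "spatial_probability",
    "create_synapses",
    "apply_structural_plasticity",
]


class ColumnFullError(RuntimeError):
    """Raised when synapse creation is requested in a column with no free slot."""


@dataclass
class ConnectionMatrix:
    """Weights of one connection, dense with zeros at absent synapses.

    ``mask`` is the authority on which synapses exist (an existing
    synapse may transiently carry weight zero under STDP depression);
    wherever ``mask`` is False, ``w`` is exactly zero.
    """

    w: np.ndarray
    mask: np.ndarray
    w_init_max: float
    w_max: float
    tag: str = ""
    plasticity: str = "static"  # "static" | "P" | "P+S"

    def __post_init__(self) -> None:
        if self.w.shape != self.mask.shape:
            raise ValueError("weight and mask shapes differ")

    @property
    def n_src(self) -> int:
        return self.w.shape[0]

    @property
    def n_tgt(self) -> int:
        return self.w.shape[1]

    def col_counts(self) -> np.ndarray:
        """Number of synapses per target column."""
        return self.mask.sum(axis=0)

    def copy(self) -> "ConnectionMatrix":
        return ConnectionMatrix(
            self.w.copy(), self.mask.copy(), self.w_init_max, self.w_max,
            self.tag, self.plasticity,
        )

    def to_triplets(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Export existing synapses as (row, col, weight) arrays."""
        rows, cols = np.nonzero(self.mask)
        return rows, cols, self.w[rows, cols]

    @classmethod
    def from_triplets(
        cls, shape, rows, cols, weights, w_init_max, w_max, tag="", plasticity="static"
    ) -> "ConnectionMatrix":
        w = np.zeros(shape, dtype=np.float64)
        mask = np.zeros(shape, dtype=bool)
        w[rows, cols] = weights
        mask[rows, cols] = True
        return cls(w, mask, w_init_max, w_max, tag, plasticity)


@dataclass(frozen=True)
class StructuralParams:
    """Thresholds and schedule constants of the structural rules.

    ``theta_w`` separates "weak" from healthy synapses (default 0.1 of
    the connection's w_max, set at network build); ``theta_c`` is the
    deletion count threshold; ``grace`` the number of free evaluations a
    new synapse receives; ``lam`` the per-application decay factor of
    the pruning target; ``floor_frac`` the fraction of the initial count
    the target may not fall below; ``w_new`` the weight of a created
    synapse (defaults to ``theta_w``, just at the deletion threshold, so
    the grace period decides its fate).
    """

    theta_w: float = 0.05
    theta_c: int = 3
    grace: int = 2
    lam: float = 0.98
    floor_frac: float = 0.5
    w_new: float | None = None
    sigma_src: float = 10.0
    sigma_tgt: float = 5.0

    def __post_init__(self) -> None:
        if self.theta_w < 0:
            raise ValueError("theta_w must be non-negative")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must lie in (0, 1]")

    @property
    def new_weight(self) -> float:
        return self.theta_w if self.w_new is None else self.w_new


@dataclass
class BookkeepingState:
    """Counters and pruning target aligned with one ConnectionMatrix.

    ``b`` mirrors the matrix sparsity (values are meaningful only where
    the mask is True).  ``c_float`` is the per-column pruning target
    kept as a float so the effective integer target follows
    round(c0 * lam**k) exactly; ``floor`` is the hard lower bound.
    """

    b: np.ndarray
    c_float: np.ndarray
    floor: int
    params: StructuralParams

    @classmethod
    def for_matrix(cls, cm: ConnectionMatrix, params: StructuralParams) -> "BookkeepingState":
        counts = cm.col_counts()
        floor = max(1, int(round(params.floor_frac * counts.max(initial=1))))
        return cls(
            b=np.zeros(cm.w.shape, dtype=np.int64),
            c_float=counts.astype(np.float64),
            floor=floor,
            params=params,
        )

    @property
    def c_target(self) -> np.ndarray:
        """Effective integer per-column target count."""
        return np.maximum(np.round(self.c_float).astype(np.int64), self.floor)

    def copy(self) -> "BookkeepingState":
        return BookkeepingState(self.b.copy(), self.c_float.copy(), self.floor, self.params)


def prune_basic(
    cm: ConnectionMatrix, theta_w: float, rng=None
) -> tuple[ConnectionMatrix, np.ndarray]:
    """Delete every synapse with weight below ``theta_w``.

    Returns the matrix and the per-column deletion counts.  ``rng`` is
    accepted for interface symmetry with the other rules; deletion
    itself is deterministic.
    """
    if theta_w < 0:
        raise ValueError("theta_w must be non-negative")
    doomed = cm.mask & (cm.w < theta_w)
    deleted = doomed.sum(axis=0)
    cm.mask[doomed] = False
    cm.w[doomed] = 0.0
    return cm, deleted


def bookkeeping_update(
    cm: ConnectionMatrix, bk: BookkeepingState
) -> tuple[BookkeepingState, np.ndarray]:
    """One bookkeeping evaluation: count weak synapses, delete persistent ones.

    Weak synapses (w < theta_w) have their counter incremented; healthy
    ones have it walked back toward zero by one (from either side, so
    grace counters also relax).  Synapses whose counter exceeds
    ``theta_c`` are removed from both matrices.  Returns per-column
    deletion counts.
    """
    if bk.b.shape != cm.w.shape:
        raise ValueError("bookkeeping matrix shape differs from connection matrix")
    weak = cm.mask & (cm.w < bk.params.theta_w)
    healthy = cm.mask & ~weak
    bk.b[weak] += 1
    bk.b[healthy] -= np.sign(bk.b[healthy])
    doomed = cm.mask & (bk.b > bk.params.theta_c)
    deleted = doomed.sum(axis=0)
    cm.mask[doomed] = False
    cm.w[doomed] = 0.0
    bk.b[doomed] = 0
    return bk, deleted


def pruning_schedule_step(bk: BookkeepingState) -> BookkeepingState:
    """Decay the per-column pruning target by one application of ``lam``.

    The float target is clamped at the floor so the effective integer
    target follows max(round(c0 * lam**k), floor).
    """
    np.maximum(bk.c_float * bk.params.lam, bk.floor, out=bk.c_float)
    return bk


def wrapped_gaussian_profile(n: int, sigma: float) -> np.ndarray:
    """Unit-peak Gaussian over circular index distance on ``n`` points."""
    d = np.minimum(np.arange(n), n - np.arange(n)).astype(np.float64)
    return np.exp(-(d**2) / (2.0 * sigma**2))


@dataclass
class PlacementDistribution:
    """Per-column placement probabilities; zero at occupied positions."""

    p: np.ndarray
    full_columns: np.ndarray  # boolean, columns with no free slot


def spatial_probability(
    cm: ConnectionMatrix, sigma_src: float = 10.0, sigma_tgt: float = 5.0
) -> PlacementDistribution:
    """Placement distribution P = exp(W * G) from Gaussian convolution.

    The connection matrix is circularly convolved with a separable
    unit-peak 2-D Gaussian (``sigma_src`` along the source/row axis,
    ``sigma_tgt`` along the target/column axis, wrapped borders to match
    the circular input code) and exponentiated, so contributions of
    nearby synapses multiply.  Occupied positions are zeroed and every
    column rescaled to sum one.  Columns without any free slot are
    flagged in ``full_columns``.
    """
    if cm.w.size == 0:
        raise ValueError("connection matrix is empty")
    a = _circulant(cm.n_src, sigma_src)
    b = _circulant(cm.n_tgt, sigma_tgt)
    conv = a @ cm.w @ b
    p = np.exp(np.minimum(conv, 700.0))
    p[cm.mask] = 0.0
    sums = p.sum(axis=0)
    full = sums == 0.0
    safe = np.where(full, 1.0, sums)
    p /= safe[np.newaxis, :]
    return PlacementDistribution(p=p, full_columns=full)


def _circulant(n: int, sigma: float) -> np.ndarray:
    g = wrapped_gaussian_profile(n, sigma)
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
    return g[idx]


def create_synapses(
    cm: ConnectionMatrix,
    column: int,
    count: int,
    placement: str = "uniform",
    dist: PlacementDistribution | None = None,
    w_new: float = 0.05,
    rng: np.random.Generator | None = None,
    bk: BookkeepingState | None = None,
) -> ConnectionMatrix:
    """Create ``count`` synapses in one column, without replacement.

    Positions are drawn uniformly over the free rows or from the spatial
    placement distribution restricted to the currently free rows.  New
    entries get weight ``w_new``; if a bookkeeping state is given, their
    counters start at ``-grace``.
    """
    if count == 0:
        return cm
    if rng is None:
        rng = np.random.default_rng()
    free = np.flatnonzero(~cm.mask[:, column])
    if count > free.size:
        raise ColumnFullError(
            f"column {column}: {count} synapses requested, {free.size} free slots"
        )
    if placement == "uniform":
        rows = rng.choice(free, size=count, replace=False)
    elif placement == "spatial":
        if dist is None:
            raise ValueError("spatial placement needs a PlacementDistribution")
        p = dist.p[free, column]
        total = p.sum()
        if total <= 0.0:
            rows = rng.choice(free, size=count, replace=False)
        else:
            rows = rng.choice(free, size=count, replace=False, p=p / total)
    else:
        raise ValueError(f"unknown placement: {placement!r}")
    cm.mask[rows, column] = True
    cm.w[rows, column] = w_new
    if bk is not None:
        bk.b[rows, column] = -bk.params.grace
    return cm


_MODES = ("basic", "bookkeeping", "bookkeeping_pruning", "spatial_pruning")


def apply_structural_plasticity(
    cm: ConnectionMatrix,
    bk: BookkeepingState,
    mode: str,
    rng: np.random.Generator,
) -> tuple[ConnectionMatrix, BookkeepingState]:
    """One structural-plasticity application: delete, prune, recreate.

    After the call every column holds min(previous count, pruning
    target) synapses: threshold/bookkeeping deletions are replaced by
    new synapses in the same column, and over-full columns (under a
    decayed pruning target) lose their weakest synapses immediately,
    bypassing the counters.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode: {mode!r} (expected one of {_MODES})")
    params = bk.params
    n_before = cm.col_counts()

    if mode == "basic":
        _, _ = prune_basic(cm, params.theta_w, rng)
        bk.b[~cm.mask] = 0
    else:
        bookkeeping_update(cm, bk)

    if mode in ("bookkeeping_pruning", "spatial_pruning"):
        pruning_schedule_step(bk)
        target = np.minimum(n_before, bk.c_target)
    else:
        target = n_before

    # Pruning: drop the weakest synapses of over-full columns.
    counts = cm.col_counts()
    for col in np.flatnonzero(counts > target):
        excess = counts[col] - target[col]
        rows = np.flatnonzero(cm.mask[:, col])
        weakest = rows[np.argsort(cm.w[rows, col], kind="stable")[:excess]]
        cm.mask[weakest, col] = False
        cm.w[weakest, col] = 0.0
        bk.b[weakest, col] = 0

    # Creation: refill columns up to their target.
    placement = "spatial" if mode == "spatial_pruning" else "uniform"
    dist = None
    counts = cm.col_counts()
    deficit_cols = np.flatnonzero(counts < target)
    if placement == "spatial" and deficit_cols.size:
        dist = spatial_probability(cm, params.sigma_src, params.sigma_tgt)
    for col in deficit_cols:
        missing = int(target[col] - counts[col])
        free = int((~cm.mask[:, col]).sum())
        if free < missing:
            # Column (nearly) full: create what fits, keep going.
            missing = free
        if missing > 0:
            create_synapses(
                cm, col, missing, placement=placement, dist=dist,
                w_new=params.new_weight, rng=rng, bk=bk,
            )
    return cm, bk
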