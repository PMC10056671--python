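"""Anchor-batch construction and the per-cell training mapping.

Three anchor modes are supported:

``balanced``
    Build an intermediate anchor batch: for each cell type shared by at least
    two batches, repeatedly draw one cell of that type from every batch
    containing it (following graph connectivity when a graph is supplied,
    uniformly at random otherwise) and emit the tuple's arithmetic-mean
    expression vector as one anchor profile.  The anchor therefore sits between
    the batches it integrates.

``max_std``
    Use the existing batch whose pooled log-normalized values have the largest
    standard deviation — the batch with the greatest internal variability,
    which tends to cover the most cell states.

``custom``
    Use a batch chosen by the caller.

Cell types that occur in only one batch are never mapped: correcting them
toward an anchor would push them into a region of expression space with no
biological support, so they pass through correction unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import AnnotatedMatrix
from .preprocess import ConnectivityGraph


@dataclass
class AnchorSet:
    """Anchor expression profiles plus bookkeeping about how they were built."""

    anchor_profiles: np.ndarray       # anchor cells x genes, >= 0
    anchor_types: np.ndarray          # cell-type label per profile
    mode: str                         # balanced_mean | max_std | custom
    source_batch: str | None = None   # set iff mode in {max_std, custom}
    max_per_type: int = 1000
    # balanced mode only: for each profile, the member cell indices of its tuple
    tuple_members: list[tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        self.anchor_profiles = np.asarray(self.anchor_profiles, dtype=float)
        self.anchor_types = np.asarray(self.anchor_types, dtype=object)
        if len(self.anchor_types) != self.anchor_profiles.shape[0]:
            raise ValueError("one type label per anchor profile required")
        if self.anchor_profiles.size and self.anchor_profiles.min() < 0:
            raise ValueError("anchor profiles must be non-negative")
        types, counts = np.unique(self.anchor_types.astype(str), return_counts=True)
        if counts.size and counts.max() > self.max_per_type:
            raise ValueError("per-type anchor profile count exceeds max_per_type")

    def profiles_of_type(self, t) -> np.ndarray:
        return np.flatnonzero(self.anchor_types == t)


@dataclass
class TrainingMapping:
    """Source-cell -> anchor-profile training pairs and the passthrough mask.

    ``stochastic`` marks mappings drawn uniformly at random (no graph); the
    training loop may resample such pairs each epoch.  ``unmapped_mask`` marks
    cells of shared types that the anchor does not cover (opt-in policy): they
    are excluded from training but still corrected through the network.
    """

    pairs: list[tuple[int, int]]
    passthrough_mask: np.ndarray
    stochastic: bool = True
    unmapped_mask: np.ndarray | None = None

    def target_index(self, n_cells: int) -> np.ndarray:
        """Anchor profile index per cell (-1 for passthrough/unmapped cells)."""
        idx = np.full(n_cells, -1, dtype=int)
        for c, a in self.pairs:
            idx[c] = a
        return idx


def _shared_and_single_types(m: AnnotatedMatrix) -> tuple[list, list]:
    presence: dict = {}
    for b, t in zip(m.batch, m.cell_type):
        presence.setdefault(t, set()).add(b)
    shared = [t for t, bs in presence.items() if len(bs) >= 2]
    single = [t for t, bs in presence.items() if len(bs) == 1]
    return shared, single


def _downsample_per_type(
    idx_by_type: dict, max_per_type: int, rng: np.random.Generator
) -> np.ndarray:
    keep: list[int] = []
    for t in sorted(idx_by_type, key=str):
        idx = np.asarray(idx_by_type[t])
        if len(idx) > max_per_type:
            idx = rng.choice(idx, size=max_per_type, replace=False)
            idx.sort()
        keep.extend(int(i) for i in idx)
    return np.asarray(sorted(keep), dtype=int)


def select_anchor_balanced(
    m: AnnotatedMatrix,
    graph: ConnectivityGraph | None = None,
    max_per_type: int = 1000,
    seed: int = 0,
) -> AnchorSet:
    """Construct an intermediate anchor batch of per-type cross-batch tuple means."""
    if m.layer_tag != "lognormalized":
        raise ValueError("anchor construction expects log-normalized values")
    shared, _ = _shared_and_single_types(m)
    if not shared:
        raise ValueError("no cell type is shared across batches: nothing to integrate")
    rng = np.random.default_rng(seed)
    neigh = graph.neighbors() if graph is not None else {}
    batches = m.batches()
    profiles: list[np.ndarray] = []
    types: list = []
    members: list[tuple[int, ...]] = []
    for t in sorted(shared, key=str):
        per_batch = {
            b: np.flatnonzero((m.batch == b) & (m.cell_type == t))
            for b in batches
            if np.any((m.batch == b) & (m.cell_type == t))
        }
        n_tuples = min(max_per_type, max(len(v) for v in per_batch.values()))
        # prefer graph-connected cells as tuple seeds so connected tuples are
        # used whenever the graph offers them
        all_t = np.concatenate(list(per_batch.values()))
        linked_seeds = np.asarray(
            [c for c in all_t if any(j in set(all_t) for j in neigh.get(int(c), []))],
            dtype=int,
        )
        for _ in range(n_tuples):
            if len(linked_seeds):
                seed_cell = int(rng.choice(linked_seeds))
                first_b = m.batch[seed_cell]
            else:
                first_b = rng.choice(sorted(per_batch, key=str))
                seed_cell = int(rng.choice(per_batch[first_b]))
            tup = [seed_cell]
            for b in per_batch:
                if b == first_b:
                    continue
                cand = per_batch[b]
                linked = [j for j in neigh.get(seed_cell, []) if j in set(cand)]
                tup.append(int(rng.choice(linked)) if linked else int(rng.choice(cand)))
            profiles.append(np.mean(m.values[tup], axis=0))
            types.append(t)
            members.append(tuple(sorted(tup)))
    return AnchorSet(
        anchor_profiles=np.asarray(profiles),
        anchor_types=np.asarray(types, dtype=object),
        mode="balanced_mean",
        source_batch=None,
        max_per_type=max_per_type,
        tuple_members=members,
    )


def _anchor_from_batch(
    m: AnnotatedMatrix, batch_id, mode: str, max_per_type: int, seed: int
) -> AnchorSet:
    rng = np.random.default_rng(seed)
    in_batch = np.flatnonzero(m.batch == batch_id)
    idx_by_type: dict = {}
    for i in in_batch:
        idx_by_type.setdefault(m.cell_type[i], []).append(int(i))
    keep = _downsample_per_type(idx_by_type, max_per_type, rng)
    return AnchorSet(
        anchor_profiles=m.values[keep],
        anchor_types=m.cell_type[keep],
        mode=mode,
        source_batch=str(batch_id),
        max_per_type=max_per_type,
    )


def pooled_std_per_batch(m: AnnotatedMatrix) -> dict:
    """Standard deviation of all values pooled over each batch's cells and genes."""
    return {b: float(np.std(m.values[m.batch == b])) for b in m.batches()}


def select_anchor_max_std(
    m: AnnotatedMatrix, max_per_type: int = 1000, seed: int = 0
) -> AnchorSet:
    """Pick the batch with the largest pooled standard deviation as the anchor."""
    if m.layer_tag != "lognormalized":
        raise ValueError("anchor construction expects log-normalized values")
    if len(m.batches()) < 2:
        raise ValueError("need at least two batches")
    stds = pooled_std_per_batch(m)
    best = max(stds.values())
    tied = [b for b, s in stds.items() if s == best]
    if len(tied) > 1:
        warnings.warn(f"pooled-std tie between batches {tied}; breaking by type count then id")
        n_types = {b: len(set(m.cell_type[m.batch == b])) for b in tied}
        most = max(n_types.values())
        tied = sorted([b for b in tied if n_types[b] == most], key=str)
    return _anchor_from_batch(m, tied[0], "max_std", max_per_type, seed)


def select_anchor_custom(
    m: AnnotatedMatrix, batch_id, max_per_type: int = 1000, seed: int = 0
) -> AnchorSet:
    """Use a caller-chosen batch as the anchor."""
    if batch_id not in set(m.batch):
        raise ValueError(f"unknown batch {batch_id!r}; available: {sorted(map(str, set(m.batch)))}")
    return _anchor_from_batch(m, batch_id, "custom", max_per_type, seed)


def build_training_mapping(
    m: AnnotatedMatrix,
    a: AnchorSet,
    graph: ConnectivityGraph | None = None,
    seed: int = 0,
    missing_anchor: str = "error",
) -> TrainingMapping:
    """Pair each correctable cell with one same-type anchor profile.

    A cell whose type occurs in only one batch is passthrough.  A cell whose
    type is shared but absent from the anchor set (possible in custom/max-std
    modes) is an internal inconsistency by default; ``missing_anchor="exclude"``
    instead leaves such cells out of the training pairs while still sending
    them through the network at correction time.
    """
    if a.anchor_profiles.shape[1] != m.n_genes:
        raise ValueError("anchor gene space does not match the matrix")
    if missing_anchor not in ("error", "exclude"):
        raise ValueError("missing_anchor must be 'error' or 'exclude'")
    shared, _ = _shared_and_single_types(m)
    shared = set(shared)
    rng = np.random.default_rng(seed)
    passthrough = np.asarray([t not in shared for t in m.cell_type], dtype=bool)
    anchor_types = set(a.anchor_types)
    neigh = graph.neighbors() if graph is not None else {}
    member_lookup: dict[int, list[int]] = {}
    if a.tuple_members is not None:
        for p_idx, tup in enumerate(a.tuple_members):
            for c in tup:
                member_lookup.setdefault(c, []).append(p_idx)
    pairs: list[tuple[int, int]] = []
    unmapped = np.zeros(m.n_cells, dtype=bool)
    for i in range(m.n_cells):
        if passthrough[i]:
            continue
        t = m.cell_type[i]
        if t not in anchor_types:
            if missing_anchor == "error":
                raise ValueError(
                    f"cell type {t!r} is shared across batches but absent from the "
                    "anchor set: inconsistent anchor/mapping state"
                )
            unmapped[i] = True
            continue
        cand = a.profiles_of_type(t)
        linked: list[int] = []
        if member_lookup:
            own = set(member_lookup.get(i, []))
            for j in neigh.get(i, []):
                own.update(member_lookup.get(j, []))
            linked = sorted(own)
        if linked:
            choice = int(rng.choice(linked))
        else:
            choice = int(rng.choice(cand))
        pairs.append((i, choice))
    return TrainingMapping(
        pairs=pairs,
        passthrough_mask=passthrough,
        stochastic=graph is None,
        unmapped_mask=unmapped if unmapped.any() else None,
    )


def resample_mapping(
    m: AnnotatedMatrix, a: AnchorSet, mapping: TrainingMapping, rng: np.random.Generator
) -> np.ndarray:
    """Redraw a uniform same-type anchor target per mapped cell (random mode)."""
    idx = mapping.target_index(m.n_cells)
    by_type = {t: a.profiles_of_type(t) for t in set(a.anchor_types)}
    for c, _ in mapping.pairs:
        cand = by_type[m.cell_type[c]]
        idx[c] = int(cand[rng.integers(len(cand))])
    return idx
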