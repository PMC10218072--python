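"""Two-stage greedy marker selection plus baseline selectors.

Stage 1 grows a decision tree over the panel: at every round the remaining
loci are scored (PIC on the root, PICsum once the panel is split), one locus
is drawn at random from the top fraction of the score ranking, and every
current leaf is subdivided by that locus's genotype classes.  The loop stops
when each leaf holds a single variety, or when no locus can split any
remaining leaf (genotypically identical varieties).

Stage 2 prunes the screened set: members are visited in a seeded random
order and removed whenever the rest still distinguishes every pair of
varieties the full matrix distinguishes.  One complete pass reaches an
irreducible ("simplified") set because removals only ever shrink what the
set can separate.

Baselines: ``hps_select`` draws loci uniformly from the high-PIC pool
(PIC > 0.45 by default) and ``rs_select`` draws uniformly from all loci.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype import GenotypeMatrix
from .polymorphism import Partition, picsum_scores


class NoInformativeLocusError(RuntimeError):
    """All candidate loci score zero: no remaining leaf can be split."""


class InsufficientLociError(RuntimeError):
    """Too few informative loci to complete the requested marker sets."""

    def __init__(self, message: str, completed: list["MarkerSet"]):
        super().__init__(message)
        self.completed = completed


@dataclass
class MarkerSet:
    """An ordered list of locus ids forming one simplified SNP set."""

    locus_ids: list[str]
    seed: int | None = None
    stage1_size: int | None = None
    set_index: int = 0

    def __post_init__(self) -> None:
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("marker set locus_ids must be unique")
        if self.stage1_size is None:
            self.stage1_size = len(self.locus_ids)
        if self.stage1_size < len(self.locus_ids):
            raise ValueError("stage1_size cannot be smaller than the pruned set")

    def __len__(self) -> int:
        return len(self.locus_ids)

    def __iter__(self):
        return iter(self.locus_ids)


@dataclass
class SelectionConfig:
    """Tunables for the two-stage selection.

    ``top_fraction`` is the slice of the score ranking eligible for the random
    draw each round (0.10 keeps the draw inside the top 10%); ``n_sets`` asks
    for several simplified sets; with ``disjoint_sets`` the loci of earlier
    sets are excluded from later runs.
    """

    top_fraction: float = 0.10
    n_sets: int = 1
    seed: int = 0
    disjoint_sets: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


# ---------------------------------------------------------------------------
# Stage 1: recursive partitioning
# ---------------------------------------------------------------------------


def select_split_locus(
    matrix: GenotypeMatrix,
    partition: Partition,
    excluded: set[str],
    rng: np.random.Generator,
    top_fraction: float = 0.10,
) -> str:
    """Draw the next split locus from the top fraction of the score ranking.

    Candidates are the non-excluded loci with a positive score (PICsum under
    the current partition; plain PIC when the partition is the single root
    leaf).  Candidates are ordered by (score desc, locus_id asc), the cut is
    ``ceil(top_fraction * n_candidates)`` and every locus tying the boundary
    score is kept eligible, so the draw is well defined even under heavy ties.
    """
    scores = picsum_scores(matrix, partition)
    candidates = [
        (j, scores[j])
        for j in range(matrix.n_loci)
        if scores[j] > 0 and matrix.loci[j].locus_id not in excluded
    ]
    if not candidates:
        raise NoInformativeLocusError("all candidate loci have zero score")
    candidates.sort(key=lambda t: (-t[1], matrix.loci[t[0]].locus_id))
    cut = math.ceil(top_fraction * len(candidates))
    boundary = candidates[cut - 1][1]
    top = [j for j, s in candidates if s >= boundary]
    pick = top[int(rng.integers(len(top)))]
    return matrix.loci[pick].locus_id


def apply_split(partition: Partition, matrix: GenotypeMatrix, locus_id: str) -> Partition:
    """Subdivide every leaf by the genotype classes of one locus.

    Within a leaf, each distinct non-missing code becomes a child; samples
    with a missing call at the locus are kept together in a child of their
    own (missing is never merged into a genotype class).  Leaves where the
    locus is monomorphic pass through unchanged, so the disjoint cover is
    preserved.
    """
    j = matrix.locus_col(locus_id)
    new_groups: list[np.ndarray] = []
    for g in partition.groups:
        col = matrix.calls[g, j]
        values = np.unique(col)
        if len(values) == 1:
            new_groups.append(g)
            continue
        for v in values:
            new_groups.append(g[col == v])
    return Partition(new_groups, partition.n_samples)


def stage1_screen(
    matrix: GenotypeMatrix,
    excluded: set[str] | None,
    rng: np.random.Generator,
    config: SelectionConfig,
) -> tuple[MarkerSet, Partition, list[list[str]]]:
    """Grow the selection tree until every leaf is a singleton.

    Returns the screened marker set ``M`` (one locus per round, in selection
    order), the final partition, and the labels of any unsplittable groups --
    varieties that are genotypically identical over the available loci.
    """
    if matrix.n_samples == 0 or matrix.n_loci == 0:
        raise ValueError("cannot screen an empty matrix")
    excluded = set(excluded or ())
    partition = Partition.single(matrix.n_samples)
    chosen: list[str] = []
    while not partition.is_fully_split():
        try:
            locus_id = select_split_locus(
                matrix, partition, excluded | set(chosen), rng, config.top_fraction
            )
        except NoInformativeLocusError:
            break
        chosen.append(locus_id)
        partition = apply_split(partition, matrix, locus_id)
    unsplittable = [
        [matrix.samples[i] for i in g] for g in partition.multi_groups()
    ]
    marker_set = MarkerSet(chosen, seed=config.seed, stage1_size=len(chosen))
    return marker_set, partition, unsplittable


# ---------------------------------------------------------------------------
# Distinguishability
# ---------------------------------------------------------------------------


def _row_group_ids(calls: np.ndarray) -> np.ndarray:
    """Group id per row, identical rows sharing an id (missing is a value)."""
    if calls.shape[1] == 0:
        return np.zeros(calls.shape[0], dtype=np.intp)
    _, inverse = np.unique(calls, axis=0, return_inverse=True)
    return inverse


def distinguishes(
    matrix: GenotypeMatrix,
    locus_ids: Sequence[str],
    _full_ids: np.ndarray | None = None,
) -> tuple[bool, list[list[str]]]:
    """Do the given loci separate every pair the full matrix separates?

    Returns ``(ok, collision_groups)``: collision groups are sets of >= 2
    varieties sharing one restricted genotype vector while differing
    somewhere in the full matrix.  Varieties identical across *all* loci are
    inseparable by definition and never counted as collisions.
    """
    cols = [matrix.locus_col(l) for l in locus_ids]
    full = _full_ids if _full_ids is not None else _row_group_ids(matrix.calls)
    restricted = _row_group_ids(matrix.calls[:, cols])
    collisions: list[list[str]] = []
    ok = True
    for gid in np.unique(restricted):
        members = np.flatnonzero(restricted == gid)
        if len(members) < 2:
            continue
        if len(np.unique(full[members])) > 1:
            ok = False
            collisions.append([matrix.samples[i] for i in members])
    return ok, collisions


# ---------------------------------------------------------------------------
# Stage 2: redundancy pruning
# ---------------------------------------------------------------------------


def stage2_prune(
    matrix: GenotypeMatrix, marker_set: MarkerSet, rng: np.random.Generator
) -> MarkerSet:
    """Delete redundant members of ``M`` in a seeded random order.

    A member is deleted iff the remaining loci still distinguish every pair
    the full matrix distinguishes.  Deletion capability only shrinks, so a
    single complete pass leaves an irreducible set.
    """
    full_ids = _row_group_ids(matrix.calls)
    ids = list(marker_set.locus_ids)
    order = rng.permutation(len(ids))
    kept = set(ids)
    for idx in order:
        candidate = ids[idx]
        trial = [l for l in ids if l in kept and l != candidate]
        ok, _ = distinguishes(matrix, trial, _full_ids=full_ids)
        if ok:
            kept.discard(candidate)
    pruned = [l for l in ids if l in kept]
    return MarkerSet(
        pruned,
        seed=marker_set.seed,
        stage1_size=marker_set.stage1_size,
        set_index=marker_set.set_index,
    )


# ---------------------------------------------------------------------------
# Full method and baselines
# ---------------------------------------------------------------------------


def dtpics_select(matrix: GenotypeMatrix, config: SelectionConfig) -> list[MarkerSet]:
    """Run the full two-stage selection ``n_sets`` times.

    With ``disjoint_sets`` the loci of earlier sets are excluded from later
    runs.  Raises :class:`InsufficientLociError` (carrying the completed
    sets) when the remaining loci can no longer separate a pair of varieties
    that the full matrix separates.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_sets)
    full_ids = _row_group_ids(matrix.calls)
    excluded: set[str] = set()
    results: list[MarkerSet] = []
    for i in range(config.n_sets):
        rng = np.random.default_rng(children[i])
        screened, partition, unsplittable = stage1_screen(matrix, excluded, rng, config)
        for g in partition.multi_groups():
            if len(np.unique(full_ids[g])) > 1:
                raise InsufficientLociError(
                    f"informative loci exhausted after {len(results)} of "
                    f"{config.n_sets} sets (cannot separate "
                    f"{[matrix.samples[k] for k in g]})",
                    completed=results,
                )
        screened.set_index = i + 1
        pruned = stage2_prune(matrix, screened, rng)
        ok, collisions = distinguishes(matrix, pruned.locus_ids, _full_ids=full_ids)
        if not ok:  # pragma: no cover - guarded by stage-1 checks
            raise AssertionError(f"pruned set fails to distinguish: {collisions}")
        results.append(pruned)
        if config.disjoint_sets:
            excluded |= set(pruned.locus_ids)
    return results


def hps_select(
    matrix: GenotypeMatrix,
    n: int,
    threshold: float = 0.45,
    rng: np.random.Generator | None = None,
) -> MarkerSet:
    """High-PIC selection baseline: n loci drawn from the PIC > threshold pool."""
    rng = rng if rng is not None else np.random.default_rng()
    scores = picsum_scores(matrix, Partition.single(matrix.n_samples))
    pool = [matrix.loci[j].locus_id for j in range(matrix.n_loci) if scores[j] > threshold]
    if len(pool) < n:
        raise ValueError(
            f"only {len(pool)} loci exceed PIC {threshold}, cannot draw {n}"
        )
    idx = rng.choice(len(pool), size=n, replace=False)
    return MarkerSet([pool[int(k)] for k in idx])


def rs_select(
    matrix: GenotypeMatrix, n: int, rng: np.random.Generator | None = None
) -> MarkerSet:
    """Random-selection baseline: n loci sampled uniformly without replacement."""
    rng = rng if rng is not None else np.random.default_rng()
    if n > matrix.n_loci:
        raise ValueError(f"cannot draw {n} loci from {matrix.n_loci}")
    idx = rng.choice(matrix.n_loci, size=n, replace=False)
    return MarkerSet([matrix.loci[int(j)].locus_id for j in idx])


def min_markers_lower_bound(n_varieties: int, n_classes: int = 2) -> int:
    """Information-theoretic floor on the marker count.

    A marker with at most ``n_classes`` genotype classes can label at most
    ``n_classes ** k`` varieties with k markers, so any distinguishing set
    needs at least ``ceil(log(n) / log(n_classes))`` markers.
    """
    if n_varieties <= 1:
        return 0
    return math.ceil(math.log(n_varieties) / math.log(n_classes) - 1e-12)


# ---------------------------------------------------------------------------
# Marker-set persistence
# ---------------------------------------------------------------------------


def write_marker_sets_json(
    sets: Sequence[MarkerSet], path: str | Path, extra: dict | None = None
) -> None:
    """Serialise marker sets (with provenance) as JSON."""
    payload = {
        "sets": [
            {
                "set_index": s.set_index,
                "seed": s.seed,
                "stage1_size": s.stage1_size,
                "locus_ids": list(s.locus_ids),
            }
            for s in sets
        ],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_marker_sets_json(path: str | Path) -> list[MarkerSet]:
    payload = json.loads(Path(path).read_text())
    return [
        MarkerSet(
            list(entry["locus_ids"]),
            seed=entry.get("seed"),
            stage1_size=entry.get("stage1_size"),
            set_index=entry.get("set_index", 0),
        )
        for entry in payload["sets"]
    ]


def write_marker_sets_tsv(
    sets: Sequence[MarkerSet], matrix: GenotypeMatrix, path: str | Path
) -> None:
    """Flat TSV export: set_index, locus_id, chrom, pos."""
    lines = ["set_index\tlocus_id\tchrom\tpos"]
    for s in sets:
        for lid in s.locus_ids:
            loc = matrix.loci[matrix.locus_col(lid)]
            lines.append(f"{s.set_index}\t{loc.locus_id}\t{loc.chrom}\t{loc.pos}")
    Path(path).write_text("\n".join(lines) + "\n")
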