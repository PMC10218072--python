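"""Fingerprint database and independent variety identification.

A fingerprint database stores, for every panel variety, its genotype strings
over the union of the chosen marker sets.  An independent query (typically
genotyped on a different platform, sharing only part of the marker loci) is
identified as the database variety with the highest similarity -- percent of
identical calls over the loci shared between query and database, missing
calls excluded.  Ties are reported rather than broken silently, and a query
whose claimed label exists in the database but is not the best match is
flagged as a potential mislabel (sample confusion in the seed stock).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genotype import GenotypeMatrix, Locus
from .selector import MarkerSet


class NoSharedMarkersError(ValueError):
    """Query and database have no shared non-missing marker locus."""


@dataclass
class IdentificationResult:
    query_label: str
    best_match: str
    similarity_pct: float
    shared_markers: int
    runner_up: str | None
    runner_up_similarity_pct: float | None
    tie: bool
    mislabel_flag: bool


class FingerprintDatabase:
    """Per-variety genotype vectors over the union of chosen marker loci."""

    def __init__(
        self,
        varieties: Sequence[str],
        marker_loci: Sequence[Locus],
        vectors: Sequence[Sequence[str | None]],
    ) -> None:
        varieties = list(varieties)
        if len(set(varieties)) != len(varieties):
            raise ValueError("variety labels must be unique")
        self.varieties = varieties
        self.marker_loci = list(marker_loci)
        self.vectors = [list(v) for v in vectors]
        for label, vec in zip(self.varieties, self.vectors):
            if len(vec) != len(self.marker_loci):
                raise ValueError(
                    f"{label}: vector length {len(vec)} != {len(self.marker_loci)} marker loci"
                )
        self._locus_index = {loc.locus_id: j for j, loc in enumerate(self.marker_loci)}

    @property
    def n_markers(self) -> int:
        return len(self.marker_loci)

    def fingerprint(self, variety: str) -> list[str | None]:
        return self.vectors[self.varieties.index(variety)]

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "varieties": self.varieties,
            "loci": [
                {
                    "locus_id": loc.locus_id,
                    "chrom": loc.chrom,
                    "pos": loc.pos,
                    "alleles": list(loc.alleles),
                }
                for loc in self.marker_loci
            ],
            "vectors": self.vectors,
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FingerprintDatabase":
        payload = json.loads(Path(path).read_text())
        loci = [
            Locus(d["locus_id"], d["chrom"], int(d["pos"]), tuple(d["alleles"]))
            for d in payload["loci"]
        ]
        return cls(payload["varieties"], loci, payload["vectors"])


def build_database(matrix: GenotypeMatrix, sets: Sequence[MarkerSet]) -> FingerprintDatabase:
    """Restrict the panel to the union of the sets' loci (duplicates merged)."""
    union: list[str] = []
    seen: set[str] = set()
    for s in sets:
        for lid in s.locus_ids:
            if lid not in seen:
                seen.add(lid)
                union.append(lid)
    sub = matrix.subset_loci(union)  # KeyError names any unknown locus id
    labels = sub.labels_matrix()
    return FingerprintDatabase(
        sub.samples, sub.loci, [list(labels[i]) for i in range(sub.n_samples)]
    )


def similarity(
    vec_a: Sequence[str | None], vec_b: Sequence[str | None]
) -> float:
    """Percent of identical calls over positions non-missing in both vectors."""
    matches = 0
    shared = 0
    for a, b in zip(vec_a, vec_b):
        if a is None or b is None:
            continue
        shared += 1
        if a == b:
            matches += 1
    if shared == 0:
        raise NoSharedMarkersError("no shared non-missing positions")
    return 100.0 * matches / shared


def identify_sample(
    db: FingerprintDatabase,
    query_label: str,
    query_loci: Sequence[str],
    query_genotypes: Sequence[str | None],
) -> IdentificationResult:
    """Identify one query as the database variety with the highest similarity.

    Similarity is computed per variety over the loci shared between the query
    and the database, skipping missing calls on either side; exact rational
    comparison is used for the argmax so that ties are detected reliably.
    """
    if len(query_loci) != len(query_genotypes):
        raise ValueError("query loci and genotypes differ in length")
    positions = []  # (db column, query genotype)
    for lid, g in zip(query_loci, query_genotypes):
        j = db._locus_index.get(lid)
        if j is not None and g is not None and g != "":
            positions.append((j, g))
    if not positions:
        raise NoSharedMarkersError(
            f"query {query_label!r} shares no informative marker with the database"
        )
    shared_markers = len(positions)

    scored: list[tuple[Fraction, int, str]] = []
    for vi, variety in enumerate(db.varieties):
        vec = db.vectors[vi]
        matches = 0
        shared = 0
        for j, g in positions:
            dbg = vec[j]
            if dbg is None:
                continue
            shared += 1
            if dbg == g:
                matches += 1
        if shared == 0:
            continue
        scored.append((Fraction(matches, shared), shared, variety))
    if not scored:
        raise NoSharedMarkersError(
            f"query {query_label!r}: no variety shares a non-missing marker"
        )
    scored.sort(key=lambda t: (-t[0], t[2]))
    best_frac, _, best = scored[0]
    tie = len(scored) > 1 and scored[1][0] == best_frac
    runner_up = scored[1][2] if len(scored) > 1 else None
    runner_up_sim = float(100 * scored[1][0]) if len(scored) > 1 else None
    mislabel = query_label in db.varieties and best != query_label
    return IdentificationResult(
        query_label=query_label,
        best_match=best,
        similarity_pct=float(100 * best_frac),
        shared_markers=shared_markers,
        runner_up=runner_up,
        runner_up_similarity_pct=runner_up_sim,
        tie=tie,
        mislabel_flag=mislabel,
    )


def identify_batch(
    db: FingerprintDatabase,
    queries: GenotypeMatrix,
    truth: Mapping[str, str] | None = None,
) -> tuple[list[IdentificationResult], dict]:
    """Identify every sample of a query matrix; summarise the batch.

    The summary reports the number of queries, the number of mislabel flags,
    identification accuracy when a truth mapping is supplied (ties count as
    incorrect), and -- for queries whose labels are absent from the database
    ("different-named" candidates) -- whether they are pairwise distinct from
    one another over the shared marker loci.
    """
    results: list[IdentificationResult] = []
    labels = queries.labels_matrix()
    for i, label in enumerate(queries.samples):
        results.append(
            identify_sample(db, label, queries.locus_ids, list(labels[i]))
        )
    if not results:
        return results, {}
    summary: dict = {
        "n_queries": len(results),
        "n_flagged": sum(r.mislabel_flag for r in results),
        "mean_shared_markers": float(np.mean([r.shared_markers for r in results])),
    }
    if truth is not None:
        from .evaluation import identification_accuracy

        summary["identification_accuracy"] = identification_accuracy(results, truth)

    foreign = [i for i, s in enumerate(queries.samples) if s not in db.varieties]
    if len(foreign) >= 2:
        shared_cols = [
            j for j, lid in enumerate(queries.locus_ids) if lid in db._locus_index
        ]
        vectors = [tuple(labels[i, j] for j in shared_cols) for i in foreign]
        summary["different_named_pairwise_distinct"] = len(set(vectors)) == len(vectors)
    return results, summary


def results_to_tsv(results: Sequence[IdentificationResult], path: str | Path) -> None:
    """Write identification results as a flat TSV mirroring the result fields."""
    header = (
        "query_label\tbest_match\tsimilarity_pct\tshared_markers\t"
        "runner_up\trunner_up_similarity_pct\ttie\tmislabel_flag"
    )
    lines = [header]
    for r in results:
        ru = "" if r.runner_up is None else r.runner_up
        rus = "" if r.runner_up_similarity_pct is None else f"{r.runner_up_similarity_pct:.2f}"
        lines.append(
            f"{r.query_label}\t{r.best_match}\t{r.similarity_pct:.2f}\t"
            f"{r.shared_markers}\t{ru}\t{rus}\t{int(r.tie)}\t{int(r.mislabel_flag)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
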