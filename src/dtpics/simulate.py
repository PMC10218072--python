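"""Synthetic genotype panels with the structure the method assumes.

The generator emulates a resequenced panel of inbred selfing lines: biallelic
loci, fully homozygous calls, per-locus major-genotype frequency drawn
uniformly from a configurable range so that the panel's PIC distribution
spans low to high values instead of collapsing onto one mode.  Optional
"derivative" varieties copy a parent and mutate a tiny fraction of calls,
reproducing the near-duplicate accessions (99.99% similar) that make
real stock collections hard to fingerprint.

``generate_test_set`` builds an independent query matrix that shares only a
fraction of loci with the panel (different genotyping platforms rarely call
the same sites), optionally adds per-call genotyping errors, plants
mislabelled samples (label says X, genotypes come from Y) and "different-
named" samples that are unnamed derivatives of a panel variety.  Every
planted fact is recorded in a truth dictionary so tests can verify recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype import GenotypeMatrix, Locus

_BASES = ("A", "C", "G", "T")


@dataclass
class SynthConfig:
    """Study conditions for panel and test-set generation.

    Defaults give a 200-variety x 5000-locus inbred panel with major-genotype
    frequencies uniform on [0.05, 0.95]; derivatives are opt-in.  The test
    set shares 16% of loci with the panel by default, mirroring how little
    two independently genotyped datasets of the same species overlap.
    """

    n_varieties: int = 200
    n_loci: int = 5000
    major_freq_range: tuple[float, float] = (0.05, 0.95)
    n_derivatives: int = 0
    derivative_similarity: float = 0.9999
    test_overlap_fraction: float = 0.16
    n_test_same: int = 68
    n_test_different: int = 12
    n_mislabels: int = 0
    test_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_varieties < 2:
            raise ValueError("need at least 2 varieties")
        if not (0 < self.derivative_similarity <= 1):
            raise ValueError("derivative_similarity must lie in (0, 1]")
        for name in ("test_overlap_fraction",):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 <= self.test_error_rate < 1):
            raise ValueError("test_error_rate must lie in [0, 1)")
        if self.n_derivatives >= self.n_varieties:
            raise ValueError("n_derivatives must leave at least one founder variety")


def _variety_names(n: int) -> list[str]:
    return [f"V{i + 1:04d}" for i in range(n)]


def generate_panel(config: SynthConfig) -> tuple[GenotypeMatrix, dict]:
    """Generate an inbred biallelic panel plus truth metadata.

    Founder varieties draw each locus independently from the locus's genotype
    frequency; derivatives copy a founder and mutate
    ``max(1, round((1 - derivative_similarity) * n_loci))`` calls.  All
    varieties are guaranteed pairwise distinct (duplicate rows are redrawn).
    """
    if config.n_varieties > 2 ** min(config.n_loci, 62):
        raise ValueError(
            f"{config.n_varieties} distinct varieties impossible with "
            f"{config.n_loci} biallelic loci"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, m = config.n_varieties, config.n_loci
    n_founders = n - config.n_derivatives

    lo, hi = config.major_freq_range
    major_freq = rng.uniform(lo, hi, size=m)

    loci: list[Locus] = []
    code_labels: list[dict[int, str]] = []
    for j in range(m):
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        a, b = _BASES[int(ref)], _BASES[int(alt)]
        loci.append(Locus(f"snp{j + 1:05d}", str(j % 5 + 1), j // 5 * 100 + 1, (a, b)))
        code_labels.append({0: f"{a}/{a}", 1: f"{b}/{b}"})

    calls = (rng.random((n_founders, m)) >= major_freq).astype(np.int16)

    def _dedupe(block: np.ndarray) -> None:
        # redraw duplicate founder rows until all rows are distinct
        for _ in range(100):
            _, first = np.unique(block, axis=0, return_index=True)
            dup = np.setdiff1d(np.arange(len(block)), first)
            if len(dup) == 0:
                return
            block[dup] = (rng.random((len(dup), m)) >= major_freq).astype(np.int16)
        raise RuntimeError("could not generate pairwise distinct varieties")

    _dedupe(calls)

    names = _variety_names(n_founders)
    parents: dict[str, str] = {}
    k_mut = max(1, int(round((1 - config.derivative_similarity) * m)))
    rows = [calls]
    for d in range(config.n_derivatives):
        p = int(rng.integers(n_founders))
        row = calls[p].copy()
        for _ in range(100):
            trial = row.copy()
            cols = rng.choice(m, size=k_mut, replace=False)
            trial[cols] = 1 - trial[cols]
            stacked = np.vstack(rows + [trial[None, :]])
            if len(np.unique(stacked, axis=0)) == len(stacked):
                break
        else:
            raise RuntimeError("could not place a distinct derivative")
        rows.append(trial[None, :])
        name = f"{names[p]}-der{d + 1}"
        names.append(name)
        parents[name] = names[p]

    all_calls = np.vstack(rows)
    matrix = GenotypeMatrix(names, loci, all_calls, code_labels)
    truth = {
        "seed": config.seed,
        "founders": names[: n_founders],
        "derivative_parents": parents,
        "major_freq": major_freq.tolist(),
    }
    return matrix, truth


def generate_test_set(
    panel: GenotypeMatrix,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Build an independent test matrix from a panel, with planted truth.

    Samples ``n_test_same`` panel varieties (same labels), relabels the calls
    of ``n_mislabels`` of them with genotypes copied from a different donor
    variety, and appends ``n_test_different`` newly named derivatives of
    random panel varieties.  Only ``test_overlap_fraction`` of panel loci are
    genotyped, and each call flips with ``test_error_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(1)[0]
    )
    m = panel.n_loci
    k_overlap = int(round(config.test_overlap_fraction * m))
    if k_overlap == 0:
        raise ValueError("test_overlap_fraction yields zero shared loci")
    if config.n_test_same > panel.n_samples:
        raise ValueError("n_test_same exceeds the panel size")
    if config.n_mislabels > config.n_test_same:
        raise ValueError("cannot mislabel more samples than there are")

    overlap_cols = np.sort(rng.choice(m, size=k_overlap, replace=False))
    loci = [panel.loci[j] for j in overlap_cols]
    code_labels = [panel.code_labels[j] for j in overlap_cols]

    chosen = rng.choice(panel.n_samples, size=config.n_test_same, replace=False)
    labels: list[str] = []
    rows: list[np.ndarray] = []
    truth_map: dict[str, str] = {}
    mislabels: list[str] = []

    mislabelled_pos = set(
        int(i) for i in rng.choice(config.n_test_same, size=config.n_mislabels, replace=False)
    ) if config.n_mislabels else set()
    for t, idx in enumerate(chosen):
        label = panel.samples[int(idx)]
        source = int(idx)
        if t in mislabelled_pos:
            # label claims this variety, but the calls come from another one
            donor = int(rng.integers(panel.n_samples))
            while donor == int(idx):
                donor = int(rng.integers(panel.n_samples))
            source = donor
            mislabels.append(label)
        labels.append(label)
        rows.append(panel.calls[source, overlap_cols].copy())
        truth_map[label] = panel.samples[source]

    different: dict[str, str] = {}
    k_mut = max(1, int(round((1 - config.derivative_similarity) * k_overlap)))
    for d in range(config.n_test_different):
        p = int(rng.integers(panel.n_samples))
        row = panel.calls[p, overlap_cols].copy()
        cols = rng.choice(k_overlap, size=k_mut, replace=False)
        row[cols] = 1 - row[cols]
        label = f"NEW{d + 1:03d}"
        labels.append(label)
        rows.append(row)
        truth_map[label] = panel.samples[p]
        different[label] = panel.samples[p]

    calls = np.vstack([r[None, :] for r in rows]).astype(np.int16)
    if config.test_error_rate > 0:
        flips = rng.random(calls.shape) < config.test_error_rate
        calls[flips] = 1 - calls[flips]

    test = GenotypeMatrix(labels, loci, calls, code_labels)
    truth = {
        "truth": truth_map,
        "mislabels": mislabels,
        "different_named": different,
        "overlap_loci": [loc.locus_id for loc in loci],
    }
    return test, truth
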