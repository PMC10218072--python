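"""Accuracy metrics and fault-tolerance simulations for marker panels.

Distinguishing accuracy asks: over a chosen marker list, what fraction of
varieties carry a genotype vector whose unique nearest match in the reference
panel is the variety itself?  On unmodified data this reduces to the fraction
of varieties with a unique restricted fingerprint.  To probe fault tolerance,
``modify_genotypes`` perturbs a fixed share of each variety's marker calls
(emulating genotype inconsistencies between sequencing runs of the same
germplasm) and accuracy is then measured against the unmodified panel.

Three simulation protocols are provided:

* a marker-mixture experiment comparing the selected set against blends with
  high-PIC and random markers at several modification rates;
* a set-combination experiment evaluating unions of k simplified sets over
  all k-combinations;
* a gradient experiment measuring accuracy as a function of the number of
  markers drawn from the pooled selection.

All experiment functions return tidy pandas DataFrames with one row per
(condition, modification rate, repeat).
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .selector import MarkerSet, _row_group_ids


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _encode_shared(query: GenotypeMatrix, reference: GenotypeMatrix, locus_ids):
    """Integer-encode both matrices over shared loci on a common label space."""
    q_cols = [query.locus_col(l) for l in locus_ids]
    r_cols = [reference.locus_col(l) for l in locus_ids]
    q = np.full((query.n_samples, len(locus_ids)), MISSING, dtype=np.int32)
    r = np.full((reference.n_samples, len(locus_ids)), MISSING, dtype=np.int32)
    for k, (jq, jr) in enumerate(zip(q_cols, r_cols)):
        labels: dict[str, int] = {}
        for code, lab in query.code_labels[jq].items():
            labels.setdefault(lab, len(labels))
        for code, lab in reference.code_labels[jr].items():
            labels.setdefault(lab, len(labels))
        for code, lab in query.code_labels[jq].items():
            q[query.calls[:, jq] == code, k] = labels[lab]
        for code, lab in reference.code_labels[jr].items():
            r[reference.calls[:, jr] == code, k] = labels[lab]
    return q, r


def _similarity_counts(q: np.ndarray, r: np.ndarray):
    """Pairwise (matches, shared non-missing) counts between rows of q and r."""
    q3 = q[:, None, :]
    r3 = r[None, :, :]
    both = (q3 != MISSING) & (r3 != MISSING)
    matches = ((q3 == r3) & both).sum(axis=2)
    shared = both.sum(axis=2)
    return matches, shared


def distinguishing_accuracy(
    matrix: GenotypeMatrix,
    locus_ids: Sequence[str],
    reference: GenotypeMatrix | None = None,
) -> float:
    """Percent of varieties whose restricted vector uniquely identifies them.

    With ``reference=None`` a variety is distinguished iff its genotype vector
    over the loci is unique in the matrix.  With a reference panel (the
    unmodified genotypes), a variety counts as distinguished iff its unique
    best similarity match in the reference is itself.
    """
    if reference is None:
        cols = [matrix.locus_col(l) for l in locus_ids]
        ids = _row_group_ids(matrix.calls[:, cols])
        _, counts = np.unique(ids, return_counts=True)
        unique = int((counts[ids] == 1).sum())
        return 100.0 * unique / matrix.n_samples

    q, r = _encode_shared(matrix, reference, list(locus_ids))
    matches, shared = _similarity_counts(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(shared > 0, matches / np.maximum(shared, 1), -1.0)
    ref_index = {s: i for i, s in enumerate(reference.samples)}
    distinguished = 0
    for i, label in enumerate(matrix.samples):
        self_j = ref_index[label]
        row = sim[i]
        best = row.max()
        if row[self_j] == best and (row == best).sum() == 1:
            distinguished += 1
    return 100.0 * distinguished / matrix.n_samples


def identification_accuracy(results, truth: Mapping[str, str]) -> float:
    """Percent of queries whose unique best match is their true variety.

    ``results`` is a list of :class:`~dtpics.identification.IdentificationResult`;
    a tied best match counts as incorrect.  Every query needs a truth entry.
    """
    if not results:
        raise ValueError("no identification results")
    correct = 0
    for res in results:
        if res.query_label not in truth:
            raise KeyError(f"no truth entry for query {res.query_label!r}")
        if not res.tie and res.best_match == truth[res.query_label]:
            correct += 1
    return 100.0 * correct / len(results)


# ---------------------------------------------------------------------------
# Genotype modification
# ---------------------------------------------------------------------------


def modify_genotypes(
    matrix: GenotypeMatrix,
    locus_ids: Sequence[str],
    rate: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Perturb ``round(rate * len(locus_ids))`` marker calls per variety.

    For each variety independently, that many loci (round half up) are chosen
    without replacement among the modifiable loci (those with >= 2 genotype
    classes observed panel-wide) and each chosen call is replaced by a
    different class observed at the locus, drawn uniformly.  ``rate=0``
    returns an identical copy.
    """
    if not (0 <= rate <= 1):
        raise ValueError("rate must lie in [0, 1]")
    out = matrix.copy()
    k = int(np.floor(rate * len(locus_ids) + 0.5))
    if k == 0:
        return out
    cols = [matrix.locus_col(l) for l in locus_ids]
    observed = []
    for j in cols:
        col = matrix.calls[:, j]
        observed.append(np.unique(col[col != MISSING]))
    modifiable = [m for m, codes in enumerate(observed) if len(codes) >= 2]
    if not modifiable:
        raise ValueError("no modifiable locus (all monomorphic) among the markers")
    k_eff = min(k, len(modifiable))
    for i in range(matrix.n_samples):
        picks = rng.choice(len(modifiable), size=k_eff, replace=False)
        for p in picks:
            m = modifiable[int(p)]
            j = cols[m]
            current = out.calls[i, j]
            alternatives = observed[m][observed[m] != current]
            out.calls[i, j] = alternatives[int(rng.integers(len(alternatives)))]
    return out


# ---------------------------------------------------------------------------
# Simulation experiments
# ---------------------------------------------------------------------------

_DEFAULT_RATES = (0.05, 0.10, 0.15)


def _evaluate_rates(matrix, locus_ids, rates, repeats, rng, label, rows):
    """Append raw + modified accuracy rows for one marker list."""
    sub = matrix.subset_loci(locus_ids)
    raw = distinguishing_accuracy(sub, locus_ids, reference=sub)
    for rep in range(1, repeats + 1):
        rows.append((label, 0.0, rep, raw))
        for rate in rates:
            modified = modify_genotypes(sub, locus_ids, rate, rng)
            acc = distinguishing_accuracy(modified, locus_ids, reference=sub)
            rows.append((label, float(rate), rep, acc))


def _as_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["label", "modification_rate", "repeat", "distinguishing_accuracy"]
    )


def mean_accuracy(result: pd.DataFrame) -> pd.Series:
    """Per-condition mean over all rate/repeat cells (raw included)."""
    return result.groupby("label")["distinguishing_accuracy"].mean()


def run_mixture_experiment(
    matrix: GenotypeMatrix,
    dtpics_set: MarkerSet,
    hpic_pool: Sequence[str],
    rates: Sequence[float] = _DEFAULT_RATES,
    repeats: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Compare five marker mixtures at equal total size across modification rates.

    Mixtures: all selected markers; 2/3 selected + 1/3 high-PIC; 1/3 selected
    + 2/3 high-PIC; all high-PIC; all random.  Each mixture is evaluated raw
    and at every modification rate with the given number of repeats.
    """
    rng = rng if rng is not None else np.random.default_rng()
    size = len(dtpics_set)
    hpic_pool = list(hpic_pool)
    dt_ids = list(dtpics_set.locus_ids)

    def draw(pool, n, exclude=()):
        avail = [l for l in pool if l not in exclude]
        if len(avail) < n:
            raise ValueError(f"pool of {len(avail)} loci cannot supply {n} markers")
        idx = rng.choice(len(avail), size=n, replace=False)
        return [avail[int(i)] for i in idx]

    n23 = round(2 * size / 3)
    n13 = round(size / 3)
    mixtures = {}
    mixtures["all DT"] = dt_ids
    part = draw(dt_ids, n23)
    mixtures["2/3 DT + 1/3 hPIC"] = part + draw(hpic_pool, size - n23, exclude=part)
    part = draw(dt_ids, n13)
    mixtures["1/3 DT + 2/3 hPIC"] = part + draw(hpic_pool, size - n13, exclude=part)
    mixtures["all hPIC"] = draw(hpic_pool, size)
    mixtures["all RS"] = draw(matrix.locus_ids, size)

    rows: list[tuple] = []
    for label, loci in mixtures.items():
        _evaluate_rates(matrix, loci, rates, repeats, rng, label, rows)
    return _as_frame(rows)


def run_combination_experiment(
    matrix: GenotypeMatrix,
    sets: Sequence[MarkerSet],
    k: int = 2,
    rates: Sequence[float] = _DEFAULT_RATES,
    repeats: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Evaluate the union of every size-k combination of simplified sets."""
    if k > len(sets):
        raise ValueError(f"k={k} exceeds the {len(sets)} available sets")
    rng = rng if rng is not None else np.random.default_rng()
    rows: list[tuple] = []
    for combo in combinations(sets, k):
        label = "+".join(str(s.set_index) for s in combo)
        union: list[str] = []
        seen: set[str] = set()
        for s in combo:
            for l in s.locus_ids:
                if l not in seen:
                    seen.add(l)
                    union.append(l)
        _evaluate_rates(matrix, union, rates, repeats, rng, label, rows)
    return _as_frame(rows)


def run_gradient_experiment(
    pool: Sequence[str],
    test_matrix: GenotypeMatrix,
    sizes: Sequence[int],
    repeats: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Accuracy as a function of the number of markers drawn from the pool.

    Only pool loci present in the test matrix are usable; each requested size
    is drawn ``repeats`` times and distinguishing accuracy recorded, yielding
    an accuracy-vs-panel-size curve.
    """
    rng = rng if rng is not None else np.random.default_rng()
    available = [l for l in pool if l in set(test_matrix.locus_ids)]
    rows: list[tuple] = []
    for size in sizes:
        if size > len(available):
            raise ValueError(
                f"size {size} exceeds the {len(available)} pool loci present in the test set"
            )
        for rep in range(1, repeats + 1):
            idx = rng.choice(len(available), size=size, replace=False)
            subset = [available[int(i)] for i in idx]
            acc = distinguishing_accuracy(test_matrix, subset)
            rows.append((f"{size} markers", float(size), rep, acc))
    df = _as_frame(rows)
    return df.rename(columns={"modification_rate": "n_markers"})
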