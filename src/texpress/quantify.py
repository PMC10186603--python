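"""EM assignment of multi-mapping reads to gene/TE features.

Repetitive sequence makes many reads align equally well to several
features.  The unique-read baseline simply discards those reads;
the EM assigner redistributes each ambiguous read over its candidate
features in proportion to iteratively re-estimated feature abundances
(an expectation–maximization fit of a multinomial mixture over
read–feature incidence; alignment scores play no role).

Initialization splits every read uniformly over its hits, which both
seeds the iteration and breaks ties symmetrically: symmetric inputs give
symmetric outputs with no randomness.  Total assigned mass equals the
number of reads exactly at every iteration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np


class QuantifyError(ValueError):
    """Invalid alignment input for the counting stage."""


@dataclass
class EMSettings:
    max_iter: int = 200
    tol: float = 1e-6  # max absolute per-feature count change between iterations
    prior: float = 0.0  # uniform pseudo-abundance added in the E-step

    def validate(self) -> "EMSettings":
        if self.max_iter < 1:
            raise QuantifyError("max_iter must be >= 1")
        if self.tol <= 0:
            raise QuantifyError("tol must be > 0")
        if self.prior < 0:
            raise QuantifyError("prior must be >= 0")
        return self


def _check_hits(alignments, index):
    for rec in alignments:
        for h in rec.hits:
            if h not in index:
                raise QuantifyError(
                    f"read {rec.read_id!r} hits unknown feature {h!r}"
                )


def count_unique(alignments, feature_ids) -> np.ndarray:
    """Integer counts from single-hit reads only; multi-mappers are dropped."""
    index = {f: i for i, f in enumerate(feature_ids)}
    _check_hits(alignments, index)
    counts = np.zeros(len(feature_ids), dtype=float)
    for rec in alignments:
        if len(rec.hits) == 1:
            (h,) = rec.hits
            counts[index[h]] += 1
    return counts


def _equivalence_classes(alignments, index):
    """Collapse reads into (hit-index tuple, multiplicity) classes."""
    classes = Counter()
    for rec in alignments:
        key = tuple(sorted(index[h] for h in rec.hits))
        classes[key] += 1
    return [(np.array(k, dtype=int), c) for k, c in sorted(classes.items())]


def em_assign(alignments, feature_ids, settings: EMSettings | None = None,
              return_history: bool = False):
    """Fractional feature counts from all reads via EM.

    E-step: each read is distributed over its hits proportional to current
    abundances plus ``settings.prior``; M-step: abundances become the summed
    read weights.  Iterates until no feature count moves by more than
    ``settings.tol`` or ``max_iter`` is reached.  Returns the abundance
    vector aligned with ``feature_ids`` (and the per-iteration history when
    ``return_history``).
    """
    settings = (settings or EMSettings()).validate()
    alignments = list(alignments)
    index = {f: i for i, f in enumerate(feature_ids)}
    _check_hits(alignments, index)
    n_features = len(feature_ids)
    classes = _equivalence_classes(alignments, index)

    # Uniform-split initialization: deterministic and symmetric, and it
    # guarantees positive mass wherever any read could land, so an
    # all-ambiguous input with zero prior is never degenerate.
    a = np.zeros(n_features, dtype=float)
    for idx, count in classes:
        a[idx] += count / len(idx)
    history = [a.copy()]

    prior = settings.prior
    for _ in range(settings.max_iter):
        new = np.zeros(n_features, dtype=float)
        for idx, count in classes:
            w = a[idx] + prior
            s = w.sum()
            if s <= 0.0:
                w = np.full(len(idx), 1.0 / len(idx))
            else:
                w = w / s
            new[idx] += count * w
        delta = np.abs(new - a).max() if n_features else 0.0
        a = new
        if return_history:
            history.append(a.copy())
        if delta < settings.tol:
            break
    return (a, history) if return_history else a


def em_log_likelihood(alignments, abundances, feature_ids) -> float:
    """Multinomial-mixture log-likelihood of reads given feature abundances.

    Abundances are normalized to mixture proportions; each read contributes
    ``log(sum of proportions over its hits)``.  Non-decreasing across EM
    iterations.
    """
    index = {f: i for i, f in enumerate(feature_ids)}
    _check_hits(alignments, index)
    a = np.asarray(abundances, dtype=float)
    total = a.sum()
    if total <= 0:
        return float("-inf") if alignments else 0.0
    p = a / total
    ll = 0.0
    for rec in alignments:
        mass = sum(p[index[h]] for h in rec.hits)
        ll += np.log(mass) if mass > 0 else float("-inf")
    return float(ll)
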