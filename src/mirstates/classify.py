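"""Discretization of per-probe expression into low / medium / high states.

Each probe is treated independently. Its log-normalized values are
exponentiated, and the algorithm searches for two "neighborhoods" of
similarly expressed values — one around a low representative ``a`` and one
around a high representative ``b`` — that jointly describe the data well.
Similarity is measured by the absolute fold change afc(x, y) = max(x,y) /
min(x,y): values within fold ``n`` of a representative belong to its
neighborhood, and the two representatives must differ by more than fold
``f`` for the split to count at all.

A candidate pair (a, b) with neighborhoods A and B over the m sample values
is scored by

    score = (|A ∪ B| / m) · (|A ∪ B| / (afc(a, mean A) · afc(b, mean B)))
            · (4·|A|·|B| / (|A| + |B|)²)

i.e. a quadratic data-coverage term, representative-centrality penalties
folded into one of the two coverage factors, and a size-distribution term
that favors balanced neighborhoods; the final score is 0 whenever
afc(a, b) ≤ f. The maximal final score over all ordered pairs of distinct
observed values and over a predefined list of (f, n) threshold pairs defines
the boundaries b1 = max(A), b2 = min(B) (switched if they overlap) and the
per-sample states: v ≤ b1 → L, v ≥ b2 → H, otherwise M. Because every term
depends only on fold changes and set sizes, the states are invariant under
adding a constant to the log values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import AnalysisConfig, ExpressionMatrix

PROBE_STATES = ("L", "M", "H")


def absolute_fold_change(a: float, b: float) -> float:
    """afc(a, b) = max(a, b) / min(a, b); symmetric, >= 1, 1 iff a == b."""
    if a <= 0 or b <= 0:
        raise ValueError(f"absolute fold change needs positive operands, got {a}, {b}")
    return a / b if a >= b else b / a


def exponentiate(values: np.ndarray) -> np.ndarray:
    """Map log-scale values to the strictly positive scale the afc needs."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("exponentiate requires finite inputs")
    return np.exp(values)


def neighborhood(a: float, values: np.ndarray, n: float) -> np.ndarray:
    """Boolean mask over ``values`` of the neighborhood of representative ``a``.

    x belongs to the neighborhood of a iff afc(x, a) <= n. ``a`` must be one
    of the observed values, so the neighborhood always contains it.
    """
    values = np.asarray(values, dtype=float)
    if not np.any(values == a):
        raise ValueError(f"representative {a} is not an observed value")
    hi = np.maximum(values, a)
    lo = np.minimum(values, a)
    return hi / lo <= n  # afc(x, a) <= n


def _pair_score(cov: int, m: int, pen_a: float, pen_b: float, na: int, nb: int) -> float:
    balance = 4 * na * nb / (na + nb) ** 2
    return (cov / m) * (cov / (pen_a * pen_b)) * balance


def score_pair(
    a: float,
    b: float,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    values: np.ndarray,
    pair: tuple[float, float],
) -> float:
    """Final score of representatives (a, b) with neighborhoods A, B over V.

    Returns 0 when the representatives are not separated by more than the
    fold threshold f of ``pair``.
    """
    f, _n = pair
    na = int(mask_a.sum())
    nb = int(mask_b.sum())
    if na == 0 or nb == 0:
        raise ValueError("score_pair requires nonempty neighborhoods")
    if absolute_fold_change(a, b) <= f:
        return 0.0
    m = len(values)
    cov = int(np.count_nonzero(mask_a | mask_b))
    pen_a = absolute_fold_change(a, float(values[mask_a].sum()) / na)
    pen_b = absolute_fold_change(b, float(values[mask_b].sum()) / nb)
    return _pair_score(cov, m, pen_a, pen_b, na, nb)


def compute_boundaries(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Boundaries from the two neighborhoods: upper limit of the lower set and
    lower limit of the upper set, switched if the sets overlap."""
    b1 = float(np.max(values_a))
    b2 = float(np.min(values_b))
    if b1 > b2:
        b1, b2 = b2, b1
    return b1, b2


def assign_states(values: np.ndarray, b1: float, b2: float) -> np.ndarray:
    """v <= b1 -> L, v >= b2 -> H, otherwise M; L wins when b1 == b2."""
    states = np.full(len(values), "M", dtype="<U1")
    states[values >= b2] = "H"
    states[values <= b1] = "L"  # applied last: L takes precedence on b1 == b2
    return states


@dataclass
class ProbeClassification:
    """Per-probe discretization result."""

    probe_id: str
    states: np.ndarray  # per-sample 'L'/'M'/'H'
    best_score: float
    chosen_pair: tuple[float, float] | None
    rep_low: float | None = None  # exponentiated scale
    rep_high: float | None = None
    boundary_low: float | None = None
    boundary_high: float | None = None
    neighborhood_low: np.ndarray | None = None  # boolean masks over samples
    neighborhood_high: np.ndarray | None = None


def classify_probe(
    values: np.ndarray,
    config: AnalysisConfig,
    probe_id: str = "",
) -> ProbeClassification:
    """Discretize one probe's log-expression vector into L/M/H states.

    Exhaustively evaluates every ordered pair of distinct observed values
    (a < b) for every configured (f, n) threshold pair and keeps the global
    maximizer. Ties are resolved by larger joint coverage |A ∪ B|, then by
    the lexicographically smallest (a, b); earlier threshold pairs win any
    remaining tie. A probe with no admissible pair (e.g. a constant vector)
    gets final score 0 and all-medium states; the probe-score filter removes
    it downstream.
    """
    values = np.asarray(values, dtype=float)
    m = len(values)
    if m < 2:
        raise ValueError("classify_probe needs at least 2 samples")
    e = exponentiate(values)
    distinct = np.unique(e)  # sorted ascending
    k = len(distinct)

    best_score = 0.0
    best_cov = -1
    best_ab: tuple[float, float] | None = None
    best = None  # (pair, mask_a, mask_b)

    for pair in config.threshold_pairs:
        f, n = pair
        # Neighborhood masks and centrality penalties per distinct value.
        masks = []
        pens = np.empty(k)
        sizes = np.empty(k, dtype=int)
        bits = []  # neighborhoods as Python-int bitmasks for fast unions
        weights = [1 << s for s in range(m)]
        for i, d in enumerate(distinct):
            mask = neighborhood(d, e, n)
            masks.append(mask)
            cnt = int(mask.sum())
            sizes[i] = cnt
            pens[i] = absolute_fold_change(float(d), float(e[mask].sum()) / cnt)
            bits.append(sum(w for w, hit in zip(weights, mask) if hit))

        for i in range(k):
            a = float(distinct[i])
            for j in range(i + 1, k):
                b = float(distinct[j])
                if b / a <= f:  # afc(a, b) <= f: separation constraint fails
                    continue
                cov = (bits[i] | bits[j]).bit_count()
                score = _pair_score(cov, m, pens[i], pens[j], int(sizes[i]), int(sizes[j]))
                if score > best_score or (
                    score == best_score
                    and (cov > best_cov or (cov == best_cov and (best_ab is None or (a, b) < best_ab)))
                ):
                    best_score = score
                    best_cov = cov
                    best_ab = (a, b)
                    best = (pair, masks[i], masks[j])

    if best is None:
        return ProbeClassification(
            probe_id=probe_id,
            states=np.full(m, "M", dtype="<U1"),
            best_score=0.0,
            chosen_pair=None,
        )

    pair, mask_a, mask_b = best
    assert best_ab is not None
    a, b = best_ab
    b1, b2 = compute_boundaries(e[mask_a], e[mask_b])
    states = assign_states(e, b1, b2)
    return ProbeClassification(
        probe_id=probe_id,
        states=states,
        best_score=best_score,
        chosen_pair=pair,
        rep_low=a,
        rep_high=b,
        boundary_low=b1,
        boundary_high=b2,
        neighborhood_low=mask_a,
        neighborhood_high=mask_b,
    )


def classify_matrix(
    matrix: ExpressionMatrix, config: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discretize every probe of an expression matrix.

    Returns ``(states, info)``: a probes x samples DataFrame over {L, M, H}
    and a per-probe sidecar with best_score, chosen thresholds and
    boundaries.
    """
    records = []
    state_rows = np.empty((len(matrix.probe_ids), len(matrix.sample_ids)), dtype="<U1")
    values = matrix.data.to_numpy()
    for r, probe in enumerate(matrix.probe_ids):
        cls = classify_probe(values[r], config, probe_id=probe)
        state_rows[r] = cls.states
        f, n = cls.chosen_pair if cls.chosen_pair is not None else (np.nan, np.nan)
        records.append(
            {
                "probe_id": probe,
                "best_score": cls.best_score,
                "fold_threshold": f,
                "neighborhood_threshold": n,
                "boundary_low": np.nan if cls.boundary_low is None else cls.boundary_low,
                "boundary_high": np.nan if cls.boundary_high is None else cls.boundary_high,
            }
        )
    states = pd.DataFrame(state_rows, index=matrix.probe_ids, columns=matrix.sample_ids)
    info = pd.DataFrame.from_records(records).set_index("probe_id")
    return states, info


def filter_probes_by_score(
    states: pd.DataFrame, info: pd.DataFrame, probe_score_factor: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep probes whose best score strictly exceeds t * n_samples.

    The attainable maximum of the score equals the number of samples, so the
    factor ``t`` expresses the cutoff as a fraction of a perfect split.
    """
    n_samples = states.shape[1]
    keep = info["best_score"] > probe_score_factor * n_samples
    keep = keep.reindex(states.index, fill_value=False)
    return states.loc[keep], info.loc[keep]
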