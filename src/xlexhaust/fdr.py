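"""Three-class target-decoy confidence estimation.

Each PSM falls into one of three classes by the origin of its two chains:
TT (both target), DD (both decoy) and TD (one of each).  A random match
involving at least one decoy chain estimates a random TT match, but TD
matches double-count the case where both chains are random (which a DD match
estimates directly), so at a score threshold s the false discovery rate among
the t(s) accepted TT matches is estimated as

    FDR(s) = (f(s) - d(s)) / t(s)

with f, d, t the numbers of TD, DD, TT PSMs scoring at or above s.  The
q-value of a PSM scoring t is the smallest FDR over all thresholds that
would accept it, q(t) = min_{s <= t} FDR(s); it is non-increasing in score.
Intra-protein and inter-protein matches form separate strata.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)


def classify_psm(psm) -> str:
    """TT / TD / DD class from the decoy flags of the two chains."""
    from .search_core import classify_pair

    return classify_pair(psm.alpha.is_decoy, psm.beta.is_decoy)


def estimate_fdr(psms, topology_filter: str | None = None) -> dict[float, float]:
    """FDR estimate at each observed score in one topology stratum.

    Counts use "score >= s" (higher scores are better). The estimate is
    clamped into [0, 1]; a threshold accepting no TT PSM gets FDR 1.
    """
    stratum = [
        m for m in psms
        if topology_filter is None or m.topology == topology_filter
    ]
    if not stratum:
        logger.warning("empty PSM stratum (topology=%s)", topology_filter)
        return {}
    scores = np.array([m.score for m in stratum])
    order = np.argsort(-scores, kind="stable")
    is_t = np.array([stratum[i].psm_class == "TT" for i in order])
    is_d = np.array([stratum[i].psm_class == "DD" for i in order])
    is_f = np.array([stratum[i].psm_class == "TD" for i in order])
    sorted_scores = scores[order]
    t_cum = np.cumsum(is_t)
    d_cum = np.cumsum(is_d)
    f_cum = np.cumsum(is_f)

    fdr_map: dict[float, float] = {}
    n = len(stratum)
    for i in range(n):
        # last position with this score (descending order) holds the ">= s" counts
        if i + 1 < n and sorted_scores[i + 1] == sorted_scores[i]:
            continue
        s = float(sorted_scores[i])
        t, d, f = int(t_cum[i]), int(d_cum[i]), int(f_cum[i])
        if t == 0:
            fdr_map[s] = 1.0
        else:
            fdr_map[s] = min(1.0, max(0.0, (f - d) / t))
    return fdr_map


def fdr_to_qvalue(fdr_map: dict[float, float]) -> dict[float, float]:
    """q(t) = min of FDR(s) over observed thresholds s <= t."""
    if not fdr_map:
        raise ValueError("empty FDR map")
    q_map: dict[float, float] = {}
    running = np.inf
    for s in sorted(fdr_map):  # ascending scores: running min over s <= t
        running = min(running, fdr_map[s])
        q_map[s] = running
    return q_map


def assign_confidence(psms) -> None:
    """Attach FDR and q-value to every PSM, stratified by topology, in place."""
    for topology in ("intra", "inter"):
        stratum = [m for m in psms if m.topology == topology]
        if not stratum:
            continue
        fdr_map = estimate_fdr(stratum)
        if not fdr_map:
            continue
        q_map = fdr_to_qvalue(fdr_map)
        for m in stratum:
            m.fdr = fdr_map[m.score]
            m.q_value = q_map[m.score]


def filter_results(psms, q_threshold: float):
    """Accepted target-target PSMs and their non-redundant peptide pairs.

    Both topology strata are filtered independently at the same threshold.
    Returns ``(accepted_psms, nonredundant_pairs)`` where the second element
    is the sorted list of unique unordered (sequence, site) pairs.
    """
    accepted = [
        m for m in psms
        if m.psm_class == "TT" and not np.isnan(m.q_value)
        and m.q_value <= q_threshold
    ]
    pairs = sorted({m.pair_key() for m in accepted})
    return accepted, pairs
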